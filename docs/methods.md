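# Methods

## The statistical model of repeatability

The package treats each independently evolved line as one draw from a
categorical distribution over adaptive *routes*, where a route is the set of
DNA mutations producing one protein product (grouping is by translated
effect, so e.g. two different 12-nt deletions inside an amino-acid repeat
that compress it identically count as one route). The null hypothesis of
interest is **equal-weight appearance and fixation**: each of the `r` routes
in the pool is equally likely per line. Observed spectra are scored against
this null with three tail statistics, estimated by Monte-Carlo resampling
(`numpy` multinomial draws) and computed exactly in rational arithmetic:

- `focal_at_least(k, n, r)` — the a-priori focal route appears ≥ k times in
  n lines. Exact tail: P(X ≥ k) with X ~ Bin(n, 1/r).
- `max_at_least(k, n, r)` — *some* route appears ≥ k times. Exact tail by
  inclusion–exclusion over route subsets; the joint probability that m
  named routes all reach k is extracted from a truncated exponential
  generating function ((Σ_{c≥k} x^c/c!)^m · (Σ_c x^c/c!)^{r−m}), all in
  `fractions.Fraction`. When 2k > n the events are disjoint and the result
  reduces to r · P(X ≥ k), which is how the 8-of-15 value 0.26469… arises.
- `focal_at_most(k, n, r)` — the focal route appears ≤ k times (k = 0 gives
  ((r−1)/r)^n).

Monte-Carlo estimates with zero hits are reported as the strict bound
`P < 1/iterations`, never as zero: at 10⁶ iterations a true tail of
1.7 × 10⁻¹⁰ (the 23-of-24 case) is essentially never hit, and the bound is
the honest summary. The default iteration count is 10⁶.

Because the pool is restricted to the routes actually observed, the focal
tails are conservative: `analytic_tail` is strictly decreasing in `r` for
k ≥ 1, so any unobserved route at any weight would only strengthen a
rejection.

**Which statistic the pipeline driver uses.** `run_repeatability_report`
applies `focal_at_least` only when a focal route is named in the
configuration (named a priori); otherwise it summarises the most frequent
route but tests with `max_at_least`. Testing the post-hoc maximum as if it
had been named in advance would inflate significance; with `max_at_least`
the flagging rule at α = 0.05 is calibrated (type-I ≤ α), which the test
suite checks by simulating diffuse-spectrum line sets. The route-pool size
defaults to the routes observed in the condition and can be widened
(`n_routes`) to a pool established across conditions, which is how the
23-of-24 headline is evaluated against r = 3.

## Classical tests

Pearson χ² (independence, df = (r−1)(c−1)), Wilcoxon rank-sum,
Kruskal–Wallis and Dunn's post-hoc comparisons are implemented directly on
midranks with tie corrections; `scipy` supplies only the χ²/normal
distribution functions and serves as an independent cross-check in the test
suite. Conventions:

- Wilcoxon's W is the rank sum of the first sample (its Mann–Whitney U is
  also returned). For tie-free samples with both n ≤ 25 the exact null
  distribution of W is used (dynamic program over rank subsets); otherwise
  a normal approximation with tie-corrected variance and an optional 0.5
  continuity correction toward the null. The exact path reproduces full
  permutation enumeration; the asymptotic path tracks it to ~0.01 at
  n = 8 + 8.
- Kruskal–Wallis H uses the tie-correction divisor 1 − Σ(t³−t)/(N³−N) and a
  χ²(groups−1) reference; at very small samples (n ≈ 8 per group) the χ²
  approximation deviates from the permutation null by up to a few
  hundredths, which is inherent to the approximation, not the
  implementation.
- Dunn's Z uses pooled-midrank means with the tie-corrected variance
  N(N+1)/12 − Σ(t³−t)/(12(N−1)); p-values are unadjusted by default with
  optional Bonferroni.

## Sequence operations

Translation uses the bacterial/archaeal genetic code (NCBI table 11)
via Biopython. Coordinates are 1-based and inclusive on the coding strand,
frame anchored at position 1 (nucleotide 289 is codon 97).

**Synonymous substitution sets** are certified at application time: a set
marked synonymous that changes the translation raises an error. Swap design
(`design_synonymous_swap`) walks every differing site within ± flank
codons (default 5) of the focal site and includes the edit iff replacing
that single base inside the first sequence's codon preserves the residue;
refused positions are reported, never silently edited.

**Divergence partitioning** classifies each differing nucleotide site with
the same codon-local rule (default): the site is synonymous iff swapping
that base alone, in the first sequence's codon context, is silent. A
whole-codon rule (all diffs in a codon inherit the codon-pair comparison)
is selectable; the two differ only on codons with multiple compensating
changes. Percentages are computed from integer site tallies and rounded to
two decimals only on report, so identity + synonymous + non-synonymous
= 100 in the gap-free case. Sequences must be equal-length and
codon-aligned; the 363-codon scale used throughout the tests (1,089 nt,
91 silent + 30 non-silent planted differences → 8.36% / 2.75% / 88.89%)
mirrors the scale of a typical sensor-kinase gene comparison between
*P. fluorescens* strains. A GenBank flat-file reader can pull a named
gene's CDS for accession-based comparisons when such files are available.

## Hairpin (inverted-repeat) scanning

The scanner enumerates arm pairs within a window (default half-width 50 nt)
around the focal site: equal-length arms of 4–12 nt whose reverse
complements match with ≤ 1 mismatch (defaults; all configurable), separated
by a loop of 3–12 nt. Three nucleotides is the steric minimum for a
single-stranded loop, and arms shorter than 3 are ubiquitous noise, so the
parameter class enforces those floors. Only *maximal* stems are reported —
candidates extendable one step outward or inward into another valid
candidate are suppressed — sorted by score (arm length − mismatches), then
smaller loop, then leftmost arm. Scoring is purely complementarity-based;
no thermodynamic folding is attempted, because the scientific argument is
about the presence and composition of complementary tracts, not folding
energies. G·T wobble pairing is off by default (double-helix DNA pairing
rules) and can be enabled. The scanner is verified against exhaustive
substring-pair enumeration on short windows, and is strand-symmetric and
deterministic. The supplementary-style stem parameters used in the original
analyses are not printed anywhere, so every output records the parameters
it was produced with.

A site is *paired* if it lies inside an arm of any reported stem, and
unpaired otherwise; hairpin-associated mutability concerns focal sites
left unpaired (in loops or outside stems) while their neighbours pair.
`compare_variants` diffs the stem sets of two equal-length variants
(matched by arm coordinates) into broken / gained / shared, tracking the
focal pairing status — the relevant readout when a handful of silent edits
perturbs local secondary structure.

## Phenotype metrics

Migration zones are measured as two perpendicular diameters. The default
reading converts their mean to a radius (r = (d₁+d₂)/4) and reports
A = πr² with its square root; an alternative (mean of the two per-axis
circle areas) is selectable by flag since either reading of an "averaged
total surface area" is defensible. Standardisation subtracts the
per-environment mean of the reference genotype on the root-area scale
(default; raw scale by flag), making the reference mean exactly 0.
Emergence-day histograms bin days 1..window (default 10) and pool
later/censored lines into a "window+1 and beyond" bin, conserving counts.

## Synthetic-data generators

Each generator is deterministic given (seed, parameters); multi-stream
generators derive child seeds through `numpy.random.SeedSequence` spawning.

- **Route outcomes**: one categorical draw per line. The hotspot regime
  default is (0.96, 0.04) over two routes — a spectrum in which the focal
  mutation appears in >95% of lines; the diffuse regime is equal weight
  over six routes. These two regimes reproduce the qualitative contrast
  between a hotspot-bearing and a hotspot-free genetic background.
- **Coding sequences**: ATG start, random non-stop codons, TAA stop.
- **Homolog pairs**: exactly the requested number of silent differences
  (placed at degenerate third positions, guaranteeing silence without
  search) and residue-changing differences (never creating stops), at most
  one edit per codon, start/stop codons untouched, with the ground-truth
  site classes returned. One edit per codon keeps the codon-local and
  whole-codon classification rules equivalent on generated data, so truth
  recovery is exact.
- **Planted stems**: a perfect reverse-complement arm pair written around a
  loop containing the focal site, leaving everything else untouched.
- **Phenotypes**: Gaussian diameters per group truncated at 0.

What the generators do *not* emulate: mutation-rate heterogeneity along a
genome, selection/fitness dynamics, sequencing error, alignment gaps, and
real codon-usage bias. Passing tests therefore demonstrate that the
*computational* chain — annotation, grouping, counting, resampling,
classification, scanning — is correct under known ground truth, not that
any particular biological system behaves this way.

## Numerical choices and problem sizes

- Exact tails use rational arithmetic and are capped at n ≤ 200 draws to
  bound the polynomial convolutions.
- Bootstrap defaults to 10⁶ iterations (seconds at these problem sizes);
  test-suite Monte-Carlo/oracle comparisons run at 10⁵ iterations with a
  4·SE acceptance band, and simulation-heavy calibration checks use a few
  hundred seeds — sizes chosen to keep the full suite in the tens of
  seconds while leaving binomial noise bands narrow enough to be
  informative.
- Divergence percentages are reported at 2 dp from integer tallies; note
  that 30/1089 rounds to 2.75.
- Tie-breaking in stem ranking (score, then loop length, then position) is
  total, so scanner output is reproducible ordered output.

## Known limitations

- Off-phase in-frame deletions are normalised by left-aligning the
  translated products and reporting the deleted residue run; when the
  junction codon re-encodes a different residue (a deletion–insertion in
  protein terms) the label still reports only the deleted run.
- The divergence partition requires pre-aligned equal-length CDSs; no
  internal aligner is bundled, and gapped columns are out of scope.
- The hairpin scanner makes no claim about folding kinetics or competing
  structures; it reports complementarity geometry only.
- Dunn p-values use the normal approximation regardless of sample size.
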