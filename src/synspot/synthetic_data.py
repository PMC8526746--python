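"""Synthetic-data generators with known ground truth for every pipeline stage.

Real inputs to the pipeline are mutation-outcome tables of independently
evolved bacterial lines, homologous coding sequences, and motility phenotype
measurements. Each generator here emulates one of those input classes under
controlled conditions — a hotspot-skewed or diffuse mutational spectrum,
a homolog pair with a prescribed number of silent and amino-acid-changing
differences, a coding sequence with a planted reverse-complement stem around
a focal site, or Gaussian migration measurements with planted group effects
— and returns the generating truth alongside, so every downstream stage can
be tested by parameter recovery without any external download.

All generators are bit-reproducible given (seed, parameters): one seed per
invocation, with child streams derived deterministically via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hairpin_scan import reverse_complement
from .mutation_annotation import EvolvedLine, MutationRecord
from .sequence_variants import CDSRecord, translate

# Default regimes: the hotspot regime mirrors a spectrum where the focal
# route dominates >95% of lines over one alternative; the diffuse regime
# spreads mass equally over six routes.
HOTSPOT_WEIGHTS = (0.96, 0.04)
DIFFUSE_N_ROUTES = 6

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class RouteWeights:
    """Per-route appearance probabilities for outcome simulation."""

    route_ids: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.route_ids) != len(self.weights):
            raise ValueError("route_ids and weights must align")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {sum(self.weights)}, not 1")

    @classmethod
    def hotspot(cls, route_ids: tuple[str, ...] = ("focal", "alt")) -> "RouteWeights":
        return cls(route_ids, HOTSPOT_WEIGHTS)

    @classmethod
    def diffuse(cls, n_routes: int = DIFFUSE_N_ROUTES) -> "RouteWeights":
        ids = tuple(f"route{i + 1}" for i in range(n_routes))
        return cls(ids, (1.0 / n_routes,) * n_routes)


@dataclass(frozen=True)
class SimulationConfig:
    n_lines: int
    conditions: tuple[tuple[str, str], ...] = (("sim", "M9"),)
    seed: int = 0
    regime: str = "hotspot"

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.regime not in ("hotspot", "diffuse"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class HomologTruth:
    """Ground truth for a generated homolog pair: each edited site's class."""

    syn_positions: list[int]
    nonsyn_positions: list[int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "syn_positions": self.syn_positions,
                "nonsyn_positions": self.nonsyn_positions,
            }
        )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_outcome_lines(weights: RouteWeights, config: SimulationConfig) -> pd.DataFrame:
    """Assign each simulated line one mutational route drawn from `weights`.

    Returns a tidy table with one row per line (line_id, strain,
    environment, route); identical seeds reproduce the table exactly.
    Conditions are cycled over lines in round-robin order.
    """
    rng = np.random.default_rng(config.seed)
    routes = rng.choice(weights.route_ids, size=config.n_lines, p=weights.weights)
    conds = [
        config.conditions[i % len(config.conditions)] for i in range(config.n_lines)
    ]
    return pd.DataFrame(
        {
            "line_id": [f"line{i + 1}" for i in range(config.n_lines)],
            "strain": [c[0] for c in conds],
            "environment": [c[1] for c in conds],
            "route": routes,
        }
    )


def gen_cds(n_codons: int, seed: int) -> CDSRecord:
    """A random coding sequence: ATG start, random non-stop body, TAA stop.

    ``n_codons`` counts all codons including start and stop; the translation
    therefore has no stop before the final position.
    """
    if n_codons < 2:
        raise ValueError("n_codons must be >= 2")
    rng = np.random.default_rng(seed)
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    seq = "ATG" + "".join(body) + "TAA"
    return CDSRecord(id=f"cds_{seed}_{n_codons}", seq=seq)


def plant_stem(
    cds: CDSRecord, focal: int, arm_len: int, loop_len: int
) -> CDSRecord:
    """Overwrite the region around `focal` with a perfect inverted repeat.

    Two exact reverse-complement arms of ``arm_len`` nt are written either
    side of a ``loop_len``-nt loop centred on the focal site; the loop bases
    and everything outside the arms are left untouched. ``arm_len=0``
    returns the input unchanged.
    """
    if arm_len == 0:
        return cds
    if arm_len < 0 or loop_len < 1:
        raise ValueError("arm_len must be >= 0 and loop_len >= 1")
    # loop spans loop_len bases with focal inside (as central as possible)
    loop_start = focal - (loop_len - 1) // 2
    loop_end = loop_start + loop_len - 1
    arm1_start = loop_start - arm_len
    arm2_end = loop_end + arm_len
    if arm1_start < 1 or arm2_end > len(cds):
        raise ValueError(
            f"planted region {arm1_start}..{arm2_end} outside 1..{len(cds)}"
        )
    arm1 = cds.seq[arm1_start - 1 : loop_start - 1]
    arm2 = reverse_complement(arm1)
    seq = (
        cds.seq[: loop_end]
        + arm2
        + cds.seq[arm2_end:]
    )
    return CDSRecord(id=f"{cds.id}|stem@{focal}", seq=seq, coding=cds.coding)


def gen_homolog_pair(
    cds: CDSRecord,
    syn_sites: int,
    nonsyn_sites: int,
    seed: int,
    window: tuple[int, int] | None = None,
) -> tuple[CDSRecord, CDSRecord, HomologTruth]:
    """Derive a homolog of `cds` with exact planted divergence.

    The second sequence differs from the first at exactly ``syn_sites``
    positions whose single-base change is silent (drawn at degenerate codon
    third positions) and ``nonsyn_sites`` positions whose change alters the
    residue without creating a stop. At most one edit per codon; start and
    stop codons are never touched. ``window`` restricts eligible codons to a
    1-based inclusive codon range.

    Returns (original, homolog, truth) where truth lists every edited
    1-based nucleotide position with its class.
    """
    if syn_sites < 0 or nonsyn_sites < 0:
        raise ValueError("site counts must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = window if window else (2, cds.n_codons - 1)
    lo, hi = max(2, lo), min(cds.n_codons - 1, hi)
    candidates = list(range(lo, hi + 1))
    rng.shuffle(candidates)

    bases = list(cds.seq)
    syn_pos: list[int] = []
    nonsyn_pos: list[int] = []

    for ci in candidates:
        if len(syn_pos) == syn_sites and len(nonsyn_pos) == nonsyn_sites:
            break
        codon = "".join(bases[3 * (ci - 1) : 3 * ci])
        aa = translate(codon)
        if len(syn_pos) < syn_sites:
            # silent swap at the third position, if the codon allows one
            alts = [
                b
                for b in _BASES
                if b != codon[2] and translate(codon[:2] + b) == aa
            ]
            if alts:
                alt = alts[int(rng.integers(len(alts)))]
                pos = 3 * ci
                bases[pos - 1] = alt
                syn_pos.append(pos)
                continue
        if len(nonsyn_pos) < nonsyn_sites:
            # residue-changing swap at a random codon offset, avoiding stops
            offsets = list(rng.permutation(3))
            done = False
            for off in offsets:
                alts = [
                    b
                    for b in _BASES
                    if b != codon[off]
                    and translate(codon[:off] + b + codon[off + 1 :]) not in (aa, "*")
                ]
                if alts:
                    alt = alts[int(rng.integers(len(alts)))]
                    pos = 3 * (ci - 1) + off + 1
                    bases[pos - 1] = alt
                    nonsyn_pos.append(pos)
                    done = True
                    break
            if done:
                continue

    if len(syn_pos) < syn_sites or len(nonsyn_pos) < nonsyn_sites:
        raise ValueError(
            f"infeasible request: placed {len(syn_pos)}/{syn_sites} synonymous "
            f"and {len(nonsyn_pos)}/{nonsyn_sites} non-synonymous edits in "
            f"codons {lo}..{hi}"
        )

    homolog = CDSRecord(id=f"{cds.id}|homolog", seq="".join(bases))
    return cds, homolog, HomologTruth(sorted(syn_pos), sorted(nonsyn_pos))


def gen_phenotype(
    group_means: list[float],
    sd: float,
    n_per_group: int,
    seed: int,
    environment: str = "M9",
) -> pd.DataFrame:
    """Gaussian migration diameters per group, truncated at 0.

    One row per replicate with columns (replicate_id, genotype,
    environment, diameter_lateral, diameter_longitudinal); both diameters
    are drawn independently around the group mean.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rngs = _child_rngs(seed, len(group_means))
    rows = []
    for g, (mean, rng) in enumerate(zip(group_means, rngs)):
        lat = np.clip(rng.normal(mean, sd, size=n_per_group), 0, None)
        lon = np.clip(rng.normal(mean, sd, size=n_per_group), 0, None)
        for i in range(n_per_group):
            rows.append(
                {
                    "replicate_id": f"g{g + 1}r{i + 1}",
                    "genotype": f"group{g + 1}",
                    "environment": environment,
                    "diameter_lateral": float(lat[i]),
                    "diameter_longitudinal": float(lon[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic reference CDS for worked annotation examples


def make_reference_cds(
    locus: str = "ntrB",
    n_codons: int = 363,
    seed: int = 2021,
    codon_overrides: dict[int, str] | None = None,
) -> CDSRecord:
    """A synthetic stand-in for a locus CDS with prescribed codons.

    Random coding sequence with selected codons overwritten (1-based codon
    index → codon string), used to construct worked examples such as a
    threonine codon at residue 97 or an LVRGL run at residues 136–140.
    The sequence is synthetic: it shares only the prescribed features with
    any real locus.
    """
    base = gen_cds(n_codons, seed)
    if not codon_overrides:
        return CDSRecord(id=f"{locus}_synthetic", seq=base.seq)
    bases = list(base.seq)
    for ci, codon in codon_overrides.items():
        if not 1 <= ci <= n_codons:
            raise ValueError(f"codon index {ci} outside 1..{n_codons}")
        if len(codon) != 3:
            raise ValueError(f"override {codon!r} is not a codon")
        bases[3 * (ci - 1) : 3 * ci] = codon
    return CDSRecord(id=f"{locus}_synthetic", seq="".join(bases))


# codons giving the worked ntrB-like examples: Thr97 (ACC, so A289C -> CCC =
# Pro), the LVRGL run at residues 136-140, Ala228 with A at nt 683
# (GCA at 682-684 -> GCC keeps Ala; use CAT His677..? -> simpler: codon 228
# = AAA, A683C -> ACA Thr), and degenerate third positions in codons 92-102.
NTRB_LIKE_OVERRIDES = {
    92: "GGC",  # third position degenerate (Gly)
    93: "ACC",
    95: "CTC",
    97: "ACC",  # Thr97: A289 is this codon's first base; A289C -> CCC (Pro)
    98: "GTT",
    100: "CCG",
    135: "GCC",  # A — flank distinct from G so deletion left-alignment stops
    136: "CTG",  # L
    137: "GTG",  # V
    138: "CGC",  # R
    139: "GGT",  # G
    140: "CTC",  # L
    # codon 141 starts with the same base as codon 137, so the off-phase
    # 12-nt deletion of sites 410-421 rebuilds an identical junction codon
    # and yields the same protein as deleting 406-417
    141: "GAA",  # E
    228: "AAA",  # A683 is the middle base; A683C -> ACA (Lys228Thr)
}


def ntrb_like_cds(seed: int = 2021) -> CDSRecord:
    """Synthetic 363-codon CDS carrying the worked-example codon features."""
    return make_reference_cds("ntrB", 363, seed, NTRB_LIKE_OVERRIDES)


def lines_m9_headline(reference_locus: str = "ntrB") -> list[EvolvedLine]:
    """The headline minimal-media outcome: 23 focal transversions + 1 deletion.

    24 independent lines in one condition, 23 carrying the focal A289C
    substitution and one carrying the 12-nt deletion Δ406–417.
    """
    lines = []
    for i in range(23):
        lines.append(
            EvolvedLine(
                line_id=f"M9-{i + 1}",
                strain="AR2",
                environment="M9",
                mutations=[
                    MutationRecord(reference_locus, "substitution", 289, 289, "A", "C")
                ],
            )
        )
    lines.append(
        EvolvedLine(
            line_id="M9-24",
            strain="AR2",
            environment="M9",
            mutations=[MutationRecord(reference_locus, "deletion", 406, 417, "", "")],
        )
    )
    return lines
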