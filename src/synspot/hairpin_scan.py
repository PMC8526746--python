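"""Inverted-repeat (quasi-palindrome) scanning around a focal nucleotide.

Short reverse-complement tracts on one DNA strand can fold into transient
single-stranded hairpins — a stem of paired arms separated by an unpaired
loop — and sites left unpaired inside such structures experience elevated
mutation rates. The scanner enumerates all arm pairs within a window around
a focal position, calls *stems*, and reports whether the focal site itself
is inside a paired arm or left unpaired.

Scoring is purely complementarity-based (arm length minus mismatches); no
thermodynamic free energy is computed. Intervals are 1-based inclusive in
the API and 0-based half-open in BED-style output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# G·T wobble pairs are off by default (DNA duplex context)
_WOBBLE = {("G", "T"), ("T", "G")}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanParams:
    """Stem-calling parameters.

    window
        Half-width in nt of the scanned region either side of the focal
        site (truncated at sequence ends).
    min_arm, max_arm
        Allowed arm lengths in nt (min 3 — shorter arms are ubiquitous
        noise).
    min_loop, max_loop
        Allowed loop lengths in nt (min 3, the steric minimum for a
        single-stranded turn).
    max_mismatch
        Mismatched pairs tolerated per arm pair (quasi-palindromes).
    wobble
        Count G·T pairs as matches when True.
    """

    window: int = 50
    min_arm: int = 4
    max_arm: int = 12
    min_loop: int = 3
    max_loop: int = 12
    max_mismatch: int = 1
    wobble: bool = False

    def __post_init__(self) -> None:
        if self.min_arm < 3:
            raise ValueError("min_arm must be >= 3")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3 (steric minimum)")
        if self.max_arm < self.min_arm or self.max_loop < self.min_loop:
            raise ValueError("max_* must be >= min_*")
        if self.max_mismatch < 0 or self.window < 1:
            raise ValueError("max_mismatch >= 0 and window >= 1 required")


@dataclass(frozen=True)
class Stem:
    """A called arm pair: arm1 < loop < arm2, 1-based inclusive intervals."""

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    loop: tuple[int, int]
    mismatches: int
    score: int

    @property
    def arm_len(self) -> int:
        return self.arm1[1] - self.arm1[0] + 1

    @property
    def loop_len(self) -> int:
        return self.loop[1] - self.loop[0] + 1

    def contains(self, pos: int) -> bool:
        return self.arm1[0] <= pos <= self.arm2[1]

    def in_arms(self, pos: int) -> bool:
        return (
            self.arm1[0] <= pos <= self.arm1[1]
            or self.arm2[0] <= pos <= self.arm2[1]
        )

    def in_loop(self, pos: int) -> bool:
        return self.loop[0] <= pos <= self.loop[1]

    def as_key(self) -> tuple:
        return (self.arm1, self.arm2)


@dataclass
class PairingProfile:
    """Per-position paired/unpaired status within the scanned window."""

    positions: list[int]
    paired: list[bool]
    focal: int
    focal_paired: bool
    supporting_stems: list[Stem] = field(default_factory=list)


def _pairs(a: str, b: str, wobble: bool) -> int:
    """Mismatch count between arm `a` and the reverse complement of arm `b`."""
    rc = reverse_complement(b)
    mm = 0
    for x, y in zip(a, rc):
        if x != y and not (wobble and (x, y) in _WOBBLE):
            mm += 1
    return mm


def _window_bounds(seq_len: int, focal: int, window: int) -> tuple[int, int]:
    return max(1, focal - window), min(seq_len, focal + window)


def find_inverted_repeats(seq: str, focal: int, params: ScanParams) -> list[Stem]:
    """Enumerate maximal stems within the window around `focal`.

    A candidate stem has two equal-length arms (``min_arm..max_arm`` nt)
    whose reverse complements match with at most ``max_mismatch``
    differences, separated by a loop of ``min_loop..max_loop`` nt, entirely
    inside the window. Only *maximal* stems are reported: a stem that can be
    extended outward (both arm outer ends) or inward (both inner ends,
    shrinking the loop) into another valid candidate is suppressed.

    Results are sorted by score (arm length − mismatches) descending, ties
    by smaller loop, then leftmost arm1.
    """
    seq = seq.upper()
    if not 1 <= focal <= len(seq):
        raise ValueError(f"focal position {focal} outside sequence")
    lo, hi = _window_bounds(len(seq), focal, params.window)

    def valid(i: int, j: int, L: int) -> bool:
        """Arm1 at i..i+L-1, arm2 at j..j+L-1 (1-based), loop between."""
        if i < lo or j + L - 1 > hi:
            return False
        if not params.min_arm <= L <= params.max_arm:
            return False
        loop_len = j - (i + L)
        if not params.min_loop <= loop_len <= params.max_loop:
            return False
        a = seq[i - 1 : i + L - 1]
        b = seq[j - 1 : j + L - 1]
        return _pairs(a, b, params.wobble) <= params.max_mismatch

    stems: list[Stem] = []
    for L in range(params.min_arm, params.max_arm + 1):
        for i in range(lo, hi - L + 2):
            first_j = i + L + params.min_loop
            last_j = min(i + L + params.max_loop, hi - L + 1)
            for j in range(first_j, last_j + 1):
                if not valid(i, j, L):
                    continue
                # maximality: outward and inward one-step extensions
                if valid(i - 1, j, L + 1) or valid(i, j - 1, L + 1):
                    continue
                a = seq[i - 1 : i + L - 1]
                b = seq[j - 1 : j + L - 1]
                mm = _pairs(a, b, params.wobble)
                stems.append(
                    Stem(
                        arm1=(i, i + L - 1),
                        arm2=(j, j + L - 1),
                        loop=(i + L, j - 1),
                        mismatches=mm,
                        score=L - mm,
                    )
                )

    stems.sort(key=lambda s: (-s.score, s.loop_len, s.arm1[0]))
    return stems


def pairing_profile(seq: str, stems: list[Stem], focal: int,
                    params: ScanParams | None = None) -> PairingProfile:
    """Per-position paired flags from the union of called stem arms."""
    params = params or ScanParams()
    lo, hi = _window_bounds(len(seq), focal, params.window)
    positions = list(range(lo, hi + 1))
    paired = [any(s.in_arms(p) for s in stems) for p in positions]
    supporting = [s for s in stems if s.in_arms(focal)]
    return PairingProfile(
        positions=positions,
        paired=paired,
        focal=focal,
        focal_paired=bool(supporting),
        supporting_stems=supporting,
    )


@dataclass
class VariantDelta:
    """Stem-level differences between a wild-type window and a variant."""

    broken: list[Stem]
    gained: list[Stem]
    shared: list[Stem]
    focal_paired_wt: bool
    focal_paired_variant: bool
    top_score_wt: int
    top_score_variant: int

    @property
    def is_empty(self) -> bool:
        return not self.broken and not self.gained


def compare_variants(
    seq_wt: str, seq_variant: str, focal: int, params: ScanParams | None = None
) -> VariantDelta:
    """Diff the called stems of two equal-length sequence variants.

    Stems are matched by arm coordinates: a stem present in the wild type
    but absent from the variant is *broken*, the converse is *gained*.
    """
    if len(seq_wt) != len(seq_variant):
        raise ValueError(
            f"sequences differ in length ({len(seq_wt)} vs {len(seq_variant)})"
        )
    params = params or ScanParams()
    wt = find_inverted_repeats(seq_wt, focal, params)
    var = find_inverted_repeats(seq_variant, focal, params)
    wt_keys = {s.as_key(): s for s in wt}
    var_keys = {s.as_key(): s for s in var}
    broken = [s for k, s in wt_keys.items() if k not in var_keys]
    gained = [s for k, s in var_keys.items() if k not in wt_keys]
    shared = [s for k, s in wt_keys.items() if k in var_keys]
    return VariantDelta(
        broken=broken,
        gained=gained,
        shared=shared,
        focal_paired_wt=pairing_profile(seq_wt, wt, focal, params).focal_paired,
        focal_paired_variant=pairing_profile(
            seq_variant, var, focal, params
        ).focal_paired,
        top_score_wt=wt[0].score if wt else 0,
        top_score_variant=var[0].score if var else 0,
    )


def stems_to_bed(stems: list[Stem], chrom: str = "seq") -> str:
    """BED-like export: 0-based half-open arm and loop intervals."""
    lines = ["#chrom\tstart\tend\tpart\tscore\tmismatches"]
    for k, s in enumerate(stems):
        for part, (a, b) in (
            ("arm1", s.arm1),
            ("loop", s.loop),
            ("arm2", s.arm2),
        ):
            lines.append(
                f"{chrom}\t{a - 1}\t{b}\tstem{k}:{part}\t{s.score}\t{s.mismatches}"
            )
    return "\n".join(lines) + "\n"
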