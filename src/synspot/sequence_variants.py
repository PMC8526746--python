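"""Synonymous substitution sets and codon-aware divergence partitioning.

Bacterial coding sequences are compared and edited at single-nucleotide
resolution while keeping track of the codon context, so that a set of edits
can be certified *synonymous* (the protein product is untouched) and the
divergence between two homologous CDSs can be split into synonymous and
non-synonymous site fractions.

Translation uses the bacterial/archaeal genetic code (NCBI translation
table 11), the code of *Pseudomonas*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

_DNA = frozenset("ACGT")
_TABLE_ID = 11
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[_TABLE_ID]

STOP = "*"


@dataclass(frozen=True)
class CDSRecord:
    """A coding (or plain) DNA sequence.

    Parameters
    ----------
    id : str
        Sequence label.
    seq : str
        Upper-case DNA over {A, C, G, T}.
    coding : bool
        When True the length must be divisible by 3 and the sequence is
        interpreted in frame starting at position 1.
    """

    id: str
    seq: str
    coding: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _DNA
        if bad:
            raise ValueError(f"{self.id}: non-ACGT characters {sorted(bad)}")
        if self.coding and len(self.seq) % 3 != 0:
            raise ValueError(
                f"{self.id}: coding sequence length {len(self.seq)} "
                "not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon(self, index: int) -> str:
        """Return the 1-based `index`-th codon."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} outside 1..{self.n_codons}")
        return self.seq[3 * (index - 1) : 3 * index]


@dataclass(frozen=True)
class Substitution:
    """A single-base edit at a 1-based CDS position."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position {self.pos} must be >= 1")
        if self.ref not in _DNA or self.alt not in _DNA:
            raise ValueError(f"bases must be in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at position {self.pos}")

    @property
    def label(self) -> str:
        return f"{self.ref}{self.pos}{self.alt}"

    def inverted(self) -> "Substitution":
        return Substitution(self.pos, self.alt, self.ref)


@dataclass(frozen=True)
class SubstitutionSet:
    """An ordered set of single-base swaps, optionally certified synonymous.

    When ``synonymous`` is True, :func:`apply_substitutions` asserts that the
    whole set leaves the translation unchanged and fails hard otherwise.
    """

    edits: tuple[Substitution, ...]
    name: str = ""
    synonymous: bool = False
    skipped: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        positions = [e.pos for e in self.edits]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate edit positions")
        object.__setattr__(
            self, "edits", tuple(sorted(self.edits, key=lambda e: e.pos))
        )

    def __len__(self) -> int:
        return len(self.edits)

    def inverted(self) -> "SubstitutionSet":
        """The ref/alt-swapped set: applying both in turn is the identity."""
        return SubstitutionSet(
            tuple(e.inverted() for e in self.edits),
            name=f"{self.name}^-1" if self.name else "",
            synonymous=self.synonymous,
        )

    @classmethod
    def from_labels(
        cls, labels: list[str] | tuple[str, ...], name: str = "", synonymous: bool = False
    ) -> "SubstitutionSet":
        """Build from compact labels like ``["C276G", "C279T"]``."""
        edits = []
        for lab in labels:
            lab = lab.strip()
            ref, alt = lab[0], lab[-1]
            pos = int(lab[1:-1])
            edits.append(Substitution(pos, ref, alt))
        return cls(tuple(edits), name=name, synonymous=synonymous)


@dataclass(frozen=True)
class DivergenceSummary:
    """Site-wise divergence between two codon-aligned CDSs.

    All percentages are computed from the integer tallies in ``counts`` and
    rounded to 2 decimal places only on report; in the gap-free case
    ``nt_identity_pct + syn_diff_pct + nonsyn_diff_pct == 100`` up to that
    rounding.
    """

    nt_identity_pct: float
    aa_identity_pct: float
    syn_diff_pct: float
    nonsyn_diff_pct: float
    counts: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "nt_identity_pct": self.nt_identity_pct,
            "aa_identity_pct": self.aa_identity_pct,
            "syn_diff_pct": self.syn_diff_pct,
            "nonsyn_diff_pct": self.nonsyn_diff_pct,
            "counts": dict(self.counts),
        }


def translate(cds: CDSRecord | str) -> str:
    """Translate a coding sequence with the bacterial code (table 11).

    Stop codons are rendered as ``*``. Internal stops are translated, not
    rejected — callers that care check for them explicitly.
    """
    seq = cds.seq if isinstance(cds, CDSRecord) else cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"length {len(seq)} not divisible by 3")
    return str(Seq(seq).translate(table=_TABLE_ID))


def codon_is_degenerate_third(codon: str, alt_base: str) -> bool:
    """True when swapping the third base of `codon` to `alt_base` is silent."""
    return translate(codon) == translate(codon[:2] + alt_base)


def apply_substitutions(cds: CDSRecord, s: SubstitutionSet) -> CDSRecord:
    """Apply every edit of `s` to `cds`, verifying refs (and synonymy).

    Raises
    ------
    ValueError
        If any edit's ref base does not match the sequence (reported for the
        first failing edit — the usual sign of applying a set designed for a
        different strain), or if a set marked synonymous changes the
        translation.
    """
    bases = list(cds.seq)
    for e in s.edits:
        if e.pos > len(bases):
            raise ValueError(f"edit {e.label} beyond sequence end {len(bases)}")
        if bases[e.pos - 1] != e.ref:
            raise ValueError(
                f"ref mismatch for edit {e.label}: sequence has "
                f"{bases[e.pos - 1]} at position {e.pos}"
            )
        bases[e.pos - 1] = e.alt
    out = CDSRecord(
        id=f"{cds.id}|{s.name}" if s.name else cds.id,
        seq="".join(bases),
        coding=cds.coding,
    )
    if s.synonymous and cds.coding and translate(out) != translate(cds):
        raise ValueError(
            f"substitution set {s.name or '(unnamed)'} marked synonymous "
            "but changes the translation"
        )
    return out


def design_synonymous_swap(
    cds_a: CDSRecord,
    cds_b: CDSRecord,
    focal: int,
    flank_codons: int,
    name: str = "",
) -> SubstitutionSet:
    """Design the silent edits that locally match `cds_a` to `cds_b`.

    Within ``flank_codons`` codons either side of the codon containing the
    1-based ``focal`` nucleotide, every position where the two sequences
    differ is considered: the edit (a-base → b-base) is included iff swapping
    that single base in ``cds_a``'s codon context preserves the residue.
    Window positions where matching ``cds_b`` would change the protein are
    skipped and recorded in ``skipped``, never edited.

    The returned set is certified synonymous (verified by translation).
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(
            f"sequences differ in length ({len(cds_a)} vs {len(cds_b)}); "
            "align before designing a swap"
        )
    if not 1 <= focal <= len(cds_a):
        raise ValueError(f"focal position {focal} outside sequence")
    focal_codon = (focal + 2) // 3
    lo_codon = max(1, focal_codon - flank_codons)
    hi_codon = min(cds_a.n_codons, focal_codon + flank_codons)
    lo_nt, hi_nt = 3 * (lo_codon - 1) + 1, 3 * hi_codon

    edits: list[Substitution] = []
    skipped: list[int] = []
    for pos in range(lo_nt, hi_nt + 1):
        a_base, b_base = cds_a.seq[pos - 1], cds_b.seq[pos - 1]
        if a_base == b_base:
            continue
        ci = (pos + 2) // 3
        codon = cds_a.codon(ci)
        off = (pos - 1) % 3
        swapped = codon[:off] + b_base + codon[off + 1 :]
        if translate(codon) == translate(swapped):
            edits.append(Substitution(pos, a_base, b_base))
        else:
            skipped.append(pos)

    out = SubstitutionSet(
        tuple(edits),
        name=name or f"{cds_a.id}->{cds_b.id}@{focal}±{flank_codons}",
        synonymous=True,
        skipped=tuple(skipped),
    )
    # certification: the designed set must never move the protein
    apply_substitutions(cds_a, out)
    return out


def partition_divergence(
    cds_a: CDSRecord, cds_b: CDSRecord, rule: str = "site"
) -> DivergenceSummary:
    """Partition nucleotide divergence into synonymous and non-synonymous sites.

    Two classification rules are available:

    ``site`` (default, codon-local)
        A differing site is synonymous iff swapping that single base of
        ``cds_a`` to ``cds_b``'s base, holding the rest of ``cds_a``'s codon
        fixed, preserves the residue.
    ``codon``
        Whole-codon classification — every differing site in a codon is
        synonymous iff the two full codons translate identically.

    Amino-acid identity is computed on the two translations. Sequences must be
    codon-aligned and of equal length (gap-free site-wise comparison).
    """
    if rule not in ("site", "codon"):
        raise ValueError(f"unknown classification rule {rule!r}")
    if len(cds_a) != len(cds_b):
        raise ValueError(
            f"length mismatch ({len(cds_a)} vs {len(cds_b)}): "
            "provide codon-aligned sequences of equal length"
        )

    n = len(cds_a)
    identical = syn = nonsyn = 0
    for pos in range(1, n + 1):
        a_base, b_base = cds_a.seq[pos - 1], cds_b.seq[pos - 1]
        if a_base == b_base:
            identical += 1
            continue
        ci = (pos + 2) // 3
        codon_a, codon_b = cds_a.codon(ci), cds_b.codon(ci)
        if rule == "site":
            off = (pos - 1) % 3
            swapped = codon_a[:off] + b_base + codon_a[off + 1 :]
            silent = translate(codon_a) == translate(swapped)
        else:
            silent = translate(codon_a) == translate(codon_b)
        if silent:
            syn += 1
        else:
            nonsyn += 1

    aa_a, aa_b = translate(cds_a), translate(cds_b)
    aa_same = sum(x == y for x, y in zip(aa_a, aa_b))
    n_aa = len(aa_a)

    return DivergenceSummary(
        nt_identity_pct=round(100.0 * identical / n, 2),
        aa_identity_pct=round(100.0 * aa_same / n_aa, 2),
        syn_diff_pct=round(100.0 * syn / n, 2),
        nonsyn_diff_pct=round(100.0 * nonsyn / n, 2),
        counts={
            "nt_sites": n,
            "nt_identical": identical,
            "syn_diff": syn,
            "nonsyn_diff": nonsyn,
            "aa_sites": n_aa,
            "aa_identical": aa_same,
        },
    )


# The six silent substitutions that convert the SBW25-derived (AR2) ntrB
# window around site 289 into the Pf0-1 sequence, and their reciprocals.
AR2_TO_PF0_SM6 = SubstitutionSet.from_labels(
    ["C276G", "C279T", "C285G", "C291G", "T294G", "G300C"],
    name="AR2-sm",
    synonymous=True,
)
PF0_TO_AR2_SM6 = SubstitutionSet.from_labels(
    ["G276C", "T279C", "G285C", "G291C", "G294T", "C300G"],
    name="Pf0-2x-sm6",
    synonymous=True,
)
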