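"""Mutation parsing, codon-level protein effects, and route grouping.

Independently evolved lines report their motility-restoring mutation as a
compact label — a substitution such as ``A289C`` or a deletion such as
``Δ406–417`` — against the coding sequence of a locus in the nitrogen
regulatory pathway (ntrB, glnK, glnA, rpoN...). This module resolves those
labels into codon-level protein consequences and groups distinct DNA changes
that yield identical protein products into a single adaptive *route class*,
the unit at which repeatability is quantified.

Coordinates are 1-based and inclusive on the coding strand, frame anchored
at position 1.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .sequence_variants import CDSRecord, translate

# En-dash and hyphen both accepted in deletion ranges; canonical output uses
# the en-dash.
_SUB_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_DEL_RE = re.compile(r"^(?:Δ|del)\s*(\d+)(?:\s*[–\-]\s*(\d+))?$")

UNIDENTIFIED = "unidentified"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class MutationRecord:
    """A parsed genetic change on a locus CDS."""

    locus: str
    kind: str  # "substitution" | "deletion"
    start: int
    end: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if self.kind == "substitution":
            if self.start != self.end or len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("substitutions are single-base")
        elif self.kind != "deletion":
            raise ValueError(f"unknown mutation kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_noop(self) -> bool:
        """A self-substitution like A289A: syntactically valid, no change."""
        return self.kind == "substitution" and self.ref == self.alt

    @property
    def label(self) -> str:
        if self.kind == "substitution":
            return f"{self.ref}{self.start}{self.alt}"
        if self.start == self.end:
            return f"Δ{self.start}"
        return f"Δ{self.start}–{self.end}"


@dataclass(frozen=True)
class ProteinEffect:
    """Codon-level consequence of a mutation on its locus CDS."""

    kind: str  # missense | synonymous | inframe_deletion | frameshift
    first_residue: int
    last_residue: int
    ref_residues: str
    alt_residues: str
    label: str

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError("first_residue > last_residue")
        if self.kind == "frameshift" and self.alt_residues:
            raise ValueError("frameshift carries no alt residues")


@dataclass
class EvolvedLine:
    """One independent replicate line of the evolution experiment."""

    line_id: str
    strain: str
    environment: str
    supplement_mM: float | None = None
    emergence_day: int | None = None
    mutations: list[MutationRecord] | str = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.emergence_day is not None and self.emergence_day < 1:
            raise ValueError("emergence_day must be >= 1")

    @property
    def is_unidentified(self) -> bool:
        return isinstance(self.mutations, str) and self.mutations == UNIDENTIFIED


@dataclass
class RouteClass:
    """Distinct DNA mutations sharing one protein product = one route."""

    key: tuple[str, str]  # (locus, protein-effect label)
    effect: ProteinEffect
    members: list[MutationRecord] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.key[0]} {self.key[1]}"


def parse_mutation(label: str, locus: str) -> MutationRecord:
    """Parse a compact mutation label into a :class:`MutationRecord`.

    Accepts ``<ref><pos><alt>`` substitutions (``A289C``) and ``Δ<start>–<end>``
    deletions (en-dash or hyphen; single-site ``Δ84`` allowed).
    """
    label = label.strip()
    m = _SUB_RE.match(label)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        return MutationRecord(locus, "substitution", pos, pos, ref, alt)
    m = _DEL_RE.match(label)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if end < start:
            raise ValueError(f"deletion end < start in {label!r}")
        return MutationRecord(locus, "deletion", start, end, "", "")
    raise ValueError(f"unrecognised mutation label {label!r}")


def codon_index(pos: int) -> int:
    """1-based codon index of a 1-based CDS nucleotide (289 → 97)."""
    if pos < 1:
        raise ValueError(f"position {pos} must be >= 1")
    return math.ceil(pos / 3)


def _check_ref(cds: CDSRecord, m: MutationRecord) -> None:
    if m.end > len(cds):
        raise ValueError(
            f"{m.label} extends past the {len(cds)}-nt {cds.id} CDS"
        )
    if m.kind == "substitution" and cds.seq[m.start - 1] != m.ref:
        raise ValueError(
            f"reference mismatch at {cds.id}:{m.start} — CDS has "
            f"{cds.seq[m.start - 1]}, mutation claims {m.ref}"
        )


def protein_effect(cds: CDSRecord, m: MutationRecord) -> ProteinEffect:
    """Compute the codon-level protein consequence of `m` on `cds`.

    Substitutions translate the affected codon before and after. Deletions
    whose length is a multiple of 3 are normalised by translating the mutant
    CDS and left-aligning identical flanking residues, so that deletions of
    different nucleotides with the same protein product (e.g. within a
    repeat) receive the same canonical label. Other deletion lengths are
    frameshifts from the first affected codon.
    """
    _check_ref(cds, m)
    protein = translate(cds)

    if m.kind == "substitution":
        ci = codon_index(m.start)
        codon = cds.codon(ci)
        off = (m.start - 1) % 3
        mutant_codon = codon[:off] + m.alt + codon[off + 1 :]
        ref_aa, alt_aa = translate(codon), translate(mutant_codon)
        kind = "synonymous" if ref_aa == alt_aa else "missense"
        return ProteinEffect(
            kind=kind,
            first_residue=ci,
            last_residue=ci,
            ref_residues=ref_aa,
            alt_residues=alt_aa,
            label=f"{ref_aa}{ci}{alt_aa}",
        )

    # deletion
    if m.length % 3 != 0:
        ci = codon_index(m.start)
        return ProteinEffect(
            kind="frameshift",
            first_residue=ci,
            last_residue=ci,
            ref_residues=protein[ci - 1],
            alt_residues="",
            label=f"{protein[ci - 1]}{ci}fs",
        )

    n_del = m.length // 3
    mutant_seq = cds.seq[: m.start - 1] + cds.seq[m.end :]
    mutant_protein = translate(CDSRecord(cds.id, mutant_seq))

    # longest common prefix, then shift the deleted run leftwards while the
    # flanking residues repeat — yields the leftmost equivalent representation
    p = 0
    while p < len(mutant_protein) and protein[p] == mutant_protein[p]:
        p += 1
    while p > 0 and protein[p - 1] == protein[p + n_del - 1]:
        p -= 1
    first = p + 1
    last = p + n_del
    deleted = protein[p : p + n_del]
    return ProteinEffect(
        kind="inframe_deletion",
        first_residue=first,
        last_residue=last,
        ref_residues=deleted,
        alt_residues="",
        label=(
            f"Δ{first}–{last} (Δ{deleted})" if n_del > 1 else f"Δ{first} (Δ{deleted})"
        ),
    )


def group_routes(
    lines: list[EvolvedLine], reference_cds: dict[str, CDSRecord]
) -> tuple[list[RouteClass], list[EvolvedLine]]:
    """Group single-mutation lines into route classes by protein product.

    Lines carrying more than one mutation are excluded from the analysis
    (a double mutant confounds the route attribution). Lines whose mutation
    could not be identified are kept under the reserved ``unidentified``
    class. Returns the route classes (insertion order) and the excluded
    lines.
    """
    classes: dict[tuple[str, str], RouteClass] = {}
    excluded: list[EvolvedLine] = []

    for line in lines:
        if line.is_unidentified:
            key = (UNIDENTIFIED, UNIDENTIFIED)
            classes.setdefault(
                key,
                RouteClass(
                    key=key,
                    effect=ProteinEffect(
                        kind="missense",
                        first_residue=1,
                        last_residue=1,
                        ref_residues="?",
                        alt_residues="?",
                        label=UNIDENTIFIED,
                    ),
                ),
            )
            continue
        muts = line.mutations
        if not isinstance(muts, list):
            raise TypeError(f"line {line.line_id}: bad mutations field {muts!r}")
        if len(muts) > 1:
            excluded.append(line)
            continue
        if not muts:
            continue
        m = muts[0]
        if m.locus not in reference_cds:
            raise KeyError(f"no reference CDS for locus {m.locus!r}")
        eff = protein_effect(reference_cds[m.locus], m)
        key = (m.locus, eff.label)
        rc = classes.setdefault(key, RouteClass(key=key, effect=eff))
        if eff.label != rc.effect.label:  # pragma: no cover - keyed identically
            raise AssertionError("route class members disagree on effect")
        rc.members.append(m)

    return list(classes.values()), excluded


def build_outcome_table(
    lines: list[EvolvedLine], reference_cds: dict[str, CDSRecord]
) -> pd.DataFrame:
    """Tally route classes per (strain, environment) condition.

    Rows are route-class labels (plus ``unidentified`` where present and an
    ``excluded`` bookkeeping row); columns are a (strain, environment)
    MultiIndex. Column sums over the non-excluded rows equal the number of
    analysed lines per condition.
    """
    classes, excluded_lines = group_routes(lines, reference_cds)
    excluded_ids = {id(l) for l in excluded_lines}

    label_of: dict[tuple[str, str], str] = {c.key: c.label for c in classes}
    label_of[(UNIDENTIFIED, UNIDENTIFIED)] = UNIDENTIFIED

    rows: list[tuple[str, str, str]] = []
    for line in lines:
        cond = (line.strain, line.environment)
        if id(line) in excluded_ids:
            rows.append((EXCLUDED, *cond))
            continue
        if line.is_unidentified:
            rows.append((UNIDENTIFIED, *cond))
            continue
        if not line.mutations:
            continue
        m = line.mutations[0]
        eff = protein_effect(reference_cds[m.locus], m)
        rows.append((f"{m.locus} {eff.label}", *cond))

    if not rows:
        return pd.DataFrame()

    df = pd.DataFrame(rows, columns=["route", "strain", "environment"])
    table = (
        df.value_counts(["route", "strain", "environment"])
        .unstack(["strain", "environment"], fill_value=0)
        .sort_index(axis=1)
    )
    # stable row order: route classes first (insertion order), then reserved
    order = [c.label for c in classes if c.key[0] != UNIDENTIFIED]
    for reserved in (UNIDENTIFIED, EXCLUDED):
        if reserved in table.index:
            order.append(reserved)
    table = table.reindex([r for r in order if r in table.index])
    return table
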