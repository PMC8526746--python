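"""File-format plumbing: FASTA, GenBank flat files, and delimited tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .mutation_annotation import UNIDENTIFIED, EvolvedLine, parse_mutation
from .sequence_variants import CDSRecord

LINES_COLUMNS = [
    "line_id",
    "strain",
    "environment",
    "supplement_mM",
    "emergence_day",
    "locus",
    "mutation",
]


def read_fasta(path: str | Path, coding: bool = True) -> list[CDSRecord]:
    return [
        CDSRecord(id=rec.id, seq=str(rec.seq), coding=coding)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[CDSRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def extract_cds_from_genbank(
    path: str | Path, gene: str | None = None, locus_tag: str | None = None
) -> CDSRecord:
    """Extract a named gene's CDS from a GenBank flat file.

    Matches CDS features by ``gene`` name or ``locus_tag`` qualifier and
    returns the spliced, strand-corrected coding sequence.
    """
    if gene is None and locus_tag is None:
        raise ValueError("provide gene or locus_tag")
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            genes = feat.qualifiers.get("gene", [])
            tags = feat.qualifiers.get("locus_tag", [])
            if (gene and gene in genes) or (locus_tag and locus_tag in tags):
                seq = str(feat.extract(rec.seq))
                name = gene or locus_tag
                return CDSRecord(id=f"{rec.id}|{name}", seq=seq)
    raise KeyError(
        f"no CDS with gene={gene!r} / locus_tag={locus_tag!r} in {path}"
    )


def read_lines_table(path: str | Path) -> list[EvolvedLine]:
    """Read evolved lines from a tab-separated table.

    Expected header columns: line_id, strain, environment, supplement_mM,
    emergence_day, locus, mutation. A mutation value of ``unidentified``
    marks a line whose causal change was not found; multiple mutations in
    one line are separated by ``;`` in both locus and mutation columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(LINES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"lines table missing columns: {sorted(missing)}")
    out: list[EvolvedLine] = []
    for _, row in df.iterrows():
        if row["mutation"].strip().lower() == UNIDENTIFIED:
            muts: list | str = UNIDENTIFIED
        elif not row["mutation"].strip():
            muts = []
        else:
            loci = [x.strip() for x in row["locus"].split(";")]
            labels = [x.strip() for x in row["mutation"].split(";")]
            if len(loci) != len(labels):
                raise ValueError(
                    f"line {row['line_id']}: locus/mutation count mismatch"
                )
            muts = [parse_mutation(lab, loc) for lab, loc in zip(labels, loci)]
        out.append(
            EvolvedLine(
                line_id=row["line_id"],
                strain=row["strain"],
                environment=row["environment"],
                supplement_mM=float(row["supplement_mM"])
                if row["supplement_mM"]
                else None,
                emergence_day=int(row["emergence_day"])
                if row["emergence_day"]
                else None,
                mutations=muts,
            )
        )
    return out


def write_lines_table(lines: list[EvolvedLine], path: str | Path) -> None:
    rows = []
    for l in lines:
        if l.is_unidentified:
            locus, mutation = "", UNIDENTIFIED
        elif isinstance(l.mutations, list) and l.mutations:
            locus = ";".join(m.locus for m in l.mutations)
            mutation = ";".join(m.label for m in l.mutations)
        else:
            locus = mutation = ""
        rows.append(
            {
                "line_id": l.line_id,
                "strain": l.strain,
                "environment": l.environment,
                "supplement_mM": "" if l.supplement_mM is None else l.supplement_mM,
                "emergence_day": "" if l.emergence_day is None else l.emergence_day,
                "locus": locus,
                "mutation": mutation,
            }
        )
    pd.DataFrame(rows, columns=LINES_COLUMNS).to_csv(path, sep="\t", index=False)
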