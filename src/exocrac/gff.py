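"""Annotation container plus FASTA/GFF3 interchange.

Internally all coordinates are 0-based half-open and strand-explicit;
GFF3 is emitted (and read back) 1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: annotation column order; intron/mature fields are nullable
COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand", "gene_class",
    "family_id", "mature_start", "mature_end", "intron_start", "intron_end",
]

KNOWN_CLASSES = {
    "mRNA", "tRNA", "snoRNA", "snRNA", "CUT", "SUT", "rRNA_unit", "ncRNA",
}


class AnnotationSet:
    """Class-labelled transcript coordinates backed by a DataFrame.

    Rows carry the gene interval (TSS..3' end for mRNA), mature-region
    boundaries (tRNA/snoRNA), optional intron, and a family identity used
    to group multi-copy tRNA genes that share a mature sequence.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        unknown = set(df["gene_class"]) - KNOWN_CLASSES
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def by_class(self, gene_class: str) -> pd.DataFrame:
        return self.df[self.df["gene_class"] == gene_class]

    def gene(self, gene_id: str) -> pd.Series:
        rows = self.df[self.df["gene_id"] == gene_id]
        if rows.empty:
            raise KeyError(f"gene {gene_id!r} not in annotation")
        return rows.iloc[0]

    # -- GFF3 interchange -------------------------------------------------

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, r in self.df.iterrows():
                attrs = [f"ID={r.gene_id}", f"gene_class={r.gene_class}"]
                if pd.notna(r.family_id):
                    attrs.append(f"family_id={r.family_id}")
                for key in ("mature_start", "mature_end",
                            "intron_start", "intron_end"):
                    val = getattr(r, key)
                    if pd.notna(val):
                        # stored 0-based; emit 1-based for *_start fields
                        off = 1 if key.endswith("start") else 0
                        attrs.append(f"{key}={int(val) + off}")
                fh.write("\t".join([
                    r.chrom, "exocrac", r.gene_class,
                    str(int(r.start) + 1), str(int(r.end)), ".",
                    r.strand, ".", ";".join(attrs),
                ]) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                chrom, _, ftype, start, end, _, strand, _, attr = (
                    line.rstrip("\n").split("\t"))
                fields = dict(
                    kv.split("=", 1) for kv in attr.split(";") if "=" in kv)
                rows.append({
                    "gene_id": fields["ID"],
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "gene_class": fields.get("gene_class", ftype),
                    "family_id": fields.get("family_id"),
                    "mature_start": _opt(fields, "mature_start", -1),
                    "mature_end": _opt(fields, "mature_end", 0),
                    "intron_start": _opt(fields, "intron_start", -1),
                    "intron_end": _opt(fields, "intron_end", 0),
                })
        return cls(pd.DataFrame(rows, columns=COLUMNS))


def _opt(fields: dict, key: str, shift: int) -> float:
    return int(fields[key]) + shift if key in fields else float("nan")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
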