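"""Read counting per transcript, RPM/RPKM layers, replicate averaging
and top-expressed selection.

Counting windows follow the class rules: mRNAs are counted between TSS
and polyadenylation site, other non-tRNA classes get a 50-nt flank on
both ends, and tRNA counts are injected from the pre/mature assignment
(gene-level pre-tRNA rows plus family-level mature rows that appear as
a single entry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gff import AnnotationSet
from .records import AlignmentRecord

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 50


def window_for(gene: pd.Series, flank: int = DEFAULT_FLANK):
    """Counting window (start, end) for one annotation row."""
    cls = gene.gene_class
    if cls == "mRNA":
        return int(gene.start), int(gene.end)
    return max(0, int(gene.start) - flank), int(gene.end) + flank


@dataclass
class CountMatrix:
    """Gene/family x sample counts with normalization layers.

    ``raw`` is reads per window; RPM and RPKM are derived layers
    regenerated on demand from raw, total_mapped and window lengths, so
    the round trip is exact by construction.
    """

    raw: pd.DataFrame  # genes x samples
    classes: pd.Series  # per gene
    window_length: pd.Series  # per gene, nt
    total_mapped: pd.Series  # per sample
    replicate_groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("negative raw counts")
        if (self.total_mapped <= 0).any():
            raise ValueError("total_mapped must be positive for all samples")

    def rpm(self) -> pd.DataFrame:
        return self.raw * 1e6 / self.total_mapped

    def rpkm(self) -> pd.DataFrame:
        return self.rpm().mul(1e3 / self.window_length, axis=0)

    def layer(self, name: str) -> pd.DataFrame:
        if name == "raw":
            return self.raw
        if name == "rpm":
            return self.rpm()
        if name == "rpkm":
            return self.rpkm()
        raise ValueError(f"unknown layer {name!r}")


def count_overlaps(alignments_by_sample: dict, annotation: AnnotationSet,
                   flank: int = DEFAULT_FLANK,
                   include_trna: bool = False,
                   primary_only: bool = False) -> CountMatrix:
    """Count sense-strand window overlaps per gene and sample.

    A read counts for a gene when its alignment overlaps the gene's
    window by >= 1 nt on the same strand; a read overlapping several
    windows counts once per window unless ``primary_only`` keeps only
    the window with maximal overlap. tRNA rows are excluded by default
    (their counts come from the pre/mature assignment). Multimapped
    reads (n_hits > 1) are counted at their lowest-coordinate placement.
    """
    df = annotation.df
    unknown = df.loc[~df["gene_class"].isin(
        {"mRNA", "tRNA", "snoRNA", "snRNA", "CUT", "SUT", "rRNA_unit",
         "ncRNA"}), "gene_id"].tolist()
    if unknown:
        raise ValueError(f"unknown class labels for: {unknown}")
    genes = df if include_trna else df[df["gene_class"] != "tRNA"]

    windows = genes.apply(window_for, axis=1, flank=flank)
    wdf = pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "chrom": genes["chrom"].to_numpy(),
        "strand": genes["strand"].to_numpy(),
        "start": [w[0] for w in windows],
        "end": [w[1] for w in windows],
    })

    counts = pd.DataFrame(0, index=wdf["gene_id"],
                          columns=list(alignments_by_sample), dtype=int)
    totals = {}
    multi = 0
    for sample, alns in alignments_by_sample.items():
        placements = _dedupe_multimapped(alns)
        totals[sample] = len(placements)
        for aln in placements:
            mask = ((wdf["chrom"] == aln.reference_id)
                    & (wdf["strand"] == aln.strand)
                    & (wdf["start"] < aln.end) & (aln.start < wdf["end"]))
            hit = wdf[mask]
            if len(hit) > 1:
                multi += 1
                if primary_only:
                    ov = np.minimum(hit["end"], aln.end) - \
                        np.maximum(hit["start"], aln.start)
                    hit = hit.loc[[ov.idxmax()]]
            counts.loc[hit["gene_id"], sample] += 1
    if multi:
        logger.info("count_overlaps: %d reads overlapped several windows",
                    multi)
    return CountMatrix(
        raw=counts,
        classes=genes.set_index("gene_id")["gene_class"],
        window_length=pd.Series((wdf["end"] - wdf["start"]).to_numpy(),
                                index=wdf["gene_id"]),
        total_mapped=pd.Series(totals, dtype=float),
    )


def _dedupe_multimapped(alns):
    """One deterministic placement per read: lowest coordinate."""
    best: dict[str, AlignmentRecord] = {}
    for a in alns:
        prev = best.get(a.read_id)
        if prev is None or (a.reference_id, a.start) < (prev.reference_id,
                                                        prev.start):
            best[a.read_id] = a
    return list(best.values())


def trna_counts(classifications, db) -> pd.Series:
    """Aggregate pre/mature calls into count rows.

    ``classifications`` is an iterable of ``(kind, target)`` tuples from
    :func:`exocrac.assign.classify_trna_read`. Pre-tRNA reads count at
    gene level; mature reads count at family level (one row per
    family); unassigned reads are dropped.
    """
    counts: dict[str, int] = {}
    for kind, target in classifications:
        if kind == "pre_tRNA":
            key = f"pre:{target}"
        elif kind == "mature":
            key = f"mature:{target}"
        else:
            continue
        counts[key] = counts.get(key, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def compute_rpm(counts, total_mapped):
    """RPM = raw x 1e6 / total mapped."""
    if np.any(np.asarray(total_mapped) <= 0):
        raise ValueError("total_mapped must be > 0")
    return counts * 1e6 / total_mapped


def compute_rpkm(counts, total_mapped, window_length):
    """RPKM = RPM x 1e3 / window length (nt)."""
    rpm = compute_rpm(counts, total_mapped)
    if isinstance(rpm, pd.DataFrame):
        return rpm.mul(1e3 / window_length, axis=0)
    return rpm * 1e3 / window_length


def average_replicates(layer: pd.DataFrame, groups: dict,
                       total_mapped: pd.Series,
                       policy: str = "mean") -> pd.DataFrame:
    """Collapse replicate columns per construct.

    ``mean`` averages the replicate columns; ``largest`` keeps the
    replicate with the most mapped reads (the rule used when one
    replicate is much shallower).
    """
    out = {}
    for construct, samples in groups.items():
        if not samples:
            raise ValueError(f"empty replicate group {construct!r}")
        sub = layer[list(samples)]
        if policy == "mean":
            out[construct] = sub.mean(axis=1)
        elif policy == "largest":
            out[construct] = sub[total_mapped[list(samples)].idxmax()]
        else:
            raise ValueError(f"unknown policy {policy!r}")
    return pd.DataFrame(out)


def select_top(layer: pd.DataFrame, classes: pd.Series, gene_class: str,
               n: int, ranking_sample: str) -> pd.Index:
    """Top-n genes of one class by the ranking sample's values.

    Ties at the cut break toward the lexicographically smaller id.
    """
    if gene_class not in set(classes):
        raise ValueError(f"unknown class {gene_class!r}")
    members = classes[classes == gene_class].index
    members = members.intersection(layer.index)
    if n > len(members):
        logger.warning("select_top: requested %d %s but only %d present",
                       n, gene_class, len(members))
        n = len(members)
    ranked = layer.loc[members, ranking_sample].sort_values(
        ascending=False, kind="stable")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    return pd.Index(order[:n])


def write_layers(matrix: CountMatrix, outdir: str | Path,
                 prefix: str = "counts") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer in ("raw", "rpm", "rpkm"):
        matrix.layer(layer).to_csv(outdir / f"{prefix}.{layer}.tsv",
                                   sep="\t")
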