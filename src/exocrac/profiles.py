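"""Per-gene pileups, anchored metagene matrices, and two-bin tRNA
binding correlation.

Pileup tracks live in transcript orientation (position 0 = 5' end of
the gene window), so metagene anchoring and 5'/3' binning read
naturally for both strands. Coverage counts full read bodies by
default; an ends-only mode counts only the 5' nucleotide of each read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gff import AnnotationSet
from .records import AlignmentRecord


@dataclass
class PileupTrack:
    """Per-position hit, deletion and substitution densities for one
    gene window, in transcript orientation."""

    gene_id: str
    coverage: np.ndarray
    deletions: np.ndarray
    substitutions: np.ndarray
    window_start: int  # genomic coordinate of track origin
    window_end: int
    strand: str
    scaling: str = "raw"

    def __post_init__(self) -> None:
        n = self.window_end - self.window_start
        for arr in (self.coverage, self.deletions, self.substitutions):
            if len(arr) != n:
                raise ValueError("track length != window length")

    @property
    def mass(self) -> float:
        return float(self.coverage.sum())

    def scaled(self, total_mapped: float) -> "PileupTrack":
        """Per-million-mapped scaling of all three tracks."""
        f = 1e6 / total_mapped
        return PileupTrack(self.gene_id, self.coverage * f,
                           self.deletions * f, self.substitutions * f,
                           self.window_start, self.window_end, self.strand,
                           scaling="per_million")


@dataclass
class MetageneMatrix:
    """Transcript x anchor-relative-position hit matrix."""

    matrix: pd.DataFrame  # rows transcripts, columns relative positions
    out_of_window: float  # pileup mass falling outside the column range
    anchor: str
    excluded: list = field(default_factory=list)

    @property
    def profile(self) -> pd.Series:
        """Summed binding profile (column sums)."""
        return self.matrix.sum(axis=0)

    @property
    def mass(self) -> float:
        return float(self.matrix.to_numpy().sum())


def _genomic_to_track(pos: int, window_start: int, window_end: int,
                      strand: str) -> int:
    if strand == "+":
        return pos - window_start
    return window_end - 1 - pos


def pileup(alignments, gene: pd.Series, flank: int = 0,
           mode: str = "coverage") -> PileupTrack:
    """Pile alignments onto one gene's window (gene body +/- flank).

    ``mode="coverage"`` increments every overlapped position;
    ``mode="ends"`` increments only the read 5' end position.
    Deletion/substitution counters increment at their event positions.
    Sense-strand alignments only.
    """
    w0 = max(0, int(gene.start) - flank)
    w1 = int(gene.end) + flank
    n = w1 - w0
    cov = np.zeros(n)
    dels = np.zeros(n)
    subs = np.zeros(n)
    for aln in alignments:
        if aln.reference_id != gene.chrom or aln.strand != gene.strand:
            continue
        lo, hi = max(aln.start, w0), min(aln.end, w1)
        if lo >= hi:
            continue
        if mode == "coverage":
            a = _genomic_to_track(lo, w0, w1, gene.strand)
            b = _genomic_to_track(hi - 1, w0, w1, gene.strand)
            a, b = min(a, b), max(a, b)
            cov[a:b + 1] += 1
        elif mode == "ends":
            end5 = aln.start if gene.strand == "+" else aln.end - 1
            if w0 <= end5 < w1:
                cov[_genomic_to_track(end5, w0, w1, gene.strand)] += 1
        else:
            raise ValueError(f"unknown pileup mode {mode!r}")
        for pos in aln.deletion_positions:
            if w0 <= pos < w1:
                dels[_genomic_to_track(pos, w0, w1, gene.strand)] += 1
        for pos in aln.substitution_positions:
            if w0 <= pos < w1:
                subs[_genomic_to_track(pos, w0, w1, gene.strand)] += 1
    return PileupTrack(gene.gene_id, cov, dels, subs, w0, w1, gene.strand)


def pileup_gene(alignments, annotation: AnnotationSet, gene_id: str,
                **kwargs) -> PileupTrack:
    return pileup(alignments, annotation.gene(gene_id), **kwargs)


def _anchor_offset(gene: pd.Series, anchor: str, flank: int):
    """Track-coordinate position of the anchor, or None if unresolvable."""
    glen = int(gene.end) - int(gene.start)
    if anchor in ("5p", "TSS"):
        return flank
    if anchor == "3p":
        return flank + glen
    if anchor == "mature3p":
        if pd.isna(gene.mature_end):
            return None
        if gene.strand == "+":
            return flank + int(gene.mature_end) - int(gene.start)
        return flank + int(gene.end) - int(gene.mature_start)
    raise ValueError(f"unknown anchor {anchor!r}")


def metagene(tracks: dict, annotation: AnnotationSet, anchor: str = "5p",
             window: tuple[int, int] = (50, 150),
             row_order: str = "length_desc",
             flank: int = 0) -> MetageneMatrix:
    """Anchor per-gene tracks and stack them into a matrix.

    ``window=(upstream, downstream)`` spans columns
    ``-upstream .. downstream-1`` relative to the anchor. Mass falling
    outside the window is excluded and reported so that matrix mass +
    out-of-window mass equals total track mass exactly. Transcripts
    whose anchor cannot be resolved are excluded and listed.
    """
    up, down = window
    cols = np.arange(-up, down)
    rows, index, excluded = [], [], []
    out_mass = 0.0
    for gene_id, track in tracks.items():
        gene = annotation.gene(gene_id)
        off = _anchor_offset(gene, anchor, flank)
        if off is None:
            excluded.append(gene_id)
            continue
        rel = np.arange(len(track.coverage)) - off
        row = np.zeros(len(cols))
        inside = (rel >= -up) & (rel < down)
        row[rel[inside] + up] = track.coverage[inside]
        out_mass += float(track.coverage[~inside].sum())
        rows.append(row)
        index.append(gene_id)
    mat = pd.DataFrame(rows, index=index, columns=cols)
    if row_order == "length_desc":
        lengths = {
            g: _mature_length(annotation.gene(g)) for g in mat.index}
        mat = mat.loc[sorted(mat.index,
                             key=lambda g: (-lengths[g], g))]
    elif row_order != "input":
        raise ValueError(f"unknown row order {row_order!r}")
    return MetageneMatrix(mat, out_mass, anchor, excluded)


def _mature_length(gene: pd.Series) -> int:
    if pd.notna(gene.mature_end):
        return int(gene.mature_end) - int(gene.mature_start)
    return int(gene.end) - int(gene.start)


def two_bin_fractions(tracks: dict, annotation: AnnotationSet,
                      flank: int = 0,
                      include_flanks: bool = False) -> pd.DataFrame:
    """Split each tRNA's binding at the mature midpoint into 5'/3'
    fractions summing to 1.

    Odd mature lengths give the extra base to the 5' bin. Flanking
    signal is excluded unless ``include_flanks``. Zero-hit tRNAs are
    dropped (they carry no fraction).
    """
    rows = {}
    for gene_id, track in tracks.items():
        gene = annotation.gene(gene_id)
        if include_flanks:
            region = track.coverage
        else:
            m0 = flank
            m1 = flank + _mature_length(gene)
            region = track.coverage[m0:m1]
        total = region.sum()
        if total == 0:
            continue
        half = (len(region) + 1) // 2  # odd: extra base to the 5' bin
        rows[gene_id] = (region[:half].sum() / total,
                         region[half:].sum() / total)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["frac_5p", "frac_3p"])


def pearson_matrix(fractions_by_sample: dict) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-tRNA 5' fractions.

    ``fractions_by_sample`` maps sample name to a Series of 5'
    fractions indexed by tRNA; only tRNAs shared by a pair contribute
    to that pair's coefficient. Replicates should be averaged first.
    """
    samples = list(fractions_by_sample)
    mat = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            sa, sb = fractions_by_sample[a], fractions_by_sample[b]
            shared = sa.index.intersection(sb.index)
            if len(shared) < 3:
                raise ValueError(
                    f"fewer than 3 shared tRNAs between {a} and {b}")
            r, _ = stats.pearsonr(sa.loc[shared], sb.loc[shared])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def write_bedgraph(track: PileupTrack, path: str | Path, chrom: str,
                   which: str = "coverage") -> None:
    """Emit one track layer as bedGraph (genomic forward coordinates)."""
    arr = getattr(track, which)
    if track.strand == "-":
        arr = arr[::-1]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.gene_id}.{which}"\n')
        for i, v in enumerate(arr):
            if v != 0:
                pos = track.window_start + i
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:g}\n")
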