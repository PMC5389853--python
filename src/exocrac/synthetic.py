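"""Toy genome and CRAC library simulation with full ground truth.

The generator emulates the structure of a CRAC sequencing library: each
read is a 3-nt random 5' barcode, a protein footprint extracted from the
genome (possibly carrying one single-nucleotide crosslink deletion and
uniform substitution errors), an optional non-genomic oligo(A) tail, and
a 3' adapter. PCR duplication produces byte-identical copies of each
molecule, so barcode+sequence deduplication has an exact ground truth.

Planted gene classes mirror the substrate classes of an exosome CRAC
experiment: multi-copy tRNA families (identical mature sequence, unique
15-nt genomic flanks), mRNAs, snoRNAs, CUTs, SUTs and an optional rDNA
unit. Coordinates are 0-based half-open throughout; GFF3 output is
1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .gff import COLUMNS, AnnotationSet, write_fasta
from .records import ReadRecord, revcomp

#: Mircat-style small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = [
    "molecule_id", "source_gene", "start", "end", "strand",
    "precursor_or_mature", "tail_length", "dup_group_size", "barcode",
    "deletion_pos",
]


@dataclass
class GenomeSpec:
    """Parameters of the planted toy genome."""

    seed: int = 0
    chrom_length: int = 50_000
    n_trna_families: int = 5
    copies_per_family: int = 3
    intron_fraction: float = 0.2
    n_mrna: int = 10
    n_snoRNA: int = 4
    n_cut: int = 4
    n_sut: int = 4
    rDNA_unit: bool = False
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)

    def __post_init__(self) -> None:
        counts = (self.n_trna_families, self.copies_per_family, self.n_mrna,
                  self.n_snoRNA, self.n_cut, self.n_sut)
        if any(c < 0 for c in counts):
            raise ValueError("all gene counts must be >= 0")
        if not 0.0 <= self.intron_fraction <= 1.0:
            raise ValueError("intron_fraction must lie in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")


@dataclass
class MixtureComponent:
    """One positional component: footprint 5' starts near anchor+offset."""

    anchor: str  # 5p | 3p | TSS | mature3p
    offset: int
    sd: float
    weight: float

    def __post_init__(self) -> None:
        if self.anchor not in {"5p", "3p", "TSS", "mature3p"}:
            raise ValueError(f"unknown anchor {self.anchor!r}")


def _default_mixtures() -> dict:
    # tRNA: 5' leader, mature body, 3' trailer (within the +/-15 nt
    # flanked region used by the pre/mature assignment database)
    return {
        "tRNA": [
            MixtureComponent("5p", -8, 3.0, 0.30),
            MixtureComponent("5p", 22, 6.0, 0.40),
            MixtureComponent("mature3p", -12, 3.0, 0.30),
        ],
        "*": [MixtureComponent("5p", 20, 25.0, 1.0)],
    }


@dataclass
class BindingModel:
    """Per-sample generative model of protein-RNA binding in a library."""

    sample_name: str
    mixtures: dict = field(default_factory=_default_mixtures)
    footprint_length: tuple[float, float] = (22.0, 3.0)
    min_footprint: int = 15
    deletion_prob: float = 0.15
    tail_prob: dict = field(default_factory=dict)  # per gene_class; '*' key
    tail_length_mean: float = 4.0
    tail_min: int = 2
    pcr_duplication: float = 3.0
    error_rate: float = 0.002
    adapter: str = DEFAULT_ADAPTER
    adapter_truncation_frac: float = 0.1
    class_weights: dict | None = None
    gene_weights: dict | None = None
    distinguishable_tails: bool = True
    distinguishable_boundaries: bool = True

    def __post_init__(self) -> None:
        for cls, comps in self.mixtures.items():
            total = sum(c.weight for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {cls!r} sum to {total}")
        for p in (self.deletion_prob, self.error_rate,
                  self.adapter_truncation_frac, *self.tail_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.footprint_length[0] < 15:
            raise ValueError("mean footprint must be >= 15 nt")
        if self.pcr_duplication < 1:
            raise ValueError("pcr_duplication must be >= 1")


class PackingError(RuntimeError):
    """Raised when planted genes cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# genome construction


def _random_seq(rng: np.random.Generator, length: int,
                composition) -> np.ndarray:
    return rng.choice(BASES, size=length, p=list(composition))


def build_toy_genome(spec: GenomeSpec):
    """Plant class-labelled genes in a random chromosome.

    Returns ``(sequences, annotation, design)`` where ``sequences`` maps
    chromosome name to string, ``annotation`` is an :class:`AnnotationSet`
    and ``design`` records the per-family mature sequences actually
    written into the genome.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = "chrI"

    # gene length plan; (label, class, family, length, intron (off,len)|None)
    plan = []
    fam_mature: dict[str, str] = {}
    for f in range(spec.n_trna_families):
        fam = f"tF{f + 1:02d}"
        mature_len = int(rng.integers(70, 91))
        has_intron = rng.random() < spec.intron_fraction
        intron = (min(37, mature_len // 2), 15) if has_intron else None
        gene_len = mature_len + (intron[1] if intron else 0)
        seq = "".join(_random_seq(rng, gene_len, spec.base_composition))
        fam_mature[fam] = seq
        for c in range(spec.copies_per_family):
            plan.append((f"{fam}_c{c + 1}", "tRNA", fam, gene_len, intron))
    for i in range(spec.n_mrna):
        plan.append((f"mRNA_{i + 1:04d}", "mRNA", None,
                     int(rng.integers(400, 1501)), None))
    for i in range(spec.n_snoRNA):
        plan.append((f"snoRNA_{i + 1:03d}", "snoRNA", None,
                     int(rng.integers(80, 201)), None))
    for i in range(spec.n_cut):
        plan.append((f"CUT_{i + 1:03d}", "CUT", None,
                     int(rng.integers(200, 601)), None))
    for i in range(spec.n_sut):
        plan.append((f"SUT_{i + 1:03d}", "SUT", None,
                     int(rng.integers(200, 601)), None))
    if spec.rDNA_unit:
        plan.append(("RDN1", "rRNA_unit", None, 3000, None))

    # sequential packing with random gaps; flanking margin keeps every
    # counting window (+/-60 nt) inside the chromosome
    margin, min_gap = 80, 40
    order = rng.permutation(len(plan))
    total = sum(p[3] for p in plan)
    free = spec.chrom_length - total - 2 * margin - min_gap * (len(plan) + 1)
    if free < 0:
        worst = max(plan, key=lambda p: p[3])[1] if plan else "none"
        raise PackingError(
            f"cannot place {len(plan)} genes ({total} nt) in "
            f"{spec.chrom_length} nt chromosome; largest class: {worst}")
    extra = rng.multinomial(free, np.ones(len(plan) + 1) / (len(plan) + 1)) \
        if plan else np.array([free])

    seq_arr = _random_seq(rng, spec.chrom_length, spec.base_composition)
    rows, pos = [], margin + min_gap + int(extra[0])
    for slot, idx in enumerate(order):
        gene_id, cls, fam, length, intron = plan[idx]
        start, end = pos, pos + length
        strand = "+" if rng.random() < 0.5 else "-"
        if cls == "tRNA":
            gene_seq = fam_mature[fam]
            planted = gene_seq if strand == "+" else revcomp(gene_seq)
            seq_arr[start:end] = list(planted)
        if intron is not None:
            off, ilen = intron
            if strand == "+":
                istart = start + off
            else:
                istart = end - off - ilen
            intron_iv = (istart, istart + ilen)
        else:
            intron_iv = (math.nan, math.nan)
        rows.append({
            "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
            "strand": strand, "gene_class": cls, "family_id": fam,
            "mature_start": start if cls in ("tRNA", "snoRNA") else math.nan,
            "mature_end": end if cls in ("tRNA", "snoRNA") else math.nan,
            "intron_start": intron_iv[0], "intron_end": intron_iv[1],
        })
        pos = end + min_gap + int(extra[slot + 1])

    sequences = {chrom: "".join(seq_arr)}
    ann = AnnotationSet(pd.DataFrame(
        rows, columns=COLUMNS).sort_values("start").reset_index(drop=True))
    _check_unique_flanks(sequences, ann)
    design = {"family_mature": fam_mature, "spec": spec}
    return sequences, ann, design


def _check_unique_flanks(sequences: dict, ann: AnnotationSet,
                         flank: int = 15) -> None:
    """tRNA copies must be distinguishable by their 15-nt genomic context."""
    seen: dict[str, str] = {}
    for _, r in ann.by_class("tRNA").iterrows():
        chrom = sequences[r.chrom]
        ctx = chrom[int(r.start) - flank:int(r.start)] + \
            chrom[int(r.end):int(r.end) + flank]
        if ctx in seen:
            raise PackingError(
                f"tRNA flank collision between {seen[ctx]} and {r.gene_id}")
        seen[ctx] = r.gene_id


# ---------------------------------------------------------------------------
# library simulation


def _transcript_to_genomic(gene: pd.Series, t0: int, t1: int):
    """Map transcript-coordinate interval [t0, t1) to genomic half-open."""
    if gene.strand == "+":
        return int(gene.start) + t0, int(gene.start) + t1
    return int(gene.end) - t1, int(gene.end) - t0


def _anchor_t(gene: pd.Series, anchor: str) -> int:
    glen = int(gene.end) - int(gene.start)
    if anchor in ("5p", "TSS"):
        return 0
    if anchor == "3p":
        return glen
    if anchor == "mature3p":
        if pd.isna(gene.mature_end):
            return glen
        if gene.strand == "+":
            return int(gene.mature_end) - int(gene.start)
        return int(gene.end) - int(gene.mature_start)
    raise ValueError(anchor)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _boundary_ambiguous(gene, t0: int, t1: int, glen: int,
                        trna_flanks: dict, fam_members: dict) -> bool:
    a = max(0, -t0)  # 5' flank overlap, nt
    b = max(0, t1 - glen)  # 3' flank overlap
    if a == 0 and b == 0:
        return False
    left, right = trna_flanks[gene.gene_id]
    part = (left[len(left) - a:] if a else "", right[:b] if b else "")
    for sib in fam_members[gene.family_id]:
        if sib == gene.gene_id:
            continue
        sl, sr = trna_flanks[sib]
        if (sl[len(sl) - a:] if a else "", sr[:b] if b else "") == part:
            return True
    return False


def simulate_library(genome: dict, annotation: AnnotationSet,
                     model: BindingModel, n_molecules: int, seed: int,
                     collision_free: bool = True):
    """Simulate one CRAC library.

    Returns ``(reads, truth)``: a list of :class:`ReadRecord` in shuffled
    order and a truth DataFrame with one row per molecule. Resampling
    statistics are attached as ``truth.attrs``.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    df = annotation.df

    # per-gene sampling weights
    w = np.ones(len(df))
    if model.class_weights is not None:
        cw = df["gene_class"].map(
            lambda c: model.class_weights.get(c, 0.0)).to_numpy(float)
        counts = df["gene_class"].map(df["gene_class"].value_counts())
        w = cw / counts.to_numpy(float)
    if model.gene_weights is not None:
        w = w * df["gene_id"].map(
            lambda g: model.gene_weights.get(g, 1.0)).to_numpy(float)
    if w.sum() <= 0:
        raise ValueError("gene sampling weights sum to zero")
    w = w / w.sum()

    # transcript-oriented 15-nt flank context of every tRNA copy, used
    # to reject footprints whose flank overlap cannot identify the copy
    trna_flanks: dict = {}
    fam_members: dict = {}
    for _, g in df[df["gene_class"] == "tRNA"].iterrows():
        chrom_seq = genome[g.chrom]
        left = chrom_seq[max(0, int(g.start) - 15):int(g.start)]
        right = chrom_seq[int(g.end):int(g.end) + 15]
        if g.strand == "-":
            left, right = revcomp(right), revcomp(left)
        trna_flanks[g.gene_id] = (left, right)
        fam_members.setdefault(g.family_id, []).append(g.gene_id)

    gene_idx = rng.choice(len(df), size=n_molecules, p=w)
    seen_keys: set = set()
    truth_rows, reads = [], []
    n_resampled = 0

    for m, gi in enumerate(gene_idx):
        gene = df.iloc[gi]
        cls = gene.gene_class
        comps = model.mixtures.get(cls) or model.mixtures.get("*")
        if comps is None:
            raise ValueError(f"no mixture for class {cls!r}")
        cw_ = np.array([c.weight for c in comps])
        glen = int(gene.end) - int(gene.start)
        max_flank = 15 if cls == "tRNA" else 60
        chrom_seq = genome[gene.chrom]

        tailed = rng.random() < model.tail_prob.get(
            cls, model.tail_prob.get("*", 0.0))

        for attempt in range(200):
            comp = comps[rng.choice(len(comps), p=cw_)]
            t0 = _anchor_t(gene, comp.anchor) + comp.offset + \
                int(round(rng.normal(0.0, comp.sd)))
            fl = max(model.min_footprint,
                     int(round(rng.normal(*model.footprint_length))))
            t1 = t0 + fl
            if t0 < -max_flank or t1 > glen + max_flank:
                n_resampled += 1
                continue
            g0, g1 = _transcript_to_genomic(gene, t0, t1)
            if g0 < 0 or g1 > len(chrom_seq):
                n_resampled += 1
                continue
            if (cls == "tRNA" and model.distinguishable_boundaries
                    and _boundary_ambiguous(gene, t0, t1, glen,
                                            trna_flanks, fam_members)):
                # a sibling copy's flank matches every flank base this
                # footprint covers: no aligner could identify the copy,
                # so the planted truth label would be unattainable
                n_resampled += 1
                continue
            if tailed and model.distinguishable_tails:
                # require a non-A reference base just past the 3' end so
                # the planted tail length equals the observable
                # non-encoded length (no genomic absorption)
                if gene.strand == "+":
                    nxt = chrom_seq[g1:g1 + 1]
                else:
                    nxt = revcomp(chrom_seq[g0 - 1:g0]) if g0 > 0 else ""
                if nxt == "A" or nxt == "":
                    n_resampled += 1
                    continue
            break
        else:
            raise RuntimeError(
                f"could not place footprint on {gene.gene_id} "
                "after 200 attempts")

        insert = chrom_seq[g0:g1]
        if gene.strand == "-":
            insert = revcomp(insert)

        # one crosslink deletion max, uniform in the middle third
        del_pos = -1
        if rng.random() < model.deletion_prob and fl >= 6:
            d = int(rng.integers(fl // 3, 2 * fl // 3))
            if gene.strand == "+":
                del_pos = g0 + d
            else:
                del_pos = g1 - 1 - d
            insert = insert[:d] + insert[d + 1:]

        tail_len = 0
        if tailed:
            p = 1.0 / max(model.tail_length_mean - model.tail_min + 1, 1.0)
            tail_len = model.tail_min - 1 + int(rng.geometric(p))
        obs = _mutate(rng, insert + "A" * tail_len, model.error_rate)

        barcode = "".join(rng.choice(BASES, size=3))
        if collision_free:
            for _ in range(100):
                if (obs, barcode) not in seen_keys:
                    break
                barcode = "".join(rng.choice(BASES, size=3))
            else:
                raise RuntimeError("barcode space exhausted for collision"
                                   f" avoidance on {gene.gene_id}")
            seen_keys.add((obs, barcode))

        ncopies = int(rng.geometric(1.0 / model.pcr_duplication))
        mol_id = f"{model.sample_name}_m{m:06d}"
        for j in range(ncopies):
            if rng.random() < model.adapter_truncation_frac:
                adapter = model.adapter[:int(rng.integers(0, 4))]
            else:
                adapter = model.adapter
            seq = barcode + obs + adapter
            reads.append(ReadRecord(f"{mol_id}_d{j}", seq, "I" * len(seq)))

        if cls == "tRNA":
            inside = (g0 >= int(gene.mature_start)
                      and g1 <= int(gene.mature_end))
            flag = "mature" if inside else "precursor"
        else:
            flag = ""
        truth_rows.append({
            "molecule_id": mol_id, "source_gene": gene.gene_id,
            "start": g0, "end": g1, "strand": gene.strand,
            "precursor_or_mature": flag, "tail_length": tail_len,
            "dup_group_size": ncopies, "barcode": barcode,
            "deletion_pos": del_pos,
        })

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth.attrs["n_resampled"] = n_resampled
    return reads, truth


# ---------------------------------------------------------------------------
# serialization


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path):
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33)
                       for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq), qual))
    return out


def write_outputs(genome: dict, annotation: AnnotationSet, reads,
                  truth: pd.DataFrame, outdir: str | Path,
                  sample_name: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, outdir / "reference.fa")
    annotation.to_gff3(outdir / "annotation.gff3")
    write_fastq(reads, outdir / f"{sample_name}.fastq")
    truth.to_csv(outdir / f"{sample_name}.truth.tsv", sep="\t", index=False)
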