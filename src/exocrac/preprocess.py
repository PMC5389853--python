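"""Read pre-processing: adapter trimming, barcode extraction,
PCR-duplicate collapsing and low-complexity filtering.

The collapse rule is the CRAC convention: reads with identical ends
(identical insert sequence, or identical alignment coordinates in
mapped mode) and identical random nucleotides in the 5' barcode are
counted as one molecule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .records import ReadRecord

# rejection codes
EMPTY_READ = "empty_read"
NO_ADAPTER = "no_adapter"
TOO_SHORT = "too_short"
LINKER_MISMATCH = "linker_mismatch"
LOW_COMPLEXITY = "low_complexity"
LOW_QUALITY = "low_quality"


@dataclass
class BarcodeSpec:
    """5' linker layout: ``n_random`` random nt, then fixed linker bases."""

    n_random: int = 3
    fixed_linker: str = ""

    @property
    def total(self) -> int:
        return self.n_random + len(self.fixed_linker)


@dataclass
class PreprocessReport:
    """Counters and the collapse multiplicity table for one library."""

    n_input: int = 0
    n_trimmed: int = 0
    n_rejected: Counter = field(default_factory=Counter)
    n_collapsed: int = 0
    n_low_complexity: int = 0
    collapse_multiplicity: dict = field(default_factory=dict)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(read: ReadRecord, adapter: str, min_overlap: int = 4,
                 max_mismatch: int = 1):
    """Remove the best 3'-anchored adapter match from a read.

    The match must cover >= ``min_overlap`` adapter bases with
    <= ``max_mismatch`` mismatches; the longest qualifying match (the
    leftmost start) wins. Reads with no qualifying match are rejected,
    mirroring the retain-only-adapter-containing-reads rule.

    Returns ``(trimmed ReadRecord, None)`` or ``(None, code)``.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    if not read.sequence:
        return None, EMPTY_READ
    seq = read.sequence
    for i in range(0, len(seq) - min_overlap + 1):
        n = min(len(adapter), len(seq) - i)
        if _mismatches(seq[i:i + n], adapter[:n]) <= max_mismatch:
            return ReadRecord(read.read_id, seq[:i], read.quality[:i],
                              barcode=read.barcode, adapter_found=True,
                              trimmed_length=len(seq) - i), None
    return None, NO_ADAPTER


def extract_barcode(read: ReadRecord, spec: BarcodeSpec = BarcodeSpec()):
    """Move the 5' random barcode (plus any fixed linker) off the insert.

    Returns ``(ReadRecord with barcode set, None)`` or ``(None, code)``.
    """
    if len(read.sequence) <= spec.total:
        return None, TOO_SHORT
    barcode = read.sequence[:spec.n_random]
    fixed = read.sequence[spec.n_random:spec.total]
    if fixed != spec.fixed_linker:
        return None, LINKER_MISMATCH
    return ReadRecord(read.read_id, read.sequence[spec.total:],
                      read.quality[spec.total:], barcode=barcode,
                      adapter_found=read.adapter_found,
                      trimmed_length=read.trimmed_length), None


def dedup_key(read: ReadRecord, mode: str = "sequence",
              coords=None) -> tuple:
    if mode == "sequence":
        return (read.sequence, read.barcode)
    if mode == "coordinates":
        if coords is None or read.read_id not in coords:
            raise ValueError(f"no coordinates for {read.read_id}")
        return (coords[read.read_id], read.barcode)
    raise ValueError(f"unknown dedup mode {mode!r}")


def collapse_duplicates(reads, mode: str = "sequence", coords=None):
    """Collapse PCR duplicates to one representative per dedup key.

    Barcodes containing N never match another key (each N-carrying read
    keeps its own identity). Output is sorted by key, so collapsing is
    deterministic and idempotent.

    Returns ``(collapsed reads, {key: multiplicity})``.
    """
    groups: dict = {}
    n_amb = 0
    for r in reads:
        if r.barcode is None:
            raise ValueError(f"{r.read_id}: barcode not extracted")
        key = dedup_key(r, mode, coords)
        if "N" in r.barcode or (mode == "sequence" and "N" in r.sequence):
            key = key + (f"__N{n_amb}",)
            n_amb += 1
        if key in groups:
            groups[key][1] += 1
        else:
            groups[key] = [r, 1]
    collapsed, report = [], {}
    for key in sorted(groups):
        rep, mult = groups[key]
        collapsed.append(rep)
        report[key] = mult
    return collapsed, report


def longest_run(seq: str) -> int:
    """Length of the longest single-nucleotide run; N never extends one."""
    best = run = 0
    prev = None
    for c in seq:
        if c == "N":
            run, prev = 0, None
            continue
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def filter_low_complexity(read: ReadRecord, threshold: float = 0.75,
                          mode: str = "run") -> bool:
    """True if the read should be kept.

    ``run`` mode drops reads whose longest homopolymer run exceeds
    ``threshold`` of the read length; ``composition`` mode uses the
    maximum single-base frequency instead. Not applied in the tRNA
    alignment branch (tails would be discarded).
    """
    seq = read.sequence
    if not seq:
        raise ValueError("empty sequence")
    if mode == "run":
        frac = longest_run(seq) / len(seq)
    elif mode == "composition":
        frac = max(seq.count(b) for b in "ACGT") / len(seq)
    else:
        raise ValueError(f"unknown low-complexity mode {mode!r}")
    return frac <= threshold


def mean_quality(read: ReadRecord) -> float:
    return sum(ord(c) - 33 for c in read.quality) / len(read.quality)


def preprocess_reads(reads, adapter: str, barcode_spec=BarcodeSpec(),
                     min_overlap: int = 4, max_mismatch: int = 1,
                     lc_threshold: float = 0.75, lc_mode: str = "run",
                     apply_lc_filter: bool = True, min_quality: float = 0.0):
    """Full pre-processing pipeline: trim, extract barcode, collapse,
    then (optionally) drop low-complexity survivors.

    ``apply_lc_filter=False`` is the tRNA-database branch. Returns
    ``(reads, PreprocessReport)``.
    """
    report = PreprocessReport(n_input=len(reads))
    kept = []
    for r in reads:
        if min_quality > 0 and mean_quality(r) < min_quality:
            report.n_rejected[LOW_QUALITY] += 1
            continue
        trimmed, code = trim_adapter(r, adapter, min_overlap, max_mismatch)
        if trimmed is None:
            report.n_rejected[code] += 1
            continue
        bc, code = extract_barcode(trimmed, barcode_spec)
        if bc is None:
            report.n_rejected[code] += 1
            continue
        kept.append(bc)
    report.n_trimmed = len(kept)
    collapsed, mult = collapse_duplicates(kept)
    report.collapse_multiplicity = mult
    report.n_collapsed = len(collapsed)
    if apply_lc_filter:
        out = []
        for r in collapsed:
            if r.sequence and filter_low_complexity(r, lc_threshold, lc_mode):
                out.append(r)
            else:
                report.n_low_complexity += 1
        collapsed = out
    return collapsed, report


def write_collapse_report(report: PreprocessReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tmultiplicity\n")
        for key, mult in report.collapse_multiplicity.items():
            fh.write(f"{'|'.join(str(k) for k in key)}\t{mult}\n")
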