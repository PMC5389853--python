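"""Non-genomically-encoded 3' oligo(A) tail calling.

TRAMP oligo-adenylates exosome substrates, so reads whose 3' terminal
adenosines are absent from the genome mark TRAMP-tailed RNA. The caller
strips the maximal 3' A-run from the insert, aligns the remaining body,
then walks the reference downstream of the body's 3' end: reference A's
there could have templated part of the run and are subtracted
(genomic absorption). What remains is the non-encoded tail length.

A run followed by genomic A's is intrinsically ambiguous — absorption
makes the caller conservative there, and the false/missed-call rate on
A-rich contexts is a property of the data, not hidden by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .records import AlignmentRecord, revcomp

NO_BODY_ALIGNMENT = "body_unaligned"
SHORT_BODY = "short_body"


@dataclass
class TailCall:
    """Tail decision for one read."""

    read_id: str
    raw_run: int
    genomic_A: int
    nonencoded_len: int
    is_tailed: bool
    no_call: str | None = None  # rejection code when the body failed
    alignment: AlignmentRecord | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.nonencoded_len <= self.raw_run:
            raise ValueError("nonencoded_len outside [0, raw_run]")


def terminal_a_run(seq: str) -> int:
    """Length of the maximal 3' A-run (pure A, case-insensitive)."""
    n = 0
    for c in reversed(seq.upper()):
        if c != "A":
            break
        n += 1
    return n


def _downstream_a_run(references: dict, aln: AlignmentRecord,
                      limit: int) -> int:
    """Reference A's immediately downstream of the alignment 3' end,
    in transcript orientation, up to ``limit``."""
    ref = references[aln.reference_id]
    n = 0
    if aln.strand == "+":
        pos = aln.end
        while pos < len(ref) and n < limit and ref[pos].upper() == "A":
            n += 1
            pos += 1
    else:
        pos = aln.start - 1
        while pos >= 0 and n < limit and revcomp(ref[pos]) == "A":
            n += 1
            pos -= 1
    return n


def detect_oligoA(insert: str, references: dict, aligner,
                  read_id: str = "read", min_tail: int = 2,
                  min_body: int = 15) -> TailCall:
    """Call a non-encoded oligo(A) tail on one insert.

    ``aligner`` maps a body sequence to a list of
    :class:`AlignmentRecord` (e.g. ``MismatchAligner.align``); the first
    placement in its deterministic order is used for absorption.
    """
    if not insert:
        raise ValueError("empty insert")
    raw_run = terminal_a_run(insert)
    body = insert[:len(insert) - raw_run]
    if len(body) < min_body:
        return TailCall(read_id, raw_run, 0, 0, False, no_call=SHORT_BODY)
    hits = aligner(read_id, body)
    if not hits:
        return TailCall(read_id, raw_run, 0, 0, False,
                        no_call=NO_BODY_ALIGNMENT)
    aln = hits[0]
    # ties across identical gene copies can differ in flanking context;
    # the true origin is among them, so absorb with the most A-rich
    # tied context (conservative: never over-calls a tail)
    genomic_a = max(_downstream_a_run(references, h, raw_run)
                    for h in hits)
    nonencoded = raw_run - genomic_a
    return TailCall(read_id, raw_run, genomic_a, nonencoded,
                    nonencoded >= min_tail, alignment=aln)


def call_tails(reads, references: dict, aligner, min_tail: int = 2,
               min_body: int = 15) -> pd.DataFrame:
    """Tail table for a collection of reads (TSV-writable)."""
    rows = []
    for r in reads:
        call = detect_oligoA(r.sequence, references, aligner,
                             read_id=r.read_id, min_tail=min_tail,
                             min_body=min_body)
        rows.append({
            "read_id": call.read_id, "raw_run": call.raw_run,
            "genomic_A": call.genomic_A,
            "nonencoded_len": call.nonencoded_len,
            "is_tailed": call.is_tailed,
            "no_call": call.no_call or "",
        })
    return pd.DataFrame(rows, columns=[
        "read_id", "raw_run", "genomic_A", "nonencoded_len", "is_tailed",
        "no_call"])


def tailed_fraction(table: pd.DataFrame, over: str = "all") -> float:
    """Fraction of reads carrying a non-encoded tail.

    ``over="all"`` treats no-call reads as untailed (the stratification
    convention); ``over="callable"`` restricts the denominator to reads
    whose body aligned.
    """
    if over == "callable":
        table = table[table["no_call"] == ""]
    elif over != "all":
        raise ValueError(f"unknown denominator {over!r}")
    if table.empty:
        raise ValueError("no reads to summarize")
    return float(table["is_tailed"].mean())
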