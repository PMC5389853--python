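"""Read placement and pre-tRNA vs mature-tRNA classification.

Multi-copy tRNA families share an identical mature (gene-body) sequence
but unique genomic flanks. Against a database of tRNA genes extended by
15 nt on both sides, a read that maps uniquely must overlap a flank and
is counted as a pre-tRNA of that gene; a read tied across several
copies of one family is counted toward the mature pool of that family.
The external aligner's "random mapped" policy is replaced by keeping
all tied best placements and classifying on the tie count, which is
deterministic.

The built-in aligner is mismatch-only plus at most one 1-nt read
deletion — the reverse-transcription signature of a crosslink site. It
seeds candidate placements with exact k-mer matches (pigeonhole tiling,
so a read with at most ``max_mismatch`` substitutions over >= 4 seed
chunks cannot escape) and verifies candidates with vectorized mismatch
counting. A deletion costs 0.5 so that an ungapped placement at the
same mismatch count always outranks a gapped one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pysam

from .gff import AnnotationSet
from .records import AlignmentRecord, encode, revcomp

logger = logging.getLogger(__name__)

_PAD = 80  # sentinel run between concatenated entries; > any read length


@dataclass
class TrnaEntry:
    """One flanked tRNA gene: genomic gene sequence +/- flank nt, in
    transcript orientation."""

    gene_id: str
    family_id: str
    sequence: str
    mature_start: int  # entry-local, transcript orientation
    mature_end: int
    flank_left: int
    flank_right: int


class FlankedTrnaDB:
    """Database of tRNA genes with flanking context."""

    def __init__(self, entries: list[TrnaEntry]):
        if not entries:
            raise ValueError("empty tRNA database")
        self.entries = entries
        self.by_id = {e.gene_id: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> dict[str, str]:
        return {e.gene_id: e.sequence for e in self.entries}

    def family_of(self, gene_id: str) -> str:
        return self.by_id[gene_id].family_id

    def aligner(self, **kwargs) -> "MismatchAligner":
        return MismatchAligner(self.sequences(), **kwargs)


def build_flanked_trna_db(annotation: AnnotationSet, genome: dict,
                          flank: int = 15) -> FlankedTrnaDB:
    """Extract every tRNA gene with ``flank`` nt of genomic context."""
    entries = []
    for _, r in annotation.by_class("tRNA").iterrows():
        chrom = genome[r.chrom]
        left = min(flank, int(r.start))
        right = min(flank, len(chrom) - int(r.end))
        if left < flank or right < flank:
            warnings.warn(
                f"{r.gene_id}: flank clipped to ({left}, {right}) at "
                "chromosome edge")
        seq = chrom[int(r.start) - left:int(r.end) + right]
        if r.strand == "-":
            seq = revcomp(seq)
            left, right = right, left
        glen = int(r.end) - int(r.start)
        entries.append(TrnaEntry(
            gene_id=r.gene_id, family_id=r.family_id, sequence=seq,
            mature_start=left, mature_end=left + glen,
            flank_left=left, flank_right=right))
    return FlankedTrnaDB(entries)


class MismatchAligner:
    """Seed-and-verify aligner over a small set of references."""

    def __init__(self, references: dict[str, str], max_mismatch: int = 2,
                 allow_deletion: bool = True, max_softclip: int = 0,
                 min_aligned: int = 15, seed_len: int = 6,
                 deletion_penalty: float = 0.5):
        self.max_mismatch = max_mismatch
        self.allow_deletion = allow_deletion
        self.max_softclip = max_softclip
        self.min_aligned = min_aligned
        self.seed_len = seed_len
        self.deletion_penalty = deletion_penalty

        self.names = list(references)
        parts, offsets = [], []
        pos = _PAD
        for name in self.names:
            offsets.append(pos)
            arr = encode(references[name])
            parts.append(arr)
            pos += len(arr) + _PAD
        self.offsets = np.array(offsets)
        self.lengths = np.array([len(references[n]) for n in self.names])
        total = pos
        concat = np.zeros(total, dtype=np.uint8)
        for off, arr in zip(self.offsets, parts):
            concat[off:off + len(arr)] = arr
        self.concat = concat

        # exact k-mer index of the concatenated forward references
        k = self.seed_len
        self.index: dict[bytes, list[int]] = {}
        data = concat.tobytes()
        for off, length in zip(self.offsets, self.lengths):
            for p in range(off, off + length - k + 1):
                self.index.setdefault(data[p:p + k], []).append(p)

    # -- candidate generation --------------------------------------------

    def _candidates(self, read: np.ndarray) -> np.ndarray:
        k, L = self.seed_len, len(read)
        if L < k:
            return np.empty(0, dtype=int)
        starts = list(range(0, L - k + 1, k))
        if starts[-1] != L - k:
            starts.append(L - k)
        data = read.tobytes()
        cands: set[int] = set()
        for o in starts:
            for p in self.index.get(data[o:o + k], ()):
                c = p - o
                cands.update((c, c - 1))
        return np.array(sorted(cands), dtype=int)

    # -- verification ----------------------------------------------------

    def _verify(self, read: np.ndarray, starts: np.ndarray):
        """Score candidate placements; returns per-candidate arrays."""
        L = len(read)
        idx = starts[:, None] + np.arange(L + 1)
        W = self.concat[idx]
        valid = W != 0
        mmA = (W[:, :L] != read) & valid[:, :L]
        mm = mmA.sum(axis=1)
        aligned = valid[:, :L].sum(axis=1)
        sc = L - aligned
        straight_ok = (valid[:, 0] & (mm <= self.max_mismatch)
                       & (sc <= self.max_softclip)
                       & (aligned >= self.min_aligned))
        score = np.where(straight_ok, mm.astype(float), np.inf)
        dbest = np.full(len(starts), -1)

        # a deletion-mode placement consumes L+1 reference bases, so a
        # read one base short of min_aligned can still span a full
        # min_aligned-nt reference footprint
        if self.allow_deletion and L >= max(2, self.min_aligned - 1):
            W2 = W[:, 1:L + 1]
            valid2 = W2 != 0
            mmB = (W2 != read) & valid2
            cumA = np.cumsum(mmA, axis=1)
            cumB = np.cumsum(mmB, axis=1)
            totB = cumB[:, -1]
            # deletion at read position d in 1..L-1:
            # mm = mmA over [0,d) + mmB over [d,L)
            d = np.arange(1, L)
            mm_del = cumA[:, d - 1] + (totB[:, None] - cumB[:, d - 1])
            inside = valid[:, 0] & valid2[:, L - 1]  # no softclip in gap mode
            best_d = np.argmin(mm_del, axis=1)
            mmd = mm_del[np.arange(len(starts)), best_d]
            del_ok = inside & (mmd <= self.max_mismatch)
            del_score = np.where(del_ok, mmd + self.deletion_penalty, np.inf)
            use_del = del_score < score
            score = np.where(use_del, del_score, score)
            dbest = np.where(use_del, best_d + 1, -1)

        return score, dbest, mmA, sc

    def _records(self, read_id, read, starts, score, dbest, mmA, sc, strand,
                 best):
        recs = []
        for i in np.flatnonzero(np.abs(score - best) < 1e-9):
            s = int(starts[i])
            ref_i = int(np.searchsorted(self.offsets, s, side="right") - 1)
            local = s - int(self.offsets[ref_i])
            L = len(read)
            if dbest[i] >= 0:
                d = int(dbest[i])
                end = local + L + 1
                dels = (local + d,)
                W = self.concat[s:s + L + 1]
                subs = [local + j for j in range(d) if W[j] != read[j]]
                subs += [local + j + 1 for j in range(d, L)
                         if W[j + 1] != read[j]]
                clip = 0
            else:
                clip = int(sc[i])
                end = local + L - clip
                dels = ()
                subs = [local + j for j in np.flatnonzero(mmA[i])]
            recs.append(AlignmentRecord(
                read_id=read_id, reference_id=self.names[ref_i],
                start=local, end=end, strand=strand, n_hits=1,
                deletion_positions=dels,
                substitution_positions=tuple(int(x) for x in subs),
                softclip_3p=clip, score=float(score[i])))
        return recs

    def align(self, read_id: str, seq: str) -> list[AlignmentRecord]:
        """All placements tied at the best score, both strands.

        ``n_hits`` on every returned record equals the tie count.
        """
        min_len = self.min_aligned - (1 if self.allow_deletion else 0)
        if len(seq) < min_len:
            return []
        if len(seq) >= _PAD:
            raise ValueError(f"read longer than {_PAD - 1} nt unsupported")
        results = []
        best = np.inf
        per_strand = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            read = encode(s)
            starts = self._candidates(read)
            if len(starts) == 0:
                per_strand.append(None)
                continue
            score, dbest, mmA, sc = self._verify(read, starts)
            smin = score.min()
            best = min(best, smin)
            per_strand.append((read, starts, score, dbest, mmA, sc))
        if not np.isfinite(best):
            return []
        for strand, payload in zip("+-", per_strand):
            if payload is None:
                continue
            read, starts, score, dbest, mmA, sc = payload
            results.extend(self._records(
                read_id, read, starts, score, dbest, mmA, sc, strand, best))
        # collapse duplicate placements (same location reachable from
        # several seeds is already unique; c/c-1 duplicates are not)
        uniq = {}
        for r in results:
            key = (r.reference_id, r.start, r.strand)
            if key not in uniq or r.score < uniq[key].score:
                uniq[key] = r
        recs = sorted(uniq.values(),
                      key=lambda r: (r.reference_id, r.start, r.strand))
        for r in recs:
            r.n_hits = len(recs)
        return recs


def align_small_ref(insert: str, db: FlankedTrnaDB, max_mismatch: int = 2,
                    read_id: str = "read", **kwargs):
    """Align one insert against a flanked tRNA database."""
    return db.aligner(max_mismatch=max_mismatch, **kwargs).align(
        read_id, insert)


def classify_trna_read(alignments: list[AlignmentRecord],
                       db: FlankedTrnaDB):
    """Classify one read's hit set.

    Returns ``(kind, target)`` with kind in {"pre_tRNA", "mature",
    "unassigned"}; target is the gene id, family id, or an ambiguity
    code. Pure function of the (sense-strand) hit set.
    """
    sense = sorted((a for a in alignments if a.strand == "+"),
                   key=lambda a: (a.reference_id, a.start))
    if not sense:
        return ("unassigned", "no_hit")
    if len(sense) == 1:
        return ("pre_tRNA", sense[0].reference_id)
    families = {db.family_of(a.reference_id) for a in sense}
    if len(families) == 1:
        return ("mature", families.pop())
    return ("unassigned", "multi_family")


def ingest_sam(path: str):
    """Stream AlignmentRecords from a SAM/BAM file.

    Deletions come from CIGAR D operations, substitutions from the MD
    tag (via aligned pairs), multiplicity from NH. Unmapped and
    malformed records are skipped and counted; the counts are attached
    to the returned list as ``.attrs`` on the enclosing dict.
    """
    records = []
    skipped = {"unmapped": 0, "malformed": 0}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                skipped["unmapped"] += 1
                continue
            try:
                dels = []
                pos = aln.reference_start
                for op, ln in aln.cigartuples:
                    if op in (0, 7, 8):  # M/=/X
                        pos += ln
                    elif op == 2:  # D
                        dels.extend(range(pos, pos + ln))
                        pos += ln
                    elif op == 3:  # N
                        pos += ln
                subs = []
                if aln.has_tag("MD"):
                    for _, rpos, base in aln.get_aligned_pairs(
                            matches_only=True, with_seq=True):
                        if base is not None and base.islower():
                            subs.append(rpos)
                clip = 0
                if aln.cigartuples[-1][0] == 4:
                    clip = aln.cigartuples[-1][1]
                n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
                records.append(AlignmentRecord(
                    read_id=aln.query_name,
                    reference_id=aln.reference_name,
                    start=aln.reference_start, end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    n_hits=int(n_hits), deletion_positions=tuple(dels),
                    substitution_positions=tuple(subs), softclip_3p=clip))
            except (ValueError, TypeError, IndexError):
                skipped["malformed"] += 1
                logger.warning("skipping malformed record %s", aln.query_name)
    logger.info("ingest_sam: skipped %s", skipped)
    return records, skipped
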