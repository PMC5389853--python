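import numpy as np
import pytest

from exocrac import (MismatchAligner, build_flanked_trna_db,
                     classify_trna_read, ingest_sam, revcomp)
from exocrac.records import AlignmentRecord

from conftest import molecule_of
from oracles import oracle_align


class TestFlankedDb:
    def test_entry_length_is_gene_plus_flanks(self, toy, trna_db):
        _, ann, _ = toy
        for entry in trna_db.entries:
            gene = ann.gene(entry.gene_id)
            assert len(entry.sequence) == (gene.end - gene.start) + 30
            assert entry.mature_start == 15
            assert entry.mature_end == len(entry.sequence) - 15

    def test_zero_flank_equals_gene_sequence(self, toy):
        genome, ann, _ = toy
        db = build_flanked_trna_db(ann, genome, flank=0)
        gene = ann.by_class("tRNA").iloc[0]
        seq = genome[gene.chrom][gene.start:gene.end]
        if gene.strand == "-":
            seq = revcomp(seq)
        assert db.by_id[gene.gene_id].sequence == seq

    def test_family_members_differ_only_in_flanks(self, trna_db):
        by_family = {}
        for e in trna_db.entries:
            by_family.setdefault(e.family_id, []).append(e)
        for members in by_family.values():
            cores = {e.sequence[e.mature_start:e.mature_end]
                     for e in members}
            assert len(cores) == 1
            flanks = {(e.sequence[:15], e.sequence[-15:]) for e in members}
            assert len(flanks) == len(members)


class TestMismatchAligner:
    def test_unique_flank_spanning_read_single_hit(self, trna_db):
        entry = trna_db.entries[0]
        seq = entry.sequence[5:35]  # spans the 5' flank
        hits = trna_db.aligner().align("r", seq)
        assert len(hits) == 1
        assert hits[0].reference_id == entry.gene_id
        assert hits[0].start == 5 and hits[0].strand == "+"

    def test_shared_mature_core_ties_across_copies(self, trna_db):
        fam = trna_db.entries[0].family_id
        members = [e for e in trna_db.entries if e.family_id == fam]
        core = members[0].sequence[
            members[0].mature_start:members[0].mature_start + 30]
        hits = trna_db.aligner().align("r", core)
        assert len(hits) == len(members)
        assert all(h.n_hits == len(members) for h in hits)
        assert {h.reference_id for h in hits} == \
            {e.gene_id for e in members}

    def test_unalignable_read_returns_empty(self, trna_db):
        assert trna_db.aligner().align("r", "T" * 30) == []

    def test_deletion_recovered_at_planted_position(self, trna_db):
        entry = trna_db.entries[0]
        seq = entry.sequence[2:32]
        deleted = seq[:14] + seq[15:]  # drop position 16 of the entry
        hits = [h for h in trna_db.aligner().align("r", deleted)
                if h.reference_id == entry.gene_id]
        assert hits
        assert hits[0].deletion_positions == (16,)

    def test_agrees_with_bruteforce_oracle(self, toy, trna_db):
        """Hit sets identical to an all-positions scan over 300 reads
        carrying up to two substitutions or a deletion plus one."""
        genome, ann, _ = toy
        rng = np.random.default_rng(99)
        refs = trna_db.sequences()
        aligner = trna_db.aligner()
        names = list(refs)
        for _ in range(300):
            name = names[rng.integers(len(names))]
            ref = refs[name]
            L = 24
            start = int(rng.integers(0, len(ref) - L - 1))
            seq = ref[start:start + L]
            n_err = int(rng.integers(0, 3))
            with_del = bool(rng.integers(0, 2))
            arr = list(seq)
            for pos in rng.choice(L - 2, size=min(n_err, 2 if not with_del
                                                  else 1), replace=False):
                arr[pos + 1] = {"A": "C", "C": "G",
                                "G": "T", "T": "A"}[arr[pos + 1]]
            if with_del:
                d = int(rng.integers(8, 16))
                arr = arr[:d] + arr[d + 1:]
            if rng.integers(0, 2):
                query = revcomp("".join(arr))
            else:
                query = "".join(arr)
            got = {(h.reference_id, h.start, h.strand)
                   for h in aligner.align("r", query)}
            assert got == oracle_align(query, refs)


class TestClassify:
    def _rec(self, ref, start=10, strand="+"):
        return AlignmentRecord("r", ref, start, start + 20, strand=strand)

    def test_unique_hit_is_pre_trna_of_that_gene(self, trna_db):
        gene = trna_db.entries[0].gene_id
        kind, target = classify_trna_read([self._rec(gene)], trna_db)
        assert (kind, target) == ("pre_tRNA", gene)

    def test_family_multimapper_is_mature_of_family(self, trna_db):
        fam = trna_db.entries[0].family_id
        members = [e.gene_id for e in trna_db.entries
                   if e.family_id == fam]
        hits = [self._rec(g) for g in members]
        kind, target = classify_trna_read(hits, trna_db)
        assert (kind, target) == ("mature", fam)

    def test_no_hits_unassigned(self, trna_db):
        assert classify_trna_read([], trna_db)[0] == "unassigned"

    def test_cross_family_hits_ambiguous(self, trna_db):
        fams = {}
        for e in trna_db.entries:
            fams.setdefault(e.family_id, e.gene_id)
        two = list(fams.values())[:2]
        kind, target = classify_trna_read(
            [self._rec(g) for g in two], trna_db)
        assert (kind, target) == ("unassigned", "multi_family")

    def test_antisense_only_hits_not_counted(self, trna_db):
        gene = trna_db.entries[0].gene_id
        kind, _ = classify_trna_read(
            [self._rec(gene, strand="-")], trna_db)
        assert kind == "unassigned"

    def test_pipeline_accuracy_on_synthetic_library(
            self, toy, trna_db, trna_library):
        """Precursor reads resolve to the right gene (>=99%); reads
        wholly inside a multi-copy mature core resolve to the right
        family (100%)."""
        collapsed, truth, _ = trna_library
        aligner = trna_db.aligner()
        by_mol = truth.set_index("molecule_id")
        pre_ok = pre_n = mat_ok = mat_n = 0
        for r in collapsed:
            kind, target = classify_trna_read(
                aligner.align(r.read_id, r.sequence), trna_db)
            row = by_mol.loc[molecule_of(r.read_id)]
            if row.precursor_or_mature == "precursor":
                pre_n += 1
                pre_ok += (kind == "pre_tRNA"
                           and target == row.source_gene)
            else:
                mat_n += 1
                mat_ok += (kind == "mature"
                           and target == trna_db.family_of(row.source_gene))
        assert pre_ok / pre_n >= 0.99
        assert mat_ok == mat_n


class TestIngestSam:
    HEADER = "@HD\tVN:1.6\n@SQ\tSN:chrI\tLN:1000\n"

    def _write(self, tmp_path, lines):
        path = tmp_path / "toy.sam"
        path.write_text(self.HEADER + "".join(lines))
        return path

    def test_cigar_deletion_position(self, tmp_path):
        line = ("r1\t0\tchrI\t101\t60\t5M1D5M\t*\t0\t0\t"
                "ACGTAACGTA\t*\n")
        recs, _ = ingest_sam(self._write(tmp_path, [line]))
        assert recs[0].deletion_positions == (105,)
        assert recs[0].start == 100 and recs[0].end == 111

    def test_md_substitution_position(self, tmp_path):
        line = ("r2\t0\tchrI\t101\t60\t11M\t*\t0\t0\t"
                "ACGTAACGTAC\t*\tMD:Z:3C7\n")
        recs, _ = ingest_sam(self._write(tmp_path, [line]))
        assert recs[0].substitution_positions == (103,)

    def test_nh_tag_sets_n_hits(self, tmp_path):
        line = ("r3\t0\tchrI\t101\t60\t10M\t*\t0\t0\t"
                "ACGTAACGTA\t*\tNH:i:4\n")
        recs, _ = ingest_sam(self._write(tmp_path, [line]))
        assert recs[0].n_hits == 4

    def test_unmapped_records_skipped_and_counted(self, tmp_path):
        lines = ["r4\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n",
                 "r5\t0\tchrI\t1\t60\t4M\t*\t0\t0\tACGT\t*\n"]
        recs, skipped = ingest_sam(self._write(tmp_path, lines))
        assert len(recs) == 1
        assert skipped["unmapped"] == 1
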