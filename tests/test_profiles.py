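import numpy as np
import pandas as pd
import pytest

from exocrac import (BindingModel, metagene, pearson_matrix, pileup,
                     simulate_library, two_bin_fractions)
from exocrac.gff import COLUMNS, AnnotationSet
from exocrac.records import AlignmentRecord


def gene_row(start=100, end=200, strand="+", gene_id="g1",
             gene_class="snoRNA"):
    return pd.Series(dict(
        gene_id=gene_id, chrom="chrI", start=start, end=end, strand=strand,
        gene_class=gene_class, family_id=None,
        mature_start=start, mature_end=end,
        intron_start=np.nan, intron_end=np.nan))


def aln(start, end, strand="+", dels=(), subs=(), read_id="r"):
    return AlignmentRecord(read_id, "chrI", start, end, strand=strand,
                           deletion_positions=tuple(dels),
                           substitution_positions=tuple(subs))


class TestPileup:
    def test_single_read_covers_its_span(self):
        track = pileup([aln(105, 115)], gene_row())
        assert track.coverage[5:15].tolist() == [1.0] * 10
        assert track.coverage.sum() == 10

    def test_deletion_position_recorded(self):
        track = pileup([aln(105, 115, dels=[108])], gene_row())
        assert track.deletions[8] == 1
        assert track.deletions.sum() == 1

    def test_per_million_scaling_halves_at_2e6(self):
        track = pileup([aln(105, 115)], gene_row())
        scaled = track.scaled(2e6)
        np.testing.assert_allclose(scaled.coverage, track.coverage * 0.5)

    def test_minus_strand_track_is_transcript_oriented(self):
        g = gene_row(strand="-")
        track = pileup([aln(190, 200, strand="-")], g)
        # read at the genomic right edge = transcript 5' end
        assert track.coverage[:10].tolist() == [1.0] * 10
        assert track.coverage[10:].sum() == 0

    def test_ends_only_mode_counts_single_position(self):
        track = pileup([aln(105, 115)], gene_row(), mode="ends")
        assert track.coverage.sum() == 1
        assert track.coverage[5] == 1

    def test_antisense_reads_excluded(self):
        track = pileup([aln(105, 115, strand="-")], gene_row())
        assert track.coverage.sum() == 0


class TestMetagene:
    def _ann(self, rows):
        return AnnotationSet(pd.DataFrame(rows, columns=COLUMNS))

    def test_single_transcript_profile_equals_its_track(self):
        g = gene_row()
        ann = self._ann([g.to_dict()])
        track = pileup([aln(110, 130)], g)
        mm = metagene({"g1": track}, ann, anchor="5p", window=(0, 100))
        np.testing.assert_allclose(mm.profile.to_numpy(), track.coverage)
        assert mm.out_of_window == 0

    def test_anchored_hits_stack(self):
        g1 = gene_row(gene_id="g1", start=100, end=200)
        g2 = gene_row(gene_id="g2", start=400, end=520)
        ann = self._ann([g1.to_dict(), g2.to_dict()])
        tracks = {
            # one covered position at mature3p - 10 for each transcript
            "g1": pileup([aln(190, 191)], g1),
            "g2": pileup([aln(510, 511)], g2),
        }
        mm = metagene(tracks, ann, anchor="mature3p", window=(20, 5))
        assert mm.profile[-10] == 2.0
        assert mm.mass == 2.0

    def test_mass_conservation_on_synthetic_library(self, toy):
        """Matrix mass + out-of-window mass equals total pileup mass."""
        genome, ann, _ = toy
        model = BindingModel("s", class_weights={"tRNA": 1.0},
                             pcr_duplication=1.0)
        _, truth = simulate_library(genome, ann, model, 500, seed=47)
        alns = [AlignmentRecord(r.molecule_id, "chrI", r.start, r.end,
                                strand=r.strand)
                for r in truth.itertuples()]
        tracks = {}
        for _, g in ann.by_class("tRNA").iterrows():
            tracks[g.gene_id] = pileup(alns, g, flank=15)
        total = sum(t.mass for t in tracks.values())
        mm = metagene(tracks, ann, anchor="mature3p", window=(30, 10),
                      flank=15)
        assert mm.mass + mm.out_of_window == pytest.approx(total, abs=1e-9)

    def test_unresolvable_anchor_excluded_and_listed(self):
        g = gene_row(gene_id="g1", gene_class="mRNA")
        g["mature_start"] = np.nan
        g["mature_end"] = np.nan
        ann = self._ann([g.to_dict()])
        track = pileup([aln(110, 130)], g)
        mm = metagene({"g1": track}, ann, anchor="mature3p")
        assert mm.excluded == ["g1"]
        assert mm.matrix.empty

    def test_rows_ordered_by_descending_mature_length(self):
        g1 = gene_row(gene_id="short", start=100, end=160)
        g2 = gene_row(gene_id="long", start=400, end=520)
        ann = self._ann([g1.to_dict(), g2.to_dict()])
        tracks = {"short": pileup([], g1), "long": pileup([], g2)}
        mm = metagene(tracks, ann, anchor="5p")
        assert list(mm.matrix.index) == ["long", "short"]


class TestTwoBin:
    def _setup(self, hits_5p, hits_3p, length=70):
        g = gene_row(start=100, end=100 + length)
        ann = self._ann = AnnotationSet(
            pd.DataFrame([g.to_dict()], columns=COLUMNS))
        alns = [aln(100 + i % (length // 2), 101 + i % (length // 2),
                    read_id=f"a{i}") for i in range(hits_5p)]
        alns += [aln(100 + length // 2 + i % (length // 2),
                     101 + length // 2 + i % (length // 2),
                     read_id=f"b{i}") for i in range(hits_3p)]
        return {"g1": pileup(alns, g)}, ann

    def test_fraction_split_at_midpoint(self):
        tracks, ann = self._setup(30, 10)
        frac = two_bin_fractions(tracks, ann)
        assert frac.loc["g1", "frac_5p"] == pytest.approx(0.75)
        assert frac.loc["g1", "frac_3p"] == pytest.approx(0.25)

    def test_odd_length_extra_base_to_5p_bin(self):
        g = gene_row(start=100, end=171)  # 71 nt
        ann = AnnotationSet(pd.DataFrame([g.to_dict()], columns=COLUMNS))
        # single hit exactly at position 35 (the 36th base: 5' bin)
        tracks = {"g1": pileup([aln(135, 136)], g)}
        frac = two_bin_fractions(tracks, ann)
        assert frac.loc["g1", "frac_5p"] == 1.0

    def test_zero_hit_trnas_dropped(self):
        g = gene_row()
        ann = AnnotationSet(pd.DataFrame([g.to_dict()], columns=COLUMNS))
        frac = two_bin_fractions({"g1": pileup([], g)}, ann)
        assert frac.empty


class TestPearson:
    def _series(self, values):
        return pd.Series(values, index=[f"t{i}" for i in range(len(values))])

    def test_identical_vectors_r_one(self):
        v = self._series([0.2, 0.5, 0.9, 0.4])
        mat = pearson_matrix({"a": v, "b": v.copy()})
        assert mat.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_mirrored_vectors_r_minus_one(self):
        v = self._series([0.2, 0.5, 0.9, 0.4])
        mat = pearson_matrix({"a": v, "b": 1.0 - v})
        assert mat.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(6)
        samples = {s: self._series(rng.random(10)) for s in "abc"}
        mat = pearson_matrix(samples)
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 1.0)

    def test_fewer_than_three_shared_trnas_rejected(self):
        a = pd.Series([0.1, 0.2], index=["t1", "t2"])
        with pytest.raises(ValueError):
            pearson_matrix({"a": a, "b": a.copy()})


class TestDeletionRecovery:
    def test_pileup_deletions_match_planted_crosslinks(
            self, toy, trna_db, trna_library):
        """>= 95% of recovered deletion positions equal the planted
        crosslink site exactly."""
        collapsed, truth, _ = trna_library
        aligner = trna_db.aligner()
        by_mol = truth.set_index("molecule_id")
        exact = unambiguous = slipped_in_run = slipped_out = 0
        for r in collapsed:
            hits = aligner.align(r.read_id, r.sequence)
            if len(hits) != 1 or not hits[0].deletion_positions:
                continue
            mol = r.read_id.rsplit("_d", 1)[0]
            row = by_mol.loc[mol]
            if row.deletion_pos < 0 or \
                    hits[0].reference_id != row.source_gene:
                continue
            entry = trna_db.by_id[hits[0].reference_id]
            planted = _entry_local(toy, entry, row)
            run = _homopolymer_run(entry.sequence, planted)
            called = hits[0].deletion_positions[0]
            if len(run) == 1:
                unambiguous += 1
                exact += called == planted
            elif called in run:
                slipped_in_run += 1  # equivalent deletion, same sequence
            else:
                slipped_out += 1
        assert unambiguous >= 30
        assert exact / unambiguous >= 0.95
        # slippage stays inside the homopolymer run
        assert slipped_out <= 0.05 * (unambiguous + slipped_in_run)


def _homopolymer_run(seq, pos):
    base = seq[pos]
    lo = pos
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = pos
    while hi + 1 < len(seq) and seq[hi + 1] == base:
        hi += 1
    return range(lo, hi + 1)


def _entry_local(toy, entry, row):
    _, ann, _ = toy
    g = ann.gene(entry.gene_id)
    if g.strand == "+":
        return int(row.deletion_pos) - (int(g.start) - entry.flank_left)
    return (int(g.end) + entry.flank_left - 1) - int(row.deletion_pos)
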