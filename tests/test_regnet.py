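"""PWM parsing, LLR scanning with exact DP p-values, and pair designation."""

import io as _io
import itertools

import numpy as np
import pandas as pd
import pytest
from Bio import motifs as bio_motifs

from droughtlight import regnet, synth
from droughtlight.errors import MemeParseError, ValidationError
from droughtlight.regnet import (
    GRID_BITS,
    Pwm,
    ScoreDistribution,
    designate_pairs,
    load_packaged_pairs,
    packaged_motifs,
    read_meme_motifs,
    scan_sequence,
    summarize_pairs,
    tf_deg_fraction,
)

MEME_TWO = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF m1
letter-probability matrix: alength= 4 w= 1 nsites= 10 E= 0
1.0 0.0 0.0 0.0

MOTIF m2 familyX
letter-probability matrix: alength= 4 w= 2 nsites= 10 E= 0
0.5 0.5 0.0 0.0
0.0 0.0 0.5 0.5
"""


class TestMemeReader:
    def test_two_motifs_in_file_order_with_pseudocount(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        pwms = read_meme_motifs(path)
        assert [p.motif_id for p in pwms] == ["m1", "m2"]
        assert pwms[1].tf_family == "familyX"
        eps = 1e-4 / (1 + 4e-4)
        np.testing.assert_allclose(pwms[0].matrix[0],
                                   [(1 + 1e-4) / (1 + 4e-4), eps, eps, eps])
        assert np.all(pwms[0].matrix > 0)

    def test_bad_column_sum_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(MEME_TWO.replace("1.0 0.0 0.0 0.0", "0.8 0.0 0.0 0.0"))
        with pytest.raises(MemeParseError, match=r"line \d+"):
            read_meme_motifs(path)

    def test_non_dna_alphabet_rejected(self, tmp_path):
        path = tmp_path / "prot.meme"
        path.write_text(MEME_TWO.replace("ALPHABET= ACGT", "ALPHABET= ACDEFGHIKLMNPQRSTVWY"))
        with pytest.raises(MemeParseError, match="alphabet"):
            read_meme_motifs(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "x.meme"
        path.write_text("MOTIF m1\n")
        with pytest.raises(MemeParseError):
            read_meme_motifs(path)

    def test_agrees_with_biopython_minimal_parser(self, tmp_path):
        # independent cross-check: same probabilities up to the pseudocount
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        ours = read_meme_motifs(path, pseudocount=0.0)
        theirs = bio_motifs.parse(_io.StringIO(MEME_TWO), "minimal")
        for mine, other in zip(ours, theirs):
            counts = np.array([other.counts[b] for b in "ACGT"]).T
            np.testing.assert_allclose(
                mine.matrix, counts / counts.sum(axis=1, keepdims=True),
                atol=1e-9)


class TestScoreDistribution:
    def test_degenerate_dinucleotide_p_is_one_sixteenth(self):
        pwm = Pwm("AC", np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float))
        dist = ScoreDistribution(pwm, [0.25] * 4)
        assert dist.pvalue(4.0) == pytest.approx(1 / 16)

    @pytest.mark.parametrize("motif_index", range(6))
    def test_dp_equals_exhaustive_enumeration(self, motif_index):
        # every packaged motif has width <= 8: enumerate all 4^L words
        pwm = packaged_motifs()[motif_index]
        L = len(pwm)
        assert L <= 8
        dist = ScoreDistribution(pwm, [0.25] * 4)
        words = np.array(list(itertools.product(range(4), repeat=L)))
        scores = dist.table[np.arange(L)[None, :], words].sum(axis=1)
        weight = 0.25**L
        for s in np.unique(scores):
            brute = weight * (scores >= s).sum()
            assert dist.pvalue_int(int(s)) == pytest.approx(brute, abs=1e-12)

    def test_discretization_sandwich_bound_against_exact_scores(self):
        # the DP p at a word's discretized score is sandwiched between the
        # exact-score tail probabilities at s +/- L*grid/2 (rounding band)
        pwm = packaged_motifs()[0]
        L = len(pwm)
        bg = np.full(4, 0.25)
        exact = np.log2(pwm.matrix / bg[None, :])
        words = np.array(list(itertools.product(range(4), repeat=L)))
        exact_scores = exact[np.arange(L)[None, :], words].sum(axis=1)
        dist = ScoreDistribution(pwm, bg)
        int_scores = dist.table[np.arange(L)[None, :], words].sum(axis=1)
        weight = 0.25**L
        band = L * GRID_BITS / 2 + 1e-9
        for wi in range(0, len(words), 533):
            dp = dist.pvalue_int(int(int_scores[wi]))
            hi = weight * (exact_scores >= exact_scores[wi] - band).sum()
            lo = weight * (exact_scores >= exact_scores[wi] + band).sum()
            assert lo - 1e-12 <= dp <= hi + 1e-12

    def test_pvalue_monotone_in_score(self):
        dist = ScoreDistribution(packaged_motifs()[1], [0.25] * 4)
        scores = np.arange(dist.min_score, dist.min_score + len(dist.probs))
        ps = [dist.pvalue_int(int(s)) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_zero_background_rejected(self):
        with pytest.raises(ValidationError):
            ScoreDistribution(packaged_motifs()[0], [0.5, 0.5, 0.0, 0.0])


class TestScanSequence:
    def test_hit_at_planted_consensus(self):
        pwm = Pwm("AC", np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float))
        hits = scan_sequence(pwm, "GGACGG", p_threshold=0.1, sequence_id="s")
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]
        assert hits[0].score_bits == pytest.approx(4.0)
        assert hits[0].p == pytest.approx(1 / 16)

    def test_reverse_complement_sequence_mirrors_hits(self):
        pwm = packaged_motifs()[0]
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seq = seq[:100] + pwm.consensus + seq[100:]
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_sequence(pwm, seq, p_threshold=1e-3)
        rev = scan_sequence(pwm, rc, p_threshold=1e-3)
        assert len(fwd) == len(rev) >= 1
        L, n = len(pwm), len(seq)
        mirrored = sorted((n - h.offset - L, "+-"["+" == h.strand]) for h in rev)
        assert sorted((h.offset, h.strand) for h in fwd) == mirrored
        assert sorted(h.score_bits for h in fwd) == pytest.approx(
            sorted(h.score_bits for h in rev))

    def test_planted_site_from_simulator_recovered(self):
        pwm = packaged_motifs()[3]  # 8-bp motif
        records, truth = synth.simulate_promoter_set(
            3, length=600, planted=[(pwm.matrix, 1, 250, "+"),
                                    (pwm.matrix, 2, 77, "-")], seed=6)
        for planted in truth.params["planted"]:
            seq = str(records[planted["seq_index"]].seq)
            hits = scan_sequence(pwm, seq, p_threshold=1e-3)
            assert any(h.offset == planted["offset"] for h in hits), planted

    def test_windows_with_n_are_skipped(self):
        pwm = Pwm("AC", np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float))
        assert scan_sequence(pwm, "GNACNG".replace("AC", "AN"),
                             p_threshold=1.0) == []

    def test_motif_longer_than_sequence_gives_empty_result(self):
        pwm = packaged_motifs()[0]
        assert scan_sequence(pwm, "ACG", p_threshold=1.0) == []


class TestPairs:
    def _degs_frames(self):
        fixture = load_packaged_pairs()
        tf = pd.DataFrame(
            {"fold_change": [p.tf_fold_change for p in fixture],
             "fdr": [p.tf_fdr for p in fixture]},
            index=[p.tf_gene for p in fixture]).groupby(level=0).first()
        tgt = pd.DataFrame(
            {"fold_change": [p.target_fold_change for p in fixture],
             "fdr": [p.target_fdr for p in fixture]},
            index=[p.target_gene for p in fixture]).groupby(level=0).first()
        return fixture, tf, tgt

    def test_no_tf_degs_gives_no_pairs(self):
        _, _, tgt = self._degs_frames()
        empty_tf = pd.DataFrame(columns=["fold_change", "fdr"])
        hit = regnet.MotifHit("m", tgt.index[0], 0, "+", 10.0, 1e-6)
        assert designate_pairs(empty_tf, [hit], {"m": "TFX"}, tgt) == []

    def test_one_tf_hitting_two_promoters_gives_two_pairs(self):
        _, tf, tgt = self._degs_frames()
        tf_gene = tf.index[0]
        hits = [regnet.MotifHit("m", tgt.index[0], 5, "+", 9.0, 1e-5),
                regnet.MotifHit("m", tgt.index[1], 9, "-", 9.0, 1e-5)]
        pairs = designate_pairs(tf.iloc[[0]], hits, {"m": tf_gene}, tgt)
        assert len(pairs) == 2
        assert all(p.tf_gene == tf_gene and len(p.hits) == 1 for p in pairs)

    def test_unassigned_motif_warns_and_is_ignored(self):
        _, tf, tgt = self._degs_frames()
        hit = regnet.MotifHit("orphan", tgt.index[0], 0, "+", 8.0, 1e-5)
        with pytest.warns(UserWarning, match="no TF assignment"):
            assert designate_pairs(tf, [hit], {}, tgt) == []

    def test_pairs_sorted_by_tf_fold_change_ascending(self):
        fixture, tf, tgt = self._degs_frames()
        hits = [regnet.MotifHit(f"m{i}", p.target_gene, 0, "+", 9.0, 1e-5)
                for i, p in enumerate(fixture)]
        m2t = {f"m{i}": p.tf_gene for i, p in enumerate(fixture)}
        pairs = designate_pairs(tf, hits, m2t, tgt)
        fcs = [p.tf_fold_change for p in pairs]
        assert fcs == sorted(fcs)

    def test_packaged_pair_table_summary_counts(self):
        summary = summarize_pairs(load_packaged_pairs())
        assert summary["total"] == 17
        assert summary["by_family"]["bZIP"] == 6
        assert summary["by_family"]["MYB_related"] == 3
        assert summary["up_regulated_tfs"] == 8
        assert summary["down_regulated_tfs"] == 9

    def test_summary_totals_conserved(self):
        summary = summarize_pairs(load_packaged_pairs())
        assert sum(summary["by_family"].values()) == summary["total"]
        assert (summary["up_regulated_tfs"] + summary["down_regulated_tfs"]
                == summary["total"])
        assert summarize_pairs([]) == {
            "total": 0, "by_family": {}, "up_regulated_tfs": 0,
            "down_regulated_tfs": 0}

    def test_end_to_end_designation_reproduces_fixture_counts(self):
        # plant one synthetic motif per fixture pair in the corresponding
        # target promoter, scan, designate, summarize: the family/direction
        # counts of the published pair table must be reproduced
        fixture, tf, tgt = self._degs_frames()
        rng = np.random.default_rng(0)
        motifs, m2t, planted, seq_ids = [], {}, [], []
        targets = sorted({p.target_gene for p in fixture})
        # 12-bp near-degenerate motifs scanned at p <= 1e-6: only the exact
        # consensus qualifies, and a chance consensus match in the unplanted
        # background is vanishingly unlikely (4^-12 per window)
        onehot = []
        for i, pair in enumerate(fixture):
            cols = rng.integers(0, 4, 12)
            matrix = np.full((12, 4), 1e-3)
            matrix[np.arange(12), cols] = 1 - 3e-3
            motif = Pwm(f"syn_{i}", matrix, tf_family=pair.tf_family)
            motifs.append(motif)
            onehot.append(np.eye(4)[cols])
            m2t[motif.motif_id] = pair.tf_gene
        seq_ids = list(targets)
        for i, pair in enumerate(fixture):
            planted.append((onehot[i], targets.index(pair.target_gene),
                            40 * i + 5, "+"))
        records, _ = synth.simulate_promoter_set(
            len(targets), length=1000, planted=planted, seed=9, seq_ids=seq_ids)
        promoters = {r.id: str(r.seq) for r in records}
        hits = regnet.scan_promoters(motifs, promoters, p_threshold=1e-6)
        pairs = designate_pairs(
            tf, hits, m2t, tgt,
            tf_families={p.tf_gene: p.tf_family for p in fixture})
        summary = summarize_pairs(pairs)
        assert summary["total"] == 17
        assert summary["by_family"]["bZIP"] == 6
        assert summary["by_family"]["MYB_related"] == 3
        assert summary["up_regulated_tfs"] == 8
        assert summary["down_regulated_tfs"] == 9


class TestTfFraction:
    def test_printed_percentage(self):
        assert round(tf_deg_fraction(1438, [1762, 2408])) == 34

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            tf_deg_fraction(5, [0, 0])
        with pytest.raises(ValidationError):
            tf_deg_fraction(11, [5, 5])
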