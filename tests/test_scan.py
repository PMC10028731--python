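"""Log-odds scanning: exact DP p-values, BH q-values, promoter extraction
and report filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sigmascan as sg
from sigmascan.io import reverse_complement
from sigmascan.scan import (
    _int_scores,
    qvalues_against_pool,
    window_pvalues,
)
from tests.conftest import random_dna, random_ppm

UNIFORM = np.full(4, 0.25)


class TestLogOdds:
    def test_masked_column_scores_zero_without_smoothing(self):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        m = sg.MotifModel(probabilities=bg[None, :])
        mat = sg.log_odds_matrix(m, bg, smoothing=0.0)
        np.testing.assert_array_equal(mat.scores, 0.0)

    def test_smoothed_formula(self):
        m = sg.MotifModel(probabilities=np.array([[1.0, 0, 0, 0]]))
        mat = sg.log_odds_matrix(m, UNIFORM, smoothing=1e-4)
        assert mat.scores[0, 0] == pytest.approx(np.log2(1.0001 / 0.2501))
        assert mat.scores[0, 1] == pytest.approx(np.log2(0.0001 / 0.2501))

    def test_zero_probability_without_smoothing_rejected(self):
        m = sg.MotifModel(probabilities=np.array([[1.0, 0, 0, 0]]))
        with pytest.raises(ValueError):
            sg.log_odds_matrix(m, UNIFORM, smoothing=0.0)


class TestScoreDistribution:
    def test_single_position_best_letter_pvalue(self):
        m = sg.MotifModel(probabilities=np.array([[0.4, 0.3, 0.2, 0.1]]))
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        si = _int_scores(mat, dist.step)
        assert dist.pvalue_of_int(int(si[0].max())) == pytest.approx(0.25)

    def test_full_support_pvalue_is_one(self, rng):
        m = sg.MotifModel(probabilities=random_ppm(rng, 4))
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        assert dist.pvalue_of_int(dist.min_score) == 1.0

    def test_tail_nonincreasing(self, rng):
        m = sg.MotifModel(probabilities=random_ppm(rng, 5))
        bg = rng.dirichlet(np.ones(4) * 3)
        mat = sg.log_odds_matrix(m, bg)
        dist = sg.score_distribution(mat, bg)
        assert np.all(np.diff(dist.tail) <= 1e-15)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_step_must_be_positive(self, rng):
        m = sg.MotifModel(probabilities=random_ppm(rng, 3))
        mat = sg.log_odds_matrix(m, UNIFORM)
        with pytest.raises(ValueError):
            sg.score_distribution(mat, UNIFORM, step=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        w = int(rng.integers(2, 7))
        m = sg.MotifModel(probabilities=random_ppm(rng, w))
        bg = rng.dirichlet(np.ones(4) * 5)
        mat = sg.log_odds_matrix(m, bg)
        dist = sg.score_distribution(mat, bg)
        si = _int_scores(mat, dist.step)
        words = np.array(list(itertools.product(range(4), repeat=w)))
        scores = si[np.arange(w), words].sum(axis=1)
        probs = np.prod(bg[words], axis=1)
        for k in (0, dist.pmf.size // 2, dist.pmf.size - 1):
            t = dist.min_score + k
            np.testing.assert_allclose(
                probs[scores >= t].sum(), dist.tail[k], atol=1e-12
            )


class TestScanSequence:
    def _matrix(self, rng, width=10, strength=0.85):
        p = np.full((width, 4), (1 - strength) / 3)
        letters = rng.integers(0, 4, width)
        p[np.arange(width), letters] = strength
        return sg.MotifModel(probabilities=p)

    def test_stringent_threshold_empty(self, rng):
        m = self._matrix(rng)
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        hits = sg.scan_sequence(mat, dist, random_dna(rng, 500), p_threshold=1e-12)
        assert hits == []

    def test_planted_consensus_is_best_hit(self, rng):
        m = self._matrix(rng)
        cons = m.consensus()
        seq = random_dna(rng, 2000)
        seq = seq[:200] + cons + seq[210:]
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        hits = sg.scan_sequence(mat, dist, seq, p_threshold=1e-3)
        best = hits[0]
        assert best.start == 200 and best.strand == "+"
        si = _int_scores(mat, dist.step)
        assert best.score == pytest.approx(si.max(axis=1).sum() * dist.step)

    def test_palindromic_matrix_equal_strand_scores(self):
        p = np.array(
            [[0.7, 0.1, 0.1, 0.1],
             [0.1, 0.6, 0.2, 0.1],
             [0.1, 0.2, 0.6, 0.1],
             [0.1, 0.1, 0.1, 0.7]]
        )  # column-reverse-complement symmetric
        m = sg.MotifModel(probabilities=p)
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        seq = "ACGTACGTGGCCAATT"
        hits = sg.scan_sequence(mat, dist, seq, p_threshold=1.0)
        by_pos = {}
        for h in hits:
            by_pos.setdefault(h.start, {})[h.strand] = h.score
        for pos, d in by_pos.items():
            assert set(d) == {"+", "-"}
            assert d["+"] == pytest.approx(d["-"])

    def test_minus_strand_site_reported_in_forward_coordinates(self, rng):
        m = self._matrix(rng)
        cons = m.consensus()
        seq = random_dna(rng, 600)
        seq = seq[:300] + reverse_complement(cons) + seq[310:]
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        hits = sg.scan_sequence(mat, dist, seq, p_threshold=1e-3)
        best = hits[0]
        assert (best.start, best.strand, best.matched_seq) == (300, "-", cons)

    def test_ambiguous_windows_skipped(self, rng):
        m = self._matrix(rng, width=4)
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        seq = m.consensus() + "N" + m.consensus()
        hits = sg.scan_sequence(mat, dist, seq, p_threshold=1.0)
        assert all("N" not in h.matched_seq for h in hits)

    def test_case_insensitive(self, rng):
        m = self._matrix(rng)
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        seq = random_dna(rng, 300)
        upper = sg.scan_sequence(mat, dist, seq, p_threshold=0.5)
        lower = sg.scan_sequence(mat, dist, seq.lower(), p_threshold=0.5)
        assert [(h.start, h.strand, h.score) for h in upper] == [
            (h.start, h.strand, h.score) for h in lower
        ]

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 5_000))
    def test_strand_coherence_under_reverse_complement(self, seed):
        rng = np.random.default_rng(seed)
        m = sg.MotifModel(probabilities=random_ppm(rng, 6))
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        seq = random_dna(rng, 120)
        fwd = sg.scan_sequence(mat, dist, seq, p_threshold=0.05)
        rev = sg.scan_sequence(mat, dist, reverse_complement(seq), p_threshold=0.05)
        L = len(seq)
        mirrored = sorted(
            (L - h.end, "+" if h.strand == "-" else "-", round(h.score, 6))
            for h in rev
        )
        assert mirrored == sorted((h.start, h.strand, round(h.score, 6)) for h in fwd)

    def test_pvalue_monotone_in_score(self, rng):
        m = sg.MotifModel(probabilities=random_ppm(rng, 8))
        mat = sg.log_odds_matrix(m, UNIFORM)
        dist = sg.score_distribution(mat, UNIFORM)
        hits = sg.scan_sequence(mat, dist, random_dna(rng, 400), p_threshold=1.0)
        hits.sort(key=lambda h: h.score)
        for a, b in zip(hits, hits[1:]):
            assert a.p_value >= b.p_value


class TestBH:
    def test_single_pvalue(self):
        np.testing.assert_allclose(sg.bh_qvalues([0.05]), [0.05])

    def test_hand_computation(self):
        np.testing.assert_allclose(sg.bh_qvalues([0.01, 0.02, 0.03]), [0.03] * 3)

    def test_saturated(self):
        np.testing.assert_allclose(sg.bh_qvalues([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.5], [-0.1]):
            with pytest.raises(ValueError):
                sg.bh_qvalues(bad)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 400))
    def test_matches_statsmodels(self, seed, n):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-8, 1.0, size=n)
        ours = sg.bh_qvalues(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_pool_lookup_consistent_with_direct_bh(self, rng):
        pool = rng.uniform(1e-6, 1.0, size=500)
        q_direct = sg.bh_qvalues(pool)
        sel = pool[:20]
        q_pool = qvalues_against_pool(sel, pool)
        np.testing.assert_allclose(q_pool, q_direct[:20], atol=1e-12)


class TestPromoters:
    GENOME = {"chr1": "".join("ACGT"[i % 4] for i in range(10_000))}

    def _ann(self, start, end, strand):
        return pd.DataFrame(
            [dict(gene_id="g", chrom="chr1", start=start, end=end, strand=strand)]
        )

    def test_plus_strand_upstream_window(self):
        (rec,) = sg.extract_promoters(self._ann(500, 900, "+"), self.GENOME)
        assert (rec.start, rec.end, rec.truncated) == (400, 500, False)
        assert rec.sequence == self.GENOME["chr1"][400:500]

    def test_plus_strand_truncated_at_contig_start(self):
        (rec,) = sg.extract_promoters(self._ann(40, 200, "+"), self.GENOME)
        assert (rec.start, rec.end, rec.truncated) == (0, 40, True)

    def test_minus_strand_reverse_complement(self):
        (rec,) = sg.extract_promoters(self._ann(500, 900, "-"), self.GENOME)
        assert (rec.start, rec.end) == (900, 1000)
        assert rec.sequence == reverse_complement(self.GENOME["chr1"][900:1000])

    def test_cds_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            sg.extract_promoters(self._ann(9_000, 11_000, "+"), self.GENOME)


class TestScanReport:
    def _hits(self):
        return [
            sg.ScanHit("a", 0, 5, "+", 10.0, 1e-6, "AAAAA", q_value=0.01),
            sg.ScanHit("b", 3, 8, "-", 8.0, 1e-4, "CCCCC", q_value=0.7),
        ]

    def test_filter_semantics(self):
        filtered, full = sg.scan_report(self._hits(), q_threshold=0.6)
        assert len(full) == 2 and len(filtered) == 1
        assert filtered.iloc[0].seq_id == "a"

    def test_saturating_threshold_keeps_all(self):
        filtered, full = sg.scan_report(self._hits(), q_threshold=1.0)
        pd.testing.assert_frame_equal(filtered, full)

    def test_empty(self):
        filtered, full = sg.scan_report([], q_threshold=0.6)
        assert filtered.empty and full.empty


class TestMaskedScanning:
    def test_masked_columns_contribute_nothing(self, sigma_motif):
        """Columns masked with the query's own composition add exactly zero
        bits to every window score."""
        rng = np.random.default_rng(0)
        query = random_dna(rng, 400)
        bg = sg.background_composition(query)
        masked = sg.mask_motif(sigma_motif, bg)
        assert masked.masked_positions  # the spacer columns
        mat = sg.log_odds_matrix(masked, bg)
        for i in masked.masked_positions:
            np.testing.assert_array_equal(mat.scores[i], 0.0)

    def test_query_background_screen_recovers_planted_promoters(self, sigma_motif):
        """Three promoters carrying planted sites are the full filtered
        report at default thresholds."""
        cfg = sg.SyntheticRegulonConfig(seed=77)
        genome, truth, _, _ = sg.simulate_regulon(cfg)
        proms = sg.extract_promoters(
            truth.gene_records, {"synthetic_chr": genome}, 100
        )
        queries = {p.fasta_id: p.sequence for p in proms}
        gene_of = {p.fasta_id: p.gene_id for p in proms}
        hits, pool = sg.scan_queries(sigma_motif, queries)
        filtered, full = sg.scan_report(hits, q_threshold=0.6)
        found_genes = {gene_of[s] for s in filtered.seq_id}
        expected = set(
            truth.gene_records[truth.gene_records.has_planted_site_in_promoter].gene_id
        )
        assert found_genes == expected
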