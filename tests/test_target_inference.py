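"""Co-expression filtering and exact-p motif scanning."""

import numpy as np
import pandas as pd
import pytest
from conftest import enumerate_word_scores, enumeration_pvalue
from scipy import stats

from arfnet.io_formats import PWMDefinition, SequenceRecord, reverse_complement
from arfnet.target_inference import (
    coexpression_filter,
    filter_by_motif,
    log_odds_matrix,
    scan_promoters,
    score_distribution,
)

UNIFORM = np.full(4, 0.25)


def random_pwm(rng, width):
    return PWMDefinition(f"m{width}", rng.dirichlet(np.ones(4) * 0.7, size=width))


class TestCoexpressionFilter:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(8)
        m = 10
        q = rng.standard_normal(m)
        rows = {
            "query": q,
            "strong_pos": q + rng.standard_normal(m) * 0.3,
            "strong_neg": -q + rng.standard_normal(m) * 0.2,
            "noise": rng.standard_normal(m),
            "clone": q.copy(),
            "flat": np.ones(m),
        }
        return pd.DataFrame(rows).T

    def test_self_and_duplicate_vectors_excluded(self, matrix):
        got = coexpression_filter(matrix, ["query"], r_min=0.0, p_max=1.0)
        assert "query" not in got.genes
        assert "clone" not in got.genes

    def test_signed_threshold_excludes_negative_correlation(self, matrix):
        got = coexpression_filter(matrix, ["query"], r_min=0.7, p_max=1.0)
        assert "strong_neg" not in got.genes
        # sanity: it is strongly anti-correlated
        r = np.corrcoef(matrix.loc["query"], matrix.loc["strong_neg"])[0, 1]
        assert r < -0.7

    def test_constant_vector_skipped(self, matrix):
        got = coexpression_filter(matrix, ["query"], r_min=-1.0 + 1e-9, p_max=1.0)
        assert "flat" not in got.genes

    def test_pvalue_matches_t_transform_and_pearsonr(self, matrix):
        got = coexpression_filter(matrix, ["query"], r_min=0.5, p_max=1.0)
        r, p = got.stats["strong_pos"]
        r_ref, p_ref = stats.pearsonr(matrix.loc["query"], matrix.loc["strong_pos"])
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)
        m = matrix.shape[1]
        t = r * np.sqrt((m - 2) / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), m - 2), rel=1e-12)

    def test_output_monotone_in_r_min(self, matrix):
        loose = coexpression_filter(matrix, ["query"], r_min=0.3, p_max=1.0).genes
        tight = coexpression_filter(matrix, ["query"], r_min=0.9, p_max=1.0).genes
        assert tight <= loose

    def test_precomputed_table_input(self):
        table = pd.DataFrame(
            {
                "query_gene": ["q", "q", "q", "other"],
                "partner_gene": ["a", "b", "q", "c"],
                "r": [0.9, 0.6, 0.99, 0.95],
                "p": [0.001, 0.001, 0.001, 0.001],
            }
        )
        got = coexpression_filter(table, ["q"])
        assert got.genes == {"a"}  # b below r_min, self excluded, other query ignored

    def test_top_k_cap(self):
        rng = np.random.default_rng(1)
        m = 30
        q = rng.standard_normal(m)
        rows = {"q": q}
        for i in range(10):
            rows[f"g{i}"] = q + rng.standard_normal(m) * 0.1
        df = pd.DataFrame(rows).T
        got = coexpression_filter(df, ["q"], top_k=3)
        assert len(got.genes) == 3


class TestScoreDistribution:
    def test_uniform_pwm_scores_zero_against_uniform_background(self):
        pwm = PWMDefinition("flat", np.full((6, 4), 0.25))
        lom = log_odds_matrix(pwm, UNIFORM, pseudocount=0.0)
        assert np.allclose(lom, 0.0)
        scores, tail = score_distribution(lom, UNIFORM)
        assert len(scores) == 1 and scores[0] == 0.0 and tail[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [4, 5, 6, 7, 8])
    def test_dp_equals_enumeration(self, width):
        rng = np.random.default_rng(width)
        for _ in range(3):
            pwm = random_pwm(rng, width)
            bg = rng.dirichlet(np.ones(4) * 4)
            lom = log_odds_matrix(pwm, bg)
            scores, tail = score_distribution(lom, bg)
            word_scores, word_probs = enumerate_word_scores(lom, bg)
            # the supports coincide exactly
            assert set(scores) == set(word_scores)
            # spot-check tail probabilities across the support
            for s in scores[:: max(1, len(scores) // 25)]:
                p_dp = tail[np.searchsorted(scores, s, side="left")]
                assert p_dp == pytest.approx(word_probs[word_scores >= s].sum(), abs=1e-12)

    def test_distribution_sums_to_one(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 6)
        lom = log_odds_matrix(pwm, UNIFORM)
        scores, tail = score_distribution(lom, UNIFORM)
        assert tail[0] == pytest.approx(1.0, abs=1e-12)

    def test_binned_fallback_close_to_exact(self):
        rng = np.random.default_rng(9)
        pwm = random_pwm(rng, 6)
        lom = log_odds_matrix(pwm, UNIFORM)
        exact_scores, exact_tail = score_distribution(lom, UNIFORM)
        from arfnet.target_inference import _binned_distribution

        b_scores, b_tail = _binned_distribution(lom, UNIFORM)
        # compare tails at a common probe grid
        for s in exact_scores[:: max(1, len(exact_scores) // 10)]:
            p_exact = exact_tail[np.searchsorted(exact_scores, s, side="left")]
            idx = np.searchsorted(b_scores, s - 1e-6, side="left")
            p_binned = b_tail[idx] if idx < len(b_scores) else 0.0
            # boundary words may shift by one lattice cell; at width 6 a
            # single word carries 0.25^6 ~ 2.4e-4 of mass
            assert p_binned == pytest.approx(p_exact, abs=1e-3)


class TestScanPromoters:
    def test_uniform_pwm_yields_no_hits(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 500))
        pwm = PWMDefinition("flat", np.full((6, 4), 0.25))
        hits = scan_promoters(
            [SequenceRecord("g", "", seq)], pwm, background=UNIFORM,
            p_max=0.5, pseudocount=0.0,
        )
        assert hits == []

    @pytest.fixture
    def planted(self):
        rng = np.random.default_rng(42)
        pwm = PWMDefinition(
            "sharp",
            np.array([[0.97, 0.01, 0.01, 0.01]] * 3 + [[0.01, 0.01, 0.01, 0.97]] * 3),
        )
        consensus = pwm.consensus()  # AAATTT
        seq = list(rng.choice(list("ACGT"), 3000))
        seq[100:106] = list(consensus)
        return pwm, "".join(seq)

    def test_planted_consensus_found_with_enumeration_pvalue(self, planted):
        pwm, seq = planted
        hits = scan_promoters(
            [SequenceRecord("g", "", seq)], pwm, background=UNIFORM, p_max=1e-3
        )
        fwd = [h for h in hits if h.strand == "+"]
        best = min(fwd, key=lambda h: h.p)
        assert best.start == 100
        lom = log_odds_matrix(pwm, UNIFORM)
        assert best.p == pytest.approx(
            enumeration_pvalue(lom, UNIFORM, best.score), abs=1e-12
        )

    def test_reverse_complement_plant_same_score_minus_strand(self, planted):
        pwm, seq = planted
        rc_site = reverse_complement(pwm.consensus())
        seq2 = seq[:1000] + rc_site + seq[1006:]
        hits = scan_promoters(
            [SequenceRecord("g", "", seq2)], pwm, background=UNIFORM, p_max=1e-3
        )
        minus = [h for h in hits if h.strand == "-" and h.start == 1000]
        plus_best = min(
            (h for h in hits if h.strand == "+" and h.start == 100), key=lambda h: h.p
        )
        assert len(minus) == 1
        assert minus[0].score == pytest.approx(plus_best.score)
        assert minus[0].p == pytest.approx(plus_best.p)

    def test_scanning_reverse_complement_mirrors_hits(self, planted):
        pwm, seq = planted
        fwd_hits = scan_promoters(
            [SequenceRecord("g", "", seq)], pwm, background=UNIFORM, p_max=1e-3
        )
        rc_hits = scan_promoters(
            [SequenceRecord("g", "", reverse_complement(seq))],
            pwm, background=UNIFORM, p_max=1e-3,
        )
        L, w = len(seq), pwm.width
        mirrored = {(L - w - h.start, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
                    for h in rc_hits}
        assert {(h.start, h.strand, round(h.score, 9)) for h in fwd_hits} == mirrored

    def test_windows_with_n_never_hit(self):
        pwm = PWMDefinition(
            "sharp", np.array([[0.97, 0.01, 0.01, 0.01]] * 4)
        )
        seq = "AANAAAA"  # every window of width 4 except the last contains N
        hits = scan_promoters(
            [SequenceRecord("g", "", seq)], pwm, background=UNIFORM, p_max=1.0,
            strand_policy="forward",
        )
        assert {h.start for h in hits} == {3}

    def test_hit_count_monotone_in_p_max(self, planted):
        pwm, seq = planted
        rec = [SequenceRecord("g", "", seq)]
        n_loose = len(scan_promoters(rec, pwm, background=UNIFORM, p_max=1e-2))
        n_tight = len(scan_promoters(rec, pwm, background=UNIFORM, p_max=1e-4))
        assert n_tight <= n_loose

    def test_bad_background_rejected(self, planted):
        pwm, seq = planted
        with pytest.raises(ValueError, match="background"):
            scan_promoters(
                [SequenceRecord("g", "", seq)], pwm, background=np.array([0.5, 0.5, 0.5, 0.5])
            )


class TestFilterByMotif:
    def test_no_hits_gives_empty_target_set(self):
        from arfnet.go_mining import GeneSet

        got = filter_by_motif(GeneSet("q", {"a", "b"}), [], promoter_ids={"a", "b"})
        assert len(got) == 0

    def test_planted_fixture_selects_exactly_planted_genes(self):
        from arfnet.synthetic_data import (
            SimulationSpec,
            default_auxre_pwm,
            generate_promoters,
        )
        from arfnet.go_mining import GeneSet

        spec = SimulationSpec(seed=21, n_genes=5)
        pwm = default_auxre_pwm()
        planted = ["G0002", "G0004"]
        recs, truth = generate_promoters(spec, pwm, planted)
        coexpressed = GeneSet("q", set(spec.gene_ids()))
        hits = scan_promoters(recs, pwm, p_max=1e-5)
        got = filter_by_motif(coexpressed, hits, promoter_ids=set(spec.gene_ids()))
        assert got.genes == set(planted)
        assert set(truth.gene) == set(planted)
        for g in planted:
            best = got.provenance[g]["best_hit"]
            row = truth[truth.gene == g].iloc[0]
            assert best.start == row.offset and best.strand == row.strand

    def test_missing_promoter_counted_and_dropped(self):
        from arfnet.go_mining import GeneSet

        got = filter_by_motif(GeneSet("q", {"a", "b"}), [], promoter_ids={"a"})
        assert got.n_no_promoter == 1
        assert "b" not in got.genes
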