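import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combotx.errors import ConfigurationError, DomainError, NoOverlapError
from combotx.gsea import (
    GeneSet,
    RankedList,
    TwoClassExpression,
    enrichment_score,
    phenotype_permutation_gsea,
    preranked_gsea,
    read_gmt,
    signal_to_noise_ranking,
    write_gmt,
)
from conftest import brute_force_es


def random_ranked(rng, n=30):
    genes = [f"g{i}" for i in range(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    return RankedList(tuple(genes), scores)


class TestGmtIO:
    def test_parses_standard_line(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("S1\tdesc\tA\tB\tC\n")
        sets = read_gmt(path)
        assert sets[0].name == "S1" and sets[0].members == ("A", "B", "C")

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\tA\nS2\tonly_desc\n")
        with pytest.raises(DomainError, match="2"):
            read_gmt(path)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        assert read_gmt(path) == []

    def test_duplicate_members_deduplicated_with_warning(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\tdesc\tA\tB\tA\n")
        with pytest.warns(UserWarning):
            sets = read_gmt(path)
        assert sets[0].members == ("A", "B")

    def test_round_trip_preserves_sets(self, tmp_path, rng):
        sets = [
            GeneSet(f"S{k}", tuple(f"g{i}" for i in rng.choice(50, 5 + k, replace=False)))
            for k in range(4)
        ]
        path = tmp_path / "rt.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets


class TestEnrichmentScore:
    def test_top_block_set_reaches_unity_unweighted(self):
        """A set occupying exactly the top k positions drives the sum to +1."""
        ranked = random_ranked(np.random.default_rng(1), n=20)
        gene_set = GeneSet("top", ranked.genes[:5])
        profile = enrichment_score(ranked, gene_set, weight_p=0.0)
        assert profile.es == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(profile.hit_indices, np.arange(5))

    def test_whole_list_set_is_degenerate(self):
        ranked = random_ranked(np.random.default_rng(2), n=10)
        with pytest.raises(DomainError):
            enrichment_score(ranked, GeneSet("all", ranked.genes))

    def test_zero_overlap_rejected(self):
        ranked = random_ranked(np.random.default_rng(3), n=10)
        with pytest.raises(NoOverlapError):
            enrichment_score(ranked, GeneSet("none", ("zz1", "zz2")))

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    def test_matches_step_by_step_oracle(self, rng, weight_p):
        for _ in range(50):
            n = int(rng.integers(8, 50))
            ranked = random_ranked(rng, n)
            k = int(rng.integers(2, n // 2))
            members = tuple(rng.choice(ranked.genes, k, replace=False))
            es = enrichment_score(ranked, GeneSet("s", members), weight_p).es
            oracle = brute_force_es(ranked.genes, ranked.scores, members, weight_p)
            assert es == pytest.approx(oracle, abs=1e-12)

    def test_running_sum_ends_at_zero(self, rng):
        """Increments and decrements balance exactly over the full walk."""
        ranked = random_ranked(rng, 25)
        for p in (0.0, 1.0):
            profile = enrichment_score(ranked, GeneSet("s", ranked.genes[3:9]), p)
            assert profile.running_sum[-1] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_transform_invariance_unweighted(self, rng):
        ranked = random_ranked(rng, 30)
        transformed = RankedList(ranked.genes, np.exp(ranked.scores))
        members = tuple(ranked.genes[i] for i in (2, 5, 11, 17))
        es1 = enrichment_score(ranked, GeneSet("s", members), 0.0).es
        es2 = enrichment_score(transformed, GeneSet("s", members), 0.0).es
        assert es1 == pytest.approx(es2, abs=1e-15)

    def test_score_doubling_invariance_weighted(self, rng):
        ranked = random_ranked(rng, 30)
        doubled = RankedList(ranked.genes, 2.0 * ranked.scores)
        members = tuple(ranked.genes[i] for i in (0, 4, 9, 20))
        es1 = enrichment_score(ranked, GeneSet("s", members), 1.0).es
        es2 = enrichment_score(doubled, GeneSet("s", members), 1.0).es
        assert es1 == pytest.approx(es2, abs=1e-12)


class TestRankedList:
    def test_tie_break_is_deterministic_by_gene_id(self):
        r = RankedList.from_scores({"b": 1.0, "a": 1.0, "c": 2.0})
        assert r.genes == ("c", "a", "b")

    def test_duplicate_genes_rejected(self):
        with pytest.raises(DomainError):
            RankedList(("a", "a"), np.array([2.0, 1.0]))

    def test_rnk_round_trip(self, tmp_path, rng):
        ranked = random_ranked(rng, 15)
        path = tmp_path / "r.rnk"
        ranked.to_rnk(path)
        back = RankedList.from_rnk(path)
        assert back.genes == ranked.genes
        np.testing.assert_allclose(back.scores, ranked.scores)


class TestPrerankedGsea:
    def planted_instance(self, seed=0, n=400, k=20, effect=3.0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        scores = rng.normal(size=n)
        planted = rng.choice(n, k, replace=False)
        scores[planted] += effect
        ranked = RankedList.from_scores(pd.Series(scores, index=genes))
        sets = [GeneSet("PLANTED", tuple(genes[i] for i in planted))]
        sets += [
            GeneSet(f"D{j}", tuple(rng.choice(genes, k, replace=False))) for j in range(4)
        ]
        return ranked, sets

    def test_too_few_permutations_rejected(self):
        ranked, sets = self.planted_instance()
        with pytest.raises(ConfigurationError):
            preranked_gsea(ranked, sets, n_perm=5)

    def test_planted_set_tops_nes_and_clears_fdr(self):
        ranked, sets = self.planted_instance(seed=4)
        results = preranked_gsea(ranked, sets, n_perm=500, seed=9)
        best = max(results, key=lambda r: r.nes)
        assert best.set_name == "PLANTED"
        assert best.fdr_q < 0.25
        assert best.direction == "up"

    def test_bit_reproducible_given_seed(self):
        ranked, sets = self.planted_instance(seed=5)
        r1 = preranked_gsea(ranked, sets, n_perm=200, seed=17)
        r2 = preranked_gsea(ranked, sets, n_perm=200, seed=17)
        assert r1 == r2

    def test_nes_sign_matches_es_and_bounds_hold(self):
        ranked, sets = self.planted_instance(seed=6)
        for r in preranked_gsea(ranked, sets, n_perm=200, seed=1):
            assert abs(r.es) <= 1.0
            assert 0.0 <= r.p_nominal <= 1.0
            assert 0.0 <= r.fdr_q <= 1.0
            assert np.sign(r.nes) == np.sign(r.es) or r.nes == 0

    def test_fdr_monotone_in_nes_within_sign(self):
        ranked, sets = self.planted_instance(seed=7, effect=0.0)
        results = preranked_gsea(ranked, sets, n_perm=300, seed=2)
        pos = sorted([r for r in results if r.nes >= 0], key=lambda r: -r.nes)
        assert all(a.fdr_q <= b.fdr_q + 1e-12 for a, b in zip(pos, pos[1:]))
        neg = sorted([r for r in results if r.nes < 0], key=lambda r: r.nes)
        assert all(a.fdr_q <= b.fdr_q + 1e-12 for a, b in zip(neg, neg[1:]))


class TestSignalToNoise:
    def two_class(self, values, labels):
        df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                          columns=[f"s{i}" for i in range(values.shape[1])])
        return TwoClassExpression(df, pd.Series(labels, index=df.columns))

    def test_equal_classes_score_zero(self):
        values = np.tile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], (4, 1))
        expr = self.two_class(values, ["A"] * 3 + ["B"] * 3)
        ranked = signal_to_noise_ranking(expr)
        np.testing.assert_allclose(ranked.scores, 0.0, atol=1e-12)

    def test_printed_example(self):
        # meanA=2, meanB=1, sdA=sdB=0.5 -> score 1.0
        a = np.array([1.5, 2.0, 2.5, 2.0])  # mean 2, sd 0.4082...
        values = np.array([[1.5, 2.0, 2.5, 0.5, 1.0, 1.5]])
        expr = self.two_class(values, ["A"] * 3 + ["B"] * 3)
        ranked = signal_to_noise_ranking(expr)
        assert ranked.scores[0] == pytest.approx((2.0 - 1.0) / (0.5 + 0.5))
        del a

    def test_matches_per_gene_oracle(self, rng):
        values = rng.normal(5, 2, size=(20, 8))
        expr = self.two_class(values, ["A"] * 4 + ["B"] * 4)
        ranked = signal_to_noise_ranking(expr)
        score = dict(zip(ranked.genes, ranked.scores))
        for i in range(20):
            a, b = values[i, :4], values[i, 4:]
            sd_a = max(a.std(ddof=1), 0.2 * abs(a.mean()) if a.mean() != 0 else 0.2)
            sd_b = max(b.std(ddof=1), 0.2 * abs(b.mean()) if b.mean() != 0 else 0.2)
            assert score[f"g{i}"] == pytest.approx((a.mean() - b.mean()) / (sd_a + sd_b))

    def test_single_class_rejected(self):
        values = np.ones((3, 4))
        with pytest.raises(ConfigurationError):
            self.two_class(values, ["A"] * 4)


class TestPhenotypePermutation:
    def expression(self, seed=0, n_genes=60, per_class=2, effect=0.0):
        rng = np.random.default_rng(seed)
        values = rng.normal(10, 1, size=(n_genes, 2 * per_class))
        values[:10, :per_class] += effect
        df = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(2 * per_class)])
        labels = pd.Series(["A"] * per_class + ["B"] * per_class, index=df.columns)
        return TwoClassExpression(df, labels)

    def test_two_vs_two_enumerates_six_splits(self):
        expr = self.expression(per_class=2)
        sets = [GeneSet("S", tuple(f"g{i}" for i in range(10)))]
        with pytest.warns(UserWarning, match="6 distinct"):
            results = phenotype_permutation_gsea(expr, sets, n_perm=100, seed=0)
        # the null holds at most 6 values, so p is a fraction with denominator <= 6
        p = results[0].p_nominal
        assert any(abs(p * d - round(p * d)) < 1e-9 for d in range(1, 7))

    def test_observed_es_equals_preranked_on_s2n_ranking(self):
        expr = self.expression(seed=3, per_class=3, effect=2.0)
        sets = [GeneSet("S", tuple(f"g{i}" for i in range(10)))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pheno = phenotype_permutation_gsea(expr, sets, n_perm=50, seed=1)
        ranked = signal_to_noise_ranking(expr)
        es = enrichment_score(ranked, sets[0]).es
        assert pheno[0].es == pytest.approx(es, abs=1e-12)

    def test_one_vs_one_falls_back_to_gene_set_permutation(self):
        expr = self.expression(per_class=1)
        sets = [GeneSet("S", tuple(f"g{i}" for i in range(10)))]
        with pytest.warns(UserWarning, match="falling back"):
            results = phenotype_permutation_gsea(expr, sets, n_perm=100, seed=2)
        assert len(results) == 1

    def test_null_data_is_insignificant(self):
        expr = self.expression(seed=8, per_class=4, effect=0.0)
        sets = [GeneSet(f"S{j}", tuple(f"g{i}" for i in range(10 * j, 10 * j + 10)))
                for j in range(3)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = phenotype_permutation_gsea(expr, sets, n_perm=60, seed=3)
        assert all(r.fdr_q > 0.25 for r in results)
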