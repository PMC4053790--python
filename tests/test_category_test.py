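import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from godiverge.annotation import GoAnnotation, GoCategory, build_categories
from godiverge import category_test as ct
from godiverge.category_test import (
    CategoryDivergenceModel,
    GenomeRates,
    count_outliers,
    expected_nonsyn_proportion,
    genome_rates,
    permutation_null,
    tail_probability,
)
evaluate_categories = ct.test_all_categories
from godiverge.codon_counts import SubstitutionCounts

from oracles import oracle_binomial_lower, oracle_binomial_upper


def sc(gene, a, A, s, S):
    return SubstitutionCounts(gene, a, A, s, S)


class TestGenomeRates:
    def test_single_gene(self):
        r = genome_rates([sc("g1", 2, 100, 3, 50)])
        assert r.ka == pytest.approx(0.02)
        assert r.ks == pytest.approx(0.06)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        r = genome_rates([sc("g1", 1, 100, 1, 100), sc("g2", 3, 100, 3, 100)])
        assert r.ka == pytest.approx(0.02)
        assert r.ks == pytest.approx(0.02)

    def test_zero_substitutions_allowed(self):
        r = genome_rates([sc("g1", 0, 100, 1, 50)])
        assert r.ka == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genome_rates([])


class TestExpectedProportion:
    def test_whole_universe_identity(self):
        counts = [sc("g1", 2, 100, 3, 50), sc("g2", 5, 200, 1, 70)]
        r = genome_rates(counts)
        sum_A = sum(c.A for c in counts)
        sum_S = sum(c.S for c in counts)
        pA = expected_nonsyn_proportion(sum_A, sum_S, r)
        tot_a = sum(c.a for c in counts)
        tot_s = sum(c.s for c in counts)
        assert pA == pytest.approx(tot_a / (tot_a + tot_s))

    def test_equal_rates_reduce_to_site_fraction(self):
        r = GenomeRates(0.05, 0.05, 1)
        assert expected_nonsyn_proportion(30, 70, r) == pytest.approx(0.3)

    def test_direct_evaluation(self):
        r = GenomeRates(0.02, 0.06, 1)
        assert expected_nonsyn_proportion(200, 100, r) == pytest.approx(0.4)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            expected_nonsyn_proportion(0, 10, GenomeRates(0.1, 0.1, 1))


class TestTailProbability:
    def test_trivial_anchors(self):
        assert tail_probability(0, 5, 0.3, "rapid") == 1.0
        assert tail_probability(2, 0, 0.5, "rapid") == pytest.approx(0.25)
        assert tail_probability(3, 0, 0.3, "slow") == 1.0

    def test_matches_direct_summation(self, rng):
        for _ in range(300):
            a = int(rng.integers(0, 201))
            s = int(rng.integers(0, 201))
            if a + s == 0:
                continue
            p = float(rng.uniform(0.01, 0.99))
            assert tail_probability(a, s, p, "rapid") == pytest.approx(
                oracle_binomial_upper(a, s, p), abs=1e-10
            )
            assert tail_probability(a, s, p, "slow") == pytest.approx(
                oracle_binomial_lower(a, s, p), abs=1e-10
            )

    def test_tails_overlap_at_observed_value(self, rng):
        """p_rapid + p_slow = 1 + P(j = a) >= 1 at integer counts."""
        for _ in range(50):
            a = int(rng.integers(0, 50))
            s = int(rng.integers(0, 50))
            if a + s == 0:
                continue
            p = float(rng.uniform(0.05, 0.95))
            tot = tail_probability(a, s, p, "rapid") + tail_probability(a, s, p, "slow")
            pmf = stats.binom.pmf(a, a + s, p)
            assert tot == pytest.approx(1.0 + pmf, abs=1e-9)
            assert tot >= 1.0 - 1e-12

    def test_monotone_in_a_at_fixed_total(self):
        n, p = 60, 0.4
        vals = [tail_probability(a, n - a, p, "rapid") for a in range(0, n + 1)]
        assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))

    def test_fractional_counts_continuous(self):
        lo = tail_probability(10, 20, 0.4, "rapid")
        mid = tail_probability(10.5, 19.5, 0.4, "rapid")
        hi = tail_probability(11, 19, 0.4, "rapid")
        assert hi < mid < lo

    def test_degenerate_expected_proportion(self):
        assert tail_probability(0, 3, 0.0, "rapid") == 1.0
        assert tail_probability(2, 3, 0.0, "rapid") == 0.0
        assert tail_probability(2, 3, 1.0, "rapid") == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tail_probability(0, 0, 0.5, "rapid")
        with pytest.raises(ValueError):
            tail_probability(1, 1, 0.5, "sideways")


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(7)
    out = []
    for i in range(60):
        A = 300.0
        S = 100.0
        out.append(sc(f"g{i:03d}", float(rng.poisson(6)), A, float(rng.poisson(6)), S))
    return out


class TestTestAllCategories:
    def test_universe_category_recovers_totals(self, small_counts):
        genes = frozenset(c.gene_id for c in small_counts)
        cat = GoCategory("GO:all", genes)
        (res,) = evaluate_categories(small_counts, [cat], min_genes=1)
        assert res.a_C == pytest.approx(sum(c.a for c in small_counts))
        assert 0 < res.p_rapid < 1

    def test_identical_membership_identical_results(self, small_counts):
        genes = frozenset(c.gene_id for c in small_counts[:25])
        r1, r2 = evaluate_categories(
            small_counts, [GoCategory("GO:x", genes), GoCategory("GO:y", genes)], min_genes=20
        )
        assert (r1.p_rapid, r1.p_slow, r1.P_A) == (r2.p_rapid, r2.p_slow, r2.P_A)

    def test_members_without_counts_dropped_and_size_rechecked(self, small_counts):
        genes = frozenset([c.gene_id for c in small_counts[:19]] + ["missing1", "missing2"])
        out = evaluate_categories(small_counts, [GoCategory("GO:x", genes)], min_genes=20)
        assert out == []


class TestCountOutliers:
    def test_strictly_below(self, small_counts):
        genes = frozenset(c.gene_id for c in small_counts[:30])
        (res,) = evaluate_categories(small_counts, [GoCategory("GO:x", genes)], min_genes=1)
        assert count_outliers([res], res.p_rapid, "rapid") == 0
        assert count_outliers([res], min(1.0 - 1e-9, res.p_rapid * 1.0001), "rapid") == (
            1 if res.p_rapid < res.p_rapid * 1.0001 else 0
        )

    def test_empty_results(self):
        assert count_outliers([], 0.05, "rapid") == 0

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            count_outliers([], 0.0, "rapid")


class TestPermutationNull:
    def test_single_gene_universe_is_degenerate(self):
        counts = [sc("g1", 5, 100, 5, 50)]
        ann = GoAnnotation({"g1": {"GO:A"}}, ["g1"])
        out = permutation_null(counts, ann, n_permutations=50, seed=1, min_genes=1)
        assert all(s.global_p == 1.0 for s in out)
        assert all(s.expected_count == s.observed_count for s in out)

    def test_same_seed_bit_reproducible(self, small_counts):
        ann = GoAnnotation(
            {c.gene_id: {"GO:A"} for c in small_counts[:25]},
            [c.gene_id for c in small_counts],
        )
        a = permutation_null(small_counts, ann, n_permutations=100, seed=42, min_genes=20)
        b = permutation_null(small_counts, ann, n_permutations=100, seed=42, min_genes=20)
        assert a == b

    def test_requires_seed_and_positive_reps(self, small_counts):
        ann = GoAnnotation({}, [c.gene_id for c in small_counts])
        with pytest.raises(ValueError):
            permutation_null(small_counts, ann, n_permutations=0, seed=1)
        with pytest.raises(ValueError):
            permutation_null(small_counts, ann, n_permutations=10, seed=None)

    def test_exhaustive_matches_direct_enumeration(self):
        """3-gene instance: expected counts equal the mean over all 3! assignments."""
        counts = [sc("g1", 30, 100, 2, 50), sc("g2", 3, 100, 9, 50), sc("g3", 4, 100, 8, 50)]
        ann = GoAnnotation({"g1": {"GO:A"}, "g2": {"GO:B"}}, ["g1", "g2", "g3"])
        thresholds = (0.1, 0.05, 0.01)
        rates = genome_rates(counts)
        by_gene = {c.gene_id: c for c in counts}
        sets = [{"GO:A"}, {"GO:B"}, set()]
        genes = ["g1", "g2", "g3"]
        expected = {("rapid", t): [] for t in thresholds}
        expected.update({("slow", t): [] for t in thresholds})
        for assign in itertools.permutations(range(3)):
            members = {}
            for gi, si in enumerate(assign):
                for term in sets[si]:
                    members.setdefault(term, []).append(genes[gi])
            n_rapid = {t: 0 for t in thresholds}
            n_slow = {t: 0 for t in thresholds}
            for term, mem in members.items():
                a = sum(by_gene[g].a for g in mem)
                s = sum(by_gene[g].s for g in mem)
                A = sum(by_gene[g].A for g in mem)
                S = sum(by_gene[g].S for g in mem)
                pA = rates.ka * A / (rates.ka * A + rates.ks * S)
                n = int(a + s)
                pr = stats.binom.sf(int(a) - 1, n, pA)
                ps = stats.binom.cdf(int(a), n, pA)
                for t in thresholds:
                    n_rapid[t] += pr < t
                    n_slow[t] += ps < t
            for t in thresholds:
                expected[("rapid", t)].append(n_rapid[t])
                expected[("slow", t)].append(n_slow[t])
        out = permutation_null(
            counts, ann, thresholds=thresholds, min_genes=1, exhaustive=True
        )
        for s in out:
            want = np.mean(expected[(s.direction, s.threshold)])
            assert s.expected_count == pytest.approx(want, abs=1e-12)
            assert s.n_permutations == 6


class TestModelResults:
    def test_fit_and_summary(self, small_counts):
        mapping = {c.gene_id: {"GO:A"} for c in small_counts[:25]}
        mapping.update({c.gene_id: {"GO:B"} for c in small_counts[25:50]})
        model = CategoryDivergenceModel(small_counts, mapping, min_genes=20)
        res = model.fit(n_permutations=200, seed=9)
        assert len(res.category_results) == 2
        table = res.category_table
        assert list(table["p_rapid"]) == sorted(table["p_rapid"])
        text = res.summary()
        assert "genome-wide ka" in text and "permutation null" in text
        assert len(res.permutation_table) == 8  # 2 directions x 4 thresholds

    def test_fit_without_permutation(self, small_counts):
        model = CategoryDivergenceModel(
            small_counts, {c.gene_id: {"GO:A"} for c in small_counts[:30]}
        )
        res = model.fit(n_permutations=None)
        assert res.permutation_summaries == []
        assert "no permutation null" in res.summary()

    def test_to_files(self, small_counts, tmp_path):
        model = CategoryDivergenceModel(
            small_counts, {c.gene_id: {"GO:A"} for c in small_counts[:30]}
        )
        res = model.fit(n_permutations=50, seed=3)
        paths = res.to_files(tmp_path)
        assert paths["categories"].exists()
        assert paths["permutation"].exists()
        meta = paths["metadata"].read_text()
        assert '"seed": 3' in meta

    def test_from_files(self, small_counts, tmp_path):
        from godiverge.codon_counts import write_counts_table

        cp = tmp_path / "counts.tsv"
        write_counts_table(small_counts, cp)
        ap = tmp_path / "ann.tsv"
        ap.write_text("".join(f"{c.gene_id}\tGO:A\n" for c in small_counts[:30]))
        model = CategoryDivergenceModel.from_files(cp, ap, min_genes=20)
        res = model.fit(n_permutations=None)
        assert len(res.category_results) == 1
        assert res.category_results[0].n_genes == 30
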