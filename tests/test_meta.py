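import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xsigmeta.errors import PipelineError, ValidationError
from xsigmeta.meta import (
    classify_consistency,
    ks_compare,
    recurrence,
    rra_rho,
    rra_score,
    run_rra,
)

from conftest import make_collection, make_table


def binomial_tail_oracle(ranks, n_lists):
    """Independent closed form: rho = min_j P(X >= j), X ~ Bin(n, r_(j))."""
    best = 1.0
    for j, r in enumerate(sorted(ranks), start=1):
        tail = sum(
            math.comb(n_lists, k) * r**k * (1 - r) ** (n_lists - k)
            for k in range(j, n_lists + 1)
        )
        best = min(best, tail)
    return best


class TestRraRho:
    def test_three_identical_small_ranks(self):
        rho = rra_rho([0.01, 0.01, 0.01], 3)
        assert rho == pytest.approx(1e-6, rel=1e-9)
        assert rra_score(rho, 3) == pytest.approx(3e-6, rel=1e-9)

    def test_single_list_is_identity(self):
        for r in (0.05, 0.3, 0.9, 1.0):
            assert rra_rho([r], 1) == pytest.approx(r, abs=1e-12)

    def test_worst_case_all_ones(self):
        assert rra_rho([1.0, 1.0, 1.0], 3) == pytest.approx(1.0)
        assert rra_score(1.0, 3) == 1.0

    def test_rank_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            rra_rho([0.0], 2)
        with pytest.raises(ValidationError):
            rra_rho([1.1], 2)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 8))
            k = int(rng.integers(1, n + 1))
            ranks = rng.uniform(1e-6, 1.0, size=k)
            assert rra_rho(ranks, n) == pytest.approx(
                binomial_tail_oracle(ranks, n), abs=1e-12
            )

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
        st.integers(0, 5),
        st.floats(0.001, 0.5),
    )
    def test_monotone_improving_a_rank_never_raises_rho(self, ranks, which, delta):
        n = len(ranks)
        base = rra_rho(ranks, n)
        improved = list(ranks)
        i = which % n
        improved[i] = max(1e-9, improved[i] - delta)
        assert rra_rho(improved, n) <= base + 1e-12

    def test_score_is_capped_bonferroni(self):
        rho = 0.4
        assert rra_score(rho, 5) == 1.0
        assert rra_score(0.001, 5) == pytest.approx(0.005)


def _noise_collection(rng, n_genes=60, n_datasets=5):
    tables = []
    for j in range(n_datasets):
        tables.append(
            make_table(
                f"d{j}",
                [f"g{i}" for i in range(n_genes)],
                rng.normal(size=n_genes),
                pvalue=list(rng.uniform(size=n_genes)),
            )
        )
    return make_collection(tables)


class TestRunRra:
    def test_requires_two_datasets(self, rng):
        with pytest.raises(PipelineError):
            run_rra({"d0": _noise_collection(rng).tables["d0"]})

    def test_top_ranked_gene_flagged_robust(self, rng):
        coll = _noise_collection(rng, n_genes=50, n_datasets=10)
        for table in coll.tables.values():
            table.data.loc[table.data["gene"] == "g0", "log2fc"] = 99.0
        results = run_rra(coll, mode="per_direction")
        up = {r.gene: r for r in results if r.direction == "up"}
        assert up["g0"].robust
        assert up["g0"].score < 1e-10

    def test_any_direction_uses_pvalues(self, rng):
        coll = _noise_collection(rng, n_genes=50, n_datasets=10)
        for table in coll.tables.values():
            table.data.loc[table.data["gene"] == "g1", "pvalue"] = 1e-9
        results = run_rra(coll, mode="any_direction")
        res = {r.gene: r for r in results}
        assert res["g1"].robust
        assert all(r.direction == "any" for r in results)

    def test_missing_genes_get_reduced_n_lists(self, rng):
        coll = _noise_collection(rng, n_genes=20, n_datasets=4)
        # drop g5 from two datasets
        for did in ("d0", "d1"):
            data = coll.tables[did].data
            coll.tables[did].data = data[data["gene"] != "g5"].reset_index(drop=True)
        results = run_rra(coll, mode="any_direction")
        res = {r.gene: r for r in results}
        assert res["g5"].n_lists == 2
        assert res["g0"].n_lists == 4

    def test_default_threshold(self, rng):
        coll = _noise_collection(rng)
        results = run_rra(coll)
        for r in results:
            assert r.robust == (r.score < 0.05)


class TestRecurrence:
    def _single_gene_collection(self, n_up, n_down, n_null=3):
        tables = []
        i = 0
        for _ in range(n_up):
            tables.append(
                make_table(f"d{i}", ["g", "x"], [1.0, 0.1], fdr=[0.01, 0.9])
            )
            i += 1
        for _ in range(n_down):
            tables.append(
                make_table(f"d{i}", ["g", "x"], [-1.0, 0.1], fdr=[0.01, 0.9])
            )
            i += 1
        for _ in range(n_null):
            tables.append(
                make_table(f"d{i}", ["g", "x"], [1.0, 0.1], fdr=[0.9, 0.9])
            )
            i += 1
        return make_collection(tables)

    def test_19_up_4_down_is_consistent(self):
        records = recurrence(self._single_gene_collection(19, 4))
        rec = {r.gene: r for r in records}["g"]
        assert rec.n_up == 19 and rec.n_down == 4
        assert rec.consistency == pytest.approx(19 / 23)
        assert rec.consistent

    def test_23_up_0_down_is_consistent(self):
        rec = {r.gene: r for r in recurrence(self._single_gene_collection(23, 0))}["g"]
        assert rec.consistency == 1.0
        assert rec.consistent

    def test_perfect_ambivalence_not_consistent(self):
        rec = {r.gene: r for r in recurrence(self._single_gene_collection(5, 5))}["g"]
        assert rec.consistency == 0.5
        assert not rec.consistent

    def test_classifier_rule(self):
        assert classify_consistency(19, 4)
        assert classify_consistency(23, 0)
        assert not classify_consistency(5, 5)
        assert not classify_consistency(0, 0)

    def test_sorted_by_total_then_gene(self):
        coll = self._single_gene_collection(3, 0, n_null=0)
        for table in coll.tables.values():
            table.data.loc[table.data["gene"] == "x", "fdr"] = 0.01
        records = recurrence(coll)
        assert [r.gene for r in records] == ["g", "x"]


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        assert p == 1.0

    def test_full_separation_three_vs_three(self):
        d, p = ks_compare([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_monotone_transform_invariance(self, rng):
        a = rng.uniform(size=6)
        b = rng.uniform(size=6) + 0.3
        d1, _ = ks_compare(a, b)
        d2, _ = ks_compare(np.exp(a), np.exp(b))
        assert d1 == pytest.approx(d2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_compare([], [1.0])

    def test_exact_matches_enumeration_on_random_small_samples(self, rng):
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            d_obs, p = ks_compare(a, b)
            pooled = np.concatenate([a, b])
            hits = total = 0
            for idx in itertools.combinations(range(9), 4):
                mask = np.zeros(9, dtype=bool)
                mask[list(idx)] = True
                xa, xb = pooled[mask], pooled[~mask]
                grid = pooled
                cdf_a = np.searchsorted(np.sort(xa), grid, side="right") / 4
                cdf_b = np.searchsorted(np.sort(xb), grid, side="right") / 5
                d = np.abs(cdf_a - cdf_b).max()
                total += 1
                hits += d >= d_obs - 1e-12
            assert p == pytest.approx(hits / total)

    def test_large_samples_use_asymptotic(self, rng):
        from scipy import stats

        a = rng.normal(size=30)
        b = rng.normal(size=25) + 0.5
        d, p = ks_compare(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
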