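import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolmark import (
    HIGH,
    INTERMEDIATE,
    LOW,
    MISSING,
    QuadrantCounts,
    StudyConfig,
    estimate_fdr,
    generate_expression,
    implication_statistic,
    quadrant_counts,
    search_partners,
    threshold_all_genes,
)

counts_strategy = st.tuples(*[st.integers(0, 60)] * 4).map(lambda t: QuadrantCounts(*t))


class TestQuadrantCounts:
    def test_direct_count(self):
        c = quadrant_counts([LOW, LOW, HIGH, HIGH], [HIGH, HIGH, LOW, HIGH])
        assert (c.n_ll, c.n_lh, c.n_hl, c.n_hh) == (0, 2, 1, 1)

    def test_intermediate_sample_excluded(self):
        base = quadrant_counts([LOW, LOW, HIGH, HIGH], [HIGH, HIGH, LOW, HIGH])
        c = quadrant_counts([LOW, INTERMEDIATE, HIGH, HIGH], [HIGH, HIGH, LOW, HIGH])
        assert c.n == base.n - 1

    def test_all_intermediate_gives_zero(self):
        c = quadrant_counts([INTERMEDIATE] * 4, [INTERMEDIATE] * 4)
        assert c.n == 0

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError):
            quadrant_counts([LOW, HIGH], [LOW])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from([LOW, INTERMEDIATE, HIGH, MISSING]), min_size=1, max_size=50),
           st.integers(0, 2**31 - 1))
    def test_totals_conserved(self, x, seed):
        y = list(np.random.default_rng(seed).choice([LOW, INTERMEDIATE, HIGH, MISSING], len(x)))
        c = quadrant_counts(x, y)
        excluded = sum(
            1 for a, b in zip(x, y) if a not in (LOW, HIGH) or b not in (LOW, HIGH)
        )
        assert c.n + excluded == len(x)


class TestImplicationStatistic:
    def test_zero_sparse_quadrant_forces_sqrt_e(self):
        s = implication_statistic(QuadrantCounts(0, 10, 10, 10))
        assert s.expected == pytest.approx(10 * 10 / 30)
        assert s.statistic == pytest.approx(np.sqrt(s.expected))
        assert s.error_rate == 0.0

    def test_exact_independence_fails(self):
        s = implication_statistic(QuadrantCounts(25, 25, 25, 25))
        assert s.statistic == 0.0 and s.error_rate == 0.5 and not s.passes

    def test_sparse_quadrant_example(self):
        s = implication_statistic(QuadrantCounts(2, 48, 38, 62), s_min=3.0, err_max=0.1)
        assert s.expected == pytest.approx(13.3333, abs=1e-3)
        assert s.statistic == pytest.approx(3.104, abs=1e-3)
        assert s.error_rate == pytest.approx(0.045, abs=1e-6)
        assert s.passes

    def test_zero_margin_not_evaluable(self):
        s = implication_statistic(QuadrantCounts(0, 0, 10, 10))  # no X-low samples
        assert not s.evaluable and not s.passes

    @settings(derandomize=True, max_examples=100)
    @given(counts_strategy)
    def test_contrapositive_symmetry(self, c):
        """X-low => Y-high and Y-low => X-high both test sparsity of the
        low-low quadrant; transposing the table must preserve S and err."""
        transposed = QuadrantCounts(c.n_ll, c.n_hl, c.n_lh, c.n_hh)
        a = implication_statistic(c, "low=>high")
        b = implication_statistic(transposed, "low=>high")
        if a.evaluable and b.evaluable:
            assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
            assert a.error_rate == pytest.approx(b.error_rate, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(counts_strategy, st.integers(2, 9))
    def test_scaling_relation(self, c, k):
        """Scaling all counts by k with o/e fixed scales S by sqrt(k)."""
        scaled = QuadrantCounts(k * c.n_ll, k * c.n_lh, k * c.n_hl, k * c.n_hh)
        a = implication_statistic(c)
        b = implication_statistic(scaled)
        if a.evaluable:
            assert b.statistic == pytest.approx(np.sqrt(k) * a.statistic, abs=1e-9)
            assert b.error_rate == pytest.approx(a.error_rate, abs=1e-12)

    def test_derived_relation_flags(self):
        from boolmark.implication import derived_relation_flags

        # both off-diagonal quadrants sparse: X and Y are equivalent
        eq = derived_relation_flags(QuadrantCounts(60, 1, 1, 60))
        assert eq["equivalent"] and not eq["opposite"]
        # both diagonal quadrants sparse: X and Y are opposite
        op = derived_relation_flags(QuadrantCounts(1, 60, 60, 1))
        assert op["opposite"] and not op["equivalent"]
        # independence: neither
        ind = derived_relation_flags(QuadrantCounts(30, 30, 30, 30))
        assert not ind["equivalent"] and not ind["opposite"]

    @settings(derandomize=True, max_examples=50)
    @given(counts_strategy)
    def test_statistic_matches_scalar_formula(self, c):
        s = implication_statistic(c, "high=>low")  # sparse quadrant (H, H)
        if s.evaluable:
            row = c.n_hl + c.n_hh
            col = c.n_lh + c.n_hh
            e = row * col / c.n
            assert s.expected == pytest.approx(e)
            assert s.statistic == pytest.approx((e - c.n_hh) / np.sqrt(e))


@pytest.fixture(scope="module")
def planted_search():
    cfg = StudyConfig(n_crc=500, n_polyp=10, n_ibd=40, n_normal=40,
                      n_genes=200, n_bimodal=20, n_de=5)
    matrix, _, truth = generate_expression(cfg, seed=21)
    _, calls = threshold_all_genes(matrix, margin=0.5)
    crc = [s for s in matrix.sample_ids if s.startswith("CRC")]
    return calls, crc, truth


class TestSearchPartners:
    def test_planted_partner_ranks_first(self, planted_search):
        calls, crc, truth = planted_search
        res = search_partners(calls, truth.target_gene, population=crc)
        passing = res[res["passes"]]
        assert passing.iloc[0]["gene_x"] == truth.marker_gene

    def test_null_matrix_rarely_passes(self):
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            calls = pd.DataFrame(
                rng.choice([LOW, HIGH], size=(50, 200)).astype(np.int8),
                index=[f"G{i}" for i in range(50)],
                columns=[f"S{i}" for i in range(200)],
            )
            res = search_partners(calls, "G0")
            total += int(res["passes"].sum())
        assert total <= 1

    def test_min_n_above_population_gives_no_passes(self, planted_search):
        calls, crc, truth = planted_search
        res = search_partners(calls, truth.target_gene, population=crc, min_n=len(crc) + 1)
        assert not res["passes"].any()

    def test_absent_target_errors(self, planted_search):
        calls, crc, _ = planted_search
        with pytest.raises(ValueError, match="NOPE"):
            search_partners(calls, "NOPE")

    def test_support_fraction_bounds(self, planted_search):
        calls, crc, truth = planted_search
        res = search_partners(calls, truth.target_gene, population=crc)
        assert ((res["support_fraction"] >= 0) & (res["support_fraction"] <= 1)).all()


class TestEstimateFdr:
    def test_planted_partner_fdr_below_cutoff(self, planted_search):
        calls, crc, truth = planted_search
        out = estimate_fdr(calls, truth.target_gene, population=crc, n_perm=50, seed=5)
        assert out["observed_passing"] >= 1
        assert out["fdr"] < 0.005

    def test_pure_null_fdr_near_one(self):
        fdrs = []
        for seed in range(5):
            rng = np.random.default_rng(4000 + seed)
            calls = pd.DataFrame(
                rng.choice([LOW, HIGH], size=(40, 150)).astype(np.int8),
                index=[f"G{i}" for i in range(40)],
                columns=[f"S{i}" for i in range(150)],
            )
            fdrs.append(estimate_fdr(calls, "G0", n_perm=30, seed=seed)["fdr"])
        assert np.mean(fdrs) >= 0.5

    def test_zero_observed_passing_convention(self):
        calls = pd.DataFrame(
            np.tile([LOW, HIGH], (3, 10)).astype(np.int8),
            index=["A", "B", "C"],
            columns=[f"S{i}" for i in range(20)],
        )
        out = estimate_fdr(calls, "A", min_n=1000, n_perm=5, seed=0)
        assert out["observed_passing"] == 0 and out["fdr"] == 1.0

    def test_seed_makes_fdr_reproducible(self, planted_search):
        calls, crc, truth = planted_search
        a = estimate_fdr(calls, truth.target_gene, population=crc, n_perm=10, seed=9)
        b = estimate_fdr(calls, truth.target_gene, population=crc, n_perm=10, seed=9)
        assert a == b
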