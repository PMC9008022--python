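import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccimap.cci import (
    CutpointError,
    DegenerateObservationError,
    cci_cutpoint,
    cci_positive,
    cci_score,
    cci_signature_genes,
    compute_cci_table,
    export_ternary_density,
    signature_score,
    ternary_project,
    ternary_project_many,
)
from ccimap.io_qc import ExpressionMatrix, SignatureSet


def lognorm_matrix(values, gene_ids=None, obs_ids=None):
    values = np.asarray(values, float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    obs_ids = obs_ids or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, gene_ids, obs_ids, layer="lognorm")


class TestSignatureScore:
    def test_arithmetic_mean(self):
        m = lognorm_matrix([[2.0], [4.0], [6.0]])
        assert signature_score(m, SignatureSet("s", ["g0", "g1", "g2"]))[0] == 4.0

    def test_all_zero_observation(self):
        m = lognorm_matrix([[0.0], [0.0]])
        assert signature_score(m, SignatureSet("s", ["g0", "g1"]))[0] == 0.0

    def test_single_gene_identity(self):
        m = lognorm_matrix([[1.5, 2.5], [9.0, 9.0]])
        np.testing.assert_array_equal(
            signature_score(m, SignatureSet("s", ["g0"])), m.values[0]
        )

    def test_no_match_error(self):
        m = lognorm_matrix([[1.0]])
        with pytest.raises(ValueError):
            signature_score(m, SignatureSet("s", ["nope"]))

    def test_raw_counts_rejected(self, small_counts):
        with pytest.raises(ValueError, match="normalized"):
            signature_score(small_counts, SignatureSet("s", ["g0"]))


class TestTernaryProject:
    @pytest.mark.parametrize(
        "abc,expected",
        [
            ((2, 1, 1), (0.5, 0.25, 0.25)),
            ((1, 1, 1), (1 / 3, 1 / 3, 1 / 3)),
            ((0, 0, 5), (0.0, 0.0, 1.0)),
        ],
    )
    def test_examples(self, abc, expected):
        np.testing.assert_allclose(ternary_project(*abc), expected, atol=1e-12)

    def test_negative_clipped(self):
        assert ternary_project(-1.0, 0.0, 2.0) == (0.0, 0.0, 1.0)

    def test_degenerate_error(self):
        with pytest.raises(DegenerateObservationError):
            ternary_project(0.0, -1.0, 0.0)

    def test_vectorized_flags_degenerate(self):
        bary, ok = ternary_project_many(np.array([[1.0, 1.0, 2.0], [0.0, 0.0, 0.0]]))
        assert ok.tolist() == [True, False]
        assert np.isnan(bary[1]).all()
        np.testing.assert_allclose(bary[0].sum(), 1.0)

    @given(
        st.tuples(
            st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 1e6)
        ).filter(lambda t: sum(t) > 1e-9)
    )
    def test_property_simplex(self, abc):
        bary = ternary_project(*abc)
        assert all(0 <= b <= 1 for b in bary)
        assert abs(sum(bary) - 1.0) < 1e-9


class TestCCIScore:
    def test_corner_derived_value(self):
        # sd of (1,0,0) with n-1 denominator = sqrt(1/3) = 0.57735...
        c1, c2, c3, sd, cci = cci_score(1.0, 0.0, 0.0, f=10.0)
        assert (c1, c2, c3) == (1.0, 0.0, 0.0)
        np.testing.assert_allclose(sd, math.sqrt(1.0 / 3.0), rtol=1e-9)
        np.testing.assert_allclose(cci, 10.0 / math.sqrt(1.0 / 3.0), rtol=1e-6)
        np.testing.assert_allclose(cci, 17.3205, atol=1e-4)

    def test_centroid_capped(self):
        *_, sd, cci = cci_score(1.0, 1.0, 1.0, f=10.0, epsilon=1e-6)
        assert sd == 0.0 and cci == 10.0 / 1e-6

    def test_three_four_five(self):
        c1, c2, c3, _, _ = cci_score(3.0, 4.0, 0.0)
        np.testing.assert_allclose((c1, c2, c3), (0.6, 0.8, 0.0), rtol=1e-12)

    def test_all_zero_error(self):
        with pytest.raises(DegenerateObservationError):
            cci_score(0.0, 0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cci_score(-1.0, 1.0, 1.0)

    def test_scale_invariance(self, rng):
        abc = rng.uniform(0.01, 5.0, size=(200, 3))
        for k in (1e-3, 0.5, 7.0, 1e4):
            base = cci_score(abc[:, 0], abc[:, 1], abc[:, 2])
            scaled = cci_score(k * abc[:, 0], k * abc[:, 1], k * abc[:, 2])
            for b, s in zip(base, scaled):
                np.testing.assert_allclose(b, s, rtol=1e-9)

    def test_permutation_symmetry(self, rng):
        a, b, c = rng.uniform(0.01, 5.0, size=3)
        ref = cci_score(a, b, c)
        import itertools

        for perm in itertools.permutations([a, b, c]):
            out = cci_score(*perm)
            np.testing.assert_allclose(sorted(out[:3]), sorted(ref[:3]), rtol=1e-12)
            np.testing.assert_allclose(out[3], ref[3], rtol=1e-12)
            np.testing.assert_allclose(out[4], ref[4], rtol=1e-12)

    def test_cosine_normalization(self, rng):
        abc = rng.uniform(0.0, 10.0, size=(10_000, 3))
        abc = abc[abc.sum(axis=1) > 0]
        c1, c2, c3, _, _ = cci_score(abc[:, 0], abc[:, 1], abc[:, 2])
        np.testing.assert_allclose(c1**2 + c2**2 + c3**2, 1.0, atol=1e-9)

    def test_corner_to_centroid_monotone(self):
        # cci is non-decreasing along the segment (1,0,0) -> (1/3,1/3,1/3)
        ts = np.linspace(0.0, 1.0, 100)
        corner, centroid = np.array([1.0, 0.0, 0.0]), np.full(3, 1.0 / 3.0)
        pts = np.outer(1 - ts, corner) + np.outer(ts, centroid)
        *_, cci = cci_score(pts[:, 0], pts[:, 1], pts[:, 2])
        assert np.all(np.diff(cci) >= -1e-9)

    def test_population_sd_mode_rescales(self):
        *_, cci_s = cci_score(2.0, 1.0, 0.5, sd_mode="sample")
        *_, cci_p = cci_score(2.0, 1.0, 0.5, sd_mode="population")
        np.testing.assert_allclose(cci_p / cci_s, math.sqrt(3.0 / 2.0), rtol=1e-12)

    def test_exact_f_over_sd_identity(self, rng):
        a, b, c = rng.uniform(0.1, 3.0, size=3)
        *_, sd, cci = cci_score(a, b, c, f=7.0, epsilon=1e-6)
        assert cci == 7.0 / max(sd, 1e-6)


class TestCCICutpoint:
    def test_bimodal_mixture_valley(self):
        rng = np.random.default_rng(42)
        scores = np.concatenate([rng.normal(15, 3, 1000), rng.normal(40, 5, 1000)])
        cut, grid = cci_cutpoint(scores)
        low95 = np.quantile(scores[:1000], 0.95)
        high5 = np.quantile(scores[1000:], 0.05)
        assert low95 < cut < high5
        assert {"score", "ecdf", "fitted"} <= set(grid.columns)

    def test_logistic_scores_error_path(self):
        rng = np.random.default_rng(7)
        scores = rng.logistic(50.0, 5.0, 5000)
        with pytest.raises(CutpointError):
            cci_cutpoint(scores)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(10, 2, 500), rng.normal(30, 3, 500)])
        cut, _ = cci_cutpoint(scores)
        cut_shift, _ = cci_cutpoint(scores + 100.0)
        np.testing.assert_allclose(cut_shift, cut + 100.0, rtol=1e-12)

    def test_too_few_scores(self):
        with pytest.raises(ValueError, match=">= 50"):
            cci_cutpoint(np.arange(10.0))

    def test_positive_is_strictly_above(self):
        mask = cci_positive(np.array([1.0, 2.0, 3.0]), 2.0)
        assert mask.tolist() == [False, False, True]


class TestCCISignatureGenes:
    def _matrix(self):
        # 4 genes x 10 cells; first 5 cells "positive"
        v = np.zeros((4, 10))
        v[0] = [3, 3, 3, 3, 3, 0.1, 0.1, 0.1, 0.1, 0.1]  # true CCI-like gene
        v[1] = 5.0  # uniform everywhere: passes base-mean+pct1, fails logfc
        v[2, :4] = 3.0  # pct1 = 0.8 exactly -> excluded (strict)
        v[3] = 0.05
        return lognorm_matrix(v)

    def test_threshold_behaviour(self):
        m = self._matrix()
        pos = {f"c{i}" for i in range(5)}
        bg = {f"c{i}" for i in range(5, 10)}
        s = cci_signature_genes(m, pos, bg)
        assert s.genes == ["g0"]

    def test_pct1_boundary_strict(self):
        m = self._matrix()
        pos = {f"c{i}" for i in range(5)}
        bg = {f"c{i}" for i in range(5, 10)}
        s = cci_signature_genes(m, pos, bg, min_pct1=0.8)
        assert "g2" not in s.genes

    def test_uniform_gene_excluded_by_foldchange(self):
        m = self._matrix()
        s = cci_signature_genes(m, {f"c{i}" for i in range(5)}, {f"c{i}" for i in range(5, 10)})
        assert "g1" not in s.genes

    def test_empty_result_warns(self):
        m = lognorm_matrix(np.full((2, 6), 2.0))
        with pytest.warns(UserWarning):
            out = cci_signature_genes(m, {"c0", "c1", "c2"}, {"c3", "c4", "c5"})
        assert out is None

    def test_overlapping_sets_rejected(self):
        m = self._matrix()
        with pytest.raises(ValueError, match="overlap"):
            cci_signature_genes(m, {"c0"}, {"c0", "c1"})

    def test_brute_force_equivalence(self, rng):
        n_genes, n_obs = 40, 30
        v = rng.gamma(2.0, 1.0, size=(n_genes, n_obs))
        v[v < 0.5] = 0.0
        m = lognorm_matrix(v)
        pos = {f"c{i}" for i in range(12)}
        bg = {f"c{i}" for i in range(12, 30)}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = cci_signature_genes(m, pos, bg, 0.1, 0.5, 0.5)
        got_genes = set() if got is None else set(got.genes)
        # naive per-gene triple-threshold filter
        want = set()
        for g in range(n_genes):
            xin = [v[g, i] for i in range(12)]
            xall = [v[g, i] for i in range(30)]
            xout = [v[g, i] for i in range(12, 30)]
            lfc = math.log(sum(math.expm1(x) for x in xin) / 12 + 1) - math.log(
                sum(math.expm1(x) for x in xout) / 18 + 1
            )
            basemean = sum(xall) / 30
            pct1 = sum(x > 0 for x in xin) / 12
            if lfc > 0.1 and basemean > 0.5 and pct1 > 0.5:
                want.add(f"g{g}")
        assert got_genes == want

    def test_planted_gene_recovered(self, normalized_cohort):
        cohort, norm = normalized_cohort
        pop = cohort.truth_population.loc[list(norm.obs_ids)]
        confused = set(pop[pop == "confused"].index)
        background = set(norm.obs_ids) - confused
        s = cci_signature_genes(norm, confused, background)
        truth = set(cohort.truth_signatures["CCI"].genes)
        assert len(set(s.genes) & truth) / len(truth) >= 0.7


class TestComputeCCITable:
    def test_row_conservation_and_cutpoint(self, normalized_cohort):
        cohort, norm = normalized_cohort
        sigs = [cohort.truth_signatures[p] for p in ("BS", "BK", "DK")]
        table = compute_cci_table(norm, sigs)
        assert len(table) == norm.n_obs
        assert table["cutpoint"].nunique() == 1
        # cci = f / max(sd, eps) exactly
        expect = 10.0 / np.maximum(table["sd_cos"], 1e-6)
        np.testing.assert_allclose(table["cci"], expect, rtol=1e-12)
        bary = table[["bary_a", "bary_b", "bary_c"]].to_numpy()
        np.testing.assert_allclose(bary.sum(axis=1), 1.0, atol=1e-9)

    def test_requires_three_signatures(self, normalized_cohort):
        _, norm = normalized_cohort
        with pytest.raises(ValueError, match="three"):
            compute_cci_table(norm, [SignatureSet("x", ["G00000"])])


class TestTernaryDensity:
    def test_centroid_peak(self, rng):
        pts = np.full((50, 3), 1.0 / 3.0) + rng.normal(0, 1e-3, size=(50, 3))
        pts = np.clip(pts, 0, None)
        pts /= pts.sum(axis=1, keepdims=True)
        grid = export_ternary_density(pts, bins=41)
        top = grid.loc[grid["density"].idxmax()]
        assert abs(top["bary_a"] - 1 / 3) < 0.05
        assert abs(top["bary_b"] - 1 / 3) < 0.05

    def test_nonnegative_finite(self, rng):
        pts = rng.dirichlet([1, 1, 1], size=100)
        grid = export_ternary_density(pts, bins=31)
        assert np.isfinite(grid["density"]).all()
        assert (grid["density"] >= 0).all()

    def test_uniform_sample_flatness(self):
        rng = np.random.default_rng(11)
        pts = rng.dirichlet([1.0, 1.0, 1.0], size=10_000)
        grid = export_ternary_density(pts, bins=50)
        interior = grid[(grid[["bary_a", "bary_b", "bary_c"]] > 0.15).all(axis=1)]
        ratio = interior["density"].max() / interior["density"].min()
        assert ratio < 3.0

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 10"):
            export_ternary_density(np.full((5, 3), 1.0 / 3.0))
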