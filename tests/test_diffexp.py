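"""NB Wald engine: normalization, dispersion, testing, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metscreen.diffexp import (
    ALPHA_MIN,
    Contrast,
    bh_adjust,
    call_degs,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)
from metscreen.types import CountMatrix, NormalizationError, ValidationError


def _matrix(counts, prefix="s"):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"g{i}" for i in range(counts.shape[0])],
        [f"{prefix}{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestSizeFactors:
    def test_exact_two_fold_scaling(self):
        a = np.array([10, 40, 100])
        cm = np.column_stack([a, 2 * a])
        sf = size_factors(cm)
        assert sf == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_identical_samples_give_unit_factors(self):
        a = np.array([[7, 7, 7], [30, 30, 30]])
        assert size_factors(a) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(0, 500, size=(50, 6))
        counts[:5] += 1  # guarantee an all-positive reference set
        expected_rows = (counts > 0).all(axis=1)
        ref = np.exp(np.log(counts[expected_rows].astype(float)).mean(axis=1))
        ratios = counts[expected_rows] / ref[:, None]
        brute = np.median(ratios, axis=0)
        assert size_factors(counts) == pytest.approx(brute, abs=1e-12)

    def test_no_universally_expressed_gene(self):
        with pytest.raises(NormalizationError):
            size_factors(np.array([[0, 5], [5, 0]]))


class TestDispersion:
    def test_floor_for_poisson_and_constant_genes(self):
        rng = np.random.default_rng(1)
        pois = rng.poisson(50, size=(200, 40)).astype(float)
        groups = [np.arange(20), np.arange(20, 40)]
        alpha = estimate_dispersion(pois, groups)
        # Poisson variance ~ mean: most genes sit at/near the floor
        assert np.median(alpha) == ALPHA_MIN
        const = np.full((3, 40), 9.0)
        assert estimate_dispersion(const, groups) == pytest.approx([ALPHA_MIN] * 3)

    def test_moment_recovery_of_true_dispersion(self):
        # 100 replicate genes at alpha=0.2, 200 samples per group
        rng = np.random.default_rng(7)
        mu, alpha = 100.0, 0.2
        y = rng.poisson(rng.gamma(1 / alpha, mu * alpha, size=(100, 400)))
        est = estimate_dispersion(y.astype(float), [np.arange(200), np.arange(200, 400)])
        inside = np.mean((est >= 0.1) & (est <= 0.3))
        assert inside >= 0.9


class TestWaldTest:
    def test_identical_counts_give_null_result(self):
        y = np.full((4, 8), 25)
        res = nb_wald_test(_matrix(y), Contrast([f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]))
        assert res["log2fc"].to_numpy() == pytest.approx([0.0] * 4)
        assert res["p"].to_numpy() == pytest.approx([1.0] * 4)

    def test_all_zero_gene_excluded_from_bh(self):
        y = np.array([[0, 0, 0, 0], [10, 12, 30, 33], [9, 11, 28, 36]])
        res = nb_wald_test(
            _matrix(y), Contrast(["s2", "s3"], ["s0", "s1"]), sf=np.ones(4)
        )
        assert res.loc["g0", "status"] == "all_zero"
        assert np.isnan(res.loc["g0", "p"]) and np.isnan(res.loc["g0", "adj_p"])
        # BH denominator = 2 tested genes
        tested = res.dropna(subset=["p"])
        assert len(tested) == 2

    def test_power_on_planted_fold_change(self):
        rng = np.random.default_rng(42)
        mu, alpha, n = 100.0, 0.1, 10
        y_null = rng.poisson(rng.gamma(1 / alpha, mu * alpha, size=(100, 2 * n)))
        y_alt = y_null.copy()
        y_alt[:, n:] = rng.poisson(rng.gamma(1 / alpha, 4 * mu * alpha, size=(100, n)))
        # every gene carries the fold change, so fix sf=1 rather than letting
        # median-of-ratios absorb the global shift
        res = nb_wald_test(
            _matrix(y_alt),
            Contrast([f"s{j}" for j in range(n, 2 * n)], [f"s{j}" for j in range(n)]),
            sf=np.ones(2 * n),
        )
        hits = ((res["adj_p"] <= 0.01) & (res["log2fc"] > 0)).sum()
        assert hits >= 95

    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(9)
        y = rng.poisson(rng.gamma(5.0, 20.0, size=(200, 12)))
        cm = _matrix(y)
        num = [f"s{j}" for j in range(6)]
        den = [f"s{j}" for j in range(6, 12)]
        fwd = nb_wald_test(cm, Contrast(num, den))
        rev = nb_wald_test(cm, Contrast(den, num))
        ok = (fwd["status"] == "tested") & (rev["status"] == "tested")
        assert np.nanmax(np.abs(fwd["log2fc"][ok] + rev["log2fc"][ok])) < 1e-9
        assert np.nanmax(np.abs(fwd["p"][ok] - rev["p"][ok])) < 1e-9

    def test_null_calibration(self):
        rng = np.random.default_rng(23)
        mu, alpha = 80.0, 0.1
        y = rng.poisson(rng.gamma(1 / alpha, mu * alpha, size=(5000, 20)))
        res = nb_wald_test(
            _matrix(y), Contrast([f"s{j}" for j in range(10, 20)], [f"s{j}" for j in range(10)])
        )
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.08

    def test_agrees_with_statsmodels_nb_glm(self):
        # independent route: per-gene GLM fit with a fixed-dispersion NB family
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        alpha = 0.15
        mu = np.array([[60.0] * 6 + [180.0] * 6, [200.0] * 6 + [90.0] * 6])
        y = rng.poisson(rng.gamma(1 / alpha, mu * alpha))
        cm = _matrix(y)
        sf = np.exp(rng.normal(0, 0.2, 12))
        num = [f"s{j}" for j in range(6, 12)]
        den = [f"s{j}" for j in range(6)]
        res = nb_wald_test(cm, Contrast(num, den), sf=sf, dispersions=np.full(2, alpha))
        x = np.array([-0.5] * 6 + [0.5] * 6)
        X = np.column_stack([np.ones(12), x])
        for g in range(2):
            fit = sm.GLM(
                y[g], X, family=sm.families.NegativeBinomial(alpha=alpha), offset=np.log(sf)
            ).fit()
            assert res["log2fc"].iloc[g] == pytest.approx(fit.params[1] / np.log(2), abs=1e-6)
            assert res["se"].iloc[g] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-4)

    def test_contrast_validation(self):
        with pytest.raises(ValidationError):
            Contrast(["a"], ["a", "b"])  # overlap
        with pytest.raises(ValidationError):
            Contrast(["a"], ["b", "c"])  # single sample without flag
        Contrast(["a"], ["b", "c"], allow_single=True)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=200))
    def test_monotone_in_p(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)


class TestCallDegs:
    def test_boundary_adj_p_included_under_le_rule(self):
        res = pd.DataFrame(
            {"log2fc": [1.0, -1.0], "adj_p": [0.1, 0.2], "status": ["tested", "tested"]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        call = call_degs(res, alpha=0.1)
        assert call.up == ["gA"] and call.down == []
        strict = call_degs(res, alpha=0.1, strict=True)
        assert strict.genes == []

    def test_partition_matches_hand_count(self):
        rng = np.random.default_rng(4)
        adj = rng.uniform(0, 1, 20)
        fc = rng.normal(0, 1, 20)
        fc[np.abs(fc) < 1e-3] = 0.5
        res = pd.DataFrame(
            {"log2fc": fc, "adj_p": adj, "status": ["tested"] * 20},
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
        )
        call = call_degs(res, alpha=0.3)
        assert len(call.up) == int(((adj <= 0.3) & (fc > 0)).sum())
        assert len(call.down) == int(((adj <= 0.3) & (fc < 0)).sum())
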