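"""Association machinery: partial correlations, BH-FDR, distance-dependence,
Steiger and paired-t comparisons, subnetwork breakdowns."""

import numpy as np
import pandas as pd
import pytest

import dfcbench as d


def make_covariates(n, rng):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": rng.uniform(8, 22, n),
            "sex": rng.integers(0, 2, n),
            "mean_rel_rms": rng.uniform(0.02, 0.2, n),
        }
    )


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        from scipy.stats import pearsonr

        r_ref, p_ref = pearsonr(x, y)
        pc = d.partial_correlation(x, y)
        assert pc.r == pytest.approx(r_ref, abs=1e-12)
        assert pc.p == pytest.approx(p_ref, rel=1e-6)

    def test_covariate_identical_to_y(self, rng):
        x = rng.standard_normal(40)
        z = rng.standard_normal(40)
        pc = d.partial_correlation(x, z, z[:, None])
        assert abs(pc.r) < 1e-10

    def test_matrix_inversion_oracle(self):
        """Closed-form first-order partial correlation r_xy.z from the
        correlation-matrix recursion, on a numeric fixture."""
        x = np.array([2.0, 4.0, 5.0, 7.0, 8.0, 11.0])
        y = np.array([1.0, 3.0, 2.0, 6.0, 9.0, 8.0])
        z = np.array([0.0, 2.0, 1.0, 4.0, 7.0, 6.0])
        c = np.corrcoef(np.vstack([x, y, z]))
        rxy, rxz, ryz = c[0, 1], c[0, 2], c[1, 2]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        pc = d.partial_correlation(x, y, z[:, None])
        assert pc.r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        covs = rng.standard_normal((n, 2))
        df = pd.DataFrame(
            {"x": x, "y": y, "c1": covs[:, 0], "c2": covs[:, 1]}
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        pc = d.partial_correlation(x, y, covs)
        assert pc.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert pc.p == pytest.approx(float(ref[p_col].iloc[0]), rel=1e-6)

    def test_degenerate_variance_flagged(self, rng):
        pc = d.partial_correlation(np.ones(20), rng.standard_normal(20))
        assert (pc.r, pc.p, pc.ok) == (0.0, 1.0, False)


class TestBhFdr:
    def test_all_ones_no_rejections(self):
        mask, k = d.bh_fdr(np.ones(10))
        assert k == 0 and not mask.any()

    def test_step_up_by_hand(self):
        mask, k = d.bh_fdr(np.array([0.001, 0.01, 0.02, 0.9]), alpha=0.05)
        assert k == 3
        assert list(mask) == [True, True, True, False]

    def test_uniform_null_rarely_rejects(self, rng):
        total = 0
        for _ in range(100):
            _, k = d.bh_fdr(rng.random(1000))
            total += k
        assert total / 100 < 1.0

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(50) ** 2
            mask, _ = d.bh_fdr(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(mask, ref)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            d.bh_fdr(np.array([0.5, 1.2]))


class TestUnitwiseAssociation:
    def test_pure_noise_near_null(self, rng):
        n, units = 200, 500
        cov = make_covariates(n, rng)
        metric = rng.standard_normal((n, units))
        res = d.unitwise_motion_association(metric, cov)
        assert res.pct_significant_fdr <= 1.0

    def test_motion_duplicated_all_significant(self, rng):
        n = 50
        cov = make_covariates(n, rng)
        metric = np.tile(cov.mean_rel_rms.to_numpy()[:, None], (1, 20))
        res = d.unitwise_motion_association(metric, cov)
        assert res.pct_significant_fdr == 100.0
        assert res.median_abs_r > 0.999

    def test_median_abs(self):
        res = d.EdgeAssociationResult(
            r=np.array([-0.3, 0.1, 0.5]),
            p=np.array([0.1, 0.2, 0.3]),
            fdr_mask=np.zeros(3, bool),
        )
        assert res.median_abs_r == pytest.approx(0.3)

    def test_constant_unit_flagged_not_dropped(self, rng):
        n = 40
        cov = make_covariates(n, rng)
        metric = rng.standard_normal((n, 5))
        metric[:, 2] = 7.0
        res = d.unitwise_motion_association(metric, cov)
        assert res.flagged[2]
        assert res.r[2] == 0.0 and res.p[2] == 1.0
        assert res.r.size == 5  # stays in the denominator


class TestDistance:
    def test_345_triangle(self):
        D = d.distance_matrix(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 0] == 0.0
        assert np.array_equal(D, D.T)

    def test_perfect_negative_linear(self, rng):
        coords = rng.uniform(-50, 50, (20, 3))
        D = d.distance_matrix(coords)
        edge_r = -d.upper_triangle(D)
        res = d.distance_dependence(edge_r, D)
        assert res.r_dd == pytest.approx(-1.0, abs=1e-12)

    def test_constant_edge_vector_flagged(self, rng):
        coords = rng.uniform(-50, 50, (10, 3))
        D = d.distance_matrix(coords)
        res = d.distance_dependence(np.zeros(45), D)
        assert (res.r_dd, res.ok) == (0.0, False)


class TestSteiger:
    def test_equal_correlations_zero(self):
        z, p = d.steiger_equality(0.4, 0.4, 0.3, 500)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        z1, _ = d.steiger_equality(0.5, 0.2, 0.3, 300)
        z2, _ = d.steiger_equality(0.2, 0.5, 0.3, 300)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_null_calibration(self, rng):
        """Rejection rate at alpha=0.05 under equal true distance-correlations
        (500 edges, 1000 Monte-Carlo draws) stays near the nominal level."""
        rho, n, reps, rejections = 0.3, 500, 1000, 0
        for _ in range(reps):
            dvec = rng.standard_normal(n)
            y1 = rho * dvec + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            y2 = rho * dvec + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            r1 = np.corrcoef(dvec, y1)[0, 1]
            r2 = np.corrcoef(dvec, y2)[0, 1]
            r12 = np.corrcoef(y1, y2)[0, 1]
            _, p = d.steiger_equality(r1, r2, r12, n)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            d.steiger_equality(1.0, 0.5, 0.3, 100)
        with pytest.raises(ValueError):
            d.steiger_equality(0.5, 0.4, 0.3, 5)


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = d.paired_t(np.arange(5.0), np.arange(5.0))
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_constant_nonzero_difference(self):
        t, df, p = d.paired_t(np.arange(4.0) + 1.0, np.arange(4.0))
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_hand_computation(self):
        """Differences {1,2,3}: t = mean / (sd/sqrt(n)) = 2 / (1/sqrt(3))."""
        t, df, p = d.paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert df == 2


class TestScalarAssociation:
    def test_exact_negative_motion(self, rng):
        cov = make_covariates(30, rng)
        pc = d.scalar_motion_association(-cov.mean_rel_rms.to_numpy(), cov)
        assert pc.r == pytest.approx(-1.0, abs=1e-9)

    def test_consistent_with_unitwise(self, rng):
        cov = make_covariates(40, rng)
        values = rng.standard_normal(40)
        pc = d.scalar_motion_association(values, cov)
        res = d.unitwise_motion_association(values[:, None], cov)
        assert pc.r == pytest.approx(res.r[0], abs=1e-12)
        assert pc.p == pytest.approx(res.p[0], rel=1e-10)

    def test_permuted_motion_null(self, rng):
        cov = make_covariates(100, rng)
        ps = []
        for _ in range(50):
            ps.append(
                d.scalar_motion_association(
                    rng.permutation(cov.mean_rel_rms.to_numpy()), cov
                ).p
            )
        assert 0.2 < np.mean(np.asarray(ps) < 0.5) < 0.8  # p roughly uniform


class TestSubnetworkBreakdown:
    def test_counting(self, atlas60):
        sig = np.zeros(60, dtype=bool)
        lab0 = atlas60.subnetwork == 0
        idx = np.flatnonzero(lab0)[:2]
        sig[idx] = True
        props = d.subnetwork_breakdown(sig, atlas60)
        assert props[0] == pytest.approx(2.0 / lab0.sum())
        assert props.drop(0).sum() == 0.0

    def test_extremes(self, atlas60):
        assert not d.subnetwork_breakdown(np.zeros(60, bool), atlas60).any()
        assert (d.subnetwork_breakdown(np.ones(60, bool), atlas60) == 1.0).all()
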