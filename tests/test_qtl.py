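import numpy as np
import pandas as pd
import pytest
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.multitest import multipletests

import vcmkit as vk
from conftest import make_matrix


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(vk.fdr_adjust([0.3]), [0.3])

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            vk.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(vk.fdr_adjust(p)[perm], vk.fdr_adjust(p[perm]))

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            q = vk.fdr_adjust(p)
            np.testing.assert_array_equal(q, brute_force_bh(p))
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], rtol=1e-12
            )

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            vk.fdr_adjust([0.5, 1.2])


class TestComputeAvcm:
    def _module(self, peak_ids):
        return vk.ChromatinModule(
            module_id="m",
            member_peaks=frozenset(peak_ids),
            chromosome="chr17",
            span=(1, 2),
            method="fdr",
            mean_r=0.5,
        )

    def test_rank_one_module_carries_all_variance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        m = make_matrix(np.vstack([x, 2 * x + 1]))
        score = vk.compute_avcm(m, self._module(["p0", "p1"]))
        assert score.variance_explained == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(score.score, z, atol=1e-10)

    def test_score_is_standardized_and_oriented(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(4, 60)))
        score = vk.compute_avcm(m, self._module(["p0", "p1", "p2", "p3"]))
        assert score.score.mean() == pytest.approx(0.0, abs=1e-12)
        assert score.score.std() == pytest.approx(1.0)
        x = m.values
        mean_signal = ((x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)).mean(0)
        assert np.corrcoef(score.score, mean_signal)[0, 1] > 0

    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(3, 80)))
        score = vk.compute_avcm(m, self._module(["p0", "p1", "p2"]))
        x = m.values
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        cov = np.cov(z)
        eigvals, eigvecs = np.linalg.eigh(cov)
        pc1 = z.T @ eigvecs[:, -1]
        cosine = np.dot(score.score, pc1) / (
            np.linalg.norm(score.score) * np.linalg.norm(pc1)
        )
        assert abs(cosine) > 1 - 1e-10
        assert score.variance_explained == pytest.approx(
            eigvals[-1] / eigvals.sum(), rel=1e-6
        )

    def test_invariant_to_member_order_and_affine_scaling(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(3, 50))
        a = vk.compute_avcm(make_matrix(vals), self._module(["p0", "p1", "p2"]))
        scaled = vals[::-1] * np.array([[3.0], [1.0], [-0.0 + 2.0]]) + 1.0
        b = vk.compute_avcm(make_matrix(scaled), self._module(["p0", "p1", "p2"]))
        np.testing.assert_allclose(a.score, b.score, atol=1e-10)

    def test_undersized_or_incomplete_modules_rejected(self):
        m = make_matrix(np.random.default_rng(6).normal(size=(2, 30)))
        with pytest.raises(ValueError, match="at least 2"):
            vk.ChromatinModule(
                module_id="m", member_peaks=frozenset(["p0"]),
                chromosome="chr17", span=(1, 2), method="fdr", mean_r=0.5,
            )
        with pytest.raises(ValueError, match="missing"):
            vk.compute_avcm(m, self._module(["p0", "zz"]))


class TestQtlScan:
    def _genotype(self, dosage):
        n = len(dosage)
        return vk.GenotypeVector(
            variant_id="v1",
            chrom="chr17",
            position=100,
            ref_allele="ATCAAA",
            alt_allele="A",
            sample_ids=[f"S{i}" for i in range(n)],
            dosage=np.asarray(dosage, float),
        )

    def test_perfect_fit_beta_one_p_zero(self):
        dosage = np.tile([0.0, 1.0, 2.0], 5)
        targets = pd.DataFrame(
            {"t": dosage}, index=[f"S{i}" for i in range(15)]
        )
        res = vk.qtl_scan(targets, [self._genotype(dosage)])
        assert res["beta"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] < 1e-100  # below any reportable floor

    def test_affine_target_recovers_slope(self):
        dosage = np.tile([0.0, 1.0, 2.0], 4)
        targets = pd.DataFrame(
            {"t": 1 + 2 * dosage}, index=[f"S{i}" for i in range(12)]
        )
        res = vk.qtl_scan(targets, [self._genotype(dosage)])
        assert res["beta"].iloc[0] == pytest.approx(2.0)

    def test_beta_matches_closed_form_and_statsmodels(self):
        rng = np.random.default_rng(7)
        dosage = rng.choice([0.0, 1.0, 2.0], size=80)
        y = 0.4 * dosage + rng.normal(size=80)
        targets = pd.DataFrame({"t": y}, index=[f"S{i}" for i in range(80)])
        res = vk.qtl_scan(targets, [self._genotype(dosage)])
        closed = np.cov(dosage, y, ddof=1)[0, 1] / dosage.var(ddof=1)
        assert res["beta"].iloc[0] == pytest.approx(closed, abs=1e-10)
        fit = OLS(y, np.column_stack([np.ones(80), dosage])).fit()
        assert res["beta"].iloc[0] == pytest.approx(fit.params[1], abs=1e-10)
        assert res["se"].iloc[0] == pytest.approx(fit.bse[1], abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_missing_dosages_dropped_per_test(self):
        dosage = np.array([0.0, 1.0, 2.0, np.nan] * 5)
        rng = np.random.default_rng(8)
        targets = pd.DataFrame(
            {"t": rng.normal(size=20)}, index=[f"S{i}" for i in range(20)]
        )
        res = vk.qtl_scan(targets, [self._genotype(dosage)])
        assert res["n"].iloc[0] == 15

    def test_constant_genotype_flagged_untestable(self):
        rng = np.random.default_rng(9)
        targets = pd.DataFrame(
            {"t": rng.normal(size=20)}, index=[f"S{i}" for i in range(20)]
        )
        res = vk.qtl_scan(targets, [self._genotype(np.ones(20))])
        assert not res["testable"].iloc[0]
        assert np.isnan(res["q"].iloc[0])


class TestScreenVariants:
    def _result(self, variant, q):
        return pd.DataFrame(
            {
                "variant_id": [variant],
                "target_id": ["t"],
                "beta": [0.5],
                "se": [0.1],
                "p": [q],
                "q": [q],
                "n": [100],
                "testable": [True],
            }
        )

    def _modules(self, size=3):
        return [
            vk.ChromatinModule(
                module_id="m0",
                member_peaks=frozenset(f"p{i}" for i in range(size)),
                chromosome="chr17",
                span=(1, 2),
                method="fdr",
                mean_r=0.6,
            )
        ]

    def test_three_way_intersection_passes(self):
        hits = vk.screen_variants(
            self._result("v", 0.01),
            self._result("v", 0.02),
            self._result("v", 0.05),
            self._modules(),
            {"v": "m0"},
        )
        assert hits == ["v"]

    def test_two_of_three_excluded(self):
        hits = vk.screen_variants(
            self._result("v", 0.01),
            self._result("v", 0.02),
            self._result("v", 0.5),
            self._modules(),
            {"v": "m0"},
        )
        assert hits == []

    def test_single_member_module_excluded(self):
        # a module must coordinate >= 2 CREs; screen enforces it structurally
        hits = vk.screen_variants(
            self._result("v", 0.01),
            self._result("v", 0.02),
            self._result("v", 0.03),
            [],
            {"v": "missing_module"},
        )
        assert hits == []


def test_null_scan_q_rate_controlled():
    """Under beta = 0 the q <= 0.10 rate stays near or below 10%."""
    rng = np.random.default_rng(10)
    hits = 0
    n_scans = 400
    for k in range(n_scans):
        dosage = rng.choice([0.0, 1.0, 2.0], size=100, p=[0.5329, 0.3942, 0.0729])
        y = rng.normal(size=100)
        targets = pd.DataFrame({"t": y}, index=[f"S{i}" for i in range(100)])
        gv = vk.GenotypeVector(
            variant_id="v", chrom="chr17", position=1, ref_allele="A",
            alt_allele="T", sample_ids=list(targets.index), dosage=dosage,
        )
        res = vk.qtl_scan(targets, [gv])
        if res["q"].iloc[0] <= 0.10:
            hits += 1
    # 3 sigma Monte-Carlo slack on a 10% binomial rate
    assert hits / n_scans <= 0.10 + 3 * np.sqrt(0.1 * 0.9 / n_scans)
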