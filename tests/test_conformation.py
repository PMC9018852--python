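import numpy as np
import pandas as pd
import pytest

import vcmkit as vk
from vcmkit.containers import CaptureCProfile, DistanceEnsemble


def small_ensemble(distances, genotype="REF", n_segments=3):
    iu, ju = np.triu_indices(n_segments, k=1)
    segments = pd.DataFrame(
        {
            "index": range(n_segments),
            "chrom": "chr17",
            "start": 8000 * np.arange(n_segments),
            "end": 8000 * (np.arange(n_segments) + 1),
        }
    )
    return DistanceEnsemble(
        genotype=genotype,
        segments=segments,
        pairs=list(zip(iu.tolist(), ju.tolist())),
        distances=np.asarray(distances, dtype=float),
    )


class TestMedianDistance:
    def test_single_cell_matrix_equals_cell(self):
        ens = small_ensemble([[10.0, 20.0, 30.0]])
        out = vk.median_distance_matrix(ens, min_obs=1)
        assert out.matrix[0, 1] == 10.0
        assert out.matrix[0, 2] == 20.0
        assert out.matrix[1, 2] == 30.0
        assert np.isnan(out.matrix[0, 0])

    def test_missing_aware_median(self):
        ens = small_ensemble(
            [[10.0, 1.0, 1.0], [np.nan, 1.0, 1.0], [20.0, 1.0, 1.0]]
        )
        out = vk.median_distance_matrix(ens, min_obs=1)
        assert out.matrix[0, 1] == 15.0
        assert out.n_observations[0, 1] == 2

    def test_min_obs_masks_sparse_pairs(self):
        d = np.full((5, 3), 10.0)
        d[1:, 0] = np.nan
        out = vk.median_distance_matrix(small_ensemble(d), min_obs=3)
        assert np.isnan(out.matrix[0, 1])
        assert out.matrix[0, 2] == 10.0

    def test_25_segments_have_300_pairs(self):
        config = vk.SimulationConfig(seed=0, orca=vk.OrcaSpec(n_cells=5))
        ref, _, _ = vk.simulate_orca_ensembles(config)
        assert ref.n_segments == 25
        assert len(ref.pairs) == 300

    def test_cell_permutation_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(50, 400, size=(40, 3))
        a = vk.median_distance_matrix(small_ensemble(d), min_obs=1)
        b = vk.median_distance_matrix(small_ensemble(d[rng.permutation(40)]), min_obs=1)
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestContactFraction:
    def test_all_below_threshold_gives_one(self):
        ens = small_ensemble(np.full((4, 3), 100.0))
        out = vk.contact_fraction(ens, threshold_nm=150.0)
        assert out.matrix[0, 1] == 1.0

    def test_half_below(self):
        ens = small_ensemble([[100.0, 100.0, 100.0], [200.0, 100.0, 100.0]])
        out = vk.contact_fraction(ens)
        assert out.matrix[0, 1] == 0.5

    def test_threshold_is_strict_and_missing_excluded(self):
        ens = small_ensemble([[150.0, np.nan, 100.0], [100.0, 120.0, 100.0]])
        out = vk.contact_fraction(ens, threshold_nm=150.0)
        assert out.matrix[0, 1] == 0.5  # 150 itself is not a contact
        assert out.matrix[0, 2] == 1.0
        assert out.n_observations[0, 2] == 1


class TestDiffMatrixTest:
    def _median(self, matrix, genotype):
        m = np.asarray(matrix, float)
        return vk.MedianDistanceMatrix(
            genotype=genotype, matrix=m, n_observations=np.full(m.shape, 100)
        )

    def _sym(self, upper):
        m = np.full((3, 3), np.nan)
        m[0, 1] = m[1, 0] = upper[0]
        m[0, 2] = m[2, 0] = upper[1]
        m[1, 2] = m[2, 1] = upper[2]
        return m

    def test_identical_matrices_give_p_one(self):
        a = self._median(self._sym([100, 200, 300]), "ALT")
        b = self._median(self._sym([100, 200, 300]), "REF")
        out = vk.diff_matrix_test(a, b)
        assert out["p"] == 1.0
        assert out["median_diff"] == 0.0

    def test_all_negative_differences_exact_binomial(self):
        S = 5  # 10 pairs, all closer in ALT
        ref = np.full((S, S), 100.0)
        np.fill_diagonal(ref, np.nan)
        alt = ref - 5.0
        out = vk.diff_matrix_test(
            self._median(alt, "ALT"), self._median(ref, "REF")
        )
        assert out["n_closer"] == 10 and out["n_further"] == 0
        assert out["p"] == pytest.approx(2 / 1024)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        S = 6
        ref = np.zeros((S, S))
        iu = np.triu_indices(S, 1)
        vals = rng.uniform(100, 300, size=len(iu[0]))
        ref[iu] = vals
        ref = ref + ref.T
        alt = ref * 0.93
        a = vk.diff_matrix_test(self._median(alt, "ALT"), self._median(ref, "REF"))
        b = vk.diff_matrix_test(self._median(ref, "REF"), self._median(alt, "ALT"))
        assert a["p"] == b["p"]
        assert a["median_diff"] == pytest.approx(-b["median_diff"])

    def test_compaction_simulation_detected(self):
        config = vk.SimulationConfig(
            seed=3, orca=vk.OrcaSpec(n_cells=2000, compaction_factor=0.9)
        )
        ref, alt, truth = vk.simulate_orca_ensembles(config)
        med_ref = vk.median_distance_matrix(ref)
        med_alt = vk.median_distance_matrix(alt)
        out = vk.diff_matrix_test(med_alt, med_ref)
        assert out["median_diff"] < 0
        assert out["p"] < 1e-10
        iu = np.triu_indices(25, 1)
        factor = np.nanmedian(med_alt.matrix[iu] / med_ref.matrix[iu])
        assert factor == pytest.approx(truth.compaction_factor, rel=0.10)

    def test_segment_mismatch_rejected(self):
        a = self._median(self._sym([1, 2, 3]), "ALT")
        b = vk.MedianDistanceMatrix(
            genotype="REF", matrix=np.zeros((4, 4)), n_observations=np.zeros((4, 4))
        )
        with pytest.raises(ValueError):
            vk.diff_matrix_test(a, b)


class TestConcordance:
    def test_self_concordance_is_one(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(size=(5, 5))
        m = (m + m.T) / 2
        assert vk.ensemble_concordance(m, m) == pytest.approx(1.0)

    def test_negated_centered_matrix_is_minus_one(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(size=(5, 5))
        m = (m + m.T) / 2
        assert vk.ensemble_concordance(m, -m) == pytest.approx(-1.0)

    def test_replicate_ensembles_concordant(self):
        base = vk.SimulationConfig(seed=6, orca=vk.OrcaSpec(n_cells=500))
        rep = vk.SimulationConfig(seed=7, orca=vk.OrcaSpec(n_cells=500))
        ref1, _, _ = vk.simulate_orca_ensembles(base)
        ref2, _, _ = vk.simulate_orca_ensembles(rep)
        m1 = vk.median_distance_matrix(ref1)
        m2 = vk.median_distance_matrix(ref2)
        assert vk.ensemble_concordance(m1.matrix, m2.matrix) >= 0.9

    def test_too_few_entries_rejected(self):
        m = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            vk.ensemble_concordance(m, m)


class TestCaptureC:
    def _profile(self, counts, starts=None, width=1000, viewpoint=5000, tad=None):
        n = len(counts)
        if starts is None:
            starts = width * np.arange(n)
        frags = pd.DataFrame(
            {
                "chrom": "chr17",
                "start": starts,
                "end": np.asarray(starts) + width,
                "count": counts,
            }
        )
        return CaptureCProfile(
            replicate_id="rep0",
            genotype="REF",
            fragments=frags,
            viewpoint=viewpoint,
            tad=tad if tad is not None else (0, width * n),
        )

    def test_mass_conservation_and_uniform_bins(self):
        profile = self._profile(np.full(10, 7.0), viewpoint=9500)
        out = vk.capturec_bin_normalize(profile, bin_bp=2000, viewpoint_exclusion_bp=400)
        assert out.fragments["count"].sum() == pytest.approx(1.0, abs=1e-12)
        # 9 kept fragments of equal count: bins hold 2/9 each except the last
        np.testing.assert_allclose(out.fragments["count"][:4], 2 / 9)

    def test_viewpoint_exclusion_removes_nearby_fragments(self):
        profile = self._profile(np.full(10, 1.0), viewpoint=5000)
        out = vk.capturec_bin_normalize(profile, bin_bp=1000, viewpoint_exclusion_bp=1000)
        # midpoints 4500 and 5500 are within 1 kb of the viewpoint
        assert out.fragments["count"][4] == 0.0
        assert out.fragments["count"][5] == 0.0
        assert out.fragments["count"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_midpoint_boundary_goes_right(self):
        # fragment [1000, 3000) has midpoint exactly 2000 -> bin [2000, 4000)
        profile = self._profile(
            [10.0], starts=np.array([1000]), width=2000, viewpoint=3500, tad=(0, 4000)
        )
        out = vk.capturec_bin_normalize(profile, bin_bp=2000, viewpoint_exclusion_bp=100)
        assert out.fragments["count"].iloc[0] == 0.0
        assert out.fragments["count"].iloc[1] == 1.0

    def test_empty_tad_after_exclusion_rejected(self):
        profile = self._profile([5.0], starts=np.array([0]), width=1000, viewpoint=500)
        with pytest.raises(ValueError, match="zero"):
            vk.capturec_bin_normalize(profile, bin_bp=500, viewpoint_exclusion_bp=600)

    def test_identical_profiles_zero_fold_change(self):
        profile = self._profile(np.arange(1.0, 11.0), viewpoint=9500)
        a = vk.capturec_bin_normalize(profile, bin_bp=2000, viewpoint_exclusion_bp=100)
        fc = vk.capturec_fold_changes([a], [a])
        np.testing.assert_allclose(fc["log2fc"], 0.0, atol=1e-12)

    def test_planted_boost_recovered(self):
        config = vk.SimulationConfig(
            seed=8, capturec=vk.CaptureCSpec(alt_boost={95: 2.0})
        )
        profiles, _ = vk.simulate_capturec(config)
        binned = {
            g: [vk.capturec_bin_normalize(p) for p in ps]
            for g, ps in profiles.items()
        }
        fc = vk.capturec_fold_changes(binned["ALT"], binned["REF"])
        assert fc["log2fc"][95] == pytest.approx(1.0, abs=0.15)

    def test_all_signal_in_viewpoint_bin_fraction_one(self):
        counts = np.zeros(10)
        counts[8] = 50.0
        profile = self._profile(counts, viewpoint=8999)
        out = vk.capturec_bin_normalize(profile, bin_bp=1000, viewpoint_exclusion_bp=100)
        fc = vk.capturec_fold_changes([out], [out])
        assert fc["viewpoint_bin_fraction"]["rep0"] == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        p1 = self._profile(np.full(10, 1.0), viewpoint=9500)
        a = vk.capturec_bin_normalize(p1, bin_bp=2000, viewpoint_exclusion_bp=100)
        b = vk.capturec_bin_normalize(p1, bin_bp=5000, viewpoint_exclusion_bp=100)
        with pytest.raises(ValueError, match="grid"):
            vk.capturec_fold_changes([a], [b])


class TestCoordinatesTransform:
    def test_euclidean_distances(self):
        xyz = np.zeros((1, 3, 3))
        xyz[0, 1] = [3.0, 4.0, 0.0]
        xyz[0, 2] = [0.0, 0.0, 10.0]
        d = vk.distances_from_coordinates(xyz)
        np.testing.assert_allclose(d[0], [5.0, 10.0, np.sqrt(9 + 16 + 100)])
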