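"""Simulator tests: geometry packing, phenotype draws, forward imaging
model, and plate-level dose effects, each against an independent oracle."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import curve_fit

from isletmt import synthetic as syn
from isletmt.errors import PackingError, StackBoundsError


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

class TestGeometry:
    def test_zero_cells_gives_empty_list(self):
        assert syn.generate_spheroid_geometry(0, 40.0, seed=1) == []

    def test_single_nucleus_contained_in_spheroid(self):
        cells = syn.generate_spheroid_geometry(
            1, 75.0, nucleus_radius_mean=3.0, nucleus_radius_cv=0.0, seed=3)
        (center, radius), = cells
        assert np.linalg.norm(center) <= 75.0 - radius <= 72.0

    def test_pairwise_nonoverlap_brute_force(self):
        """Every pair of placed nuclei is separated by at least the sum of
        radii — checked by exhaustive O(n²) comparison."""
        cells = syn.generate_spheroid_geometry(200, 40.0, seed=7)
        assert len(cells) == 200
        for i in range(len(cells)):
            ci, ri = np.asarray(cells[i][0]), cells[i][1]
            assert np.linalg.norm(ci) <= 40.0 - ri + 1e-9
            for j in range(i + 1, len(cells)):
                cj, rj = np.asarray(cells[j][0]), cells[j][1]
                assert np.linalg.norm(ci - cj) >= ri + rj - 1e-9

    def test_deterministic_given_seed(self):
        a = syn.generate_spheroid_geometry(50, 40.0, seed=5)
        b = syn.generate_spheroid_geometry(50, 40.0, seed=5)
        assert a == b

    def test_infeasible_packing_raises_with_achieved_count(self):
        with pytest.raises(PackingError):
            # total nuclear volume far above 60% of the spheroid ball
            syn.generate_spheroid_geometry(2000, 15.0, nucleus_radius_mean=3.0,
                                           seed=1)

    def test_overcrowded_but_feasible_volume_raises_packing_error(self):
        # volume-feasible but too dense for non-overlapping rejection placement
        with pytest.raises(PackingError) as exc:
            syn.generate_spheroid_geometry(
                500, 20.0, nucleus_radius_mean=2.0, nucleus_radius_cv=0.0,
                seed=1, max_attempts=50)
        assert exc.value.achieved < 500


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def geometry():
    return syn.generate_spheroid_geometry(100, 40.0, seed=11)


class TestPhenotypes:
    def test_degenerate_beta_fraction_one(self, geometry):
        model = syn.PhenotypeModel(beta_fraction=1.0)
        cells = syn.assign_phenotypes(geometry, model, seed=1)
        assert all(c.is_beta for c in cells)

    def test_zero_proliferation_rates(self, geometry):
        model = syn.PhenotypeModel(prolif_rate_beta=0.0, prolif_rate_nonbeta=0.0)
        cells = syn.assign_phenotypes(geometry, model, seed=1)
        assert not any(c.is_proliferating for c in cells)

    def test_deterministic_given_seed(self, geometry):
        model = syn.PhenotypeModel()
        a = syn.assign_phenotypes(geometry, model, seed=9)
        b = syn.assign_phenotypes(geometry, model, seed=9)
        assert all(x == y for x, y in zip(a, b))

    def test_nkx_attenuation_in_proliferating_beta(self, geometry):
        """Proliferating β-cells carry attenuated NKX6.1: with CV 0 the
        amplitude ratio equals the attenuation factor exactly."""
        model = syn.PhenotypeModel(beta_fraction=1.0, prolif_rate_beta=0.5,
                                   nkx_cv_beta=0.0, nkx_prolif_attenuation=0.6)
        cells = syn.assign_phenotypes(geometry, model, seed=2)
        prolif = [c.channel_amplitudes["nkx6_1"] for c in cells if c.is_proliferating]
        quiet = [c.channel_amplitudes["nkx6_1"] for c in cells if not c.is_proliferating]
        assert prolif and quiet
        assert np.allclose(prolif, 0.6 * model.nkx_mean_beta)
        assert np.allclose(quiet, model.nkx_mean_beta)

    def test_beta_counts_match_exact_binomial(self):
        """Across 500 seeds the β count of a 1700-cell microtissue stays
        inside the exact Binomial(1700, 0.5) 99.9% interval ≥ 99% of the
        time (exact binomial oracle)."""
        n, p = 1700, 0.5
        lo, hi = sps.binom.ppf(0.0005, n, p), sps.binom.ppf(0.9995, n, p)
        geometry = [((0.0, 0.0, 0.0), 3.0)] * n  # positions are irrelevant here
        model = syn.PhenotypeModel(beta_fraction=p)
        inside = 0
        for seed in range(500):
            cells = syn.assign_phenotypes(geometry, model, seed=seed)
            k = sum(c.is_beta for c in cells)
            inside += lo <= k <= hi
        assert inside >= 0.99 * 500


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

NOISE_FREE = dict(photon_scale=math.inf, noise_gaussian_sd=0.0)


class TestRender:
    def test_empty_cell_list_gives_background(self):
        optics = syn.OpticsConfig(background_level=8.0)
        stacks = syn.render_stack([], optics, (10, 40, 40), seed=3)
        data = stacks["dapi"].data
        se = data.std() / math.sqrt(data.size)
        assert abs(data.mean() - 8.0) < 3 * se + 1e-9

    def test_noise_free_peak_at_true_centroid(self):
        """The brightest DAPI voxel of a single noise-free nucleus lies
        within one voxel of the true center."""
        optics = syn.OpticsConfig(**NOISE_FREE)
        cell = syn.GroundTruthCell(0, (2.0, -3.0, 1.0), 3.0, True, False,
                                   {"dapi": 100.0})
        shape = (12, 60, 60)
        stacks = syn.render_stack([cell], optics, shape, seed=None)
        peak = np.unravel_index(np.argmax(stacks["dapi"].data), shape)
        vox = np.array(optics.voxel_size)
        ext = np.array(shape) * vox
        true_zyx = (np.array([cell.center[2], cell.center[1], cell.center[0]])
                    + ext / 2) / vox - 0.5
        assert np.all(np.abs(np.array(peak) - true_zyx) <= 1.0)

    def test_integrated_signal_increases_with_cell_count(self):
        """Noise-free integrated DAPI signal above background is strictly
        increasing in the number of identical-amplitude nuclei."""
        optics = syn.OpticsConfig(**NOISE_FREE)
        shape = (20, 120, 120)
        totals = []
        for n in (10, 50, 100):
            geom = syn.generate_spheroid_geometry(
                n, 25.0, nucleus_radius_cv=0.0, seed=13)
            cells = [syn.GroundTruthCell(i, c, r, True, False, {"dapi": 100.0})
                     for i, (c, r) in enumerate(geom)]
            grid = syn.render_stack(cells, optics, shape, seed=None)["dapi"]
            totals.append(float(np.sum(grid.data - optics.background_level)))
        assert totals[0] < totals[1] < totals[2]

    def test_linearity_of_forward_model(self):
        """render(A∪B) − bg == (render(A) − bg) + (render(B) − bg) for
        disjoint cell sets, noise-free."""
        optics = syn.OpticsConfig(**NOISE_FREE)
        shape = (14, 80, 80)
        geom = syn.generate_spheroid_geometry(20, 18.0, seed=17)
        cells = [syn.GroundTruthCell(i, c, r, True, False, {"dapi": 50.0 + i})
                 for i, (c, r) in enumerate(geom)]
        a, b = cells[:10], cells[10:]
        bg = optics.background_level
        img_ab = syn.render_stack(a + b, optics, shape, seed=None)["dapi"].data
        img_a = syn.render_stack(a, optics, shape, seed=None)["dapi"].data
        img_b = syn.render_stack(b, optics, shape, seed=None)["dapi"].data
        np.testing.assert_allclose(img_ab - bg, (img_a - bg) + (img_b - bg),
                                   atol=1e-8)

    def test_out_of_bounds_cell_raises_listing_ids(self):
        optics = syn.OpticsConfig()
        cell = syn.GroundTruthCell(42, (100.0, 0.0, 0.0), 3.0, True, False,
                                   {"dapi": 100.0})
        with pytest.raises(StackBoundsError) as exc:
            syn.render_stack([cell], optics, (10, 50, 50), seed=1)
        assert 42 in exc.value.offending_ids

    def test_identical_seed_and_config_bit_identical(self):
        optics = syn.OpticsConfig()
        geom = syn.generate_spheroid_geometry(30, 25.0, seed=19)
        cells = syn.assign_phenotypes(geom, syn.PhenotypeModel(), seed=20)
        a = syn.render_stack(cells, optics, (20, 110, 110), seed=21)
        b = syn.render_stack(cells, optics, (20, 110, 110), seed=21)
        for ch in syn.CHANNELS:
            np.testing.assert_array_equal(a[ch].data, b[ch].data)


# --------------------------------------------------------------------------
# plate simulation
# --------------------------------------------------------------------------

class TestPlate:
    def test_null_dose_matches_baseline_rate(self):
        """With dose 0 everywhere, the mean simulated EdU⁺ fraction stays
        within Monte-Carlo error of the phenotype baseline."""
        layout = syn.default_layout(doses=(0.0,), n_mts=30)
        phenotype = syn.PhenotypeModel(prolif_rate_beta=0.02, prolif_rate_nonbeta=0.02)
        mts = syn.simulate_plate(layout, phenotype=phenotype, seed=3, render=False)
        fracs = [np.mean([c.is_proliferating for c in mt.truth]) for mt in mts]
        n_cells = 30 * len(mts[0].truth)
        se = math.sqrt(0.02 * 0.98 / n_cells)
        assert abs(np.mean(fracs) - 0.02) < 4 * se

    def test_expected_proliferation_monotone_in_dose(self):
        """Hill-response expected proliferation is non-decreasing in dose."""
        model = syn.DoseEffectModel(ec50=0.7, hill=1.3)
        phenotype = syn.PhenotypeModel()
        doses = np.linspace(0, 10, 50)
        probs = [model.expected_total_prolif(d, phenotype) for d in doses]
        assert np.all(np.diff(probs) >= -1e-12)

    def test_unknown_layout_column_rejected(self):
        layout = syn.default_layout().drop(columns=["donor"])
        with pytest.raises(Exception, match="donor"):
            syn.simulate_plate(layout, seed=1, render=False)

    def test_ec50_recovery_from_simulated_fractions(self):
        """Fitting the Hill curve to per-MT EdU⁺ fractions (12 MTs/dose,
        5 doses) recovers the generative EC50 within a factor of 2 in
        ≥ 90% of seeds."""
        layout = syn.default_layout(n_mts=12)
        dose_model = syn.DoseEffectModel()
        n_seeds, ok = 60, 0

        def hill(d, base, emax, ec50, h):
            return base + (emax - base) * d ** h / (ec50 ** h + d ** h)

        for seed in range(n_seeds):
            mts = syn.simulate_plate(layout, dose_model, seed=seed, render=False)
            doses = np.array([mt.dose for mt in mts])
            fracs = np.array([np.mean([c.is_proliferating for c in mt.truth])
                              for mt in mts])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    popt, _ = curve_fit(hill, doses, fracs,
                                        p0=[0.005, 0.05, 2.0, 2.0],
                                        bounds=([0, 0, 0.05, 0.3],
                                                [0.2, 0.5, 20, 8]),
                                        maxfev=20000)
                except RuntimeError:
                    continue
            ok += dose_model.ec50 / 2 <= popt[2] <= dose_model.ec50 * 2
        assert ok >= 0.90 * n_seeds

    def test_simulation_reproducible_given_seed(self):
        layout = syn.default_layout(doses=(0.0, 5.0), n_mts=2)
        a = syn.simulate_plate(layout, seed=5, render=False)
        b = syn.simulate_plate(layout, seed=5, render=False)
        for x, y in zip(a, b):
            assert x.mt_id == y.mt_id
            assert x.truth == y.truth
            assert x.functional == y.functional
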