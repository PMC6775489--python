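"""Generators: known-truth construction, determinism, calibration."""
import math

import numpy as np
import pytest

from tenswood import kinematics, synthetic
from tenswood.synthetic import (ComponentSpec, UpliftModel, arc_trace_xy,
                                analytic_lift, gen_azimuthal_profile,
                                gen_component_profiles, gen_de_tables,
                                gen_promoters, gen_spectral_map,
                                gen_stem_traces)
from tenswood import regulatory as reg


class TestComponentProfiles:
    def test_single_band_peaks_at_center_with_unit_area(self, grid):
        p = gen_component_profiles([ComponentSpec("c", [(1376, 10, 1)])], grid)
        assert grid[np.argmax(p[0])] == 1376
        assert np.trapezoid(p[0], grid) == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)

    def test_zero_bands_rejected(self, grid):
        with pytest.raises(ValueError):
            ComponentSpec("empty", [])

    def test_center_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="outside grid"):
            gen_component_profiles([ComponentSpec("c", [(100, 10, 1)])], grid)

    def test_two_equal_bands_match_pointwise_gaussian_sum(self, grid):
        spec = ComponentSpec("c", [(1000, 15, 1), (1200, 15, 1)])
        p = gen_component_profiles([spec], grid)[0]
        # independent pointwise oracle
        oracle = (np.exp(-0.5 * ((grid - 1000) / 15) ** 2)
                  + np.exp(-0.5 * ((grid - 1200) / 15) ** 2))
        oracle /= np.trapezoid(oracle, grid)
        np.testing.assert_allclose(p, oracle, atol=1e-12)
        # symmetry about the midpoint 1100
        i_mid = int(np.argmin(np.abs(grid - 1100)))
        lo, hi = p[i_mid - 80:i_mid], p[i_mid + 1:i_mid + 81][::-1]
        np.testing.assert_allclose(lo, hi, rtol=1e-9)


class TestSpectralMap:
    def test_noiseless_map_factorizes_exactly(self, noiseless_map, profiles):
        recon = noiseless_map.true_concentrations @ profiles
        np.testing.assert_array_equal(noiseless_map.intensities, recon)

    def test_fixed_seed_is_bit_identical(self, tw_layout, profiles, grid):
        kw = dict(noise_sd=0.01, baseline=(0.001,), spike_rate=0.1, seed=42)
        a = gen_spectral_map(tw_layout, profiles, grid, **kw)
        b = gen_spectral_map(tw_layout, profiles, grid, **kw)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_negative_noise_rejected(self, tw_layout, profiles, grid):
        with pytest.raises(ValueError):
            gen_spectral_map(tw_layout, profiles, grid, noise_sd=-0.1)

    def test_noise_sd_matches_nominal_level(self, profiles, grid):
        # >= 1000 voxels, compare per-voxel residual sd to its nominal level
        layout = synthetic.default_layer_layout("TW", rows=15, cols=70)
        smap = gen_spectral_map(layout, profiles, grid, noise_sd=0.01, seed=5)
        clean = smap.true_concentrations @ profiles
        resid = smap.intensities - clean
        scale = clean.max()
        nominal = 0.01 * np.maximum(clean.max(axis=1), 0.05 * scale)
        ratio = resid.std(axis=1) / nominal
        assert smap.n_voxels >= 1000
        assert np.all(np.abs(ratio - 1) < 0.2)

    def test_lumen_has_no_polymer_signal(self, tw_layout):
        for comp, w in zip(("cellulose", "lignin"),
                           tw_layout.weights["lumen"][:2]):
            assert w == 0.0


class TestStemTraces:
    def test_zero_curvature_gives_straight_horizontal_line(self):
        xy = arc_trace_xy(0.0, 2.0, 100)
        assert np.all(xy[:, 1] == 0)
        assert xy[-1, 0] == pytest.approx(2.0)

    def test_half_circle_closes_over_base(self):
        xy = arc_trace_xy(180.0, 1.0, 1000)
        # half circle: endpoint directly above the base
        assert xy[-1, 0] == pytest.approx(0.0, abs=1e-9)
        assert xy[-1, 1] == pytest.approx(2.0 / math.pi, abs=1e-3)

    def test_trace_arc_length_matches_stem_length(self):
        for curv in (0.0, 45.0, 180.0):
            xy = arc_trace_xy(curv, 3.0, 500)
            seg = np.diff(xy, axis=0)
            length = np.sum(np.hypot(seg[:, 0], seg[:, 1]))
            assert abs(length - 3.0) / 3.0 < 1e-3

    def test_genotype_lift_ratio_matches_analytic_arc_formula(self):
        a = 150.0
        model = UpliftModel(days=10, genotypes={
            "A": (a, 10.0, 0.0), "B": (0.48 * a, 10.0, 0.0)},
            trees_per_genotype=2, points_per_trace=800)
        traces = gen_stem_traces(model, seed=0)
        final = [t for t in traces if t.day == 10]
        lifts = {}
        for g in ("A", "B"):
            vals = [kinematics.normalized_lift(t) for t in final
                    if t.genotype == g]
            lifts[g] = np.mean(vals)
        expected = analytic_lift(0.48 * a) / analytic_lift(a)
        assert lifts["B"] / lifts["A"] == pytest.approx(expected, abs=1e-3)


class TestAzimuthalProfile:
    def test_single_population_at_zero_is_one_gaussian(self):
        prof = gen_azimuthal_profile(mu_g=0.0, sigma_g=5.0, mu_s=40.0,
                                     weight_s=0.0, background=0.0,
                                     noise_sd=0.0)
        expected = np.exp(-0.5 * (prof.phi / 5.0) ** 2)
        np.testing.assert_allclose(prof.intensity, expected, atol=1e-12)

    def test_s_population_puts_local_maxima_at_plus_minus_mu(self):
        prof = gen_azimuthal_profile(mu_g=0.0, sigma_g=3.0, mu_s=40.0,
                                     sigma_s=8.0, weight_s=0.7,
                                     background=0.0, noise_sd=0.0)
        inten = prof.intensity
        # argmax oracle over the positive side away from the axial peak
        pos = prof.phi > 15
        assert prof.phi[pos][np.argmax(inten[pos])] == pytest.approx(40, abs=1)
        neg = prof.phi < -15
        assert prof.phi[neg][np.argmax(inten[neg])] == pytest.approx(-40, abs=1)

    def test_tension_wood_range_parameters_give_bimodal_shape(self):
        # small near-axial G angles, larger S angles: three local maxima
        prof = gen_azimuthal_profile(mu_g=2.0, sigma_g=4.0, mu_s=30.0,
                                     sigma_s=8.0, weight_s=0.6,
                                     background=0.05, noise_sd=0.0)
        inten = prof.intensity
        interior = np.arange(1, len(inten) - 1)
        peaks = [i for i in interior
                 if inten[i] >= inten[i - 1] and inten[i] >= inten[i + 1]]
        peak_angles = sorted(prof.phi[i] for i in peaks)
        assert len(peak_angles) == 3
        assert abs(peak_angles[1]) <= 5
        assert 20 <= peak_angles[2] <= 40 and -40 <= peak_angles[0] <= -20

    def test_invalid_angle_ordering_rejected(self):
        with pytest.raises(ValueError):
            gen_azimuthal_profile(mu_g=50.0, mu_s=40.0)


class TestDETables:
    def test_zero_fraction_yields_empty_et_set(self):
        wt, eti, truth = gen_de_tables(n_genes=200, frac_et_dependent=0.0,
                                       seed=1)
        et, _ = reg.et_dependent(reg.classify_drgs(wt), reg.classify_drgs(eti))
        assert truth.et_dependent == set()
        assert et == set()

    def test_planted_genes_recovered_exactly_by_set_logic(self):
        wt, eti, truth = gen_de_tables(n_genes=1000, frac_et_dependent=0.3,
                                       seed=3)
        et, _ = reg.et_dependent(reg.classify_drgs(wt), reg.classify_drgs(eti))
        assert len(truth.et_dependent) == 300
        assert et == truth.et_dependent

    def test_seeds_change_tables_but_not_marginal_counts(self):
        wt1, _, t1 = gen_de_tables(n_genes=500, frac_et_dependent=0.2, seed=1)
        wt2, _, t2 = gen_de_tables(n_genes=500, frac_et_dependent=0.2, seed=2)
        assert not wt1["log2FC"].equals(wt2["log2FC"])
        # class sizes are deterministic rounds of n * frac
        assert len(t1.et_dependent) == len(t2.et_dependent) == 100


class TestPromoters:
    def test_planted_motif_found_at_recorded_position(self):
        seqs, truth = gen_promoters(n_genes=5, length=500,
                                    plant={"ATTTCAAA": {"Potri.000002": [100]}},
                                    seed=0)
        hits = reg.scan_motif(seqs["Potri.000002"], "ATTTCAAA")
        assert 100 in [h.position for h in hits]
        assert truth.motif_positions["ATTTCAAA"]["Potri.000002"] == [100]

    def test_chance_hit_rate_matches_closed_form(self):
        # uniform background, 8-mer with 1 degenerate-free pattern:
        # E[hits per promoter] = (L - 7) * (1/4)^8
        n, length = 1000, 2000
        seqs, _ = gen_promoters(n_genes=n, length=length, seed=11)
        motif = "ATTTCAAA"
        counts = [len(reg.scan_motif(s, motif)) for s in seqs.values()]
        expect = (length - 7) * 0.25**8
        se = math.sqrt(expect / n)  # Poisson-like SE of the mean
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_empty_plant_map_leaves_truth_empty(self):
        _, truth = gen_promoters(n_genes=3, length=100, seed=0)
        assert truth.motif_positions == {}

    def test_overlong_promoter_rejected(self):
        with pytest.raises(ValueError):
            gen_promoters(n_genes=1, length=2500)
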