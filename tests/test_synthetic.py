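import numpy as np
import pytest

from quenchbind.data_model_io import intensity_at_analysis_wavelength, titration_to_frame
from quenchbind.errors import ValidationError
from quenchbind.synthetic import (
    SimulationConfig,
    gaussian_band,
    ka_at_temperature,
    simulate_assay_tables,
    simulate_titration,
    solve_free_ligand,
    true_ka_by_temp,
)
from quenchbind.thermodynamics import fit_vant_hoff


class TestKaAtTemperature:
    def test_athermal_binding_is_temperature_independent(self):
        kas = {ka_at_temperature(0.0, 60.0, t) for t in (280.0, 300.0, 320.0)}
        assert max(kas) == pytest.approx(min(kas), rel=1e-12)

    def test_reference_scale(self):
        # default generator parameters put K_A(290 K) at the 5.29e4 L/mol scale
        assert ka_at_temperature(-1368.0, 85.72, 290.0) == pytest.approx(5.29e4, rel=5e-3)

    def test_round_trip_with_vant_hoff_fit(self):
        dh, ds = -1368.0, 85.72
        ka = {t: ka_at_temperature(dh, ds, t) for t in (290.0, 300.0, 310.0)}
        fit = fit_vant_hoff(ka)
        assert fit.delta_h == pytest.approx(dh, rel=1e-9)
        assert fit.delta_s == pytest.approx(ds, rel=1e-9)


class TestFreeLigandSolver:
    def test_no_protein_no_depletion(self):
        qf, theta = solve_free_ligand(5e-5, 0.0, 5e4, 1.19)
        assert qf == 5e-5

    def test_zero_affinity_limit(self):
        qf, theta = solve_free_ligand(5e-5, 1e-5, 0.0, 1.19)
        assert (qf, theta) == (5e-5, 0.0)

    def test_brute_force_grid_oracle(self):
        """Fixed point matches a 1e6-point grid search on random draws."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            q = 10 ** rng.uniform(-5.0, -3.5)
            p = q * rng.uniform(0.05, 0.3)  # titration regime: [P] < [Q]
            ka = 10 ** rng.uniform(3.5, 5.5)
            n = rng.uniform(0.8, 1.5)
            qf, _ = solve_free_ligand(q, p, ka, n)
            grid = np.linspace(q - p, q, 1_000_001)
            theta = (ka * grid) ** n / (1 + (ka * grid) ** n)
            resid = np.abs(grid - (q - p * theta))
            qf_brute = grid[np.argmin(resid)]
            assert qf == pytest.approx(qf_brute, rel=1e-6)

    def test_self_consistency_residual(self):
        qf, theta = solve_free_ligand(8e-5, 1e-5, 5.29e4, 1.19)
        assert qf == pytest.approx(8e-5 - 1e-5 * theta, rel=1e-10)


class TestSimulateTitration:
    def test_determinism_byte_identical_csv(self, tmp_path):
        cfg = SimulationConfig(noise_sd=0.01, seed=7)
        a = titration_to_frame(simulate_titration(cfg).series).to_csv(index=False)
        b = titration_to_frame(simulate_titration(cfg).series).to_csv(index=False)
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate_titration(SimulationConfig(noise_sd=0.01, seed=1))
        b = simulate_titration(SimulationConfig(noise_sd=0.01, seed=2))
        assert not np.array_equal(a.series[0].intensities, b.series[0].intensities)

    def test_noiseless_intensity_strictly_decreasing(self, noiseless_sim):
        for s in noiseless_sim.series:
            assert np.all(np.diff(s.intensities) < 0)

    def test_exothermic_truth_gives_decreasing_ka(self):
        ka = true_ka_by_temp(SimulationConfig())
        vals = [ka[t] for t in sorted(ka)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_manifest_records_truth(self, noiseless_sim):
        m = noiseless_sim.manifest
        assert m["config"]["n_true"] == 1.19
        assert set(m["ka_true_by_temperature"]) == {"290.0", "300.0", "310.0"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            simulate_titration(SimulationConfig(molar_ratios=(1, 2, 3)))
        with pytest.raises(ValidationError):
            simulate_titration(SimulationConfig(noise_sd=-0.1))

    def test_ka_override_used_directly(self):
        cfg = SimulationConfig(ka_true={290.0: 5.0e4, 300.0: 4.0e4, 310.0: 3.0e4})
        assert true_ka_by_temp(cfg) == {290.0: 5.0e4, 300.0: 4.0e4, 310.0: 3.0e4}

    def test_recovery_error_grows_with_noise(self):
        """Median K_A estimation error is monotone over noise levels."""
        from quenchbind.binding import fit_double_log

        medians = []
        for noise in (0.0, 0.005, 0.01, 0.02):
            errs = []
            for seed in range(100):
                cfg = SimulationConfig(
                    temperatures=(290.0,), noise_sd=noise, seed=seed, replicates=3
                )
                sim = simulate_titration(cfg)
                truth = sim.manifest["ka_true_by_temperature"]["290.0"]
                fit = fit_double_log(sim.series[0])
                errs.append(abs(fit.ka - truth) / truth)
            medians.append(np.median(errs))
        assert all(b > a for a, b in zip(medians, medians[1:]))


class TestAssayTables:
    def test_noiseless_curve_recovers_coefficients_exactly(self):
        from quenchbind.assays import fit_standard_curve

        tables, truth = simulate_assay_tables(seed=0)
        df = tables["standard_curve"]
        curve = fit_standard_curve(list(zip(df["conc_mg_ml"], df["absorbance"])))
        assert curve.slope == pytest.approx(truth["standard_curve"]["slope"], rel=1e-12)
        assert curve.intercept == pytest.approx(
            truth["standard_curve"]["intercept"], rel=1e-12
        )

    def test_seed_determinism(self):
        a, _ = simulate_assay_tables(seed=3, noise_sd=0.01)
        b, _ = simulate_assay_tables(seed=3, noise_sd=0.01)
        for k in a:
            assert a[k].equals(b[k])

    def test_noisy_curve_slope_within_one_percent(self):
        from quenchbind.assays import fit_standard_curve

        tables, truth = simulate_assay_tables(seed=5, noise_sd=0.01, n_curve_points=100)
        df = tables["standard_curve"]
        curve = fit_standard_curve(list(zip(df["conc_mg_ml"], df["absorbance"])))
        assert curve.slope == pytest.approx(truth["standard_curve"]["slope"], rel=0.01)


def test_gaussian_band_extraction():
    spec = gaussian_band(center_nm=330.0, width_nm=25.0, amplitude=1000.0)
    assert intensity_at_analysis_wavelength(spec, 330.0) == pytest.approx(1000.0)
    # symmetric flanks
    left = intensity_at_analysis_wavelength(spec, 320.0)
    right = intensity_at_analysis_wavelength(spec, 340.0)
    assert left == pytest.approx(right, rel=1e-9)
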