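"""Artificial clinical data: noise law, representative selection, thinning."""

import numpy as np
import pytest

from kinfault import (Perturbation, SamplingSpec, Trajectory, add_noise,
                      apply_perturbation, generate_clinical, read_clinical,
                      select_representative, simulate, thin,
                      trajectory_similarity, write_clinical)


def constant_traj(value=10.0, n=10000):
    t = np.arange(n, dtype=float) / 3600
    return Trajectory(times=t, values=np.full((n, 1), value),
                      output_names=("y",))


class TestAddNoise:
    def test_zero_noise_is_identity(self, steady_traj):
        out = add_noise(steady_traj, 0.0, seed=5)
        assert np.array_equal(out.values, steady_traj.values)

    def test_seeded_draws_reproducible(self, steady_traj):
        a = add_noise(steady_traj, 0.2, seed=7)
        b = add_noise(steady_traj, 0.2, seed=7)
        assert np.array_equal(a.values, b.values)
        c = add_noise(steady_traj, 0.2, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_moments_match_stated_gaussian_law(self):
        # constant 10 nM profile, 20% noise: draws ~ Normal(10, 2)
        noisy = add_noise(constant_traj(10.0, 10000), 0.2, seed=1)
        assert np.mean(noisy.values) == pytest.approx(10.0, abs=0.1)
        assert np.std(noisy.values) == pytest.approx(2.0, abs=0.1)

    def test_zero_entries_stay_zero(self):
        t = np.arange(5.0)
        traj = Trajectory(times=t, values=np.zeros((5, 1)),
                          output_names=("y",))
        assert np.array_equal(add_noise(traj, 0.5, seed=0).values,
                              traj.values)

    def test_clamping_flag(self):
        traj = constant_traj(1.0, 5000)
        clamped = add_noise(traj, 1.0, seed=2, clamp=True)
        raw = add_noise(traj, 1.0, seed=2, clamp=False)
        assert clamped.values.min() == 0.0
        assert raw.values.min() < 0.0
        mask = raw.values >= 0
        assert np.array_equal(clamped.values[mask], raw.values[mask])

    def test_negative_fraction_rejected(self, steady_traj):
        with pytest.raises(ValueError):
            add_noise(steady_traj, -0.1, seed=0)

    def test_sd_scales_linearly_with_fraction(self):
        sds = [np.std(add_noise(constant_traj(10.0, 20000), f, seed=3,
                                clamp=False).values)
               for f in (0.2, 0.4, 0.6, 0.8)]
        ratios = np.array(sds) / sds[0]
        assert np.allclose(ratios, [1, 2, 3, 4], rtol=0.05)


class TestGenerateClinical:
    def test_noise_free_dataset_equals_perturbed_simulation(
            self, steady_model, steady_spec):
        truth = Perturbation("rate_up", "r2", 1000.0)
        ds = generate_clinical(steady_model, truth, 0.0, steady_spec)
        clean = simulate(apply_perturbation(steady_model, truth), steady_spec)
        assert np.array_equal(ds.trajectory.values, clean.values)
        assert ds.truth == truth

    def test_noise_coverage_near_gaussian_68pct(self, steady_model):
        truth = Perturbation("rate_up", "r2", 1000.0)
        spec = SamplingSpec(10, 60)  # dense grid for a tight estimate
        ds = generate_clinical(steady_model, truth, 0.2, spec, seed=1)
        clean = simulate(apply_perturbation(steady_model, truth), spec)
        mask = clean.values > 1e-6
        frac = np.mean(np.abs(ds.trajectory.values - clean.values)[mask]
                       <= 0.2 * clean.values[mask])
        assert frac == pytest.approx(0.68, abs=0.04)

    def test_bookkeeping(self, osc_model, osc_spec):
        truth = Perturbation("molecule_up", "ikba_nfkb", 10.0)
        ds = generate_clinical(osc_model, truth, 0.2, osc_spec, seed=7)
        assert len(ds.trajectory.times) == 91
        assert ds.truth == truth and ds.seed == 7
        assert ds.source_model == osc_model.name

    def test_replicate_average_recovers_clean_profile(self, steady_model):
        # expectation recovery: the mean of many noisy replicates converges
        # to the clean profile within sampling error
        truth = Perturbation("rate_up", "r2", 100.0)
        spec = SamplingSpec(10, 2)
        clean = simulate(apply_perturbation(steady_model, truth), spec)
        reps = np.stack([
            generate_clinical(steady_model, truth, 0.2, spec, seed=s)
            .trajectory.values for s in range(200)])
        mean, sd = reps.mean(axis=0), reps.std(axis=0, ddof=1)
        se = sd / np.sqrt(len(reps))
        mask = clean.values > 1e-3
        z = np.abs(mean - clean.values)[mask] / se[mask]
        # pointwise 3-SE check, allowing the expected rare exceedances
        assert np.mean(z < 3) > 0.98


class TestSelectRepresentative:
    def test_minimizes_dissimilarity_over_scanned_set(self, steady_model,
                                                      steady_spec,
                                                      steady_cache):
        from kinfault import candidate_universe
        grid = [10.0, 50.0]
        rep = select_representative(steady_model, "rate_up", grid,
                                    steady_spec, sim_cache=steady_cache)
        normal = simulate(steady_model, steady_spec)
        scores = {}
        for cand in candidate_universe(steady_model, "rate_up"):
            for fold in grid:
                p = Perturbation("rate_up", cand, fold)
                traj = simulate(apply_perturbation(steady_model, p),
                                steady_spec)
                scores[(cand, fold)] = trajectory_similarity(
                    normal, traj)[0].S
        assert scores[(rep.target, rep.fold)] == min(scores.values())

    def test_identity_fold_ties_break_by_candidate_order(self, steady_model,
                                                         steady_spec):
        rep = select_representative(steady_model, "rate_up", [1.0],
                                    steady_spec)
        assert rep.target == steady_model.rate_constant_names[0]
        assert rep.fold == 1.0

    def test_empty_grid_rejected(self, steady_model):
        with pytest.raises(ValueError):
            select_representative(steady_model, "rate_up", [])


class TestThin:
    def test_same_density_unchanged(self, steady_model, steady_spec):
        ds = generate_clinical(steady_model,
                               Perturbation("rate_up", "r2", 10.0),
                               0.2, steady_spec, seed=0)
        assert thin(ds, 6) is ds

    def test_six_to_one_per_hour(self, osc_model, osc_spec):
        ds = generate_clinical(osc_model,
                               Perturbation("molecule_up", "ikba_nfkb", 10.0),
                               0.2, osc_spec, seed=0)
        out = thin(ds, 1)
        assert len(out.trajectory.times) == 16
        assert out.trajectory.times[0] == 0.0
        assert np.allclose(np.diff(out.trajectory.times), 1.0)
        assert out.density_per_hour == 1

    def test_non_divisible_density_rejected(self, steady_model, steady_spec):
        ds = generate_clinical(steady_model,
                               Perturbation("rate_up", "r2", 10.0),
                               0.0, steady_spec)
        with pytest.raises(ValueError, match="divide"):
            thin(ds, 4)

    def test_thinning_composes(self, steady_model, steady_spec):
        ds = generate_clinical(steady_model,
                               Perturbation("rate_up", "r2", 10.0),
                               0.2, steady_spec, seed=3)
        via_3 = thin(thin(ds, 3), 1)
        direct = thin(ds, 1)
        assert np.array_equal(via_3.trajectory.values,
                              direct.trajectory.values)


class TestClinicalIO:
    def test_round_trip_with_sidecar(self, steady_model, steady_spec,
                                     tmp_path):
        truth = Perturbation("molecule_down", "pp2", 0.01)
        ds = generate_clinical(steady_model, truth, 0.2, steady_spec, seed=11)
        path = tmp_path / "clin.csv"
        write_clinical(ds, path)
        assert (tmp_path / "clin.json").exists()
        back = read_clinical(path)
        assert np.allclose(back.trajectory.values, ds.trajectory.values,
                           rtol=1e-15)
        assert back.truth == truth
        assert back.noise_fraction == 0.2
        assert back.seed == 11
        assert back.density_per_hour == 6
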