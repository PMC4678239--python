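"""The fault scan: universes, oracle equivalence, ranking and sweeps."""

import numpy as np
import pytest

from kinfault import (CandidateResult, FoldGrid, Perturbation, RankTable,
                      SamplingSpec, SimulationCache, apply_perturbation,
                      candidate_universe, confirm_with_RA, density_sweep,
                      generate_clinical, noise_sweep, preexisting_set, scan,
                      simulate, trajectory_similarity)
from kinfault.models import Reaction, ReactionNetwork, KineticModel


@pytest.fixture(scope="module")
def toy_model():
    """Three-reaction cascade: stimulus activates A -> B -> C (C decays)."""
    net = ReactionNetwork(
        ["A", "B", "C"], "u",
        [Reaction("r1", (("A", 1), ("u", 1)), (("B", 1), ("u", 1))),
         Reaction("r2", (("B", 1),), (("C", 1),)),
         Reaction("r3", (("C", 1),), ())])
    return KineticModel(
        name="toy", state_names=("A", "B", "C"),
        initial_state=np.array([5.0, 0.0, 0.0]),
        rate_constant_names=net.reaction_names,
        rate_constants=np.array([2e-4, 5e-4, 2e-4]),
        stimulus_name="u", stimulus=10.0, output_names=("C",),
        rhs=net.rhs, default_horizon_h=5.0, network=net)


class TestCandidateUniverse:
    @pytest.mark.parametrize("kind", ["rate_up", "rate_down"])
    def test_rate_kinds_scan_every_reaction(self, steady_model, kind):
        assert candidate_universe(steady_model, kind) == \
            steady_model.rate_constant_names

    @pytest.mark.parametrize("kind", ["molecule_up", "molecule_down"])
    def test_molecule_kinds_scan_preexisting_only(self, steady_model, kind):
        assert set(candidate_universe(steady_model, kind)) == \
            set(preexisting_set(steady_model))

    def test_no_preexisting_molecules_warns(self):
        model = KineticModel(
            name="empty", state_names=("a",),
            initial_state=np.array([0.0]),
            rate_constant_names=("k1",), rate_constants=np.array([1e-3]),
            stimulus_name="u", stimulus=1.0, output_names=("a",),
            rhs=lambda x, k, u: np.array([k[0] * u - k[0] * x[0]]))
        with pytest.warns(UserWarning, match="no preexisting"):
            assert candidate_universe(model, "molecule_up") == ()


class TestScan:
    def test_scan_max_S_matches_brute_force_enumeration(self, toy_model):
        # oracle equivalence on the 3-reaction cascade with a 3-point grid
        spec = SamplingSpec(5, 6)
        grid = FoldGrid(up=(2.0, 5.0, 10.0), down=(0.5,))
        truth = Perturbation("rate_up", "r2", 5.0)
        ds = generate_clinical(toy_model, truth, 0.2, spec, seed=4)
        table = scan(toy_model, ds, "rate_up", grid, spec)

        for cand in toy_model.rate_constant_names:
            best_s, best_fold = -1.0, None
            for fold in grid.up:
                p = Perturbation("rate_up", cand, fold)
                traj = simulate(apply_perturbation(toy_model, p), spec)
                s = trajectory_similarity(ds.trajectory, traj)[0].S
                if s > best_s:
                    best_s, best_fold = s, fold
            row = table.result_for(cand)
            assert row.S == best_s
            assert row.best_fold == best_fold

    def test_noise_free_in_grid_truth_self_matches(self, toy_model):
        spec = SamplingSpec(5, 6)
        grid = FoldGrid(up=(2.0, 5.0, 10.0), down=(0.5,))
        truth = Perturbation("rate_up", "r2", 5.0)
        ds = generate_clinical(toy_model, truth, 0.0, spec)
        table = scan(toy_model, ds, "rate_up", grid, spec)
        assert table.rows[0].candidate == "r2"
        assert table.rows[0].S == 1.0
        assert table.rows[0].best_fold == 5.0

    def test_every_candidate_appears_exactly_once(self, steady_model,
                                                  steady_spec, steady_cache):
        truth = Perturbation("molecule_down", "pp2", 0.01)
        ds = generate_clinical(steady_model, truth, 0.2, steady_spec, seed=0)
        table = scan(steady_model, ds, "molecule_down", spec=steady_spec,
                     cache=steady_cache)
        cands = [r.candidate for r in table.rows]
        assert sorted(cands) == sorted(preexisting_set(steady_model))
        svals = [r.S for r in table.rows]
        assert svals == sorted(svals, reverse=True) or \
            any(np.isfinite(r.RA_distance) for r in table.rows)

    def test_fixed_seed_scans_are_identical(self, steady_model, steady_spec,
                                            steady_cache):
        truth = Perturbation("rate_up", "r5", 1000.0)
        grid = FoldGrid(up=(10.0, 100.0, 1000.0), down=(0.1,))
        tables = []
        for _ in range(2):
            ds = generate_clinical(steady_model, truth, 0.2, steady_spec,
                                   seed=42)
            tables.append(scan(steady_model, ds, "rate_up", grid,
                               steady_spec, cache=steady_cache))
        a, b = tables
        assert [r.candidate for r in a.rows] == [r.candidate for r in b.rows]
        assert [r.S for r in a.rows] == [r.S for r in b.rows]

    def test_clinical_off_grid_rejected(self, steady_model, steady_spec):
        from kinfault.errors import GridMismatchError
        ds = generate_clinical(steady_model,
                               Perturbation("rate_up", "r2", 10.0),
                               0.0, SamplingSpec(10, 3))
        with pytest.raises(GridMismatchError):
            scan(steady_model, ds, "rate_up", spec=steady_spec)


def _row(candidate, S, ra):
    return CandidateResult(candidate=candidate, kind="rate_up", best_fold=10.0,
                           S=S, shape_term=S, magnitude_term=1.0,
                           per_output_S={}, RA_distance=ra)


class TestConfirmWithRA:
    def test_distinct_S_order_unchanged(self):
        table = RankTable(rows=[_row("a", 0.9, 5.0), _row("b", 0.7, 0.0),
                                _row("c", 0.5, 1.0)], condition="rate_up")
        out = confirm_with_RA(table, top_k=3)
        assert [r.candidate for r in out.rows] == ["a", "b", "c"]

    def test_tied_S_reordered_by_RA_distance(self):
        table = RankTable(rows=[_row("a", 0.900, 3.0), _row("b", 0.899, 0.0)],
                          condition="rate_up")
        out = confirm_with_RA(table, top_k=2)
        assert [r.candidate for r in out.rows] == ["b", "a"]

    def test_clear_S_winner_never_demoted(self):
        table = RankTable(rows=[_row("a", 0.95, 9.9), _row("b", 0.80, 0.0)],
                          condition="rate_up")
        out = confirm_with_RA(table, top_k=2)
        assert out.rows[0].candidate == "a"

    def test_medium_difference_fault_confirmed_by_RA(self, osc_model,
                                                     osc_spec, osc_cache):
        # a moderate-fold fault: S margins shrink, but the truth keeps both
        # rank 1 and the closest oscillation features among the top 5
        truth = Perturbation("molecule_down", "tradd", 0.1)
        ds = generate_clinical(osc_model, truth, 0.2, osc_spec, seed=3)
        table = confirm_with_RA(
            scan(osc_model, ds, "molecule_down", spec=osc_spec,
                 cache=osc_cache))
        assert table.rows[0].candidate == "tradd"
        closest = min(table.rows[:5], key=lambda r: r.RA_distance)
        assert closest.candidate == "tradd"


class TestSweeps:
    def test_zero_noise_sweep_recovers_exactly(self, toy_model):
        spec = SamplingSpec(5, 6)
        grid = FoldGrid(up=(2.0, 5.0, 10.0), down=(0.5,))
        truth = Perturbation("rate_up", "r2", 5.0)
        runs, agg = noise_sweep(toy_model, truth, [0.0], [0, 1, 2],
                                grid=grid, spec=spec)
        assert (runs["rank_of_truth"] == 1).all()
        assert (runs["S_of_truth"] == 1.0).all()
        assert agg["rank1_fraction"].iloc[0] == 1.0

    def test_density_sweep_base_matches_plain_scan(self, toy_model):
        spec = SamplingSpec(5, 6)
        grid = FoldGrid(up=(2.0, 5.0, 10.0), down=(0.5,))
        truth = Perturbation("rate_up", "r2", 5.0)
        df = density_sweep(toy_model, truth, [6], grid=grid, seed=1,
                           base_density=6)
        ds = generate_clinical(toy_model, truth, 0.2, spec, seed=1)
        table = scan(toy_model, ds, "rate_up", grid, spec)
        assert df["rank_of_truth"].iloc[0] == table.rank_of("r2")
        assert df["S_of_truth"].iloc[0] == table.result_for("r2").S

    def test_non_divisible_density_propagates_error(self, toy_model):
        truth = Perturbation("rate_up", "r2", 5.0)
        with pytest.raises(ValueError, match="divide"):
            density_sweep(toy_model, truth, [4], seed=0, base_density=6)


class TestFoldGrid:
    def test_default_up_grid_spacing(self):
        grid = FoldGrid()
        assert grid.up[:3] == (5.0, 10.0, 15.0)
        assert grid.up[-2:] == (900.0, 1000.0)
        assert 100.0 in grid.up and 200.0 in grid.up

    def test_down_grid_contains_decades(self):
        grid = FoldGrid()
        for f in (1e-1, 1e-2, 1e-3, 1e-4):
            assert f in grid.down

    def test_fold_of_one_rejected(self):
        with pytest.raises(ValueError):
            FoldGrid(up=(1.0, 5.0))
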