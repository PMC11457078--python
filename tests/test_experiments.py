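"""Tests of the fitness-grid, multi-environment and perturbation experiments."""

import math

import numpy as np
import pytest

from imdsim import (
    EnvironmentSpec,
    FitnessGrid,
    ImdParameters,
    MultiEnvConfig,
    PerturbationConfig,
    WalkConfig,
    compute_piw,
    delta_counts,
    delta_scan,
    evaluate_environment,
    gamma_scan,
    generate_environment,
    run_encounter_simulation,
    run_fitness_grid,
    sample_multi_environment,
)

TINY_WALKS = WalkConfig(n_steps=200, n_walks=3, seed=0)


def _grid(f_ind, f_con):
    f_ind = np.atleast_2d(np.asarray(f_ind, dtype=float))
    return FitnessGrid(
        densities=list(range(f_ind.shape[0])),
        patchiness_levels=list(range(f_ind.shape[1])),
        F_induced=f_ind,
        F_constitutive=np.atleast_2d(np.asarray(f_con, dtype=float)),
        A_opt=np.zeros_like(f_ind),
    )


class TestPIW:
    def test_all_wins(self):
        assert compute_piw(_grid([[0.9, 0.8]], [[0.5, 0.5]])) == 1.0

    def test_ties_count_as_constitutive_wins(self):
        assert compute_piw(_grid([[0.5, 0.5]], [[0.5, 0.5]])) == 0.0

    def test_fraction_of_wins(self):
        outcomes = [True, True, True, False, False, False, False, False]
        assert compute_piw(outcomes) == 0.375

    def test_invariant_to_ordering(self):
        outcomes = [True, False, True, False]
        assert compute_piw(outcomes) == compute_piw(outcomes[::-1])

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            compute_piw([])


class TestFitnessGrid:
    def test_shapes_validated(self):
        with pytest.raises(ValueError):
            FitnessGrid(
                densities=[1, 2],
                patchiness_levels=[1],
                F_induced=np.zeros((1, 1)),
                F_constitutive=np.zeros((2, 1)),
                A_opt=np.zeros((2, 1)),
            )

    def test_single_cell_grid_runs_and_is_consistent(self):
        grid = run_fitness_grid(
            ImdParameters(), 0.1, densities=[20], patchiness_levels=[1],
            walk_cfg=TINY_WALKS, size=30, seed=5,
        )
        assert grid.F_induced.shape == (1, 1)
        np.testing.assert_allclose(
            grid.delta_F, grid.F_constitutive - grid.F_induced
        )

    def test_grid_is_reproducible(self):
        kwargs = dict(
            densities=[10, 40], patchiness_levels=[1, 10],
            walk_cfg=TINY_WALKS, size=30, seed=5,
        )
        a = run_fitness_grid(ImdParameters(), 0.1, **kwargs)
        b = run_fitness_grid(ImdParameters(), 0.1, **kwargs)
        np.testing.assert_array_equal(a.F_induced, b.F_induced)
        np.testing.assert_array_equal(a.F_constitutive, b.F_constitutive)

    def test_sterile_row_favors_induction(self):
        """No bacteria: induction is free (F=1), constitutive pays its floor."""
        grid = run_fitness_grid(
            ImdParameters(), 0.1, densities=[0], patchiness_levels=[1],
            walk_cfg=TINY_WALKS, size=30, seed=2,
        )
        assert grid.F_induced[0, 0] == 1.0
        assert grid.F_constitutive[0, 0] == pytest.approx(math.exp(-0.01))
        assert grid.A_opt[0, 0] == pytest.approx(0.01)
        assert grid.delta_F[0, 0] < 0


class TestMultiEnvironmentSampling:
    def _pool(self):
        # hand-built pool: constitutive wins each environment in isolation
        grid = np.round(np.arange(1, 201) * 0.01, 10)
        curves = [np.exp(-(b / (grid + 0.05) + grid)) for b in (0.3, 1.5)]
        f_ind = [c.max() - 0.01 for c in curves]
        return f_ind, curves, grid

    def test_single_environment_draws_never_win(self):
        f_ind, curves, _ = self._pool()
        cfg = MultiEnvConfig(j=1, n_repeats=200, seed=1)
        assert sample_multi_environment(cfg, f_ind, curves) == 0.0

    @pytest.mark.parametrize("q", [0.0, 1.0])
    def test_degenerate_two_environment_weights_reduce_to_single(self, q):
        f_ind, curves, _ = self._pool()
        cfg = MultiEnvConfig(n_repeats=200, q=q, seed=2)
        assert sample_multi_environment(cfg, f_ind, curves) == 0.0

    def test_two_environment_pool_matches_exhaustive_oracle(self):
        f_ind, curves, _ = self._pool()
        cfg = MultiEnvConfig(j=2, n_repeats=50, seed=3)
        piw = sample_multi_environment(cfg, f_ind, curves)
        # only one unordered draw exists; compute its outcome by hand
        fi = (f_ind[0] + f_ind[1]) / 2
        fc = ((curves[0] + curves[1]) / 2).max()
        assert piw == (1.0 if fi > fc else 0.0)

    def test_symmetric_pool_gives_symmetric_q_curve(self):
        f_ind, curves, _ = self._pool()
        piw_q = sample_multi_environment(
            MultiEnvConfig(n_repeats=2000, q=0.3, seed=4), f_ind, curves
        )
        piw_1mq = sample_multi_environment(
            MultiEnvConfig(n_repeats=2000, q=0.7, seed=4), f_ind, curves
        )
        assert abs(piw_q - piw_1mq) <= 0.05

    def test_oversized_draw_rejected(self):
        f_ind, curves, _ = self._pool()
        with pytest.raises(ValueError):
            sample_multi_environment(MultiEnvConfig(j=3, n_repeats=10), f_ind, curves)


class TestGammaScan:
    def test_identity_perturbation_reproduces_unperturbed_piw(self, small_env):
        params = ImdParameters()
        scan = gamma_scan(
            params, PerturbationConfig(gammas=(1.0,)), [0.1], [small_env], TINY_WALKS
        )
        res = evaluate_environment(params, 0.1, small_env, TINY_WALKS)
        expected = 1.0 if res["F_induced"] > res["F_constitutive"] else 0.0
        assert scan.loc[0, "piw"] == expected

    def test_scan_is_deterministic(self, small_env):
        cfg = PerturbationConfig(gammas=(0.5, 1.0))
        a = gamma_scan(ImdParameters(), cfg, [0.1], [small_env], TINY_WALKS)
        b = gamma_scan(ImdParameters(), cfg, [0.1], [small_env], TINY_WALKS)
        assert a.equals(b)

    def test_removing_input_feedback_raises_amp_and_lowers_regulators(self, small_env):
        """gamma -> 0 silences PGRP-LB/Pirk, so AMP output (and cost) grows."""
        base = ImdParameters()
        low = base.replace(beta3=0.01 * base.beta3, beta4=0.01 * base.beta4)
        walks = WalkConfig(n_steps=500, n_walks=5, seed=13)
        m_base = run_encounter_simulation("induced", base, small_env, walks).mean()
        m_low = run_encounter_simulation("induced", low, small_env, walks).mean()
        assert m_low["L"] < m_base["L"]
        assert m_low["P"] < m_base["P"]
        assert m_low["A"] > m_base["A"]


class TestDeltaScan:
    def test_singleton_scan_marks_unperturbed_best_everywhere(self, small_env):
        scan = delta_scan(
            ImdParameters(), PerturbationConfig(deltas=(1.0,)), [0.1],
            [small_env], TINY_WALKS,
        )
        assert scan["best"].all()

    def test_best_deltas_partition_the_environments(self):
        envs = [
            generate_environment(EnvironmentSpec(density=d, patchiness=1, size=30, seed=s))
            for d, s in ((20, 1), (60, 2), (120, 3))
        ]
        scan = delta_scan(
            ImdParameters(), PerturbationConfig(deltas=(1.0, 2.0, 4.0)),
            [0.1, 0.5], envs, TINY_WALKS,
        )
        counts = delta_counts(scan)
        assert counts.groupby("k0")["n_environments"].sum().eq(len(envs)).all()

    def test_scan_must_include_unperturbed_value(self, small_env):
        with pytest.raises(ValueError):
            delta_scan(
                ImdParameters(), PerturbationConfig(deltas=(2.0, 4.0)), [0.1],
                [small_env], TINY_WALKS,
            )

    def test_without_repressosome_fitness_ignores_binding_energy(self, small_env):
        """beta5=0 keeps S at zero, so Zs never enters the dynamics."""
        params = ImdParameters(beta5=0.0)
        scan = delta_scan(
            params, PerturbationConfig(deltas=(1.0, 2.0, 4.0, 10.0)), [0.1],
            [small_env], TINY_WALKS,
        )
        fits = scan["F_induced"].to_numpy()
        assert np.all(fits == fits[0])  # bitwise identical trajectories
        best = scan[scan["best"]]
        assert (best["delta"] == 1.0).all()  # ties break to the smallest delta
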