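"""Deterministic single-plant model: cost, deposition, occupancy, fitness,
and the 0.01-mm adaptive walk."""

import math

import numpy as np
import pytest

from seedrift import (
    DetParams,
    Landscape1D,
    calibrate_kernel,
    deposition_pmf,
    det_fitness,
    habitable_mask,
    lambda_of_size,
    occupancy_prob,
    optimize_seed_size,
    seed_cost,
    seeds_per_cell,
)


class TestSeedCost:
    def test_zero_cost_constant(self):
        assert seed_cost(17.0, 0.0) == 0.0

    def test_frozen_examples(self):
        # c1 * pi * S^3 / 6
        assert seed_cost(30.0, 1e-4) == pytest.approx(1.413717, rel=1e-6)
        assert seed_cost(0.5, 1e-4) == pytest.approx(6.544985e-6, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            seed_cost(-1.0, 1e-4)
        with pytest.raises(ValueError):
            seed_cost(5.0, -1e-4)


class TestSeedsPerCell:
    def test_frozen_example(self, flat_kernel):
        # lambda = 0.5 everywhere, no cost: 7 seeds split [4, 2, 1]
        p = DetParams(n_tot=7, g=0.3, c1=0.0, d_max=3)
        np.testing.assert_allclose(
            seeds_per_cell(1.0, flat_kernel, p), [4.0, 2.0, 1.0], rtol=1e-12
        )

    def test_strictly_decreasing_with_distance(self, kernel_fig3a):
        p = DetParams(d_max=500)
        n_d = seeds_per_cell(10.0, kernel_fig3a, p)
        assert np.all(np.diff(n_d) < 0)

    def test_mass_conservation_over_random_draws(self, rng):
        """Total deposition equals the cost-discounted seed budget (100 draws)."""
        for _ in range(100):
            d05 = rng.uniform(20, 300)
            d30 = rng.uniform(50, 750)
            k = calibrate_kernel(d05, d30)
            s = rng.uniform(0.5, 25.0)
            c1 = rng.uniform(0, 1e-4)
            p = DetParams(
                n_tot=float(rng.integers(100, 100_000)),
                g=rng.uniform(0, 1),
                c1=c1,
                d_max=int(rng.integers(1, 5000)),
            )
            total = seeds_per_cell(s, k, p).sum()
            expected = p.n_tot * (1.0 - seed_cost(s, p.c1))
            assert total == pytest.approx(expected, rel=1e-9)

    def test_prohibitive_cost_raises(self, kernel_fig3a):
        p = DetParams(c1=1e-4)
        with pytest.raises(ValueError):
            seeds_per_cell(30.0, kernel_fig3a, p)  # c ≈ 1.41 >= 1


class TestOccupancyProb:
    def test_examples(self):
        assert occupancy_prob(0.0, 0.5) == 0.0
        assert occupancy_prob(3.0, 1.0) == 1.0
        assert occupancy_prob(2.0, 0.3) == pytest.approx(0.51, rel=1e-12)

    def test_real_valued_exponent(self):
        assert occupancy_prob(0.5, 0.3) == pytest.approx(1 - 0.7**0.5, rel=1e-12)

    def test_small_probability_accuracy(self):
        # 1-(1-g)^n ~ n*g for tiny g*n; naive power form would lose precision
        val = occupancy_prob(1e-8, 1e-8)
        assert val == pytest.approx(1e-16, rel=1e-6)


class TestDetFitness:
    def test_zero_survival_means_zero_fitness(self, kernel_fig3a, small_window):
        p = DetParams(g=0.0, d_max=small_window.d_max)
        assert det_fitness(5.0, small_window, kernel_fig3a, p) == 0.0

    def test_single_habitable_cell_certain_occupancy(self, flat_kernel):
        ls = Landscape1D(x_h=1, x_ipd=10, mode="bounded", d_max=3)
        p = DetParams(n_tot=7, g=1.0, c1=0.0, d_max=3)
        assert det_fitness(1.0, ls, flat_kernel, p) == pytest.approx(1.0)

    def test_cost_above_one_gives_zero_fitness(self, kernel_fig3a, small_window):
        p = DetParams(c1=1e-4, d_max=small_window.d_max)
        assert det_fitness(30.0, small_window, kernel_fig3a, p) == 0.0

    def test_matches_brute_force_cell_loop(self, rng):
        """Oracle: apply deposition + occupancy cell by cell, mask matrix cells."""
        for _ in range(50):
            k = calibrate_kernel(rng.uniform(20, 300), rng.uniform(50, 750))
            p = DetParams(
                n_tot=float(rng.integers(100, 20_000)),
                g=rng.uniform(0.01, 1.0),
                c1=rng.uniform(0, 5e-5),
                d_max=int(rng.integers(10, 400)),
            )
            ls = Landscape1D(
                x_h=int(rng.integers(1, 60)),
                x_ipd=int(rng.integers(0, 60)),
                mode="bounded",
                d_max=p.d_max,
            )
            s = rng.uniform(0.5, 20.0)
            lam = lambda_of_size(s, k)
            n_d = p.n_tot * (1 - seed_cost(s, p.c1)) * deposition_pmf(lam, p.d_max)
            brute = sum(
                occupancy_prob(n_d[d], p.g)
                for d in range(p.d_max)
                if habitable_mask(ls, p.d_max)[d]
            )
            assert det_fitness(s, ls, k, p) == pytest.approx(brute, rel=1e-12)

    def test_monte_carlo_occupancy_oracle(self, rng):
        """Mechanical simulation (multinomial landing + Bernoulli germination)
        reproduces the analytic per-cell occupancy probability.

        g is small so the binomial landing counts and the expected-count
        exponent of the occupancy formula agree to well within Monte-Carlo
        error (their gap is O(N p^2 g^2)).
        """
        k = calibrate_kernel(50.0, 300.0)
        p = DetParams(n_tot=10_000, g=0.01, c1=0.0, d_max=100)
        s = 10.0
        lam = lambda_of_size(s, k)
        pmf = deposition_pmf(lam, p.d_max)
        n_rep = 10_000
        counts = rng.multinomial(int(p.n_tot), pmf, size=n_rep)
        occupied = rng.random(counts.shape) < -np.expm1(
            counts * math.log1p(-p.g)
        )
        freq = occupied.mean(axis=0)
        expected = occupancy_prob(p.n_tot * pmf, p.g)
        se = np.sqrt(expected * (1 - expected) / n_rep)
        z = np.abs(freq - expected) / np.maximum(se, 1e-12)
        # Bonferroni bound over 100 cells at family-wise alpha = 0.001
        assert z.max() < 4.06


class TestOptimizeSeedSize:
    def test_flat_fitness_keeps_initial_size(self, kernel_fig3a, small_window):
        p = DetParams(g=0.0, d_max=small_window.d_max)
        assert optimize_seed_size(8.0, small_window, kernel_fig3a, p) == pytest.approx(8.0)

    def test_prohibitive_cost_drives_to_minimum(self, flat_kernel):
        """With a size-independent kernel, fitness strictly decreases with the
        cost of larger seeds, so the walk ends at 0.5 mm; verified against an
        exhaustive grid scan."""
        ls = Landscape1D(x_h=50, x_ipd=0, mode="bounded", d_max=100)
        p = DetParams(n_tot=100, g=0.3, c1=1e-3, d_max=100)
        s_star = optimize_seed_size(5.0, ls, flat_kernel, p)
        assert s_star == pytest.approx(0.5)
        grid = np.round(np.arange(0.5, 5.0 + 1e-9, 0.01), 10)
        fits = [det_fitness(s, ls, flat_kernel, p) for s in grid]
        assert np.argmax(fits) == 0

    def test_walk_matches_grid_scan_oracle(self, kernel_fig3a):
        """The walk's endpoint is the first local optimum on the monotone path
        from s_init over the full 0.01-mm grid (continuous habitat, small window)."""
        ls = Landscape1D(x_h=50, x_ipd=0, mode="bounded", d_max=200)
        p = DetParams(d_max=200)
        s_init = 0.5
        s_star = optimize_seed_size(s_init, ls, kernel_fig3a, p)

        grid = np.round(np.arange(0.5, 30.0 + 1e-9, 0.01), 10)
        fits = np.array([det_fitness(s, ls, kernel_fig3a, p) for s in grid])
        # independent oracle: walk the precomputed fitness array
        i = 0
        while True:
            f_down = fits[i - 1] if i > 0 else -np.inf
            f_up = fits[i + 1] if i < len(grid) - 1 else -np.inf
            if f_down <= fits[i] and f_up <= fits[i]:
                break
            i = i - 1 if (f_down > fits[i] and f_down >= f_up) else i + 1
        assert s_star == pytest.approx(grid[i], abs=1e-9)

    def test_trajectory_never_decreases_fitness(self, kernel_fig3a):
        ls = Landscape1D(x_h=50, x_ipd=100, mode="bounded", d_max=1000)
        p = DetParams(d_max=1000)
        _, history = optimize_seed_size(5.0, ls, kernel_fig3a, p, return_history=True)
        fits = [f for _, f in history]
        assert all(b >= a for a, b in zip(fits[:-1], fits[1:]))
        assert len(history) <= 2951

    def test_off_grid_start_is_snapped(self, kernel_fig3a, small_window, caplog):
        p = DetParams(g=0.0, d_max=small_window.d_max)
        s_star = optimize_seed_size(1.2345, small_window, kernel_fig3a, p)
        assert s_star == pytest.approx(1.23)
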