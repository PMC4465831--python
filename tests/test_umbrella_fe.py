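"""Free-energy core tests: bias model, WHAM, θ diagnostic, ΔG integration.

Oracles: exact Boltzmann sampling (no dynamics) for WHAM statistics, Gaussian
closed forms for window offsets, symbolic integrals for ΔG, and a
test-local binless MBAR estimator as an independent cross-check of the
histogram WHAM solution.
"""

import numpy as np
import pytest

from coopbind.umbrella_fe import (
    KB,
    FreeEnergyProfile,
    Thermo,
    UmbrellaDataset,
    UmbrellaWindow,
    bias_energy,
    dG_error,
    pmf_to_dG,
    theta_consistency,
    threshold_sweep,
    wham,
    wham_error,
    window_grid,
)

KT300 = KB * 300.0


def boltzmann_window(center, k, n, seed, kT=KT300):
    """Exact samples from the biased density on a flat landscape:
    N(center, kT/2k)."""
    rng = np.random.default_rng(seed)
    return UmbrellaWindow(center, k,
                          rng.normal(center, np.sqrt(kT / (2 * k)), n),
                          equil_fraction=0.0)


def mbar_free_energies(dataset, tol=1e-9, max_iter=50_000):
    """Independent binless MBAR self-consistent iteration (in kT units).

    f_i = -ln Σ_n exp(-u_i(x_n)) / Σ_j N_j exp(f_j - u_j(x_n)), iterated to
    convergence over the pooled samples of all windows.
    """
    kT = dataset.thermo.kT
    xs = np.concatenate([w.production for w in dataset.windows])
    n_j = np.array([len(w.production) for w in dataset.windows], dtype=float)
    u = np.array([w.bias(xs) for w in dataset.windows]) / kT  # (K, N)
    f = np.zeros(len(n_j))
    for _ in range(max_iter):
        denom = (n_j[:, None] * np.exp(f[:, None] - u)).sum(axis=0)
        f_new = -np.log(np.exp(-u) @ (1.0 / denom))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f * kT


class TestBiasEnergy:
    def test_single_pair_at_center_zero(self):
        assert bias_energy([3.0], 3.0, 300.0) == 0.0

    def test_single_pair_above_center(self):
        # only the minimal pair is biased beyond the center
        assert bias_energy([3.1], 3.0, 300.0) == pytest.approx(3.0)

    def test_multi_pair_branch_sums(self):
        # both pairs below the center contribute
        assert bias_energy([2.9, 2.9], 3.0, 300.0) == pytest.approx(6.0)

    def test_mixed_pairs_only_inside_contribute(self):
        # one pair inside, one outside: minimal distance < center, so only
        # pairs below the center are restrained
        u = bias_energy([2.9, 3.5], 3.0, 300.0)
        assert u == pytest.approx(300.0 * 0.01)

    def test_minimal_pair_when_all_outside(self):
        u = bias_energy([3.4, 3.9], 3.0, 250.0)
        assert u == pytest.approx(250.0 * 0.16)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bias_energy([], 3.0, 300.0)


class TestWindowGrid:
    def test_published_grid_sixty_windows(self):
        centers = window_grid(2.55, 5.5, 0.05)
        assert len(centers) == 60
        assert centers[0] == pytest.approx(2.55)
        assert centers[-1] == pytest.approx(5.50)

    def test_degenerate_single_center(self):
        assert list(window_grid(3.0, 3.0, 0.05)) == [3.0]

    def test_uniform_spacing(self):
        centers = window_grid(2.55, 5.5, 0.05)
        np.testing.assert_allclose(np.diff(centers), 0.05, atol=1e-12)


class TestDatasetIO:
    def test_save_load_roundtrip(self, tmp_path):
        ds = UmbrellaDataset(
            [boltzmann_window(3.0, 100.0, 500, 1),
             boltzmann_window(3.2, 100.0, 500, 2)],
            Thermo(310.0),
        )
        ds.save(tmp_path)
        back = UmbrellaDataset.load(tmp_path)
        assert back.thermo.temperature == 310.0
        for w0, w1 in zip(ds.windows, back.windows):
            assert w1.center == w0.center and w1.k == w0.k
            np.testing.assert_allclose(w1.samples, w0.samples, atol=1e-6)

    def test_unsorted_windows_canonicalized(self):
        ds = UmbrellaDataset(
            [boltzmann_window(3.4, 50.0, 100, 3),
             boltzmann_window(3.0, 50.0, 100, 4)]
        )
        assert list(ds.centers) == sorted(ds.centers)


class TestWham:
    def test_single_window_flat_landscape(self):
        ds = UmbrellaDataset([boltzmann_window(4.0, 50.0, 100_000, 5)])
        prof = wham(ds)
        sigma = np.sqrt(KT300 / (2 * 50.0))
        central = np.abs(prof.bin_centers - 4.0) <= 2 * sigma
        g = prof.values[central]
        assert g.max() - g.min() < 0.12  # flat within estimator noise

    def test_two_window_offset_matches_gaussian_closed_form(self):
        """Window free-energy offset on a flat landscape is
        (kT/2)·ln(k₂/k₁) — the Gaussian partition-function ratio."""
        k1, k2 = 50.0, 200.0
        ds = UmbrellaDataset(
            [boltzmann_window(3.50, k1, 200_000, 6),
             boltzmann_window(3.58, k2, 200_000, 7)]
        )
        prof = wham(ds)
        df = prof.window_free_energies[1] - prof.window_free_energies[0]
        expected = 0.5 * KT300 * np.log(k2 / k1)
        assert df == pytest.approx(expected, abs=0.02)

    def test_profile_invariant_under_window_permutation(self):
        wins = [boltzmann_window(3.0 + 0.1 * i, 80.0, 20_000, 10 + i)
                for i in range(5)]
        p1 = wham(UmbrellaDataset(list(wins)))
        p2 = wham(UmbrellaDataset(wins[::-1]))
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-6)

    def test_gauge_invariance_additive_bias_constant(self):
        """Adding a constant to every window bias leaves G unchanged: the
        WHAM equations only see bias differences within each window."""

        class ShiftedWindow(UmbrellaWindow):
            def bias(self, x):
                return super().bias(x) + 7.3

        base = [boltzmann_window(3.0 + 0.1 * i, 80.0, 20_000, 20 + i)
                for i in range(4)]
        shifted = [ShiftedWindow(w.center, w.k, w.samples, 0.0)
                   for w in base]
        p1 = wham(UmbrellaDataset(base))
        p2 = wham(UmbrellaDataset(shifted))
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)

    def test_nonoverlapping_windows_warn(self):
        ds = UmbrellaDataset(
            [boltzmann_window(3.0, 500.0, 5_000, 30),
             boltzmann_window(4.5, 500.0, 5_000, 31)]
        )
        with pytest.warns(UserWarning, match="no occupied bins"):
            wham(ds)

    def test_matches_independent_mbar(self, umbrella_dataset):
        """Histogram WHAM window offsets agree with a binless MBAR
        estimator on the identical (subsampled) dataset within 0.05
        kcal/mol."""
        sub = UmbrellaDataset(
            [UmbrellaWindow(w.center, w.k, w.production[::50][:1500], 0.0)
             for w in umbrella_dataset.windows],
            umbrella_dataset.thermo,
        )
        prof = wham(sub, bin_width=0.005)
        f_wham = prof.window_free_energies
        f_mbar = mbar_free_energies(sub)
        diff = (f_wham - f_wham[0]) - (f_mbar - f_mbar[0])
        assert np.max(np.abs(diff)) < 0.05


class TestWhamError:
    def test_error_shrinks_with_sample_size(self):
        def errs(n, seed):
            ds = UmbrellaDataset(
                [boltzmann_window(3.0, 80.0, n, seed),
                 boltzmann_window(3.1, 80.0, n, seed + 1)]
            )
            e = wham_error(ds, n_boot=60, seed=seed)
            prof = wham(ds)
            sigma = np.sqrt(KT300 / 160.0)
            centers, _ = (prof.bin_centers, prof.values)
            central = ((centers > 3.0 - sigma) & (centers < 3.1 + sigma))
            return e[central].mean()

        e1 = errs(4_000, 40)
        e2 = errs(8_000, 50)
        assert e2 / e1 == pytest.approx(1 / np.sqrt(2), rel=0.20)

    def test_degenerate_samples_zero_error(self):
        w = UmbrellaWindow(3.0, 100.0, np.full(1000, 3.0), 0.0)
        ds = UmbrellaDataset([w])
        err = wham_error(ds, n_boot=20, seed=0)
        assert err[0] == 0.0

    def test_bootstrap_coverage(self):
        """Bootstrap error bars bracket the truth at roughly the nominal
        rate: over many seeds, ~68% of central bins lie within one error of
        the flat reference."""
        hits, total = 0, 0
        for seed in range(40):
            ds = UmbrellaDataset(
                [boltzmann_window(3.0, 50.0, 1_500, 100 + seed)])
            prof = wham(ds, bin_width=0.02)
            err = wham_error(ds, n_boot=40, seed=seed, bin_width=0.02)
            sigma = np.sqrt(KT300 / 100.0)
            central = np.abs(prof.bin_centers - 3.0) <= 1.5 * sigma
            # reference is flat; anchor both at their central mean
            g = prof.values[central] - prof.values[central].mean()
            e = err[central]
            ok = np.abs(g) <= np.maximum(e, 1e-12)
            hits += int(ok.sum())
            total += int(len(ok))
        coverage = hits / total
        assert 0.5 <= coverage <= 0.95

    def test_too_few_replicates_rejected(self):
        ds = UmbrellaDataset([boltzmann_window(3.0, 50.0, 100, 0)])
        with pytest.raises(ValueError, match=">= 20"):
            wham_error(ds, n_boot=5)


class TestTheta:
    def test_identical_sampling_statistics_near_zero(self):
        ds = UmbrellaDataset(
            [boltzmann_window(3.00, 80.0, 100_000, 60),
             boltzmann_window(3.05, 80.0, 100_000, 61)]
        )
        theta = theta_consistency(ds)
        assert theta.theta[0] < 0.1

    def test_disjoint_support_maximal(self):
        ds = UmbrellaDataset(
            [boltzmann_window(3.0, 500.0, 1_000, 62),
             boltzmann_window(4.5, 500.0, 1_000, 63)]
        )
        theta = theta_consistency(ds)
        assert theta.theta[0] == 2.0


def piecewise_profile(g, w_b, w_u, lower=3.0, width=0.002):
    """Bound plateau at G=-g of width w_b, unbound plateau at 0 of width
    w_u."""
    x = np.arange(lower, lower + w_b + w_u + width / 2, width)
    # the step sits strictly below the threshold so the discontinuity is
    # integrated on the bound side only
    vals = np.where(x < lower + w_b - width / 2, -g, 0.0)
    return FreeEnergyProfile(x, vals, width), lower + w_b, lower + w_b + w_u


class TestPmfToDG:
    def test_piecewise_constant_closed_form(self):
        """ΔG = -kT·ln(w_b·e^{g/kT}/w_u); for g=3, w_b=0.75, w_u=2.0 at
        300 K the closed form gives -2.4153 kcal/mol."""
        prof, thr, upper = piecewise_profile(3.0, 0.75, 2.0)
        est = pmf_to_dG(prof, Thermo(300.0), thr, upper)
        closed = -KT300 * np.log(0.75 * np.exp(3.0 / KT300) / 2.0)
        assert closed == pytest.approx(-2.4153, abs=5e-4)
        assert est.dG == pytest.approx(closed, abs=0.01)

    def test_flat_profile_equal_widths_zero(self):
        prof, thr, upper = piecewise_profile(0.0, 1.0, 1.0)
        est = pmf_to_dG(prof, Thermo(300.0), thr, upper)
        assert est.dG == pytest.approx(0.0, abs=1e-9)

    def test_linear_ramp_matches_symbolic_oracle(self):
        """G = a + b·x: both integrals have the closed form
        -(kT/b)·[e^{-G/kT}] between the limits."""
        a, b = -5.0, 2.0
        width = 0.01
        x = np.arange(3.0, 5.5 + width / 2, width)
        prof = FreeEnergyProfile(x, a + b * x, width)
        thr, upper = 4.0, 5.5
        est = pmf_to_dG(prof, Thermo(300.0), thr, upper)

        def integral(lo, hi):
            return (KT300 / b) * (np.exp(-(a + b * lo) / KT300)
                                  - np.exp(-(a + b * hi) / KT300))

        closed = -KT300 * np.log(integral(3.0, thr) / integral(thr, upper))
        assert est.dG == pytest.approx(closed, abs=1e-3)

    def test_shift_invariance(self):
        prof, thr, upper = piecewise_profile(2.0, 0.5, 1.5)
        shifted = FreeEnergyProfile(prof.bin_centers, prof.values + 11.0,
                                    prof.bin_width)
        t = Thermo(300.0)
        assert (pmf_to_dG(shifted, t, thr, upper).dG
                == pytest.approx(pmf_to_dG(prof, t, thr, upper).dG,
                                 abs=1e-9))

    def test_bin_refinement_stable(self):
        t = Thermo(300.0)
        vals = []
        for width in (0.01, 0.005):
            x = np.arange(3.0, 5.5 + width / 2, width)
            g = 2.0 * np.sin(2 * np.pi * (x - 3.0) / 2.5) ** 2
            prof = FreeEnergyProfile(x, g, width)
            vals.append(pmf_to_dG(prof, t, 4.0, 5.5).dG)
        assert abs(vals[1] - vals[0]) < 0.01

    def test_threshold_outside_rejected(self):
        prof, thr, upper = piecewise_profile(1.0, 0.5, 0.5)
        with pytest.raises(ValueError, match="outside"):
            pmf_to_dG(prof, Thermo(300.0), 2.0, upper)


class TestDgError:
    def _noisy_profile(self):
        width = 0.01
        x = np.arange(3.0, 5.5 + width / 2, width)
        g = 1.5 * np.sin(2 * np.pi * (x - 3.0) / 2.5) ** 2
        err = np.full(len(x), 0.05)
        return FreeEnergyProfile(x, g, width, error=err)

    def test_zero_errors_zero(self):
        prof = self._noisy_profile()
        prof.error = np.zeros_like(prof.error)
        assert dG_error(prof, Thermo(300.0), 4.0) == 0.0

    def test_linear_scaling(self):
        prof = self._noisy_profile()
        e1 = dG_error(prof, Thermo(300.0), 4.0)
        prof.error = prof.error * 3.0
        assert dG_error(prof, Thermo(300.0), 4.0) == pytest.approx(3 * e1,
                                                                   rel=1e-9)

    def test_linear_agrees_with_monte_carlo(self):
        prof = self._noisy_profile()
        t = Thermo(300.0)
        lin = dG_error(prof, t, 4.0)
        mc = dG_error(prof, t, 4.0, method="monte-carlo", n_mc=2000, seed=1)
        assert lin == pytest.approx(mc, rel=0.15)


class TestBiasEnergyProperties:
    """Invariants of the piecewise restraint, over random pair lists."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        d=st.lists(st.floats(0.1, 10.0), min_size=1, max_size=12),
        d_c=st.floats(0.5, 8.0),
        k=st.floats(1.0, 500.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_nonnegative_and_branch_consistent(self, d, d_c, k):
        u = bias_energy(d, d_c, k)
        assert u >= 0.0
        d_min = min(d)
        if d_min >= d_c:
            assert u == pytest.approx(k * (d_min - d_c) ** 2)
        else:
            assert u == pytest.approx(
                sum(k * (x - d_c) ** 2 for x in d if x < d_c))

    @given(
        start=st.floats(0.5, 5.0),
        n=st.integers(1, 200),
        spacing=st.floats(0.01, 0.5),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_window_grid_count_and_spacing(self, start, n, spacing):
        stop = start + (n - 1) * spacing
        centers = window_grid(start, stop, spacing)
        assert len(centers) == n
        if n > 1:
            np.testing.assert_allclose(np.diff(centers), spacing, rtol=1e-9)


class TestThresholdSweep:
    def test_default_seven_thresholds(self):
        width = 0.01
        x = np.arange(2.6, 5.5 + width / 2, width)
        prof = FreeEnergyProfile(x, np.zeros(len(x)), width)
        ests = threshold_sweep(prof, Thermo(300.0))
        assert len(ests) == 7
        assert [e.threshold for e in ests] == pytest.approx(
            [3.1, 3.3, 3.5, 3.7, 3.9, 4.1, 4.3])

    def test_single_well_magnitude_grows_past_well(self):
        """Once the threshold passes the well, moving it further into the
        flat region only shrinks the unbound integral: |ΔG| grows."""
        width = 0.005
        x = np.arange(2.6, 5.5 + width / 2, width)
        g = -2.5 * np.exp(-0.5 * ((x - 3.0) / 0.15) ** 2)
        prof = FreeEnergyProfile(x, g - g.min(), width)
        ests = threshold_sweep(prof, Thermo(300.0),
                               thresholds=np.arange(3.5, 5.3, 0.2))
        dgs = np.array([e.dG for e in ests])
        assert np.all(np.diff(np.abs(dgs)) >= 0)
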