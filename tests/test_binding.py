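"""Ligand-depletion isotherm, per-residue fits and global-Kd aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cspfit.binding import (
    BindingFit,
    FitConfig,
    GlobalKd,
    aggregate_global_kd,
    fit_residue,
    fraction_bound,
    isotherm,
)
from cspfit.csp import ASSIGNED, ResidueCSP
from cspfit.errors import InputError
from cspfit.peaklist import TitrationPoint, TitrationSeries


def quadratic_root_oracle(L, P, kd, ddmax):
    """Independent route: [PL] is the smaller root of
    x^2 - (L+P+kd) x + L*P = 0; Δδ = ddmax * [PL]/P."""
    roots = np.roots([1.0, -(L + P + kd), L * P])
    pl = min(roots.real)
    return ddmax * pl / P


def make_series(ratios, P=0.1):
    points = tuple(
        TitrationPoint(r * P, P, (), molar_ratio=r) for r in ratios
    )
    return TitrationSeries(points)


def traj_csp(resnum, values):
    traj = np.asarray(values, dtype=float)
    end = traj[~np.isnan(traj)][-1]
    return ResidueCSP(resnum, "A", ASSIGNED, csp_traj=traj, endpoint_csp=float(end))


RATIOS = (0, 1, 2, 4, 8, 16, 32)


class TestIsotherm:
    def test_no_ligand_means_no_shift(self):
        assert isotherm(0.0, 0.1, 0.3, 1.0) == 0.0

    def test_closed_form_value(self):
        # (0.5 - sqrt(0.21)) / 0.2
        expected = (0.5 - math.sqrt(0.21)) / 0.2
        assert isotherm(0.1, 0.1, 0.3, 1.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.208712, abs=1e-6)

    def test_tight_binding_limit_is_stoichiometric(self):
        # kd -> 0 with L = 2P: all protein bound, Δδ -> ddmax
        assert isotherm(0.2, 0.1, 1e-12, 1.0) == pytest.approx(1.0, abs=1e-5)

    def test_agrees_with_quadratic_root_oracle(self, rng):
        for _ in range(2000):
            L = rng.uniform(0, 10)
            P = rng.uniform(1e-3, 1)
            kd = 10 ** rng.uniform(-3, 1)
            ddmax = rng.uniform(0.01, 1)
            a = isotherm(L, P, kd, ddmax)
            b = quadratic_root_oracle(L, P, kd, ddmax)
            assert a == pytest.approx(b, rel=1e-10, abs=1e-12)

    def test_hyperbolic_limit_for_trace_protein(self, rng):
        for _ in range(200):
            kd = 10 ** rng.uniform(-2, 1)
            L = rng.uniform(1e-3, 10)
            P = 1e-9 * kd
            assert isotherm(L, P, kd, 1.0) == pytest.approx(
                L / (L + kd), rel=1e-6
            )

    @given(
        kd=st.floats(1e-3, 10), P=st.floats(1e-3, 1),
        L1=st.floats(1e-6, 10), L2=st.floats(1e-6, 10),
    )
    def test_strictly_increasing_in_ligand(self, kd, P, L1, L2):
        lo, hi = sorted((L1, L2))
        if hi - lo > 1e-9:
            assert isotherm(lo, P, kd, 1.0) < isotherm(hi, P, kd, 1.0)

    @given(
        kd1=st.floats(1e-3, 10), kd2=st.floats(1e-3, 10),
        P=st.floats(1e-3, 1), L=st.floats(1e-3, 10),
    )
    def test_strictly_decreasing_in_kd(self, kd1, kd2, P, L):
        lo, hi = sorted((kd1, kd2))
        if hi - lo > 1e-9:
            assert isotherm(L, P, hi, 1.0) < isotherm(L, P, lo, 1.0)

    def test_value_bounded_by_ddmax(self, rng):
        L = rng.uniform(0, 50, 1000)
        v = isotherm(L, 0.1, 0.3, 0.7)
        assert np.all(v >= 0) and np.all(v <= 0.7 + 1e-12)

    def test_invalid_concentrations_rejected(self):
        with pytest.raises(InputError):
            isotherm(0.1, 0.0, 0.3, 1.0)
        with pytest.raises(InputError):
            isotherm(-0.1, 0.1, 0.3, 1.0)


class TestFitResidue:
    def test_noiseless_round_trip_recovers_truth(self):
        series = make_series(RATIOS)
        y = isotherm(np.array(series.ligand_concs), 0.1, 0.3, 0.2)
        fit = fit_residue(traj_csp(172, y), series)
        assert fit.converged
        assert fit.kd == pytest.approx(0.3, abs=1e-6)
        assert fit.ddmax == pytest.approx(0.2, abs=1e-6)
        assert fit.saturated  # 32:1 at kd=0.3 is ~91% bound

    def test_fit_lands_within_one_cell_of_grid_search_oracle(self):
        series = make_series(RATIOS)
        L = np.array(series.ligand_concs)
        y = isotherm(L, 0.1, 0.3, 0.2)
        kd_grid = np.logspace(-3, 1, 500)
        dd_grid = np.logspace(-2, 0, 500)
        sse = np.empty((500, 500))
        for i, kd in enumerate(kd_grid):
            pred = isotherm(L[None, :], 0.1, kd, 1.0) * dd_grid[:, None]
            sse[i] = np.sum((pred - y[None, :]) ** 2, axis=1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        fit = fit_residue(traj_csp(172, y), series)
        dlog_kd = abs(math.log10(fit.kd) - math.log10(kd_grid[i]))
        dlog_dd = abs(math.log10(fit.ddmax) - math.log10(dd_grid[j]))
        assert dlog_kd <= 4.0 / 499 + 1e-12  # one grid cell in log10 units
        assert dlog_dd <= 2.0 / 499 + 1e-12

    def test_weak_binder_with_short_titration_is_unsaturated(self):
        series = make_series((0, 0.5, 1, 2))
        y = isotherm(np.array(series.ligand_concs), 0.1, 5.0, 0.2)
        # independent check of the expected end-state at the truth
        assert fraction_bound(0.2, 0.1, 5.0) < 0.8
        fit = fit_residue(traj_csp(172, y), series, FitConfig(saturation_cutoff=0.8))
        assert not fit.saturated

    def test_broadened_points_are_ignored(self):
        series = make_series(RATIOS)
        y = isotherm(np.array(series.ligand_concs), 0.1, 0.3, 0.2)
        y[3] = np.nan
        fit = fit_residue(traj_csp(172, y), series)
        assert fit.kd == pytest.approx(0.3, abs=1e-6)
        assert fit.n_points == 5

    def test_too_few_points_is_an_error(self):
        series = make_series(RATIOS)
        y = np.full(len(RATIOS), np.nan)
        y[:3] = isotherm(np.array(series.ligand_concs[:3]), 0.1, 0.3, 0.2)
        with pytest.raises(InputError, match="3 defined non-apo"):
            fit_residue(traj_csp(172, y), series)


def make_fit(resnum, kd, saturated=True, converged=True):
    return BindingFit(
        residue_number=resnum, kd=kd, ddmax=0.2, kd_stderr=0.01,
        converged=converged, saturated=saturated,
        frac_bound_end=0.9 if saturated else 0.5, n_points=6, rmse=0.001,
    )


class TestAggregateGlobalKd:
    def test_two_sd_outlier_excluded_then_mean_recomputed(self):
        # {0.3 x5, 10}: mean 1.917, SD 3.960; |10-1.917| >= 2 SD -> drop the 10
        fits = [make_fit(i, 0.3) for i in range(5)] + [make_fit(99, 10.0)]
        gk = aggregate_global_kd(fits, significant=range(100))
        assert not gk.is_lower_limit
        assert gk.residues_excluded == {99}
        assert gk.mean_kd == pytest.approx(0.3)
        assert gk.sd_kd == pytest.approx(0.0, abs=1e-12)
        assert len(gk.residues_used) == 5

    def test_identical_kds_exclude_nothing(self):
        fits = [make_fit(i, 0.4) for i in range(4)]
        gk = aggregate_global_kd(fits, significant=range(10))
        assert gk.mean_kd == pytest.approx(0.4)
        assert gk.sd_kd == 0.0
        assert gk.residues_excluded == frozenset()

    def test_mostly_unsaturated_fits_give_lower_limit_at_min_kd(self):
        kds = [2.0, 2.5, 0.9, 3.0]
        fits = [
            make_fit(i, kd, saturated=(i == 2)) for i, kd in enumerate(kds)
        ]
        gk = aggregate_global_kd(fits, significant=range(10))
        assert gk.is_lower_limit
        assert gk.limit_value == pytest.approx(0.9)
        assert math.isnan(gk.mean_kd)
        assert "> 0.9" in gk.describe()

    def test_unconverged_and_nonsignificant_fits_are_not_candidates(self):
        fits = [make_fit(i, 0.3) for i in range(4)]
        fits.append(make_fit(50, 99.0, converged=False))
        fits.append(make_fit(60, 99.0))  # not significant
        gk = aggregate_global_kd(fits, significant=range(10))
        assert gk.mean_kd == pytest.approx(0.3)

    def test_fewer_than_two_candidates_is_an_error(self):
        with pytest.raises(InputError, match=">= 2"):
            aggregate_global_kd([make_fit(0, 0.3)], significant=[0])
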