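"""Result-level analyses: locating errors, field statistics, energy budgets.

These are pure functions of logged simulation output (power logs, field
summaries, decoded positions), so re-running them on saved tables reproduces
the reports exactly.  The one exception is :func:`field_size_sweep`, which
re-runs the whole simulation pipeline across a grid of mean tuning widths to
map how place-field size trades locating accuracy against energy cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ErrorSeries",
    "FieldStatistics",
    "CenterCorrelation",
    "EnergyDistributionReport",
    "SweepResult",
    "locating_errors",
    "field_statistics",
    "center_correlation",
    "energy_report",
    "field_size_sweep",
]


@dataclass
class ErrorSeries:
    """Relative locating errors e(t) = ||Loc(t) - X(t)|| / L."""

    errors: np.ndarray
    mean: float
    max: float
    last_100: np.ndarray

    def trend_slope(self, window: int = 5000) -> tuple[float, float]:
        """OLS slope (per step) and its p-value over the trailing window.

        A drifting (diverging) error series shows a significantly positive
        slope; a stationary one does not.
        """
        tail = self.errors[-window:]
        t = np.arange(len(tail), dtype=float)
        res = stats.linregress(t, tail)
        return float(res.slope), float(res.pvalue)


def locating_errors(
    true_positions: np.ndarray, decoded_positions: np.ndarray, arena_side: float
) -> ErrorSeries:
    """Per-step relative locating error between decoded and true positions."""
    true_positions = np.asarray(true_positions, float)
    decoded_positions = np.asarray(decoded_positions, float)
    if true_positions.shape != decoded_positions.shape:
        raise ValueError("true and decoded position sequences are misaligned")
    e = np.linalg.norm(decoded_positions - true_positions, axis=1) / arena_side
    return ErrorSeries(errors=e, mean=float(e.mean()), max=float(e.max()), last_100=e[-100:])


@dataclass
class FieldStatistics:
    """Population distributions of peak power and place-field size."""

    max_power: np.ndarray
    field_size: np.ndarray
    power_bin_edges: np.ndarray
    size_bin_edges: np.ndarray


def field_statistics(summary) -> FieldStatistics:
    """Distributions of per-cell maximum firing power and field size.

    Histogram binning uses the Freedman-Diaconis rule (falling back to a
    single bin for degenerate samples).
    """
    mp = np.asarray(summary.max_power, float)
    fs = np.asarray(summary.field_size, float)
    if mp.size < 1:
        raise ValueError("need at least one cell")

    def edges(x):
        try:
            e = np.histogram_bin_edges(x, bins="fd")
        except (ValueError, MemoryError):
            e = np.histogram_bin_edges(x, bins=1)
        return e if len(e) > 1 else np.array([x.min(), x.max() + 1.0])

    return FieldStatistics(
        max_power=mp, field_size=fs, power_bin_edges=edges(mp), size_bin_edges=edges(fs)
    )


@dataclass
class CenterCorrelation:
    """Pairwise coordinate correlations of the field centers and the fraction
    of total variance carried by the leading principal axis (1/3 for an
    isotropic cloud, 1 for perfectly collinear centers)."""

    r_xy: float
    r_xz: float
    r_yz: float
    leading_axis_fraction: float


def center_correlation(centers: np.ndarray) -> CenterCorrelation:
    """Collinearity diagnostics of the place-field centers."""
    c = np.asarray(centers, float)
    c = c[np.all(np.isfinite(c), axis=1)]
    if len(np.unique(c, axis=0)) < 3:
        raise ValueError("center correlation needs at least 3 distinct centers")
    cov = np.cov((c - c.mean(axis=0)).T)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    ev = np.linalg.eigvalsh(cov)
    return CenterCorrelation(
        r_xy=float(corr[0, 1]),
        r_xz=float(corr[0, 2]),
        r_yz=float(corr[1, 2]),
        leading_axis_fraction=float(ev[-1] / ev.sum()),
    )


@dataclass
class EnergyDistributionReport:
    """Normality diagnosis of the per-cell total energy budget."""

    energies: np.ndarray
    statistic: float
    p_value: float
    alpha: float
    verdict: str  # "reject" or "fail-to-reject"
    bin_edges: np.ndarray


def energy_report(energies: np.ndarray, alpha_level: float = 0.01) -> EnergyDistributionReport:
    """Lilliefors test of normality (mean and variance estimated) on the
    per-cell energy totals at significance ``alpha_level``."""
    e = np.asarray(energies, float)
    if e.size < 20:
        raise ValueError("energy report needs at least 20 cells")
    if np.ptp(e) == 0.0:
        raise ValueError("energies are constant; the test statistic is undefined")
    stat, p = lilliefors(e, dist="norm")
    verdict = "reject" if p < alpha_level else "fail-to-reject"
    try:
        edges = np.histogram_bin_edges(e, bins="fd")
    except (ValueError, MemoryError):
        edges = np.histogram_bin_edges(e, bins=10)
    return EnergyDistributionReport(
        energies=e, statistic=float(stat), p_value=float(p),
        alpha=alpha_level, verdict=verdict, bin_edges=edges,
    )


@dataclass
class SweepResult:
    """Outcome of a mean-tuning-width sweep."""

    records: pd.DataFrame      # columns: sigma_mean, seed, mean_error, mean_field_size, mean_energy
    aggregates: pd.DataFrame   # per sigma_mean means over seeds
    argmin_sigma: float        # grid value with the smallest mean error


def field_size_sweep(
    sigma_mean_grid,
    seeds_per_point: int = 3,
    base_seed: int = 0,
    n_cells: int = 200,
    n_steps: int = 10_000,
    **config_overrides,
) -> SweepResult:
    """Run the full pipeline across a grid of mean tuning widths.

    For each grid value and seed the simulation is run end to end and the
    mean relative locating error, mean field size and mean per-cell energy
    are recorded; aggregates are means over seeds.  Larger tuning widths give
    larger place fields, hence more supra-threshold time and more energy;
    the locating error is typically U-shaped across the grid.
    """
    from .cli_io import RunConfig, simulate_run  # deferred: cli_io imports analysis

    grid = [float(s) for s in sigma_mean_grid]
    if not grid:
        raise ValueError("sigma grid must be non-empty")
    rows = []
    for sm in grid:
        for k in range(seeds_per_point):
            cfg = RunConfig(
                seed=base_seed * 1009 + k,
                **{"net.sigma_mean": sm, "net.n_cells": n_cells,
                   "env.n_steps": n_steps, **config_overrides},
            )
            res = simulate_run(cfg)
            rows.append(
                dict(
                    sigma_mean=sm,
                    seed=int(cfg["seed"]),
                    mean_error=res.errors.mean,
                    mean_field_size=float(np.mean(res.summary.field_size)),
                    mean_energy=float(np.mean(res.summary.total_energy)),
                )
            )
    records = pd.DataFrame(rows)
    aggregates = records.groupby("sigma_mean", as_index=False).mean().drop(columns="seed")
    argmin_sigma = float(aggregates.loc[aggregates["mean_error"].idxmin(), "sigma_mean"])
    return SweepResult(records=records, aggregates=aggregates, argmin_sigma=argmin_sigma)
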