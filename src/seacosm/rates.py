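"""Net growth rates from abundance time courses.

Group-specific cell densities (cells mL^-1, e.g. from CARD-FISH counts) are
assumed to grow exponentially over the sampled interval; the net growth rate
is the slope of the ordinary least-squares regression of ln(abundance) on
time, converted from per hour to per day.  Rates are fitted per replicate
bottle and then aggregated to replicate means and standard deviations.

Also hosts the small derived-quantity calculators used around microscopy
counts: fraction-of-total to absolute abundance, aerobic anoxygenic
phototroph (AAP) counts from infrared minus chlorophyll images, and
leucine-incorporation to carbon production.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ABUNDANCE_COLUMNS",
    "WindowFit",
    "RateEstimates",
    "validate_abundance_table",
    "fit_exponential_window",
    "estimate_rates",
    "group_absolute_abundance",
    "aap_count",
    "leucine_to_production",
]

#: Canonical tidy-table columns for one cell-density observation.
ABUNDANCE_COLUMNS = (
    "season",
    "treatment",
    "replicate",
    "group",
    "time_h",
    "cells_per_ml",
)

KEY_COLUMNS = ("season", "treatment", "replicate", "group", "time_h")


def validate_abundance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy abundance table in place and return it.

    Checks column presence, numeric dtypes, non-negative time and abundance,
    and uniqueness of the (season, treatment, replicate, group, time) key.
    """
    missing = [c for c in ABUNDANCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"abundance table missing columns: {missing}")
    for col in ("time_h", "cells_per_ml"):
        values = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[values.isna() & table[col].notna()]
        if len(bad):
            raise ValueError(f"non-numeric {col} at rows {list(bad[:5])}")
        table = table.assign(**{col: values})
    if (table["time_h"] < 0).any():
        rows = table.index[table["time_h"] < 0]
        raise ValueError(f"negative time_h at rows {list(rows[:5])}")
    if (table["cells_per_ml"] < 0).any():
        rows = table.index[table["cells_per_ml"] < 0]
        raise ValueError(f"negative cells_per_ml at rows {list(rows[:5])}")
    dup = table.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        rows = table.index[dup]
        raise ValueError(
            f"duplicate (season, treatment, replicate, group, time_h) keys at rows {list(rows[:6])}"
        )
    return table


@dataclass(frozen=True)
class WindowFit:
    """ln-linear regression result for one abundance series.

    ``k`` is in day^-1.  ``r_squared`` is None for a two-point fit, where the
    slope is the exact two-point log difference and r² is uninformative.
    """

    k: float
    t_start_h: float
    t_end_h: float
    n_points: int
    r_squared: float | None
    mode: str


def _ols_log_slope(times_h: np.ndarray, log_n: np.ndarray) -> tuple[float, float]:
    """Slope (h^-1) and r² of OLS of log abundance on time."""
    t = times_h - times_h.mean()
    y = log_n - log_n.mean()
    stt = float(t @ t)
    slope = float(t @ y) / stt
    ss_tot = float(y @ y)
    if ss_tot == 0.0:
        return slope, 1.0  # constant series: slope 0, perfect fit
    resid = y - slope * t
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return slope, r2


def fit_exponential_window(
    times_h,
    abundances,
    min_points: int = 3,
    mode: str = "full",
) -> WindowFit:
    """Net growth rate from ln(abundance) vs time.

    Parameters
    ----------
    times_h
        Sampling times in hours; must be distinct.
    abundances
        Cell densities (cells mL^-1); must all be strictly positive, since
        the fit is on logarithms.
    min_points
        Minimum window length for ``best_window`` scanning (default 3).
    mode
        ``"full"`` regresses over the whole series.  ``"best_window"`` scans
        every contiguous sub-series of at least ``min_points`` observations
        and returns the one with maximal r², breaking ties in favour of the
        longer window and then the earlier start — intended for series with
        a lag phase or late saturation, where only part of the time course
        is exponential.

    Returns
    -------
    WindowFit
        Rate in day^-1 (slope × 24), the window used, and the fit r².
    """
    times = np.asarray(times_h, dtype=float)
    values = np.asarray(abundances, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("times and abundances must be 1-D and the same length")
    if times.size < 2:
        raise ValueError("need at least 2 observations to estimate a rate")
    nonpos = np.flatnonzero(values <= 0)
    if nonpos.size:
        raise ValueError(
            f"abundance must be > 0 for a log-linear fit; offending indices {nonpos.tolist()}"
        )
    if np.unique(times).size != times.size:
        raise ValueError("sampling times must be distinct")
    order = np.argsort(times)
    times, values = times[order], values[order]
    log_n = np.log(values)

    if mode not in ("full", "best_window"):
        raise ValueError(f"unknown mode {mode!r}")

    def fit_span(i: int, j: int) -> tuple[float, float | None]:
        """Slope (h^-1) and r² over points i..j inclusive."""
        n = j - i + 1
        if n == 2:
            slope = (log_n[j] - log_n[i]) / (times[j] - times[i])
            return slope, None
        return _ols_log_slope(times[i : j + 1], log_n[i : j + 1])

    if mode == "full" or times.size <= max(min_points, 2):
        slope, r2 = fit_span(0, times.size - 1)
        return WindowFit(
            k=slope * 24.0,
            t_start_h=float(times[0]),
            t_end_h=float(times[-1]),
            n_points=times.size,
            r_squared=r2,
            mode=mode,
        )

    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    width = max(min_points, 3)  # r² needs >= 3 points to discriminate
    best: tuple[float, int, int] | None = None  # (r2, length, -start) maximised
    best_span = (0, times.size - 1)
    tol = 1e-12
    for i in range(times.size):
        for j in range(i + width - 1, times.size):
            _, r2 = fit_span(i, j)
            key = (r2, j - i + 1, -i)
            if best is None or _window_better(key, best, tol):
                best = key
                best_span = (i, j)
    i, j = best_span
    slope, r2 = fit_span(i, j)
    return WindowFit(
        k=slope * 24.0,
        t_start_h=float(times[i]),
        t_end_h=float(times[j]),
        n_points=j - i + 1,
        r_squared=r2,
        mode=mode,
    )


def _window_better(
    key: tuple[float, int, int], best: tuple[float, int, int], tol: float
) -> bool:
    """Window ordering: max r², then longer, then earlier start (r² ties within tol)."""
    if key[0] > best[0] + tol:
        return True
    if key[0] < best[0] - tol:
        return False
    return key[1:] > best[1:]


@dataclass
class RateEstimates:
    """Per-replicate rate fits, replicate-aggregated rates, and data issues.

    ``per_replicate`` has one row per (season, treatment, group, replicate);
    ``aggregated`` one row per (season, treatment, group) with the replicate
    mean and standard deviation; ``issues`` records series that could not be
    fitted and treatment-coverage gaps, without aborting the run.
    """

    per_replicate: pd.DataFrame
    aggregated: pd.DataFrame
    issues: pd.DataFrame


def estimate_rates(
    table: pd.DataFrame, mode: str = "full", min_points: int = 3
) -> RateEstimates:
    """Fit net growth rates for every series in a tidy abundance table.

    Each (season, treatment, group, replicate) series is fitted with
    :func:`fit_exponential_window`; replicate rates are then averaged per
    (season, treatment, group) with the sample standard deviation across
    bottles.  Series that cannot be fitted (fewer than two points, zero
    counts) and groups missing from treatments covered by the rest of the
    experiment are reported in ``issues`` rather than raising.
    """
    table = validate_abundance_table(table.copy())
    rows: list[dict] = []
    issues: list[dict] = []
    for (season, treatment, group, replicate), sub in table.groupby(
        ["season", "treatment", "group", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_h")
        try:
            fit = fit_exponential_window(
                sub["time_h"].to_numpy(),
                sub["cells_per_ml"].to_numpy(),
                min_points=min_points,
                mode=mode,
            )
        except ValueError as err:
            issues.append(
                {
                    "season": season,
                    "treatment": treatment,
                    "group": group,
                    "replicate": replicate,
                    "issue": str(err),
                }
            )
            continue
        rows.append(
            {
                "season": season,
                "treatment": treatment,
                "group": group,
                "replicate": replicate,
                "k": fit.k,
                "t_start_h": fit.t_start_h,
                "t_end_h": fit.t_end_h,
                "n_points": fit.n_points,
                "r_squared": fit.r_squared,
                "mode": fit.mode,
            }
        )
    per_replicate = pd.DataFrame(
        rows,
        columns=[
            "season",
            "treatment",
            "group",
            "replicate",
            "k",
            "t_start_h",
            "t_end_h",
            "n_points",
            "r_squared",
            "mode",
        ],
    )

    if len(per_replicate):
        aggregated = (
            per_replicate.groupby(["season", "treatment", "group"], sort=True)["k"]
            .agg(k_mean="mean", k_sd="std", n_replicates="count")
            .reset_index()
        )
        aggregated["k_sd"] = aggregated["k_sd"].fillna(0.0)
    else:
        aggregated = pd.DataFrame(
            columns=["season", "treatment", "group", "k_mean", "k_sd", "n_replicates"]
        )

    # Coverage gaps: a group absent from a treatment that other groups cover.
    for season, sub in table.groupby("season"):
        treatments = set(sub["treatment"].unique())
        for group, gsub in sub.groupby("group"):
            for missing in sorted(treatments - set(gsub["treatment"].unique())):
                issues.append(
                    {
                        "season": season,
                        "treatment": missing,
                        "group": group,
                        "replicate": None,
                        "issue": "group not observed in this treatment",
                    }
                )
    issues_df = pd.DataFrame(
        issues, columns=["season", "treatment", "group", "replicate", "issue"]
    )
    return RateEstimates(per_replicate, aggregated, issues_df)


def group_absolute_abundance(fraction_of_dapi: float, dapi_total: float) -> float:
    """Absolute group abundance (cells mL^-1) from its fraction of total DAPI counts."""
    if not (0.0 <= fraction_of_dapi <= 1.0):
        raise ValueError(f"fraction_of_dapi must be in [0, 1]; got {fraction_of_dapi}")
    if dapi_total < 0:
        raise ValueError("dapi_total must be >= 0")
    return fraction_of_dapi * dapi_total


def aap_count(infrared_positive: int, chl_positive: int) -> int:
    """AAP cell count: infrared-positive cells minus Chl a-containing cells.

    Chlorophyll autofluorescence bleeds into the infrared image, so
    picophytoplankton must be subtracted; a negative difference (counting
    scatter) is clamped to zero with a warning.
    """
    if infrared_positive < 0 or chl_positive < 0:
        raise ValueError("counts must be >= 0")
    diff = infrared_positive - chl_positive
    if diff < 0:
        warnings.warn(
            f"Chl-positive count ({chl_positive}) exceeds infrared count "
            f"({infrared_positive}); AAP count clamped to 0",
            stacklevel=2,
        )
        return 0
    return diff


def leucine_to_production(
    leu_pmol_per_l_per_h: float, ccf_kgc_per_mol: float = 1.5
) -> float:
    """Convert leucine incorporation to carbon production (µgC L^-1 day^-1).

    pmol → mol (1e-12), times the carbon conversion factor in kgC per mol
    leucine (default 1.5), kg → µg (1e9), hours → day (24); net factor
    0.024 × ccf.
    """
    if leu_pmol_per_l_per_h < 0:
        raise ValueError("leucine incorporation rate must be >= 0")
    if ccf_kgc_per_mol < 0:
        raise ValueError("conversion factor must be >= 0")
    return leu_pmol_per_l_per_h * 1e-12 * ccf_kgc_per_mol * 1e9 * 24.0
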