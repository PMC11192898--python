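"""Gap-free yearly values per series via spline (GAM) smoothing or the chain method.

Series with six or more records are smoothed with a cubic regression
spline fitted to natural-log abundances, with basis dimension equal to
half the number of records (the index pipeline's convention for the
smoothing parameter); predictions are exponentiated back.  Shorter
series, constant series, and series whose spline fit fails fall back to
the chain method: log-linear interpolation of missing years between
consecutive observed records.  Neither method extrapolates beyond the
first or last observed year.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import patsy

from .model import LpiError, PopulationSeries, ProcessedSeries


class GamFitError(LpiError):
    """Spline smoothing failed; the caller should fall back to the chain method."""


@dataclass(frozen=True)
class GamDiagnostics:
    converged: bool
    finite_positive: bool  # predictions at observed years finite and > 0
    deviance_explained: float


def spline_df(n_records: int) -> int:
    """Basis dimension: half the record count, never below 3."""
    return max(3, round(n_records / 2))


@lru_cache(maxsize=4096)
def _design_matrices(
    obs_offsets: tuple[int, ...], span: int, df: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-regression-spline design matrices at observed and at all years.

    Cached because simulated ensembles contain thousands of series on the
    same year grid.
    """
    x_obs = np.asarray(obs_offsets, dtype=float)
    dm = patsy.dmatrix("cr(x, df=%d)" % df, {"x": x_obs})
    x_all = np.arange(span, dtype=float)
    dm_all = patsy.build_design_matrices([dm.design_info], {"x": x_all})[0]
    return np.asarray(dm), np.asarray(dm_all)


def _gam_fit(series: PopulationSeries) -> tuple[np.ndarray, np.ndarray, GamDiagnostics]:
    """Fit the log-scale spline; return (years, predicted values, diagnostics)."""
    years = np.asarray(series.years)
    values = series.values
    if np.any(values <= 0):
        raise LpiError(
            f"population {series.population_id!r}: non-positive value reached "
            "the smoother (zero policy should have removed or shifted it)"
        )
    offsets = tuple(int(y - years[0]) for y in years)
    span = int(years[-1] - years[0] + 1)
    df = min(spline_df(len(years)), len(years))
    log_values = np.log(values)
    try:
        X_obs, X_all = _design_matrices(offsets, span, df)
        beta, _, rank, _ = np.linalg.lstsq(X_obs, log_values, rcond=None)
        pred_obs = X_obs @ beta
        pred_all = X_all @ beta
        converged = bool(np.all(np.isfinite(beta)))
    except (np.linalg.LinAlgError, patsy.PatsyError):
        empty = np.full(span, np.nan)
        return (
            np.arange(years[0], years[-1] + 1),
            empty,
            GamDiagnostics(False, False, 0.0),
        )
    tss = float(np.sum((log_values - log_values.mean()) ** 2))
    rss = float(np.sum((log_values - pred_obs) ** 2))
    dev_expl = 1.0 if tss == 0 else 1.0 - rss / tss
    fitted = np.exp(pred_all)
    finite_positive = bool(
        np.all(np.isfinite(pred_all)) and np.all(fitted > 0)
    )
    diag = GamDiagnostics(converged, finite_positive, dev_expl)
    return np.arange(years[0], years[-1] + 1), fitted, diag


def gam_fit_ok(diag: GamDiagnostics, deviance_threshold: float = 0.0) -> bool:
    """Whether a spline fit is acceptable.

    The default criterion is convergence plus finite, strictly positive
    predictions; a minimum deviance-explained can additionally be required
    (disabled at the default threshold of 0).
    """
    if not (diag.converged and diag.finite_positive):
        return False
    if deviance_threshold > 0 and diag.deviance_explained < deviance_threshold:
        return False
    return True


def fit_gam_log(series: PopulationSeries) -> ProcessedSeries:
    """Spline-smoothed yearly values for one series (natural-log scale fit).

    Raises :class:`GamFitError` when the fit does not satisfy
    :func:`gam_fit_ok`; callers fall back to :func:`chain_interpolate`.
    """
    if series.n_records < 2:
        raise LpiError("need at least 2 records")
    all_years, fitted, diag = _gam_fit(series)
    if not gam_fit_ok(diag):
        raise GamFitError(
            f"population {series.population_id!r}: spline fit unusable"
        )
    return ProcessedSeries(
        population_id=series.population_id,
        method="gam",
        years=all_years,
        values=fitted,
        source=series,
    )


def chain_interpolate(series: PopulationSeries) -> ProcessedSeries:
    """Log-linear interpolation of missing years between observed records.

    Observed values pass through unchanged; a gap between (y1, v1) and
    (y2, v2) is filled on the line joining ln v1 and ln v2, i.e. filled
    values are geometric interpolants of the endpoints.
    """
    if series.n_records < 2:
        raise LpiError(
            f"population {series.population_id!r}: chain method needs >= 2 records"
        )
    years = np.asarray(series.years, dtype=float)
    values = series.values
    if np.any(values <= 0):
        raise LpiError(
            f"population {series.population_id!r}: non-positive value reached "
            "the smoother (zero policy should have removed or shifted it)"
        )
    all_years = np.arange(int(years[0]), int(years[-1]) + 1)
    log_filled = np.interp(all_years.astype(float), years, np.log(values))
    filled = np.exp(log_filled)
    # exactness at observed years, immune to interp round-off
    observed_idx = (years - years[0]).astype(int)
    filled[observed_idx] = values
    return ProcessedSeries(
        population_id=series.population_id,
        method="chain",
        years=all_years,
        values=filled,
        source=series,
    )


def select_method(
    series: PopulationSeries,
    min_records_for_gam: int = 6,
    deviance_threshold: float = 0.0,
) -> str:
    """Choose ``"gam"`` or ``"chain"`` for a series.

    The spline is used only for series of at least ``min_records_for_gam``
    records whose values are not all equal and whose trial fit passes
    :func:`gam_fit_ok`; everything else uses the chain method.
    """
    if series.n_records < min_records_for_gam:
        return "chain"
    values = series.values
    if np.all(values == values[0]):
        return "chain"
    _, _, diag = _gam_fit(series)
    return "gam" if gam_fit_ok(diag, deviance_threshold) else "chain"


def smooth_series(
    series: PopulationSeries,
    min_records_for_gam: int = 6,
    deviance_threshold: float = 0.0,
) -> ProcessedSeries:
    """Run method selection and return the processed (gap-free) series.

    Equivalent to :func:`select_method` followed by the chosen method, but
    fits the trial spline only once.
    """
    values = series.values
    if series.n_records >= min_records_for_gam and not np.all(values == values[0]):
        all_years, fitted, diag = _gam_fit(series)
        if gam_fit_ok(diag, deviance_threshold):
            return ProcessedSeries(
                population_id=series.population_id,
                method="gam",
                years=all_years,
                values=fitted,
                source=series,
            )
    return chain_interpolate(series)
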