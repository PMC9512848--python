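"""Evaluation metrics for the assimilation and decomposition pipeline.

Interannual variability, biomass assimilation bias, temporal trend
agreement, LULCC intensity, detrended climate-carbon Spearman correlation
maps with significance, area-weighted regional aggregation, and the
fractional error scaling applied to global stock aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import TransitionForcing, ValidationError, TC_PER_PGC


def iav(series) -> float:
    """Interannual variability: sample SD (n-1) over the mean, absolute.

    Undefined for a zero mean (raises)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValidationError("IAV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValidationError("IAV undefined for zero-mean series")
    return float(abs(x.std(ddof=1) / mean))


def assimilation_bias(assimilated: np.ndarray, observed: np.ndarray,
                      years: Optional[np.ndarray] = None):
    """Biomass assimilation bias: time-mean (assimilated - observed) stocks.

    Inputs are (n_yr, n_cell) stock series in t C; cells where either
    series is missing in a year are ignored for that year.  Returns
    ``(bias_field, global_mean_pg, global_sd_pg)`` with the global annual
    bias aggregated in Pg C and its interannual SD.
    """
    a = np.asarray(assimilated, dtype=float)
    o = np.asarray(observed, dtype=float)
    if a.shape != o.shape:
        raise ValidationError("assimilated/observed series misaligned")
    diff = a - o
    with np.errstate(invalid="ignore"):
        bias_field = np.nanmean(diff, axis=0)
    annual = np.nansum(diff, axis=1) / TC_PER_PGC
    sd = float(annual.std(ddof=1)) if annual.size > 1 else 0.0
    return bias_field, float(annual.mean()), sd


def temporal_agreement(series_a, series_b) -> float:
    """Fraction of year-over-year changes with the same sign in both series.

    A zero change agrees only with a zero change."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need two equal-length series of length >= 2")
    sa = np.sign(np.diff(a))
    sb = np.sign(np.diff(b))
    return float(np.mean(sa == sb))


def lulcc_intensity(forcing: TransitionForcing) -> np.ndarray:
    """Mean annual cleared-plus-harvested area percentage per cell."""
    cleared = forcing.clearing.sum(axis=(2, 3))
    return 100.0 * (cleared + forcing.harvest).mean(axis=0)


def detrend(series) -> np.ndarray:
    """Anomalies as residuals from an OLS linear fit against time."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValidationError("detrending needs at least 3 points")
    t = np.arange(x.size, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    return x - (slope * t + intercept)


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p-value for tie-free Spearman rho."""
    ranks = np.arange(n, dtype=float)
    target = abs(rho)
    count = 0
    total = 0
    denom = n * (n * n - 1)
    for perm in permutations(range(n)):
        d = ranks - np.asarray(perm, dtype=float)
        r = 1.0 - 6.0 * float(d @ d) / denom
        if abs(r) >= target - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_correlation(x, y, exact_n: int = 9):
    """Spearman rank correlation with average-rank ties and two-sided p.

    Uses the large-sample t approximation; for n <= ``exact_n`` with
    tie-free data the p-value comes from exact permutation enumeration.
    Returns (rho, p); (nan, nan) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("need >= 4 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    n = x.size
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= exact_n and not ties:
        p = _spearman_exact_p(float(rho), n)
    return float(rho), float(p)


def spearman_map(carbon_anom: np.ndarray, climate_anom: np.ndarray,
                 alpha: float = 0.05):
    """Per-cell Spearman correlation between anomaly series.

    Inputs are (n_yr, n_cell).  Returns ``(rho, p, significant)`` fields;
    cells with a constant series get NaN and are masked insignificant.
    """
    c = np.asarray(carbon_anom, dtype=float)
    k = np.asarray(climate_anom, dtype=float)
    if c.shape != k.shape:
        raise ValidationError("anomaly fields misaligned")
    if c.shape[0] < 4:
        raise ValidationError("need >= 4 paired years per cell")
    n_cell = c.shape[1]
    rho = np.full(n_cell, np.nan)
    p = np.full(n_cell, np.nan)
    for i in range(n_cell):
        rho[i], p[i] = spearman_correlation(c[:, i], k[:, i])
    sig = np.where(np.isnan(p), False, p < alpha)
    return rho, p, sig


def regional_aggregate(field_series: np.ndarray, region_labels: np.ndarray,
                       region_names: Optional[dict] = None) -> pd.DataFrame:
    """Per-region annual sums of an extensive per-cell series.

    ``field_series`` is (n_yr, n_cell) in absolute units (t C or
    t C yr^-1 -- already area-integrated); regions partition the global
    total exactly.  Unlabelled cells (label < 0) carrying nonzero values
    trigger a warning column ``_unlabelled``.
    """
    f = np.asarray(field_series, dtype=float)
    labels = np.asarray(region_labels, dtype=int)
    if labels.shape[0] != f.shape[1]:
        raise ValidationError("region mask does not cover the grid")
    out = {}
    for lab in np.unique(labels):
        name = (region_names or {}).get(int(lab), f"region_{int(lab)}")
        if lab < 0:
            name = "_unlabelled"
        out[name] = f[:, labels == lab].sum(axis=1)
    return pd.DataFrame(out)


def scale_uncertainty(value: float, fraction: float = 0.005):
    """Symmetric fractional error bounds: (value, value*fraction) so that
    the interval is value +/- value*fraction."""
    if fraction < 0:
        raise ValidationError("error fraction must be >= 0")
    half = abs(value) * fraction
    return float(value - half), float(value + half)


@dataclass
class DiagnosticsReport:
    """Bundle of the evaluation metrics for one paired run."""

    iav_transient_flux: float
    iav_fixed_flux: float
    iav_sland: float
    bias_field: np.ndarray
    bias_global_pg: float
    bias_sd_pg: float
    agreement_global: float
    lulcc_intensity_pct: np.ndarray
    rho_temp: np.ndarray
    p_temp: np.ndarray
    rho_precip: np.ndarray
    p_precip: np.ndarray


def evaluate(result, temp_anom: np.ndarray, precip_anom: np.ndarray,
             forcing: TransitionForcing) -> DiagnosticsReport:
    """Compute the full diagnostic suite for a DecompositionResult."""
    eluc_t = result.eluc_transient["total"].to_numpy()[1:]
    eluc_f = result.eluc_fixed["total"].to_numpy()[1:]
    sland = result.sland["S_LAND_B"].to_numpy()
    bias_field, bias_pg, bias_sd = assimilation_bias(
        result.transient.assim_stock, result.transient.obs_stock)
    obs_glob = np.nansum(result.transient.obs_stock, axis=1)
    asm_glob = np.nansum(result.transient.assim_stock, axis=1)
    carbon_anom = np.apply_along_axis(detrend, 0, result.transient.stock_boy)
    t_anom = np.apply_along_axis(detrend, 0, temp_anom)
    p_anom = np.apply_along_axis(detrend, 0, precip_anom)
    rho_t, p_t, _ = spearman_map(carbon_anom, t_anom)
    rho_p, p_p, _ = spearman_map(carbon_anom, p_anom)
    return DiagnosticsReport(
        iav_transient_flux=iav(eluc_t) if eluc_t.mean() != 0 else float("nan"),
        iav_fixed_flux=iav(eluc_f) if eluc_f.mean() != 0 else float("nan"),
        iav_sland=iav(sland) if sland.mean() != 0 else float("nan"),
        bias_field=bias_field, bias_global_pg=bias_pg, bias_sd_pg=bias_sd,
        agreement_global=temporal_agreement(asm_glob, obs_glob),
        lulcc_intensity_pct=lulcc_intensity(forcing),
        rho_temp=rho_t, p_temp=p_t, rho_precip=rho_p, p_precip=p_p)
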