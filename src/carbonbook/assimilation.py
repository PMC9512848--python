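"""Assimilation of observed grid-cell woody biomass carbon densities.

Observed cell-mean densities (t C ha^-1) are distributed across the two
woody land cover types (primary, secondary) and the eight woody PFTs by the
model's own current biomass fractions, unrealistically dense cells are
excluded by configurable thresholds, excluded/missing cells are filled by
linear barycentric interpolation, and the equilibrium pools are
re-initialized from the assimilated stocks each year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .core import (
    GridSpec, PoolState, ValidationError,
    J_V, J_S, WOODY_J, K_OTHER, N_PFT, REGROW,
)

N_WOODY = len(WOODY_J)


# ---------------------------------------------------------------------------
# Density series
# ---------------------------------------------------------------------------

@dataclass
class DensitySeries:
    """Annual observed cell-mean woody biomass carbon densities (t C ha^-1)."""

    years: np.ndarray          # (n_yr,), contiguous
    values: np.ndarray         # (n_yr, n_cell)
    valid: np.ndarray          # (n_yr, n_cell) bool

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or \
                self.values.shape[0] != self.years.size:
            raise ValidationError("density series shapes are inconsistent")
        if self.years.size > 1 and np.any(np.diff(self.years) != 1):
            raise ValidationError("density series years must be contiguous")
        if np.any(self.values[self.valid] < 0):
            raise ValidationError("valid densities must be non-negative")

    def year_index(self, year: int) -> int:
        idx = int(year - self.years[0])
        if idx < 0 or idx >= self.years.size:
            raise ValidationError(f"year {year} outside density series")
        return idx


# ---------------------------------------------------------------------------
# Biomass fractions (distribution weights)
# ---------------------------------------------------------------------------

def compute_biomass_fractions(state: PoolState) -> np.ndarray:
    """Fraction of each cell's woody biomass per (woody cover, PFT).

    f[cell, jw, l] = C[cell, jw, l] / C[cell], computed from the state's
    living stocks; cells with zero woody stock fall back to the static
    cover x PFT area-fraction weights.  Fractions sum to 1 on every cell.
    """
    living = state.living_stock_jl()           # (n_cell, N_COVER, N_PFT)
    woody = living[:, WOODY_J, :]              # (n_cell, 2, N_PFT)
    if np.any(woody < -1e-6):
        raise ValidationError("negative woody stock encountered")
    woody = np.clip(woody, 0.0, None)
    tot = woody.sum(axis=(1, 2))
    f = np.zeros_like(woody)
    has = tot > 0
    f[has] = woody[has] / tot[has, None, None]

    # area-fraction fallback for empty cells
    area_w = state.cover_frac[:, WOODY_J][:, :, None] * state.pft_frac[:, None, :]
    area_tot = area_w.sum(axis=(1, 2))
    fallback = np.zeros_like(area_w)
    ok = area_tot > 0
    fallback[ok] = area_w[ok] / area_tot[ok, None, None]
    fallback[~ok, 0, :] = state.pft_frac[~ok] / \
        np.maximum(state.pft_frac[~ok].sum(axis=1, keepdims=True), 1e-300)
    f[~has] = fallback[~has]
    return f


def distribute_density(rho: np.ndarray, area: np.ndarray,
                       fractions: np.ndarray) -> np.ndarray:
    """Assimilated stocks C_as[cell, woody cover, PFT] = rho * A * f.

    The sum over (cover, PFT) reproduces rho * A exactly per cell.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValidationError("densities must be non-negative")
    return rho[:, None, None] * area[:, None, None] * fractions


def derive_cell_densities(stocks: np.ndarray, cover_frac: np.ndarray,
                          pft_frac: np.ndarray, area: np.ndarray) -> np.ndarray:
    """Per-(woody cover, PFT) densities (t C ha^-1) from assimilated stocks.

    density = stock / (A * cover fraction * PFT fraction); zero-area slots
    must carry zero stock.
    """
    slot_area = (area[:, None, None] * cover_frac[:, WOODY_J][:, :, None]
                 * pft_frac[:, None, :])
    zero = slot_area <= 1e-12
    if np.any(np.abs(stocks[zero]) > 1e-9):
        raise ValidationError("nonzero stock on a zero-area cover/PFT slot")
    out = np.zeros_like(stocks)
    np.divide(stocks, slot_area, out=out, where=~zero)
    return out


# ---------------------------------------------------------------------------
# Threshold exclusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdPolicy:
    """Exclusion rule for inconsistent woody biomass carbon densities.

    ``uniform`` masks densities at or above ``uniform_limit`` (default
    375 t C ha^-1, just above the source dataset's maximum of ~374).
    ``percentile`` additionally masks, per (woody cover, PFT) over the whole
    series, values above the given percentile of the sub-375 distribution.
    """

    mode: str = "uniform"            # "uniform" | "percentile"
    uniform_limit: float = 375.0
    percentile: float = 99.0

    def __post_init__(self):
        if self.mode not in ("uniform", "percentile"):
            raise ValidationError(f"unknown threshold mode {self.mode!r}")
        if not (0.0 < self.percentile <= 100.0):
            raise ValidationError("percentile must be in (0, 100]")


@dataclass
class ExclusionReport:
    """Per-layer exclusion bookkeeping from threshold application."""

    n_values: int = 0
    n_excluded_uniform: int = 0
    n_excluded_percentile: int = 0
    cutoffs: Optional[np.ndarray] = None   # (2, N_PFT) percentile cutoffs
    rows: list = field(default_factory=list)  # (year, cell, cover, pft, value, rule)

    @property
    def excluded_fraction(self) -> float:
        n = self.n_excluded_uniform + self.n_excluded_percentile
        return n / self.n_values if self.n_values else 0.0


def percentile_cutoffs(density_series: np.ndarray, valid: np.ndarray,
                       policy: ThresholdPolicy) -> np.ndarray:
    """Per-(woody cover, PFT) percentile cutoffs over the whole series.

    Computed on values already below the uniform limit; layers with no such
    values get the uniform limit (nothing extra excluded).
    """
    if density_series.size == 0:
        raise ValidationError("empty density series")
    cut = np.full((N_WOODY, N_PFT), policy.uniform_limit)
    for jw in range(N_WOODY):
        for l in range(N_PFT):
            vals = density_series[:, :, jw, l][valid[:, :, jw, l]]
            vals = vals[vals < policy.uniform_limit]
            if vals.size:
                cut[jw, l] = np.percentile(vals, policy.percentile)
    return np.minimum(cut, policy.uniform_limit)


def apply_thresholds(density_series: np.ndarray, valid: np.ndarray,
                     policy: ThresholdPolicy,
                     cutoffs: Optional[np.ndarray] = None,
                     years: Optional[np.ndarray] = None):
    """Mask inconsistent per-(cover, PFT) densities across the whole series.

    ``density_series`` is (n_yr, n_cell, 2, N_PFT); ``valid`` marks
    observed slots.  Returns ``(mask, report)`` where ``mask`` is True for
    slots that remain valid after exclusion.  Percentile-mode exclusions
    are a superset of uniform-mode exclusions at the same limit.
    """
    d = np.asarray(density_series, dtype=float)
    if d.size == 0:
        raise ValidationError("empty density series")
    if not np.all(np.isfinite(d[valid])):
        raise ValidationError("densities must be finite")
    report = ExclusionReport(n_values=int(valid.sum()))
    excl_u = valid & (d >= policy.uniform_limit)
    report.n_excluded_uniform = int(excl_u.sum())
    mask = valid & ~excl_u
    if policy.mode == "percentile":
        if cutoffs is None:
            cutoffs = percentile_cutoffs(d, valid, policy)
        report.cutoffs = cutoffs
        excl_p = mask & (d > cutoffs[None, None, :, :])
        report.n_excluded_percentile = int(excl_p.sum())
        mask = mask & ~excl_p
    if years is not None:
        bad = np.argwhere(valid & ~mask)
        for t, c, jw, l in bad:
            rule = "uniform" if d[t, c, jw, l] >= policy.uniform_limit \
                else "percentile"
            report.rows.append((int(years[t]), int(c), ("v", "s")[jw],
                                int(l), float(d[t, c, jw, l]), rule))
    return mask, report


# ---------------------------------------------------------------------------
# Interpolation of excluded / missing cells
# ---------------------------------------------------------------------------

def interpolate_missing(values: np.ndarray, valid: np.ndarray,
                        grid: GridSpec) -> np.ndarray:
    """Fill masked cells of one annual field by linear barycentric interpolation.

    Interpolation runs on the cell-centre (lon, lat) coordinates; cells
    outside the convex hull of the valid cells are filled with the nearest
    valid value.  Valid cells are returned unchanged; a complete field is
    the identity.  Requires at least 3 non-collinear valid cells.
    """
    values = np.asarray(values, dtype=float).ravel()
    valid = np.asarray(valid, dtype=bool).ravel()
    if valid.all():
        return values.copy()
    n_valid = int(valid.sum())
    if n_valid < 3:
        raise ValidationError("interpolation needs >= 3 valid cells")
    lon2, lat2 = np.meshgrid(grid.lon, grid.lat)
    pts = np.column_stack([lon2.ravel(), lat2.ravel()])
    good = pts[valid]
    # collinearity check via rank of centred coordinates
    if np.linalg.matrix_rank(good - good.mean(axis=0), tol=1e-10) < 2:
        raise ValidationError("valid cells are collinear; cannot interpolate")
    lin = LinearNDInterpolator(good, values[valid])
    near = NearestNDInterpolator(good, values[valid])
    out = values.copy()
    hole = ~valid
    filled = lin(pts[hole])
    outside = ~np.isfinite(filled)
    if np.any(outside):
        filled[outside] = near(pts[hole][outside])
    out[hole] = filled
    return out


# ---------------------------------------------------------------------------
# Pool re-initialization (transient mode)
# ---------------------------------------------------------------------------

def reinitialize_pools(state: PoolState, assimilated: np.ndarray):
    """Re-initialize the equilibrium pools from the assimilated stocks.

    ``assimilated`` is (n_cell, 2, N_PFT) over the woody covers and is the
    *standing* woody biomass the model should carry after assimilation.  The
    main excess pools must already have been folded into the
    assimilation-era legacy bank (they are required to be zero here).
    Because the legacy banks keep tracking regrowth deficits of earlier
    land-use events, the equilibrium pools are set so that the living stock
    (equilibrium plus legacy regrowth deficits) equals the assimilated
    stock exactly.  Equilibrium stock is booked under history 'g'.

    Returns ``(new_state, injection)`` where ``injection`` (t C) is the net
    external carbon added by the overwrite, for the run's mass ledger.
    """
    if np.any(np.abs(state.excess) > 1e-6):
        raise ValidationError("main excess pools must be folded (zero) "
                              "before re-initialization")
    assimilated = np.asarray(assimilated, dtype=float)
    if np.any(assimilated < 0):
        raise ValidationError("assimilated stocks must be non-negative")
    new = state.copy()
    before = new.eq.sum()
    leg_regrow = (state.leg_pre[REGROW] + state.leg_post[REGROW]).sum(axis=2)
    new.eq[:] = 0.0
    for i, j in enumerate(WOODY_J):
        # deficits are negative, so this books eq >= assimilated stock
        new.eq[:, j, K_OTHER, :] = assimilated[:, i, :] - leg_regrow[:, j, :]
    injection = float(new.eq.sum() - before)
    return new, injection
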