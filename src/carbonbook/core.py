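"""Bookkeeping kernel: carbon pools, land-use transitions, exponential relaxation.

The model tracks living woody biomass carbon on a regular lat-lon grid,
partitioned by land cover type, land-use history type and plant functional
type (PFT).  Each (cell, cover, history, PFT) slot carries

* an *equilibrium* pool |CBAR| -- the stock the vegetation strives toward,
* signed *excess* pools -- departures from equilibrium that relax
  exponentially: positive excess is dead material decaying to the
  atmosphere (release), negative excess is a regrowth deficit filling in
  from the atmosphere (uptake).

Excess pools come in two components that carry distinct time constants:
``DECAY`` (cleared or harvested material en route to the atmosphere) and
``REGROW`` (standing-biomass deficit of the recovering stand).  On top of
the main excess pools two *legacy* pool banks track fluxes committed by
land use before the assimilation era (pre-T0) and by land use during the
assimilation era but before the current year (post-T0).

Sign convention throughout: carbon release to the atmosphere is positive,
uptake by vegetation is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
M2_PER_HA = 1.0e4
TC_PER_PGC = 1.0e9  # 1 Pg C = 1e9 t C

COVER_TYPES = ("v", "s", "c", "p")  # primary ("virgin"), secondary, cropland, pasture
WOODY_COVERS = ("v", "s")
HISTORY_TYPES = ("l", "h", "a", "g")  # clearing, harvest, abandonment, other
N_COVER = len(COVER_TYPES)
N_HISTORY = len(HISTORY_TYPES)
N_PFT = 8  # woody PFTs

J_V, J_S, J_C, J_P = range(N_COVER)
K_CLEAR, K_HARVEST, K_ABANDON, K_OTHER = range(N_HISTORY)
WOODY_J = (J_V, J_S)

# excess-pool components
DECAY, REGROW = 0, 1
N_COMPONENT = 2

FLUX_CATEGORIES = ("clearing", "harvest", "abandonment", "other")
N_CAT = len(FLUX_CATEGORIES)

# (component, history) -> reporting category
_CATEGORY_OF = np.full((N_COMPONENT, N_HISTORY), FLUX_CATEGORIES.index("other"))
_CATEGORY_OF[DECAY, K_CLEAR] = FLUX_CATEGORIES.index("clearing")
_CATEGORY_OF[DECAY, K_HARVEST] = FLUX_CATEGORIES.index("harvest")
_CATEGORY_OF[REGROW, K_HARVEST] = FLUX_CATEGORIES.index("harvest")
_CATEGORY_OF[REGROW, K_ABANDON] = FLUX_CATEGORIES.index("abandonment")


class ValidationError(ValueError):
    """Raised when model inputs violate a structural precondition."""


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid with spherical cell areas.

    Cell areas (ha) are computed from the cell bounds on a sphere:
    ``A = R^2 * dlon_rad * (sin(lat_top) - sin(lat_bottom)) / 1e4``.
    """

    lat: np.ndarray  # cell-centre latitudes, degrees, descending or ascending
    lon: np.ndarray  # cell-centre longitudes, degrees

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        for name, c in (("lat", lat), ("lon", lon)):
            if c.ndim != 1 or c.size < 1:
                raise ValidationError(f"{name} must be a 1-D coordinate array")
            if c.size > 1:
                d = np.diff(c)
                if not np.allclose(d, d[0], rtol=1e-8, atol=1e-10) or d[0] == 0:
                    raise ValidationError(f"{name} spacing must be regular and nonzero")

    @property
    def n_lat(self) -> int:
        return self.lat.size

    @property
    def n_lon(self) -> int:
        return self.lon.size

    @property
    def n_cell(self) -> int:
        return self.lat.size * self.lon.size

    def _dlat(self) -> float:
        return float(abs(np.diff(self.lat)[0])) if self.n_lat > 1 else 1.0

    def _dlon(self) -> float:
        return float(abs(np.diff(self.lon)[0])) if self.n_lon > 1 else 1.0

    @property
    def cell_area(self) -> np.ndarray:
        """Area per cell in ha, flattened row-major (lat, lon) -> (n_cell,)."""
        dlat, dlon = self._dlat(), self._dlon()
        top = np.radians(np.clip(self.lat + dlat / 2.0, -90.0, 90.0))
        bot = np.radians(np.clip(self.lat - dlat / 2.0, -90.0, 90.0))
        band = EARTH_RADIUS_M**2 * np.radians(dlon) * (np.sin(top) - np.sin(bot))
        area = np.repeat(band / M2_PER_HA, self.n_lon)
        if np.any(area <= 0):
            raise ValidationError("cell areas must be strictly positive")
        return area

    @classmethod
    def regular(cls, n_lat: int, n_lon: int, lat_min: float = 40.0,
                lat_max: float = 60.0, lon_min: float = 0.0,
                lon_max: float = 20.0) -> "GridSpec":
        dlat = (lat_max - lat_min) / n_lat
        dlon = (lon_max - lon_min) / n_lon
        lat = lat_max - dlat / 2.0 - dlat * np.arange(n_lat)  # descending, as stored
        lon = lon_min + dlon / 2.0 + dlon * np.arange(n_lon)
        return cls(lat=lat, lon=lon)


# ---------------------------------------------------------------------------
# Time constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeConstantTable:
    """Relaxation time constants tau (years) per (component, cover, history, PFT).

    Decay-type pools (cleared/harvested material) and regrowth-type pools
    carry distinct constants.  All entries must be strictly positive.
    """

    tau: np.ndarray  # (N_COMPONENT, N_COVER, N_HISTORY, N_PFT)

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        if tau.shape != (N_COMPONENT, N_COVER, N_HISTORY, N_PFT):
            raise ValidationError(f"tau table has shape {tau.shape}")
        if not np.all(tau > 0):
            raise ValidationError("all time constants must be > 0")
        object.__setattr__(self, "tau", tau)

    @classmethod
    def default(cls, tau_clearing: float = 1.0, tau_harvest_decay: float = 2.0,
                tau_regrowth: float = 15.0) -> "TimeConstantTable":
        tau = np.ones((N_COMPONENT, N_COVER, N_HISTORY, N_PFT))
        tau[DECAY, :, K_CLEAR, :] = tau_clearing
        tau[DECAY, :, K_HARVEST, :] = tau_harvest_decay
        tau[REGROW, :, :, :] = tau_regrowth
        return cls(tau=tau)

    @property
    def retention(self) -> np.ndarray:
        """Per-pool one-year retention factor e^(-1/tau)."""
        return np.exp(-1.0 / self.tau)


# ---------------------------------------------------------------------------
# Pool state
# ---------------------------------------------------------------------------

def _pool_array(n_cell: int) -> np.ndarray:
    return np.zeros((n_cell, N_COVER, N_HISTORY, N_PFT))


def _excess_array(n_cell: int) -> np.ndarray:
    return np.zeros((N_COMPONENT, n_cell, N_COVER, N_HISTORY, N_PFT))


@dataclass
class PoolState:
    """Full carbon-pool state of the model at the end of a given year.

    All stocks in t C.  ``cover_frac`` is the (dynamic) area fraction of
    each land cover type per cell; ``pft_frac`` is the temporally constant
    PFT area fraction per cell (sums to 1 over the woody PFTs).
    """

    grid: GridSpec
    cover_frac: np.ndarray          # (n_cell, N_COVER)
    pft_frac: np.ndarray            # (n_cell, N_PFT)
    eq: np.ndarray                  # (n_cell, N_COVER, N_HISTORY, N_PFT)
    excess: np.ndarray              # (N_COMPONENT, n_cell, ...)
    leg_pre: np.ndarray             # legacy pools, events before T0
    leg_post: np.ndarray            # legacy pools, assimilation-era events
    year: int = 0

    def copy(self) -> "PoolState":
        return PoolState(grid=self.grid, cover_frac=self.cover_frac.copy(),
                         pft_frac=self.pft_frac.copy(), eq=self.eq.copy(),
                         excess=self.excess.copy(), leg_pre=self.leg_pre.copy(),
                         leg_post=self.leg_post.copy(), year=self.year)

    # -- aggregates ---------------------------------------------------------

    def total_carbon(self) -> float:
        """Sum of every tracked pool (t C), including dead decaying material."""
        return float(self.eq.sum() + self.excess.sum()
                     + self.leg_pre.sum() + self.leg_post.sum())

    def living_stock_jl(self) -> np.ndarray:
        """Living woody biomass per (cell, cover, PFT): equilibrium plus all
        regrowth (standing-deficit) excess components."""
        return (self.eq.sum(axis=2)
                + self.excess[REGROW].sum(axis=2)
                + self.leg_pre[REGROW].sum(axis=2)
                + self.leg_post[REGROW].sum(axis=2))

    def living_stock_cell(self) -> np.ndarray:
        """Living woody biomass per cell (t C)."""
        return self.living_stock_jl().sum(axis=(1, 2))

    def living_density_cell(self) -> np.ndarray:
        """Cell-mean living woody biomass carbon density (t C ha^-1)."""
        return self.living_stock_cell() / self.grid.cell_area


def initialize_equilibrium(stocks: np.ndarray, grid: GridSpec,
                           cover_frac: np.ndarray, pft_frac: np.ndarray,
                           year: int = 0) -> PoolState:
    """Place all biomass carbon in equilibrium pools under history 'g'.

    ``stocks`` is indexed (cell, cover, PFT) in t C; all excess and legacy
    pools start at zero (vegetation assumed in equilibrium).
    """
    stocks = np.asarray(stocks, dtype=float)
    if stocks.shape != (grid.n_cell, N_COVER, N_PFT):
        raise ValidationError(f"stocks shape {stocks.shape} != "
                              f"({grid.n_cell}, {N_COVER}, {N_PFT})")
    if np.any(stocks < 0):
        raise ValidationError("initial stocks must be non-negative")
    cover_frac = np.asarray(cover_frac, dtype=float)
    pft_frac = np.asarray(pft_frac, dtype=float)
    if np.any(cover_frac < 0) or np.any(cover_frac.sum(axis=1) > 1 + 1e-9):
        raise ValidationError("cover fractions must be >= 0 and sum to <= 1")
    state = PoolState(grid=grid, cover_frac=cover_frac.copy(),
                      pft_frac=pft_frac.copy(), eq=_pool_array(grid.n_cell),
                      excess=_excess_array(grid.n_cell),
                      leg_pre=_excess_array(grid.n_cell),
                      leg_post=_excess_array(grid.n_cell), year=year)
    state.eq[:, :, K_OTHER, :] = stocks
    return state


# ---------------------------------------------------------------------------
# Transition forcing
# ---------------------------------------------------------------------------

@dataclass
class TransitionForcing:
    """Annual fractional-area land-use transitions per cell.

    * ``clearing[t, cell, src, tgt]`` -- fraction of the cell moving from
      woody cover src in (v, s) to agricultural cover tgt in (c, p);
    * ``abandonment[t, cell, src]`` -- fraction moving from src in (c, p)
      to secondary land;
    * ``harvest[t, cell]`` -- fraction of the cell wood-harvested on
      secondary land (no cover change, j = j').
    """

    years: np.ndarray               # (n_yr,) contiguous
    clearing: np.ndarray            # (n_yr, n_cell, 2, 2)
    abandonment: np.ndarray         # (n_yr, n_cell, 2)
    harvest: np.ndarray             # (n_yr, n_cell)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        for name in ("clearing", "abandonment", "harvest"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr < 0):
                raise ValidationError(f"{name} fractions must be >= 0")
        n_yr = self.years.size
        if self.years.size > 1 and np.any(np.diff(self.years) != 1):
            raise ValidationError("forcing years must be contiguous")
        n_cell = self.harvest.shape[1]
        if self.clearing.shape != (n_yr, n_cell, 2, 2):
            raise ValidationError("clearing has wrong shape")
        if self.abandonment.shape != (n_yr, n_cell, 2):
            raise ValidationError("abandonment has wrong shape")

    @property
    def n_cell(self) -> int:
        return self.harvest.shape[1]

    def year_index(self, year: int) -> int:
        idx = int(year - self.years[0])
        if idx < 0 or idx >= self.years.size:
            raise ValidationError(f"year {year} outside forcing range")
        return idx

    @classmethod
    def zeros(cls, years, n_cell: int) -> "TransitionForcing":
        years = np.asarray(years, dtype=int)
        n = years.size
        return cls(years=years, clearing=np.zeros((n, n_cell, 2, 2)),
                   abandonment=np.zeros((n, n_cell, 2)),
                   harvest=np.zeros((n, n_cell)))


# ---------------------------------------------------------------------------
# Flux ledger
# ---------------------------------------------------------------------------

@dataclass
class FluxLedger:
    """Annual carbon fluxes to/from the atmosphere, release-positive (t C).

    Split by timing (instantaneous = relaxation of last year's transitions;
    legacy pre-T0; legacy post-T0) and by transition category.
    """

    years: list = field(default_factory=list)
    inst: list = field(default_factory=list)      # each (n_cell, N_CAT)
    leg_pre: list = field(default_factory=list)
    leg_post: list = field(default_factory=list)

    def record(self, year: int, inst: np.ndarray, leg_pre: np.ndarray,
               leg_post: np.ndarray) -> None:
        self.years.append(int(year))
        self.inst.append(inst)
        self.leg_pre.append(leg_pre)
        self.leg_post.append(leg_post)

    def _stack(self, rows) -> np.ndarray:
        if not rows:
            return np.zeros((0, 0, N_CAT))
        return np.stack(rows)

    @property
    def inst_arr(self) -> np.ndarray:
        return self._stack(self.inst)

    @property
    def leg_pre_arr(self) -> np.ndarray:
        return self._stack(self.leg_pre)

    @property
    def leg_post_arr(self) -> np.ndarray:
        return self._stack(self.leg_post)

    def total(self) -> np.ndarray:
        """theta_total per (year, cell, category): exact sum of the parts."""
        return total_flux(self.inst_arr, self.leg_pre_arr, self.leg_post_arr)

    def annual_total_tc(self) -> np.ndarray:
        """Global theta_total per year (t C yr^-1)."""
        return self.total().sum(axis=(1, 2))

    def annual_by_category_tc(self) -> np.ndarray:
        """Global theta_total per (year, category) in t C yr^-1."""
        return self.total().sum(axis=1)


def total_flux(theta_inst: np.ndarray, theta_leg_pre: np.ndarray,
               theta_leg_post: np.ndarray) -> np.ndarray:
    """Total flux: instantaneous + pre-T0 legacy + post-T0 legacy, elementwise."""
    a, b, c = (np.asarray(x, dtype=float) for x in
               (theta_inst, theta_leg_pre, theta_leg_post))
    if not (a.shape == b.shape == c.shape):
        raise ValidationError("flux components must share a shape")
    return a + b + c


def _categorize(theta_pools: np.ndarray) -> np.ndarray:
    """Collapse a (N_COMPONENT, n_cell, j, k, l) flux array to (n_cell, N_CAT)."""
    n_cell = theta_pools.shape[1]
    out = np.zeros((n_cell, N_CAT))
    for comp in range(N_COMPONENT):
        for k in range(N_HISTORY):
            out[:, _CATEGORY_OF[comp, k]] += theta_pools[comp, :, :, k, :].sum(axis=(1, 2))
    return out


# ---------------------------------------------------------------------------
# Relaxation and legacy accounting
# ---------------------------------------------------------------------------

def _relax(delta: np.ndarray, retention: np.ndarray):
    """One-year exponential relaxation of a signed excess bank.

    Returns (new_delta, theta) with theta = delta * (1 - e^(-1/tau)),
    carrying the pool's sign (positive excess -> release)."""
    new = delta * retention
    theta = delta - new
    return new, theta


def relax_step(state: PoolState, tau: TimeConstantTable):
    """Relax the main excess pools and the pre-T0 legacy pools by one year.

    Returns ``(new_state, theta_inst_pools, theta_leg_pre_pools)`` where the
    theta arrays are per-pool fluxes (t C, release-positive), shape
    (N_COMPONENT, n_cell, cover, history, PFT).  Post-T0 legacy pools are
    advanced separately by :func:`update_legacy_pools`.
    """
    r = tau.retention[:, None, :, :, :]
    new = state.copy()
    new.excess, theta_inst = _relax(state.excess, r)
    new.leg_pre, theta_pre = _relax(state.leg_pre, r)
    return new, theta_inst, theta_pre


def update_legacy_pools(state: PoolState, prior_year_excess: np.ndarray,
                        tau: TimeConstantTable):
    """Advance the assimilation-era legacy pools by one year.

    ``prior_year_excess`` is the excess carbon to fold into the legacy bank
    (in the simulation driver this is the post-relaxation remainder of the
    previous year's main excess pools, so that pooled accounting equals a
    per-event exponential ledger).  Update per pool:

        theta(t)  = leg(t-1) * (1 - e^(-1/tau))
        leg(t)    = leg(t-1) + injection - theta(t)

    Returns ``(new_state, theta_leg_post_pools)``.
    """
    inj = np.asarray(prior_year_excess, dtype=float)
    if inj.shape != state.leg_post.shape:
        raise ValidationError(f"injection shape {inj.shape} != "
                              f"{state.leg_post.shape}")
    r = tau.retention[:, None, :, :, :]
    new = state.copy()
    decayed, theta_post = _relax(state.leg_post, r)
    new.leg_post = decayed + inj
    return new, theta_post


# ---------------------------------------------------------------------------
# Land-use transitions
# ---------------------------------------------------------------------------

_FRAC_EPS = 1e-12


def apply_transitions(state: PoolState, forcing: TransitionForcing, year: int,
                      harvest_intensity: float = 1.0,
                      regrowth_target_density: Optional[np.ndarray] = None):
    """Apply one year of land-use transitions to the pool state.

    Carbon moved by clearing/harvest is drawn from the source cover's living
    biomass (equilibrium plus standing regrowth excess) at the living
    density, proportionally across PFTs by the static PFT area fractions:

    * clearing (v/s -> c/p): the standing stock of the cleared area enters a
      positive decaying excess pool (history 'l'); the target cover is
      booked at its woody equilibrium (zero for cropland/pasture);
    * harvest (secondary, j=j'): ``harvest_intensity`` of the stand biomass
      on the harvested area enters a positive decaying excess ('h') and an
      equal-magnitude negative regrowth excess ('h') stays on the stand;
    * abandonment (c/p -> s): the new secondary land is booked at the
      regrowth target density with an equal negative regrowth excess ('a').

    ``regrowth_target_density`` is the secondary-land living density
    (t C ha^-1) per (cell, PFT) that abandoned land regrows toward; by
    default it is diagnosed from the current state.  Returns
    ``(new_state, created_excess)`` where ``created_excess`` has the excess
    bank's shape and holds the net excess created this year.  No carbon is
    created or destroyed: the pool total is invariant.
    """
    ti = forcing.year_index(year)
    clear = forcing.clearing[ti]          # (n_cell, 2, 2)
    aband = forcing.abandonment[ti]       # (n_cell, 2)
    harv = forcing.harvest[ti]            # (n_cell,)
    if not (0.0 <= harvest_intensity <= 1.0):
        raise ValidationError("harvest intensity must be in [0, 1]")

    n_cell = state.grid.n_cell
    new = state.copy()
    created = _excess_array(n_cell)

    out_frac = np.zeros((n_cell, N_COVER))
    out_frac[:, J_V] = clear[:, 0].sum(axis=1)
    out_frac[:, J_S] = clear[:, 1].sum(axis=1) + harv  # harvested area must exist
    out_frac[:, J_C] = aband[:, 0]
    out_frac[:, J_P] = aband[:, 1]
    if np.any(out_frac > state.cover_frac + _FRAC_EPS):
        raise ValidationError("transition area exceeds available cover fraction")

    # living stock per (cell, j, l): equilibrium plus every standing-deficit
    # (regrowth) component, legacy banks included -- clearing a stand with
    # regrowth debt cancels the debt's future uptake
    living_jl = state.living_stock_jl()

    # regrowth target: current living secondary density per (cell, pft),
    # falling back to primary where secondary is empty
    if regrowth_target_density is None:
        regrowth_target_density = diagnose_secondary_density(state)
    rho_tgt = np.asarray(regrowth_target_density, dtype=float)
    if rho_tgt.shape != (n_cell, N_PFT):
        raise ValidationError("regrowth target density must be (n_cell, n_pft)")
    if np.any(rho_tgt < 0):
        raise ValidationError("regrowth target density must be >= 0")

    # --- clearing: scale source pools, move stock to decay excess ----------
    for src_i, j in enumerate(WOODY_J):
        a = clear[:, src_i].sum(axis=1)                 # total cleared fraction
        frac = state.cover_frac[:, j]
        active = a > 0
        if not np.any(active):
            continue
        scale = np.zeros(n_cell)
        scale[active] = a[active] / frac[active]
        moved = living_jl[:, j, :] * scale[:, None]     # (n_cell, n_pft)
        if np.any(moved < -1e-9):
            raise ValidationError("clearing would move negative carbon "
                                  "(standing deficit exceeds equilibrium)")
        keep = (1.0 - scale)[:, None, None]
        new.eq[:, j] *= keep
        new.excess[REGROW, :, j] *= keep
        new.leg_pre[REGROW, :, j] *= keep
        new.leg_post[REGROW, :, j] *= keep
        # target woody equilibrium is zero on cropland/pasture, so the full
        # moved stock decays: (rho_source - rho_target_eq) * area
        new.excess[DECAY, :, j, K_CLEAR, :] += moved
        created[DECAY, :, j, K_CLEAR, :] += moved

    # --- harvest on secondary land -----------------------------------------
    active = harv > 0
    if np.any(active):
        frac_s = state.cover_frac[:, J_S]
        scale = np.zeros(n_cell)
        scale[active] = harv[active] / frac_s[active]
        removed = harvest_intensity * living_jl[:, J_S, :] * scale[:, None]
        new.excess[DECAY, :, J_S, K_HARVEST, :] += removed
        new.excess[REGROW, :, J_S, K_HARVEST, :] -= removed
        created[DECAY, :, J_S, K_HARVEST, :] += removed
        created[REGROW, :, J_S, K_HARVEST, :] -= removed

    # --- abandonment: book new secondary land at the regrowth target -------
    b_total = aband.sum(axis=1)                         # fraction joining 's'
    active = b_total > 0
    if np.any(active):
        area = state.grid.cell_area * b_total           # ha abandoned
        booked = rho_tgt * (area[:, None] * state.pft_frac)  # (n_cell, n_pft)
        new.eq[:, J_S, K_ABANDON, :] += booked
        new.excess[REGROW, :, J_S, K_ABANDON, :] -= booked
        created[REGROW, :, J_S, K_ABANDON, :] -= booked

    # --- area bookkeeping ---------------------------------------------------
    new.cover_frac[:, J_V] -= clear[:, 0].sum(axis=1)
    new.cover_frac[:, J_S] -= clear[:, 1].sum(axis=1)
    new.cover_frac[:, J_C] += clear[:, :, 0].sum(axis=1) - aband[:, 0]
    new.cover_frac[:, J_P] += clear[:, :, 1].sum(axis=1) - aband[:, 1]
    new.cover_frac[:, J_S] += b_total
    np.clip(new.cover_frac, 0.0, None, out=new.cover_frac)

    return new, created


def diagnose_secondary_density(state: PoolState) -> np.ndarray:
    """Living secondary-land density per (cell, PFT), t C ha^-1.

    Where secondary land is (near) absent the primary density is used; where
    no woody vegetation exists at all the target is zero.
    """
    area = state.grid.cell_area
    dens = np.zeros((state.grid.n_cell, N_PFT))
    living = state.eq.sum(axis=2) + state.excess[REGROW].sum(axis=2) \
        + state.leg_pre[REGROW].sum(axis=2) + state.leg_post[REGROW].sum(axis=2)
    for j in (J_S, J_V):
        slot_area = area[:, None] * state.cover_frac[:, [j]] * state.pft_frac
        ok = (slot_area > _FRAC_EPS) & (dens == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(slot_area > _FRAC_EPS, living[:, j, :] / np.maximum(slot_area, _FRAC_EPS), 0.0)
        dens = np.where(ok, d, dens)
    return np.clip(dens, 0.0, None)
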