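"""Self-contained synthetic worlds with an exact ground-truth ledger.

The generator emulates the inputs the pipeline consumes -- an annual
gridded woody biomass carbon density series, land-use transition forcing,
static cover/PFT maps and climate anomaly fields -- with the statistical
structure the analysis assumes: a secular environmental trend (emulating
CO2 fertilization), temperature-coupled interannual variability, and
LULCC-driven losses computed by the same transition rules as the
bookkeeping kernel.  Every generated component is recorded in a
ground-truth ledger so that recovery of the environmental sink and of the
land-use flux can be checked exactly.

Construction: an internal land-use-only ("base") simulation evolves the
initial equilibrium world under the generated forcing; the observable
density path is the base living density times a per-cell environmental
multiplier

    m(c, t) = (1 + trend)^(t - T0) * (1 + c_T * T'(c, t) + eps(c, t))

so the annual stock change splits exactly into an environmental part
(base stock times the multiplier change) and a LULCC part (multiplier
times the base stock change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import core
from .assimilation import DensitySeries
from .core import (
    GridSpec, PoolState, TimeConstantTable, TransitionForcing,
    ValidationError, N_CAT, N_PFT, _categorize,
    apply_transitions, initialize_equilibrium, relax_step,
)

DEFAULT_PFT_EQ_DENSITY = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0)


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Parameters of a synthetic world (desk scale by default: 20x20, 20 yr)."""

    n_lat: int = 20
    n_lon: int = 20
    t0: int = 2000
    n_years: int = 20
    seed: int = 0
    pft_eq_density: tuple = DEFAULT_PFT_EQ_DENSITY   # t C ha^-1, primary land
    secondary_density_factor: float = 0.8
    env_trend: float = 0.005          # fractional yr^-1
    env_noise_sd: float = 0.01        # multiplier noise SD
    temp_coupling: float = 0.02       # fractional density response per K
    temp_anom_sd: float = 1.0         # K
    precip_anom_sd: float = 50.0      # mm
    clearing_rate: float = 0.003      # fraction of the source cover yr^-1
    harvest_rate: float = 0.002
    abandonment_rate: float = 0.001
    harvest_intensity: float = 1.0
    noise_sd: float = 2.0             # observation noise, t C ha^-1
    missing_fraction: float = 0.02
    tau: TimeConstantTable = field(default_factory=TimeConstantTable.default)

    def __post_init__(self):
        if len(self.pft_eq_density) != N_PFT:
            raise ValidationError(f"need {N_PFT} PFT equilibrium densities")
        for name in ("env_noise_sd", "temp_anom_sd", "clearing_rate",
                     "harvest_rate", "abandonment_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValidationError("missing_fraction must be in [0, 1)")
        # rates are per unit source-cover area; the cumulative fraction
        # affected must stay below the available cover
        worst = (self.clearing_rate + self.harvest_rate) * 1.5 * self.n_years
        if worst > 0.9:
            raise ValidationError("clearing/harvest rates would exhaust the "
                                  "source cover over the simulated span")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.t0, self.t0 + self.n_years)


@dataclass
class GroundTruthLedger:
    """Exact decomposition of the synthetic world's annual stock changes.

    ``stock(t) = stock(t-1) + env_change(t) + lulcc_change(t)`` holds
    exactly; stocks are beginning-of-year living stocks in t C.  ``events``
    stores, per year, the excess pools created by that year's transitions
    (the committed-flux ledger); the analytic legacy flux schedule follows
    by closed-form exponential decay.
    """

    years: np.ndarray
    stock: np.ndarray            # (n_yr,) t C, beginning of year
    env_change: np.ndarray       # (n_yr,) t C, zero in the first year
    lulcc_change: np.ndarray     # (n_yr,) t C, zero in the first year
    events: list                 # [(year, created excess array)]
    tau: TimeConstantTable
    # cumulative survival of standing (regrowth) cohorts against later
    # clearing, per (year index = end of that year, cell, cover); computed
    # from the forcing alone
    regrow_survival: Optional[np.ndarray] = None

    def check_identity(self) -> float:
        """Max abs error of the stock = cumulative-change identity (t C)."""
        recon = np.concatenate([[self.stock[0]], self.stock[0]
                                + np.cumsum((self.env_change + self.lulcc_change)[1:])])
        return float(np.max(np.abs(recon - self.stock)))

    def expected_flux_schedule(self, years: np.ndarray) -> np.ndarray:
        """Analytic per-event exponential flux schedule, (n_yr, N_CAT) t C.

        An excess pool delta created by an event in year e releases
        delta * (1 - e^(-1/tau)) * e^(-(m-1)/tau) in year e + m (m >= 1),
        with the pool's sign.  Standing (regrowth) cohorts are additionally
        clipped by later clearing of their cover: the cohort surviving into
        year t carries the forcing-derived survival factor for the years
        e+1 .. t-1.
        """
        years = np.asarray(years, dtype=int)
        out = np.zeros((years.size, N_CAT))
        r = self.tau.retention[:, None, :, :, :]
        y0 = int(self.years[0])
        for e_year, created in self.events:
            ie = e_year - y0
            for i, t in enumerate(years):
                m = t - e_year
                if m < 1:
                    continue
                ev = created.copy()
                if self.regrow_survival is not None:
                    surv = (self.regrow_survival[t - y0 - 1]
                            / self.regrow_survival[ie])   # (n_cell, N_COVER)
                    ev[core.REGROW] *= surv[:, :, None, None]
                flux_pools = ev * (1.0 - r) * r ** (m - 1)
                out[i] += _categorize(flux_pools).sum(axis=0)
        return out


@dataclass
class SyntheticWorld:
    """A generated world: pipeline inputs plus the exact truth ledger."""

    config: SyntheticWorldConfig
    grid: GridSpec
    init_state: PoolState        # pre-T0 equilibrium state
    forcing: TransitionForcing
    densities: DensitySeries     # degraded observations (noise + mask)
    clean_densities: DensitySeries
    temp_anom: np.ndarray        # (n_yr, n_cell) K
    precip_anom: np.ndarray      # (n_yr, n_cell) mm
    env_multiplier: np.ndarray   # (n_yr, n_cell)
    ledger: GroundTruthLedger


def _generate_cover_pft(rng, n_cell):
    cover = rng.dirichlet([4.0, 3.0, 1.5, 1.5], size=n_cell) * 0.95
    pft = rng.dirichlet(np.ones(N_PFT), size=n_cell)
    return cover, pft


def _generate_forcing(cfg: SyntheticWorldConfig, rng, cover: np.ndarray
                      ) -> TransitionForcing:
    """Annual transitions; rates are per unit *source-cover* area, so the
    forcing can never exhaust a cover fraction at desk time scales."""
    years = cfg.years
    n_cell = cover.shape[0]
    n_yr = years.size
    u = lambda: rng.uniform(0.5, 1.5, size=(n_yr, n_cell))
    v0 = cover[None, :, core.J_V]
    s0 = cover[None, :, core.J_S]
    clearing = np.zeros((n_yr, n_cell, 2, 2))
    c = cfg.clearing_rate * u()
    clearing[:, :, 0, 0] = 0.4 * c * v0   # v -> c
    clearing[:, :, 0, 1] = 0.2 * c * v0   # v -> p
    clearing[:, :, 1, 0] = 0.3 * c * s0   # s -> c
    clearing[:, :, 1, 1] = 0.1 * c * s0   # s -> p
    aband = np.zeros((n_yr, n_cell, 2))
    b = cfg.abandonment_rate * u()
    aband[:, :, 0] = 0.7 * b * cover[None, :, core.J_C]
    aband[:, :, 1] = 0.3 * b * cover[None, :, core.J_P]
    harvest = cfg.harvest_rate * u() * s0
    return TransitionForcing(years=years, clearing=clearing,
                             abandonment=aband, harvest=harvest)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a synthetic world; the same seed yields identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = GridSpec.regular(cfg.n_lat, cfg.n_lon)
    n_cell = grid.n_cell
    area = grid.cell_area
    years = cfg.years
    n_yr = years.size

    cover, pft = _generate_cover_pft(rng, n_cell)
    rho_eq = np.asarray(cfg.pft_eq_density)
    stocks = np.zeros((n_cell, core.N_COVER, N_PFT))
    for j, fac in ((core.J_V, 1.0), (core.J_S, cfg.secondary_density_factor)):
        stocks[:, j, :] = (rho_eq[None, :] * fac * area[:, None]
                           * cover[:, [j]] * pft)
    init_state = initialize_equilibrium(stocks, grid, cover, pft,
                                        year=cfg.t0 - 1)

    forcing = _generate_forcing(cfg, rng, cover)

    # climate anomalies and the environmental multiplier path
    temp_anom = rng.normal(0.0, cfg.temp_anom_sd, size=(n_yr, n_cell))
    precip_anom = rng.normal(0.0, cfg.precip_anom_sd, size=(n_yr, n_cell))
    eps = rng.normal(0.0, cfg.env_noise_sd, size=(n_yr, n_cell)) \
        if cfg.env_noise_sd > 0 else np.zeros((n_yr, n_cell))
    trend = (1.0 + cfg.env_trend) ** np.arange(n_yr)
    mult = trend[:, None] * (1.0 + cfg.temp_coupling * temp_anom + eps)
    if np.any(mult <= 0):
        raise ValidationError("environmental multiplier driven non-positive; "
                              "reduce noise/coupling amplitudes")

    # land-use-only base world, evolved by the bookkeeping kernel itself
    base = init_state.copy()
    rho_base = np.zeros((n_yr, n_cell))
    events = []
    for i, t in enumerate(years):
        t = int(t)
        if i > 0:
            base, _ti, _tp = relax_step(base, cfg.tau)
        rho_base[i] = base.living_density_cell()
        base, created = apply_transitions(
            base, forcing, t, harvest_intensity=cfg.harvest_intensity)
        events.append((t, created))

    rho_clean = rho_base * mult
    if np.any(rho_clean < 0):
        raise ValidationError("generated densities went negative")

    # survival of standing (regrowth) cohorts against later clearing,
    # derived from the forcing alone (cover areas evolve independently of
    # carbon): the model scales standing pools of cover j by
    # (1 - cleared_fraction / cover_fraction) each year
    cf = cover.copy()
    survival = np.ones((n_yr, n_cell, core.N_COVER))
    running = np.ones((n_cell, core.N_COVER))
    for i in range(n_yr):
        clear_out = np.zeros((n_cell, core.N_COVER))
        clear_out[:, core.J_V] = forcing.clearing[i, :, 0].sum(axis=1)
        clear_out[:, core.J_S] = forcing.clearing[i, :, 1].sum(axis=1)
        scale = np.where(cf > 1e-12,
                         1.0 - clear_out / np.maximum(cf, 1e-300), 1.0)
        running = running * scale
        survival[i] = running
        cf[:, core.J_V] -= forcing.clearing[i, :, 0].sum(axis=1)
        cf[:, core.J_S] -= forcing.clearing[i, :, 1].sum(axis=1)
        cf[:, core.J_C] += forcing.clearing[i, :, :, 0].sum(axis=1) \
            - forcing.abandonment[i, :, 0]
        cf[:, core.J_P] += forcing.clearing[i, :, :, 1].sum(axis=1) \
            - forcing.abandonment[i, :, 1]
        cf[:, core.J_S] += forcing.abandonment[i].sum(axis=1)

    base_stock = (rho_base * area[None, :])
    stock = (rho_clean * area[None, :]).sum(axis=1)
    env_change = np.zeros(n_yr)
    lulcc_change = np.zeros(n_yr)
    env_change[1:] = (base_stock[1:] * np.diff(mult, axis=0)).sum(axis=1)
    lulcc_change[1:] = (mult[:-1] * np.diff(base_stock, axis=0)).sum(axis=1)
    ledger = GroundTruthLedger(years=years, stock=stock,
                               env_change=env_change,
                               lulcc_change=lulcc_change,
                               events=events, tau=cfg.tau,
                               regrow_survival=survival)

    clean = DensitySeries(years=years, values=rho_clean,
                          valid=np.ones((n_yr, n_cell), dtype=bool))
    degraded = degrade_observations(clean, cfg.noise_sd, cfg.missing_fraction,
                                    seed=int(rng.integers(2**31)))
    return SyntheticWorld(config=cfg, grid=grid, init_state=init_state,
                          forcing=forcing, densities=degraded,
                          clean_densities=clean, temp_anom=temp_anom,
                          precip_anom=precip_anom, env_multiplier=mult,
                          ledger=ledger)


def degrade_observations(densities: DensitySeries, noise_sd: float,
                         missing_fraction: float, seed: int) -> DensitySeries:
    """Additive Gaussian observation noise (truncated at zero) plus a random
    validity mask; reproducible by seed."""
    if noise_sd < 0:
        raise ValidationError("noise SD must be >= 0")
    if not (0.0 <= missing_fraction < 1.0):
        raise ValidationError("missing fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = densities.values.copy()
    if noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, noise_sd, values.shape), 0.0, None)
    valid = densities.valid.copy()
    if missing_fraction > 0:
        valid &= rng.random(values.shape) >= missing_fraction
    return DensitySeries(years=densities.years.copy(), values=values,
                         valid=valid)
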