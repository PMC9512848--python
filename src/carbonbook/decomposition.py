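"""Twin transient/fixed simulations and the E_LUC / S_LAND decomposition.

The *transient* run re-assimilates the observed woody biomass carbon
densities every year, so its stock changes carry both land-use and
environmental signals.  The *fixed* run assimilates only the first year
(T0) and afterwards evolves by land-use transitions alone.  Run over the
same forcing from the same T0 state, the difference of their annual stock
changes isolates the environmental woody-biomass sink:

    S_LAND_B(t) = -[dC_trans(t) - dC_fix(t)]          (release-positive)

while each run's atmosphere fluxes, aggregated from the bookkeeping
ledger, give the land-use flux E_LUC_B of that setup.  Stock output for
year X represents the end of year X; stock changes between X and X+1 are
attributed to year X+1, so flux series start at T0+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import assimilation as asm
from .core import (
    FluxLedger, PoolState, TimeConstantTable, TransitionForcing,
    ValidationError, _categorize, _excess_array,
    FLUX_CATEGORIES, TC_PER_PGC, relax_step, update_legacy_pools,
    apply_transitions,
)

MODES = ("transient", "fixed")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one bookkeeping simulation run.

    Paired transient/fixed runs must share forcing, T0 and the T0 state;
    the mode alone decides whether pools are re-initialized after T0.
    The sign convention is fixed: release to atmosphere positive.
    """

    mode: str = "transient"
    t0: int = 2000
    t_end: int = 2019
    policy: asm.ThresholdPolicy = field(default_factory=asm.ThresholdPolicy)
    tau: TimeConstantTable = field(default_factory=TimeConstantTable.default)
    harvest_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")
        if self.t_end < self.t0:
            raise ValidationError("t_end must be >= t0")


@dataclass
class SimulationResult:
    """Output of one run: stock series, flux ledger, mass bookkeeping."""

    years: np.ndarray
    stock_boy: np.ndarray       # living stock per (year, cell), start of year, t C
    stock_eoy: np.ndarray       # living stock per (year, cell), end of year, t C
    total_pools: np.ndarray     # all tracked pools per year (end of year), t C
    ledger: FluxLedger
    injections: np.ndarray      # assimilation injections per year, t C
    assim_stock: np.ndarray     # assimilated stock per (year, cell), t C (NaN if none)
    obs_stock: np.ndarray       # raw observed stock per (year, cell), t C (NaN invalid)
    initial_total: float        # tracked pools before the first year, t C
    final_state: PoolState
    exclusion_reports: list

    def global_stock_eoy(self) -> np.ndarray:
        return self.stock_eoy.sum(axis=1)

    def mass_closure_residual(self) -> float:
        """initial + injections - cumulative fluxes - final, relative."""
        flux = self.ledger.annual_total_tc().sum()
        lhs = self.initial_total + self.injections.sum() - flux
        rhs = self.final_state.total_carbon()
        scale = max(abs(self.initial_total), abs(rhs), 1.0)
        return (lhs - rhs) / scale


def _prepare_year(state: PoolState, rho: np.ndarray, valid: np.ndarray,
                  policy: asm.ThresholdPolicy, cutoffs, years=None, t=None):
    """Threshold check + interpolation + distribution for one year.

    Returns (C_as stocks, cell validity after exclusion, report, filled rho).
    """
    grid = state.grid
    area = grid.cell_area
    f = asm.compute_biomass_fractions(state)
    dens_jl = np.full((1, grid.n_cell, 2, asm.N_PFT), np.nan)
    ok = valid.copy()
    stocks_raw = asm.distribute_density(np.where(valid, rho, 0.0), area, f)
    dens_jl[0] = asm.derive_cell_densities(
        stocks_raw, state.cover_frac, state.pft_frac, area)
    valid_jl = np.broadcast_to(valid[None, :, None, None], dens_jl.shape)
    mask_jl, report = asm.apply_thresholds(dens_jl, valid_jl, policy,
                                           cutoffs=cutoffs, years=years)
    # a cell survives only if every observed layer survives
    ok = valid & mask_jl[0].all(axis=(1, 2))
    rho_full = asm.interpolate_missing(np.where(ok, rho, np.nan), ok, grid)
    rho_full = np.clip(rho_full, 0.0, None)
    c_as = asm.distribute_density(rho_full, area, f)
    return c_as, ok, report, rho_full


def run_simulation(config: RunConfig, forcing: TransitionForcing,
                   densities: asm.DensitySeries, init: PoolState,
                   layer_cutoffs: Optional[np.ndarray] = None,
                   _collect_densities: Optional[list] = None) -> SimulationResult:
    """Run one bookkeeping simulation (transient or fixed mode).

    Yearly order of operations: (1) realize relaxation and legacy fluxes
    from the prior year's pools, (2) transient only: fold the post-
    relaxation main excess into the assimilation-era legacy bank and
    re-initialize from the assimilated densities, (3) apply this year's
    land-use transitions.  The initialization year T0 realizes no fluxes;
    at T0 the inherited excess pools move undecayed into the pre-era
    legacy bank and both modes assimilate the T0 density field.
    """
    years = np.arange(config.t0, config.t_end + 1)
    for y in years:
        densities.year_index(int(y))   # raises on misalignment
        forcing.year_index(int(y))
    if config.policy.mode == "percentile" and layer_cutoffs is None:
        layer_cutoffs = collect_percentile_cutoffs(config, forcing, densities, init)

    state = init.copy()
    n_yr, n_cell = years.size, state.grid.n_cell
    area = state.grid.cell_area
    stock_boy = np.zeros((n_yr, n_cell))
    stock_eoy = np.zeros((n_yr, n_cell))
    total_pools = np.zeros(n_yr)
    injections = np.zeros(n_yr)
    assim_stock = np.full((n_yr, n_cell), np.nan)
    obs_stock = np.full((n_yr, n_cell), np.nan)
    ledger = FluxLedger()
    reports = []
    initial_total = state.total_carbon()
    zero_inj = _excess_array(n_cell)

    for i, t in enumerate(years):
        t = int(t)
        if t == config.t0:
            state.leg_pre = state.leg_pre + state.excess
            state.excess = np.zeros_like(state.excess)
            ledger.record(t, np.zeros((n_cell, len(FLUX_CATEGORIES))),
                          np.zeros((n_cell, len(FLUX_CATEGORIES))),
                          np.zeros((n_cell, len(FLUX_CATEGORIES))))
        else:
            state, th_inst, th_pre = relax_step(state, config.tau)
            if config.mode == "transient":
                state, th_post = update_legacy_pools(state, state.excess,
                                                     config.tau)
                state.excess = np.zeros_like(state.excess)
            else:
                state, th_post = update_legacy_pools(state, zero_inj,
                                                     config.tau)
            ledger.record(t, _categorize(th_inst), _categorize(th_pre),
                          _categorize(th_post))

        ti = densities.year_index(t)
        rho = densities.values[ti]
        valid = densities.valid[ti]
        obs_stock[i, valid] = rho[valid] * area[valid]

        if config.mode == "transient" or t == config.t0:
            c_as, ok, report, _rho_full = _prepare_year(
                state, rho, valid, config.policy, layer_cutoffs,
                years=[t], t=t)
            if _collect_densities is not None:
                f = asm.compute_biomass_fractions(state)
                stocks_raw = asm.distribute_density(
                    np.where(valid, rho, 0.0), area, f)
                _collect_densities.append((
                    asm.derive_cell_densities(stocks_raw, state.cover_frac,
                                              state.pft_frac, area), valid))
            reports.append(report)
            state, inj = asm.reinitialize_pools(state, c_as)
            injections[i] = inj
            assim_stock[i] = c_as.sum(axis=(1, 2))

        state.year = t
        stock_boy[i] = state.living_stock_cell()
        state, _created = apply_transitions(
            state, forcing, t, harvest_intensity=config.harvest_intensity)
        stock_eoy[i] = state.living_stock_cell()
        total_pools[i] = state.total_carbon()

    return SimulationResult(years=years, stock_boy=stock_boy,
                            stock_eoy=stock_eoy, total_pools=total_pools,
                            ledger=ledger, injections=injections,
                            assim_stock=assim_stock, obs_stock=obs_stock,
                            initial_total=initial_total, final_state=state,
                            exclusion_reports=reports)


def collect_percentile_cutoffs(config: RunConfig, forcing: TransitionForcing,
                               densities: asm.DensitySeries,
                               init: PoolState) -> np.ndarray:
    """Pass 1 of the percentile threshold: run with the uniform limit only,
    collect the per-(cover, PFT) density series, return percentile cutoffs."""
    probe = RunConfig(mode="transient", t0=config.t0, t_end=config.t_end,
                      policy=asm.ThresholdPolicy(
                          mode="uniform", uniform_limit=config.policy.uniform_limit),
                      tau=config.tau, harvest_intensity=config.harvest_intensity,
                      seed=config.seed)
    collected: list = []
    run_simulation(probe, forcing, densities, init,
                   _collect_densities=collected)
    dens = np.stack([d for d, _v in collected])
    valid = np.stack([np.broadcast_to(v[:, None, None], d.shape)
                      for d, v in collected])
    return asm.percentile_cutoffs(dens, valid, config.policy)


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def compute_eluc(ledger: FluxLedger, years: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Annual global land-use flux (Pg C yr^-1), release-positive, by category.

    Fluxes are aggregated over all cells; categories sum to the total
    exactly.  Requesting years outside the ledger raises.
    """
    led_years = np.asarray(ledger.years, dtype=int)
    by_cat = ledger.annual_by_category_tc() / TC_PER_PGC
    df = pd.DataFrame(by_cat, index=pd.Index(led_years, name="year"),
                      columns=list(FLUX_CATEGORIES))
    df["total"] = df[list(FLUX_CATEGORIES)].sum(axis=1)
    if years is not None:
        years = np.asarray(years, dtype=int)
        if np.any(~np.isin(years, led_years)):
            raise ValidationError("requested years outside the simulated run")
        df = df.loc[years]
    return df


def compute_sland(trans_stocks: np.ndarray, fix_stocks: np.ndarray,
                  years: np.ndarray) -> pd.DataFrame:
    """Environmental woody-biomass sink per year (Pg C yr^-1).

    ``trans_stocks``/``fix_stocks`` are global end-of-year stock series in
    t C on identical year ranges.  With dC(t) = C(t) - C(t-1),

        S_LAND_B(t) = -(dC_trans(t) - dC_fix(t))

    so that net uptake (transient stocks growing faster) is negative.  The
    first year is undefined; the series starts at years[1].
    """
    trans_stocks = np.asarray(trans_stocks, dtype=float)
    fix_stocks = np.asarray(fix_stocks, dtype=float)
    years = np.asarray(years, dtype=int)
    if trans_stocks.shape != fix_stocks.shape or trans_stocks.size != years.size:
        raise ValidationError("stock series must share one year range")
    d_trans = np.diff(trans_stocks)
    d_fix = np.diff(fix_stocks)
    sland = -(d_trans - d_fix) / TC_PER_PGC
    return pd.DataFrame({"dC_trans": d_trans / TC_PER_PGC,
                         "dC_fix": d_fix / TC_PER_PGC,
                         "S_LAND_B": sland},
                        index=pd.Index(years[1:], name="year"))


@dataclass
class DecompositionResult:
    """Paired-run output: stock series, E_LUC per setup, S_LAND_B."""

    years: np.ndarray
    transient: SimulationResult
    fixed: SimulationResult
    eluc_transient: pd.DataFrame    # Pg C yr^-1 by category
    eluc_fixed: pd.DataFrame
    sland: pd.DataFrame             # Pg C yr^-1, starts at T0+1

    def summary(self) -> pd.DataFrame:
        """Annual global series (Pg C): stocks, E_LUC per setup, S_LAND_B."""
        df = pd.DataFrame({
            "stock_transient": self.transient.global_stock_eoy() / TC_PER_PGC,
            "stock_fixed": self.fixed.global_stock_eoy() / TC_PER_PGC,
            "E_LUC_transient": self.eluc_transient["total"],
            "E_LUC_fixed": self.eluc_fixed["total"],
        }, index=pd.Index(self.years, name="year"))
        df["S_LAND_B"] = self.sland["S_LAND_B"].reindex(df.index)
        return df

    def eq6_partition(self) -> pd.DataFrame:
        """Observable attribution of annual woody stock changes (Pg C yr^-1).

        LULCC source/sink terms come from the transient-run ledger split by
        flux sign; the legacy-regrowth sink is the uptake part of the
        legacy fluxes; the net environmental term is only observable as the
        twin-run stock difference (S_LAND_B) and is reported as such.
        """
        tot = self.transient.ledger.total()          # (yr, cell, cat)
        inst = self.transient.ledger.inst_arr
        leg = self.transient.ledger.leg_pre_arr + self.transient.ledger.leg_post_arr
        years = pd.Index(self.transient.ledger.years, name="year")
        src = np.clip(inst, 0, None).sum(axis=(1, 2)) / TC_PER_PGC
        snk = np.clip(inst, None, 0).sum(axis=(1, 2)) / TC_PER_PGC
        reg = np.clip(leg, None, 0).sum(axis=(1, 2)) / TC_PER_PGC
        leg_rel = np.clip(leg, 0, None).sum(axis=(1, 2)) / TC_PER_PGC
        df = pd.DataFrame({"dC_source": src, "dC_sink": snk,
                           "dC_reg_leg": reg, "legacy_release": leg_rel,
                           "total_flux": tot.sum(axis=(1, 2)) / TC_PER_PGC},
                          index=years)
        df["dC_env_net"] = self.sland["S_LAND_B"].reindex(years)
        return df


def run_decomposition(forcing: TransitionForcing, densities: asm.DensitySeries,
                      init: PoolState, t0: int, t_end: int,
                      policy: Optional[asm.ThresholdPolicy] = None,
                      tau: Optional[TimeConstantTable] = None,
                      harvest_intensity: float = 1.0,
                      seed: int = 0) -> DecompositionResult:
    """Run the paired transient/fixed simulations and decompose the fluxes.

    Both runs share one forcing object and the same T0 state; the fixed run
    keeps the T0 assimilated densities throughout.
    """
    policy = policy or asm.ThresholdPolicy()
    tau = tau or TimeConstantTable.default()
    kw = dict(t0=t0, t_end=t_end, policy=policy, tau=tau,
              harvest_intensity=harvest_intensity, seed=seed)
    cutoffs = None
    if policy.mode == "percentile":
        cutoffs = collect_percentile_cutoffs(
            RunConfig(mode="transient", **kw), forcing, densities, init)
    res_t = run_simulation(RunConfig(mode="transient", **kw), forcing,
                           densities, init, layer_cutoffs=cutoffs)
    res_f = run_simulation(RunConfig(mode="fixed", **kw), forcing,
                           densities, init, layer_cutoffs=cutoffs)
    years = res_t.years
    sland = compute_sland(res_t.global_stock_eoy(), res_f.global_stock_eoy(),
                          years)
    return DecompositionResult(years=years, transient=res_t, fixed=res_f,
                               eluc_transient=compute_eluc(res_t.ledger),
                               eluc_fixed=compute_eluc(res_f.ledger),
                               sland=sland)
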