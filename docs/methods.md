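# Methods

## Model structure

`carbonbook` is a bookkeeping model of living woody biomass carbon on a
regular lat–lon grid. Soil, litter, dead-wood and explicit product-pool
dynamics are out of scope; all dead material en route to the atmosphere is
represented by a single aggregated decaying excess pool per history type.

Pools are indexed by (cell, cover type j, history type k, PFT l) with
j ∈ {primary "virgin" v, secondary s, cropland c, pasture p},
k ∈ {clearing l, harvest h, abandonment a, other g}, and 8 woody PFTs.
Woody biomass exists only on v and s. Each slot carries an equilibrium
pool (the stock vegetation strives toward) and signed excess pools in two
components with distinct time constants:

* **decay** — cleared or harvested material committed to the atmosphere
  (positive; release),
* **regrow** — standing-biomass deficit of a recovering stand (negative;
  uptake as it fills in).

Excess pools relax exponentially: δ(t) = δ(t−1)·e^(−1/τ), with the flux
θ(t) = δ(t−1)·(1 − e^(−1/τ)) booked at the start of the year *after* the
driving event. Release to the atmosphere is positive throughout. (The
convention is stated both ways in the literature this design follows; the
release-positive form is used consistently here, so an environmental sink
is negative.)

### Transitions

Transitions are fractional cell areas per year, distributed across PFTs
by the temporally constant PFT area fractions. Carbon moved by clearing
and harvest is drawn at the **living** density of the source cover —
equilibrium plus every standing (regrow) excess component, legacy banks
included — and the standing pools of a cleared cover are scaled down
proportionally, which cancels the future uptake of regrowth debt on land
that is cleared again. This choice (rather than transferring at the
equilibrium density) is what makes the twin-run decomposition exact: a
transient run fed the fixed run's own stock trajectory reproduces the
fixed run to numerical precision. Cropland and pasture carry zero woody
equilibrium, so clearing commits the full standing stock. Harvest removes
an intensity fraction *h* (default 1.0) of stand biomass on the harvested
area and books an equal regrowth deficit on the stand; abandonment books
new secondary land at the current living secondary density (primary
density as fallback where secondary is absent) with an equal negative
regrowth excess. Dead (decay-component) pools are not affected by later
transitions: committed material keeps decaying regardless of subsequent
land use.

### Legacy accounting

Annual re-initialisation of the pools in the transient run would lose the
fluxes committed by earlier land use, so these are tracked in two
separate pool banks: events before the assimilation start T0 (folded in,
undecayed, at initialisation) and assimilation-era events before the
current year. Each year the driver realises the instantaneous flux of the
previous year's excess, then folds the **post-relaxation remainder** into
the assimilation-era bank, whose own update is

    θ_leg(t) = δ_leg(t−1) · (1 − e^(−1/τ)),
    δ_leg(t) = δ_leg(t−1) + injection − θ_leg(t).

Injecting the remainder (not the pre-relaxation excess) is required for
carbon conservation — the first-year flux is already booked as the
instantaneous term — and makes pooled accounting exactly equal to a
per-event exponential ledger (each cohort decays independently with the
same τ, so the pooled exponential is the sum of cohort exponentials).
The total flux per year is the exact sum of the instantaneous, pre-T0
legacy and post-T0 legacy terms.

### Assimilation

Observed cell-mean densities ρ_Ba(t) (t C ha⁻¹) are distributed over
(cover, PFT) by the model's own biomass fractions f = C_B,j,l / C_B
(static cover×PFT area weights where the cell has no stock), giving
stocks ρ·A·f that sum to ρ·A exactly. The equilibrium pools are then set
so that the **living** stock — equilibrium plus tracked legacy regrowth
deficits — equals the assimilated stock; the overwrite difference is
booked as an external injection in the run's mass ledger. Exclusion of
inconsistent densities supports two policies applied per (PFT, cover)
layer over the whole series: a uniform limit (default 375 t C ha⁻¹, just
above the source product's maximum) and a percentile cutoff (default
99th) of the sub-limit distribution. The percentile cutoffs depend on the
assimilated layer densities, which depend on the run itself, so they are
computed in a first pass under the uniform limit only and applied in a
second pass. Excluded or missing cells are filled per year by linear
barycentric interpolation on cell-centre coordinates, nearest-valid value
outside the convex hull. Pipelines that need both policies run them
separately and report mean and range.

### Decomposition

The paired runs share one forcing object and the same T0 state. Yearly
order: (1) realise relaxation/legacy fluxes from prior-year pools,
(2) transient only: fold excess into the legacy bank and re-initialise
from this year's densities, (3) apply this year's transitions. Stock
output for year X is end-of-year X; changes between X and X+1 are
attributed to X+1, so flux series start at T0+1 and the initialisation
year realises no flux. The environmental sink is the release-positive
stock-difference

    S_LAND,B(t) = −[ΔC_trans(t) − ΔC_fix(t)],  ΔC(t) = C(t) − C(t−1),

so faster transient growth (uptake) gives a negative sink. E_LUC,B per
setup is the ledger aggregate in Pg C yr⁻¹ (1 Pg = 10⁹ t), split by
clearing / harvest / abandonment / other; the two must not be combined
into a net land–atmosphere balance, since S_LAND,B includes stock changes
whose atmospheric exchange is delayed through litter and soil. Of the
conceptual five-term partition of ΔC (land-use sources, land-use sinks,
legacy regrowth, environmental sources, environmental sinks) only the
ledger categories and the legacy uptake are separately observable; the
environmental terms are reported via the twin-run difference only.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ clearing decay | 1 yr | decay of cleared material |
| τ harvest decay | 2 yr | decay of harvested material |
| τ regrowth | 15 yr | stand recovery after harvest/abandonment |
| harvest intensity h | 1.0 | fraction of stand biomass removed per harvested area |
| uniform density limit | 375 t C ha⁻¹ | exclusion threshold |
| percentile level | 99 | layer-wise percentile cutoff |

The τ defaults are plausible placeholders of the right order (fast decay
of slash and products, decadal regrowth); the linear-response estimates
they would be converted from are not available here, so every τ is
configurable per (component, cover, history, PFT). Internal units are
t C and t C ha⁻¹; Pg C appears only in reporting.

## Synthetic worlds

The generator emulates the pipeline's inputs at desk scale (20×20 cells,
20 years, 8 PFTs by default). An internal land-use-only simulation —
driven by the same transition kernel — produces a base living-density
path; the observable density is that path times a per-cell environmental
multiplier m(c,t) = (1+trend)^(t−T0) · (1 + c_T·T′(c,t) + ε), with trend
0.005 yr⁻¹ (a CO₂-fertilisation-like secular gain of ~10% over 20 years),
temperature coupling c_T = 0.02 K⁻¹ on anomalies of SD 1 K, and
multiplier noise SD 0.01. Transition rates are per unit source-cover area
(clearing 0.003, harvest 0.002, abandonment 0.001 yr⁻¹, each with ±50%
uniform year-to-year variation), PFT equilibrium densities span
30–240 t C ha⁻¹ with secondary land at 0.8× primary, and observations are
degraded with zero-truncated Gaussian noise (SD 2 t C ha⁻¹ — small
against the ≥30 t C ha⁻¹ densities, so truncation bias is negligible) and
a 2% random validity mask. These values are chosen once as realistic
desk-scale analogues of a global product and forcing.

The ground-truth ledger splits each annual stock change exactly into an
environmental part (base stock × multiplier change) and a land-use part
(multiplier × base stock change), and records every committed excess
cohort; the analytic flux schedule decays each cohort in closed form,
with standing cohorts additionally carrying a forcing-derived survival
factor against later clearing. What the generator does **not** emulate:
realistic spatial covariance of satellite products, fire/mortality
processes, cover/PFT-map inconsistencies (so the assimilation-bias
diagnostic is near zero by construction on synthetic worlds), and
non-woody vegetation. Passing recovery tests therefore demonstrate the
accounting and decomposition machinery, not the realism of any particular
global estimate.

## Numerical choices

* Interannual variability is sample SD (n−1) over the mean, reported as
  an absolute value; undefined (error) for zero-mean series.
* Detrending is OLS-linear against year; residuals sum to zero to 1e-9.
* Spearman correlation uses average-rank ties and two-sided p-values via
  the large-sample t approximation, with exact permutation enumeration
  for tie-free series of length ≤ 9; constant series give NaN and are
  masked insignificant. No multiple-testing correction on the p < 0.05
  significance map.
* Trend agreement counts equal signs of year-over-year changes; a zero
  change agrees only with a zero change.
* Conservative regridding factorises into longitudinal overlap and
  sin(latitude) band overlap, preserving global area-weighted integrals
  to 1e-9 relative.
* NetCDF I/O uses the NetCDF3-classic backend; density inputs in
  kg C m⁻² are converted ×10 on read.
* Transitions within a year are simultaneous (all drawn against the
  beginning-of-year state); a transition demanding more area than the
  source cover holds is an error, as is clearing that would move negative
  carbon.
* Mass closure (initial pools + assimilation injections − cumulative
  fluxes = final pools) holds to ~1e-15 relative and is asserted at 1e-9.

## Limitations

* One aggregated decaying pool per history type — no on-site/product
  sub-pool split, so τ is an effective constant per category.
* Transitions do not touch dead decay pools or redistribute legacy decay
  pools when cover moves; legacy regrowth pools are clipped by clearing
  but not by harvest.
* With land use *and* environmental change active, the attribution of
  the synergy (richer stands → larger clearing emissions) follows the
  twin-run definition; the generator's env/LULCC split uses a different
  (exact but convention-dependent) factorisation, so the two agree only
  when one driver is absent — this mirrors the definitional character of
  the decomposition itself.
* The percentile-threshold two-pass scheme approximates a fully
  self-consistent fixed point by a single iteration.
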