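# Methods

## Model structure and assumptions

The population model is a deterministic, discrete-time (annual) map over
real-valued counts. One sex is modelled; with an equal sex ratio the chick
survival parameter `b` corresponds to `2b` in a two-sex census. There is no
age structure, no spatial arrangement of territories, and no demographic
stochasticity: the analytic equilibria (e.g. `N* = bK/μ` at the 10⁴–10⁵
scale) presuppose a mean-field treatment, and territory counts derived from
island area are deliberately left continuous rather than floored.

Territories are redistributed from scratch every year. A bird breeds only if
it (a) wins a territory and (b) is not wounded this year; floaters and healed
wounded re-enter competition the following year. Strategies are pure and
inherited parent-to-offspring — which is what makes the all-aggressive state
absorbing: once the non-aggressive lineage is extinct there is no mutational
or behavioural route back, hence hysteresis. (In the classic game the mixed-
strategy reading gives the same equilibrium frequencies; only the pure-
strategy reading supports irreversible fixation.)

The contest game uses the standard Hawk–Dove win probabilities with the costs
*separated* from the payoff matrix and charged demographically: the matrix
sets only the division of territories, while injury risk removes
`c(NA−1)NA` hawks from the current year's breeding pool. Two regularisations
are applied where the printed expressions leave the admissible region:

* the self-exclusion factors `(NA−1)`, `(NF−1)` are clamped at 0 below one
  individual, so win shares cannot go negative for fractional counts;
* the expected-casualty term `c(NA−1)NA` is a linear-in-encounters
  approximation that would exceed the hawk count for `NA > ~1/c`; the wounded
  count is clamped to `[0, NA]` since a casualty count cannot exceed the
  population. At every equilibrium of interest the clamp is slack (the
  injury-balanced hawk count `1 + (b−μ)/(bc)` is always below `1 + 1/c`), so
  the clamp only shapes transients.

The piecewise territory-limited / individual-limited birth terms are
implemented as `min(breeding pool, share of territories)`, which coincides
with the piecewise forms including at the tie. The model is stated and
implemented as a difference-equation system throughout.

Parameter defaults and units: `b = 0.15` yr⁻¹ (unknown empirically for the
study species; one egg per year caps it at 1), `μ = 1/30` yr⁻¹ (30-year mean
lifespan of a large flightless pigeon), `c = 2.5·10⁻⁴` per pairwise hawk
encounter (not estimable from data; the sensitivity scan covers it),
`a_T = 0.104 km²` per territory. Time is years before present, decreasing
toward 0.

## Equilibria, stability and the tipping point

At an interior fixed point doves must be territory-limited (self-limitation
would need `b = μ`) and hawks must be injury-limited, which pins
`NA* = 1 + (b−μ)/(bc)` independent of `K`; substituting into the dove balance
gives a quadratic in `NF*` whose discriminant
`(bK/μ−1)² − 4(bK/μ)(1+(b−μ)/(bc))` vanishes at the saddle-node. The tipping
point is the larger root of the corresponding quadratic in `x = bK/μ`
(the smaller root lies below the region where the interior branch exists).

The implementation treats the 2-D map itself as ground truth: interior fixed
points are found by Newton-type root-finding from a coarse log grid of seeds
bounded by two map properties (hawk count below the injury ceiling `1 + 1/c`,
dove count below `bK/μ`), accepted only if the map residual is below 1e-9
relative, and the closed form above serves as an independent cross-check in
the tests. Stability is classified from the eigenvalue moduli of a central
finite-difference Jacobian (relative step 1e-6, one-sided at the axes), with
a 1e-9 margin so neutral numerical noise is not labelled stable. The fold is
located without the closed form by bisecting on the existence of interior
equilibria and then fitting a quadratic in `K` to the squared branch
separation (exactly polynomial near a fold) and extrapolating to zero; the
test suite requires closed-form/numeric agreement to 0.1% over randomized
parameter draws.

## Forcing and hypsometry

Area forcing is ingested as CSV (`time_ky_bp,area_km2`) or computed
hypsometrically from a gridded topo-bathymetry: a cell is land iff its
elevation is strictly above the instantaneous sea level (cells exactly at the
datum are sea — an arbitrary but fixed convention), with cos(latitude) cell
areas on geographic grids. Enclosed depressions count as sea; no
connectivity, reef growth, erosion, or glacio-isostatic adjustment is
modelled, so this is a deliberately reduced stand-in for a full coastline
reconstruction. Coarse forcing is linearly interpolated to the model's annual
step. Coastline retreat between two stands is the maximum Euclidean
centre-to-centre distance from a flooded old-coastline cell to the nearest
new-coastline cell (coastline = land cell with a sea 4-neighbour).

## Synthetic study conditions

The generator emulates the two island archetypes and the late-Pleistocene
forcing; its defaults are the study conditions and are fixed once:

* **Sea level**: sawtooth cycles, 100 ky period, 130 m amplitude, 20 ky
  deglacial rise, phase-anchored so the present is a cycle boundary; the
  default 120→0 ky BP window therefore starts at a glacial maximum and spans
  a full cycle. Sampled at 0.5 ky and interpolated to years.
* **Mauritius-like cone**: 1852 km² at the present datum; apex 666 m chosen
  so the island loses 30% of its glacial-maximum area over a 130 m rise
  (`(apex/(apex+130))² = 0.7`). 0.5 km cells over a 60 km extent.
* **Rodrigues-like cone-on-guyot**: 398 m summit, ≈162 km² at the datum and
  a 1262 km² wave-cut platform at −55 m (steep 1000 m/km flanks beyond).
  These two areas are anchored to the demographic equilibria they imply at
  the default rates — ≈7,000 birds at the interglacial minimum and ≈54,600
  at the glacial maximum — which places ~87% of the island's area loss in
  the few centuries in which the deglacial rise crosses the platform depth.
  The datum area includes the shallow lagoon as land; the island's dry
  landmass alone (108 km²) would imply a smaller minimum population.
  0.25 km cells over a 42 km extent keep the discretisation error of the
  small datum cone near 1%.

What the synthetic fixtures do *not* emulate: real hypsometry (both profiles
are radially symmetric), geographically varying relative sea level,
millennial-scale sea-level noise (available but off by default), and the
irregular timing of real terminations. Passing tests on these fixtures
demonstrate the mechanism — ordering of competition peaks, threshold
crossing, fixation, hysteresis — not quantitative predictions for the real
islands; peak floater excesses on the synthetic sawtooth (≈39% vs ≈0.1%) are
much larger/smaller than on reconstructed area curves, whose gentler slopes
produce peaks of a few percent.

## Experiments

*Floater excess* runs the dove-only model, started at the equilibrium of the
initial territory count after a 10/μ-year burn-in at that constant forcing
(making the equilibrium baseline exact at the window start), and reports
`R(t) = F_sim(t)/F_eq(K(t))` with `F_eq = K(b−μ)/μ`, plus the peak excess
`100·(max R − 1)`. Displaced birds count as floaters in the year the island
shrinks. The peak over the window is reported; the full series is written so
any other reading (specific years, means) is recoverable.

*Fixation* seeds `seed_fraction` (default 1%, configurable — the emergence of
aggression is outside the model, so "a few aggressive birds" is a free
choice) of the equilibrium population as hawks at the window start, runs the
two-strategy model, and reports the first threshold crossing `K(t) < K*`,
the fixation time (`fA > 1 − 10⁻⁶`), and whether fixation survived the
forcing's recovery above `K*`.

## Numerical choices and limitations

Fixed-point residual tolerance 1e-9 relative; fixation threshold `1 − 10⁻⁶`
on `fA`; convergence horizons in tests sized to the slowest relevant
timescale (`1/μ = 30` yr per e-fold near equilibria, slower near the fold).
The report bundle and scenario builds are pure functions of their configs, so
reruns are byte-identical (summaries carry no timestamps). Problem sizes used
throughout — 120,001 annual steps per scenario, 25-point bifurcation grids,
0.25–0.5 km DEM cells — were chosen to keep discretisation error near or
below 1%.

The model is suited to qualitative mechanism analysis, not quantitative
prediction: parameters for the extinct study species are order-of-magnitude
estimates, the one-sex annual census is coarse, and the tipping-point *area*
(though not its existence) moves with `b`, `μ`, `c` — which is exactly what
the sensitivity scan tabulates.
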