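# Methods

`holoflux` models the metabolic interactions of the two-member microbiome of
the deep-sea glass sponge *Aphrocallistes beatrix*: the ammonia-oxidizing
archaeon *Nitrosoabyssus spongiisocia* (an autotroph) and the bacterial
scavenger *Zeuxoniibacter abyssi* (a vitamin-B12-auxotrophic heterotroph),
plus the archaeal virus whose lysis recycles archaeal biomass — cobalamin
included — into the shared medium.

## Flux balance analysis

Each organism is a reduced, hand-curated stoichiometric model (~25
metabolites, ~35 reactions). FBA maximizes the biomass-reaction flux v_bio
subject to steady state S·v = 0 (all metabolites balanced; boundary turnover
flows through export-positive exchange reactions), reaction bounds, and
per-metabolite uptake limits. Because the biomass optimum is usually
degenerate, a second parsimonious stage minimizes Σ|v| at the fixed optimal
growth, which makes every reported flux vector unique and reproducible. Both
stages are plain LPs solved with HiGHS (through `scipy.optimize.linprog`).

Numerical conventions: fluxes in mmol gDW⁻¹ h⁻¹, concentrations in mmol L⁻¹,
biomass in gDW; any flux below 1e-9 is reported as exactly 0, so "no growth"
assertions are exact; the parsimonious stage confines growth to within 1e-6
(relative) of its optimum and pins it back with a dominant objective weight.
Unbounded objectives are diagnosed by re-solving under huge finite bounds and
reporting the reactions pinned there (the unbounded cycle).

`minimal_requirement` finds the smallest uptake bound of one metabolite that
reaches a growth floor by bisection on [0, 1e6] to a relative tolerance of
1e-4, returning +∞ when no finite supply suffices (the signature of a true
auxotrophy rather than a quantitative limitation).

## The curated models

Only pathways named in the source genomes' expression data are encoded, each
as one or a few lumped reactions. Lumps conserve carbon explicitly (the
bookkeeping is stated in each reaction's `evidence` field) but not H/O, so
elemental balancing applies only to the fully specified reactions (e.g.
taurine transamination, DMSP cleavage); lumps are validated structurally and
listed as "unchecked". ATP and reductant yields are round literature-typical
values; `red` is a one-electron equivalent.

Autotroph highlights:

* Ammonia oxidation: NH4 + O2 + 2e⁻ → NH2OH (AmoABC, vmax 80 mmol gDW⁻¹ h⁻¹ —
  this cap sets μ_max ≈ 0.30 h⁻¹), NH2OH → NO → NO2⁻ recovering 4e⁻; the
  electron-transport lump yields 1 ATP per 2e⁻. The nitric-oxide intermediate
  is represented but not exchanged.
* Carbon fixation: one 3HP/4HB-cycle lump, 2.5 CO2 + 5 ATP + 5e⁻·5 →
  acetyl-CoA + 0.1 fumarate + 0.1 formate. The C4/C1 byproducts are obligate
  overflow; a no-energy disposal valve (fumarate oxidized to exported CO2)
  guarantees that blocking fumarate export never changes growth, while the
  parsimonious objective still prefers plain export — this is how fumarate
  cross-feeding emerges without being forced.
* Maintenance: a fixed non-growth ATP demand of 20 mmol gDW⁻¹ h⁻¹. This is
  what makes survival require a minimum ammonium supply: with the default
  transporter affinity (κ = 2500 L gDW⁻¹ h⁻¹, uptake bound u = κ·C in
  medium-based tests) the threshold falls at 8 µmol L⁻¹ ammonium — between
  the ambient deep-sea baseline (1 µmol L⁻¹, a configurable default) and the
  20-fold host-enriched level the simulations use.
* Cobalamin: synthesized internally (biomass contains a 1e-4 mass fraction of
  B12) and salvageable from the medium through a transporter capped at
  6e-6 mmol gDW⁻¹ h⁻¹ — roughly a quarter of the biosynthetic demand at
  maximal growth. Salvage matters ecologically: growing archaea compete with the
  bacterium for lysis-released B12, and the cap controls how much escapes to
  the auxotroph (see "Calibration" below).

Heterotroph highlights:

* Taurine catabolism (2-oxoglutarate transamination → sulfoacetaldehyde →
  acetyl-CoA + sulfite; sulfite oxidized to exported sulfate), creatine and
  choline funnelled through sarcosine whose oxidase obligately releases H2O2,
  betaine entering the same demethylation series, DMSP cleaved to exported
  DMS plus acrylate (activated by propionate-CoA ligase through 3HP-CoA),
  fumarate assimilated and respired, formate oxidized, and lysed archaeal
  biomass catabolized (one C5/N1 "organic matter" unit, 113 g/mol, yielding
  acetyl-CoA plus obligate acetate, CO2 and NH4 release — the acetate is the
  overflow the archaeon can use mixotrophically).
* A futile ATP hydrolysis valve (lb = 0) lets substrates whose catabolism
  over-produces ATP (taurine, fumarate) run at steady state; without it the
  LP forbids those pathways entirely.
* Organic transporters saturate (vmax 2 mmol gDW⁻¹ h⁻¹ for taurine,
  creatine, fumarate and lysate organics; 0.3 for DMSP; 0.1 for the trace
  betaine/choline; 0.5 for formate and acetate). The caps set the
  co-utilization regime: during vigorous growth no single substrate covers
  the carbon demand, so the parsimonious optimum draws taurine, creatine,
  fumarate and lysate together — which is what puts the reported
  ammonium/CO2 return fluxes and the sarcosine-derived H2O2 export into the
  community flux profile. Without saturation a parsimonious cell would ride
  its single cheapest carbon source.
* Biomass requires B12 with **no** synthesis route, so growth without
  external cobalamin is exactly zero for every substrate combination; the
  biomass B12 quota is 3e-4 g per gDW. Growth is capped at 0.35 h⁻¹.

Biomass composition (the lysable constituents) is {organic matter: 1-f_B12,
B12: f_B12} for both organisms. Exact genome-scale biomass formulas are not
reproducible here; compositions are parameterized defaults.

## The seawater medium

Inorganics use literature seawater values (DIC 2.3, sulfate 28 mmol L⁻¹)
except oxygen, a site measurement (6.7 mg/L ÷ 32 g/mol = 0.209 mmol L⁻¹),
and ammonium (baseline × 20). Organics default to taurine ≈ creatine at
C0 = 10 µmol L⁻¹ with DMSP = C0/15, betaine = C0/10⁴, choline = C0/10⁵ —
magnitudes reverse-engineered from the reported uptake-flux ratios because
the measured concentration table is not published; their provenance strings
say so. Measured tables (analyte × specimen, ppb) convert via per-analyte
molar masses assuming unit aqueous density.

## The arena

A 40 × 40 grid (1600 units, one cell per unit) represents a 12 × 12 mm patch;
each grid holds a medium volume of 1.8e-7 L (2 mm depth — the printed
per-grid area is internally inconsistent with the arena dimensions, so the
geometry is configuration with this documented default; population ratios are
insensitive to it). 95% of grids start occupied, identities drawn by
largest-remainder apportionment from metagenome coverage shares (S29-like
94.6 : 4.5 by default). Each cycle (Δt = 1 h): growth (per-agent parsimonious
FBA with uptake bounds = local amount / (biomass·Δt)), division (agents at
2× the 3e-13 gDW unit mass split into a free Moore neighbor), 2% random
removal (host clearance; biomass leaves the system), scheduled archaeal lysis
(biomass × release efficiency converted through the biomass composition into
local metabolite amounts), then 4-neighbor diffusion with reflecting edges
(mixing fraction 0.5 per cycle; 0.2 for macromolecular lysate). Removal and
lysis are deliberately separate processes: removal destroys biomass, lysis
recycles it, which is what makes the B12 flux attributable to the virus.
Dissolved lysate products (the organic-matter lump and B12) additionally
decay at 5% per cycle — the host takes up dissolved organic matter and
cobalamin is labile in oxic seawater. This loss term is what lets the
community *relax*: without it, cobalamin released during a high-lysis
excursion persists indefinitely as a reservoir and the flux state never
returns to its pre-excursion form.

Agents already at the division threshold skip the FBA step until space frees
(quiescence). This bounds per-agent biomass, keeps the one-cell-per-grid
picture meaningful, and avoids unbounded drawdown of the closed medium; it is
configurable. Every agent additionally pays a biomass-specific endogenous
maintenance of 0.03 h⁻¹ — cells that cannot grow shrink, and die once below
half the unit mass (starvation death, biomass leaves the system). Without
this mortality the bacterial population ratchets: any density it reaches
during a high-lysis episode persists indefinitely because background removal
is the only loss, and the community has no unique attractor to return to.
The arena is closed (no replenishment) by default; a per-cycle inflow is
available in configuration.

Performance: per-cell solutions are cached keyed on the uptake-bound vector
down-quantized onto a 5%-resolution log grid; bounds above the organism's
maximum achievable uptake (precomputed per exchange by LP) are clamped to it.
Quantizing downward guarantees a cached solution never overdraws a local
pool. Well-fed agents therefore share one cache entry, and a 50-cycle default
run solves only a few hundred LPs.

Determinism: one seeded generator drives placement, agent order, division
targets, removal and lysis; identical configuration + seed reproduces a
trajectory bit-for-bit.

Mass accounting: lysis exactly conserves mass (released mmol × molar mass =
lysed biomass × efficiency); diffusion is conservative; the per-cycle biomass
and per-metabolite pool ledgers close to floating-point/LP tolerance
(`mass_balance_report`). Note the lumped reaction stoichiometry itself does
not conserve substrate *mass* between uptake and biomass — that is a known
property of lumped models, not an accounting bug.

## Calibration of the B12 economy

Two parameters are not printed anywhere and control the killing-the-winner
equilibrium: the heterotroph's biomass B12 quota and the archaeal salvage
cap. A mean-field balance fixes their roles: at lysis rate L the bacterium's
B12 supply is release minus archaeal re-uptake minus environmental decay,
(L − α·g_A)·B_A·f_A − δ·P (α the salvaged fraction of archaeal demand, P the
standing pool), and its equilibrium abundance satisfies removal·B_H =
supply/f_H. The archaeal salvage term makes the bacterial share superlinear
in L — the property that lets one parameter set match both observed
community states. The defaults (f_H = 3e-4, salvage cap 6e-6, decay
δ = 0.1 cycle⁻¹) were then fixed against the two observed coverage states
(≈95:5 at 5% lysis, ≈66:34 at 20%) in the spatial simulation and are not
tuned further; the intermediate lysis rates and the mirror-state behavior
follow from the mechanism, not from fitting.

## Stable states and cross-feeding

State detection scans the cycles × (organism, metabolite) community
exchange-flux matrix left to right, extending a window while every series
stays within a relative tolerance (default 5%) of its window mean, scaled by
the window's own maximum magnitude; windows shorter than 5 cycles are
discarded. Top-flux tables rank window means by |flux| (water and protons
excluded), always appending betaine, choline, creatine, DMSP and B12 rows;
ties break lexicographically. Cross-feeding edges connect net secretors to
net consumers with flux min(secretion, uptake), the environment carrying the
remainder; lysis-mediated transfers are attributed to the lysed organism as
secretion, so the virus-driven B12 edge appears as autotroph → heterotroph.
Per-cell display fluxes (fmol h⁻¹ cell⁻¹) divide by the mean population over
the window.

## What the synthetic data emulates — and what it does not

The measurement-table generator reproduces the *format* and ordering of a
UHPLC quantification table (five analytes, multiplicative lognormal noise of
cv 0.2, values clipped to the 1–200 ppb calibration span) but not
chromatography artifacts, matrix effects or censoring. Coverage tables
reproduce the two published read-recruitment share pairs, optionally
Dirichlet-jittered. Toy metabolic networks are feasible by construction
(chain backbone plus shunts) and small enough for exhaustive vertex
enumeration, which is the solver's independent oracle. Passing tests on
these inputs validates the machinery and the encoded interaction logic; it
does not validate the reduced models against unpublished genome-scale
reconstructions, whose absolute flux values are not reproducible here.

## Problem sizes used in the shipped analyses

Replicate community runs use 5 seeds × 50 cycles at each lysis rate; the
mirror-state analysis averages 8 replicate 230-cycle schedules (60 basal
cycles, a 20-cycle 20%-lysis excursion, 150 cycles of relaxation) because
the ~30-cell bacterial population carries demographic noise that only
replicate averaging removes; the removal-rate estimate pools 1000
growth-free cycles; solver validation sweeps 1000 random toy networks.
These sizes give Monte-Carlo errors well inside the tolerances quoted with
each result.

## Known limitations

* Lumped stoichiometry: absolute flux values are not comparable with
  genome-scale reconstructions; ratios, orderings, gates (auxotrophy,
  ammonium threshold) and population structure are the meaningful outputs.
* Growth kinetics are availability-capped FBA, not Michaelis–Menten;
  mortality is background removal, lysis, and starvation below half the
  unit mass — there is no explicit virion population; lysis is a scheduled
  rate, not an infection model.
* The timescale is compressed: growth-rate caps were chosen so population
  turnover happens over tens of cycles; per-cycle rates should be read in
  protocol units, not as in-situ physiological rates.
* The archaeal B12 salvage transporter is a mechanistic inference (cobalamin
  salvage is widespread in ammonia-oxidizing archaea) whose capacity is a
  calibrated parameter, not a measured one.
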