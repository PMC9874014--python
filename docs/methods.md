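# Methods

## Scope and shape

`enerflow` implements a supply-and-demand model of whole-cell
energetics. The supply side predicts a cell's maximum capacity to
generate ATP by abundance-constrained flux balance analysis (FBA); the
demand side distributes that capacity across ATP/GTP-consuming protein
classes. Between the two sits a rule-based imputation step that
completes the label-free proteome the constraints are built from. The
package is organised as a library of composable stages
(`completerot`, `gpr`, `fba`, `demand`, `annotation`, `measurements`)
plus a `pipeline` module and a thin CLI; a `synthetic` module generates
every input at desk scale.

## Supply model

FBA solves `max v_obj` subject to `S·v = 0` and `lb ≤ v ≤ ub` with a
generic ATP-hydrolysis sink as objective. The LP is solved with HiGHS
(via `scipy.optimize.linprog`) at primal/dual feasibility 1e-9.
Infeasibility is taken from solver status, never from residual
heuristics, because the blank regions of the parameter sweep are defined
by status. Only the objective value of an FBA optimum is unique;
reported flux vectors may have alternate optima and the exchange report
warns accordingly.

**Internal bounds.** Each enzymatic reaction's effective abundance is
the minsum evaluation of its gene–reaction rule (min over AND, sum over
OR); genes absent from the abundance map contribute 0, so a complex
missing a subunit is blocked — consistent with working on the imputed
proteome, where a genuine zero means "not detected in any tissue". The
effective abundance maps to a bound through

    s(a) = a(1+k) / (a + k·a_max),  upper = b_max·s(a),

with `a_max` the largest effective abundance, so the most abundant
reaction is pinned at `b_max` for every `k`. As `k → ∞` this approaches
the linear map `a/a_max`; as `k → 0` every expressed enzyme saturates
to 1. The transform is this package's explicit parameterisation of a
"Michaelis–Menten-like" compression; other codebases may parameterise
the same idea differently, so the conventional value k = 0.016 should be
treated as a coordinate on a calibration axis, not a transferable
constant. Reversible reactions get symmetric bounds (−upper, +upper);
irreversible ones keep a zero lower bound. Gene-free reactions keep
model defaults.

**Exchange bounds.** In DMEM mode the uptake bound of metabolite *m* is
`−r·b_max·(mM_m / mM_glucose)`, glucose at 25 mM by convention;
metabolites absent from the medium get uptake 0 (efflux stays open).
Gases and other species whose availability a medium recipe does not set
(`o2_e`, `h2o_e`, `co2_e` by default) are left at model defaults via
`ExchangeSpec.free_exchanges`. In measured mode, measured fluxes are
first rescaled so the condition's glucose uptake equals −25 model units
and then mapped through the same `r·b_max/25` unit as DMEM glucose;
signs are preserved, so measured secretion constrains efflux. A measured
secretion is treated as a *floor* (lower bound) by default — the cell
must export at least what was measured — with `ceiling` and `equality`
variants exposed, since a measured efflux under-determines the bound
type.

**Sweep, ratio, calibration.** The `(k, r)` grid is sampled
logarithmically (defaults span 0.001–1 in k and 0.0125–1.6 in r,
including the conventional 0.016 and 0.05); each cell rebuilds bounds
and re-solves. The dimensionless ATP-per-glucose ratio uses the
*realised* glucose flux at optimum (not the bound); when the optimum
takes no glucose the ratio is undefined and reported as NaN. A switch for
bound-based ratios was considered and rejected: the realised flux is the
quantity that cancels units when multiplied by a measured uptake.
Multiplying ratio by measured glucose uptake (pmol·ng⁻¹·day⁻¹) converts
the whole grid to measured units; calibration selects the cell
minimising |capacity − measured ATP|, breaking ties toward smaller r
then smaller k (prefer the most constrained parameterisation).

## Imputation (ComPleteROT-style rules)

Missing values are filled per sample (column-wise), preserving replicate
independence — pooling replicates before computing class statistics is
the main alternative and is deliberately not done, since downstream
statistics expect independent replicates. The statistic is chosen by
tissue-expression category: class **average** for "Detected in all",
class **minimum** for "Detected in many/some/single" and "#N/A", and
**zero** for "Not detected". Minima are taken over detected, non-zero
values. If the level-1 functional class has no detected member in that
sample the cascade falls back to level 2, then to the whole table
(level 3) — nearest class first, as the most informative choice — and
finally to a flagged global 0. Observed values are never altered and the
operation is idempotent.

## Demand model

Consumers are the proteins annotated with cofactor ATP or GTP. An
optional complex-definition file aggregates members by the same min/sum
rules as the supply side; proteins without a definition act as monomers
(no demand-side complex catalogue is assumed). Corrected abundance uses
the same compression `k` as the calibrated supply side, normalised to
the most abundant consumer. Weights are corrected abundance × kcat,
with missing kcats imputed as the arithmetic mean of known kcats within
the same cofactor pool. Shares are weights normalised to 1; a class's
flux is `total_capacity × Σ shares`. ATP and GTP consumers share one
capacity pool by default (`cofactor_filter` splits them). The budget's
"% of total expression" denominator defaults to the consumer total and
accepts an all-protein total via `total_expression`.

The protein-synthesis estimate takes the amino-acid-tRNA-ligase class's
ATP flux F (pmol·ng⁻¹·day⁻¹): amino-acid flux F/2 (2 ATP per activated
residue), total rate F/2 × 110/1000 per day (110 Da per average residue,
pg→ng), net rate total − turnover with turnover defaulting to 0.5/day.
Note this stoichiometry is reported as-is: applied to a reference
wild-type ligase flux of 12.51 pmol·ng⁻¹·day⁻¹ it gives a net rate of
0.188/day, which does not reduce to the independently reported 0.135/day;
the residual is surfaced by the acceptance script rather than absorbed
into a correction factor, because the missing term (e.g. GTP costs of
elongation or a different capacity column) is not identifiable from the
published numbers.

## Measurements

Daily fluxes follow the replicate convention "value at day d minus the
replicate-average value at day d−1, per day", with a symmetric variant
behind a flag; per-cell and per-ng-protein normalisations divide by the
mean cell concentration and protein-per-cell over the same day pair.
Consumption is negative everywhere; magnitudes appear only at the
exchange-bound interface. The value compared against the supply model is
the mean of the day-1→2 and day-2→3 rates (the 24–72 h window). Net
protein synthesis is (p72 − p24)/2 days. Experiment-level normalisation
rescales each experiment to the grand mean.

## Ranking

Condition ranks per group are dense ranks of abundance sums with ties
shared as averaged positions. Where the original analysis uses post-hoc
significance to declare ties, this package substitutes a pluggable
policy: a relative-difference threshold (default 5%) or an externally
supplied boolean significance matrix. This keeps inferential statistics
out of the core while preserving the rank semantics. The 43→19
localization merge ships as an editable TSV fixture, not code.

## Synthetic data

The toy network lumps central carbon metabolism: glycolysis
(glucose → 2 pyruvate + 2 ATP), fermentation (pyruvate → lactate +
H⁺, both exported), pyruvate oxidation (pyruvate + 3 O₂ → 15 ATP, so
32 ATP per fully oxidised glucose), an optional glutamine branch
(glutamine + 3 O₂ → 20 ATP — a round number chosen so glutamine beats
pyruvate per O₂ and oxygen allocation is non-trivial), an optional GTP
branch, and an ATP-demand sink. The maximum ATP flux has a closed form
(greedy oxygen allocation) recorded with the model and verified against
the LP across random bounds. Shifting the oxygen/glucose bounds moves
the optimum between fermentative and oxidative regimes, giving the
sweep heatmap genuine structure at desk scale.

The synthetic proteome draws per-class log-normal abundances (class
means spanning ~1e4–1e7 intensity units, within-class log-sd 0.8 ≈
0.35 dex, typical LFQ dispersion) for 20 classes × 50 proteins × 3
replicate samples by default. Tissue-expression categories are assigned
with HPA-like frequencies (55% "Detected in all" down to 2% "Not
detected"); masking probabilities are stratified by category (10% for
ubiquitous up to 100% for "Not detected", whose true abundance is 0)
and average ≈20% missingness overall. One seed fixes everything
bit-for-bit. What this generator does *not* emulate: intensity-dependent
(MNAR) missingness within a category, batch effects, correlated
replicates, shared peptides. Passing recovery tests therefore show the
rules behave as specified under the stated class-structure assumption,
not that imputation is unbiased on real LFQ data.

The `toy_bundle` helper assembles a coherent input set: the toy model,
a proteome covering its metabolic genes (always observed, so supply
bounds are exact) plus class-structured ATP/GTP consumers including an
amino-acid-tRNA-ligase class, kcats for ~40% of consumers, a DMEM-like
medium (glucose 25 mM, glutamine 4 mM), measured fluxes (glucose −15,
glutamine −2, lactate +25 pmol·ng⁻¹·day⁻¹) and a measured total ATP
production rate of 187 pmol·ng⁻¹·day⁻¹, all in the range reported for
fibroblast-like cells.

## Numerical choices and limitations

- LP tolerances 1e-9; mass-balance residual asserted ≤ 1e-6·b_max.
- Calibration ties break toward smaller r, then smaller k.
- The imputation recovery tolerance (class means within 25% of truth at
  1000 proteins / ~20% masking) was measured on the generator before
  being fixed; the observed maximum relative error is ~0.19–0.25 across
  seeds.
- Problem sizes in tests and the acceptance script (toy network of ~15
  reactions, 1000-protein proteomes, 6×8 sweep grids) are chosen so the
  whole suite runs in seconds while every code path — including the
  measured-mode normalisation and the kcat-weighted demand side — is
  exercised.
- One pipeline run handles one condition; replicate columns are averaged
  after imputation. Multi-condition studies run the pipeline per
  condition and compare outputs (e.g. with `rank_groups`).
- Not implemented, deliberately: flux variability analysis, parsimonious
  FBA, biomass objectives, thermodynamic or enzyme-capacity refinements,
  model-based (MNAR/MAR likelihood) imputation, and substrate-
  availability corrections on the demand side.
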