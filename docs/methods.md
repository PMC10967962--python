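# Methods

This note documents the models and procedures implemented in `tigsmm`,
the parameters that matter, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Constraint-based model and FBA

A metabolic model is the tuple (metabolites, reactions, compartments,
biomass id).  Reactions carry signed stoichiometry (negative =
consumed), bounds lb_i ≤ v_i ≤ ub_i in mmol gDW⁻¹ h⁻¹, an optional GPR
boolean tree (AND = enzyme complex, OR = isozymes) and a kind tag
(enzymatic, spontaneous, transport, exchange, biomass).  Exchange
reactions are written "metabolite ↔ ∅" so uptake is negative flux; all
user-facing uptake rates are magnitudes.  Bounds missing from a file
default to (−1000, 1000) for reversible and (0, 1000) for irreversible
reactions — the conventional finite proxy for "unconstrained".

FBA maximizes the biomass flux over {v : S·v = 0, lb ≤ v ≤ ub} with
scipy's HiGHS solver.  Optimal solutions are checked against
‖S·v‖∞ ≤ 1e-6 before being returned; infeasibility and unboundedness
are reported as statuses, never as silent zeros.  Medium setup
(`apply_uptake`) closes every exchange to secretion-only, reopens a
configurable nutrient list to uptake −1000 (ammonium, phosphate,
sulfate, water, protons in a typical fungal minimal medium), and sets
the carbon exchange lower bound to −rate.

Degenerate optima are expected in flux analysis: the package asserts
objective values and feasibility invariants, never full flux vectors.

### Brute-force LP oracle

`enumerate_vertices_oracle` recomputes the LP optimum for models of at
most 12 reactions by enumerating basic feasible solutions: every vertex
of the polytope has ≥ n − rank(S) coordinates at a bound, so the oracle
fixes each such subset at every bound combination (batched as one
least-squares solve with 2^k right-hand sides) and keeps the best
feasible point.  Infinite bounds are clamped to ±1e7; an optimum that
rests on a clamped coordinate — and strictly beats every vertex that
does not — is declared unbounded.  The oracle shares no code with the
HiGHS path and is the independent check used throughout the test suite.

## Expression integration (GIMME)

Expression x_i is lifted from genes onto reactions by one of two rules:

* `max_over_genes` (default): the maximum FPKM over the reaction's
  genes — a reaction is considered activatable by any one expressed
  gene;
* `gpr_aware`: AND → min, OR → max over the GPR tree, reflecting that a
  complex needs all subunits.

Reactions without a GPR, or whose genes are all absent from the table,
are *unscored* and carry zero penalty — missing evidence is not treated
as silence, because zeroing would inject penalties without data.

The threshold x_threshold is a percentile (default 50) of the FPKM
values of the model's metabolic genes, computed per condition with
linear interpolation between order statistics.  The percentile
population is restricted to metabolic genes by default because the
integrated model contains only those; an all-genes option exists for
sensitivity analysis.

Penalties follow c_i = max(0, x_threshold − x_i).  Phase 1 computes the
FBA maximum μ*; phase 2 raises the biomass lower bound to f·μ* and
minimizes Σ c_i·|v_i|.  The absolute value is handled exactly by
splitting reversible fluxes into non-negative forward/backward parts
(objective c_i(v⁺+v⁻)); this is valid because all c_i ≥ 0, so no
optimum keeps both parts positive for a penalized reaction.  Fluxes
with a fixed sign need no split (|v| = ±v).  The strict inequalities of
the textbook formulation are implemented as non-strict bounds, as is
universal in LP practice.

The growth fraction f is deliberately exposed: fixing growth at the
unconstrained FBA maximum (f = 1.0) is one reading of "use the maximum
as the boundary"; the original GIMME formulation uses a fraction.  The
default is f = 0.90, and a replication profile that pins growth at the
maximum simply sets f = 1.0.  A matching brute-force oracle
(`enumerate_gimme_oracle`) solves phase 2 for tiny models by
enumerating the sign orthants of penalized reversible fluxes (the
objective is linear within each orthant) and running vertex enumeration
in each.

Active/inactive calls use a zero tolerance of 1e-6 on |v_i|,
separating LP round-off from biological activity; this tolerance is a
config knob because alternate optima can shift borderline reactions.

## Activity comparison and pathway classification

Venn partitions of active sets are exact set algebra; sizes are checked
to be conserved (|A-only| + |B-only| + |core| = |A∪B|).  Pathway
breakdowns read the subsystem labels deposited in the model — no
database calls at run time.  Reactions carrying several `;`-separated
labels count once under the first label by default (`multi_count`
enables one count per label).

## Reporter metabolites

Gene-level inputs are two-sided p-values with a direction of change —
an interface, not something this package computes, so any upstream
differential-expression method can feed it.  For a direction of
interest d ∈ {up, down}:

    p_dir = p/2 if the gene moved in d, else 1 − p/2
    Z_g = Φ⁻¹(1 − p_dir),  clamped to p_dir ∈ [1e-300, 1 − 1e-16]

A metabolite's neighborhood is the union of GPR genes over all
reactions with nonzero stoichiometry for it; k is the size of its
intersection with the scored genes.  Z_raw = Σ Z_g/√k is standardized
against the background of random size-k subsets of the scored genes:
exhaustive enumeration when C(n, k) ≤ 1e5, otherwise Monte-Carlo
sampling (default 10 000 sets) from one seeded generator, with a σ
floor of 1e-12 to keep constant universes finite (they score
Z_corrected = 0).  Significance is the plain uncorrected p < α
(default 0.05) per direction, and no currency-metabolite exclusion is
applied by default — both choices match common practice for this
statistic, and the exclusion list is a parameter.  Sampling without
replacement is implemented by drawing with replacement and resampling
rows with duplicates, which is exact and fast for k ≪ n.

Under the null (uniform p, random directions) the corrected score is
approximately standard normal, so the significant fraction at α = 0.05
sits near 0.05; the test suite verifies 0.05 ± 0.02 over 200 simulated
datasets and that a planted coherent neighborhood (three genes at
p ≈ 0.001) ranks first in ≥ 95 % of seeds.

## Synthetic data

The generators produce all pipeline inputs at desk scale:

* **Models**: a backbone — carbon exchange (uptake capacity 10) →
  transport → linear chain → biomass — guarantees growth > 0 by
  construction (no rejection sampling), decorated with parallel
  duplicate reactions carrying fresh GPRs; ~30 % of chain steps are
  reversible.  Gene ids use `CCMX_%04d`, a format chosen to never
  collide with real locus tags.
* **FPKM**: log-normal with μ = 2, σ = 1.2 on the log scale — a
  long-tailed distribution with most mass between 1 and 100 FPKM,
  the shape of typical fungal RNA-seq libraries; two conditions with
  independent noise.  Genes of planted "low" reactions are drawn
  uniformly from [0, 0.5), far below the distribution's lower quartile
  (≈ 3.3), so planted reactions reliably fall under a median threshold.
* **Gene statistics**: null genes get p ~ Uniform(0, 1] with random
  direction; genes of planted hot metabolites get p ~ Beta(0.11, 1)
  (median ≈ 0.002) and a shared "up" direction.

Everything is deterministic per seed.  What the generators do *not*
emulate: genome-scale network topology (loops, cofactor coupling,
compartment shuttles), mass/charge balance, correlated expression
between genes, and library-size effects in FPKM.  Passing tests
therefore demonstrate the correctness of the algorithms and their
implementations, not the biological fidelity of any particular
genome-scale reconstruction.

## Problem sizes and numerical choices

The validation suite runs 200 random networks of 5–8 metabolites and
6–12 reactions against the LP oracles (the oracle's cost grows
combinatorially, which is why it is capped at 12 reactions), 200
reporter null datasets of 500 genes × 50 metabolites, and 100 planted
recovery seeds.  LP feasibility is checked at 1e-6; oracle/solver
agreement at 1e-6; bound violations tolerated to 1e-9.  Percentile
interpolation is linear; ties in alternate LP optima are resolved by
the solver's vertex choice, which is deterministic for a fixed input
but not guaranteed across solver versions — borderline active counts
can shift between environments, which is why counts are asserted only
on fixtures with unique optima.

## Known limitations

* Only SBML L3+FBC v2 and the documented TSV dialect are read; `.mat`
  and spreadsheet model files are out of scope.
* No FVA, parsimonious FBA, iMAT/INIT-style integration, or knockout
  screening; GIMME is the single integration method.
* Reporter scoring uses gene sets as the sampling unit; reaction-set
  sampling is a variant not implemented.
* The pipeline assumes one biomass reaction and one limiting carbon
  exchange per condition.
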