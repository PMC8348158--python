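# Methods

## Scope and model

gemflux implements constraint-based analysis of a genome-scale
metabolic network under steady state: flux vectors v satisfy S·v = 0
and lb ≤ v ≤ ub, where S is the stoichiometric matrix. Everything else
in the package is machinery for (i) shrinking the network to the
reactions a given transcriptome supports, (ii) translating expression
and respirometry into bounds, and (iii) characterizing and comparing
the resulting flux spaces.

## Expression discretization

Counts are TPM-normalized (rate = count / kilobases, scaled to 10⁶ per
sample). Discretization assumes the log₂(TPM+1) distribution of
detected genes is a two-component Gaussian mixture — a low
(unexpressed/background) and a high (expressed) curve. Zero-TPM genes
are excluded from the fit and labelled unexpressed outright, because
the RNA-seq zero mass is not Gaussian and would drag the low component.

The EM fit uses four deterministic quantile-pair initializations
(10/90, 25/75, 2/60, 5/50 percentiles). On zero-inflated data EM has a
recurring pathological optimum — one broad component spanning both
curves plus one narrow spike — so among the candidate fits we prefer
the best-likelihood fit whose components actually separate
(μ_high − σ_high ≥ μ_low + σ_low), falling back to raw likelihood and,
if every fit degenerates (vanishing σ, weight < 10⁻³, or constant
input), to quantile thresholds. The fit is deterministic given a seed.

Thresholds sit `z_margin` (default 1.0) standard deviations inside
each component: expressed above μ_high − z·σ_high, unexpressed below
μ_low + z·σ_low, unknown in between. If the thresholds cross, the
midpoint of the component means splits the two certain categories and
nothing is unknown. Raising a gene's TPM can never demote its label.
One mixture is fitted per sample; a pooled fit across samples is
available (`pooled_fit`) for designs where per-sample depth is low.

## GPR rules and reaction classification

GPR rules parse with `and` binding tighter than `or`; nested
same-operator nodes are flattened, so serialization round-trips to a
structurally identical AST. Discrete evaluation maps and→min, or→max
over {+1, 0, −1}: a complex is as expressed as its weakest subunit,
one isozyme suffices. Rule value +1/0/−1 makes the reaction
core/noncore/inactive; reactions without a rule are noncore — absence
of evidence must not close transport or spontaneous reactions.
Continuous evaluation (for E-Flux) maps and→min and or→sum by default,
since isozymes add catalytic capacity; or→max is available.

## Consistency pruning and extraction

A reaction is flux-consistent if some steady-state solution gives it
|v| ≥ ε (default 10⁻⁴, against default bound magnitude 1000 — far above
double-precision noise, far below any meaningful flux).
`fastcc_consistent` certifies reactions in batches with the support LP
(maximize Σ z_i, z_i ≤ v_i, 0 ≤ z_i ≤ ε), repeats with flipped sign for
reversible reactions, and settles stragglers with targeted per-reaction
max/min LPs, so its output provably equals the per-reaction
flux-variability definition while using far fewer LPs.

`fastcore_extract` builds a minimal consistent subnetwork containing a
core set by alternating the support LP (which core reactions can reach
ε together) with a sparsity LP (minimize Σ|v| over noncore reactions
while supported core reactions are pinned on). The pin is scaled to
10⁴·ε — with plain ε-pins, an L1-minimal mode's upstream reactions can
sit below the support threshold purely through stoichiometric ratios,
producing inconsistent extracts; the scale backs off geometrically if
bounds make it infeasible. Reversible core reactions unsupported
forward are retried with flipped sign. Two refinements sharpen the L1
cardinality surrogate: an iteratively re-weighted L1 polish
(w ← 1/(|v|+ε), three rounds, plus single-flip sign variants for
reversible core reactions) and a greedy redundancy elimination that
drops added reactions, in fixed id order, whenever the subnetwork stays
consistent (a cheap structural producer/consumer check filters most
candidates before any LP). On exhaustively enumerable instances
(≤12 reactions) the result matches the true minimum; at scale it
remains a heuristic, like the underlying algorithm family. Extraction
is deterministic given the solver and configuration.

Core reactions that pruning reveals to be blocked are demoted with a
log message rather than failing the build: an expressed enzyme can be
legitimately stranded by unexpressed neighbours.

## Metabolic tasks

A task asks whether the network can produce stated outputs from stated
inputs with every exchange closed. Inputs re-open the metabolite's own
exchange — capped by the model's uptake capacity, so a
respirometry-capped oxygen exchange stays capped during task checks —
and internal metabolites (e.g. NADH for a reoxidation task) get
temporary injection columns. Outputs become demands at the stated
minima; a 0 minimum marks a permitted byproduct secretion (CO₂, water,
ammonium, lactate), which must be listed explicitly because everything
else is closed. Tasks naming metabolites absent from the model report
infeasible with reason "unsupported". The packaged brain-energetics
task list covers aerobic/anaerobic ATP from glucose, ATP from a
palmitate-like fatty acid and from glutamate, lactate secretion, NADH
reoxidation in both compartments, complete glucose oxidation, and
phosphocreatine buffering.

## E-Flux and respirometry constraints

Each scored reaction's upper bound becomes
`min(ub, v_max · score / max score)` with the per-model maximum score
as denominator; reversible reactions get the mirrored lower bound, a
zero score closes the reaction, unscored reactions are untouched. The
mapping is invariant to rescaling all scores and monotone in any single
score. Capping at the original bound magnitude keeps overrides
tightenings only.

Respirometry caps oxygen uptake at `scale × measured flux`
(pmol O₂ s⁻¹ mg⁻¹). No principled unit bridge exists between
respirometry and model flux units, so `scale` is a single configurable
factor; by default the pipeline auto-calibrates it so the control
group's cap sits 5% above the control optimum's oxygen uptake —
non-binding for controls, proportionally binding for groups with lower
measured respiration. The OxPhos titration state is used by default
(configurable).

The analysis pipeline opens all exchange bounds to ±1000 before
applying E-Flux (`open_exchanges`, default on): with E-Flux the
expression-derived caps, not arbitrary medium limits, should be the
binding constraints, otherwise group differences in expression cannot
reach the flux solution.

## Flux simulation

* **FBA** maximizes c·v; infeasibility/unboundedness is reported in the
  solution status.
* **pFBA** fixes c·v ≥ fraction·optimum (default 1.0) and minimizes
  Σ|v| via auxiliary t ≥ |v| variables. Reported fluxes are therefore
  canonical at degenerate optima; plain FBA fluxes are
  solver-dependent and documented as such.
* **FVA** reports per-reaction min/max at a stated fraction of the
  optimum.
* **Sampling** runs hit-and-run in null-space coordinates: v = v₀ + Nα
  with N an orthonormal null-space basis of S, so S·v = 0 holds along
  the whole chain; the segment inside the box bounds is computed per
  step and the step is uniform on it. The chain warm-starts from the
  mean of FVA extreme-point solutions, thins by 100 by default, and
  re-projects onto the affine space periodically to cancel drift. An
  ACHR-style variant (directions through the running sample center) is
  available. Ensembles are reproducible given a seed, and a verifier
  asserts S·v = 0 within 10⁻⁶ and bounds within 10⁻⁹ for every sample.

Numerical conventions: solver feasibility/optimality at HiGHS defaults
(≈10⁻⁹/10⁻⁷), equality comparisons at 10⁻⁶.

## Profiles and group comparison

A flux distribution is summarized per subsystem as Σ|v|, L1-normalized
to 1 — comparable across models of different sizes and invariant to
uniform flux scaling (dividing by objective flux instead is available
via configuration). Profiles are compared by cosine similarity,
clustered agglomeratively on cosine distance (average linkage by
default), and embedded in 2-D by PCA or UMAP (UMAP falls back to PCA
with a warning when unavailable). Sampled group ensembles are compared
per reaction by group medians, median difference against the reference
group, a histogram overlap coefficient, and the rank-sum statistic —
descriptive only; no significance claims are attached, because flux
samples are not independent observations of a population. Z-scoring
per subsystem appears only in heatmap displays, never in analysis.

## Synthetic data: what it emulates and what it does not

`make_toy_model` is a hand-designed (not sampled) brain-energetics
network: glycolysis (lumped upper/lower), TCA cycle, OXPHOS with
separate complex I, complex II, a glycerol-3-phosphate shuttle and ATP
synthase over an explicit quinone pool and pumped-proton species
(4 H⁺ per NADH at complex I, 6 per quinol at complex III+IV, 4 per ATP),
β-oxidation of a palmitate-like C16 fatty acid, glutamate anaplerosis,
a phosphocreatine buffer, and the transport/exchange scaffolding, with
GPR rules over 61 synthetic genes named after the corresponding mouse
enzymes. The proton stoichiometry makes ATP yields auditable integers:
32 per glucose aerobically (malate–aspartate shuttle), 2 anaerobically,
106 per fatty acid, 10 per glutamate, 6 O₂ per glucose. The
malate–aspartate shuttle is reversible, so closing complex I leaves
aerobic ATP production feasible through complex II and the
glycerol-3-phosphate shuttle at reduced yield (22 per glucose) — the
substrate of the compensation analysis. The amino-acid and creatine
subsystems exist precisely because normalized subsystem shares cancel
under uniform scaling: an energy route whose genes the disease does not
touch is what lets the disease group's glycolysis/OXPHOS *share* (not
just absolute flux) fall. The ATP-demand ceiling (10⁵) sits above any
attainable supply so expression caps, never the demand bound, limit
the optimum.

`simulate_expression` draws per-gene baseline log₂ abundances once per
cohort — right-skewed (floor 3 + Exp(1)) for expressed genes,
left-skewed (ceiling −6 − Exp(1)) for silent ones — multiplies genes
in the down-regulated subsystems by `disease_fold` (0.25) in the
disease group and `treated_fold` (0.6) in the treated group, and draws
negative-binomial counts (dispersion 0.005, library sizes 0.7–1×10⁶)
for 3 mice per group. 300 expressed and 200 silent background genes
pad the transcriptome so the mixture fit sees a realistically sized
bimodal distribution. The skew directions and the deep silent floor
are chosen so both populations fall inside the μ ± z·σ thresholds of
the fitted curves — a symmetric Gaussian population can never exceed
Φ(1) ≈ 84% recovery at z = 1 — and most silent genes draw zero counts,
consistent with treating zeros as unexpressed. The low dispersion and
deep-ish libraries reflect isogenic littermates and, more importantly,
desk scale: a real ~1600-reaction model averages per-gene noise over
many reactions per subsystem, while the toy's subsystems hold 1–5
reactions each, so matching the study-scale per-subsystem
signal-to-noise requires the low-variability end of the realistic
regime. What the generator does **not** emulate: isoform structure,
batch effects, library-preparation biases, gene-length bias beyond the
TPM model, correlated co-regulation beyond the planted subsystem folds,
and any treatment mechanism — the treated group is an expression-level
phenocopy. Passing recovery tests therefore demonstrates that the
pipeline recovers planted directional signals under idealized noise,
not that it is robust to real-data artifacts.

`simulate_respirometry` produces per-group oxygen fluxes
(base 100 pmol s⁻¹ mg⁻¹ × group factor: control 1, disease =
disease_fold, treated = treated_fold) with Gaussian noise (σ = 4),
for all six titration states as fixed multiples of the OxPhos state.

## Known limitations

* Extraction minimality is heuristic beyond exhaustively checkable
  sizes; no MILP formulation is provided.
* Loopless FBA and thermodynamic constraints are out of scope; pFBA's
  Σ|v| minimization suppresses but does not forbid futile cycles at
  sub-optimal objective fractions.
* The hit-and-run sampler uses a dense null-space basis; it is meant
  for models up to a few hundred reactions, not full genome scale.
* The respirometry→flux unit bridge is a calibration choice, not a
  measurement; only relative group differences are meaningful.
* SBML support targets Level 3 + FBC v2 (the profile BiGG exports);
  older dialects are rejected with a clear message, and subsystem
  annotations ride in reaction notes.
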