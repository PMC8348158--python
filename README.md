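# gemflux

Context-specific genome-scale metabolic modelling from RNA-seq, built
for studies that ask how a disease state and a treatment reshape tissue
metabolism — e.g. comparing cerebellar energy metabolism between
control, disease-model, and treated animal groups.

Starting from raw gene counts and a stoichiometric network, gemflux

1. normalizes counts to TPM and decomposes each sample's log₂(TPM+1)
   distribution into two Gaussian "expression curves", labelling every
   gene **expressed / unknown / unexpressed**;
2. maps gene labels to reactions through gene–protein–reaction (GPR)
   rules (`and` → min over complex subunits, `or` → max over isozymes),
   partitioning reactions into **core / noncore / inactive** sets;
3. removes inactive reactions, prunes everything that cannot carry
   flux ε in any steady state (FASTCC-style consistency testing), and
   extracts a minimal flux-consistent subnetwork containing every core
   reaction (FASTCORE-style support/sparsity LPs with an iteratively
   re-weighted L1 polish);
4. re-applies expression continuously as **E-Flux** bound caps
   (`ub' = v_max · score / max score`) and caps oxygen uptake with
   measured high-resolution respirometry;
5. simulates and compares the resulting models: FBA, parsimonious FBA
   (min Σ|v| at the optimum), flux variability analysis, hit-and-run
   flux sampling, subsystem flux profiles, cosine similarity,
   hierarchical clustering, 2-D embedding, and descriptive per-reaction
   group comparisons.

All linear programs solve `max c·v  s.t.  S·v = 0, lb ≤ v ≤ ub` and
variants thereof through scipy's HiGHS interface. Models read and write
BiGG-style JSON and SBML Level 3 + FBC v2.

A first-class synthetic-data module generates the entire study offline:
a hand-designed ~48-reaction brain-energetics network with auditable
integer ATP yields, three-group negative-binomial RNA-seq counts with
disease down-regulation planted in OXPHOS/glycolysis/β-oxidation, and
matching respirometry — so every pipeline stage is testable against
known ground truth.

## Worked example

```python
import gemflux as gf
from gemflux.pipeline import RunConfig, build_sample_models, analyze_models

model = gf.make_toy_model()
cohort = gf.SyntheticCohortConfig(seed=1)
expr, truth = gf.simulate_expression(model, cohort)
resp = gf.simulate_respirometry(cohort)

config = RunConfig(seed=1, n_samples=200, thinning=25)
models, stats = build_sample_models(model, expr, config, resp)
results = analyze_models(models, config)

for group in ("control", "treated", "disease"):
    p = next(pr for pr in results["profiles"] if pr.label == group).values
    print(f"{group:8s} oxphos+glycolysis share = {p.get('oxphos',0)+p.get('glycolysis',0):.3f}")
comp = results["comparison"]
row = comp[comp.reaction_id == "ATPS"].iloc[0]
print("ATP synthase sampled medians:",
      {g: round(float(row[f"median_{g}"]), 1) for g in ("control", "treated", "disease")})
```

prints (seed 1):

```
control  oxphos+glycolysis share = 0.236
treated  oxphos+glycolysis share = 0.192
disease  oxphos+glycolysis share = 0.103
ATP synthase sampled medians: {'control': 24.5, 'treated': 16.2, 'disease': 8.4}
```

— the disease group's pFBA flux share in energy subsystems drops to
less than half the control share and its sampled ATP-synthase flux
falls accordingly, while the treated group sits between the two: the
planted expression pattern (disease fold 0.25, treated fold 0.6 on
OXPHOS/glycolysis/β-oxidation genes) propagates through
discretization, extraction, E-Flux and respirometry caps into the
simulated flux states. On the unmodified toy network, `gf.fba`
reproduces the designed yields: 32 ATP per glucose aerobically, 2
anaerobically, 106 per palmitate-like fatty acid, 10 per glutamate.

The same workflow is scriptable from the shell:

```bash
gemflux simulate --out data --seed 1
gemflux analyze --model data/model.json --counts data/counts.tsv \
    --lengths data/lengths.tsv --respirometry data/respirometry.tsv \
    --out results --seed 1
gemflux tasks --model data/model.json --tasks data/tasks.yaml
```

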