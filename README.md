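# traingp

Training-population design analysis for genomic prediction in multi-parent
wheat-style breeding populations.

The package simulates a breeding program end to end — founder genomes,
bi-/tri-parental crosses with a prescribed parent-sharing structure, F2:4
lines genotyped as family bulks, multi-environment yield trials with
AR1×AR1 spatial noise — and then runs the full prediction pipeline on it:

1. **simdata** — crossing-design solver, meiosis/selfing simulator (Haldane
   model, single-seed descent, F4 bulks), additive QTL traits, unbalanced
   trial allocation, plot-level yield simulation.
2. **spatial** — per-trial REML fit of a separable AR1×AR1 spatial model
   (with nugget and an optional iid genotype effect); spatially adjusted
   plot values and per-trial summary tables.
3. **phenoblue** — across-trial line BLUEs from the adjusted plots
   (trial means + sum-to-zero line effects, exact normal-equations solve).
4. **kinship** — VanRaden (method 1) genomic relationship matrix, diagonal
   stabilization, segregating-marker filtering.
5. **gblup** — AI-REML variance components with EM fallback and
   normalized-component convergence, GBLUP prediction of unphenotyped lines
   (mixed-model equations ≡ conditional-mean formula), line heritability
   σ²g/(σ²g + v/n).
6. **evalcv** — every resampling design: tenfold by crosses, tenfold by
   lines, leave-one-cross-out, training-fraction masking,
   crosses-by-lines grids, relatedness-stratified sets with partial
   validation-cross inclusion; Pearson accuracies per cross and pooled,
   Wald and paired-t significance tests, top-k accuracy.
7. **cli** — one-config orchestration with seeds, logging and a JSON
   manifest.

## Command line

```bash
# full pipeline: simulate -> adjust -> BLUEs -> GRM -> GBLUP -> CV
traingp run --config config.yaml --out results/run1

# population + trial data only
traingp simulate --config config.yaml --seed 1 --out results/sim1

# individual cross-validation schemes
traingp cv loco --seed 1 --reps 2 --out results/loco
traingp cv tenfold --seed 1 --reps 2 --out results/tenfold
```

The config is YAML mirroring `traingp.cli.RunConfig`; `preset:
reference_defaults` selects the reference population structure (27 parents,
39 bi- + 5 tri-parental crosses, 68 lines per cross, 4 trials). All
randomness flows from a single `seed`, and reruns are byte-identical.

Every stage writes plain CSV (genotypes, map, plots, adjusted values,
BLUEs, GRM as dense CSV and id-id-value triplets, variance components, CV
results) plus `manifest.json` with per-stage seeds, wall times and SHA-256
checksums.

## Library sketch

```python
from traingp import simdata, kinship, gblup, phenoblue, evalcv

design = simdata.design_crosses(27, seed=1)          # 44 crosses, 2992 lines
gmap = simdata.GeneticMap.uniform(10, 200, 150.0)
pop = simdata.generate_population(design, gmap, seed=1)

grm = kinship.stabilize(kinship.compute_grm(kinship.filter_segregating(pop)[0]))
# ... BLUEs from trial data, then:
for d in evalcv.leave_one_cross_out(design):
    vc = gblup.fit_aireml(blues.loc[list(d.training)], grm)
    preds = gblup.predict_lines(vc, blues.loc[list(d.training)], grm)
```
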