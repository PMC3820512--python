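# tcflow

Temporally-constrained minimum-cost flow inference of active gene
sub-networks from time-course expression data.

## The problem

A stimulated cell (the motivating setting is dendritic cells responding to
a TLR ligand such as LPS) changes its transcriptome in waves: an initial
burst of immediate-response genes, a middle phase of intermediate
regulators, and a late phase of effectors. Differential-expression lists
capture each wave separately but say nothing about how the waves are
wired together — and they miss the regulators whose activity changes
without a detectable change in transcript level. `tcflow` connects the
waves through a large scored molecular interaction network (protein–
protein, TF–target, post-translational, functional and inhibitory arcs)
and extracts the most reliable routes from the early genes to the late
genes that pass through the intermediate ones, surfacing both the staged
genes and the silent connectors between them.

It is a library first (everything below is importable from `tcflow`), with
short narrative scripts in `examples/` and a thin `tcflow` CLI for shell
use.

## The model

Genes passing the expression filters (≥ 2 fpkm at half the time points,
≥ 10 fpkm at ≥ 2 time points, > 2-fold change) are staged by the time
window of their peak |log2 fold change|: T1 (0.5–1 h) are flow sources, T2
(2–4 h) mandatory transit nodes, T3 (6–8 h) flow targets. An auxiliary
source S feeds T1, T3 drains into an auxiliary sink T, and the sub-network
is the support of the optimal single-commodity flow

    min_f   Σ_(i,j) a_ij f_ij  −  κ1 Σ_(g∈T1) f_Sg
    s.t.    0 ≤ f_ij ≤ C_ij,   flow conserved,   every unit transits ≥ 1 T2 gene

with arc costs `a = 1 − w′` inversely related to the interaction
reliability `w` (scaled per source database onto [0, 0.8]), and capacities
`C = F_g/⟨F⟩ + ē_g/⟨ē⟩ (+ κ2·w on T2 arcs)` encoding the staged gene's
fold change and abundance relative to its group. The transit requirement
is enforced exactly by a two-layer graph transform and the whole problem
is solved as an LP (HiGHS). A gene's score is its node flow (sum of
incoming arc flows); flow > 1 marks high-confidence genes.

Around the core solve the package provides: randomization p-values
(re-solving with random stage sets of the real sizes), flux-variability
style bounds over alternate optima, Opsahl-weighted hop-capped shortest
paths and reference-pathway matching, knockout re-analysis (delete a gene
and its arcs before solving), a (κ1, κ2) grid sweep with the
unreliable-edge selection rule, a non-temporal baseline mode
(ResponseNet-style: no transit constraint, interior capacities 1), and a
seeded synthetic-fixture generator with planted cascades for end-to-end
validation.

## Worked example

```sh
python examples/01_simulate_and_solve.py
```

prints, for a 300-gene network with 10 planted three-stage cascades:

```
30 genes pass the filters; stage sizes {'T1': 10, 'T2': 10, 'T3': 10}
network: 300 genes, 1676 directed arcs
objective -1.497, total source flow 14.970 (negative objective = the kappa1 reward exceeds the routing cost)
planted-gene recovery at flow > 1: recall 1.00, precision 1.00, per stage {'T1': 1.0, 'T2': 1.0, 'T3': 1.0}
```

Every planted gene — sources, intermediates and effectors — is recovered
with node flow above the high-confidence threshold and nothing else is.
`examples/02_temporal_vs_baseline.py` shows why the transit constraint
matters: the non-temporal baseline recovers **0.00** of the planted
intermediate regulators on the same fixture, while the temporal mode
recovers **1.00**, and its flow decomposition crosses an intermediate
regulator on all 10 paths. `examples/03_significance_and_stability.py`
and `examples/04_paths_and_knockout.py` demonstrate the p-values,
stability bounds, path extraction and knockout analysis.

The same pipeline runs from the shell:

```sh
tcflow simulate --nodes 300 --cascades 10 --seed 7 --out fixtures/
tcflow solve --network fixtures/interactions.tsv \
             --expression fixtures/expression.tsv \
             --kappa1 0.5 --kappa2 0 --out run/
```

Real data enters through the same two TSV dialects: a gene × time
expression matrix (first column gene, remaining columns hours, time 0
required) and a five-column interaction table (source, target, type,
database, raw reliability score).

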