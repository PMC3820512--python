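# Methods

## Overview

`tcflow` infers an active gene sub-network from a three-stage time-course
expression experiment and a scored molecular interaction network by
minimum-cost flow optimization. The key modelling idea is temporal: flow
enters at the early-response genes, must transit at least one
intermediate regulator, and leaves at the late effectors, so the optimal
sub-network is a set of time-respecting routes rather than a static
module. This document records the model, the numerical choices, the
defaults and why they were chosen, and what the synthetic validation does
and does not establish.

## Expression preparation

For gene *i* with abundance `e_ij` (fpkm-like units) at time *j* and
baseline `e_i0`, the per-time fold change is
`|log2((e_ij + c) / (e_i0 + c))|` with pseudocount `c` (default 1.0 fpkm);
`F_i` is the maximum over the used time points, `ē_i` the mean abundance
over the used time points plus the baseline. Log base 2 makes the 2-fold
selection cut-off read `F_i > 1`; the base is configurable for users who
prefer natural-log conventions. The pseudocount keeps fold changes finite
for genes silent at baseline and may be set to 0 for exact checks on
strictly positive data.

Three filters select the analysed genes: abundance ≥ 2 fpkm at ≥ 50% of
the considered time points (baseline included), ≥ 10 fpkm at ≥ 2 time
points, and fold change > 2-fold at ≥ 1 time point. Filtered genes are
staged by the window containing the argmax of the per-time fold change;
exact ties break toward the earliest time point, a deliberate early-
detection bias that mirrors the causal ordering of a response. Windows
default to T1 = {0.5, 1}, T2 = {2, 3, 4}, T3 = {6, 8} hours but are
configurable triples, so the method applies to any time course with a
baseline and three phases.

## Network assembly

Interaction records carry a type (`ppi`, `tf_target`, `ptm`,
`functional`, `inhibition`), a source database tag and a raw reliability
score; manually curated sources use the sentinel score 999. Scores are
min–max scaled onto [0, 0.8] *within each source database* — raw scales
are incomparable across sources — so a source's best record always maps
to 0.8 and its worst to 0 (constant-score sources, including all-curated
ones, map uniformly to 0.8). `ppi` records contribute arcs in both
directions; every other type contributes one directed arc. Duplicate arcs
across sources keep the maximum scaled weight (the most generous
reliability; the choice matters little because costs are monotone in w).
Gene/protein namespaces are merged by an optional caller-supplied rename
table (e.g. an ortholog map produced elsewhere); identifiers are
otherwise opaque case-sensitive strings. `inhibition` and `ptm` arcs keep
their type tag but are treated like any directed arc in the flow model.
Knockout analysis deletes the listed genes and their incident arcs from a
copy of the network before solving.

## The flow problem

Let w be an arc's scaled reliability. Arc costs are `a = 1 − w′` where
`w′ = min(0.8, w · (1 + 0.1 · C))` adds a small bonus, proportional to
the arc's capacity C, for arcs touching staged genes ("weights adjusted
to correspond to their capacities"). The 0.8 cap keeps every interaction
cost in [0.2, 1]: strictly positive costs mean minimum-cost solutions
contain no gratuitous circulation and antiparallel shuttling on
bidirectional ppi pairs is strictly suboptimal, so no anti-cycling
constraint is needed. The bonus rate and all capacity/cost formulas are
injectable parameters, isolated behind `build_problem`, so alternative
functional forms drop in without touching the solver.

Capacities encode the expression evidence of the staged gene an arc
serves: `C = F_g/⟨F⟩ + ē_g/⟨ē⟩` with group means taken over the gene's
stage, the first term rewarding relative induction strength and the
second rewarding well-supported (abundant) transcripts. S→T1 and T3→T
arcs use the terminal gene's statistics; arcs incident to a T2 gene use
the T2 gene's statistics only — path selection inside the network is
thereby driven by the intermediate regulators, not by their neighbours —
plus a tuning term `κ2 · w`. All remaining arcs have constant capacity 1.
Direct arcs between T1 and T3 genes are excluded. Auxiliary S/T arcs
carry zero cost: with interaction costs bounded below by 0.2 and a
minimal temporal route of two interaction arcs (T1→T2→T3, cost ≥ 0.4),
any positive cost on the auxiliary arcs would make the standard operating
point κ1 = 0.5 yield an empty network; free terminals keep the reward
comparison purely about interaction reliability.

The objective is `min Σ a_ij f_ij − κ1 Σ_{g∈T1} f_Sg`: κ1 is the per-unit
reward for activating a source gene, so exactly the routes cheaper than
κ1 carry flow, and capacities bound the problem. Three modes:

* **temporal_strict** (default): the transit requirement — every unit of
  flow crosses ≥ 1 intermediate regulator — is enforced exactly by a
  two-layer transform. Every non-T2 node is duplicated into a pre-transit
  and post-transit copy; arcs stay within their layer; T2 genes are
  single nodes entered from either layer and exited into the post layer;
  S attaches to the pre layer, T to the post layer. The sink is then only
  reachable through a T2 gene. The two layer copies of an arc share the
  original capacity through a coupling constraint, so mapped-back flows
  never exceed it.
* **temporal_aggregate**: the literal linear-constraint alternative,
  `Σ inflow(T2) ≥ ε · outflow(S)` (ε default 1) on the single-layer
  graph. It bounds aggregate transit but does not certify per-path
  transit; strict mode is the default and is what all reported results
  use.
* **responsenet**: the non-temporal baseline. No transit requirement,
  interior capacities fixed at 1, source reward γ (default 0.5, matching
  the temporal operating point); costs and terminal capacities are
  identical to the temporal modes so the comparison isolates the
  constraint.

The LP is assembled sparse and solved with scipy's HiGHS interface.
Arc order is deterministic and the solver is deterministic, so identical
configurations reproduce identical tables; degeneracy among optima is
quantified (not hidden) by the stability analysis. Flows mapped back to
original arcs sum the layer copies. A gene's node flow is the sum of its
incoming arc flows, including the S arc for source genes; flow > 1 marks
high-confidence genes. Arcs with flow above 1e−6 are "active". Flow
decomposition operates on the internal layered graph — where every
strict-mode source-to-sink path provably crosses a T2 gene — and maps
node sequences back to genes; a decomposed unit may therefore revisit a
non-T2 gene (enter a regulator through a neighbour and return through
it), which is a legitimate flow pattern, not an artifact.

**Correctness cross-check.** An exhaustive oracle, independent of the LP,
enumerates all profitable source-to-sink walks (cost below κ1, per-arc
usage bounded by capacity, T2-crossing in strict mode) and searches every
integral assignment of flow units to them. On hundreds of random
instances with ≤ 8 nodes and integral capacities ≤ 3 the LP objective
equals the integral optimum in both modes — the layered relaxation shows
no integrality gap on any instance tested.

**κ sweep.** κ1 and κ2 default to a grid of 0–5 in steps of 0.5 (121
combinations). Among solutions whose active sub-network contains < 1%
unreliable arcs (w < 0.5), the sweep selects the one activating the most
source genes; ties prefer smaller κ1 then κ2. On the default synthetic
fixture the sweep selects (0.5, 0), which is also the fixed operating
point used by the examples and the acceptance runs.

## Randomization significance

Gene-level support is a recurrence frequency under stage randomization:
the problem is re-solved R times (default 5000; desk-scale runs and tests
use 200) with the three stage sets drawn disjoint and uniformly from all
network genes, in the real sizes, at the same (κ1, κ2). Sampled genes
keep their real expression statistics; genes never profiled receive their
sampled group's median F and ē so capacities stay defined. A run counts
for gene g when g's node flow is at least its optimal flow *and* every
interaction incident to g that is active in the optimum is active in the
run; p = count/R (optional (count+1)/(R+1) smoothing). Infeasible runs
count as non-qualifying.

A property to be aware of: this p-value ranks genes (it decreases with
flow, and planted cascade genes sit at p ≈ 0 with off-cascade genes
higher), but it is **not** a calibrated tail probability. Because
qualification requires the gene's specific active-arc configuration to
recur, p-values are concentrated near 0 even for sub-networks built from
purely random stagings — measured Kolmogorov distances from uniform of
0.8–1.0 on background-only networks across reward levels. Treat p as a
relative reliability score within a run, not as a frequentist error rate;
no multiple-testing correction is applied, consistent with its use for
ranking.

## Alternate-optima stability

With the optimal objective pinned (inequality `c·x ≤ opt + 1e−9·(1+|opt|)`,
always feasible since the optimum is a lower bound; widened once by 10³
on numerical failure), each active arc's flow is alternately maximized
and minimized — two LPs per arc, the flux-variability scheme of
constraint-based metabolic modelling. An arc is unchanged when its bounds
differ by < 1e−6 flow units; a node is unchanged when all its incident
active arcs are. Bounds are reported for the arcs of the optimal active
sub-network (an unused parallel route of equal cost shows up as a (0, 1)
interval on the used one, not as a new arc).

## Path extraction

Active arcs get Opsahl-style lengths `f̄ / f_ij` (mean active flow over
arc flow): an arc carrying the mean flow has length exactly 1, stronger
arcs are shorter, and all-equal flows reduce to unweighted hop counting.
Shortest paths between stage groups (consecutive pairs T1→T2 and T2→T3 by
default; any ordered pairs on request) honour a hard hop cap (default 3
arcs) via a label-setting dynamic program over (node, hops) states —
plain Dijkstra cannot express the cap. Length ties break toward the
lexicographically smallest node sequence for reproducibility. Reference
pathways are supplied as plain directed edge lists or gene-set tables
(any source; a KEGG export is the intended shape): matching reports the
longest directed path present in both the active sub-network and the
pathway (depth-limited DFS, default cap 8 edges), and co-membership
reports the fraction of predicted paths with ≥ k genes (and all genes) in
one reference set.

## Synthetic fixtures

The generator emulates the data shape the method consumes, with planted
ground truth. Defaults define the study conditions used throughout the
tests and acceptance runs: 300 genes, 10 planted cascades (one T1 gene →
one designated T2 gene → one T3 gene, wired with curated-score arcs), a
background of ~4 interaction records per gene drawn from three mock
source databases (two continuous score dialects plus one curated-999
source, exercising every scaling path), log-normal baseline expression
(median 20 fpkm, σ = 0.6), 5-fold induction inside the designated window,
and 10% multiplicative noise clipped so background genes stay strictly
below the 2-fold filter. Sub-threshold background is enforced by
construction, not by chance, so filter counts are deterministic; planted
baselines are floored at 5 fpkm so planted genes deterministically clear
the abundance filters. One seed fixes everything; identical seeds give
byte-identical tables.

What the fixtures do not emulate: transcriptional kinetics (values are
independent across time points), correlated or count-based measurement
noise, hub-dominated degree distributions, pathway-structured network
modularity, or incomplete/incorrect interactions. Perfect recovery on
fixtures therefore demonstrates algorithmic correctness of the pipeline —
filters, staging, scaling, the transit constraint, significance and
stability — not expected performance on a real interactome, where
reliability scores are noisy and true cascades overlap.

## Problem sizes and tolerances

Desk-scale runs use the 300-gene fixture (≈ 1700 arcs; a strict-mode LP
has ≈ 3300 variables and solves in tens of milliseconds), R = 200
randomizations, 20-seed null ensembles on 120-gene background networks,
and oracle batches of 100–150 instances per mode — sizes chosen so every
validation completes in minutes on one CPU while keeping the planted
structure non-trivial. Conservation and capacity are verified to 1e−9
relative tolerance after every solve; active-arc and stability tolerances
are 1e−6; oracle comparisons use 1e−7 absolute.

## Known limitations

* Exactly three stages; responses that do not partition into three waves
  need a different staging, and grouping time points can hide
  relationships between genes expressed within the same window.
* The transit constraint is single-commodity: one unit passing any T2
  gene satisfies it; there is no per-cascade matching of sources to
  targets.
* The randomization p-value is anti-conservative under the null (see
  above) and is best read as a ranking score.
* Capacity and cost functional forms are sensible defaults with the
  documented rationale, exposed as injection points rather than claimed
  to be canonical.
* Sampling-interval blindness is inherited from the data: events faster
  than the first sampling interval are invisible to the staging.
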