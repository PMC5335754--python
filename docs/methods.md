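# Methods

## Purpose and model overview

`subnetbench` benchmarks *active subnetwork detection*: finding a connected
set of genes in a protein–protein interaction (PPI) network whose expression
changes jointly between two phenotypes.  Because published detectors are
closed, heterogeneous tools, the harness does not re-implement them; instead
it provides (i) a network-conditioned simulator that generates ground-truthed
case/control expression data, (ii) the evaluation statistics used to compare
detectors, and (iii) two transparent reference searchers so the loop runs
end-to-end.

The simulation has two stages.

### Stage 1 — binary DE/EE states from a Markov random field

Every gene *i* carries a state X_i ∈ {0, 1} (0 = equally expressed, EE;
1 = differentially expressed, DE).  A planted connected subnetwork G₀
is initialized to X = 1, the rest to 0.  Single-site updates then draw each
state from

    p_i(k | rest) ∝ exp(γ_k − β μ_i(1−k)),   k ∈ {0, 1},

where γ₀, γ₁ are external fields, β ≥ 0 is the coupling strength and
μ_i(1−k) measures disagreement between the candidate state k and gene i's
neighborhood N_i, modified by a self-retention weight w ≥ 0.  Writing
X¹ = X and X⁰ = 1 − X, three μ variants are provided (`mu_mode`):

- **`discordance`** (default):
  μ = (w·X_i^{1−k} + Σ_{j∈N_i} X_j^{1−k}) / (w + |N_i|).
  The w-weighted *fraction* of the closed neighborhood disagreeing with k.
  Large w favours keeping the current (initially planted) state; β smooths
  states along edges.  P(keep) is non-decreasing in w but saturates at
  logistic(β + γ-terms), so retention is strong, not absolute.
- **`count`**: the unnormalized numerator w·X_i^{1−k} + Σ_j X_j^{1−k}.
  Two exact properties motivate keeping this variant first-class.  With
  w = 0 it is the exact single-site (Gibbs) conditional of the Ising-type
  joint P(X) ∝ exp(Σ_i γ_{X_i} − β Σ_{(i,j)∈E} 1{X_i≠X_j}) on *any* graph
  — this is what lets the sampler be validated against brute-force
  Boltzmann enumeration on a 3-node path.  And as w → ∞ the flip
  probability decays as e^{−βw}, so the initialization is retained exactly
  in the limit (already at w = 50, β = 1 flips are numerically impossible).
- **`literal`**: μ = (w·(1−X_i^{1−k}) + Σ_j (1−X_j^{1−k})) / (w + |N_i|).
  Here the numerator counts *agreement* with k, so large w actively flips
  initial states — the opposite of a retention weight.  Kept for
  completeness and sensitivity analysis, not recommended.  (Its printed
  denominator Σ_j (X_j^{1−k}+X_j^k) is identically |N_i|.)

The normalized `discordance` form is the default because it makes w and β
separately interpretable at the benchmark's canonical w = 50: w trades
self-retention against neighborhood smoothing within a bounded exponent,
producing both retained true positives and a controlled stream of false
positives, which is exactly the regime the benchmark needs.  Under the
defaults (γ₀ = γ₁ = 0, β = 1, one sweep), a background gene flips to DE
with probability ≈ logistic(−β) ≈ 0.27 and a planted gene is retained with
probability ≈ logistic(β) ≈ 0.73; the sweep-by-sweep DE counts are logged
so users can judge burn-in if they raise `n_sweeps`.

Defaults: γ₀ = γ₁ = 0 and β = 1 (the external fields and coupling are free
knobs of the benchmark, not calibrated quantities), w = 50 (the benchmark's
canonical retention weight), `n_sweeps` = 1, deterministic sorted update
order (a `random_scan` switch exists; both are seeded and reproducible).

### Stage 2 — expression from the hierarchical Gamma-Gamma model

Given states, expression is drawn from the Gamma-Gamma (GG) model: a latent
per-gene scale β_g ~ Gamma(shape α₀, scale ν) and observations
y ~ Gamma(shape α, scale β_g), density

    p(y | α, β_g) = y^{α−1} e^{−y/β_g} / (β_g^α Γ(α)),

with gene mean μ_g = α β_g and marginal mean α·α₀·ν.  An EE gene shares one
β_g across both phenotypes; a DE gene draws independent case and control
scales from the same prior, the classical GG convention for differential
expression (the generative recipe "sample expression given the states"
leaves the DE mechanism open; condition-specific scales is the convention
of the model this parameterization comes from).  Defaults α = 10, α₀ = 0.9,
ν = 0.5, 50 case + 50 control samples.  "Gamma(α₀, ν)" is read as
shape/scale, matching the printed density's scale parameterization; a
`nu_is_rate` switch provides the rate reading.

Per-gene scores for the searchers come from a two-sided Welch t-test
(default; pooled-variance t and Wilcoxon rank-sum are selectable), with
z = Φ⁻¹(1 − p/2)·sign(t), p-values floored at 1e−300, and zero-variance
genes reported as p = 1, z = 0.

## Evaluation statistics

Against the planted G₀: TP/FP/FN over node sets, precision TP/(TP+FP),
recall TP/(TP+FN), F = 2PR/(P+R).  An empty recovered set reports
precision 0 (with a warning) rather than NaN so tables always tabulate.
Against a reference disease-gene list: fold enrichment
(recovered · n_network)/(n_reference · selected), computed in exact rational
arithmetic before conversion to float.  Edges of a result are counted and
reported but never scored.  Table output rounds half-even to 3 decimals;
full precision is kept internally.

## Reference searchers

Both maximize the aggregate score z_A = Σ_{i∈A} z_i / √|A| of a connected
set A — the scoring statistic of the classical active-modules method,
imported as-is; its Monte-Carlo background calibration is deliberately not
applied (raw aggregate only), a stated limitation.  One practical
consequence: greedy growth from a very high-z seed often terminates after
one or two nodes, because (S + z_c)/√(n+1) > S/√n demands increasingly
large z_c — visible in the full-scale benchmark, where greedy returns tiny
modules while annealing returns large ones.

- **Greedy**: start at the highest-z node (or user seeds); repeatedly add
  the candidate within `max_depth` hops whose addition (plus a shortest
  connecting path, for depth > 1 — "search depth" is read as hop radius)
  most increases z_A; stop at the first non-improving step.  Deterministic;
  ties broken lexicographically by node id; the score trajectory is
  strictly increasing.
- **Simulated annealing**: a binary inclusion flag per node, initialized by
  a seeded fair coin; each iteration toggles a uniformly random node and
  evaluates the largest included connected component (size ties broken by
  higher score, then lexicographically), accepting improvements always and
  deteriorations with probability exp(Δ/T) under geometric cooling
  (defaults T₀ = 2.0, factor 0.999, 5000 iterations).  The best-seen
  component is returned; its score is monotone non-decreasing.

## Pipeline and reproducibility

`run_benchmark` chains network → ground truth → MRF states → GG expression
→ DE test → searchers → evaluation, writing every stage output plus a
manifest of all parameters and derived seeds.  Per-stage seeds are obtained
by SHA-256 hashing of "(global seed):(stage name)" reduced below 2³¹, so
toggling one searcher never changes the simulated data, and the manifest
alone reproduces a run byte-for-byte.  Ground truth is grown by seeded
random-walk expansion (add a uniformly random node adjacent to the current
subset) so the planted set is connected, matching its role as a
*subnetwork*; `ground_truth_mode=uniform` drops the connectivity constraint
for sensitivity analysis.  The largest-connected-component extraction
breaks size ties by lexicographically smallest member.

## What the generator does and does not emulate

The fixture generator produces connected Barabási–Albert graphs by default
(scale-free degree mixing comparable to a curated human PPI subnetwork of
~5,200 genes and ~18,200 interactions; Erdős–Rényi and grid models are
available).  The full-scale configuration — 5,000-node network, 274-gene
planted subnetwork, 50 + 50 samples — mirrors the canonical benchmark
conditions at which the evaluation statistics were designed, and runs in
well under a minute per benchmark on one CPU.  The simulator does **not**
emulate microarray preprocessing artifacts (missing-value imputation,
probe-to-gene collapsing, normalization), correlated co-expression beyond
the shared network states, batch effects, or identifier-mapping noise.
Passing tests therefore demonstrate fidelity to the stated generative
model, not performance on real microarray data.

## Numerical choices and degenerate inputs

- Conditional probabilities subtract the maximum exponent before
  exponentiation; p₁ + p₀ = 1 to 1e−12 by construction.
- Fold enrichment uses `fractions.Fraction`; precision·(TP+FP) = TP holds
  exactly for representable counts.
- Empty recovered set → precision 0 + warning; empty selection → fold
  enrichment undefined (error in the low-level function, `None` + warning
  in the report path).
- Self-loops are dropped at load time (a binary interaction of a gene with
  itself carries no network information here); duplicate and reversed edge
  lines collapse.
- Tie-breaks (greedy candidate, component choice, LCC, seed start) are all
  lexicographic by node id for determinism.

## Known limitations

- The reference searchers are baselines, not re-implementations of any
  published tool; absolute precision/recall from them should not be read as
  that tool's performance.
- The aggregate z-score is uncalibrated (no background correction), which
  systematically favours small high-z modules for greedy and large modules
  for annealing.
- MRF parameters γ and β are benchmark knobs with no estimation procedure
  (simulation only, by design).
- One published comparison value (the jAM_GS fold enrichment) is internally
  inconsistent with its own printed counts; the harness recomputes
  2.026 from those counts and excludes that cell from arithmetic checks.
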