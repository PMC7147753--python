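# Methods

## Model and assumptions

The cascade model assumes that stage-specific drivers of a
differentiation time course are *peaking* genes: high at exactly one
time point, low elsewhere. Stage membership is therefore defined by
correlation to a one-hot template, not by clustering or differential
expression, and the candidate pool is restricted to the source nodes of
a user-supplied directed regulatory network — genes with no outgoing
regulatory edge can never enter a cascade column. Cascade edges make no
causal claim beyond "this regulator has a predicted binding interaction
with this same-stage or next-stage regulator"; the background network is
taken as given and is independent of the expression data.

Expression values are used as-is (any non-negative unit); the algorithm
depends only on within-gene profile shape, since Pearson correlation is
invariant to positive affine transforms of the profile. For the same
reason the template's "100 vs 1" encoding is immaterial.

## Template correlation

For a replicate-mean profile `x` over `T` time points and the one-hot
template at stage `s`, the Pearson correlation reduces to

    r_s = (x_s − x̄) / (σ_pop(x) · √(T − 1))

which implies `Σ_s r_s² = T/(T−1)` for every non-constant profile. Two
consequences shape the design:

* a gene can exceed a typical `minC` (0.6) for at most a couple of
  stages at small `T`, and the package assigns each gene to its
  **argmax stage only** (ties → earlier stage), keeping columns unique;
* zero-variance profiles have undefined correlation and are silently
  excluded (counted in the log), not errors — flat genes simply have no
  peak stage.

Replicates are collapsed by the arithmetic mean per time point before
correlating. The `minE` floor is applied **before** collapsing and is
strict: a gene must have at least one raw value strictly greater than
`minE` in any replicate or time point. Correlating against collapsed
means (rather than per-replicate profiles) is this package's choice; it
matches the template's per-time-point definition and makes `r`
independent of replicate count.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `minE` | strict expression floor on raw values | 4 | matrix units |
| `minC` | minimum template correlation | 0.6 | dimensionless |
| `maxS` | per-stage column cap | 10 | genes |
| `top_fraction` | per-PWM site retention when building a network | 0.05 | fraction |

Defaults follow common practice for this method family; `minE` is
dataset-scale dependent (published analyses use 4 on one normalized
dataset and 30 on another) and should be set to exclude genes whose
*peak* is still noise-level. Ranking ties are broken by
(correlation desc, gene symbol asc); at the per-PWM score cutoff by
(score desc, target asc, input order). Both rules exist only to make
runs deterministic.

## Network construction

From a scored binding-prediction table, each PWM's predicted sites are
ranked by score and the top `⌈f·n⌉` (floor of one, so every scored PWM
contributes at least its best site) are kept; each kept (PWM, target)
yields an edge from every TF gene the PWM maps to — PWMs shared within a
TF family fan out to all family members. Duplicate edges collapse.
Retention is monotone in `f` under the fixed tie-break.

## Stage columns and edges

Stages with no qualifying gene produce no column, and cross-stage edges
bridge each column to the next **non-empty** column, so a quiet time
point does not disconnect the cascade. Within-stage edges are labelled
one-way or reciprocal; per-node same-stage and next-stage out-fans rank
candidate master regulators.

## Enrichment

One-sided Fisher's exact test (hypergeometric upper tail) per column
and term, Bonferroni-corrected over the number of terms actually tested
(k ≥ 1 overlap; testing zero-overlap terms would only inflate the
factor), significant terms ranked by fold enrichment then p. The default
universe is all dataset genes that pass `minE` and carry at least one
annotation — conditioning on detectability, the standard choice for
expression-derived sets. The annotation map is flat: no GO-graph
ancestor propagation is performed.

## Null models

Three seeded randomizations emulate the specificity controls: profile
re-assignment (permute gene labels over rows; all genes or regulators
only), full matrix permutation (permute every cell), and fresh random
values (uniform on [0, max] by default) on the template's design. The
first two conserve the value multiset exactly. A fourth control removes
the regulator restriction. These support a comparative argument —
planted/real enrichments vanish under randomization — not a formal
significance framework. Every generator seed is recorded.

## Synthetic benchmark

`PlantedDesign` defaults: 5 time points × 2 replicates, 8 planted
regulators per stage peaking at 100 units over a baseline of 1, 800
background genes on flat log-normal baselines (median ≈ 20, so `minE`
has bite), additive Gaussian noise sd 5 truncated at zero, planted
within-/cross-stage edges at density 0.3 plus decoy edges.

Two proportions are deliberately scaled to mirror real TF networks
rather than chosen for convenience:

* **regulator pool ≫ column slots** — half the background genes source
  decoy edges, making the regulator universe (~440 genes) an order of
  magnitude larger than the 50 cascade slots, as with hundreds of TFs
  competing for 10–12 slots per stage. A small pool would let several
  members of one annotation term co-occur in a random column, producing
  spurious Bonferroni-significant terms under the null models.
* **terms mix TFs with effectors** — each stage's dedicated term holds
  its 8 planted regulators plus 30 downstream non-regulator genes, like
  a GO process term. Regulator-only terms are over-sensitive to chance
  overlap when columns are, by construction, all regulators.

What the fixture does **not** emulate: count noise (no library-size or
dispersion model), correlated replicates, multi-peak or ramp profiles,
and annotation hierarchies. Passing tests on it therefore demonstrate
algorithmic correctness and null specificity at realistic proportions,
not robustness to RNA-seq noise models.

With `noise_sd = 0` every planted profile is an exact affine image of
its template (r = 1) and background genes are constant (excluded), so
the pipeline must recover the planted assignment exactly; recovery
degrades monotonically with noise.

## Numerical choices and degenerate inputs

* Correlations are computed by the closed form (vectorized); tests pin
  it to direct Pearson at 1e-10.
* Fisher p-values come from the hypergeometric survival function,
  exact to ~1e-15 against integer-arithmetic tail sums.
* `T = 1` designs, empty regulator universes, inconsistent 2×2 tables
  and non-finite or negative expression values are rejected with
  specific errors; empty stage sets and empty networks are valid and
  yield empty results.
* Matrices round-trip through CSV at full precision (`repr` formatting
  on write, correctly-rounded `float()` parsing on read).

## Problem sizes

The test suite and the acceptance script run the correlation identity
on 6,000 random profiles (T = 3..8), the Fisher oracle on all ~46k
2×2 tables with N ≤ 30, the retention rule on 800 (n, fraction) cases,
structural invariants on 100 random fixtures, recovery on 10 seeds and
the null models on 20 repetitions — sizes chosen to exercise every code
path at desk scale while keeping a full run around ten seconds.

## Known limitations

Single-peak templates only (no ramps or multi-peak libraries);
consecutive-stage edges only (no longer-range time-lagged links); flat
annotation maps; no miRNA-target scoring — miRNA edges enter only via a
user-supplied edge list; the unrestricted-gene ablation shares the maxS
cap, so it shows dilution, not an exhaustive alternative model.
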