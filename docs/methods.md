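# Methods

This note documents the statistical models, the defaults and their
rationale, the synthetic-data generator, and the numerical choices made
where the design was genuinely open.

## Characteristic-direction differential expression

Per study the two classes (cases, controls) are compared geometrically: the
reported per-gene statistics are the components of the unit vector

    b ∝ Σ̂γ⁻¹ d,     d = μ̄_case − μ̄_control,
    Σ̂γ = γ Σ̂ + (1 − γ) ν I,

where Σ̂ is the pooled within-class sample covariance (degrees of freedom
n₁ + n₂ − 2), ν = tr(Σ̂)/p its mean diagonal element, and γ ∈ (0, 1] a
shrinkage weight. γ → 0 shrinks toward the spherical covariance ν I, making
b proportional to the raw mean difference; γ = 1 uses the sample covariance
alone. Default γ = 0.5, a middle ground that damps the unstable small
eigenvalues of Σ̂ without discarding covariance structure entirely.

**Subspace solve.** With genes ≫ samples, Σ̂ has rank ≤ n − 2. The solve is
carried out in the PCA basis of the within-class-centred data (top
k = min(n − 2, 30) right singular vectors; k is also capped at the numerical
rank): eigendirections with sample variance λᵢ are scaled by
1/(γλᵢ + (1 − γ)ν) and the component of d orthogonal to the subspace — whose
sample variance is 0 — is scaled by 1/((1 − γ)ν). When k equals the rank
this reproduces the dense full-space solve exactly (verified to 1e−8 in the
tests); truncating k below the rank treats the discarded directions like the
orthogonal complement. At γ = 1 the orthogonal scale would be infinite; the
out-of-subspace component of d is dropped instead (a pseudo-inverse solve),
which only matters for rank-deficient inputs at exactly γ = 1.

**Orientation and degeneracy.** The vector is L2-normalised and oriented so
the gene with the largest positive mean difference carries a positive
coefficient (falling back to sign(b·d) if that component is numerically
zero); positive components therefore always mean "up in cases". Inputs with
zero within-class variance or identical class means raise a degeneracy
error — there is no discriminating direction to report.

**Signatures.** Genes are ranked by |b_g| descending with lexicographic
tie-breaks, the top 500 genes overall are kept and split by sign into the
up/down lists. The 500-gene budget is interpreted as a total across both
directions; a per-direction reading is possible and callers who want it can
simply raise the cutoff and truncate the two lists themselves. Coefficients
of exactly zero are assigned to neither list.

## Co-DEG consensus

A gene enters the co-up (co-down) set when it appears in the up (down) list
of at least `min_support = 2` independent studies of the same category —
genes reported by a single study are treated as study-specific noise and
filtered. A gene that meets the threshold in *both* directions is flagged
`conflicting` and excluded from both sets: keeping it in either would
contaminate direction-specific enrichment downstream, and a gene whose sign
flips across studies is not a reliable consensus marker. Raising
`min_support` can only shrink the consensus sets (tested as a property).

## Enrichment and the combined score

Over-representation of a query gene list in each term of a GMT library uses
the hypergeometric upper tail P(X ≥ k) (equivalently the one-sided Fisher
exact test), with Benjamini–Hochberg correction across the terms actually
tested (those with overlap ≥ 1; zero-overlap terms carry p = 1 and would
only dilute the correction).

The **universe** defaults to (library universe) ∩ (genes measured in the
contributing studies). Testing against the whole genome inflates
significance for genes that were never measurable; callers who want the
genome-wide universe can pass it explicitly.

The **rank-deviation z-score** requires a null model of where each term
ranks under uninformative queries: `build_null_rank_model` draws `n_random =
1000` random queries per query size from the universe, ranks all terms by p
ascending (tied p-values share their average rank, so exchangeable terms
have identical null distributions), and stores each term's rank mean μ_r and
sd σ_r (σ floored at 1e−6; a seed is mandatory and the model is exactly
reproducible). Then z = (μ_r − r_observed)/σ_r, positive when the term ranks
better than expected, and the **combined score** is c = |ln p_adj| · z,
using the natural log of the BH-adjusted p. When no null model is supplied,
a closed-form uniform-rank null (μ = (T+1)/2, σ = √((T²−1)/12) over T terms)
is used as a deterministic fallback.

Because the hypergeometric tail is discrete, the test is conservative: the
achievable p just below 0.05 can be far smaller than 0.05 when terms and
queries are small relative to the universe. The type-I calibration check
therefore uses large decoy terms (200–600 genes in a 2000-gene universe with
200-gene queries), where the discrete tail is nearly continuous and the
false-positive fraction sits close to the nominal level (~0.04).

## Upstream-regulator networks and hubs

TF-target enrichment of the co-up (and, separately, co-down) genes yields
the top 10 TFs by combined score. These seed a Genes2Networks expansion: the
subnetwork contains the seeds plus every protein on a shortest path of
length ≤ 2 (default; 1–3 supported) between two seeds in the background PPI,
with the induced PPI edges; seeds absent from the PPI are kept as isolated
nodes. Kinase-substrate enrichment is then run with the subnetwork's
proteins as the query, and the top 10 kinases are attached through
phosphorylation edges to their substrates in the network. A kinase already
present in the network has its role upgraded to `kinase` so that every
phosphorylation edge has a kinase endpoint.

Centralities are computed on the simple undirected graph, ignoring edge
kinds: betweenness is the unnormalised sum over unordered node pairs
(endpoints excluded) of the fraction of shortest paths through the node;
core numbers come from standard k-core peeling. Hubs are ranked by (k-core
desc, betweenness desc, degree desc, symbol asc) — k-core first because the
most deeply embedded proteins are the best candidates for master regulators,
with betweenness and degree as successively finer tie-breaks. Both
centralities are validated against brute-force oracles (exhaustive
simple-path enumeration; exhaustive subset minimum-degree search).

## Drug connectivity

With only gene *sets* available for query and drugs (no ranked profiles),
connectivity is the signed Jaccard statistic

    score = ½[(J(q_up, d_up) + J(q_down, d_down)) − (J(q_up, d_down) + J(q_down, d_up))]

which is exactly +1 for a perfect mimic, −1 for a perfect reverser, 0 when
all four overlaps are empty, antisymmetric under swapping a drug's sets, and
bounded in [−1, 1] (property-tested). It approximates rank-based
connectivity scoring for set-valued signatures. The association p-value is
the smallest hypergeometric upper-tail p over the four quadrant overlaps,
Bonferroni-multiplied by 4 and capped at 1.

## Synthetic-data generator

The generator emulates a multi-study case/control meta-analysis on the log2
scale: per study, gene baselines μ_g ~ U(6, 12) and residuals N(0, base_sd²)
with base_sd = 1. Planted co-DEGs (50 up + 50 down by default) are shifted
by ±2 standard deviations in the cases of *every* study; 30 private DEGs per
study are shifted (random sign) in one study only. Defaults: 3 studies of
10 cases vs 10 controls over 20000 genes — genome-scale, so that the
500-gene signature cutoff selects ~2.5% of genes per study, as it would on
real arrays. (At a few thousand genes a 500-gene cutoff covers so much of
the panel that chance two-study agreement floods the consensus; panel size
is a study condition, not a tuning knob.)

Regulator structure: 10 planted TFs whose 20-gene target sets are drawn from
the planted co-DEGs (plus 5 non-DEG decoy genes per term), among 50
size-matched decoy TFs drawn from non-DEG genes; a background PPI that is a
star from a hub protein to every planted TF plus 200 random edges; 10
planted kinases whose substrate sets cover the hub and planted TFs, among 30
decoy kinases; a pathway library with one planted term per direction; and a
drug library whose planted reverser carries 80% samples of the co-down/co-up
sets as its up/down sets, among 20 size-matched random decoys. All
randomness derives from one root seed via `SeedSequence([seed, domain])`
with fixed per-component domain constants.

What the simulation does **not** model: probe-level microarray artifacts,
batch effects, platform differences between studies, count noise of RNA-seq,
correlated co-expression modules, or realistic PPI topology (scale-free
degree distributions). Passing the recovery tests therefore demonstrates the
pipeline's correctness and calibration under idealised Gaussian conditions,
not its power on real heterogeneous GEO data.

## Pipeline, determinism and sizes

`run_full_pipeline` executes eight stages (load/simulate, QC,
differential expression, signatures, consensus, functional enrichment,
regulatory network, connectivity), writes every report as a TSV with fixed
`%.6g` float formatting plus SIF/GraphML networks and a `manifest.json`, and
raises a `PipelineError` naming the failing stage. All collections are
iterated in sorted order and all randomness is seeded, so a rerun with the
same seed is byte-identical (tested file-by-file).

Signature-integrity QC rejects a study when any sample ID appears in both
the case and control groups, and drops (with counts) gene symbols absent
from a caller-supplied valid-symbol list; which symbol snapshot to use is
the caller's choice, passed as an input file.

Problem sizes used in the test suite and acceptance script — full pipeline
at the default conditions above (runs in a few seconds), determinism check
on a 1500-gene configuration, brute-force centrality oracles on 200 random
graphs of ≤ 9 (betweenness) and ≤ 12 (k-core) nodes, exhaustive
hypergeometric enumeration for universes ≤ 12, and 1000-query type-I and
null-rank simulations — were chosen so every guarantee is checked exactly or
with ample Monte-Carlo resolution while the whole suite stays fast.

## Known limitations

- The CD shrinkage weight γ and the PCA dimension cap (30) are pragmatic
  defaults; no data-driven selection of γ is implemented.
- BH is applied per library per query; no correction across the multiple
  libraries/directions a pipeline run tests.
- The G2N expansion considers only shortest paths between seed pairs, not
  all paths ≤ the length bound, and does not weight intermediates by how
  many seed pairs they connect.
- Set-based connectivity ignores effect-size ordering within signatures;
  with ranked drug profiles a rank-correlation statistic would be
  preferable.
- The conflicting-gene rule (exclude from both consensus sets) is one of
  several defensible choices; support counts for both directions are always
  reported so users can revisit it.
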