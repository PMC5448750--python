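# Methods

This note documents the models and procedures `connscreen` implements, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Expression densities and normalisation

The quantitative unit is the *expression density*: for a brain region R, the
number of expressing pixels in R divided by the number of pixels intersecting
R, per gene per developmental stage. Densities are dimensionless, nonnegative
and (for real atlas data) bounded by 1. Seven stages are assumed by default —
E11.5, E13.5, E15.5, E18.5, P4, P14, P28 — spanning regional patterning,
axon pathfinding, synaptogenesis and plasticity. Stage order is taken from
column order because stage labels are not lexically sortable.

Missing cells are explicit. Genes with *no* measurement at any stage carry no
information and are removed before normalisation (`filter_all_missing`); the
filter is idempotent and order-preserving.

Each gene is normalised by its own mean over *present* stages:
n_{g,t} = d_{g,t} / mean_t(d_{g,t}). A value of 1 is "this gene at its own
average level"; the transform is scale-invariant and makes temporal shapes
comparable across genes with very different absolute levels. Using the
present-value mean is the only choice that preserves the value-1-equals-
average semantics when stages are missing. Genes whose present values are all
zero have no defined shape; they are flagged and excluded from clustering
rather than divided by zero.

For clustering, missing cells must be filled. The default policy replaces
them with 1.0 — the gene's own average, which is neutral under Euclidean
distance on relative profiles and keeps every measured gene in the analysis.
A `drop-gene` policy is available for sensitivity checks. How the original
analysis handled missing stages inside k-means is not documented anywhere we
can verify, so the fill-with-one default is a declared surrogate, not a
reconstruction.

## k-means and the k sweep

Clustering is Lloyd's algorithm under squared Euclidean distance with random
centroid initialisation (k distinct genes sampled per restart), run for many
restarts keeping the minimal-inertia solution. Defaults: 1000 restarts,
max_iter 300, convergence when the largest centroid shift falls below 1e-8.
"Iterated a thousand times" descriptions of this kind of analysis are
ambiguous between restarts and Lloyd iterations; we read it as restarts — the
standard guard against local minima — and surface both knobs. An empty
cluster during an update is reseeded deterministically at the point farthest
from its assigned centroid, so all k clusters stay non-empty.

Because no single k is "correct" for temporal profiles, `sweep_k` fits every
k in a range (default 6–18) and scores each adjacent pair: every (k+1)-cluster
is mapped to the k-cluster with maximal member overlap, and the stability
score is the summed maximal overlaps over the gene count — exactly 1 when the
finer partition refines the coarser one. High scores across the sweep
indicate clusters subdividing rather than reshuffling, i.e. a roughly
hierarchical temporal organisation. k = 10 is the conventional operating
point downstream (large clusters peaking at every stage); it is
config-overridable.

Cluster labels are arbitrary (initialisation-dependent). All downstream logic
refers to clusters through their *chronological rank*: clusters are ordered
by the stage at which their mean normalised profile peaks (argmax, ties to
the earliest stage; rank ties broken by larger peak value, then label).
Exact memberships at a given k are not a reproduction target — they are
stochastic under restart seeding — which is why enrichment reproduction
against published numbers consumes published assignments rather than
re-clustered ones.

## Localisation consensus and functional groups

Four predictor outputs per protein are combined: signal peptide (yes/no),
GPI-site quality (P = predicted, S = second site, or none), a compartment
call from the ten-compartment vocabulary (gol, cyt, csk, end, ext, mit, nuc,
per, pla, ves) with a transmembrane-helix count, and an independent TM-helix
count. The decision table, applied in order:

1. *extracellular evidence* := signal peptide, or GPI quality ∈ {P, S}, or
   compartment ∈ {ext, pla};
2. both TM counts ≥ 2 → **multi-pass** (disagreement in the exact count is
   irrelevant);
3. TM counts agreeing at 1, or a GPI site → **GPI/single-pass**;
4. TM counts agreeing at 0 with extracellular evidence → **secreted**;
5. otherwise compartment nuc → **nuclear**, else **cytoplasmic** (organelle
   compartments — gol, end, mit, per, ves, csk — are absorbed here);
6. disagreeing TM counts not covered by rule 2 resolve from the larger count
   (1 → GPI/single-pass, ≥ 2 → multi-pass) and set `needs_curation`.

Proteins with no evidence at all are `unannotated`. The original screen
resolved TM-count disagreements by manual curation; rule 6 replaces that with
a deterministic rule plus the `needs_curation` flag, and an override file
(gene → category) lets a curated table be reproduced exactly. Treating the
plasma-membrane compartment as extracellular evidence is a design choice
consistent with the screen's focus on surface proteins; the exact precedence
the original curators used is not recoverable, so the table here is a
declared reconstruction with the override file as the escape hatch.

Functional grouping uses six groups in priority order: (1) axon guidance and
cell adhesion, (2) synapse, (3) receptor tyrosine kinases/ligands and
patterning, (4) neurotransmission (GPCRs, ion channels, gap junctions),
(5) chromatin and transcription-factor activity, (6) other/unannotated. The
first matching flag wins, so a guidance-annotated kinase lands in group 1.

## Enrichment statistics

Cluster × category tables are tested with the plain Pearson chi-square
against the independence expectation E_ij = R_i C_j / N, df = (r−1)(c−1), no
continuity correction (the tables are large: df 36/45 omnibus, df 9
follow-ups). Unannotated genes are excluded from the localisation table by
default, so the tested population is the annotated genes; per-category
follow-ups collapse to category-vs-rest where "rest" is the *other annotated*
categories, keeping one consistent population across the test family (the
include-unannotated variant is available via `exclude=()` for
reconciliation). Follow-ups are Bonferroni-corrected: threshold α/m with
α = 0.05 and m the number of categories (0.01 for five localisation
categories, 0.05/6 ≈ 0.008 for six groups). p-values are computed in double
precision and only banded (< 0.001 etc.) in human-readable reports.
Observed/expected ratios per cell form the enrichment profile; cells with
zero expectation are reported as missing.

## The candidate funnel

Clusters of interest are those with observed/expected > 1 for GPI/single-pass
proteins AND > 1 for functional group 1 or 2 — the profile of a cluster
likely to harbour connectivity labels — unless an explicit label set is
given. The funnel counts the genes of those clusters, keeps the
extracellular ones (secreted, GPI/single-pass, multi-pass), and removes genes
flagged `uniform` by the external visual screen. Spatial uniformity cannot
encode target-specific information, but the selective/differential/uniform
judgement is made on atlas images by a human; it enters only as a flag table
with provenance recorded, and genes without flags are retained as `unknown`.

## Markov clustering and the family filter

The similarity graph keeps each query's top-N hits (default 200; ties at the
cutoff are all kept), drops self-hits, and symmetrises asymmetric pair scores
by the maximum. Score semantics (bit score, −log E-value, …) are opaque to
the algorithm.

MCL runs on the column-stochastic matrix with self-loops added at each
node's maximum incident weight (scale-robust across heterogeneous score
ranges; a unit-loop policy is available). Each iteration applies expansion
(matrix power e = 2), inflation (entrywise power r = 2.0 followed by column
renormalisation) and pruning of entries below 1e-5; convergence is declared
when the largest entry change falls below 1e-6 (cap 100 iterations;
non-convergence returns the current clustering with a warning flag). The
converged flow matrix is interpreted deterministically: rows with nonzero
diagonal are attractors, attractors connected by residual flow form one
attractor system, every node joins the system of the lowest-id attractor
that reaches it, and unreached nodes become singletons. Higher inflation
gives finer partitions (checked empirically on seeded graphs in the test
suite; it is a strong regularity of the algorithm, not a theorem).

A cluster passes the candidate filter iff it contains (a) a mammalian member
and (b) a fly or worm member, (c) a mammalian transmembrane member carrying a
whitelisted motif (Ig, FN3, cadherin, LRR, EGF, CUB, sema, plexin repeat),
and (d) no member of a blacklisted family with an already-demonstrated
guidance role (DCC/Neogenin, Robos, Slits, L1CAMs, Contactins, Eph receptors,
Ephrins, FGFs/FGFRs, RPTPs, cadherins, protocadherins, semaphorins, plexins,
integrins). Requiring the motif on a *mammalian* member reflects the screen's
goal of mammalian candidates; a strict variant additionally requiring an
invertebrate member with the motif is behind a flag, since which member must
carry the motif is genuinely open.

## Synthetic data

The generator defines the study-scale conditions for all tests:

* **Expression**: n = 1996 genes × 7 stages. Gene g of archetype a gets
  d_{g,t} = bump_a(t) · exp(σ z_{g,t}), clipped to [0, 1], where bump_a is a
  triangular profile rising from 0.05 to 0.5 at the archetype's peak stage
  (half-width two stages). Defaults: seven archetypes, one peaking at each
  stage, equal mixing; multiplicative log-normal noise σ = 0.3 (realistic
  within-archetype scatter that still leaves archetypes separable);
  independent missingness at rate 0.01 (a gene is never left fully missing).
  The real survey publishes no noise model; the triangular-bump/log-normal
  choice preserves nonnegativity and the one-peak-per-cluster structure and
  was fixed once.
* **Full survey stand-in**: the 2002-gene variant appends the six named
  genes that have no thalamic data at any stage, all-missing, shuffled into
  the table — a synthetic stand-in reproducing the real survey's documented
  structure for filter tests.
* **Annotations**: localisation categories and functional groups are drawn
  from the real survey's marginal composition (907/293/286/267/240/3 and
  286/91/360/270/677/312 of 1996) — either sampled per gene with
  per-archetype odds multipliers (for planting enrichment), or apportioned
  exactly (largest remainder) and randomly permuted when no enrichment is
  requested. Predictor evidence is then generated consistent with the drawn
  category, so the consensus decision table round-trips it. Each generator
  uses its own seeded random stream: the annotation stream must not replay
  the expression stream's uniforms, or categories would be spuriously
  coupled to archetypes at equal seeds.
* **Similarity graph**: a planted-partition model — default ten families of
  eight proteins, within-family edges at p = 0.9 with scores uniform on
  [50, 100], between-family edges at p = 0.02 with scores uniform on
  [5, 15], taxa cycling through mouse/human/fly/worm per family, Ig motif
  and TM by default, with per-family templates to plant filter failures.

What the synthetic benchmarks show: the pipeline recovers planted temporal
archetypes (ARI ≥ 0.9 at σ = 0.3; exact at σ = 0), the chi-square machinery
is calibrated under the null (rejection rate ≈ 0.05) and powerful against a
3× planted enrichment at survey scale (≥ 90%), and MCL recovers planted
families exactly at the stated densities. What they do not show: robustness
to spatially structured signal, correlated or informative missingness,
probe-level artefacts, non-unimodal temporal profiles, or realistic BLAST
score distributions — none of which the generator emulates.

## Problem sizes and numerical choices

Tests and the acceptance script run the statistical simulations at the sizes
stated above (1000 null replicates; 100 power replicates with 5 k-means
restarts each; 5 seeds for recovery benchmarks; 20 restarts for ARI
benchmarks), chosen as the package's own benchmark configuration. Tolerances:
normalisation invariants at 1e-9, chi-square versus the independent oracle at
1e-8 relative, k-means convergence 1e-8, MCL convergence 1e-6 with pruning
1e-5. All randomness flows through `numpy.random.default_rng` with explicit
seeds; ties everywhere break toward the lower label/earlier stage/lower id,
so every code path is deterministic given its seed.

## Known limitations

* The published per-gene supplementary workbook (cluster labels and curated
  annotations for each of the 1996 genes) is not redistributable with this
  package, so the printed enrichment statistics (χ² = 122.694 etc.) and the
  896/426 funnel can only be verified by users who export that table
  themselves; the corresponding tests fail (by design, loudly) until then.
* k-means memberships are initialisation-dependent; only statistics computed
  *from* a fixed assignment are reproducible targets.
* The visual selective/differential/uniform screen is not modelled — no
  surrogate statistic is imposed on top of the flag interface.
* Proteome assembly, BLAST, and the external localisation/motif predictors
  are out of scope; their outputs are consumed as input tables.
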