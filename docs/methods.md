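# Methods

`microtopics` implements topic-model-based discovery and cross-cohort
validation of microbiome *community types*: groups of bacterial genera that
co-occur across stool samples and whose prevalence differs between patients
and controls. This note documents the models, the numerical choices, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Model

A genus-level 16S count table is treated as a document-term corpus: samples
are documents, genera are terms, reads are word tokens. Latent Dirichlet
allocation assumes each sample d draws topic proportions
θ_d ~ Dirichlet(α), and each read draws a topic z ~ Cat(θ_d) and then a
genus w ~ Cat(β_z). A topic — a probability distribution β_k over genera —
is interpreted as a community type; θ_d describes each sample's fractional
membership across communities.

### Variational EM

Inference is deterministic coordinate ascent on the evidence lower bound
(ELBO) with the fully factorised posterior q(θ_d)=Dirichlet(γ_d),
q(z)=Cat(φ). Reads of the same genus in a sample share a responsibility
vector, so the E-step collapses over the vocabulary:

    φ_dvk ∝ β_kv · exp(ψ(γ_dk)),      γ_dk = α_k + Σ_v n_dv φ_dvk

iterated until the normalised γ rows change by < `estep_tol` (mean absolute
change, default 1e-6; cap 50 sweeps). The M-step sets
β_kv ∝ η + Σ_d n_dv φ_dvk and, by default, re-estimates the K-vector α by
Newton–Raphson on the Dirichlet likelihood of E[log θ] (linear-time inverse
Hessian; step-halving keeps α positive and the objective ascending). The
outer loop stops when the relative ELBO change falls below `em_tol`
(default 1e-4; cap 100 iterations).

The reported ELBO includes the η·Σ log β smoothing term, making the trace
non-decreasing by construction — this is asserted per iteration in tests.
All E-step updates are vectorised across documents through the identity
s_dv = Σ_k exp(ψ(γ_dk)) β_kv, so no D×V×K array is materialised and a fit
at D=200, V=100, K=5 takes well under a second.

Defaults mirror the common VEM convention: initial α = 50/K (then
estimated), fixed symmetric η = 0.1, one restart with an explicit seed
(`n_restarts` for robustness studies; best final ELBO wins). β is
initialised from corpus term frequencies perturbed per topic by Gamma(5)
multiplicative noise — strong enough to break symmetry, weak enough to stay
near the data marginal. β and γ are stored on the probability scale because
the cross-cohort validation operates on probability vectors.

Fractional counts are accepted (topic-abundance tables can re-enter any
stage); integer genus counts are the documented ingest path.

### Choosing the number of topics

`tune_topic_number` fits one model per candidate K (one seed, no restarts)
and evaluates two minimisation metrics:

* **density** (`cao_juan_metric`): mean pairwise cosine similarity among the
  K topic rows of β. Well-separated topics score near 0; duplicated topics
  (overfitting) push it toward 1.
* **divergence** (`arun_metric`): symmetric KL between the normalised
  singular-value spectrum of β and the normalised document-length-weighted
  topic mass Σ_d N_d γ_d, both sorted descending, entries floored at 1e-12
  before logs (spectra of a balanced factorisation agree; degenerate topics
  at large K create vanishing singular values and a large divergence).

Per-dataset optima are combined by averaging every per-dataset, per-metric
argmin and rounding half away from zero (`combine_dataset_optima`); the
result becomes the pipeline's K.

**Known limitation.** On corpora whose true topics are nearly disjoint over
genera (which symmetric-Dirichlet topic draws produce), the divergence
metric has no signal *below* the true K: underfitted models merge disjoint
topics into still nearly orthogonal blends, so both spectra stay matched
and the metric is ~0 for every K ≤ K_true, jumping only when K exceeds
K_true. Its argmin below the jump is then decided by noise. We verified the
same behaviour with an independent LDA implementation, so it is a property
of the metric, not of this fit. The density metric does not share the
problem (merged topics leave a clear minimum at the true K) and is the more
reliable of the two on such data; the divergence metric remains useful as
an upper-bound (overfitting) detector.

## Preprocessing

Amplicon features are aggregated to genus (sum of counts per genus; totals
conserved), then genera with pooled relative abundance — genus total reads
over grand total reads — strictly below 1e-5 are removed, per cohort
independently. A presence-fraction reading of "prevalence < 1e-5" is
incoherent below 100 000 samples, so the relative-abundance reading is
implemented; the criterion and threshold are echoed in every
`FilterReport` so runs are auditable. Total-sum scaling rescales each
sample to a fixed total (default 1e6) and is idempotent at fixed scale.

## Read-to-topic assignment

`assign_reads_to_topics` multiplies each sample's topic probabilities γ_d
by its read depth, yielding a samples × topics table whose rows sum to the
sample depth — a "document-term matrix" over topics that re-enters the
pipeline as an ordinary count table. Default output is fractional
(`rounding="none"`); `rounding="nearest"` applies largest-remainder
apportionment (floor all, hand leftover units to the largest remainders,
ties to the lower index) so integer row sums are conserved exactly. Topic
identifiers carry the originating cohort label ("exploratory:Topic 4") so
cross-cohort reports are unambiguous.

## Differential abundance

Topic-level testing uses a bias-corrected compositional linear model (the
LinDA procedure, implemented here):

1. y_ji = log((count_ji + 0.5) / depth_i) — the 0.5 pseudocount matches the
   reference count-mode convention and tolerates fractional topic counts;
2. per-feature OLS of y_j on the group indicator (optional numeric
   covariates supported), giving coefficient b_j and standard error;
3. a compositional shift moves every b_j equally, so the mode of {b_j} —
   Gaussian KDE with Silverman bandwidth, maximised over a 512-point grid
   spanning the coefficient range — is subtracted from every coefficient;
4. t-test of the corrected coefficient with the regression's residual
   degrees of freedom; Benjamini–Hochberg adjustment.

Effects are natural-log fold changes, positive = higher in cases; the case
level defaults to the second group level in first-seen order
(reference-first factor coding) and can be named explicitly. Features with
zero residual variance get p = 1 and a `degenerate` flag. Winsorisation is
deliberately not implemented (the supported analysis path disables it).
Simulations in the test suite show type-I error ≈ 0.05 under the null and
near-complete detection of a 4× single-feature compositional boost at
n=50/group with unchanged features' corrected effects centered on zero.

Genus-level screening follows the classical route: TSS to 1e6, two-sided
Wilcoxon rank-sum per genus (exact by enumeration when n ≤ 12 without
ties, otherwise normal approximation with continuity and tie corrections;
all-identical input returns p = 1), BH adjustment. In both families a
feature is significant only when p ≤ 0.05 AND q ≤ 0.25 (conjunctive), and
BH is applied within each analysis family per cohort.

## Cross-cohort validation

Two cohorts retain different genus sets, so topic-term matrices are first
re-expressed over the union vocabulary with zeros for absent genera and
**no renormalisation** — renormalising would inflate similarity between
topics concentrated on shared taxa. The full K_A × K_B cosine matrix is
thresholded at ≥ 0.80 (inclusive, configurable); pairs form a bipartite
graph whose connected components are the community types. Matching is
deliberately many-to-many: several exploratory topics matching one
validation topic form a single community. A community is *validated* when
it contains a significant exploratory topic matched to a significant
validation topic (`both-significant`, the default rule); the laxer
`exploratory-significant` rule requires only the exploratory side.

## Synthetic data

The generator draws cohorts from the exact generative process the model
assumes: β_k ~ symmetric Dirichlet(η₀=0.1) over V genera (sparse,
realistic for genus tables); per-sample depths log-normal (mean 2×10⁴,
σ_log 0.3) emulating uneven sequencing; θ_d ~ Dirichlet(α_d) with base
concentration α₀=0.5 and the case samples' prior mass multiplied by
`effect_size` on `effect_topics` — a *prevalence* shift, not a content
shift, matching how disease-associated communities differ between groups;
counts ~ Multinomial(depth, βᵀθ_d). Default dimensions (D≈60, V≈170, K≈8)
mirror genus-level case-control cohorts. Paired cohorts share the first
`n_shared` topic rows verbatim (cross-cohort cosine exactly 1 on the
truth) and can drop a random genus subset from the validation cohort to
emulate unequal genus retention — note that dropping can remove a dominant
genus of a shared topic and legitimately break its cross-cohort identity,
so recovery tests that assert exact planted-pair counts generate without
dropping.

What the generator does **not** emulate: phylogenetic correlation between
genera, overdispersion beyond the Dirichlet-multinomial hierarchy,
zero-inflation beyond multinomial sampling zeros, sequencing error, or
shared dominant taxa across topics. Passing recovery tests therefore show
the inference machinery is correct under the model's own assumptions, not
that real stool cohorts satisfy those assumptions.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes — recovery at
D=200, V=100, K=5, depth 10⁴; tuning grids 2..10 over 10 seeds; paired
matching at D=100, K=8 over 20 seeds; calibration at 200 null replicates —
chosen so the full suite completes in minutes on one core while leaving
each property comfortably identifiable. Every random draw flows from an
explicit integer seed; the same configuration reproduces every pipeline
output byte for byte (float I/O uses round-trip-safe formatting, and run
logs contain no timestamps).
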