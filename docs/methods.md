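# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `tfcollab`, in the order the pipeline runs.

## Expression model and preprocessing

The input is a genes × samples matrix of non-negative FPKM-scale values
with every sample assigned to an ordered tissue group. Genes whose zero
fraction strictly exceeds `max_zero_frac` (default 0.92) are dropped;
the zero test is exact equality to 0.0, because FPKM tables print
literal zeros — no tolerance knob. With 78 samples the boundary is
sharp: 72 zeros (92.3%) drops a gene, 71 (91.0%) keeps it.

Correlation work defaults to log2(FPKM + 1). Raw FPKM has heavy tails
that let a few extreme samples dominate Pearson correlation; the log
transform is monotone (so Spearman results are unchanged) and maps
zeros to zero. Raw-scale correlation remains available. No cross-sample
normalisation (TMM, quantile) is applied: FPKM is used as-is.

## CCG ranking and the SCCM

Each TF's co-expressed gene list is the top *k* (default 100) genes by
descending correlation, ties broken by ascending gene id so lists are a
pure function of the input. The candidate pool is *all* genes: TFs may
appear in each other's CCG lists, and the classification step reports
how many merged CCGs are themselves TFs inside or outside the analyzed
subnetworks. Constant profiles get correlation 0; a constant TF is
flagged and emitted with an all-zero ranking rather than dropped, so
downstream bookkeeping stays aligned.

The SCCM entry for TFs *i*, *j* is the raw intersection size of their
lists (0..k); the diagonal is defined as *k*. Raw intersection — not a
rank-weighted variant — keeps the threshold semantics literal: an edge
exists when two TFs share at least `min_shared` (default 25) CCGs, with
the boundary value retained ("at least").

## Triple-Link decomposition

Seed-and-extend with three explicit rules, all ties broken by ascending
TF id so the decomposition is deterministic:

* **Seed**: the unassigned pair with maximal shared count
  (lexicographically smallest id pair among ties); extraction stops when
  the best remaining pair falls below `min_shared`.
* **Growth**: a candidate qualifies when it has links
  (count ≥ `min_shared`) to at least `min_links` = 3 current members —
  to *all* members while the subnetwork is still smaller than 3. Among
  qualifiers, the one with the greatest summed counts to current members
  is admitted. The admission count of 3 mirrors the "triple link" idea:
  a newcomer must collaborate with three established members, which
  suppresses chains of weak pairwise links; it is configurable.
* **Close**: when no candidate qualifies, the subnetwork is emitted,
  its members leave the pool, and extraction repeats.

Pairs are emitted as size-2 subnetworks; TFs that never join anything
are reported but not emitted. Because extraction only removes pairs
from the pool, seed weights are non-increasing across subnetworks —
earlier subnetworks carry the strongest collaborations. A single
threshold (25) is used throughout rather than a descending schedule.

Subnetwork selection for downstream biology is deliberately *reported,
not automated*: the package emits the PC1 concordance ranking,
annotation summaries and known-gene counts, and leaves the cut to the
analyst.

## PC1 screening

Member profiles are z-scored across samples (each TF weighs equally),
samples are the observations, and PC1 comes from the SVD of the
samples × members matrix. The explained-variance ratio is the first
squared singular value over the total. Concordance is |Pearson r|
between PC1 and the mean member z-profile, so it is invariant to the
arbitrary PC sign; exported PC1 scores are oriented to correlate
non-negatively with the mean profile. Per-tissue-group PC1 means
summarise where along the de-/re-differentiation axis a subnetwork is
active. There is no published numeric criterion for "expression tracks
PC1"; the concordance statistic is this package's operationalisation.
Constant member profiles are excluded with a warning; fewer than two
usable members is an error.

## Hypergeometric enrichment

Both enrichment stages share one kernel: the upper-tail probability
P(X ≥ k) for X ~ Hypergeometric(N, K, n), evaluated via the scipy
survival function (log-space stable). Gene-set enrichment tests every
annotation term; BH adjustment runs across *all* tested terms, with
zero-overlap terms kept in the denominator but dropped from the output.
The default universe is the set of genes surviving the sparsity filter —
the background should match the space actually tested — and is
configurable. Annotation sets are used as given; no ontology-ancestor
expansion is performed. Fold enrichment is (k/n)/(K/N); the default
significance cutoff is adjusted p ≤ 0.05.

Motif enrichment counts genes-with-hit (≥ 1 hit anywhere in the
promoter), not raw occurrences, as the hypergeometric success: the
occurrence total and the percentage of foreground genes with the motif
are reported alongside. Occurrence-level counting would violate the
hypergeometric's sampling-without-replacement model, since one promoter
can host many hits.

## PWM scanning

Promoters are supplied directly as FASTA (default length 2000 bp; a
strand-aware genome-extraction helper exists but is optional, keeping
the core testable without a genome download). PWMs are read from MEME
minimal format (via Bio.motifs) or CIS-BP-style text matrices; zero
cells are floored at 1e-3 and columns renormalised, so log-odds are
finite. Each window on each strand is scored
`sum_j log2(p(base_j, j) / bg(base_j))` and normalised to [0, 1]
against the analytic worst/best scores under the background, so the
consensus scores exactly 1 and the anti-consensus exactly 0. The
default background is the 0-order base composition of the scanned
promoter set (uniform available); the default threshold 0.85 means
"within 15% of the best attainable score". Windows containing N are
skipped. Reverse-strand hits are found by scanning with the
reverse-complemented matrix, which preserves the score multiset under
reverse-complementing the sequence.

## TGMI

Profiles are discretised into 3 equal-frequency bins by rank (ties to
the lower bin), which makes the whole stage invariant to monotone
transforms — raw and log inputs give identical results. Three bins is a
deliberate bias/variance compromise at n ≈ 78: plug-in information
estimates on a 3×3×3 table already carry a bias of roughly
(bins−1)²·bins / (2n ln 2) ≈ 0.11 bits, and finer binning inflates it
quadratically. The permutation null absorbs this bias because null and
observed statistics share the estimator.

Each triple (TF, G1, G2) is summarised by five plug-in quantities: the
TF-coupling informations I(T;G1), I(T;G2) and the conditional profile
I(T;G1|G2), I(T;G2|G1), I(G1;G2|T). The null permutes only the TF's
labels, preserving the G1–G2 joint — the hypothesis under test is
TF-independence. P-values are upper-tail with the add-one estimator
(never exactly 0; floor 1/(n_perm+1)); BH runs per component across all
triples of a run (per-run, not pooled across runs or subnetworks). A
triple is significant when both TF-coupling components pass the
adjusted threshold.

Why the marginal informations gate rather than the conditional ones:
under the common-regulator model this stage targets (both BP genes
responding to the TF), the TF *explains* the G1–G2 dependence.
Conditioning on the true TF therefore pushes I(G1;G2|T) toward zero
while permuting the TF restores the marginal dependence — an upper-tail
test on that component is powerless precisely when the TF is the
genuine regulator, so it is reported as a conditional-independence
diagnostic (small observed value + large null = the TF accounts for the
pair's covariation) but does not gate. Conditioning the TF-coupling
statistics on the correlated partner gene similarly discards shared
signal: at a TF–gene correlation of 0.6 with 78 samples, measured
detection power of the conditional pair falls below one half, while the
marginal pair detects over 90% of such triples at the same calibrated
false-positive rate. All five statistics are exported per triple, so a
conditional-gating rule can be applied post hoc if desired.

The interference frequency counts the *distinct* BP genes a TF shares
at least one significant triple with — a gene repeated across many
triples counts once — so the maximum frequency equals the BP-list size
(6 BP genes give a ceiling of 6). Ranking is by descending frequency,
ties by ascending TF id. BP gene lists are user inputs; no ontology
lookup happens inside the stage.

## Synthetic data generator

The generator reproduces the *shape* of the target compendium —
78 samples in 8 ordered tissue groups (4, 4, 13, 11, 7, 11, 22, 6) —
with three planted structures:

* **Modules**: log-expression of each member is
  loading × factor + N(0, noise_sd), loadings ~ N(1, loading_sd)
  clipped positive; a single shared factor is the simplest model that
  yields overlapping top-k CCG lists within a module and near-zero
  overlap across modules. Factors can carry per-tissue-group mean
  shifts, giving PC1 screening a phase-structured signal.
* **Triples**: each BP gene is an independent baseline plus
  effect × (TF log-profile, centered) + noise — genuine TF→pair
  information flow, making TGMI power measurable. A TF–gene correlation
  of ρ corresponds to effect/noise via ρ = e·σ_T / √(e²σ_T² + σ²).
* **Promoters/annotations**: i.i.d. uniform background sequence with
  PWM-drawn instances placed at recorded positions and strands;
  annotation files with one term of exactly controlled query overlap.

Values map to the positive scale as max(2^logexpr − 1, 0), so the log2
transform recovers log-profiles exactly in the noiseless limit
(within-module correlation exactly 1 — the planted-signal sanity
check). Zero inflation is i.i.d. per entry. One root seed derives
independent per-artifact streams, so regenerating one artifact never
perturbs another and identical configs are byte-identical.

Defaults in the bundled fixture: 400 genes (30 TFs), noise_sd 0.5 in
log2 units (within-module correlations ≈ 0.8–0.95, matching tight
co-expression modules), zero-inflation 0.02, two modules of 8 and 6 TFs
with 60/50 CCGs, four triples with effect 0.9 over six BP genes, k = 50
(scaled with the 400-gene pool so module lists dominate chance
overlap), min_shared 25, 1000 permutations.

What the generator does **not** emulate: read-level count noise and
FPKM quantification error, within-tissue replicate correlation beyond
the shared factor (groups act only through factor mean shifts), batch
effects, and realistic promoter composition (no GC skew, repeats, or
competing motifs). Passing tests therefore demonstrate algorithmic
correctness and calibration under the planted model, not performance on
real compendia. A further small-fixture caveat measured during
development: with only a few hundred background genes, a background TF
whose profile is by chance tilted toward a module factor acquires many
of that module's genes in its top-k list at once (the module moves as a
correlated block) and can be co-admitted to the module's subnetwork;
recovery checks therefore assert that planted members are complete and
co-assigned, not that subnetworks contain nothing else. At genome scale
the effect shrinks with the relative module size.

## Numerical choices

* Ties everywhere (ranking cutoffs, seeds, admission, TF ranking) break
  by ascending identifier — every stage is a pure function of its
  inputs.
* Plug-in information estimates clip tiny negative rounding residues to
  0; permutation comparisons use a 1e-12 tolerance so equal statistics
  count as ties in the null.
* PCA uses SVD of the z-scored member matrix rather than forming a
  covariance matrix.
* Hypergeometric tails delegate to `scipy.stats.hypergeom.sf`; BH to
  `statsmodels.stats.multitest`.
* Pipeline stages cache on SHA-256 input checksums and re-load their
  own TSV outputs, so a re-run with unchanged inputs is byte-identical
  and each stage is independently re-runnable from files.

## Problem sizes

The bundled fixture and the acceptance script use 400 genes × 78
samples, 30 TFs, 1000 permutations and 225 null triples — sizes chosen
so the full pipeline, including permutation testing, completes in a few
seconds on one CPU while leaving every statistical check adequately
powered (the planted-recall condition was verified at 94% detection
over 50 replicates at TF–gene correlation 0.6).

## Known limitations

* The Triple-Link admission rule (3 links, single threshold) is one
  concrete reading of a seed-and-extend family; alternatives (descending
  threshold schedules, rank-weighted SCCM entries) are not implemented.
* Permutation p-values are bounded below by 1/(n_perm+1); with BH over
  many triples, very small target FDRs need more permutations.
* The TGMI gate tests marginal TF coupling; a TF correlated with BP
  genes through a confounder (e.g. shared module membership) can reach
  nonzero interference frequency. This mirrors the behaviour of
  correlation-based regulator screens generally; the conditional
  profile exported per triple is the tool for post-hoc scrutiny.
* Enrichment results inherit whatever bias the chosen universe carries;
  the filtered-gene default is a choice, not a law.
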