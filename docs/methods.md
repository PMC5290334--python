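# Methods

## Scope and data model

The package analyzes miRNA read-count matrices (miRNA × sample,
integer counts) with a sample table assigning each sample to one of
three groups: `unaffected`, `nonprogressed`, `progressed`. All matrices
travel as pandas DataFrames; counts and z-scores serialize as TSV,
metadata as CSV, models and reports as JSON, networks as Pajek `.net`.

## Quantification

Mature miRNAs are counted by exact substring membership per read: a
read containing a miRNA's sequence anywhere increments that miRNA by
one, a read containing two distinct miRNA sequences increments both,
and a read containing the same sequence twice still counts once —
counting is per-read membership, not per-occurrence. No
reverse-complement search is performed (small-RNA libraries are
strand-resolved) and no mismatches are tolerated. The trimmed-isoform
variant removes 2 nt from the 5′ end and 4 nt from the 3′ end of every
canonical sequence before counting; since every trimmed probe is a
substring of its original, trimmed counts dominate canonical counts
row-wise. The low-abundance sample-exclusion threshold is a required
user parameter with no claimed default: what counts as a failed library
depends on the sequencing depth of the study at hand.

## Normalization

1. **Robust-expression filter**: keep miRNAs with ≥ `min_total`
   (default 10 000) reads summed over all samples (inclusive bound).
2. **Superabundance filter**: drop any miRNA holding more than half the
   grand total of reads; such a miRNA dominates every sample's top-k
   mean and would imprint itself on all quotients.
3. **Top-30 quotient**: divide each sample's counts by the mean of that
   sample's 30 largest counts. Any per-sample multiplicative factor
   (library size) cancels exactly. Ties at the k-th largest count are
   broken deterministically (count descending, then miRNA id
   ascending).
4. **Reference z-scores**: standardize each miRNA by the mean and
   sample s.d. (n − 1 denominator) over unaffected-group samples only,
   so "0" always means "typical of unaffected comparison subjects" and
   the high-risk groups are never part of their own scale.

Technical-duplicate QC computes the Pearson correlation of the
duplicate pair's z-columns and its percentile among all n(n−1)/2
sample-pair correlations. "Dropping the k least-concordant miRNAs" is
operationalized as removing the k smallest per-miRNA contributions
(x_i − x̄)(y_i − ȳ) to the centered cross-product — the quantity whose
sum determines the numerator of r.

The null tail P(R > r) for the correlation of two independent
dim-length normal vectors uses the exact t-transform,
`t = r sqrt((dim−2)/(1−r²))` with dim−2 degrees of freedom. At
(r = 0.61, dim = 136) this gives 1.6E−15; published accounts of the
same QC sometimes quote 9.3E−15, which no standard exact null
reproduces — the package reports the exact tail. The one-sided
convention is used throughout because the derived critical value 0.5878
is exactly the one-sided 0.001 quantile at n = 25.

PCR concordance: Cq matrices are mean-centered per subject (missing
values drop out of the average), and per-subject Spearman correlations
are computed between −Cq and read counts — Cq falls as abundance rises,
so concordance is reported on the positive scale (`negate_cq=False`
restores the raw orientation).

## The CALF classifier

CALF performs greedy forward selection over markers with weights
restricted to {+1, −1}. Iteration 1 picks the marker minimizing the
two-sided pooled-variance Student t-test p-value between the two
classes, signed so the classifier increases with risk (positive class
mean higher). Every later iteration evaluates each unused marker with
both signs added to the running sum and accepts the best candidate only
if it strictly lowers the p-value; selection stops at `max_markers`
(default 6) or at the first iteration with no improvement. Ties break
deterministically (smaller p, then lexicographically smaller miRNA id,
then +1 before −1). Zero-variance candidates receive p = 1 and are
thereby never preferred. Candidate signs are re-searched at every
iteration rather than fixed once per marker — the more general
procedure, which reduces to the pre-oriented one whenever
pre-orientation is optimal.

Coarse weights are the point: refitting real-valued coefficients on
perturbed subsets rarely reproduces identical values, whereas ±1
weights frequently reappear verbatim, which is what the stability
selection stage counts.

AUC is the Mann–Whitney probability (ties count ½), computed by rank
sums and identical to brute-force pair counting. ROC curves are
empirical over all thresholds; the confidence band is a pointwise
percentile bootstrap (classes resampled independently) of sensitivity
on a fixed 1−specificity grid.

## Resampling validation

The framework validates the model-building *procedure*, not a fixed
score vector:

* **Permutation null** — class labels of the two compared groups are
  permuted (class sizes preserved; the unaffected reference group is
  never permuted, since it defines the z-score scale), the entire
  greedy training re-runs per permutation, and the training AUCs form
  the null. "Exceeds" is strict (pseudo > true); the add-one Monte
  Carlo p-value is (k+1)/(N+1). A maximum-likelihood beta fit to the
  pseudo AUCs provides a smooth alternative p-value that can
  extrapolate beyond the observed null range; if the MLE does not
  converge (heavily tied pseudo AUCs at small n) the beta p-value is
  reported as NaN and the rank-based p-value stands.
* **Stability selection** — per trial, an independent uniform
  without-replacement subset of ⌊0.8 · class size⌋ from each class;
  counts tally how often each marker is selected, sign-blind.
* **Integration** — markers selected in at least `min_count` stability
  trials *and* present in the full-data model are retained with the
  full-data weights; an empty intersection raises rather than returning
  an empty classifier.
* **Subset robustness** — the fixed integrated model is scored on
  random 25+25 subsets; the medication-confound variant fills each
  subset with all flagged (or all unflagged) samples first.

Training AUCs of pseudo classifiers sit well above 0.5 even on pure
noise — the greedy search overfits by construction, which is exactly
why the null must re-run the whole search rather than re-score a fixed
model.

## Correlation networks

For each group, `n_trials` (default 1000) random subsets of
`subset_size` (default 25) samples are drawn; Pearson correlations of
all node pairs (default: the 40 most abundant miRNAs, 780 pairs) are
computed per subset; a pair becomes an edge when r strictly exceeds the
critical value in strictly more than `edge_min` (default 500) trials.
The critical value is the one-sided upper `p_tail` quantile of the null
correlation at the subset size, by inversion of the t-transform —
0.5878 for (0.001, 25) — and is mutually inverse with the tail function
to 1e−9. Under an iid null the expected exceedance count is
780 × 0.001 = 0.78 per trial, and no pair approaches the majority rule;
the frequency rule thus substitutes for explicit multiple-testing
control. Negative correlations never create edges. Undefined subset
correlations (constant node) count as non-exceedance. Node sets are
preserved under thresholding so a miRNA absent from one group's edge
set remains visible as an isolated node in comparisons.

## Sequence similarity

Smith–Waterman local alignment with linear (per-symbol) gap penalty and
zero floor; defaults match +1, mismatch −1, gap −1. One optimal
traceback's match/mismatch/gap decomposition is returned and always
reconstructs the score. Sequence canonicalization uppercases, maps
T→U, and strips non-letter noise (stray punctuation in transcribed
sequences). The panel test draws `n_trials` same-size panels from a
disjoint background pool, averages each panel's C(k,2) pairwise scores,
and counts null means **at or above** the observed mean (inclusive);
the p-value is again add-one Monte Carlo. Pool pair scores are aligned
once and reused across draws. The embedded `RISK_PANEL_V21` constant
carries the miRBase v21 mature sequences of the five-miRNA leukocyte
risk panel (miR-941, miR-103a-3p, miR-92a-3p, miR-199a-3p, miR-31-5p);
their ten pairwise unit-weight scores average 6.4.

## Synthetic cohorts

The generator emulates a 27/37/30-subject, 136-miRNA cohort of robustly
expressed miRNAs:

* **Counts**: negative binomial (dispersion α, default 0.01 — technical
  overdispersion typical of high-count features) around a log-normal
  latent mean with biological log-s.d. σ (default 0.3, between-subject
  CV ≈ 35%); baseline abundances log-normal across miRNAs with a floor
  that keeps every row above the default robustness filter at cohort
  scale.
* **Library size**: one multiplicative factor per sample, log-uniform
  on [0.5, 2], hence removed exactly by quotient normalization.
* **Planted markers**: default five (three down, two up in the
  progressed group) at 1.2 reference-s.d. Effects are stated as the
  standardized (pooled-s.d.) group difference the analysis observes; a
  multiplicative count model cannot realize that with a naive log
  shift, so the planted log-shift is calibrated in closed form
  (`u = e^δ = [1 + sqrt(c(2−c))]/(1−c)`, `c = (effect·CV)²/2`), which
  is symmetric under up/down regulation and bounded by
  `effect·CV < √2` — the largest standardized difference a
  multiplicative shift can produce.
* **Co-regulation**: one latent factor per sample with fixed Rademacher
  (±1) per-miRNA loading signs and weight √strength, giving
  equally-loaded pairs a correlation of ≈ +strength (opposite pairs
  ≈ −strength). Loading signs must vary across miRNAs: a factor
  loading every miRNA identically is indistinguishable from library
  size and is cancelled exactly by quotient normalization. Planted
  miRNAs carry no loading so their group effect stays clean. Defaults:
  0.85 / 0.85 / 0.30 for unaffected / nonprogressed / progressed,
  reproducing the qualitative contrast of dense correlation networks in
  the first two groups and a sparse one in the third.
* **Technical duplicates**: log-counts plus iid normal noise, rounded
  back to integers. **Reads**: each read embeds exactly one sampled
  miRNA at a random offset with rejection-sampled flanking bases that
  never create a second exact match.

What the generator does **not** emulate: isomiR biology beyond the
fixed trim proxy, adapter contamination, sequencing error, batch
effects, clinical covariates beyond a binary medication flag, or
realistic sparse network topology (the single-factor design makes all
equally-loaded miRNAs one correlated block). Passing tests therefore
demonstrate correctness of the machinery under the assumed generative
model, not clinical validity on real cohorts.

## Numerical and design choices

* Sample s.d. everywhere uses the n − 1 denominator.
* Strict inequalities: "exceeds" for correlation thresholds and pseudo
  AUCs, "> edge_min" for network edges; inclusive "≥" only for the
  similarity null (deliberately conservative under ties).
* Per-stage seeds derive from a master seed by CRC32 of
  `"<master>:<stage>"`, all below 2³¹, so stages re-run in isolation
  reproduce their in-pipeline draws; identical configuration implies
  byte-identical reports.
* The descriptive observation that normalized values span about a 4×
  range in the motivating study is treated as descriptive only; no
  winsorization or clamping is applied.
* Degenerate inputs: zero-variance t-test inputs yield p = 1 with a
  warning; constant columns make correlations undefined and raise;
  all-sample exclusions and empty model integrations are hard errors.

## Problem sizes in the test suite

The shipped tests run the full resampling machinery at reduced scale
chosen to exercise every code path with comfortable statistical power:
permutation type-I control uses 400 replicates of 200 permutations on
40-marker, 15+15-sample null cohorts; planted-marker recovery uses 50
generator seeds at the full 27/37/30 × 136 design; null-network
sparsity uses 20 seeds of 1000 trials; the Smith–Waterman oracle
battery uses 200 random short pairs. Full-scale runs (1000 permutations
and subsets) are the library defaults.

## Known limitations

* The greedy search optimizes the training metric and overfits by
  design; all performance claims must come from the resampling
  framework, never from training AUCs.
* With the default six-marker limit and 1.2-s.d. planted effects, the
  greedy recovers ≥ 4 of 5 planted markers in roughly 70–80% of
  cohorts — later iterations sometimes prefer noise markers that
  complement the running sum over genuine markers with weaker realized
  effects. This is a property of training-metric greedy selection, not
  an implementation defect; stability selection is the intended remedy.
* The beta-fit p-value depends on the fitted family far in the tail;
  the rank-based Monte Carlo p-value is the primary quantity.
* Exact-substring quantification undercounts genuine isomiRs other than
  the fixed trim proxy and cannot handle sequencing errors.
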