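# Methods

## Problem setting

Interaction databases record which drug-target pairs *do* interact;
non-interactions are almost never deposited. A classifier trained on
"known positives vs randomly sampled negatives" therefore learns from a
negative class contaminated with hidden positives. This package treats
the task as positive-unlabeled (PU) learning: from a positive set P and
an unlabeled pool U it (i) extracts a reliable-negative set RN and an
extracted-positive set EP, (ii) assigns the remaining ambiguous pairs A
soft class-membership weights, and (iii) trains a weighted-slack SVM
that uses all three groups.

## Pair representation

Each pair is the concatenation F = [G; O; A; B]:

- **G** — drug descriptors, ingested as a dense table (1444 PaDEL
  columns at the published scale). The package never computes chemical
  descriptors itself; any column count is accepted and recorded.
- **O** — binary protein-domain indicator over a fixed, ordered
  vocabulary (1331 human PFAM domains at scale). Annotations outside the
  vocabulary are ignored with a warning.
- **A** — Chou's type-I pseudo amino acid composition with lambda = 30
  (50 entries). Sequence-order correlation factors average squared
  differences of hydrophobicity, hydrophilicity and side-chain mass,
  each standardized to zero mean / unit variance over the 20 residues;
  the weight w = 0.05. These property tables and w are the canonical
  published defaults — the surrounding method cites PAAC without fixing
  them, so they are this package's choice.
- **B** — 400 bi-gram features of the PSI-BLAST PSSM,
  B[i,j] = sum_k T[k,i] T[k+1,j]. The raw log-odds are squashed
  elementwise through 1/(1+e^-s) before the bi-gram sum so B is scale
  bounded; the source bi-gram method normalizes scores to (0,1), and raw
  log-odds would make B unbounded. A `transform="none"` escape hatch
  exists for analysis.

At the published scale the protein block is 1781-d and the pair vector
3225-d.

## Feature selection

Each feature gets da(f) = (as_P + as_U) * ln(|P|/as_P + |U|/as_U) with
natural log, where as_S counts samples of S "having" f. Columns whose
observed values are within {0,1} are used as-is (present iff 1); other
columns are binarized once at their strict median over P ∪ U (a
`nonzero` mode is available). Zero counts are replaced by 0.5 inside
the ratios only, a standard continuity correction. The top-k (default
300) features by da are kept, ties broken toward the lower feature
index.

Limitation worth knowing: the count factor (as_P + as_U) means that with
|U| >> |P| the score is dominated by overall frequency in U, and a
moderately class-shifted continuous feature may rank below a frequent
uninformative one. The score behaves as intended when the pools are
comparable in size or the discriminative features are strongly
unbalanced. This is a property of the published score, reproduced
faithfully.

## Reliable-negative extraction (consensus of two PU learners)

- **Spy classifier.** ceil(spy_ratio·|P|) positives (default 15%) are
  planted into U. A Gaussian naive Bayes model (per-feature normal
  likelihoods; the features after selection are continuous or binary,
  so the multinomial text model of the original spy technique does not
  apply) is refined by EM: labeled positives keep responsibility 1,
  the unlabeled side's positive responsibilities are re-estimated until
  the largest change falls below 1e-4 or 50 iterations (non-convergence
  warns and uses the last iterate). The negative threshold is the 5th
  percentile of spy posteriors; unlabeled samples below it are negative.
- **Rocchio classifier.** c+ = 16·mean(x/|x| over P) − 4·mean(x/|x| over
  U), c− with roles swapped; a sample is positive iff it is strictly
  more cosine-similar to c+ than to c−.
- **Consensus.** RN = both negative, EP = both positive, A = the rest.
  EP joins P for all downstream stages. The positive consensus rule
  mirrors the stated negative rule. An empty RN is an error, since
  downstream training needs a negative class.

The AND rule makes RN high-precision by construction; EP inherits the
spy side's permissive positive rule and is therefore *not*
high-precision, which matters at desk scale (see Limitations).

## Similarity weights of ambiguous samples

RN is split into a = round(t·|RN|/(|A|+|RN|)) k-means modules (t = 30
total budget; "U" in the published count formulas is read as the
ambiguous remainder, so the RN and ambiguous clusterings share the
budget: a + n ≈ t). Each module i yields a prototype pair by the same
Rocchio construction (alpha = 16, beta = 4): n_i from the module against
P, p_i from P against the module.

- **Local:** A is split into n = round(t·|A|/(|A|+|RN|)) k-means
  clusters; each member is temporarily tagged positive iff its best
  positive-prototype cosine strictly beats its best negative-prototype
  cosine (ties tag negative — conservative toward not inflating the
  positive side); every member of a cluster shares (pos fraction, neg
  fraction).
- **Global:** GloP = sum_i sim(x,p_i) / sum_i (sim(x,p_i)+sim(x,n_i)),
  with cosines floored at 0 so the pair stays in [0,1]; if everything
  floors to zero the sample gets (0.5, 0.5) with a warning. Zero-norm
  vectors have cosine 0 against anything.
- **Combined:** W^P = (1−alpha)·LocP + alpha·GloP with balance
  alpha = 0.6; likewise W^N. All three pairs sum to 1 per sample and
  this is asserted on every run.

k-means uses k-means++ with 10 restarts on a seeded stream; cluster
counts round to nearest and floor at 1 with a warning.

## Weighted-slack SVM

The training objective penalizes slack per group: C1 on P, C4 on RN,
and for each ambiguous x both C2·W^P(x) toward the positive side and
C3·W^N(x) toward the negative side. The problem is solved by reduction
to a per-sample-penalty C-SVM: each ambiguous sample contributes two
rows with opposite signs and its two scaled penalties, giving the dual
per-row box constraints 0 ≤ lambda_r ≤ c_r. Rows with penalty below
1e-12 are dropped (their constraint is vacuous). The box-constrained QP
itself is solved by libsvm through scikit-learn with per-sample
weights; tests verify the reduction against an independent generic
convex-QP solution (SLSQP on the dual) to 1e-5 on random instances.
Kernel is RBF with gamma defaulting to 1/(number of selected features);
solver tolerance 1e-6 by default, bias from margin support vectors. A
test point is positive iff its decision score is strictly positive — a
score of exactly 0 is negative.

The penalty grid for search is powers of two over exponents [-5, 5].
The published description of the grid step is internally ambiguous
(a multiplicative step of 2^-4 over that range gives 161 points per
parameter, infeasible as a 4-D product), so the exponent step is
configuration (default 0.5) and the search by default ties C1..C4 to a
single value; the full 4-D product is available. Ties prefer smaller
penalties, then smaller gamma.

## Evaluation protocol

Repeated pairwise cross-validation: each trial partitions all pairs
into `folds` (default 5) random, roughly equal subsets; each fold is
held out with labels masked, and inside the training portion r percent
(default 30) of known interactions form P while everything else joins
U. The entire pipeline is refit from scratch per fold. Masked known
interactions count as positives and masked unlabeled pairs as
negatives — the gold-standard convention in this literature; AUC is
computed from decision scores (Mann-Whitney, ties one half), precision
and recall from the strict sign rule, with zero denominators defined as
0 under a warning. A leakage assertion (training ids disjoint from test
ids) runs on every fold. A `baseline="random"` mode replaces the
consensus extractor with uniform random negatives at three negatives
per positive — mirroring the common negative-ratio-3 practice — and a
plain two-class SVM.

Note that pairwise CV (masking pairs, not whole drugs or targets) lets
entity-level regularities cross folds: a promiscuous drug's training
pairs inform its test pairs. Cold-start splits are deliberately out of
scope.

## Synthetic data: what it emulates, and what it does not

The generator draws latent vectors per drug and target, scores pairs
with a logistic of the latent dot product, and marks the top
`positive_rate` fraction as truly interacting, so interaction hubs
arise naturally. Features are per-entity blocks (drug half, target
half) with per-pair Gaussian noise on continuous columns and rare flips
on binary columns (binary_fraction 0.4 ≈ the domain-indicator share of
real representations); `n_informative` evenly spaced columns carry the
class signal — a mean shift of `effect_size` for continuous columns, a
raised Bernoulli rate for binary ones. Only `label_rate` of true
interactions are revealed; the generator records ground truth for every
pair.

Default conditions: 200 drugs × 50 targets (10 000 pairs), positive
rate 0.03, label rate 0.3, effect size 1.0, noise sd 1.0, 50 features
of which 15 informative, latent dimension 4, seed 11. The 10 000-pair
scale keeps a 20-seed extraction study in seconds; pipeline-level
cross-validation studies use a smaller 80 × 12 layout with 40 features
so a 10-seed × 5-fold full-pipeline run stays fast.

The generator does not emulate real descriptor distributions (PaDEL
value ranges, domain co-occurrence, PSSM structure), assay noise, or
biased database deposition. Passing tests on it show the machinery is
correct and that extraction recovers planted structure; they do not
certify performance on any real corpus.

## Known limitations

- On well-separated synthetic data the *pipeline's* ranking advantage
  over the random-negative baseline does not materialize even though RN
  precision is clearly superior: the consensus EP set (whose positive
  rule is permissive by construction) dilutes the positive class, and
  RN is a biased, "easy" subset of the negatives, so a plain SVM on
  P plus random negatives can rank better. The advantage claimed for
  the method lives in regimes with heavily contaminated unlabeled pools
  and harder class geometry than the desk-scale generator produces.
  The package reports both pipelines so users can compare on their own
  data.
- The spy EM uses a Gaussian naive Bayes event model; heavily
  non-Gaussian continuous descriptors may violate it.
- The discriminant-ability score's frequency bias (above).
- Algorithmic determinism holds given a seed; k-means restarts make
  cluster identities, not memberships, seed-dependent.
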