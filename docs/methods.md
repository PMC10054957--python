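# Methods

## Model

`pepnb` scores a candidate peptide x for presentation by one HLA class I
allele with a naive Bayes classifier trained on presented peptides only.
The generative assumption is that, conditional on class, the 29 features
of x are independent with equal weight, so

    p(+ | x) = 1 / (1 + (p(−)/p(+)) · Π_f P(f(x)|−) / P(f(x)|+)).

Because non-presented peptides are never observed experimentally, the
negative class is modeled as random protein sequence: P(f|−) for a
single-position feature is the background amino-acid frequency, and for a
position-pair feature the product of the two background marginals (the
residues of a random non-binder carry no dependency). This removes both
the need for sampled decoys at training time and the sampling variance
they would introduce. All accumulation is in log space; the score of
record is the total log odds ratio, since the prior odds p(−)/p(+) shift
every peptide's probability identically and can never reorder candidates.

### Position labels

Binding specificity concentrates near the peptide termini, so positions
are named by terminal distance: labels 1–5 from the N terminus, 7–9 and 0
(the C-terminal residue Ω) from the C terminus; label 6 does not exist.
The scheme is length-invariant across 8–13-mers, which lets one model
serve all lengths. Two conventions needed fixing where the naming rule is
silent:

* **8-mers** have one residue carrying both labels 5 and 7 (the fifth
  residue is also the fourth from the end). That residue is tallied under
  *both* labels during training and read under both at scoring, so every
  feature is defined for every length. Dropping one label instead would
  leave a feature undefined for 8-mers.
* **11–13-mers** have 2–4 unlabeled middle residues; they contribute to
  no feature. This is deliberate: the middle of long ligands bulges out
  of the groove and carries little binding signal.

### Feature selection

Dependencies between positions within an allele's peptidome ("interactive
motifs") are measured by the plug-in mutual information
I(f_i;f_j) = H(f_i) + H(f_j) − H(f_i,f_j) on the 20×20 joint count table,
in nats. Of the 36 unordered label pairs, the 10 highest-MI pairs on the
pooled training data of all alleles are the pan-allelic features; each
allele then contributes its own top-10 pairs, skipping pan-allelic keys
(taking the 11th, 12th, … best) until ten distinct ones accumulate. With
the nine singles the feature count is always 29. Choices made here:

* **Estimator.** Plug-in (maximum-likelihood) entropies, zero-count cells
  contributing zero. No bias correction: the plug-in bias
  (≈ (K−1)/2n nats) is nearly uniform across the candidate pairs at fixed
  n, so it barely perturbs the *ranking*, which is all selection uses.
* **Log base.** Natural log throughout. The base rescales every MI by the
  same constant, so the selected set is base-independent; nats were chosen
  to match the log-odds scores.
* **Ties** break lexicographically on the canonical label order
  1,2,3,4,5,7,8,9,0, making selection deterministic and seed-free.
* **Pooling.** MI is computed on all lengths pooled through the label map
  rather than per length; 8-mers contribute their shared residue to both
  labels 5 and 7. A side effect is that the (5,7) pair shows inflated MI
  whenever 8-mers are present (the two labels coincide there); this is a
  property of the naming scheme, not an artifact of the estimator, and
  the pair is eligible for selection like any other.

### Smoothing

Conditional tables P(f|+) are Laplace-smoothed with pseudo-count α = 1 per
cell (20 cells for singles, 400 for pairs) by default — the simplest
estimator guaranteeing strict positivity. A BLOSUM62 strategy is provided
for ablation: the same total pseudo-mass (α · #cells) is distributed
according to a row-stochastic substitution kernel
K(a|b) ∝ p(a)·2^{s(a,b)/2} derived from the BLOSUM62 half-bit log-odds
scores (pairs use the kernel independently on both positions), so sparse
tables borrow strength from biochemically similar residues. In practice
additive smoothing discriminates better — substitution matrices encode
sequence *evolution*, which is not the process generating positional
dependencies in presented peptides.

### Background frequencies

The default background is the Swiss-Prot release-wide amino-acid
composition built into the package (`BackgroundModel.natural()`);
`from_proteome()` tallies a user-supplied FASTA (with one pseudo-count per
residue so tiny proteomes stay strictly positive), and `uniform()` is
available for sensitivity checks. The built-in natural table, rather than
a uniform fallback, is the default because "random protein sequence" is
the intended negative model and uniform composition misstates it by up to
two-fold per residue.

### Prior odds

Default p(−)/p(+) = 10⁵ − 1, i.e. one presented peptide per 10⁵ random
candidates. With neutral evidence (log odds 0) the posterior is exactly
10⁻⁵. The large prior also keeps posteriors away from saturation at 1,
where double-precision probabilities collapse into ties; the log odds
score itself never saturates and is what `rank_peptides` sorts by.

## Deconvolution

A patient's eluted pool mixes peptides from up to six allotypes
(homozygous duplicates collapse). One round of pseudo-labeling is the
default cycle: score every eluted peptide under each allotype's
public-data model, assign it to the top *two* allotypes, add assignments
to both alleles' training sets, re-run feature selection on the augmented
data, refit. Assigning to two alleles hedges the label noise of hard
assignment at the cost of some cross-contamination; `top_k=1` restricts
to the best allele, and `rounds` iterates the cycle. Allotypes with no
public data are seeded by `fallback_assign`: the eluted peptides whose
maximum log odds under every modeled allotype falls below τ (default 0 —
evidence does not favor binding to any modeled allele). τ = 0 is the
parameter-free reading of "not confidently claimed"; raising it grows the
orphan seed set at the cost of purity.

## Benchmarking

Decoys are contiguous substrings of a proteome — real sequences, not
residue shuffles — drawn uniformly over eligible window start sites, 99
per positive. Draws colliding with a positive (or containing non-canonical
letters) are redrawn so the 1:99 ratio is exact; when rejection sampling
stalls, the sampler enumerates the eligible windows of that length and
either samples from them directly or raises an exhaustion error. Decoy
lengths follow the positives' empirical length distribution, removing
length as a confounder. Duplicate decoys are allowed (`unique=True`
forbids them); only coincidence with positives is excluded.

Metrics use ≥-threshold semantics with ties treated identically.
Precision at 40% recall takes the highest threshold whose recall is at
least the target (exact equality is generally unattainable on finite
sets); the reverse calibration reports the threshold reaching a target
precision with maximal recall, returning recall 0 with a warning when the
target is unreachable. AUROC equals the tie-adjusted Mann–Whitney
statistic. Curve computation is delegated to scikit-learn; the test suite
checks both directions against exhaustive threshold sweeps and an O(n²)
pairwise count.

## Synthetic data

The generators produce the statistical structure the estimators must
recover, with analytically known truth:

* **Allele peptidomes**: per-label marginal distributions (PWM columns),
  i.i.d. positions, plus planted couplings — with probability λ a pair's
  residues are redrawn from a 20×20 joint. The λ-mixture construction
  keeps the generator's true MI computable for oracle tests; λ = 0
  recovers exact independence. The realistic preset uses anchor weight
  0.7 at labels 2 and 0 (e.g. 70% leucine at P2, the rest following
  natural frequencies) and a mild 0.25 preference elsewhere, matching the
  anchor-dominated look of real eluted data. "Strong" alleles in the
  end-to-end discrimination checks use anchor weight 0.9 —
  near-deterministic anchors; at the realistic 0.7 the 1:99
  precision-at-40%-recall bound of 0.5 is not robust to seed choice.
  On 8-mers the shared label-5/7 index samples from the label-5 column,
  so the fitted label-7 marginal is analytically the length mixture
  p(L=8)·pwm₅ + p(L>8)·pwm₇ — the recovery tests compare against that.
* **Proteomes**: i.i.d. sequences at natural composition, Poisson lengths
  around 350.
* **Patients**: mixtures of allele generators with known proportions;
  truth labels are emitted for evaluation but never shown to the method.

Not emulated: MS detectability bias, missed cleavages, chimeric spectra,
peptides shared between alleles, or real anchor co-occurrence structure.
Passing tests therefore demonstrate estimator correctness and the internal
consistency of the pipeline, not expected performance on real
immunopeptidomics data.

## Problem sizes and numerical choices

The default suite and the acceptance script run at sizes chosen to make
the statistical assertions stable: MI oracle checks on ≤200 peptides,
PWM recovery at n = 5000 (TV ≤ 0.03), coupling recovery over 100
replicates of 800 peptides, deconvolution on 2–6-allele patients with 250
public peptides per allele and 300-peptide pools, benchmarks at 100
positives × 99 decoys each. Degenerate inputs fail loudly: empty training
sets, single-class score sets, zero-variation corpora and exhausted decoy
pools raise typed errors rather than returning NaN. Model JSON round
trips are bit-exact (background frequencies are only re-normalized when
they do not already sum to 1).

## Known limitations

* Pair conditionals are estimated on 400-cell tables; below a few hundred
  training peptides they lean heavily on the smoothing prior.
* The pan-allelic feature list is only as pan-allelic as the training
  panel is diverse.
* The naive Bayes independence assumption double-counts evidence shared
  between overlapping features (e.g. a single and a pair containing the
  same position); scores remain well-ordered but are not calibrated
  likelihoods, which is why the probability is reported with its prior
  explicitly.
* Deconvolution accuracy degrades as allotype motifs overlap; the
  synthetic patients use well-separated anchors and so bound performance
  from above.
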