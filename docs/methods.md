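# Methods

## The median-confidence procedure

The core statistic compares the population medians of two independent
groups without distributional assumptions. For a sample of size $n$ from a
continuous distribution, the number of observations below the population
median is Binomial($n$, ½), so
$P(\mathrm{med} < x_{(i)}) = P(Y \le i-1)$ and
$P(\mathrm{med} > x_{(j)}) = P(Y \ge j)$ hold for every distribution.
Treating the groups as independent, the confidence in the claim
$\mathrm{med}_A < \mathrm{med}_B$ for an order pair with
$a_{(i)} < b_{(j)}$ is the product of the two tails. The implementation
maximizes this product over the full $(i, j)$ grid for both directions and
reports the better one. After the data are seen, the probability statement
becomes a *confidence* statement — the quantity is post-data and should
not be read as a frequentist p-value or a posterior probability.

Numerical choices:

- Tails are computed from exact integer binomial coefficients
  (`math.comb`), so the only floating error is the final division; at
  $n = 25$ the tail $P(Y \le 17) = 0.978357\ldots$ is exact to machine
  precision.
- Admissibility is **strict** ($a_{(i)} < b_{(j)}$); tied values never
  satisfy the constraint. This is the conservative reading for data with
  ties: with all ranks tied across two samples of 25, the attainable
  product stays below 0.90 and nothing is flagged at the miR threshold.
- Because $P(Y \le i-1)$ is increasing in $i$ and $P(Y \ge j)$ decreasing
  in $j$, only the largest admissible $i$ matters per $j$; the search is
  $O(n \log n)$ per direction and verified against brute-force grid
  enumeration in the tests.
- An exact tie between the two directions' maxima (including the all-tied
  case, where no admissible pair exists) yields an *indeterminate*
  statement with confidence 0.

Differential-expression thresholds are 0.90 for miRs and 0.80 for genes
and proteins, applied per molecule with **no multiple-testing
correction**. This mirrors the source analysis design; users scanning
thousands of molecules should expect the null flag rate implied by the
threshold (observed ≈ 2–4 % at τ = 0.90 with $n = 25/25$ in the
synthetic checks) and treat flagged lists as candidate sets, not
error-controlled discoveries.

## Preprocessing

**qPCR.** A miR is excluded when its CT exceeds the detection limit
(default 38) in strictly more than 60 % of samples; CT exactly at the
limit counts as detected. Retained-but-undetected entries are
floor-imputed at the limit before transformation — the least-information
choice, keeping $2^{-\Delta CT}$ defined while acknowledging the value is
only a bound. Per sample, the reference is the median CT of the
*detected* endogenous controls (defaults RNU44, RNU48, MammU6);
expression is $2^{-(CT - \mathrm{ref})}$. A sample in which every control
is undetected is an error naming the sample. Adding a constant to every
CT of a sample (a plate efficiency shift) leaves that sample's
expressions unchanged, which the tests assert.

**Microarray.** A probe is removed when its low-signal flag covers
strictly more than 30 % of the samples of *at least one* group (the
per-group rule keeps genes expressed in only one group). Replicate probes
collapse to the gene level by the arithmetic mean; genes losing all
probes are dropped and listed. Between-sample normalization is quantile
normalization — every sample's sorted vector becomes the cross-sample
mean of order statistics. This is the package's own reproducible stand-in
for platform-vendor normalization chains; since the downstream statistic
is rank-based within each molecule, the choice mainly affects the index
classifier's ratios, not the direction statements.

**Protein (RPPA-like) input** is taken as already loading-corrected and
linear; the package applies no further normalization.

## Target integration

Predicted (miR, target) pairs are retained when supported by at least 3
of 7 prediction sources. Regulation calls are made only for pairs whose
*both* members are flagged differential with a determinate direction
(requiring the miR too, not only the target, is a documented choice):
opposite directions give *inverse*, equal give *concordant*. At the
protein layer a protein counts as inversely regulated when **any** of its
differential regulator miRs opposes its direction — a protein with mixed
regulators is inverse; this is the only rule consistent with the packaged
24-protein panel's 15/9 split, which the tests pin. mRNA–protein
concordance requires equal directions and both confidences ≥ 0.80; a
missing confidence (a target quantified only by follow-up qPCR) can never
reach the threshold and is flagged explicitly rather than guessed.

## Pair-ratio index classification

The index of a sample is $\prod_k v_{u_k} / v_{d_k}$ over selected
(up, down) molecule pairs, so up-group samples score high. The default
orientation is directional (up-member over down-member); a literal
max-over-min orientation is available as a switch because the field's
phrasing of such indices is ambiguous. Non-positive values are replaced
by a pseudo-value $\varepsilon = 10^{-6}$ to keep the index finite.

Cutoffs live on the log scale, where the index is additive over pairs and
ratios are symmetric: candidates are geometric midpoints between adjacent
distinct index values, scored by Youden's $J$ for the rule
index ≥ cutoff → up-group, ties resolved toward the smaller cutoff.

Selection ranks all (up, down) combinations of flagged opposite-direction
molecules by the product of member confidences (ties broken
lexicographically) and adds pairs greedily, **never reusing a molecule**
— $k$ pairs always involve $2k$ distinct molecules. Without this
constraint a single molecule with one outlier sample can dominate every
top-ranked pair and cap the achievable accuracy; with it, pair noise
averages out and the planted-data checks reach perfect leave-one-out
classification. After each addition the pair set is evaluated by
leave-one-out (the cutoff is refit in every fold; the pair set itself is
selected once on the full data, a mild optimism shared by the emulated
design), stopping when sensitivity and specificity targets (defaults
0.85/0.85) are met or the budget (default 4 pairs) is exhausted; if the
targets are unreachable the best prefix by $J$ is returned with a warning
flag. A knowledge-based restriction of candidate molecules (e.g. to
cancer-associated genes) is supported as a user-supplied allow-list, not
hard-coded. The sklearn wrapper (`PairRatioIndexClassifier`) exposes the
same machinery as fit/predict with `pairs_`, `cutoff_` and `report_`
fitted attributes.

## Dichotomization and association

Per-molecule expression is dichotomized at the Youden-optimal midpoint
cutoff with the AUC computed as the rank (Mann–Whitney) statistic, ties
counted half, oriented so "over" aligns with the higher-median group.
Constant input yields AUC 0.5 and a rule flagged degenerate. The under/
over labels are crossed with a dichotomous clinical variable; association
uses the **uncorrected** Pearson chi-square by default (this choice
reproduces the reference study's stage-column p-values on the packaged
counts, e.g. 13.256 on 1 df for the strongest miR–stage table), with the
two-sided Fisher exact test available where margins are small or zero.
Samples missing the clinical value are dropped pairwise and counted.
Note the packaged tumor-size counts do not reproduce some of the
originally reported tumor-size p-values under either test variant; only
the stage cells are used as pinned regressions.

Surrogate luminal subtyping: ER+ iff ≥ 10 % stained nuclei, PR+ iff
≥ 20 %, Ki67 high iff ≥ 14 %, HER2+ iff 3+ or FISH-positive 2+ (an
unresolved 2+ raises an explicit error). Luminal A = ER+ PR+ HER2− with
low Ki67; luminal B = ER+ HER2− with high Ki67 and/or PR−, or any ER+
HER2+; ER− records are not luminal. Every valid ER+ record maps to A or
B (property-tested).

## Synthetic data: what it emulates and what it does not

The generator plants a known truth so every stage is testable without
access to patient data. Defaults encode the emulated study conditions:
25 + 25 samples, 100 miRs with 3 endogenous controls, detection limit 38,
8 % of molecules planted (round(fraction × n), directions alternating
up/down from the first molecule), shift of 3 within-group SDs.

Base distributions are deliberately simple location-shift models: CT ∼
Normal(28, 2) (up-regulation lowers CT), controls Normal(24, 0.5) with no
group effect, array log2 ∼ Normal(8, 1.5) with replicate-probe noise
SD 0.3, protein log2 ∼ Normal(4, 1) exponentiated to the linear scale. A
trailing 15 % of null miRs are "unexpressed": each sample exceeds the
detection limit with probability 0.75, exercising the 60 % exclusion
rule. A 10 % "dim gene" subset carries tripled flag probability to
exercise the 30 % probe filter. The prediction map gives every planted
(miR, target) pair 3–7 supporting sources and every decoy 0–2, so the
vote filter separates them by construction. Clinical dichotomous
variables are drawn with group probabilities ½ ± effect/2 (effect 0 =
exchangeable, 1 = perfectly separating), independently per variable.

Not emulated: real TLDA/Agilent/RPPA noise shapes (heteroscedasticity,
probe cross-hybridization, spatial slide effects), batch structure,
correlated molecules, survival outcomes. Passing tests therefore show
the *procedures* are implemented correctly and calibrated under clean
location-shift conditions — not that the specific molecules reported for
any real cohort would be recovered.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds carried in
configs; pipelines are byte-identical across reruns. The Monte-Carlo
checks use 10,000 draws for coverage calibration (tolerance: 3 binomial
standard errors) and 200 seeded replicates for planted-truth recovery,
with the gene/protein layers kept small in the recovery study since only
the miR layer enters those checks. The gene-count defaults
(200 genes, 30 proteins) keep a full pipeline run in the low seconds.

## Known limitations

- The confidence maximization assumes continuous data; heavy ties lower
  attainable confidence (by design) but the procedure does not model
  discreteness beyond strict admissibility.
- Greedy, confidence-ranked pair selection is not globally optimal; it
  mirrors the emulated sequential design rather than exhaustive subset
  search.
- Leave-one-out refits only the cutoff, not the pair selection, so the
  reported sensitivity/specificity carry some selection optimism.
- Quantile normalization assumes the bulk of genes are non-differential;
  with very wide planted fractions it can attenuate true shifts.
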