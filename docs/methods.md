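# Methods

## Problem and model

`epistab` detects pairwise SNP–SNP interactions (epistasis) in
case-control data. With additive genotype coding $x_{ij} \in \{0,1,2\}$
(the count of a designated allele at SNP $j$) the disease model is the
logistic regression with all main effects and all pairwise products,

$$
\operatorname{logit} \pi_i \;=\; \beta_0 \;+\; \sum_{j=1}^m \beta_j x_{ij}
\;+\; \sum_{j<k} \xi_{jk}\, x_{ij} x_{ik},
$$

so $m$ SNPs yield $p = m + \binom{m}{2}$ candidate features. For
pathway-scale panels ($m$ in the hundreds) $p$ reaches tens of thousands
while $n$ is a few thousand, so selection must be sparse.

## Penalized estimation

Coefficients are estimated by minimizing the sample-size-normalized
penalized deviance

$$
\ell(\theta) = -\tfrac{2}{n}\log L(\theta) + \sum_j p_\lambda(\theta_j),
$$

with the intercept and any covariates (age, sex, pack-years, principal
components) always unpenalized. Two penalties are provided:

* **LASSO**: $p_\lambda(\theta) = \lambda |\theta|$.
* **SCAD** (shape constant $a > 2$, default $a = 3.7$, the conventional
  choice): $p'_\lambda(\theta) = \lambda\,1\{|\theta| \le \lambda\}
  + \frac{(a\lambda - |\theta|)_+}{a-1}\,1\{|\theta| > \lambda\}$, i.e.
  the L1 rate near zero, a quadratic taper on
  $(\lambda, a\lambda]$, and a constant penalty $(a{+}1)\lambda^2/2$
  beyond $a\lambda$. Large coefficients are therefore left unshrunk
  (near-oracle behaviour), which is the substantive difference from the
  LASSO inside stability selection.

**Normalization.** The deviance is divided by $n$ (the glmnet/ncvreg
convention). This is essential, not cosmetic: it puts $\lambda$ on the
scale of the standardized coefficients, so realistic effect sizes
($|\theta| \approx 0.1$–$0.5$) actually reach the SCAD taper and plateau.
With an unnormalized deviance the selection-relevant $\lambda$ is
$O(\sqrt n)$, every coefficient sits in the linear region, and SCAD
degenerates to the LASSO exactly.

**Solver.** Iteratively reweighted least squares with cyclic coordinate
descent on the quadratic surrogate, using the *exact* univariate
minimizer of $\tfrac{c}{2}(\theta - z)^2 + p_\lambda(\theta)$ per
coordinate (soft-thresholding for the LASSO; for SCAD the candidate
minimizer of each of the three $|\theta|$-regions is clipped to its
region and the best kept — exact even when the middle piece is concave).
Paths run over a log-spaced grid of 100 $\lambda$ values from
$\lambda_{\max}$ (the smallest $\lambda$ with an empty active set,
computed from the score at the covariates-only null fit) down to
$0.05\,\lambda_{\max}$, warm-starting each point from the previous one.
A working-set strategy (solve on the active set, add features violating
the zero-coefficient condition $|\tfrac{2}{n} X_j'(y - \mu)| \le
\lambda$, repeat) keeps the cost near $O(n \cdot |{\rm active}|)$ per
grid point. Convergence is declared at a maximum coefficient change
below $10^{-6}$; coefficients under $10^{-8}$ are reported as zero.
SCAD solutions are stationary points of a nonconvex objective, not
certified global minima; all correctness checks are stated at the
KKT/stationarity level. Complete separation is flagged per grid point
when a coefficient reaches the solver bound (|θ| = 50).

**Tuning for the plain fits.** Single LASSO/SCAD fits choose $\lambda$
by cross-validated predictive AUC: stratified folds, out-of-fold
probabilities pooled per $\lambda$, ties broken toward the larger
$\lambda$ (sparser model). The fold count and grid density for these
baselines are implementation choices (benchmark default: 5 folds, 50
grid points, ratio 0.1).

## Stability selection and error control

Stability selection runs the penalized path on $B$ stratified
subsamples, each containing half of the cases and half of the controls
drawn without replacement (defaults $B = 500$ for data analysis; the
benchmark harness uses $B = 100$). The regularization region $\Lambda$
is set by a variable budget $q$: each subsample's path is truncated at
the smallest $\lambda$ for which the cumulative ever-active set would
exceed $q$, so the per-subsample union $|\cup_{\lambda \in \Lambda}
\hat S^\lambda|$ never exceeds $q$. The default budget is the
conservative $q = \lfloor\sqrt p\rfloor$.

Selection probabilities are estimated per feature as
$\hat\Pi_k = \max_{\lambda \in \Lambda} \#\{b : k \in \hat
S^\lambda_b\}/B$ on a common $\lambda$ grid (computed once from the full
sample). The union-frequency variant
$\#\{b: k \in \cup_\lambda \hat S_b^\lambda\}/B$, which upper-bounds the
max-over-$\lambda$ estimate, is also reported for diagnostics.

With $q_\Lambda$ the Monte Carlo mean union size, the exchangeability
bound on falsely selected variables is
$E[V] \le q_\Lambda^2 / ((2\pi_{\rm thr} - 1) p)$, giving the FDR bound
$q_\Lambda / ((2\pi_{\rm thr} - 1) p)$ after dividing by the stable-set
size ($\approx q_\Lambda$). Solving for the threshold at target FDR
$\alpha$:

$$
\pi_{\rm thr} = \tfrac12\left(1 + \frac{q_\Lambda}{p\,\alpha}\right),
\qquad q_\Lambda \le p\,\alpha .
$$

Features with $\hat\Pi_k \ge \pi_{\rm thr}$ form the stable set. When
$q_\Lambda > p\alpha$ no threshold in $(\tfrac12, 1]$ achieves the
bound and the run aborts with advice to shrink $q$ or raise $\alpha$.
$\alpha$ defaults to 0.2 in the simulation harness and 0.1 in the CLI
(matching the two-stage application setting).

Because marker correlation (LD) strains the exchangeability assumption,
a permutation calibration is provided: the phenotype is permuted, the
feature with the largest marginal score statistic located, stability
selection rerun, and that feature's $\hat\Pi$ compared with
$\pi_{\rm thr}$ — a direct conservativeness check of the bound on the
data at hand.

**Two-stage workflow.** Discovery runs with $q = \lfloor\sqrt p\rfloor$;
replication reruns on the second cohort with $q$ reset to the discovery
stable-set size (minimum 1). A pair is confirmed when the interaction is
stable in both stages, its subsample-averaged coefficient sign agrees
across stages, and the two main-effect signs do not contradict each
other (a never-selected main effect, mean sign 0, is not treated as a
contradiction — the direction-concordance rule is otherwise unspecified
in the two-stage protocol and this is the package's reading).

## Synthetic data

The generator emulates a pathway-scale region organized in haplotype
blocks. Default region: 327 common SNPs in 26 blocks with sizes from 2
to 64 markers; per-SNP MAF drawn uniformly from [0.05, 0.5]. Each
individual is the sum of two independent haplotypes drawn from a
Gaussian copula: within a block the latent correlation decays as
$\rho^{|i-j|}$ (AR(1), default $\rho = 0.8$, chosen to mimic the strong
within-block/weak between-block r² contrast of EM-partitioned LD maps),
blocks are independent, and the latent value is thresholded at the
normal MAF quantile — so marginally each SNP is Binomial(2, MAF) and in
Hardy-Weinberg equilibrium by construction. Scaled regions (for desk-
scale runs) use a deterministic cycle of small block sizes.

Phenotypes follow the logistic interaction model exactly, with three
canonical sparse scenarios at designed odds ratios 1.3/1.4/1.5 applied
to every causal term:

| scenario | main effects | interaction | default positions (327-SNP region) |
|---|---|---|---|
| A | none | one | SNP33 × SNP197 |
| B | one (on the pair) | one | SNP18 + SNP18 × SNP134 |
| C | both pair members | one | SNP33 + SNP134 + SNP33 × SNP134 |

Causal pair members always come from distinct blocks; scaled regions map
the positions proportionally. The population intercept $\beta_0$
defaults to 0 (≈50% prevalence), exposed as a parameter since the
generative prevalence is otherwise unconstrained. The benchmark draws a
population of 20,000, samples 1,000 cases and 1,000 controls, runs the
four methods (LASSO, SCAD, _S_LASSO, _S_SCAD) and scores each selected
set against the known causal features.

**What the generator does not emulate.** Real LD maps are
irregular — varying block strength, long-range r², allele-frequency-
dependent haplotype structure. The Gaussian-copula AR(1) model
reproduces the block pattern but not those irregularities, so absolute
power/FDR levels obtained on real genotype panels are reproducible
only approximately; ordering claims (stability SCAD vs stability LASSO,
stability vs plain CV-tuned fits) are the robust targets. Passing tests
demonstrate correctness of the machinery and the qualitative contrasts,
not calibrated absolute power on real genotypes.

## Evaluation metrics

For a selection over $p$ features with $t_0$ true signals:
TPR $= TP/(TP+FN)$; estimated FDR $= FP/(FP+TP)$ (0 when nothing is
selected); Matthews correlation coefficient with the 0-on-zero-
denominator convention; and a rank-based selection AUC over all
true×noise pairs with half credit for ties, computed in $O(p\log p)$ via
midranks (the per-feature score is $\hat\Pi$ for stability methods and
the absolute fitted coefficient at the CV-selected $\lambda$ for plain
fits — the latter is a package choice, exposed as an option). Benchmark
tables report mean and standard error ($sd/\sqrt{R}$) across replicates.

Note that the selection AUC scores the *ranking* of selection
probabilities, so for a powerful selector it sits near 1. It should not
be confused with predictive AUC on held-out phenotypes (the quantity
inside `cv_auc_select`), which for weak genetic effects lands near
0.5–0.65 regardless of selection quality; benchmark tables here report
only the selection-ranking version.

## Quality control

Per-SNP filters in standard GWAS order: call rate (default ≥ 95%), MAF
(default ≥ 0.05), and a 1-df chi-square goodness-of-fit test of
Hardy-Weinberg equilibrium (default p ≥ 1e-4; the HWE test form is a
package choice — the protocol names only thresholds — and the chi-square
form is the common GWAS screen and closed-form testable). Monomorphic
SNPs return HWE p = 1 by convention. Missing genotypes surviving QC are
mean-imputed per SNP before feature expansion, keeping the design dense
and deterministic. Optional greedy VIF pruning (remove the largest-VIF
SNP while any VIF exceeds the bound, default bound 2, off by default)
handles near-collinear markers; when $n \le m$ the VIFs come from a
ridge-stabilized correlation matrix. Sample alignment between genotype,
phenotype and covariate files is by sample-id join; any mismatch is an
error, never a silent reorder.

## Determinism and problem sizes

All randomness flows from explicit integer seeds; subsample $b$ uses an
independent generator seeded `seed + b`, so results are reproducible and
independent of execution order. The test suite and the acceptance
script run the scaled problem sizes — m=40 benchmark (30 replicates,
B=100), m=30 null control (50 runs, B=100), population-scale (n=20,000)
parameter recovery on the full 327-SNP region — chosen so the whole
suite completes on a single CPU in minutes. The full-scale preset
(m=327, B=200, 50 replicates) is wired behind the CLI's
`--preset full-scale --full` guard and runs for hours.

## Known limitations

* The FDR bound rests on an exchangeability assumption that LD-correlated
  features violate; the permutation calibration exists precisely because
  the bound can be optimistic in principle (in practice it is
  conservative on these data models).
* At small scaled sizes ($p$ in the hundreds) the ratio
  $q_\Lambda/(p\alpha)$ is much larger than at pathway scale, the
  threshold sits close to the null selection probabilities of
  full-sample flukes, and occasional single-feature false stable
  selections occur; the expected-false-selection bound still holds.
* No three-way interactions, no gene-environment products, no
  complementary-pairs subsampling, no group penalties.
* Genome-wide exhaustive pair search is out of scope; the method is
  intended for pathway-scale panels after biological or marginal
  filtering.
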