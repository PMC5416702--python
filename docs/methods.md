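# Methods

## The model

`epiloci` scores groups of SNPs for case/control association while including
all pairwise SNP–SNP interaction effects within the group.  For each group
$y$ (case or control) and each subsample $s$ (ancestry stratum or study), the
distribution of the coded genotype vector $a = (a_1, \dots, a_m)$ is modeled
as a Potts-like discrete exponential family

$$P^{y,s}(a) \propto \exp\Big( \sum_i h^{y,s}_i(a_i) + \sum_{i<j} J^{y,s}_{ij}(a_i, a_j) \Big),$$

with the gauge fixed at the reference level: $h_i(0) = 0$ and
$J_{ij}(a, 0) = J_{ij}(0, b) = 0$; couplings are symmetric,
$J_{ij}(a,b) = J_{ji}(b,a)$.  Three codings of the minor-allele dosage are
supported: *genotypic* (three unordered categories, the default and the best
fit in practice), *dominant* (carrier indicator) and *recessive* (homozygous
minor indicator).

The disease risk score of an individual is the log-likelihood ratio
$u(a) = \log P^{\text{case},s}(a) - \log P^{\text{control},s}(a)$, centered
per subsample (see below).  Classifying by $u$ makes the approach a discrete
discriminant analysis: the two class-conditional distributions are estimated
separately and compared.

## Independent-loci (IL) limit and meta-analysis

With all couplings forced to zero the model factorizes over SNPs and the
fields have the closed form $h_i(a) = \ln\big((n_i(a)+\kappa)/(n_i(0)+\kappa)\big)$
with pseudocount $\kappa = 0.5$ guarding empty cells.  Per-SNP association is
tested by the likelihood-ratio (G) statistic of the group-by-level
contingency table, computed within each subsample and summed,
$q = \sum_s q_s$, referred to $\chi^2$ with $(L-1) \cdot S$ degrees of
freedom.  Because individual-level information enters only within
subsamples, allele-frequency divergence between strata (e.g. ancestry
groups) does not inflate the test; the genomic inflation factor
$\lambda_g$ (median observed 1-df quantile / 0.4549) confirms calibration.
Monomorphic SNPs contribute $q_s = 0$ but their degrees of freedom are still
counted, which is slightly conservative.

## Penalized pseudo-likelihood for the interacting model

Exact likelihood is intractable for $m$ beyond a dozen SNPs, so couplings
are estimated by maximizing the per-individual pseudo-log-likelihood
$\tfrac1n \sum_n \sum_i \ln P(a_i \mid a_{-i})$ — a product of per-site
multinomial logistic conditionals — minus a ridge penalty
$\lambda(\varepsilon)\, \lVert J \rVert^2$ on couplings.  Fields carry only a
weak Gaussian prior equivalent to the IL pseudocount ($\lambda_h = \kappa/n$).
The per-site conditionals are fit jointly in one vectorized L-BFGS
optimization (the objective is separable over sites, so this is identical to
per-site fits but orders of magnitude faster), and the two asymmetric
estimates of each coupling are averaged:
$J_{ij} \leftarrow (\hat J_{ij} + \hat J_{ji}^{\top})/2$.

The regularization parameter $\varepsilon \in [0,1]$ interpolates between the
IL limit and the unpenalized interacting limit through

$$\lambda(\varepsilon) = \lambda_0 (1/\varepsilon - 1) + \lambda_{\min}.$$

At $\varepsilon = 0$ the exact IL solution is returned with no optimization
(bit-identical fields, zero couplings).  The scale $\lambda_0 = 0.01$
(configurable) is set from the observation that the per-individual Fisher
information per coupling parameter is of order 0.1 for common variants:
with $\lambda_0 = 1$ couplings would be shrunk below 10% of their value for
every $\varepsilon < 0.9$, leaving the whole grid flat at the IL value,
whereas $\lambda_0 = 0.01$ places the half-shrinkage point near
$\varepsilon \approx 0.2$ and reproduces the expected phenomenology — AUC
rising from the IL limit, an interior maximum, and an overfitting drop at
$\varepsilon = 1$.  $\lambda_{\min} = 10^{-5}$ is a numerical floor that
keeps the $\varepsilon = 1$ objective bounded under quasi-separation; it
contributes $\sim 10^{-4}$ of the per-individual objective and biases even
the rarest coupling cells by well under the sampling noise at the sample
sizes used here.

Numerical settings: L-BFGS with memory 20, gradient tolerance $10^{-6}$
(default; the cross-validation driver defaults to $10^{-5}$ and the largest
simulation studies use $10^{-4}$, which changes AUCs by far less than their
confidence intervals), at most 500 iterations, fields initialized at the IL
solution and parameters warm-started along the $\varepsilon$ grid.  A stop
without formal convergence is accepted with a warning when the gradient
inf-norm is below $\max(100\,\text{tol}, 10^{-3})$; anything worse raises an
error carrying the gradient norm.

## Cross-validated AUC and epsilon optimization

A SNP group is scored by 5-fold cross-validation with folds stratified by
subsample and case/control label (train:test 4:1).  Within each training
fold, models for both groups are fit per subsample at each $\varepsilon$ of
the grid (default $\{0, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1\}$); test
individuals are scored and all test scores are pooled — after subtracting
each subsample's mean raw score of *training controls*, which makes scores
comparable across subsamples (the pseudo-likelihood leaves per-subsample
normalizers unidentified) — into a single Mann–Whitney AUC per
$\varepsilon$ (ties counted 1/2).  The reported statistic is the maximum of
the AUC($\varepsilon$) curve; its 95% CI uses the DeLong variance estimate.

Genome-wide mode selects SNPs by meta IL P-value below a cutoff computed on
the *training fold only*.  Whole-sample pre-CV selection is deliberately not
an option in the scoring path: selecting on all data first leaks test-set
information and severely inflates AUC.  `leakage_probe` quantifies this by
running both variants side by side on (ideally null) data; on a null cohort
with 5000 SNPs and a 0.01 cutoff the leaked arm inflates AUC by ~0.2 while
the clean arm stays at chance.

One pooled AUC over all test folds is reported rather than a mean of
per-fold AUCs: it uses every case–control comparison once and matches the
single AUC quoted per SNP set.

## Significance calibration and heritability

Significance of an observed AUC is estimated by permutation: labels are
shuffled within each subsample (preserving group counts and the population
structure the meta-analysis conditions on), the full cross-validation is
re-run, and the empirical P is the add-one fraction
$(\#\{\text{null} \ge \text{obs}\} + 1)/(n_{\text{perm}} + 1)$ — valid,
never zero, and converging to the plain fraction.  Because
$-\log_{10} P$ is close to linear in AUC above $\approx 0.51$, an OLS line
fitted on permutation points (restricted to AUC > 0.51 and to points not
right-censored at the $1/(n_{\text{perm}}+1)$ resolution floor) extrapolates
significance to AUCs whose direct estimate would need astronomically many
shuffles.  Multiple testing is handled by Bonferroni thresholds
($\alpha/n$) or Benjamini–Hochberg q-values (Storey's estimator behind a
flag); rank agreement between analyses uses Kendall's $\tau$-b.

AUC is converted to liability-scale variance explained under the
liability-threshold model: with prevalence $K$ (default 0.025,
configurable), threshold $T = \Phi^{-1}(1-K)$ and mean liabilities
$i_{\text{case}} = \phi(T)/K$, $i_{\text{ctrl}} = -\phi(T)/(1-K)$, the
forward map is

$$\mathrm{AUC}(h^2) = \Phi\!\left(\frac{h^2 (i_{\text{case}} - i_{\text{ctrl}})}
{\sqrt{h^2[1 - h^2 i_{\text{case}}(i_{\text{case}}-T)] + h^2[1 - h^2 i_{\text{ctrl}}(i_{\text{ctrl}}-T)]}}\right),$$

strictly increasing in $h^2$, inverted by bisection to $10^{-10}$.  At
$K = 0.025$ this gives $h^2 \approx 3.2\%$ for AUC 0.62 and
$\approx 0.09\%$ for AUC 0.52.

## The synthetic cohort generator

The generator emulates the statistical structure of multi-ancestry
case/control panels without any real genotypes: several subpopulations whose
null-SNP allele frequencies follow the Balding–Nichols model
(Beta$(p(1-F)/F,\ (1-p)(1-F)/F)$ around ancestral frequency $p$, divergence
$F$), Hardy–Weinberg equilibrium within subpopulation, optional uniform
missingness, and optionally unequal case:control ratios across
subpopulations (a structure-confounded null that inflates a naive pooled
scan but not the meta-analysis).  Ancestral frequencies default to uniform
on (0.1, 0.4); default $F_{st} = 0.05$, of the order of continental-scale
human divergence.

Causal truth comes in three kinds.  *Null*: no causal SNPs.  *Additive*:
causal SNPs drawn at shifted frequencies in cases.  *Epistatic*: SNP pairs
carry a coupling $J$ in the case distribution whose fields are solved by a
damped Newton iteration on the enumerated pair table (tolerance $10^{-10}$)
so that case and control per-SNP marginals agree exactly — the signal lives
purely in the pairwise joint distribution and is invisible to single-SNP
tests *by construction*, which is the paper-scale phenomenon the package
exists to detect.  Planted parameters are shared across subpopulations; only
null SNPs carry Balding–Nichols divergence.  Small systems are sampled
exactly by enumeration ($L^m \le 3^{12}$); larger ones by parallel Gibbs
chains (default 500 burn-in sweeps), validated against the enumeration
oracle at small $m$ (total-variation distance < 0.02).

What the generator does *not* emulate: linkage disequilibrium beyond what
planted couplings induce, genotyping batch effects or intensity artifacts,
imputation error, relatedness, or sex chromosomes.  Passing tests therefore
demonstrate correctness of the inference machinery under the stated
generative assumptions, not robustness to every artifact of real array data.

## Simulation study sizes

The bundled studies are scaled to a desktop: the planted-epistasis recovery
study uses 10 marginal-matched pairs among 100 SNPs, 2000 cases + 2000
controls, 10 seeds, and a coarse $\varepsilon$ grid $\{0, 0.1, 0.2, 0.5\}$;
the selection-leakage study uses 5000 null SNPs and an IL-only grid; the
permutation studies use 19 permutations per null set (100 sets) and 200 per
calibration point with 16-SNP sets whose planted shifts are graded inside
the AUC band resolvable at that permutation depth.  Coupling recovery is
checked at $n = 50{,}000$ enumeration-sampled individuals, where the rare
homozygote–homozygote coupling cell still has sampling sd $\approx 0.05$ —
bounds on recovery error are therefore evaluated on medians over a few
seeds.

## Known limitations

* The $\varepsilon \mapsto \lambda$ mapping is a reconstruction from the
  stated limits; only its endpoints (IL at 0, unpenalized at 1) are pinned
  down, and $\lambda_0$ is a package choice.
* Pairwise couplings only; higher-order interaction terms are represented
  only through their pairwise shadows.
* Pseudo-likelihood is consistent but not efficient; coupling estimates in
  rare level cells are noisy at realistic sample sizes.
* The HWE QC test is run in controls only, and MAF on pooled groups —
  common practice, but a convention, not an identity.
* Permutation P-values are limited by $1/(n_{\text{perm}}+1)$; the linear
  calibration extrapolates beyond that floor under a linearity assumption
  checked only within the calibrated range.
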