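# Methods

## The problem

Given RNA-Seq gene expression $X = (X_1,\dots,X_P)$ (exposures), protein
abundances $M = (M_1,\dots,M_K)$ (mediators), clinical covariates
$Z = (Z_1,\dots,Z_Q)$ and a right-censored survival time $T$ with event
indicator $\delta$, the package identifies gene–protein pairs $(j, s)$ for
which part of gene $j$'s effect on survival is transmitted through protein
$s$, and estimates the corresponding direct and indirect effects on the
log-survival-time scale.

The working models are accelerated failure time (AFT) and linear
regressions:

$$\log T = \beta_X^\top X + \beta_Z^\top Z + \beta_M^\top M + b\,\varepsilon,
\qquad M_k = \alpha_{Xk}^\top X + \alpha_{Zk}^\top Z + \xi_k .$$

The AFT error $\varepsilon$ can be standard normal (log-normal $T$,
default), minimum-Gumbel (Weibull $T$) or logistic (log-logistic $T$);
$b$ is a scale parameter. Within the counterfactual framework, the
interventional direct effect (IDE) of gene $j$ is $\beta_{Xj}$ and the
interventional indirect effect (IIE) through protein $s$ is the product
$\alpha_{js}\beta_{Ms}$, both interpretable as differences in expected log
survival time per unit (by default per one standard deviation) increase in
the exposure. Identification requires the usual no-unmeasured-confounding
assumptions for exposure–outcome, mediator–outcome and exposure–mediator
relations given $Z$; nothing in the software can verify these.

## The three-step pipeline

**Step 1 — penalized screening.** Both omics layers are reduced with sparse
fits that ignore $Z$ (the covariates re-enter in Step 3):

* mediators: a rank-based AFT fit of $\log T$ on all $K$ proteins using the
  Gehan loss
  $L(\beta) = n^{-2}\sum_i \delta_i \sum_j \max(0, e_j - e_i)$,
  $e_i = \log t_i - x_i^\top\beta$, with an elastic-net penalty (lasso by
  default). The active set is $\mathcal S_1$.
* exposures: the same fit of $\log T$ on all $P$ genes; active set
  $\mathcal A_T$.
* for each $k \in \mathcal S_1$: an MCP-penalized least-squares regression
  of $M_k$ on all genes; active set $\mathcal J_{1k}$.

The Gehan loss is convex, intercept-free (only residual differences enter)
and scale-free, which is why no scale parameter appears in the penalized
outcome fits. Tuning parameters are chosen by 5-fold cross-validation
(event-stratified folds, seeded) on a 50-point log-spaced path from
$\lambda_{\max}$ down to $0.01\lambda_{\max}$, with the one-standard-error
rule. The 1-SE rule matters here: with strongly correlated mediator blocks,
minimizing CV prediction loss keeps far too many correlated proxies,
because prediction and support recovery are different objectives; the
minimum-CV rule remains available (`cv_rule="min"`).

**Step 2 — sure-independence screening.** Each surviving mediator is refit
without penalties: a parametric AFT maximum-likelihood fit
$\log T \sim X_{\mathcal A_T} + M_s$ gives $\hat\beta_{Ms}$, and OLS
$M_s \sim X_{\mathcal J_{1s}}$ gives $\hat\alpha_{js}$. All candidate pairs
are ranked by $|\hat\alpha_{js}\hat\beta_{Ms}|$ and the top
$\lceil n/\log n\rceil$ pairs are kept (global ranking; ties at the
threshold are kept in full; a configurable multiplier enlarges the budget).
Survivors are $\mathcal S_2$ and $\mathcal J_{2s}$.

**Step 3 — joint-significance testing.** One covariate-adjusted AFT fit
$\log T \sim X_{\mathcal A_T} + M_{\mathcal S_2} + Z$ supplies
$\hat\beta_{Ms}$ with standard errors from the observed information; one
OLS $M_s \sim X_{\mathcal J_{2s}} + Z$ per mediator supplies
$\hat\alpha_{js}$. Each screened pair is tested against the composite null
$\alpha_{js}\beta_{Ms} = 0$ with
$P^{\max}_{js} = \max(P_{\alpha_{js}}, P_{\beta_{Ms}})$, two-sided normal
reference. Benjamini–Hochberg adjustment is applied over the **full
family of $P\times K$ candidate pairs**, pairs eliminated by screening
carrying $P^{\max}=1$. This choice is deliberate: Steps 1–2 select, out of
all $K$ proteins, exactly those whose spurious sample association with the
outcome is largest, so the p-values reaching Step 3 under the null are
extreme order statistics of the whole layer. A BH family restricted to the
screened pairs cannot control FDR in that situation; the full-family
adjustment restores control at a negligible cost in power because
true-pair p-values are orders of magnitude below either threshold. The
screened-only family remains available (`bh_family="matrix"`).

Discoveries are pairs with adjusted $P^{\max} < q$ (default $q=0.05$). The
IIE confidence interval is delta-method (Sobel):
$\mathrm{se} = \sqrt{\hat\alpha^2\mathrm{se}_\beta^2 +
\hat\beta^2\mathrm{se}_\alpha^2}$; effects are reported per 1-SD exposure
increase by default (`effect_scale="unit"` switches to per-unit).

## Numerical implementation

*Parametric AFT maximum likelihood* is implemented as damped Newton
iterations on $(\beta, \log b)$ with analytic gradient and Hessian and
step-halving; standard errors come from the observed information. A
vectorized batch mode fits hundreds of single-feature models
simultaneously, which is what makes the all-pairs comparator and the
univariate pre-screen affordable (≈1 ms per fit; results agree with
lifelines to ~1e-6, which the test suite checks). Fits used inside SMAHP
are strict (non-convergence raises); the SIS+SIS comparator deliberately
accepts non-converged fits with ridge-damped information, mirroring how R's
survival tooling behaves on its badly overparameterized high-censoring
designs.

*Penalized Gehan AFT* uses a Huber-smoothed hinge with bandwidth
$h = \mathrm{sd}(\log t)/\sqrt n$ (an induced-smoothing-scale choice that
vanishes at the root-$n$ rate), solved by FISTA with backtracking line
search, Nesterov momentum and adaptive restart, warm starts along the
descending $\lambda$ path. Convergence is declared on the KKT residual of
the penalized smoothed problem (tolerance $10^{-5}\cdot 10\lambda_{\max}$,
max 5000 iterations) — a step-size-based criterion is unreliable here
because the correlated-block designs make the Lipschitz bound loose and the
iteration can crawl. Exact zeros come from the soft-threshold proximal
step. Loss and gradient are evaluated in O(n log n) by sorting the
residuals: pairs separated by at least h carry weight exactly one and
are counted with prefix sums, and only the narrow mid zone is visited
explicitly (the test suite checks this against the literal pairwise
double loop). The exposed `gehan_loss` is the exact (unsmoothed) loss.

*MCP / lasso / elastic-net least squares* is cyclic coordinate descent on
standardized columns with the standard one-dimensional MCP update
($\gamma > 1$; default 3.0). Both solvers are numba-compiled.

*Censoring calibration.* Censoring times are exponential; the rate solves
$E[1 - e^{-\rho T}] = \text{target}$ by root-finding on a Monte-Carlo
sample of $10^5$ latent event times drawn from the same generative law
(deterministically seeded from the configuration), so the realized
censoring fraction is correct in expectation for every scenario and error
family. Rates are cached per generative configuration.

## What the generator emulates — and what it does not

The synthetic datasets follow the simulation design described in the
package overview: i.i.d. (or exchangeably correlated) Gaussian exposures
with mean 0.4 and sd 0.5; two covariates $Z_1\sim N(0.12, 0.75^2)$,
$Z_2\sim\mathrm{Bern}(0.3)$; mediators in four blocks — 40% driven by a
shared 10% exposure hub at effect 0.8 plus covariates (noise sd 0.5), 40%
driven by a second hub (sd 0.3), 10% covariate-only, 10% pure noise — and
an AFT outcome with effects 0.8 (genes), 4.0 (proteins), 0.12 (covariates).
The block-shared hub reading of "40% of the M are associated with 10% of
X" was chosen over per-mediator subsets because it reproduces the
comparator fingerprints (the naive method's FDR ≈ 0.944 arises exactly
from the 0.9-correlated mediator blocks it creates).

The number of genuinely outcome-associated features is a free parameter of
the design; the defaults are 2 genes with direct effects and 4 proteins
(drawn from the two exposure-driven blocks, so every selected protein
carries a real mediated path), giving 20 true (gene, protein) pairs per
dataset with $p=50$.

Features of real proteogenomic data the generator does **not** emulate:
heavy-tailed and missing-not-at-random abundances, batch structure,
library-size effects in RNA-Seq counts (the negative-binomial variant is
marginal, not count-model-faithful), measurement error shared between the
two layers, and informative censoring. Passing the simulation study
therefore demonstrates correct behavior of the statistical machinery under
its own assumptions, not robustness to everything a real cohort can do.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `PenaltySpec.family` | outcome: lasso; mediator: MCP | sparsity penalty |
| `PenaltySpec.gamma` | 3.0 | MCP concavity (>1); larger → closer to lasso |
| `PenaltySpec.cv_folds / cv_rule` | 5, "1se" | CV folds and selection rule |
| `SmahpConfig.error_family` | log_normal | AFT error distribution |
| `SmahpConfig.sis_multiplier` | 1.0 | screening budget multiple of n/log n |
| `SmahpConfig.q` | 0.05 | BH discovery threshold |
| `SmahpConfig.bh_family` | all_pairs | BH family: p·k or screened u·r |
| `SmahpConfig.effect_scale` | sd | effect reporting scale |
| `SimulationConfig.censoring_target` | 0.25 | calibrated censoring fraction |

## Degenerate inputs and edge behavior

Constant features are dropped from penalized fits with a warning and get
p = 1 in the univariate pre-screen. All-censored outcomes raise (the AFT
likelihood is unbounded, the Gehan loss undefined). An empty $\mathcal S_1$
or $\mathcal S_2$ terminates the pipeline with an explicitly staged empty
result rather than an error. Ties in the Step-2 ranking at the threshold
are all kept; ties in pre-screen p-values break lexicographically by
feature id.

## Problem sizes used in the shipped study replication

The scenario replications run 30 seeded replicates per setting in the
acceptance script and 8–15 in the test suite (the published study used
200); Monte-Carlo standard errors are reported alongside every mean so the
residual replication noise is visible. Parameter-recovery and null-FDR
checks use 100 replicates at n = 2000 and n = 400 respectively.

## Known limitations

Single-mediator pathways only: sequential or cumulative multi-mediator
effects are out of scope. No hazard-ratio output (the AFT formulation is
the point). The delta-method IIE interval is symmetric and can undercover
for small $|\alpha\beta|$ at small $n$. Inference is conditional on the
selected sets; the full-family BH adjustment compensates empirically (null
FDR is checked in the test suite) but carries no finite-sample
post-selection guarantee.
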