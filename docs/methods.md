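# Methods

## The problem

In photo-elicitation interview surveys, informants are shown photos of
individually catalogued animals and asked whether they recognize each one,
what name they use for it, how they recognize it, and what traits they
perceive. The scientific question is whether the informants' individual-level
knowledge is reliable enough to use as data: do they recognize the animals,
do they agree with each other on names, and how certain is a given name?
`lekid` operationalizes this as five indices plus a regression layer linking
each index to covariates.

## Indices and their conventions

**Recognition (RI)** and **concordance (CDI)** are per photo. RI is the
fraction of presentations that elicited a positive recognition. CDI is
(n_R − n_N)/(n_R − 1) over the n_R recognitions and their n_N distinct
canonical names. Conventions where the definitions are silent:

* Names are canonicalized (trim, lowercase, collapse whitespace) before any
  comparison; case and spacing variants are transcription noise, not
  disagreement. A user-supplied synonym table can merge known spelling
  variants; nothing else is merged automatically.
* A recognition without a name ("I know it but not its name") counts toward
  n_R and contributes one *shared* pseudo-category to n_N
  (`unknown_policy="category"`, the default). Treating each nameless answer
  as a distinct name would deflate CDI for reasons unrelated to disagreement;
  excluding them entirely (`"exclude"`) is available as a switch.
* CDI is undefined (NaN) for n_R ≤ 1 — the formula divides by n_R − 1 — and
  undefined values are excluded from summaries and models, with the count
  reported in the exclusion log. Any imputation would be arbitrary.
* The per-photo modal recognition method breaks ties toward `marks`, the
  reference category of interest; ties are rare and determinism is required.

**Consensus (CI, ACI).** CI for a fisher pair is matching names over shared
photos. A match requires both to have *recognized* the photo and given the
same canonical non-sentinel name: two "don't know" answers never match,
because mutual ignorance is not consensus. The default denominator is all
photos presented to both (failing to recognize a shared photo counts against
consensus); `denominator="recognized_both"` restricts it to photos both
recognized, since the verbal definition admits either reading. Pair
eligibility — at least `min_shared = 3` common *presented* photos, the
small-sample restriction of the original design — is independent of the
denominator switch. ACI is the unweighted mean of a fisher's eligible CIs;
weighting by the number of shared photos was considered and rejected to keep
the index comparable with the verbal definition.

**Certainty (CeI, CF, CeIc).** Citations of a name are counted once per
(fisher, photo) response. CeI reads "assigned to the same photo" as citations
to the name's *modal* photo — the only data-driven referent when no
ground-truth assignment of names to photos exists — which maximizes CeI and
therefore makes low observed certainty a conservative finding. CF divides a
name's citations by those of the most popular name, so CeIc = CeI·CF ≤ CeI
with equality exactly for (co-)most-popular names. Modal perceived attributes
break ties to `unknown` rather than invent a determinate covariate; the
recognition method has no unknown level, so its ties resolve to `marks` like
the index table's.

## Beta regression

Indices live on [0, 1] with non-constant variance, so each is modelled as
y_i ~ Beta(μ_i φ, (1 − μ_i) φ), logit(μ_i) = x_iᵀβ, with a single precision
φ (no precision covariates, no interactions, no random effects).

Numerical choices:

* **Boundary values.** Observed 0s and 1s are inadmissible under the beta
  density and are compressed with y′ = (y(n − 1) + 0.5)/n before fitting;
  every application is counted in the exclusion log. Dropping boundary
  observations instead would bias the samples toward intermediate agreement.
* **Optimization.** The likelihood is maximized in (β, log φ) by BFGS with
  analytic gradients, started from logit of the sample mean on the intercept,
  zeros on slopes, and a method-of-moments φ. A single L-BFGS-B polish is
  attempted if BFGS reports failure. μ is clipped to [1e−10, 1 − 1e−10] and
  log φ to ±30 only to keep the surface finite when the optimizer overshoots;
  interior optima are unaffected.
* **Inference.** Standard errors come from the inverse observed information
  (central-difference Hessian at the optimum); z = β̂/SE with two-sided normal
  p-values at the 0.05 level; φ's SE is delta-method from log φ.
  AIC = −2ℓ + 2(k + 1), counting φ.
* The implementation is cross-checked in the test suite against an
  independent beta-regression implementation (statsmodels `BetaModel`) and
  against direct log-density summation and grid search.

**Model selection** is backward elimination from the full additive model:
at each step the single term whose removal most reduces AIC is dropped,
stopping when no removal helps. Akaike weights are normalized over the set of
models actually visited along the path (including rejected drops), since a
full enumeration is not what a backward path produces; an `all_subsets` mode
fits every subset when an exhaustive table is wanted. Models with ΔAIC < 2
form the retained set; the best model is always in it.

**Diagnostics** are simulation-based scaled quantile residuals: for each
observation, the fraction of draws from its fitted beta distribution falling
below the observed value (ties randomized uniformly), tested against
Uniform(0, 1) by Kolmogorov–Smirnov. Under a correctly specified model the
pass rate at the 0.05 level is ≈ 95%, which the acceptance checks verify
empirically. The default 250 simulations keeps the granularity of the
residuals (1/250) well below the KS resolution at the sample sizes involved.

## The synthetic generator

The generator emulates the study design: `n_fishers = 38`, a
`n_photos = 30` catalog, 8–10 photos per interview sampled uniformly without
replacement, each photo at most once per fisher. Its mechanisms, with
defaults:

* **Recognition**: Bernoulli(expit(intercept + mark_effect·marked)) with
  intercept 0 and mark_effect 1.065 — a plausible effect size for
  mark-driven recognition on the logit scale — and `p_marked = 0.6`, giving
  a mean recognition rate near 0.63.
* **Naming**: given recognition, the true catalog name with probability set
  by learning mode (vertical 0.9, horizontal 0.5, individual 0.4 — graded to
  produce the vertical-learning consensus advantage); with probability 0.1
  the fisher declines to name ("unknown"); otherwise a draw from the catalog
  names weighted by Zipf(1.0) over a random popularity ranking. This single
  fallback mechanism produces popular-name reuse across photos, the failure
  mode the certainty indices measure.
* **Covariates**: fisher age uniform 18–80, two fishing sites, learning-mode
  proportions (0.5, 0.3, 0.2), dependence 0.5; dolphin home range
  lognormal(3, 0.5), encounter rate Beta(2, 5), good/bad behavior 0.5.
  Perceived sex/behavior are noisy-correct (0.8 correct, else uniform);
  perceived age is Normal(true, 5) clipped to [0, 80] and missing with
  probability 0.1. Deliberately weak structure: the certainty model found no
  covariate effects in the motivating study, and strong synthetic effects
  would make null scenarios dishonest.
* Learning mode affects only naming accuracy, never recognition probability,
  so the ACI contrast is not confounded with RI.

The scenario library pins four regimes: `paper_like` (all mechanisms on),
`perfect_knowledge` (all indices exactly 1 — an exact limit, not a tolerance
check), `no_knowledge` (naming purely from the popularity pool, whose mean
pairwise CI equals the analytic collision probability Σp_k²), and `null` (no
mark effect, equal accuracies — for type-I-error checks).

What the generator does **not** emulate: real informants' memory and
familiarity effects (recognition is iid across photos given mark status),
spatial structure in home ranges and encounter rates (covariates are drawn,
not mechanistic), inter-informant social transmission of names, and
photo-specific difficulty. Passing tests therefore show that the pipeline
recovers the structure it assumes, at the study's scale — not that the
assumed structure is true of any real fishery.

## Problem sizes in the checks

The calibration checks use sizes chosen to make Monte-Carlo noise small
relative to the tolerances: 100 replicates of n = 300 observations for
coefficient bias/coverage and selection rates (effect 1.0, φ = 15), 100
replicates of n = 200 for residual calibration, 150 fishers for the Zipf
collision limit, and exhaustive enumeration (all label multisets of size ≤ 6
over three names; all 5-name draw sequences of length ≤ 5) wherever a finite
oracle exists.

## Known limitations

* CI/ACI treat all shared photos equally; a pair sharing 3 photos and one
  sharing 10 contribute CIs of very different precision to ACI.
* The modal-photo reading of CeI is one of two defensible interpretations of
  "assigned to the same photo"; the alternative (per-photo maximum agreement)
  is not implemented.
* Backward elimination explores one path; Akaike weights over the visited set
  are conditional on that path (use `all_subsets` for path-free weights).
* With 30 photos the dolphin-covariate models are small-sample; Wald
  inference there is approximate, which the residual diagnostics only
  partially probe.
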