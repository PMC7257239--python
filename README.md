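# lekid

**Can informants individually recognize — and consistently name — the wild
animals they interact with?** `lekid` answers this question quantitatively for
interview surveys built on photo-elicitation, the design used to study
artisanal fishers who fish cooperatively with bottlenose dolphins: each fisher
is shown a random subset of photos from an individual-identification catalog
and asked whether they recognize the dolphin, what they call it, how they
recognize it, and what traits they perceive.

The package computes five agreement/certainty indices from such interviews and
relates them to informant and animal covariates with beta regression:

| Index | Level | Definition |
|---|---|---|
| RI | photo | positive recognitions / presentations |
| CDI | photo | (n_R − n_N)/(n_R − 1), with n_R recognitions carrying n_N distinct names; 1 = unanimous naming, 0 = all names different, undefined for n_R ≤ 1 |
| CI | fisher pair | matching names / photos presented to both fishers |
| ACI | fisher | mean CI over pairs sharing ≥ 3 presented photos |
| CeI, CF, CeIc | name | CeI = citations to the name's modal photo / total citations; CF = total citations / citations of the most popular name; CeIc = CeI·CF |

Each index lies in [0, 1] and is modelled as y ~ Beta(μφ, (1 − μ)φ) with
logit(μ) = xᵀβ, fitted by maximum likelihood. Covariates are selected by
backward elimination on AIC with Akaike weights (models with ΔAIC < 2
retained) and checked with simulation-based scaled quantile residuals, which
are uniform under a correctly specified model.

Because real interview data of this kind are typically not redistributable,
the package ships a seeded synthetic-survey generator that reproduces the
study design (38 fishers, a 30-photo catalog, 8–10 photos per interview) and
the mechanisms the analysis probes: mark-driven recognition,
learning-mode-dependent naming accuracy, and Zipf-weighted reuse of popular
names. Every pipeline stage is testable against its known ground truth.

## Worked example

```bash
lekid run --scenario paper_like --seed 42 --out demo/
```

or equivalently from Python:

```python
from lekid import RunConfig, run
report = run(RunConfig(scenario="paper_like", seed=42, out_dir="demo"))
```

The run writes `photo_indices.csv`, `pairwise_ci.csv`, `fisher_aci.csv`,
`name_certainty.csv`, per-response model-selection and best-fit tables,
`summary.json` and a markdown report. The report begins:

```
- Recognition Index: RI = 0.63 ± 0.16 SD (n = 30 photos)
- Concordance Index: CDI = 0.60 ± 0.19 SD (defined for 30 photos)
- Average Consensus Index: ACI = 0.14 ± 0.07 SD, range 0.01–0.30 (38 of 38 fishers)
- Certainty Index: CeI = 0.72 ± 0.23 SD; corrected CeIc = 0.17 ± 0.06 SD (30 names)
```

Fishers recognize most photos (RI near 0.63 here) but agree far less on what
the dolphins are called, and a fisher's average consensus with others (ACI) is
low. The best recognition model picks up the mark effect built into the
scenario:

```
### RI: `RI ~ home_range + encounter_rate + C(modal_recognition_method)`

| term                                 |   estimate |     se |       z |      p |
|:-------------------------------------|-----------:|-------:|--------:|-------:|
| Intercept                            |    -0.7338 | 0.3833 | -1.9147 | 0.0555 |
| C(modal_recognition_method)[T.marks] |     0.7051 | 0.1998 |  3.5293 | 0.0004 |
| home_range                           |     0.0237 | 0.0126 |  1.8808 | 0.0600 |
| encounter_rate                       |     1.6007 | 0.7380 |  2.1689 | 0.0301 |
```

Dolphins recognized by long-lasting dorsal-fin marks have significantly higher
recognition than those recognized by body form (positive `marks` coefficient
on the logit scale), while consensus is driven by how fishers learned the
tactic (`ACI ~ C(learning_mode)`: vertical learners — who learned from
relatives — agree more).

Other entry points: `lekid simulate` writes a synthetic dataset with its
ground truth; `lekid indices | consensus | certainty | fit` run single stages
on any three CSVs following the documented schema; `lekid replicate`
aggregates selection frequencies and coefficient distributions across seeds.

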