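"""End-to-end pipeline: simulate/load -> indices -> consensus -> certainty -> models.

One :func:`run` executes the five quantifications in order on a dataset
(either loaded from CSVs or drawn from a named synthetic scenario), fits the
four covariate models —

* RI   ~ dolphin covariates + recognition type (per photo),
* CDI  ~ dolphin covariates + recognition type (photos with defined CDI),
* ACI  ~ fisher covariates (included fishers only),
* CeIc ~ name-level aggregated perceived attributes,

— each by backward AIC selection over the additive candidate set, runs scaled
residual diagnostics on the best model of each response, and writes every
table as CSV plus a markdown report and a machine-readable ``summary.json``.
Records dropped at any stage (undefined CDI, ineligible pairs, missing
covariates, boundary squeezes) are counted in the exclusion log; nothing is
dropped silently.  :func:`replicate` repeats the analysis across consecutive
seeds and aggregates selection frequencies and coefficient distributions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .betareg import (
    CollinearityError,
    ModelSelectionTable,
    ResidualDiagnostics,
    backward_select,
    scaled_residuals,
    squeeze_to_open_interval,
)
from .certainty import corrected_certainty_table
from .consensus import aci_table
from .data import Dataset, read_dataset, write_dataset
from .indices import photo_index_table
from .simulate import generate, scenario_library

logger = logging.getLogger("lekid")

__all__ = ["RunConfig", "RunReport", "run", "replicate", "analyze"]

#: Candidate terms per response (patsy term strings).
MODEL_CANDIDATES = {
    "RI": ["home_range", "encounter_rate", "C(behavior_class)",
           "C(modal_recognition_method)"],
    "CDI": ["home_range", "encounter_rate", "C(behavior_class)",
            "C(modal_recognition_method)"],
    "ACI": ["age_years", "C(fishing_site)", "C(learning_mode)", "C(dependence)"],
    "CeIc": ["mean_perceived_age", "C(modal_sex)", "C(modal_behavior)",
             "C(modal_method)"],
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    scenario: str | None = None
    responses_path: str | None = None
    fishers_path: str | None = None
    photos_path: str | None = None
    out_dir: str = "lekid_out"
    cutoff: float = 0.5
    min_shared: int = 3
    unknown_policy: str = "category"
    ci_denominator: str = "presented_both"
    delta_threshold: float = 2.0
    n_simulations: int = 250
    selection_mode: str = "backward"
    seed: int = 0
    make_plots: bool = False

    def validate(self) -> None:
        csv_in = all(p is not None for p in
                     (self.responses_path, self.fishers_path, self.photos_path))
        if (self.scenario is None) == (not csv_in):
            raise ValueError("provide exactly one of: scenario, or all three CSV paths")


@dataclass
class AnalysisResult:
    """In-memory result of one analysis pass (no file I/O)."""

    photo_table: object
    aci: object
    certainty: object
    selections: dict[str, ModelSelectionTable]
    diagnostics: dict[str, ResidualDiagnostics]
    exclusions: dict[str, int]
    model_notes: dict[str, str] = field(default_factory=dict)


@dataclass
class RunReport:
    """Serializable account of a pipeline run."""

    index_summaries: dict
    model_tables: dict
    best_fits: dict
    diagnostics: dict
    exclusions: dict
    provenance: dict

    def to_summary_dict(self) -> dict:
        return {
            "index_summaries": self.index_summaries,
            "model_tables": self.model_tables,
            "best_fits": self.best_fits,
            "diagnostics": self.diagnostics,
            "exclusions": self.exclusions,
            "provenance": self.provenance,
        }


def _usable_terms(frame: pd.DataFrame, terms: list[str]) -> tuple[list[str], list[str]]:
    """Drop candidate terms that cannot be estimated on this frame."""
    kept, dropped = [], []
    for term in terms:
        col = term[2:-1] if term.startswith("C(") else term
        values = frame[col].dropna()
        n_levels = values.nunique()
        if n_levels < 2:
            dropped.append(term)
        else:
            kept.append(term)
    return kept, dropped


def _fit_response(frame: pd.DataFrame, response: str, candidates: list[str],
                  settings: "RunConfig", rng: np.random.Generator,
                  exclusions: dict[str, int], notes: dict[str, str],
                  ) -> tuple[ModelSelectionTable | None, ResidualDiagnostics | None]:
    cols = [c[2:-1] if c.startswith("C(") else c for c in candidates]
    data = frame[[response] + cols].dropna()
    n_dropped = len(frame) - len(data)
    if n_dropped:
        exclusions[f"{response}_rows_dropped_missing"] = int(n_dropped)
    if len(data) < len(candidates) + 3:
        notes[response] = f"skipped: only {len(data)} usable rows"
        return None, None

    terms, dropped_terms = _usable_terms(data, candidates)
    if dropped_terms:
        notes[response] = f"terms without variation dropped: {dropped_terms}"

    y = data[response].to_numpy(dtype=float)
    n_boundary = int(np.sum((y == 0.0) | (y == 1.0)))
    if n_boundary:
        exclusions[f"{response}_boundary_values_squeezed"] = n_boundary
        logger.info("%s: %d boundary values compressed into (0,1)", response, n_boundary)
    data = data.assign(**{response: squeeze_to_open_interval(y, len(y))})

    try:
        sel = backward_select(data, response, terms,
                              delta_threshold=settings.delta_threshold,
                              mode=settings.selection_mode)
    except (CollinearityError, np.linalg.LinAlgError) as exc:
        notes[response] = f"model fitting failed: {exc}"
        return None, None
    diag = None
    if sel.best_fit.converged:
        diag = scaled_residuals(sel.best_fit, n_simulations=settings.n_simulations,
                                rng=rng)
    else:
        notes[response] = "best fit did not converge; diagnostics skipped"
    return sel, diag


def analyze(dataset: Dataset, settings: RunConfig,
            rng: np.random.Generator | None = None) -> AnalysisResult:
    """Run every quantification and model on an in-memory dataset."""
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    exclusions: dict[str, int] = {"responses_in": int(len(dataset.responses))}
    notes: dict[str, str] = {}

    photo_tab = photo_index_table(dataset, high_cutoff=settings.cutoff,
                                  unknown_policy=settings.unknown_policy)
    exclusions["photos_cdi_undefined"] = photo_tab.summary["n_cdi_undefined"]

    aci = aci_table(dataset, min_shared=settings.min_shared,
                    denominator=settings.ci_denominator)
    exclusions["fishers_excluded_no_eligible_pair"] = (
        aci.summary["n_fishers_total"] - aci.summary["n_fishers_included"])

    certainty = corrected_certainty_table(dataset)

    selections: dict[str, ModelSelectionTable] = {}
    diagnostics: dict[str, ResidualDiagnostics] = {}

    frames = {
        "RI": photo_tab.frame,
        "CDI": photo_tab.frame.rename(columns={"CDI": "CDI"}),
        "ACI": aci.frame,
        "CeIc": certainty.frame,
    }
    for response, candidates in MODEL_CANDIDATES.items():
        sel, diag = _fit_response(frames[response], response, candidates,
                                  settings, rng, exclusions, notes)
        if sel is not None:
            selections[response] = sel
        if diag is not None:
            diagnostics[response] = diag

    exclusions["responses_used"] = exclusions["responses_in"]
    return AnalysisResult(photo_table=photo_tab, aci=aci, certainty=certainty,
                          selections=selections, diagnostics=diagnostics,
                          exclusions=exclusions, model_notes=notes)


def _load_or_simulate(config: RunConfig) -> Dataset:
    if config.scenario is not None:
        library = scenario_library()
        if config.scenario not in library:
            raise ValueError(f"unknown scenario {config.scenario!r}; "
                             f"available: {sorted(library)}")
        gen_cfg = library[config.scenario].with_(seed=config.seed)
        dataset, _ = generate(gen_cfg)
        return dataset
    return read_dataset(config.responses_path, config.fishers_path, config.photos_path)


def _best_fit_record(sel: ModelSelectionTable) -> dict:
    fit = sel.best_fit
    return {
        "formula": sel.best_formula,
        "n_obs": int(fit.nobs),
        "loglik": round(fit.llf, 6),
        "aic": round(fit.aic, 6),
        "phi": round(fit.phi, 6),
        "converged": bool(fit.converged),
        "terms": [
            {"term": name,
             "estimate": round(float(fit.params[name]), 6),
             "se": round(float(fit.bse[name]), 6),
             "z": round(float(fit.zvalues[name]), 6),
             "p": round(float(fit.pvalues[name]), 6)}
            for name in fit.params.index],
    }


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else round(v, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "input"
    try:
        dataset = _load_or_simulate(config)
        write_dataset(dataset, out / "dataset")

        stage = "analysis"
        result = analyze(dataset, config)

        stage = "output"
        result.photo_table.to_csv(out / "photo_indices.csv")
        result.aci.pairwise.to_csv(out / "pairwise_ci.csv", index=False)
        result.aci.to_csv(out / "fisher_aci.csv")
        result.certainty.to_csv(out / "name_certainty.csv")
        for response, sel in result.selections.items():
            sel.to_csv(out / f"model_selection_{response}.csv")
            fit = sel.best_fit
            pd.DataFrame({
                "term": fit.params.index, "estimate": fit.params.to_numpy(),
                "se": fit.bse.to_numpy(), "z": fit.zvalues.to_numpy(),
                "p": fit.pvalues.to_numpy(),
            }).to_csv(out / f"best_fit_{response}.csv", index=False)
        for response, diag in result.diagnostics.items():
            diag.to_frame().to_csv(out / f"residuals_{response}.csv", index=False)

        report = RunReport(
            index_summaries={
                "photo": result.photo_table.summary,
                "consensus": result.aci.summary,
                "certainty": result.certainty.summary,
            },
            model_tables={
                resp: sel.frame.round(6).to_dict(orient="records")
                for resp, sel in result.selections.items()},
            best_fits={resp: _best_fit_record(sel)
                       for resp, sel in result.selections.items()},
            diagnostics={
                resp: {"ks_statistic": round(d.uniformity_statistic, 6),
                       "ks_p": round(d.uniformity_p, 6),
                       "n_simulations": d.n_simulations}
                for resp, d in result.diagnostics.items()},
            exclusions=result.exclusions,
            provenance={
                "package_version": __version__,
                "seed": config.seed,
                "scenario": config.scenario,
                "cutoff": config.cutoff,
                "min_shared": config.min_shared,
                "unknown_policy": config.unknown_policy,
                "ci_denominator": config.ci_denominator,
                "delta_threshold": config.delta_threshold,
                "n_simulations": config.n_simulations,
                "selection_mode": config.selection_mode,
                "model_notes": result.model_notes,
            },
        )
        summary = _round_floats(report.to_summary_dict())
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        (out / "report.md").write_text(_render_report(report))
        if config.make_plots:
            _write_plots(result, out)
        return report
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _render_report(report: RunReport) -> str:
    ph = report.index_summaries["photo"]
    co = report.index_summaries["consensus"]
    ce = report.index_summaries["certainty"]
    lines = [
        "# Interview-survey identification analysis",
        "",
        "## Index summaries",
        "",
        f"- Recognition Index: RI = {ph['ri_mean']:.2f} ± {ph['ri_sd']:.2f} SD "
        f"(n = {ph['n_photos']} photos)",
        f"- Concordance Index: CDI = {ph['cdi_mean']:.2f} ± {ph['cdi_sd']:.2f} SD "
        f"(defined for {ph['n_cdi_defined']} photos)",
        f"- Average Consensus Index: ACI = {co['aci_mean']:.2f} ± {co['aci_sd']:.2f} SD, "
        f"range {co['aci_min']:.2f}–{co['aci_max']:.2f} "
        f"({co['n_fishers_included']} of {co['n_fishers_total']} fishers)",
        f"- Certainty Index: CeI = {ce['cei_mean']:.2f} ± {ce['cei_sd']:.2f} SD; "
        f"corrected CeIc = {ce['ceic_mean']:.2f} ± {ce['ceic_sd']:.2f} SD "
        f"({ce['n_names']} names)",
        "",
        "## Best models",
        "",
    ]
    for resp, rec in report.best_fits.items():
        lines.append(f"### {resp}: `{rec['formula']}`")
        lines.append("")
        lines.append(f"logLik = {rec['loglik']:.3f}, AIC = {rec['aic']:.3f}, "
                     f"phi = {rec['phi']:.3f}, n = {rec['n_obs']}")
        lines.append("")
        table = pd.DataFrame(rec["terms"])
        lines.append(table.to_markdown(index=False, floatfmt=".4f"))
        lines.append("")
        diag = report.diagnostics.get(resp)
        if diag:
            lines.append(f"Scaled-residual KS uniformity: D = {diag['ks_statistic']:.3f}, "
                         f"p = {diag['ks_p']:.3f} ({diag['n_simulations']} simulations)")
            lines.append("")
    lines.append("## Exclusions")
    lines.append("")
    for key, value in sorted(report.exclusions.items()):
        lines.append(f"- {key}: {value}")
    lines.append("")
    prov = report.provenance
    lines.append("## Provenance")
    lines.append("")
    lines.append(f"- lekid {prov['package_version']}, seed {prov['seed']}, "
                 f"scenario {prov['scenario']}")
    lines.append("")
    return "\n".join(lines)


def _write_plots(result: AnalysisResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.photo_table.frame
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    axes[0].hist(frame["RI"], bins=10, color="steelblue")
    axes[0].set_xlabel("Recognition Index")
    axes[1].hist(frame["CDI"].dropna(), bins=10, color="indianred")
    axes[1].set_xlabel("Concordance Index")
    fig.tight_layout()
    fig.savefig(out / "indices_hist.png", dpi=120)
    plt.close(fig)


@dataclass
class ReplicateSummary:
    """Aggregated statistics over replicated pipeline runs."""

    n_replicates: int
    n_failed: int
    index_means: pd.DataFrame
    inclusion: pd.DataFrame      # response, term, times_in_best, frequency, ci_low, ci_high
    coefficients: pd.DataFrame   # response, term, replicate, estimate, se


def replicate(config: RunConfig, n_replicates: int) -> ReplicateSummary:
    """Re-run the analysis across seeds seed..seed+n-1 and aggregate.

    Per replicate: index summary means, best-model term inclusion, and the
    coefficient estimates of the full-model terms that survived selection.
    Inclusion frequencies carry Wilson binomial confidence intervals.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config.validate()

    from statsmodels.stats.proportion import proportion_confint

    idx_rows, coef_rows = [], []
    inclusion_counts: dict[tuple[str, str], int] = {}
    fitted_counts: dict[str, int] = {}
    n_failed = 0

    for i in range(n_replicates):
        seed = config.seed + i
        try:
            if config.scenario is not None:
                gen_cfg = scenario_library()[config.scenario].with_(seed=seed)
                dataset, _ = generate(gen_cfg)
            else:
                dataset = read_dataset(config.responses_path, config.fishers_path,
                                       config.photos_path)
            rep_cfg = RunConfig(**{**vars(config), "seed": seed})
            result = analyze(dataset, rep_cfg, rng=np.random.default_rng(seed))
        except Exception as exc:
            logger.warning("replicate %d (seed %d) failed: %s", i, seed, exc)
            n_failed += 1
            continue

        idx_rows.append({
            "replicate": i, "seed": seed,
            "ri_mean": result.photo_table.summary["ri_mean"],
            "cdi_mean": result.photo_table.summary["cdi_mean"],
            "aci_mean": result.aci.summary["aci_mean"],
            "cei_mean": result.certainty.summary["cei_mean"],
            "ceic_mean": result.certainty.summary["ceic_mean"],
        })
        for resp, sel in result.selections.items():
            fitted_counts[resp] = fitted_counts.get(resp, 0) + 1
            best_terms = _terms_of(sel.best_formula)
            for term in MODEL_CANDIDATES[resp]:
                if term in best_terms:
                    inclusion_counts[(resp, term)] = inclusion_counts.get(
                        (resp, term), 0) + 1
            fit = sel.best_fit
            for name in fit.params.index:
                coef_rows.append({"response": resp, "term": name, "replicate": i,
                                  "estimate": float(fit.params[name]),
                                  "se": float(fit.bse[name])})

    incl_rows = []
    for resp in MODEL_CANDIDATES:
        n_fit = fitted_counts.get(resp, 0)
        for term in MODEL_CANDIDATES[resp]:
            k = inclusion_counts.get((resp, term), 0)
            if n_fit:
                lo, hi = proportion_confint(k, n_fit, method="wilson")
            else:
                lo = hi = float("nan")
            incl_rows.append({"response": resp, "term": term,
                              "times_in_best": k, "n_fitted": n_fit,
                              "frequency": k / n_fit if n_fit else float("nan"),
                              "ci_low": float(lo), "ci_high": float(hi)})

    return ReplicateSummary(
        n_replicates=n_replicates, n_failed=n_failed,
        index_means=pd.DataFrame(idx_rows),
        inclusion=pd.DataFrame(incl_rows),
        coefficients=pd.DataFrame(coef_rows),
    )


def _terms_of(formula: str) -> set[str]:
    rhs = formula.split("~", 1)[1]
    return {t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"}
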