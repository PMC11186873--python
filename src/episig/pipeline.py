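"""End-to-end workflows: single-cohort discovery and combined-cohort runs.

``run_discovery`` chains the full procedure on a beta matrix: sample and
probe QC, M-value transform, PCA outlier screen, age/sex control
matching, cell-type deconvolution, moderated differential methylation,
three-stage probe selection, LOOCV, SVM training with 75/25 splitting of
the non-matched cohorts, MVP scoring, per-cohort specificity, and
unsupervised separation metrics. ``run_combined`` pools several case
cohorts into one case group (the combined-episignature design) and adds
per-source-cohort MVP summaries.

Every run can write its artifacts plus a machine-readable run manifest
(parameters, seeds, counts) sufficient to reproduce it; re-running with
the same inputs and config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import io
from .classifier import (
    DEFAULT_CUTOFF,
    MvpClassifier,
    TrainingDesign,
    build_design,
    evaluate_specificity,
    score_mvp,
    train_mvp,
)
from .containers import BetaMatrix
from .deconvolution import estimate_proportions, proportions_to_covariates
from .dmp import call_dmps
from .errors import ConfigError
from .evaluate import separation_report
from .matching import MatchResult, audit_match, match_controls
from .preprocess import QcReport, beta_to_m, filter_probes, filter_samples, pca_outlier_screen
from .selection import EpisignatureSelector, SelectionConfig, run_loocv, select_episignature


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a discovery or combined run."""

    match_ratio: int = 4
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    max_failure: float = 0.05
    eps: float = 1e-3
    dmp_min_abs_delta: float = 0.05
    dmp_max_q: float = 0.01
    svm_c: float = 1.0
    svm_cutoff: float = DEFAULT_CUTOFF
    split: float = 0.75
    split_seed: int = 0
    holdout_cohorts: tuple = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection"] = asdict(self.selection)
        d["holdout_cohorts"] = list(self.holdout_cohorts)
        return d


@dataclass
class DiscoveryResult:
    """All stage outputs of one run."""

    case_cohorts: List[str]
    case_ids: List[str]
    sample_qc: QcReport
    probe_qc: QcReport
    outlier_report: QcReport
    match: MatchResult
    match_summary: dict
    proportions: pd.DataFrame
    selector: EpisignatureSelector
    loocv: pd.DataFrame
    dmp_ids: List[str]
    design: TrainingDesign
    model: MvpClassifier
    mvp: pd.DataFrame
    specificity: pd.DataFrame
    separation: dict
    config: PipelineConfig

    @property
    def episignature(self) -> pd.DataFrame:
        return self.selector.selection_

    @property
    def probe_stats(self) -> pd.DataFrame:
        return self.selector.stats_

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "case_cohorts": self.case_cohorts,
            "n_cases": len(self.case_ids),
            "n_matched_controls": len(self.match.control_ids),
            "n_probes_after_qc": int(self.selector.stats_.shape[0]),
            "episignature_size": len(self.selector.probes_),
            "n_dmps": len(self.dmp_ids),
            "loocv_iterations": int(self.loocv.shape[0]),
            "excluded_samples": self.sample_qc.excluded_samples,
            "n_excluded_probes": len(self.probe_qc.excluded_probes),
            "outlier_samples": sorted(self.outlier_report.outlier_samples),
            "split_seed": self.config.split_seed,
        }


def run_discovery(
    beta: BetaMatrix,
    reference: pd.DataFrame,
    case_cohorts: Sequence[str] = ("syndrome_a",),
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Path] = None,
) -> DiscoveryResult:
    """Run the full episignature discovery workflow on one case group.

    ``case_cohorts`` names the cohort label(s) whose ``group == 'case'``
    samples form the case group; all ``group == 'control'`` samples form
    the matching pool. Other case cohorts participate only as
    other-disorder samples in the classifier design and specificity
    evaluation.
    """
    if beta.samples is None:
        raise ConfigError("beta matrix must carry a sample sheet")
    unknown = set(case_cohorts) - set(beta.samples["cohort"])
    if unknown:
        raise ConfigError(f"unknown cohort label(s): {sorted(unknown)}")

    # 1. quality control: samples first, then probes
    beta_qc, sample_qc = filter_samples(beta, max_failure=config.max_failure)
    beta_qc, probe_qc = filter_probes(beta_qc)
    m = beta_to_m(beta_qc, eps=config.eps)
    outlier_report = pca_outlier_screen(m)

    samples = beta_qc.samples
    case_mask = samples["cohort"].isin(case_cohorts) & (samples["group"] == "case")
    case_ids = list(samples.index[case_mask])
    pool = samples[samples["group"] == "control"]

    # 2. matched controls, cell proportions, covariates
    match = match_controls(samples.loc[case_ids], pool, ratio=config.match_ratio)
    control_ids = match.control_ids
    match_summary = audit_match(match, samples.loc[case_ids], pool)
    proportions = estimate_proportions(beta_qc, reference)
    covariates = proportions_to_covariates(proportions)

    # 3. probe selection and its reproducibility
    selector = select_episignature(
        beta_qc, case_ids, control_ids, config.selection, covariates
    )
    loocv = run_loocv(beta_qc, case_ids, control_ids, config.selection, covariates)
    dmp_ids = list(
        call_dmps(selector.stats_, config.dmp_min_abs_delta, config.dmp_max_q)
    )

    # 4. classifier
    design = build_design(
        samples,
        case_ids,
        control_ids,
        split=config.split,
        seed=config.split_seed,
        holdout_cohorts=config.holdout_cohorts,
    )
    model = train_mvp(
        beta_qc, selector.probes_, design, C=config.svm_c, cutoff=config.svm_cutoff
    )
    roles = design.roles()
    mvp = score_mvp(model, beta_qc, samples.index, roles=roles.to_dict())
    mvp["cohort"] = samples["cohort"]
    mvp["group"] = samples["group"]
    test_sets = {
        cohort: [s for s in members.index if s in set(design.test_ids)]
        for cohort, members in samples.groupby("cohort", sort=True)
    }
    specificity = evaluate_specificity(
        model, beta_qc, {c: ids for c, ids in test_sets.items() if ids}
    )

    # 5. unsupervised verification on the probe-selection cohort
    training_cohort = case_ids + control_ids
    labels = pd.Series(
        ["case"] * len(case_ids) + ["control"] * len(control_ids),
        index=training_cohort,
    )
    separation = separation_report(
        beta_qc.values.loc[selector.probes_, training_cohort], labels
    )

    result = DiscoveryResult(
        case_cohorts=list(case_cohorts),
        case_ids=case_ids,
        sample_qc=sample_qc,
        probe_qc=probe_qc,
        outlier_report=outlier_report,
        match=match,
        match_summary=match_summary,
        proportions=proportions,
        selector=selector,
        loocv=loocv,
        dmp_ids=dmp_ids,
        design=design,
        model=model,
        mvp=mvp,
        specificity=specificity,
        separation=separation,
        config=config,
    )
    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def run_combined(
    beta: BetaMatrix,
    reference: pd.DataFrame,
    case_cohorts: Sequence[str],
    config: PipelineConfig = PipelineConfig(match_ratio=2),
    out_dir: Optional[Path] = None,
) -> DiscoveryResult:
    """Pool several case cohorts into one case group and rerun discovery.

    The per-source-cohort MVP summary lands in ``result.mvp`` (which
    carries each sample's cohort) and in the run manifest.
    """
    if len(case_cohorts) < 1:
        raise ConfigError("at least one case cohort must be named")
    return run_discovery(beta, reference, case_cohorts, config, out_dir)


def per_cohort_mvp_summary(result: DiscoveryResult) -> pd.DataFrame:
    """Median MVP score and positive rate per source cohort."""
    grouped = result.mvp.groupby("cohort")
    return pd.DataFrame(
        {
            "n": grouped.size(),
            "median_mvp": grouped["mvp_score"].median(),
            "positive_rate": grouped["call"].apply(
                lambda s: float((s == "positive").mean())
            ),
        }
    )


def write_artifacts(result: DiscoveryResult, out_dir: Path) -> Dict[str, Path]:
    """Write every stage output plus the run manifest; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def save(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        paths[name] = path

    save(
        "qc_report.json",
        lambda p: io.write_json(
            {
                "samples": result.sample_qc.to_dict(),
                "probes": result.probe_qc.to_dict(),
                "outliers": result.outlier_report.to_dict(),
            },
            p,
        ),
    )
    save("match.csv", lambda p: result.match.to_frame().to_csv(p, index=False))
    save("match_summary.json", lambda p: io.write_json(result.match_summary, p))
    save(
        "cell_proportions.csv",
        lambda p: result.proportions.rename_axis("sample_id").to_csv(p),
    )
    save(
        "probe_stats.tsv",
        lambda p: result.probe_stats.rename_axis("probe_id").to_csv(p, sep="\t"),
    )
    save(
        "episignature.tsv",
        lambda p: result.episignature.to_csv(p, sep="\t"),
    )
    save("dmps.tsv", lambda p: pd.Series(result.dmp_ids, name="probe_id").to_csv(p, sep="\t", index=False))
    save("loocv.csv", lambda p: result.loocv.to_csv(p, index=False))
    save("model.json", lambda p: result.model.to_json(p))
    save("mvp.csv", lambda p: result.mvp.to_csv(p))
    save("specificity.csv", lambda p: result.specificity.to_csv(p))
    save("separation.json", lambda p: io.write_json(result.separation, p))
    save(
        "per_cohort_mvp.csv",
        lambda p: per_cohort_mvp_summary(result).to_csv(p),
    )
    save("run_manifest.json", lambda p: io.write_json(result.manifest(), p))
    return paths
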