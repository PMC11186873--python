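"""Three-stage episignature probe selection and its LOOCV driver.

Stage 1 ranks probes by the product of effect size and evidence,
``|delta_beta| * (-ln q)`` with ``q`` the BH-adjusted p-value, and keeps
the top ``i`` (default 1000). Stage 2 computes each surviving probe's
AUROC for separating cases from controls and keeps the top ``j``
(default 500); the ranking uses ``max(auroc, 1 - auroc)`` so that hypo-
and hypermethylated probes compete on equal footing. Stage 3 scans the
stage-2 ranking greedily and drops any probe whose absolute Pearson
correlation with an already-kept probe exceeds ``k`` (default 0.75) on
the training samples.

The selection is wrapped in a scikit-learn style estimator,
:class:`EpisignatureSelector`, so it can sit inside pipelines and
cross-validation loops; the module-level functions expose the
individual stages.

Reproducibility of a signature is assessed by leave-one-out
cross-validation: each case in turn is held out, stages 1-3 are re-run
on the remaining samples, and the held-out sample is assigned to the
case or control side by the nearer group centroid (Euclidean distance,
beta scale, selected probes) — a formalisation of the visual
"does the test sample cluster with the cases" criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from . import dmp
from .containers import BetaMatrix
from .errors import ConfigError, ValidationError
from .preprocess import beta_to_m


@dataclass(frozen=True)
class SelectionConfig:
    """Stage sizes and thresholds of the three-stage selection."""

    i_product: int = 1000
    j_auroc: int = 500
    k_corr: float = 0.75
    value_scale: str = "beta"  # scale for AUROC and correlation pruning

    def __post_init__(self) -> None:
        if self.j_auroc > self.i_product:
            raise ConfigError("j_auroc must not exceed i_product")
        if not 0.0 < self.k_corr <= 1.0:
            raise ConfigError("k_corr must lie in (0, 1]")
        if self.value_scale not in ("beta", "m"):
            raise ConfigError("value_scale must be 'beta' or 'm'")


def product_score(stats_table: pd.DataFrame) -> pd.Series:
    """Stage-1 score ``|delta_beta| * (-ln q_bh)``, q floored at 1e-300."""
    q = stats_table["q_bh"].clip(lower=dmp.P_FLOOR)
    return (stats_table["delta_beta"].abs() * (-np.log(q))).rename("product_score")


def select_stage1(
    scores: pd.Series, q_bh: pd.Series, i_product: int = 1000
) -> List[str]:
    """Top ``i`` probes by product score; ties by smaller q, then probe id."""
    # mergesort is stable, so pre-sorting by probe id makes it the final
    # tie-break level after score (descending) and q (ascending)
    order = (
        pd.DataFrame({"score": scores, "q": q_bh})
        .sort_index()
        .sort_values(by=["score", "q"], ascending=[False, True], kind="mergesort")
    )
    return list(order.index[:i_product])


def probe_auroc(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """AUROC via the Mann-Whitney statistic.

    Returns the probability that a case value exceeds a control value,
    ties counted one half. Raw orientation: 1.0 means every case is
    above every control; hypomethylated signature probes score near 0.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValidationError("both groups must be non-empty for AUROC")
    combined = np.concatenate([case, control])
    ranks = rankdata(combined)
    r1 = ranks[: case.size].sum()
    u = r1 - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def _auroc_matrix(
    values: pd.DataFrame, case_ids: List[str], control_ids: List[str]
) -> pd.Series:
    """Row-wise raw AUROC for a probes x samples value matrix."""
    case = values[case_ids].to_numpy(dtype=float)
    control = values[control_ids].to_numpy(dtype=float)
    n1, n2 = case.shape[1], control.shape[1]
    ranks = rankdata(np.hstack([case, control]), axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    return pd.Series(u / (n1 * n2), index=values.index, name="auroc")


def select_stage2(
    stage1_probes: Sequence[str],
    values: pd.DataFrame,
    case_ids: Iterable[str],
    control_ids: Iterable[str],
    j_auroc: int = 500,
    scores: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Top ``j`` probes by orientation-free AUROC ``max(a, 1-a)``.

    Ties are broken by higher product score, then probe id. Returns a
    DataFrame (index = probe, in rank order) with ``auroc`` (raw) and
    ``auroc_ranking`` columns.
    """
    stage1_probes = list(stage1_probes)
    case_ids, control_ids = list(case_ids), list(control_ids)
    auroc = _auroc_matrix(values.loc[stage1_probes], case_ids, control_ids)
    table = pd.DataFrame(
        {
            "auroc": auroc,
            "auroc_ranking": np.maximum(auroc, 1.0 - auroc),
            "product_score": (
                scores.reindex(stage1_probes)
                if scores is not None
                else pd.Series(0.0, index=stage1_probes)
            ),
        }
    )
    table = table.sort_index().sort_values(
        by=["auroc_ranking", "product_score"],
        ascending=[False, False],
        kind="mergesort",
    )
    return table.iloc[:j_auroc]


def prune_correlated(
    ranked_probes: Sequence[str], values: pd.DataFrame, k_corr: float = 0.75
) -> List[str]:
    """Greedy correlation pruning in rank order.

    A probe is kept iff its absolute Pearson correlation with every
    already-kept probe is at most ``k_corr`` on the provided (training)
    samples. Zero-variance probes are excluded with a warning since
    their correlation is undefined.
    """
    ranked_probes = list(ranked_probes)
    X = values.loc[ranked_probes].to_numpy(dtype=float)  # probes x samples
    sd = X.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        bad = [p for p, z in zip(ranked_probes, zero_var) if z]
        warnings.warn(
            f"{len(bad)} zero-variance probes excluded from pruning "
            f"(correlation undefined): {bad[:5]}"
        )
    Z = np.zeros_like(X)
    ok = ~zero_var
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    n = X.shape[1]
    kept_idx: List[int] = []
    for i, probe in enumerate(ranked_probes):
        if zero_var[i]:
            continue
        if kept_idx:
            r = Z[kept_idx] @ Z[i] / (n - 1)
            if np.any(np.abs(r) > k_corr):
                continue
        kept_idx.append(i)
    return [ranked_probes[i] for i in kept_idx]


class EpisignatureSelector(BaseEstimator):
    """Scikit-learn style wrapper around the three-stage selection.

    ``fit`` expects ``X`` as a samples x probes beta-value DataFrame and
    ``y`` as a binary case indicator; cell-proportion covariates may be
    passed as a fit parameter. ``transform`` restricts a samples x
    probes matrix to the selected probes in selection order.

    Attributes
    ----------
    probes_ : list of str
        Selected probes, in stage-2 rank order.
    selection_ : pandas.DataFrame
        One row per selected probe: product_score, auroc, selection_rank.
    stats_ : pandas.DataFrame
        Full per-probe statistics table from the moderated linear model.
    """

    def __init__(
        self,
        i_product: int = 1000,
        j_auroc: int = 500,
        k_corr: float = 0.75,
        value_scale: str = "beta",
        eps: float = 1e-3,
    ):
        self.i_product = i_product
        self.j_auroc = j_auroc
        self.k_corr = k_corr
        self.value_scale = value_scale
        self.eps = eps

    @property
    def _config(self) -> SelectionConfig:
        return SelectionConfig(
            i_product=self.i_product,
            j_auroc=self.j_auroc,
            k_corr=self.k_corr,
            value_scale=self.value_scale,
        )

    def fit(self, X: pd.DataFrame, y, covariates: Optional[pd.DataFrame] = None):
        cfg = self._config  # validates parameters
        y = np.asarray(y)
        if X.shape[0] != y.size:
            raise ValidationError("X rows and y length differ")
        case_ids = list(X.index[y == 1])
        control_ids = list(X.index[y == 0])
        beta = X.T  # probes x samples
        m = beta_to_m(beta, eps=self.eps)
        stats_table = dmp.probe_stats(beta, m, case_ids, control_ids, covariates)
        values = beta if cfg.value_scale == "beta" else m
        scores = product_score(stats_table)
        stage1 = select_stage1(scores, stats_table["q_bh"], cfg.i_product)
        stage2 = select_stage2(
            stage1, values, case_ids, control_ids, cfg.j_auroc, scores
        )
        kept = prune_correlated(list(stage2.index), values, cfg.k_corr)
        self.stats_ = stats_table
        self.stage1_probes_ = stage1
        self.stage2_ = stage2
        self.probes_ = kept
        self.selection_ = pd.DataFrame(
            {
                "product_score": scores.reindex(kept),
                "auroc": stage2["auroc"].reindex(kept),
                "selection_rank": np.arange(1, len(kept) + 1),
            }
        )
        self.selection_.index.name = "probe_id"
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "probes_"):
            raise ValidationError("selector is not fitted")
        missing = [p for p in self.probes_ if p not in X.columns]
        if missing:
            raise ValidationError(f"input lacks selected probes: {missing[:5]}")
        return X[self.probes_]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def select_episignature(
    beta: BetaMatrix | pd.DataFrame,
    case_ids: Iterable[str],
    control_ids: Iterable[str],
    config: SelectionConfig = SelectionConfig(),
    covariates: Optional[pd.DataFrame] = None,
) -> EpisignatureSelector:
    """Run the three-stage selection on a probes x samples beta matrix."""
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    case_ids, control_ids = list(case_ids), list(control_ids)
    sample_ids = case_ids + control_ids
    X = values[sample_ids].T
    y = np.array([1] * len(case_ids) + [0] * len(control_ids))
    selector = EpisignatureSelector(
        i_product=config.i_product,
        j_auroc=config.j_auroc,
        k_corr=config.k_corr,
        value_scale=config.value_scale,
    )
    cov = covariates.loc[sample_ids] if covariates is not None else None
    return selector.fit(X, y, covariates=cov)


def run_loocv(
    beta: BetaMatrix | pd.DataFrame,
    case_ids: Iterable[str],
    control_ids: Iterable[str],
    config: SelectionConfig = SelectionConfig(),
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One leave-one-out iteration per case.

    Each iteration re-derives the episignature from the remaining cases
    and all controls and assigns the held-out case to the nearer group
    centroid. Returns one row per iteration with the held-out sample id,
    the iteration's probe-set size, the assignment, and whether the
    assignment was the case side.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    case_ids, control_ids = list(case_ids), list(control_ids)
    if len(case_ids) < 3:
        raise ValidationError("LOOCV needs at least 3 cases")
    rows = []
    for held_out in case_ids:
        train_cases = [c for c in case_ids if c != held_out]
        selector = select_episignature(
            values, train_cases, control_ids, config, covariates
        )
        probes = selector.probes_
        case_centroid = values.loc[probes, train_cases].mean(axis=1)
        control_centroid = values.loc[probes, control_ids].mean(axis=1)
        test = values.loc[probes, held_out]
        d_case = float(np.linalg.norm(test - case_centroid))
        d_control = float(np.linalg.norm(test - control_centroid))
        assigned = "case" if d_case <= d_control else "control"
        rows.append(
            {
                "held_out": held_out,
                "n_probes": len(probes),
                "distance_case": d_case,
                "distance_control": d_control,
                "assigned": assigned,
                "correct": assigned == "case",
            }
        )
    return pd.DataFrame(rows)
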