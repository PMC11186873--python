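"""Per-probe differential-methylation statistics.

Each probe's M-values are regressed on a design matrix (intercept, case
indicator, cell-proportion covariates) by ordinary least squares. The
residual variances are then shrunk toward a pooled prior by empirical
Bayes: a scaled-F prior is fitted to the observed variances by matching
the first two moments of ``log s2`` (digamma/trigamma inversion), and
the posterior variance

    s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)

yields a moderated t-statistic on ``d0 + df`` degrees of freedom.
P-values are Benjamini-Hochberg adjusted. Effect sizes are reported on
two scales: the regression coefficient on the M scale and delta-beta
(case mean minus control mean) on the beta scale — inference runs on M,
thresholds are stated on beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix
from .errors import ValidationError

#: floor applied to p/q-values before any logarithm downstream
P_FLOOR = 1e-300

PROBE_STAT_COLUMNS = [
    "delta_beta",
    "coef_m",
    "s2",
    "df_residual",
    "t_moderated",
    "p_raw",
    "q_bh",
]


@dataclass(frozen=True)
class ModerationHyperparams:
    """Scaled-F prior for the residual variances."""

    d0: float  # prior degrees of freedom; may be math.inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("prior degrees of freedom must be >= 0")
        if not self.s0_sq > 0:
            raise ValidationError("prior variance must be positive")


def build_design(
    case_indicator: pd.Series, covariates: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Assemble intercept + case indicator + optional covariate columns."""
    design = pd.DataFrame(
        {"intercept": 1.0, "case": case_indicator.astype(float)},
        index=case_indicator.index,
    )
    if covariates is not None:
        cov = covariates.loc[case_indicator.index].astype(float)
        # an identically-zero covariate carries no information and would only
        # make the design singular; dropping it reduces exactly to the
        # smaller model
        cov = cov.loc[:, (cov != 0).any(axis=0)]
        design = design.join(cov)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return design


def fit_probewise(
    m: pd.DataFrame, design: pd.DataFrame, coef: str = "case"
) -> pd.DataFrame:
    """OLS per probe; returns coef_m, s2, df_residual (+ the variance factor).

    ``m`` is probes x samples; ``design`` is samples x terms with sample
    order matching ``m``'s columns.
    """
    if list(m.columns) != list(design.index):
        design = design.loc[m.columns]
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError("design matrix is rank deficient")
    Y = m.to_numpy(dtype=float)  # probes x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T  # k x n
    coefs = Y @ pinv.T  # probes x k
    resid = Y - coefs @ X.T
    df = n - k
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df if df > 0 else np.full(Y.shape[0], np.nan)
    s2 = np.where(s2 < 0, 0.0, s2)  # numerical guard
    j = list(design.columns).index(coef)
    out = pd.DataFrame(
        {
            "coef_m": coefs[:, j],
            "s2": s2,
            "df_residual": float(df),
        },
        index=m.index,
    )
    out.attrs["coef_variance_factor"] = float(xtx_inv[j, j])
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_hyperparams(s2: np.ndarray, df: float) -> ModerationHyperparams:
    """Fit (d0, s0_sq) by moment matching on log variances.

    Under the scaled-F model, ``e = log s2 - digamma(df/2) + log(df/2)``
    has mean ``log s0_sq + digamma(d0/2) - log(d0/2)`` and excess
    variance ``trigamma(d0/2)`` beyond the sampling term
    ``trigamma(df/2)``; inverting the trigamma recovers d0.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValidationError("all residual variances are zero; cannot moderate")
    if positive.size < 10:
        raise ValidationError("need at least 10 probes to estimate the prior")
    z = np.log(positive)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        # no excess dispersion beyond sampling noise: point prior at the
        # pooled variance
        d0 = math.inf
        s0_sq = float(positive.mean())
    return ModerationHyperparams(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(
    fits: pd.DataFrame,
    hyper: ModerationHyperparams | str = "estimate",
    coef_variance_factor: Optional[float] = None,
) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values per probe.

    ``fits`` is the output of :func:`fit_probewise`. ``hyper`` may be
    explicit hyperparameters or ``"estimate"`` to fit them from the
    observed variances. ``d0 = 0`` reproduces the ordinary t-statistic;
    ``d0 = inf`` replaces every variance with the prior.
    """
    s2 = fits["s2"].to_numpy(dtype=float)
    df = float(fits["df_residual"].iloc[0])
    if coef_variance_factor is None:
        coef_variance_factor = fits.attrs.get("coef_variance_factor")
    if coef_variance_factor is None:
        raise ValidationError("coefficient variance factor not available")
    if isinstance(hyper, str):
        if hyper != "estimate":
            raise ValidationError(f"unknown hyper mode {hyper!r}")
        hyper = estimate_hyperparams(s2, df)
    if np.all(s2 == 0) and hyper.d0 == 0:
        raise ValidationError("all residual variances are zero; t undefined")
    if math.isinf(hyper.d0):
        s2_tilde = np.full_like(s2, hyper.s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (hyper.d0 * hyper.s0_sq + df * s2) / (hyper.d0 + df)
        df_total = hyper.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits["coef_m"].to_numpy() / np.sqrt(s2_tilde * coef_variance_factor)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fits.copy()
    out["t_moderated"] = t
    out["p_raw"] = p
    out.attrs["hyperparams"] = hyper
    out.attrs["df_total"] = df_total
    return out


def compute_delta_beta(
    beta: BetaMatrix | pd.DataFrame,
    case_ids: Iterable[str],
    control_ids: Iterable[str],
) -> pd.Series:
    """Per-probe case mean minus control mean, on the beta scale."""
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise ValidationError("both groups must be non-empty")
    if set(case_ids) & set(control_ids):
        raise ValidationError("case and control id sets overlap")
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    delta = values[case_ids].mean(axis=1) - values[control_ids].mean(axis=1)
    return delta.rename("delta_beta")


def adjust_bh(p_raw: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    arr = np.asarray(p_raw, dtype=float)
    if arr.size == 0:
        return p_raw
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p_raw, pd.Series):
        return pd.Series(q, index=p_raw.index, name="q_bh")
    return q


def probe_stats(
    beta: BetaMatrix | pd.DataFrame,
    m: pd.DataFrame,
    case_ids: Iterable[str],
    control_ids: Iterable[str],
    covariates: Optional[pd.DataFrame] = None,
    hyper: ModerationHyperparams | str = "estimate",
) -> pd.DataFrame:
    """Full per-probe statistics table for a case/control comparison.

    Combines OLS on M-values (restricted to cases + controls), empirical
    Bayes moderation, BH adjustment and beta-scale delta-beta into one
    probe x statistic table with :data:`PROBE_STAT_COLUMNS`.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    sample_ids = case_ids + control_ids
    indicator = pd.Series(
        [1.0] * len(case_ids) + [0.0] * len(control_ids), index=sample_ids
    )
    cov = covariates.loc[sample_ids] if covariates is not None else None
    design = build_design(indicator, cov)
    fits = fit_probewise(m[sample_ids], design)
    moderated = ebayes_moderate(fits, hyper=hyper)
    moderated["q_bh"] = adjust_bh(moderated["p_raw"])
    moderated["delta_beta"] = compute_delta_beta(beta, case_ids, control_ids)
    stats_table = moderated[PROBE_STAT_COLUMNS]
    stats_table.attrs.update(moderated.attrs)
    return stats_table


def call_dmps(
    stats_table: pd.DataFrame, min_abs_delta: float = 0.05, max_q: float = 0.01
) -> pd.Index:
    """Differentially methylated probes: |delta_beta| > 5% AND q < 0.01.

    Both inequalities are strict; a probe at exactly the threshold is
    not called.
    """
    mask = (stats_table["delta_beta"].abs() > min_abs_delta) & (
        stats_table["q_bh"] < max_q
    )
    return stats_table.index[mask]
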