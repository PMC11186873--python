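"""Sample/probe quality control, M-value transform, PCA outlier screen.

Quality control mirrors standard methylation-array practice: arrays with
more than 5% failed probes are dropped, then probes are removed when
they sit on an allosome, overlap a SNP, cross-react, are vendor-flagged,
or still carry missing values after sample exclusion. "Probe failure"
is operationalised as a missing (NaN) entry; detection p-values are not
part of this artifact's contract.

Linear modelling downstream runs on M-values, ``M = log2(b/(1-b))``
with beta clipped to ``[eps, 1-eps]`` (base-2 logit, the standard
M-value convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .containers import BetaMatrix
from .errors import ConfigError, EmptyCohortError, ValidationError

PROBE_EXCLUSION_REASONS = (
    "allosome",
    "snp",
    "vendor",
    "crossreactive",
    "missing_after_sample_qc",
)

#: M-value matrix: same axes as the beta matrix it came from.
MValueMatrix = pd.DataFrame


@dataclass
class QcReport:
    """Record of quality-control exclusions and flagged outliers."""

    excluded_samples: Dict[str, float] = field(default_factory=dict)
    excluded_probes: Dict[str, str] = field(default_factory=dict)
    outlier_samples: Dict[str, List[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.excluded_probes.values()) - set(PROBE_EXCLUSION_REASONS)
        if bad:
            raise ValidationError(f"unknown probe exclusion reasons: {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            "excluded_samples": self.excluded_samples,
            "excluded_probes": self.excluded_probes,
            "outlier_samples": self.outlier_samples,
        }


def filter_samples(
    beta: BetaMatrix, max_failure: float = 0.05
) -> Tuple[BetaMatrix, QcReport]:
    """Drop samples whose probe-failure fraction exceeds ``max_failure``.

    The inequality is strict: a sample failing exactly 5% of probes is
    retained at the default threshold.
    """
    frac = beta.values.isna().mean(axis=0)
    dropped = frac[frac > max_failure]
    keep = [s for s in beta.sample_ids if s not in dropped.index]
    if not keep:
        raise EmptyCohortError("all samples exceeded the probe-failure threshold")
    report = QcReport(excluded_samples={s: float(f) for s, f in dropped.items()})
    return beta.subset_samples(keep), report


def filter_probes(beta: BetaMatrix) -> Tuple[BetaMatrix, QcReport]:
    """Remove flagged probes; each removal carries exactly one reason.

    Reasons are checked in a fixed priority order (allosome, SNP,
    vendor, cross-reactive, residual missingness) so the report
    partitions the removed probes.
    """
    if beta.manifest is None:
        raise ValidationError("probe filtering requires a manifest")
    man = beta.manifest.loc[beta.probe_ids]
    reasons: Dict[str, str] = {}
    checks = [
        (man["chrom"].isin(["chrX", "chrY"]), "allosome"),
        (man["snp_flag"].astype(bool), "snp"),
        (man["excluded_by_vendor_flag"].astype(bool), "vendor"),
        (man["crossreactive_flag"].astype(bool), "crossreactive"),
        (beta.values.isna().any(axis=1), "missing_after_sample_qc"),
    ]
    for mask, reason in checks:
        for probe in beta.probe_ids[np.asarray(mask)]:
            reasons.setdefault(probe, reason)
    keep = [p for p in beta.probe_ids if p not in reasons]
    return beta.subset_probes(keep), QcReport(excluded_probes=reasons)


def beta_to_m(beta: BetaMatrix | pd.DataFrame, eps: float = 1e-3) -> MValueMatrix:
    """Base-2 logit transform with clipping: ``M = log2(b'/(1-b'))``.

    ``b' = clip(beta, eps, 1-eps)``; missing values propagate.
    """
    if not 0.0 < eps < 0.5:
        raise ConfigError("eps must lie in (0, 0.5)")
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    clipped = values.clip(lower=eps, upper=1.0 - eps)
    return np.log2(clipped / (1.0 - clipped))


def m_to_beta(m: MValueMatrix) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` (up to clipping)."""
    return 1.0 / (1.0 + 2.0 ** (-m))


def pca_outlier_screen(
    m: MValueMatrix, n_components: int = 2, sd_threshold: float = 3.0
) -> QcReport:
    """Flag samples extreme on the leading principal components.

    Samples are scored on the top ``n_components`` PCs of the M-value
    matrix (samples as observations); a sample is flagged when any of
    its scores is more than ``sd_threshold`` standard deviations from
    that component's mean. Flagged samples are reported, not removed —
    outlier exclusion is a human decision.
    """
    values = m.to_numpy(dtype=float).T  # samples x probes
    n_samples = values.shape[0]
    if n_samples < 3:
        raise ValidationError("PCA outlier screen needs at least 3 samples")
    if n_samples < n_components:
        raise ValidationError("fewer samples than requested components")
    centered = values - values.mean(axis=0)
    # scores via SVD; deterministic and cheap for cohort-scale data
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.abs(scores - scores.mean(axis=0)) / sd
    outliers = {}
    for i, sample in enumerate(m.columns):
        if (z[i] > sd_threshold).any():
            outliers[sample] = [float(v) for v in scores[i]]
    return QcReport(outlier_samples=outliers)
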