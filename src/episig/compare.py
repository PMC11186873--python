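"""Cross-cohort DMP comparison: overlap, global shift, relatedness tree.

Given per-cohort DMP profiles (probes passing |delta-beta| > 5% and
BH q < 0.01), this module computes

* the asymmetric overlap matrix — entry (A, B) is the percentage of A's
  DMPs also present in B's DMPs,
* the global methylation difference — the signed mean delta-beta across
  a cohort's DMPs (negative for predominantly hypomethylated profiles),
* a tree-and-leaf relatedness tree — per cohort the ``min(cap, #DMPs)``
  lowest-q DMPs are pooled, a probes x cohorts matrix of cohort median
  beta values is assembled over the pooled probes, and the cohort
  columns are clustered by Ward's method on Euclidean distance,
* CGI and gene-context annotation proportions of a DMP set, using the
  categorical classes carried in the probe manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import BetaMatrix, CGI_CLASSES, GENE_CLASSES
from .errors import ConfigError, ValidationError
from .evaluate import LinkageTree, ward_cluster


@dataclass
class CohortDmpProfile:
    """One cohort's DMP set with statistics and median methylation."""

    cohort: str
    #: DMP probes with at least delta_beta and q_bh columns
    dmps: pd.DataFrame
    #: median beta across the cohort's case samples, indexed by probe
    median_beta: pd.Series

    @property
    def dmp_ids(self) -> set:
        return set(self.dmps.index)

    @property
    def n_dmps(self) -> int:
        return len(self.dmps)


@dataclass(frozen=True)
class ComparisonConfig:
    """Tree construction parameters."""

    max_dmps_for_tree: int = 500
    rank_by: str = "q_bh"  # or "p_raw"

    def __post_init__(self) -> None:
        if self.max_dmps_for_tree < 1:
            raise ConfigError("max_dmps_for_tree must be positive")
        if self.rank_by not in ("q_bh", "p_raw"):
            raise ConfigError("rank_by must be 'q_bh' or 'p_raw'")


def build_profile(
    cohort: str,
    stats_table: pd.DataFrame,
    dmp_ids: Sequence[str],
    beta: BetaMatrix | pd.DataFrame,
    sample_ids: Sequence[str],
) -> CohortDmpProfile:
    """Assemble a cohort's DMP profile from its statistics and samples."""
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    dmp_ids = list(dmp_ids)
    return CohortDmpProfile(
        cohort=cohort,
        dmps=stats_table.loc[dmp_ids],
        median_beta=values.loc[:, list(sample_ids)].median(axis=1),
    )


def overlap_matrix(profiles: Sequence[CohortDmpProfile]) -> pd.DataFrame:
    """Asymmetric DMP overlap in percent: (A, B) = 100 |A∩B| / |A|.

    The diagonal is exactly 100. A cohort with an empty DMP set yields
    NaN entries in its row (the ratio is undefined).
    """
    if len(profiles) < 2:
        raise ValidationError("overlap matrix needs at least 2 cohorts")
    names = [p.cohort for p in profiles]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate cohort labels")
    sets = {p.cohort: p.dmp_ids for p in profiles}
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            if not sets[a]:
                out.loc[a, b] = np.nan
            elif a == b:
                out.loc[a, b] = 100.0
            else:
                out.loc[a, b] = 100.0 * len(sets[a] & sets[b]) / len(sets[a])
    return out


def global_methylation_difference(profile: CohortDmpProfile) -> float:
    """Signed mean delta-beta across the cohort's DMPs (NaN if empty)."""
    if profile.n_dmps == 0:
        return float("nan")
    return float(profile.dmps["delta_beta"].mean())


def tree_and_leaf(
    profiles: Sequence[CohortDmpProfile],
    config: ComparisonConfig = ComparisonConfig(),
) -> LinkageTree:
    """Ward/Euclidean tree over cohorts from median beta at top DMPs.

    Per cohort, the ``min(max_dmps_for_tree, #DMPs)`` DMPs with the
    lowest adjusted p-values contribute; the union of contributions
    defines the probe rows. Cohorts with zero DMPs are excluded with a
    warning.
    """
    usable: List[CohortDmpProfile] = []
    for p in profiles:
        if p.n_dmps == 0:
            warnings.warn(f"cohort {p.cohort!r} has no DMPs; excluded from tree")
        else:
            usable.append(p)
    if len(usable) < 2:
        raise ValidationError("tree needs at least 2 cohorts with DMPs")
    chosen: Dict[str, List[str]] = {}
    for p in usable:
        n = min(config.max_dmps_for_tree, p.n_dmps)
        # stable sort after an index pre-sort: ties in q resolve by probe id
        ranked = p.dmps.sort_index().sort_values(by=[config.rank_by], kind="mergesort")
        chosen[p.cohort] = list(ranked.index[:n])
    probes = sorted(set().union(*chosen.values()))
    matrix = pd.DataFrame(
        {p.cohort: p.median_beta.reindex(probes) for p in usable}, index=probes
    )
    if matrix.isna().any().any():
        raise ValidationError("median beta missing for some pooled probes")
    return ward_cluster(matrix)


def annotate_dmps(
    dmp_ids: Sequence[str], manifest: pd.DataFrame
) -> Dict[str, Dict[str, float]]:
    """Category proportions of a DMP set in the CGI and gene vocabularies.

    Proportions sum to 1 per vocabulary over the annotated probes;
    probes absent from the manifest are counted as unannotated with a
    warning. An empty DMP set yields NaN proportions.
    """
    dmp_ids = list(dmp_ids)
    result: Dict[str, Dict[str, float]] = {}
    vocabularies = {"cgi_class": CGI_CLASSES, "gene_class": GENE_CLASSES}
    if not dmp_ids:
        for column, classes in vocabularies.items():
            result[column] = {c: float("nan") for c in classes}
        result["unannotated"] = {"count": 0.0}
        return result
    present = [p for p in dmp_ids if p in manifest.index]
    absent = len(dmp_ids) - len(present)
    if absent:
        warnings.warn(f"{absent} DMPs absent from manifest; counted as unannotated")
    for column, classes in vocabularies.items():
        counts = manifest.loc[present, column].value_counts()
        total = counts.sum()
        result[column] = {
            c: (float(counts.get(c, 0)) / total if total else float("nan"))
            for c in classes
        }
    result["unannotated"] = {"count": float(absent)}
    return result


def common_probe_filter(
    manifest: pd.DataFrame, whitelist: Optional[Sequence[str]] = None
) -> pd.Index:
    """Optional probe whitelist (e.g. probes shared by array generations)."""
    if whitelist is None:
        return manifest.index
    return manifest.index.intersection(pd.Index(whitelist))
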