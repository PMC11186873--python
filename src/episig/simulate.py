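"""Synthetic blood-methylation cohort generator.

Emulates the statistical structure that the episignature pipeline
assumes in real EPIC-array data from peripheral blood:

* a probe x sample beta matrix whose per-probe baselines are bimodal
  (mostly unmethylated or mostly methylated CpGs, plus an intermediate
  fraction),
* per-sample variation in blood cell composition, modelled as a
  Dirichlet mixture over cell-type reference profiles — the confounder
  the linear model later adjusts for,
* a planted set of differentially methylated probes in case samples,
  predominantly hypomethylated, with effects defined on the beta scale,
* measurement noise that is Gaussian on the M (logit) scale, so beta
  values stay inside (0, 1) and the M-value linear model downstream is
  well specified,
* optional overlapping "sister" syndromes that share a tunable fraction
  of the planted signature, and optional injected probe failures for
  quality-control testing.

The generator returns the ground truth (planted probes, signed effects,
true cell proportions) so parameter-recovery tests can score every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .containers import BetaMatrix, CGI_CLASSES, GENE_CLASSES
from .errors import ConfigError

# Marginal class frequencies used when drawing probe annotation context.
_CGI_PROBS = (0.30, 0.25, 0.10, 0.35)
_GENE_PROBS = (0.25, 0.15, 0.30, 0.25, 0.05)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic case/control methylation cohort.

    Defaults follow the discovery-cohort conditions the pipeline is
    designed around: 13 cases against a pool of 200 candidate controls,
    ages 2-47 years, both sexes, a planted signature of 300 probes that
    is 80% hypomethylated in cases, and logit-scale noise of 0.3.
    """

    n_probes: int = 20000
    n_cases: int = 13
    n_validation_cases: int = 0
    n_control_pool: int = 200
    n_cell_types: int = 6
    signature_size: int = 300
    effect_delta_beta: float = 0.10
    hypo_fraction: float = 0.8
    overlap_fraction_secondary: float = 0.5
    overlap_fraction_tertiary: Optional[float] = None  # None: same as secondary
    noise_sd_logit: float = 0.3
    age_range_years: Tuple[float, float] = (2.0, 47.0)
    probe_failure_rate: float = 0.0
    seed: int = 0
    # cell-mixture model
    n_discriminating_probes: int = 500
    dirichlet_alpha: float = 5.0
    fixed_cell_proportions: bool = False
    case_cell_shift: float = 0.0  # optional confounding shift, off by default

    def __post_init__(self) -> None:
        if self.signature_size >= self.n_probes:
            raise ConfigError("signature_size must be smaller than n_probes")
        for name in (
            "hypo_fraction",
            "overlap_fraction_secondary",
            "overlap_fraction_tertiary",
            "probe_failure_rate",
        ):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_cell_types < 2:
            raise ConfigError("n_cell_types must be at least 2")
        if self.noise_sd_logit < 0:
            raise ConfigError("noise_sd_logit must be non-negative")
        if self.age_range_years[0] > self.age_range_years[1]:
            raise ConfigError("age_range_years must be (min, max)")
        if self.signature_size + self.n_discriminating_probes > self.n_probes:
            raise ConfigError(
                "signature and discriminating probe sets must fit in n_probes"
            )


@dataclass
class GroundTruth:
    """Truth labels of a simulated cohort, for parameter-recovery tests."""

    #: signed beta-scale effect per planted probe, keyed by cohort label
    cohort_effects: Dict[str, pd.Series]
    #: true cell-type proportions, samples x cell types, rows sum to 1
    cell_proportions: pd.DataFrame
    #: mean beta of each cell type at the discriminating probes
    reference_profiles: pd.DataFrame
    #: probes shared with the primary cohort, keyed by secondary cohort label
    shared_probe_ids: Dict[str, Set[str]] = field(default_factory=dict)

    @property
    def planted_probe_ids(self) -> Set[str]:
        """Planted probes of the primary cohort."""
        first = next(iter(self.cohort_effects))
        return set(self.cohort_effects[first].index)

    def planted_for(self, cohort: str) -> Set[str]:
        return set(self.cohort_effects[cohort].index)


# ---------------------------------------------------------------------------
# building blocks


def _probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(1, n + 1)], name="probe_id")


def _make_manifest(rng: np.random.Generator, probe_ids: pd.Index) -> pd.DataFrame:
    n = len(probe_ids)
    chrom = rng.choice([f"chr{i}" for i in range(1, 23)], size=n)
    start = rng.integers(10_000, 200_000_000, size=n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + 2,
            "cgi_class": rng.choice(CGI_CLASSES, size=n, p=_CGI_PROBS),
            "gene_class": rng.choice(GENE_CLASSES, size=n, p=_GENE_PROBS),
            "snp_flag": False,
            "crossreactive_flag": False,
            "excluded_by_vendor_flag": False,
        },
        index=probe_ids,
    )


def _baseline_betas(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal probe baselines typical of methylation arrays."""
    comp = rng.choice(3, size=n, p=(0.4, 0.4, 0.2))
    out = np.empty(n)
    low = comp == 0
    high = comp == 1
    mid = comp == 2
    out[low] = rng.beta(2.0, 10.0, size=low.sum())
    out[high] = rng.beta(10.0, 2.0, size=high.sum())
    out[mid] = rng.beta(5.0, 5.0, size=mid.sum())
    return np.clip(out, 0.03, 0.97)


def _logit2(b: np.ndarray) -> np.ndarray:
    return np.log2(b / (1.0 - b))


def _expit2(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp2(-m))


def _draw_signs(rng: np.random.Generator, n: int, hypo_fraction: float) -> np.ndarray:
    return np.where(rng.random(n) < hypo_fraction, -1.0, 1.0)


class _CohortBuilder:
    """Shared machinery for the single- and multi-syndrome generators."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.probe_ids = _probe_ids(config.n_probes)
        self.manifest = _make_manifest(self.rng, self.probe_ids)
        self.baseline = _baseline_betas(self.rng, config.n_probes)
        # reserve the first blocks of a random permutation for the planted
        # and cell-type-discriminating probe sets so they never overlap
        perm = self.rng.permutation(config.n_probes)
        self._free = list(perm)
        self.discriminating_idx = np.sort(
            np.array([self._free.pop() for _ in range(config.n_discriminating_probes)])
        )
        self.cell_types = [f"cell{k}" for k in range(1, config.n_cell_types + 1)]
        self.reference = self._make_reference()

    def take_signature(self, size: int) -> np.ndarray:
        if size > len(self._free):
            raise ConfigError("not enough free probes for the requested signatures")
        return np.sort(np.array([self._free.pop(0) for _ in range(size)], dtype=int))

    def _make_reference(self) -> pd.DataFrame:
        cfg = self.config
        dev = self.rng.normal(0.0, 0.02, size=(cfg.n_probes, cfg.n_cell_types))
        dev[self.discriminating_idx] = self.rng.normal(
            0.0, 0.15, size=(len(self.discriminating_idx), cfg.n_cell_types)
        )
        ref = np.clip(self.baseline[:, None] + dev, 0.02, 0.98)
        return pd.DataFrame(ref, index=self.probe_ids, columns=self.cell_types)

    def draw_proportions(self, n: int) -> np.ndarray:
        cfg = self.config
        if cfg.fixed_cell_proportions:
            return np.full((n, cfg.n_cell_types), 1.0 / cfg.n_cell_types)
        w = self.rng.dirichlet(
            np.full(cfg.n_cell_types, cfg.dirichlet_alpha), size=n
        )
        return w

    def sample_block(
        self, n: int, effects: Optional[pd.Series], shift_first_cell: float = 0.0
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Beta values (probes x n) and true proportions for one group."""
        cfg = self.config
        w = self.draw_proportions(n)
        if shift_first_cell:
            w[:, 0] = np.clip(w[:, 0] + shift_first_cell, 0.0, None)
            w /= w.sum(axis=1, keepdims=True)
        x = self.reference.to_numpy() @ w.T  # probes x n
        if effects is not None:
            idx = self.probe_ids.get_indexer(effects.index)
            x[idx, :] += effects.to_numpy()[:, None]
        x = np.clip(x, 0.01, 0.99)
        if cfg.noise_sd_logit > 0:
            m = _logit2(x) + self.rng.normal(0.0, cfg.noise_sd_logit, size=x.shape)
            x = _expit2(m)
        return x, w

    def make_effects(self, idx: np.ndarray) -> pd.Series:
        cfg = self.config
        # give planted probes mid-range, cell-type-invariant baselines so the
        # added effect is never flattened by the [0.01, 0.99] clip and the
        # noise-free limit recovers the planted delta-beta exactly
        self.baseline[idx] = self.rng.uniform(0.2, 0.8, size=len(idx))
        self.reference.iloc[idx] = np.repeat(
            self.baseline[idx, None], cfg.n_cell_types, axis=1
        )
        signs = _draw_signs(self.rng, len(idx), cfg.hypo_fraction)
        return pd.Series(
            signs * cfg.effect_delta_beta, index=self.probe_ids[idx], name="effect"
        )

    def sheet_rows(self, ids, group: str, cohort: str) -> pd.DataFrame:
        cfg = self.config
        n = len(ids)
        lo, hi = cfg.age_range_years
        return pd.DataFrame(
            {
                "sex": self.rng.choice(["M", "F"], size=n),
                "age_years": np.round(self.rng.uniform(lo, hi, size=n), 1),
                "group": group,
                "cohort": cohort,
            },
            index=pd.Index(ids, name="sample_id"),
        )


def _assemble(
    builder: _CohortBuilder,
    blocks: Sequence[Tuple[str, str, str, Optional[pd.Series], int]],
) -> Tuple[BetaMatrix, pd.DataFrame, pd.DataFrame]:
    """blocks: (id_prefix, group, cohort, effects, n) per sample group."""
    cfg = builder.config
    columns, sheets, mats, props = [], [], [], []
    for prefix, group, cohort, effects, n in blocks:
        shift = cfg.case_cell_shift if group == "case" else 0.0
        x, w = builder.sample_block(n, effects, shift_first_cell=shift)
        ids = [f"{prefix}{i:03d}" for i in range(1, n + 1)]
        columns.extend(ids)
        mats.append(x)
        props.append(pd.DataFrame(w, index=ids, columns=builder.cell_types))
        sheets.append(builder.sheet_rows(ids, group, cohort))
    values = pd.DataFrame(
        np.hstack(mats), index=builder.probe_ids, columns=columns
    )
    samples = pd.concat(sheets)
    proportions = pd.concat(props)
    proportions.index.name = "sample_id"
    return BetaMatrix(values, builder.manifest, samples), samples, proportions


# ---------------------------------------------------------------------------
# public API


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Simulate one case cohort plus a control pool.

    Returns the beta matrix (manifest and sample sheet attached), the
    sample sheet, and the :class:`GroundTruth`. Deterministic for a
    fixed ``config.seed``.
    """
    builder = _CohortBuilder(config)
    sig_idx = builder.take_signature(config.signature_size)
    effects = builder.make_effects(sig_idx)
    blocks = [("case_", "case", "syndrome_a", effects, config.n_cases)]
    if config.n_validation_cases:
        # independent case samples carrying the same planted effects; the
        # study design scores these against the model but never trains on them
        blocks.append(
            (
                "caseV_",
                "case",
                "syndrome_a_validation",
                effects,
                config.n_validation_cases,
            )
        )
    blocks.append(("ctrl_", "control", "control_pool", None, config.n_control_pool))
    beta, samples, props = _assemble(builder, blocks)
    truth = GroundTruth(
        cohort_effects={"syndrome_a": effects},
        cell_proportions=props,
        reference_profiles=builder.reference.iloc[builder.discriminating_idx],
    )
    if config.probe_failure_rate > 0:
        beta = inject_failures(
            beta,
            {s: config.probe_failure_rate for s in beta.sample_ids},
            seed=config.seed + 1,
        )
    return beta, samples, truth


def simulate_overlapping_syndromes(
    config: SimulationConfig, n_secondary: int, n_tertiary: int
) -> Tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Simulate three case cohorts with partially shared signatures.

    Cohorts ``syndrome_b`` and ``syndrome_c`` each share exactly
    ``round(overlap_fraction * signature_size)`` planted probes (the
    leading block of cohort a's signature, with the same signed effects)
    with ``syndrome_a``; the remainders of their signatures are disjoint
    from ``syndrome_a``'s and from each other. The tertiary cohort uses
    ``overlap_fraction_tertiary`` when set (e.g. 0 to emulate an
    unrelated disorder), otherwise ``overlap_fraction_secondary``.
    """
    builder = _CohortBuilder(config)
    size = config.signature_size
    f_b = config.overlap_fraction_secondary
    f_c = (
        config.overlap_fraction_tertiary
        if config.overlap_fraction_tertiary is not None
        else f_b
    )

    idx_a = builder.take_signature(size)
    effects_a = builder.make_effects(idx_a)

    def secondary_effects(fraction: float) -> pd.Series:
        n_shared = round(fraction * size)
        shared = effects_a.iloc[:n_shared]
        fresh_idx = builder.take_signature(size - n_shared)
        fresh = builder.make_effects(fresh_idx)
        return pd.concat([shared, fresh])

    effects_b = secondary_effects(f_b)
    effects_c = secondary_effects(f_c)

    beta, samples, props = _assemble(
        builder,
        [
            ("caseA_", "case", "syndrome_a", effects_a, config.n_cases),
            ("caseB_", "case", "syndrome_b", effects_b, n_secondary),
            ("caseC_", "case", "syndrome_c", effects_c, n_tertiary),
            ("ctrl_", "control", "control_pool", None, config.n_control_pool),
        ],
    )
    truth = GroundTruth(
        cohort_effects={
            "syndrome_a": effects_a,
            "syndrome_b": effects_b,
            "syndrome_c": effects_c,
        },
        cell_proportions=props,
        reference_profiles=builder.reference.iloc[builder.discriminating_idx],
        shared_probe_ids={
            "syndrome_b": set(effects_b.index) & set(effects_a.index),
            "syndrome_c": set(effects_c.index) & set(effects_a.index),
        },
    )
    return beta, samples, truth


def inject_failures(
    beta: BetaMatrix, sample_failure_profile: Mapping[str, float], seed: int
) -> BetaMatrix:
    """Set a fraction of each named sample's entries to missing.

    The number of failed entries per sample is ``round(fraction *
    n_probes)``, chosen uniformly without replacement under ``seed``.
    Unknown sample ids raise :class:`KeyError`.
    """
    rng = np.random.default_rng(seed)
    out = beta.copy()
    n = out.n_probes
    for sample_id, fraction in sample_failure_profile.items():
        if sample_id not in out.values.columns:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        if not 0.0 <= fraction <= 1.0:
            raise ConfigError(f"failure fraction must be in [0, 1], got {fraction!r}")
        k = round(fraction * n)
        if k == 0:
            continue
        idx = rng.choice(n, size=k, replace=False)
        col = out.values.columns.get_loc(sample_id)
        out.values.iloc[idx, col] = np.nan
    return out


def null_config(**overrides) -> SimulationConfig:
    """A convenience config with no planted effect (global null)."""
    base = SimulationConfig(effect_delta_beta=0.0)
    return replace(base, **overrides)
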