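"""Core in-memory containers.

The pipeline's universal currency is the :class:`BetaMatrix`: a probe x
sample matrix of methylation fractions (beta values, in ``[0, 1]``,
``NaN`` for failed probes) together with a per-probe manifest and a
per-sample sheet. Both annotations are plain :class:`pandas.DataFrame`
objects so that downstream code can use ordinary pandas idioms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Columns required in a probe manifest.
MANIFEST_COLUMNS = [
    "chrom",
    "start",
    "end",
    "cgi_class",
    "gene_class",
    "snp_flag",
    "crossreactive_flag",
    "excluded_by_vendor_flag",
]

#: Columns required in a sample sheet.
SAMPLE_SHEET_COLUMNS = ["sex", "age_years", "group", "cohort"]

CGI_CLASSES = ("island", "shore", "shelf", "inter_cgi")
GENE_CLASSES = ("promoter", "exon", "intron", "intergenic", "exon_intron_boundary")


@dataclass
class BetaMatrix:
    """Probe x sample beta values with attached manifest and sample sheet.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample id. Entries
        are methylation fractions in ``[0, 1]``; ``NaN`` marks a failed
        (missing) measurement.
    manifest
        DataFrame indexed by probe id with :data:`MANIFEST_COLUMNS`.
        Coordinates are 0-based, half-open.
    samples
        DataFrame indexed by sample id with :data:`SAMPLE_SHEET_COLUMNS`.
    """

    values: pd.DataFrame
    manifest: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe ids in beta matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in beta matrix")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("beta values outside [0, 1]")
        if self.manifest is not None:
            missing = set(self.values.index) - set(self.manifest.index)
            if missing:
                raise ValidationError(
                    f"{len(missing)} probes absent from manifest (e.g. {sorted(missing)[:3]})"
                )
        if self.samples is not None:
            missing = set(self.values.columns) - set(self.samples.index)
            if missing:
                raise ValidationError(
                    f"{len(missing)} samples absent from sample sheet (e.g. {sorted(missing)[:3]})"
                )

    # -- convenience -----------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        probe_ids = list(probe_ids)
        manifest = self.manifest.loc[probe_ids] if self.manifest is not None else None
        return BetaMatrix(self.values.loc[probe_ids], manifest, self.samples)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        sample_ids = list(sample_ids)
        samples = self.samples.loc[sample_ids] if self.samples is not None else None
        return BetaMatrix(self.values[sample_ids], self.manifest, samples)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            self.values.copy(),
            None if self.manifest is None else self.manifest.copy(),
            None if self.samples is None else self.samples.copy(),
        )


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and return it unchanged.

    Enforces unique sample ids, the ``M``/``F`` sex vocabulary, and
    non-negative ages.
    """
    if sheet.index.has_duplicates:
        raise ValidationError("duplicate sample ids in sample sheet")
    bad_sex = set(sheet["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValidationError(f"sex values outside {{M, F}}: {sorted(bad_sex)}")
    if (sheet["age_years"] < 0).any():
        raise ValidationError("negative age in sample sheet")
    return sheet
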