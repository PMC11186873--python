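"""Reference-based blood cell-type deconvolution.

Estimates per-sample leukocyte proportions by constrained projection of
the sample's beta profile onto cell-type reference profiles at a set of
discriminating probes (the Houseman approach in its practical form:
non-negative least squares followed by normalisation to the simplex).
The estimated proportions feed the differential-methylation design
matrix as confounder covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import BetaMatrix
from .errors import ValidationError


class CellTypeDeconvolver(BaseEstimator, TransformerMixin):
    """Estimate cell-type proportions from beta values by NNLS.

    Parameters
    ----------
    reference : pandas.DataFrame
        Discriminating probes x cell types, mean beta per cell type,
        all values in ``[0, 1]``.

    Attributes
    ----------
    shared_probes_ : list of str
        Probes common to the reference and the fitted beta matrix.
    """

    def __init__(self, reference: pd.DataFrame):
        self.reference = reference

    def _validate_reference(self) -> pd.DataFrame:
        ref = self.reference
        if ref.shape[1] < 2:
            raise ValidationError("reference needs at least 2 cell types")
        arr = ref.to_numpy(dtype=float)
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValidationError("reference profile means must lie in [0, 1]")
        return ref

    def fit(self, X: BetaMatrix | pd.DataFrame, y=None) -> "CellTypeDeconvolver":
        ref = self._validate_reference()
        values = X.values if isinstance(X, BetaMatrix) else X
        shared = [p for p in ref.index if p in values.index]
        if len(shared) < ref.shape[1]:
            raise ValidationError(
                f"only {len(shared)} discriminating probes shared with the "
                f"cohort; need at least {ref.shape[1]} (one per cell type)"
            )
        self.shared_probes_ = shared
        return self

    def transform(self, X: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
        """Per-sample simplex weights over the reference cell types."""
        values = X.values if isinstance(X, BetaMatrix) else X
        R = self.reference.loc[self.shared_probes_].to_numpy(dtype=float)
        B = values.loc[self.shared_probes_].to_numpy(dtype=float)
        out = np.empty((B.shape[1], R.shape[1]))
        for j in range(B.shape[1]):
            w, _ = nnls(R, B[:, j])
            total = w.sum()
            out[j] = w / total if total > 0 else np.full_like(w, 1.0 / len(w))
        return pd.DataFrame(
            out,
            index=pd.Index(values.columns, name="sample_id"),
            columns=self.reference.columns,
        )


def estimate_proportions(
    beta: BetaMatrix | pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """NNLS cell-proportion estimates, normalised to sum to 1 per sample."""
    return CellTypeDeconvolver(reference).fit(beta).transform(beta)


def proportions_to_covariates(proportions: pd.DataFrame) -> pd.DataFrame:
    """Drop the last cell type to avoid collinearity with the intercept."""
    return proportions.iloc[:, :-1].copy()
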