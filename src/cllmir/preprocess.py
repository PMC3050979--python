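"""Mock-array normalization of raw bead intensities.

The reference ("mock") array is the per-feature arithmetic mean of all
samples on the log2 scale. Each sample is then mapped onto the mock
frame by an ordinary-least-squares linear correction: fit
``mock = a + b * sample`` and replace the sample with ``a + b * sample``.
A sample that is a global affine distortion of the cohort profile is
restored to the mock exactly; correcting the mock against itself is the
identity.

Pipeline order: floor raw intensities at 1 -> log2 -> drop excluded
features -> build mock -> correct each sample. The mock is built AFTER
exclusions so background artifacts never contaminate the reference.
High-background features (miR-146b-5p on the real platform) are excluded
by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .signature import matching_ids

__all__ = [
    "DEFAULT_EXCLUSIONS",
    "MockArrayNormalizer",
    "build_mock_array",
    "fit_and_apply_linear_correction",
    "normalize_matrix",
]

#: Features dropped before normalization (abnormally high background).
DEFAULT_EXCLUSIONS = ("hsa-miR-146b-5p",)


def build_mock_array(log2_matrix: pd.DataFrame) -> pd.Series:
    """Per-feature mean of log2 expression across >=2 samples."""
    if log2_matrix.shape[1] == 0 or log2_matrix.shape[0] == 0:
        raise ValueError("cannot build a mock array from an empty matrix")
    if log2_matrix.shape[1] < 2:
        raise ValueError("mock array requires at least 2 samples")
    return log2_matrix.mean(axis=1)


def fit_and_apply_linear_correction(sample, mock):
    """OLS-fit ``mock ~ a + b*sample`` and return (corrected, (a, b)).

    The corrected vector is ``a + b*sample`` — the sample mapped onto
    the mock frame. Raises for length mismatch, <3 points, or a
    constant sample (undefined slope).
    """
    sample = np.asarray(sample, dtype=float)
    mock = np.asarray(mock, dtype=float)
    if sample.shape != mock.shape:
        raise ValueError("sample and mock must have equal length")
    if sample.size < 3:
        raise ValueError("linear correction needs at least 3 features")
    if np.ptp(sample) == 0:
        raise ValueError("sample vector is constant; slope undefined")
    b, a = np.polyfit(sample, mock, 1)
    return a + b * sample, (float(a), float(b))


class MockArrayNormalizer(TransformerMixin, BaseEstimator):
    """Map raw bead intensities onto a cohort mock-array reference.

    scikit-learn transformer convention: ``X`` is samples x features.
    ``fit`` floors, logs and averages the training samples into the
    mock profile; ``transform`` corrects each sample onto it.

    Parameters
    ----------
    exclude : sequence of str
        Feature ids dropped before the mock is built (species-prefix
        tolerant, so ``hsa-miR-146b-5p`` matches ``miR-146b-5p``).
    floor : float
        Raw intensities are floored here before log2 (bead MFI near
        zero is noise).

    Attributes
    ----------
    mock_ : pandas.Series
        Per-feature log2 reference profile (after exclusions).
    feature_names_in_, excluded_features_, n_features_in_
    """

    def __init__(self, exclude=DEFAULT_EXCLUSIONS, floor: float = 1.0):
        self.exclude = exclude
        self.floor = floor

    # -- helpers -----------------------------------------------------
    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])

    def _log2_kept(self, X: pd.DataFrame) -> pd.DataFrame:
        kept = [c for c in X.columns if c not in self.excluded_features_]
        return np.log2(X[kept].clip(lower=self.floor))

    # -- estimator API ----------------------------------------------
    def fit(self, X, y=None):
        X = self._to_frame(X)
        if (X.values <= 0).any():
            warnings.warn("non-positive raw intensities floored before log2")
        excluded = matching_ids(X.columns, list(self.exclude))
        if len(self.exclude) and not excluded:
            warnings.warn(
                f"none of the exclusion ids {list(self.exclude)} are present"
            )
        if len(excluded) == X.shape[1]:
            raise ValueError("all features excluded; nothing to normalize")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.excluded_features_ = list(excluded)
        log2 = self._log2_kept(X)
        self.mock_ = build_mock_array(log2.T)
        return self

    def transform(self, X):
        check_is_fitted(self, "mock_")
        X = self._to_frame(X)
        log2 = self._log2_kept(X)
        if list(log2.columns) != list(self.mock_.index):
            raise ValueError("feature set differs from the fitted mock array")
        corrected = np.empty_like(log2.values)
        coefs = {}
        mock = self.mock_.to_numpy()
        for i, (sid, row) in enumerate(log2.iterrows()):
            corrected[i], coefs[sid] = fit_and_apply_linear_correction(
                row.to_numpy(), mock
            )
        self.correction_coefficients_ = coefs
        return pd.DataFrame(corrected, index=log2.index, columns=log2.columns)


def normalize_matrix(raw: pd.DataFrame, exclude=DEFAULT_EXCLUSIONS):
    """Normalize a features-x-samples raw intensity matrix.

    Returns ``(normalized, provenance)`` where *normalized* is the
    log2-scale corrected matrix (excluded features absent) and
    *provenance* records the exclusions applied and per-sample
    correction coefficients ``(a, b)``.
    """
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError("cannot normalize an empty matrix")
    norm = MockArrayNormalizer(exclude=exclude)
    corrected = norm.fit(raw.T).transform(raw.T).T
    provenance = {
        "scale": "log2",
        "floor": norm.floor,
        "excluded_requested": list(exclude),
        "excluded_applied": norm.excluded_features_,
        "correction_coefficients": {
            s: {"a": a, "b": b}
            for s, (a, b) in norm.correction_coefficients_.items()
        },
        "mock": {f: float(v) for f, v in norm.mock_.items()},
    }
    return corrected, provenance
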