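"""Shared scaffolding for the transductive three-way imputers.

All imputers in this package are scikit-learn-style estimators that
operate on a single incomplete I x J x K array: ``fit`` runs the
imputation on the array it is given and ``transform`` returns the
completed version of that same array.  Because the methods impute the
very array they are fitted on (there is no out-of-sample completion),
``fit_transform`` is the natural entry point, mirroring other
transductive estimators.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import METArray, MissingPattern, StandardizedMET, back_transform, standardize

__all__ = ["BaseMETImputer", "pattern_from_mask", "as_standardized", "spawn_rngs"]


def pattern_from_mask(mask: np.ndarray) -> MissingPattern:
    """Classify the missing entries of a mask into cells and whole columns."""
    I, J, K = mask.shape
    col_missing = ~mask.any(axis=0)  # (J, K)
    columns = {(int(j), int(k)) for j, k in np.argwhere(col_missing)}
    cells = {
        (int(i), int(j), int(k))
        for i, j, k in np.argwhere(~mask)
        if (int(j), int(k)) not in columns
    }
    n = len(cells) + I * len(columns)
    return MissingPattern(cells=cells, columns=columns, percent=n / mask.size, seed=-1)


def as_standardized(X) -> StandardizedMET:
    """Coerce raw input (ndarray with NaN, METArray, StandardizedMET)."""
    if isinstance(X, StandardizedMET):
        return X
    if not isinstance(X, METArray):
        X = METArray(np.asarray(X, dtype=float))
    return standardize(X)


def spawn_rngs(random_state, n: int) -> list[np.random.Generator]:
    """Independent per-imputation RNG streams from one master seed."""
    ss = np.random.SeedSequence(random_state)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


class BaseMETImputer(TransformerMixin, BaseEstimator):
    """Common fit/transform plumbing for the multiple-imputation methods.

    Subclasses implement ``_impute_all(std, pattern, missing, random_state)``
    returning an (H, n_missing) array of standardized-scale estimates,
    one row per imputation, columns aligned with ``missing`` (the sorted
    list of missing (i, j, k) triples).

    Fitted attributes
    -----------------
    missing_indices_ : (n_missing, 3) int array of missing cells.
    estimates_ : (H, n_missing) per-imputation standardized estimates.
    estimate_mean_ : (n_missing,) average over imputations — the values
        entered into the final "estimated data array".
    standardized_ : the StandardizedMET the imputer worked on.
    completed_std_ : (I, J, K) completed array on the standardized scale.
    """

    def fit(self, X, y=None):
        std = as_standardized(X)
        self.standardized_ = std
        pattern = pattern_from_mask(std.mask)
        missing = sorted(pattern.all_cells(std.shape[0]))
        self.missing_indices_ = np.array(missing, dtype=int).reshape(-1, 3)
        if missing:
            est = self._impute_all(std, pattern, missing, self.random_state)
            self.estimates_ = np.asarray(est, dtype=float)
            self.estimate_mean_ = self.estimates_.mean(axis=0)
        else:
            self.estimates_ = np.empty((0, 0))
            self.estimate_mean_ = np.empty(0)
        completed = std.values.copy()
        if missing:
            idx = tuple(self.missing_indices_.T)
            completed[idx] = self.estimate_mean_
        self.completed_std_ = completed
        self.n_imputations_ = self.estimates_.shape[0]
        return self

    def transform(self, X=None):
        """Return the completed array on the scale of the fitted input.

        If the input was a raw array, values are back-transformed with
        the per-column location/scale; columns that were wholly missing
        have no identifiable scale and are returned on the standardized
        scale (with a warning).
        """
        if not hasattr(self, "completed_std_"):
            raise RuntimeError("imputer is not fitted")
        std = self.standardized_
        raw = back_transform(std, self.completed_std_)
        undefined = ~np.isfinite(std.col_sd)
        if np.any(undefined):
            warnings.warn(
                "wholly missing column(s) have no observed scale; returning "
                "their imputations on the standardized scale",
                stacklevel=2,
            )
            for j, k in np.argwhere(undefined):
                raw[:, j, k] = self.completed_std_[:, j, k]
        return raw

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)

    def _impute_all(self, std, pattern, missing, random_state):  # pragma: no cover
        raise NotImplementedError
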