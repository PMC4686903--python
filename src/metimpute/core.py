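"""Core data model for three-way multi-environment trial (MET) arrays.

A MET array holds measurements of I genotypes grown in J environments,
scored on K attributes: a three-way three-mode array ``x[i, j, k]``.  This
module provides the array container with an explicit missing-value mask,
column standardization (centering/scaling every environment-attribute
column over genotypes, which removes environment main effects while
preserving within-environment attribute correlations), lossless two-way
"wide" rearrangements, random missing-pattern generation, and plain-text
I/O (long CSV, per-attribute frontal slices, JSON patterns).

Missing entries are carried as NaN and never enter arithmetic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METArray",
    "StandardizedMET",
    "MissingPattern",
    "WideView",
    "standardize",
    "back_transform",
    "to_wide",
    "generate_missing",
    "apply_pattern",
    "read_long_csv",
    "write_long_csv",
    "read_slices",
    "write_slices",
    "read_pattern",
    "write_pattern",
]

Orientation = Literal["genotypes_by_env_attr", "env_by_geno_attr"]


def _default_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


@dataclass
class METArray:
    """Three-way I x J x K trial array with an observation mask.

    Parameters
    ----------
    values : ndarray of shape (I, J, K)
        Measured values; entries where ``mask`` is False are ignored and
        stored as NaN.
    mask : ndarray of bool, shape (I, J, K)
        True where the cell is observed.
    genotype_ids, environment_ids, attribute_ids : sequences of str
        Unique axis labels; generated (``G1..``, ``E1..``, ``A1..``) if
        omitted.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    genotype_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    environment_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    attribute_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-d array (I, J, K)")
        I, J, K = self.values.shape
        if I < 2 or J < 2 or K < 1:
            raise ValueError(f"need I >= 2, J >= 2, K >= 1; got {(I, J, K)}")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed entries must be finite")
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan
        if self.genotype_ids is None:
            self.genotype_ids = _default_labels("G", I)
        if self.environment_ids is None:
            self.environment_ids = _default_labels("E", J)
        if self.attribute_ids is None:
            self.attribute_ids = _default_labels("A", K)
        for name, labels, n in (
            ("genotype_ids", self.genotype_ids, I),
            ("environment_ids", self.environment_ids, J),
            ("attribute_ids", self.attribute_ids, K),
        ):
            labels = list(labels)
            if len(labels) != n:
                raise ValueError(f"{name}: expected {n} labels, got {len(labels)}")
            if len(set(labels)) != n:
                raise ValueError(f"{name}: labels must be unique")
            setattr(self, name, labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "METArray":
        return METArray(
            self.values.copy(),
            self.mask.copy(),
            list(self.genotype_ids),
            list(self.environment_ids),
            list(self.attribute_ids),
        )


@dataclass
class StandardizedMET:
    """Column-standardized MET array plus the per-(j, k) location/scale.

    ``col_mean``/``col_sd`` are NaN for wholly missing columns (no
    observed genotype in that environment-attribute combination), where
    the physical scale is unidentifiable.
    """

    values: np.ndarray
    mask: np.ndarray
    col_mean: np.ndarray
    col_sd: np.ndarray
    genotype_ids: Sequence[str]
    environment_ids: Sequence[str]
    attribute_ids: Sequence[str]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "StandardizedMET":
        return StandardizedMET(
            self.values.copy(),
            self.mask.copy(),
            self.col_mean.copy(),
            self.col_sd.copy(),
            list(self.genotype_ids),
            list(self.environment_ids),
            list(self.attribute_ids),
        )


@dataclass
class MissingPattern:
    """A realized missingness design: individual cells plus whole columns.

    ``cells`` holds (i, j, k) triples; ``columns`` holds (j, k) pairs,
    each meaning every genotype is missing for that environment-attribute
    combination.  The two sets are disjoint by construction.
    """

    cells: set[tuple[int, int, int]]
    columns: set[tuple[int, int]]
    percent: float
    seed: int

    def n_missing(self, I: int) -> int:
        return len(self.cells) + I * len(self.columns)

    def column_cells(self, I: int) -> set[tuple[int, int, int]]:
        return {(i, j, k) for (j, k) in self.columns for i in range(I)}

    def all_cells(self, I: int) -> set[tuple[int, int, int]]:
        return self.cells | self.column_cells(I)


@dataclass
class WideView:
    """Two-way rearrangement of a three-way array with its index bijection."""

    matrix: np.ndarray
    orientation: Orientation
    shape3: tuple[int, int, int]

    def triple(self, row: int, col: int) -> tuple[int, int, int]:
        """Map wide (row, col) back to the (i, j, k) cell it came from."""
        I, J, K = self.shape3
        if self.orientation == "genotypes_by_env_attr":
            k, j = divmod(col, J)
            return (row, j, k)
        k, i = divmod(col, I)
        return (i, row, k)  # row indexes environments

    def to_array(self) -> np.ndarray:
        """Inverse rearrangement back to the (I, J, K) array."""
        I, J, K = self.shape3
        if self.orientation == "genotypes_by_env_attr":
            return self.matrix.reshape(I, K, J).transpose(0, 2, 1)
        return self.matrix.reshape(J, K, I).transpose(2, 0, 1)


def standardize(raw: METArray) -> StandardizedMET:
    """Column-standardize each environment-attribute column over genotypes.

    For each column (j, k), observed entries are centered by their mean
    and scaled by their sample standard deviation (denominator
    ``n_obs - 1``).  This removes the environment main effect (each fully
    observed standardized column sums to zero over genotypes) while
    leaving within-environment attribute correlations unchanged.

    Raises
    ------
    ValueError
        If a column has exactly one observed value or zero variance;
        wholly missing columns are allowed and flagged with NaN
        mean/scale.
    """
    I, J, K = raw.shape
    vals = raw.values
    mask = raw.mask
    n_obs = mask.sum(axis=0)  # (J, K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(np.where(mask, vals, np.nan), axis=0)
        col_sd = np.nanstd(np.where(mask, vals, np.nan), axis=0, ddof=1)
    bad = (n_obs == 1) | ((n_obs >= 2) & ~(col_sd > 0))
    if np.any(bad):
        j, k = np.argwhere(bad)[0]
        raise ValueError(
            f"column (environment={j}, attribute={k}) has "
            f"{n_obs[j, k]} observed value(s) and sd "
            f"{col_sd[j, k] if n_obs[j, k] > 1 else float('nan'):.3g}; "
            "cannot standardize"
        )
    col_mean = np.where(n_obs == 0, np.nan, col_mean)
    col_sd = np.where(n_obs == 0, np.nan, col_sd)
    std = (vals - col_mean[None, :, :]) / col_sd[None, :, :]
    std[~mask] = np.nan
    return StandardizedMET(
        std,
        mask.copy(),
        col_mean,
        col_sd,
        list(raw.genotype_ids),
        list(raw.environment_ids),
        list(raw.attribute_ids),
    )


def back_transform(std: StandardizedMET, values: np.ndarray | None = None) -> np.ndarray:
    """Undo column standardization: ``value * col_sd + col_mean``.

    Columns with undefined scale (wholly missing in the input) come back
    as NaN.
    """
    v = std.values if values is None else values
    return v * std.col_sd[None, :, :] + std.col_mean[None, :, :]


def to_wide(std: StandardizedMET | METArray, orientation: Orientation = "genotypes_by_env_attr") -> WideView:
    """Rearrange the three-way array as a two-way wide matrix.

    ``genotypes_by_env_attr`` gives the I x (J*K) matrix with
    environments nested within attributes (columns ordered attribute-
    major: all environments of attribute 1, then attribute 2, ...);
    ``env_by_geno_attr`` gives the J x (I*K) matrix with genotypes nested
    within attributes.  Missing entries stay NaN.
    """
    I, J, K = std.shape
    if orientation == "genotypes_by_env_attr":
        mat = std.values.transpose(0, 2, 1).reshape(I, K * J)
    elif orientation == "env_by_geno_attr":
        mat = std.values.transpose(1, 2, 0).reshape(J, K * I)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return WideView(mat, orientation, (I, J, K))


def generate_missing(
    raw: METArray,
    percent: float,
    n_columns: int = 0,
    seed: int = 0,
    max_redraws: int = 1000,
) -> MissingPattern:
    """Draw a random missingness pattern over a fully observed array.

    ``round(percent * I * J * K)`` entries are made missing in total:
    ``n_columns`` distinct (environment, attribute) columns chosen
    uniformly (contributing I entries each), and the remainder as
    individual cells drawn uniformly without replacement outside those
    columns.  Patterns that would empty an entire genotype-attribute row
    (a genotype missing in every environment for some attribute) are
    rejected and redrawn.
    """
    if not 0.0 < percent < 1.0:
        raise ValueError(f"percent must be in (0, 1); got {percent}")
    if not np.all(raw.mask):
        raise ValueError("generate_missing requires a fully observed array")
    I, J, K = raw.shape
    total = int(round(percent * I * J * K))
    if total < I * n_columns:
        raise ValueError(
            f"percent {percent} yields {total} missing entries, fewer than "
            f"the {I * n_columns} implied by {n_columns} missing column(s)"
        )
    rng = np.random.default_rng(seed)
    flat_all = np.arange(I * J * K)
    for _ in range(max_redraws):
        col_idx = rng.choice(J * K, size=n_columns, replace=False) if n_columns else np.array([], dtype=int)
        columns = {(int(c) // K, int(c) % K) for c in col_idx}
        in_cols = np.zeros((I, J, K), dtype=bool)
        for j, k in columns:
            in_cols[:, j, k] = True
        pool = flat_all[~in_cols.ravel()]
        n_cells = total - I * n_columns
        chosen = rng.choice(pool, size=n_cells, replace=False) if n_cells else np.array([], dtype=int)
        cells = {tuple(int(v) for v in np.unravel_index(c, (I, J, K))) for c in chosen}
        miss = in_cols.copy()
        for i, j, k in cells:
            miss[i, j, k] = True
        # reject if any genotype x attribute row would be wholly missing
        if not np.any(miss.all(axis=1)):
            return MissingPattern(cells=cells, columns=columns, percent=percent, seed=seed)
    raise RuntimeError(
        f"could not draw a pattern avoiding empty genotype rows in {max_redraws} attempts"
    )


def apply_pattern(raw: METArray, pattern: MissingPattern) -> METArray:
    """Return a copy of ``raw`` with the pattern's entries masked out."""
    out = raw.copy()
    I = raw.shape[0]
    for i, j, k in pattern.all_cells(I):
        out.mask[i, j, k] = False
        out.values[i, j, k] = np.nan
    return out


# ---------------------------------------------------------------------------
# I/O


def write_long_csv(arr: METArray, path: str | Path) -> None:
    I, J, K = arr.shape
    i, j, k = np.meshgrid(np.arange(I), np.arange(J), np.arange(K), indexing="ij")
    df = pd.DataFrame(
        {
            "genotype": np.asarray(arr.genotype_ids)[i.ravel()],
            "environment": np.asarray(arr.environment_ids)[j.ravel()],
            "attribute": np.asarray(arr.attribute_ids)[k.ravel()],
            "value": arr.values.ravel(),
        }
    )
    df.to_csv(path, index=False, na_rep="")


def read_long_csv(path: str | Path) -> METArray:
    """Read a long-format CSV (genotype, environment, attribute, value).

    An empty value field marks a missing cell.  Label order follows
    first appearance in the file.
    """
    df = pd.read_csv(path, dtype={"genotype": str, "environment": str, "attribute": str})
    required = {"genotype", "environment", "attribute", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long CSV must have columns {sorted(required)}")
    g = pd.unique(df["genotype"])
    e = pd.unique(df["environment"])
    a = pd.unique(df["attribute"])
    gi = {v: n for n, v in enumerate(g)}
    ei = {v: n for n, v in enumerate(e)}
    ai = {v: n for n, v in enumerate(a)}
    vals = np.full((len(g), len(e), len(a)), np.nan)
    vals[
        df["genotype"].map(gi).to_numpy(),
        df["environment"].map(ei).to_numpy(),
        df["attribute"].map(ai).to_numpy(),
    ] = df["value"].to_numpy(dtype=float)
    return METArray(vals, genotype_ids=list(g), environment_ids=list(e), attribute_ids=list(a))


def write_slices(arr: METArray, directory: str | Path) -> None:
    """Write one genotypes x environments CSV per attribute (frontal slices)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, attr in enumerate(arr.attribute_ids):
        pd.DataFrame(
            arr.values[:, :, k], index=arr.genotype_ids, columns=arr.environment_ids
        ).to_csv(directory / f"{attr}.csv", na_rep="")


def read_slices(paths: Sequence[str | Path], attribute_ids: Sequence[str] | None = None) -> METArray:
    frames = [pd.read_csv(p, index_col=0) for p in paths]
    base = frames[0]
    for f in frames[1:]:
        if not (f.index.equals(base.index) and f.columns.equals(base.columns)):
            raise ValueError("frontal slices must share genotype and environment labels")
    vals = np.stack([f.to_numpy(dtype=float) for f in frames], axis=2)
    if attribute_ids is None:
        attribute_ids = [Path(p).stem for p in paths]
    return METArray(
        vals,
        genotype_ids=[str(x) for x in base.index],
        environment_ids=[str(x) for x in base.columns],
        attribute_ids=list(attribute_ids),
    )


def write_pattern(pattern: MissingPattern, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "cells": sorted(map(list, pattern.cells)),
                "columns": sorted(map(list, pattern.columns)),
                "seed": pattern.seed,
                "percent": pattern.percent,
            },
            fh,
            indent=1,
        )


def read_pattern(path: str | Path) -> MissingPattern:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return MissingPattern(
        cells={tuple(c) for c in d["cells"]},
        columns={tuple(c) for c in d["columns"]},
        percent=d["percent"],
        seed=d["seed"],
    )
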