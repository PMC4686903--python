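"""Comparison machinery: Rubin's-rules pooling, coverage of 95% CIs, NRMSE.

The evaluation deletes values from a fully observed array, imputes them,
and asks two questions.  Efficiency: pool the H imputations per missing
value by Rubin's rules,

    Ubar = mean_h U_h                   (within-imputation variance)
    B_m  = var_h(Qhat_hm)               (between-imputation variance)
    T_m  = Ubar + (1 + 1/H) B_m         (total variance)
    nu_m = (H-1) [1 + Ubar / ((1 + 1/H) B_m)]^2

and count how often the t-interval Qbar_m +/- t_{nu,0.975} sqrt(T_m)
contains the known deleted value ("Coverage CI").  Here U_h is the
variance of the imputed estimates across missing values within
imputation h, following the source protocol for these arrays rather
than the classical sampling-variance reading.  Accuracy: the final
estimated array (average of the individual imputations) is
re-standardized column-wise and compared to the original standardized
array by NRMSE = sqrt(mean[(x - xhat)^2] / var(x)) over all cells.

The repetition protocol draws a fresh missing pattern per repetition,
runs 100 imputations, pools them into H = 5 sets of 20 for the coverage
computation, and averages all 100 for the final array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .core import METArray, MissingPattern, StandardizedMET, generate_missing, standardize

__all__ = [
    "RubinSummary",
    "rubin_pool",
    "within_variance",
    "pool_imputations",
    "coverage_ci",
    "nrmse",
    "run_experiment",
    "run_column_experiment",
    "summarize",
]


@dataclass
class RubinSummary:
    U_bar: float
    B_between: np.ndarray  # per missing value
    T_total: np.ndarray
    nu_H: np.ndarray
    H: int
    Q_bar: np.ndarray


def within_variance(estimates_h: np.ndarray) -> float:
    """U_h: sample variance of one imputation's estimates across values."""
    return float(np.var(np.asarray(estimates_h, dtype=float), ddof=1))


def rubin_pool(estimates: np.ndarray, within_vars: np.ndarray) -> RubinSummary:
    """Pool H imputation vectors by Rubin's rules (per missing value).

    ``estimates`` is (H, M); ``within_vars`` the H scalars U_h.  B is
    computed per value; nu_H is infinite where B = 0.
    """
    estimates = np.asarray(estimates, dtype=float)
    H, M = estimates.shape
    if H < 2:
        raise ValueError("Rubin pooling needs H >= 2 imputations")
    within_vars = np.asarray(within_vars, dtype=float).ravel()
    if within_vars.size != H:
        raise ValueError("need one within-imputation variance per imputation")
    U_bar = float(within_vars.mean())
    Q_bar = estimates.mean(axis=0)
    B = estimates.var(axis=0, ddof=1)
    T = U_bar + (1.0 + 1.0 / H) * B
    with np.errstate(divide="ignore"):
        nu = (H - 1) * (1.0 + U_bar / ((1.0 + 1.0 / H) * B)) ** 2
    nu = np.where(B > 0, nu, np.inf)
    return RubinSummary(U_bar, B, T, nu, H, Q_bar)


def pool_imputations(estimates: np.ndarray, pool_h: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly allocate the imputations into pool_h sets and average each.

    E.g. 100 imputations pooled as 5 sets of 20 give the H = 5 pooled
    imputation vectors used in the coverage computation.
    """
    estimates = np.asarray(estimates, dtype=float)
    n = estimates.shape[0]
    if n % pool_h:
        raise ValueError(f"{n} imputations cannot be split into {pool_h} equal sets")
    perm = rng.permutation(n).reshape(pool_h, n // pool_h)
    return estimates[perm].mean(axis=1)


def coverage_ci(
    truth: np.ndarray,
    estimates: np.ndarray,
    within_vars: np.ndarray,
    level: float = 0.95,
) -> tuple[float, np.ndarray, RubinSummary]:
    """Percentage of Rubin-rule CIs containing the true deleted values.

    Where B = 0 for a value (all imputations identical) the interval
    degenerates to a normal interval on U_bar alone, with a warning.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    summ = rubin_pool(estimates, within_vars)
    alpha = 0.5 + level / 2.0
    q = np.empty_like(summ.T_total)
    finite = np.isfinite(summ.nu_H)
    q[finite] = stats.t.ppf(alpha, summ.nu_H[finite])
    if np.any(~finite):
        warnings.warn(
            f"{int((~finite).sum())} value(s) had zero between-imputation "
            "variance; using a normal interval on U_bar alone",
            stacklevel=2,
        )
        q[~finite] = stats.norm.ppf(alpha)
    half = q * np.sqrt(summ.T_total)
    covered = np.abs(truth - summ.Q_bar) <= half
    return 100.0 * covered.mean(), covered, summ


def nrmse(original_std: np.ndarray, completed_std: np.ndarray) -> float:
    """Normalized RMSE after re-standardizing the completed array.

    The completed array (standardized scale, now without missing
    entries) is column-standardized again — imputation shifts column
    means/scales, which moves even the observed entries — and compared
    with the original standardized array over every cell.  Invariant to
    per-column affine changes of the completed array.
    """
    x = np.asarray(original_std, dtype=float)
    y = np.asarray(completed_std, dtype=float)
    if x.shape != y.shape:
        raise ValueError("arrays must share a shape")
    mu = y.mean(axis=0, keepdims=True)
    sd = y.std(axis=0, ddof=1, keepdims=True)
    y = (y - mu) / sd
    return float(np.sqrt(np.mean((x - y) ** 2) / np.var(x)))


def _mask_pattern(std: StandardizedMET, pattern: MissingPattern) -> StandardizedMET:
    out = std.copy()
    for i, j, k in pattern.all_cells(std.shape[0]):
        out.mask[i, j, k] = False
        out.values[i, j, k] = np.nan
    return out


def _configured(imputer, n_imputations, seed):
    imp = clone(imputer)
    params = imp.get_params()
    if "n_imputations" in params:
        imp.set_params(n_imputations=n_imputations)
    if "random_state" in params:
        imp.set_params(random_state=int(seed))
    return imp


def _rep_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_experiment(
    raw: METArray,
    imputer,
    percents=(0.05, 0.10, 0.15, 0.20, 0.25),
    scope: str = "cells",
    n_reps: int = 10,
    n_imputations: int = 100,
    pool_h: int = 5,
    seed: int = 0,
    label: str | None = None,
) -> pd.DataFrame:
    """Repetition protocol over missing-cell percentages.

    Per repetition a pattern with one designated missing column plus
    random cells totalling round(percent * I*J*K) entries is drawn, the
    imputer run, coverage computed from the pooled imputations and
    NRMSE from the averaged completed array.  ``scope`` selects which
    deleted values enter the coverage: "cells" (excluding the
    designated column, as when only the cell task is under study) or
    "all".  Requires a fully observed input (the deleted values are the
    truth).
    """
    if scope not in ("cells", "all"):
        raise ValueError("scope must be 'cells' or 'all'")
    if not np.all(raw.mask):
        raise ValueError("evaluation needs a fully observed array")
    std_full = standardize(raw)
    I = raw.shape[0]
    label = label or type(imputer).__name__
    rows = []
    for percent in percents:
        seeds = _rep_seeds(seed + int(round(percent * 10000)), n_reps)
        for rep, s in enumerate(seeds):
            rng = np.random.default_rng(s)
            pattern = generate_missing(raw, percent, n_columns=1, seed=s)
            masked = _mask_pattern(std_full, pattern)
            imp = _configured(imputer, n_imputations, s)
            imp.fit(masked)
            idx = imp.missing_indices_
            truth = std_full.values[tuple(idx.T)]
            multiple = getattr(imp, "estimates_", None) is not None and imp.estimates_.shape[0] >= 2
            cov = np.nan
            if multiple:
                if scope == "cells":
                    colcells = pattern.column_cells(I)
                    sel = np.array([tuple(t) not in colcells for t in idx])
                else:
                    sel = np.ones(len(idx), dtype=bool)
                pooled = pool_imputations(imp.estimates_[:, sel], pool_h, rng)
                u = np.array([within_variance(p) for p in pooled])
                cov, _, _ = coverage_ci(truth[sel], pooled, u)
            completed = masked.values.copy()
            completed[tuple(idx.T)] = imp.estimate_mean_
            err = nrmse(std_full.values, completed)
            rows.append(
                dict(method=label, percent=percent, scope=scope,
                     repetition=rep, coverage=cov, nrmse=err)
            )
    return pd.DataFrame(rows)


def run_column_experiment(
    raw: METArray,
    imputer,
    n_imputations: int = 100,
    pool_h: int = 5,
    seed: int = 0,
    attributes=None,
    max_envs: int = 10,
    label: str | None = None,
) -> pd.DataFrame:
    """Missing-column protocol: delete one environment column at a time.

    For each attribute, each environment (all of them when J <= max_envs,
    else max_envs drawn without replacement) is deleted in turn as a
    wholly missing column, imputed, and its coverage recorded; means and
    standard errors per attribute summarize the J (or max_envs)
    coverages.
    """
    if not np.all(raw.mask):
        raise ValueError("evaluation needs a fully observed array")
    I, J, K = raw.shape
    std_full = standardize(raw)
    label = label or type(imputer).__name__
    attrs = range(K) if attributes is None else attributes
    rows = []
    master = np.random.default_rng(seed)
    for k in attrs:
        if J <= max_envs:
            envs = np.arange(J)
        else:
            envs = np.sort(master.choice(J, size=max_envs, replace=False))
        for j in envs:
            s = int(np.random.SeedSequence([seed, int(k), int(j)]).generate_state(1)[0] % 2**31)
            rng = np.random.default_rng(s)
            pattern = MissingPattern(cells=set(), columns={(int(j), int(k))}, percent=I / raw.values.size, seed=s)
            masked = _mask_pattern(std_full, pattern)
            imp = _configured(imputer, n_imputations, s)
            imp.fit(masked)
            idx = imp.missing_indices_
            truth = std_full.values[tuple(idx.T)]
            pooled = pool_imputations(imp.estimates_, pool_h, rng)
            u = np.array([within_variance(p) for p in pooled])
            cov, _, _ = coverage_ci(truth, pooled, u)
            rows.append(
                dict(method=label, attribute=raw.attribute_ids[k], environment=raw.environment_ids[j], coverage=cov)
            )
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame, by=("method", "percent", "scope")) -> pd.DataFrame:
    """Mean and standard error of coverage / NRMSE over repetitions."""
    by = [b for b in by if b in df.columns]
    metrics = [c for c in ("coverage", "nrmse") if c in df.columns]
    agg = df.groupby(list(by))[metrics].agg(["mean", "sem"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
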