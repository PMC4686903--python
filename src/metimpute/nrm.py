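"""Normal regression model (NRM) imputation.

Each standardized environment-attribute column x_jk (I genotype
responses) is regressed on a design matrix X* assembled from the rest of
the I x (J*K) wide matrix, with zeros standing in for missing values so
that they do not contribute to the fit.  Four design options are
supported, differing in which columns enter:

1. all other JK-1 columns;
2. the K(J-1) columns of the other environments;
3. as (1), but environment j's other-attribute columns are rescaled by
   their within-environment correlation with the target attribute
   (KJ-1 columns);
4. only environment j's other K-1 attribute columns.

Coefficients come from least squares (non-Bayesian) or from a conjugate
normal/inverse-gamma Gibbs sampler with prior beta ~ N(0, tau^2 I) and
sigma^2 ~ IG(nu0/2, S0/2); missing cells are drawn as
X*_m beta_hat + z * sigma_hat.

A wholly missing column has no responses to regress on, so it is
predicted through the J x K(K-1)/2 matrix R of within-environment
attribute-pair correlations: either each unavailable correlation is
replaced by its average over the other environments ("avg" rule) or the
missing row of R is filled by a through-origin regression on the
complete rows ("linreg" rule); the prediction is the correlation-
weighted mean of the environment's other attribute columns plus noise
scaled by the average fitted residual sd over the non-missing columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .base import BaseMETImputer, spawn_rngs
from .core import StandardizedMET, to_wide

__all__ = [
    "DesignMatrix",
    "NrmParams",
    "CorrelationR",
    "build_design",
    "nrm_mle",
    "nrm_gibbs",
    "impute_cells_nrm",
    "correlation_R",
    "impute_column_avg",
    "impute_column_linreg",
    "average_residual_sd",
    "NRMImputer",
]


@dataclass
class DesignMatrix:
    """I x N design for one target column, with zeros for missing values."""

    option: int
    matrix: np.ndarray
    target: tuple[int, int]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def split(self, observed_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(X*_obs, X*_m) blocks given the response's observed-row mask."""
        observed_rows = np.asarray(observed_rows, dtype=bool)
        return self.matrix[observed_rows], self.matrix[~observed_rows]


@dataclass
class NrmParams:
    beta_hat: np.ndarray
    sigma2_hat: float
    method: str
    n_obs: int
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2_hat < 0:
            raise ValueError("sigma2_hat must be nonnegative")


@dataclass
class CorrelationR:
    """Within-environment attribute-pair correlations, one row per environment.

    Column order follows the fixed pair sequence (0,1), (0,2), ...,
    (K-2, K-1); entries are NaN where a pair cannot be computed.
    """

    matrix: np.ndarray  # (J, K*(K-1)//2)
    n_attributes: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        K = self.n_attributes
        return [(a, b) for a in range(K) for b in range(a + 1, K)]

    def slot(self, k1: int, k2: int) -> int:
        if k1 == k2:
            raise ValueError("no diagonal slot")
        a, b = min(k1, k2), max(k1, k2)
        K = self.n_attributes
        return a * K - a * (a + 1) // 2 + (b - a - 1)

    def get(self, j: int, k1: int, k2: int) -> float:
        return float(self.matrix[j, self.slot(k1, k2)])


def _wide_col(j: int, k: int, J: int) -> int:
    return k * J + j  # attribute-major, environment-minor


def build_design(
    std: StandardizedMET,
    target: tuple[int, int],
    option: int = 3,
    R: CorrelationR | None = None,
) -> DesignMatrix:
    """Assemble the design matrix for one target column (j, k).

    Missing entries appear as exact zeros, so they contribute nothing to
    the regression.  Option 3 requires ``R``; unavailable correlations
    enter as zero (their design columns are all-zero in that case
    anyway, or carry no usable signal).
    """
    I, J, K = std.shape
    j, k = target
    if option not in (1, 2, 3, 4):
        raise ValueError(f"design option must be in 1..4, got {option}")
    wide = to_wide(std, "genotypes_by_env_attr").matrix
    X0 = np.where(np.isfinite(wide), wide, 0.0)
    env_j_cols = [_wide_col(j, kk, J) for kk in range(K) if kk != k]
    tgt = _wide_col(j, k, J)
    if option == 1:
        keep = [c for c in range(J * K) if c != tgt]
        mat = X0[:, keep]
    elif option == 2:
        drop = set(env_j_cols) | {tgt}
        keep = [c for c in range(J * K) if c not in drop]
        mat = X0[:, keep]
    elif option == 3:
        if R is None:
            raise ValueError("option 3 needs the correlation matrix R")
        mat = X0.copy()
        for kk in range(K):
            if kk == k:
                continue
            r = R.get(j, k, kk)
            mat[:, _wide_col(j, kk, J)] *= r if np.isfinite(r) else 0.0
        keep = [c for c in range(J * K) if c != tgt]
        mat = mat[:, keep]
    else:  # option 4
        mat = X0[:, env_j_cols]
    return DesignMatrix(option=option, matrix=mat, target=(j, k))


def nrm_mle(y, X: DesignMatrix | np.ndarray) -> NrmParams:
    """Least-squares fit on the observed rows of one column.

    The residual variance uses the printed denominator (n_obs - 2);
    rank-deficient designs are handled by the minimum-norm solution.
    """
    mat = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    obs = np.isfinite(y)
    n = int(obs.sum())
    if n < 3:
        raise ValueError(f"need >= 3 observed responses, got {n}")
    beta, *_ = np.linalg.lstsq(mat[obs], y[obs], rcond=None)
    resid = y[obs] - mat[obs] @ beta
    sigma2 = float(resid @ resid) / (n - 2)
    return NrmParams(beta, sigma2, "mle", n)


def _batched_gibbs_regression(
    Xs: np.ndarray,  # (C, I, N), rows of missing responses zeroed
    ys: np.ndarray,  # (C, I), missing entries zeroed
    ns: np.ndarray,  # (C,) observed counts
    tau2: float,
    nu0: float,
    s0: float,
    n_samples: int,
    burn_in: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate Gibbs chains for C regressions run in lock-step.

    Zeroed rows contribute nothing to X'X, X'y or the residual sum of
    squares, so padding all chains to I rows is exact.  The beta
    conditional N(A, B) with B^-1 = X'X / sigma2 + I / tau2 is sampled
    through the eigendecomposition of X'X (computed once per chain), so
    each sweep costs O(N^2) per chain.
    """
    if not 0 <= burn_in < n_samples:
        raise ValueError("need 0 <= burn_in < n_samples")
    C, I, N = Xs.shape
    XtX = np.einsum("cin,cim->cnm", Xs, Xs)
    Xty = np.einsum("cin,ci->cn", Xs, ys)
    lam, V = np.linalg.eigh(XtX)
    lam = np.maximum(lam, 0.0)
    # start from the ridge solution at sigma2 = 1
    w = 1.0 / (lam + 1.0 / tau2)
    beta = np.einsum("cnm,cm->cn", V, w * np.einsum("cmn,cm->cn", V, Xty))
    shape = (nu0 + ns) / 2.0
    beta_sum = np.zeros((C, N))
    s2_sum = np.zeros(C)
    kept = 0
    for t in range(n_samples):
        e = ys - np.einsum("cin,cn->ci", Xs, beta)
        rss = np.einsum("ci,ci->c", e, e)
        s2 = ((s0 + rss) / 2.0) / rng.gamma(shape, 1.0, size=C)
        w = 1.0 / (lam / s2[:, None] + 1.0 / tau2)
        rhs = Xty / s2[:, None]
        A = np.einsum("cnm,cm->cn", V, w * np.einsum("cmn,cm->cn", V, rhs))
        z = rng.standard_normal((C, N))
        beta = A + np.einsum("cnm,cm->cn", V, np.sqrt(w) * z)
        if t >= burn_in:
            beta_sum += beta
            s2_sum += s2
            kept += 1
    return beta_sum / kept, s2_sum / kept


def nrm_gibbs(
    y,
    X: DesignMatrix | np.ndarray,
    tau2: float = 1.0,
    nu0: float = 4.0,
    s0: float = 2.0,
    n_samples: int = 5500,
    burn_in: int = 500,
    random_state=None,
) -> NrmParams:
    """Posterior-mean coefficients and variance from the conjugate sampler.

    Default hyper-parameters nu0 = 4, S0 = 2 give the inverse-gamma prior
    on sigma^2 a mean of 1, matching the unit scale of standardized
    columns; beta's prior is N(0, tau^2 I).
    """
    mat = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    obs = np.isfinite(y)
    n = int(obs.sum())
    if n < 3:
        raise ValueError(f"need >= 3 observed responses, got {n}")
    Xz = np.where(obs[:, None], mat, 0.0)
    yz = np.where(obs, y, 0.0)
    rng = np.random.default_rng(random_state)
    beta, s2 = _batched_gibbs_regression(
        Xz[None], yz[None], np.array([n]), tau2, nu0, s0, n_samples, burn_in, rng
    )
    return NrmParams(
        beta[0],
        float(s2[0]),
        "gibbs",
        n,
        {"tau2": tau2, "nu0": nu0, "s0": s0, "n_samples": n_samples, "burn_in": burn_in},
    )


def impute_cells_nrm(params: NrmParams, Xm: np.ndarray, random_state=None) -> np.ndarray:
    """Draw missing entries as Xm beta_hat + z sigma_hat."""
    rng = np.random.default_rng(random_state)
    Xm = np.atleast_2d(np.asarray(Xm, dtype=float))
    z = rng.standard_normal(Xm.shape[0])
    return Xm @ params.beta_hat + z * np.sqrt(params.sigma2_hat)


def correlation_R(std: StandardizedMET, min_obs: int = 3) -> CorrelationR:
    """Pairwise-complete Pearson correlations per environment and pair.

    Pairs with fewer than ``min_obs`` jointly observed genotypes (or a
    degenerate constant vector) are marked NaN with a warning; all pairs
    involving a wholly missing column are NaN.
    """
    I, J, K = std.shape
    P = K * (K - 1) // 2
    out = np.full((J, P), np.nan)
    short = 0
    pairs = [(a, b) for a in range(K) for b in range(a + 1, K)]
    for j in range(J):
        for s, (a, b) in enumerate(pairs):
            xa = std.values[:, j, a]
            xb = std.values[:, j, b]
            joint = np.isfinite(xa) & np.isfinite(xb)
            if joint.sum() < min_obs:
                short += 1
                continue
            va, vb = xa[joint], xb[joint]
            sa, sb = va.std(), vb.std()
            if sa == 0 or sb == 0:
                short += 1
                continue
            out[j, s] = np.corrcoef(va, vb)[0, 1]
    if short:
        warnings.warn(
            f"{short} environment-attribute pair(s) lacked {min_obs} jointly "
            "observed genotypes or were degenerate; their correlations are NA",
            stacklevel=2,
        )
    return CorrelationR(out, K)


def _avg_correlations(R: CorrelationR, j_prime: int, k_prime: int) -> np.ndarray:
    """Mean correlation of k' with each other attribute over environments != j'.

    NaN entries are skipped (the mean runs over the environments actually
    available); an attribute with no available correlation gets 0.
    """
    K = R.n_attributes
    rbar = np.zeros(K)
    for k in range(K):
        if k == k_prime:
            continue
        col = np.delete(R.matrix[:, R.slot(k, k_prime)], j_prime)
        col = col[np.isfinite(col)]
        rbar[k] = col.mean() if col.size else 0.0
    return rbar


def _column_prediction(std: StandardizedMET, j_prime: int, k_prime: int, r_weights: np.ndarray) -> np.ndarray:
    """Correlation-weighted mean of environment j' 's other attribute columns."""
    I, J, K = std.shape
    donors = np.delete(np.arange(K), k_prime)
    vals = std.values[:, j_prime, :][:, donors]
    vals = np.where(np.isfinite(vals), vals, 0.0)
    return vals @ r_weights[donors] / (K - 1)


def _check_column_target(std: StandardizedMET, j_prime: int, k_prime: int) -> None:
    I, J, K = std.shape
    if K < 2:
        raise ValueError("imputing a wholly missing column needs at least 2 attributes")
    others = [k for k in range(K) if k != k_prime]
    if not any(np.isfinite(std.values[:, j_prime, k]).any() for k in others):
        raise ValueError(
            f"environment {j_prime} has no observed attribute besides {k_prime}; "
            "cannot predict the missing column"
        )


def impute_column_avg(
    std: StandardizedMET,
    target: tuple[int, int],
    R: CorrelationR,
    sigma_bar: float,
    random_state=None,
    noise: bool = True,
) -> np.ndarray:
    """Average-correlation prediction of a wholly missing column.

    Each unavailable correlation r_kk'(j') is replaced by its mean over
    the other environments; the prediction is the weighted mean of the
    environment's other attribute columns plus z * sigma_bar noise.
    """
    j_prime, k_prime = target
    _check_column_target(std, j_prime, k_prime)
    rbar = _avg_correlations(R, j_prime, k_prime)
    pred = _column_prediction(std, j_prime, k_prime, rbar)
    if noise:
        rng = np.random.default_rng(random_state)
        pred = pred + rng.standard_normal(pred.size) * sigma_bar
    return pred


def _linreg_correlations(R: CorrelationR, j_prime: int, k_prime: int) -> np.ndarray:
    """Fill row j' of R by through-origin regression on complete rows.

    Each complete donor row r_j is regressed against the observed slots
    of r_j' to give one scalar slope; the slopes' predictions of the
    missing slots (the pairs involving k') are averaged over donors.
    """
    K = R.n_attributes
    miss_slots = [R.slot(k, k_prime) for k in range(K) if k != k_prime]
    row = R.matrix[j_prime]
    obs_slots = [s for s in range(R.matrix.shape[1]) if s not in miss_slots and np.isfinite(row[s])]
    donor_rows = [
        j
        for j in range(R.matrix.shape[0])
        if j != j_prime and np.all(np.isfinite(R.matrix[j]))
    ]
    if len(donor_rows) < 2:
        raise ValueError(
            "fewer than 2 environments have complete correlation rows; "
            "use the average-correlation rule instead"
        )
    preds = np.zeros(K)
    if obs_slots:
        counted = 0
        acc = np.zeros(len(miss_slots))
        for j in donor_rows:
            rj = R.matrix[j]
            denom = float(rj[obs_slots] @ rj[obs_slots])
            if denom == 0:
                continue
            slope = float(rj[obs_slots] @ row[obs_slots]) / denom
            acc += slope * rj[miss_slots]
            counted += 1
        if counted:
            filled = acc / counted
        else:
            filled = np.nanmean(R.matrix[donor_rows][:, miss_slots], axis=0)
    else:
        # K = 2: a single slot per row; nothing observed in row j' to
        # anchor a slope, fall back to the donor average of that slot
        filled = np.nanmean(R.matrix[donor_rows][:, miss_slots], axis=0)
    others = [k for k in range(K) if k != k_prime]
    for k, v in zip(others, filled):
        preds[k] = v
    return preds


def impute_column_linreg(
    std: StandardizedMET,
    target: tuple[int, int],
    R: CorrelationR,
    sigma_bar: float,
    random_state=None,
    noise: bool = True,
) -> np.ndarray:
    """Linear-correlation prediction of a wholly missing column.

    The missing entries of row j' of R are predicted by regressing the
    complete donor rows on the observed part of row j'; the filled
    correlations then weight the environment's other attribute columns.
    """
    j_prime, k_prime = target
    _check_column_target(std, j_prime, k_prime)
    rhat = _linreg_correlations(R, j_prime, k_prime)
    pred = _column_prediction(std, j_prime, k_prime, rhat)
    if noise:
        rng = np.random.default_rng(random_state)
        pred = pred + rng.standard_normal(pred.size) * sigma_bar
    return pred


def average_residual_sd(std: StandardizedMET) -> float:
    """Mean fitted residual sd over the non-missing columns.

    Each column with observed data is regressed on its environment's
    other attributes (option-4 design, least squares); the sigma_jk of
    those fits are averaged.  Used as the noise scale when predicting a
    wholly missing column.
    """
    I, J, K = std.shape
    if K < 2:
        raise ValueError("average residual sd needs at least 2 attributes")
    sds = []
    for j in range(J):
        for k in range(K):
            y = std.values[:, j, k]
            if int(np.isfinite(y).sum()) < 3:
                continue
            X = build_design(std, (j, k), option=4)
            try:
                p = nrm_mle(y, X)
            except ValueError:
                continue
            sds.append(np.sqrt(p.sigma2_hat))
    if not sds:
        raise ValueError("no column had enough observed responses to fit")
    return float(np.mean(sds))


class NRMImputer(BaseMETImputer):
    """Normal-regression-model imputer.

    Parameters
    ----------
    design : {1, 2, 3, 4}, default 3
        Design-matrix option for missing-cell regressions.
    method : {"mle", "gibbs"}
        Non-Bayesian least squares (parameters fixed across imputations,
        only the draw noise varies) or the conjugate Gibbs sampler
        (chains re-run per imputation).
    column_rule : {"avg", "linreg"}
        Rule for wholly missing columns.
    tau2, nu0, s0 : Gibbs prior hyper-parameters.
    n_imputations, gibbs_samples, burn_in, random_state : as elsewhere.
    """

    def __init__(
        self,
        design: int = 3,
        method: str = "mle",
        column_rule: str = "avg",
        tau2: float = 1.0,
        nu0: float = 4.0,
        s0: float = 2.0,
        n_imputations: int = 100,
        gibbs_samples: int = 5500,
        burn_in: int = 500,
        random_state: int | None = None,
    ):
        self.design = design
        self.method = method
        self.column_rule = column_rule
        self.tau2 = tau2
        self.nu0 = nu0
        self.s0 = s0
        self.n_imputations = n_imputations
        self.gibbs_samples = gibbs_samples
        self.burn_in = burn_in
        self.random_state = random_state

    def _impute_all(self, std, pattern, missing, random_state):
        if self.method not in ("mle", "gibbs"):
            raise ValueError(f"method must be 'mle' or 'gibbs', got {self.method!r}")
        if self.column_rule not in ("avg", "linreg"):
            raise ValueError(f"column_rule must be 'avg' or 'linreg', got {self.column_rule!r}")
        I, J, K = std.shape
        H = self.n_imputations
        R = correlation_R(std) if (self.design == 3 or pattern.columns) else None
        idx_of = {t: m for m, t in enumerate(missing)}
        out = np.empty((H, len(missing)))
        rngs = spawn_rngs(random_state, H)

        # --- wholly missing columns: deterministic predictions + noise
        col_preds: dict[tuple[int, int], np.ndarray] = {}
        if pattern.columns:
            sbar = average_residual_sd(std)
            rule = impute_column_avg if self.column_rule == "avg" else impute_column_linreg
            for (j, k) in sorted(pattern.columns):
                col_preds[(j, k)] = rule(std, (j, k), R, sbar, noise=False)
            for h, rng in enumerate(rngs):
                for (j, k), pred in col_preds.items():
                    z = rng.standard_normal(I)
                    for i in range(I):
                        out[h, idx_of[(i, j, k)]] = pred[i] + z[i] * sbar

        # --- missing cells, grouped by column
        by_col: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
        for t in pattern.cells:
            by_col.setdefault((t[1], t[2]), []).append(t)
        cols = sorted(by_col)
        if not cols:
            return out
        designs = {c: build_design(std, c, self.design, R) for c in cols}
        ys = {c: std.values[:, c[0], c[1]] for c in cols}
        miss_rows = {c: np.array(sorted(t[0] for t in by_col[c]), dtype=int) for c in cols}
        if self.method == "mle":
            fits = {c: nrm_mle(ys[c], designs[c]) for c in cols}
            for h, rng in enumerate(rngs):
                for c in cols:
                    p = fits[c]
                    Xm = designs[c].matrix[miss_rows[c]]
                    vals = Xm @ p.beta_hat + rng.standard_normal(len(miss_rows[c])) * np.sqrt(
                        p.sigma2_hat
                    )
                    for i, v in zip(miss_rows[c], vals):
                        out[h, idx_of[(int(i), c[0], c[1])]] = v
        else:
            Xz = np.stack(
                [
                    np.where(np.isfinite(ys[c])[:, None], designs[c].matrix, 0.0)
                    for c in cols
                ]
            )
            yz = np.stack([np.where(np.isfinite(ys[c]), ys[c], 0.0) for c in cols])
            ns = np.array([int(np.isfinite(ys[c]).sum()) for c in cols])
            if np.any(ns < 3):
                c = cols[int(np.argmin(ns))]
                raise ValueError(f"column {c} has {ns.min()} observed responses (< 3)")
            for h, rng in enumerate(rngs):
                beta, s2 = _batched_gibbs_regression(
                    Xz, yz, ns, self.tau2, self.nu0, self.s0,
                    self.gibbs_samples, self.burn_in, rng,
                )
                for ci, c in enumerate(cols):
                    Xm = designs[c].matrix[miss_rows[c]]
                    vals = Xm @ beta[ci] + rng.standard_normal(len(miss_rows[c])) * np.sqrt(s2[ci])
                    for i, v in zip(miss_rows[c], vals):
                        out[h, idx_of[(int(i), c[0], c[1])]] = v
        return out
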