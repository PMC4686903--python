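"""Predictive mean matching (PMM) imputation.

For each target column the normal regression model is refitted on a
bootstrap resample of the observed responses (rows resampled jointly
with their design rows).  Observed and missing entries are both pushed
through the fitted regression; each missing entry is matched to the
observed entries whose predictions are closest under

    d^2 = (pred_obs - pred_miss)^2 / sigma2_hat

and one of the C closest donors is drawn uniformly — the imputation is
that donor's ACTUAL observed value, so every PMM-imputed value is an
element of the observed data.

A wholly missing column is predicted (without noise) by the
average-correlation rule; donor attributes drawn at random from the
environment's other attributes are predicted from cross-environment
regressions, and matching runs between the two prediction vectors, the
donated values being observed entries of the donor attribute columns.
"""

from __future__ import annotations

import warnings

import numpy as np

from .base import BaseMETImputer, spawn_rngs
from .core import StandardizedMET
from .nrm import (
    build_design,
    correlation_R,
    impute_column_avg,
    nrm_gibbs,
    nrm_mle,
    _batched_gibbs_regression,
    _wide_col,
)
from .core import to_wide

__all__ = ["PMMImputer", "pmm_impute_cells", "pmm_impute_column"]


def _fit(y, X, method, gibbs_samples, burn_in, tau2, nu0, s0, rng):
    if method == "mle":
        return nrm_mle(y, X)
    return nrm_gibbs(
        y, X, tau2=tau2, nu0=nu0, s0=s0,
        n_samples=gibbs_samples, burn_in=burn_in, random_state=rng,
    )


def _draw_donor(d2: np.ndarray, n_donors: int, rng) -> int:
    """Index of a uniformly drawn donor among the C smallest distances.

    Ties and ordering are resolved by stable sort on donor position,
    so results are reproducible.
    """
    c = min(n_donors, d2.size)
    pool = np.argsort(d2, kind="stable")[:c]
    return int(pool[rng.integers(c)])


def pmm_impute_cells(
    std: StandardizedMET,
    target: tuple[int, int],
    missing_rows: np.ndarray,
    rng: np.random.Generator,
    n_donors: int = 3,
    design: int = 3,
    method: str = "mle",
    bootstrap_size: int | None = None,
    R=None,
    gibbs_samples: int = 5500,
    burn_in: int = 500,
    tau2: float = 1.0,
    nu0: float = 4.0,
    s0: float = 2.0,
) -> np.ndarray:
    """One PMM imputation of the missing cells in column ``target``.

    Bootstraps the observed rows, refits the regression, matches
    predictions and donates actual observed values.
    """
    j, k = target
    y = std.values[:, j, k]
    obs_rows = np.flatnonzero(np.isfinite(y))
    if obs_rows.size < 3:
        raise ValueError(f"column {target} has {obs_rows.size} observed responses (< 3)")
    if n_donors > obs_rows.size:
        warnings.warn(
            f"donor pool reduced to the {obs_rows.size} available observed values",
            stacklevel=2,
        )
    I0 = obs_rows.size if bootstrap_size is None else int(bootstrap_size)
    if not 1 <= I0 <= obs_rows.size:
        raise ValueError("bootstrap_size must be in 1..n_observed")
    X = build_design(std, target, design, R)
    boot = obs_rows[rng.integers(obs_rows.size, size=I0)]
    yb = y[boot]
    Xb = X.matrix[boot]
    params = _fit(yb, Xb, method, gibbs_samples, burn_in, tau2, nu0, s0, rng)
    pred_obs = Xb @ params.beta_hat
    pred_miss = X.matrix[missing_rows] @ params.beta_hat
    s2 = max(params.sigma2_hat, 1e-300)
    out = np.empty(missing_rows.size)
    for m, pm in enumerate(pred_miss):
        d2 = (pred_obs - pm) ** 2 / s2
        out[m] = yb[_draw_donor(d2, n_donors, rng)]
    return out


def pmm_impute_column(
    std: StandardizedMET,
    target: tuple[int, int],
    rng: np.random.Generator,
    n_donors: int = 3,
    method: str = "mle",
    R=None,
    gibbs_samples: int = 5500,
    burn_in: int = 500,
    tau2: float = 1.0,
    nu0: float = 4.0,
    s0: float = 2.0,
) -> np.ndarray:
    """One PMM imputation of a wholly missing column (j', k').

    The missing column is predicted by the average-correlation rule
    (no noise); a random subset of the other attributes is predicted
    from designs over the other J-1 environments; matching between the
    two prediction vectors selects actual observed donor values.
    """
    I, J, K = std.shape
    j_p, k_p = target
    if K < 2:
        raise ValueError("a wholly missing column needs at least 2 attributes")
    if R is None:
        R = correlation_R(std)
    pred_miss = impute_column_avg(std, target, R, sigma_bar=0.0, noise=False)
    others = [
        k for k in range(K)
        if k != k_p and np.isfinite(std.values[:, j_p, k]).sum() >= 3
    ]
    if not others:
        raise ValueError(f"no eligible donor attribute for column {target}")
    n_k = int(rng.integers(1, K)) if K > 2 else 1
    n_k = min(n_k, len(others))
    subset = rng.choice(others, size=n_k, replace=False)
    wide = to_wide(std, "genotypes_by_env_attr").matrix
    X0 = np.where(np.isfinite(wide), wide, 0.0)
    # design shared by the subset: its attributes over the other J-1 environments
    dcols = [_wide_col(j, kk, J) for kk in subset for j in range(J) if j != j_p]
    Xd = X0[:, dcols]
    cand_vals: list[np.ndarray] = []
    cand_pred: list[np.ndarray] = []
    cand_s2: list[np.ndarray] = []
    for k in subset:
        yk = std.values[:, j_p, k]
        obs = np.isfinite(yk)
        params = _fit(yk, Xd, method, gibbs_samples, burn_in, tau2, nu0, s0, rng)
        pred_k = Xd @ params.beta_hat
        s2 = max(params.sigma2_hat, 1e-300)
        cand_vals.append(yk[obs])
        cand_pred.append(pred_k[obs])
        cand_s2.append(np.full(int(obs.sum()), s2))
    cand_vals = np.concatenate(cand_vals)
    cand_pred = np.concatenate(cand_pred)
    cand_s2 = np.concatenate(cand_s2)
    out = np.empty(I)
    for i in range(I):
        d2 = (cand_pred - pred_miss[i]) ** 2 / cand_s2
        out[i] = cand_vals[_draw_donor(d2, n_donors, rng)]
    return out


class PMMImputer(BaseMETImputer):
    """Predictive-mean-matching imputer.

    Parameters
    ----------
    n_donors : int, default 3
        Donor pool size C: a donor is drawn uniformly from the C
        observed values with the closest predictions.
    design : design-matrix option for the cell regressions (default 3).
    method : {"mle", "gibbs"} fit for the underlying regressions.
    bootstrap_size : resample size I0 (default: the observed count).
    Other parameters as in NRMImputer.
    """

    def __init__(
        self,
        n_donors: int = 3,
        design: int = 3,
        method: str = "mle",
        bootstrap_size: int | None = None,
        tau2: float = 1.0,
        nu0: float = 4.0,
        s0: float = 2.0,
        n_imputations: int = 100,
        gibbs_samples: int = 5500,
        burn_in: int = 500,
        random_state: int | None = None,
    ):
        self.n_donors = n_donors
        self.design = design
        self.method = method
        self.bootstrap_size = bootstrap_size
        self.tau2 = tau2
        self.nu0 = nu0
        self.s0 = s0
        self.n_imputations = n_imputations
        self.gibbs_samples = gibbs_samples
        self.burn_in = burn_in
        self.random_state = random_state

    def _impute_all(self, std, pattern, missing, random_state):
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        idx_of = {t: m for m, t in enumerate(missing)}
        R = correlation_R(std) if (self.design == 3 or pattern.columns) else None
        by_col: dict[tuple[int, int], np.ndarray] = {}
        for t in pattern.cells:
            by_col.setdefault((t[1], t[2]), [])
        for t in pattern.cells:
            by_col[(t[1], t[2])].append(t[0])  # type: ignore[arg-type]
        miss_rows = {c: np.array(sorted(rs), dtype=int) for c, rs in by_col.items()}
        cols = sorted(miss_rows)
        rngs = spawn_rngs(random_state, self.n_imputations)
        out = np.empty((self.n_imputations, len(missing)))
        kw = dict(
            n_donors=self.n_donors,
            method=self.method,
            gibbs_samples=self.gibbs_samples,
            burn_in=self.burn_in,
            tau2=self.tau2,
            nu0=self.nu0,
            s0=self.s0,
        )
        designs = {c: build_design(std, c, self.design, R) for c in cols}
        for h, rng in enumerate(rngs):
            if cols and self.method == "gibbs":
                vals_by_col = self._cells_gibbs_batch(std, cols, miss_rows, designs, rng)
                for c in cols:
                    for i, v in zip(miss_rows[c], vals_by_col[c]):
                        out[h, idx_of[(int(i), c[0], c[1])]] = v
            else:
                for c in cols:
                    vals = pmm_impute_cells(
                        std, c, miss_rows[c], rng,
                        design=self.design, bootstrap_size=self.bootstrap_size, R=R, **kw,
                    )
                    for i, v in zip(miss_rows[c], vals):
                        out[h, idx_of[(int(i), c[0], c[1])]] = v
            for (j, k) in sorted(pattern.columns):
                vals = pmm_impute_column(std, (j, k), rng, R=R, **kw)
                for i, v in enumerate(vals):
                    out[h, idx_of[(i, j, k)]] = v
        return out

    def _cells_gibbs_batch(self, std, cols, miss_rows, designs, rng):
        """One imputation of all cell columns with the Gibbs chains batched.

        Equivalent to looping ``pmm_impute_cells`` per column but runs
        the C conjugate chains in lock-step (zero-padded bootstrap
        blocks), which is much faster when many columns carry missing
        cells.
        """
        boots = {}
        sizes = {}
        for c in cols:
            y = std.values[:, c[0], c[1]]
            obs_rows = np.flatnonzero(np.isfinite(y))
            if obs_rows.size < 3:
                raise ValueError(f"column {c} has {obs_rows.size} observed responses (< 3)")
            I0 = obs_rows.size if self.bootstrap_size is None else int(self.bootstrap_size)
            if not 1 <= I0 <= obs_rows.size:
                raise ValueError("bootstrap_size must be in 1..n_observed")
            boots[c] = obs_rows[rng.integers(obs_rows.size, size=I0)]
            sizes[c] = I0
        pad = max(sizes.values())
        N = designs[cols[0]].n
        C = len(cols)
        Xb = np.zeros((C, pad, N))
        yb = np.zeros((C, pad))
        for ci, c in enumerate(cols):
            b = boots[c]
            Xb[ci, : b.size] = designs[c].matrix[b]
            yb[ci, : b.size] = std.values[:, c[0], c[1]][b]
        ns = np.array([sizes[c] for c in cols])
        beta, s2 = _batched_gibbs_regression(
            Xb, yb, ns, self.tau2, self.nu0, self.s0,
            self.gibbs_samples, self.burn_in, rng,
        )
        vals_by_col = {}
        for ci, c in enumerate(cols):
            b = boots[c]
            pred_obs = designs[c].matrix[b] @ beta[ci]
            pred_miss = designs[c].matrix[miss_rows[c]] @ beta[ci]
            yvals = std.values[:, c[0], c[1]][b]
            sc = max(float(s2[ci]), 1e-300)
            vals = np.empty(miss_rows[c].size)
            for m, pm in enumerate(pred_miss):
                d2 = (pred_obs - pm) ** 2 / sc
                vals[m] = yvals[_draw_donor(d2, self.n_donors, rng)]
            vals_by_col[c] = vals
        return vals_by_col
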