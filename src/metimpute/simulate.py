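"""Variance-components simulator for fully observed MET fixture arrays.

Values follow the additive mixed-model structure

    x_ijk = g_ik + e_jk + (ge)_ijk + eps_ijk

with zero-mean normal effects: genotype effects g_i. are drawn jointly
across attributes (the only source of cross-attribute covariance, with
a configurable correlation matrix), while environment, interaction and
residual effects are independent across attributes with per-attribute
variances.  All effects are independent across their own indices.

The shipped presets mirror the shapes of the simulated arrays used in
three-way MET imputation studies (60x10x6, 80x15x6, 100x20x5,
120x60x4); ``synthetic_dataset1`` / ``synthetic_dataset2`` are
synthetic stand-ins at the shapes of the two real trial arrays
(58x8x6 soybean-style, 50x31x4 wheat-style) for use where the real
deposited data are unavailable.  Fixture variance components default to
a unit total split (0.3, 0.2, 0.2, 0.3) over (G, E, GE, eps) with
genotype cross-attribute correlation 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import METArray

__all__ = [
    "SimConfig",
    "simulate_met",
    "PRESETS",
    "preset_config",
    "synthetic_dataset1",
    "synthetic_dataset2",
]

_DEFAULT_SPLIT = (0.3, 0.2, 0.2, 0.3)  # (G, E, GE, eps)
_DEFAULT_CORR = 0.5


@dataclass
class SimConfig:
    """Dimensions and per-attribute variance components of one array."""

    I: int
    J: int
    K: int
    var_G: np.ndarray = None  # type: ignore[assignment]
    var_E: np.ndarray = None  # type: ignore[assignment]
    var_GE: np.ndarray = None  # type: ignore[assignment]
    var_eps: np.ndarray = None  # type: ignore[assignment]
    genotype_attr_corr: np.ndarray = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        def _vec(v, default):
            if v is None:
                v = default
            v = np.broadcast_to(np.asarray(v, dtype=float), (self.K,)).copy()
            if np.any(v < 0):
                raise ValueError("variance components must be nonnegative")
            return v

        self.var_G = _vec(self.var_G, _DEFAULT_SPLIT[0])
        self.var_E = _vec(self.var_E, _DEFAULT_SPLIT[1])
        self.var_GE = _vec(self.var_GE, _DEFAULT_SPLIT[2])
        self.var_eps = _vec(self.var_eps, _DEFAULT_SPLIT[3])
        if self.genotype_attr_corr is None:
            C = np.full((self.K, self.K), _DEFAULT_CORR)
            np.fill_diagonal(C, 1.0)
            self.genotype_attr_corr = C
        self.genotype_attr_corr = np.asarray(self.genotype_attr_corr, dtype=float)
        C = self.genotype_attr_corr
        if C.shape != (self.K, self.K) or not np.allclose(C, C.T):
            raise ValueError("genotype_attr_corr must be a symmetric K x K matrix")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("genotype_attr_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(C)) < -1e-10:
            raise ValueError("genotype_attr_corr must be positive semidefinite")


def simulate_met(cfg: SimConfig) -> METArray:
    """Draw one fully observed array under the mixed-model structure."""
    rng = np.random.default_rng(cfg.seed)
    I, J, K = cfg.I, cfg.J, cfg.K
    sd_G = np.sqrt(cfg.var_G)
    cov_G = cfg.genotype_attr_corr * np.outer(sd_G, sd_G)
    # eigh-based square root tolerates semidefinite correlation matrices
    lam, V = np.linalg.eigh(cov_G)
    A = V * np.sqrt(np.maximum(lam, 0.0))
    g = rng.standard_normal((I, K)) @ A.T  # (I, K)
    e = rng.standard_normal((J, K)) * np.sqrt(cfg.var_E)
    ge = rng.standard_normal((I, J, K)) * np.sqrt(cfg.var_GE)
    eps = rng.standard_normal((I, J, K)) * np.sqrt(cfg.var_eps)
    x = g[:, None, :] + e[None, :, :] + ge + eps
    return METArray(x)


PRESETS: dict[str, tuple[int, int, int]] = {
    "dataset3": (60, 10, 6),
    "dataset4": (80, 15, 6),
    "dataset5": (100, 20, 5),
    "dataset6": (120, 60, 4),
}


def preset_config(name: str, seed: int = 0) -> SimConfig:
    """Config for one of the shipped fixture presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    I, J, K = PRESETS[name]
    return SimConfig(I=I, J=J, K=K, seed=seed)


def synthetic_dataset1(seed: int = 0) -> METArray:
    """Synthetic stand-in at the 58 x 8 x 6 soybean-trial shape.

    This is NOT the deposited soybean dataset: it is a simulated array
    of the same dimensions drawn from the fixture variance components,
    for offline testing and benchmarking.
    """
    return simulate_met(SimConfig(I=58, J=8, K=6, seed=seed))


def synthetic_dataset2(seed: int = 0) -> METArray:
    """Synthetic stand-in at the 50 x 31 x 4 wheat-trial shape.

    NOT a real trial dataset; a simulated fixture of the same shape.
    """
    return simulate_met(SimConfig(I=50, J=31, K=4, seed=seed))
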