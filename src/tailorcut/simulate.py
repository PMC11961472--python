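"""Replicate data generation: multivariate normal and Vale–Maurelli non-normal.

Non-normal margins are produced by Fleishman's cubic transform
``Y = a + bZ + cZ^2 + dZ^3`` of a standard normal Z, with coefficients solved
so Y has mean 0, variance 1 and target skewness / excess kurtosis.  For a
target item correlation matrix the normals are drawn with an *intermediate*
correlation per pair, solved from the cubic relation between the pre- and
post-transform correlations, so the transformed data recovers the target
(Vale–Maurelli construction).  With normal margins every transform is the
identity and the intermediate matrix equals the target, so the non-normal
path reproduces the plain normal path bit for bit.

Seeding is counter-based: each replicate draws from
``SeedSequence(master_seed, spawn_key=(crc32(population_label), rep_index))``
so streams are reproducible, order-independent and parallelizable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import optimize

from .model_spec import ParameterSet

__all__ = [
    "MarginSpec",
    "SimConfig",
    "fleishman_coefficients",
    "intermediate_correlation",
    "generate_dataset",
]


@dataclass
class MarginSpec:
    """Per-item target skewness and excess kurtosis."""

    skewness: np.ndarray
    excess_kurtosis: np.ndarray

    def __post_init__(self) -> None:
        self.skewness = np.atleast_1d(np.asarray(self.skewness, dtype=float))
        self.excess_kurtosis = np.atleast_1d(
            np.asarray(self.excess_kurtosis, dtype=float))
        if self.skewness.shape != self.excess_kurtosis.shape:
            raise ValueError("skewness and excess_kurtosis must have equal length")
        bad = self.excess_kurtosis < self.skewness**2 - 2.0
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"margin {i}: excess kurtosis {self.excess_kurtosis[i]} violates "
                f"the feasibility bound >= skew^2 - 2 = {self.skewness[i]**2 - 2}")

    def is_normal(self) -> bool:
        return bool(np.all(self.skewness == 0) and np.all(self.excess_kurtosis == 0))

    def broadcast(self, p: int) -> "MarginSpec":
        if self.skewness.size == 1:
            return MarginSpec(np.full(p, self.skewness[0]),
                              np.full(p, self.excess_kurtosis[0]))
        if self.skewness.size != p:
            raise ValueError(f"margins specify {self.skewness.size} items, data has {p}")
        return self


@dataclass
class SimConfig:
    """Monte Carlo settings: sample size, replications, seed, margins."""

    n: int
    n_reps: int = 500
    master_seed: int = 0
    margins: Union[str, MarginSpec] = "normal"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if isinstance(self.margins, str) and self.margins != "normal":
            raise ValueError(f"unknown margins spec {self.margins!r}")

    def margin_spec(self, p: int) -> MarginSpec:
        if isinstance(self.margins, str):
            return MarginSpec(np.zeros(p), np.zeros(p))
        return self.margins.broadcast(p)


# ---------------------------------------------------------------------------
# Fleishman polynomial coefficients
# ---------------------------------------------------------------------------

def _fleishman_system(x: np.ndarray, skew: float, exkurt: float) -> np.ndarray:
    b, c, d = x
    var = b**2 + 6 * b * d + 2 * c**2 + 15 * d**2
    g1 = 2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2)
    g2 = 24 * (b * d + c**2 * (1 + b**2 + 28 * b * d)
               + d**2 * (12 + 48 * b * d + 141 * c**2 + 225 * d**2))
    return np.array([var - 1.0, g1 - skew, g2 - exkurt])


def fleishman_coefficients(skew: float, exkurt: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) of the Fleishman cubic transform.

    ``Y = a + bZ + cZ^2 + dZ^3`` has mean 0, unit variance and the requested
    skewness and excess kurtosis; ``a = -c`` enforces the zero mean.
    Moment tolerance of the nonlinear solve: 1e-10.
    """
    if exkurt < skew**2 - 2.0:
        raise ValueError(
            f"(skew={skew}, exkurt={exkurt}) infeasible: needs exkurt >= skew^2 - 2")
    if skew == 0.0 and exkurt == 0.0:
        return (0.0, 1.0, 0.0, 0.0)
    starts = [(1.0, 0.0, 0.0), (0.9, 0.1 * np.sign(skew or 1.0), 0.05),
              (0.8, 0.2 * np.sign(skew or 1.0), 0.1)]
    for x0 in starts:
        sol = optimize.root(_fleishman_system, x0, args=(skew, exkurt),
                            method="hybr", tol=1e-13)
        if np.max(np.abs(_fleishman_system(sol.x, skew, exkurt))) < 1e-10:
            b, c, d = sol.x
            return (-c, float(b), float(c), float(d))
    raise RuntimeError(
        f"Fleishman solve did not converge for (skew={skew}, exkurt={exkurt})")


def intermediate_correlation(r_target: float, coef_i, coef_j) -> float:
    """Pre-transform correlation giving ``r_target`` after Fleishman transforms.

    Solves the cubic
    ``r = rho*(b_i b_j + 3 b_i d_j + 3 d_i b_j + 9 d_i d_j)
    + rho^2 * 2 c_i c_j + rho^3 * 6 d_i d_j`` for rho in [-1, 1].
    """
    if abs(r_target) > 1.0:
        raise ValueError(f"|r_target| = {abs(r_target)} > 1")
    _, bi, ci, di = coef_i
    _, bj, cj, dj = coef_j
    k1 = bi * bj + 3 * bi * dj + 3 * di * bj + 9 * di * dj
    k2 = 2 * ci * cj
    k3 = 6 * di * dj
    if k2 == 0.0 and k3 == 0.0:
        # linear case (includes normal margins, where k1 == 1 exactly)
        if k1 == 0.0:
            if r_target == 0.0:
                return 0.0
            raise ValueError("no real root in [-1, 1] for the intermediate correlation")
        rho = r_target / k1
    else:
        roots = np.roots([k3, k2, k1, -r_target])
        real = roots[np.abs(roots.imag) < 1e-9].real
        real = real[(real >= -1.0 - 1e-12) & (real <= 1.0 + 1e-12)]
        if real.size == 0:
            raise ValueError(
                f"no real root in [-1, 1] for target correlation {r_target}")
        rho = float(real[np.argmin(np.abs(real - r_target))])
    if not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
        raise ValueError(f"intermediate correlation {rho} outside [-1, 1]")
    return float(np.clip(rho, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

_PLAN_CACHE: dict = {}


def _vale_maurelli_plan(sigma: np.ndarray, margins: MarginSpec):
    """Cholesky factor of the intermediate correlation matrix + transforms."""
    key = (sigma.tobytes(), margins.skewness.tobytes(),
           margins.excess_kurtosis.tobytes())
    if key in _PLAN_CACHE:
        return _PLAN_CACHE[key]
    p = sigma.shape[0]
    sd = np.sqrt(np.diag(sigma))
    if np.any(sd <= 0):
        raise ValueError("population covariance has a nonpositive variance")
    corr = sigma / np.outer(sd, sd)
    coefs = [fleishman_coefficients(margins.skewness[i], margins.excess_kurtosis[i])
             for i in range(p)]
    inter = np.eye(p)
    for i in range(p):
        for j in range(i):
            inter[i, j] = inter[j, i] = intermediate_correlation(
                corr[i, j], coefs[i], coefs[j])
    try:
        chol = np.linalg.cholesky(inter)
    except np.linalg.LinAlgError:
        adj = np.abs(inter - corr)
        np.fill_diagonal(adj, -np.inf)
        i, j = np.unravel_index(np.argmax(adj), adj.shape)
        raise ValueError(
            "intermediate correlation matrix is not positive definite; the "
            f"largest Vale-Maurelli adjustment is for item pair ({i}, {j}) "
            f"(target {corr[i, j]:.4f} -> intermediate {inter[i, j]:.4f})")
    plan = (chol, coefs, sd)
    if len(_PLAN_CACHE) > 64:
        _PLAN_CACHE.clear()
    _PLAN_CACHE[key] = plan
    return plan


def replicate_rng(master_seed: int, population_label: str, rep_index: int) -> np.random.Generator:
    """Independent substream for one replicate of one population."""
    label_key = zlib.crc32(population_label.encode("utf-8"))
    ss = np.random.SeedSequence(master_seed, spawn_key=(label_key, rep_index))
    return np.random.default_rng(ss)


def generate_dataset(pop: Union[ParameterSet, np.ndarray], cfg: SimConfig,
                     rep_index: int, population_label: str = "pop") -> np.ndarray:
    """Draw one n x p replicate dataset from a population model.

    Deterministic given ``(master_seed, population_label, rep_index)``.
    ``pop`` may be a :class:`ParameterSet` or a covariance matrix directly.
    """
    sigma = pop.implied_covariance() if isinstance(pop, ParameterSet) \
        else np.asarray(pop, dtype=float)
    p = sigma.shape[0]
    margins = cfg.margin_spec(p)
    chol, coefs, sd = _vale_maurelli_plan(sigma, margins)
    rng = replicate_rng(cfg.master_seed, population_label, rep_index)
    z = rng.standard_normal((cfg.n, p))
    y = z @ chol.T
    for i, (a, b, c, d) in enumerate(coefs):
        if (a, b, c, d) != (0.0, 1.0, 0.0, 0.0):
            col = y[:, i]
            y[:, i] = a + col * (b + col * (c + col * d))
    return y * sd
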