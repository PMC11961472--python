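"""CFA model structures: parsing, parameter matrices and implied moments.

A confirmatory factor model for p observed items and m latent factors is

    Sigma(theta) = Lambda Psi Lambda' + Theta

with Lambda the p x m loading matrix, Psi the m x m factor covariance matrix
and Theta the p x p residual covariance matrix.  Population models are held
as fully numeric :class:`ParameterSet` objects; analysis models (the models
whose fit is tested) are :class:`AnalysisModel` objects carrying a free/fixed
pattern per parameter cell.

Model syntax
------------
A small dialect of the de-facto SEM model language, one statement per line,
``#`` starts a comment:

``f1 =~ x1 + x2 + 0.5*x3``
    factor ``f1`` is measured by the listed items; a numeric premultiplier
    fixes that loading.
``a ~~ b`` / ``a ~~ 0.7*b``
    free (resp. fixed) covariance between two factors or two items;
    ``a ~~ a`` refers to a variance.

Regression paths (``~``) are reserved and rejected: only measurement models
are in scope.  Defaults: residual variances free, residual covariances fixed
at zero, factor covariances free, and identification either by fixing the
first loading of each factor to 1 (``marker_loading``, the default) or by
fixing factor variances to 1 (``unit_factor_variance``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterSet",
    "AnalysisModel",
    "ModelDoF",
    "ModelSyntaxError",
    "parse_model",
    "implied_covariance",
    "split_factor",
    "add_residual_correlations",
]


class ModelSyntaxError(ValueError):
    """Raised when a model-definition string cannot be parsed."""


# ---------------------------------------------------------------------------
# Parameter sets (population models / fitted solutions)
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Numeric CFA parameter matrices defining a population model.

    Parameters
    ----------
    lam : (p, m) loading matrix.
    psi : (m, m) factor covariance matrix.
    theta : (p, p) residual covariance matrix.
    item_names, factor_names : ordered labels.
    """

    lam: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    item_names: list[str] = field(default_factory=list)
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lam = np.atleast_2d(np.asarray(self.lam, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        p, m = self.lam.shape
        if self.psi.shape != (m, m):
            raise ValueError(f"psi must be {m}x{m}, got {self.psi.shape}")
        if self.theta.shape != (p, p):
            raise ValueError(f"theta must be {p}x{p}, got {self.theta.shape}")
        if not np.allclose(self.psi, self.psi.T):
            raise ValueError("psi must be symmetric")
        if not np.allclose(self.theta, self.theta.T):
            raise ValueError("theta must be symmetric")
        if not self.item_names:
            self.item_names = [f"x{i + 1}" for i in range(p)]
        if not self.factor_names:
            self.factor_names = [f"f{a + 1}" for a in range(m)]
        if len(self.item_names) != p or len(self.factor_names) != m:
            raise ValueError("label lengths inconsistent with matrix dimensions")

    @property
    def p(self) -> int:
        return self.lam.shape[0]

    @property
    def m(self) -> int:
        return self.lam.shape[1]

    def implied_covariance(self) -> np.ndarray:
        return implied_covariance(self)

    def is_positive_definite(self) -> bool:
        try:
            np.linalg.cholesky(self.implied_covariance())
            return True
        except np.linalg.LinAlgError:
            return False


def implied_covariance(params: ParameterSet) -> np.ndarray:
    """Model-implied covariance matrix ``Lambda Psi Lambda' + Theta``.

    Symmetric by construction (symmetrized against rounding).
    """
    sigma = params.lam @ params.psi @ params.lam.T + params.theta
    return (sigma + sigma.T) / 2.0


def split_factor(pop: ParameterSet, item_partition, r: float) -> ParameterSet:
    """Split a one-factor population into correlated factors.

    The loadings and residual covariances are kept; the single factor is
    replaced by one factor per partition cell, each inheriting the parent
    factor's variance, with pairwise correlation ``r``.  ``r = 1`` therefore
    reproduces the original implied covariance exactly.

    Parameters
    ----------
    pop : one-factor population model.
    item_partition : sequence of item-name (or index) lists, disjoint and
        jointly covering all items.
    r : factor correlation in (-1, 1] (1 is the degenerate no-split case).
    """
    if pop.m != 1:
        raise ValueError("split_factor requires a one-factor population")
    if not -1.0 < r <= 1.0:
        raise ValueError(f"factor correlation r={r} outside (-1, 1]")
    cells = [_resolve_items(cell, pop.item_names) for cell in item_partition]
    if any(len(c) == 0 for c in cells):
        raise ValueError("empty partition cell")
    flat = [i for cell in cells for i in cell]
    if sorted(flat) != list(range(pop.p)):
        raise ValueError("partition must cover all items disjointly")

    k = len(cells)
    lam = np.zeros((pop.p, k))
    for a, cell in enumerate(cells):
        lam[cell, a] = pop.lam[cell, 0]
    phi = float(pop.psi[0, 0])
    psi = np.full((k, k), r * phi)
    np.fill_diagonal(psi, phi)
    names = [f"{pop.factor_names[0]}_{a + 1}" for a in range(k)]
    return ParameterSet(lam, psi, pop.theta.copy(), list(pop.item_names), names)


def add_residual_correlations(pop: ParameterSet, pairs, r: float) -> ParameterSet:
    """Add residual correlations of size ``r`` between the given item pairs.

    For each pair (i, j) the residual covariance is set to
    ``r * sqrt(theta_ii * theta_jj)``; everything else is unchanged.  The
    resulting residual matrix must leave the implied covariance positive
    definite.
    """
    theta = pop.theta.copy()
    seen = set()
    for pair in pairs:
        i, j = (_resolve_item(x, pop.item_names) for x in pair)
        if i == j:
            raise ValueError(f"pair {pair!r} is not a distinct item pair")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate pair {pair!r}")
        seen.add(key)
        cov = r * np.sqrt(theta[i, i] * theta[j, j])
        theta[i, j] = theta[j, i] = cov
    out = ParameterSet(pop.lam.copy(), pop.psi.copy(), theta,
                       list(pop.item_names), list(pop.factor_names))
    if not out.is_positive_definite():
        raise ValueError("residual correlations make the implied covariance non-PD")
    return out


def _resolve_item(x, names: list[str]) -> int:
    if isinstance(x, (int, np.integer)):
        if not 0 <= x < len(names):
            raise ValueError(f"item index {x} out of range")
        return int(x)
    try:
        return names.index(x)
    except ValueError:
        raise ValueError(f"unknown item {x!r}") from None


def _resolve_items(xs, names: list[str]) -> list[int]:
    return [_resolve_item(x, names) for x in xs]


# ---------------------------------------------------------------------------
# Analysis models (free/fixed patterns)
# ---------------------------------------------------------------------------

@dataclass
class ModelDoF:
    """Degrees-of-freedom bookkeeping for a covariance-structure model."""

    p: int
    q: int
    df: int


@dataclass
class AnalysisModel:
    """A CFA model structure with free/fixed parameter pattern.

    Boolean masks mark free cells; ``*_fixed`` holds the values of fixed
    cells (and is ignored where the mask is True).  ``psi``/``theta`` masks
    and fixed matrices are symmetric.
    """

    item_names: list[str]
    factor_names: list[str]
    lam_free: np.ndarray
    lam_fixed: np.ndarray
    psi_free: np.ndarray
    psi_fixed: np.ndarray
    theta_free: np.ndarray
    theta_fixed: np.ndarray
    identification: str = "marker_loading"

    @property
    def p(self) -> int:
        return len(self.item_names)

    @property
    def m(self) -> int:
        return len(self.factor_names)

    @property
    def q(self) -> int:
        tri_psi = np.tril(self.psi_free)
        tri_theta = np.tril(self.theta_free)
        return int(self.lam_free.sum() + tri_psi.sum() + tri_theta.sum())

    def dof(self) -> ModelDoF:
        p, q = self.p, self.q
        df = p * (p + 1) // 2 - q
        if df < 0:
            raise ValueError(f"model has {q} free parameters but only "
                             f"{p * (p + 1) // 2} covariance moments (t-rule)")
        return ModelDoF(p=p, q=q, df=df)

    @property
    def df(self) -> int:
        return self.dof().df

    # -- free-parameter packing (shared by the estimator) -------------------

    def free_indices(self):
        """Index triples of free cells: (kind, i, j) in a fixed order."""
        idx = []
        p, m = self.p, self.m
        for i in range(p):
            for a in range(m):
                if self.lam_free[i, a]:
                    idx.append(("lam", i, a))
        for a in range(m):
            for b in range(a + 1):
                if self.psi_free[a, b]:
                    idx.append(("psi", a, b))
        for i in range(p):
            for j in range(i + 1):
                if self.theta_free[i, j]:
                    idx.append(("theta", i, j))
        return idx

    def build_matrices(self, x: np.ndarray) -> ParameterSet:
        """Assemble a ParameterSet from a free-parameter vector."""
        lam = self.lam_fixed.copy()
        psi = self.psi_fixed.copy()
        theta = self.theta_fixed.copy()
        for val, (kind, i, j) in zip(x, self.free_indices()):
            if kind == "lam":
                lam[i, j] = val
            elif kind == "psi":
                psi[i, j] = psi[j, i] = val
            else:
                theta[i, j] = theta[j, i] = val
        return ParameterSet(lam, psi, theta, list(self.item_names),
                            list(self.factor_names))

    def serialize(self) -> str:
        """Render back to model syntax; parse(serialize(m)) has m's pattern."""
        lines = []
        for a, f in enumerate(self.factor_names):
            terms = []
            for i, it in enumerate(self.item_names):
                if self.lam_free[i, a]:
                    terms.append(it)
                elif self.lam_fixed[i, a] != 0.0:
                    terms.append(f"{self.lam_fixed[i, a]:g}*{it}")
            if terms:
                lines.append(f"{f} =~ " + " + ".join(terms))
        for a in range(self.m):
            for b in range(a, self.m):
                fa, fb = self.factor_names[a], self.factor_names[b]
                default_free = True
                default_fixed = None
                if a == b and self.identification == "unit_factor_variance":
                    default_fixed = 1.0
                if self.psi_free[a, b]:
                    if not default_free or default_fixed is not None:
                        lines.append(f"{fa} ~~ {fb}")
                elif default_fixed is None or self.psi_fixed[a, b] != default_fixed:
                    lines.append(f"{fa} ~~ {self.psi_fixed[a, b]:g}*{fb}")
        for i in range(self.p):
            for j in range(i, self.p):
                ii, jj = self.item_names[i], self.item_names[j]
                if i == j:
                    if not self.theta_free[i, j]:
                        lines.append(f"{ii} ~~ {self.theta_fixed[i, j]:g}*{jj}")
                elif self.theta_free[i, j]:
                    lines.append(f"{ii} ~~ {jj}")
                elif self.theta_fixed[i, j] != 0.0:
                    lines.append(f"{ii} ~~ {self.theta_fixed[i, j]:g}*{jj}")
        return "\n".join(lines) + "\n"


_TERM_RE = re.compile(r"^(?:(?P<mult>[+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\*)?(?P<name>[A-Za-z_][A-Za-z0-9_.]*)$")


def _parse_term(tok: str, lineno: int):
    m = _TERM_RE.match(tok.strip())
    if m is None:
        raise ModelSyntaxError(f"line {lineno}: cannot parse term {tok!r}")
    mult = m.group("mult")
    return (None if mult is None else float(mult)), m.group("name")


def parse_model(text: str, identification: str = "marker_loading") -> AnalysisModel:
    """Parse a model-definition string into an :class:`AnalysisModel`.

    Raises :class:`ModelSyntaxError` with the offending line number on
    malformed statements, duplicate parameters, factors without items, or
    names used in ``~~`` statements that are neither declared factors nor
    items loaded on some factor.
    """
    if identification not in ("marker_loading", "unit_factor_variance"):
        raise ValueError(f"unknown identification rule {identification!r}")

    factor_items: dict[str, list[tuple[str, float | None]]] = {}
    cov_statements: list[tuple[int, str, str, float | None]] = []

    statements = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for stmt in line.split(";"):
            if stmt.strip():
                statements.append((lineno, stmt.strip()))

    for lineno, stmt in statements:
        if "=~" in stmt:
            lhs, rhs = stmt.split("=~", 1)
            fname = lhs.strip()
            if not re.match(r"^[A-Za-z_][A-Za-z0-9_.]*$", fname):
                raise ModelSyntaxError(f"line {lineno}: bad factor name {fname!r}")
            items = factor_items.setdefault(fname, [])
            for tok in rhs.split("+"):
                mult, name = _parse_term(tok, lineno)
                if any(n == name for n, _ in items):
                    raise ModelSyntaxError(
                        f"line {lineno}: duplicate loading of {name!r} on {fname!r}")
                items.append((name, mult))
        elif "~~" in stmt:
            lhs, rhs = stmt.split("~~", 1)
            lname = lhs.strip()
            mult, rname = _parse_term(rhs, lineno)
            cov_statements.append((lineno, lname, rname, mult))
        elif "~" in stmt:
            raise ModelSyntaxError(
                f"line {lineno}: regression paths ('~') are reserved and not "
                "supported; only measurement models (=~, ~~) are handled")
        else:
            raise ModelSyntaxError(f"line {lineno}: unrecognized statement {stmt!r}")

    if not factor_items:
        raise ModelSyntaxError("model defines no factors (no '=~' statements)")
    for f, items in factor_items.items():
        if not items:
            raise ModelSyntaxError(f"factor {f!r} has no items (unidentified)")

    factor_names = list(factor_items)
    item_names: list[str] = []
    for items in factor_items.values():
        for name, _ in items:
            if name in factor_items:
                raise ModelSyntaxError(f"{name!r} used both as factor and item")
            if name not in item_names:
                item_names.append(name)

    p, m = len(item_names), len(factor_names)
    lam_free = np.zeros((p, m), dtype=bool)
    lam_fixed = np.zeros((p, m))
    psi_free = np.ones((m, m), dtype=bool)   # factor (co)variances free by default
    psi_fixed = np.zeros((m, m))
    theta_free = np.zeros((p, p), dtype=bool)
    np.fill_diagonal(theta_free, True)        # residual variances free by default
    theta_fixed = np.zeros((p, p))

    marker_done: dict[str, bool] = {f: False for f in factor_names}
    for a, f in enumerate(factor_names):
        for name, mult in factor_items[f]:
            i = item_names.index(name)
            if mult is not None:
                lam_free[i, a] = False
                lam_fixed[i, a] = mult
                marker_done[f] = True
            else:
                lam_free[i, a] = True

    if identification == "marker_loading":
        for a, f in enumerate(factor_names):
            if not marker_done[f]:
                name = factor_items[f][0][0]
                i = item_names.index(name)
                lam_free[i, a] = False
                lam_fixed[i, a] = 1.0
    else:  # unit_factor_variance
        psi_free[np.diag_indices(m)] = False
        psi_fixed[np.diag_indices(m)] = 1.0

    seen_cov: set[tuple[str, str, str]] = set()
    for lineno, lname, rname, mult in cov_statements:
        if lname in factor_names and rname in factor_names:
            a, b = factor_names.index(lname), factor_names.index(rname)
            key = ("psi", *sorted((lname, rname)))
            if key in seen_cov:
                raise ModelSyntaxError(f"line {lineno}: duplicate parameter "
                                       f"{lname} ~~ {rname}")
            seen_cov.add(key)
            if mult is None:
                psi_free[a, b] = psi_free[b, a] = True
                psi_fixed[a, b] = psi_fixed[b, a] = 0.0
            else:
                psi_free[a, b] = psi_free[b, a] = False
                psi_fixed[a, b] = psi_fixed[b, a] = mult
        elif lname in item_names and rname in item_names:
            i, j = item_names.index(lname), item_names.index(rname)
            key = ("theta", *sorted((lname, rname)))
            if key in seen_cov:
                raise ModelSyntaxError(f"line {lineno}: duplicate parameter "
                                       f"{lname} ~~ {rname}")
            seen_cov.add(key)
            if mult is None:
                theta_free[i, j] = theta_free[j, i] = True
                theta_fixed[i, j] = theta_fixed[j, i] = 0.0
            else:
                theta_free[i, j] = theta_free[j, i] = False
                theta_fixed[i, j] = theta_fixed[j, i] = mult
        else:
            bad = lname if lname not in factor_names and lname not in item_names \
                else rname
            raise ModelSyntaxError(
                f"line {lineno}: {bad!r} is neither a declared factor nor an "
                "item loaded on some factor (or the statement mixes a factor "
                "with an item)")

    model = AnalysisModel(item_names, factor_names, lam_free, lam_fixed,
                          psi_free, psi_fixed, theta_free, theta_fixed,
                          identification=identification)
    model.dof()  # t-rule check
    return model
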