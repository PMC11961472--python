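"""ROC analysis of H0 vs. H1 fit-index distributions and Youden cutoffs.

Misspecified-population (H1) fits are the positives.  A replicate is
classified positive (flagged as misspecified) when its index value falls
strictly on the worse-fit side of the cutoff; a value exactly at the cutoff
counts as a pass, matching cutoff statements of the form "chi2 <= 28.03" or
"CFI >= .972".  Candidate cutoffs are the observed values of the pooled
sample.  The AUC is the trapezoidal area of the empirical ROC curve, which
equals pairwise concordance (ties counted 1/2, the Mann-Whitney identity).

Indices whose AUC falls below a screening threshold (default .80) are
discarded before cutoffs are generated; when several survive, the one with
the highest AUC is the most decisive.  An AUC below .5 marks a pathology
(correctly specified models looking *worse* than misspecified ones): the
report is flagged and no cutoff is endorsed, never silently re-oriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "IndexDistributions",
    "RocCurve",
    "CutoffReport",
    "ScreenResult",
    "roc_curve",
    "auc_pairwise",
    "optimal_cutoff",
    "screen_indices",
]


@dataclass
class IndexDistributions:
    """Paired samples of one fit index under the H0 and H1 populations."""

    h0_values: np.ndarray
    h1_values: np.ndarray
    higher_is_better: bool
    index_name: str = ""

    def __post_init__(self) -> None:
        self.h0_values = np.asarray(self.h0_values, dtype=float).ravel()
        self.h1_values = np.asarray(self.h1_values, dtype=float).ravel()
        if self.h0_values.size == 0 or self.h1_values.size == 0:
            raise ValueError("both H0 and H1 samples must be non-empty")
        if np.any(~np.isfinite(self.h0_values)) or np.any(~np.isfinite(self.h1_values)):
            raise ValueError("index distributions contain non-finite values")

    def badness_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Values oriented so larger = worse fit."""
        s = -1.0 if self.higher_is_better else 1.0
        return s * self.h0_values, s * self.h1_values


@dataclass
class RocCurve:
    """Empirical ROC curve: (fpr, tpr) points and trapezoidal AUC."""

    points: np.ndarray   # (k, 2) array, fpr/tpr, ordered from (0,0) to (1,1)
    auc: float


@dataclass
class CutoffReport:
    """Youden-optimal tailored cutoff and its error rates for one index."""

    index_name: str
    auc: float
    cutoff: float
    comparator: str              # "<=" (lower-is-better) or ">=" (CFI variants)
    sensitivity: float
    specificity: float
    accuracy: float
    flagged: bool = False        # AUC < .5 pathology: cutoff not endorsed
    passed_auc_threshold: Optional[bool] = None
    note: str = ""

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def type1(self) -> float:
        return 1.0 - self.specificity

    @property
    def type2(self) -> float:
        return 1.0 - self.sensitivity

    def passes(self, value: float) -> bool:
        """Does an observed index value pass (accept) this cutoff?"""
        return value <= self.cutoff if self.comparator == "<=" else value >= self.cutoff

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(youden=self.youden, type1=self.type1, type2=self.type2)
        return d


def roc_curve(dist: IndexDistributions) -> RocCurve:
    """ROC curve over observed-value cutoffs; positives are H1 fits."""
    s0, s1 = dist.badness_scores()
    y = np.concatenate([np.zeros(s0.size), np.ones(s1.size)])
    scores = np.concatenate([s0, s1])
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=pts, auc=auc)


def auc_pairwise(dist: IndexDistributions) -> float:
    """AUC as pairwise concordance: share of (H1, H0) pairs with the H1
    value strictly worse, ties counted 1/2.  Independent of the curve route.
    """
    s0, s1 = dist.badness_scores()
    # rank-based Mann-Whitney keeps this exact and O(n log n)
    diff = s1[:, None] - s0[None, :]
    if diff.size <= 4_000_000:
        return float(np.mean((diff > 0) + 0.5 * (diff == 0)))
    from scipy.stats import rankdata
    pooled = np.concatenate([s0, s1])
    ranks = rankdata(pooled)
    r1 = ranks[s0.size:].sum()
    u = r1 - s1.size * (s1.size + 1) / 2.0
    return float(u / (s0.size * s1.size))


def _confusion_rates(dist: IndexDistributions, cutoffs: np.ndarray):
    """Sensitivity/specificity at each candidate cutoff (vectorized).

    Classification is strict: positive iff strictly worse than the cutoff.
    """
    s0, s1 = dist.badness_scores()
    sign = -1.0 if dist.higher_is_better else 1.0
    t = sign * cutoffs
    sens = np.mean(s1[None, :] > t[:, None], axis=1)
    spec = np.mean(s0[None, :] <= t[:, None], axis=1)
    return sens, spec


def optimal_cutoff(dist: IndexDistributions,
                   auc_threshold: Optional[float] = None) -> CutoffReport:
    """Youden-optimal cutoff over the pooled observed values.

    Ties in the Youden index are broken toward higher specificity (lower
    type I error), then toward the more conservative cutoff (the one
    accepting more models).  Reports sensitivity, specificity, accuracy and
    the implied type I / type II error rates; an AUC below .5 flags the
    report and no cutoff is endorsed.
    """
    curve = roc_curve(dist)
    candidates = np.unique(np.concatenate([dist.h0_values, dist.h1_values]))
    sens, spec = _confusion_rates(dist, candidates)
    youden = sens + spec - 1.0
    # lexicographic argmax: youden, then specificity, then conservatism
    order = np.lexsort((
        candidates if not dist.higher_is_better else -candidates,
        spec,
        youden,
    ))
    k = order[-1]
    n0, n1 = dist.h0_values.size, dist.h1_values.size
    tp, tn = sens[k] * n1, spec[k] * n0
    accuracy = (tp + tn) / (n0 + n1)
    comparator = ">=" if dist.higher_is_better else "<="
    flagged = curve.auc < 0.5
    note = ""
    if flagged:
        note = ("AUC below .5: correctly specified models show worse index "
                "values than misspecified ones; cutoff not endorsed")
    report = CutoffReport(
        index_name=dist.index_name, auc=curve.auc,
        cutoff=float(candidates[k]), comparator=comparator,
        sensitivity=float(sens[k]), specificity=float(spec[k]),
        accuracy=float(accuracy), flagged=flagged, note=note)
    if auc_threshold is not None:
        report.passed_auc_threshold = curve.auc >= auc_threshold
    return report


@dataclass
class ScreenResult:
    """Outcome of the AUC screening step."""

    kept: list[CutoffReport]
    discarded: list[CutoffReport]
    best_indices: list[str] = field(default_factory=list)
    warning: str = ""

    @property
    def best_index(self) -> Optional[str]:
        return self.best_indices[0] if len(self.best_indices) == 1 else None


def screen_indices(reports: list[CutoffReport],
                   auc_threshold: float = 0.80) -> ScreenResult:
    """Keep indices with AUC >= threshold; identify the best performer(s).

    Flagged (AUC < .5) reports are never kept.  When nothing survives the
    screen the misspecification may be too weak to detect in this scenario;
    the result carries that warning and endorses no cutoffs.
    """
    kept, discarded = [], []
    for r in reports:
        r.passed_auc_threshold = (r.auc >= auc_threshold) and not r.flagged
        if r.passed_auc_threshold:
            kept.append(r)
        else:
            if not r.note:
                r.note = f"AUC below threshold ({r.auc:.3f} < {auc_threshold})"
            discarded.append(r)
    if not kept:
        return ScreenResult(kept, discarded, [], warning=(
            "no fit index reached the AUC threshold: the misspecification of "
            "the analysis model relative to the H1 population might not be "
            "strong enough to be detected in this scenario"))
    best_auc = max(r.auc for r in kept)
    best = [r.index_name for r in kept if r.auc == best_auc]
    return ScreenResult(kept, discarded, best)
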