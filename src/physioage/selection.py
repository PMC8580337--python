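"""Age binning, Fisher-score trait ranking, and LDA projection.

These are the per-split front end of the physiological-age pipeline:
individuals are binned by chronological age into half-open equal-width
intervals, traits are ranked by a class-size-weighted Fisher score
(between-bin over within-bin variance), the top k are kept, and the kept
traits are optionally projected onto N-1 linear discriminants where N is
the number of age bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


@dataclass(frozen=True)
class AgeBins:
    edges: np.ndarray        # strictly increasing, len = n_bins + 1
    centers: np.ndarray      # interval midpoints, one per kept bin
    assignment: np.ndarray   # per-individual bin index into centers

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    def labels(self) -> np.ndarray:
        """Per-individual bin-center age, the classification target."""
        return self.centers[self.assignment]


@dataclass(frozen=True)
class FisherRanking:
    scores: np.ndarray   # per trait, input order
    order: np.ndarray    # trait indices sorted by descending score
    k_selected: int

    @property
    def ranks(self) -> np.ndarray:
        r = np.empty(len(self.order), dtype=int)
        r[self.order] = np.arange(1, len(self.order) + 1)
        return r

    @property
    def selected(self) -> np.ndarray:
        return self.order[: self.k_selected]


def make_age_bins(ages: np.ndarray, width: float = 5.0) -> AgeBins:
    """Equal-width half-open bins [lo, lo+width) anchored at a width multiple.

    Empty bins are dropped; an age exactly on an interior edge belongs to
    the upper bin. Centers are midpoints of the kept intervals.
    """
    ages = np.asarray(ages, dtype=float)
    if width <= 0:
        raise ValueError("bin width must be positive")
    if len(np.unique(ages)) < 2:
        raise ValueError("need at least 2 distinct ages to bin")
    lo = np.floor(ages.min() / width) * width
    n = int(np.floor((ages.max() - lo) / width)) + 1
    edges = lo + width * np.arange(n + 1)
    idx = np.floor((ages - lo) / width).astype(int)
    # keep only non-empty bins, remapping indices
    occupied = np.unique(idx)
    remap = {b: i for i, b in enumerate(occupied)}
    centers = np.array([(edges[b] + edges[b + 1]) / 2 for b in occupied])
    assignment = np.array([remap[b] for b in idx])
    kept_edges = np.append(edges[occupied], edges[occupied[-1] + 1])
    return AgeBins(edges=kept_edges, centers=centers, assignment=assignment)


def fisher_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Class-size-weighted Fisher score per trait column.

    F_j = sum_k n_k (mu_jk - mu_j)^2 / sum_k n_k var_jk with population
    variances; a zero denominator (trait constant within every class)
    yields score 0.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, inv = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes for Fisher scoring")
    n_k = np.bincount(inv).astype(float)
    if (n_k == 0).any():
        raise ValueError("empty class encountered")
    # per-class sums via indicator matmul
    ind = np.zeros((len(classes), len(labels)))
    ind[inv, np.arange(len(labels))] = 1.0
    sums = ind @ X
    mu_k = sums / n_k[:, None]
    sq = ind @ (X * X)
    var_k = sq / n_k[:, None] - mu_k**2
    var_k = np.maximum(var_k, 0.0)  # numerical floor
    mu = X.mean(axis=0)
    num = (n_k[:, None] * (mu_k - mu) ** 2).sum(axis=0)
    den = (n_k[:, None] * var_k).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(den > 0, num / den, 0.0)
    return scores


def rank_traits(values: np.ndarray, bins: AgeBins, k: int | None = None) -> FisherRanking:
    """Rank traits by Fisher score against age-bin labels; ties keep input order."""
    scores = fisher_scores(values, bins.assignment)
    order = np.argsort(-scores, kind="stable")
    k = values.shape[1] if k is None else int(k)
    if not 1 <= k <= values.shape[1]:
        raise ValueError(f"k={k} outside 1..{values.shape[1]}")
    return FisherRanking(scores=scores, order=order, k_selected=k)


@dataclass
class LDAProjection:
    """Fitted linear discriminant projection to n_classes - 1 dimensions."""

    model: LinearDiscriminantAnalysis
    n_components: int

    def transform(self, values: np.ndarray) -> np.ndarray:
        return self.model.transform(np.asarray(values, dtype=float))


def lda_fit(values: np.ndarray, labels: np.ndarray) -> LDAProjection:
    """Fit LDA of traits on class labels, projecting to N-1 discriminants."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("LDA requires >= 2 classes")
    n_comp = len(classes) - 1
    n_comp = min(n_comp, values.shape[1])
    model = LinearDiscriminantAnalysis(n_components=n_comp)
    model.fit(np.asarray(values, dtype=float), labels)
    return LDAProjection(model=model, n_components=n_comp)


def lda_transform(projection: LDAProjection, values: np.ndarray) -> np.ndarray:
    return projection.transform(values)


def select_k(
    evaluate_k,
    candidate_ks: list[int],
) -> tuple[int, list[tuple[int, float, float]]]:
    """Choose the trait count k maximizing mean test R² over repeated splits.

    ``evaluate_k(k)`` must return (mean_r2, sd_r2) over the configured number
    of training/testing splits with the top-k Fisher traits. Returns the
    argmax k (ties -> smallest k) and the full (k, mean, sd) curve.
    """
    if not candidate_ks:
        raise ValueError("candidate_ks must be non-empty")
    curve = []
    for k in sorted(set(int(k) for k in candidate_ks)):
        mean_r2, sd_r2 = evaluate_k(k)
        curve.append((k, float(mean_r2), float(sd_r2)))
    best = max(curve, key=lambda t: (t[1], -t[0]))
    return best[0], curve
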