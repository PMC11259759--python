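"""Dataset splitting, evaluation metrics and the soft-voting ensemble.

The unit of splitting is the unique data point (one antibody at one
concentration on one coating), so the same molecule measured under two
conditions may straddle splits — matching how the training datasets were
handled.  An optional group-by-sequence mode assigns all of a molecule's
points to one split to prevent leakage.

The 80/10/10 convention: train = floor(0.8 N); the remainder splits
val-first (ceil) / test (rest), so the combined blinded holdout is
N - floor(0.8 N) — 333 points for N = 1664, 600 for N = 2998.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .errors import ValidationError
from .records import AssayPoint


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    group_by_sequence: bool = False

    def sizes(self, n: int) -> tuple[int, int, int]:
        n_train = math.floor(self.fractions[0] * n)
        rem = n - n_train
        n_val = math.ceil(rem / 2)
        return n_train, n_val, rem - n_val


def split_dataset(points: Sequence, spec: SplitSpec):
    """Random 80/10/10 partition into (train, val, test) lists."""
    n = len(points)
    if n < 10:
        raise ValidationError(f"need at least 10 points to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    if spec.group_by_sequence:
        keys = [p.antibody.sequence_key() for p in points]
        uniq = list(dict.fromkeys(keys))
        order = rng.permutation(len(uniq))
        shuffled_groups = [uniq[i] for i in order]
        index = {k: i for i, k in enumerate(shuffled_groups)}
        perm = sorted(range(n), key=lambda i: (index[keys[i]], i))
    else:
        perm = rng.permutation(n)
    n_train, n_val, n_test = spec.sizes(n)
    train = [points[i] for i in perm[:n_train]]
    val = [points[i] for i in perm[n_train : n_train + n_val]]
    test = [points[i] for i in perm[n_train + n_val :]]
    return train, val, test


@dataclass
class MetricPanel:
    auc: Optional[float]
    accuracy: float
    precision: float
    recall: float
    f1: float
    n: int
    n_positive: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> MetricPanel:
    """ROC AUC (rank-based, ties averaged) plus thresholded binary metrics."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValidationError("labels and probabilities differ in length")
    pred = (p >= threshold).astype(int)
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else None
    return MetricPanel(
        auc=auc,
        accuracy=float(accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        n=int(y.size),
        n_positive=int(y.sum()),
    )


def subgroup_metrics(points: Sequence[AssayPoint], probabilities,
                     grouping: str, domain_sets: Optional[dict] = None,
                     threshold: float = 0.5) -> dict[str, MetricPanel]:
    """Metric panels per antibody subgroup.

    ``grouping='chains'`` splits HC-only molecules (every location code in
    {0, 1, 3}; requires *domain_sets*) from those with both HC and LC;
    ``grouping='specificity'`` splits monospecific from bispecific using the
    format annotation.  Empty groups are simply absent from the result.
    """
    probs = np.asarray(probabilities, dtype=float)
    if len(points) != probs.size:
        raise ValidationError("points and probabilities differ in length")
    masks: dict[str, list[bool]] = {}
    if grouping == "chains":
        if domain_sets is None:
            raise ValidationError("grouping='chains' requires domain_sets")
        flags = [domain_sets[p.antibody.id].hc_only() for p in points]
        masks["hc_only"] = flags
        masks["hc_and_lc"] = [not f for f in flags]
    elif grouping == "specificity":
        flags = [p.antibody.is_bispecific() for p in points]
        masks["bispecific"] = flags
        masks["monospecific"] = [not f for f in flags]
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    out: dict[str, MetricPanel] = {}
    for name, mask in masks.items():
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        out[name] = compute_metrics(
            [points[i].label for i in idx], probs[idx], threshold
        )
    return out


@dataclass
class EnsembleSpec:
    """Soft-voting ensemble: the best-validation-AUC member weighs 0.5, the
    others share the remaining 0.5 equally (0.25 each for three members)."""

    names: list
    val_aucs: list
    weights: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.names) != len(self.val_aucs):
            raise ValidationError("names and val_aucs differ in length")
        if not self.weights:
            self.weights = self._derive_weights()
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("ensemble weights must sum to 1")

    def _derive_weights(self) -> list:
        k = len(self.val_aucs)
        if k == 1:
            return [1.0]
        best = int(np.argmax(self.val_aucs))  # first argmax: registration order
        rest = 0.5 / (k - 1)
        return [0.5 if i == best else rest for i in range(k)]


def soft_vote(member_probs: Sequence, spec: EnsembleSpec) -> np.ndarray:
    """Weighted mean of member probabilities."""
    mats = [np.asarray(p, dtype=float) for p in member_probs]
    if len(mats) != len(spec.weights):
        raise ValidationError(
            f"{len(mats)} member predictions but {len(spec.weights)} weights"
        )
    if any(((m < 0) | (m > 1)).any() for m in mats):
        raise ValidationError("member probabilities must lie in [0, 1]")
    return sum(w * m for w, m in zip(spec.weights, mats))


@dataclass
class QuadrantSummary:
    pearson_r: float
    pct_clean_both: float
    pct_bvp_only: float
    pct_bsa_only: float
    pct_polyreactive_both: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def quadrant_analysis(bvp_folds: dict, bsa_folds: dict,
                      threshold: float = 2.0) -> QuadrantSummary:
    """Cross-assay agreement at one concentration.

    Inputs map antibody id -> fold over control in each assay; ids must pair
    up exactly.  Returns the Pearson correlation of the fold values and the
    percentage of antibodies per quadrant (clean/polyreactive in each assay),
    summing to 100.
    """
    orphans = sorted(set(bvp_folds) ^ set(bsa_folds))
    if orphans:
        raise ValidationError(f"unpaired antibody ids: {orphans}")
    if len(bvp_folds) < 2:
        raise ValidationError("need at least two paired antibodies")
    ids = sorted(bvp_folds)
    bvp = np.array([bvp_folds[i] for i in ids], dtype=float)
    bsa = np.array([bsa_folds[i] for i in ids], dtype=float)
    r = float(stats.pearsonr(bvp, bsa).statistic)
    bvp_hot = bvp > threshold
    bsa_hot = bsa > threshold
    n = len(ids)
    pct = lambda m: 100.0 * float(np.count_nonzero(m)) / n  # noqa: E731
    return QuadrantSummary(
        pearson_r=r,
        pct_clean_both=pct(~bvp_hot & ~bsa_hot),
        pct_bvp_only=pct(bvp_hot & ~bsa_hot),
        pct_bsa_only=pct(~bvp_hot & bsa_hot),
        pct_polyreactive_both=pct(bvp_hot & bsa_hot),
        n=n,
    )
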