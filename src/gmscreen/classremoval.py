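"""Class-removal analysis of panel classifiability.

Measures how well a feature matrix separates the panel's cancer classes via
the out-of-bag (OOB) error of a random forest, then asks which classes are
responsible for the error: at each step the class contributing the largest
number of OOB-misclassified samples is removed and the error re-estimated.
Because removing any class simplifies the problem, the progressive trace is
compared with a null obtained by removing the same number of classes at
random (500 draws per step by default). A progressive trace well below the
null mean indicates that specific small or heterogeneous classes - not mere
problem shrinkage - drive the error.

A varSelRF-style backward elimination is included: from an initial fit's
importance ranking, the least important fraction of features is dropped
each round (importances are not recomputed), the OOB error recorded, and
the smallest feature set within one standard error of the minimum returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = ["OOBResult", "RemovalTrace", "oob_error", "backward_select",
           "progressive_removal", "random_removal_null", "median_impute"]


@dataclass
class OOBResult:
    oob_error: float
    per_class_misclassified: dict[str, int]
    votes: pd.DataFrame  # per-sample OOB vote fractions, columns = classes


@dataclass
class RemovalTrace:
    step: int
    removed_class: str | None
    remaining_classes: list[str]
    oob_error: float
    per_class_misclassified: dict[str, int]
    null_mean_oob: float = float("nan")
    null_reps: int = 0


def median_impute(features: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Per-feature (column) median imputation; all-NaN columns become 0."""
    x = np.asarray(features, dtype=float)
    if not np.isnan(x).any():
        return x
    med = np.nanmedian(x, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    idx = np.where(np.isnan(x))
    x = x.copy()
    x[idx] = med[idx[1]]
    return x


def _forest_seed(seed: int, *context: int) -> int:
    """Stable sub-seed below 2**31 for one forest fit."""
    return int(np.random.SeedSequence((seed, *context)).generate_state(1)[0] % (2 ** 31))


def oob_error(features, labels: Sequence[str], n_trees: int = 1000,
              seed: int = 0) -> OOBResult:
    """Out-of-bag error of a seeded random forest (plain bootstrap).

    ``features`` is samples-by-features and must be complete (impute first,
    e.g. with :func:`median_impute`); requires at least two classes. Samples
    that were drawn into every tree's bootstrap (possible with few trees)
    have no OOB vote and are counted as misclassified.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be samples x features aligned with labels")
    if np.isnan(x).any():
        raise ValueError("features contain missing values; impute first")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes for classification")
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                bootstrap=True, random_state=_forest_seed(seed),
                                n_jobs=1)
    rf.fit(x, y)
    votes = rf.oob_decision_function_
    has_vote = votes.sum(axis=1) > 0
    pred = rf.classes_[np.argmax(votes, axis=1)]
    wrong = (pred != y) | ~has_vote
    per_class = {str(c): int(wrong[y == c].sum()) for c in classes}
    return OOBResult(oob_error=float(wrong.mean()),
                     per_class_misclassified=per_class,
                     votes=pd.DataFrame(votes, columns=[str(c) for c in rf.classes_]))


def _class_sizes(labels: np.ndarray) -> dict[str, int]:
    vals, counts = np.unique(labels, return_counts=True)
    return {str(v): int(c) for v, c in zip(vals, counts)}


def _worst_class(result: OOBResult, labels: np.ndarray) -> str:
    """Class with the largest OOB-misclassified count; ties go to the
    smaller class, then to label order."""
    sizes = _class_sizes(labels)
    items = sorted(result.per_class_misclassified.items(),
                   key=lambda kv: (-kv[1], sizes[kv[0]], kv[0]))
    return items[0][0]


def progressive_removal(features, labels: Sequence[str], n_steps: int,
                        n_trees: int = 1000, seed: int = 0) -> list[RemovalTrace]:
    """Remove the worst class ``n_steps`` times, re-estimating OOB error.

    Step 0 is the full panel (``removed_class=None``); step k removes the
    class with the largest OOB-misclassified count at step k-1.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(str)
    n_classes = len(np.unique(y))
    if n_steps >= n_classes - 1:
        raise ValueError(f"n_steps must be < n_classes - 1 = {n_classes - 1}")
    traces: list[RemovalTrace] = []
    keep = np.ones(len(y), dtype=bool)
    removed: str | None = None
    for step in range(n_steps + 1):
        res = oob_error(x[keep], y[keep], n_trees=n_trees, seed=_forest_seed(seed, step))
        traces.append(RemovalTrace(
            step=step, removed_class=removed,
            remaining_classes=sorted(np.unique(y[keep]).tolist()),
            oob_error=res.oob_error,
            per_class_misclassified=res.per_class_misclassified))
        if step < n_steps:
            removed = _worst_class(res, y[keep])
            keep &= y != removed
    return traces


def random_removal_null(features, labels: Sequence[str], n_steps: int,
                        reps: int = 500, n_trees: int = 1000,
                        seed: int = 0) -> list[tuple[float, int]]:
    """Per-step random-removal null: for each step k, the mean OOB error over
    ``reps`` random draws of k classes removed from the FULL class set (draws
    are not nested across steps). Returns ``[(null_mean_oob, reps), ...]``
    for k = 0..n_steps; k = 0 equals the full-panel OOB error.

    Distinct class subsets are fitted once (with a subset-derived forest
    seed) and the mean weighted by how often each subset was drawn.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(str)
    classes = sorted(np.unique(y).tolist())
    if n_steps >= len(classes) - 1:
        raise ValueError(f"n_steps must be < n_classes - 1 = {len(classes) - 1}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9151)))
    cache: dict[tuple[int, ...], float] = {}

    def subset_oob(removed_idx: tuple[int, ...]) -> float:
        if removed_idx not in cache:
            drop = {classes[i] for i in removed_idx}
            keep = ~np.isin(y, list(drop))
            res = oob_error(x[keep], y[keep], n_trees=n_trees,
                            seed=_forest_seed(seed, 7, *removed_idx))
            cache[removed_idx] = res.oob_error
        return cache[removed_idx]

    out: list[tuple[float, int]] = [(subset_oob(()), 1)]
    for k in range(1, n_steps + 1):
        draws = [tuple(sorted(rng.choice(len(classes), size=k, replace=False)))
                 for _ in range(reps)]
        out.append((float(np.mean([subset_oob(d) for d in draws])), reps))
    return out


def backward_select(features, labels: Sequence[str], drop_fraction: float = 0.2,
                    se_rule: float = 1.0, n_trees: int = 1000,
                    seed: int = 0,
                    feature_ids: Sequence[str] | None = None
                    ) -> tuple[list[str], pd.DataFrame]:
    """Backward feature elimination with the one-standard-error rule.

    Features are ranked once by the initial fit's impurity importances; each
    round drops the ``drop_fraction`` least important remaining features and
    records the OOB error of a fresh fit. The selected set is the smallest
    whose OOB error is within ``se_rule * sqrt(p(1-p)/n)`` of the minimum.
    Returns ``(selected_ids, trace)`` where trace has one row per round with
    columns ``n_features, oob_error``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(str)
    n, p = x.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(p)]
    feature_ids = list(feature_ids)
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError("drop_fraction must be in [0, 1)")

    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                random_state=_forest_seed(seed, 1), n_jobs=1)
    rf.fit(x, y)
    order = np.argsort(-rf.feature_importances_, kind="stable")  # best first

    current = list(order)
    rounds: list[dict] = []
    sets: list[list[int]] = []
    round_no = 0
    while True:
        res = oob_error(x[:, current], y, n_trees=n_trees,
                        seed=_forest_seed(seed, 2, round_no))
        rounds.append({"n_features": len(current), "oob_error": res.oob_error})
        sets.append(list(current))
        n_drop = int(np.floor(drop_fraction * len(current)))
        if drop_fraction > 0:
            n_drop = max(n_drop, 1)
        if n_drop == 0 or len(current) - n_drop < 2:
            break
        current = current[:len(current) - n_drop]  # order is best-first
        round_no += 1

    trace = pd.DataFrame(rounds)
    errs = trace["oob_error"].to_numpy()
    min_err = float(errs.min())
    se = float(np.sqrt(min_err * (1.0 - min_err) / n))
    ok = errs <= min_err + se_rule * se
    best_round = int(np.where(ok)[0][np.argmin(trace.loc[ok, "n_features"].to_numpy())])
    selected = sorted(feature_ids[i] for i in sets[best_round])
    return selected, trace
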