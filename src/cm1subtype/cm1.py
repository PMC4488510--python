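"""CM1 discriminative probe scoring and balanced top-k selection.

For a probe *i* and a one-vs-rest split of the samples into a class of
interest *X* and the remaining classes *Y*, the CM1 score is

    CM1_i(X, Y) = (mean(x_i) - mean(y_i)) / (1 + (max(y_i) - min(y_i)))

i.e. the difference between the class means normalised by one plus the
expression range in the rest group.  Large positive scores flag probes
up-regulated in the class of interest relative to all other classes,
large negative scores down-regulated ones; the ``1 +`` keeps the
denominator >= 1, so |CM1| never exceeds the raw mean difference and the
score is invariant under a global shift of the data.

Per class, probes are ranked separately on the positive and the negative
side (rank 1 = most extreme score on that side); the *balanced top-k*
selection keeps the ``k_pos`` best positive and ``k_neg`` best negative
probes per class and unions them across classes, deduplicating probes
picked by several classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cm1subtype.types import DomainError, validate_expression_matrix, validate_labels


def cm1_score(values_x, values_y) -> float:
    """CM1 score of one probe for a two-group split (class vs rest)."""
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("cm1_score requires non-empty sample groups")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("cm1_score requires finite values")
    return float((x.mean() - y.mean()) / (1.0 + (y.max() - y.min())))


def cm1_rank_all(
    matrix: pd.DataFrame,
    labels: pd.Series,
    classes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Score and rank every probe against every one-vs-rest class split.

    Returns a long-format table with one row per (probe, class):
    columns ``probe_id, class, score, x_mean, y_mean, y_max, y_min, side,
    rank``.  ``side`` is ``pos`` for score >= 0 else ``neg``; ``rank`` is
    the 1-based position within the class and side, positive side ordered
    by descending score, negative side by ascending score, ties broken
    lexicographically by probe identifier.
    """
    validate_expression_matrix(matrix)
    validate_labels(labels, samples=matrix.columns)
    labels = labels.reindex(matrix.columns)
    if classes is None:
        from cm1subtype.types import category_order

        classes = tuple(category_order(set(labels.unique())))
    for cls in classes:
        if (labels == cls).sum() == 0:
            raise DomainError(f"class {cls!r} has no labelled samples")

    values = matrix.to_numpy(dtype=float)
    lab = labels.to_numpy()
    frames: list[pd.DataFrame] = []
    for cls in classes:
        in_x = lab == cls
        if (~in_x).sum() < 2:
            raise DomainError(
                f"class {cls!r} leaves fewer than two rest samples; range undefined"
            )
        x = values[:, in_x]
        y = values[:, ~in_x]
        x_mean = x.mean(axis=1)
        y_mean = y.mean(axis=1)
        y_max = y.max(axis=1)
        y_min = y.min(axis=1)
        score = (x_mean - y_mean) / (1.0 + (y_max - y_min))
        part = pd.DataFrame(
            {
                "probe_id": matrix.index.to_numpy(),
                "class": cls,
                "score": score,
                "x_mean": x_mean,
                "y_mean": y_mean,
                "y_max": y_max,
                "y_min": y_min,
            }
        )
        part["side"] = np.where(part["score"] >= 0, "pos", "neg")
        ranks = np.empty(len(part), dtype=int)
        for side, ascending in (("pos", False), ("neg", True)):
            mask = part["side"] == side
            sub = part.loc[mask].sort_values(
                ["score", "probe_id"], ascending=[ascending, True], kind="mergesort"
            )
            ranks[sub.index.to_numpy()] = np.arange(1, len(sub) + 1)
        part["rank"] = ranks
        frames.append(part)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ProbeSelection:
    """Balanced top-k probe selection per class plus the deduplicated union."""

    per_class: dict[str, list[str]]
    union: list[str]
    duplicate_count: int

    def __len__(self) -> int:
        return len(self.union)


def balanced_top_k(table: pd.DataFrame, k_pos: int = 5, k_neg: int = 5) -> ProbeSelection:
    """Select the top-``k_pos`` positive and top-``k_neg`` negative probes per class.

    The union preserves first-seen order across classes (classes in table
    order, positive side before negative); ``duplicate_count`` counts the
    selections collapsed away by deduplication.
    """
    required = {"probe_id", "class", "score", "side", "rank"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"CM1 table lacks columns: {sorted(missing)}")
    per_class: dict[str, list[str]] = {}
    ordered_union: list[str] = []
    seen: set[str] = set()
    total_selected = 0
    for cls in table["class"].unique():
        sub = table[table["class"] == cls]
        if len(sub) < k_pos + k_neg:
            raise DomainError(
                f"class {cls!r} has {len(sub)} probes, fewer than requested "
                f"{k_pos + k_neg}"
            )
        chosen: list[str] = []
        for side, k in (("pos", k_pos), ("neg", k_neg)):
            side_tab = sub[sub["side"] == side].sort_values("rank")
            if len(side_tab) < k:
                raise DomainError(
                    f"class {cls!r} has only {len(side_tab)} probes on the "
                    f"{side} side, {k} requested"
                )
            chosen.extend(side_tab["probe_id"].head(k).tolist())
        per_class[cls] = chosen
        total_selected += len(chosen)
        for pid in chosen:
            if pid not in seen:
                seen.add(pid)
                ordered_union.append(pid)
    return ProbeSelection(
        per_class=per_class,
        union=ordered_union,
        duplicate_count=total_selected - len(ordered_union),
    )
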