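"""Shared vocabulary and container validation.

Expression data travels as a pandas DataFrame with probes as rows
(unique probe identifiers in the index) and samples as columns; labels as
a pandas Series indexed by sample identifier.  The five intrinsic
subtypes use their conventional short codes, with ``INC`` reserved for
samples on which an ensemble reaches no majority.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical display order of the five intrinsic subtypes:
#: luminal A, luminal B, HER2-enriched, normal-like, basal-like.
SUBTYPES: tuple[str, ...] = ("LA", "LB", "H", "N", "B")

#: Marker for samples without a strict-majority consensus label.
INC: str = "INC"

#: Fixed category order used by every report and contingency table.
CATEGORIES: tuple[str, ...] = SUBTYPES + (INC,)


class DomainError(ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(ValueError):
    """A configuration object violates its invariants."""


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a probes x samples expression matrix and return it unchanged.

    Raises :class:`DomainError` on duplicate probe/sample identifiers or
    non-finite values.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise DomainError("expression matrix must be a pandas DataFrame")
    if matrix.empty:
        raise DomainError("expression matrix is empty")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise DomainError(f"duplicate probe identifiers: {dupes[:5]}")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise DomainError(f"duplicate sample identifiers: {dupes[:5]}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DomainError("expression matrix contains non-finite values")
    return matrix


def validate_labels(
    labels: pd.Series,
    samples: pd.Index | None = None,
    allowed: tuple[str, ...] | None = None,
) -> pd.Series:
    """Check a per-sample label vector and return it unchanged.

    When *samples* is given, the label index must match it as a set.  When
    *allowed* is given, every label must come from that vocabulary.
    """
    if not isinstance(labels, pd.Series):
        raise DomainError("labels must be a pandas Series indexed by sample id")
    if labels.empty:
        raise DomainError("label vector is empty")
    if labels.index.duplicated().any():
        raise DomainError("duplicate sample identifiers in label vector")
    if samples is not None:
        missing = set(samples) - set(labels.index)
        extra = set(labels.index) - set(samples)
        if missing or extra:
            raise DomainError(
                f"label/sample mismatch: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}"
            )
    if allowed is not None:
        unknown = set(labels.unique()) - set(allowed)
        if unknown:
            raise DomainError(f"unknown labels: {sorted(unknown)}")
    return labels


def category_order(present: set[str]) -> list[str]:
    """Order categories canonically (LA, LB, H, N, B, INC), extras last."""
    ordered = [c for c in CATEGORIES if c in present]
    ordered += sorted(present - set(CATEGORIES))
    return ordered
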