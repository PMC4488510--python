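"""Interrater agreement statistics between categorical labellings.

The suite compares two (or more) subtype labellings of the same samples:

* **Cramér's V** — sqrt(chi2 / (N * min(r-1, c-1))) on an r x c
  contingency table; plain Pearson chi-squared, no continuity correction.
* **Average sensitivity** — the mean over row categories of the diagonal
  fraction n_ii / n_i., i.e. the per-class recall averaged over classes.
* **Fleiss' kappa** — chance-corrected multi-rater agreement on an
  s x c ratings matrix (n_ij = raters assigning category j to sample i,
  each row summing to the rater count k).
* **Adjusted Rand Index** — chance-corrected pair-counting agreement
  between two partitions, computed from the contingency table with exact
  binomial-coefficient sums.
* **Jensen-Shannon distance** — the square root of the base-2
  Jensen-Shannon divergence between two label distributions; a true
  metric on [0, 1].

The inconsistent label ``INC`` is a first-class category throughout:
with the default ``include_inc=True`` a no-consensus outcome counts as
its own class in every statistic, which is how a strict-majority
ensemble's reliability should be scored (an INC sample is a real
disagreement, not missing data).  ARI and kappa are evaluated in exact
integer / rational arithmetic before the final division, so printed
three-decimal reference values are reproduced without floating-point
ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, entropy

from cm1subtype.types import DomainError, INC, category_order


# ---------------------------------------------------------------------------
# contingency tables and ratings matrices


def contingency(
    labels_a: pd.Series, labels_b: pd.Series, include_inc: bool = True
) -> pd.DataFrame:
    """Cross-classify two labellings of the same samples.

    Rows follow *labels_a*, columns *labels_b*; categories appear in the
    canonical order LA, LB, H, N, B, INC (extras alphabetically last).
    With ``include_inc=False`` every sample labelled INC by either side
    is dropped and N shrinks accordingly.
    """
    a_ids, b_ids = set(labels_a.index), set(labels_b.index)
    if a_ids != b_ids:
        raise DomainError(
            f"labellings cover different samples: only-in-a="
            f"{sorted(a_ids - b_ids)[:5]} only-in-b={sorted(b_ids - a_ids)[:5]}"
        )
    b = labels_b.reindex(labels_a.index)
    a = labels_a
    if not include_inc:
        keep = (a != INC) & (b != INC)
        a, b = a[keep], b[keep]
    rows = category_order(set(a.unique()))
    cols = category_order(set(b.unique()))
    table = pd.crosstab(a, b).reindex(index=rows, columns=cols, fill_value=0)
    table.index.name = "a"
    table.columns.name = "b"
    return table.astype(int)


def ratings_from_contingency(table: pd.DataFrame) -> pd.DataFrame:
    """Expand a two-rater contingency table into an s x c ratings matrix.

    Each sample counted in cell (i, j) contributes one rating of row
    category i and one of column category j (k = 2).  The category set is
    the union of row and column categories in canonical order.
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise DomainError("contingency counts must be non-negative")
    cats = category_order(set(table.index) | set(table.columns))
    pos = {c: k for k, c in enumerate(cats)}
    rows = []
    for i, row_cat in enumerate(table.index):
        for j, col_cat in enumerate(table.columns):
            n = int(t[i, j])
            if n == 0:
                continue
            rating = np.zeros(len(cats), dtype=int)
            rating[pos[row_cat]] += 1
            rating[pos[col_cat]] += 1
            rows.extend([rating] * n)
    return pd.DataFrame(rows, columns=cats)


def ratings_from_labels(*labellings: pd.Series) -> pd.DataFrame:
    """Build an s x c ratings matrix from k >= 2 labellings (one per rater)."""
    if len(labellings) < 2:
        raise DomainError("need at least two labellings (raters)")
    index = labellings[0].index
    for lab in labellings[1:]:
        if set(lab.index) != set(index):
            raise DomainError("all labellings must cover the same samples")
    cats = category_order(set().union(*(set(l.unique()) for l in labellings)))
    counts = np.zeros((len(index), len(cats)), dtype=int)
    pos = {c: k for k, c in enumerate(cats)}
    for lab in labellings:
        aligned = lab.reindex(index)
        for i, value in enumerate(aligned.to_numpy()):
            counts[i, pos[value]] += 1
    return pd.DataFrame(counts, index=index, columns=cats)


# ---------------------------------------------------------------------------
# statistics


def cramers_v(table: pd.DataFrame) -> float:
    """Cramér's V association statistic, phi = sqrt(chi2 / (N min(r-1, c-1))).

    Categories with a zero marginal are dropped first (their expected
    counts are zero, leaving chi-squared undefined); a warning records
    the drop.
    """
    t = pd.DataFrame(table).astype(float)
    zero_rows = t.index[t.sum(axis=1) == 0].tolist()
    zero_cols = t.columns[t.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        warnings.warn(
            f"dropping zero-marginal categories rows={zero_rows} cols={zero_cols}",
            stacklevel=2,
        )
        t = t.drop(index=zero_rows, columns=zero_cols)
    r, c = t.shape
    n = float(t.to_numpy().sum())
    if n <= 0:
        raise DomainError("contingency table has no observations")
    if r < 2 or c < 2:
        raise DomainError(f"need at least a 2x2 table after dropping, got {r}x{c}")
    chi2 = chi2_contingency(t.to_numpy(), correction=False)[0]
    return float(sqrt(chi2 / (n * min(r - 1, c - 1))))


def average_sensitivity(table: pd.DataFrame) -> float:
    """Mean over row categories of the correctly-matched fraction n_ii/n_i.

    Every row category must also appear among the columns (extra columns
    such as INC are allowed and simply dilute the matched fraction).
    """
    t = pd.DataFrame(table)
    missing = [r for r in t.index if r not in t.columns]
    if missing:
        raise DomainError(f"row categories absent from columns: {missing}")
    total = 0.0
    for cat in t.index:
        row_sum = float(t.loc[cat].sum())
        if row_sum == 0:
            raise DomainError(f"row category {cat!r} has no samples")
        total += float(t.loc[cat, cat]) / row_sum
    return total / len(t.index)


def fleiss_kappa(ratings: pd.DataFrame) -> float:
    """Fleiss' kappa over an s x c ratings matrix with k raters per sample.

    kappa = (P_bar - P_e) / (1 - P_e) with P_e = sum_j p_j^2 and
    p_j the pooled probability of category j; evaluated in exact rational
    arithmetic.  Raises when every rating falls in one category
    (P_e = 1, kappa undefined).
    """
    n = np.asarray(ratings, dtype=int)
    if n.ndim != 2 or n.shape[0] < 1:
        raise DomainError("ratings matrix must be 2-D with at least one sample")
    if (n < 0).any():
        raise DomainError("ratings counts must be non-negative")
    row_sums = n.sum(axis=1)
    k = int(row_sums[0])
    if k < 2:
        raise DomainError("Fleiss' kappa requires at least two raters")
    if not (row_sums == k).all():
        raise DomainError("every sample must receive exactly k ratings")
    s = n.shape[0]
    sk = s * k
    col = n.sum(axis=0)
    # P_e = sum p_j^2 as an exact fraction
    pe = Fraction(int((col.astype(object) ** 2).sum()), sk * sk)
    if pe == 1:
        raise DomainError(
            "all ratings fall in a single category; kappa is undefined"
        )
    sum_sq = int((n.astype(object) ** 2).sum())
    numerator = Fraction(sum_sq) - sk * (1 + (k - 1) * pe)
    denominator = sk * (k - 1) * (1 - pe)
    return float(numerator / denominator)


def adjusted_rand_index(table: pd.DataFrame) -> float:
    """Adjusted Rand Index from a contingency table, exact arithmetic.

    ARI = (sum_ij C(n_ij,2) - E) / (0.5 (a + b) - E) with
    a = sum_i C(n_i.,2), b = sum_j C(n_.j,2), E = a b / C(N,2).
    Equals 1 for identical partitions, ~0 for independent ones.
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise DomainError("contingency counts must be non-negative")
    n_total = int(t.sum())
    if n_total < 2:
        raise DomainError("ARI requires at least two samples")
    sum_ij = sum(comb(int(x), 2) for x in t.ravel())
    a = sum(comb(int(x), 2) for x in t.sum(axis=1))
    b = sum(comb(int(x), 2) for x in t.sum(axis=0))
    pairs = comb(n_total, 2)
    expected = Fraction(a * b, pairs)
    denominator = Fraction(a + b, 2) - expected
    if denominator == 0:
        # both partitions put everything in one block: perfect agreement
        return 1.0
    return float((sum_ij - expected) / denominator)


def js_distance(p, q) -> float:
    """Square root of the base-2 Jensen-Shannon divergence; a metric on [0,1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise DomainError("p and q must be 1-D vectors of equal length")
    if (p < 0).any() or (q < 0).any():
        raise DomainError("probabilities must be non-negative")
    if abs(p.sum() - 1) > 1e-9 or abs(q.sum() - 1) > 1e-9:
        raise DomainError("p and q must each sum to 1")
    m = 0.5 * (p + q)
    jsd = entropy(m, base=2) - 0.5 * (entropy(p, base=2) + entropy(q, base=2))
    # clip tiny negative round-off before the square root
    return float(sqrt(max(jsd, 0.0)))


LANDIS_KOCH_BANDS = (
    (0.0, "poor"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


def landis_koch_band(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value.

    < 0 poor; [0, 0.2] slight; (0.2, 0.4] fair; (0.4, 0.6] moderate;
    (0.6, 0.8] substantial; (0.8, 1] almost perfect.
    """
    if kappa > 1:
        raise DomainError(f"kappa cannot exceed 1, got {kappa}")
    if kappa < 0:
        return "poor"
    for upper, band in LANDIS_KOCH_BANDS:
        if kappa <= upper:
            return band
    return "almost perfect"


# ---------------------------------------------------------------------------
# combined report


@dataclass(frozen=True)
class AgreementReport:
    """All agreement statistics between two labellings of one sample set."""

    cramers_v: float
    average_sensitivity: float
    fleiss_kappa: float
    kappa_band: str
    adjusted_rand_index: float
    js_distance: float
    include_inc: bool
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "cramers_v": self.cramers_v,
            "average_sensitivity": self.average_sensitivity,
            "fleiss_kappa": self.fleiss_kappa,
            "kappa_band": self.kappa_band,
            "adjusted_rand_index": self.adjusted_rand_index,
            "js_distance": self.js_distance,
            "include_inc": self.include_inc,
            "n_samples": self.n_samples,
        }


def _label_distribution(labels: pd.Series, cats: list[str]) -> np.ndarray:
    counts = labels.value_counts().reindex(cats, fill_value=0).to_numpy(dtype=float)
    return counts / counts.sum()


def agreement_report(
    labels_a: pd.Series, labels_b: pd.Series, include_inc: bool = True
) -> AgreementReport:
    """Compute the full agreement suite between two labellings.

    Rows of the underlying contingency table follow *labels_a* (treated
    as the reference for average sensitivity), columns *labels_b*.
    """
    table = contingency(labels_a, labels_b, include_inc=include_inc)
    kappa = fleiss_kappa(ratings_from_contingency(table))
    cats = category_order(set(table.index) | set(table.columns))
    a = labels_a if include_inc else labels_a[(labels_a != INC) & (labels_b != INC)]
    b = labels_b if include_inc else labels_b[(labels_a != INC) & (labels_b != INC)]
    return AgreementReport(
        cramers_v=cramers_v(table),
        average_sensitivity=average_sensitivity(table),
        fleiss_kappa=kappa,
        kappa_band=landis_koch_band(kappa),
        adjusted_rand_index=adjusted_rand_index(table),
        js_distance=js_distance(
            _label_distribution(a, cats), _label_distribution(b, cats)
        ),
        include_inc=include_inc,
        n_samples=int(np.asarray(table).sum()),
    )
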