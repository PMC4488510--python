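"""Published METABRIC/ROCK consensus contingency tables.

These are the printed cross-classification tables from the original
METABRIC/ROCK ensemble-relabelling study: original PAM50 subtype labels
versus the strict-majority consensus of 24 classifiers trained with the
CM1 probe list (``cm1_vs_original``) or the PAM50 probe list
(``pam50_vs_original``), and the two consensus labellings against each
other (``cm1_vs_pam50``), on the METABRIC discovery (997 samples) and
validation (989) sets and the integrated ROCK Affymetrix set (1570).

Rows carry the first labelling, columns the second; ``INC`` marks
samples on which the ensemble reached no strict majority.  The headline
agreement values of that study (e.g. ARI 0.757 and Fleiss kappa 0.814 on
the discovery set with the CM1 list) are exactly recomputable from these
integer tables, which is what the acceptance checks do.
"""

from __future__ import annotations

import pandas as pd

from cm1subtype.types import CATEGORIES, SUBTYPES

_COLS = list(CATEGORIES)        # LA LB H N B INC
_ROWS5 = list(SUBTYPES)         # LA LB H N B
_ROWS6 = list(CATEGORIES)


def _table(rows: list[str], data: list[list[int]]) -> pd.DataFrame:
    t = pd.DataFrame(data, index=pd.Index(rows, name="a"), columns=_COLS)
    t.columns.name = "b"
    return t


#: (comparison, dataset) -> contingency table.
TABLES: dict[tuple[str, str], pd.DataFrame] = {
    # consensus with the CM1 list (rows) vs original PAM50 labels (columns)
    ("cm1_vs_original", "discovery"): _table(_ROWS5, [
        [435, 19, 2, 2, 0, 8],
        [24, 234, 0, 0, 0, 10],
        [4, 4, 67, 0, 2, 10],
        [13, 0, 8, 31, 0, 6],
        [0, 0, 10, 2, 103, 3],
    ]),
    ("cm1_vs_original", "validation"): _table(_ROWS5, [
        [252, 2, 0, 0, 0, 1],
        [62, 156, 0, 0, 0, 6],
        [23, 45, 71, 2, 2, 10],
        [80, 0, 0, 59, 0, 5],
        [6, 7, 22, 19, 142, 17],
    ]),
    ("cm1_vs_original", "rock"): _table(_ROWS5, [
        [452, 122, 2, 0, 0, 17],
        [18, 371, 42, 0, 2, 14],
        [0, 1, 13, 0, 0, 0],
        [115, 8, 36, 74, 56, 50],
        [0, 0, 0, 7, 166, 4],
    ]),
    # consensus with the PAM50 list (rows) vs original PAM50 labels (columns)
    ("pam50_vs_original", "discovery"): _table(_ROWS5, [
        [440, 17, 1, 1, 0, 7],
        [25, 239, 0, 0, 0, 4],
        [0, 5, 72, 0, 1, 9],
        [9, 0, 2, 34, 1, 12],
        [0, 0, 7, 1, 103, 7],
    ]),
    ("pam50_vs_original", "validation"): _table(_ROWS5, [
        [254, 0, 0, 0, 0, 1],
        [56, 162, 0, 0, 0, 6],
        [21, 39, 80, 0, 0, 13],
        [82, 0, 0, 55, 0, 7],
        [4, 7, 20, 14, 145, 23],
    ]),
    ("pam50_vs_original", "rock"): _table(_ROWS5, [
        [530, 46, 2, 0, 0, 15],
        [53, 327, 34, 0, 3, 30],
        [0, 0, 12, 0, 0, 2],
        [105, 4, 18, 92, 67, 53],
        [0, 0, 3, 0, 172, 2],
    ]),
    # CM1-list consensus (rows) vs PAM50-list consensus (columns)
    ("cm1_vs_pam50", "discovery"): _table(_ROWS6, [
        [450, 15, 0, 4, 0, 7],
        [20, 235, 0, 0, 0, 2],
        [0, 0, 75, 2, 1, 9],
        [0, 0, 0, 28, 0, 7],
        [0, 0, 2, 0, 101, 2],
        [4, 11, 5, 2, 3, 12],
    ]),
    ("cm1_vs_pam50", "validation"): _table(_ROWS6, [
        [390, 14, 1, 4, 0, 14],
        [12, 185, 8, 0, 0, 5],
        [0, 1, 83, 0, 1, 8],
        [6, 0, 0, 61, 1, 12],
        [0, 0, 1, 0, 140, 3],
        [9, 8, 7, 4, 3, 8],
    ]),
    ("cm1_vs_pam50", "rock"): _table(_ROWS6, [
        [550, 8, 0, 10, 0, 17],
        [112, 361, 0, 0, 0, 29],
        [0, 4, 67, 0, 8, 21],
        [0, 0, 0, 67, 0, 7],
        [0, 0, 0, 2, 219, 3],
        [26, 4, 2, 13, 15, 25],
    ]),
}


def get_table(comparison: str, dataset: str) -> pd.DataFrame:
    """Return a copy of one published contingency block."""
    key = (comparison, dataset)
    if key not in TABLES:
        raise KeyError(
            f"unknown block {key}; comparisons="
            f"{sorted({c for c, _ in TABLES})}, datasets="
            f"{sorted({d for _, d in TABLES})}"
        )
    return TABLES[key].copy()
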