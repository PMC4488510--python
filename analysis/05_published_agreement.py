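#!/usr/bin/env python
"""Recompute the published METABRIC/ROCK agreement values.

The published study printed the full contingency tables between the
original PAM50 labels and the ensemble-consensus labels (and between the
two consensus labellings) for the METABRIC discovery/validation sets and
the ROCK set.  Those integer tables determine the agreement statistics
exactly, so the headline values are recomputable without any
controlled-access data: this script runs ARI, Fleiss' kappa (two raters,
INC as its own category), Cramér's V and average sensitivity over every
transcribed block and writes results/published_agreement.csv.
"""

from pathlib import Path

import pandas as pd

from cm1subtype.agreement import (
    adjusted_rand_index,
    average_sensitivity,
    cramers_v,
    fleiss_kappa,
    landis_koch_band,
    ratings_from_contingency,
)
from cm1subtype.published_tables import TABLES

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for (comparison, dataset), table in TABLES.items():
        kappa = fleiss_kappa(ratings_from_contingency(table))
        rows.append(
            {
                "comparison": comparison,
                "dataset": dataset,
                "n": int(table.to_numpy().sum()),
                "ari": round(adjusted_rand_index(table), 4),
                "fleiss_kappa": round(kappa, 4),
                "kappa_band": landis_koch_band(kappa),
                "cramers_v": round(cramers_v(table), 4),
                "average_sensitivity": round(average_sensitivity(table), 4),
            }
        )
    result = pd.DataFrame(rows)
    ROOT.mkdir(parents=True, exist_ok=True)
    result.to_csv(ROOT / "published_agreement.csv", index=False)
    print(result.to_string(index=False))


if __name__ == "__main__":
    main()
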