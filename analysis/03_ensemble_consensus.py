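#!/usr/bin/env python
"""Consensus subtype assignment by a 24-classifier ensemble.

Two settings, as in a discovery/validation study design:

* 10-fold cross-validation on the discovery cohort — every sample is
  predicted by models that never saw it; and
* train/test transfer — models fit once on the full discovery cohort
  predict (a) the independent replicate cohort on the same platform and
  (b) its affinely distorted second-platform view, after probe mapping
  (highest-variance target wins) and per-probe min-max normalisation of
  each platform separately.

A sample's consensus label needs a strict majority (>12 of 24 votes);
otherwise it is marked INC.  Writes prediction matrices and consensus
labels under results/consensus/.
"""

import warnings
from pathlib import Path

import pandas as pd

from cm1subtype.ensemble import cross_validate_consensus, train_test_consensus
from cm1subtype.simulate import read_expression, read_labels

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def report(name: str, consensus: pd.DataFrame, truth: pd.Series) -> None:
    accuracy = (consensus["consensus"].reindex(truth.index) == truth).mean()
    inc = (consensus["consensus"] == "INC").mean()
    print(f"{name}: accuracy={accuracy:.3f} INC={inc:.3f}")


def main() -> None:
    data = ROOT / "data"
    matrix = read_expression(data / "discovery_expression.tsv")
    labels = read_labels(data / "discovery_labels.csv")
    probes = (ROOT / "selection" / "probe_selection.txt").read_text().split()

    out = ROOT / "consensus"
    out.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        predictions, consensus = cross_validate_consensus(
            matrix, labels, probes, folds=10, seed=SEED
        )
    predictions.to_csv(out / "cv_predictions.csv")
    consensus.to_csv(out / "cv_consensus.csv")
    report("cross-validation (discovery)", consensus, labels)

    replicate = read_expression(data / "replicate_expression.tsv")
    rep_labels = read_labels(data / "replicate_labels.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, same_platform = train_test_consensus(
            matrix, labels, replicate, probes, seed=SEED
        )
    same_platform.to_csv(out / "replicate_consensus.csv")
    report("train/test (same platform)", same_platform, rep_labels)

    platform2 = read_expression(data / "platform2_expression.tsv")
    mapping = pd.read_csv(data / "platform2_mapping.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, transferred = train_test_consensus(
            matrix, labels, platform2, probes,
            mapping=mapping, normalize=True, seed=SEED,
        )
    transferred.to_csv(out / "platform2_consensus.csv")
    report("train/test (cross-platform, min-max normalised)", transferred, rep_labels)


if __name__ == "__main__":
    main()
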