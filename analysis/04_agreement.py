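#!/usr/bin/env python
"""Agreement between the original labels and the ensemble consensus.

For each classification setting of 03_ensemble_consensus.py this
computes the full suite — Cramér's V, average sensitivity, Fleiss'
kappa with its Landis-Koch band, the Adjusted Rand Index and the
square-root Jensen-Shannon distance — treating INC as its own category,
plus a class-distribution report with pairwise JS distances between the
labellings.  Writes results/agreement/.
"""

import json
from pathlib import Path

from cm1subtype.agreement import agreement_report, contingency
from cm1subtype.pipeline import distribution_report
from cm1subtype.simulate import read_labels

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "agreement"
    out.mkdir(parents=True, exist_ok=True)

    settings = {
        "cross_validation": ("discovery_labels.csv", "cv_consensus.csv"),
        "replicate": ("replicate_labels.csv", "replicate_consensus.csv"),
        "platform2": ("replicate_labels.csv", "platform2_consensus.csv"),
    }
    all_reports = {}
    label_sets = {}
    for name, (truth_file, consensus_file) in settings.items():
        truth = read_labels(ROOT / "data" / truth_file)
        consensus = read_labels(ROOT / "consensus" / consensus_file)
        report = agreement_report(truth, consensus, include_inc=True)
        all_reports[name] = report.to_dict()
        label_sets[f"{name}_consensus"] = consensus
        contingency(truth, consensus).to_csv(out / f"contingency_{name}.csv")
        print(f"{name}: kappa={report.fleiss_kappa:.3f} ({report.kappa_band}) "
              f"ARI={report.adjusted_rand_index:.3f} V={report.cramers_v:.3f} "
              f"AS={report.average_sensitivity:.3f}")

    label_sets["original_discovery"] = read_labels(
        ROOT / "data" / "discovery_labels.csv"
    )
    dist = distribution_report(label_sets)
    dist["proportions"].to_csv(out / "distribution.csv")
    dist["js"].to_csv(out / "js_distance.csv")

    with open(out / "agreement.json", "w") as fh:
        json.dump(all_reports, fh, indent=2)
    print(f"wrote {out}/agreement.json and distribution/JS reports")


if __name__ == "__main__":
    main()
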