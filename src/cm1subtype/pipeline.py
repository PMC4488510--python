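"""End-to-end pipeline orchestration and reporting.

``run_pipeline`` wires the stages together — generate or load expression
data, select probes by CM1 score (or accept an external probe list such
as a PAM50-style panel), classify by ensemble consensus, and evaluate
agreement against the reference labels — writing every intermediate
artifact as CSV so a rerun with the same config reproduces the files
byte for byte.

``distribution_report`` and ``marker_crosstab`` produce the
class-distribution and clinical-marker summaries: per-dataset label
proportions over the six categories, pairwise square-root
Jensen-Shannon distances between those distributions, and subtype x
marker-status (ER/PR/HER2) crosstabs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cm1subtype import agreement, cm1, ensemble, simulate
from cm1subtype.types import CATEGORIES, ConfigurationError, DomainError

log = logging.getLogger("cm1subtype")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with all seeds explicit.

    Exactly one data source must be set: either ``expression_path`` +
    ``labels_path`` or a ``generator`` config.  Exactly one probe-list
    source is used: the CM1 selection computed from the data (default)
    or an externally supplied list (``probe_list_path``).
    """

    expression_path: str | None = None
    labels_path: str | None = None
    generator: simulate.GeneratorConfig | None = None
    probe_list_path: str | None = None
    k_pos: int = 5
    k_neg: int = 5
    roster_names: list[str] | None = None
    folds: int = 10
    seed: int = 0
    include_inc: bool = True
    output_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        have_files = self.expression_path is not None and self.labels_path is not None
        have_generator = self.generator is not None
        if have_files == have_generator:
            raise ConfigurationError(
                "exactly one of (expression_path + labels_path) or generator "
                "must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "generator" in raw and raw["generator"] is not None:
            raw["generator"] = simulate.GeneratorConfig(**raw["generator"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        if self.generator is not None:
            raw["generator"] = dataclasses.asdict(self.generator)
            raw["generator"]["class_sizes"] = list(self.generator.class_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run generate/load -> select -> classify -> evaluate; write artifacts.

    Returns a mapping of artifact name to written path.  Artifacts:
    ``expression, labels, cm1_table, probe_selection, predictions,
    consensus, contingency, agreement, distribution``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.generator is not None:
        log.info("simulate: %s", config.generator)
        matrix, labels, manifest = simulate.generate_dataset(config.generator)
        simulate.write_manifest(manifest, out / "manifest.csv")
        paths["manifest"] = out / "manifest.csv"
    else:
        log.info("load: %s / %s", config.expression_path, config.labels_path)
        try:
            matrix = simulate.read_expression(config.expression_path)
            labels = simulate.read_labels(config.labels_path)
        except (OSError, pd.errors.ParserError, DomainError) as exc:
            raise DomainError(
                f"stage load: cannot read input "
                f"({config.expression_path}, {config.labels_path}): {exc}"
            ) from exc
    simulate.write_expression(matrix, out / "expression.tsv")
    simulate.write_labels(labels, out / "labels.csv")
    paths["expression"] = out / "expression.tsv"
    paths["labels"] = out / "labels.csv"
    log.info("data: %d probes x %d samples", *matrix.shape)

    if config.probe_list_path is not None:
        probe_list = [
            line.strip()
            for line in Path(config.probe_list_path).read_text().splitlines()
            if line.strip()
        ]
        log.info("select: external probe list of %d probes", len(probe_list))
        selection: list[str] | cm1.ProbeSelection = probe_list
        union = probe_list
    else:
        table = cm1.cm1_rank_all(matrix, labels)
        table.to_csv(out / "cm1_table.csv", index=False)
        paths["cm1_table"] = out / "cm1_table.csv"
        selection = cm1.balanced_top_k(table, config.k_pos, config.k_neg)
        union = selection.union
        log.info(
            "select: %d unique probes (%d duplicates across classes)",
            len(union), selection.duplicate_count,
        )
    (out / "probe_selection.txt").write_text("\n".join(union) + "\n")
    paths["probe_selection"] = out / "probe_selection.txt"

    roster = ensemble.build_roster(config.roster_names, seed=config.seed)
    log.info("classify: %d classifiers, %d folds, seed %d",
             len(roster), config.folds, config.seed)
    predictions, consensus = ensemble.cross_validate_consensus(
        matrix, labels, selection, roster=roster,
        folds=config.folds, seed=config.seed,
    )
    predictions.to_csv(out / "predictions.csv")
    consensus.to_csv(out / "consensus.csv")
    paths["predictions"] = out / "predictions.csv"
    paths["consensus"] = out / "consensus.csv"

    report = agreement.agreement_report(
        labels, consensus["consensus"], include_inc=config.include_inc
    )
    table_ab = agreement.contingency(
        labels, consensus["consensus"], include_inc=config.include_inc
    )
    table_ab.to_csv(out / "contingency.csv")
    paths["contingency"] = out / "contingency.csv"
    with open(out / "agreement.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    paths["agreement"] = out / "agreement.json"
    log.info("evaluate: kappa=%.3f (%s) ARI=%.3f",
             report.fleiss_kappa, report.kappa_band, report.adjusted_rand_index)

    dist = distribution_report(
        {"original": labels, "consensus": consensus["consensus"]}
    )
    dist["proportions"].to_csv(out / "distribution.csv")
    paths["distribution"] = out / "distribution.csv"
    return paths


def distribution_report(label_sets: dict[str, pd.Series]) -> dict[str, pd.DataFrame]:
    """Label proportions per dataset plus pairwise JS distances.

    Returns ``{"proportions": datasets x categories, "js": datasets x
    datasets symmetric distance matrix}`` over the fixed category order.
    """
    if len(label_sets) < 2:
        raise DomainError("distribution report needs at least two labellings")
    cats = list(CATEGORIES)
    rows = {}
    for name, labels in label_sets.items():
        if labels.empty:
            raise DomainError(f"labelling {name!r} is empty")
        counts = labels.value_counts().reindex(cats, fill_value=0).astype(float)
        rows[name] = counts / counts.sum()
    props = pd.DataFrame(rows).T
    props.index.name = "dataset"
    names = list(props.index)
    js = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = agreement.js_distance(props.loc[a].to_numpy(), props.loc[b].to_numpy())
            js.loc[a, b] = js.loc[b, a] = d
    return {"proportions": props, "js": js}


MARKER_TOKENS = ("positive", "negative", "missing")


def marker_crosstab(labels: pd.Series, marker: pd.Series) -> pd.DataFrame:
    """Subtype x clinical-marker-status counts (ER/PR/HER2-style).

    *marker* holds ``positive`` / ``negative`` / ``missing`` per sample
    (NaN counts as missing).  Missing is tallied in its own column so it
    can be excluded from downstream proportions.
    """
    marker = marker.reindex(labels.index).fillna("missing")
    unknown = set(marker.unique()) - set(MARKER_TOKENS)
    if unknown:
        raise DomainError(f"unknown marker status tokens: {sorted(unknown)}")
    from cm1subtype.types import category_order

    rows = category_order(set(labels.unique()))
    table = pd.crosstab(labels, marker).reindex(
        index=rows, columns=list(MARKER_TOKENS), fill_value=0
    )
    table.index.name = "subtype"
    table.columns.name = "status"
    return table.astype(int)
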