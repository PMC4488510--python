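"""Synthetic five-subtype expression data with planted marker structure.

The generator emulates the shape of log2-normalised microarray intensity
data: five unequally sized subtype classes, a small set of planted up- and
down-regulated marker probes per class on a background of non-informative
probes, and i.i.d. Gaussian noise on every entry.  A second "platform"
view can be derived by dropping a fraction of probes uniformly at random
and applying an affine intensity distortion, mimicking a transfer from one
array vendor to another with partial probe overlap.

Every sampled quantity flows from the explicit seed in the config; there
is no hidden global randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cm1subtype.types import SUBTYPES, ConfigurationError, DomainError


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-marker expression simulator.

    Parameters
    ----------
    n_probes:
        Number of non-informative background probes.
    markers_per_class:
        Number of planted up-regulated probes per class; the same number
        of down-regulated probes is planted, so each class contributes
        ``2 * markers_per_class`` markers.
    class_sizes:
        Sample counts of the five subtypes, in canonical order
        (LA, LB, H, N, B).  Unequal sizes are the realistic regime.
    effect_size:
        Mean log2 shift of a planted marker inside its own class
        (up-markers: +effect_size, down-markers: -effect_size).
    noise_sd:
        Standard deviation of the Gaussian noise added to every entry
        (log2 units).
    baseline_mean:
        Background mean expression (log2 units).
    seed:
        Seed for the generator's private RNG.
    """

    n_probes: int = 300
    markers_per_class: int = 2
    class_sizes: tuple[int, ...] = (93, 54, 17, 12, 24)
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ConfigurationError(f"n_probes must be positive, got {self.n_probes}")
        if self.markers_per_class <= 0:
            raise ConfigurationError(
                f"markers_per_class must be positive, got {self.markers_per_class}"
            )
        sizes = tuple(int(s) for s in self.class_sizes)
        if len(sizes) != 5:
            raise ConfigurationError(
                f"class_sizes must list five counts, got {len(sizes)}"
            )
        if any(s <= 0 for s in sizes):
            raise ConfigurationError(f"class_sizes must all be positive, got {sizes}")
        object.__setattr__(self, "class_sizes", sizes)
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.effect_size < 0:
            raise ConfigurationError(
                f"effect_size must be >= 0, got {self.effect_size}"
            )

    @property
    def total_probes(self) -> int:
        return self.n_probes + 5 * 2 * self.markers_per_class

    @property
    def total_samples(self) -> int:
        return int(sum(self.class_sizes))


@dataclass(frozen=True)
class PlatformDistortion:
    """Affine cross-platform distortion with partial probe overlap.

    ``overlap_fraction`` of probes are retained uniformly at random on the
    second platform; retained values become ``scale * x + offset`` plus
    optional fresh Gaussian noise (``noise_sd``, default 0).
    """

    overlap_fraction: float = 0.8
    scale: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_fraction <= 1:
            raise ConfigurationError(
                f"overlap_fraction must be in (0, 1], got {self.overlap_fraction}"
            )
        if self.scale <= 0:
            raise ConfigurationError(f"scale must be > 0, got {self.scale}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a labelled probes x samples expression matrix.

    Returns
    -------
    matrix:
        DataFrame of shape (total_probes, total_samples), log2 scale.
    labels:
        Series mapping sample id -> subtype code.
    manifest:
        DataFrame with columns ``probe_id, class, direction`` listing every
        planted marker (direction ``up`` or ``down``).
    """
    rng = np.random.default_rng(config.seed)

    sample_ids: list[str] = []
    labels_list: list[str] = []
    for cls, size in zip(SUBTYPES, config.class_sizes):
        for i in range(size):
            sample_ids.append(f"S_{cls}_{i:04d}")
            labels_list.append(cls)
    labels = pd.Series(labels_list, index=pd.Index(sample_ids, name="sample_id"), name="subtype")

    marker_ids: list[str] = []
    manifest_rows: list[tuple[str, str, str]] = []
    for cls in SUBTYPES:
        for j in range(config.markers_per_class):
            pid = f"MK_{cls}_UP_{j:03d}"
            marker_ids.append(pid)
            manifest_rows.append((pid, cls, "up"))
        for j in range(config.markers_per_class):
            pid = f"MK_{cls}_DN_{j:03d}"
            marker_ids.append(pid)
            manifest_rows.append((pid, cls, "down"))
    background_ids = [f"BG_{i:05d}" for i in range(config.n_probes)]
    probe_ids = marker_ids + background_ids

    n_probes, n_samples = len(probe_ids), len(sample_ids)
    means = np.full((n_probes, n_samples), config.baseline_mean, dtype=float)
    class_mask = {cls: (labels.to_numpy() == cls) for cls in SUBTYPES}
    for row, (pid, cls, direction) in enumerate(manifest_rows):
        shift = config.effect_size if direction == "up" else -config.effect_size
        means[row, class_mask[cls]] += shift

    values = means + rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    matrix = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )
    manifest = pd.DataFrame(manifest_rows, columns=["probe_id", "class", "direction"])
    return matrix, labels, manifest


def derive_second_platform(
    matrix: pd.DataFrame,
    distortion: PlatformDistortion,
    manifest: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive a partially overlapping, affinely distorted platform view.

    ``round(overlap_fraction * n_probes)`` probes are kept (uniform sample
    without replacement, original row order preserved) and renamed with a
    platform prefix; values become ``scale * x + offset`` plus fresh noise.

    Returns the distorted matrix and a mapping table with columns
    ``source_probe, target_probe``.  If a *manifest* of planted markers is
    supplied and the dropout removes every marker of some class, a warning
    is recorded in ``mapping.attrs["warnings"]`` (not an error).
    """
    if matrix.empty:
        raise DomainError("cannot derive a second platform from an empty matrix")
    rng = np.random.default_rng(distortion.seed)

    n = matrix.shape[0]
    n_keep = int(round(distortion.overlap_fraction * n))
    n_keep = max(n_keep, 1)
    keep_pos = np.sort(rng.choice(n, size=n_keep, replace=False))
    kept = matrix.iloc[keep_pos]

    values = distortion.scale * kept.to_numpy(dtype=float) + distortion.offset
    if distortion.noise_sd > 0:
        values = values + rng.normal(0.0, distortion.noise_sd, size=values.shape)

    target_ids = [f"P2_{pid}" for pid in kept.index]
    out = pd.DataFrame(values, index=pd.Index(target_ids, name="probe_id"), columns=kept.columns)
    mapping = pd.DataFrame(
        {"source_probe": kept.index.to_numpy(), "target_probe": target_ids}
    )
    mapping.attrs["warnings"] = []
    if manifest is not None and len(manifest):
        retained = set(kept.index)
        for cls, group in manifest.groupby("class"):
            if not (set(group["probe_id"]) & retained):
                mapping.attrs["warnings"].append(
                    f"class {cls} lost all planted markers in the platform transfer"
                )
    return out, mapping


# ---------------------------------------------------------------------------
# plain-text writers / readers


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write probes x samples matrix as tab-delimited text."""
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    from cm1subtype.types import validate_expression_matrix

    matrix = pd.read_csv(path, sep="\t", index_col=0)
    return validate_expression_matrix(matrix)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("subtype").to_csv(path, index_label="sample_id")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DomainError(f"label file {path} must have sample_id and subtype columns")
    return pd.Series(
        df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="sample_id"),
        name="subtype",
    )


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)
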