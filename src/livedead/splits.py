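"""Leakage-free grouped train/validation/test splitting and class weights.

Patches cropped from the same raw capture are near-duplicates of their
neighbours, so the split is performed at the raw-image level: all patches
sharing a ``raw_image_id`` land in the same partition. Raw images are
assigned greedily (largest patch count first, seeded tie-breaking) to the
partition furthest below its target patch fraction, which approaches the
80/10/10 split despite unequal patches per image. Discarded-label patches
are removed before splitting.

Class weights for imbalance-corrected sampling are the inverse per-class
counts; a with-replacement sampler using them draws each class with equal
expected frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitManifest", "ClassWeights", "grouped_split", "manifest_counts",
           "class_weights"]

PARTITIONS = ("train", "valid", "test")


@dataclass
class SplitManifest:
    """Per-patch partition assignment plus the split's provenance."""

    assignments: pd.DataFrame  # columns: patch_id, raw_image_id, label, partition
    fractions: tuple[float, float, float]
    seed: int

    def partition_of(self, raw_image_id: str) -> str:
        parts = self.assignments.loc[
            self.assignments["raw_image_id"] == raw_image_id, "partition"
        ].unique()
        if len(parts) != 1:
            raise AssertionError(f"group {raw_image_id} split across {parts}")
        return str(parts[0])

    def to_csv(self, path) -> None:
        self.assignments.to_csv(path, index=False)


@dataclass(frozen=True)
class ClassWeights:
    """Per-class sampling weights proportional to inverse class counts."""

    weights: dict[str, float]

    def probabilities(self, labels: np.ndarray) -> np.ndarray:
        """Per-sample with-replacement draw probabilities (normalized)."""
        w = np.array([self.weights[l] for l in labels], dtype=float)
        return w / w.sum()


def grouped_split(labels: pd.DataFrame,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> SplitManifest:
    """Split labeled patches into train/valid/test grouped by raw image.

    ``labels`` needs columns (patch_id, raw_image_id, label); rows labeled
    "discarded" are excluded first. Requires at least as many distinct raw
    images as partitions.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    df = labels.loc[labels["label"] != "discarded",
                    ["patch_id", "raw_image_id", "label"]].copy()
    group_sizes = df.groupby("raw_image_id").size()
    if len(group_sizes) < len(PARTITIONS):
        raise ValueError(
            f"need >= {len(PARTITIONS)} distinct raw images to split, "
            f"got {len(group_sizes)}"
        )
    rng = np.random.default_rng(seed)
    groups = group_sizes.sample(frac=1.0, random_state=rng).sort_values(
        ascending=False, kind="stable")

    total = int(group_sizes.sum())
    targets = np.array(fractions) * total
    assigned = np.zeros(3)
    allocation: dict[str, str] = {}
    for rid, size in groups.items():
        deficit = targets - assigned
        k = int(np.argmax(deficit))
        allocation[rid] = PARTITIONS[k]
        assigned[k] += size

    df["partition"] = df["raw_image_id"].map(allocation)
    return SplitManifest(assignments=df.reset_index(drop=True),
                         fractions=tuple(fractions), seed=seed)


def manifest_counts(manifest: SplitManifest) -> pd.DataFrame:
    """Per-partition live/dead counts and totals (the dataset summary table)."""
    df = manifest.assignments
    if len(df) == 0:
        table = pd.DataFrame(0, index=list(PARTITIONS), columns=["live", "dead"])
        table["total"] = 0
        table.index.name = "partition"
        return table
    table = (df.groupby(["partition", "label"]).size()
             .unstack(fill_value=0)
             .reindex(index=list(PARTITIONS), fill_value=0)
             .reindex(columns=["live", "dead"], fill_value=0))
    table["total"] = table["live"] + table["dead"]
    table.columns.name = None
    return table


def class_weights(counts: dict[str, int] | pd.Series) -> ClassWeights:
    """Inverse-count weights, unnormalized (the sampler normalizes)."""
    items = dict(counts)
    if not items:
        raise ValueError("no classes given")
    for cls, n in items.items():
        if n <= 0:
            raise ValueError(f"class {cls!r} has non-positive count {n}")
    return ClassWeights(weights={cls: 1.0 / n for cls, n in items.items()})
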