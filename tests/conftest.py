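"""Shared fixtures: small synthetic datasets and one full pipeline run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import livedead as ld
from livedead import empty_filter, evaluation, labeling, splits, training

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# Printed reference mixture of per-patch mean fluorescence (intensity units):
# low (live) and high (dead) components of the no-treatment distribution.
REFERENCE_MIXTURE = ld.FluorMixture(
    mu_live=224.51, sigma_live=34.46, mu_dead=550.44, sigma_dead=153.55,
    weight_live=0.5,
)


@pytest.fixture(scope="session")
def reference_mixture() -> ld.FluorMixture:
    return REFERENCE_MIXTURE


@pytest.fixture(scope="session")
def small_pair():
    """One small synthetic raw pair with per-region ground truth."""
    cfg = ld.SyntheticConfig(
        n_raw_images=1, image_width=672, image_height=448,
        cells_per_image=(18, 30), frac_dead_cells=0.5, frac_empty_regions=0.0,
        rng_seed=42,
    )
    pair, records = ld.generate_raw_pair(cfg, 0)
    return cfg, pair, records


def _region_state(records, x, y):
    for r in records:
        if r.x0 <= x < r.x1 and r.y0 <= y < r.y1:
            return r
    raise AssertionError("patch offset outside every region")


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """Full pipeline on synthetic data with well-separated morphology.

    generate -> patchify -> empty-filter -> weak-label -> grouped split ->
    train tiny backbone -> evaluate. Session-scoped: several tests assert
    different properties of the same run.
    """
    cfg = ld.SyntheticConfig(
        n_raw_images=84, image_width=672, image_height=448,
        cells_per_image=(30, 60), frac_dead_cells=0.5,
        frac_empty_regions=0.10, rng_seed=7,
    )
    pairs_records = [ld.generate_raw_pair(cfg, i) for i in range(cfg.n_raw_images)]

    all_patches = []
    region_of = {}
    for pair, records in pairs_records:
        for p in ld.crop_patches(pair, stride=224):
            all_patches.append(p)
            region_of[p.patch_id] = _region_state(records, p.x_offset, p.y_offset)

    # curate empty patches: detector fitted on ground-truth-flagged examples
    # drawn from the first images, applied to everything
    backbone = empty_filter.RandomConvFeatureExtractor(seed=0)
    train_pool = [p for p in all_patches
                  if int(p.raw_image_id.rsplit("_", 1)[1]) < 20]
    empties = [p for p in train_pool if region_of[p.patch_id].empty]
    nonempties = [p for p in train_pool if not region_of[p.patch_id].empty]
    feats = {
        "empty": [empty_filter.extract_features(p.bright_field_8bit, backbone,
                                                p.patch_id) for p in empties],
        "cells": [empty_filter.extract_features(p.bright_field_8bit, backbone,
                                                p.patch_id) for p in nonempties],
    }
    detector = empty_filter.fit_empty_detector(feats["empty"], feats["cells"])
    kept, discarded = empty_filter.filter_patches(all_patches, detector, backbone)

    means = [labeling.mean_fluorescence(p.fluorescence) for p in kept]
    mixture = labeling.fit_mixture(means, seed=0)
    thresholds = labeling.derive_thresholds(mixture)
    labels, _ = labeling.label_dataset(kept, thresholds)
    frame = labeling.labels_to_frame(labels)

    manifest = splits.grouped_split(frame, fractions=(0.8, 0.1, 0.1), seed=7)
    counts = splits.manifest_counts(manifest)
    weights = splits.class_weights(counts.loc["train", ["live", "dead"]])

    id2patch = {p.patch_id: p for p in kept}

    def arrays(part):
        sub = manifest.assignments[manifest.assignments["partition"] == part]
        x = np.stack([id2patch[i].bright_field_8bit / 255.0
                      for i in sub["patch_id"]])
        y = np.array([training.CLASS_ORDER.index(l) for l in sub["label"]])
        fluor = np.array([labeling.mean_fluorescence(id2patch[i].fluorescence)
                          for i in sub["patch_id"]])
        ids = sub["patch_id"].tolist()
        return x, y, fluor, ids

    x_tr, y_tr, _, _ = arrays("train")
    x_va, y_va, _, _ = arrays("valid")
    x_te, y_te, fl_te, ids_te = arrays("test")

    config = training.TrainConfig(backbone="tiny_test", learning_rate=1e-3,
                                  batch_size=4, epochs=12, seed=0)
    model = training.train(config, (x_tr, y_tr), (x_va, y_va), weights)

    scores = training.predict(model, x_te)[:, 0]
    truth = np.array([training.CLASS_ORDER[i] for i in y_te])
    report = evaluation.evaluate(scores, truth, mean_fluor=fl_te,
                                 n_boot=500, seed=0)

    return {
        "config": cfg, "patches": all_patches, "region_of": region_of,
        "detector": detector, "backbone": backbone,
        "kept": kept, "discarded": discarded,
        "mixture": mixture, "thresholds": thresholds, "labels": frame,
        "manifest": manifest, "counts": counts, "weights": weights,
        "model": model, "scores": scores, "truth": truth,
        "test_ids": ids_te, "test_x": x_te, "test_fluor": fl_te,
        "report": report,
    }
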