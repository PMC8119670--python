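"""Weak live/dead labeling of patches from mean fluorescence.

A patch's label is derived from the average propidium-iodide fluorescence
over its pixels: PI enters only membrane-compromised cells, so low means
indicate live cells and high means dead cells. The decision thresholds come
from a two-component Gaussian mixture fitted (by EM, best of several
restarts) to the per-patch means of a reference condition:

    live_max = mu_live + sigma_live
    dead_min = mu_dead - sigma_dead

Patches with mean below ``live_max`` are labeled live, above ``dead_min``
dead, and anything in the closed band ``[live_max, dead_min]`` is discarded
as ambiguous. Means are computed on raw 16-bit intensities (the thresholds
live on that scale, above the 8-bit maximum), and the same thresholds are
applied unchanged to every condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .patches import PatchPair

__all__ = [
    "MixtureModel",
    "LabelThresholds",
    "PatchLabel",
    "mean_fluorescence",
    "fit_mixture",
    "derive_thresholds",
    "assign_label",
    "label_dataset",
]

LABELS = ("live", "dead", "discarded")


@dataclass(frozen=True)
class MixtureModel:
    """A fitted two-component 1-D Gaussian mixture, components sorted by mean.

    The low-mean component is named live, the high-mean one dead — strictly
    by sorted mean, never by EM fit order.
    """

    mu_live: float
    sigma_live: float
    mu_dead: float
    sigma_dead: float
    weight_live: float
    log_likelihood: float = float("nan")
    n: int = 0
    seed: int | None = None
    restart_log_likelihoods: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.mu_live < self.mu_dead:
            raise ValueError("components must be sorted: mu_live < mu_dead")
        if self.sigma_live < 0 or self.sigma_dead < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0.0 < self.weight_live < 1.0:
            raise ValueError("weight_live must lie in (0, 1)")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "mu_live", "sigma_live", "mu_dead", "sigma_dead", "weight_live",
            "log_likelihood", "n", "seed")}
        d["restart_log_likelihoods"] = list(self.restart_log_likelihoods)
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class LabelThresholds:
    """Live/dead cut-offs; the open interval between them is the discard band."""

    live_max: float
    dead_min: float

    def __post_init__(self) -> None:
        if not self.live_max < self.dead_min:
            raise ValueError(
                f"degenerate discard band: live_max ({self.live_max}) must be "
                f"< dead_min ({self.dead_min}); refusing to label"
            )

    def to_json(self) -> str:
        return json.dumps({"live_max": self.live_max, "dead_min": self.dead_min})


@dataclass(frozen=True)
class PatchLabel:
    patch_id: str
    mean_fluorescence: float
    label: str
    raw_image_id: str | None = None


def mean_fluorescence(patch: np.ndarray) -> float:
    """Arithmetic mean of all pixels of a fluorescence patch (raw scale)."""
    arr = np.asarray(patch)
    if arr.size == 0:
        raise ValueError("cannot average an empty patch")
    return float(arr.mean(dtype=np.float64))


def fit_mixture(means: Sequence[float], n_components: int = 2,
                n_restarts: int = 10, seed: int = 0,
                tol: float = 1e-6) -> MixtureModel:
    """Fit a two-component Gaussian mixture to per-patch means by EM.

    Runs ``n_restarts`` independent k-means-initialized EM fits with derived
    seeds and keeps the one with the highest log-likelihood; every restart's
    log-likelihood is retained in the returned model's diagnostics. Raises if
    fewer points than components are given or no restart converges.
    """
    x = np.asarray(means, dtype=float).reshape(-1, 1)
    if x.shape[0] < max(10, n_components):
        raise ValueError(f"need at least 10 values to fit, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("means must be finite")
    if n_components != 2:
        raise ValueError("only the two-component live/dead mixture is supported")

    best = None
    candidates: list[float] = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_restarts):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        gm = GaussianMixture(n_components=2, n_init=1, init_params="kmeans",
                             tol=tol, random_state=rs)
        gm.fit(x)
        if not gm.converged_:
            continue
        ll = float(gm.score(x) * x.shape[0])
        candidates.append(ll)
        if best is None or ll > best[0]:
            best = (ll, gm)
    if best is None:
        raise RuntimeError(
            f"EM did not converge in any of {n_restarts} restarts "
            f"(n={x.shape[0]}, tol={tol})"
        )
    ll, gm = best
    mus = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(mus)
    return MixtureModel(
        mu_live=float(mus[order[0]]), sigma_live=float(sigmas[order[0]]),
        mu_dead=float(mus[order[1]]), sigma_dead=float(sigmas[order[1]]),
        weight_live=float(gm.weights_[order[0]]),
        log_likelihood=ll, n=int(x.shape[0]), seed=seed,
        restart_log_likelihoods=tuple(candidates),
    )


def derive_thresholds(model: MixtureModel) -> LabelThresholds:
    """Cut-offs one component standard deviation into the gap, from each side."""
    return LabelThresholds(
        live_max=model.mu_live + model.sigma_live,
        dead_min=model.mu_dead - model.sigma_dead,
    )


def assign_label(mean: float, thresholds: LabelThresholds) -> str:
    """live below ``live_max``, dead above ``dead_min``, discarded between.

    Values exactly equal to a threshold fall in the discard band (the band
    boundaries are treated conservatively).
    """
    if mean < thresholds.live_max:
        return "live"
    if mean > thresholds.dead_min:
        return "dead"
    return "discarded"


def label_dataset(patches: Iterable[PatchPair], thresholds: LabelThresholds,
                  conditions: dict[str, str] | None = None):
    """Label every patch and tabulate per-class (and per-condition) counts.

    ``conditions`` optionally maps raw_image_id -> condition so the summary
    can be broken down by experimental condition. Returns
    ``(labels, summary)`` with ``summary`` a DataFrame of counts.
    """
    labels: list[PatchLabel] = []
    rows = []
    for p in patches:
        m = mean_fluorescence(p.fluorescence)
        lab = assign_label(m, thresholds)
        labels.append(PatchLabel(patch_id=p.patch_id, mean_fluorescence=m,
                                 label=lab, raw_image_id=p.raw_image_id))
        rows.append({
            "label": lab,
            "condition": (conditions or {}).get(p.raw_image_id, "all"),
        })
    if rows:
        summary = (pd.DataFrame(rows)
                   .groupby(["condition", "label"]).size()
                   .unstack(fill_value=0)
                   .reindex(columns=list(LABELS), fill_value=0))
    else:
        summary = pd.DataFrame(columns=list(LABELS))
    return labels, summary


def labels_to_frame(labels: Sequence[PatchLabel]) -> pd.DataFrame:
    return pd.DataFrame([
        {"patch_id": l.patch_id, "raw_image_id": l.raw_image_id,
         "mean_fluorescence": l.mean_fluorescence, "label": l.label}
        for l in labels
    ])


def write_labels(labels: Sequence[PatchLabel], path: str | Path) -> None:
    labels_to_frame(labels).to_csv(path, index=False)
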