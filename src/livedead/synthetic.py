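"""Synthetic paired bright-field / fluorescence image generator.

Emulates the statistical structure of an adherent-monolayer viability assay:
a transmitted-light (bright-field) channel in which live cells appear as
mostly uniform gray bodies with small dark nuclei and dead cells as blurred
dark halos, and a propidium-iodide-like fluorescence channel in which the
per-region mean intensity follows a two-component Gaussian mixture — a low
component over regions of live cells and a high component over regions of
dead cells. A configurable fraction of regions is left empty (background
only), mimicking sparsely seeded culture areas.

The generator works on a grid of patch-sized regions so that every pixel of
the image belongs to exactly one region with a known state, target mean
fluorescence and emptiness flag. Those ground-truth records let every
downstream stage (patch cropping, empty-patch filtering, weak labeling,
training, evaluation) be tested without any real dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "FluorMixture",
    "SyntheticConfig",
    "GroundTruthRecord",
    "generate_raw_pair",
    "generate_dataset",
    "sample_fluorescence_means",
    "is_bimodal",
]

PATCH_SIZE = 224

# Bright-field rendering levels (16-bit scale). Only the contrast between
# background, cell body, nucleus and dead halo matters for the classifiers.
_BF_BACKGROUND = 30000.0
_BF_LIVE_BODY_DELTA = -2500.0
_BF_NUCLEUS_DELTA = -14000.0
_BF_DEAD_BODY_DELTA = -16000.0
_UINT16_MAX = 65535


@dataclass(frozen=True)
class FluorMixture:
    """Two-component Gaussian mixture of per-region mean fluorescence.

    The low component models regions of live cells (propidium iodide is
    excluded by intact membranes), the high component regions of dead cells.
    Intensities are raw 16-bit-scale units and may exceed 255.
    """

    mu_live: float = 224.51
    sigma_live: float = 34.46
    mu_dead: float = 550.44
    sigma_dead: float = 153.55
    weight_live: float = 0.5

    def __post_init__(self) -> None:
        if not self.mu_live < self.mu_dead:
            raise ValueError(
                f"mu_live ({self.mu_live}) must be < mu_dead ({self.mu_dead})"
            )
        if self.sigma_live < 0 or self.sigma_dead < 0:
            raise ValueError("mixture sigmas must be non-negative")
        if not 0.0 < self.weight_live < 1.0:
            raise ValueError("weight_live must lie in (0, 1)")

    @property
    def mean(self) -> float:
        """Analytic mean of the mixture."""
        w = self.weight_live
        return w * self.mu_live + (1.0 - w) * self.mu_dead


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic acquisition run."""

    n_raw_images: int = 8
    image_width: int = 1344
    image_height: int = 1024
    cells_per_image: tuple[int, int] = (40, 80)
    frac_dead_cells: float = 0.5
    frac_empty_regions: float = 0.15
    fluor_mixture: FluorMixture = field(default_factory=FluorMixture)
    noise_sd: float = 15.0
    condition: str = "no_treatment"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dead_cells", "frac_empty_regions"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.image_width < PATCH_SIZE or self.image_height < PATCH_SIZE:
            raise ValueError(
                "image dimensions must accommodate at least one "
                f"{PATCH_SIZE}x{PATCH_SIZE} patch, got "
                f"{self.image_width}x{self.image_height}"
            )
        if self.n_raw_images < 1:
            raise ValueError("n_raw_images must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.cells_per_image
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_image must be a (lo, hi) range with 1 <= lo <= hi")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        d = json.loads(text)
        d["fluor_mixture"] = FluorMixture(**d["fluor_mixture"])
        d["cells_per_image"] = tuple(d["cells_per_image"])
        return cls(**d)


@dataclass
class GroundTruthRecord:
    """Ground truth for one patch-sized region of a generated image.

    ``cells`` holds ``(cx, cy, state)`` tuples (pixel centres, live|dead);
    ``true_mean_fluorescence`` is the realized pixel average over the region.
    """

    raw_image_id: str
    region_index: int
    x0: int
    y0: int
    x1: int
    y1: int
    state: str  # "live" | "dead" | "empty"
    empty: bool
    true_mean_fluorescence: float
    cells: list[tuple[int, int, str]] = field(default_factory=list)


def _region_grid(width: int, height: int) -> list[tuple[int, int, int, int]]:
    """Partition the image into a grid of roughly patch-sized regions.

    Every pixel belongs to exactly one region; region edges are chosen so
    the grid covers the full image even when dimensions are not multiples
    of the patch size.
    """
    ncols = max(1, width // PATCH_SIZE)
    nrows = max(1, height // PATCH_SIZE)
    xs = np.linspace(0, width, ncols + 1).round().astype(int)
    ys = np.linspace(0, height, nrows + 1).round().astype(int)
    regions = []
    for r in range(nrows):
        for c in range(ncols):
            regions.append((int(xs[c]), int(ys[r]), int(xs[c + 1]), int(ys[r + 1])))
    return regions


def _add_ellipse(canvas: np.ndarray, cy: float, cx: float, ry: float, rx: float,
                 theta: float, value: float) -> None:
    """Add ``value`` inside an ellipse, computed only on its bounding box."""
    h, w = canvas.shape
    r = int(np.ceil(max(ry, rx))) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    mask = (xr / rx) ** 2 + (yr / ry) ** 2 <= 1.0
    canvas[y0:y1, x0:x1][mask] += value


def _render_brightfield(width: int, height: int, records: list[GroundTruthRecord],
                        noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    img = np.full((height, width), _BF_BACKGROUND, dtype=np.float64)
    live_canvas = np.zeros_like(img)
    dead_canvas = np.zeros_like(img)
    for rec in records:
        for cx, cy, state in rec.cells:
            theta = rng.uniform(0, np.pi)
            if state == "live":
                ry, rx = rng.uniform(18, 30, size=2)
                _add_ellipse(live_canvas, cy, cx, ry, rx, theta, _BF_LIVE_BODY_DELTA)
                nr = rng.uniform(4, 7)
                _add_ellipse(live_canvas, cy, cx, nr, nr, 0.0, _BF_NUCLEUS_DELTA)
            else:
                ry, rx = rng.uniform(22, 38, size=2)
                _add_ellipse(dead_canvas, cy, cx, ry, rx, theta, _BF_DEAD_BODY_DELTA)
    # live cells keep sharp contours; dead cells smear into blurred dark halos
    live_canvas = gaussian_filter(live_canvas, sigma=1.0)
    dead_canvas = gaussian_filter(dead_canvas, sigma=6.0)
    img += live_canvas + dead_canvas
    img += rng.normal(0.0, 600.0 + 10.0 * noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, _UINT16_MAX).astype(np.uint16)


def _render_fluorescence(width: int, height: int, records: list[GroundTruthRecord],
                         mixture: FluorMixture, noise_sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((height, width), dtype=np.float64)
    for rec in records:
        h, w = rec.y1 - rec.y0, rec.x1 - rec.x0
        if rec.state == "dead":
            target = rng.normal(mixture.mu_dead, mixture.sigma_dead)
            base = rng.normal(mixture.mu_live, mixture.sigma_live)
            base = max(base, 0.0)
            tile = rng.normal(base, noise_sd, size=(h, w))
            # one bright blob per dead cell; amplitude solved so the region
            # pixel mean hits the drawn high-component target
            bumps = np.zeros((h, w))
            centers = [(cx - rec.x0, cy - rec.y0) for cx, cy, s in rec.cells] or [
                (w / 2, h / 2)
            ]
            yy, xx = np.mgrid[0:h, 0:w]
            for bx, by in centers:
                s = rng.uniform(18, 30)
                bumps += np.exp(-(((xx - bx) ** 2) + ((yy - by) ** 2)) / (2 * s * s))
            total = bumps.sum()
            if total > 0 and target > base:
                tile += (target - base) * (h * w) / total * bumps
        else:
            # live and empty regions: low-component background only
            target = rng.normal(mixture.mu_live, mixture.sigma_live)
            target = max(target, 0.0)
            tile = rng.normal(target, noise_sd, size=(h, w))
        img[rec.y0:rec.y1, rec.x0:rec.x1] = tile
    return np.clip(np.rint(img), 0, _UINT16_MAX).astype(np.uint16)


def generate_raw_pair(config: SyntheticConfig, image_index: int):
    """Generate one registered bright-field/fluorescence pair with ground truth.

    Returns ``(pair, records)`` where ``pair`` is a
    :class:`livedead.patches.RawImagePair` and ``records`` lists one
    :class:`GroundTruthRecord` per patch-sized region. Deterministic in
    ``(config.rng_seed, image_index)``.
    """
    from .patches import RawImagePair  # local import to avoid a cycle

    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, image_index)))
    width, height = config.image_width, config.image_height
    regions = _region_grid(width, height)
    n_regions = len(regions)

    n_cells_total = int(rng.integers(config.cells_per_image[0],
                                     config.cells_per_image[1] + 1))
    per_region = max(1, round(n_cells_total / n_regions))

    raw_image_id = f"syn_{config.condition}_{image_index:04d}"
    records: list[GroundTruthRecord] = []
    for i, (x0, y0, x1, y1) in enumerate(regions):
        empty = bool(rng.random() < config.frac_empty_regions)
        if empty:
            state = "empty"
            cells: list[tuple[int, int, str]] = []
        else:
            state = "dead" if rng.random() < config.frac_dead_cells else "live"
            n_c = max(1, int(rng.integers(max(1, per_region - 1), per_region + 2)))
            cells = []
            for _ in range(n_c):
                cx = int(rng.integers(x0 + 15, max(x0 + 16, x1 - 15)))
                cy = int(rng.integers(y0 + 15, max(y0 + 16, y1 - 15)))
                cells.append((cx, cy, state))
        records.append(GroundTruthRecord(
            raw_image_id=raw_image_id, region_index=i,
            x0=x0, y0=y0, x1=x1, y1=y1,
            state=state, empty=empty, true_mean_fluorescence=np.nan, cells=cells,
        ))

    bf = _render_brightfield(width, height, records, config.noise_sd, rng)
    fl = _render_fluorescence(width, height, records, config.fluor_mixture,
                              config.noise_sd, rng)
    for rec in records:
        rec.true_mean_fluorescence = float(
            fl[rec.y0:rec.y1, rec.x0:rec.x1].mean()
        )
    pair = RawImagePair(raw_image_id=raw_image_id, bright_field=bf,
                        fluorescence=fl, condition=config.condition)
    return pair, records


def generate_dataset(config: SyntheticConfig, out_dir: str | Path):
    """Generate and write a full synthetic dataset.

    Writes 16-bit TIFF channel pairs, a ``manifest.csv`` with columns
    (raw_image_id, channel, path, condition), a ``ground_truth.csv`` of
    per-region records and a JSON copy of the config. Returns
    ``(pairs, records_df)``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    gt_rows = []
    pairs = []
    for idx in range(config.n_raw_images):
        pair, records = generate_raw_pair(config, idx)
        pairs.append(pair)
        for channel, arr in (("bright_field", pair.bright_field),
                             ("fluorescence", pair.fluorescence)):
            fname = f"{pair.raw_image_id}_{channel}.tif"
            tifffile.imwrite(out / fname, arr)
            manifest_rows.append({
                "raw_image_id": pair.raw_image_id, "channel": channel,
                "path": fname, "condition": pair.condition,
            })
        for rec in records:
            gt_rows.append({
                "raw_image_id": rec.raw_image_id, "region_index": rec.region_index,
                "x0": rec.x0, "y0": rec.y0, "x1": rec.x1, "y1": rec.y1,
                "state": rec.state, "empty": rec.empty,
                "true_mean_fluorescence": rec.true_mean_fluorescence,
                "n_cells": len(rec.cells),
            })
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    gt = pd.DataFrame(gt_rows)
    gt.to_csv(out / "ground_truth.csv", index=False)
    (out / "config.json").write_text(config.to_json())
    return pairs, gt


def sample_fluorescence_means(mixture: FluorMixture, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. per-patch mean-fluorescence values from the mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mixture.sigma_live < 0 or mixture.sigma_dead < 0:
        raise ValueError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    is_live = rng.random(n) < mixture.weight_live
    draws = np.where(
        is_live,
        rng.normal(mixture.mu_live, mixture.sigma_live, size=n),
        rng.normal(mixture.mu_dead, mixture.sigma_dead, size=n),
    )
    return draws


def is_bimodal(values: np.ndarray, grid_size: int = 512) -> bool:
    """Dip-style bimodality check: does a KDE of ``values`` have >= 2 modes?

    Smooths with a Gaussian KDE (Scott bandwidth) and counts strict local
    maxima of the density on a regular grid spanning the data range.
    """
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values for a bimodality check")
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), grid_size)
    dens = kde(grid)
    interior = dens[1:-1]
    maxima = (interior > dens[:-2]) & (interior > dens[2:])
    return int(maxima.sum()) >= 2
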