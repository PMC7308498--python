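"""End-to-end runs and the two experiment harnesses.

``run_segment`` executes preprocess -> adaptive Frangi -> radii on one image
and writes all artifacts with a provenance sidecar.  ``run_thickness_sweep``
scores the central slab of a series of projection thicknesses against a truth
volume; ``run_noise_sweep`` measures segmentation robustness of the plain and
adaptive filters across noise levels on seeded phantoms.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import frangi, metrics, radii, synth
from .preprocess import (ImageVolume, ProjectionImage, central_projection, load_volume,
                         mip, mip_series, normalize_intensity)

logger = logging.getLogger("vesselrad")

THICKNESSES_MM = (4, 8, 16, 24, 32, 48, "full")


@dataclass
class RunConfig:
    """Resolved pipeline defaults; every field is JSON-serializable."""

    sigma_min: float = 0.8
    sigma_step: float = 0.2
    beta: float = 0.5
    c: float | str = "auto"
    fm_threshold: float = 0.001
    coarse_frac: float = 0.5
    seed_percentile: float = 99.5
    target_spacing: float = 0.23
    thicknesses: tuple = THICKNESSES_MM
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.fm_threshold <= 1):
            raise ValueError("fm_threshold must lie in (0, 1]")
        if not (0 < self.coarse_frac <= 1):
            raise ValueError("coarse_frac must lie in (0, 1]")
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thicknesses"] = list(self.thicknesses)
        return d

    def frangi_params(self) -> frangi.FrangiParams:
        return frangi.FrangiParams(
            beta=self.beta, c=self.c, sigma_min=self.sigma_min, sigma_step=self.sigma_step
        )

    def stage_seed(self, stage: int) -> int:
        """Fan the global seed out to per-stage seeds (stable, re-runnable)."""
        return int((self.seed * 100003 + stage * 101) % (2**31))


def _save_png(arr: np.ndarray, path: Path) -> None:
    a = np.asarray(arr, dtype=np.float64)
    m = a.max() if a.max() > 0 else 1.0
    Image.fromarray((a / m * 65535).astype(np.uint16)).save(path)


def _as_projection(inp, config: RunConfig) -> ProjectionImage:
    if isinstance(inp, ProjectionImage):
        return inp
    if isinstance(inp, np.ndarray) and inp.ndim == 2:
        return ProjectionImage(
            data=inp, pixel_size=config.target_spacing,
            thickness_mm=config.target_spacing, center_index=0, axis=2,
        )
    if isinstance(inp, (str, Path)):
        vol = load_volume(inp)
        return mip(vol, axis=2, thickness_mm="full")
    if isinstance(inp, ImageVolume):
        return mip(inp, axis=2, thickness_mm="full")
    raise TypeError(f"cannot interpret input of type {type(inp)!r}")


def run_segment(config: RunConfig, inp, out_dir: str | Path, mode: str = "adaptive") -> dict:
    """Segment one image and write all artifacts.

    Writes the binary mask, vesselness and winning-scale maps, radii map,
    radii histogram CSV, scalar metrics JSON and a provenance sidecar with
    every resolved parameter.  Returns the artifact path dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    proj = _as_projection(inp, config)
    proj = normalize_intensity(proj)

    mask, vmap, plan = frangi.segment(
        proj.data,
        params=config.frangi_params(),
        mode=mode,
        coarse_frac=config.coarse_frac,
        fm_threshold=config.fm_threshold,
        seed_percentile=config.seed_percentile,
    )
    logger.info("segmentation done in %.1fs; %d scale regions", time.time() - t0,
                len(plan.sigma_set_per_region))
    for rid, ladder in sorted(plan.sigma_set_per_region.items()):
        logger.info("region %d: radii_max %.2f px, sigmas %s", rid,
                    plan.radii_max_per_region[rid], list(ladder))

    skel = radii.skeletonize(mask)
    rmap = radii.radii_map(mask, skel, pixel_size=proj.pixel_size)
    hist = radii.radii_histogram(rmap)
    scalars = {
        "volume_ml": radii.vessel_volume(mask, (proj.pixel_size,) * 3),
        "length_m": radii.vessel_length(skel, pixel_size=proj.pixel_size),
        "n_bifurcations": radii.count_bifurcations(skel),
        "max_radius_px": float(rmap.values.max()),
        "n_skeleton_px": int(skel.sum()),
    }

    paths = {
        "mask": out / "mask.png",
        "vesselness": out / "vesselness.png",
        "sigma_argmax": out / "sigma_argmax.png",
        "radii_map": out / "radii_map.png",
        "histogram": out / "radii_histogram.csv",
        "metrics": out / "metrics.json",
        "sidecar": out / "provenance.json",
    }
    Image.fromarray((mask * 255).astype(np.uint8)).save(paths["mask"])
    _save_png(vmap.data, paths["vesselness"])
    _save_png(vmap.sigma_argmax, paths["sigma_argmax"])
    _save_png(rmap.values, paths["radii_map"])
    pd.DataFrame(hist.to_rows(), columns=["bin_low", "bin_high", "count"]).to_csv(
        paths["histogram"], index=False
    )
    paths["metrics"].write_text(json.dumps(scalars, indent=2))
    sidecar = {
        "config": config.to_dict(),
        "mode": mode,
        "projection": proj.provenance(),
        "sigma_plan": plan.to_dict(),
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return {k: str(v) for k, v in paths.items()}


def _truth_slab(truth: ImageVolume, proj: ProjectionImage) -> np.ndarray:
    """Binary truth for a slab: MIP of the truth mask over the same slab."""
    tm = mip(truth, axis=proj.axis, center_index=proj.center_index,
             thickness_mm=proj.thickness_mm)
    return tm.data >= 0.5


def run_thickness_sweep(config: RunConfig, volume: ImageVolume, truth: ImageVolume | None = None) -> pd.DataFrame:
    """Segment the central slab at each projection thickness and score it.

    Emits one row per thickness: (thickness_mm, dice, jaccard, f_score, ccc,
    max_radius_px).  Score columns are NaN without a truth volume.
    Thicknesses exceeding the volume extent are skipped with a warning.
    """
    rows = []
    for t in config.thicknesses:
        try:
            series = mip_series(volume, t, axis=2)
        except ValueError as e:
            logger.warning("thickness %s skipped: %s", t, e)
            continue
        proj = central_projection(series)
        if proj.data.max() <= 0:
            logger.warning("thickness %s skipped: central slab is empty", t)
            continue
        proj = normalize_intensity(proj)
        mask, _, _ = frangi.segment(
            proj.data, params=config.frangi_params(),
            coarse_frac=config.coarse_frac, fm_threshold=config.fm_threshold,
            seed_percentile=config.seed_percentile,
        )
        skel = radii.skeletonize(mask)
        rmap = radii.radii_map(mask, skel, pixel_size=proj.pixel_size)
        row = {
            "thickness_mm": float(proj.thickness_mm),
            "max_radius_px": float(rmap.values.max()),
        }
        if truth is not None:
            tmask = _truth_slab(truth, proj)
            scores = metrics.segmentation_scores(mask, tmask)
            row.update(dice=scores.dice, jaccard=scores.jaccard,
                       f_score=scores.f_score, ccc=scores.ccc)
        else:
            row.update(dice=np.nan, jaccard=np.nan, f_score=np.nan, ccc=np.nan)
        rows.append(row)
    cols = ["thickness_mm", "dice", "jaccard", "f_score", "ccc", "max_radius_px"]
    return pd.DataFrame(rows, columns=cols)


def run_noise_sweep(
    config: RunConfig,
    phantom_spec: synth.PhantomSpec,
    levels=(0, 50, 100, 150, 200),
    seeds=(0, 1, 2),
    gradient: float = 0.0,
) -> pd.DataFrame:
    """Dice of plain vs adaptive segmentation across noise levels.

    One seeded phantom per seed; per (level, seed, method) the noisy image is
    segmented and scored against the noise-free truth mask.  An optional
    background gradient is applied after the noise.
    """
    bad = set(levels) - set(synth.NOISE_LEVELS)
    if bad:
        raise ValueError(f"invalid noise levels {sorted(bad)}")
    rows = []
    for seed in seeds:
        phantom = synth.generate_phantom(replace(phantom_spec, seed=seed))
        for level in levels:
            noise_seed = int((config.seed * 100003 + seed * 1009 + level) % (2**31))
            img = synth.add_columnwise_noise(phantom.image, level, seed=noise_seed)
            if gradient > 0:
                img = synth.add_background_gradient(img, max_fraction=gradient)
            for mode in ("plain_frangi", "adaptive"):
                mask, _, _ = frangi.segment(
                    img, params=config.frangi_params(),
                    mode="plain" if mode == "plain_frangi" else "adaptive",
                    coarse_frac=config.coarse_frac,
                    fm_threshold=config.fm_threshold,
                    seed_percentile=config.seed_percentile,
                )
                rows.append({
                    "level": level, "seed": seed, "method": mode,
                    "dice": metrics.dice(mask, phantom.truth_mask),
                })
    return pd.DataFrame(rows, columns=["level", "seed", "method", "dice"])
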