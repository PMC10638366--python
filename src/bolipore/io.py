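"""File I/O, run configuration and the end-to-end measurement pipeline.

SEM TIFFs rarely carry a trustworthy physical scale, so the pixel size is
always supplied explicitly (sidecar config / CLI option) and attached to
the image on read.  Coordinates are 0-based row-major with the origin at
the top-left pixel; areas are reported in µm² only.

Output CSVs are UTF-8, comma-separated, '.' decimal, with a mandatory
header row, and are re-parseable by this module's own readers.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image as PILImage

from .core import ChamberMap, PoreLabelMap, SEMImage
from .morphometrics import measure_pores, specimen_params
from .roi import (
    DEFAULT_WINDOW,
    SpecimenTooSmallError,
    WindowUnattainableError,
    order_chambers,
    select_roi,
)
from .segmentation import SegConfig, remove_artifacts, segment_pores_classical

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "read_labelmap",
    "write_labelmap",
    "read_specimen_csv",
    "run_pipeline",
]

SPECIMEN_CSV_COLUMNS = [
    "specimen_id",
    "location",
    "species",
    "status",
    "roi_area_um2",
    "n_pores",
    "pore_density",
    "mean_pore_size_um2",
    "porosity_pct",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    pixel_size: float = 1.0
    method: str = "classical"  # classical | learned | ground_truth
    seg: SegConfig = field(default_factory=SegConfig)
    window: tuple[float, float] = DEFAULT_WINDOW
    apply_corrections: bool = False
    outdir: "str | None" = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not self.window[0] < self.window[1]:
            raise ValueError("window lower bound must be below upper bound")
        if self.method not in ("classical", "learned", "ground_truth"):
            raise ValueError("method must be classical, learned or ground_truth")
        self.seg.validate()

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegConfig(**raw.pop("seg", {}))
        window = tuple(raw.pop("window", DEFAULT_WINDOW))
        cfg = RunConfig(seg=seg, window=window, **raw)
        cfg.validate()
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        return d


def read_image(path, pixel_size: "float | None" = None, to_gray: bool = False) -> SEMImage:
    """Read a TIFF or PNG as a calibrated SEM image.

    ``pixel_size`` (µm/pixel) is mandatory — SEM files are treated as
    uncalibrated rasters.  RGB input is refused unless ``to_gray`` requests
    a luminance conversion.
    """
    path = Path(path)
    if pixel_size is None:
        raise ValueError("pixel_size (µm/pixel) is required to calibrate the image")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:
        if not to_gray:
            raise ValueError(
                f"{path.name} is RGB; pass to_gray=True for a luminance conversion"
            )
        arr = np.asarray(
            PILImage.fromarray(arr.astype(np.uint8)).convert("L")
        )
    return SEMImage(arr, pixel_size=pixel_size, id=path.stem)


def write_image(path, image: SEMImage) -> None:
    """Write an image as TIFF (any depth) or PNG (8-bit only)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        if image.pixels.dtype != np.uint8:
            raise ValueError("PNG output supports 8-bit images only; use TIFF")
        PILImage.fromarray(image.pixels).save(path)


def write_labelmap(path, labelmap: PoreLabelMap) -> None:
    tifffile.imwrite(Path(path), labelmap.labels.astype(np.int32))


def read_labelmap(path, provenance: str = "ground_truth") -> PoreLabelMap:
    return PoreLabelMap(tifffile.imread(Path(path)), provenance=provenance)


def read_specimen_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPECIMEN_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"specimen CSV missing columns: {sorted(missing)}")
    return df


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    inputs,
    model=None,
) -> tuple[pd.DataFrame, dict]:
    """Run segment → (correct) → ROI-select → measure for a set of specimens.

    ``inputs`` is either a dict ``{"preset": ..., "n": ..., "seed": ...}``
    describing a synthetic cohort, or a list of
    ``(SEMImage, ChamberMap, artifact_mask_or_None)`` triples.  Specimens
    that fail the size window are recorded with a status message instead of
    aborting the run.

    Returns the per-specimen table and a manifest sufficient to replay the
    run.
    """
    from . import __version__
    from .learned import segment_pores_learned
    from .synth import generate_cohort

    config.validate()
    t_start = time.time()
    manifest: dict = {
        "tool": "bolipore",
        "version": __version__,
        "config": config.snapshot(),
        "seeds": {"run": config.seed},
        "inputs": None,
        "timings_s": {},
    }

    triples = []
    if isinstance(inputs, dict):
        preset = inputs.get("preset", "default")
        n = int(inputs.get("n", 1))
        seed = int(inputs.get("seed", config.seed))
        manifest["inputs"] = {"synthetic": {"preset": preset, "n": n, "seed": seed}}
        manifest["seeds"]["cohort"] = seed
        t0 = time.time()
        base = inputs.get("base_spec")
        cohort = generate_cohort(n, preset, seed, base_spec=base)
        manifest["timings_s"]["generate"] = round(time.time() - t0, 3)
        for img, gt in cohort:
            mask = gt.debris_mask if config.apply_corrections else None
            triples.append((img, gt.chamber_map, mask, gt))
    else:
        if not inputs:
            raise ValueError("no inputs supplied")
        manifest["inputs"] = {
            "images": [
                {"id": img.id, "sha256": _sha256(np.ascontiguousarray(img.pixels).tobytes())}
                for img, *_ in inputs
            ]
        }
        for item in inputs:
            img, chambers, artifact = item[0], item[1], (item[2] if len(item) > 2 else None)
            triples.append((img, chambers, artifact, None))

    rows = []
    t_seg = 0.0
    for img, chambers, artifact_mask, gt in triples:
        row = {c: "" for c in SPECIMEN_CSV_COLUMNS}
        row["specimen_id"] = img.id
        row["location"] = manifest["inputs"].get("synthetic", {}).get("preset", "") if isinstance(manifest["inputs"], dict) and "synthetic" in manifest["inputs"] else ""
        row["species"] = "B. spissa"
        try:
            t0 = time.time()
            if config.method == "classical":
                lm = segment_pores_classical(img, config.seg)
            elif config.method == "learned":
                if model is None:
                    raise ValueError("learned method requires a trained model")
                lm = segment_pores_learned(img, model, config.seg)
            else:  # ground_truth
                if gt is None:
                    raise ValueError("ground_truth method requires synthetic inputs")
                lm = gt.pore_mask
            t_seg += time.time() - t0
            if artifact_mask is not None and config.method != "ground_truth":
                lm = remove_artifacts(lm, artifact_mask)
            order = order_chambers(chambers)
            roi = select_roi(chambers, order, window=config.window, pixel_size=img.pixel_size)
            records = measure_pores(lm, roi, img.pixel_size)
            m = specimen_params(
                records,
                roi,
                meta={"specimen_id": img.id, "location": row["location"], "species": row["species"]},
            )
            row.update(
                status="ok",
                roi_area_um2=m.roi_area,
                n_pores=m.n_pores,
                pore_density=m.pore_density,
                mean_pore_size_um2=m.mean_pore_size,
                porosity_pct=m.porosity,
            )
        except (SpecimenTooSmallError, WindowUnattainableError) as exc:
            row["status"] = str(exc)
            warnings.warn(f"{img.id}: {exc}", stacklevel=2)
        rows.append(row)
    manifest["timings_s"]["segment"] = round(t_seg, 3)
    manifest["timings_s"]["total"] = round(time.time() - t_start, 3)

    table = pd.DataFrame(rows, columns=SPECIMEN_CSV_COLUMNS)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "specimens.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return table, manifest
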