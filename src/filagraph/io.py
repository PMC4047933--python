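"""Image and tabular I/O, confocal z-stack projection, config serialisation."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .image import IntensityImage
from .pipeline import PipelineConfig

__all__ = [
    "read_image",
    "write_image",
    "max_project",
    "write_outputs",
    "load_config",
    "save_config",
]


def read_image(path, channel: int | None = None, pixel_size_um: float | None = None) -> IntensityImage:
    """Read an 8- or 16-bit grayscale TIFF/PNG as an IntensityImage.

    Values are kept on the file's scale (no rescaling).  A colour image is
    rejected unless ``channel`` selects one plane.  3-D TIFFs (z-stacks) are
    returned as-is in ``meta['stack']`` slices via :func:`read_stack`; use
    :func:`max_project` for z-compression.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            data = tifffile.imread(path)
        else:
            data = iio.imread(path)
    except Exception as exc:  # pragma: no cover - corrupt files
        raise ValueError(f"could not read image {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 3:
        if data.shape[-1] in (3, 4):  # colour
            if channel is None:
                raise ValueError(
                    f"{path} is multi-channel; select a plane with --channel"
                )
            data = data[..., channel]
        else:
            raise ValueError(
                f"{path} has shape {data.shape}; expected a single 2-D plane "
                "(read z-stacks with read_stack and max_project)"
            )
    if data.ndim != 2:
        raise ValueError(f"{path} is not a 2-D grayscale image (shape {data.shape})")
    meta = {"path": str(path), "dtype": str(data.dtype)}
    return IntensityImage(data.astype(float), pixel_size_um=pixel_size_um, meta=meta)


def read_stack(path, channel: int | None = None) -> list[IntensityImage]:
    """Read a multi-page TIFF as a list of slices."""
    data = np.asarray(tifffile.imread(Path(path)))
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:
        if channel is None:
            raise ValueError(f"{path} is multi-channel; select one with --channel")
        data = data[..., channel]
    return [IntensityImage(plane.astype(float)) for plane in data]


def write_image(path, pixels: np.ndarray, dtype=None) -> None:
    """Write a 2-D array as TIFF (any dtype) or PNG (integer dtypes)."""
    path = Path(path)
    arr = np.asarray(pixels)
    if dtype is not None:
        arr = arr.astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def max_project(stack: list[IntensityImage]) -> IntensityImage:
    """Pixelwise maximum across a confocal z-stack (z-compression)."""
    if not stack:
        raise ValueError("empty stack")
    shapes = {im.pixels.shape for im in stack}
    if len(shapes) != 1:
        raise ValueError(f"slices differ in shape: {sorted(shapes)}")
    proj = np.maximum.reduce([im.pixels for im in stack])
    return IntensityImage(
        proj,
        pixel_size_um=stack[0].pixel_size_um,
        meta={"projection": "max", "n_slices": len(stack)},
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_outputs(out_dir, result, distribution=None, report=None) -> dict:
    """Write per-filament CSV, histogram CSV, summary JSON and config echo.

    ``result`` is a :class:`filagraph.pipeline.TraceResult`.  Returns the
    mapping of artifact name to path.  Repeated runs on identical inputs
    produce byte-identical CSV bodies.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    orientations = result.mean_orientations_rad() if result.paths else np.asarray([])
    rows = []
    for i, (p, length) in enumerate(zip(result.paths, result.lengths_px)):
        row = {
            "id": i,
            "length_px": round(float(length), 4),
            "n_pixels": int(len(p.pixels)),
            "mean_orientation_rad": round(float(orientations[i]), 4),
            "closed": bool(p.closed),
        }
        if result.config.pixel_size_um is not None:
            row["length_um"] = round(float(length * result.config.pixel_size_um), 4)
        rows.append(row)
    filaments_csv = out_dir / "filaments.csv"
    pd.DataFrame(
        rows,
        columns=["id", "length_px", "n_pixels", "mean_orientation_rad", "closed"]
        + (["length_um"] if result.config.pixel_size_um is not None else []),
    ).to_csv(filaments_csv, index=False)
    paths["filaments"] = filaments_csv

    summary = {
        "n_filaments": int(len(result.paths)),
        "weighted_mean": None,
        "weighted_mean_se": None,
        "unit": "um" if result.config.pixel_size_um else "px",
        "seed": result.config.seed,
    }
    if distribution is not None:
        hist_csv = out_dir / "histogram.csv"
        pd.DataFrame(
            {
                "bin_left": distribution.bin_edges[:-1],
                "bin_right": distribution.bin_edges[1:],
                "count": distribution.counts,
            }
        ).to_csv(hist_csv, index=False)
        paths["histogram"] = hist_csv
        summary["weighted_mean"] = (
            None
            if np.isnan(distribution.weighted_mean)
            else float(distribution.weighted_mean)
        )
        summary["weighted_mean_se"] = (
            None
            if np.isnan(distribution.weighted_mean_se)
            else float(distribution.weighted_mean_se)
        )
    summary_json = out_dir / "summary.json"
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["summary"] = summary_json

    config_yaml = out_dir / "config.yaml"
    save_config(result.config, config_yaml)
    paths["config"] = config_yaml

    if report is not None:
        report_json = out_dir / "validation.json"
        report_json.write_text(json.dumps(report.to_json_dict(), indent=2))
        paths["validation"] = report_json
    return paths
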