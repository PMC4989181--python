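"""Reading and writing of image sets, masks, tables and manifests.

On disk a worm is three text-manifest-described files: a multi-page 16-bit
grayscale TIFF with one page per band (page order = ascending wavenumber,
recorded in the manifest), an 8-bit single-page label TIFF, and optionally a
16-bit single-page GFP TIFF.  Assay and record tables are plain CSV with a
header row.  The manifest is a flat TOML file recording seed, strain, pixel
size and the band page order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import tomllib

from .types import AccumulationRecord, BandFrame, ReproductionAssayRow, WormImageSet


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, np.integer, np.floating)):
        return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_manifest(path, mapping: dict) -> None:
    """Write a flat key-value mapping as TOML (stdlib has no TOML writer)."""
    lines = [f"{key} = {_toml_value(value)}" for key, value in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_image_set(image_set: WormImageSet, bands_path, labels_path,
                    gfp_path=None, manifest_path=None, *,
                    seed: int | None = None, strain: str | None = None) -> None:
    """Write one worm: multi-page band TIFF, label TIFF, optional GFP TIFF + manifest."""
    wavenumbers = sorted(image_set.bands)
    pages = np.stack([image_set.bands[wn].data.astype(np.uint16) for wn in wavenumbers])
    tifffile.imwrite(bands_path, pages, photometric="minisblack")
    tifffile.imwrite(labels_path, image_set.labels.astype(np.uint8),
                     photometric="minisblack")
    if gfp_path is not None and image_set.gfp is not None:
        tifffile.imwrite(gfp_path, image_set.gfp.astype(np.uint16),
                         photometric="minisblack")
    if manifest_path is not None:
        manifest = {
            "worm_id": image_set.worm_id,
            "pixel_size_um": image_set.pixel_size,
            "band_wavenumbers_cm1": list(map(float, wavenumbers)),
            "bands_file": str(Path(bands_path).name),
            "labels_file": str(Path(labels_path).name),
        }
        if gfp_path is not None and image_set.gfp is not None:
            manifest["gfp_file"] = str(Path(gfp_path).name)
        if seed is not None:
            manifest["seed"] = int(seed)
        if strain is not None:
            manifest["strain"] = strain
        write_manifest(manifest_path, manifest)


def read_image_set(bands_path, labels_path, wavenumbers, pixel_size: float,
                   gfp_path=None, worm_id: str = "worm") -> WormImageSet:
    """Reassemble a :class:`WormImageSet` from its on-disk files."""
    pages = tifffile.imread(bands_path)
    if pages.ndim == 2:
        pages = pages[None]
    wavenumbers = list(map(float, wavenumbers))
    if len(wavenumbers) != len(pages):
        raise ValueError(f"{len(pages)} TIFF pages but {len(wavenumbers)} wavenumbers")
    bands = {wn: BandFrame(wn, page, pixel_size)
             for wn, page in zip(wavenumbers, pages)}
    labels = tifffile.imread(labels_path)
    gfp = tifffile.imread(gfp_path) if gfp_path is not None else None
    return WormImageSet(bands=bands, labels=labels, pixel_size=pixel_size,
                        gfp=gfp, worm_id=worm_id)


def read_image_set_from_manifest(manifest_path) -> WormImageSet:
    """Load a worm via its manifest; file paths resolve next to the manifest."""
    manifest = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    gfp = manifest.get("gfp_file")
    return read_image_set(
        root / manifest["bands_file"], root / manifest["labels_file"],
        manifest["band_wavenumbers_cm1"], float(manifest["pixel_size_um"]),
        gfp_path=(root / gfp) if gfp else None,
        worm_id=str(manifest.get("worm_id", "worm")),
    )


def records_to_frame(records: list[AccumulationRecord]) -> pd.DataFrame:
    rows = [{
        "worm_id": r.worm_id, "component_id": r.component_id, "area_um2": r.area,
        "mean_intensity": r.mean_intensity, "mean_ratio": r.mean_ratio,
        "centroid_row_um": r.centroid[0], "centroid_col_um": r.centroid[1],
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "worm_id", "component_id", "area_um2", "mean_intensity", "mean_ratio",
        "centroid_row_um", "centroid_col_um"])


def write_records(records: list[AccumulationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_assay_rows(rows: list[ReproductionAssayRow], path) -> None:
    pd.DataFrame([{
        "worm_id": r.worm_id, "initial_retained": r.initial_retained,
        "eggs_laid": r.eggs_laid, "final_retained": r.final_retained,
        "elapsed_h": r.elapsed, "gonad_arms": r.gonad_arms,
    } for r in rows]).to_csv(path, index=False)


def read_assay_rows(path) -> list[ReproductionAssayRow]:
    df = pd.read_csv(path)
    return [ReproductionAssayRow(
        worm_id=str(r.worm_id), initial_retained=int(r.initial_retained),
        eggs_laid=int(r.eggs_laid), final_retained=int(r.final_retained),
        elapsed=float(r.elapsed_h), gonad_arms=int(r.gonad_arms),
    ) for r in df.itertuples(index=False)]
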