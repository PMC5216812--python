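"""Readers and writers for the plain-text and raster formats the CLI uses.

Count matrices and clinical tables travel as TSV; images as multi-channel
16-bit TIFF (channel order: PAS, CD31) or single-channel TIFF/PNG; masks as
8-bit 0/255 PNG; ground truth and reports as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .expression import CountMatrix
from .synthetic_data import GroundTruthImage
from .survival import SurvivalRecord
from .vm_imaging import TwoChannelImage

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_two_channel_image",
    "write_image_bundle",
    "write_mask_png",
    "read_mask_png",
    "survival_records_from_clinical",
]

CLINICAL_COLUMNS = ["sample_id", "days", "event", "stage", "dsg2_cnv_amplified"]


def write_counts_tsv(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(df)


def write_clinical_tsv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "days", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required column(s): {missing}")
    return df


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_image_bundle(gt: GroundTruthImage, outdir: str | Path) -> dict:
    """Write a generated image as TIFF + mask PNGs + a JSON truth sidecar.

    Channels are scaled to the 16-bit range; the scale factor is recorded in
    the sidecar so intensities can be recovered exactly up to quantization.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img = gt.image
    peak = max(img.pas.max(), img.cd31.max(), 1e-12)
    scale = 65535.0 / peak
    stack = np.stack([img.pas, img.cd31])
    tifffile.imwrite(
        outdir / "image.tif", np.rint(stack * scale).astype(np.uint16)
    )
    write_mask_png(gt.true_network_mask, outdir / "true_network_mask.png")
    write_mask_png(gt.true_vessel_mask, outdir / "true_vessel_mask.png")
    write_mask_png(gt.true_tissue_mask, outdir / "true_tissue_mask.png")
    truth = {
        "true_vm_area_fraction": gt.true_vm_area_fraction,
        "intensity_scale": scale,
        "channel_order": ["pas", "cd31"],
    }
    if gt.spec is not None:
        truth["spec"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(gt.spec).items()
        }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path), dtype=float)
    return np.asarray(iio.imread(path), dtype=float)


def read_two_channel_image(
    pas_path: str | Path,
    cd31_path: str | Path | None = None,
    tissue_path: str | Path | None = None,
) -> TwoChannelImage:
    """Load a two-channel image.

    Either a single multi-channel TIFF (PAS first, CD31 second) or two
    single-channel files; an optional mask PNG supplies the tissue extent.
    """
    pas_path = Path(pas_path)
    arr = _read_raster(pas_path)
    if cd31_path is None:
        if arr.ndim != 3 or arr.shape[0] < 2:
            raise ValueError(
                f"{pas_path} is not a multi-channel stack and no cd31 file given"
            )
        pas, cd31 = arr[0], arr[1]
    else:
        if arr.ndim == 3:
            arr = arr[0]
        pas = arr
        cd31 = _read_raster(Path(cd31_path))
        if cd31.ndim == 3:
            cd31 = cd31[0]
    tissue = read_mask_png(tissue_path) if tissue_path is not None else None
    return TwoChannelImage(pas=pas, cd31=cd31, tissue_mask=tissue)


def survival_records_from_clinical(
    clinical: pd.DataFrame, groups: dict
) -> list[SurvivalRecord]:
    """Build records for the samples present in ``groups`` (label values
    'high'/'low' are kept, everything else ignored). Rows with missing or
    negative times are dropped."""
    records = []
    for row in clinical.itertuples(index=False):
        g = groups.get(row.sample_id)
        if g not in ("high", "low"):
            continue
        days = getattr(row, "days", None)
        if days is None or pd.isna(days) or days < 0:
            continue
        records.append(
            SurvivalRecord(
                sample_id=str(row.sample_id),
                time_days=float(days),
                event=bool(int(row.event)),
                group=g,
            )
        )
    return records
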