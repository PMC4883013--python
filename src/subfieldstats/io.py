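"""Readers and writers for the file formats the analyses touch.

Volume tables and pedigrees travel as UTF-8 CSV with a header row;
label images as NIfTI (.nii / .nii.gz).  A small parser for
FreeSurfer-style whitespace-delimited subfield stats text is included.

Missing data are handled complete-case per analysis: subjects lacking
any requested rater column are dropped (and the count logged), which is
the natural rule for paired designs.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    FormatError,
    InsufficientDataError,
    LabelVolume,
    MeasurementTable,
    Pedigree,
)

logger = logging.getLogger(__name__)

# v5.3 subfield volumes are reported on a 0.5 mm isotropic voxel basis;
# one such voxel is (0.5 mm)^3 = 1/8 mm^3.
HALFMM_VOXEL_DIVISOR = 8.0


def halfmm_to_mm3(value):
    """Convert a volume from 0.5-mm-isotropic voxel units to mm^3.

    A 0.5 mm isotropic voxel has volume (0.5 mm)^3, so voxel-basis
    volumes are divided by (1 mm / 0.5 mm)^3 = 8.

    Parameters
    ----------
    value : float or array-like
        Volume(s) in 0.5-mm voxel units; must be >= 0.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("volumes must be non-negative")
    out = arr / HALFMM_VOXEL_DIVISOR
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def read_volume_table(
    path: str | os.PathLike,
    region: str,
    rater_columns: list[str],
    subject_column: str = "subject_id",
) -> MeasurementTable:
    """Read a subjects x raters volume table for one region from CSV.

    Rows with any requested rater column missing are dropped
    (complete-case) and the number dropped is logged.

    Raises
    ------
    FormatError
        If a named column is absent.
    InsufficientDataError
        If fewer than 2 complete rows remain.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = [subject_column] + list(rater_columns)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    sub = df[needed]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info(
            "%s: dropped %d of %d subjects with incomplete rater columns",
            path, n_dropped, len(sub),
        )
    if len(complete) < 2:
        raise InsufficientDataError(
            f"{path}: only {len(complete)} complete rows; need at least 2"
        )
    return MeasurementTable(
        region_name=region,
        rater_labels=list(rater_columns),
        values=complete[list(rater_columns)].to_numpy(dtype=float),
        subject_ids=complete[subject_column].astype(str).tolist(),
    )


def write_volume_table(table: MeasurementTable, path: str | os.PathLike) -> None:
    """Write a measurement table to CSV (inverse of :func:`read_volume_table`)."""
    table.to_frame().reset_index().to_csv(path, index=False)


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read and validate a twin pedigree from CSV.

    Expected columns: individual_id, family_id, zygosity (MZ/DZ),
    sex (F/M), age (years).  Families that are not twin pairs, or rows
    with unknown zygosity/sex codes, raise :class:`FormatError`.
    """
    df = pd.read_csv(path)
    return Pedigree(df)


def write_pedigree(pedigree: Pedigree, path: str | os.PathLike) -> None:
    pedigree.table.to_csv(path, index=False)


def read_label_volume(
    path: str | os.PathLike,
    label_map: Mapping[int, str] | None = None,
) -> LabelVolume:
    """Read a 3-D integer label image from NIfTI.

    Voxel sizes are taken from the header.  Images stored with a
    floating-point on-disk dtype are rejected: a segmentation is a
    label field, and float storage signals the wrong kind of input.
    """
    img = nib.load(str(path))
    disk_dtype = img.get_data_dtype()
    if not np.issubdtype(disk_dtype, np.integer):
        raise FormatError(
            f"{path}: label images must be integer-valued, got dtype {disk_dtype}"
        )
    data = np.asanyarray(img.dataobj).astype(np.int32)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    return LabelVolume(
        grid=data,
        voxel_size=tuple(float(z) for z in zooms),
        label_map=dict(label_map) if label_map else {},
    )


def write_label_volume(volume: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label volume as NIfTI with voxel sizes in the affine."""
    affine = np.diag(list(volume.voxel_size) + [1.0])
    img = nib.Nifti1Image(volume.grid.astype(np.int16), affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


def read_freesurfer_stats(path: str | os.PathLike) -> dict[str, float]:
    """Parse FreeSurfer-style subfield stats text: one 'region volume'
    pair per line, whitespace-delimited, '#' comments ignored."""
    volumes: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'region volume', got {line!r}"
                )
            name, value = parts
            try:
                volumes[name] = float(value)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: volume is not a number: {value!r}"
                ) from exc
    return volumes


def bilateral_average(
    records: pd.DataFrame,
    subject_column: str = "subject_id",
    region_column: str = "region",
    hemisphere_column: str = "hemisphere",
    volume_column: str = "volume",
) -> pd.DataFrame:
    """Average left and right hemisphere volumes per subject and region.

    Input is a long table with one row per (subject, region,
    hemisphere).  Output has one row per (subject, region) with
    volume = (left + right) / 2; subjects missing either hemisphere for
    a region are dropped.
    """
    hemis = set(records[hemisphere_column].unique())
    unknown = hemis - {"left", "right"}
    if unknown:
        raise FormatError(f"unknown hemisphere label(s): {sorted(unknown)}")
    wide = records.pivot_table(
        index=[subject_column, region_column],
        columns=hemisphere_column,
        values=volume_column,
    )
    if "left" not in wide.columns or "right" not in wide.columns:
        raise FormatError("both 'left' and 'right' hemisphere records are required")
    wide = wide.dropna(subset=["left", "right"])
    out = wide.assign(volume=(wide["left"] + wide["right"]) / 2.0)
    return out[["volume"]].reset_index()


def wide_volume_frame(
    tables: Iterable[MeasurementTable],
) -> pd.DataFrame:
    """Stack single-region tables into a subjects x regions frame of the
    first rater column (helper for region-keyed pipelines)."""
    cols = {}
    for t in tables:
        cols[t.region_name] = pd.Series(
            t.values[:, 0], index=pd.Index(t.subject_ids, name="subject_id")
        )
    return pd.DataFrame(cols)
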