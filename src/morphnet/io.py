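"""Readers and writers: NIfTI volumes at ingest, tab-separated text elsewhere.

All tabular artifacts are diff-able TSV with 10-significant-digit numeric
formatting; similarity matrices carry region labels as header row and
column and are symmetry-checked on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .network import SimilarityMatrix

logger = logging.getLogger("morphnet")

FLOAT_FORMAT = "%.10g"


class IOError_(ValueError):
    pass


class AlignmentError(IOError_):
    pass


class LabelError(IOError_):
    pass


class IntegrityError(IOError_):
    pass


def read_gm_and_atlas(gm_path, atlas_path):
    """Load a GM map and its parcellation atlas from NIfTI.

    Both must share the voxel grid and affine; atlas values must be
    integers.  Returns ``(gm array, int atlas array, affine)``.
    """
    gm_img = nib.load(str(gm_path))
    atlas_img = nib.load(str(atlas_path))
    gm = np.asarray(gm_img.get_fdata())
    atlas = np.asarray(atlas_img.get_fdata())
    if gm.shape != atlas.shape:
        raise AlignmentError(
            f"GM shape {gm.shape} != atlas shape {atlas.shape}"
        )
    if not np.allclose(gm_img.affine, atlas_img.affine, atol=1e-6):
        raise AlignmentError("GM and atlas affines differ")
    if not np.all(atlas == np.round(atlas)):
        raise LabelError("atlas contains non-integer labels")
    atlas = atlas.astype(int)
    labels = np.unique(atlas[atlas > 0])
    logger.info(
        "atlas census: %d regions, %d labelled voxels",
        labels.size,
        int((atlas > 0).sum()),
    )
    return gm, atlas, gm_img.affine


def write_nifti(volume: np.ndarray, path, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def write_matrix(matrix: SimilarityMatrix, path) -> None:
    """Write a similarity matrix as labelled TSV (10 significant digits)."""
    labels = [f"R{r}" for r in matrix.region_ids]
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="region")


def read_matrix(path, subject_id: str = "") -> SimilarityMatrix:
    """Read a matrix written by :func:`write_matrix`, revalidating symmetry."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise IntegrityError(f"{path}: matrix not square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise IntegrityError(f"{path}: matrix not symmetric")
    values = (values + values.T) / 2  # remove formatting round-off
    region_ids = [int(str(c).lstrip("R")) for c in df.columns]
    sid = subject_id or Path(path).stem
    return SimilarityMatrix(values=values, subject_id=sid, region_ids=region_ids)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_matrix_dir(matrices_dir) -> list[SimilarityMatrix]:
    """All ``*.tsv`` matrices of a directory, sorted by file name."""
    paths = sorted(Path(matrices_dir).glob("*.tsv"))
    if not paths:
        raise IOError_(f"no matrix TSVs under {matrices_dir}")
    return [read_matrix(p) for p in paths]
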