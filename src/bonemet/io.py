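"""Readers and writers for the pipeline's on-disk formats.

Formats: expression TSV (genes as rows, first column the gene id) with a
sidecar sample->group TSV; 8-bit grayscale PNG/TIFF images and masks;
variant TSV (see :mod:`bonemet.variants`); tidy times CSV (group, time_s);
gene-score TSV and model-summary JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .axis import ExpressionMatrix, MetastasisAxisResults


def write_expression_tsv(
    X: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path
) -> None:
    X.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    X.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample_id")


def read_expression_tsv(
    matrix_path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample_id")["group"]
    return ExpressionMatrix(values, groups)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0,1] or boolean array as 8-bit grayscale."""
    if image.dtype == bool:
        data = (image * 255).astype(np.uint8)
    else:
        data = (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8)
    iio.imwrite(Path(path), data)


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as float grayscale in [0, 1] (RGB is averaged)."""
    data = np.asarray(iio.imread(Path(path)), dtype=float)
    if data.ndim == 3:
        data = data.mean(axis=2)
    peak = 65535.0 if data.max() > 255 else 255.0
    return data / peak


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0.5


def write_times_csv(times: pd.DataFrame, path: str | Path) -> None:
    times.to_csv(path, index=False)


def read_times_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"group", "time_s"} <= set(df.columns):
        raise ValueError("times CSV needs columns 'group' and 'time_s'")
    return df


def write_variant_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["allele_freq"] = out["allele_freq"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)


def write_scores_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="gene_id")


def write_model_json(results: MetastasisAxisResults, path: str | Path) -> None:
    payload = {
        "singular_values": results.singular_values.tolist(),
        "variance_explained": results.variance_explained.tolist(),
        "axis": results.axis.tolist(),
        "axis_angle_deg": results.axis_angle_deg,
        "centroids": {
            g: row.tolist() for g, row in results.centroids.iterrows()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
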