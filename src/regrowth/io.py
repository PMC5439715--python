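"""Plain-text table I/O for the package's data schemas.

Everything is tab-separated with a header row. Expression studies are a
pair of files: a genes x samples matrix TSV (index column ``gene``) and a
samples metadata TSV (columns sample_id, dose_gy, day, replicate, batch).
Dye intensities are one value per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ExpressionStudy

__all__ = [
    "write_table",
    "read_table",
    "write_expression_study",
    "read_expression_study",
    "write_intensities",
    "read_intensities",
]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_study(study: ExpressionStudy, matrix_path, samples_path):
    matrix_path, samples_path = Path(matrix_path), Path(samples_path)
    matrix_path.parent.mkdir(parents=True, exist_ok=True)
    study.matrix.rename_axis("gene").to_csv(matrix_path, sep="\t")
    study.samples.to_csv(samples_path, sep="\t", index=False)
    return matrix_path, samples_path


def read_expression_study(matrix_path, samples_path, log_scale: bool = False) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    samples = pd.read_csv(samples_path, sep="\t")
    return ExpressionStudy(matrix=matrix, samples=samples, log_scale=log_scale)


def write_intensities(values, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.8g")
    return path


def read_intensities(path) -> np.ndarray:
    return np.loadtxt(path, dtype=float).ravel()
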