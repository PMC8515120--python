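"""Plain-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .nmr import SpectraMatrix, FeatureTable

__all__ = [
    "read_spectra_tsv",
    "write_spectra_tsv",
    "read_sample_table",
    "read_feature_csv",
    "write_feature_csv",
]


def write_spectra_tsv(spectra: SpectraMatrix, path) -> None:
    """Wide TSV: header row is the ppm axis, rows are subjects."""
    df = pd.DataFrame(
        spectra.intensities,
        index=pd.Index(spectra.subject_ids, name="sample_id"),
        columns=[f"{v:.6f}" for v in spectra.ppm],
    )
    df.to_csv(path, sep="\t")


def read_spectra_tsv(path) -> SpectraMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ppm = np.array([float(c) for c in df.columns])
    return SpectraMatrix(
        ppm=ppm, intensities=df.to_numpy(dtype=float), subject_ids=[str(i) for i in df.index]
    )


def read_sample_table(path, sep: str | None = None) -> pd.DataFrame:
    """KO/genus/clinical table with sample ids in the first column."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def write_feature_csv(features: FeatureTable, path) -> None:
    out = features.values.copy()
    out.columns = [
        f"{cid}@{features.metadata.loc[cid, 'apex_ppm']:.4f}" for cid in out.columns
    ]
    out.to_csv(path, index_label="sample_id")


def read_feature_csv(path) -> FeatureTable:
    df = pd.read_csv(path, index_col=0)
    ids, apex = [], []
    for col in df.columns:
        cid, _, ppm = col.partition("@")
        ids.append(cid)
        apex.append(float(ppm) if ppm else np.nan)
    df.columns = ids
    meta = pd.DataFrame({"apex_ppm": apex}, index=pd.Index(ids, name="cluster_id"))
    return FeatureTable(values=df, metadata=meta)
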