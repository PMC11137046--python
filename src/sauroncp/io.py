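"""Delimited-text readers and writers for all pipeline inputs and outputs.

Conventions: tables are comma-delimited with a header row; feature matrices
are samples-in-rows with the sample id in the first column (matrices stored
genes-in-rows, as expression portals ship them, can be transposed on load
with ``transpose=True``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .data import FeatureMatrix, ResponseBundle, SplitSpec

__all__ = [
    "read_feature_matrix", "write_feature_matrix",
    "read_response", "write_response",
    "read_split", "write_split",
    "read_dose_response", "read_cmax_table",
    "read_config",
]


def read_feature_matrix(path, transpose: bool = False) -> FeatureMatrix:
    """First column sample id, header row feature ids; no missing values."""
    df = pd.read_csv(path, index_col=0)
    if transpose:
        df = df.T
    if df.isna().any().any():
        raise ValueError(f"feature matrix {path} contains missing values")
    return FeatureMatrix(df.to_numpy(dtype=float), df.index.tolist(),
                         df.columns.tolist())


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    pd.DataFrame(fm.values, index=pd.Index(fm.sample_ids, name="sample_id"),
                 columns=fm.feature_ids).to_csv(path)


def read_response(path) -> tuple[list, ResponseBundle]:
    """Columns: sample_id, y, d [, threshold_1 ... on the first row only]."""
    df = pd.read_csv(path)
    thresh_cols = [c for c in df.columns if c.startswith("threshold_")]
    thresholds = (df.loc[0, thresh_cols].to_numpy(dtype=float)
                  if thresh_cols else None)
    labels = tuple(int(v) for v in df.attrs.get("labels", ())) or None
    d = df["d"].to_numpy(dtype=int)
    y = df["y"].to_numpy(dtype=float)
    if thresholds is not None:
        bundle = ResponseBundle.from_continuous(y, thresholds)
        if not np.array_equal(bundle.d, d):
            raise ValueError(f"discrete response in {path} does not match its thresholds")
    else:
        labels_asc = tuple(sorted(set(d.tolist())))
        bundle = ResponseBundle(y, d, labels_asc, None)
    return df["sample_id"].tolist(), bundle


def write_response(sample_ids, bundle: ResponseBundle, path) -> None:
    df = pd.DataFrame({"sample_id": sample_ids, "y": bundle.y, "d": bundle.d})
    if bundle.thresholds is not None:
        for j, t in enumerate(bundle.thresholds, start=1):
            df[f"threshold_{j}"] = [t] + [np.nan] * (len(df) - 1)
    df.to_csv(path, index=False)


def read_split(path, alpha: float = 0.1) -> SplitSpec:
    """Columns: sample_id, part (train/calibration/test)."""
    df = pd.read_csv(path)
    parts = {p: df.loc[df["part"] == p, "sample_id"].tolist()
             for p in ("train", "calibration", "test")}
    return SplitSpec(parts["train"], parts["calibration"], parts["test"], alpha)


def write_split(split: SplitSpec, path) -> None:
    rows = ([{"sample_id": s, "part": "train"} for s in split.train_ids]
            + [{"sample_id": s, "part": "calibration"} for s in split.cal_ids]
            + [{"sample_id": s, "part": "test"} for s in split.test_ids])
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dose_response(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"drug", "cell_line", "concentration_uM", "viability"}
    if not required <= set(df.columns):
        raise ValueError(f"dose-response table {path} must have columns {sorted(required)}")
    return df


def read_cmax_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"drug", "cmax_uM"} <= set(df.columns):
        raise ValueError(f"CMax table {path} must have columns drug, cmax_uM")
    if (df["cmax_uM"] <= 0).any():
        raise ValueError("CMax concentrations must be strictly positive")
    return df


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
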