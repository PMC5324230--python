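"""Readers and writers for every table the pipeline touches.

All interchange is tab-separated UTF-8 with a header row; beta and
detection matrices use probes as rows and samples as columns (the common
450K export layout).  Missing values are encoded ``NA``.  Probes carrying
any NA beta are dropped at read time with a logged count, since downstream
statistics assume complete rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError

logger = logging.getLogger("methylgc")

FLOAT_FORMAT = "%.6g"


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            probe = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"{path}: non-numeric cell at probe {probe!r}, sample {col!r}"
            )
    return df.astype(float)


def read_beta_matrix(path, detection_path=None) -> BetaMatrix:
    """Read a probe x sample beta TSV (and optional aligned detection TSV).

    Probes with any missing beta are excluded with a logged count.  A
    detection matrix must carry identical probe and sample labels.
    """
    values = _read_matrix(path)
    n_na = int(values.isna().any(axis=1).sum())
    if n_na:
        logger.info("dropping %d probes with missing beta-values", n_na)
        values = values.dropna(axis=0)
    detection = None
    if detection_path is not None:
        detection = _read_matrix(detection_path)
        if not (set(values.index) <= set(detection.index)
                and list(detection.columns) == list(values.columns)):
            raise ValidationError(
                f"detection table {detection_path} labels do not match "
                f"beta table {path}"
            )
        detection = detection.loc[values.index]
    return BetaMatrix(values, detection)


def write_beta_matrix(beta: BetaMatrix, path, detection_path=None) -> None:
    beta.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                       index_label="probe_id")
    if detection_path is not None and beta.detection_p is not None:
        beta.detection_p.to_csv(detection_path, sep="\t",
                                float_format=FLOAT_FORMAT,
                                index_label="probe_id")


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     dtype={"gene_symbols": str})
    df["gene_symbols"] = df["gene_symbols"].fillna("")
    if df["snp_flag"].dtype == object:
        df["snp_flag"] = df["snp_flag"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
    return ProbeAnnotation(df)


def write_probe_annotation(annot: ProbeAnnotation, path) -> None:
    annot.df.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> SampleSheet:
    """Read and validate the per-sample metadata TSV.

    Unknown columns are preserved as opaque extras.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    known = set(SampleSheet.REQUIRED) | {"gc_subgroup", "onset"}
    extras = [c for c in df.columns
              if c not in known and not c.startswith("cellprop_")]
    return SampleSheet(df, extras=extras)


def write_sample_sheet(samples: SampleSheet, path) -> None:
    samples.df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                      index_label="sample_id")


def read_assay_table(path) -> pd.DataFrame:
    """Read the dexamethasone assay plate table.

    One row per subject with triplicate optical densities per condition:
    ``control_od_1..3``, ``stimulated_od_1..3``, ``suppressed_od_1..3``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    required = [f"{cond}_od_{i}" for cond in
                ("control", "stimulated", "suppressed") for i in (1, 2, 3)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"assay table missing columns: {missing}")
    if (df[required] < 0).any().any():
        raise ValidationError("optical densities must be non-negative")
    return df.astype(float)


def write_assay_table(assay: pd.DataFrame, path) -> None:
    assay.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                 index_label="sample_id")


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    """Write a generic stage-output table with the pipeline float format."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index=index_label is not None, index_label=index_label,
              na_rep="NA")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
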