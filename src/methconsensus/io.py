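"""Readers and writers for the pipeline's tabular dialects.

Beta matrix: TSV, first column probe id, header row of sample ids.
Annotation: CSV indexed by probe_id; detection p-values live in a
companion TSV (probes x samples). Sample sheets, cohort tables and result
tables: CSV with header. All writers emit UTF-8 with "\\n" newlines.

Out-of-range beta cells (<=0 or >=1) are clamped to (1e-6, 1-1e-6) at
load time, with the clamp count logged and returned.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BETA_CEIL, BETA_FLOOR, BetaMatrix, ProbeAnnotation

log = logging.getLogger(__name__)


def clamp_beta(values: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Clamp values into (1e-6, 1-1e-6); returns (clamped, n_clamped)."""
    arr = values.to_numpy(dtype=float)
    out_of_range = (arr <= 0.0) | (arr >= 1.0)
    n = int(out_of_range.sum())
    if n:
        arr = np.clip(arr, BETA_FLOOR, BETA_CEIL)
        log.warning("clamped %d out-of-range beta values into (1e-6, 1-1e-6)", n)
    return pd.DataFrame(arr, index=values.index, columns=values.columns), n


def _read_table(path, sep, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    first = df.columns[0]
    if df[first].duplicated().any():
        dup = df.loc[df[first].duplicated(), first].iloc[0]
        raise ValueError(f"duplicate {index_col} '{dup}' in {path}")
    df = df.set_index(first)
    df.index.name = index_col
    return df


def read_beta_matrix(path) -> BetaMatrix:
    df = _read_table(path, "\t", "probe_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in beta matrix {path}: {exc}") from exc
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"missing/non-numeric value in beta matrix {path} at "
            f"probe {df.index[row]}, sample {df.columns[col]}")
    values, _ = clamp_beta(df)
    return BetaMatrix(values)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    _write_df(beta.values, path, sep="\t", index_label="probe_id")


def read_annotation(path, detection_p_path=None) -> ProbeAnnotation:
    tab = _read_table(path, ",", "probe_id")
    tab["island_flag"] = tab["island_flag"].astype(bool)
    tab["sex_chrom_flag"] = tab["sex_chrom_flag"].astype(bool)
    tab["snp_maf"] = pd.to_numeric(tab["snp_maf"], errors="coerce")
    detection = None
    if detection_p_path is not None:
        detection = _read_table(detection_p_path, "\t", "probe_id").astype(float)
    return ProbeAnnotation(tab, detection_p=detection)


def write_annotation(annot: ProbeAnnotation, path, detection_p_path=None) -> None:
    tab = annot.table.copy()
    if annot.nearest_gene is not None and "nearest_gene" not in tab.columns:
        tab["nearest_gene"] = annot.nearest_gene
    _write_df(tab, path, sep=",", index_label="probe_id")
    if detection_p_path is not None and annot.detection_p is not None:
        _write_df(annot.detection_p, detection_p_path, sep="\t",
                  index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    return _read_table(path, ",", "sample_id")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    _write_df(sheet, path, sep=",", index_label="sample_id")


def read_cohort(path) -> pd.DataFrame:
    return _read_table(path, ",", "patient_id")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    _write_df(cohort, path, sep=",", index_label="patient_id")


def write_result_table(df: pd.DataFrame, path, sep: str = "\t",
                       index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep=sep, index=index)


def export_probes_bed(annot: ProbeAnnotation, positions: pd.DataFrame, path) -> None:
    """Write probe positions as BED (0-based, half-open).

    ``positions`` must carry columns chrom, start, end indexed by probe id.
    """
    bed = positions[["chrom", "start", "end"]].copy()
    bed["name"] = positions.index
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        bed.to_csv(fh, sep="\t", header=False, index=False)


def _write_df(df: pd.DataFrame, path, sep: str, index_label: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep=sep, index=True, index_label=index_label)
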