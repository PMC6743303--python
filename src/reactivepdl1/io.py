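"""Tabular IO and TCGA-style barcode parsing.

Three table types flow through the pipeline, all plain delimited text:

* expression matrix — genes in rows, samples in columns, log2-scale values
  (log2 FPKM for RNAseq, log2 intensity for arrays); missing cells are not
  permitted, raw FPKM should be transformed as ``log2(FPKM + 1)`` upstream;
* clinical table — one row per sample with ``sample_id``, ``time`` (positive
  follow-up time), ``event`` (1 = death/event observed, 0 = censored) and a
  ``cohort`` label;
* copy-number table — per-sample GISTIC-thresholded calls, integer codes in
  {-2, -1, 0, 1, 2} (2 = high-level amplification, -2 = deep deletion).

TSV is the canonical dialect; a ``delimiter`` argument admits CSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import BarcodeParseError, FormatError, ValidationError

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("sample_id", "time", "event", "cohort")
CNV_COLUMNS = ("sample_id", "code")
GISTIC_CODES = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-sample follow-up: positive time, 0/1 event flag, cohort label."""

    sample_id: str
    time: float
    event: int
    cohort: str


@dataclass(frozen=True)
class CnvCall:
    """GISTIC-thresholded copy-number call for one sample."""

    sample_id: str
    code: int

    @property
    def amplified(self) -> bool:
        return self.code == 2

    @property
    def deleted(self) -> bool:
        return self.code == -2


@dataclass(frozen=True)
class Barcode:
    """Parsed TCGA sample barcode.

    ``TCGA-AB-1234-01A-11R-XXXX-07`` splits into patient ``TCGA-AB-1234``,
    sample code ``01``, vial ``A`` and portion ``11``.  Two barcodes with the
    same patient and sample code but different portion codes denote different
    physical portions of the same tumor.
    """

    raw: str
    patient_id: str
    sample_code: str
    vial: str
    portion: str

    @property
    def portion_key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.sample_code, self.portion)


def _find_duplicates(items) -> list[str]:
    seen, dups = set(), []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


def read_expression_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    First row holds sample ids, first column gene ids, body is numeric and
    complete. Duplicate ids and non-numeric or missing cells raise
    :class:`FormatError` naming the offender; row/column order is preserved.
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=delimiter))
    sample_ids = header[1:]
    dups = _find_duplicates(sample_ids)
    if dups:
        raise FormatError(f"duplicate sample id(s) in {path}: {dups}")
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.columns = sample_ids
    dups = _find_duplicates(raw.index.tolist())
    if dups:
        raise FormatError(f"duplicate gene id(s) in {path}: {dups}")
    def _to_float(cell):  # correctly-rounded strtod; NaN marks bad cells
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    values = raw.map(_to_float)
    bad = ~np.isfinite(values.to_numpy(dtype=float)) | raw.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-numeric or missing cell at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    expr = values.astype(float)
    expr.index = expr.index.astype(str)
    expr.index.name = "gene_id"
    logger.info("read expression matrix %s: %d genes x %d samples",
                path, *expr.shape)
    return expr


def write_expression_matrix(expr: pd.DataFrame, path, delimiter: str = "\t") -> None:
    validate_expression(expr)
    # %.17g guarantees bit-exact float round-trips through text
    expr.to_csv(path, sep=delimiter, index_label="gene_id",
                float_format="%.17g")


def validate_expression(expr: pd.DataFrame) -> None:
    """Enforce the expression-matrix invariants on an in-memory frame."""
    if expr.index.has_duplicates:
        raise FormatError(f"duplicate gene id(s): {_find_duplicates(expr.index)}")
    if expr.columns.has_duplicates:
        raise FormatError(f"duplicate sample id(s): {_find_duplicates(expr.columns)}")
    if not np.all(np.isfinite(expr.to_numpy(dtype=float))):
        raise ValidationError("expression matrix contains non-finite values")


def read_clinical(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a clinical survival table (sample_id, time, event, cohort).

    Columns are matched by header name in any order. Rows with missing time
    or event are dropped and counted in the log; negative/zero times and
    event values outside {0, 1} raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table {path} lacks column(s) {missing}")
    df = df.loc[:, list(CLINICAL_COLUMNS)]
    n_before = len(df)
    df = df.dropna(subset=["time", "event"]).reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("clinical table %s: dropped %d row(s) with missing "
                    "time/event", path, n_dropped)
    df["sample_id"] = df["sample_id"].astype(str)
    df["cohort"] = df["cohort"].astype(str)
    df["time"] = df["time"].astype(float)
    if (df["time"] <= 0).any():
        bad = df.loc[df["time"] <= 0, "sample_id"].iloc[0]
        raise ValidationError(f"non-positive follow-up time for sample {bad!r}")
    ev = df["event"].astype(float)
    if not ev.isin([0.0, 1.0]).all():
        bad = df.loc[~ev.isin([0.0, 1.0]), "sample_id"].iloc[0]
        raise ValidationError(f"event flag outside {{0,1}} for sample {bad!r}")
    df["event"] = ev.astype(int)
    logger.info("read clinical table %s: %d records", path, len(df))
    return df


def write_clinical(clinical: pd.DataFrame, path, delimiter: str = "\t") -> None:
    clinical.loc[:, list(CLINICAL_COLUMNS)].to_csv(path, sep=delimiter, index=False)


def read_cnv(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read per-sample GISTIC-thresholded copy-number calls."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in CNV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"CNV table {path} lacks column(s) {missing}")
    df = df.loc[:, list(CNV_COLUMNS)]
    df["sample_id"] = df["sample_id"].astype(str)
    df["code"] = df["code"].astype(int)
    if not df["code"].isin(GISTIC_CODES).all():
        bad = df.loc[~df["code"].isin(GISTIC_CODES)].iloc[0]
        raise ValidationError(
            f"CNV code {bad['code']} for sample {bad['sample_id']!r} outside "
            f"the GISTIC five-level set {GISTIC_CODES}"
        )
    return df


def write_cnv(cnv: pd.DataFrame, path, delimiter: str = "\t") -> None:
    cnv.loc[:, list(CNV_COLUMNS)].to_csv(path, sep=delimiter, index=False)


def parse_barcode(raw: str) -> Barcode:
    """Parse a TCGA-style sample barcode into its fixed-width fields.

    Requires at least four dash-separated fields with field 4 carrying the
    two-character sample code plus one-character vial. The portion code is
    the first two characters of field 5 when present (empty otherwise;
    portion-level operations require it).
    """
    fields = raw.split("-")
    if len(fields) < 4:
        raise BarcodeParseError(f"barcode {raw!r} has fewer than 4 fields")
    if len(fields[3]) < 3:
        raise BarcodeParseError(
            f"barcode {raw!r}: field 4 ({fields[3]!r}) shorter than sample+vial"
        )
    portion = fields[4][:2] if len(fields) > 4 and len(fields[4]) >= 2 else ""
    return Barcode(
        raw=raw,
        patient_id="-".join(fields[:3]),
        sample_code=fields[3][:2],
        vial=fields[3][2],
        portion=portion,
    )


def load_config(path) -> dict:
    """Load a flat key-value YAML config mirroring the CLI flags."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} is not a flat key-value document")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
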