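"""Readers and writers for the pipeline's on-disk formats.

Counts travel as Matrix Market (1-based on disk, 0-based in memory)
plus sidecar gene/cell lists; metadata, annotation and PSI tables are
TSV with a header row; reports are JSON with sorted keys.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .types import (
    STAGE_ORDER,
    AnalysisConfig,
    CountMatrix,
    EVENT_TYPES,
    FormatError,
    SchemaError,
    ValidationError,
)

_LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def get_logger(name: str = "spermseq") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


log = get_logger(__name__)


# ---------------------------------------------------------------------------
# count matrices

def read_count_matrix(mtx_path, genes_path, cells_path) -> CountMatrix:
    """Read an MTX + genes.tsv + cells.tsv triple into a CountMatrix.

    Spike-in rows are inferred from the ``ERCC-`` gene-id prefix.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except ValueError as exc:
        raise FormatError(f"invalid Matrix Market file {mtx_path}: {exc}") from exc
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    if mat.data.size and not np.issubdtype(mat.dtype, np.integer):
        if np.any(mat.data != np.floor(mat.data)):
            raise ValidationError(f"non-integer entries in {mtx_path}")
    return CountMatrix(genes=genes, cells=cells, counts=mat.astype(np.int64))


def write_count_matrix(cm: CountMatrix, mtx_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts))
    Path(genes_path).write_text("".join(f"{g}\n" for g in cm.genes))
    Path(cells_path).write_text("".join(f"{c}\n" for c in cm.cells))


def _read_id_column(path) -> list[str]:
    lines = [ln.split("\t")[0].strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln]
    if not ids:
        raise FormatError(f"empty id list {path}")
    return ids


# ---------------------------------------------------------------------------
# typed tables

CELL_META_COLUMNS = ("cell_id", "stage", "mapping_rate", "batch")
GENE_ANNOTATION_COLUMNS = ("gene_id", "chromosome", "biotype")
PSI_KEY_COLUMNS = ("gene_id", "event_id", "event_type")

_BIOTYPES = ("protein_coding", "lncRNA", "spike_in")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV into a validated typed table.

    ``schema`` is one of ``cell_meta``, ``gene_annotation``, ``psi``.
    Unknown columns are preserved untouched.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_table(df, schema)


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    if schema == "cell_meta":
        return _validate_cell_meta(df)
    if schema == "gene_annotation":
        return _validate_gene_annotation(df)
    if schema == "psi":
        return _validate_psi(df)
    raise SchemaError(f"unknown table schema {schema!r}")


def _require(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required columns {missing}")


def _validate_cell_meta(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, CELL_META_COLUMNS, "cell metadata")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"duplicate cell_id {dup!r} in cell metadata")
    bad = set(df["stage"]) - set(STAGE_ORDER)
    if bad:
        raise ValidationError(f"unknown stage codes {sorted(bad)} in cell metadata")
    rates = df["mapping_rate"].to_numpy(dtype=float)
    if np.any(~np.isfinite(rates)) or np.any(rates < 0) or np.any(rates > 1):
        raise ValidationError("mapping_rate must be a fraction in [0, 1]")
    return df


def _validate_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, GENE_ANNOTATION_COLUMNS, "gene annotation")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r} in annotation")
    bad = set(df["biotype"]) - set(_BIOTYPES)
    if bad:
        raise ValidationError(f"unknown biotypes {sorted(bad)}")
    spike = df["biotype"] == "spike_in"
    ercc = df["chromosome"] == "ERCC"
    if not (spike == ercc).all():
        raise ValidationError("biotype spike_in must coincide with chromosome 'ERCC'")
    for flag in ("is_tf", "is_splicing_regulator", "is_surface_marker"):
        if flag not in df.columns:
            df[flag] = False
        df[flag] = df[flag].astype(bool)
    return df


def _validate_psi(df: pd.DataFrame) -> pd.DataFrame:
    _require(df, PSI_KEY_COLUMNS, "PSI event")
    bad = set(df["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValidationError(f"unknown AS event types {sorted(bad)}")
    if df.duplicated(subset=["gene_id", "event_id"]).any():
        raise ValidationError("event_id must be unique within gene in the PSI table")
    for sample in psi_samples(df):
        psi = df[f"{sample}.psi"].to_numpy(dtype=float)
        cov = df[f"{sample}.cov"].astype(bool).to_numpy()
        vals = psi[cov]
        if vals.size and (np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 100)):
            raise ValidationError(
                f"PSI values for sample {sample!r} outside [0, 100] where coverage is sufficient"
            )
    return df


def psi_samples(df: pd.DataFrame) -> list[str]:
    """Sample names of a PSI table (columns come in '<s>.psi'/'<s>.cov' pairs)."""
    samples = [c[:-4] for c in df.columns if c.endswith(".psi")]
    for s in samples:
        if f"{s}.cov" not in df.columns:
            raise SchemaError(f"PSI table has {s}.psi but no {s}.cov coverage column")
    return samples


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reports & config

def write_report(report: Mapping, path) -> None:
    """Serialize a (possibly nested) report to JSON with stable key order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_plain(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (list, tuple, set, np.ndarray)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(AnalysisConfig().__dict__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)


def save_config(cfg: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
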