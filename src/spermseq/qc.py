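"""Cell quality control, spike-in normalization, and expression transforms.

QC keeps a cell only if its mapping rate exceeds 40%, it detects more
than 2,000 genes (a gene counts as detected when its UMI count is
strictly greater than 1), and its endogenous UMI total lies in
[20,000, 1,000,000].  Technical depth differences are corrected with
ERCC spike-in size factors: each cell's factor is its spike-in total
divided by the mean spike-in total, so factors average to one.

Two distinct detection rules coexist deliberately: QC detection is
UMI > 1; expression analyses downstream call a gene expressed in a cell
when TPM >= 1.  They are never conflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import get_logger
from .types import (
    CountMatrix,
    ExpressionMatrix,
    NormalizationError,
    ValidationError,
)

log = get_logger(__name__)


@dataclass
class QcThresholds:
    min_mapping_rate: float = 0.40   # exclusive
    min_genes_detected: int = 2000   # exclusive
    umi_min: int = 20_000            # inclusive
    umi_max: int = 1_000_000         # inclusive

    def __post_init__(self) -> None:
        if self.umi_min >= self.umi_max:
            raise ValidationError("umi_min must be below umi_max")


def genes_detected(cell_counts: np.ndarray) -> int:
    """Number of detected genes in one cell: UMI count strictly > 1."""
    return int(np.count_nonzero(np.asarray(cell_counts) > 1))


def qc_filter(
    cm: CountMatrix,
    cell_meta: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three-standard cell filter.

    Returns the kept cell ids (matrix order) and a table of rejected
    cells naming every failed criterion.  UMI totals and detection
    counts are computed over endogenous (non-spike) genes only.
    """
    thr = thresholds or QcThresholds()
    meta = cell_meta.set_index("cell_id")
    missing = [c for c in cm.cells if c not in meta.index]
    if missing:
        raise ValidationError(f"cells without metadata: {missing[:5]}")
    if meta["mapping_rate"].isna().any():
        raise ValidationError("mapping_rate missing for some cells")

    endo = cm.counts[cm.nonspike_mask()]
    totals = np.asarray(endo.sum(axis=0)).ravel()
    detected = np.asarray((endo > 1).sum(axis=0)).ravel()

    kept: list[str] = []
    rejected: list[dict] = []
    for j, cell in enumerate(cm.cells):
        reasons = []
        if not meta.at[cell, "mapping_rate"] > thr.min_mapping_rate:
            reasons.append("mapping_rate")
        if not detected[j] > thr.min_genes_detected:
            reasons.append("genes_detected")
        if not (thr.umi_min <= totals[j] <= thr.umi_max):
            reasons.append("umi_total")
        if reasons:
            rejected.append(
                {
                    "cell_id": cell,
                    "mapping_rate": float(meta.at[cell, "mapping_rate"]),
                    "genes_detected": int(detected[j]),
                    "umi_total": int(totals[j]),
                    "reasons": ";".join(reasons),
                }
            )
        else:
            kept.append(cell)
    rej = pd.DataFrame(
        rejected,
        columns=["cell_id", "mapping_rate", "genes_detected", "umi_total", "reasons"],
    )
    log.info("QC kept %d/%d cells", len(kept), cm.n_cells)
    return kept, rej


def spike_size_factors(cm: CountMatrix) -> pd.Series:
    """Per-cell spike-in size factors: spike total / mean spike total."""
    if cm.spike_rows.size == 0:
        raise NormalizationError("count matrix has no spike-in rows")
    spike_totals = np.asarray(cm.counts[cm.spike_rows].sum(axis=0), dtype=float).ravel()
    zero = np.flatnonzero(spike_totals == 0)
    if zero.size:
        raise NormalizationError(
            f"zero spike-in total in cell(s) {[cm.cells[i] for i in zero[:5]]}"
        )
    factors = spike_totals / spike_totals.mean()
    return pd.Series(factors, index=cm.cells, name="size_factor")


def normalize_counts(
    cm: CountMatrix, factors: pd.Series, *, log2: bool = False
) -> ExpressionMatrix:
    """Divide each cell's counts by its size factor; optionally log2(x+1)."""
    f = factors.reindex(cm.cells).to_numpy(dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValidationError("size factors must be positive for every cell")
    values = cm.counts.toarray().astype(float) / f[None, :]
    if log2:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(
        genes=list(cm.genes), cells=list(cm.cells), values=values,
        scale="log" if log2 else "tpm",
    )


def tpm(cm: CountMatrix) -> ExpressionMatrix:
    """Counts scaled to one million per cell over endogenous genes.

    UMIs count molecules, so no gene-length term applies.  Spike-in
    genes are excluded from both the output and the denominator.
    """
    mask = cm.nonspike_mask()
    endo = cm.counts[mask].toarray().astype(float)
    totals = endo.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cell(s) with zero endogenous counts (should have failed QC): "
            f"{[cm.cells[i] for i in zero[:5]]}"
        )
    values = endo / totals[None, :] * 1e6
    genes = [g for g, keep in zip(cm.genes, mask) if keep]
    return ExpressionMatrix(genes=genes, cells=list(cm.cells), values=values, scale="tpm")


def log_expr(em: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM/10 + 1)."""
    if em.scale != "tpm":
        raise ValidationError("log_expr expects a TPM-scale matrix")
    return ExpressionMatrix(
        genes=list(em.genes),
        cells=list(em.cells),
        values=np.log2(em.values / 10.0 + 1.0),
        scale="log",
    )
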