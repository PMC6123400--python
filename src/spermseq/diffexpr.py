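"""Differential expression between cell groups.

The test is a two-tailed Student's (equal-variance) t-test per gene on
log2(TPM/10 + 1) values, with Benjamini-Hochberg adjustment across the
tested genes.  The reported effect size is the Seurat-style average
difference computed back on the linear scale,

    avg_diff = log2(mean(2^x - 1) + 1) - log2(mean(2^y - 1) + 1),

which for well-expressed genes approximates the log2 fold change of
mean expression.  A gene is called up when p < 0.05, FDR < 0.05 and
avg_diff > 1 (down symmetrically at < -1); everything else is ``ns``.
Genes with zero variance in both groups are reported ``ns`` with p = 1,
which keeps NaNs out of downstream tables.

Two screens reuse the same machinery: the splicing-regulator screen
(restricted to a curated regulator gene set, significance at
FDR <= 0.05 and |avg_diff| >= 1) and a one-vs-rest surface-marker
screen per cell cluster.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import get_logger
from .types import ExpressionMatrix, PipelineError, ValidationError

log = get_logger(__name__)

DEG_COLUMNS = ["gene_id", "mean_a", "mean_b", "avg_diff", "p_value", "fdr", "call"]


def avg_log_diff(x: np.ndarray, y: np.ndarray) -> float:
    """Average expression difference between two groups of log-scale values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("avg_log_diff requires two non-empty groups")
    return float(
        np.log2(np.mean(np.exp2(x) - 1.0) + 1.0)
        - np.log2(np.mean(np.exp2(y) - 1.0) + 1.0)
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_test(
    em: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    diff_threshold: float = 1.0,
    diff_inclusive: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group comparison on a log-scale matrix.

    Returns one row per gene with group means, avg_diff, raw p, BH FDR
    over all tested genes, and the call in {up, down, ns}.
    """
    if em.scale != "log":
        raise ValidationError("deg_test expects a log-scale expression matrix")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 cells")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    ia = em.cell_indices(group_a)
    ib = em.cell_indices(group_b)
    a = em.values[:, ia]
    b = em.values[:, ib]

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=True)
    # zero pooled variance -> t undefined; report ns with p = 1
    var_zero = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(var_zero | ~np.isfinite(p), 1.0, p)

    lin_a = np.mean(np.exp2(a) - 1.0, axis=1)
    lin_b = np.mean(np.exp2(b) - 1.0, axis=1)
    diff = np.log2(lin_a + 1.0) - np.log2(lin_b + 1.0)

    fdr = bh_adjust(p)
    if diff_inclusive:
        strong = np.abs(diff) >= diff_threshold
    else:
        strong = np.abs(diff) > diff_threshold
    sig = (p < p_threshold) & (fdr < fdr_threshold if not diff_inclusive else fdr <= fdr_threshold) & strong
    call = np.where(sig & (diff > 0), "up", np.where(sig & (diff < 0), "down", "ns"))
    call = np.where(var_zero, "ns", call)

    return pd.DataFrame(
        {
            "gene_id": em.genes,
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "avg_diff": diff,
            "p_value": p,
            "fdr": fdr,
            "call": call,
        },
        columns=DEG_COLUMNS,
    )


def splicing_regulator_screen(
    em: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    regulators: Sequence[str],
) -> pd.DataFrame:
    """DEG test restricted to the splicing-regulator gene set.

    Significance follows the volcano-plot convention for this screen:
    p < 0.05, FDR <= 0.05 and |avg_diff| >= 1.
    """
    if len(regulators) == 0:
        raise PipelineError("empty splicing-regulator gene set")
    present = [g for g in regulators if g in set(em.genes)]
    if not present:
        log.warning("no splicing-regulator genes present in the matrix")
        return pd.DataFrame(columns=DEG_COLUMNS)
    sub = ExpressionMatrix(
        genes=present,
        cells=list(em.cells),
        values=em.values[em.gene_indices(present)],
        scale="log",
    )
    return deg_test(sub, group_a, group_b, diff_inclusive=True)


def surface_marker_screen(
    em: ExpressionMatrix,
    cluster_labels: Mapping[str, str],
    markers: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """One-vs-rest DEG test per cluster over surface-marker genes.

    Returns per-cluster tables ranked by avg_diff (descending), so the
    top rows are the cluster-enriched marker candidates.
    """
    clusters = sorted({cluster_labels[c] for c in em.cells})
    if len(clusters) < 2:
        raise PipelineError("surface-marker screen needs at least 2 clusters")
    present = [g for g in markers if g in set(em.genes)]
    if not present:
        log.warning("no surface-marker genes present in the matrix")
        return {k: pd.DataFrame(columns=DEG_COLUMNS) for k in clusters}
    sub = ExpressionMatrix(
        genes=present,
        cells=list(em.cells),
        values=em.values[em.gene_indices(present)],
        scale="log",
    )
    out: dict[str, pd.DataFrame] = {}
    for k in clusters:
        inside = [c for c in em.cells if cluster_labels[c] == k]
        outside = [c for c in em.cells if cluster_labels[c] != k]
        res = deg_test(sub, inside, outside)
        out[k] = res.sort_values("avg_diff", ascending=False).reset_index(drop=True)
    return out
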