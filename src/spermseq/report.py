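"""Publication-style summary arithmetic and expressed-gene tallies."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, PipelineError, ValidationError


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at a fixed decimal, as tallies are printed.

    Python's builtin round() is banker's rounding (63.765 -> 63.76 at 2
    decimals); printed percentages follow the half-up convention
    (63.765 -> 63.8 at 1 decimal), so this goes through Decimal.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator <= 0:
        raise PipelineError("percentage needs a positive denominator")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator must lie in [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, 1)


def expressed_tally(
    em: ExpressionMatrix,
    annotation: pd.DataFrame,
    *,
    detect_tpm: float = 1.0,
) -> pd.DataFrame:
    """Expressed-gene counts (TPM >= threshold in >= 1 cell) by biotype and
    chromosome class (autosome / X / Y)."""
    ann = annotation.set_index("gene_id")
    idx = [g for g in em.genes if g in ann.index]
    detected = pd.Series(
        (em.values[em.gene_indices(idx)] >= detect_tpm).any(axis=1), index=idx
    )
    rows = []
    for biotype in sorted(ann.loc[idx, "biotype"].unique()):
        if biotype == "spike_in":
            continue
        genes_bt = [g for g in idx if ann.at[g, "biotype"] == biotype]
        for chrom_class in ("autosome", "X", "Y"):
            if chrom_class == "autosome":
                genes = [g for g in genes_bt if ann.at[g, "chromosome"] not in ("X", "Y", "ERCC")]
            else:
                genes = [g for g in genes_bt if ann.at[g, "chromosome"] == chrom_class]
            n = len(genes)
            k = int(detected[genes].sum()) if n else 0
            rows.append(
                {
                    "biotype": biotype,
                    "chromosome_class": chrom_class,
                    "n_annotated": n,
                    "n_expressed": k,
                    "pct_expressed": percentage(k, n) if n else None,
                }
            )
    return pd.DataFrame(rows)


def per_stage_gene_umi_profile(
    em: ExpressionMatrix,
    normalized_umi: pd.Series,
    cell_stages: pd.Series,
    *,
    detect_tpm: float = 1.0,
) -> pd.DataFrame:
    """Per-stage boxplot summaries of detected genes and normalized UMI.

    Detected genes per cell use TPM >= 1; whiskers extend 1.5 x IQR
    beyond the quartiles, clipped to the data range.  One-cell stages
    are flagged degenerate (quartiles collapse onto the single value).
    """
    if em.scale != "tpm":
        raise ValidationError("per_stage_gene_umi_profile expects a TPM matrix")
    detected = pd.Series((em.values >= detect_tpm).sum(axis=0), index=em.cells)
    stage_of = cell_stages.reindex(em.cells)
    rows = []
    from .types import STAGE_ORDER

    for stage in [s for s in STAGE_ORDER if s in set(stage_of)]:
        cells = stage_of.index[stage_of == stage]
        for metric, series in (("genes_detected", detected), ("normalized_umi", normalized_umi)):
            vals = series.reindex(cells).to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = max(vals.min(), q1 - 1.5 * iqr)
            hi = min(vals.max(), q3 + 1.5 * iqr)
            rows.append(
                {
                    "stage": stage,
                    "metric": metric,
                    "n_cells": int(vals.size),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": lo,
                    "whisker_high": hi,
                    "degenerate": bool(vals.size < 2),
                }
            )
    return pd.DataFrame(rows)
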