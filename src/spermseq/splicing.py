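"""Alternative-splicing event consideration and transition dynamics.

Events (exon-exon junction EEJ, intron retention IR, alternative donor
ALTD, alternative acceptor ALTA) arrive with per-sample inclusion
values (PSI/PSU/PIR, 0-100) and a per-sample coverage flag.  An event
is *considered* when its inclusion sits in the mid band 10-90 in at
least 10% (ceiling) of the sufficiently covered samples, or in at
least 3 of them; with 50 covered samples the 10% branch demands 5.

Within one sample, a considered event is *present* when that sample has
sufficient coverage and an in-band inclusion value there.  A gene is an
AS gene in a sample when its present events span at least two event
types.

Between consecutive stage-merged samples x -> y, the change in a gene's
present event sets (Sx, Sy, with type sets Tx, Ty) falls into exactly
one of five situations:

    1  Sx == Sy != {}        events kept still
    2  both non-empty, Tx == Ty, Sx != Sy   events changed, types kept
    3  both non-empty, Tx != Ty             types changed (e.g. EEJ -> IR)
    4  Sx != {} and Sy == {}                all lost (EEJ -> NA)
    5  Sx == {} and Sy != {}                gained from none (NA -> EEJ)

Genes with Sx == Sy == {} are not emitted.  Situations 2-5 mark a gene
splicing-regulated across that transition.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import psi_samples
from .types import STAGE_ORDER, ValidationError

TRANSITION_COLUMNS = ["gene_id", "stage_x", "stage_y", "situation", "is_splicing_regulated"]


def event_considered(
    psi: Sequence[float],
    covered: Sequence[bool],
    *,
    low: float = 10.0,
    high: float = 90.0,
    frac: float = 0.10,
    min_samples: int = 3,
) -> bool:
    """Global consideration rule for one event across samples."""
    psi = np.asarray(psi, dtype=float)
    covered = np.asarray(covered, dtype=bool)
    n_cov = int(covered.sum())
    if n_cov == 0:
        return False
    vals = psi[covered]
    k = int(np.count_nonzero((vals >= low) & (vals <= high)))
    return k >= math.ceil(frac * n_cov) or k >= min_samples


def considered_sets(
    table: pd.DataFrame,
    *,
    low: float = 10.0,
    high: float = 90.0,
    frac: float = 0.10,
    min_samples: int = 3,
) -> dict[str, set[tuple[str, str, str]]]:
    """Per-sample sets of present considered events.

    Returns {sample: {(gene_id, event_id, event_type), ...}} where an
    event appears in a sample iff it passes the global consideration
    rule and is in-band with sufficient coverage in that sample.
    """
    samples = psi_samples(table)
    psi = table[[f"{s}.psi" for s in samples]].to_numpy(dtype=float)
    cov = table[[f"{s}.cov" for s in samples]].to_numpy(dtype=bool)
    in_band = cov & (psi >= low) & (psi <= high)
    n_cov = cov.sum(axis=1)
    k = in_band.sum(axis=1)
    thresh = np.ceil(frac * n_cov)
    considered = (n_cov > 0) & ((k >= thresh) | (k >= min_samples))

    keys = list(zip(table["gene_id"], table["event_id"], table["event_type"]))
    out: dict[str, set] = {s: set() for s in samples}
    for j, s in enumerate(samples):
        present = considered & in_band[:, j]
        out[s] = {keys[i] for i in np.flatnonzero(present)}
    return out


def as_genes(sample_events: set[tuple[str, str, str]]) -> set[str]:
    """Genes whose present events in a sample span >= 2 distinct types."""
    types_by_gene: dict[str, set[str]] = {}
    for gene, _event, etype in sample_events:
        types_by_gene.setdefault(gene, set()).add(etype)
    return {g for g, ts in types_by_gene.items() if len(ts) >= 2}


def classify_transition(
    gene: str,
    stage_x: str,
    stage_y: str,
    sets: Mapping[str, set[tuple[str, str, str]]],
    *,
    stage_order: Sequence[str] = STAGE_ORDER,
) -> dict | None:
    """Classify one gene's splicing change between consecutive samples.

    Returns a transition record, or None when the gene has no present
    events in either sample.
    """
    order = [s for s in stage_order if s in sets]
    try:
        ix, iy = order.index(stage_x), order.index(stage_y)
    except ValueError as exc:
        raise ValidationError(f"unknown sample stage: {exc}") from exc
    if iy != ix + 1:
        raise ValidationError(
            f"{stage_x} -> {stage_y} are not consecutive in the sample order {order}"
        )
    sx = {(e, t) for g, e, t in sets[stage_x] if g == gene}
    sy = {(e, t) for g, e, t in sets[stage_y] if g == gene}
    situation = _situation(sx, sy)
    if situation is None:
        return None
    return {
        "gene_id": gene,
        "stage_x": stage_x,
        "stage_y": stage_y,
        "situation": situation,
        "is_splicing_regulated": situation in (2, 3, 4, 5),
    }


def _situation(sx: set, sy: set) -> int | None:
    if not sx and not sy:
        return None
    if sx and not sy:
        return 4
    if not sx and sy:
        return 5
    if sx == sy:
        return 1
    tx = {t for _e, t in sx}
    ty = {t for _e, t in sy}
    return 2 if tx == ty else 3


def classify_all_transitions(
    sets: Mapping[str, set[tuple[str, str, str]]],
    *,
    stage_order: Sequence[str] = STAGE_ORDER,
) -> pd.DataFrame:
    """Transition records for every gene over every consecutive sample pair."""
    order = [s for s in stage_order if s in sets]
    rows = []
    for sx, sy in zip(order[:-1], order[1:]):
        genes = {g for g, _e, _t in sets[sx] | sets[sy]}
        for g in sorted(genes):
            rec = classify_transition(g, sx, sy, sets, stage_order=stage_order)
            if rec is not None:
                rows.append(rec)
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def event_change_tally(
    sets: Mapping[str, set[tuple[str, str, str]]],
    stage_x: str,
    stage_y: str,
) -> pd.DataFrame:
    """Per-type counts of changed events across one transition.

    A changed event (present in exactly one of the two samples) is
    classified by its status in the latter stage: its own type when it
    is present at y, and 'NA' when it was lost.
    """
    sx, sy = sets[stage_x], sets[stage_y]
    gained = sy - sx
    lost = sx - sy
    counts: dict[str, int] = {}
    for _g, _e, t in gained:
        counts[t] = counts.get(t, 0) + 1
    counts["NA"] = len(lost)
    total = sum(counts.values())
    rows = [
        {
            "latter_status": t,
            "n_events": n,
            "fraction": (n / total) if total else 0.0,
        }
        for t, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["latter_status", "n_events", "fraction"])


def expression_splicing_association(
    deg: pd.DataFrame,
    sets: Mapping[str, set[tuple[str, str, str]]],
    stage_x: str,
    stage_y: str,
) -> pd.DataFrame:
    """AS status of DEGs across a stage transition.

    Up-regulated genes are described by their present event types in the
    latter stage; down-regulated genes by the former stage.  Genes with
    no present events get status 'NA'.  ``deg`` is a deg_test result for
    groups (stage_y cells) vs (stage_x cells), so 'up' means higher at y.
    """
    rows = []
    for _, r in deg[deg["call"] != "ns"].iterrows():
        sample = stage_y if r["call"] == "up" else stage_x
        types = sorted({t for g, _e, t in sets[sample] if g == r["gene_id"]})
        rows.append(
            {
                "gene_id": r["gene_id"],
                "call": r["call"],
                "sample": sample,
                "as_status": "+".join(types) if types else "NA",
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "call", "sample", "as_status"])
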