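"""Transcription-factor co-expression networks.

Pairwise Pearson correlation of TF expression (log2(TPM/10+1)) over the
pooled cells of a cluster pair, thresholded at > 0.35 for the
mitotic-to-meiotic transition and > 0.45 for the meiotic-to-postmeiotic
transition, then pruned to the 3-core so every surviving TF keeps at
least three edges.  The threshold applies to the signed correlation, so
strong negative partners are excluded by construction.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import get_logger
from .types import ExpressionMatrix, PipelineError, ValidationError

log = get_logger(__name__)

TRANSITION_THRESHOLDS = {"mitotic_to_meiotic": 0.35, "meiotic_to_postmeiotic": 0.45}


def tf_correlations(
    em: ExpressionMatrix,
    cells: Sequence[str],
    tf_genes: Sequence[str],
    *,
    method: str = "pearson",
) -> pd.DataFrame:
    """Symmetric TF x TF correlation table over the given cells.

    TFs with zero variance across the cells are dropped with a warning
    (their correlation is undefined).
    """
    if len(cells) < 3:
        raise PipelineError("correlation needs at least 3 cells")
    if em.scale != "log":
        raise ValidationError("tf_correlations expects a log-scale matrix")
    present = [g for g in tf_genes if g in set(em.genes)]
    sub = em.values[np.ix_(em.gene_indices(present), em.cell_indices(cells))]
    keep = sub.std(axis=1) > 0
    dropped = [g for g, k in zip(present, keep) if not k]
    if dropped:
        log.warning("dropping %d zero-variance TFs (e.g. %s)", len(dropped), dropped[:3])
    present = [g for g, k in zip(present, keep) if k]
    sub = sub[keep]
    if method == "pearson":
        corr = np.corrcoef(sub)
    elif method == "spearman":
        import scipy.stats

        corr = scipy.stats.spearmanr(sub, axis=1).statistic
        corr = np.atleast_2d(corr)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return pd.DataFrame(np.atleast_2d(corr), index=present, columns=present)


def build_network(
    correlations: pd.DataFrame,
    threshold: float,
    *,
    min_degree: int = 3,
    prune: str = "iterative",
    transition: str | None = None,
) -> nx.Graph:
    """Threshold a correlation table into a pruned co-expression graph.

    Edges keep pairs with correlation strictly above the threshold;
    ``iterative`` pruning then takes the min_degree-core (removing
    low-degree nodes until a fixed point), while ``one_pass`` removes
    them only once.  The empty graph is a legal result.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    tfs = list(correlations.index)
    g = nx.Graph()
    vals = correlations.to_numpy()
    for i in range(len(tfs)):
        for j in range(i + 1, len(tfs)):
            if vals[i, j] > threshold:
                g.add_edge(tfs[i], tfs[j], weight=float(vals[i, j]))
    if prune == "iterative":
        g = nx.k_core(g, k=min_degree) if g.number_of_nodes() else g
    elif prune == "one_pass":
        g.remove_nodes_from([n for n, d in dict(g.degree()).items() if d < min_degree])
    else:
        raise ValidationError(f"unknown prune mode {prune!r}")
    g = nx.Graph(g)
    g.graph["threshold"] = threshold
    g.graph["transition"] = transition
    assert all(d >= min_degree for _n, d in g.degree()) or prune == "one_pass"
    assert all(w > threshold for _u, _v, w in g.edges(data="weight"))
    return g


def edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"tf_a": u, "tf_b": v, "correlation": w}
        for u, v, w in sorted(g.edges(data="weight"))
    ]
    return pd.DataFrame(rows, columns=["tf_a", "tf_b", "correlation"])
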