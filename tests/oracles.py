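"""Independent brute-force oracles, written separately from the pipeline.

These deliberately re-derive each rule from its plain statement rather
than calling (or sharing code with) the implementation they check.
"""

from __future__ import annotations

STAGES = [
    "A1", "In", "BS", "BG2", "G1", "ePL", "mPL", "lPL", "L", "Z",
    "eP", "mP", "lP", "D", "MI", "MII", "RS2", "RS4", "RS6", "RS8",
]


def bh_bruteforce(pvals):
    """BH adjusted values from the definition: the minimum over j >= rank(i)
    of p_(j) * n / j, capped at 1."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [None] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * n / rank)
        adj[i] = min(running_min, 1.0)
    return adj


def msci_bruteforce(expressed_by_stage: dict[str, bool]) -> tuple[str, str]:
    """Category + subtype from a stage -> expressed mapping, rule by rule."""
    e = expressed_by_stage
    before_ep = [s for s in STAGES if STAGES.index(s) < STAGES.index("eP")]
    before_mii = [s for s in STAGES if STAGES.index(s) < STAGES.index("MII")]
    from_mii = [s for s in STAGES if STAGES.index(s) >= STAGES.index("MII")]

    expressed_pre = any(e[s] for s in before_ep)
    expressed_d = e["D"]
    expressed_post = any(e[s] for s in from_mii)
    expressed_pach = e["eP"] or e["mP"] or e["lP"]

    if expressed_pre and not expressed_d:
        subtype = "TYPE_I" if not expressed_pach else "TYPE_II"
        # silent from MII onward => subjected to postmeiotic silencing
        category = "MSCI_PMSC" if not expressed_post else "MSCI_ESCAPE_PMSC"
        return category, subtype
    if expressed_pre and expressed_d:
        return "ESCAPE_MSCI", "NA"
    if not any(e[s] for s in before_mii) and expressed_post:
        return "RS_SPECIFIC", "NA"
    return "OTHER", "NA"


def transition_bruteforce(events_x: set, events_y: set):
    """Situation 1..5 (or None) from the five plain statements.

    Events are (event_id, event_type) pairs present in each sample.
    """
    if not events_x and not events_y:
        return None
    if events_x and not events_y:
        return 4
    if not events_x and events_y:
        return 5
    if events_x == events_y:
        return 1
    types_x = {t for _, t in events_x}
    types_y = {t for _, t in events_y}
    if types_x == types_y:
        return 2
    return 3


def pearson_bruteforce(u, v):
    """Pearson correlation straight from the formula."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    su = sum((a - mu) ** 2 for a in u) ** 0.5
    sv = sum((b - mv) ** 2 for b in v) ** 0.5
    return cov / (su * sv)
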