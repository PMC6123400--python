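"""Sex-chromosome gene classification across spermatogenesis stages.

Meiotic sex chromosome inactivation (MSCI) silences the X and Y from
pachynema onward; postmeiotic sex chromatin (PMSC) can keep genes
silent in spermatids, or genes can reactivate ("escape PMSC").  The
classifier works on a per-gene, per-stage expressed/silent profile:

    expressed at stage s  <=>  mean TPM > 1  and  TPM >= 1 in >= 3 cells

and assigns each sex-linked gene exactly one category:

    MSCI        expressed at >= 1 stage before eP, silent at D
                  subtype TYPE_I  if silent across eP/mP/lP
                  subtype TYPE_II otherwise
                  MSCI_PMSC        if silent from MII onward
                  MSCI_ESCAPE_PMSC if expressed at >= 1 stage from MII on
    ESCAPE_MSCI expressed at >= 1 stage before eP, and expressed at D
    RS_SPECIFIC silent at every stage before MII, expressed from MII on
    OTHER       everything else in the expressed universe

PMSC naming note: the literature uses "PMSC gene" both for genes that
remain silent postmeiotically and for their complement.  The default
here (``pmsc_semantics="results"``) takes MSCI_PMSC = silent from MII
onward, i.e. subjected to PMSC silencing; ``"methods"`` flips the two
labels for users who prefer the opposite convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .report import percentage
from .types import (
    STAGE_ORDER,
    ExpressionMatrix,
    StagingError,
    ValidationError,
    stage_index,
)

PRE_EP = STAGE_ORDER[: stage_index("eP")]           # A1 .. Z
PACHYTENE = ("eP", "mP", "lP")
DIPLOTENE = "D"
POST_MII = STAGE_ORDER[stage_index("MII"):]         # MII .. RS8
PRE_MII = STAGE_ORDER[: stage_index("MII")]         # A1 .. MI


@dataclass
class StageExpressionTable:
    """Per (gene, stage) summaries feeding the expressed-at-stage rule.

    ``mean_tpm`` and ``n_ge1`` are genes x stages DataFrames (columns in
    stage order); ``n_cells`` maps each stage to its cell count.
    """

    mean_tpm: pd.DataFrame
    n_ge1: pd.DataFrame
    n_cells: dict[str, int]

    def __post_init__(self) -> None:
        if list(self.mean_tpm.columns) != list(self.n_ge1.columns):
            raise ValidationError("stage axes of mean_tpm and n_ge1 differ")
        for s in self.mean_tpm.columns:
            if (self.n_ge1[s] > self.n_cells[s]).any():
                raise ValidationError(f"n_cells_ge1 exceeds n_cells at stage {s}")

    @property
    def stages(self) -> list[str]:
        return list(self.mean_tpm.columns)


def stage_expression_table(em: ExpressionMatrix, cell_stages: pd.Series) -> StageExpressionTable:
    """Summarize a TPM matrix per stage (mean TPM, cells with TPM >= 1)."""
    if em.scale != "tpm":
        raise ValidationError("stage_expression_table expects a TPM matrix")
    stages = [s for s in STAGE_ORDER if s in set(cell_stages)]
    mean_tpm = {}
    n_ge1 = {}
    n_cells = {}
    stage_of = cell_stages.reindex(em.cells)
    if stage_of.isna().any():
        raise ValidationError("every cell needs a stage label")
    for s in stages:
        cols = np.flatnonzero((stage_of == s).to_numpy())
        block = em.values[:, cols]
        mean_tpm[s] = block.mean(axis=1)
        n_ge1[s] = (block >= 1.0).sum(axis=1)
        n_cells[s] = int(cols.size)
    return StageExpressionTable(
        mean_tpm=pd.DataFrame(mean_tpm, index=em.genes),
        n_ge1=pd.DataFrame(n_ge1, index=em.genes),
        n_cells=n_cells,
    )


def expressed_at_stage(gene: str, stage: str, table: StageExpressionTable) -> bool:
    """True iff mean TPM > 1 and TPM >= 1 in at least 3 cells at the stage."""
    if table.n_cells[stage] < 3:
        raise StagingError(
            f"stage {stage} has {table.n_cells[stage]} cells; the expressed-at-stage "
            "rule needs at least 3"
        )
    return bool(
        (table.mean_tpm.at[gene, stage] > 1.0) and (table.n_ge1.at[gene, stage] >= 3)
    )


def expressed_matrix(table: StageExpressionTable) -> pd.DataFrame:
    """Boolean genes x stages expressed-at-stage matrix."""
    small = [s for s in table.stages if table.n_cells[s] < 3]
    if small:
        raise StagingError(f"stages with fewer than 3 cells: {small}")
    return (table.mean_tpm > 1.0) & (table.n_ge1 >= 3)


def sex_linked_universe(
    annotation: pd.DataFrame,
    em: ExpressionMatrix,
    table: StageExpressionTable | None = None,
    *,
    biotype: str = "protein_coding",
) -> tuple[list[str], list[str]]:
    """Sex-linked genes of a biotype expressed anywhere, and the per-stage
    expressed subset (expressed-at-stage at >= 1 stage) if a table is given.
    """
    ann = annotation.set_index("gene_id")
    sex = [
        g for g in em.genes
        if g in ann.index
        and ann.at[g, "chromosome"] in ("X", "Y")
        and ann.at[g, "biotype"] == biotype
    ]
    idx = em.gene_indices(sex)
    any_cell = (em.values[idx] >= 1.0).any(axis=1)
    detected = [g for g, keep in zip(sex, any_cell) if keep]
    if table is None:
        return detected, []
    E = expressed_matrix(table)
    staged = [g for g in detected if E.loc[g].any()]
    return detected, staged


def classify_profile(expressed: pd.Series, *, pmsc_semantics: str = "results") -> tuple[str, str]:
    """Classify one gene's per-stage expressed profile.

    ``expressed`` is a boolean Series indexed by stage code (all 20
    stages required).  Returns (category, subtype) with subtype in
    {TYPE_I, TYPE_II, NA}.
    """
    missing = [s for s in STAGE_ORDER if s not in expressed.index]
    if missing:
        raise ValidationError(f"profile missing stages {missing}")
    e = expressed
    pre = any(bool(e[s]) for s in PRE_EP)
    at_d = bool(e[DIPLOTENE])
    post = any(bool(e[s]) for s in POST_MII)
    pre_mii = any(bool(e[s]) for s in PRE_MII)
    pach = any(bool(e[s]) for s in PACHYTENE)

    if pre and not at_d:
        subtype = "TYPE_II" if pach else "TYPE_I"
        silent_post = not post
        if pmsc_semantics == "results":
            category = "MSCI_PMSC" if silent_post else "MSCI_ESCAPE_PMSC"
        elif pmsc_semantics == "methods":
            category = "MSCI_ESCAPE_PMSC" if silent_post else "MSCI_PMSC"
        else:
            raise ValidationError(f"unknown pmsc_semantics {pmsc_semantics!r}")
        return category, subtype
    if pre and at_d:
        return "ESCAPE_MSCI", "NA"
    if not pre_mii and post:
        return "RS_SPECIFIC", "NA"
    return "OTHER", "NA"


def classify_sex_linked(
    genes,
    table: StageExpressionTable,
    *,
    pmsc_semantics: str = "results",
) -> pd.DataFrame:
    """Classify sex-linked genes from their stage expression table.

    Genes must belong to the per-stage expressed universe (expressed at
    at least one stage).
    """
    E = expressed_matrix(table)
    rows = []
    for g in genes:
        profile = E.loc[g]
        if not profile.any():
            raise ValidationError(
                f"gene {g} is not expressed at any stage; it is outside the "
                "classification universe"
            )
        category, subtype = classify_profile(profile, pmsc_semantics=pmsc_semantics)
        rows.append({"gene_id": g, "category": category, "msci_subtype": subtype})
    return pd.DataFrame(rows, columns=["gene_id", "category", "msci_subtype"])


def lncrna_msci_mode(
    annotation: pd.DataFrame,
    em: ExpressionMatrix,
    table: StageExpressionTable,
    *,
    pmsc_semantics: str = "results",
) -> pd.DataFrame:
    """Same classification rules applied to the lncRNA biotype."""
    _, staged = sex_linked_universe(annotation, em, table, biotype="lncRNA")
    return classify_sex_linked(staged, table, pmsc_semantics=pmsc_semantics)


def msci_summary(labels: pd.DataFrame, expressed: pd.DataFrame | None = None) -> dict:
    """Counts, percentages (round-half-up, 1 decimal) and cross-tabs.

    MSCI vs escape percentages are over genes expressed before eP
    (MSCI + ESCAPE_MSCI); subtype and PMSC splits are over MSCI genes.
    When the boolean expressed matrix is supplied, the summary also
    reports diplotene-to-postmeiotic persistence: of the genes expressed
    at D, how many stay expressed at some stage from MII onward.
    """
    counts = labels["category"].value_counts().to_dict()
    n_msci = counts.get("MSCI_PMSC", 0) + counts.get("MSCI_ESCAPE_PMSC", 0)
    n_escape = counts.get("ESCAPE_MSCI", 0)
    pre_ep_total = n_msci + n_escape
    msci_rows = labels[labels["category"].isin(["MSCI_PMSC", "MSCI_ESCAPE_PMSC"])]
    n_type1 = int((msci_rows["msci_subtype"] == "TYPE_I").sum())
    n_type2 = int((msci_rows["msci_subtype"] == "TYPE_II").sum())
    n_pmsc_silent = counts.get("MSCI_PMSC", 0)
    n_pmsc_escape = counts.get("MSCI_ESCAPE_PMSC", 0)

    def pct(n, d):
        return percentage(n, d) if d > 0 else None

    summary = {
        "counts": {c: int(counts.get(c, 0)) for c in
                   ["MSCI_PMSC", "MSCI_ESCAPE_PMSC", "ESCAPE_MSCI", "RS_SPECIFIC", "OTHER"]},
        "n_universe": int(len(labels)),
        "n_msci": int(n_msci),
        "n_escape_msci": int(n_escape),
        "n_expressed_before_eP": int(pre_ep_total),
        "pct_msci": pct(n_msci, pre_ep_total),
        "pct_escape_msci": pct(n_escape, pre_ep_total),
        "n_type_i": n_type1,
        "n_type_ii": n_type2,
        "pct_type_i": pct(n_type1, n_msci),
        "pct_type_ii": pct(n_type2, n_msci),
        "n_pmsc_silent": int(n_pmsc_silent),
        "n_pmsc_escape": int(n_pmsc_escape),
        "pct_pmsc_silent": pct(n_pmsc_silent, n_msci),
        "pct_pmsc_escape": pct(n_pmsc_escape, n_msci),
    }
    if expressed is not None:
        genes = [g for g in labels["gene_id"] if g in expressed.index]
        sub = expressed.loc[genes]
        at_d = sub[DIPLOTENE]
        persist = sub.loc[at_d, list(POST_MII)].any(axis=1)
        summary["n_expressed_at_D"] = int(at_d.sum())
        summary["n_D_persist_postmeiotic"] = int(persist.sum())
        summary["pct_D_persist_postmeiotic"] = pct(int(persist.sum()), int(at_d.sum()))
    return summary
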