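"""Synthetic staged scRNA-seq data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
20 ordered stages, gene-wise negative-binomial UMI counts (variance =
mean + mean^2/dispersion) scaled by a per-cell technical size factor
that also drives the ERCC spike-in totals, Bernoulli dropout, planted
stage-step differential expression, sex-linked genes planted into every
MSCI category with a safe expressed/silent margin (mean TPM 50 vs
0.02), PSI tables planted into the five transition situations, and
spermatid populations drawn with or without intercellular transcript
sharing.

Every planted label is re-derivable from the planted profile by the
analysis modules themselves, so downstream recovery tests have an exact
oracle.  All draws are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .msci import PACHYTENE, POST_MII, PRE_EP, PRE_MII, StageExpressionTable, classify_profile
from .types import (
    EVENT_TYPES,
    STAGE_ORDER,
    STAGE_TO_CLUSTER,
    ConfigError,
    CountMatrix,
)

DEFAULT_MSCI_COUNTS = {
    "MSCI_PMSC": 40,
    "MSCI_ESCAPE_PMSC": 40,
    "ESCAPE_MSCI": 30,
    "RS_SPECIFIC": 20,
    "OTHER": 20,
}


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic dataset."""

    stages: tuple[str, ...] = STAGE_ORDER
    cells_per_stage: int = 57   # ~1,136 profiled cells over 20 stages
    n_autosomal: int = 4000
    n_x: int = 150
    n_y: int = 20
    n_spikeins: int = 30
    # noise model
    dispersion: float = 0.5          # NB size; var = m + m^2/dispersion
    spike_dispersion: float = 20.0   # spike-ins carry technical noise only
    dropout: float = 0.10            # Bernoulli zeroing after the NB draw
    size_factor_sigma: float = 0.15  # lognormal spread of per-cell factors
    # expression scales (expected counts per cell at size factor 1)
    autosomal_log_mean: float = math.log(15.0)
    autosomal_log_sigma: float = 1.0
    spike_mean: float = 100.0        # per spike-in gene
    # planted sex-linked categories (expressed/silent margins in TPM)
    msci_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MSCI_COUNTS))
    type1_fraction: float = 0.5
    expressed_tpm: float = 50.0
    silent_tpm: float = 0.02
    # planted DEGs between consecutive stages
    n_deg_per_transition: int = 30
    deg_log2_effect: float = 2.0
    deg_base_mean: float = 30.0      # planted on well-detected genes
    deg_base_sigma: float = 0.5
    # fraction of background autosomal genes silenced everywhere
    autosomal_silent_fraction: float = 0.0
    # flagged gene panels
    n_regulator_background: int = 10
    n_markers: int = 8
    n_tfs: int = 60
    tf_module_size: int = 8
    # PSI table planting
    as_genes_per_situation: int = 2
    psi_noise: float = 4.0
    coverage_missing_rate: float = 0.05
    # sharing scenario
    sharing_stages: tuple[str, ...] = ("RS2", "RS4", "RS6", "RS8")
    sharing_cells_per_stage: int = 100
    sharing_n_autosomal: int = 300
    sharing_autosomal_mean: float = 20.0
    sharing_sex_mean: float = 10.0
    x_load_ratio: float = 2.0
    # plumbing
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.msci_counts.values()) > self.n_x + self.n_y:
            raise ConfigError("more planted sex-linked categories than sex-linked genes")
        for rate in (self.dropout, self.coverage_missing_rate, self.type1_fraction,
                     self.autosomal_silent_fraction):
            if not 0 <= rate <= 1:
                raise ConfigError("rates must lie in [0, 1]")
        if self.deg_log2_effect <= 0 or self.x_load_ratio <= 0:
            raise ConfigError("effect sizes must be positive")
        if self.expressed_tpm < 5 or self.silent_tpm > 0.1:
            raise ConfigError("expressed/silent TPM margins must be >= 5 / <= 0.1")
        unknown = set(self.msci_counts) - {
            "MSCI_PMSC", "MSCI_ESCAPE_PMSC", "ESCAPE_MSCI", "RS_SPECIFIC", "OTHER"
        }
        if unknown:
            raise ConfigError(f"unknown planted categories {sorted(unknown)}")


@dataclass
class TruthLabels:
    """Planted ground truth emitted alongside the synthetic data."""

    msci: pd.DataFrame                                   # gene_id, category, msci_subtype
    expressed_profile: pd.DataFrame                      # bool, sex genes x stages
    deg: dict[tuple[str, str], dict[str, list[str]]]     # transition -> up/down gene lists
    situations: dict[tuple[str, str, str], int]          # (gene, x, y) -> situation 1..5
    gamete: dict[str, str]                               # cell -> "X" | "Y" (sharing runs)
    sharing: bool | None
    size_factors: pd.Series
    marker_cluster: dict[str, str]
    tf_modules: dict[str, int]


# ---------------------------------------------------------------------------
# count matrix simulation

def _nb_counts(rng: np.random.Generator, means: np.ndarray, dispersion) -> np.ndarray:
    """NB(mean, dispersion) via the gamma-Poisson mixture; mean 0 stays 0.

    ``dispersion`` may be a scalar or a per-row array broadcast over cells.
    """
    shape = np.asarray(dispersion, dtype=float)
    if shape.ndim == 1:
        shape = shape[:, None]
    lam = rng.gamma(np.broadcast_to(shape, means.shape), means / shape)
    return rng.poisson(lam)


def _size_factors(rng: np.random.Generator, n: int, sigma: float, noiseless: bool) -> np.ndarray:
    f = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    f = f / f.mean()
    if noiseless:
        f = np.round(f, 2)
        f[f <= 0] = 0.01
    return f


def _plant_sex_profiles(spec: SimulationSpec, rng: np.random.Generator,
                        sex_genes: list[str]) -> pd.DataFrame:
    """Boolean expressed-at-stage profiles realizing each planted category."""
    profiles = {}
    pool = list(sex_genes)
    rng.shuffle(pool)
    cursor = 0

    def take(n):
        nonlocal cursor
        out = pool[cursor:cursor + n]
        cursor += n
        return out

    def subset(stages, p=0.5, min_n=1):
        stages = list(stages)
        chosen = [s for s in stages if rng.random() < p]
        while len(chosen) < min_n:
            chosen.append(stages[rng.integers(len(stages))])
        return set(chosen)

    def profile(on: set[str]) -> pd.Series:
        return pd.Series({s: s in on for s in STAGE_ORDER})

    for category, n in spec.msci_counts.items():
        for gene in take(n):
            if category in ("MSCI_PMSC", "MSCI_ESCAPE_PMSC"):
                type1 = rng.random() < spec.type1_fraction
                on = subset(PRE_EP)
                if not type1:
                    on |= subset(PACHYTENE)
                if category == "MSCI_ESCAPE_PMSC":
                    on |= subset(POST_MII)
            elif category == "ESCAPE_MSCI":
                on = subset(PRE_EP) | {"D"} | subset(POST_MII, p=0.3, min_n=0)
            elif category == "RS_SPECIFIC":
                on = subset(POST_MII)
            else:  # OTHER: expressed only inside eP..MI (outside PRE, incl. PREMII)
                on = subset(("eP", "mP", "lP", "MI"), p=0.0, min_n=1)
            profiles[gene] = profile(on)

    # remaining sex genes: broadly expressed housekeeping-like profiles
    for gene in pool[cursor:]:
        profiles[gene] = profile(set(STAGE_ORDER))

    if not profiles:
        return pd.DataFrame(columns=list(STAGE_ORDER), dtype=bool)
    prof = pd.DataFrame(profiles).T.reindex(sex_genes)
    prof.columns = list(STAGE_ORDER)
    return prof


def simulate_dataset(spec: SimulationSpec) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Simulate a full labeled dataset: counts, cell metadata, annotation, truth."""
    rng = np.random.default_rng(spec.seed)
    stages = list(spec.stages)
    n_transitions = len(stages) - 1

    auto_genes = [f"GA{i:05d}" for i in range(spec.n_autosomal)]
    x_genes = [f"GX{i:04d}" for i in range(spec.n_x)]
    y_genes = [f"GY{i:03d}" for i in range(spec.n_y)]
    spike_genes = [f"ERCC-{i:05d}" for i in range(1, spec.n_spikeins + 1)]
    sex_genes = x_genes + y_genes
    genes = auto_genes + sex_genes + spike_genes

    need = spec.n_deg_per_transition * n_transitions + spec.n_markers + spec.n_tfs
    if need > spec.n_autosomal:
        raise ConfigError(
            f"{need} planted autosomal roles exceed {spec.n_autosomal} autosomal genes"
        )

    # --- expected count means per gene x stage (size factor 1) ---
    n_stages = len(stages)
    base = rng.lognormal(spec.autosomal_log_mean, spec.autosomal_log_sigma, spec.n_autosomal)
    M_auto = np.tile(base[:, None], (1, n_stages))

    # planted DEGs: step change from stage y onward, disjoint genes per transition
    deg_truth: dict[tuple[str, str], dict[str, list[str]]] = {}
    cursor = 0
    fold = 2.0 ** spec.deg_log2_effect
    for t in range(n_transitions):
        ids = list(range(cursor, cursor + spec.n_deg_per_transition))
        cursor += spec.n_deg_per_transition
        up, down = [], []
        for gi in ids:
            M_auto[gi, :] = rng.lognormal(math.log(spec.deg_base_mean), spec.deg_base_sigma)
            if rng.random() < 0.5:
                M_auto[gi, t + 1:] *= fold
                up.append(auto_genes[gi])
            else:
                M_auto[gi, t + 1:] /= fold
                down.append(auto_genes[gi])
        deg_truth[(stages[t], stages[t + 1])] = {"up": up, "down": down}

    # surface markers: low everywhere, high within one cluster's stages
    marker_cluster: dict[str, str] = {}
    clusters = sorted(set(STAGE_TO_CLUSTER.values()))
    marker_ids = list(range(cursor, cursor + spec.n_markers))
    cursor += spec.n_markers
    for k, gi in enumerate(marker_ids):
        clus = clusters[k % len(clusters)]
        M_auto[gi, :] = 2.0
        for sj, s in enumerate(stages):
            if STAGE_TO_CLUSTER.get(s) == clus:
                M_auto[gi, sj] = 40.0
        marker_cluster[auto_genes[gi]] = clus

    # TF modules: co-regulated blocks sharing an on/off stage profile
    tf_modules: dict[str, int] = {}
    tf_ids = list(range(cursor, cursor + spec.n_tfs))
    cursor += spec.n_tfs
    module_stage_sets = [
        {s for s in stages if STAGE_TO_CLUSTER.get(s) == "C1"},
        {s for s in stages if STAGE_TO_CLUSTER.get(s) in ("C6", "C7")},
        {s for s in stages if STAGE_TO_CLUSTER.get(s) in ("C2", "C3")},
    ]
    for k, gi in enumerate(tf_ids):
        module = k // spec.tf_module_size
        tf_modules[auto_genes[gi]] = module
        if module < len(module_stage_sets):
            on = module_stage_sets[module]
            M_auto[gi, :] = [100.0 if s in on else 0.5 for s in stages]
        # later TFs keep their independent constant baseline

    # optionally silence a block of background autosomal genes everywhere
    n_silent = int(round(spec.autosomal_silent_fraction * spec.n_autosomal))
    if n_silent:
        hi = spec.n_autosomal - spec.n_regulator_background
        lo = hi - n_silent
        if lo < cursor:
            raise ConfigError("autosomal_silent_fraction overlaps planted gene roles")
        M_auto[lo:hi, :] = 0.0

    # sex-linked genes: planted category profiles at TPM margins
    profile = _plant_sex_profiles(spec, rng, sex_genes)
    total_auto = M_auto.mean(axis=1).sum()
    m_expressed = spec.expressed_tpm / 1e6 * total_auto
    m_silent = spec.silent_tpm / 1e6 * total_auto
    M_sex = np.where(profile[list(stages)].to_numpy(), m_expressed, m_silent)

    M_spike = np.full((spec.n_spikeins, n_stages), spec.spike_mean)
    M = np.vstack([M_auto, M_sex, M_spike])

    # --- cells ---
    cells = [f"cell_{s}_{i:03d}" for s in stages for i in range(spec.cells_per_stage)]
    cell_stage = [s for s in stages for _ in range(spec.cells_per_stage)]
    factors = _size_factors(rng, len(cells), spec.size_factor_sigma, spec.noiseless)

    dispersions = np.concatenate(
        [
            np.full(len(genes) - spec.n_spikeins, spec.dispersion),
            np.full(spec.n_spikeins, spec.spike_dispersion),
        ]
    )
    counts = np.empty((len(genes), len(cells)), dtype=np.int64)
    for sj, s in enumerate(stages):
        cols = [j for j, cs in enumerate(cell_stage) if cs == s]
        means = M[:, sj][:, None] * factors[cols][None, :]
        if spec.noiseless:
            block = np.rint(means).astype(np.int64)
        else:
            block = _nb_counts(rng, means, dispersions)
            keep = rng.random(block.shape) >= spec.dropout
            block = block * keep
        counts[:, cols] = block

    cm = CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(counts))

    cell_meta = pd.DataFrame(
        {
            "cell_id": cells,
            "stage": cell_stage,
            "cluster": [STAGE_TO_CLUSTER.get(s) for s in cell_stage],
            "mapping_rate": rng.uniform(0.55, 0.95, len(cells)),
            "batch": [f"B{(i % 2) + 1}" for i in range(len(cells))],
        }
    )

    regulators = set(deg_truth[("Z", "eP")]["up"] + deg_truth[("Z", "eP")]["down"]) \
        if ("Z", "eP") in deg_truth else set()
    regulators |= set(auto_genes[-spec.n_regulator_background:])
    annotation = pd.DataFrame(
        {
            "gene_id": genes,
            "chromosome": (
                [f"chr{(i % 19) + 1}" for i in range(spec.n_autosomal)]
                + ["X"] * spec.n_x + ["Y"] * spec.n_y + ["ERCC"] * spec.n_spikeins
            ),
            "biotype": (
                ["protein_coding"] * (spec.n_autosomal + spec.n_x + spec.n_y)
                + ["spike_in"] * spec.n_spikeins
            ),
            "is_tf": [g in tf_modules for g in genes],
            "is_splicing_regulator": [g in regulators for g in genes],
            "is_surface_marker": [g in marker_cluster for g in genes],
        }
    )

    labels = [classify_profile(profile.loc[g]) for g in sex_genes]
    msci = pd.DataFrame(
        {
            "gene_id": sex_genes,
            "category": [c for c, _ in labels],
            "msci_subtype": [st for _, st in labels],
        }
    )

    truth = TruthLabels(
        msci=msci,
        expressed_profile=profile,
        deg=deg_truth,
        situations={},
        gamete={},
        sharing=None,
        size_factors=pd.Series(factors, index=cells, name="size_factor"),
        marker_cluster=marker_cluster,
        tf_modules=tf_modules,
    )
    _check_planted_counts(spec, truth)
    return cm, cell_meta, annotation, truth


def _check_planted_counts(spec: SimulationSpec, truth: TruthLabels) -> None:
    got = truth.msci["category"].value_counts().to_dict()
    for cat, n in spec.msci_counts.items():
        have = got.get(cat, 0)
        if cat == "ESCAPE_MSCI":
            # unplanted broadly-expressed genes also classify as escape
            if have < n:
                raise ConfigError(f"planting produced {have} < {n} {cat} genes")
        elif have != n:
            raise ConfigError(f"planting produced {have} != {n} {cat} genes")


def true_stage_expression_table(spec: SimulationSpec, truth: TruthLabels) -> StageExpressionTable:
    """The noiseless per-stage table implied by the planted profiles.

    Mean TPM equals the planted margin (expressed vs silent) and every
    cell of an expressed stage detects the gene, so running the
    classifier on this table must reproduce the planted labels exactly.
    """
    prof = truth.expressed_profile
    mean_tpm = prof.astype(float) * spec.expressed_tpm
    mean_tpm[~prof] = spec.silent_tpm
    n_ge1 = prof.astype(int) * spec.cells_per_stage
    n_cells = {s: spec.cells_per_stage for s in prof.columns}
    return StageExpressionTable(mean_tpm=mean_tpm, n_ge1=n_ge1, n_cells=n_cells)


# ---------------------------------------------------------------------------
# PSI table simulation

def simulate_psi_table(spec: SimulationSpec) -> tuple[pd.DataFrame, TruthLabels]:
    """Stage-merged PSI table with transitions planted into the 5 situations.

    Each planted gene realizes its situation at one assigned consecutive
    transition via events that are in the 10-90 band everywhere except
    at the single sample that defines the change, so the global
    consideration rule holds with a wide margin and PSI jitter or
    dropped coverage flags never flip the planted label.
    """
    rng = np.random.default_rng(spec.seed + 1)
    samples = list(spec.stages)
    n = len(samples)
    if n < 2:
        raise ConfigError("PSI simulation needs at least two stage-merged samples")

    rows: list[dict] = []
    situations: dict[tuple[str, str, str], int] = {}
    gidx = 0

    def in_band():
        return 50.0 + rng.uniform(-1, 1) * min(spec.psi_noise, 35.0)

    def out_band():
        return 95.0 + rng.uniform(-1, 1) * min(spec.psi_noise, 3.0)

    def add_event(gene, event_id, etype, out_at: set[int], protect: set[int]):
        row = {"gene_id": gene, "event_id": event_id, "event_type": etype}
        dropped = 0
        for j, s in enumerate(samples):
            covered = True
            if j not in protect and dropped < n - 5:
                if rng.random() < spec.coverage_missing_rate:
                    covered = False
                    dropped += 1
            row[f"{s}.psi"] = (out_band() if j in out_at else in_band()) if covered else np.nan
            row[f"{s}.cov"] = covered
        rows.append(row)

    for t in range(n - 1):
        x, y = samples[t], samples[t + 1]
        for situation in (1, 2, 3, 4, 5):
            for _ in range(spec.as_genes_per_situation):
                gene = f"ASG{gidx:04d}"
                gidx += 1
                protect = {t, t + 1}
                if situation == 1:
                    add_event(gene, f"{gene}.e1", "EEJ", set(), protect)
                    add_event(gene, f"{gene}.e2", "IR", set(), protect)
                elif situation == 2:
                    add_event(gene, f"{gene}.e1", "EEJ", {t + 1}, protect)
                    add_event(gene, f"{gene}.e2", "EEJ", {t}, protect)
                elif situation == 3:
                    add_event(gene, f"{gene}.e1", "EEJ", {t + 1}, protect)
                    add_event(gene, f"{gene}.e2", "IR", {t}, protect)
                elif situation == 4:
                    add_event(gene, f"{gene}.e1", "EEJ", {t + 1}, protect)
                else:
                    add_event(gene, f"{gene}.e1", "EEJ", {t}, protect)
                situations[(gene, x, y)] = situation

    table = pd.DataFrame(rows)
    truth = TruthLabels(
        msci=pd.DataFrame(columns=["gene_id", "category", "msci_subtype"]),
        expressed_profile=pd.DataFrame(),
        deg={},
        situations=situations,
        gamete={},
        sharing=None,
        size_factors=pd.Series(dtype=float),
        marker_cluster={},
        tf_modules={},
    )
    return table, truth


# ---------------------------------------------------------------------------
# sharing scenario

def simulate_sharing_scenario(
    spec: SimulationSpec, sharing: bool
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Spermatid-stage counts with or without intercellular transcript sharing.

    With sharing, every spermatid draws X- and Y-linked counts from one
    common distribution.  Without sharing, half the cells are X-bearing
    (X-linked means scaled by the X-load ratio, Y-linked means zero) and
    half Y-bearing (X-linked at the common mean, Y-linked doubled).
    """
    rng = np.random.default_rng(spec.seed + 2)
    stages = list(spec.sharing_stages)
    n_cells = spec.sharing_cells_per_stage

    auto_genes = [f"GA{i:05d}" for i in range(spec.sharing_n_autosomal)]
    x_genes = [f"GX{i:04d}" for i in range(spec.n_x)]
    y_genes = [f"GY{i:03d}" for i in range(spec.n_y)]
    spike_genes = [f"ERCC-{i:05d}" for i in range(1, spec.n_spikeins + 1)]
    genes = auto_genes + x_genes + y_genes + spike_genes

    base = np.concatenate(
        [
            rng.lognormal(math.log(spec.sharing_autosomal_mean), 0.8, spec.sharing_n_autosomal),
            np.full(spec.n_x, spec.sharing_sex_mean),
            np.full(spec.n_y, spec.sharing_sex_mean),
            np.full(spec.n_spikeins, spec.spike_mean),
        ]
    )
    ix = slice(spec.sharing_n_autosomal, spec.sharing_n_autosomal + spec.n_x)
    iy = slice(ix.stop, ix.stop + spec.n_y)

    cells, cell_stage, gamete = [], [], {}
    counts = np.empty((len(genes), len(stages) * n_cells), dtype=np.int64)
    factors = _size_factors(rng, len(stages) * n_cells, spec.size_factor_sigma, spec.noiseless)

    col = 0
    for s in stages:
        bearings = np.array(["X"] * (n_cells // 2) + ["Y"] * (n_cells - n_cells // 2))
        rng.shuffle(bearings)
        for i in range(n_cells):
            cell = f"cell_{s}_{i:03d}"
            cells.append(cell)
            cell_stage.append(s)
            gamete[cell] = str(bearings[i])
            means = base.copy()
            if not sharing:
                if bearings[i] == "X":
                    means[ix] = base[ix] * spec.x_load_ratio
                    means[iy] = 0.0
                else:
                    means[iy] = base[iy] * 2.0
            means = means * factors[col]
            if spec.noiseless:
                counts[:, col] = np.rint(means).astype(np.int64)
            else:
                disp = np.where(
                    np.arange(len(genes)) >= len(genes) - spec.n_spikeins,
                    spec.spike_dispersion,
                    spec.dispersion,
                )
                draw = _nb_counts(rng, means[:, None], disp).ravel()
                keep = rng.random(draw.shape) >= spec.dropout
                counts[:, col] = draw * keep
            col += 1

    cm = CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(counts))
    cell_meta = pd.DataFrame(
        {
            "cell_id": cells,
            "stage": cell_stage,
            "cluster": [STAGE_TO_CLUSTER.get(s) for s in cell_stage],
            "mapping_rate": rng.uniform(0.55, 0.95, len(cells)),
            "batch": "B1",
        }
    )
    annotation = pd.DataFrame(
        {
            "gene_id": genes,
            "chromosome": (
                [f"chr{(i % 19) + 1}" for i in range(spec.sharing_n_autosomal)]
                + ["X"] * spec.n_x + ["Y"] * spec.n_y + ["ERCC"] * spec.n_spikeins
            ),
            "biotype": (
                ["protein_coding"] * (spec.sharing_n_autosomal + spec.n_x + spec.n_y)
                + ["spike_in"] * spec.n_spikeins
            ),
            "is_tf": False,
            "is_splicing_regulator": False,
            "is_surface_marker": False,
        }
    )
    truth = TruthLabels(
        msci=pd.DataFrame(columns=["gene_id", "category", "msci_subtype"]),
        expressed_profile=pd.DataFrame(),
        deg={},
        situations={},
        gamete=gamete,
        sharing=sharing,
        size_factors=pd.Series(factors, index=cells, name="size_factor"),
        marker_cluster={},
        tf_modules={},
    )
    return cm, cell_meta, annotation, truth


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """A copy of the spec with a different seed (conditions unchanged)."""
    return replace(spec, seed=seed)
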