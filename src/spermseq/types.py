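"""Domain types shared across the pipeline.

The analysis follows male germ cells through 20 ordered developmental
stages, from differentiating spermatogonia (A1) to step 7-8 round
spermatids (RS8).  Stage identity is carried as a plain string code; all
stage arithmetic ("before early pachytene", "from MII onward") goes
through the order defined here, and unknown codes are hard errors so a
corrupted stage column can never silently reorder the axis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

#: The 20 stage codes in developmental order: differentiating
#: spermatogonia (A1, In, BS, BG2), preleptotene spermatocytes (G1,
#: ePL, mPL, lPL), meiotic prophase I (L, Z, eP, mP, lP, D), the two
#: meiotic divisions (MI, MII) and round spermatid steps (RS2..RS8).
STAGE_ORDER: tuple[str, ...] = (
    "A1", "In", "BS", "BG2", "G1", "ePL", "mPL", "lPL", "L", "Z",
    "eP", "mP", "lP", "D", "MI", "MII", "RS2", "RS4", "RS6", "RS8",
)

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGE_ORDER)}

#: Coarse cluster membership used by the simulator's cell metadata
#: (cluster labels are otherwise consumed as input, never recomputed).
STAGE_TO_CLUSTER: dict[str, str] = {
    "A1": "C1", "In": "C1", "BS": "C1", "BG2": "C1", "G1": "C1", "ePL": "C1",
    "mPL": "C2", "lPL": "C2",
    "L": "C3", "Z": "C3",
    "eP": "C4", "mP": "C4", "lP": "C4",
    "D": "C5", "MI": "C5", "MII": "C5", "RS2": "C5",
    "RS4": "C6", "RS6": "C6",
    "RS8": "C7",
}

CLUSTERS: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")

EVENT_TYPES: tuple[str, ...] = ("EEJ", "IR", "ALTD", "ALTA")

MSCI_CATEGORIES: tuple[str, ...] = (
    "MSCI_PMSC", "MSCI_ESCAPE_PMSC", "ESCAPE_MSCI", "RS_SPECIFIC", "OTHER",
)

SPIKE_PREFIX_RE = re.compile(r"^ERCC-")


class PipelineError(Exception):
    """Base class for all typed pipeline errors."""


class FormatError(PipelineError):
    """Malformed input file (dimension mismatch, bad header, ...)."""


class SchemaError(PipelineError):
    """Table is missing a required column."""


class ValidationError(PipelineError):
    """Values violate a domain invariant (range, uniqueness, type)."""


class ConfigError(PipelineError):
    """Infeasible or inconsistent configuration / simulation spec."""


class NormalizationError(PipelineError):
    """Normalization cannot proceed (e.g. zero spike-in total)."""


class StagingError(PipelineError):
    """A stage cannot support the requested per-stage rule."""


def stage_index(code: str) -> int:
    try:
        return STAGE_INDEX[code]
    except KeyError:
        raise ValidationError(f"unknown stage code {code!r}; expected one of {STAGE_ORDER}")


def stages_before(code: str, *, inclusive: bool = False) -> tuple[str, ...]:
    i = stage_index(code)
    return STAGE_ORDER[: i + 1] if inclusive else STAGE_ORDER[:i]


def stages_from(code: str, *, inclusive: bool = True) -> tuple[str, ...]:
    i = stage_index(code)
    return STAGE_ORDER[i:] if inclusive else STAGE_ORDER[i + 1:]


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with designated spike-in rows.

    UMI counts approximate transcript molecule numbers per gene per
    cell.  Spike-in rows (synthetic ERCC standards, identified by the
    ``ERCC-`` id prefix) are carried in the same matrix but excluded
    from endogenous-gene computations (detection, TPM denominators).
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    spike_rows: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.genes) or n_cells != len(self.cells):
            raise FormatError(
                f"matrix is {n_genes}x{n_cells} but {len(self.genes)} genes / "
                f"{len(self.cells)} cells were supplied"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in count matrix")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell ids in count matrix")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise ValidationError("UMI counts must be non-negative integers")
        if self.spike_rows is None:
            self.spike_rows = np.array(
                [i for i, g in enumerate(self.genes) if SPIKE_PREFIX_RE.match(g)],
                dtype=int,
            )
        else:
            self.spike_rows = np.asarray(self.spike_rows, dtype=int)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def spike_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_genes, dtype=bool)
        mask[self.spike_rows] = True
        return mask

    def nonspike_mask(self) -> np.ndarray:
        return ~self.spike_mask()

    def cell_indices(self, cell_ids: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cells)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise ValidationError(f"unknown cell ids: {missing[:5]}")
        return np.array([lookup[c] for c in cell_ids], dtype=int)


@dataclass
class ExpressionMatrix:
    """Dense genes x cells expression values on a named scale.

    ``scale`` is ``"tpm"`` (per-cell counts scaled to one million over
    endogenous genes; UMI data carry no gene-length term) or ``"log"``
    (elementwise log2(TPM/10 + 1)).
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    scale: str = "tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise FormatError("expression values shape does not match gene/cell axes")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        if self.scale not in ("tpm", "log"):
            raise ValidationError(f"unknown expression scale {self.scale!r}")

    def gene_indices(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def cell_indices(self, cell_ids: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cells)}
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise ValidationError(f"unknown cell ids: {missing[:5]}")
        return np.array([lookup[c] for c in cell_ids], dtype=int)


@dataclass
class AnalysisConfig:
    """All tunable thresholds with the study's defaults.

    Expression/DEG thresholds live here so every stage of the pipeline
    reads the same numbers; see the QC and DEG modules for what each
    governs.
    """

    # cell QC
    min_mapping_rate: float = 0.40          # exclusive
    min_genes_detected: int = 2000          # exclusive; detection = UMI > 1
    umi_min: int = 20_000                   # inclusive
    umi_max: int = 1_000_000                # inclusive
    # expression detection (analysis side, distinct from the QC rule)
    detect_tpm: float = 1.0                 # expressed cell: TPM >= 1
    # per-stage expressed-gene rule
    stage_mean_tpm: float = 1.0             # mean TPM > 1
    stage_min_cells: int = 3                # TPM >= 1 in >= 3 cells
    # DEG calls
    deg_p: float = 0.05
    deg_fdr: float = 0.05
    deg_abs_diff: float = 1.0               # strict > for DEGs, >= for the regulator screen
    # AS event consideration
    psi_low: float = 10.0
    psi_high: float = 90.0
    consider_frac: float = 0.10
    consider_min: int = 3
    # TF networks
    corr_m2m: float = 0.35
    corr_m2p: float = 0.45
    min_degree: int = 3
    # misc
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)
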