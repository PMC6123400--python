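"""Simulate the staged spermatogenesis dataset used by the downstream scripts.

The dataset is regenerated deterministically (seed 11) by every later
script, so only its summary is written here, not the matrix itself.
"""

from pathlib import Path

from spermseq.io import write_report, write_table
from spermseq.simulate import SimulationSpec, simulate_dataset, simulate_psi_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main() -> None:
    spec = SimulationSpec(seed=SEED)
    cm, meta, ann, truth = simulate_dataset(spec)
    psi, psi_truth = simulate_psi_table(spec)

    summary = {
        "seed": SEED,
        "n_genes": cm.n_genes,
        "n_spikeins": int(cm.spike_rows.size),
        "n_cells": cm.n_cells,
        "stages": sorted(set(meta["stage"])),
        "planted_msci_categories": truth.msci["category"].value_counts().to_dict(),
        "planted_deg_transitions": len(truth.deg),
        "planted_as_situations": len(psi_truth.situations),
    }
    OUT.mkdir(exist_ok=True)
    write_report(summary, OUT / "01_dataset_summary.json")
    write_table(truth.msci, OUT / "01_truth_msci.tsv")
    print(f"simulated {cm.n_genes} genes x {cm.n_cells} cells over "
          f"{len(set(meta['stage']))} stages (seed {SEED})")
    print(f"planted: {summary['planted_msci_categories']}, "
          f"{len(truth.deg)} DEG transitions, "
          f"{len(psi_truth.situations)} splicing-transition labels")


if __name__ == "__main__":
    main()
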