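# spermseq

Staged single-cell RNA-seq analysis of mouse spermatogenesis, built for
studies that profile synchronized germ cells across the full
developmental ladder — 20 ordered stages from type A1 spermatogonia
through meiotic prophase I and the meiotic divisions to step 7–8 round
spermatids. The package implements the complete downstream pipeline on
UMI count matrices with ERCC spike-ins: cell quality control, spike-in
normalization, differential expression, the sex-chromosome (MSCI/PMSC)
gene classification, alternative-splicing transition dynamics,
transcription-factor co-expression networks, and the spermatid
transcript-sharing test. A first-class simulator generates fully
labeled synthetic datasets so every stage of the pipeline can be
validated against planted ground truth.

## The statistics at the core

**Per-stage expression rule.** A gene is *expressed at stage s* iff its
mean TPM at s exceeds 1 **and** at least 3 cells of s have TPM ≥ 1.
(TPM for UMI data is per-cell counts scaled to 10⁶ with no gene-length
term; analyses run on log₂(TPM/10 + 1).)

**MSCI/PMSC classification.** Meiotic sex chromosome inactivation
silences X- and Y-linked genes from pachynema onward. With E(s) the
rule above, a sex-linked gene expressed somewhere is classified:

- **MSCI** — expressed at ≥ 1 stage before eP, silent at D; subtype
  TYPE_I if silent across eP/mP/lP, else TYPE_II; within MSCI,
  **MSCI_PMSC** if silent from MII onward (subject to postmeiotic sex
  chromatin silencing) and **MSCI_ESCAPE_PMSC** if re-expressed;
- **ESCAPE_MSCI** — expressed before eP and still expressed at D;
- **RS_SPECIFIC** — silent at every stage before MII, expressed from
  MII onward;
- **OTHER** — anything else.

**Differential expression.** Per-gene two-tailed Student's t-test on
log values, Benjamini–Hochberg FDR over the tested genes, and the
average difference computed on the linear scale,
`avg_diff = log2(mean(2^x − 1) + 1) − log2(mean(2^y − 1) + 1)`;
a DEG requires p < 0.05, FDR < 0.05 and |avg_diff| > 1.

**Splicing transitions.** An AS event (EEJ/IR/ALTD/ALTA, inclusion
measured as PSI/PSU/PIR) is *considered* when 10 ≤ PSI ≤ 90 in ≥ 10%
(ceiling) of sufficiently covered samples, or in ≥ 3 of them. Between
consecutive stage-merged samples a gene's event sets fall into exactly
one of five situations (kept / changed events / changed types / all
lost / all gained); situations 2–5 mark splicing-regulated genes.

**TF networks.** Pearson correlation of TF expression over pooled cells
of a cluster pair, edges above 0.35 (mitotic→meiotic) or 0.45
(meiotic→postmeiotic), pruned to the 3-core.

**Transcript sharing.** Haploid spermatids are X- or Y-bearing, but
cytoplasmic bridges may equalize transcripts. The package scores each
stage's separability: 2-means on the first principal axis of the
sex-linked expression submatrix, silhouette of the split calibrated
against a unimodal Monte-Carlo null (≈ 0 means sharing-consistent, ≈ 1
means two clean groups).

## Worked example

The numbered scripts under `analysis/` run the full study on a
simulated dataset (seed 11: 4,200 genes including 170 sex-linked and 30
spike-ins, 1,140 cells over 20 stages) and write tables to `results/`:

```sh
python analysis/01_simulate.py
python analysis/04_msci.py
python analysis/07_sharing.py
```

prints

```
simulated 4200 genes x 1140 cells over 20 stages (seed 11)
planted: {'ESCAPE_MSCI': 50, 'MSCI_ESCAPE_PMSC': 40, 'MSCI_PMSC': 40,
          'RS_SPECIFIC': 20, 'OTHER': 20}, 19 DEG transitions, 190
          splicing-transition labels
...
sex-linked universe: 170 detected, 170 expressed at >= 1 stage
categories: {'MSCI_PMSC': 40, 'MSCI_ESCAPE_PMSC': 40, 'ESCAPE_MSCI': 50,
             'RS_SPECIFIC': 20, 'OTHER': 20}
MSCI 61.5% vs escape 38.5% of genes expressed before early pachytene
planted-category recovery: 1.000
...
sharing: per-stage scores [0.056, 0.066, -0.015, 0.172] (median 0.061)
non_sharing: per-stage scores [0.74, 0.776, 0.738, 0.728] (median 0.739)
```

Every planted MSCI category is recovered exactly through the noisy
pipeline (negative-binomial counts, dropout, spike-in scaling), and the
sharing score cleanly separates the two simulated scenarios: under
complete sharing the spermatids form one cloud (scores near 0), without
sharing the X- and Y-bearing halves split (scores near 0.75).

A `spermseq` CLI exposes the same operations on files
(`spermseq simulate|qc|deg|msci|as-dynamics|tf-network|sharing|report`).

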