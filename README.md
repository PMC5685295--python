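# methylsilence

Identify genes silenced by CpG-island DNA methylation from paired
methylation (Illumina 450K-style β-values) and expression arrays.

The package is aimed at epigenomics analysts comparing a hypomethylated
reference sample against hypermethylated targets — the motivating setting
is germ-cell-tumour cell lines, where a seminoma line serves as the
reference against non-seminoma lines (yolk sac tumour, embryonal
carcinoma, teratoma) — and answering: *which genes are methylated AND
silenced, above what level of differential methylation is that coupling
more than chance, and does demethylation reactivate them?*

## The statistic at the core

For each gene, methylation is summarized as the unweighted mean β over
island CpGs near the TSS (TSS1500/TSS200/5′UTR/first exon) and, separately,
over gene-body island CpGs. Differential methylation is
Δβ = β̄(target) − β̄(reference). Genes are placed in Δβ bins of width
0.05 and cross-tabulated against three expression categories (≥2-fold
lower in target / no difference / ≥2-fold higher). Under the null that
expression category is independent of the methylation bin, expected
counts are

    exp_ij = row_total_i × column_marginal_j / grand_total,

and each bin gets Pearson's χ² on 2 df (upper-tail p = exp(−χ²/2)).
The silencing threshold is data-driven: the lowest bin with
obs_correlating ≥ 2 × exp_correlating and p < 0.05, with no qualifying bin
below. Genes at or above that cut with a ≥2-fold expression deficit are
called silenced (flagged `body_only` when only a gene-body island is
differentially methylated). Reactivation after demethylating treatment is
quantified by the Pfaffl ratio E_t^ΔCt_t / E_r^ΔCt_r against a
housekeeping reference.

A synthetic-data module generates manifest/β/expression/qPCR datasets
with planted ground truth for validating the whole pipeline; see
`docs/methods.md` for the model and its limits.

## Worked example

The published 19-bin contingency table for the yolk-sac-tumour vs
seminoma comparison ships with the package; everything except its observed
counts is recomputed:

```sh
$ methylsilence table1-check
...
0.65    (11, 16, 2)     (5.42, 20.75, 2.82)     7.058   0.02933 *
0.70    (16, 9, 5)      (5.61, 21.47, 2.92)     27.947  8.541e-07       ***
...
grand total 4127; selected delta-beta cut: 0.65
```

Reading the 0.65 row: of 29 genes with Δβ in [0.65, 0.70), 11 were ≥2-fold
lower in the methylated line against 5.42 expected — more than twice
chance, p = 0.029 — so 0.65 is the lowest Δβ at which the
methylation–silencing coupling is both substantial and significant, and it
becomes the classification cut for that comparison.

End-to-end on synthetic data:

```sh
$ printf 'n_genes: 150\nn_target_samples: 2\nseed: 3\n' > sim.yaml
$ methylsilence simulate --config sim.yaml --out demo
simulated 150 genes, 1913 probes, 7 silenced (seed 3) -> demo
$ methylsilence run --manifest demo/manifest.csv --beta demo/beta.tsv \
    --detp demo/detection_p.tsv --expr demo/expression.tsv \
    --reference seminoma --out demo/results
INFO methylsilence: QC: 1913 probes in, 0 removed, 1913 retained
INFO methylsilence: nonseminoma_1: selected delta-beta cut 0.70
wrote 7 artifacts to demo/results
$ head -3 demo/results/silenced_genes.tsv
gene    comparison      region_basis    delta_beta      fold_change     body_only
G00056  nonseminoma_1   TSS     0.7735670555    5.350788239     False
G00058  nonseminoma_1   TSS     0.7186049585    6.124433353     False
```

Each call line is one gene silenced by methylation in one comparison: its
island Δβ against the reference, the expression fold deficit, and whether
the evidence is body-island-only. The same workflow is available as
library calls (`simulate_methylome`, `run_analysis`, …); see the module
docstrings.

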