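"""End-to-end orchestration: QC -> gene-level methylation -> integration.

`run_analysis` ties the modules together for one reference sample against
every other sample in the beta matrix: probe QC, island-mean aggregation,
delta-beta, expression fold changes, the per-comparison contingency table
with its data-driven threshold, and the silenced-gene calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import AnalysisConfig
from .io_formats import BetaMatrix, ExpressionMatrix, Manifest
from .integration import (
    BinnedDeltaBeta,
    ContingencyBin,
    ThresholdDecision,
    bin_delta_beta,
    classify_silenced,
    contingency_table,
    select_threshold,
)
from .methylome import QCReport, delta_beta, gene_island_beta, qc_filter
from .transcriptome import fold_changes, background_filter

log = logging.getLogger("methylsilence")

__all__ = ["ComparisonResult", "PipelineResult", "run_analysis"]


@dataclass
class ComparisonResult:
    """Integration output for one target sample against the reference."""

    target_sample: str
    table: list[ContingencyBin]
    threshold: ThresholdDecision
    negative_delta_genes: set[str]
    silenced: pd.DataFrame


@dataclass
class PipelineResult:
    qc_report: QCReport
    profiles: pd.DataFrame
    delta: pd.DataFrame
    fold_changes: pd.DataFrame
    comparisons: dict[str, ComparisonResult] = field(default_factory=dict)

    def silenced_calls(self) -> pd.DataFrame:
        frames = [c.silenced for c in self.comparisons.values() if len(c.silenced)]
        if not frames:
            return pd.DataFrame(
                columns=["gene", "comparison", "region_basis", "delta_beta", "fold_change", "body_only"]
            )
        return pd.concat(frames, ignore_index=True)


def run_analysis(
    manifest: Manifest,
    beta: BetaMatrix,
    expr: ExpressionMatrix,
    reference_sample: str,
    config: AnalysisConfig | None = None,
    conversion_ratios: dict[str, float] | None = None,
) -> PipelineResult:
    """Run the full methylation-silencing analysis against one reference.

    For each non-reference sample the contingency analysis selects its own
    delta-beta cut; when no bin qualifies, the comparison yields no
    silenced-gene calls (an empty table, not an error).
    Genes without expression data are excluded from binning and from the
    contingency table — they cannot enter any expression category.
    """
    cfg = config or AnalysisConfig()
    if reference_sample not in beta.samples:
        raise ValueError(f"reference sample {reference_sample!r} not in beta matrix")

    beta_qc, report = qc_filter(
        beta,
        manifest,
        detp_threshold=cfg.detp_threshold,
        log2_intensity_min=cfg.log2_intensity_min,
        conversion_ratio_max=cfg.conversion_ratio_max,
        conversion_ratios=conversion_ratios,
    )
    log.info(
        "QC: %d probes in, %d removed, %d retained",
        report.n_probes_in,
        report.n_removed_total,
        report.n_probes_out,
    )

    expr_f = background_filter(expr)
    log.info("background filter: %d of %d genes retained", len(expr_f.genes), len(expr.genes))

    profiles = gene_island_beta(beta_qc, manifest)
    delta = delta_beta(profiles, reference_sample)
    fc = fold_changes(expr_f, reference_sample, de_cut=cfg.de_cut)
    log.info(
        "profiles: %d gene x sample rows; delta-beta records: %d", len(profiles), len(delta)
    )

    result = PipelineResult(report, profiles, delta, fc)
    with_expr = set(expr_f.genes)

    for target in beta_qc.samples:
        if target == reference_sample:
            continue
        d_t = delta[(delta["target_sample"] == target) & delta["gene"].isin(with_expr)]
        fc_t = fc[fc["target_sample"] == target]
        tss = d_t[d_t["region_basis"] == "TSS"]
        if tss.empty:
            log.info("%s: no TSS delta-beta records; skipping", target)
            continue
        binned = bin_delta_beta(tss, width=cfg.bin_width)
        table = contingency_table(binned, fc_t, width=cfg.bin_width)
        decision = select_threshold(
            table, ratio_min=cfg.ratio_min, alpha=cfg.alpha, comparison=target
        )
        if decision.selected_delta_beta_cut is None:
            log.info("%s: no qualifying bin; no silenced-gene calls", target)
            silenced = classify_silenced(d_t.iloc[0:0], fc_t, cut=1.1, fold_cut=cfg.de_cut)
        else:
            log.info(
                "%s: selected delta-beta cut %.2f", target, decision.selected_delta_beta_cut
            )
            silenced = classify_silenced(
                d_t, fc_t, cut=decision.selected_delta_beta_cut, fold_cut=cfg.de_cut
            )
        result.comparisons[target] = ComparisonResult(
            target_sample=target,
            table=table,
            threshold=decision,
            negative_delta_genes=binned.negative_genes,
            silenced=silenced,
        )
    return result


def contingency_frame(table: list[ContingencyBin]) -> pd.DataFrame:
    """Flatten a contingency table to the exported TSV layout."""
    rows = []
    for b in table:
        rows.append(
            {
                "bin_lo": b.bin_lo,
                "bin_hi": b.bin_hi,
                "obs_correlating": b.obs[0],
                "obs_no_difference": b.obs[1],
                "obs_anticorrelating": b.obs[2],
                "exp_correlating": b.exp[0],
                "exp_no_difference": b.exp[1],
                "exp_anticorrelating": b.exp[2],
                "total": b.total,
                "chi2": b.chi2,
                "p": b.p,
                "stars": b.stars,
            }
        )
    return pd.DataFrame(rows)
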