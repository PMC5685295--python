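"""Probe QC, CpG-island annotation and discovery, and gene-level methylation.

The analysis treats one hypomethylated cell line (the seminoma line in the
germ-cell-tumour setting) as the reference and scores every other sample
against it.  Gene-level methylation is summarized as the unweighted mean
beta over all island CpGs in the TSS-associated region (TSS1500 / TSS200 /
5'UTR / first exon) and, separately, over island CpGs in the gene body.
A gene is called methylated when that island-mean beta is >= 0.6 and the
differential methylation score is delta-beta = target mean - reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, Manifest, TSS_REGIONS

__all__ = [
    "QCReport",
    "qc_filter",
    "annotate_island_relation",
    "find_cpg_islands",
    "region_methylation_summary",
    "gene_island_beta",
    "call_methylated",
    "delta_beta",
]


@dataclass
class QCReport:
    """Itemized account of probe-level quality filtering."""

    n_probes_in: int
    n_removed_detection_p: int
    n_removed_intensity: int
    n_removed_multi_site: int
    n_removed_multi_gene: int
    n_probes_out: int
    conversion_ratio_per_sample: dict[str, float] = field(default_factory=dict)
    flagged_samples: list[str] = field(default_factory=list)

    @property
    def n_removed_total(self) -> int:
        return (
            self.n_removed_detection_p
            + self.n_removed_intensity
            + self.n_removed_multi_site
            + self.n_removed_multi_gene
        )


def qc_filter(
    beta: BetaMatrix,
    manifest: Manifest,
    detp_threshold: float = 0.05,
    log2_intensity_min: float = 11.1,
    conversion_ratio_max: float = 0.2,
    conversion_ratios: dict[str, float] | None = None,
) -> tuple[BetaMatrix, QCReport]:
    """Remove unreliable probes and report every removal.

    Removal rules, applied in order (each probe is attributed to the first
    rule it fails, so the counts sum to the number removed):

    * mean detection p across samples strictly greater than ``detp_threshold``;
    * averaged log2 signal intensity strictly below ``log2_intensity_min``
      in either channel (skipped when no intensity table is attached);
    * probe maps to multiple genomic sites (multi-site);
    * probe annotated to multiple gene symbols (multi-gene).

    Samples whose bisulfite conversion ratio is >= ``conversion_ratio_max``
    are flagged in the report but never removed.  Raises ``ValueError`` if
    nothing survives.
    """
    probes = beta.probes
    ann = manifest.df.reindex(probes)

    keep = pd.Series(True, index=probes)
    removed = {"detection_p": 0, "intensity": 0, "multi_site": 0, "multi_gene": 0}

    if beta.detection_p is not None:
        fail_detp = beta.detection_p.mean(axis=1) > detp_threshold
        removed["detection_p"] = int((keep & fail_detp).sum())
        keep &= ~fail_detp

    if beta.intensity is not None:
        fail_int = (beta.intensity < log2_intensity_min).any(axis=1)
        removed["intensity"] = int((keep & fail_int).sum())
        keep &= ~fail_int

    fail_multi_site = ann["multi_site"].fillna(False).astype(bool)
    removed["multi_site"] = int((keep & fail_multi_site).sum())
    keep &= ~fail_multi_site

    fail_multi_gene = ann["multi_gene"].fillna(False).astype(bool)
    removed["multi_gene"] = int((keep & fail_multi_gene).sum())
    keep &= ~fail_multi_gene

    if not keep.any():
        raise ValueError("quality filtering removed every probe")

    ratios = dict(conversion_ratios or {})
    flagged = [s for s, r in ratios.items() if r >= conversion_ratio_max]

    report = QCReport(
        n_probes_in=len(probes),
        n_removed_detection_p=removed["detection_p"],
        n_removed_intensity=removed["intensity"],
        n_removed_multi_site=removed["multi_site"],
        n_removed_multi_gene=removed["multi_gene"],
        n_probes_out=int(keep.sum()),
        conversion_ratio_per_sample=ratios,
        flagged_samples=flagged,
    )
    return beta.subset(probes[keep]), report


# ---------------------------------------------------------------------------
# Island-relative annotation
# ---------------------------------------------------------------------------


def annotate_island_relation(
    pos: int,
    strand_of_gene: str,
    islands: Sequence[tuple[int, int]],
) -> str:
    """Classify a position relative to CpG islands (all 1-based inclusive).

    Distance to the nearest island edge d: inside an island -> ``Island``;
    0 < d <= 2000 -> shore; 2000 < d <= 4000 -> shelf; beyond -> ``OpenSea``.
    The north/south prefix is strand-aware: north is 5' of the associated
    gene, so for a minus-strand gene the upstream (north) side lies at
    higher coordinates.
    """
    if strand_of_gene not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand_of_gene!r}")
    if not islands:
        return "OpenSea"

    best_d = None
    best_left = True  # position lies left (lower coordinate) of its nearest island
    for start, end in islands:
        if start <= pos <= end:
            return "Island"
        if pos < start:
            d, left = start - pos, True
        else:
            d, left = pos - end, False
        if best_d is None or d < best_d:
            best_d, best_left = d, left

    if best_d > 4000:
        return "OpenSea"
    band = "Shore" if best_d <= 2000 else "Shelf"
    upstream = best_left if strand_of_gene == "+" else not best_left
    return f"{'N' if upstream else 'S'}_{band}"


# ---------------------------------------------------------------------------
# CpG island discovery
# ---------------------------------------------------------------------------


def _window_ok(
    gc_frac: float, oe: float, n_count: int, min_gc: float, min_oe: float
) -> bool:
    return n_count == 0 and gc_frac > min_gc and oe > min_oe


def _interval_stats(
    cum_c: np.ndarray, cum_g: np.ndarray, cum_cg: np.ndarray, cum_n: np.ndarray, i: int, j: int
) -> tuple[float, float, int]:
    """GC fraction, observed/expected CpG ratio and N count for seq[i:j]."""
    length = j - i
    c = int(cum_c[j] - cum_c[i])
    g = int(cum_g[j] - cum_g[i])
    # CG dinucleotides fully inside [i, j)
    cg = int(cum_cg[max(j - 1, i)] - cum_cg[i])
    n = int(cum_n[j] - cum_n[i])
    gc_frac = (c + g) / length
    oe = (cg * length) / (c * g) if c > 0 and g > 0 else 0.0
    return gc_frac, oe, n


def find_cpg_islands(
    seq: str,
    min_len: int = 500,
    min_gc: float = 0.55,
    min_oe: float = 0.65,
) -> list[tuple[int, int]]:
    """Locate CpG islands by the classic sliding-window composition rule.

    A window of ``min_len`` bp qualifies when its GC fraction exceeds
    ``min_gc`` and its observed-to-expected CpG ratio
    ``count(CG) * L / (count(C) * count(G))`` exceeds ``min_oe``; windows
    containing N never qualify.  The scan steps 1 bp; overlapping or
    adjacent qualifying windows are merged, and each merged interval is
    re-tested as a whole, trimming one base from both ends per step until
    it satisfies both criteria or shrinks below ``min_len`` (discarded).

    Returns non-overlapping (start, end) intervals, 1-based inclusive.
    """
    seq = seq.upper()
    n = len(seq)
    if n < min_len:
        return []

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    is_cg = np.zeros(n, dtype=bool)
    is_cg[:-1] = is_c[:-1] & is_g[1:]

    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])

    L = min_len
    starts = np.arange(0, n - L + 1)
    c = cum_c[starts + L] - cum_c[starts]
    g = cum_g[starts + L] - cum_g[starts]
    cg = cum_cg[starts + L - 1] - cum_cg[starts]
    nn = cum_n[starts + L] - cum_n[starts]
    gc_frac = (c + g) / L
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((c > 0) & (g > 0), cg * L / np.maximum(c * g, 1), 0.0)
    ok = (nn == 0) & (gc_frac > min_gc) & (oe > min_oe)

    islands: list[tuple[int, int]] = []
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return islands

    # contiguous runs of qualifying window starts -> merged candidate intervals
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_bounds = zip(
        np.concatenate([[0], breaks + 1]), np.concatenate([breaks, [idx.size - 1]])
    )
    for a, b in run_bounds:
        i, j = int(idx[a]), int(idx[b]) + L  # 0-based half-open candidate
        while j - i >= min_len:
            gcf, oev, ncount = _interval_stats(cum_c, cum_g, cum_cg, cum_n, i, j)
            if _window_ok(gcf, oev, ncount, min_gc, min_oe):
                islands.append((i + 1, j))  # to 1-based inclusive
                break
            i += 1
            j -= 1
    return islands


# ---------------------------------------------------------------------------
# Region-wise methylation summary
# ---------------------------------------------------------------------------


def region_methylation_summary(
    beta: BetaMatrix,
    manifest: Manifest,
    meth_cut: float = 0.6,
    unmeth_cut: float = 0.3,
) -> pd.DataFrame:
    """Fraction of CpGs methylated / intermediate / unmethylated per
    sample and island-relation class.

    A CpG is methylated when beta >= ``meth_cut``, unmethylated when
    beta < ``unmeth_cut``, intermediate otherwise; missing betas are
    excluded from the denominators.  Fractions sum to 1 in every class.
    """
    relation = manifest.df.reindex(beta.probes)["island_relation"]
    rows = []
    for sample in beta.samples:
        vals = beta.beta[sample]
        for rel, grp in vals.groupby(relation):
            grp = grp.dropna()
            total = len(grp)
            if total == 0:
                continue
            meth = int((grp >= meth_cut).sum())
            unmeth = int((grp < unmeth_cut).sum())
            rows.append(
                {
                    "sample": sample,
                    "island_relation": rel,
                    "n_cpgs": total,
                    "methylated": meth / total,
                    "intermediate": (total - meth - unmeth) / total,
                    "unmethylated": unmeth / total,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene-level island aggregation and methylation calls
# ---------------------------------------------------------------------------


def _island_probe_frame(beta: BetaMatrix, manifest: Manifest) -> pd.DataFrame:
    """Long-format island-probe betas annotated with gene and region basis.

    Multi-gene and multi-site probes are excluded; probes on multiple
    islands of the same gene are pooled (the aggregate is the mean over all
    qualifying CpGs, not a mean of island means).
    """
    ann = manifest.df.reindex(beta.probes)
    usable = (
        (ann["island_relation"] == "Island")
        & ~ann["multi_gene"].fillna(False).astype(bool)
        & ~ann["multi_site"].fillna(False).astype(bool)
    )
    ann = ann.loc[usable]
    basis = np.where(
        ann["gene_region"].isin(TSS_REGIONS),
        "TSS",
        np.where(ann["gene_region"] == "Body", "Body", ""),
    )
    ann = ann.assign(region_basis=basis)
    ann = ann.loc[ann["region_basis"] != ""]
    if ann.empty:
        return pd.DataFrame(columns=["gene", "region_basis", "sample", "beta"])

    long = (
        beta.beta.loc[ann.index]
        .join(ann[["gene_symbols", "region_basis"]])
        .explode("gene_symbols")
        .rename(columns={"gene_symbols": "gene"})
        .dropna(subset=["gene"])
        .melt(id_vars=["gene", "region_basis"], var_name="sample", value_name="beta")
        .dropna(subset=["beta"])
    )
    return long


def gene_island_beta(beta: BetaMatrix, manifest: Manifest) -> pd.DataFrame:
    """Per gene x sample mean beta over TSS-associated and body island CpGs.

    Returns columns ``gene``, ``sample``, ``tss_island_mean_beta``,
    ``tss_island_cpg_count``, ``body_island_mean_beta``,
    ``body_island_cpg_count``; an aggregate is NaN exactly when its CpG
    count is 0 (genes with no qualifying probes in a region get no value,
    never a default).
    """
    long = _island_probe_frame(beta, manifest)
    if long.empty:
        return pd.DataFrame(
            columns=[
                "gene",
                "sample",
                "tss_island_mean_beta",
                "tss_island_cpg_count",
                "body_island_mean_beta",
                "body_island_cpg_count",
            ]
        )
    agg = (
        long.groupby(["gene", "sample", "region_basis"])["beta"]
        .agg(["mean", "count"])
        .unstack("region_basis")
    )
    out = pd.DataFrame(index=agg.index)
    for basis, prefix in (("TSS", "tss"), ("Body", "body")):
        mean = agg.get(("mean", basis))
        count = agg.get(("count", basis))
        out[f"{prefix}_island_mean_beta"] = mean if mean is not None else np.nan
        out[f"{prefix}_island_cpg_count"] = (
            count.fillna(0).astype(int) if count is not None else 0
        )
    return out.reset_index()


def call_methylated(profiles: pd.DataFrame, cut: float = 0.6) -> pd.DataFrame:
    """Binary methylation call per gene x sample x region basis.

    A gene is methylated in a region when its island-mean beta is >= ``cut``
    (boundary inclusive).  Missing aggregates yield no call (pd.NA).
    """
    out = profiles.copy()
    for prefix in ("tss", "body"):
        mean = out[f"{prefix}_island_mean_beta"]
        out[f"{prefix}_methylated"] = pd.array(
            np.where(mean.isna(), None, mean >= cut), dtype="boolean"
        )
    return out


def delta_beta(profiles: pd.DataFrame, reference_sample: str) -> pd.DataFrame:
    """Differential methylation of every sample against the reference.

    One record per gene x non-reference sample x region basis where both
    the target and reference island aggregates exist; the score is
    target mean beta minus reference mean beta (negative values retained).
    """
    if reference_sample not in set(profiles["sample"]):
        raise ValueError(f"reference sample {reference_sample!r} not in profiles")
    records = []
    for basis, prefix in (("TSS", "tss"), ("Body", "body")):
        col = f"{prefix}_island_mean_beta"
        wide = profiles.pivot(index="gene", columns="sample", values=col)
        ref = wide[reference_sample]
        for sample in wide.columns:
            if sample == reference_sample:
                continue
            d = wide[sample] - ref
            d = d.dropna()
            records.append(
                pd.DataFrame(
                    {
                        "gene": d.index,
                        "target_sample": sample,
                        "reference_sample": reference_sample,
                        "region_basis": basis,
                        "delta_beta": d.to_numpy(),
                    }
                )
            )
    if not records:
        return pd.DataFrame(
            columns=["gene", "target_sample", "reference_sample", "region_basis", "delta_beta"]
        )
    return pd.concat(records, ignore_index=True)
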