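"""Methylation-expression integration: the core contingency analysis.

Genes are binned by differential island methylation (delta-beta, 0.05-wide
bins) and cross-tabulated against three expression categories: correlating
(>= 2-fold lower expression in the methylated target line), no difference,
and anti-correlating (>= 2-fold higher in the target).  Expected counts per
bin come from the table-wide column marginals under the null hypothesis
that lower expression does not associate with methylation; each bin gets a
Pearson chi-squared statistic on 2 degrees of freedom (no continuity
correction — this reproduces the published per-bin p-values).

The silencing threshold is chosen from the data: the lowest bin whose
observed correlating count is at least twice its expected value with
p < 0.05, provided no lower bin also qualifies.  Genes at or above that
cut with a >= 2-fold expression deficit are classified as silenced by
methylation, on a TSS-island or gene-body-island basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome import HIGHER_IN_REFERENCE, HIGHER_IN_TARGET, NO_DIFFERENCE

__all__ = [
    "ContingencyBin",
    "ThresholdDecision",
    "BinnedDeltaBeta",
    "bin_delta_beta",
    "contingency_table",
    "contingency_from_counts",
    "select_threshold",
    "classify_silenced",
    "methylation_venn",
    "stars_for_p",
]

CATEGORIES = (HIGHER_IN_REFERENCE, NO_DIFFERENCE, HIGHER_IN_TARGET)


def stars_for_p(p: float | None) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ContingencyBin:
    """One delta-beta interval of the observed/expected contingency table."""

    bin_lo: float
    bin_hi: float
    obs: tuple[int, int, int]  # correlating, no difference, anti-correlating
    exp: tuple[float, float, float]
    total: int
    chi2: float | None
    p: float | None
    stars: str


@dataclass(frozen=True)
class ThresholdDecision:
    """Outcome of the data-driven delta-beta threshold search."""

    comparison: str
    selected_delta_beta_cut: float | None
    qualifying: dict[float, bool]


@dataclass(frozen=True)
class BinnedDeltaBeta:
    """Delta-beta bin assignment plus the reciprocal (negative) gene set."""

    bins: dict[float, set[str]]
    negative_genes: set[str]


def bin_delta_beta(records: pd.DataFrame, width: float = 0.05) -> BinnedDeltaBeta:
    """Assign genes to half-open delta-beta bins [k*w, (k+1)*w).

    ``records`` must be restricted to one comparison and one region basis.
    A delta of exactly 1.0 falls in the top bin; genes with negative delta
    (reference hypermethylated relative to target) are excluded from the
    table and returned separately.
    """
    if len(records) and records["gene"].duplicated().any():
        dup = records.loc[records["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(
            f"gene {dup!r} appears twice; restrict records to one comparison "
            "and one region basis before binning"
        )
    top = int(round(1.0 / width)) - 1
    bins: dict[float, set[str]] = {}
    negative: set[str] = set()
    for gene, d in zip(records["gene"], records["delta_beta"]):
        if d < 0:
            negative.add(gene)
            continue
        k = min(int(np.floor(d / width + 1e-9)), top)
        bins.setdefault(round(k * width, 10), set()).add(gene)
    return BinnedDeltaBeta(bins, negative)


def contingency_from_counts(
    obs: np.ndarray, bin_lo: np.ndarray, width: float = 0.05
) -> list[ContingencyBin]:
    """Build the contingency table from an (n_bins, 3) observed-count array.

    Expected counts are row_total x column_marginal / grand_total with
    marginals over the whole table; chi-squared has 2 df with no continuity
    correction.  Bins with zero total keep exp = 0 and an undefined p
    (reported blank), never dropped.
    """
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observed counts must have shape (n_bins, 3)")
    if obs.size == 0:
        raise ValueError("empty contingency table")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    grand = obs.sum()
    if grand == 0:
        raise ValueError("contingency table has no genes")

    out: list[ContingencyBin] = []
    for i, lo in enumerate(np.asarray(bin_lo, dtype=float)):
        exp = row_tot[i] * col_tot / grand
        if row_tot[i] == 0:
            chi2_val: float | None = None
            p: float | None = None
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(exp > 0, (obs[i] - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
            chi2_val = float(terms.sum())
            p = float(stats.chi2.sf(chi2_val, df=2))
        out.append(
            ContingencyBin(
                bin_lo=round(float(lo), 10),
                bin_hi=round(float(lo) + width, 10),
                obs=tuple(int(x) for x in obs[i]),
                exp=tuple(float(x) for x in exp),
                total=int(row_tot[i]),
                chi2=chi2_val,
                p=p,
                stars=stars_for_p(p if p is not None else float("nan")),
            )
        )
    return out


def contingency_table(
    binned: BinnedDeltaBeta | Mapping[float, set[str]],
    fc: pd.DataFrame,
    width: float = 0.05,
) -> list[ContingencyBin]:
    """Cross-tabulate binned genes against expression categories.

    ``fc`` must carry one fold-change record per binned gene (columns
    ``gene`` and ``direction``); a missing record is an error — genes
    without expression data must be excluded before binning.  Empty bins
    between occupied ones are retained with zero counts.
    """
    bins = binned.bins if isinstance(binned, BinnedDeltaBeta) else dict(binned)
    if not bins:
        raise ValueError("empty contingency table: no binned genes")
    direction = fc.set_index("gene")["direction"]
    if direction.index.has_duplicates:
        raise ValueError("fold-change table has duplicate genes for one comparison")

    max_lo = max(bins)
    n_bins = int(round(max_lo / width)) + 1
    lows = np.round(np.arange(n_bins) * width, 10)
    obs = np.zeros((n_bins, 3), dtype=int)
    for lo, genes in bins.items():
        i = int(round(lo / width))
        for gene in genes:
            if gene not in direction.index:
                raise ValueError(f"no fold-change record for binned gene {gene!r}")
            obs[i, CATEGORIES.index(direction[gene])] += 1
    return contingency_from_counts(obs, lows, width=width)


def select_threshold(
    table: list[ContingencyBin],
    ratio_min: float = 2.0,
    alpha: float = 0.05,
    comparison: str = "",
) -> ThresholdDecision:
    """Pick the data-driven delta-beta cut from the contingency table.

    A bin qualifies when its observed correlating count is at least
    ``ratio_min`` times the expected value (substantial) and its
    chi-squared p is below ``alpha`` (significant).  The selected cut is
    the lowest qualifying bin boundary with no qualifying bin below it;
    None when no bin qualifies.
    """
    qualifying: dict[float, bool] = {}
    for b in table:
        ok = (
            b.p is not None
            and b.p < alpha
            and b.exp[0] > 0
            and b.obs[0] >= ratio_min * b.exp[0]
        )
        qualifying[b.bin_lo] = bool(ok)
    hits = sorted(lo for lo, ok in qualifying.items() if ok)
    return ThresholdDecision(
        comparison=comparison,
        selected_delta_beta_cut=hits[0] if hits else None,
        qualifying=qualifying,
    )


def classify_silenced(
    delta: pd.DataFrame,
    fc: pd.DataFrame,
    cut: float,
    fold_cut: float = 2.0,
) -> pd.DataFrame:
    """Call genes silenced by methylation for one comparison.

    A TSS call requires delta-beta >= ``cut`` on the TSS-island basis and a
    >= ``fold_cut`` expression deficit in the target line
    (higher_in_reference); a Body call likewise on the gene-body basis.
    Body calls carry ``body_only=True`` when the gene has no TSS-island
    aggregate or its TSS delta-beta is below the cut — silencing there is
    attributable to body-island methylation alone.

    Raising the cut can only shrink the call set (monotonicity).
    """
    fcx = fc.set_index("gene")
    tss_delta = (
        delta.loc[delta["region_basis"] == "TSS"].set_index("gene")["delta_beta"]
    )
    rows = []
    for basis in ("TSS", "Body"):
        sub = delta.loc[delta["region_basis"] == basis]
        for row in sub.itertuples(index=False):
            if row.delta_beta < cut:
                continue
            if row.gene not in fcx.index:
                continue  # no expression data: cannot enter any category
            rec = fcx.loc[row.gene]
            if rec["direction"] != HIGHER_IN_REFERENCE or rec["fold_change"] < fold_cut:
                continue
            body_only = False
            if basis == "Body":
                body_only = (
                    row.gene not in tss_delta.index
                    or tss_delta[row.gene] < cut
                )
            rows.append(
                {
                    "gene": row.gene,
                    "comparison": row.target_sample,
                    "region_basis": basis,
                    "delta_beta": row.delta_beta,
                    "fold_change": float(rec["fold_change"]),
                    "body_only": body_only,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "comparison", "region_basis", "delta_beta", "fold_change", "body_only"],
    )


def methylation_venn(calls: Mapping[str, Iterable[str]]) -> dict[frozenset, int]:
    """Exact disjoint-region counts for per-sample methylated-gene sets.

    Returns one entry per non-empty subset of sample names (2^k - 1 keys),
    counting the genes belonging to exactly that subset; region counts sum
    to the size of the union.
    """
    sets = {name: set(v) for name, v in calls.items()}
    names = list(sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions[frozenset(combo)] = len(inside - outside)
    return regions
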