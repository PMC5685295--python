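"""Concordance of cell-line silencing calls with external tumour cohorts.

External studies enter as per-gene fold-change tables (expression in the
reference-like histology over the target-like histology).  A silencing call
is concordant with a study when the external fold change exceeds the
concordance cut (default 1.5-fold, strict) in the same direction; genes
absent from a study are 'not assessable' there and excluded from both
numerator and denominator.  Overlap significance uses the one-sided
upper-tail binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OverlapTest", "concordance_with_primary", "binomial_overlap"]


@dataclass(frozen=True)
class OverlapTest:
    """One-sided binomial test of a set overlap against a background rate."""

    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    background_rate: float
    p_value: float


def _external_series(table: pd.DataFrame) -> pd.Series:
    if "gene" in table.columns and "fold" in table.columns:
        s = table.set_index("gene")["fold"]
    elif table.shape[1] >= 2:
        s = table.set_index(table.columns[0])[table.columns[1]]
    else:
        raise ValueError("external table needs (gene, fold) columns")
    s.index = s.index.astype(str).str.upper()
    if s.index.has_duplicates:
        s = s.groupby(level=0).max()
    return s.astype(float)


def concordance_with_primary(
    calls: pd.DataFrame,
    external: Mapping[str, pd.DataFrame],
    fold_cut: float = 1.5,
) -> pd.DataFrame:
    """Mark each silenced gene's concordance with external cohorts.

    ``calls`` needs a ``gene`` column (one row per call; duplicate genes are
    collapsed).  Gene symbols match case-insensitively and exactly — alias
    resolution is a data-curation step, and unmatched genes are recorded as
    not assessable.  Returns one row per called gene with the external fold
    per study, per-study concordance flags (fold strictly > ``fold_cut``),
    ``n_assessable``, ``concordant_any`` and ``concordant_all`` (the latter
    over the studies where the gene is assessable, False when none are).
    """
    studies = {name: _external_series(tab) for name, tab in external.items()}
    genes = sorted(set(calls["gene"].astype(str)))
    rows = []
    for gene in genes:
        key = gene.upper()
        row: dict = {"gene": gene}
        flags = []
        for name, folds in sorted(studies.items()):
            fold = folds.get(key, np.nan)
            row[f"fold_{name}"] = fold
            conc = bool(fold > fold_cut) if not np.isnan(fold) else None
            row[f"concordant_{name}"] = conc
            if conc is not None:
                flags.append(conc)
        row["n_assessable"] = len(flags)
        row["concordant_any"] = any(flags)
        row["concordant_all"] = bool(flags) and all(flags)
        rows.append(row)
    return pd.DataFrame(rows)


def binomial_overlap(
    n: int, k: int, m: int, p0: float | None = None, set_b_size: int | None = None
) -> OverlapTest:
    """Upper-tail binomial probability of observing >= k overlaps.

    ``m`` genes are tested against a comparison set within a universe of
    ``n`` genes; under the null each tested gene hits the comparison set
    independently with probability ``p0`` (defaulting to set_b_size / n).
    The survival function is evaluated in log space by scipy, so extreme
    tails (p < 1e-30) remain accurate.
    """
    if not (0 <= k <= m <= n):
        raise ValueError(f"need 0 <= k <= m <= n, got k={k}, m={m}, n={n}")
    if p0 is None:
        if set_b_size is None:
            raise ValueError("give p0 or set_b_size")
        if not (0 <= set_b_size <= n):
            raise ValueError("set_b_size must lie within the universe")
        p0 = set_b_size / n
    if not (0 <= p0 <= 1):
        raise ValueError(f"background rate must be in [0, 1], got {p0}")
    p = float(stats.binom.sf(k - 1, m, p0)) if k > 0 else 1.0
    return OverlapTest(
        universe_size=n,
        set_a_size=m,
        set_b_size=set_b_size if set_b_size is not None else int(round(p0 * n)),
        overlap=k,
        background_rate=float(p0),
        p_value=min(p, 1.0),
    )
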