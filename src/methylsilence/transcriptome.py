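"""Expression filtering, gene aggregation, fold changes and group tests.

Fold changes are computed on the normalized linear intensity scale as
max(reference, target) / min(reference, target) with the direction carried
separately, so every fold change is >= 1 and a record is 'no difference'
exactly when the ratio is below the two-fold cut.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = [
    "background_filter",
    "aggregate_probes_to_genes",
    "fold_changes",
    "welch_one_tailed",
    "HIGHER_IN_REFERENCE",
    "HIGHER_IN_TARGET",
    "NO_DIFFERENCE",
]

HIGHER_IN_REFERENCE = "higher_in_reference"
HIGHER_IN_TARGET = "higher_in_target"
NO_DIFFERENCE = "no_difference"


def background_filter(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose signal is below control background in every sample.

    A gene survives if it exceeds (or equals) the per-sample background
    threshold in at least one sample; it is removed only when it fails in
    all of them.
    """
    below = expr.values.lt(expr.background, axis=1)
    keep = ~below.all(axis=1)
    return ExpressionMatrix(expr.values.loc[keep], expr.background.copy())


def aggregate_probes_to_genes(
    expr: ExpressionMatrix, probe2gene: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Collapse probe-level intensities to genes by the unweighted mean.

    Probes missing from the mapping are dropped.
    """
    mapping = pd.Series(probe2gene)
    genes = mapping.reindex(expr.values.index)
    vals = expr.values.loc[genes.notna()]
    gene_vals = vals.groupby(genes.dropna()).mean()
    gene_vals.index.name = expr.values.index.name
    return ExpressionMatrix(gene_vals, expr.background.copy())


def fold_changes(
    expr: ExpressionMatrix, reference_sample: str, de_cut: float = 2.0
) -> pd.DataFrame:
    """Per-gene fold change of every sample against the reference.

    Returns columns ``gene``, ``target_sample``, ``reference_sample``,
    ``fold_change`` (>= 1) and ``direction``
    (higher_in_reference / higher_in_target / no_difference, the latter
    whenever the ratio is < ``de_cut``).  Requires strictly positive
    intensities (run the background filter and aggregation first).
    """
    if reference_sample not in expr.values.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    nonpos = expr.values.le(0).any(axis=1)
    if nonpos.any():
        raise ValueError(
            f"non-positive intensity for gene {expr.values.index[nonpos][0]!r}; "
            "fold changes need strictly positive values"
        )
    ref = expr.values[reference_sample]
    frames = []
    for sample in expr.values.columns:
        if sample == reference_sample:
            continue
        target = expr.values[sample]
        ratio = np.maximum(ref, target) / np.minimum(ref, target)
        direction = np.where(
            ratio < de_cut,
            NO_DIFFERENCE,
            np.where(ref > target, HIGHER_IN_REFERENCE, HIGHER_IN_TARGET),
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene": expr.values.index,
                    "target_sample": sample,
                    "reference_sample": reference_sample,
                    "fold_change": ratio.to_numpy(),
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def welch_one_tailed(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test, right tail (mean(a) > mean(b)).

    Uses the Welch-Satterthwaite degrees of freedom.  When both groups are
    constant and equal the statistic is defined as 0 with p = 0.5 (no
    evidence either way); each group needs at least two observations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, 0.5
        return (np.inf if diff > 0 else -np.inf), (0.0 if diff > 0 else 1.0)
    t = diff / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = float(stats.t.sf(t, df))
    return float(t), p
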