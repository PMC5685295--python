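"""Efficiency-corrected relative quantification for demethylation assays.

After treating cells with a demethylating agent (5-aza-2-deoxycytidine),
reactivation of a silenced gene shows up as a lower threshold cycle (Ct)
in the treated condition.  The relative expression ratio against a
housekeeping reference (ACTB in the original experiments) is the Pfaffl
ratio

    ratio = E_target ** dCt_target / E_ref ** dCt_ref,

with dCt = mean Ct(control) - mean Ct(treated) and E the amplification
efficiency per cycle (2 = perfect doubling).  Significance of reactivation
is assessed by a seed-controlled bootstrap over replicates, since a ratio
of means carries no closed-form null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QpcrAssay", "pfaffl_ratio", "reactivation_test", "read_ct_table"]


@dataclass(frozen=True)
class QpcrAssay:
    """Replicate Ct values for one gene under control and treated conditions."""

    gene: str
    ct_control: tuple[float, ...]
    ct_treated: tuple[float, ...]
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ct_control", tuple(float(x) for x in self.ct_control))
        object.__setattr__(self, "ct_treated", tuple(float(x) for x in self.ct_treated))
        if not self.ct_control or not self.ct_treated:
            raise ValueError(f"{self.gene}: need >= 1 Ct replicate per condition")
        if any(x <= 0 for x in self.ct_control + self.ct_treated):
            raise ValueError(f"{self.gene}: Ct values must be positive")
        if not (1.0 <= self.efficiency <= 2.2):
            raise ValueError(
                f"{self.gene}: amplification efficiency {self.efficiency} outside [1, 2.2]"
            )

    @property
    def delta_ct(self) -> float:
        """Mean Ct(control) - mean Ct(treated); positive when reactivated."""
        return float(np.mean(self.ct_control) - np.mean(self.ct_treated))


def read_ct_table(
    table: pd.DataFrame, gene: str, condition_col: str = "condition", efficiency: float = 2.0
) -> QpcrAssay:
    """Build an assay from a tidy (gene, condition, replicate, ct) table."""
    sub = table.loc[table["gene"].astype(str) == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not present in Ct table")
    ctrl = sub.loc[sub[condition_col] == "control", "ct"].astype(float)
    trt = sub.loc[sub[condition_col] == "treated", "ct"].astype(float)
    return QpcrAssay(gene, tuple(ctrl), tuple(trt), efficiency)


def pfaffl_ratio(target: QpcrAssay, reference: QpcrAssay) -> float:
    """Relative expression ratio of target vs reference gene (Pfaffl)."""
    return float(
        target.efficiency**target.delta_ct / reference.efficiency**reference.delta_ct
    )


def reactivation_test(
    target: QpcrAssay,
    reference: QpcrAssay,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Point ratio plus a one-sided bootstrap p for reactivation (ratio > 1).

    Each bootstrap draw resamples the replicates of all four gene x
    condition cells with replacement and recomputes the Pfaffl ratio; the
    p-value is the add-one-smoothed fraction of bootstrap ratios <= 1.
    Deterministic for a fixed seed; requires >= 3 replicates per condition.
    """
    cells = (target.ct_control, target.ct_treated, reference.ct_control, reference.ct_treated)
    if any(len(c) < 3 for c in cells):
        raise ValueError("reactivation test needs >= 3 replicates per condition")
    rng = np.random.default_rng(seed)
    arrs = [np.asarray(c) for c in cells]
    means = [
        a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1) for a in arrs
    ]
    d_t = means[0] - means[1]
    d_r = means[2] - means[3]
    ratios = target.efficiency**d_t / reference.efficiency**d_r
    p = (1 + int((ratios <= 1.0).sum())) / (n_boot + 1)
    return pfaffl_ratio(target, reference), float(p)
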