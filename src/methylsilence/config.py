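"""Analysis configuration: every named threshold with its default value.

The defaults are the published analysis settings; a YAML config file can
override any subset of them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    # probe QC
    detp_threshold: float = 0.05          # mean detection p above this -> probe removed
    log2_intensity_min: float = 11.1      # averaged log2 signal below this (either channel) -> removed
    conversion_ratio_max: float = 0.2     # samples at/above this bisulfite ratio are flagged
    # methylation calling
    meth_cut: float = 0.6                 # island-mean beta >= this -> methylated
    unmeth_cut: float = 0.3               # beta < this -> unmethylated
    # island discovery
    island_min_len: int = 500
    island_min_gc: float = 0.55
    island_min_oe: float = 0.65
    # integration
    bin_width: float = 0.05
    de_cut: float = 2.0                   # fold-change magnitude for 'differentially expressed'
    ratio_min: float = 2.0                # observed >= ratio_min x expected -> 'substantial'
    alpha: float = 0.05
    # cross-study concordance
    concordance_fold_cut: float = 1.5
    # qPCR
    qpcr_efficiency: float = 2.0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Merge a YAML file (if any) over the default thresholds."""
    if path is None:
        return AnalysisConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return AnalysisConfig(**data)
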