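import numpy as np
import pandas as pd
import pytest

from methylsilence import BetaMatrix, Manifest

MANIFEST_DEFAULTS = dict(
    gene_symbols="",
    chrom="chr1",
    pos=100,
    gene_region="Body",
    island_relation="OpenSea",
    island_id="",
)


def manifest_from_rows(rows):
    """Build a validated Manifest from partial row dicts."""
    recs = []
    for i, r in enumerate(rows):
        recs.append({"probe_id": f"cg{i:03d}", **MANIFEST_DEFAULTS, **r})
    return Manifest.from_frame(pd.DataFrame(recs))


def beta_from_dict(values, samples=("ref", "t1")):
    """BetaMatrix from {probe_id: (beta per sample)}."""
    df = pd.DataFrame.from_dict(values, orient="index", columns=list(samples))
    return BetaMatrix(df.astype(float))


@pytest.fixture
def island_gene():
    """One gene with pooled TSS islands (2 + 4 probes), a body island and
    an open-sea probe; a second gene with only open-sea probes."""
    rows = [
        # gene A: TSS island 1 (2 probes), TSS island 2 (4 probes)
        {"gene_symbols": "A", "gene_region": "TSS200", "island_relation": "Island", "island_id": "cgi1", "pos": 1000},
        {"gene_symbols": "A", "gene_region": "TSS1500", "island_relation": "Island", "island_id": "cgi1", "pos": 1050},
        {"gene_symbols": "A", "gene_region": "UTR5", "island_relation": "Island", "island_id": "cgi2", "pos": 2000},
        {"gene_symbols": "A", "gene_region": "FirstExon", "island_relation": "Island", "island_id": "cgi2", "pos": 2040},
        {"gene_symbols": "A", "gene_region": "TSS200", "island_relation": "Island", "island_id": "cgi2", "pos": 2080},
        {"gene_symbols": "A", "gene_region": "TSS1500", "island_relation": "Island", "island_id": "cgi2", "pos": 2120},
        # gene A body island
        {"gene_symbols": "A", "gene_region": "Body", "island_relation": "Island", "island_id": "cgi3", "pos": 5000},
        {"gene_symbols": "A", "gene_region": "Body", "island_relation": "Island", "island_id": "cgi3", "pos": 5050},
        # gene A open sea (never aggregated)
        {"gene_symbols": "A", "gene_region": "Body", "island_relation": "OpenSea", "pos": 9000},
        # gene B: open sea only
        {"gene_symbols": "B", "island_relation": "OpenSea", "pos": 20000},
        {"gene_symbols": "B", "island_relation": "OpenSea", "pos": 21000},
    ]
    manifest = manifest_from_rows(rows)
    tss = [0.10, 0.20, 0.65, 0.70, 0.75, 0.80]  # pooled mean (ref)
    beta = beta_from_dict(
        {
            "cg000": (tss[0], 0.90),
            "cg001": (tss[1], 0.92),
            "cg002": (tss[2], 0.88),
            "cg003": (tss[3], 0.91),
            "cg004": (tss[4], 0.95),
            "cg005": (tss[5], 0.89),
            "cg006": (0.10, 0.85),
            "cg007": (0.20, 0.87),
            "cg008": (0.50, 0.50),
            "cg009": (0.40, 0.60),
            "cg010": (0.45, 0.55),
        }
    )
    return manifest, beta
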