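"""Tabular input/output for the methylation-silencing pipeline.

This module owns every on-disk format the pipeline touches: the probe
annotation manifest (CSV), beta-value / detection-p / expression matrices
(TSV), result export (TSV tables, a JSON run summary and a BED track of
differentially methylated islands), and the packaged worked-example
contingency table of observed differential-expression counts per
differential-methylation bin.

Coordinates are 1-based inclusive internally (array-manifest convention);
only the BED export converts to 0-based half-open.  Missing beta values
are NaN, never 0 — a beta of 0 is a legitimate fully-unmethylated call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Manifest",
    "BetaMatrix",
    "ExpressionMatrix",
    "Table1Fixture",
    "read_manifest",
    "read_matrix",
    "load_table1_fixture",
    "write_results",
    "GENE_REGIONS",
    "ISLAND_RELATIONS",
    "TSS_REGIONS",
]

GENE_REGIONS = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: gene-region labels whose island probes contribute to the TSS-associated
#: aggregate (within 1,500 bp upstream of the TSS, the 5'UTR or first exon)
TSS_REGIONS = frozenset({"TSS1500", "TSS200", "UTR5", "FirstExon"})

MANIFEST_COLUMNS = (
    "probe_id",
    "gene_symbols",
    "chrom",
    "pos",
    "gene_region",
    "island_relation",
    "island_id",
)


class FormatError(ValueError):
    """An input file violates the expected tabular contract."""


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Manifest:
    """Validated probe annotation table, indexed by probe id.

    Columns: ``gene_symbols`` (tuple of symbols, possibly empty), ``chrom``,
    ``pos`` (1-based bp), ``gene_region``, ``island_relation``, ``island_id``
    (None unless the probe sits in an island), plus derived boolean flags
    ``multi_gene`` (probe annotated to more than one gene; such probes are
    excluded from gene-level analysis downstream) and ``multi_site`` (probe
    mapping to multiple genomic sites, chrom label containing "MULTI").
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Manifest":
        missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"manifest is missing column(s): {', '.join(missing)}")
        df = frame.loc[:, list(MANIFEST_COLUMNS)].copy()

        dup = df["probe_id"][df["probe_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate probe_id: {dup.iloc[0]!r}")

        try:
            df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric pos in manifest: {exc}") from exc
        bad_pos = df.index[df["pos"] < 1]
        if len(bad_pos):
            raise FormatError(f"manifest row {bad_pos[0]}: pos must be >= 1")

        for col, allowed in (("gene_region", GENE_REGIONS), ("island_relation", ISLAND_RELATIONS)):
            bad = df.loc[~df[col].isin(allowed), col]
            if len(bad):
                raise FormatError(
                    f"manifest row {bad.index[0]}: unparseable {col} {bad.iloc[0]!r}"
                )

        symbols = df["gene_symbols"].fillna("").astype(str)
        df["gene_symbols"] = [
            tuple(s for s in cell.split(";") if s) for cell in symbols
        ]
        df["multi_gene"] = [len(t) > 1 for t in df["gene_symbols"]]
        df["multi_site"] = df["chrom"].astype(str).str.upper().str.contains("MULTI")

        island_id = df["island_id"]
        if island_id.dtype != object:
            island_id = island_id.astype(object)
        df["island_id"] = island_id.where(island_id.notna() & (island_id != ""), None)
        no_id = df.index[(df["island_relation"] == "Island") & df["island_id"].isna()]
        if len(no_id):
            raise FormatError(
                f"manifest row {no_id[0]}: island_relation=Island requires island_id"
            )

        df = df.set_index("probe_id")
        return cls(df)

    def subset(self, probe_ids) -> "Manifest":
        return Manifest(self.df.loc[probe_ids])


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate the probe annotation manifest (CSV).

    Multiple gene symbols are ';'-separated in the ``gene_symbols`` column;
    such probes are retained but flagged ``multi_gene`` for downstream
    exclusion.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"cannot parse manifest {path}: {exc}") from exc
    return Manifest.from_frame(frame)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def _validate_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    try:
        out = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in {what} matrix: {exc}") from exc
    return out.astype(float)


@dataclass
class BetaMatrix:
    """Probe x sample beta values with optional parallel QC tables.

    ``beta`` holds methylation fractions in [0, 1] (NaN = failed probe);
    ``detection_p`` is the aligned per-probe detection p-value table;
    ``intensity`` holds per-probe averaged log2 signal intensity, one column
    per channel (e.g. ``log2_red``, ``log2_green``).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    intensity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value out of [0, 1] at probe {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}: {vals[i, j]}"
            )
        if self.detection_p is not None:
            dp = self.detection_p
            if not dp.index.equals(self.beta.index) or not dp.columns.equals(self.beta.columns):
                # tolerate same labels in different order
                try:
                    self.detection_p = dp.loc[self.beta.index, self.beta.columns]
                except KeyError as exc:
                    raise FormatError(
                        "detection-p table is not aligned with the beta table"
                    ) from exc

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns

    def subset(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(
            self.beta.loc[probe_ids],
            None if self.detection_p is None else self.detection_p.loc[probe_ids],
            None if self.intensity is None else self.intensity.loc[probe_ids],
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample normalized expression intensities (non-negative).

    ``background`` holds the per-sample control-background threshold below
    which a signal is considered unreliable; defaults to 0 for every sample.
    """

    values: pd.DataFrame
    background: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id in expression matrix: {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = vals < 0
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"negative expression at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {vals[i, j]}"
            )
        if self.background is None:
            self.background = pd.Series(0.0, index=self.values.columns)
        else:
            self.background = self.background.astype(float).reindex(self.values.columns)
            if self.background.isna().any() or (self.background < 0).any():
                raise FormatError("background thresholds must be non-negative, one per sample")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def read_matrix(path: str | Path, kind: str) -> "BetaMatrix | ExpressionMatrix | pd.DataFrame":
    """Read a TSV matrix (first column = row id, one column per sample).

    kind='beta' returns a :class:`BetaMatrix` (detection-p attached
    separately), kind='detection_p' returns the raw DataFrame for attachment,
    kind='expression' returns an :class:`ExpressionMatrix` with zero
    background thresholds (set them afterwards if known).
    """
    if kind not in ("beta", "detection_p", "expression"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {kind} matrix {path}: {exc}") from exc
    df = _validate_numeric(df, kind)
    if kind == "beta":
        return BetaMatrix(df)
    if kind == "detection_p":
        vals = df.to_numpy()
        with np.errstate(invalid="ignore"):
            if ((vals < 0) | (vals > 1)).any():
                raise FormatError("detection p-values must lie in [0, 1]")
        return df
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Packaged contingency-table fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table1Fixture:
    """The published 19-bin contingency table (YST vs seminoma, CpG islands).

    Rows are 0.05-wide differential-methylation bins from 0 to 0.95; columns
    hold the observed gene counts in three expression categories
    (correlating = >2-fold lower in the methylated line, no difference,
    anti-correlating) together with the printed expected counts, p-values
    and significance stars for cross-checking recomputation.
    """

    df: pd.DataFrame

    @property
    def bin_lo(self) -> np.ndarray:
        return self.df["bin_lo"].to_numpy(dtype=float)

    @property
    def observed(self) -> np.ndarray:
        """(n_bins, 3) observed counts: correlating, no-difference, anti."""
        return self.df[
            ["obs_correlating", "obs_no_difference", "obs_anticorrelating"]
        ].to_numpy(dtype=int)

    @property
    def grand_total(self) -> int:
        return int(self.observed.sum())

    @property
    def column_totals(self) -> tuple[int, int, int]:
        c = self.observed.sum(axis=0)
        return int(c[0]), int(c[1]), int(c[2])


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged printed contingency table."""
    with resources.files("methylsilence.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"p_printed": str, "stars_printed": str})
    df["stars_printed"] = df["stars_printed"].fillna("")
    widths = (df["bin_hi"] - df["bin_lo"]).to_numpy()
    if not np.allclose(widths, 0.05):
        raise FormatError("fixture bins must all be 0.05 wide")
    if not np.all(np.diff(df["bin_lo"].to_numpy()) > 0):
        raise FormatError("fixture bin_lo must be strictly increasing")
    return Table1Fixture(df)


# ---------------------------------------------------------------------------
# Result export
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping | None = None,
    silenced_islands: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write result tables as TSV plus a JSON run summary.

    ``silenced_islands``, if given, must have columns ``chrom``, ``start``,
    ``end`` (1-based inclusive) and ``gene``; it is additionally exported as
    a BED file (0-based half-open) with the gene symbol in the name field.

    Returns a mapping from artifact name to written path.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory {out}: {exc}") from exc

    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written[name] = path

    summary_payload = dict(summary or {})
    summary_payload.setdefault("tables", {name: len(t) for name, t in tables.items()})
    summary_path = out / "run_summary.json"
    summary_path.write_text(json.dumps(summary_payload, indent=2, default=str) + "\n")
    written["run_summary"] = summary_path

    if silenced_islands is not None and len(silenced_islands):
        bed_path = out / "silenced_islands.bed"
        with bed_path.open("w") as fh:
            for row in silenced_islands.itertuples(index=False):
                fh.write(f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t{row.gene}\n")
        written["silenced_islands_bed"] = bed_path
    return written
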