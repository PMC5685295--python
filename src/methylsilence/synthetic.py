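"""Synthetic annotated methylome / expression / qPCR data with known truth.

The generator emulates the statistical structure the analysis assumes: a
hypomethylated reference sample (seminoma-like) against target samples
(non-seminoma-like) in which a planted subset of genes is hypermethylated
across TSS-associated and/or gene-body CpG islands, with island-mean
delta-beta drawn from a configurable effect range (defaults near the
0.65-0.9 band where real silencing effects concentrated).  Expression is
coupled so that a tunable fraction of hypermethylated genes is silenced
(>= the configured fold deficit before noise), and a Ct-replicate table
emulates demethylation-reactivation qPCR.

Beta values are drawn from two-parameter beta distributions — the standard
noise model for array methylation fractions — with defaults giving mean
0.1 (unmethylated islands) and 0.8 (methylated).  Every dataset uses its
own RNG stream keyed by (seed, dataset name), so generating one dataset
never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ExpressionMatrix, Manifest

__all__ = ["SimConfig", "SyntheticTruth", "simulate_methylome", "simulate_expression", "simulate_qpcr"]

REFERENCE_SAMPLE = "seminoma"


def _rng(seed: int, dataset: str) -> np.random.Generator:
    """Independent stream per dataset name under one master seed."""
    return np.random.default_rng([seed, zlib.crc32(dataset.encode())])


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator.

    The defaults mirror the structure of the cell-line comparison the
    pipeline was built for: one hypomethylated reference plus three target
    lines, a few percent of genes hypermethylated with island-mean
    delta-beta in the 0.65-0.9 band, and about half of hypermethylated
    genes silenced at >= 3-fold.
    """

    n_genes: int = 2000
    n_target_samples: int = 3
    probes_per_island: tuple[int, int] = (4, 10)
    fraction_hypermethylated_tss: float = 0.05
    fraction_hypermethylated_body: float = 0.03
    fraction_silenced_given_hypermethylated: float = 0.5
    fraction_with_body_island: float = 0.4
    beta_params_unmeth: tuple[float, float] = (1.0, 9.0)  # mean 0.1
    beta_params_meth: tuple[float, float] = (8.0, 2.0)  # mean 0.8
    delta_beta_effect_range: tuple[float, float] = (0.65, 0.9)
    expr_fold_range_silenced: tuple[float, float] = (3.0, 10.0)
    expr_noise_cv: float = 0.1
    qpcr_delta_ct: float = 3.0
    qpcr_ct_sd: float = 0.1
    qpcr_replicates: int = 3
    qpcr_efficiency: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_hypermethylated_tss",
            "fraction_hypermethylated_body",
            "fraction_silenced_given_hypermethylated",
            "fraction_with_body_island",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.delta_beta_effect_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("delta_beta_effect_range must be an interval within [0, 1]")
        flo, fhi = self.expr_fold_range_silenced
        if not (2.0 <= flo <= fhi):
            raise ValueError("expr_fold_range_silenced must be an interval >= 2")
        if self.expr_noise_cv < 0:
            raise ValueError("expr_noise_cv must be non-negative")
        if self.probes_per_island[0] < 1 or self.probes_per_island[0] > self.probes_per_island[1]:
            raise ValueError("probes_per_island must be a non-empty positive range")
        # island means are clamped at 0.985 during the draw, so the planted
        # effect is only guaranteed when the range's lower edge fits below it
        a, b = self.beta_params_unmeth
        if lo + a / (a + b) > 0.95:
            raise ValueError(
                "infeasible config: the unmethylated mean plus the minimum "
                "delta-beta effect would push island betas above 1"
            )

    @property
    def sample_names(self) -> list[str]:
        return [REFERENCE_SAMPLE] + [
            f"nonseminoma_{i + 1}" for i in range(self.n_target_samples)
        ]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth, one row per gene.

    Columns: ``hypermethylated_tss``, ``hypermethylated_body``, ``silenced``
    (silenced implies hypermethylated somewhere in the generator's causal
    model), ``true_delta_beta`` (0 for unaffected genes) and
    ``true_fold_change`` (1 for non-silenced genes).
    """

    df: pd.DataFrame
    seed: int

    @property
    def silenced_genes(self) -> set[str]:
        return set(self.df.index[self.df["silenced"]])

    @property
    def hypermethylated_genes(self) -> set[str]:
        return set(
            self.df.index[self.df["hypermethylated_tss"] | self.df["hypermethylated_body"]]
        )


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

_GENE_SPACING = 50_000
_TSS_OFFSET = 10_000
_ISLAND_HALF = 500
_BODY_ISLAND_OFFSET = 5_000
_TSS_REGION_LABELS = ("TSS1500", "TSS200", "UTR5", "FirstExon")


def _beta_draw(rng: np.random.Generator, mean: float, kappa: float, size: int) -> np.ndarray:
    mean = float(np.clip(mean, 0.01, 0.99))
    return rng.beta(mean * kappa, (1 - mean) * kappa, size=size)


def _island_betas_with_delta(
    rng: np.random.Generator, ref: np.ndarray, delta: float, kappa: float = 60.0
) -> np.ndarray:
    """Target island betas whose mean exceeds the reference mean by delta.

    Probe values are drawn around the shifted mean and recentred so the
    island-mean delta-beta equals the planted effect exactly (up to the
    rare clip at the [0, 1] boundary).
    """
    m1 = float(np.clip(ref.mean() + delta, 0.02, 0.985))
    vals = _beta_draw(rng, m1, kappa, ref.size)
    vals = vals + (m1 - vals.mean())
    return np.clip(vals, 0.0, 1.0)


def simulate_methylome(cfg: SimConfig) -> tuple[Manifest, BetaMatrix, SyntheticTruth]:
    """Generate the annotated probe manifest, beta matrix and ground truth.

    Every gene gets a TSS-associated island (probes labelled TSS1500 /
    TSS200 / 5'UTR / first exon); a subset carries a body island; shore,
    shelf and open-sea probes are placed in the +-2 kb bands consistent
    with the annotation rules.  The reference sample draws island betas
    from the unmethylated distribution; hypermethylated genes shift the
    island mean in the target samples by the planted delta-beta.  Output is
    deterministic for a fixed seed.
    """
    rng = _rng(cfg.seed, "methylome")
    samples = cfg.sample_names
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    n_hyper_tss = rng.random(cfg.n_genes) < cfg.fraction_hypermethylated_tss
    n_hyper_body = rng.random(cfg.n_genes) < cfg.fraction_hypermethylated_body
    has_body = n_hyper_body | (rng.random(cfg.n_genes) < cfg.fraction_with_body_island)
    hyper_any = n_hyper_tss | n_hyper_body
    silenced = hyper_any & (
        rng.random(cfg.n_genes) < cfg.fraction_silenced_given_hypermethylated
    )
    d_lo, d_hi = cfg.delta_beta_effect_range
    true_delta = np.where(hyper_any, rng.uniform(d_lo, d_hi, cfg.n_genes), 0.0)
    f_lo, f_hi = cfg.expr_fold_range_silenced
    true_fold = np.where(silenced, rng.uniform(f_lo, f_hi, cfg.n_genes), 1.0)

    a_u, b_u = cfg.beta_params_unmeth
    a_m, b_m = cfg.beta_params_meth
    p_lo, p_hi = cfg.probes_per_island

    manifest_rows: list[dict] = []
    beta_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    probe_no = 0

    def add_probe(gene_i: int, pos: int, region: str, relation: str, island_id, values):
        nonlocal probe_no
        pid = f"cg{probe_no:08d}"
        probe_no += 1
        manifest_rows.append(
            {
                "probe_id": pid,
                "gene_symbols": genes[gene_i],
                "chrom": "chrSim",
                "pos": int(pos),
                "gene_region": region,
                "island_relation": relation,
                "island_id": island_id,
            }
        )
        probe_ids.append(pid)
        beta_rows.append(np.asarray(values, dtype=float))

    for g in range(cfg.n_genes):
        tss = g * _GENE_SPACING + _TSS_OFFSET
        islands = [("tss", tss - _ISLAND_HALF, tss + _ISLAND_HALF - 1, n_hyper_tss[g])]
        if has_body[g]:
            s = tss + _BODY_ISLAND_OFFSET
            islands.append(("body", s, s + 2 * _ISLAND_HALF - 1, n_hyper_body[g]))

        for kind, start, end, hyper in islands:
            n_probes = int(rng.integers(p_lo, p_hi + 1))
            positions = np.sort(rng.choice(np.arange(start, end + 1), n_probes, replace=False))
            ref_vals = rng.beta(a_u, b_u, n_probes)
            per_sample = [ref_vals]
            for _ in samples[1:]:
                if hyper:
                    per_sample.append(
                        _island_betas_with_delta(rng, ref_vals, true_delta[g])
                    )
                else:
                    per_sample.append(rng.beta(a_u, b_u, n_probes))
            mat = np.column_stack(per_sample)
            island_id = f"CGI_{genes[g]}_{kind}"
            for k, pos in enumerate(positions):
                region = (
                    str(rng.choice(_TSS_REGION_LABELS)) if kind == "tss" else "Body"
                )
                add_probe(g, pos, region, "Island", island_id, mat[k])

        # flanking structure: one shore, one shelf, one open-sea probe
        shore_pos = tss - _ISLAND_HALF - int(rng.integers(1, 2000))
        add_probe(
            g, shore_pos, "TSS1500", "N_Shore", None, rng.beta(2.0, 4.0, len(samples))
        )
        shelf_pos = tss - _ISLAND_HALF - int(rng.integers(2001, 4000))
        add_probe(g, shelf_pos, "Body", "N_Shelf", None, rng.beta(3.0, 2.0, len(samples)))
        sea_pos = tss + 20_000
        add_probe(g, sea_pos, "Intergenic", "OpenSea", None, rng.beta(a_m, b_m, len(samples)))

    manifest = Manifest.from_frame(pd.DataFrame(manifest_rows).astype({"pos": int}))
    beta_df = pd.DataFrame(np.vstack(beta_rows), index=probe_ids, columns=samples)
    detp = pd.DataFrame(
        rng.uniform(0.0, 0.02, beta_df.shape), index=probe_ids, columns=samples
    )
    intensity = pd.DataFrame(
        rng.normal(13.0, 0.4, size=(len(probe_ids), 2)),
        index=probe_ids,
        columns=["log2_red", "log2_green"],
    ).clip(lower=11.2)
    beta = BetaMatrix(beta_df, detection_p=detp, intensity=intensity)

    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "hypermethylated_tss": n_hyper_tss,
                "hypermethylated_body": n_hyper_body,
                "silenced": silenced,
                "true_delta_beta": true_delta,
                "true_fold_change": true_fold,
            },
            index=pd.Index(genes, name="gene"),
        ),
        seed=cfg.seed,
    )
    return manifest, beta, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(truth: SyntheticTruth, cfg: SimConfig) -> ExpressionMatrix:
    """Expression intensities coupled to the planted silencing truth.

    The reference sample carries a lognormally distributed baseline per
    gene; silenced genes are divided by their true fold change in every
    target sample; all values then receive multiplicative lognormal noise
    with coefficient of variation ``expr_noise_cv`` (mean-corrected, so
    zero noise reproduces the planted folds exactly).
    """
    rng = _rng(cfg.seed, "expression")
    genes = truth.df.index
    samples = cfg.sample_names
    base = 500.0 * rng.lognormal(0.0, 0.5, len(genes))
    folds = np.where(truth.df["silenced"], truth.df["true_fold_change"], 1.0)

    vals = np.empty((len(genes), len(samples)))
    vals[:, 0] = base
    for j in range(1, len(samples)):
        vals[:, j] = base / folds

    if cfg.expr_noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.expr_noise_cv**2))
        noise = rng.lognormal(-(sigma**2) / 2, sigma, vals.shape)
        vals = vals * noise

    df = pd.DataFrame(vals, index=genes, columns=samples)
    return ExpressionMatrix(df, pd.Series(0.0, index=samples))


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    genes: list[str], reactivated: set[str], cfg: SimConfig
) -> pd.DataFrame:
    """Tidy Ct-replicate table for a demethylation-reactivation experiment.

    Reactivated genes amplify ``qpcr_delta_ct`` cycles earlier in the
    treated condition; the housekeeping reference gene ACTB is equal across
    conditions up to replicate noise (sd ``qpcr_ct_sd``).  Always includes
    the ACTB rows and >= 3 replicates per condition.
    """
    rng = _rng(cfg.seed, "qpcr")
    n_rep = max(int(cfg.qpcr_replicates), 3)
    rows = []

    def emit(gene: str, base_control: float, delta: float) -> None:
        for condition, centre in (("control", base_control), ("treated", base_control - delta)):
            for rep in range(1, n_rep + 1):
                noise = rng.normal(0.0, cfg.qpcr_ct_sd) if cfg.qpcr_ct_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct": centre + noise,
                    }
                )

    emit("ACTB", 18.0, 0.0)
    for gene in genes:
        if gene == "ACTB":
            continue
        emit(gene, 30.0, cfg.qpcr_delta_ct if gene in reactivated else 0.0)
    return pd.DataFrame(rows)
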