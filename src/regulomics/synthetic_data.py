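"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the three data layers the analysis
integrates: (1) two TF peak sets in which planted direct-target genes carry
strong promoter peaks for BOTH factors over a uniform background; (2)
negative-binomial control/knockdown count matrices in which the planted
targets shift concordantly (same sign) in both knockdowns; and (3) a
tumor/normal expression cohort in which the planted signature genes are
shifted in tumors and survival hazard is tied to the metagene score.  A truth
ledger records every planted effect for recovery tests.

Everything is a deterministic function of the seed; writing the same
configuration twice produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    ClinicalTable,
    CountMatrix,
    GeneModel,
    GeneSet,
    Peak,
    PeakSet,
    write_clinical,
    write_gene_models,
    write_matrix,
    write_peaks,
)

TF_NAMES = ("gata4", "gata6")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults mirror the reduced-scale design the pipeline is exercised
    against: one 50 Mb chromosome with 2000 genes (70% coding), 200 planted
    direct targets with lognormal promoter-peak signal for both TFs over a
    5-peaks-per-Mb uniform background, 4-vs-4 NB counts at dispersion 0.1
    with concordant +-U(0.5, 1.5) log2 knockdown shifts, and a 100-tumor /
    50-normal cohort with a 1.5-z tumor shift for planted signature genes and
    exponential survival whose log-hazard is 0.8 x the metagene z-score.
    """

    seed: int = 42
    genome_length: int = 50_000_000
    chrom: str = "chr1"
    n_genes: int = 2000
    coding_fraction: float = 0.70
    n_planted_targets: int = 200
    planted_up_fraction: float = 0.75
    promoter_signal_mu: float = 2.0  # LogNormal(mu, sigma) of planted promoter peaks
    promoter_signal_sigma: float = 0.5
    background_signal_mu: float = 1.0
    background_signal_sigma: float = 0.5
    background_peaks_per_mb: float = 5.0
    distal_peak_prob: float = 0.3  # optional extra distal peak per planted target
    kd_fc_low: float = 0.5  # |log2fc| ~ Uniform(low, high), sign shared across TFs
    kd_fc_high: float = 1.5
    nb_dispersion: float = 0.1
    samples_per_arm: int = 4
    base_expr_log_mu: float = 4.0  # lognormal baseline mean counts (median ~55)
    base_expr_log_sigma: float = 1.0
    n_tumor: int = 100
    n_normal: int = 50
    tumor_shift_z: float = 1.5
    survival_beta: float = 0.8
    baseline_hazard: float = 0.05
    censor_max: float = 40.0

    def validate(self) -> None:
        if self.n_planted_targets > self.n_genes:
            raise ValueError("more planted targets than genes")
        for name in ("genome_length", "n_genes", "samples_per_arm", "n_tumor", "n_normal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0 or self.background_peaks_per_mb < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class SimulatedData:
    """In-memory fixture bundle plus the truth ledger."""

    config: SimulationConfig
    genes: GeneSet
    peaks: dict[str, PeakSet]  # tf -> PeakSet
    counts: dict[str, CountMatrix]  # tf -> control/KD count matrix
    tumor: pd.DataFrame
    normal: pd.DataFrame
    clinical: ClinicalTable
    truth: dict


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _simulate_genes(cfg: SimulationConfig, rng: np.random.Generator) -> GeneSet:
    margin = 200_000  # keep TSS windows inside the chromosome
    starts = np.sort(
        rng.integers(margin, cfg.genome_length - margin, size=cfg.n_genes)
    )
    lengths = np.clip(
        rng.lognormal(np.log(10_000), 0.8, size=cfg.n_genes), 1_000, 150_000
    ).astype(int)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    is_coding = rng.random(cfg.n_genes) < cfg.coding_fraction
    noncoding_kinds = rng.choice(
        ["lincRNA", "pseudogene", "other_noncoding"],
        size=cfg.n_genes,
        p=[0.5, 0.3, 0.2],
    )
    genes = []
    for i in range(cfg.n_genes):
        end = min(int(starts[i]) + int(lengths[i]), cfg.genome_length - 1)
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                chrom=cfg.chrom,
                start=int(starts[i]),
                end=end,
                strand=str(strands[i]),
                biotype="protein_coding" if is_coding[i] else str(noncoding_kinds[i]),
            )
        )
    return GeneSet(genes)


def _simulate_peaks(
    cfg: SimulationConfig,
    genes: GeneSet,
    planted_ids: list[str],
    rng: np.random.Generator,
) -> PeakSet:
    peaks: list[Peak] = []
    n_bg = int(round(cfg.genome_length / 1e6 * cfg.background_peaks_per_mb))
    for _ in range(n_bg):
        width = int(np.clip(rng.normal(300, 60), 150, 800))
        start = int(rng.integers(0, cfg.genome_length - width))
        summit = start + int(rng.integers(width // 4, 3 * width // 4))
        signal = float(rng.lognormal(cfg.background_signal_mu, cfg.background_signal_sigma))
        peaks.append(Peak(cfg.chrom, start, start + width, summit, signal))
    for gid in planted_ids:
        g = genes[gid]
        summit = int(np.clip(g.tss + rng.integers(-1000, 1001), 100, cfg.genome_length - 100))
        half = int(np.clip(rng.normal(200, 40), 100, 500))
        signal = float(rng.lognormal(cfg.promoter_signal_mu, cfg.promoter_signal_sigma))
        peaks.append(
            Peak(cfg.chrom, max(summit - half, 0), summit + half, summit, signal)
        )
        if rng.random() < cfg.distal_peak_prob:
            offset = int(rng.integers(10_000, 50_000)) * (1 if rng.random() < 0.5 else -1)
            s2 = int(np.clip(g.tss + offset, 100, cfg.genome_length - 100))
            half2 = int(np.clip(rng.normal(200, 40), 100, 500))
            sig2 = float(rng.lognormal(cfg.background_signal_mu, cfg.background_signal_sigma))
            peaks.append(Peak(cfg.chrom, max(s2 - half2, 0), s2 + half2, s2, sig2))
    return PeakSet(peaks)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson if dispersion 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _simulate_counts(
    cfg: SimulationConfig,
    gene_ids: list[str],
    base_mean: np.ndarray,
    log2fc: pd.Series,
    rng: np.random.Generator,
    tf: str,
) -> CountMatrix:
    n = cfg.samples_per_arm
    effect = np.ones(len(gene_ids))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g, fc in log2fc.items():
        effect[idx[g]] = 2.0 ** fc
    size_factor = rng.uniform(0.8, 1.2, size=2 * n)
    cols, data, groups = [], [], {}
    for j in range(n):
        cols.append(f"{tf}_ctrl_{j + 1}")
        data.append(_nb_draw(rng, base_mean * size_factor[j], cfg.nb_dispersion))
        groups[cols[-1]] = "control"
    for j in range(n):
        cols.append(f"{tf}_kd_{j + 1}")
        data.append(_nb_draw(rng, base_mean * effect * size_factor[n + j], cfg.nb_dispersion))
        groups[cols[-1]] = "kd"
    values = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    values.index.name = "gene_id"
    return CountMatrix(values=values, sample_groups=groups)


def _simulate_cohort(
    cfg: SimulationConfig,
    gene_ids: list[str],
    directions: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, ClinicalTable]:
    n_genes = len(gene_ids)
    base = rng.normal(5.0, 1.5, size=n_genes)  # per-gene baseline, log2 scale
    shift = np.zeros(n_genes)
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g, d in directions.items():
        shift[idx[g]] = cfg.tumor_shift_z * (1.0 if d == "up" else -1.0)

    tumor_log = base[:, None] + shift[:, None] + rng.normal(0, 1, (n_genes, cfg.n_tumor))
    normal_log = base[:, None] + rng.normal(0, 1, (n_genes, cfg.n_normal))
    tumor_cols = [f"tumor_{i + 1}" for i in range(cfg.n_tumor)]
    normal_cols = [f"normal_{i + 1}" for i in range(cfg.n_normal)]
    tumor = pd.DataFrame(2.0 ** tumor_log, index=gene_ids, columns=tumor_cols)
    normal = pd.DataFrame(2.0 ** normal_log, index=gene_ids, columns=normal_cols)
    tumor.index.name = normal.index.name = "gene_id"

    # per-tumor metagene deviation of the planted up-signature drives hazard
    up_idx = [idx[g] for g, d in directions.items() if d == "up"]
    if up_idx:
        dev = (tumor_log[up_idx] - base[up_idx, None]).mean(axis=0)
        z = (dev - dev.mean()) / dev.std(ddof=0)
    else:
        z = np.zeros(cfg.n_tumor)
    time, event = simulate_survival(
        z, cfg.survival_beta, cfg.baseline_hazard, cfg.censor_max, rng
    )
    stages = rng.integers(1, 5, size=cfg.n_tumor)
    clin = pd.DataFrame(
        {
            "class": ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
            "stage": list(stages.astype(float)) + [np.nan] * cfg.n_normal,
            "time": list(np.round(time, 4)) + [np.nan] * cfg.n_normal,
            "event": list(event.astype(float)) + [np.nan] * cfg.n_normal,
        },
        index=pd.Index(tumor_cols + normal_cols, name="sample_id"),
    )
    return tumor, normal, ClinicalTable(clin)


def simulate_survival(
    metagene_z: np.ndarray,
    beta: float,
    baseline_hazard: float,
    censor_max: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with proportional-hazards link to the metagene z.

    hazard_i = baseline_hazard * exp(beta * z_i); censoring uniform on
    (0, censor_max).  Returns (observed time, event indicator).
    """
    z = np.asarray(metagene_z, dtype=float)
    hazard = baseline_hazard * np.exp(beta * z)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0, censor_max, size=len(z))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return time, event


def simulate_all(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> SimulatedData:
    """Generate the full fixture bundle (and optionally write it as text files).

    Files written: genes.tsv, <tf>.narrowPeak, counts_<tf>.tsv,
    groups_<tf>.tsv, cohort_tumor.tsv, cohort_normal.tsv, clinical.tsv,
    truth.json.  Identical config (incl. seed) gives byte-identical files.
    """
    cfg = config or SimulationConfig()
    cfg.validate()

    genes = _simulate_genes(cfg, _spawn(cfg.seed, 0))
    rng_plant = _spawn(cfg.seed, 1)
    planted_ids = sorted(
        rng_plant.choice(genes.gene_ids, size=cfg.n_planted_targets, replace=False)
    )
    n_up = int(round(cfg.planted_up_fraction * cfg.n_planted_targets))
    up_ids = sorted(rng_plant.choice(planted_ids, size=n_up, replace=False))
    directions = pd.Series(
        {g: ("up" if g in set(up_ids) else "down") for g in planted_ids}
    )

    peaks = {
        tf: _simulate_peaks(cfg, genes, planted_ids, _spawn(cfg.seed, 10 + k))
        for k, tf in enumerate(TF_NAMES)
    }

    rng_expr = _spawn(cfg.seed, 20)
    base_mean = rng_expr.lognormal(
        cfg.base_expr_log_mu, cfg.base_expr_log_sigma, size=cfg.n_genes
    )
    true_fcs: dict[str, pd.Series] = {}
    counts: dict[str, CountMatrix] = {}
    for k, tf in enumerate(TF_NAMES):
        rng_fc = _spawn(cfg.seed, 30 + k)
        mag = rng_fc.uniform(cfg.kd_fc_low, cfg.kd_fc_high, size=len(planted_ids))
        sign = directions.map({"up": 1.0, "down": -1.0}).to_numpy()
        fc = pd.Series(sign * mag, index=planted_ids)
        true_fcs[tf] = fc
        counts[tf] = _simulate_counts(
            cfg, genes.gene_ids, base_mean, fc, _spawn(cfg.seed, 40 + k), tf
        )

    tumor, normal, clinical = _simulate_cohort(
        cfg, genes.gene_ids, directions, _spawn(cfg.seed, 50)
    )

    truth = {
        "planted_targets": {g: directions[g] for g in planted_ids},
        "true_log2fc": {tf: {g: float(v) for g, v in s.items()} for tf, s in true_fcs.items()},
        "cohort_effect_genes": {g: directions[g] for g in planted_ids},
        "tumor_shift_z": cfg.tumor_shift_z,
        "survival_beta": cfg.survival_beta,
        "baseline_hazard": cfg.baseline_hazard,
        "config": asdict(cfg),
    }
    data = SimulatedData(
        config=cfg, genes=genes, peaks=peaks, counts=counts,
        tumor=tumor, normal=normal, clinical=clinical, truth=truth,
    )
    if out_dir is not None:
        write_fixture(data, out_dir)
    return data


def simulate_null(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> SimulatedData:
    """Fixture with all planted effect sizes zero (for type-I-error suites)."""
    cfg = replace(
        config or SimulationConfig(),
        n_planted_targets=0,
        tumor_shift_z=0.0,
        survival_beta=0.0,
    )
    return simulate_all(cfg, out_dir)


def write_fixture(data: SimulatedData, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_models(data.genes, out / "genes.tsv")
    for tf, pk in data.peaks.items():
        write_peaks(pk, out / f"{tf}.narrowPeak")
    for tf, cm in data.counts.items():
        write_matrix(cm, out / f"counts_{tf}.tsv")
        pd.DataFrame(
            sorted(cm.sample_groups.items()), columns=["sample_id", "group"]
        ).to_csv(out / f"groups_{tf}.tsv", sep="\t", index=False)
    write_matrix(data.tumor, out / "cohort_tumor.tsv")
    write_matrix(data.normal, out / "cohort_normal.tsv")
    write_clinical(data.clinical, out / "clinical.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(data.truth, fh, indent=2, sort_keys=True)
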