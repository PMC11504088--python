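"""Single-command pipeline runner with a reproducibility manifest.

Sequences the stages annotate -> regulatory scores -> differential
expression / integration -> signature selection -> cohort evaluation, either
on user-supplied inputs or on the built-in synthetic fixtures.  Every output
is tied to input digests, the configuration snapshot, and the seed in
``manifest.json``; rerunning with identical inputs reproduces identical
digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import (
    align_clinical,
    read_clinical,
    read_gene_models,
    read_matrix,
    read_peaks,
    read_sample_groups,
)
from .peak_landscape import (
    annotation_enrichment,
    annotations_to_frame,
    assign_peaks,
    reldist,
    tss_distribution,
)
from .regscore import build_tss_profile, calibrate_scores, combine_tf_scores, raw_scores
from .kd_integration import de_test, deregulogram, log_cpm, overlap_degs, score_fc_trend
from .signature_selection import panel_report, select_signature
from .clinomics import (
    cross_normalize,
    km_logrank,
    metagene_score,
    multicancer_panel,
    roc_by_stage,
    roc_table,
    strata_compare,
)
from .synthetic_data import TF_NAMES, SimulationConfig, simulate_all

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and parameters for one pipeline run."""

    out_dir: str = "report"
    seed: int = 42
    simulate: bool = True
    # input paths (ignored when simulate=True)
    genes: str | None = None
    peaks: dict[str, str] = field(default_factory=dict)  # tf name -> path
    counts: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    tumor_matrix: str | None = None
    normal_matrix: str | None = None
    clinical: str | None = None
    # analysis parameters
    window_bp: int = 100_000
    bin_bp: int = 100
    combine_mode: str = "mean"
    score_min: float = 10.0
    alpha: float = 0.05
    min_linear_fc: float = 1.25
    trend_window: int = 200
    genome_length: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sanitize(obj):
    """Replace NaN with None recursively so emitted JSON stays strict."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.payload = {
            "tool_version": __version__,
            "config": asdict(config),
            "inputs": {},
            "stages": {},
            "status": "running",
        }

    def add_input(self, name: str, path: Path) -> None:
        self.payload["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(self, name: str, seconds: float, outputs: dict[str, Path]) -> None:
        self.payload["stages"][name] = {
            "wall_seconds": round(seconds, 3),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
        }

    def fail(self, stage: str, error: Exception) -> None:
        self.payload["status"] = "failed"
        self.payload["failed_stage"] = stage
        self.payload["error"] = f"{type(error).__name__}: {error}"

    def finish(self) -> None:
        if self.payload["status"] == "running":
            self.payload["status"] = "ok"

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.payload, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full integration pipeline; returns the key result metrics.

    On stage failure the completed stages' outputs are left in place, the
    manifest records the failing stage, and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    results: dict = {}
    stage_name = "setup"
    truth = None
    try:
        t0 = _time.perf_counter()
        if config.simulate:
            fixture_dir = out / "fixtures"
            sim = simulate_all(SimulationConfig(seed=config.seed), fixture_dir)
            genes = sim.genes
            peaks = sim.peaks
            counts = sim.counts
            tumor, normal, clinical = sim.tumor, sim.normal, sim.clinical
            truth = sim.truth
            genome_length = sim.config.genome_length
            for f in sorted(fixture_dir.iterdir()):
                manifest.add_input(f.name, f)
        else:
            required = {
                "genes": config.genes,
                "tumor_matrix": config.tumor_matrix,
                "normal_matrix": config.normal_matrix,
                "clinical": config.clinical,
            }
            for name, p in list(required.items()) + [
                (f"peaks[{k}]", v) for k, v in config.peaks.items()
            ] + [(f"counts[{k}]", v) for k, v in config.counts.items()]:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input {name}: {p}")
            genes = read_gene_models(config.genes)
            peaks = {tf: read_peaks(p) for tf, p in config.peaks.items()}
            counts = {}
            for tf, p in config.counts.items():
                cm = read_matrix(p)
                cm.sample_groups = read_sample_groups(config.groups[tf])
                counts[tf] = cm
            tumor = read_matrix(config.tumor_matrix).values
            normal = read_matrix(config.normal_matrix).values
            clinical = read_clinical(config.clinical)
            genome_length = config.genome_length or int(
                max(g.end for g in genes) * 1.05
            )
            for name, p in required.items():
                manifest.add_input(name, Path(p))
        tf_names = sorted(peaks)
        manifest.stage("setup", _time.perf_counter() - t0, {})

        # --- annotate ---------------------------------------------------
        stage_name = "annotate"
        t0 = _time.perf_counter()
        outputs = {}
        annotations = {}
        for tf in tf_names:
            ann = assign_peaks(peaks[tf], genes)
            annotations[tf] = ann
            annotations_to_frame(ann).to_csv(out / f"annot_{tf}.tsv", sep="\t", index=False)
            tss_distribution(ann).to_csv(out / f"tss_distribution_{tf}.tsv", sep="\t")
            annotation_enrichment(ann, genes, genome_length).to_csv(
                out / f"enrichment_{tf}.tsv", sep="\t"
            )
            outputs[f"annot_{tf}"] = out / f"annot_{tf}.tsv"
            outputs[f"tss_distribution_{tf}"] = out / f"tss_distribution_{tf}.tsv"
            outputs[f"enrichment_{tf}"] = out / f"enrichment_{tf}.tsv"
        if len(tf_names) == 2:
            _vals, hist = reldist(peaks[tf_names[0]], peaks[tf_names[1]])
            hist.to_csv(out / "reldist.tsv", sep="\t", index=False)
            outputs["reldist"] = out / "reldist.tsv"
        manifest.stage("annotate", _time.perf_counter() - t0, outputs)

        # --- regulatory scores ------------------------------------------
        stage_name = "regscore"
        t0 = _time.perf_counter()
        scaled = {}
        for tf in tf_names:
            profile = build_tss_profile(peaks[tf], genes, config.window_bp, config.bin_bp)
            raw = raw_scores(genes, peaks[tf], profile)
            scaled[tf] = calibrate_scores(raw, tf=tf)
        combined = combine_tf_scores(
            scaled[tf_names[0]]["scaled"], scaled[tf_names[1]]["scaled"],
            mode=config.combine_mode,
        )
        score_table = pd.DataFrame(
            {f"scaled_{tf}": scaled[tf]["scaled"] for tf in tf_names}
        )
        score_table["combined"] = combined
        score_table.to_csv(out / "scores.tsv", sep="\t", index_label="gene_id")
        manifest.stage(
            "regscore", _time.perf_counter() - t0, {"scores": out / "scores.tsv"}
        )

        # --- differential expression ------------------------------------
        stage_name = "de"
        t0 = _time.perf_counter()
        detables = {}
        outputs = {}
        biotypes = genes.biotypes()
        for tf in tf_names:
            norm = log_cpm(counts[tf])
            detables[tf] = de_test(norm, counts[tf].sample_groups, biotypes=biotypes)
            detables[tf].to_csv(out / f"de_{tf}.tsv", sep="\t")
            outputs[f"de_{tf}"] = out / f"de_{tf}.tsv"
        manifest.stage("de", _time.perf_counter() - t0, outputs)

        # --- integration --------------------------------------------------
        stage_name = "integrate"
        t0 = _time.perf_counter()
        det_a, det_b = detables[tf_names[0]], detables[tf_names[1]]
        records, summary = deregulogram(det_a, det_b, alpha=config.alpha)
        records.to_csv(out / "deregulogram.tsv", sep="\t")
        from .kd_integration import classify_degs

        cls_a = classify_degs(det_a, config.alpha, config.min_linear_fc)
        cls_b = classify_degs(det_b, config.alpha, config.min_linear_fc)
        overlap = overlap_degs(cls_a, cls_b, biotypes)
        overlap.to_csv(out / "deg_overlap.tsv", sep="\t", index=False)
        trend = score_fc_trend(combined, det_a["log2fc"], config.trend_window)
        trend.to_csv(out / "trend.tsv", sep="\t")
        results["deregulogram"] = summary
        manifest.stage(
            "integrate",
            _time.perf_counter() - t0,
            {
                "deregulogram": out / "deregulogram.tsv",
                "deg_overlap": out / "deg_overlap.tsv",
                "trend": out / "trend.tsv",
            },
        )

        # --- signature selection -----------------------------------------
        stage_name = "select"
        t0 = _time.perf_counter()
        panel = select_signature(
            combined, det_a, det_b, biotypes,
            score_min=config.score_min, alpha=config.alpha,
            min_linear_fc=config.min_linear_fc,
        )
        panel.to_json(out / "panel.json")
        report = panel_report(panel)
        report.to_csv(out / "panel_report.tsv", sep="\t", index=False)
        results["panel"] = {
            "total": int(len(panel)),
            "pct_upregulated": float(report.loc[report["group"] == "total", "pct_upregulated"].iloc[0]),
        }
        if truth is not None and truth["planted_targets"]:
            planted = set(truth["planted_targets"])
            selected = set(panel.all_genes)
            tp = len(planted & selected)
            results["recovery"] = {
                "sensitivity": tp / len(planted),
                "fdp": (len(selected) - tp) / len(selected) if selected else 0.0,
            }
        manifest.stage(
            "select",
            _time.perf_counter() - t0,
            {"panel": out / "panel.json", "panel_report": out / "panel_report.tsv"},
        )

        # --- clinomics ----------------------------------------------------
        stage_name = "clinomics"
        t0 = _time.perf_counter()
        clinical = align_clinical(pd.concat([tumor, normal], axis=1), clinical)
        zmat = cross_normalize(tumor, normal)
        outputs = {}
        clin = clinical.data
        # evaluate the truth-planted signatures when available, else the
        # recovered panel; both paths exercise the same operations
        if truth is not None and truth["planted_targets"]:
            up_panel = sorted(g for g, d in truth["planted_targets"].items() if d == "up")
            down_panel = sorted(g for g, d in truth["planted_targets"].items() if d == "down")
        else:
            up_panel, down_panel = panel.up_genes, panel.down_genes
        for name, genes_list in (("up", up_panel), ("down", down_panel)):
            if not genes_list:
                continue
            score = metagene_score(zmat, genes_list)
            stage_res = roc_by_stage(
                score, zmat.labels, clin["stage"].reindex(score.index)
            )
            roc_table(stage_res).to_csv(out / f"roc_{name}.tsv", sep="\t", index=False)
            outputs[f"roc_{name}"] = out / f"roc_{name}.tsv"
            results[f"auc_{name}"] = stage_res["pooled"].auc
            tumors = clin.index[clin["class"] == "tumor"]
            surv = clin.loc[tumors]
            if surv["event"].sum() >= 2:
                comp, km = km_logrank(
                    score.loc[tumors], surv["time"], surv["event"]
                )
                for grp, tab in km.items():
                    tab.to_csv(out / f"km_{name}_{grp}.tsv", sep="\t", index=False)
                    outputs[f"km_{name}_{grp}"] = out / f"km_{name}_{grp}.tsv"
                results[f"survival_{name}"] = {
                    "chi2": comp.logrank_chi2, "p": comp.p, "direction": comp.direction,
                }
            strata = strata_compare(
                score.loc[tumors], clin.loc[tumors, "stage"]
            )
            results[f"strata_{name}"] = {"H": strata["H"], "p": strata["p"]}
        with open(out / "clinomics.json", "w") as fh:
            json.dump(_sanitize(results), fh, indent=2, sort_keys=True)
        outputs["clinomics"] = out / "clinomics.json"
        manifest.stage("clinomics", _time.perf_counter() - t0, outputs)
    except Exception as exc:
        manifest.fail(stage_name, exc)
        manifest.write(out / "manifest.json")
        log.error("pipeline failed at stage %r: %s", stage_name, exc)
        raise
    manifest.finish()
    manifest.write(out / "manifest.json")
    return _sanitize(results)
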