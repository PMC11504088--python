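"""Knockdown transcriptome integration.

Differential expression for control-vs-knockdown count matrices (Welch t on
log-CPM with Benjamini-Hochberg correction), DEG classification at a linear
fold-change gate, cross-knockdown overlap and deregulogram summaries, and the
regulatory-score-vs-fold-change trend curve.  Externally produced DE tables
with the same columns can be substituted for the built-in test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import CountMatrix

log = logging.getLogger(__name__)

DE_COLUMNS = ["log2fc", "p", "p_adj", "mean_expr", "biotype"]
_P_FLOOR = 1e-300  # keep p in (0, 1] when Welch t degenerates to +-inf


def log_cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """log2(1e6 * count / library_size + 1); library size = column sum."""
    df = counts.values if isinstance(counts, CountMatrix) else counts
    lib = df.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    return np.log2(1e6 * df / lib + 1.0)


def de_test(
    normalized: pd.DataFrame,
    groups: dict[str, str],
    control: str = "control",
    treatment: str | None = None,
    biotypes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene Welch two-sample t on normalized (log-CPM) values.

    log2fc = mean(treatment) - mean(control); p adjusted by Benjamini-Hochberg
    over all tested genes.  Genes with zero variance in both groups and equal
    means get p = 1.  Requires >= 2 samples per group.
    """
    labels = pd.Series({s: groups[s] for s in normalized.columns if s in groups})
    if treatment is None:
        others = sorted(set(labels) - {control})
        if len(others) != 1:
            raise ValueError(f"cannot infer treatment group from labels {sorted(set(labels))}")
        treatment = others[0]
    ctrl_cols = labels.index[labels == control]
    trt_cols = labels.index[labels == treatment]
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need at least 2 samples per group")

    x_ctrl = normalized[ctrl_cols].to_numpy()
    x_trt = normalized[trt_cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x_trt, x_ctrl, axis=1, equal_var=False)
    log2fc = x_trt.mean(axis=1) - x_ctrl.mean(axis=1)
    degenerate = np.isnan(p)
    # both groups constant: equal means -> no evidence (p=1); unequal means
    # with zero variance -> maximal evidence, floored to keep p in (0, 1]
    p = np.where(degenerate & (np.abs(log2fc) < 1e-12), 1.0, p)
    p = np.where(np.isnan(p), _P_FLOOR, p)
    p = np.clip(p, _P_FLOOR, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    p_adj = np.clip(np.maximum(p_adj, p), _P_FLOOR, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "mean_expr": normalized[list(ctrl_cols) + list(trt_cols)].mean(axis=1),
        },
        index=normalized.index,
    )
    table["biotype"] = (
        biotypes.reindex(table.index) if biotypes is not None else "other_noncoding"
    )
    table.index.name = "gene_id"
    return table


def classify_degs(
    detable: pd.DataFrame,
    alpha: float = 0.05,
    min_linear_fc: float = 1.25,
    fc_on_log_scale: bool = False,
) -> pd.Series:
    """Per-gene {up, down, ns} at adjusted-p alpha and a fold-change gate.

    The gate is inclusive ("at least equal to") and interpreted on the linear
    scale by default: |log2fc| >= log2(min_linear_fc).  Set
    ``fc_on_log_scale=True`` to require |log2fc| >= min_linear_fc instead.
    """
    thr = min_linear_fc if fc_on_log_scale else np.log2(min_linear_fc)
    sig = detable["p_adj"] <= alpha
    out = pd.Series("ns", index=detable.index, name="deg_class")
    out[sig & (detable["log2fc"] >= thr)] = "up"
    out[sig & (detable["log2fc"] <= -thr)] = "down"
    return out


def overlap_degs(
    class_a: pd.Series, class_b: pd.Series, biotypes: pd.Series
) -> pd.DataFrame:
    """Counts of common (same-direction) DEGs split coding vs non-coding."""
    universe = class_a.index.intersection(class_b.index)
    a = class_a.loc[universe]
    b = class_b.loc[universe]
    coding = biotypes.reindex(universe) == "protein_coding"
    rows = []
    for direction in ("up", "down"):
        common = (a == direction) & (b == direction)
        rows.append(("coding", direction, int((common & coding).sum())))
        rows.append(("noncoding", direction, int((common & ~coding).sum())))
    return pd.DataFrame(rows, columns=["biotype_group", "direction", "common_count"])


def deregulogram(
    detable_a: pd.DataFrame, detable_b: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Per-gene fold-change pairs across the two knockdowns plus a summary.

    sig_class records in which contrasts the gene is significant; concordant
    means same fold-change sign (defined only when both are nonzero).  The
    summary reports Pearson r of fold changes and percent concordant over
    genes significant in both contrasts (r missing below 3 genes).
    """
    universe = detable_a.index.intersection(detable_b.index)
    a = detable_a.loc[universe]
    b = detable_b.loc[universe]
    sig_a = a["p_adj"] <= alpha
    sig_b = b["p_adj"] <= alpha
    sig_class = pd.Series("neither", index=universe)
    sig_class[sig_a & ~sig_b] = "tf1_only"
    sig_class[~sig_a & sig_b] = "tf2_only"
    sig_class[sig_a & sig_b] = "both"
    both_nonzero = (a["log2fc"] != 0) & (b["log2fc"] != 0)
    concordant = pd.Series(pd.NA, index=universe, dtype="boolean")
    concordant[both_nonzero] = (
        np.sign(a.loc[both_nonzero, "log2fc"]) == np.sign(b.loc[both_nonzero, "log2fc"])
    )
    records = pd.DataFrame(
        {
            "fc_tf1": a["log2fc"],
            "fc_tf2": b["log2fc"],
            "sig_class": sig_class,
            "concordant": concordant,
        }
    )
    records.index.name = "gene_id"

    both = records[records["sig_class"] == "both"]
    if len(both) >= 3:
        r = float(stats.pearsonr(both["fc_tf1"], both["fc_tf2"])[0])
    else:
        log.warning("deregulogram: <3 genes significant in both; r reported missing")
        r = float("nan")
    defined = both["concordant"].dropna()
    pct = 100.0 * defined.mean() if len(defined) else float("nan")
    summary = {
        "n_both": int(len(both)),
        "pearson_r": r,
        "pct_concordant": float(pct),
    }
    return records, summary


def score_fc_trend(
    scores: pd.Series, fcs: pd.Series, window_genes: int = 200
) -> pd.DataFrame:
    """Rolling-mean fold change over genes ranked by ascending regulatory score.

    A centered rolling mean of the stated window (shrunk at the edges) is
    taken over the score-sorted fold changes; output length equals the number
    of genes.  Ties in score are broken by gene_id for determinism.
    """
    if window_genes < 1:
        raise ValueError("window must be >= 1")
    universe = scores.index.intersection(fcs.index)
    df = pd.DataFrame({"score": scores.loc[universe], "log2fc": fcs.loc[universe]})
    order = np.lexsort((np.asarray(universe), df["score"].to_numpy()))
    df = df.iloc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    df["trend"] = (
        df["log2fc"].rolling(window=window_genes, center=True, min_periods=1).mean()
    )
    df.index.name = "gene_id"
    return df
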