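"""Cohort-level evaluation of metagene signatures.

Cross-normalization of tumor and normal expression matrices (upper-quartile
scaling to a common target, log2, per-gene z over the pooled cohort),
per-sample metagene scores, ROC diagnostics (pair-counting AUC with
Hanley-McNeil confidence intervals and Youden-optimal operating point),
Kaplan-Meier / log-rank prognostics at a median split, Kruskal-Wallis strata
comparisons, and a multi-cohort tumor-vs-normal panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class ZMatrix:
    """Genes x samples standardized expression over a pooled tumor+normal cohort."""

    data: pd.DataFrame  # genes x samples
    labels: pd.Series  # sample -> {tumor, normal}

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.labels.index):
            self.labels = self.labels.reindex(self.data.columns)
        mean = self.data.mean(axis=1)
        sd = self.data.std(axis=1, ddof=0)
        if (mean.abs() > 1e-9).any() or ((sd - 1).abs() > 1e-9).any():
            raise ValueError("ZMatrix rows must have mean 0 and sd 1")


@dataclass
class ROCResult:
    """AUC with CI, Youden-optimal sensitivity/specificity, and class sizes."""

    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


@dataclass
class SurvivalComparison:
    """Log-rank comparison of high vs low score groups (median split)."""

    logrank_chi2: float
    p: float
    n_high: int
    n_low: int
    direction: str  # which group has worse survival: "high" or "low"


def cross_normalize(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    method: str = "upper_quartile",
) -> ZMatrix:
    """Merge tumor and normal matrices into one standardized cohort.

    Steps: intersect genes (logged); per-sample upper-quartile scaling to a
    fixed common target (1000, so that rescaling any single sample is exactly
    absorbed; or full quantile normalization with ``method="quantile"``);
    log2(x+1); per-gene z-score over all pooled samples.  Genes with zero
    variance after the log transform are dropped with a warning, as are
    samples whose upper quartile is zero.
    """
    shared = tumor.index.intersection(normal.index)
    dropped = len(tumor.index.union(normal.index)) - len(shared)
    if dropped:
        log.info("cross_normalize: %d genes outside the shared universe dropped", dropped)
    pooled = pd.concat([tumor.loc[shared], normal.loc[shared]], axis=1)
    labels = pd.Series(
        ["tumor"] * tumor.shape[1] + ["normal"] * normal.shape[1], index=pooled.columns
    )

    if method == "upper_quartile":
        uq = pooled[pooled > 0].quantile(0.75)
        bad = uq.index[uq.isna() | (uq <= 0)]
        for s in bad:
            log.warning("sample %r has zero upper quartile; dropped", s)
        pooled = pooled.drop(columns=bad)
        labels = labels.drop(index=bad)
        uq = uq.drop(index=bad)
        pooled = pooled * (1000.0 / uq)
    elif method == "quantile":
        ranks = pooled.rank(method="average")
        ref = np.sort(pooled.to_numpy(), axis=0).mean(axis=1)
        pooled = pd.DataFrame(
            np.asarray([np.interp(ranks[c], np.arange(1, len(ref) + 1), ref) for c in pooled]).T,
            index=pooled.index,
            columns=pooled.columns,
        )
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    logged = np.log2(pooled + 1.0)
    sd = logged.std(axis=1, ddof=0)
    flat = sd.index[sd == 0]
    if len(flat):
        log.warning("%d zero-variance genes dropped during z-scoring", len(flat))
    logged = logged.drop(index=flat)
    z = logged.sub(logged.mean(axis=1), axis=0).div(sd.drop(index=flat), axis=0)
    return ZMatrix(data=z, labels=labels)


def metagene_score(zmatrix: ZMatrix | pd.DataFrame, gene_list: list[str]) -> pd.Series:
    """Per-sample mean z over the panel genes present in the matrix."""
    data = zmatrix.data if isinstance(zmatrix, ZMatrix) else zmatrix
    present = [g for g in gene_list if g in data.index]
    missing = set(gene_list) - set(present)
    for g in sorted(missing):
        log.warning("panel gene %r absent from matrix", g)
    if not present:
        raise ValueError("no panel gene present in the expression matrix")
    score = data.loc[present].mean(axis=0)
    score.name = "metagene_score"
    return score


def _auc_pair_counting(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks (ties count 1/2)."""
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)
    n_pos, n_neg = len(pos), len(neg)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(scores: pd.Series, labels: pd.Series, positive: str = "tumor") -> ROCResult:
    """Pair-counting AUC with Hanley-McNeil 95% CI and Youden-optimal cut."""
    labels = labels.reindex(scores.index)
    pos = scores[labels == positive].to_numpy(dtype=float)
    neg = scores[labels != positive].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for ROC analysis")
    auc = _auc_pair_counting(pos, neg)

    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (len(pos) - 1) * (q1 - auc**2)
        + (len(neg) - 1) * (q2 - auc**2)
    ) / (len(pos) * len(neg))
    se = np.sqrt(max(var, 0.0))
    ci_low = float(np.clip(auc - 1.959963984540054 * se, 0.0, auc))
    ci_high = float(np.clip(auc + 1.959963984540054 * se, auc, 1.0))

    y = (labels == positive).astype(int).to_numpy()
    fpr, tpr, _thr = roc_curve(y, scores.to_numpy(dtype=float))
    j = int(np.argmax(tpr - fpr))
    return ROCResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        sensitivity=float(tpr[j]),
        specificity=float(1 - fpr[j]),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def roc_by_stage(
    scores: pd.Series,
    labels: pd.Series,
    stages: pd.Series,
    min_tumors: int = 3,
) -> dict[str, ROCResult]:
    """One ROC per tumor stage (that stage's tumors vs all normals) plus pooled.

    Down-signatures are expected to score AUC < 0.5; callers can report 1-auc
    alongside (see :func:`roc_table`).  Stages with fewer than ``min_tumors``
    tumors are skipped with a warning.
    """
    labels = labels.reindex(scores.index)
    stages = stages.reindex(scores.index)
    normals = scores.index[labels == "normal"]
    out: dict[str, ROCResult] = {"pooled": roc_auc(scores, labels)}
    for stage in sorted(stages.dropna().unique()):
        tumors = scores.index[(labels == "tumor") & (stages == stage)]
        if len(tumors) < min_tumors:
            log.warning("stage %s has <%d tumors; skipped", stage, min_tumors)
            continue
        subset = scores.loc[list(tumors) + list(normals)]
        out[f"stage_{stage:g}" if isinstance(stage, float) else f"stage_{stage}"] = roc_auc(
            subset, labels.loc[subset.index]
        )
    return out


def roc_table(results: dict[str, ROCResult]) -> pd.DataFrame:
    """Flatten stage->ROCResult into a table reporting both auc and 1-auc."""
    rows = []
    for name, r in results.items():
        rows.append(
            (name, r.auc, 1 - r.auc, r.ci_low, r.ci_high, r.sensitivity,
             r.specificity, r.n_pos, r.n_neg)
        )
    return pd.DataFrame(
        rows,
        columns=["stratum", "auc", "auc_flipped", "ci_low", "ci_high",
                 "sensitivity", "specificity", "n_pos", "n_neg"],
    )


def _observed_expected_high(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> tuple[float, float]:
    """Observed and expected event counts for the high group over pooled event times."""
    obs = exp = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_high = (at_risk & high).sum()
        d = ((time == t) & (event == 1)).sum()
        d_high = ((time == t) & (event == 1) & high).sum()
        obs += d_high
        exp += d * n_high / n
    return obs, exp


def km_logrank(
    scores: pd.Series,
    time: pd.Series,
    event: pd.Series,
    split: str = "median",
    curves: bool = True,
) -> tuple[SurvivalComparison, dict[str, pd.DataFrame]]:
    """Median-split log-rank comparison with Kaplan-Meier step tables.

    Samples at or below the median score go to the low group (ties to low).
    Returns the comparison and, when ``curves`` is true, per-group KM
    step-function tables.  Requires >= 2 events and both groups nonempty.
    """
    df = pd.DataFrame({"score": scores, "time": time, "event": event}).dropna()
    if (df["event"] == 1).sum() < 2:
        raise ValueError("need at least 2 events for a survival comparison")
    if split != "median":
        raise ValueError(f"unknown split rule {split!r}")
    cut = df["score"].median()
    high = (df["score"] > cut).to_numpy()
    if not high.any() or high.all():
        raise ValueError("median split produced an empty group")

    t = df["time"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=int)
    res = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
    obs, exp = _observed_expected_high(t, e, high)
    comparison = SurvivalComparison(
        logrank_chi2=float(res.test_statistic),
        p=float(min(max(res.p_value, np.finfo(float).tiny), 1.0)),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        direction="high" if obs >= exp else "low",
    )
    tables: dict[str, pd.DataFrame] = {}
    if curves:
        for name, mask in (("high", high), ("low", ~high)):
            kmf = KaplanMeierFitter()
            kmf.fit(t[mask], e[mask], label=name)
            sf = kmf.survival_function_.reset_index()
            sf.columns = ["time", "survival"]
            tables[name] = sf
    return comparison, tables


def strata_compare(scores: pd.Series, strata: pd.Series) -> dict:
    """Kruskal-Wallis omnibus across strata plus BH-adjusted pairwise rank-sum tests."""
    strata = strata.reindex(scores.index)
    groups = {k: scores[strata == k].to_numpy() for k in sorted(strata.dropna().unique())}
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 strata with >= 2 samples each")
    h, p = stats.kruskal(*groups.values())
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            stat, pw = stats.mannwhitneyu(
                groups[names[i]], groups[names[j]], alternative="two-sided"
            )
            rows.append((names[i], names[j], float(stat), float(pw)))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "U", "p"])
    if len(pairwise):
        pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return {"H": float(h), "p": float(p), "pairwise": pairwise}


def multicancer_panel(
    cohorts: dict[str, tuple[pd.DataFrame, pd.Series]],
    panel_genes: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tumor-vs-normal metagene comparison per cohort, BH-corrected across cohorts.

    Each cohort is a (z-matrix genes x samples, sample->class labels) pair.
    Direction comes from the median score difference; cohorts missing a class
    are skipped with a warning.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    rows = []
    for name, (matrix, labels) in cohorts.items():
        labels = labels.reindex(matrix.columns)
        if not {"tumor", "normal"} <= set(labels.dropna().unique()):
            log.warning("cohort %r missing a class; skipped", name)
            continue
        score = metagene_score(matrix, panel_genes)
        t = score[labels == "tumor"]
        n = score[labels == "normal"]
        _stat, p = stats.mannwhitneyu(t, n, alternative="two-sided")
        rows.append(
            (name, "up" if t.median() >= n.median() else "down", float(p),
             len(t), len(n))
        )
    table = pd.DataFrame(rows, columns=["cohort", "direction", "p", "n_tumor", "n_normal"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] <= alpha
    return table
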