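"""TIP-style per-gene regulatory scores.

The score summarizes a transcription factor's binding evidence for a gene:
a genome-wide average binding profile around the TSS is learned first, and
each gene's score is the profile-weighted sum of its own binding signal.
Peak signal is painted uniformly across the peak interval (only peak-level
data are in scope, not read pileups).  Scores are z-normalized and calibrated
so that the median positive raw score maps to 10, making a "score >= 10"
threshold mean "at or above the positive-score median".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .genome_io import GeneSet, PeakSet

log = logging.getLogger(__name__)


@dataclass
class WeightProfile:
    """Nonnegative weights over strand-oriented TSS offsets in [-W, W], summing to 1."""

    window_bp: int
    bin_bp: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        n_expected = 2 * self.window_bp // self.bin_bp + 1
        if len(self.weights) != n_expected:
            raise ValueError(
                f"profile length {len(self.weights)} != expected {n_expected}"
            )
        if (self.weights < 0).any():
            raise ValueError("negative profile weight")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("profile weights must sum to 1")

    @property
    def offsets(self) -> np.ndarray:
        """Strand-oriented bp offsets of each bin (negative = upstream)."""
        return np.arange(-self.window_bp, self.window_bp + 1, self.bin_bp)


def _binned_signal(
    genes: GeneSet, peaks: PeakSet, window_bp: int, bin_bp: int
) -> tuple[np.ndarray, list[str]]:
    """Signal matrix (genes x bins): summed peak signal at each strand-oriented
    TSS offset.  Bin d samples the genomic point tss + strand * offset(d);
    a peak contributes its signal where that point lies in [start, end)."""
    offsets = np.arange(-window_bp, window_bp + 1, bin_bp)
    gene_ids = [g.gene_id for g in genes]
    signal = np.zeros((len(gene_ids), len(offsets)))

    by_chrom = peaks.by_chrom()
    events: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, plist in by_chrom.items():
        # step-function coverage: +signal at start, -signal at end
        pos = np.concatenate(
            [[p.start for p in plist], [p.end for p in plist]]
        ).astype(float)
        delta = np.concatenate(
            [[p.signal for p in plist], [-p.signal for p in plist]]
        )
        order = np.argsort(pos, kind="mergesort")
        pos, delta = pos[order], delta[order]
        events[chrom] = (pos, np.cumsum(delta))

    for gi, g in enumerate(genes):
        if g.chrom not in events:
            continue
        pos, cum = events[g.chrom]
        sgn = 1 if g.strand == "+" else -1
        points = g.tss + sgn * offsets
        idx = np.searchsorted(pos, points, side="right")
        vals = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
        # clip tiny negatives from float cancellation in the cumulative sum
        signal[gi] = np.maximum(vals, 0.0)
    return signal, gene_ids


def build_tss_profile(
    peaks: PeakSet,
    genes: GeneSet,
    window_bp: int = 100_000,
    bin_bp: int = 100,
    smooth_bins: int = 5,
) -> WeightProfile:
    """Average binding profile around the TSS, smoothed and normalized to sum 1.

    weights(d) = mean over genes of binding signal at offset d, then a
    moving average of ``smooth_bins`` bins, then normalization.  Raises if no
    peak overlaps any gene window.
    """
    if len(genes) == 0:
        raise ValueError("need at least one gene")
    signal, _ = _binned_signal(genes, peaks, window_bp, bin_bp)
    mean_profile = signal.mean(axis=0)
    if mean_profile.sum() <= 0:
        raise ValueError("empty profile: no peak signal overlaps any gene window")
    if smooth_bins > 1:
        # nearest-edge padding keeps a flat profile exactly flat
        mean_profile = uniform_filter1d(
            mean_profile, size=smooth_bins, mode="nearest"
        )
        mean_profile = np.maximum(mean_profile, 0.0)  # clip filter round-off
    weights = mean_profile / mean_profile.sum()
    return WeightProfile(window_bp=window_bp, bin_bp=bin_bp, weights=weights)


def raw_scores(genes: GeneSet, peaks: PeakSet, profile: WeightProfile) -> pd.Series:
    """Per-gene raw score: sum over bins of profile weight x binding signal."""
    signal, gene_ids = _binned_signal(genes, peaks, profile.window_bp, profile.bin_bp)
    return pd.Series(signal @ profile.weights, index=gene_ids, name="raw")


def gene_raw_score(gene_id: str, genes: GeneSet, peaks: PeakSet, profile: WeightProfile) -> float:
    """Raw regulatory score of a single gene (zero iff no overlapping signal)."""
    return float(raw_scores(genes, peaks, profile).loc[gene_id])


def calibrate_scores(raw: pd.Series, tf: str = "") -> pd.DataFrame:
    """z-normalize raw scores and rescale so the positive-score median maps to 10.

    scaled = 10 * raw / median(raw over genes with raw > 0), so scaled >= 10
    iff raw is at or above the positive-score median.  The scaling is a
    positive multiple of raw, hence rank-preserving.  The median is taken over
    strictly positive scores so that sparse inputs cannot collapse the scale.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 genes to calibrate")
    sd = raw.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("all raw scores equal; z-score undefined")
    positive = raw[raw > 0]
    if positive.empty:
        raise ValueError("no positive raw scores; scale undefined")
    med = float(positive.median())
    out = pd.DataFrame(
        {
            "tf": tf,
            "raw": raw,
            "z": (raw - raw.mean()) / sd,
            "scaled": 10.0 * raw / med,
        }
    )
    out.index.name = "gene_id"
    return out


def combine_tf_scores(
    scores_a: pd.Series, scores_b: pd.Series, mode: str = "mean"
) -> pd.Series:
    """Elementwise combination of two TFs' scaled scores over the gene union.

    Genes missing from one TF are treated as score 0 with a warning.
    """
    if mode not in ("mean", "min", "max"):
        raise ValueError(f"unknown combine mode {mode!r}")
    universe = scores_a.index.union(scores_b.index)
    for name, s in (("first", scores_a), ("second", scores_b)):
        missing = universe.difference(s.index)
        if len(missing):
            log.warning(
                "%d genes missing from %s TF scores; treated as 0", len(missing), name
            )
    a = scores_a.reindex(universe, fill_value=0.0)
    b = scores_b.reindex(universe, fill_value=0.0)
    if mode == "mean":
        combined = (a + b) / 2.0
    elif mode == "min":
        combined = np.minimum(a, b)
    else:
        combined = np.maximum(a, b)
    combined.name = "combined_score"
    return combined
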