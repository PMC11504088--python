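"""Peak-to-gene annotation, TSS-distance distributions, enrichment over background,
and the relative-distance (reldist) co-occurrence statistic.

Distances are measured summit-to-TSS and strand-oriented: upstream of the TSS
is negative regardless of strand.  Distance categories are bins on |distance|;
the defaults ([0,1), [1,3), [3,5), [5,10), [10,100), [100,inf) kb) are
configurable because promoter sub-binning conventions vary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneSet, Peak, PeakSet

log = logging.getLogger(__name__)

DEFAULT_BIN_EDGES_BP: tuple[float, ...] = (0, 1_000, 3_000, 5_000, 10_000, 100_000, math.inf)
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "prom_0_1kb",
    "prom_1_3kb",
    "prom_3_5kb",
    "tss_5_10kb",
    "distal_10_100kb",
    "distal_gt100kb",
)
PROMOTER_CATEGORIES = frozenset(DEFAULT_CATEGORIES[:3])

GENIC_FEATURES = ("promoter", "exon", "intron", "downstream", "intergenic")


@dataclass(frozen=True)
class PeakAnnotation:
    """A peak assigned to its nearest-TSS gene."""

    peak: Peak
    gene_id: str | None
    signed_distance: int | None  # summit - TSS, negated for '-' strand genes
    category: str
    genic_feature: str


def _category_labels(edges: Sequence[float]) -> tuple[str, ...]:
    if tuple(edges) == DEFAULT_BIN_EDGES_BP:
        return DEFAULT_CATEGORIES
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hi_s = "inf" if math.isinf(hi) else f"{hi / 1000:g}kb"
        labels.append(f"tss_{lo / 1000:g}_{hi_s}")
    return tuple(labels)


def _categorize(abs_distance: float, edges: Sequence[float], labels: Sequence[str]) -> str:
    idx = int(np.searchsorted(np.asarray(edges[1:-1]), abs_distance, side="right"))
    return labels[idx]


def assign_peaks(
    peaks: PeakSet,
    genes: GeneSet,
    bin_edges_bp: Sequence[float] = DEFAULT_BIN_EDGES_BP,
    downstream_bp: int = 3_000,
    exons: dict[str, list[tuple[int, int]]] | None = None,
) -> list[PeakAnnotation]:
    """Assign each peak to the gene with minimal |summit - TSS|.

    Ties are broken by lexicographic gene_id.  Peaks on chromosomes without
    genes are annotated with ``gene_id=None`` in the most distal category and
    logged.  ``exons`` optionally maps gene_id to exon intervals so intragenic
    summits can be split into exon vs intron; without it, intragenic summits
    are labelled intron.
    """
    labels = _category_labels(bin_edges_bp)
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[np.ndarray, list]] = {}
    for chrom, gs in by_chrom.items():
        gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gs_sorted]), gs_sorted)

    out: list[PeakAnnotation] = []
    for peak in peaks:
        if peak.chrom not in index:
            log.warning(
                "peak %s:%d-%d on chromosome with no genes", peak.chrom, peak.start, peak.end
            )
            out.append(PeakAnnotation(peak, None, None, labels[-1], "intergenic"))
            continue
        tss_arr, gs_sorted = index[peak.chrom]
        i = int(np.searchsorted(tss_arr, peak.summit))
        # candidates flanking the insertion point; scan equal-TSS runs for the
        # lexicographically smallest gene_id among minimal-distance genes
        cand_idx = []
        if i > 0:
            cand_idx.append(i - 1)
        if i < len(tss_arr):
            cand_idx.append(i)
        best = None
        best_dist = None
        for j in cand_idx:
            d = abs(peak.summit - int(tss_arr[j]))
            if best_dist is None or d < best_dist:
                best_dist, best = d, gs_sorted[j]
            elif d == best_dist:
                # walk the run of genes sharing this TSS (sorted by gene_id)
                k = j
                while k > 0 and tss_arr[k - 1] == tss_arr[j]:
                    k -= 1
                cand = gs_sorted[k]
                if cand.gene_id < best.gene_id:
                    best = cand
        assert best is not None
        gene = best
        d = peak.summit - gene.tss
        signed = d if gene.strand == "+" else -d
        category = _categorize(abs(signed), bin_edges_bp, labels)
        # genic feature relative to the assigned gene
        if gene.start <= peak.summit < gene.end:
            feature = "intron"
            if exons is not None:
                for s, e in exons.get(gene.gene_id, ()):
                    if s <= peak.summit < e:
                        feature = "exon"
                        break
        else:
            if gene.strand == "+":
                in_downstream = gene.end <= peak.summit < gene.end + downstream_bp
            else:
                in_downstream = gene.start - downstream_bp <= peak.summit < gene.start
            if in_downstream:
                feature = "downstream"
            elif category in PROMOTER_CATEGORIES or (
                tuple(bin_edges_bp) != DEFAULT_BIN_EDGES_BP and abs(signed) < 5_000
            ):
                feature = "promoter"
            else:
                feature = "intergenic"
        out.append(PeakAnnotation(peak, gene.gene_id, int(signed), category, feature))
    return out


def annotations_to_frame(annotations: list[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                a.peak.chrom, a.peak.start, a.peak.end, a.peak.summit, a.peak.signal,
                a.gene_id, a.signed_distance, a.category, a.genic_feature,
            )
            for a in annotations
        ],
        columns=[
            "chrom", "start", "end", "summit", "signal",
            "gene_id", "signed_distance", "category", "genic_feature",
        ],
    )


def tss_distribution(
    annotations: list[PeakAnnotation],
    categories: Sequence[str] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Counts and percentages of peaks per distance category (sums to 100%)."""
    if not annotations:
        raise ValueError("empty annotation list")
    counts = pd.Series([a.category for a in annotations]).value_counts()
    counts = counts.reindex(categories, fill_value=0)
    table = pd.DataFrame({"count": counts})
    table["percentage"] = 100.0 * table["count"] / table["count"].sum()
    table.index.name = "category"
    return table


def _territory_bp(
    genes: GeneSet,
    genome_length: float,
    bin_edges_bp: Sequence[float],
    chrom_lengths: dict[str, float] | None = None,
) -> pd.Series:
    """Total bp per category, i.e. genomic territory whose nearest-TSS distance
    falls in each |distance| bin.  Computed exactly from the sorted TSS layout:
    every inter-TSS segment is a pair of linear distance ramps."""
    labels = _category_labels(bin_edges_bp)
    chroms = sorted({g.chrom for g in genes})
    if chrom_lengths is None:
        if len(chroms) != 1:
            raise ValueError("chrom_lengths required for multi-chromosome gene sets")
        chrom_lengths = {chroms[0]: float(genome_length)}
    territory = np.zeros(len(labels))
    edges = np.asarray(bin_edges_bp, dtype=float)

    def add_ramp(length: float) -> None:
        # one ramp covering distances (0, length], 1 bp per unit distance
        if length <= 0:
            return
        lo = np.minimum(edges[:-1], length)
        hi = np.minimum(edges[1:], length)
        territory[:] += np.maximum(hi - lo, 0.0)

    for chrom in chroms:
        tss = np.sort([g.tss for g in genes if g.chrom == chrom])
        L = chrom_lengths[chrom]
        add_ramp(tss[0])  # left flank
        for a, b in zip(tss[:-1], tss[1:]):
            half = (b - a) / 2.0
            add_ramp(half)
            add_ramp((b - a) - half)
        add_ramp(L - tss[-1])  # right flank
    return pd.Series(territory, index=labels, name="territory_bp")


def annotation_enrichment(
    annotations: list[PeakAnnotation],
    genes: GeneSet,
    genome_length: float,
    bin_edges_bp: Sequence[float] = DEFAULT_BIN_EDGES_BP,
    chrom_lengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Length-normalized peak density per category over the genome-wide density.

    A ratio of 1 means the category holds exactly its territory's share of
    peaks; >1 means enrichment beyond what region size alone explains.
    Zero-territory categories get a missing ratio.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    dist = tss_distribution(annotations, _category_labels(bin_edges_bp))
    territory = _territory_bp(genes, genome_length, bin_edges_bp, chrom_lengths)
    n_total = dist["count"].sum()
    global_density = n_total / genome_length
    with np.errstate(divide="ignore", invalid="ignore"):
        density = dist["count"].to_numpy() / territory.to_numpy()
        ratio = density / global_density
    table = pd.DataFrame(
        {
            "count": dist["count"],
            "territory_bp": territory,
            "enrichment": np.where(territory.to_numpy() > 0, ratio, np.nan),
        }
    )
    table.index.name = "category"
    return table


def reldist(
    set_a: PeakSet, set_b: PeakSet, n_bins: int = 50
) -> tuple[np.ndarray, pd.DataFrame]:
    """Relative distance of each A midpoint between its flanking B midpoints.

    For an A midpoint between consecutive B midpoints at distances d_left and
    d_right, the relative distance is min(d_left, d_right)/(d_left + d_right),
    in [0, 0.5]; under spatial independence it is uniform.  A midpoints outside
    B's span are skipped; chromosomes with fewer than two B midpoints are
    skipped with a warning.  Returns the values and a 50-bin histogram.
    """
    a_by = set_a.by_chrom()
    b_by = set_b.by_chrom()
    values: list[float] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        b_mid = np.sort(np.array([p.midpoint for p in b_by[chrom]], dtype=float))
        if len(b_mid) < 2:
            log.warning("reldist: chromosome %s has <2 reference midpoints; skipped", chrom)
            continue
        a_mid = np.array([p.midpoint for p in a_by[chrom]], dtype=float)
        inside = (a_mid >= b_mid[0]) & (a_mid <= b_mid[-1])
        a_mid = a_mid[inside]
        if a_mid.size == 0:
            continue
        i = np.clip(np.searchsorted(b_mid, a_mid, side="right"), 1, len(b_mid) - 1)
        left, right = b_mid[i - 1], b_mid[i]
        d_left, d_right = a_mid - left, right - a_mid
        values.extend(np.minimum(d_left, d_right) / (d_left + d_right))
    vals = np.asarray(values, dtype=float)
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 0.5))
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    hist["fraction"] = hist["count"] / max(len(vals), 1)
    return vals, hist
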