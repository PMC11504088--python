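"""Three-criterion selection of metagene signatures from combined ChIP + RNA evidence.

A gene enters the panel iff (i) its combined scaled regulatory score is at or
above the threshold (default 10, i.e. at or above the positive-score median),
(ii) it is significantly deregulated in the SAME direction in both knockdown
contrasts, and (iii) its fold change passes the inclusive +-1.25 linear gate
in both.  Admitted genes are split into four disjoint signatures by direction
(up/down) and biotype (protein_coding vs everything else).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kd_integration import classify_degs

log = logging.getLogger(__name__)

QUADRANTS = ("coding_up", "coding_down", "noncoding_up", "noncoding_down")


@dataclass
class SignaturePanel:
    """Four disjoint gene lists plus per-gene admitting evidence."""

    coding_up: list[str] = field(default_factory=list)
    coding_down: list[str] = field(default_factory=list)
    noncoding_up: list[str] = field(default_factory=list)
    noncoding_down: list[str] = field(default_factory=list)
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        lists = [getattr(self, q) for q in QUADRANTS]
        flat = [g for lst in lists for g in lst]
        if len(flat) != len(set(flat)):
            raise ValueError("signature lists must be pairwise disjoint")

    @property
    def all_genes(self) -> list[str]:
        return [g for q in QUADRANTS for g in getattr(self, q)]

    @property
    def up_genes(self) -> list[str]:
        return self.coding_up + self.noncoding_up

    @property
    def down_genes(self) -> list[str]:
        return self.coding_down + self.noncoding_down

    def __len__(self) -> int:
        return len(self.all_genes)

    def to_json(self, path: str | Path) -> None:
        payload = {q: getattr(self, q) for q in QUADRANTS}
        payload["provenance"] = self.provenance.reset_index().to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SignaturePanel":
        with open(path) as fh:
            payload = json.load(fh)
        prov = pd.DataFrame(payload.get("provenance", []))
        if not prov.empty:
            prov = prov.set_index("gene_id")
        return cls(
            coding_up=payload["coding_up"],
            coding_down=payload["coding_down"],
            noncoding_up=payload["noncoding_up"],
            noncoding_down=payload["noncoding_down"],
            provenance=prov,
        )


def select_signature(
    scores: pd.Series,
    detable_a: pd.DataFrame,
    detable_b: pd.DataFrame,
    biotypes: pd.Series,
    score_min: float = 10.0,
    alpha: float = 0.05,
    min_linear_fc: float = 1.25,
    max_fc_gap_log2: float | None = None,
) -> SignaturePanel:
    """Intersect the three selection criteria and split genes into quadrants.

    "Equally and unidirectionally affected" is operationalized as
    same-direction significance in both knockdowns; set ``max_fc_gap_log2``
    (e.g. 0.5) for the stricter optional mode that additionally bounds
    |fc_tf1 - fc_tf2|.
    """
    universe = scores.index.intersection(detable_a.index).intersection(detable_b.index)
    universe = universe.sort_values()  # deterministic regardless of input order
    cls_a = classify_degs(detable_a.loc[universe], alpha, min_linear_fc)
    cls_b = classify_degs(detable_b.loc[universe], alpha, min_linear_fc)

    same_dir = (cls_a == cls_b) & (cls_a != "ns")
    strong = scores.loc[universe] >= score_min
    admitted = same_dir & strong
    if max_fc_gap_log2 is not None:
        gap = (detable_a.loc[universe, "log2fc"] - detable_b.loc[universe, "log2fc"]).abs()
        admitted &= gap <= max_fc_gap_log2

    kept = universe[admitted]
    if len(kept) == 0:
        log.warning("signature selection admitted no genes; returning empty panel")
    coding = biotypes.reindex(kept) == "protein_coding"
    direction = cls_a.loc[kept]

    panel = SignaturePanel(
        coding_up=sorted(kept[(direction == "up") & coding]),
        coding_down=sorted(kept[(direction == "down") & coding]),
        noncoding_up=sorted(kept[(direction == "up") & ~coding]),
        noncoding_down=sorted(kept[(direction == "down") & ~coding]),
        provenance=pd.DataFrame(
            {
                "score": scores.loc[kept],
                "fc_tf1": detable_a.loc[kept, "log2fc"],
                "fc_tf2": detable_b.loc[kept, "log2fc"],
                "p_adj_tf1": detable_a.loc[kept, "p_adj"],
                "p_adj_tf2": detable_b.loc[kept, "p_adj"],
                "direction": direction,
                "biotype": biotypes.reindex(kept),
            }
        ).rename_axis("gene_id"),
    )
    return panel


def panel_report(panel: SignaturePanel) -> pd.DataFrame:
    """Counts per quadrant plus total and percent upregulated."""
    counts = {q: len(getattr(panel, q)) for q in QUADRANTS}
    total = sum(counts.values())
    pct_up = 100.0 * (counts["coding_up"] + counts["noncoding_up"]) / total if total else 0.0
    rows = [(q, counts[q]) for q in QUADRANTS]
    rows.append(("total", total))
    report = pd.DataFrame(rows, columns=["group", "count"])
    report["pct_upregulated"] = np.where(report["group"] == "total", pct_up, np.nan)
    return report
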