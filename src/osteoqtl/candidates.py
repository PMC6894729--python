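"""Positional candidates and the 0-10 summary candidate-score rubric.

Candidates are protein-coding genes overlapping a QTL support interval.
Each receives up to 10 points from four components:

* cis-regulation (0-3): cis-eQTL in bone = 3, cartilage or muscle = 2,
  any other tissue = 1, none = 0;
* average bone score (1-3): [0, 1) = 1, [1, 3] = 2, > 3 = 3;
* highest bone score (0-1): 1 point when the maximum over the 34 terms lies
  in [5, 10] (a footnote variant grants 2 points above 10);
* coding variants (0-3): any nonsense / frameshift / splice-site variant
  = 3, otherwise the Grantham sum of missense variants banded at < 100 = 1,
  100-300 = 2, > 300 = 3; no nonsynonymous variant = 0.

Genes scoring above 4 are flagged as strong candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "positional_candidates",
    "grade_bone_score",
    "grade_variants",
    "grade_cis",
    "summary_score",
    "annotate_known",
    "CandidateScore",
]

_SEVERE = {"nonsense", "frameshift", "splice"}
_CIS_POINTS = {"bone": 3, "cartilage": 2, "muscle": 2}


def positional_candidates(
    interval: tuple[object, float, float],
    annotations: pd.DataFrame,
    protein_coding_only: bool = True,
) -> list[str]:
    """Genes overlapping a closed interval ``(chrom, start_mb, end_mb)``.

    Any overlap counts, including genes spanning an edge.  ``annotations``
    is a BED-like frame with columns chrom, start_mb, end_mb, gene, biotype.
    """
    chrom, start, end = interval
    if start > end:
        raise ValueError(f"interval start {start} exceeds end {end}")
    sub = annotations[annotations["chrom"].astype(str) == str(chrom)]
    if protein_coding_only:
        sub = sub[sub["biotype"] == "protein_coding"]
    hit = (sub["start_mb"] <= end) & (sub["end_mb"] >= start)
    return sub.loc[hit, "gene"].tolist()


def grade_bone_score(average: float, maximum: float, footnote_max_rule: bool = False) -> tuple[int, int]:
    """Rubric points for the average and maximum bone scores.

    Average: [0, 1) -> 1, [1, 3] -> 2, > 3 -> 3 (boundaries fall in the
    middle band so the partition is total).  Maximum: 1 point iff in
    [5, 10]; with ``footnote_max_rule`` a maximum above 10 earns 2 points
    instead of 0.
    """
    if average < 0 or maximum < 0:
        raise ValueError("bone scores must be nonnegative")
    if average > 3:
        avg_pts = 3
    elif average >= 1:
        avg_pts = 2
    else:
        avg_pts = 1
    if 5 <= maximum <= 10:
        max_pts = 1
    elif maximum > 10 and footnote_max_rule:
        max_pts = 2
    else:
        max_pts = 0
    return avg_pts, max_pts


def grade_variants(variants: pd.DataFrame) -> int:
    """SNP rubric points for one gene's variant rows.

    ``variants`` has columns ``consequence`` and ``grantham`` (missense
    only).  Severe classes dominate; otherwise the missense Grantham sum is
    banded (<100 -> 1, 100-300 -> 2 inclusive, >300 -> 3); synonymous-only
    or empty tables score 0.
    """
    if variants is None or len(variants) == 0:
        return 0
    cons = variants["consequence"].astype(str)
    if cons.isin(_SEVERE).any():
        return 3
    missense = variants[cons == "missense"]
    if missense.empty:
        return 0
    total = float(missense["grantham"].fillna(0).sum())
    if total > 300:
        return 3
    if total >= 100:
        return 2
    return 1


def grade_cis(tissues) -> int:
    """Cis-regulation points: best tissue wins (bone 3, cartilage/muscle 2, other 1)."""
    tissues = [str(t).lower() for t in tissues]
    if not tissues:
        return 0
    return max(_CIS_POINTS.get(t, 1) for t in tissues)


@dataclass
class CandidateScore:
    """Four rubric components and their 0-10 sum for one gene."""

    gene: str
    cis_points: int
    avg_points: int
    max_points: int
    snp_points: int

    def __post_init__(self) -> None:
        for v in (self.cis_points, self.avg_points, self.max_points, self.snp_points):
            if v < 0:
                raise ValueError("negative rubric component")
        if not 0 <= self.summary <= 11:
            raise ValueError(f"summary {self.summary} out of range")

    @property
    def summary(self) -> int:
        return self.cis_points + self.avg_points + self.max_points + self.snp_points

    @property
    def strong(self) -> bool:
        return self.summary > 4


def summary_score(
    gene: str,
    bone_avg: float | None,
    bone_max: float | None,
    variants: pd.DataFrame | None,
    cis_tissues,
    footnote_max_rule: bool = False,
) -> CandidateScore:
    """Full rubric for one gene from its raw evidence.

    Genes without a computable bone score (no expression probe) receive 0
    average-grade points rather than the 1-point floor, which presumes a
    score exists.  Missing variant or cis evidence scores 0.
    """
    if bone_avg is None or (isinstance(bone_avg, float) and np.isnan(bone_avg)):
        avg_pts, max_pts = 0, 0
    else:
        avg_pts, max_pts = grade_bone_score(
            bone_avg, 0.0 if bone_max is None else bone_max, footnote_max_rule
        )
    return CandidateScore(
        gene=gene,
        cis_points=grade_cis(cis_tissues),
        avg_points=avg_pts,
        max_points=max_pts,
        snp_points=grade_variants(variants),
    )


def annotate_known(
    genes,
    known_lists: dict[str, set[str]],
    scores: pd.DataFrame | None = None,
    ignorome_threshold: float = 3.0,
) -> pd.DataFrame:
    """Membership flags per curated list and a three-way category.

    Categories: ``validated`` (present in any curated/experimental list),
    ``ignorome`` (absent from every list but with average bone score at or
    above the threshold), otherwise ``uncategorized``.
    """
    score_map = (
        scores.set_index("gene")["average"] if scores is not None else pd.Series(dtype=float)
    )
    rows = []
    for gene in genes:
        flags = {name: gene in members for name, members in known_lists.items()}
        in_any = any(flags.values())
        avg = float(score_map.get(gene, np.nan))
        if in_any:
            category = "validated"
        elif np.isfinite(avg) and avg >= ignorome_threshold:
            category = "ignorome"
        else:
            category = "uncategorized"
        rows.append({"gene": gene, **flags, "average": avg, "category": category})
    return pd.DataFrame(rows)
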