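"""Coexpression bone scores, GO-set eigengenes and the bone ignorome.

A gene's "bone score" quantifies guilt-by-association with skeletal
biology: take the probe's top-1000 coexpression neighborhood (by absolute
Spearman correlation across strains), test that neighborhood for
over-representation of each of 34 bone-associated GO terms with the
hypergeometric upper tail

    p = 1 - sum_{i=0}^{k-1} C(m, i) C(M - m, N - i) / C(M, N),

where M is the number of unique genes targeted by any probe, N the unique
genes in the neighborhood, m the term size and k the overlap, and average
-log10(p) over the terms.  Genes scoring at or above a threshold (3.0) with
no known link to the skeleton form the bone ignorome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSetCollection

__all__ = [
    "top_covariates",
    "hypergeom_enrichment",
    "bone_score",
    "bone_score_table",
    "gene_scores",
    "reference_calibration",
    "eigengenes",
    "classify_ignorome",
    "BoneScoreRow",
]


def _rank_matrix(expr: ExpressionMatrix) -> np.ndarray:
    mat = expr.values.to_numpy(float)
    return np.apply_along_axis(stats.rankdata, 1, mat)


def top_covariates(
    probe: str,
    expr: ExpressionMatrix,
    top_k: int = 1000,
    _ranks: np.ndarray | None = None,
) -> tuple[list[str], set[str]]:
    """Top-|Spearman| coexpression neighborhood of a probe.

    Returns ``(probes, unique mapped genes)``; the seed probe is excluded.
    Ties in |r| at the boundary are broken by probe id (lexicographic).
    """
    if probe not in expr.probes:
        raise KeyError(probe)
    if len(expr.strains) < 3:
        raise ValueError("need >= 3 strains")
    ranks = _ranks if _ranks is not None else _rank_matrix(expr)
    i = expr.probes.get_loc(probe)
    y = ranks[i] - ranks[i].mean()
    yss = float(y @ y)
    if yss == 0:
        raise ValueError(f"probe {probe} is constant across strains")
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.einsum("ij,ij->i", rc, rc) * yss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, rc @ y / denom, np.nan)
    order = sorted(
        (j for j in range(len(r)) if j != i and np.isfinite(r[j])),
        key=lambda j: (-abs(r[j]), expr.probes[j]),
    )
    if top_k > len(order):
        warnings.warn(f"top_k={top_k} exceeds {len(order)} available probes")
    chosen = [expr.probes[j] for j in order[:top_k]]
    return chosen, expr.genes_of(chosen)


def hypergeom_enrichment(N: int, k: int, m: int, M: int) -> float:
    """Upper-tail hypergeometric enrichment p = P(X >= k).

    X counts term genes in a neighborhood of N genes drawn from a universe
    of M genes of which m belong to the term.  Computed in log space via
    the survival function for numerical stability; k = 0 gives p = 1.
    """
    if not (0 <= k <= min(m, N) <= M) or m > M:
        raise ValueError(f"invalid hypergeometric bounds N={N}, k={k}, m={m}, M={M}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, m, N))


@dataclass
class BoneScoreRow:
    """Per-probe enrichment profile over the gene-set collection."""

    probe: str
    gene: str | None
    neighborhood_genes: int  # N
    term_logp: dict[str, float] = field(default_factory=dict)  # -log10 p per term
    average: float = 0.0
    maximum: float = 0.0


def bone_score(
    probe: str,
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    top_k: int = 1000,
    _ranks: np.ndarray | None = None,
) -> BoneScoreRow:
    """Average and maximum -log10 enrichment of a probe's neighborhood."""
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    _, genes = top_covariates(probe, expr, top_k, _ranks=_ranks)
    M = expr.universe_size
    N = len(genes)
    logp = {}
    for term, members in collection:
        members = members & set(expr.probe_to_gene.dropna())
        m = len(members)
        if m == 0:
            logp[term] = 0.0
            continue
        k = len(genes & members)
        p = hypergeom_enrichment(N, k, m, M)
        logp[term] = float(-np.log10(max(p, 1e-300)))
    vals = np.array(list(logp.values())) if logp else np.array([0.0])
    gene = expr.probe_to_gene.get(probe)
    return BoneScoreRow(
        probe=probe,
        gene=None if pd.isna(gene) else gene,
        neighborhood_genes=N,
        term_logp=logp,
        average=float(vals.mean()),
        maximum=float(vals.max()),
    )


def bone_score_table(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    probes=None,
    top_k: int = 1000,
) -> pd.DataFrame:
    """Bone scores for many probes: probe, gene, N, average, maximum."""
    ranks = _rank_matrix(expr)
    probes = list(probes) if probes is not None else list(expr.probes)
    rows = []
    for p in probes:
        try:
            r = bone_score(p, expr, collection, top_k, _ranks=ranks)
        except ValueError:  # constant probe: excluded
            continue
        rows.append((r.probe, r.gene, r.neighborhood_genes, r.average, r.maximum))
    return pd.DataFrame(rows, columns=["probe", "gene", "N", "average", "maximum"])


def gene_scores(table: pd.DataFrame, combine: str = "max") -> pd.DataFrame:
    """Collapse probe-level scores to genes.

    ``combine='max'`` calls a gene bone-linked if any of its probes is
    (the default); ``'mean'`` averages over probes.
    """
    if combine not in ("max", "mean"):
        raise ValueError(f"unknown combine rule {combine!r}")
    grouped = table.dropna(subset=["gene"]).groupby("gene")[["average", "maximum"]]
    return (grouped.max() if combine == "max" else grouped.mean()).reset_index()


def reference_calibration(
    reference_genes, scores: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Mean score of reference (well-known bone) genes, and flags.

    Returns the reference mean of the ``average`` column and a copy of
    ``scores`` with a boolean ``meets_reference`` column marking genes whose
    score meets or exceeds that mean.
    """
    ref = scores[scores["gene"].isin(set(reference_genes))]
    if ref.empty:
        raise ValueError("no reference genes found in the score table")
    ref_mean = float(ref["average"].mean())
    out = scores.copy()
    out["meets_reference"] = out["average"] >= ref_mean
    return ref_mean, out


def eigengenes(
    member_genes,
    expr: ExpressionMatrix,
    n_components: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component summary profiles of a gene set across strains.

    Member-gene probe rows are standardized across strains and decomposed
    by SVD; each eigengene (a per-strain profile) is sign-oriented to
    correlate positively with the member-gene mean profile.  Returns
    ``(components, explained_variance_fractions)`` where components has
    shape ``(k, n_strains)``, k <= n_components (with a warning when fewer
    genes than components are available).
    """
    member_genes = set(member_genes)
    mask = expr.probe_to_gene.isin(member_genes).to_numpy()
    mat = expr.values.to_numpy(float)[mask]
    sd = mat.std(axis=1, ddof=0)
    usable = sd > 0
    mat = mat[usable]
    if mat.shape[0] == 0:
        raise ValueError("no usable member genes with expression")
    if len(expr.strains) < 3:
        raise ValueError("need >= 3 strains")
    z = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, ddof=0, keepdims=True)
    k = min(n_components, z.shape[0])
    if k < n_components:
        warnings.warn(f"only {k} usable genes; returning {k} components")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    total = float((s**2).sum())
    comps = vt[:k]
    explained = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    mean_profile = z.mean(axis=0)
    for i in range(k):
        if np.dot(comps[i], mean_profile) < 0:
            comps[i] = -comps[i]
    return comps, explained


def classify_ignorome(
    scores: pd.DataFrame, known_bone_genes, threshold: float = 3.0
) -> dict[str, set[str]]:
    """Partition genes into known / ignorome / other by score and literature.

    The ignorome is the set of genes whose average bone score meets the
    threshold but that are absent from the known-gene list.
    """
    known_bone_genes = set(known_bone_genes)
    genes = scores.dropna(subset=["gene"])
    high = set(genes.loc[genes["average"] >= threshold, "gene"])
    all_genes = set(genes["gene"])
    known = all_genes & known_bone_genes
    ignorome = high - known_bone_genes
    other = all_genes - known - ignorome
    return {"known": known, "ignorome": ignorome, "other": other}
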