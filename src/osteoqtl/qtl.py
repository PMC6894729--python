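"""Haley-Knott interval mapping on recombinant-inbred strain means.

The mapping model is ordinary least squares of strain means on the expected
additive genotype code (B = -1, D = +1) at each marker or pseudomarker,
optionally with strain-level covariates in both the null and the full model.
Linkage is reported on the likelihood-ratio scale used by GeneNetwork,

    LRS = n * ln(RSS_null / RSS_full),        LOD = LRS / (2 ln 10),

and genome-wide significance comes from permuting strain means against
strain labels.  Because RI strains are produced by repeated sib mating, the
recombination fraction observed between two markers is inflated relative to
a single meiosis: R = 4r / (1 + 6r), with r obtained from the cM distance
through the Haldane map function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

LOD_PER_LRS = 1.0 / (2.0 * np.log(10.0))

__all__ = [
    "haldane_r",
    "ri_expansion",
    "expected_genotype",
    "hk_scan",
    "permutation_thresholds",
    "lod_support_interval",
    "composite_scan",
    "sex_by_genotype",
    "QTLScanResult",
    "SexByGenotypeTest",
]


def haldane_r(d_cm) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ri_expansion(r) -> np.ndarray | float:
    """Apparent recombination between RI strains from the per-meiosis fraction.

    Sib-mated RI lines accumulate recombinations over many generations;
    the expected fraction of discordant strain pairs is R = 4r/(1+6r).
    """
    r = np.asarray(r, dtype=float)
    return 4.0 * r / (1.0 + 6.0 * r)


def _ri_switch_prob(d_cm):
    return ri_expansion(haldane_r(d_cm))


def expected_genotype(
    pos_cm: float,
    left: tuple[float, float] | None = None,
    right: tuple[float, float] | None = None,
) -> float:
    """Conditional expectation of the +/-1 genotype code at ``pos_cm``.

    ``left`` and ``right`` are ``(cM, code)`` pairs for the nearest informative
    flanking markers (codes must be -1 or +1).  With both flanks, the strain's
    chromosome is treated as a Markov chain with RI-expanded switch
    probabilities per sub-interval; with one flank the expectation decays
    toward 0 with distance.  Returns NaN when no flank is available.
    """
    if left is None and right is None:
        return np.nan
    if left is not None and right is not None:
        cl, gl = left
        cr, gr = right
        if not (cl <= pos_cm <= cr):
            raise ValueError("position outside the flanking interval")
        r1 = _ri_switch_prob(pos_cm - cl)
        r2 = _ri_switch_prob(cr - pos_cm)
        # P(state at pos == gl | both flanks), two-state chain
        if gl == gr:
            num_same = (1 - r1) * (1 - r2)
            denom = num_same + r1 * r2
        else:
            num_same = (1 - r1) * r2
            denom = num_same + r1 * (1 - r2)
        p_left = num_same / denom
        return gl * p_left + (-gl) * (1 - p_left)
    (cm, g) = left if left is not None else right
    r1 = _ri_switch_prob(abs(pos_cm - cm))
    return g * (1.0 - 2.0 * r1)


@dataclass
class QTLScanResult:
    """Genome scan profile with optional permutation thresholds.

    ``table`` columns: chrom, locus, cM, Mb, lrs, lod, additive, n.
    ``thresholds`` is ``(suggestive_lrs, significant_lrs)`` or None.
    The additive effect follows the B/D convention: a negative value means
    the B allele is associated with higher trait values.
    """

    table: pd.DataFrame
    thresholds: tuple[float, float] | None = None

    def peak(self) -> pd.Series:
        """Row of the genome-wide maximum LRS (leftmost on ties)."""
        tab = self.table.dropna(subset=["lrs"])
        if tab.empty:
            raise ValueError("scan has no mapped positions")
        best = tab["lrs"].max()
        hits = tab[tab["lrs"] == best]
        return hits.iloc[0]

    @property
    def max_lrs(self) -> float:
        return float(self.table["lrs"].max())


def _scan_grid(gm: GenotypeMatrix, step: float | None) -> pd.DataFrame:
    """Markers plus pseudomarkers every ``step`` cM (markers only if None)."""
    rows = []
    for chrom, sub in gm.markers.groupby("chrom", sort=False):
        cms = sub["cM"].to_numpy(float)
        mbs = sub["Mb"].to_numpy(float)
        loci = sub["locus"].tolist()
        grid = list(cms)
        if step is not None and len(cms) > 1:
            extra = np.arange(cms[0], cms[-1], step)[1:]
            grid = np.union1d(np.round(cms, 9), np.round(extra, 9))
        for cm in np.atleast_1d(grid):
            j = np.searchsorted(np.round(cms, 9), cm)
            if j < len(cms) and abs(cms[j] - cm) < 1e-9:
                locus, mb = loci[j], mbs[j]
            else:
                locus = f"c{chrom}_pseudo_{cm:g}"
                mb = float(np.interp(cm, cms, mbs))
            rows.append((chrom, locus, float(cm), float(mb)))
    return pd.DataFrame(rows, columns=["chrom", "locus", "cM", "Mb"])


def expected_genotype_matrix(
    gm: GenotypeMatrix, step: float | None = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scan grid and (n_strains x n_positions) expected-code matrix.

    At genotyped markers the observed code is used (H -> 0, U -> NaN, i.e.
    the strain is dropped at that position).  At pseudomarkers the code is
    the RI conditional expectation given the nearest informative flanks.
    """
    grid = _scan_grid(gm, step)
    codes = gm.numeric()
    X = np.full((gm.n_strains, len(grid)), np.nan)
    marker_cm = gm.markers["cM"].to_numpy(float)
    marker_chrom = gm.markers["chrom"].to_numpy()
    for chrom in gm.markers["chrom"].unique():
        mk_idx = np.flatnonzero(marker_chrom == chrom)
        cms = marker_cm[mk_idx]
        gpos = np.flatnonzero(grid["chrom"].to_numpy() == chrom)
        gcm = grid["cM"].to_numpy(float)[gpos]
        # map grid position -> marker index if it coincides with a marker
        at_marker = {}
        for k, cm in enumerate(gcm):
            j = np.searchsorted(cms, cm)
            for jj in (j - 1, j):
                if 0 <= jj < len(cms) and abs(cms[jj] - cm) < 1e-9:
                    at_marker[k] = mk_idx[jj]
        for si in range(gm.n_strains):
            row = codes[si, mk_idx]
            inf = np.flatnonzero(np.abs(row) == 1.0)  # informative: B or D only
            inf_cm = cms[inf]
            for k, cm in enumerate(gcm):
                if k in at_marker:
                    X[si, gpos[k]] = codes[si, at_marker[k]]
                    continue
                j = np.searchsorted(inf_cm, cm)
                left = (inf_cm[j - 1], row[inf[j - 1]]) if j > 0 else None
                right = (inf_cm[j], row[inf[j]]) if j < len(inf) else None
                X[si, gpos[k]] = expected_genotype(cm, left, right)
    return grid, X


def _residualizer(design: np.ndarray):
    """Function projecting out ``design`` columns; observations in rows."""
    q, _ = np.linalg.qr(design)

    def resid(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    return resid, design.shape[1]


def _missing_patterns(X: np.ndarray):
    """Group column indices of X by their pattern of missing rows."""
    miss = np.isnan(X)
    groups: dict[bytes, list[int]] = {}
    for j in range(X.shape[1]):
        groups.setdefault(miss[:, j].tobytes(), []).append(j)
    for key, cols in groups.items():
        rows = ~np.frombuffer(key, dtype=bool)
        yield np.flatnonzero(rows), np.asarray(cols)


def _fit_positions(y, X, covariates=None):
    """Per-position LRS, additive slope and n for y ~ [1, C] + x_j."""
    n_pos = X.shape[1]
    lrs = np.full(n_pos, np.nan)
    beta = np.full(n_pos, np.nan)
    nobs = np.zeros(n_pos, dtype=int)
    for rows, cols in _missing_patterns(X):
        if rows.size < 3:
            continue
        D = np.ones((rows.size, 1))
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, float))
            if C.shape[0] != y.size:
                C = C.T
            D = np.column_stack([D, C[rows]])
            if np.linalg.matrix_rank(D) < D.shape[1]:
                raise ValueError("collinear covariates")
        resid, _ = _residualizer(D)
        yt = resid(y[rows])
        Xt = resid(X[np.ix_(rows, cols)])
        rss0 = float(yt @ yt)
        xss = np.einsum("ij,ij->j", Xt, Xt)
        num = Xt.T @ yt
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(xss > 1e-12, num / np.where(xss > 0, xss, 1.0), 0.0)
            rss1 = rss0 - np.where(xss > 1e-12, num**2 / np.where(xss > 0, xss, 1.0), 0.0)
        n = rows.size
        with np.errstate(divide="ignore"):
            stat = np.where(
                rss1 > 1e-12 * max(rss0, 1e-300),
                n * np.log(np.maximum(rss0, 1e-300) / np.clip(rss1, 1e-300, None)),
                np.inf,
            )
        if rss0 <= 1e-300:
            stat = np.zeros_like(stat)
        if np.any(np.isinf(stat)):
            warnings.warn("perfect fit at some positions; LRS reported as inf")
        lrs[cols] = stat
        beta[cols] = b
        nobs[cols] = n
    return lrs, beta, nobs


def _align_trait(trait: pd.Series, gm: GenotypeMatrix, min_strains: int = 8):
    """Strains present in both the trait vector and the genotypes."""
    trait = trait.dropna()
    common = [s for s in gm.strains if s in trait.index]
    if len(common) < min_strains:
        raise ValueError(
            f"only {len(common)} strains with both trait and genotype (need >= {min_strains})"
        )
    return trait.loc[common].to_numpy(float), gm.subset_strains(common), common


def hk_scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    step: float | None = 1.0,
    min_strains: int = 8,
) -> QTLScanResult:
    """Haley-Knott genome scan of strain means.

    Parameters
    ----------
    trait
        Strain means indexed by strain id.
    covariates
        Optional strain-level covariates (index = strain id); they enter
        both the null and the full model at every position.
    step
        Pseudomarker spacing in cM; ``None`` scans genotyped markers only.
    min_strains
        Minimum strains with both trait and genotype (default 8; tiny
        worked examples can lower it).
    """
    y, gm, common = _align_trait(trait, genotypes, min_strains)
    C = covariates.loc[common].to_numpy(float) if covariates is not None else None
    grid, X = expected_genotype_matrix(gm, step)
    lrs, beta, nobs = _fit_positions(y, X, C)
    tab = grid.copy()
    tab["lrs"] = lrs
    tab["lod"] = lrs * LOD_PER_LRS
    tab["additive"] = beta
    tab["n"] = nobs
    return QTLScanResult(tab)


def permutation_thresholds(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    n_perm: int = 2000,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    step: float | None = 1.0,
    full_output: bool = False,
):
    """Genome-wide LRS thresholds from a permutation null.

    Strain means are permuted against strain labels ``n_perm`` times; each
    permutation is rescanned and its genome-wide maximum recorded.  The
    significant threshold is the 95th percentile of this null-maximum
    distribution (genome-wide p = 0.05) and the suggestive threshold the
    63rd-from-top, i.e. 37th percentile (genome-wide p = 0.63).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y, gm, common = _align_trait(trait, genotypes)
    C = covariates.loc[common].to_numpy(float) if covariates is not None else None
    _, X = expected_genotype_matrix(gm, step)
    n = y.size
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    max_lrs = np.zeros(n_perm)
    for rows, cols in _missing_patterns(X):
        if rows.size < 3:
            continue
        D = np.ones((rows.size, 1))
        if C is not None:
            D = np.column_stack([D, np.atleast_2d(C)[rows]])
        resid, _ = _residualizer(D)
        Yt = resid(perms[:, rows].T).T  # permutations in rows, observations in columns
        Xt = resid(X[np.ix_(rows, cols)])
        rss0 = np.einsum("ij,ij->i", Yt, Yt)
        xss = np.einsum("ij,ij->j", Xt, Xt)
        ok = xss > 1e-12
        num = Yt @ Xt[:, ok]
        rss1 = rss0[:, None] - num**2 / xss[ok][None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            block = rows.size * np.log(rss0[:, None] / np.clip(rss1, 1e-300, None))
        if block.size:
            np.maximum(max_lrs, np.nanmax(block, axis=1), out=max_lrs)
    significant = float(np.percentile(max_lrs, 95.0))
    suggestive = float(np.percentile(max_lrs, 37.0))
    if full_output:
        return (suggestive, significant), max_lrs
    return suggestive, significant


def lod_support_interval(
    result: QTLScanResult, drop: float = 1.5
) -> tuple[object, float, float]:
    """LOD-drop support interval around the genome-wide peak.

    Returns ``(chromosome, start_Mb, end_Mb)`` for the maximal contiguous
    run of positions on the peak chromosome, containing the peak, whose LOD
    stays within ``drop`` units of the peak LOD.
    """
    peak = result.peak()
    sub = result.table[result.table["chrom"] == peak["chrom"]].reset_index(drop=True)
    thresh = peak["lod"] - drop
    above = (sub["lod"] >= thresh).to_numpy()
    pk = int(np.flatnonzero((sub["cM"] == peak["cM"]) & (sub["lrs"] == peak["lrs"]))[0])
    lo = pk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = pk
    while hi < len(sub) - 1 and above[hi + 1]:
        hi += 1
    return peak["chrom"], float(sub.loc[lo, "Mb"]), float(sub.loc[hi, "Mb"])


def composite_scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    background_markers: list[str],
    exclusion_cm: float = 10.0,
    step: float | None = 1.0,
) -> QTLScanResult:
    """Composite interval mapping: condition the scan on background markers.

    The numeric codes of ``background_markers`` enter both models as
    covariates.  Positions within ``exclusion_cm`` of a background marker on
    the same chromosome are reported as missing (the covariate would absorb
    the test signal there).
    """
    if not background_markers:
        return hk_scan(trait, genotypes, step=step)
    loci = genotypes.markers["locus"].tolist()
    missing = [m for m in background_markers if m not in loci]
    if missing:
        raise ValueError(f"background markers not in map: {missing}")
    idx = [loci.index(m) for m in background_markers]
    codes = genotypes.numeric()[:, idx]
    # mean-impute rare missing background codes so covariate rows stay usable
    col_mean = np.nanmean(codes, axis=0)
    codes = np.where(np.isnan(codes), col_mean, codes)
    cov = pd.DataFrame(codes, index=genotypes.strains)
    res = hk_scan(trait, genotypes, covariates=cov, step=step)
    bg = genotypes.markers.iloc[idx]
    tab = res.table
    mask = np.zeros(len(tab), dtype=bool)
    for _, brow in bg.iterrows():
        mask |= (tab["chrom"] == brow["chrom"]).to_numpy() & (
            np.abs(tab["cM"].to_numpy(float) - float(brow["cM"])) <= exclusion_cm
        )
    tab.loc[mask, ["lrs", "lod", "additive"]] = np.nan
    return QTLScanResult(tab)


@dataclass
class SexByGenotypeTest:
    marker: str
    p_value: float
    model: str = "value ~ sex + genotype + sex:genotype on strain-by-sex means"


def sex_by_genotype(
    strain_sex_means: pd.DataFrame, genotypes: GenotypeMatrix, marker: str
) -> SexByGenotypeTest:
    """Uncorrected p value for a sex-by-genotype interaction at ``marker``.

    ``strain_sex_means`` needs columns ``strain``, ``sex`` and ``value``
    (per strain-by-sex means).  A fixed-effects OLS of the means on sex,
    genotype and their product is fitted; the reported p is the t/F test of
    the interaction coefficient, uncorrected for multiple testing.
    """
    import statsmodels.api as sm

    loci = genotypes.markers["locus"].tolist()
    if marker not in loci:
        raise ValueError(f"marker {marker!r} not in genotype map")
    geno = pd.Series(genotypes.numeric()[:, loci.index(marker)], index=genotypes.strains)
    df = strain_sex_means.copy()
    df["geno"] = df["strain"].map(geno)
    df = df.dropna(subset=["value", "geno"])
    both = df.groupby("strain")["sex"].nunique()
    if not (both >= 2).any():
        raise ValueError("no strain with both sexes present")
    sex_num = (df["sex"] == "M").astype(float).to_numpy()
    X = np.column_stack([
        np.ones(len(df)),
        sex_num,
        df["geno"].to_numpy(float),
        sex_num * df["geno"].to_numpy(float),
    ])
    fit = sm.OLS(df["value"].to_numpy(float), X).fit()
    p = float(fit.pvalues[3])
    if np.isnan(p):
        p = 1.0
    return SexByGenotypeTest(marker=marker, p_value=p)
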