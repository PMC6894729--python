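"""Heritability, jackknife precision, sex-difference tests and correlations.

Broad-sense heritability of a trait in an RI family is estimated as the
sample variance of strain means divided by the sample variance of all
individual values.  Its precision is assessed by a leave-one-strain-out
jackknife,

    V_JK(h2) = (n-1)/n * sum_i (h_(-i) - hbar)^2,

where hbar is the heritability computed from all strains and n the number
of strains; the coefficient of error is 100 * sqrt(V_JK) / hbar.  Sex
differences in heritability are tested with a normal z statistic whose
denominator plugs the jackknife variances into the standard two-sample
form, z = (h_F - h_M) / sqrt(s_F^2/n_1 + s_M^2/n_2); with 35 traits tested
the Bonferroni two-tailed critical value is |z| >= 3.18.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "heritability",
    "jackknife_h2",
    "sex_diff_z",
    "bonferroni_critical_z",
    "trait_correlation_matrix",
    "pheno_expr_correlation",
    "HeritabilityEstimate",
    "SexDiffTest",
]


@dataclass
class HeritabilityEstimate:
    trait: str
    sex: str
    h2: float
    v_jk: float = np.nan
    coeff_error_pct: float = np.nan
    n_strains: int = 0


@dataclass
class SexDiffTest:
    trait: str
    z: float
    alpha_per_test: float
    critical_z: float
    significant: bool


def _h2_ratio(groups: list[np.ndarray]) -> float:
    """var(strain means) / var(all values), sample (n-1) variances."""
    means = np.array([g.mean() for g in groups])
    allv = np.concatenate(groups)
    total = allv.var(ddof=1)
    if total == 0:
        return np.nan
    return float(means.var(ddof=1) / total)


def _as_groups(values_by_strain) -> list[np.ndarray]:
    if isinstance(values_by_strain, dict):
        items = values_by_strain.items()
    else:  # pandas groupby-able frame with strain/value columns
        items = (
            (k, g)
            for k, g in pd.DataFrame(values_by_strain).groupby("strain")["value"]
        )
    groups = [np.asarray(pd.Series(v).dropna(), dtype=float) for _, v in items]
    return [g for g in groups if g.size > 0]


def heritability(
    values_by_strain, trait: str = "", sex: str = "pooled"
) -> HeritabilityEstimate:
    """Broad-sense heritability from individual values grouped by strain.

    ``values_by_strain`` is a mapping strain -> values, or a DataFrame with
    ``strain`` and ``value`` columns.  The estimate is not clamped to [0, 1];
    unbalanced small designs can exceed 1.  Zero total variance yields NaN.
    """
    groups = _as_groups(values_by_strain)
    if len(groups) < 3:
        raise ValueError(f"need >= 3 strains with data, got {len(groups)}")
    return HeritabilityEstimate(
        trait=trait, sex=sex, h2=_h2_ratio(groups), n_strains=len(groups)
    )


def jackknife_h2(values_by_strain, trait: str = "", sex: str = "pooled") -> HeritabilityEstimate:
    """Heritability with leave-one-strain-out jackknife variance and CE%.

    hbar in the jackknife sum is the all-strain estimate (the estimator's
    own value), per the definition above.
    """
    groups = _as_groups(values_by_strain)
    n = len(groups)
    if n < 4:
        raise ValueError(f"jackknife needs >= 4 strains, got {n}")
    h_full = _h2_ratio(groups)
    h_loo = np.array([_h2_ratio(groups[:i] + groups[i + 1 :]) for i in range(n)])
    v_jk = (n - 1) / n * float(np.sum((h_loo - h_full) ** 2))
    ce = 100.0 * np.sqrt(v_jk) / h_full if h_full != 0 else np.nan
    return HeritabilityEstimate(
        trait=trait, sex=sex, h2=h_full, v_jk=v_jk, coeff_error_pct=ce, n_strains=n
    )


def bonferroni_critical_z(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-tailed Bonferroni per-test alpha and normal critical value."""
    alpha_per_test = alpha / n_tests
    return alpha_per_test, float(stats.norm.isf(alpha_per_test / 2.0))


def sex_diff_z(
    female: HeritabilityEstimate,
    male: HeritabilityEstimate,
    n_tests: int,
    n1: int | None = None,
    n2: int | None = None,
    alpha: float = 0.05,
    divide_by_n: bool = True,
) -> SexDiffTest:
    """Normal z test for a female-male heritability difference.

    The denominator plugs jackknife variances into the two-sample form,
    sqrt(s_F^2/n1 + s_M^2/n2), with n1/n2 the strain counts (the study used
    n1 = n2 = 35 strains measured in both sexes).  Note the jackknife
    variance is already a variance of the estimator, so this form shrinks
    the SE a second time; ``divide_by_n=False`` gives the conventional
    sqrt(s_F^2 + s_M^2) denominator for comparison.
    """
    v1, v2 = female.v_jk, male.v_jk
    if not (v1 > 0 and v2 > 0):
        raise ValueError("jackknife variances must be positive")
    n1 = n1 if n1 is not None else female.n_strains
    n2 = n2 if n2 is not None else male.n_strains
    if divide_by_n:
        denom = np.sqrt(v1 / n1 + v2 / n2)
    else:
        denom = np.sqrt(v1 + v2)
    z = float((female.h2 - male.h2) / denom)
    alpha_per_test, crit = bonferroni_critical_z(n_tests, alpha)
    return SexDiffTest(
        trait=female.trait,
        z=z,
        alpha_per_test=alpha_per_test,
        critical_z=crit,
        significant=bool(abs(z) >= crit),
    )


def trait_correlation_matrix(
    strain_means: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise-complete trait-by-trait correlations on strain means.

    Rows of ``strain_means`` are strains, columns are traits.  Pairs with
    fewer than 3 overlapping strains, and constant traits, come out NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    return strain_means.corr(method=method, min_periods=3)


def pheno_expr_correlation(
    trait_means: pd.Series, expression, top_k: int = 1000
) -> pd.DataFrame:
    """Transcripts ranked by |Spearman r| against a trait across strains.

    Only strains present in both the trait vector and the expression matrix
    are used (>= 3 required).  Constant probes are excluded from the
    ranking.  Returns the top ``top_k`` rows with probe, gene, r and n.
    """
    common = [s for s in expression.strains if s in trait_means.index]
    common = [s for s in common if np.isfinite(trait_means[s])]
    if len(common) < 3:
        raise ValueError("fewer than 3 overlapping strains")
    y = stats.rankdata(trait_means[common].to_numpy(float))
    mat = expression.values[common].to_numpy(float)
    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    yc = y - y.mean()
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, rc @ yc / denom, np.nan)
    df = pd.DataFrame(
        {
            "probe": expression.probes,
            "gene": expression.probe_to_gene.to_numpy(),
            "r": r,
            "n": len(common),
        }
    ).dropna(subset=["r"])
    df = df.reindex(df["r"].abs().sort_values(ascending=False, kind="mergesort").index)
    return df.head(top_k).reset_index(drop=True)
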