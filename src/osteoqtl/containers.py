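"""In-memory containers shared across the pipeline.

Genotypes, expression matrices and gene-set collections are each used by
several analysis stages, so their container classes live here rather than
with any single stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Numeric coding of recombinant-inbred allele calls. ``B`` and ``D`` are the
#: two parental homozygotes, ``H`` a residual heterozygote (coded 0, i.e. no
#: additive contribution), ``U`` an unknown call (missing).
ALLELE_CODES = {"B": -1.0, "D": 1.0, "H": 0.0, "U": np.nan}


class MapError(ValueError):
    """Raised when a genetic map is not monotone within a chromosome."""


@dataclass
class GenotypeMatrix:
    """Strains x ordered markers with a chromosome/cM/Mb map.

    Parameters
    ----------
    strains
        Strain identifiers, one per row of ``calls``.
    markers
        DataFrame with columns ``chrom``, ``locus``, ``cM``, ``Mb`` in map
        order (cM non-decreasing within chromosome).
    calls
        Array of shape ``(n_strains, n_markers)`` holding single-character
        allele calls from ``{B, D, H, U}``.
    """

    strains: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.strains), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        bad = set(np.unique(self.calls)) - set(ALLELE_CODES)
        if bad:
            raise ValueError(f"unknown allele codes: {sorted(bad)}")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            cm = sub["cM"].to_numpy(float)
            if np.any(np.diff(cm) < 0):
                raise MapError(f"cM positions decrease within chromosome {chrom}")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def numeric(self) -> np.ndarray:
        """Float matrix with B=-1, D=+1, H=0, U=NaN."""
        out = np.empty(self.calls.shape, dtype=float)
        for code, value in ALLELE_CODES.items():
            out[self.calls == code] = value
        return out

    def subset_strains(self, strains: list[str]) -> "GenotypeMatrix":
        idx = [self.strains.index(s) for s in strains]
        return GenotypeMatrix(list(strains), self.markers, self.calls[idx])


@dataclass
class ExpressionMatrix:
    """Probes x strains log2-scale expression with a probe-to-gene map."""

    values: pd.DataFrame  # index = probe ids, columns = strain ids
    probe_to_gene: pd.Series  # index = probe ids, values = gene symbols

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids in expression matrix")
        self.probe_to_gene = self.probe_to_gene.reindex(self.values.index)

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def strains(self) -> pd.Index:
        return self.values.columns

    @property
    def universe_size(self) -> int:
        """Number of unique genes targeted by any probe (the enrichment universe M)."""
        return int(self.probe_to_gene.dropna().nunique())

    def genes_of(self, probes) -> set[str]:
        """Unique mapped genes among ``probes``."""
        genes = self.probe_to_gene.reindex(probes).dropna()
        return set(genes)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO terms), as read from a GMT file."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")
            self.sets[term] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)
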