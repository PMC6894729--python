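"""Readers and writers for the pipeline's text formats.

* GeneNetwork-style ``.geno``: ``@``-prefixed header directives (family
  type, maternal/paternal allele symbols), then a tab-separated table with
  columns Chr, Locus, cM, Mb followed by one column per strain; cells are
  single-letter calls B/D/H/U.
* GMT gene sets: one set per line, ``name<TAB>description<TAB>member...``.
* Plain TSV with a header row for phenotype, expression, annotation and
  variant tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ALLELE_CODES, GeneSetCollection, GenotypeMatrix

__all__ = [
    "read_geno",
    "write_geno",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
]


class GenoParseError(ValueError):
    pass


def read_geno(path) -> GenotypeMatrix:
    """Parse a GeneNetwork-dialect .geno file.

    Unknown allele symbols raise a parse error naming the locus and strain;
    a non-monotone cM map raises a map error.
    """
    path = Path(path)
    header = None
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "@")):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:4] != ["Chr", "Locus", "cM", "Mb"]:
                    raise GenoParseError(
                        f"{path}:{lineno}: expected header 'Chr Locus cM Mb <strains...>'"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise GenoParseError(
                    f"{path}:{lineno}: row has {len(fields)} columns, header has {len(header)}"
                )
            rows.append(fields)
    if header is None or not rows:
        raise GenoParseError(f"{path}: no genotype rows found")
    strains = header[4:]
    markers = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "locus": [r[1] for r in rows],
            "cM": [float(r[2]) for r in rows],
            "Mb": [float(r[3]) for r in rows],
        }
    )
    calls = np.empty((len(strains), len(rows)), dtype="<U1")
    for j, r in enumerate(rows):
        for i, cell in enumerate(r[4:]):
            if cell not in ALLELE_CODES:
                raise GenoParseError(
                    f"{path}: unknown allele {cell!r} at locus {r[1]} strain {strains[i]}"
                )
            calls[i, j] = cell
    return GenotypeMatrix(strains, markers, calls)


def write_geno(gm: GenotypeMatrix, path, family: str = "riset") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("@name:synthetic\n@type:%s\n@mat:B\n@pat:D\n@het:H\n@unk:U\n" % family)
        fh.write("\t".join(["Chr", "Locus", "cM", "Mb", *gm.strains]) + "\n")
        for j, row in gm.markers.iterrows():
            cells = gm.calls[:, j].tolist()
            fh.write(
                "\t".join(
                    [str(row["chrom"]), str(row["locus"]), f"{row['cM']:g}", f"{row['Mb']:g}", *cells]
                )
                + "\n"
            )


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (one gene set per line; members deduplicated)."""
    import warnings

    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term, desc, *members = fields
            members = [m for m in members if m]
            if len(set(members)) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in {term}; deduplicated")
            sets[term] = frozenset(members)
            names[term] = desc
    if not sets:
        import warnings as _w

        _w.warn(f"{path}: empty GMT file")
        return GeneSetCollection({}, {})
    return GeneSetCollection(sets, names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w") as fh:
        for term, members in collection:
            desc = collection.names.get(term, "")
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def read_expression(values_path, probe_map_path):
    """Expression TSV (probes x strains, header = strains) + 2-column probe map."""
    from .containers import ExpressionMatrix

    values = pd.read_csv(values_path, sep="\t", index_col=0)
    pmap = pd.read_csv(probe_map_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values, pmap)


def write_expression(expr, values_path, probe_map_path) -> None:
    expr.values.to_csv(values_path, sep="\t")
    expr.probe_to_gene.rename("gene").to_csv(probe_map_path, sep="\t", index_label="probe")
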