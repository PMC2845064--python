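"""Delimited-text I/O for genotype matrices, phenotype tables, marker maps and fits.

All on-disk formats are plain tab- or comma-delimited text (the delimiter is
sniffed from the header line).  Genotypes are held internally in signed coding
``{-1, 0, +1}`` for the genotypes ``0_0``, ``0_1`` and ``1_1``; dosage coding
``{0, 1, 2}`` is accepted at the boundary and recoded by subtracting one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenotypeMatrix",
    "PhenotypeTable",
    "MarkerMap",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_map",
    "write_map",
    "read_fit",
    "write_fit",
    "align_phenotypes",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: no records")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes in signed coding.

    Attributes
    ----------
    individuals : list of str
        Ordered individual identifiers (rows).
    snp_ids : list of str
        Ordered marker identifiers (columns).
    codes : ndarray of shape (n, N), dtype int8
        Genotype codes, each entry in ``{-1, 0, +1}``.
    """

    individuals: list
    snp_ids: list
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        n, N = self.codes.shape
        if len(self.individuals) != n:
            raise ValueError(f"{len(self.individuals)} individual ids for {n} rows")
        if len(self.snp_ids) != N:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {N} columns")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.snp_ids)) != N:
            raise ValueError("duplicate SNP ids")
        bad = ~np.isin(self.codes, (-1, 0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype code out of range at individual {self.individuals[i]!r}, "
                f"SNP {self.snp_ids[j]!r}: {self.codes[i, j]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the SNP columns selected by ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snp_ids=[self.snp_ids[j] for j in keep],
            codes=self.codes[:, keep],
        )


@dataclass
class PhenotypeTable:
    """Phenotypes and fixed-effect design for a set of individuals.

    ``X`` always carries a leading column of ones (the general mean), so the
    number of fixed effects ``f`` is at least 1.
    """

    individuals: list
    y: np.ndarray
    X: np.ndarray
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.individuals)
        if self.y.shape != (n,):
            raise ValueError("y length does not match number of individuals")
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValueError("X row count does not match number of individuals")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the general mean (all ones)")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")

    @property
    def n_fixed_effects(self) -> int:
        return self.X.shape[1]


@dataclass
class MarkerMap:
    """Genetic map: one record per locus (markers and QTL).

    Chromosome indices are 1-based; positions are centimorgans within the
    chromosome, non-decreasing within each chromosome.
    """

    ids: list
    chromosome: np.ndarray
    position_cM: np.ndarray
    locus_class: np.ndarray  # 'marker' or 'qtl'

    def __post_init__(self):
        self.chromosome = np.asarray(self.chromosome, dtype=int)
        self.position_cM = np.asarray(self.position_cM, dtype=float)
        self.locus_class = np.asarray(self.locus_class, dtype=object)
        L = len(self.ids)
        if not (len(self.chromosome) == len(self.position_cM) == len(self.locus_class) == L):
            raise ValueError("map fields have inconsistent lengths")
        if len(set(self.ids)) != L:
            raise ValueError("duplicate locus ids in map")
        if (self.position_cM < 0).any():
            raise ValueError("negative map position")
        for c in np.unique(self.chromosome):
            pos = self.position_cM[self.chromosome == c]
            if (np.diff(pos) < 0).any():
                raise ValueError(f"positions decrease within chromosome {c}")
        unknown = set(self.locus_class) - {"marker", "qtl"}
        if unknown:
            raise ValueError(f"unknown locus class {unknown}")

    @property
    def n_loci(self) -> int:
        return len(self.ids)

    def is_marker(self) -> np.ndarray:
        return self.locus_class == "marker"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "chromosome": self.chromosome,
                "position_cM": self.position_cM,
                "class": self.locus_class,
            }
        )


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, coding: str = "signed") -> GenotypeMatrix:
    """Read a delimited genotype file (rows = individuals, columns = SNPs).

    The first column holds individual ids and the header row SNP ids.  With
    ``coding='dosage'`` entries are minor-allele counts ``{0, 1, 2}`` and are
    recoded to signed form by subtracting 1.
    """
    if coding not in ("signed", "dosage"):
        raise ValueError(f"unknown coding {coding!r}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: no records")
    values = df.to_numpy()
    parsed = np.full(values.shape, -128, dtype=np.int8)
    valid = {"signed": {"-1": -1, "0": 0, "1": 1, "+1": 1},
             "dosage": {"0": -1, "1": 0, "2": 1}}[coding]
    for tok, code in valid.items():
        parsed[values == tok] = code
    bad = parsed == -128
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: bad genotype token {values[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} (coding={coding})"
        )
    return GenotypeMatrix(
        individuals=[str(s) for s in df.index],
        snp_ids=[str(s) for s in df.columns],
        codes=parsed,
    )


def write_genotypes(path, gm: GenotypeMatrix, coding: str = "signed", sep: str = "\t") -> None:
    codes = gm.codes if coding == "signed" else gm.codes.astype(np.int16) + 1
    if coding not in ("signed", "dosage"):
        raise ValueError(f"unknown coding {coding!r}")
    df = pd.DataFrame(codes, index=gm.individuals, columns=gm.snp_ids)
    df.to_csv(path, sep=sep, index_label="id")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> PhenotypeTable:
    """Read a delimited phenotype file: id, trait value, optional covariates.

    A column of ones (the general mean) is prepended to the covariates to form
    the fixed-effect design ``X``.  Missing trait values or non-numeric
    covariates are errors; no imputation is done.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no records")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least an id and a trait column")
    ids = [str(s) for s in df.iloc[:, 0]]
    try:
        y = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric trait value ({exc})") from None
    if np.isnan(y).any():
        row = ids[int(np.flatnonzero(np.isnan(y))[0])]
        raise FormatError(f"{path}: missing trait value for individual {row!r}")
    cov_names = list(df.columns[2:])
    try:
        cov = df.iloc[:, 2:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric covariate ({exc})") from None
    if cov.size and np.isnan(cov).any():
        raise FormatError(f"{path}: missing covariate value")
    X = np.column_stack([np.ones(len(ids))] + ([cov] if cov.size else []))
    return PhenotypeTable(individuals=ids, y=y, X=X, covariate_names=cov_names)


def write_phenotypes(path, pt: PhenotypeTable, sep: str = "\t") -> None:
    data = {"id": pt.individuals, "trait": pt.y}
    for j, name in enumerate(pt.covariate_names):
        data[name] = pt.X[:, 1 + j]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def align_phenotypes(gm: GenotypeMatrix, pt: PhenotypeTable) -> PhenotypeTable:
    """Reorder a phenotype table to the genotype matrix's individual order.

    Alignment is by id; an id set mismatch is an error, never a silent reorder
    or intersection.
    """
    if set(gm.individuals) != set(pt.individuals):
        missing = sorted(set(gm.individuals) - set(pt.individuals))[:5]
        extra = sorted(set(pt.individuals) - set(gm.individuals))[:5]
        raise ValueError(
            f"genotype/phenotype id mismatch (missing phenotypes for {missing}, "
            f"unmatched phenotypes {extra})"
        )
    order = {ind: k for k, ind in enumerate(pt.individuals)}
    idx = np.array([order[ind] for ind in gm.individuals])
    return PhenotypeTable(
        individuals=list(gm.individuals),
        y=pt.y[idx],
        X=pt.X[idx],
        covariate_names=list(pt.covariate_names),
    )


# ---------------------------------------------------------------------------
# marker maps


def read_map(path) -> MarkerMap:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    required = {"id", "chromosome", "position_cM", "class"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: map file needs columns {sorted(required)}")
    return MarkerMap(
        ids=[str(s) for s in df["id"]],
        chromosome=df["chromosome"].to_numpy(),
        position_cM=df["position_cM"].to_numpy(),
        locus_class=df["class"].to_numpy(),
    )


def write_map(path, mp: MarkerMap, sep: str = "\t") -> None:
    mp.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# fit files


def write_fit(path, *, snp_ids, g, xi=None, sigma2_g=None, inclusion_freq=None,
              b=None, sigma2_e=None, meta=None, sep: str = "\t") -> None:
    """Write a fitted marker-effect model as a header block plus a SNP table.

    Header lines start with ``#`` and carry the fixed effects, the residual
    variance and any method metadata (iterations, convergence, prior settings).
    """
    meta = dict(meta or {})
    lines = []
    if b is not None:
        lines.append("#b\t" + "\t".join(repr(float(v)) for v in np.atleast_1d(b)))
    if sigma2_e is not None:
        lines.append(f"#sigma2_e\t{float(sigma2_e)!r}")
    for key, val in meta.items():
        lines.append(f"#{key}\t{val}")
    cols = {"snp_id": snp_ids, "g": np.asarray(g, dtype=float)}
    if xi is not None:
        cols["xi"] = np.asarray(xi, dtype=float)
    if sigma2_g is not None:
        cols["sigma2_g"] = np.asarray(sigma2_g, dtype=float)
    if inclusion_freq is not None:
        cols["inclusion_freq"] = np.asarray(inclusion_freq, dtype=float)
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        pd.DataFrame(cols).to_csv(fh, sep=sep, index=False)


def read_fit(path, sep: str = "\t"):
    """Read a fit file back as ``(table, b, sigma2_e, meta)``."""
    b = None
    sigma2_e = None
    meta = {}
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            key, _, rest = line[1:].rstrip("\n").partition("\t")
            if key == "b":
                b = np.array([float(v) for v in rest.split("\t")])
            elif key == "sigma2_e":
                sigma2_e = float(rest)
            else:
                meta[key] = rest
    table = pd.read_csv(path, sep=sep, skiprows=header_rows)
    return table, b, sigma2_e, meta
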