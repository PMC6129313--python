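"""Readers and writers for GWAS text formats.

Supported genotype dialects:

* PLINK text (``.ped`` + ``.map``) — hard calls as allele pairs.
* Oxford/SNPTEST ``.gen`` + ``.sample`` — per-genotype probability triples,
  collapsed on import to the expected dosage ``0*p(AA) + 1*p(AB) + 2*p(BB)``.
* BIMBAM mean-genotype — one row per SNP: id, effect allele, other allele,
  then per-sample dosages.
* Generic delimited dosage tables (simuPOP/ForSim/GenomePop2/GENOME exports)
  with configurable separator, orientation, header and ID column.

Everything is written with fixed-notation floats at a configurable precision
so that identical inputs give byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeData, Kinship

__all__ = [
    "FormatError",
    "read_genotypes",
    "write_genotypes",
    "GENOTYPE_FORMATS",
]

#: allele letters used when a dialect needs explicit alleles: dosage counts
#: copies of the effect allele EFFECT_ALLELE.
EFFECT_ALLELE = "A"
OTHER_ALLELE = "B"


class FormatError(ValueError):
    """A file does not parse under the named dialect."""

    def __init__(self, fmt: str, message: str, line: int | None = None):
        loc = f", line {line}" if line is not None else ""
        super().__init__(f"[{fmt}{loc}] {message}")
        self.format = fmt
        self.line = line


def _fmt(value: float, precision: int) -> str:
    return f"{value:.{precision}f}"


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i+1}" for i in range(n)]


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def write_plink_text(genotypes: GenotypeData, prefix: str) -> list[str]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; hard calls only."""
    d = genotypes.dosages
    if not np.array_equal(d, np.round(d)):
        raise FormatError(
            "plink_text", "PLINK .ped holds hard calls; dosages must be integers"
        )
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    pair = {0: f"{OTHER_ALLELE} {OTHER_ALLELE}",
            1: f"{EFFECT_ALLELE} {OTHER_ALLELE}",
            2: f"{EFFECT_ALLELE} {EFFECT_ALLELE}"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            calls = " ".join(pair[int(v)] for v in d[i])
            fh.write(f"{sid} {sid} 0 0 0 -9 {calls}\n")
    with open(map_path, "w") as fh:
        for j, snp in enumerate(genotypes.snp_ids):
            fh.write(
                f"{genotypes.chromosomes[j]} {snp} 0 {genotypes.positions[j]}\n"
            )
    return [ped_path, map_path]


def read_plink_text(
    prefix: str, effect_allele: str = EFFECT_ALLELE, missing: str = "error"
) -> GenotypeData:
    """Read ``<prefix>.ped`` + ``<prefix>.map`` into dosages of `effect_allele`.

    ``missing='error'`` (default) rejects '0 0' genotypes; ``missing='mean'``
    imputes them with the column mean dosage.
    """
    snp_ids, chroms, positions = [], [], []
    with open(f"{prefix}.map") as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if len(tok) < 4:
                raise FormatError(
                    "plink_text", f".map row has {len(tok)} fields, expected 4", ln
                )
            chroms.append(tok[0])
            snp_ids.append(tok[1])
            positions.append(int(tok[3]))
    s = len(snp_ids)
    sample_ids, rows = [], []
    with open(f"{prefix}.ped") as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if len(tok) != 6 + 2 * s:
                raise FormatError(
                    "plink_text",
                    f".ped row has {len(tok)} fields, expected {6 + 2 * s} "
                    f"(6 + 2 x {s} SNPs)",
                    ln,
                )
            sample_ids.append(tok[1])
            alleles = tok[6:]
            row = np.empty(s)
            for j in range(s):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    if missing == "error":
                        raise FormatError(
                            "plink_text", f"missing genotype at SNP {snp_ids[j]}", ln
                        )
                    row[j] = np.nan
                else:
                    row[j] = (a1 == effect_allele) + (a2 == effect_allele)
            rows.append(row)
    dosages = np.asarray(rows)
    if np.isnan(dosages).any():
        all_missing = np.all(np.isnan(dosages), axis=0)
        if all_missing.any():
            bad = snp_ids[int(np.where(all_missing)[0][0])]
            raise FormatError(
                "plink_text", f"SNP {bad} is missing in every sample; "
                "cannot mean-impute"
            )
        col_mean = np.nanmean(dosages, axis=0)
        nan_r, nan_c = np.where(np.isnan(dosages))
        dosages[nan_r, nan_c] = col_mean[nan_c]
    return GenotypeData(
        dosages=dosages,
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        allele_freqs=dosages.mean(axis=0) / 2.0,
    )


# ---------------------------------------------------------------------------
# Oxford gen/sample (SNPTEST, HAPGEN2, IMPUTE)
# ---------------------------------------------------------------------------

def write_oxford_gen(
    genotypes: GenotypeData, prefix: str, precision: int = 6
) -> list[str]:
    """Write ``<prefix>.gen`` and ``<prefix>.sample``.

    A dosage d is encoded as the probability triple (1, 0, 0)/(0, 1, 0)/
    (0, 0, 1) for hard calls and (1 - d/2, 0, d/2) otherwise, so the
    expected-dosage collapse on re-import reproduces d exactly.
    """
    gen_path, sample_path = f"{prefix}.gen", f"{prefix}.sample"
    d = genotypes.dosages
    with open(gen_path, "w") as fh:
        for j, snp in enumerate(genotypes.snp_ids):
            lead = (
                f"{genotypes.chromosomes[j]} {snp} {snp} "
                f"{genotypes.positions[j]} {EFFECT_ALLELE} {OTHER_ALLELE}"
            )
            probs = []
            for v in d[:, j]:
                if v == int(v):
                    trip = [0.0, 0.0, 0.0]
                    trip[int(v)] = 1.0
                else:
                    trip = [1.0 - v / 2.0, 0.0, v / 2.0]
                probs.append(" ".join(_fmt(p, precision) for p in trip))
            fh.write(lead + " " + " ".join(probs) + "\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for sid in genotypes.sample_ids:
            fh.write(f"{sid} {sid} 0\n")
    return [gen_path, sample_path]


def read_oxford_gen(prefix: str) -> GenotypeData:
    """Read ``.gen``/``.sample``; probability triples collapse to dosage."""
    sample_ids = []
    with open(f"{prefix}.sample") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise FormatError("oxford_gen", ".sample needs two header lines")
    for ln, line in enumerate(lines[2:], 3):
        tok = line.split()
        if not tok:
            continue
        sample_ids.append(tok[0])
    n = len(sample_ids)
    snp_ids, chroms, positions, cols = [], [], [], []
    with open(f"{prefix}.gen") as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if len(tok) != 6 + 3 * n:
                raise FormatError(
                    "oxford_gen",
                    f".gen row has {len(tok)} fields, expected {6 + 3 * n} "
                    f"(6 + 3 x {n} samples in .sample)",
                    ln,
                )
            chroms.append(tok[0])
            snp_ids.append(tok[1])
            positions.append(int(tok[3]))
            trips = np.asarray(tok[6:], dtype=float).reshape(n, 3)
            cols.append(trips @ np.array([0.0, 1.0, 2.0]))
    dosages = np.column_stack(cols) if cols else np.empty((n, 0))
    return GenotypeData(
        dosages=dosages,
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        allele_freqs=dosages.mean(axis=0) / 2.0,
    )


# ---------------------------------------------------------------------------
# BIMBAM mean genotype
# ---------------------------------------------------------------------------

def write_bimbam_mean(
    genotypes: GenotypeData, path: str, precision: int = 6
) -> list[str]:
    """One row per SNP: id, effect allele, other allele, per-sample dosages."""
    with open(path, "w") as fh:
        for j, snp in enumerate(genotypes.snp_ids):
            vals = ", ".join(
                _fmt(v, precision) for v in genotypes.dosages[:, j]
            )
            fh.write(f"{snp}, {EFFECT_ALLELE}, {OTHER_ALLELE}, {vals}\n")
    return [path]


def read_bimbam_mean(path: str, sep: str = ",") -> GenotypeData:
    snp_ids, cols = [], []
    n = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = [t.strip() for t in line.strip().split(sep)]
            if len(tok) < 4:
                raise FormatError(
                    "bimbam_mean",
                    f"row has {len(tok)} fields, expected id, 2 alleles and dosages",
                    ln,
                )
            if n is None:
                n = len(tok) - 3
            elif len(tok) - 3 != n:
                raise FormatError(
                    "bimbam_mean",
                    f"row has {len(tok) - 3} dosages, expected {n}",
                    ln,
                )
            snp_ids.append(tok[0])
            try:
                cols.append(np.asarray(tok[3:], dtype=float))
            except ValueError as exc:
                raise FormatError("bimbam_mean", f"non-numeric dosage: {exc}", ln)
    dosages = np.column_stack(cols)
    s = len(snp_ids)
    return GenotypeData(
        dosages=dosages,
        sample_ids=_default_ids("id", n),
        snp_ids=snp_ids,
        chromosomes=["0"] * s,
        positions=list(range(1, s + 1)),
        allele_freqs=dosages.mean(axis=0) / 2.0,
    )


# ---------------------------------------------------------------------------
# Generic delimited dosage tables
# ---------------------------------------------------------------------------

def write_delimited(
    genotypes: GenotypeData,
    path: str,
    sep: str = "\t",
    snps_in_rows: bool = False,
    header: bool = True,
    ids: bool = True,
    precision: int = 6,
) -> list[str]:
    df = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=genotypes.snp_ids,
    )
    if snps_in_rows:
        df = df.T
        df.index.name = "snp_id"
    df.to_csv(
        path,
        sep=sep,
        header=header,
        index=ids,
        float_format=f"%.{precision}f",
    )
    return [path]


def read_delimited(
    path: str,
    sep: str = "\t",
    snps_in_rows: bool = False,
    header: bool = True,
    ids: bool = True,
) -> GenotypeData:
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if header else None,
            index_col=0 if ids else None,
        )
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError("delimited", f"cannot parse table: {exc}")
    if snps_in_rows:
        df = df.T
    dosages = df.to_numpy(dtype=float)
    n, s = dosages.shape
    # after orientation normalization the row labels are sample IDs and the
    # column labels SNP IDs, but each is only meaningful if the file actually
    # carried it (header row / ID column, relative to the on-disk orientation)
    have_sample_ids = header if snps_in_rows else ids
    have_snp_ids = ids if snps_in_rows else header
    sample_ids = (
        [str(i) for i in df.index] if have_sample_ids else _default_ids("id", n)
    )
    snp_ids = (
        [str(c) for c in df.columns] if have_snp_ids else _default_ids("snp", s)
    )
    return GenotypeData(
        dosages=dosages,
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chromosomes=["0"] * s,
        positions=list(range(1, s + 1)),
        allele_freqs=dosages.mean(axis=0) / 2.0,
    )


# ---------------------------------------------------------------------------
# dispatchers
# ---------------------------------------------------------------------------

GENOTYPE_FORMATS = ("plink_text", "oxford_gen", "bimbam_mean", "delimited")


def read_genotypes(path: str, format: str, **options) -> GenotypeData:
    """Read a genotype panel; orientation is normalized to samples x SNPs.

    ``path`` is the file path for single-file dialects and the shared prefix
    (without extension) for ``plink_text`` and ``oxford_gen``.
    """
    if format == "plink_text":
        return read_plink_text(path, **options)
    if format == "oxford_gen":
        return read_oxford_gen(path, **options)
    if format == "bimbam_mean":
        return read_bimbam_mean(path, **options)
    if format == "delimited":
        return read_delimited(path, **options)
    raise ValueError(f"unknown genotype format {format!r}; use one of {GENOTYPE_FORMATS}")


def write_genotypes(
    genotypes: GenotypeData, path: str, format: str, **options
) -> list[str]:
    """Write a genotype panel; returns the list of files produced."""
    if format == "plink_text":
        return write_plink_text(genotypes, path, **options)
    if format == "oxford_gen":
        return write_oxford_gen(genotypes, path, **options)
    if format == "bimbam_mean":
        return write_bimbam_mean(genotypes, path, **options)
    if format == "delimited":
        return write_delimited(genotypes, path, **options)
    raise ValueError(f"unknown genotype format {format!r}; use one of {GENOTYPE_FORMATS}")


# ---------------------------------------------------------------------------
# phenotype / covariate / kinship writers and matrix helpers
# ---------------------------------------------------------------------------

def write_gemma_phenotype(Y: np.ndarray, path: str, precision: int = 6) -> str:
    """GEMMA -p convention: N rows, P whitespace-separated columns, no header."""
    with open(path, "w") as fh:
        for row in np.atleast_2d(Y):
            fh.write(" ".join(_fmt(v, precision) for v in row) + "\n")
    return path


def write_gemma_kinship(kinship: Kinship, path: str, precision: int = 6) -> str:
    """GEMMA -k convention: plain N x N whitespace matrix, no header."""
    return write_gemma_phenotype(kinship.matrix, path, precision)


def write_square_matrix(
    matrix: np.ndarray, path: str, sep: str = "\t",
    ids: list[str] | None = None, precision: int = 6,
) -> str:
    """Delimited square matrix, optional ID header row + column."""
    df = pd.DataFrame(matrix, index=ids, columns=ids)
    df.to_csv(
        path, sep=sep, header=ids is not None, index=ids is not None,
        float_format=f"%.{precision}f",
    )
    return path


def read_square_matrix(
    path: str, sep: str = "\t", ids: bool = False
) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited square matrix written by :func:`write_square_matrix`."""
    if ids:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
        labels = [str(i) for i in df.index]
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        labels = None
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(
            "square_matrix", f"matrix is {mat.shape[0]} x {mat.shape[1]}, not square"
        )
    return mat, labels


def write_csv_matrix(
    values: np.ndarray,
    path: str,
    sample_ids: list[str],
    column_ids: list[str],
    precision: int = 6,
) -> str:
    """CSV with a header row and sample-ID first column."""
    df = pd.DataFrame(
        values, index=pd.Index(sample_ids, name="sample_id"), columns=column_ids
    )
    df.to_csv(path, float_format=f"%.{precision}f")
    return path


def read_csv_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_snptest_sample(
    path: str,
    sample_ids: list[str],
    phenotypes: np.ndarray,
    trait_ids: list[str],
    covariates: np.ndarray | None = None,
    covariate_ids: list[str] | None = None,
    covariate_types: list[str] | None = None,
    precision: int = 6,
) -> str:
    """SNPTEST .sample file with phenotypes typed 'P' and covariates 'C'/'D'.

    The second header line gives per-column types: 0 for identifiers and
    missingness, then the covariate codes ('C' continuous, 'D' discrete),
    then 'P' for each quantitative phenotype.
    """
    if covariates is None:
        covariates = np.empty((len(sample_ids), 0))
        covariate_ids, covariate_types = [], []
    if covariate_types is None:
        covariate_types = ["C"] * covariates.shape[1]
    if covariate_ids is None:
        covariate_ids = _default_ids("cov", covariates.shape[1])
    header = ["ID_1", "ID_2", "missing", *covariate_ids, *trait_ids]
    types = ["0", "0", "0", *covariate_types, *["P"] * len(trait_ids)]
    with open(path, "w") as fh:
        fh.write(" ".join(header) + "\n")
        fh.write(" ".join(types) + "\n")
        for i, sid in enumerate(sample_ids):
            cov = [
                _fmt(v, precision) if t == "C" else str(int(v))
                for v, t in zip(covariates[i], covariate_types)
            ]
            phe = [_fmt(v, precision) for v in np.atleast_2d(phenotypes)[i]]
            fh.write(" ".join([sid, sid, "0", *cov, *phe]) + "\n")
    return path


def write_plink_phenotype(
    path: str,
    sample_ids: list[str],
    phenotypes: np.ndarray,
    trait_ids: list[str],
    precision: int = 6,
) -> str:
    """PLINK alternate-phenotype file: FID IID then one column per trait."""
    with open(path, "w") as fh:
        fh.write("FID IID " + " ".join(trait_ids) + "\n")
        for i, sid in enumerate(sample_ids):
            vals = " ".join(_fmt(v, precision) for v in phenotypes[i])
            fh.write(f"{sid} {sid} {vals}\n")
    return path
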