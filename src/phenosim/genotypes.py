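"""Biallelic genotype simulation, import and kinship (GRM) estimation.

Genotypes are held as an N x S dosage matrix: for each sample (row) and SNP
(column) the count of the designated effect allele, 0/1/2 for hard calls or a
continuous value in [0, 2] for imputed imports.  The kinship matrix is the
sample-covariance estimate ``K = X X^T / m`` with ``m`` the mean diagonal of
``X X^T``, so that ``mean(diag(K)) == 1`` by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeData",
    "Kinship",
    "simulate_genotypes",
    "estimate_kinship",
    "sample_causal_snps",
    "round_half_away",
]

logger = logging.getLogger(__name__)


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def round_half_away(x: float) -> int:
    """Round with halves away from zero (so 0.5 -> 1, -0.5 -> -1).

    Used for every count derived from a fraction (theta * S, gamma * K) so
    that subset sizes are reproducible across platforms; Python's built-in
    round() is banker's rounding and would map 0.5 -> 0.
    """
    return int(math.floor(abs(x) + 0.5) * math.copysign(1.0, x))


@dataclass
class GenotypeData:
    """An N x S panel of allele dosages with sample/SNP annotation."""

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    chromosomes: list[str]
    positions: list[int]
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        n, s = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n} dosage rows"
            )
        for name, seq in (
            ("snp_ids", self.snp_ids),
            ("chromosomes", self.chromosomes),
            ("positions", self.positions),
        ):
            if len(seq) != s:
                raise ValueError(f"{len(seq)} {name} for {s} dosage columns")
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if self.allele_freqs.shape != (s,):
            raise ValueError("allele_freqs must have one entry per SNP")
        if self.dosages.size and (
            self.dosages.min() < 0 or self.dosages.max() > 2
        ):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def empirical_freqs(self) -> np.ndarray:
        """Per-SNP effect-allele frequency estimated as column mean / 2."""
        return self.dosages.mean(axis=0) / 2.0

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeData":
        idx = list(indices)
        return GenotypeData(
            dosages=self.dosages[:, idx],
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chromosomes=[self.chromosomes[i] for i in idx],
            positions=[self.positions[i] for i in idx],
            allele_freqs=self.allele_freqs[idx],
        )


@dataclass
class Kinship:
    """N x N genetic relationship matrix normalized to mean diagonal 1."""

    matrix: np.ndarray
    sample_ids: list[str]
    normalizer_m: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match matrix dimension")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric (tol 1e-10)")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    allele_freqs=(0.05, 0.5),
    seed=None,
) -> GenotypeData:
    """Simulate unlinked biallelic SNPs.

    Each SNP column j is drawn iid across samples from Binomial(2, f_j):
    two allele draws per diploid sample at the requested frequency.  Columns
    are mutually independent — there is deliberately no linkage
    disequilibrium; LD-structured panels come from importing the output of an
    external genotype simulator instead.

    Parameters
    ----------
    allele_freqs
        Either a sequence of ``n_snps`` frequencies, or a (low, high) pair
        from which per-SNP frequencies are drawn uniformly.
    seed
        Int seed or :class:`numpy.random.Generator`.
    """
    if n_samples <= 0 or n_snps <= 0:
        raise ValueError("n_samples and n_snps must be positive")
    rng = _as_rng(seed)
    freqs = np.asarray(allele_freqs, dtype=float)
    if freqs.shape == (2,) and n_snps != 2:
        freqs = rng.uniform(freqs[0], freqs[1], size=n_snps)
    elif freqs.ndim == 0:
        freqs = np.full(n_snps, float(freqs))
    if freqs.shape != (n_snps,):
        raise ValueError(
            "allele_freqs must be a (low, high) range or one value per SNP"
        )
    if freqs.min() < 0 or freqs.max() > 1:
        raise ValueError("allele frequencies must lie in [0, 1]")
    dosages = rng.binomial(2, freqs, size=(n_samples, n_snps)).astype(float)
    return GenotypeData(
        dosages=dosages,
        sample_ids=[f"id_{i+1}" for i in range(n_samples)],
        snp_ids=[f"snp_{j+1}" for j in range(n_snps)],
        chromosomes=["1"] * n_snps,
        positions=list(range(1, n_snps + 1)),
        allele_freqs=freqs,
    )


def estimate_kinship(genotypes: GenotypeData, standardize: bool = True) -> Kinship:
    """Estimate the GRM as ``K = X X^T / m``, ``m = mean(diag(X X^T))``.

    With ``standardize`` (default) columns are centered and scaled to unit
    variance first, the usual GRM construction; zero-variance SNPs are
    dropped with a logged warning.  Raw dosage mode keeps X as-is.  The 1/m
    normalization applies in both modes, so the mean diagonal is always 1.
    """
    if genotypes.n_samples < 2:
        raise ValueError("kinship estimation needs at least 2 samples")
    X = genotypes.dosages
    if standardize:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "dropping %d zero-variance SNP(s) before standardized kinship",
                n_dropped,
            )
        X = X[:, keep]
        if X.shape[1] == 0:
            raise ValueError("no variable SNPs left for standardized kinship")
        X = (X - X.mean(axis=0)) / sd[keep]
    XXt = X @ X.T
    m = float(np.mean(np.diag(XXt)))
    if m == 0.0:
        raise ValueError(
            "cannot normalize kinship: X X^T has zero mean diagonal "
            "(all-constant genotype matrix)"
        )
    K = XXt / m
    K = (K + K.T) / 2.0  # enforce exact symmetry against float noise
    return Kinship(matrix=K, sample_ids=list(genotypes.sample_ids), normalizer_m=m)


def sample_causal_snps(
    genotypes: GenotypeData,
    n_causal: int,
    theta: float,
    seed=None,
) -> tuple[GenotypeData, GenotypeData]:
    """Draw causal SNPs without replacement and split them shared/independent.

    A fraction ``theta`` of the causal set carries effects shared across all
    traits; the remainder acts independently on a trait subset.  Returns the
    (shared, independent) genotype column subsets; either may be empty
    (zero-column panel) at the theta boundaries.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if n_causal > genotypes.n_snps:
        raise ValueError(
            f"requested {n_causal} causal SNPs from a panel of {genotypes.n_snps}"
        )
    if n_causal < 0:
        raise ValueError("n_causal must be non-negative")
    rng = _as_rng(seed)
    chosen = rng.choice(genotypes.n_snps, size=n_causal, replace=False)
    n_shared = round_half_away(theta * n_causal)
    shared_idx = np.sort(chosen[:n_shared])
    ind_idx = np.sort(chosen[n_shared:])
    return genotypes.subset_snps(shared_idx), genotypes.subset_snps(ind_idx)
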