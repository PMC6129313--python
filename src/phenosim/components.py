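"""The five phenotype components and their shared/independent designs.

A phenotype for N samples and P traits is assembled from additive N x P
terms: genetic variant effects X B, infinitesimal (polygenic) genetic effects
U, non-genetic covariate effects W A, correlated non-genetic effects T, and
observational noise Psi.  Variant, covariate, infinitesimal and noise terms
can each be split into a *shared* part acting identically (perfectly
correlated) across all traits — the rank-one constructions below — and an
*independent* part acting on traits separately, which is how pleiotropy and
trait-specific architecture are dialled in.

The infinitesimal effect is a matrix-variate normal draw with separable
covariance: vec(U) ~ N(0, C (x) K) for kinship K and trait covariance C,
realized as U = B Z A^T with K = B B^T, C = A A^T and Z iid standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .genotypes import GenotypeData, Kinship, round_half_away

__all__ = [
    "EffectSizeMatrix",
    "CovariateSet",
    "TraitCovariance",
    "PhenotypeComponent",
    "make_shared_effect_sizes",
    "make_independent_effect_sizes",
    "genetic_variant_component",
    "simulate_covariates",
    "covariate_component",
    "kinship_factor",
    "matrix_normal_sample",
    "infinitesimal_component",
    "build_trait_covariance",
    "validate_trait_covariance",
    "correlated_noise_component",
    "observational_noise_component",
]

logger = logging.getLogger(__name__)

ROLES = (
    "genetic_variant",
    "infinitesimal",
    "covariate",
    "correlated_noise",
    "observational_noise",
)
PARTS = ("shared", "independent", "whole")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class EffectSizeMatrix:
    """(n_predictors x P) effect sizes with their generating law and design."""

    values: np.ndarray
    law: str
    law_params: tuple
    design: str
    affected_traits: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))


@dataclass
class CovariateSet:
    """N x K covariate matrix with per-column specs and gamma partition."""

    values: np.ndarray
    specs: list[dict]
    gamma: float
    shared_cols: list[int]
    independent_cols: list[int]

    @property
    def shared_values(self) -> np.ndarray:
        return self.values[:, self.shared_cols]

    @property
    def independent_values(self) -> np.ndarray:
        return self.values[:, self.independent_cols]


@dataclass
class TraitCovariance:
    """P x P trait covariance C for the correlated non-genetic effect."""

    matrix: np.ndarray
    origin: str = "user_supplied"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def n_traits(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PhenotypeComponent:
    """One N x P additive phenotype term, tagged with role and sub-part."""

    values: np.ndarray
    role: str
    part: str = "whole"
    target_variance: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.part not in PARTS:
            raise ValueError(f"unknown part {self.part!r}; expected one of {PARTS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("component values must be finite")

    @property
    def label(self) -> str:
        return f"{self.role}:{self.part}"


# ---------------------------------------------------------------------------
# effect-size matrices
# ---------------------------------------------------------------------------

def _uniform_product_vectors(n: int, p: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Generator vectors whose entrywise products are exactly Uniform(0, 1).

    Draw g ~ Gamma(1/2, 1) per entry of each vector and set the entry to
    exp(-g).  The negative log of any product b_s[i] * b_p[j] is then the sum
    of two independent Gamma(1/2, 1) variables, i.e. Exp(1), and
    exp(-Exp(1)) is Uniform(0, 1): a rank-one construction with exactly
    uniform entries.
    """
    b_s = np.exp(-rng.gamma(0.5, 1.0, size=n))
    b_p = np.exp(-rng.gamma(0.5, 1.0, size=p))
    return b_s, b_p


def make_shared_effect_sizes(
    n_predictors: int,
    P: int,
    law: str = "normal",
    law_params: tuple = (0.0, 1.0),
    seed=None,
) -> EffectSizeMatrix:
    """Shared effect sizes: the outer product of a predictor and a trait vector.

    Because every column is a scalar multiple of ``b_s`` (plus, for the
    uniform law, a constant offset), all trait columns are perfectly
    correlated — one predictor moves every affected trait proportionally.

    normal law: ``b_s ~ N(mu_bs, sd_bs^2)``, ``b_p ~ N(0, 1)``,
    values ``= b_s b_p^T``.  uniform law: the entrywise product of two
    transformed-exponential generator vectors is exactly Uniform(0, 1),
    affine-mapped onto ``[low, high]``.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if n_predictors < 0:
        raise ValueError("n_predictors must be >= 0")
    rng = _as_rng(seed)
    if law == "normal":
        mu, sd = law_params
        if sd <= 0:
            raise ValueError("normal law needs sd > 0")
        b_s = rng.normal(mu, sd, size=n_predictors)
        b_p = rng.normal(0.0, 1.0, size=P)
        values = np.outer(b_s, b_p)
    elif law == "uniform":
        low, high = law_params
        if not low < high:
            raise ValueError("uniform law needs low < high")
        b_s, b_p = _uniform_product_vectors(n_predictors, P, rng)
        values = low + (high - low) * np.outer(b_s, b_p)
    else:
        raise ValueError(f"unknown effect-size law {law!r}")
    return EffectSizeMatrix(
        values=values.reshape(n_predictors, P),
        law=law,
        law_params=tuple(law_params),
        design="shared",
    )


def make_independent_effect_sizes(
    n_predictors: int,
    P: int,
    P_ind: int,
    law: str = "normal",
    law_params: tuple = (0.0, 1.0),
    seed=None,
    per_row: bool = False,
) -> EffectSizeMatrix:
    """Independent effect sizes restricted to ``P_ind`` randomly chosen traits.

    The matrix is filled iid from the chosen law, then the ``P - P_ind``
    unaffected traits have their columns zeroed.  By default a single trait
    subset applies to all predictors; ``per_row=True`` redraws the subset per
    predictor row.
    """
    if not 1 <= P_ind <= P:
        raise ValueError(f"P_ind must lie in [1, {P}], got {P_ind}")
    if n_predictors < 0:
        raise ValueError("n_predictors must be >= 0")
    rng = _as_rng(seed)
    if law == "normal":
        mu, sd = law_params
        if sd <= 0:
            raise ValueError("normal law needs sd > 0")
        values = rng.normal(mu, sd, size=(n_predictors, P))
    elif law == "uniform":
        low, high = law_params
        if not low < high:
            raise ValueError("uniform law needs low < high")
        values = rng.uniform(low, high, size=(n_predictors, P))
    else:
        raise ValueError(f"unknown effect-size law {law!r}")
    if per_row:
        affected = np.zeros((n_predictors, P), dtype=bool)
        for i in range(n_predictors):
            affected[i, rng.choice(P, size=P_ind, replace=False)] = True
        values = np.where(affected, values, 0.0)
        affected_traits = np.where(affected.any(axis=0))[0]
    else:
        affected_traits = np.sort(rng.choice(P, size=P_ind, replace=False))
        mask = np.zeros(P, dtype=bool)
        mask[affected_traits] = True
        values = np.where(mask, values, 0.0)
    return EffectSizeMatrix(
        values=values.reshape(n_predictors, P),
        law=law,
        law_params=tuple(law_params),
        design="independent",
        affected_traits=affected_traits,
    )


# ---------------------------------------------------------------------------
# genetic variant effects
# ---------------------------------------------------------------------------

def genetic_variant_component(
    shared_snps: GenotypeData,
    ind_snps: GenotypeData,
    B_shared: EffectSizeMatrix,
    B_ind: EffectSizeMatrix,
) -> tuple[PhenotypeComponent, PhenotypeComponent]:
    """Genetic variant effects: ``X_shared B_shared`` and ``X_ind B_ind``.

    Zero-column SNP subsets yield explicit N x P zero matrices, so the
    assembly stage sees a uniform component list at the theta boundaries.
    """
    if shared_snps.n_snps != B_shared.values.shape[0]:
        raise ValueError(
            f"{shared_snps.n_snps} shared SNPs vs "
            f"{B_shared.values.shape[0]} shared effect rows"
        )
    if ind_snps.n_snps != B_ind.values.shape[0]:
        raise ValueError(
            f"{ind_snps.n_snps} independent SNPs vs "
            f"{B_ind.values.shape[0]} independent effect rows"
        )
    if B_shared.values.shape[1] != B_ind.values.shape[1]:
        raise ValueError("shared and independent effect matrices disagree on P")
    P = B_shared.values.shape[1]
    n = shared_snps.n_samples
    shared = shared_snps.dosages @ B_shared.values if shared_snps.n_snps else np.zeros((n, P))
    ind = ind_snps.dosages @ B_ind.values if ind_snps.n_snps else np.zeros((n, P))
    return (
        PhenotypeComponent(shared, "genetic_variant", "shared",
                           extras={"effect_sizes": B_shared,
                                   "snp_ids": list(shared_snps.snp_ids)}),
        PhenotypeComponent(ind, "genetic_variant", "independent",
                           extras={"effect_sizes": B_ind,
                                   "snp_ids": list(ind_snps.snp_ids)}),
    )


# ---------------------------------------------------------------------------
# non-genetic covariates
# ---------------------------------------------------------------------------

def _draw_covariate(spec: dict, n: int, rng) -> np.ndarray:
    dist = spec.get("dist")
    if dist == "normal":
        return rng.normal(spec.get("mean", 0.0), spec["sd"], size=n)
    if dist == "uniform":
        low, high = spec["low"], spec["high"]
        if not low < high:
            raise ValueError(f"uniform covariate needs low < high, got {spec}")
        return rng.uniform(low, high, size=n)
    if dist == "binomial":
        p = spec["p"]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"binomial covariate needs p in [0, 1], got {p}")
        return rng.binomial(1, p, size=n).astype(float)
    if dist == "categorical":
        probs = np.asarray(spec["probs"], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"categorical probabilities sum to {probs.sum()}, expected 1"
            )
        # levels enter the effect product as integer codes 0..L-1
        return rng.choice(len(probs), size=n, p=probs).astype(float)
    raise ValueError(f"unknown covariate distribution {dist!r}")


def simulate_covariates(
    n_samples: int, specs: list[dict], gamma: float, seed=None
) -> CovariateSet:
    """Draw the N x K covariate matrix column-by-column from its specs.

    The first ``round(gamma * K)`` columns are designated shared (affecting
    all traits); the rest are independent.  Covariates mimic e.g. sex
    (binomial), age (normal/uniform) or batch/site (categorical).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = _as_rng(seed)
    cols = [_draw_covariate(spec, n_samples, rng) for spec in specs]
    values = np.column_stack(cols) if cols else np.empty((n_samples, 0))
    k = len(specs)
    n_shared = round_half_away(gamma * k)
    return CovariateSet(
        values=values,
        specs=list(specs),
        gamma=gamma,
        shared_cols=list(range(n_shared)),
        independent_cols=list(range(n_shared, k)),
    )


def covariate_component(
    covariates: CovariateSet,
    A_shared: EffectSizeMatrix,
    A_ind: EffectSizeMatrix,
) -> tuple[PhenotypeComponent, PhenotypeComponent]:
    """Covariate effects ``W_shared A_shared`` and ``W_ind A_ind``."""
    W_s, W_i = covariates.shared_values, covariates.independent_values
    if W_s.shape[1] != A_shared.values.shape[0]:
        raise ValueError(
            f"{W_s.shape[1]} shared covariates vs "
            f"{A_shared.values.shape[0]} shared effect rows"
        )
    if W_i.shape[1] != A_ind.values.shape[0]:
        raise ValueError(
            f"{W_i.shape[1]} independent covariates vs "
            f"{A_ind.values.shape[0]} independent effect rows"
        )
    if A_shared.values.shape[1] != A_ind.values.shape[1]:
        raise ValueError("shared and independent effect matrices disagree on P")
    P = A_shared.values.shape[1]
    n = covariates.values.shape[0]
    shared = W_s @ A_shared.values if W_s.shape[1] else np.zeros((n, P))
    ind = W_i @ A_ind.values if W_i.shape[1] else np.zeros((n, P))
    return (
        PhenotypeComponent(shared, "covariate", "shared",
                           extras={"effect_sizes": A_shared}),
        PhenotypeComponent(ind, "covariate", "independent",
                           extras={"effect_sizes": A_ind}),
    )


# ---------------------------------------------------------------------------
# infinitesimal genetic effects
# ---------------------------------------------------------------------------

def kinship_factor(kinship: Kinship, tolerance: float = 1e-8) -> np.ndarray:
    """Factor ``B`` with ``K = B B^T`` via symmetric eigendecomposition.

    Eigenvalues below ``max(eig) * 1e-12`` are treated as numerically zero
    and dropped, so rank-deficient kinship matrices are supported (the
    returned factor has M = numerical rank columns).  An eigenvalue below
    ``-tolerance`` means K is not PSD and raises.
    """
    eigvals, eigvecs = np.linalg.eigh(kinship.matrix)
    if eigvals[0] < -tolerance:
        raise ValueError(
            f"kinship matrix is not positive semi-definite: "
            f"eigenvalue {eigvals[0]:.3e} < -{tolerance:.1e}"
        )
    cutoff = eigvals[-1] * 1e-12
    keep = eigvals > max(cutoff, 0.0)
    return eigvecs[:, keep] * np.sqrt(eigvals[keep])


def matrix_normal_sample(
    row_factor: np.ndarray,
    trait_loadings: np.ndarray,
    seed=None,
    size: int | None = None,
) -> np.ndarray:
    """Draw ``U = B Z A^T`` with ``Z`` iid standard normal.

    For B with ``K = B B^T`` and A with ``C = A A^T`` this realizes
    ``vec(U) ~ N(0, C (x) K)`` (columns stacked).  With ``size`` given, an
    array of ``size`` independent replicates is returned — used by the
    Monte-Carlo check of the Kronecker covariance.
    """
    rng = _as_rng(seed)
    m = row_factor.shape[1]
    ell = trait_loadings.shape[1]
    if size is None:
        Z = rng.standard_normal((m, ell))
        return row_factor @ Z @ trait_loadings.T
    Z = rng.standard_normal((size, m, ell))
    return np.einsum("nm,rml,pl->rnp", row_factor, Z, trait_loadings)


def infinitesimal_component(
    kin_factor: np.ndarray,
    P: int,
    design: str,
    seed=None,
) -> PhenotypeComponent:
    """Polygenic background ``U = B Z A^T`` with kinship-structured rows.

    shared design: A has one normally distributed column and zeros elsewhere
    (column rank one), so all traits are driven by the same latent sample
    vector and are perfectly correlated.  independent design: A is diagonal
    with normal entries, so traits are conditionally independent given the
    kinship structure.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    rng = _as_rng(seed)
    A = np.zeros((P, P))
    if design == "shared":
        A[:, 0] = rng.normal(0.0, 1.0, size=P)
    elif design == "independent":
        np.fill_diagonal(A, rng.normal(0.0, 1.0, size=P))
    else:
        raise ValueError(f"design must be 'shared' or 'independent', got {design!r}")
    U = matrix_normal_sample(kin_factor, A, rng)
    return PhenotypeComponent(
        U, "infinitesimal", design, extras={"trait_loadings": A}
    )


# ---------------------------------------------------------------------------
# correlated non-genetic effects
# ---------------------------------------------------------------------------

def build_trait_covariance(P: int, r: float) -> TraitCovariance:
    """Exponential-decay trait correlation: entry (i, j) = r^|i-j|.

    Adjacent traits correlate at r, traits two apart at r^2, and so on — a
    simple stand-in for spatially or serially ordered phenotypes (e.g.
    neighbouring image-derived traits).  These Kac–Murdock–Szego matrices
    are positive definite for |r| < 1.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return TraitCovariance(
        matrix=toeplitz(np.power(float(r), np.arange(P))),
        origin="exponential_decay",
    )


def validate_trait_covariance(matrix: np.ndarray) -> TraitCovariance:
    """Validate a user-supplied C: symmetric (tol 1e-8), PSD within tolerance.

    Tiny negative eigenvalues (above ``-1e-8 * max(eig)``) are clipped to
    zero with a logged warning; anything lower raises.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("trait covariance must be a square matrix")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("trait covariance must be symmetric (tol 1e-8)")
    eigvals, eigvecs = np.linalg.eigh((matrix + matrix.T) / 2.0)
    floor = -1e-8 * max(eigvals[-1], 0.0)
    if eigvals[0] < floor:
        raise ValueError(
            f"trait covariance is not PSD: eigenvalue {eigvals[0]:.3e}"
        )
    if eigvals[0] < 0:
        logger.warning(
            "clipping %d small negative eigenvalue(s) of trait covariance",
            int((eigvals < 0).sum()),
        )
        matrix = (eigvecs * np.clip(eigvals, 0.0, None)) @ eigvecs.T
    return TraitCovariance(matrix=matrix, origin="user_supplied")


def correlated_noise_component(
    n_samples: int, cov: TraitCovariance, seed=None
) -> PhenotypeComponent:
    """Correlated non-genetic effect: rows iid ``N(0, C)``."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = _as_rng(seed)
    eigvals, eigvecs = np.linalg.eigh(cov.matrix)
    if eigvals[0] < -1e-8 * max(abs(eigvals[-1]), 1.0):
        raise ValueError(
            f"trait covariance is not PSD: eigenvalue {eigvals[0]:.3e}"
        )
    keep = eigvals > 0
    L = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    T = rng.standard_normal((n_samples, int(keep.sum()))) @ L.T
    return PhenotypeComponent(
        T, "correlated_noise", "whole", extras={"trait_covariance": cov}
    )


# ---------------------------------------------------------------------------
# observational noise
# ---------------------------------------------------------------------------

def observational_noise_component(
    n_samples: int, P: int, design: str, seed=None
) -> PhenotypeComponent:
    """Observational noise ``Psi = B A`` with ``B`` an N x P iid normal matrix.

    shared design: A has one normally distributed row and zeros elsewhere
    (row rank one), giving perfect trait correlation; independent design:
    A is diagonal with normal entries, giving asymptotically uncorrelated
    traits.
    """
    if n_samples <= 0 or P < 1:
        raise ValueError("n_samples and P must be positive")
    rng = _as_rng(seed)
    B = rng.standard_normal((n_samples, P))
    A = np.zeros((P, P))
    if design == "shared":
        A[0, :] = rng.normal(0.0, 1.0, size=P)
    elif design == "independent":
        np.fill_diagonal(A, rng.normal(0.0, 1.0, size=P))
    else:
        raise ValueError(f"design must be 'shared' or 'independent', got {design!r}")
    return PhenotypeComponent(
        B @ A, "observational_noise", design, extras={"trait_loadings": A}
    )
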