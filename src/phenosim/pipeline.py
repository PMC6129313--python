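"""End-to-end simulation pipeline: genotypes → components → scaling →
phenotypes → output.

Randomness: the config seed feeds a single :class:`numpy.random.SeedSequence`
which is spawned into one child stream per simulation stage, in a fixed
order independent of which components are requested.  Two runs with the same
config and seed are therefore bitwise identical, and adding a component does
not perturb the draws of the others.
"""

from __future__ import annotations

import logging

import numpy as np

from . import formats as fmt
from .assembly import PhenotypeResult, VarianceBudget, assemble_phenotype
from .components import (
    build_trait_covariance,
    correlated_noise_component,
    covariate_component,
    genetic_variant_component,
    infinitesimal_component,
    kinship_factor,
    make_independent_effect_sizes,
    make_shared_effect_sizes,
    matrix_normal_sample,
    observational_noise_component,
    simulate_covariates,
    validate_trait_covariance,
)
from .config import SimulationConfig, validate_config
from .genotypes import (
    GenotypeData,
    Kinship,
    estimate_kinship,
    sample_causal_snps,
    simulate_genotypes,
)
from .output import OutputBundle, write_bundle, write_component_matrices

__all__ = ["run_simulation", "PipelineError"]

logger = logging.getLogger(__name__)

#: fixed spawn order of per-stage RNG streams (recorded in the manifest)
STREAMS = (
    "genotypes",
    "causal_snps",
    "variant_effects_shared",
    "variant_effects_independent",
    "covariates",
    "covariate_effects_shared",
    "covariate_effects_independent",
    "infinitesimal_shared",
    "infinitesimal_independent",
    "correlated_noise",
    "observational_noise_shared",
    "observational_noise_independent",
)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(STREAMS, children)}


def run_simulation(
    config: SimulationConfig | dict | str,
    seed: int | None = None,
    out_dir: str | None = None,
    formats: list[str] | None = None,
) -> tuple[PhenotypeResult, list[str]]:
    """Run the five-stage simulation described by ``config``.

    ``seed``, ``out_dir`` and ``formats`` override the corresponding config
    entries (the CLI's flag layer).  Returns the phenotype result and the
    list of files written (empty when no output directory is configured).
    """
    if not isinstance(config, SimulationConfig):
        config = validate_config(config)
    used_seed = config.seed if seed is None else seed
    rng = _streams(used_seed)
    n, p = config.n_samples, config.n_traits
    roles = config.roles
    law = config.effect_sizes["law"]
    law_params = tuple(config.effect_sizes["params"])

    # --- stage 1: genotypes -------------------------------------------------
    genotypes: GenotypeData | None = None
    need_genotypes = (
        "genetic_variant" in roles
        or ("infinitesimal" in roles and config.kinship["source"] == "estimate")
    )
    try:
        if need_genotypes:
            g = config.genotypes
            if g["source"] == "simulate":
                freqs = (
                    g["allele_freqs"]
                    if g.get("allele_freqs") is not None
                    else tuple(g["allele_freq_range"])
                )
                genotypes = simulate_genotypes(
                    n, g["n_snps"], allele_freqs=freqs, seed=rng["genotypes"]
                )
            else:
                genotypes = fmt.read_genotypes(
                    g["path"], g["format"], **g.get("options", {})
                )
                if genotypes.n_samples != n:
                    raise ValueError(
                        f"imported panel has {genotypes.n_samples} samples, "
                        f"config says {n}"
                    )
            logger.info(
                "genotypes: %d samples x %d SNPs (%s)",
                genotypes.n_samples, genotypes.n_snps, g["source"],
            )
    except Exception as exc:
        raise PipelineError("genotypes", exc) from exc

    sample_ids = genotypes.sample_ids if genotypes is not None else [
        f"id_{i+1}" for i in range(n)
    ]
    trait_ids = [f"trait_{j+1}" for j in range(p)]

    # --- stage 2: kinship ---------------------------------------------------
    kinship: Kinship | None = None
    try:
        if "infinitesimal" in roles:
            k = config.kinship
            if k["source"] == "estimate":
                kinship = estimate_kinship(genotypes, standardize=k["standardize"])
            else:
                matrix, labels = fmt.read_square_matrix(
                    k["path"], sep=k.get("sep", "\t"), ids=k.get("ids", False)
                )
                kinship = Kinship(
                    matrix=matrix, sample_ids=labels or sample_ids,
                )
            logger.info("kinship: %d x %d (%s)", kinship.n_samples,
                        kinship.n_samples, k["source"])
    except Exception as exc:
        raise PipelineError("kinship", exc) from exc

    # --- stage 3: components ------------------------------------------------
    components = []
    covariates = None
    try:
        if "genetic_variant" in roles:
            c = config.causal
            shared_snps, ind_snps = sample_causal_snps(
                genotypes, c["n_causal"], c["theta"], seed=rng["causal_snps"]
            )
            B_shared = make_shared_effect_sizes(
                shared_snps.n_snps, p, law, law_params,
                seed=rng["variant_effects_shared"],
            )
            B_ind = make_independent_effect_sizes(
                ind_snps.n_snps, p, c["p_independent"], law, law_params,
                seed=rng["variant_effects_independent"],
            )
            components.extend(
                genetic_variant_component(shared_snps, ind_snps, B_shared, B_ind)
            )
            logger.info(
                "genetic variant effects: %d shared + %d independent causal SNPs",
                shared_snps.n_snps, ind_snps.n_snps,
            )
        if "covariate" in roles:
            cv = config.covariates
            covariates = simulate_covariates(
                n, cv["specs"], cv["gamma"], seed=rng["covariates"]
            )
            A_shared = make_shared_effect_sizes(
                len(covariates.shared_cols), p, law, law_params,
                seed=rng["covariate_effects_shared"],
            )
            A_ind = make_independent_effect_sizes(
                len(covariates.independent_cols), p, config.causal["p_independent"],
                law, law_params, seed=rng["covariate_effects_independent"],
            )
            components.extend(covariate_component(covariates, A_shared, A_ind))
            logger.info(
                "covariates: %d shared + %d independent",
                len(covariates.shared_cols), len(covariates.independent_cols),
            )
        if "infinitesimal" in roles:
            factor = kinship_factor(kinship)
            components.append(infinitesimal_component(
                factor, p, "shared", seed=rng["infinitesimal_shared"]))
            components.append(infinitesimal_component(
                factor, p, "independent", seed=rng["infinitesimal_independent"]))
            logger.info("infinitesimal effects: kinship rank %d", factor.shape[1])
        if "correlated_noise" in roles:
            tc = config.trait_correlation
            if tc.get("path"):
                matrix, _ = fmt.read_square_matrix(
                    tc["path"], sep=tc.get("sep", "\t"), ids=tc.get("ids", False)
                )
                cov = validate_trait_covariance(matrix)
            else:
                cov = build_trait_covariance(p, tc["r"])
            components.append(
                correlated_noise_component(n, cov, seed=rng["correlated_noise"])
            )
        if "observational_noise" in roles:
            components.append(observational_noise_component(
                n, p, "shared", seed=rng["observational_noise_shared"]))
            components.append(observational_noise_component(
                n, p, "independent", seed=rng["observational_noise_independent"]))
    except Exception as exc:
        raise PipelineError("components", exc) from exc

    # --- stage 4: scaling and assembly ---------------------------------------
    try:
        budget = VarianceBudget.from_totals(config.budget_totals())
        result = assemble_phenotype(
            components, budget, sample_ids=sample_ids, trait_ids=trait_ids
        )
        for (role, part), a in sorted(result.scale_factors.items()):
            logger.info("scaled %s:%s by a=%.6g (target %.4f)",
                        role, part, a, budget.entries[(role, part)])
    except Exception as exc:
        raise PipelineError("assembly", exc) from exc

    # --- stage 5: output ------------------------------------------------------
    files: list[str] = []
    out = config.output
    directory = out_dir if out_dir is not None else out.get("directory")
    try:
        if directory:
            bundle = OutputBundle(
                directory=directory,
                formats=list(formats if formats is not None else out["formats"]),
                precision=out["precision"],
            )
            files = write_bundle(
                result, genotypes, covariates, kinship, bundle,
                manifest_extra={
                    "seed": used_seed,
                    "rng_streams": list(STREAMS),
                },
            )
            if out.get("write_components", True):
                files.extend(write_component_matrices(
                    result, directory, precision=out["precision"]
                ))
            logger.info("wrote %d files to %s", len(files), directory)
    except Exception as exc:
        raise PipelineError("output", exc) from exc

    return result, files
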