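"""The packaged case-study configuration at desk scale.

A three-trait simulation with ten causal SNPs whose effects are shared
across all traits, four non-genetic covariates (two binary, two normal), an
infinitesimal genetic effect on the kinship estimated from the simulated
panel, a correlated non-genetic effect with exponentially decaying trait
correlation, and observational noise.  Total genetic variance is 40%
(leaving 60% for the non-genetic terms) and every split component carries
80% of its variance in its shared part.  The split of the 40% between
variant and infinitesimal effects, the non-genetic split, the covariate
parameters and the trait correlation r are this package's own defaults (see
docs/methods.md); the headline 40/60/80 structure is what analyses built on
this configuration should rely on.

Dimensions default to N=200 samples and a 100-SNP panel so the full
pipeline runs in seconds.
"""

from __future__ import annotations

import copy

from .config import SimulationConfig, validate_config

CASE_STUDY_CONFIG: dict = {
    "n_samples": 200,
    "n_traits": 3,
    "seed": 0,
    "genotypes": {
        "source": "simulate",
        "n_snps": 100,
        "allele_freq_range": [0.05, 0.5],
    },
    "kinship": {"source": "estimate", "standardize": True},
    "causal": {"n_causal": 10, "theta": 1.0},  # all variant effects shared
    "effect_sizes": {"law": "normal", "params": [0.0, 1.0]},
    "covariates": {
        "gamma": 0.5,  # 2 of 4 covariates shared
        "specs": [
            {"dist": "binomial", "p": 0.5},
            {"dist": "normal", "mean": 0.0, "sd": 1.0},
            {"dist": "binomial", "p": 0.3},
            {"dist": "normal", "mean": 0.0, "sd": 1.0},
        ],
    },
    "trait_correlation": {"r": 0.7},
    "variance": {
        "genetic_variant": {"total": 0.20, "shared": 1.0},
        "infinitesimal": {"total": 0.20, "shared": 0.8},
        "covariate": {"total": 0.20, "shared": 0.8},
        "correlated_noise": {"total": 0.10},
        "observational_noise": {"total": 0.30, "shared": 0.8},
    },
    "output": {"directory": None, "formats": ["csv", "gemma"], "precision": 6},
}


def case_study_config(
    seed: int | None = None, n_samples: int | None = None, **overrides
) -> SimulationConfig:
    """Validated case-study configuration, optionally reseeded or resized."""
    cfg = copy.deepcopy(CASE_STUDY_CONFIG)
    if seed is not None:
        cfg["seed"] = int(seed)
    if n_samples is not None:
        cfg["n_samples"] = int(n_samples)
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return validate_config(cfg)
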