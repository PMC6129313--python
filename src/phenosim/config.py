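"""Simulation configuration: schema, defaults and validation.

A configuration is a nested mapping (usually a YAML file) describing the
full simulation: dimensions, genotype and kinship sources, the causal-SNP
split, covariate specs, effect-size laws, trait correlation, the variance
budget with shared fractions, the seed and output settings.  Validation
collects *every* violation before raising, so a bad file is fixed in one
round trip.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

from .genotypes import round_half_away

__all__ = ["SimulationConfig", "ConfigError", "validate_config", "DEFAULTS"]

#: roles whose budget can be split shared/independent; correlated noise is
#: always a single whole matrix.
SPLIT_ROLES = ("genetic_variant", "infinitesimal", "covariate", "observational_noise")
ALL_ROLES = SPLIT_ROLES + ("correlated_noise",)

DEFAULTS: dict[str, Any] = {
    "n_samples": 100,
    "n_traits": 3,
    "seed": 0,
    "genotypes": {
        "source": "simulate",          # simulate | import
        "n_snps": 100,
        "allele_freq_range": [0.05, 0.5],
        "allele_freqs": None,          # explicit per-SNP list overrides range
        "path": None,
        "format": None,
        "options": {},
    },
    "kinship": {
        "source": "estimate",          # estimate | import
        "standardize": True,
        "path": None,
        "sep": "\t",
        "ids": False,
    },
    "causal": {
        "n_causal": 10,
        "theta": 1.0,
        "p_independent": None,         # defaults to n_traits
    },
    "effect_sizes": {
        "law": "normal",
        "params": [0.0, 1.0],
    },
    "covariates": {
        "gamma": 1.0,
        "specs": [],
    },
    "trait_correlation": {
        "r": 0.8,
        "path": None,
        "sep": "\t",
        "ids": False,
    },
    "variance": {},
    "output": {
        "directory": None,
        "formats": ["csv"],
        "precision": 6,
        "write_components": True,
    },
}

KNOWN_FORMATS = ("csv", "gemma", "plink", "bimbam", "snptest")


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors)
        )


@dataclass
class SimulationConfig:
    """A validated, fully defaulted simulation configuration."""

    n_samples: int
    n_traits: int
    seed: int
    genotypes: dict
    kinship: dict
    causal: dict
    effect_sizes: dict
    covariates: dict
    trait_correlation: dict
    variance: dict
    output: dict
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def roles(self) -> list[str]:
        """Roles with a positive total variance share, i.e. components simulated."""
        return [r for r in ALL_ROLES if self.variance.get(r, {}).get("total", 0) > 0]

    def budget_totals(self) -> dict[str, tuple[float, float | None]]:
        """role -> (total share, shared fraction or None) for VarianceBudget."""
        out: dict[str, tuple[float, float | None]] = {}
        for role in self.roles:
            entry = self.variance[role]
            s = entry.get("shared") if role in SPLIT_ROLES else None
            out[role] = (float(entry["total"]), s)
        return out


def _merge_defaults(raw: dict) -> dict:
    cfg = copy.deepcopy(DEFAULTS)
    for key, value in raw.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _check_fraction(errors: list[str], value, key: str) -> None:
    if not isinstance(value, (int, float)) or not 0.0 <= value <= 1.0:
        errors.append(f"{key}: must be a fraction in [0, 1], got {value!r}")


def validate_config(raw) -> SimulationConfig:
    """Validate a raw config (dict, YAML text, or file path) into a
    :class:`SimulationConfig` with all defaults resolved.

    Raises :class:`ConfigError` carrying every violation found, each naming
    the offending key.  Validation is idempotent: re-validating a validated
    config's fields reproduces it.
    """
    if isinstance(raw, SimulationConfig):
        raw = {
            k: getattr(raw, k)
            for k in (
                "n_samples", "n_traits", "seed", "genotypes", "kinship",
                "causal", "effect_sizes", "covariates", "trait_correlation",
                "variance", "output",
            )
        }
    if isinstance(raw, str):
        raw = yaml.safe_load(raw)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])
    unknown = set(raw) - set(DEFAULTS)
    cfg = _merge_defaults(raw)
    errors: list[str] = [f"unknown configuration key {k!r}" for k in sorted(unknown)]

    if not isinstance(cfg["n_samples"], int) or cfg["n_samples"] <= 0:
        errors.append(f"n_samples: must be a positive integer, got {cfg['n_samples']!r}")
    if not isinstance(cfg["n_traits"], int) or cfg["n_traits"] <= 0:
        errors.append(f"n_traits: must be a positive integer, got {cfg['n_traits']!r}")
    if not isinstance(cfg["seed"], int):
        errors.append(f"seed: must be an integer, got {cfg['seed']!r}")

    geno = cfg["genotypes"]
    if geno["source"] not in ("simulate", "import"):
        errors.append(f"genotypes.source: must be 'simulate' or 'import', got {geno['source']!r}")
    elif geno["source"] == "import":
        if not geno.get("path"):
            errors.append("genotypes.path: required when genotypes.source is 'import'")
        if not geno.get("format"):
            errors.append("genotypes.format: required when genotypes.source is 'import'")
    else:
        if not isinstance(geno.get("n_snps"), int) or geno["n_snps"] <= 0:
            errors.append(f"genotypes.n_snps: must be a positive integer, got {geno.get('n_snps')!r}")

    kin = cfg["kinship"]
    if kin["source"] not in ("estimate", "import"):
        errors.append(f"kinship.source: must be 'estimate' or 'import', got {kin['source']!r}")
    elif kin["source"] == "import" and not kin.get("path"):
        errors.append("kinship.path: required when kinship.source is 'import'")

    causal = cfg["causal"]
    _check_fraction(errors, causal.get("theta"), "causal.theta")
    if not isinstance(causal.get("n_causal"), int) or causal["n_causal"] < 0:
        errors.append(f"causal.n_causal: must be a non-negative integer, got {causal.get('n_causal')!r}")
    if causal.get("p_independent") is None:
        causal["p_independent"] = cfg["n_traits"]
    p_ind = causal["p_independent"]
    if not isinstance(p_ind, int) or not 1 <= p_ind <= cfg["n_traits"]:
        errors.append(
            f"causal.p_independent: must be an integer in [1, {cfg['n_traits']}], got {p_ind!r}"
        )

    eff = cfg["effect_sizes"]
    if eff["law"] not in ("normal", "uniform"):
        errors.append(f"effect_sizes.law: must be 'normal' or 'uniform', got {eff['law']!r}")
    params = eff.get("params", [])
    if len(params) != 2:
        errors.append(f"effect_sizes.params: expected two values, got {params!r}")
    elif eff["law"] == "normal" and params[1] <= 0:
        errors.append(f"effect_sizes.params: normal law needs sd > 0, got {params[1]!r}")
    elif eff["law"] == "uniform" and not params[0] < params[1]:
        errors.append(f"effect_sizes.params: uniform law needs low < high, got {params!r}")

    cov = cfg["covariates"]
    _check_fraction(errors, cov.get("gamma"), "covariates.gamma")
    for i, spec in enumerate(cov.get("specs", [])):
        if not isinstance(spec, dict) or spec.get("dist") not in (
            "normal", "uniform", "binomial", "categorical",
        ):
            errors.append(
                f"covariates.specs[{i}]: dist must be normal, uniform, binomial "
                f"or categorical, got {spec!r}"
            )
        elif spec["dist"] == "categorical":
            probs = spec.get("probs", [])
            if abs(sum(probs) - 1.0) > 1e-8:
                errors.append(
                    f"covariates.specs[{i}]: categorical probs sum to {sum(probs)}, expected 1"
                )

    tc = cfg["trait_correlation"]
    if tc.get("path") is None and not (
        isinstance(tc.get("r"), (int, float)) and abs(tc["r"]) < 1
    ):
        errors.append(f"trait_correlation.r: must satisfy |r| < 1, got {tc.get('r')!r}")

    var = cfg["variance"]
    if not isinstance(var, dict) or not var:
        errors.append(
            "variance: at least one phenotype component must be requested"
        )
        var = {}
    total = 0.0
    for role, entry in var.items():
        if role not in ALL_ROLES:
            errors.append(f"variance.{role}: unknown component role")
            continue
        if isinstance(entry, (int, float)):
            entry = {"total": float(entry)}
            var[role] = entry
        x = entry.get("total")
        if not isinstance(x, (int, float)) or x < 0:
            errors.append(f"variance.{role}.total: must be a non-negative number, got {x!r}")
            continue
        total += x
        if role in SPLIT_ROLES:
            entry.setdefault("shared", 1.0 if role == "genetic_variant" else 0.5)
            _check_fraction(errors, entry["shared"], f"variance.{role}.shared")
    if var and abs(total - 1.0) > 1e-6:
        errors.append(f"variance budget: fractions must sum to 1, got {total}")

    # boundary consistency: an empty sub-part cannot carry positive budget
    gv = var.get("genetic_variant")
    if isinstance(gv, dict) and gv.get("total", 0) > 0 and not errors:
        n_shared_snps = round_half_away(causal["theta"] * causal["n_causal"])
        s = gv.get("shared", 1.0)
        if n_shared_snps == 0 and gv["total"] * s > 0:
            errors.append(
                "variance.genetic_variant.shared: positive shared budget but "
                "theta yields no shared causal SNPs"
            )
        if n_shared_snps == causal["n_causal"] and gv["total"] * (1 - s) > 0:
            errors.append(
                "variance.genetic_variant.shared: positive independent budget "
                "but theta selects all causal SNPs as shared"
            )
    cv = var.get("covariate")
    if isinstance(cv, dict) and cv.get("total", 0) > 0:
        k = len(cov.get("specs", []))
        if k == 0:
            errors.append(
                "covariates.specs: covariate component has positive budget but "
                "no covariates are specified"
            )
        else:
            n_shared_cov = round_half_away(cov["gamma"] * k)
            s = cv.get("shared", 0.5)
            if n_shared_cov == 0 and cv["total"] * s > 0:
                errors.append(
                    "variance.covariate.shared: positive shared budget but "
                    "gamma yields no shared covariates"
                )
            if n_shared_cov == k and cv["total"] * (1 - s) > 0:
                errors.append(
                    "variance.covariate.shared: positive independent budget "
                    "but gamma makes all covariates shared"
                )
    if isinstance(gv, dict) and gv.get("total", 0) > 0:
        if geno["source"] == "simulate" and isinstance(geno.get("n_snps"), int) \
                and isinstance(causal.get("n_causal"), int) \
                and causal["n_causal"] > geno["n_snps"]:
            errors.append(
                f"causal.n_causal: {causal['n_causal']} causal SNPs requested "
                f"from a simulated panel of {geno['n_snps']}"
            )

    out = cfg["output"]
    for f in out.get("formats", []):
        if f not in KNOWN_FORMATS:
            errors.append(f"output.formats: unknown format {f!r}; use {KNOWN_FORMATS}")
    if not isinstance(out.get("precision"), int) or out["precision"] < 1:
        errors.append(f"output.precision: must be a positive integer, got {out.get('precision')!r}")

    if errors:
        raise ConfigError(errors)
    return SimulationConfig(
        n_samples=cfg["n_samples"],
        n_traits=cfg["n_traits"],
        seed=cfg["seed"],
        genotypes=geno,
        kinship=kin,
        causal=causal,
        effect_sizes=eff,
        covariates=cov,
        trait_correlation=tc,
        variance=var,
        output=out,
        raw=raw,
    )


def load_config(path: str) -> SimulationConfig:
    """Read and validate a YAML configuration file."""
    with open(path) as fh:
        return validate_config(fh.read())
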