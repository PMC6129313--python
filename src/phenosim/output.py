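"""Output bundles: simulated data in formats association tools consume.

``write_bundle`` emits phenotypes, genotypes, covariates and kinship in any
subset of {csv, gemma, plink, bimbam, snptest} plus a JSON manifest;
``write_component_matrices`` saves every scaled component, the scale-factor
map and the causal-SNP ground truth so downstream methods can be scored
against the known simulation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import formats as fmt
from .assembly import PhenotypeResult, variance_report, variance_report_table
from .components import CovariateSet
from .genotypes import GenotypeData, Kinship

__all__ = ["OutputBundle", "write_bundle", "write_component_matrices"]


@dataclass
class OutputBundle:
    """Where and how to write a simulation's outputs."""

    directory: str
    formats: list[str] = field(default_factory=lambda: ["csv"])
    precision: int = 6

    def __post_init__(self) -> None:
        unknown = set(self.formats) - {"csv", "gemma", "plink", "bimbam", "snptest"}
        if unknown:
            raise ValueError(f"unknown output format(s): {sorted(unknown)}")


def _covariate_types(covariates: CovariateSet | None) -> list[str]:
    if covariates is None:
        return []
    return [
        "D" if spec.get("dist") in ("binomial", "categorical") else "C"
        for spec in covariates.specs
    ]


def write_bundle(
    result: PhenotypeResult,
    genotypes: GenotypeData | None,
    covariates: CovariateSet | None,
    kinship: Kinship | None,
    bundle: OutputBundle,
    manifest_extra: dict | None = None,
) -> list[str]:
    """Write every requested format's complete companion-file set.

    Sample order is the result's ``sample_ids`` everywhere; a mismatch with
    the genotype or kinship sample IDs raises before anything is written.
    """
    if genotypes is not None and genotypes.sample_ids != result.sample_ids:
        raise ValueError("genotype sample IDs do not match the phenotype result")
    if kinship is not None and kinship.sample_ids != result.sample_ids:
        raise ValueError("kinship sample IDs do not match the phenotype result")
    os.makedirs(bundle.directory, exist_ok=True)
    d = bundle.directory
    p = bundle.precision
    files: list[str] = []

    def path(name: str) -> str:
        return os.path.join(d, name)

    for f in bundle.formats:
        if f == "csv":
            files.append(fmt.write_csv_matrix(
                result.Y, path("phenotypes.csv"),
                result.sample_ids, result.trait_ids, precision=p,
            ))
            if covariates is not None and covariates.values.shape[1]:
                files.append(fmt.write_csv_matrix(
                    covariates.values, path("covariates.csv"),
                    result.sample_ids,
                    [f"cov_{i+1}" for i in range(covariates.values.shape[1])],
                    precision=p,
                ))
            if kinship is not None:
                files.append(fmt.write_square_matrix(
                    kinship.matrix, path("kinship.csv"), sep=",",
                    ids=kinship.sample_ids, precision=p,
                ))
        elif f == "gemma":
            files.append(fmt.write_gemma_phenotype(
                result.Y, path("phenotypes_gemma.txt"), precision=p))
            if kinship is not None:
                files.append(fmt.write_gemma_kinship(
                    kinship, path("kinship_gemma.txt"), precision=p))
            if covariates is not None and covariates.values.shape[1]:
                # GEMMA -c expects a leading intercept column of ones
                W = np.column_stack(
                    [np.ones(covariates.values.shape[0]), covariates.values]
                )
                files.append(fmt.write_gemma_phenotype(
                    W, path("covariates_gemma.txt"), precision=p))
            if genotypes is not None:
                files.extend(fmt.write_bimbam_mean(
                    genotypes, path("genotypes_gemma.txt"), precision=p))
        elif f == "bimbam":
            if genotypes is not None:
                files.extend(fmt.write_bimbam_mean(
                    genotypes, path("genotypes_bimbam.txt"), precision=p))
            files.append(fmt.write_gemma_phenotype(
                result.Y, path("phenotypes_bimbam.txt"), precision=p))
        elif f == "plink":
            if genotypes is not None:
                files.extend(fmt.write_plink_text(genotypes, path("genotypes")))
            files.append(fmt.write_plink_phenotype(
                path("phenotypes_plink.txt"), result.sample_ids,
                result.Y, result.trait_ids, precision=p,
            ))
        elif f == "snptest":
            if genotypes is not None:
                files.extend(fmt.write_oxford_gen(
                    genotypes, path("genotypes_snptest"), precision=p))
                sample_path = os.path.join(d, "genotypes_snptest.sample")
                if sample_path in files:
                    files.remove(sample_path)
                    os.remove(sample_path)
            cov_vals = covariates.values if covariates is not None else None
            files.append(fmt.write_snptest_sample(
                path("genotypes_snptest.sample"), result.sample_ids,
                result.Y, result.trait_ids,
                covariates=cov_vals,
                covariate_types=_covariate_types(covariates) or None,
                precision=p,
            ))

    report = variance_report(result)
    manifest = {
        "n_samples": len(result.sample_ids),
        "n_traits": len(result.trait_ids),
        "formats": list(bundle.formats),
        "precision": p,
        "budget": (
            {f"{r}:{part}": x for (r, part), x in result.budget.entries.items()}
            if result.budget else None
        ),
        "scale_factors": {
            f"{r}:{part}": a for (r, part), a in result.scale_factors.items()
        },
        "variance_report": report,
        "files": sorted(os.path.relpath(f, d) for f in files),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = path("manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append(mpath)
    return files


def write_component_matrices(
    result: PhenotypeResult, destination: str, precision: int = 6
) -> list[str]:
    """Save each scaled component, the scale factors and the causal-SNP truth.

    The per-component matrices sum to the saved phenotype (at the output
    precision), and re-applying the stored variance scale factors to the
    unscaled components reproduces the scaled ones — the ground truth needed
    to benchmark variance-decomposition or association methods.
    """
    os.makedirs(destination, exist_ok=True)
    files: list[str] = []
    for comp in result.components:
        name = f"component_{comp.role}_{comp.part}.csv"
        files.append(fmt.write_csv_matrix(
            comp.values, os.path.join(destination, name),
            result.sample_ids, result.trait_ids, precision=precision,
        ))
    sf_path = os.path.join(destination, "scale_factors.json")
    with open(sf_path, "w") as fh:
        json.dump(
            {f"{r}:{part}": a for (r, part), a in result.scale_factors.items()},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    files.append(sf_path)

    causal_rows = []
    for comp in result.components:
        if comp.role != "genetic_variant":
            continue
        eff = comp.extras.get("effect_sizes")
        snp_ids = comp.extras.get("snp_ids", [])
        if eff is None:
            continue
        a = result.scale_factors.get((comp.role, comp.part), 1.0)
        scaled_eff = eff.values * np.sqrt(a)
        for i, snp in enumerate(snp_ids):
            row = {"snp_id": snp, "part": comp.part}
            for j in range(scaled_eff.shape[1]):
                row[result.trait_ids[j]] = scaled_eff[i, j]
            causal_rows.append(row)
    if causal_rows:
        import pandas as pd

        causal_path = os.path.join(destination, "causal_snps.csv")
        pd.DataFrame(causal_rows).to_csv(
            causal_path, index=False, float_format=f"%.{precision}f"
        )
        files.append(causal_path)

    report = variance_report(result)
    rpath = os.path.join(destination, "variance_report.json")
    with open(rpath, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append(rpath)
    tpath = os.path.join(destination, "variance_report.tsv")
    variance_report_table(report).to_csv(
        tpath, sep="\t", index=False, float_format=f"%.{precision}f"
    )
    files.append(tpath)
    return files
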