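"""Variance-budget scaling and phenotype assembly.

Each simulated component is rescaled so that its average column variance
V_col (mean over traits of the per-trait sample variance) explains exactly a
requested fraction x of total phenotypic variance: the variance scale factor
is a = x / V_col and the matrix entries are multiplied by sqrt(a), after
which the realized mean column variance equals x to machine precision.  The
final phenotype Y is the plain sum of the scaled components:

    Y = X_s B_s + X_i B_i + W_s A_s + W_i A_i + U_s + U_i + T + Psi_s + Psi_i

Only the per-component variances are exact; the total variance of Y equals 1
in expectation only, because independently simulated components have O(1/sqrt(N))
sample cross-covariances that scaling does not remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import PhenotypeComponent, ROLES

__all__ = [
    "VarianceBudget",
    "PhenotypeResult",
    "scale_component",
    "assemble_phenotype",
    "variance_report",
    "mean_column_variance",
]

BUDGET_TOL = 1e-6


def mean_column_variance(values: np.ndarray) -> float:
    """Mean over traits of the per-trait sample variance (n-1 denominator)."""
    return float(np.mean(np.var(values, axis=0, ddof=1)))


@dataclass
class VarianceBudget:
    """Map (role, part) -> target fraction of total phenotypic variance."""

    entries: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (role, part), x in self.entries.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} in variance budget")
            if x < 0:
                raise ValueError(f"budget fraction for {role}:{part} is negative")
        total = self.total
        if abs(total - 1.0) > BUDGET_TOL:
            raise ValueError(
                f"variance budget must sum to 1 (tolerance {BUDGET_TOL}); got {total}"
            )

    @classmethod
    def from_totals(cls, totals: dict[str, tuple[float, float | None]]) -> "VarianceBudget":
        """Build a budget from per-component totals and shared fractions.

        ``totals`` maps role -> (x, s) where x is the component's total share
        and s its shared fraction; a split component gets sub-budgets x*s
        (shared) and x*(1-s) (independent), ``s=None`` means unsplit (whole).
        """
        entries: dict[tuple[str, str], float] = {}
        for role, (x, s) in totals.items():
            if s is None:
                entries[(role, "whole")] = x
            else:
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"shared fraction for {role} must be in [0, 1]")
                entries[(role, "shared")] = x * s
                entries[(role, "independent")] = x * (1.0 - s)
        return cls(entries)

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))

    @property
    def total_genetic(self) -> float:
        return float(
            sum(x for (role, _), x in self.entries.items()
                if role in ("genetic_variant", "infinitesimal"))
        )

    @property
    def total_noise(self) -> float:
        return self.total - self.total_genetic


@dataclass
class PhenotypeResult:
    """Final phenotype, its scaled components, and the applied scale factors."""

    Y: np.ndarray
    components: list[PhenotypeComponent]
    scale_factors: dict[tuple[str, str], float]
    sample_ids: list[str]
    trait_ids: list[str]
    budget: VarianceBudget | None = None
    unscaled_components: list[PhenotypeComponent] = field(default_factory=list)


def scale_component(
    component: PhenotypeComponent, x: float
) -> tuple[PhenotypeComponent, float]:
    """Rescale a component to explain exactly the fraction ``x`` of variance.

    Returns the scaled component and the variance scale factor
    ``a = x / V_col``; entries are multiplied by ``sqrt(a)`` so the rescaled
    mean column variance is x exactly.  ``x = 0`` maps any component to the
    zero matrix.  A component with zero average column variance cannot be
    scaled to a positive target and raises.
    """
    if x < 0:
        raise ValueError("target variance fraction must be >= 0")
    if x == 0.0:
        scaled = PhenotypeComponent(
            np.zeros_like(component.values), component.role, component.part,
            target_variance=0.0, extras=dict(component.extras),
        )
        return scaled, 0.0
    vbar = mean_column_variance(component.values)
    if vbar == 0.0:
        raise ValueError(
            f"component {component.label} is constant (zero average column "
            f"variance); cannot scale it to explain {x} of total variance"
        )
    a = x / vbar
    scaled = PhenotypeComponent(
        component.values * np.sqrt(a), component.role, component.part,
        target_variance=x, extras=dict(component.extras),
    )
    return scaled, a


def assemble_phenotype(
    components: list[PhenotypeComponent],
    budget: VarianceBudget,
    sample_ids: list[str] | None = None,
    trait_ids: list[str] | None = None,
) -> PhenotypeResult:
    """Scale every component to its budget entry and sum them into Y.

    The budget keys must match the provided components exactly — a missing
    or extra (role, part) is a configuration bug and raises rather than
    being silently renormalized.
    """
    keys = [(c.role, c.part) for c in components]
    if len(set(keys)) != len(keys):
        dupes = {k for k in keys if keys.count(k) > 1}
        raise ValueError(f"duplicate component keys: {sorted(dupes)}")
    missing = set(budget.entries) - set(keys)
    extra = set(keys) - set(budget.entries)
    if missing or extra:
        raise ValueError(
            f"budget/component mismatch: missing components for {sorted(missing)}, "
            f"components without budget entry {sorted(extra)}"
        )
    shapes = {c.values.shape for c in components}
    if len(shapes) != 1:
        raise ValueError(f"components disagree on N x P shape: {sorted(shapes)}")
    scaled: list[PhenotypeComponent] = []
    factors: dict[tuple[str, str], float] = {}
    for comp in components:
        sc, a = scale_component(comp, budget.entries[(comp.role, comp.part)])
        scaled.append(sc)
        factors[(comp.role, comp.part)] = a
    Y = np.sum([c.values for c in scaled], axis=0)
    n, p = Y.shape
    return PhenotypeResult(
        Y=Y,
        components=scaled,
        scale_factors=factors,
        sample_ids=sample_ids or [f"id_{i+1}" for i in range(n)],
        trait_ids=trait_ids or [f"trait_{j+1}" for j in range(p)],
        budget=budget,
        unscaled_components=list(components),
    )


def _safe_corr(values: np.ndarray) -> tuple[np.ndarray | None, bool]:
    """Pearson trait-by-trait correlation, or (None, True) if degenerate."""
    if np.allclose(values.std(axis=0), 0.0):
        return None, True
    sd = values.std(axis=0)
    if np.any(sd == 0):
        return None, True
    return np.corrcoef(values, rowvar=False).reshape(
        values.shape[1], values.shape[1]
    ), False


def variance_report(result: PhenotypeResult) -> dict:
    """Realized variances and trait correlations for Y and every component.

    Everything is recomputed directly from the stored matrices, so the
    report can be regenerated from saved outputs and compared against the
    one emitted at simulation time.
    """
    report: dict = {"components": {}, "phenotype": {}}
    genetic = 0.0
    for comp in result.components:
        v_traits = np.var(comp.values, axis=0, ddof=1)
        vbar = float(v_traits.mean())
        corr, degenerate = _safe_corr(comp.values)
        report["components"][comp.label] = {
            "role": comp.role,
            "part": comp.part,
            "per_trait_variance": v_traits.tolist(),
            "mean_column_variance": vbar,
            "target_variance": comp.target_variance,
            "scale_factor": result.scale_factors.get((comp.role, comp.part)),
            "trait_correlation": None if degenerate else corr.tolist(),
            "degenerate": degenerate,
        }
        if comp.role in ("genetic_variant", "infinitesimal"):
            genetic += vbar
    vy = np.var(result.Y, axis=0, ddof=1)
    corr_y, degenerate_y = _safe_corr(result.Y)
    total = float(sum(
        c["mean_column_variance"] for c in report["components"].values()
    ))
    report["phenotype"] = {
        "per_trait_variance": vy.tolist(),
        "mean_column_variance": float(vy.mean()),
        "trait_correlation": None if degenerate_y else corr_y.tolist(),
        "sum_component_variance": total,
        "genetic_variance_share": genetic / total if total else float("nan"),
        "noise_variance_share": (total - genetic) / total if total else float("nan"),
    }
    return report


def variance_report_table(report: dict) -> pd.DataFrame:
    """Flatten the per-component section of a variance report to a table."""
    rows = []
    for label, entry in report["components"].items():
        rows.append(
            {
                "component": label,
                "role": entry["role"],
                "part": entry["part"],
                "target_variance": entry["target_variance"],
                "mean_column_variance": entry["mean_column_variance"],
                "scale_factor": entry["scale_factor"],
            }
        )
    return pd.DataFrame(rows)
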