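"""Equilibrium speciation of one metal with competing ligands.

The chemistry is restricted to mononuclear complexes ``M + n L <-> MLn`` with
``n`` of 1 or 2, described by a conditional association constant ``K_A``
(M^-1, n = 1) or cumulative formation constant ``beta2`` (M^-2, n = 2).
Given analytical (total) concentrations, the equilibrium is the root of the
metal mass balance

    M + sum_i K_i * M * L_i(M)^n_i  =  M_total,

where each free-ligand concentration ``L_i(M)`` follows in closed form from
its own mass balance at trial free metal ``M``. The balance is strictly
increasing in ``M``, so the root is unique and bracketed by construction.

Constants are treated as conditional for the working buffer (the titrations
this models used 10 mM HEPES pH 7, 20 mM NaCl, 80 mM KCl with reductant);
activity corrections, pH, and Cu(II) redox chemistry are out of scope.
All concentrations are molar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.optimize import brentq

from .errors import ConfigurationError, SolverError

__all__ = [
    "BindingModel",
    "SolutionComposition",
    "SpeciationResult",
    "free_ligand_given_free_metal",
    "solve_speciation",
]

#: Relative metal-balance residual demanded of a converged solution.
RESIDUAL_RTOL = 1e-12
#: Iteration cap for the bracketed root-find.
MAX_ITER = 200


@dataclass(frozen=True)
class BindingModel:
    """Metal-binding scheme of one ligand.

    Parameters
    ----------
    ligand_name:
        Label used to match the ligand in a :class:`SolutionComposition`.
    ligands_per_complex:
        1 for ML (constant is ``K_A``, M^-1), 2 for ML2 (constant is the
        cumulative ``beta2``, M^-2).
    formation_constant:
        Conditional association constant. Zero denotes a non-binding ligand
        (e.g. a cysteine-to-serine mutant control).
    metal_per_complex:
        Always 1; polynuclear and ternary complexes are rejected.
    """

    ligand_name: str
    ligands_per_complex: int
    formation_constant: float
    metal_per_complex: int = 1

    def __post_init__(self) -> None:
        if self.metal_per_complex != 1:
            raise ConfigurationError(
                f"{self.ligand_name!r}: only mononuclear complexes are supported "
                f"(metal_per_complex={self.metal_per_complex})"
            )
        if self.ligands_per_complex not in (1, 2):
            raise ConfigurationError(
                f"{self.ligand_name!r}: ligands_per_complex must be 1 or 2, "
                f"got {self.ligands_per_complex}"
            )
        k = self.formation_constant
        if not math.isfinite(k) or k < 0:
            raise ValueError(
                f"{self.ligand_name!r}: formation constant must be finite and >= 0, got {k}"
            )

    @classmethod
    def one_to_one_from_kd(cls, ligand_name: str, kd: float) -> "BindingModel":
        """Build a 1:1 model from a dissociation constant (K_A = 1/K_D, exact)."""
        if not (kd > 0 and math.isfinite(kd)):
            raise ValueError(f"K_D must be positive and finite, got {kd}")
        return cls(ligand_name, 1, 1.0 / kd)

    @property
    def kd(self) -> float:
        """Dissociation constant of a 1:1 model (round-trips with the constructor)."""
        if self.ligands_per_complex != 1:
            raise ConfigurationError("K_D is defined only for 1:1 models")
        if self.formation_constant == 0:
            return math.inf
        return 1.0 / self.formation_constant


@dataclass(frozen=True)
class SolutionComposition:
    """Analytical concentrations (M) of metal and ligands in one cuvette state."""

    metal_total: float
    ligand_totals: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_conc("metal_total", self.metal_total)
        for name, tot in self.ligand_totals.items():
            _require_conc(f"ligand {name!r}", tot)

    def with_metal_total(self, metal_total: float) -> "SolutionComposition":
        return SolutionComposition(metal_total, dict(self.ligand_totals))


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium free and complexed concentrations (M)."""

    free_metal: float
    free_ligands: Mapping[str, float]
    complexes: Mapping[str, float]

    def metal_balance_residual(self, metal_total: float) -> float:
        """Relative metal mass-balance error (0 for metal_total = 0)."""
        if metal_total == 0:
            return abs(self.free_metal + sum(self.complexes.values()))
        return abs(
            (self.free_metal + sum(self.complexes.values()) - metal_total) / metal_total
        )


def _require_conc(label: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{label}: concentration must be finite and >= 0, got {value}")


def free_ligand_given_free_metal(
    ligand_total: float, free_metal: float, model: BindingModel
) -> float:
    """Free ligand concentration satisfying the ligand mass balance at fixed free metal.

    Solves ``L + n * K * M * L**n = ligand_total`` in closed form: for n = 1,
    ``L = total / (1 + K M)``; for n = 2, the positive root of
    ``2 K M L**2 + L - total = 0``, evaluated in the cancellation-free form
    ``2 total / (1 + sqrt(1 + 8 K M total))``.
    """
    _require_conc("ligand_total", ligand_total)
    _require_conc("free_metal", free_metal)
    if ligand_total == 0.0:
        return 0.0
    km = model.formation_constant * free_metal
    if km == 0.0:
        return ligand_total
    if model.ligands_per_complex == 1:
        return ligand_total / (1.0 + km)
    return 2.0 * ligand_total / (1.0 + math.sqrt(1.0 + 8.0 * km * ligand_total))


def _bound_metal(free_metal: float, totals: Sequence[float], models: Sequence[BindingModel]) -> float:
    bound = 0.0
    for tot, model in zip(totals, models):
        lig = free_ligand_given_free_metal(tot, free_metal, model)
        bound += model.formation_constant * free_metal * lig**model.ligands_per_complex
    return bound


def solve_speciation(
    comp: SolutionComposition, models: Sequence[BindingModel]
) -> SpeciationResult:
    """Solve the full equilibrium of a metal/probe/competitor mixture.

    Every ligand named in ``comp`` must have exactly one model (extra models
    are rejected too). The root-find runs on log10(free metal) with a bracket
    that provably contains the root, using Brent's method (bisection-
    safeguarded), and verifies the metal balance to ``RESIDUAL_RTOL``.
    """
    names = [m.ligand_name for m in models]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate ligand models: {sorted(names)}")
    missing = set(comp.ligand_totals) - set(names)
    extra = set(names) - set(comp.ligand_totals)
    if missing or extra:
        raise ConfigurationError(
            f"ligand/model mismatch: composition ligands without a model {sorted(missing)}, "
            f"models without a ligand {sorted(extra)}"
        )

    totals = [comp.ligand_totals[m.ligand_name] for m in models]
    mt = comp.metal_total

    if mt == 0.0:
        return SpeciationResult(
            free_metal=0.0,
            free_ligands={m.ligand_name: t for m, t in zip(models, totals)},
            complexes={m.ligand_name: 0.0 for m in models},
        )

    capacity = sum(
        m.formation_constant * t**m.ligands_per_complex for m, t in zip(models, totals)
    )
    if capacity == 0.0:  # no ligands, or none that bind
        free_metal = mt
    else:
        def balance(log_m: float) -> float:
            m = 10.0**log_m
            return (m + _bound_metal(m, totals, models) - mt) / mt

        hi = math.log10(mt)  # balance(hi) >= 0 since bound >= 0
        # At M = 0.5*mt/(1+capacity), M + bound <= M*(1+capacity) = 0.5*mt < mt.
        lo = math.log10(0.5 * mt / (1.0 + capacity))
        log_m = brentq(balance, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=MAX_ITER)
        free_metal = 10.0**log_m

    free_ligands = {
        m.ligand_name: free_ligand_given_free_metal(t, free_metal, m)
        for m, t in zip(models, totals)
    }
    complexes = {
        m.ligand_name: m.formation_constant
        * free_metal
        * free_ligands[m.ligand_name] ** m.ligands_per_complex
        for m in models
    }
    result = SpeciationResult(free_metal, free_ligands, complexes)
    residual = result.metal_balance_residual(mt)
    if residual > RESIDUAL_RTOL:
        raise SolverError(
            f"speciation did not converge: relative metal-balance residual "
            f"{residual:.3e} > {RESIDUAL_RTOL:.0e}",
            residual=residual,
        )
    return result
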