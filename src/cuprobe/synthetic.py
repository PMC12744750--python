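"""Seeded synthetic competition-titration datasets.

Generates noisy replicated isotherms with the statistical structure of
anaerobic Cu(I) probe-competition experiments: a control series (probe alone)
and a competition series (probe + competitor), n = 2-3 replicates, and
signal-proportional Gaussian noise (default 1% of each point's noise-free
absorbance -- the scatter of careful anaerobic titrations is small and mostly
concentration/pipetting error, hence multiplicative). Identical
(design, seed) pairs reproduce byte-identical CSV output; the random source
is numpy's PCG64 so outputs are portable across platforms.

The built-in designs encode the bench conditions of the POLARIS/ATX1
competition experiments (probe and competitor totals, replicate counts, and
per-replicate probe concentrations where the experiments used slightly
different BCA batches). What the generator does *not* emulate: baseline
drift, competitor insolubility, slow Cu(I) exchange, and spectral overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants
from .speciation import BindingModel, SolutionComposition
from .titration import Isotherm, OpticalModel, simulate_isotherm

__all__ = ["ExperimentDesign", "TruthRecord", "generate_titration_dataset", "builtin_designs"]


def default_metal_grid(compositions: Mapping[str, SolutionComposition],
                       models: Sequence[BindingModel], n_steps: int = 30) -> tuple[float, ...]:
    """0 to 1.5x the stoichiometric endpoint (sum of totals/n) in ``n_steps`` steps."""
    by_name = {m.ligand_name: m for m in models}
    endpoint = max(
        sum(tot / by_name[name].ligands_per_complex for name, tot in comp.ligand_totals.items()
            if by_name[name].formation_constant > 0)
        for comp in compositions.values()
    )
    return tuple(np.linspace(0.0, 1.5 * endpoint, n_steps + 1))


@dataclass(frozen=True)
class ExperimentDesign:
    """One synthetic experiment: series compositions, truth, optics, noise, seed.

    ``compositions`` maps series_id to the cuvette composition (all series
    share the optics and metal grid). ``replicate_ligand_totals`` optionally
    overrides ligand totals per (series_id, replicate) -- used when replicate
    probe batches differed. ``noise_sd_fraction`` is the Gaussian sd as a
    fraction of each point's noise-free signal (multiplicative).
    """

    name: str
    compositions: Mapping[str, SolutionComposition]
    true_models: tuple[BindingModel, ...]
    optics: OpticalModel
    metal_grid: tuple[float, ...]
    n_replicates: int = 3
    noise_sd_fraction: float = 0.01
    seed: int = 0
    replicate_ligand_totals: Mapping[tuple[str, int], Mapping[str, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.noise_sd_fraction < 0 or not math.isfinite(self.noise_sd_fraction):
            raise ValueError(
                f"noise_sd_fraction must be finite and >= 0, got {self.noise_sd_fraction}"
            )
        if len(self.metal_grid) < 2:
            raise ValueError("metal_grid needs at least 2 points")


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters, for parameter-recovery checks."""

    design_name: str
    models: tuple[BindingModel, ...]
    optics: OpticalModel
    noise_sd_fraction: float
    seed: int

    def to_text(self) -> str:
        lines = [f"design = {self.design_name}",
                 f"seed = {self.seed}",
                 f"noise_sd_fraction = {self.noise_sd_fraction:g}",
                 f"epsilon_probe_complex = {self.optics.epsilon_probe_complex:g}",
                 f"wavelength_nm = {self.optics.wavelength_nm:g}",
                 f"path_length_cm = {self.optics.path_length_cm:g}"]
        for m in self.models:
            lines.append(
                f"model_{m.ligand_name} = n:{m.ligands_per_complex} K:{m.formation_constant:.6g}"
            )
        return "\n".join(lines) + "\n"


def generate_titration_dataset(design: ExperimentDesign) -> tuple[Isotherm, TruthRecord]:
    """Noisy replicated dataset plus the truth record that generated it.

    Each (series, replicate) curve is the noise-free speciation prediction
    perturbed point-wise by multiplicative Gaussian noise
    ``A * (1 + N(0, noise_sd_fraction))``, clipped at zero absorbance.
    Replicates and series consume draws in a fixed order, so a given
    (design, seed) is exactly reproducible.
    """
    rng = np.random.default_rng(design.seed)
    frames = []
    for series_id, comp in design.compositions.items():
        for rep in range(1, design.n_replicates + 1):
            overrides = design.replicate_ligand_totals.get((series_id, rep))
            if overrides:
                totals = dict(comp.ligand_totals) | dict(overrides)
                rep_comp = SolutionComposition(comp.metal_total, totals)
            else:
                rep_comp = comp
            series_models = [
                m for m in design.true_models if m.ligand_name in rep_comp.ligand_totals
            ]
            clean = simulate_isotherm(
                rep_comp, series_models, design.optics, design.metal_grid,
                series_id=series_id, replicate=rep,
            )
            absorb = clean.data["absorbance"].to_numpy(float)
            if design.noise_sd_fraction > 0:
                absorb = absorb * (1.0 + rng.normal(0.0, design.noise_sd_fraction, absorb.size))
                absorb = np.clip(absorb, 0.0, None)
            frame = clean.data.copy()
            frame["absorbance"] = absorb
            frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    # The competition series' composition is the informative template for fitting.
    template = list(design.compositions.values())[-1]
    isotherm = Isotherm(data, composition=template, optics=design.optics)
    truth = TruthRecord(
        design_name=design.name,
        models=design.true_models,
        optics=design.optics,
        noise_sd_fraction=design.noise_sd_fraction,
        seed=design.seed,
    )
    return isotherm, truth


def _bca(total: float) -> SolutionComposition:
    return SolutionComposition(0.0, {"BCA": total})


def _bca_plus(bca_total: float, name: str, total: float) -> SolutionComposition:
    return SolutionComposition(0.0, {"BCA": bca_total, name: total})


def builtin_designs(seed: int = 0, noise_sd_fraction: float = 0.01) -> dict[str, ExperimentDesign]:
    """Ready-made designs mirroring the published competition experiments.

    * ``fig5B``  -- 85.3 uM BCA control vs. ~87 uM BCA + 44.8 uM synthetic PLS
      (2:1), replicate BCA batches 88.3/84/88.4 uM.
    * ``fig5D``  -- 17.3 uM BCA alone, n = 2.
    * ``fig5E``  -- 10 uM BCA +/- 14 uM MBP:PLS (2:1), 0-30 uM Cu(I).
    * ``fig5E_mutant`` -- as fig5E with a non-binding (C6S/C17S-style) competitor.
    * ``fig5F``  -- 50 uM BCA +/- 10 uM MBP:PLS (2:1), 0-60 uM Cu(I) in 2 uM steps.
    * ``fig5H``  -- 20 uM BCA +/- 20 uM ATX1 (1:1).
    """
    uM = 1e-6
    bca = BindingModel("BCA", 2, constants.BCA_BETA2)
    pls = BindingModel("PLS", 2, constants.PLS_BETA2)
    pls_mutant = BindingModel("PLS", 2, 0.0)
    atx1 = BindingModel.one_to_one_from_kd("ATX1", constants.ATX1_KD)
    optics = OpticalModel(
        epsilon_probe_complex=constants.BCA_EPSILON_358,
        wavelength_nm=constants.BCA_WAVELENGTH_NM,
    )

    def design(name, compositions, models, grid=None, n_replicates=3, **kw):
        grid = tuple(grid) if grid is not None else default_metal_grid(compositions, models)
        return ExperimentDesign(
            name=name, compositions=compositions, true_models=tuple(models),
            optics=optics, metal_grid=grid, n_replicates=n_replicates,
            noise_sd_fraction=noise_sd_fraction, seed=seed, **kw,
        )

    designs = {
        "fig5B": design(
            "fig5B",
            {"control": _bca(85.3 * uM), "PLS": _bca_plus(87.0 * uM, "PLS", 44.8 * uM)},
            [bca, pls],
            grid=np.linspace(0.0, 100 * uM, 51),
            replicate_ligand_totals={
                ("PLS", 1): {"BCA": 88.3 * uM},
                ("PLS", 2): {"BCA": 84.0 * uM},
                ("PLS", 3): {"BCA": 88.4 * uM},
            },
        ),
        "fig5D": design(
            "fig5D", {"control": _bca(17.3 * uM)}, [bca], n_replicates=2,
        ),
        "fig5E": design(
            "fig5E",
            {"control": _bca(10 * uM), "PLS": _bca_plus(10 * uM, "PLS", 14 * uM)},
            [bca, pls],
            grid=np.linspace(0.0, 30 * uM, 31),
        ),
        "fig5E_mutant": design(
            "fig5E_mutant",
            {"control": _bca(10 * uM), "PLS": _bca_plus(10 * uM, "PLS", 14 * uM)},
            [bca, pls_mutant],
            grid=np.linspace(0.0, 30 * uM, 31),
        ),
        "fig5F": design(
            "fig5F",
            {"control": _bca(50 * uM), "PLS": _bca_plus(50 * uM, "PLS", 10 * uM)},
            [bca, pls],
            grid=np.arange(0.0, 61 * uM, 2 * uM),
        ),
        "fig5H": design(
            "fig5H",
            {"control": _bca(20 * uM), "ATX1": _bca_plus(20 * uM, "ATX1", 20 * uM)},
            [bca, atx1],
        ),
    }
    return designs
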