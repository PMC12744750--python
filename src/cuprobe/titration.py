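"""Absorbance titration isotherms, withheld-metal and stoichiometry inference.

A competition titration follows formation of a chromophoric probe-metal
complex (for BCA, the 2:1 Cu(BCA)2 complex at 358 nm) as total metal is
stepped up. A competitor that out-competes the probe sequesters the first
equivalents of metal, displacing the isotherm to the right; the size of the
displacement per mole of competitor reveals the binding stoichiometry
(one Cu(I) equivalent withheld per 2 peptides for a 2:1 ligand:metal complex).

"Withheld metal" is operationalised as the horizontal shift between the
competition and control isotherms measured at half-maximal probe signal,
which is robust to plateau noise; the half-max reference is the control's own
asymptote (mean of its top 10% of points by metal total). Titration grids are
coarse (1-2 uM steps), so crossings are located by piecewise-linear
interpolation.

CSV interface: columns ``series_id, replicate, cu_total_uM, absorbance``
(header mandatory, comma separator, decimal point, UTF-8); concentrations are
uM at the file boundary and molar everywhere in memory.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CSVFormatError, SolverError
from .speciation import BindingModel, SolutionComposition, solve_speciation

__all__ = [
    "OpticalModel",
    "Isotherm",
    "simulate_isotherm",
    "withheld_metal",
    "infer_stoichiometry",
    "StoichiometryInference",
    "read_titration_csv",
    "write_titration_csv",
]

CSV_COLUMNS = ("series_id", "replicate", "cu_total_uM", "absorbance")


@dataclass(frozen=True)
class OpticalModel:
    """Beer-Lambert optics: absorbance = baseline + epsilon * path * [probe complex]."""

    epsilon_probe_complex: float
    wavelength_nm: float = 358.0
    path_length_cm: float = 1.0
    baseline: float = 0.0
    probe_ligand: str = "BCA"

    def __post_init__(self) -> None:
        if not self.epsilon_probe_complex > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon_probe_complex}")
        if not self.path_length_cm > 0:
            raise ValueError(f"path length must be > 0, got {self.path_length_cm}")
        if self.baseline < 0:
            raise ValueError(f"baseline must be >= 0, got {self.baseline}")

    def absorbance(self, probe_complex: float) -> float:
        return self.baseline + self.epsilon_probe_complex * self.path_length_cm * probe_complex


@dataclass(frozen=True)
class Isotherm:
    """Ordered (total metal, absorbance) series with replicate structure.

    ``data`` columns: series_id (str), replicate (int), metal_total (M, strictly
    increasing within each series/replicate), absorbance (finite).
    """

    data: pd.DataFrame
    composition: SolutionComposition | None = None
    optics: OpticalModel | None = None

    def __post_init__(self) -> None:
        df = self.data
        required = {"series_id", "replicate", "metal_total", "absorbance"}
        if missing := required - set(df.columns):
            raise ValueError(f"isotherm table missing columns: {sorted(missing)}")
        if not np.isfinite(df["absorbance"]).all():
            raise ValueError("non-finite absorbance values")
        if (df["metal_total"] < 0).any():
            raise ValueError("negative metal_total values")
        for (sid, rep), grp in df.groupby(["series_id", "replicate"], sort=False):
            mt = grp["metal_total"].to_numpy()
            if not np.all(np.diff(mt) > 0):
                raise ValueError(
                    f"metal_total must be strictly increasing within replicate "
                    f"(series {sid!r}, replicate {rep})"
                )

    def series_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["series_id"]))

    def select(self, series_id: str) -> "Isotherm":
        sub = self.data[self.data["series_id"] == series_id].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no series {series_id!r}; have {self.series_ids()}")
        return replace(self, data=sub)

    def mean_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-averaged curve: (metal grid, mean absorbance), grid ascending."""
        g = self.data.groupby("metal_total", sort=True)["absorbance"].mean()
        return g.index.to_numpy(float), g.to_numpy(float)


def simulate_isotherm(
    comp_template: SolutionComposition,
    models: Sequence[BindingModel],
    optics: OpticalModel,
    metal_grid: Sequence[float],
    *,
    series_id: str = "simulated",
    replicate: int = 1,
) -> Isotherm:
    """Noise-free predicted isotherm over an ascending total-metal grid.

    One point per grid value: the probe-complex concentration from the full
    speciation solve, mapped through the optical model. Deterministic.
    """
    grid = np.asarray(metal_grid, dtype=float)
    if grid.size < 2:
        raise ValueError("metal_grid needs at least 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("metal_grid must be sorted strictly ascending")
    probe = optics.probe_ligand
    if probe not in comp_template.ligand_totals:
        raise ConfigurationError(
            f"probe ligand {probe!r} absent from composition "
            f"{sorted(comp_template.ligand_totals)}"
        )
    absorbances = np.empty_like(grid)
    for i, mt in enumerate(grid):
        try:
            spec = solve_speciation(comp_template.with_metal_total(mt), models)
        except SolverError as err:
            raise SolverError(
                f"speciation failed at metal_total = {mt:.6g} M: {err}",
                residual=err.residual,
            ) from err
        absorbances[i] = optics.absorbance(spec.complexes[probe])
    df = pd.DataFrame(
        {
            "series_id": series_id,
            "replicate": replicate,
            "metal_total": grid,
            "absorbance": absorbances,
        }
    )
    return Isotherm(df, composition=comp_template, optics=optics)


def _half_max_crossing(grid: np.ndarray, signal: np.ndarray, level: float, label: str) -> float:
    """Leftmost piecewise-linear upward crossing of ``level``."""
    above = signal >= level
    if not above.any():
        raise ValueError(
            f"{label} isotherm never reaches half-maximal signal ({level:.4g}); "
            "widen the titration to higher total metal"
        )
    i = int(np.argmax(above))
    if i == 0:
        return float(grid[0])
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = signal[i - 1], signal[i]
    return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))


def withheld_metal(with_competitor: Isotherm, control: Isotherm) -> float:
    """Metal (M) withheld from the probe by the competitor.

    Horizontal displacement between the replicate-averaged competition and
    control isotherms at half-maximal probe signal, where "maximal" is the
    control's plateau estimate (mean of its top 10% of points). Non-negative
    for a competitor that binds; ~0 for identical isotherms.
    """
    g_ctrl, a_ctrl = control.mean_curve()
    g_comp, a_comp = with_competitor.mean_curve()
    n_top = max(1, math.ceil(0.1 * a_ctrl.size))
    asymptote = float(a_ctrl[-n_top:].mean())
    level = float(a_ctrl[0]) + 0.5 * (asymptote - float(a_ctrl[0]))
    x_ctrl = _half_max_crossing(g_ctrl, a_ctrl, level, "control")
    x_comp = _half_max_crossing(g_comp, a_comp, level, "competition")
    return x_comp - x_ctrl


@dataclass(frozen=True)
class StoichiometryInference:
    """Ligand:metal ratio inferred from withheld metal."""

    ratio: int
    raw_ratio: float
    warning: str | None = None


def infer_stoichiometry(competitor_total: float, withheld: float) -> StoichiometryInference:
    """Ligands per metal in the competitor complex: round(total / withheld).

    A 2:1 peptide:Cu(I) complex withholds half an equivalent per peptide; a
    1:1 chaperone withholds one. Deviations > 20% from the nearest integer
    are flagged, not rejected.
    """
    if not competitor_total > 0:
        raise ValueError(f"competitor_total must be > 0, got {competitor_total}")
    if not withheld > 0:
        raise ValueError(
            f"competitor does not withhold metal (withheld = {withheld:.4g} M); "
            "stoichiometry is undefined"
        )
    raw = competitor_total / withheld
    ratio = max(1, round(raw))
    warning = None
    if abs(raw - ratio) > 0.2 * ratio:
        warning = (
            f"unrounded ratio {raw:.3g} deviates more than 20% from {ratio}; "
            "check competitor solubility/concentration or titration range"
        )
    return StoichiometryInference(ratio=ratio, raw_ratio=raw, warning=warning)


def write_titration_csv(isotherm: Isotherm, path_or_buf) -> None:
    """Write the titration CSV (uM at the boundary, 6 significant figures)."""
    df = pd.DataFrame(
        {
            "series_id": isotherm.data["series_id"],
            "replicate": isotherm.data["replicate"],
            "cu_total_uM": isotherm.data["metal_total"] * 1e6,
            "absorbance": isotherm.data["absorbance"],
        }
    )
    df.to_csv(path_or_buf, index=False, float_format="%.6g")


def read_titration_csv(path_or_buf) -> Isotherm:
    """Read the titration CSV, with row/column diagnostics on malformed input."""
    try:
        df = pd.read_csv(path_or_buf, dtype=str, skipinitialspace=True)
    except Exception as err:  # pandas raises a zoo of parser errors
        raise CSVFormatError(f"cannot parse titration CSV: {err}") from err
    if missing := set(CSV_COLUMNS) - set(df.columns):
        raise CSVFormatError(
            f"titration CSV header missing columns {sorted(missing)}; "
            f"expected {list(CSV_COLUMNS)}, got {list(df.columns)}"
        )
    out = pd.DataFrame({"series_id": df["series_id"].astype(str)})
    for col, kind in (("replicate", int), ("cu_total_uM", float), ("absorbance", float)):
        values = []
        for row, raw in enumerate(df[col], start=2):  # header is line 1
            try:
                values.append(kind(raw))
            except (TypeError, ValueError) as err:
                raise CSVFormatError(
                    f"line {row}, column {col!r}: cannot parse {raw!r} as {kind.__name__}"
                ) from err
        out[col] = values
    out["metal_total"] = out.pop("cu_total_uM") * 1e-6
    out = out[["series_id", "replicate", "metal_total", "absorbance"]]
    try:
        return Isotherm(out)
    except ValueError as err:
        raise CSVFormatError(f"invalid titration data: {err}") from err


def isotherm_to_csv_text(isotherm: Isotherm) -> str:
    buf = io.StringIO()
    write_titration_csv(isotherm, buf)
    return buf.getvalue()
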