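"""Formation-constant estimation from competition isotherms.

The unknown constant is fitted on the log10 scale (constants of interest span
~10^14-10^20) by minimising the unweighted residual sum of squares between
observed absorbances and isotherms simulated with the full speciation model,
using bounded Brent minimisation -- the objective is smooth and unimodal in
log10 K, and a bounded search needs no starting guess. Probe constants and
optics are held fixed and known.

Uncertainty comes from a seeded residual bootstrap (small n, nonlinear model;
asymptotic covariance would not be trustworthy). The discrimination envelope
re-evaluates the RSS with the constant displaced 10x tighter and 10x weaker,
the classic visual check that competition data actually constrain the
affinity.

Identifiability: competition only informs the constant while the competitor's
effective affinity (K * total^n) is comparable to the probe's at the bench
concentrations. A fitted constant far *below* that window leaves no signature
in the data at all -- the result is flagged non-converged with an
upper-bound-only warning. Far *above* the window, the stoichiometric
displacement persists and residual information survives in the low-signal
region (noise on absorbance is typically signal-proportional), so the result
carries an advisory warning but is not rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np
from scipy.optimize import minimize_scalar

from .errors import FitError
from .speciation import BindingModel, SolutionComposition, solve_speciation
from .titration import Isotherm, OpticalModel

__all__ = [
    "FitResult",
    "fit_affinity",
    "discrimination_envelope",
    "fit_binding_1to1_depletion",
]

LOG10_BOUNDS = (5.0, 30.0)
#: Effective-affinity ratio beyond which competition data stop constraining K.
DETECTION_WINDOW = 1e3


@dataclass(frozen=True)
class FitResult:
    """Fitted constant (log10 scale) with uncertainty and diagnostics.

    ``envelope``, when populated, is (rss_fit, rss_tighter, rss_weaker) at the
    fitted constant and at constant*factor / constant/factor.
    """

    log10_constant: float
    stderr_log10: float
    rss: float
    n_points: int
    converged: bool
    model: BindingModel
    fixed_models: tuple[BindingModel, ...] = ()
    optics: OpticalModel | None = None
    warnings: tuple[str, ...] = ()
    envelope: tuple[float, float, float] | None = None
    envelope_factor: float | None = None
    bootstrap_seed: int | None = None
    n_bootstrap: int = 0
    baseline: float | None = None
    floor: float | None = None
    ceiling: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def constant(self) -> float:
        return 10.0**self.log10_constant

    def report(self) -> str:
        """Flat key=value text report."""
        lines = [
            f"log10_constant = {self.log10_constant:.6f}",
            f"constant = {self.constant:.6g}",
            f"stderr_log10 = {self.stderr_log10:.4g}",
            f"rss = {self.rss:.6g}",
            f"n_points = {self.n_points}",
            f"converged = {self.converged}",
            f"ligand = {self.model.ligand_name}",
            f"ligands_per_complex = {self.model.ligands_per_complex}",
        ]
        if self.model.ligands_per_complex == 1 and self.constant > 0:
            lines.append(f"kd = {1.0 / self.constant:.6g}")
        if self.baseline is not None:
            lines.append(f"baseline = {self.baseline:.6g}")
        if self.floor is not None:
            lines.append(f"floor = {self.floor:.6g}")
        if self.ceiling is not None:
            lines.append(f"ceiling = {self.ceiling:.6g}")
        if self.envelope is not None:
            at, tighter, weaker = self.envelope
            lines += [
                f"rss_fit = {at:.6g}",
                f"rss_{self.envelope_factor:g}x_tighter = {tighter:.6g}",
                f"rss_{self.envelope_factor:g}x_weaker = {weaker:.6g}",
            ]
        if self.bootstrap_seed is not None:
            lines.append(f"bootstrap_seed = {self.bootstrap_seed}")
        lines.append(f"n_bootstrap = {self.n_bootstrap}")
        for w in self.warnings:
            lines.append(f"warning = {w}")
        return "\n".join(lines) + "\n"


def _predicted(
    log10_k: float,
    metal_totals: np.ndarray,
    comp: SolutionComposition,
    unknown: BindingModel,
    fixed_models: Sequence[BindingModel],
    optics: OpticalModel,
) -> np.ndarray:
    """Simulated absorbance at each observed metal total (solved once per unique value)."""
    trial = replace(unknown, formation_constant=10.0**log10_k)
    models = [trial, *fixed_models]
    uniq, inverse = np.unique(metal_totals, return_inverse=True)
    probe = optics.probe_ligand
    pred = np.empty_like(uniq)
    for i, mt in enumerate(uniq):
        spec = solve_speciation(comp.with_metal_total(mt), models)
        pred[i] = optics.absorbance(spec.complexes[probe])
    return pred[inverse]


def replicate_sd_weights(metal_totals: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """1/SD weights from the replicate spread at each metal total.

    SDs are floored at 10% of the median positive SD so that noise-free
    points (e.g. the zero-metal baseline) do not get infinite weight.
    """
    uniq, inverse = np.unique(metal_totals, return_inverse=True)
    sds = np.array([np.std(obs[inverse == i], ddof=1) if (inverse == i).sum() > 1 else np.nan
                    for i in range(uniq.size)])
    if np.isnan(sds).all():
        raise ValueError("replicate-SD weighting needs replicated metal totals")
    positive = sds[np.isfinite(sds) & (sds > 0)]
    floor = 0.1 * float(np.median(positive)) if positive.size else 1.0
    sds = np.where(np.isfinite(sds), np.maximum(sds, floor), np.nanmedian(sds))
    return 1.0 / sds[inverse]


def _fit_once(
    obs: np.ndarray,
    metal_totals: np.ndarray,
    comp: SolutionComposition,
    unknown: BindingModel,
    fixed_models: Sequence[BindingModel],
    optics: OpticalModel,
    fit_baseline: bool,
    bounds: tuple[float, float],
    weights: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray]:
    """Returns (log10_k, baseline, residuals) minimising the (weighted) RSS."""
    w = np.ones_like(obs) if weights is None else weights

    def residuals(log10_k: float) -> tuple[np.ndarray, float]:
        pred = _predicted(log10_k, metal_totals, comp, unknown, fixed_models, optics)
        base = float(np.sum(w * w * (obs - pred)) / np.sum(w * w)) if fit_baseline else 0.0
        return obs - pred - base, base

    def rss(log10_k: float) -> float:
        r, _ = residuals(log10_k)
        rw = w * r
        return float(rw @ rw)

    res = minimize_scalar(rss, bounds=bounds, method="bounded", options={"xatol": 1e-7})
    if not res.success:
        raise FitError(f"bounded minimisation failed: {res.message}")
    r, base = residuals(res.x)
    return float(res.x), base, r


def fit_affinity(
    data: Isotherm,
    unknown: BindingModel,
    fixed_models: Sequence[BindingModel],
    optics: OpticalModel,
    *,
    fit_baseline: bool = False,
    n_bootstrap: int = 200,
    seed: int = 0,
    bounds_log10: tuple[float, float] = LOG10_BOUNDS,
    weight_by_replicate_sd: bool = False,
) -> FitResult:
    """Estimate the competitor's formation constant from a competition isotherm.

    ``data`` must carry a composition template (totals of probe and
    competitor); the metal total is taken from each observed point. The
    ``unknown`` model's constant acts only as a stoichiometry/name template.
    ``fit_baseline`` adds a free additive baseline (closed form given K).
    ``n_bootstrap`` residual resamples give ``stderr_log10``; 0 disables.
    ``weight_by_replicate_sd`` switches from unweighted least squares (the
    default; bench data rarely carry an error model) to 1/SD weights from the
    replicate spread at each metal total.
    """
    comp = data.composition
    if comp is None:
        raise ValueError("isotherm carries no composition template")
    metal_totals = data.data["metal_total"].to_numpy(float)
    obs = data.data["absorbance"].to_numpy(float)
    if np.unique(metal_totals).size < 6:
        raise ValueError("need at least 6 distinct metal totals to fit an affinity")
    weights = replicate_sd_weights(metal_totals, obs) if weight_by_replicate_sd else None

    log10_k, baseline, resid = _fit_once(
        obs, metal_totals, comp, unknown, fixed_models, optics, fit_baseline, bounds_log10,
        weights,
    )
    rss = float(resid @ resid)

    warnings: list[str] = []
    converged = True
    if min(log10_k - bounds_log10[0], bounds_log10[1] - log10_k) < 0.05:
        converged = False
        warnings.append(
            f"fitted constant at the search bound ({log10_k:.2f} in {bounds_log10}); "
            "the data do not determine it"
        )

    # Detection window: compare effective affinities at the analytical totals.
    try:
        probe_model = next(m for m in fixed_models if m.ligand_name == optics.probe_ligand)
    except StopIteration:
        raise ValueError(f"no fixed model for probe ligand {optics.probe_ligand!r}") from None
    if unknown.ligand_name not in comp.ligand_totals:
        raise ValueError(f"composition lacks the unknown ligand {unknown.ligand_name!r}")
    probe_total = comp.ligand_totals[optics.probe_ligand]
    comp_total = comp.ligand_totals[unknown.ligand_name]
    eff_probe = probe_model.formation_constant * probe_total**probe_model.ligands_per_complex
    eff_comp = 10.0**log10_k * comp_total**unknown.ligands_per_complex
    if eff_probe > 0 and comp_total > 0:
        ratio = eff_comp / eff_probe
        if ratio < 1.0 / DETECTION_WINDOW:
            converged = False
            warnings.append(
                f"competitor affinity is >{DETECTION_WINDOW:g}x below the probe's "
                f"detection window (effective ratio {ratio:.2g}); no competition "
                "signature -- treat the estimate as an upper bound only"
            )
        elif ratio > DETECTION_WINDOW:
            warnings.append(
                f"competitor affinity is >{DETECTION_WINDOW:g}x above the probe's "
                f"detection window (effective ratio {ratio:.2g}); the estimate rests "
                "on the low-signal region -- treat as a lower bound unless noise is "
                "signal-proportional"
            )

    stderr = float("nan")
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted_curve = obs - resid
        estimates = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            resampled = fitted_curve + rng.choice(resid, size=resid.size, replace=True)
            estimates[b], _, _ = _fit_once(
                resampled, metal_totals, comp, unknown, fixed_models, optics,
                fit_baseline, bounds_log10, weights,
            )
        stderr = float(np.std(estimates, ddof=1))

    return FitResult(
        log10_constant=log10_k,
        stderr_log10=stderr,
        rss=rss,
        n_points=int(obs.size),
        converged=converged,
        model=replace(unknown, formation_constant=10.0**log10_k),
        fixed_models=tuple(fixed_models),
        optics=optics,
        warnings=tuple(warnings),
        bootstrap_seed=seed if n_bootstrap > 0 else None,
        n_bootstrap=n_bootstrap,
        baseline=baseline if fit_baseline else None,
    )


def discrimination_envelope(fit: FitResult, data: Isotherm, factor: float = 10.0) -> FitResult:
    """RSS at the fitted constant vs. ``factor``x tighter and weaker.

    On data generated by the model, the fitted RSS is the smallest of the
    three; a shallow envelope means the data do not discriminate affinities.
    """
    if not factor >= 1.0:
        raise ValueError(f"envelope factor must be >= 1, got {factor}")
    if not fit.converged:
        raise FitError("cannot compute a discrimination envelope for a non-converged fit")
    if fit.optics is None or data.composition is None:
        raise ValueError("fit/data lack the optics or composition context")
    metal_totals = data.data["metal_total"].to_numpy(float)
    obs = data.data["absorbance"].to_numpy(float)
    base = fit.baseline or 0.0

    def rss_at(log10_k: float) -> float:
        pred = _predicted(
            log10_k, metal_totals, data.composition, fit.model, fit.fixed_models, fit.optics
        )
        r = obs - pred - base
        return float(r @ r)

    shift = math.log10(factor)
    envelope = (
        rss_at(fit.log10_constant),
        rss_at(fit.log10_constant + shift),
        rss_at(fit.log10_constant - shift),
    )
    return replace(fit, envelope=envelope, envelope_factor=factor)


def fit_binding_1to1_depletion(
    series: Sequence[tuple[float, float]],
    labeled_total: float,
    *,
    noise_tolerance: float = 5.0,
) -> FitResult:
    """1:1 binding fit with ligand depletion (thermophoresis dilution series).

    For labeled partner at total ``T`` (not in vast excess over K_D) and
    titrant total ``L``, the bound fraction follows the exact quadratic
    mass-action law

        bound = (L + T + K_D - sqrt((L + T + K_D)^2 - 4 L T)) / 2,
        response = floor + (ceiling - floor) * bound / T.

    K_D is fitted on the log10 scale together with the response floor and
    ceiling (lmfit least squares). If the titrant saturates the labeled
    partner everywhere, K_D is flagged unidentifiable (ceiling still
    recovered); a response drop between consecutive titrant steps larger than
    ``noise_tolerance`` x RMSE raises a non-monotonicity warning.
    """
    pts = sorted((float(t), float(r)) for t, r in series)
    if len(pts) < 6:
        raise ValueError("need at least 6 dilution points")
    if not labeled_total > 0:
        raise ValueError(f"labeled_total must be > 0, got {labeled_total}")
    titrant = np.array([p[0] for p in pts])
    response = np.array([p[1] for p in pts])
    if (titrant < 0).any():
        raise ValueError("negative titrant concentrations")

    T = labeled_total

    def bound_fraction(L: np.ndarray, kd: float) -> np.ndarray:
        s = L + T + kd
        return (s - np.sqrt(s * s - 4.0 * L * T)) / (2.0 * T)

    def model(params: lmfit.Parameters) -> np.ndarray:
        kd = 10.0 ** params["log10_kd"].value
        floor = params["floor"].value
        ceiling = params["ceiling"].value
        return floor + (ceiling - floor) * bound_fraction(titrant, kd)

    span = float(response.max() - response.min()) or 1.0
    params = lmfit.Parameters()
    positive = titrant[titrant > 0]
    params.add("log10_kd", value=float(np.log10(np.median(positive))), min=-15.0, max=3.0)
    params.add("floor", value=float(response[0]), min=response.min() - span, max=response.max() + span)
    params.add("ceiling", value=float(response[-1]), min=response.min() - span, max=response.max() + span)
    out = lmfit.minimize(lambda p: response - model(p), params, method="leastsq")
    if not out.success:
        raise FitError(f"1:1 depletion fit failed: {out.message}")
    log10_kd = float(out.params["log10_kd"].value)
    floor = float(out.params["floor"].value)
    ceiling = float(out.params["ceiling"].value)
    resid = response - model(out.params)
    rss = float(resid @ resid)
    rmse = math.sqrt(rss / max(1, resid.size - 3))

    warnings: list[str] = []
    converged = True
    # K_D is pinned only if the dilution series brackets half-saturation: when
    # even the smallest positive titrant is predicted above half-bound, the
    # data are a plateau and (K_D, floor) trade off along a flat ridge.
    kd_hat = 10.0**log10_kd
    if positive.size and float(bound_fraction(positive.min(), kd_hat)) > 0.5:
        converged = False
        warnings.append(
            f"titrant saturates the labeled partner over the whole series "
            f"(predicted bound fraction {float(bound_fraction(positive.min(), kd_hat)):.2f} "
            f"at the smallest titrant {positive.min():.2g} M); K_D is "
            "unidentifiable, only the ceiling is determined"
        )
    # Robust noise scale (MAD): a single aberrant dip should not mask itself.
    mad = float(np.median(np.abs(resid - np.median(resid)))) * 1.4826
    drops = np.diff(response)
    if (drops < -noise_tolerance * max(mad, 1e-12)).any():
        warnings.append(
            "response is non-monotone in the titrant beyond noise tolerance; "
            "check for aggregation or pipetting errors"
        )

    stderr = out.params["log10_kd"].stderr
    return FitResult(
        log10_constant=-log10_kd,  # association constant K_A = 1/K_D
        stderr_log10=float(stderr) if stderr is not None else float("nan"),
        rss=rss,
        n_points=int(response.size),
        converged=converged,
        model=BindingModel("labeled_partner_titrant", 1, 10.0**-log10_kd),
        warnings=tuple(warnings),
        floor=floor,
        ceiling=ceiling,
        extra={"kd": 10.0**log10_kd, "rmse": rmse},
    )
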