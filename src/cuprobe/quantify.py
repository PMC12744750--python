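"""Peptide quantification utilities: extinction coefficients and A280 conversion."""

from __future__ import annotations

from . import constants

__all__ = ["extinction_coefficient_280", "concentration_from_a280"]


def extinction_coefficient_280(n_tyr: int, n_trp: int, n_cystine: int = 0) -> float:
    """Sequence-based molar extinction coefficient at 280 nm (M^-1 cm^-1).

    Pace/Edelhoch residue contributions: 1490 per tyrosine, 5500 per
    tryptophan, 125 per cystine (disulfide); the reduced-cysteine convention
    is ``n_cystine = 0``. For the 36-residue POLARIS peptide (2 Tyr, no Trp,
    cysteines reduced) this gives 2980 M^-1 cm^-1.
    """
    counts = {"n_tyr": n_tyr, "n_trp": n_trp, "n_cystine": n_cystine}
    for label, n in counts.items():
        if n < 0 or n != int(n):
            raise ValueError(f"{label} must be a non-negative integer, got {n}")
    return (
        constants.EPSILON_280_TYR * n_tyr
        + constants.EPSILON_280_TRP * n_trp
        + constants.EPSILON_280_CYSTINE * n_cystine
    )


def concentration_from_a280(
    absorbance: float,
    epsilon: float,
    path_length_cm: float = 1.0,
    calibration_factor: float = 1.0,
) -> float:
    """Molar concentration from A280 via Beer-Lambert, with optional calibration.

    ``calibration_factor`` rescales the Beer-Lambert estimate when an
    orthogonal assay (e.g. quantitative amino-acid analysis) shows the
    sequence-based extinction coefficient misstates the true one -- synthetic
    PLS required a factor of 2.27.
    """
    if absorbance < 0:
        raise ValueError(f"absorbance must be >= 0, got {absorbance}")
    if not epsilon > 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if not path_length_cm > 0:
        raise ValueError(f"path length must be > 0, got {path_length_cm}")
    if not calibration_factor > 0:
        raise ValueError(f"calibration factor must be > 0, got {calibration_factor}")
    return calibration_factor * absorbance / (epsilon * path_length_cm)
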