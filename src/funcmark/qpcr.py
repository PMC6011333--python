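"""qPCR standard curves, amplification efficiency and copy-number conversion.

A standard curve regresses the quantification cycle Ct on log10 of template
concentration over a dilution series.  The slope gives the amplification
efficiency

    E = 10^(-1/slope) - 1,

so perfect per-cycle doubling corresponds to slope −1/log10(2) ≈ −3.3219 and
E = 100%; slopes of −3.0 and −3.9 bracket the commonly accepted 80–115%
window.  Template mass converts to gene copies through

    copies = mass(g) · N_A / (template_bp · 660 g/mol),

with 660 g/mol the average molar mass of a DNA base pair.  Unknown samples
are quantified by inverting the curve and flagged as below the quantification
limit when their Ct exceeds that of the most dilute standard.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

AVOGADRO = 6.02214076e23  # molecules / mol
BP_MOLAR_MASS = 660.0  # g / mol per base pair


@dataclass(frozen=True)
class CurvePoint:
    """One standard: template concentration (g/μL) and its measured Ct."""

    conc_g_per_ul: float
    ct: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.conc_g_per_ul <= 0:
            raise ValueError("concentration must be positive")
        if self.ct <= 0:
            raise ValueError("Ct must be positive")


@dataclass(frozen=True)
class StandardCurve:
    slope: float  #: cycles per log10(concentration)
    intercept: float  #: cycles
    r2: float
    mse: float  #: residual mean square about the line (divisor n−2)
    efficiency: float | None  #: fractional efficiency, None if slope >= 0
    conc_min: float  #: most dilute standard fitted
    conc_max: float
    ct_limit: float  #: mean Ct of the most dilute standard (quantification limit)

    @property
    def efficiency_percent(self) -> float | None:
        return None if self.efficiency is None else 100.0 * self.efficiency

    @property
    def valid(self) -> bool:
        return self.slope < 0


@dataclass(frozen=True)
class QuantResult:
    copies_per_reaction: float
    copies_per_g: float
    below_limit: bool
    conc_g_per_ul: float


def fit_standard_curve(
    points: Sequence[CurvePoint], per_replicate: bool = False
) -> StandardCurve:
    """Ordinary least squares of Ct on log10(concentration).

    By default replicates are averaged per concentration before fitting (the
    usual instrument convention); ``per_replicate=True`` fits all points for
    sensitivity analysis.  Requires at least 3 distinct concentrations.
    """
    if not points:
        raise ValueError("no standard points")
    by_conc: dict[float, list[float]] = {}
    for p in points:
        by_conc.setdefault(p.conc_g_per_ul, []).append(p.ct)
    if len(by_conc) < 3:
        raise ValueError(
            f"need >= 3 distinct concentrations, got {len(by_conc)}"
        )
    if per_replicate:
        x = np.array([math.log10(p.conc_g_per_ul) for p in points])
        y = np.array([p.ct for p in points])
    else:
        concs = sorted(by_conc)
        x = np.log10(concs)
        y = np.array([float(np.mean(by_conc[c])) for c in concs])

    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    mse = float(resid @ resid / (len(x) - 2))
    if fit.slope >= 0:
        warnings.warn("non-negative slope: efficiency undefined", stacklevel=2)
        eff = None
    else:
        eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    lowest = min(by_conc)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        mse=mse,
        efficiency=eff,
        conc_min=lowest,
        conc_max=max(by_conc),
        ct_limit=float(np.mean(by_conc[lowest])),
    )


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency, 100·(10^(−1/slope) − 1)."""
    if slope == 0:
        raise ValueError("slope must be non-zero")
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def copies_from_mass(mass_g: float, template_bp: int) -> tuple[float, int]:
    """Gene copies in a DNA mass: mass·N_A/(template_bp·660).

    Returns the real-valued count and its nearest-integer rounding (the form
    quoted for detection limits).
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    if template_bp <= 0:
        raise ValueError("template_bp must be positive")
    copies = mass_g * AVOGADRO / (template_bp * BP_MOLAR_MASS)
    return copies, round(copies)


def quantify_sample(
    ct: float,
    curve: StandardCurve,
    template_bp: int,
    reaction_fraction: float = 1.0,
    soil_g: float = 1.0,
) -> QuantResult:
    """Convert a sample Ct to copy numbers through a standard curve.

    ``reaction_fraction`` is the fraction of the nucleic-acid extract loaded
    into the reaction (e.g. 2 μL of a 100 μL extract = 0.02); ``soil_g`` the
    grams of soil the extract came from.  Concentration is reported on the
    same per-μL scale as the standards; copies are computed from it via the
    mass-to-copies formula.  ``below_limit`` flags Ct values beyond the most
    dilute standard (not quantifiable rather than zero).
    """
    if not curve.valid:
        raise ValueError("standard curve has non-negative slope")
    if not (0 < reaction_fraction <= 1):
        raise ValueError("reaction_fraction must be in (0, 1]")
    if soil_g <= 0:
        raise ValueError("soil_g must be positive")
    conc = 10.0 ** ((ct - curve.intercept) / curve.slope)
    copies, _ = copies_from_mass(conc, template_bp)
    per_g = copies / reaction_fraction / soil_g
    return QuantResult(
        copies_per_reaction=copies,
        copies_per_g=per_g,
        below_limit=ct > curve.ct_limit,
        conc_g_per_ul=conc,
    )
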