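"""Electrochemical verification mathematics.

Post-processing of equivalent-circuit EIS parameters and potentiodynamic
polarization data into inhibition efficiencies, plus Langmuir adsorption
thermodynamics:

* polarization resistance  Rp = Rct + RF
* EIS efficiency           IE% = 100 (1 - Rp_blank / Rp_inh)
* Tafel efficiency         IE% = 100 (1 - i_corr / i_corr_blank)
* CPE impedance            Z = Y0^-1 (j w)^-n  and the capacitance
  conversions Cdl = Y0^(1/n) (Rs^-1 + Rct^-1)^((n-1)/n), CF = Y0 w'^(n-1)
* surface coverage         theta = IE% / 100
* Langmuir isotherm        C/theta = 1/k_ads + C, fitted by OLS of C/theta
  on C; k_ads = 1/intercept
* adsorption free energy   dG_ads = -R T ln(55.5 k_ads), in kJ/mol, where
  55.5 mol/L is the molar concentration of water.  |dG| < 20 kJ/mol
  indicates physisorption, 20-40 a combined mechanism, > 40 chemisorption.

Raw-spectrum circuit fitting and Tafel-slope extraction are out of scope;
inputs are the already-fitted circuit/polarization parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

__all__ = [
    "GAS_CONSTANT",
    "WATER_MOLARITY",
    "LIDOCAINE_MOLAR_MASS",
    "EISRecord",
    "PolarizationRecord",
    "LangmuirResult",
    "polarization_resistance",
    "eis_efficiency",
    "tafel_efficiency",
    "cpe_impedance",
    "double_layer_capacitance",
    "film_capacitance",
    "coverage",
    "ppm_to_molar",
    "langmuir_fit",
    "classify_adsorption",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
WATER_MOLARITY = 55.5  # mol / L
#: Molar mass of lidocaine (g/mol), the experimentally verified inhibitor.
LIDOCAINE_MOLAR_MASS = 234.34
#: Default "room temperature" for adsorption thermodynamics (K).
DEFAULT_TEMPERATURE = 293.15


@dataclass(frozen=True)
class EISRecord:
    """Fitted equivalent-circuit parameters at one inhibitor concentration."""

    conc: float  # ppm
    rs: float  # ohm cm^2
    n_cpe: float
    cdl: float  # uF / cm^2
    rct: float  # ohm cm^2
    cf: Optional[float] = None  # uF / cm^2
    n2: Optional[float] = None
    rmol: Optional[float] = None  # ohm cm^2
    rtotal: Optional[float] = None  # ohm cm^2

    def __post_init__(self) -> None:
        for attr in ("rs", "rct", "rmol", "rtotal"):
            val = getattr(self, attr)
            if val is not None and val < 0:
                raise ValueError(f"{attr} must be non-negative, got {val}")
        if not -1.0 <= self.n_cpe <= 1.0:
            raise ValueError(f"CPE exponent must lie in [-1, 1], got {self.n_cpe}")
        if self.rtotal is not None and self.rmol is not None:
            if abs(self.rtotal - (self.rct + self.rmol)) > 0.01:
                raise ValueError(
                    f"rtotal ({self.rtotal}) inconsistent with rct + rmol "
                    f"({self.rct + self.rmol}) at {self.conc} ppm"
                )


@dataclass(frozen=True)
class PolarizationRecord:
    """Tafel-analysis parameters at one inhibitor concentration."""

    conc: float  # ppm
    ecorr: float  # mV vs Ag/AgCl
    icorr: float  # uA / cm^2
    ba: float  # mV / decade
    bc: float  # mV / decade (cathodic slope magnitude)

    def __post_init__(self) -> None:
        if not self.icorr > 0:
            raise ValueError(f"corrosion current must be positive, got {self.icorr}")


@dataclass(frozen=True)
class LangmuirResult:
    """Langmuir isotherm fit with adsorption thermodynamics.

    ``slope`` is dimensionless (ideally 1); ``intercept`` carries the
    concentration units (1/k_ads); ``k_ads`` and ``dg_ads`` are only
    meaningful when concentrations were supplied in mol/L.  ``k_ads``,
    ``dg_ads``, and ``mechanism`` are None when the fitted intercept is
    non-positive.
    """

    slope: float
    intercept: float
    r2: float
    k_ads: Optional[float]  # L / mol
    dg_ads: Optional[float]  # kJ / mol
    mechanism: Optional[str]
    temperature: float  # K


def polarization_resistance(rct: float, rf: float = 0.0) -> float:
    """Total polarization resistance Rp = Rct + RF (ohm cm^2)."""
    if rct < 0 or rf < 0:
        raise ValueError(f"resistances must be non-negative, got rct={rct}, rf={rf}")
    return rct + rf


def eis_efficiency(rp_blank: float, rp_inh: float) -> float:
    """Inhibition efficiency from polarization resistances.

    IE% = 100 (Rp_blank^-1 - Rp_inh^-1) / Rp_blank^-1 = 100 (1 - Rp_blank/Rp_inh).
    """
    if rp_blank <= 0 or rp_inh <= 0:
        raise ZeroDivisionError(
            f"polarization resistances must be positive, got blank={rp_blank}, inhibited={rp_inh}"
        )
    return 100.0 * (1.0 - rp_blank / rp_inh)


def tafel_efficiency(icorr_blank: float, icorr: float) -> float:
    """Inhibition efficiency from corrosion current densities.

    IE% = 100 (1 - i_corr / i_corr_blank).
    """
    if icorr_blank <= 0:
        raise ZeroDivisionError(f"blank corrosion current must be positive, got {icorr_blank}")
    return 100.0 * (1.0 - icorr / icorr_blank)


def cpe_impedance(y0: float, n: float, ang_freq: float) -> complex:
    """Constant-phase-element impedance Z = Y0^-1 (j w)^-n.

    Limits: n=0 a pure resistance 1/Y0, n=1 a capacitance 1/(j w Y0),
    n=0.5 a Warburg element (phase -45 degrees), n=-1 an inductance.
    """
    if y0 <= 0:
        raise ValueError(f"CPE constant must be positive, got {y0}")
    if ang_freq <= 0:
        raise ValueError(f"angular frequency must be positive, got {ang_freq}")
    return (1.0 / y0) * (1j * ang_freq) ** (-n)


def double_layer_capacitance(y0: float, n: float, rs: float, rct: float) -> float:
    """Double-layer capacitance from CPE parameters.

    Cdl = Y0^(1/n) (Rs^-1 + Rct^-1)^((n-1)/n); reduces to Y0 at n=1.
    """
    if y0 <= 0:
        raise ValueError(f"CPE constant must be positive, got {y0}")
    if not 0 < n <= 1:
        raise ValueError(f"CPE exponent must lie in (0, 1], got {n}")
    if rs <= 0 or rct <= 0:
        raise ValueError(f"resistances must be positive, got rs={rs}, rct={rct}")
    return y0 ** (1.0 / n) * (1.0 / rs + 1.0 / rct) ** ((n - 1.0) / n)


def film_capacitance(y0: float, n: float, ang_freq_at_max_zreal: float) -> float:
    """Film capacitance CF = Y0 w'^(n-1), w' the frequency of maximal Z_real."""
    if y0 <= 0:
        raise ValueError(f"CPE constant must be positive, got {y0}")
    if ang_freq_at_max_zreal <= 0:
        raise ValueError(f"angular frequency must be positive, got {ang_freq_at_max_zreal}")
    return y0 * ang_freq_at_max_zreal ** (n - 1.0)


def coverage(ie: float) -> float:
    """Surface coverage theta = IE% / 100."""
    return ie / 100.0


def ppm_to_molar(conc_ppm: float, molar_mass: float) -> float:
    """Convert a dilute aqueous concentration from ppm (mg/L) to mol/L."""
    if molar_mass <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass}")
    return conc_ppm * 1e-3 / molar_mass


def classify_adsorption(dg_ads: float) -> str:
    """Adsorption mechanism from the magnitude of dG_ads (kJ/mol).

    |dG| < 20: physisorption; 20 <= |dG| <= 40: combined; |dG| > 40:
    chemisorption.  Boundary values are assigned to the combined class.
    """
    if not np.isfinite(dg_ads):
        raise ValueError(f"dg_ads must be finite, got {dg_ads}")
    mag = abs(dg_ads)
    if mag < 20.0:
        return "physisorption"
    if mag <= 40.0:
        return "combined"
    return "chemisorption"


def langmuir_fit(
    conc: Sequence[float],
    theta: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE,
) -> LangmuirResult:
    """Fit the linearized Langmuir isotherm C/theta = 1/k_ads + C.

    Ordinary least squares of ``C/theta`` on ``C`` (>= 3 points).  The
    slope and R-squared are invariant to a uniform rescaling of the
    concentration units; the intercept, ``k_ads = 1/intercept``, and the
    adsorption free energy ``dG = -R T ln(55.5 k_ads)`` (kJ/mol) assume
    concentrations in mol/L.  A non-positive fitted intercept leaves
    ``k_ads``/``dg_ads``/``mechanism`` as None.
    """
    c = np.asarray(conc, dtype=float)
    th = np.asarray(theta, dtype=float)
    if c.shape != th.shape or c.ndim != 1:
        raise ValueError("conc and theta must be 1-D sequences of equal length")
    if c.size < 3:
        raise ValueError(f"Langmuir fit requires at least 3 points, got {c.size}")
    if np.any(c <= 0):
        raise ValueError("all concentrations must be positive")
    if np.any((th <= 0) | (th > 1)):
        raise ValueError("all coverages must lie in (0, 1]")

    fit = scipy.stats.linregress(c, c / th)
    slope = float(fit.slope)
    intercept = float(fit.intercept)
    r2 = float(fit.rvalue**2)

    if intercept > 0:
        k_ads = 1.0 / intercept
        dg_ads = -GAS_CONSTANT * temperature * np.log(WATER_MOLARITY * k_ads) / 1000.0
        mechanism = classify_adsorption(dg_ads)
    else:
        k_ads = dg_ads = mechanism = None
    return LangmuirResult(
        slope=slope,
        intercept=intercept,
        r2=r2,
        k_ads=k_ads,
        dg_ads=dg_ads,
        mechanism=mechanism,
        temperature=temperature,
    )
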