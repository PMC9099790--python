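"""HSAB (hard-soft acid-base) reactivity descriptors from frontier-orbital energies.

Conceptual-DFT descriptors are the quantum-chemical half of the descriptor
vector used to model corrosion-inhibition efficiency.  Starting from the HOMO
and LUMO energies of an inhibitor molecule (in eV), Koopmans' theorem gives
the vertical ionization energy ``I = -E_HOMO`` and electron affinity
``A = -E_LUMO``, from which follow

* absolute electronegativity  ``chi = (I + A) / 2``,
* global hardness             ``eta = (I - A) / 2``,
* chemical potential          ``mu  = -chi``,
* global electrophilicity     ``omega = mu**2 / (2 * eta)``,
* fraction of electrons transferred to the metal surface
  ``delta_n = (chi_metal - chi_inh) / (2 * (eta_metal + eta_inh))``.

The metal reference defaults to the bulk-iron values conventional in the
corrosion-inhibition literature, ``chi = 7.0 eV`` and ``eta = 0.0 eV``
(a perfect electron sink).

Electrophilicity modes
----------------------
Two conventions for ``omega`` are exposed:

``standard``
    The textbook definition ``omega = chi**2 / (2 * eta)``.
``table_compatible``
    The empirical relation ``omega = chi / 4``.  Published descriptor tables
    for this model family tabulate electrophilicity values that obey
    ``chi / 4`` exactly rather than the textbook formula (for dipyridamole
    the textbook value is 3.79 eV against a tabulated 0.77 eV).  This mode
    exists to reproduce those tables and to feed the frozen published
    regression model, whose electrophilicity coefficient was fitted against
    values on this scale.  Use ``standard`` for any new analysis.

All energies are in eV throughout; no unit conversion is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "CompoundRecord",
    "HSABDescriptors",
    "MetalReference",
    "IRON_REFERENCE",
    "koopmans",
    "global_reactivity",
    "electrophilicity",
    "fraction_electrons_transferred",
    "compute_descriptors",
]

OMEGA_MODES = ("standard", "table_compatible")


@dataclass(frozen=True)
class MetalReference:
    """Electronegativity and hardness of the metal surface (eV)."""

    chi: float = 7.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if not self.chi > 0:
            raise ValueError(f"metal electronegativity must be positive, got {self.chi}")
        if self.eta < 0:
            raise ValueError(f"metal hardness must be non-negative, got {self.eta}")


#: Bulk iron, the default electron acceptor for steel-surface inhibition.
IRON_REFERENCE = MetalReference(chi=7.0, eta=0.0)


@dataclass(frozen=True)
class CompoundRecord:
    """One drug molecule: physicochemical + frontier-orbital descriptors.

    Parameters
    ----------
    name : str
        Compound identifier.
    mw : float
        Molecular weight, Da.  Must be positive.
    pka : float
        Acid dissociation constant, -log10 Ka.
    logp, logs : float
        Octanol-water partition and aqueous solubility coefficients.
    psa : float
        Polar surface area, square Angstrom.
    alpha : float
        Polarizability, cubic Angstrom.
    e_homo, e_lumo : float
        Frontier-orbital energies, eV; ``e_homo <= e_lumo`` is required.
    ie_obs : float, optional
        Experimental inhibition efficiency, percent in [0, 100].
    omega, delta_n : float, optional
        Pre-tabulated electrophilicity / fraction of electrons transferred.
        When absent they are derived from the orbital energies; synthetic
        benchmark tables carry independently drawn values here.
    """

    name: str
    mw: float
    pka: float
    logp: float
    logs: float
    psa: float
    alpha: float
    e_homo: float
    e_lumo: float
    ie_obs: Optional[float] = None
    omega: Optional[float] = None
    delta_n: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"{self.name}: molecular weight must be positive, got {self.mw}")
        if self.e_homo > self.e_lumo:
            raise ValueError(
                f"{self.name}: e_homo ({self.e_homo}) must not exceed e_lumo ({self.e_lumo})"
            )
        if self.ie_obs is not None and not 0.0 <= self.ie_obs <= 100.0:
            raise ValueError(f"{self.name}: observed IE% must lie in [0, 100], got {self.ie_obs}")

    def with_ie(self, ie_obs: float) -> "CompoundRecord":
        return replace(self, ie_obs=ie_obs)


@dataclass(frozen=True)
class HSABDescriptors:
    """Derived reactivity quantities for one compound (all energies in eV)."""

    ionization: float
    affinity: float
    chi: float
    eta: float
    mu: float
    omega: float
    delta_n: float


def koopmans(e_homo: float, e_lumo: float) -> tuple[float, float]:
    """Ionization energy and electron affinity via Koopmans' theorem.

    Returns ``(I, A) = (-e_homo, -e_lumo)``.  Raises ``ValueError`` when
    ``e_homo > e_lumo`` (which would imply negative hardness).
    """
    if e_homo > e_lumo:
        raise ValueError(f"invalid orbital ordering: e_homo ({e_homo}) > e_lumo ({e_lumo})")
    return -e_homo, -e_lumo


def global_reactivity(ionization: float, affinity: float) -> tuple[float, float, float]:
    """Electronegativity, hardness, and chemical potential from (I, A).

    chi = (I + A)/2, eta = (I - A)/2, mu = -chi.
    """
    if ionization < affinity:
        raise ValueError(
            f"negative hardness: ionization ({ionization}) < affinity ({affinity})"
        )
    chi = 0.5 * (ionization + affinity)
    eta = 0.5 * (ionization - affinity)
    return chi, eta, -chi


def electrophilicity(chi: float, eta: float, mode: str = "standard") -> float:
    """Global electrophilicity omega (eV).

    ``standard`` evaluates chi**2 / (2 eta) and requires ``eta > 0``;
    ``table_compatible`` evaluates chi / 4 (see module docstring).
    """
    if mode == "standard":
        if eta == 0:
            raise ZeroDivisionError("electrophilicity undefined for zero hardness (standard mode)")
        return chi * chi / (2.0 * eta)
    if mode == "table_compatible":
        return chi / 4.0
    raise ValueError(f"unknown electrophilicity mode {mode!r}; expected one of {OMEGA_MODES}")


def fraction_electrons_transferred(
    chi_inh: float, eta_inh: float, metal: MetalReference = IRON_REFERENCE
) -> float:
    """Fraction of electrons transferred from inhibitor to metal surface.

    delta_n = (chi_metal - chi_inh) / (2 (eta_metal + eta_inh)).  A larger
    value indicates a stronger electron-donating inhibitor and, empirically,
    higher inhibition efficiency.
    """
    denom = metal.eta + eta_inh
    if denom == 0:
        raise ZeroDivisionError("fraction of electrons transferred undefined: both hardnesses are zero")
    return (metal.chi - chi_inh) / (2.0 * denom)


def compute_descriptors(
    record: CompoundRecord,
    metal: MetalReference = IRON_REFERENCE,
    mode: str = "standard",
) -> HSABDescriptors:
    """Full HSAB descriptor set for one compound.

    Composes :func:`koopmans`, :func:`global_reactivity`,
    :func:`electrophilicity`, and :func:`fraction_electrons_transferred`.
    Errors from the component operations propagate unchanged.
    """
    ionization, affinity = koopmans(record.e_homo, record.e_lumo)
    chi, eta, mu = global_reactivity(ionization, affinity)
    omega = electrophilicity(chi, eta, mode=mode)
    delta_n = fraction_electrons_transferred(chi, eta, metal=metal)
    assert math.isfinite(delta_n)
    return HSABDescriptors(
        ionization=ionization,
        affinity=affinity,
        chi=chi,
        eta=eta,
        mu=mu,
        omega=omega,
        delta_n=delta_n,
    )
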