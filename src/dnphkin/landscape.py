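"""Transition-state-theory conversions and reaction-coordinate energy landscapes.

Rate constants and activation free energies are interconverted with the
Eyring equation, k = kappa * (kB*T/h) * exp(-dG/RT), with the transmission
(recrossing) coefficient kappa = 1 by default.  The landscape orders the
states of the double-displacement cycle (E+S, ES, the two transition states
and the product complexes) and places each barrier from its macroscopic rate
constant; the bimolecular well depth additionally needs a reference
concentration, since a second-order step has no intrinsic unimolecular free
energy.  Equilibrium binding thermodynamics (dG from KD, TdS = dH - dG)
round out the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .schemes import RateConstantSet

__all__ = [
    "TSTContext",
    "EnergyLandscape",
    "BindingThermo",
    "dG_from_rate",
    "rate_from_dG",
    "ddG_from_fold_change",
    "build_landscape",
    "binding_thermo",
]

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.98720425e-3
#: Boltzmann constant over Planck constant, K^-1 s^-1
KB_OVER_H = 2.08366e10


@dataclass(frozen=True)
class TSTContext:
    """Physical constants and conditions for Eyring conversions."""

    temperature: float = 298.15
    transmission_coefficient: float = 1.0
    gas_constant: float = R_KCAL
    boltzmann_over_planck: float = KB_OVER_H

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if not 0 < self.transmission_coefficient <= 1:
            raise ValueError("transmission_coefficient must lie in (0, 1]")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature

    @property
    def prefactor(self) -> float:
        """kappa * kB*T/h in s^-1."""
        return self.transmission_coefficient * self.boltzmann_over_planck * self.temperature


def dG_from_rate(k: float, ctx: TSTContext = TSTContext()) -> float:
    """Activation free energy (kcal/mol) for a first-order rate constant (s^-1)."""
    if k <= 0 or not math.isfinite(k):
        raise ValueError(f"rate constant must be finite and > 0, got {k}")
    return ctx.rt * math.log(ctx.prefactor / k)


def rate_from_dG(dG: float, ctx: TSTContext = TSTContext()) -> float:
    """Exact inverse of :func:`dG_from_rate`."""
    return ctx.prefactor * math.exp(-dG / ctx.rt)


def ddG_from_fold_change(fold: float, ctx: TSTContext = TSTContext()) -> float:
    """Change in barrier height (kcal/mol) for a fold-change in rate."""
    if fold <= 0 or not math.isfinite(fold):
        raise ValueError(f"fold change must be finite and > 0, got {fold}")
    return ctx.rt * math.log(fold)


@dataclass(frozen=True)
class EnergyLandscape:
    """Ordered reaction-coordinate states with relative free energies.

    ``relative_G`` is referenced to E+S at 0 kcal/mol.  When k5 is absent the
    landscape is truncated after the first half-reaction and ``truncated``
    is set.
    """

    states: tuple[str, ...]
    relative_G: np.ndarray
    reference_concentration: float  # uM, placement of the bimolecular step
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.states) != self.relative_G.size:
            raise ValueError("states and relative_G lengths differ")
        for i, label in enumerate(self.states):
            if label.startswith("TS"):
                if self.relative_G[i] <= self.relative_G[i - 1] or (
                    i + 1 < self.relative_G.size
                    and self.relative_G[i] <= self.relative_G[i + 1]
                ):
                    raise ValueError(
                        f"transition state {label} is not above both adjacent minima"
                    )

    def energy(self, state: str) -> float:
        return float(self.relative_G[self.states.index(state)])

    def barriers(self) -> dict[str, float]:
        """Forward barrier out of each minimum preceding a transition state."""
        out: dict[str, float] = {}
        for i, label in enumerate(self.states):
            if label.startswith("TS"):
                out[f"{label}-{self.states[i-1]}"] = float(
                    self.relative_G[i] - self.relative_G[i - 1]
                )
        return out


def build_landscape(
    rates: RateConstantSet,
    ctx: TSTContext = TSTContext(),
    reference_concentration: float = 10.0,
    *,
    exergonic_drop: float = 2.0,
) -> EnergyLandscape:
    """Assemble the free-energy profile implied by the rate constants.

    The ES well depth is dG_bind = RT ln(KD / C_ref) with KD = k2/k1 and the
    reference concentration C_ref in uM (default 10 uM, the substrate
    concentration of the single-turnover experiments).  Barriers out of ES
    and E-X come from k3 and k5 through the Eyring equation.  The absolute
    depth of the irreversible product wells is not fixed by the data; they
    are drawn ``exergonic_drop`` kcal/mol below the preceding well, which
    affects presentation only, never the barriers.
    """
    if reference_concentration <= 0:
        raise ValueError("reference_concentration must be > 0 uM")
    if rates.k1 <= 0 or rates.k2 <= 0:
        raise ValueError("landscape requires k1 > 0 and k2 > 0")
    g_es = ctx.rt * math.log(rates.kd_app / reference_concentration)
    states: list[str] = ["E+S", "ES"]
    energies: list[float] = [0.0, g_es]
    truncated = True
    if rates.k3 is not None and rates.k3 > 0:
        ts1 = g_es + dG_from_rate(rates.k3, ctx)
        g_exp = g_es - exergonic_drop
        states += ["TS1", "E-X+P"]
        energies += [ts1, g_exp]
        if rates.k5 is not None and rates.k5 > 0:
            ts2 = g_exp + dG_from_rate(rates.k5, ctx)
            states += ["TS2", "E+P+Q"]
            energies += [ts2, g_exp - exergonic_drop]
            truncated = False
    return EnergyLandscape(
        states=tuple(states),
        relative_G=np.asarray(energies, dtype=float),
        reference_concentration=reference_concentration,
        truncated=truncated,
    )


@dataclass(frozen=True)
class BindingThermo:
    """Equilibrium binding thermodynamics at temperature T.

    All energies in kcal/mol; KD in M.  TdS is None when dH is not supplied.
    """

    kd: float
    dG: float
    dH: float | None = None
    TdS: float | None = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("KD must be > 0 M")
        if self.dH is not None and self.TdS is not None:
            if abs(self.dG - (self.dH - self.TdS)) > 1e-9:
                raise ValueError("dG = dH - TdS violated beyond 1e-9 kcal/mol")


def binding_thermo(
    kd: float | None = None,
    dG: float | None = None,
    dH: float | None = None,
    ctx: TSTContext = TSTContext(),
) -> BindingThermo:
    """Complete the binding-thermodynamics triple from KD or dG (plus dH).

    Exactly one of ``kd`` (in M) or ``dG`` (kcal/mol) must be supplied;
    dG = RT ln(KD) against the 1 M standard state.
    """
    if (kd is None) == (dG is None):
        raise ValueError("supply exactly one of kd or dG")
    if kd is not None:
        if kd <= 0:
            raise ValueError("KD must be > 0 M")
        dG = ctx.rt * math.log(kd)
    else:
        kd = math.exp(dG / ctx.rt)
    TdS = (dH - dG) if dH is not None else None
    return BindingThermo(kd=kd, dG=dG, dH=dH, TdS=TdS)
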