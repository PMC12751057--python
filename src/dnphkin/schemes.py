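"""Minimal mass-action kinetic schemes for double-displacement N-hydrolase catalysis.

The mechanism modelled here describes an enzyme (E) that hydrolyses a
nucleotide substrate (S) through a covalent intermediate (E-X, the
deoxyribosylated enzyme), releasing the nucleobase product (P) and the
sugar-phosphate product (Q) in two sequential half-reactions::

    E + S  <=>  ES          k1 (uM^-1 s^-1) forward, k2 (s^-1) reverse
    ES     -->  E-X + P     k3 (s^-1), chemistry + first product release
    E-X    -->  E  + Q      k5 (s^-1), chemistry + second product release

The two chemical steps are macroscopic and treated as irreversible.  Three
scheme variants are supported: binding only (one reversible step), two-step
(binding + first half-reaction; the natural model for single-turnover data
where enzyme is in excess) and three-step (the full catalytic cycle).

Units are fixed internally at uM and s; second-order constants are converted
to M^-1 s^-1 only at reporting boundaries (see :func:`derived_constants`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SchemeVariant",
    "Reaction",
    "KineticScheme",
    "RateConstantSet",
    "ReactionConditions",
    "ConcentrationTimecourse",
    "IntegrationError",
    "build_scheme",
    "simulate_timecourse",
    "derived_constants",
]

#: Largest tolerated undershoot below zero concentration (uM).  Anything more
#: negative indicates integrator failure and raises IntegrationError.
UNDERSHOOT_TOL = 1e-12


class SchemeVariant(str, Enum):
    """The three nested variants of the minimal mechanism."""

    BINDING_ONLY = "binding_only"
    TWO_STEP = "two_step"
    THREE_STEP = "three_step"


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces unphysical output."""


@dataclass(frozen=True)
class Reaction:
    """One elementary (or macroscopic) mass-action step.

    ``reverse_label`` is None for irreversible steps.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_label: str
    reverse_label: str | None = None

    @property
    def reversible(self) -> bool:
        return self.reverse_label is not None


@dataclass(frozen=True)
class KineticScheme:
    """Species and reactions of one mechanism variant.

    Species order is deterministic and fixed by :func:`build_scheme`.
    """

    variant: SchemeVariant
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    @property
    def rate_labels(self) -> tuple[str, ...]:
        labels: list[str] = []
        for rxn in self.reactions:
            labels.append(rxn.rate_label)
            if rxn.reverse_label is not None:
                labels.append(rxn.reverse_label)
        return tuple(labels)


_SCHEMES: dict[SchemeVariant, KineticScheme] = {
    SchemeVariant.BINDING_ONLY: KineticScheme(
        variant=SchemeVariant.BINDING_ONLY,
        species=("E", "S", "ES"),
        reactions=(Reaction(("E", "S"), ("ES",), "k1", "k2"),),
    ),
    SchemeVariant.TWO_STEP: KineticScheme(
        variant=SchemeVariant.TWO_STEP,
        species=("E", "S", "ES", "EX", "P"),
        reactions=(
            Reaction(("E", "S"), ("ES",), "k1", "k2"),
            Reaction(("ES",), ("EX", "P"), "k3"),
        ),
    ),
    SchemeVariant.THREE_STEP: KineticScheme(
        variant=SchemeVariant.THREE_STEP,
        species=("E", "S", "ES", "EX", "P", "Q"),
        reactions=(
            Reaction(("E", "S"), ("ES",), "k1", "k2"),
            Reaction(("ES",), ("EX", "P"), "k3"),
            Reaction(("EX",), ("E", "Q"), "k5"),
        ),
    ),
}


def build_scheme(variant: SchemeVariant | str) -> KineticScheme:
    """Return the kinetic scheme for ``variant``.

    Raises ValueError with an explicit message for unknown variants.
    """
    try:
        variant = SchemeVariant(variant)
    except ValueError:
        valid = ", ".join(v.value for v in SchemeVariant)
        raise ValueError(
            f"unknown scheme variant {variant!r}; expected one of: {valid}"
        ) from None
    return _SCHEMES[variant]


def _check_rate(name: str, value: float | None, required: bool) -> None:
    if value is None:
        if required:
            raise ValueError(f"rate constant {name} is required but absent")
        return
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"rate constant {name}={value} must be finite and >= 0")


@dataclass(frozen=True)
class RateConstantSet:
    """Rate constants of the minimal mechanism.

    k1 is bimolecular (uM^-1 s^-1); k2, k3, k5 are unimolecular (s^-1).
    k3/k5 are macroscopic constants that each lump chemistry with product
    release.  Values must be finite and non-negative; zero is admitted only
    for the no-flux limiting case, and any derived ratio (KD_app, Eyring
    conversion) demands strictly positive inputs.
    """

    k1: float
    k2: float
    k3: float | None = None
    k5: float | None = None

    def __post_init__(self) -> None:
        _check_rate("k1", self.k1, required=True)
        _check_rate("k2", self.k2, required=True)
        _check_rate("k3", self.k3, required=False)
        _check_rate("k5", self.k5, required=False)

    @property
    def kd_app(self) -> float:
        """Apparent dissociation constant k2/k1 in uM."""
        if self.k1 <= 0:
            raise ValueError("KD_app = k2/k1 requires k1 > 0")
        return self.k2 / self.k1

    def require(self, variant: SchemeVariant) -> None:
        """Check that every rate label of ``variant`` is present."""
        if variant in (SchemeVariant.TWO_STEP, SchemeVariant.THREE_STEP):
            if self.k3 is None:
                raise ValueError(f"{variant.value} scheme requires k3")
        if variant is SchemeVariant.THREE_STEP and self.k5 is None:
            raise ValueError("three_step scheme requires k5")

    def as_dict(self) -> dict[str, float]:
        out = {"k1": self.k1, "k2": self.k2}
        if self.k3 is not None:
            out["k3"] = self.k3
        if self.k5 is not None:
            out["k5"] = self.k5
        return out

    def replace(self, **kwargs: float) -> "RateConstantSet":
        merged = {"k1": self.k1, "k2": self.k2, "k3": self.k3, "k5": self.k5}
        merged.update(kwargs)
        return RateConstantSet(**merged)


@dataclass(frozen=True)
class ReactionConditions:
    """Mixing-cell conditions for one experiment.

    active_fraction models half-of-the-sites reactivity: only that fraction
    of the total enzyme participates in binding and turnover.
    """

    enzyme_total: float
    substrate_total: float
    active_fraction: float = 1.0
    temperature: float = 298.15
    path_length: float = 0.5
    dead_time: float = 0.9e-3
    label: str = ""

    def __post_init__(self) -> None:
        if self.enzyme_total < 0 or self.substrate_total < 0:
            raise ValueError("enzyme_total and substrate_total must be >= 0")
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active_fraction must lie in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0 cm")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0 s")

    @property
    def enzyme_active(self) -> float:
        return self.active_fraction * self.enzyme_total


@dataclass(frozen=True)
class ConcentrationTimecourse:
    """Per-species concentrations (uM) on a strictly increasing time grid (s)."""

    scheme: KineticScheme
    conditions: ReactionConditions
    time: np.ndarray
    data: np.ndarray  # shape (n_time, n_species), columns in scheme.species order

    def __post_init__(self) -> None:
        if self.data.shape != (self.time.size, len(self.scheme.species)):
            raise ValueError("data shape inconsistent with time grid and species")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time grid must be strictly increasing")

    def concentration(self, species: str) -> np.ndarray:
        try:
            idx = self.scheme.species.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in scheme") from None
        return self.data[:, idx]

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentration(species)

    def as_frame(self):
        """Return the timecourse as a pandas DataFrame (column time_s first)."""
        import pandas as pd

        frame = pd.DataFrame(self.data, columns=list(self.scheme.species))
        frame.insert(0, "time_s", self.time)
        return frame

    def conservation_residuals(self) -> dict[str, np.ndarray]:
        """Deviation of each conserved sum from its nominal value (uM)."""
        out: dict[str, np.ndarray] = {}
        e_act = self.conditions.enzyme_active
        s0 = self.conditions.substrate_total
        enzyme = self["E"] + self["ES"]
        if "EX" in self.scheme.species:
            enzyme = enzyme + self["EX"]
        out["enzyme"] = enzyme - e_act
        substrate = self["S"] + self["ES"]
        if self.scheme.variant is SchemeVariant.TWO_STEP:
            substrate = substrate + self["EX"]
        elif self.scheme.variant is SchemeVariant.THREE_STEP:
            substrate = substrate + self["EX"] + self["Q"]
        out["substrate"] = substrate - s0
        if self.scheme.variant is SchemeVariant.THREE_STEP:
            out["product_split"] = self["P"] - (self["EX"] + self["Q"])
        return out


def _reduced_rhs(variant: SchemeVariant, rates: RateConstantSet,
                 e0: float, s0: float):
    """Right-hand side in reduced coordinates.

    States are the complexes/products not fixed by conservation:
    binding_only -> [ES]; two_step -> [ES, EX]; three_step -> [ES, EX, Q].
    E, S, P are reconstructed algebraically, so the conservation sums hold to
    machine precision in the output.
    """
    k1, k2 = rates.k1, rates.k2
    if variant is SchemeVariant.BINDING_ONLY:
        def rhs(t, y):
            es = y[0]
            return [k1 * (e0 - es) * (s0 - es) - k2 * es]
        return rhs
    k3 = rates.k3
    if variant is SchemeVariant.TWO_STEP:
        def rhs(t, y):
            es, ex = y
            e = e0 - es - ex
            s = s0 - es - ex
            return [k1 * e * s - (k2 + k3) * es, k3 * es]
        return rhs
    k5 = rates.k5

    def rhs(t, y):
        es, ex, q = y
        e = e0 - es - ex
        s = s0 - es - ex - q
        d_es = k1 * e * s - (k2 + k3) * es
        d_ex = k3 * es - k5 * ex
        d_q = k5 * ex
        return [d_es, d_ex, d_q]

    return rhs


def _assemble(variant: SchemeVariant, reduced: np.ndarray,
              e0: float, s0: float) -> np.ndarray:
    """Map reduced states back to the full species matrix."""
    if variant is SchemeVariant.BINDING_ONLY:
        es = reduced[0]
        return np.column_stack([e0 - es, s0 - es, es])
    if variant is SchemeVariant.TWO_STEP:
        es, ex = reduced
        return np.column_stack([e0 - es - ex, s0 - es - ex, es, ex, ex])
    es, ex, q = reduced
    p = ex + q
    return np.column_stack([e0 - es - ex, s0 - es - ex - q, es, ex, p, q])


def simulate_timecourse(
    scheme: KineticScheme,
    rates: RateConstantSet,
    conditions: ReactionConditions,
    time_grid: Sequence[float] | np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-13,
    method: str = "LSODA",
) -> ConcentrationTimecourse:
    """Numerically integrate the scheme from the standard initial state.

    The initial state at t = 0 is E = active_fraction * enzyme_total,
    S = substrate_total, with all complexes and products at zero.  The
    integration always starts at t = 0 even when the requested grid starts
    later (stopped-flow dead time).

    Raises IntegrationError on solver failure or undershoot below
    -1e-12 uM; concentrations are never clipped.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("time_grid must be a 1-D array with >= 1 points")
    if t[0] < 0:
        raise ValueError("time_grid must start at or after t = 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("time_grid must be strictly increasing")
    rates.require(scheme.variant)

    e0 = conditions.enzyme_active
    s0 = conditions.substrate_total
    n_reduced = {"binding_only": 1, "two_step": 2, "three_step": 3}[scheme.variant.value]
    y0 = np.zeros(n_reduced)

    if t[-1] == 0.0:
        reduced = np.zeros((n_reduced, t.size))
    else:
        sol = solve_ivp(
            _reduced_rhs(scheme.variant, rates, e0, s0),
            (0.0, float(t[-1])),
            y0,
            t_eval=t,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"ODE integration failed: {sol.message}")
        if np.any(~np.isfinite(sol.y)):
            raise IntegrationError("ODE integration produced non-finite values")
        reduced = sol.y

    data = _assemble(scheme.variant, reduced, e0, s0)
    low = data.min()
    if low < -UNDERSHOOT_TOL:
        raise IntegrationError(
            f"concentration undershoot {low:.3e} uM exceeds tolerance "
            f"-{UNDERSHOOT_TOL:.0e} uM; integration is unreliable"
        )
    return ConcentrationTimecourse(scheme=scheme, conditions=conditions, time=t, data=data)


#: conversion from uM^-1 s^-1 to M^-1 s^-1
_PER_UM_TO_PER_M = 1e6


def derived_constants(
    rates: RateConstantSet,
    quantities: Iterable[str] | None = None,
) -> dict[str, float]:
    """Closed-form steady-state constants implied by the mechanism.

    Returns whichever of the following are computable from the supplied
    rates (all requested ones if ``quantities`` is given, else everything
    available):

    - ``kd_app``       = k2/k1                        (uM)
    - ``kcat_over_km`` = k1*k3/(k2+k3)                (M^-1 s^-1)
    - ``kcat``         = k3*k5/(k3+k5)                (s^-1)
    - ``km``           = kcat / (kcat/KM)             (uM)

    kcat/KM is the specificity constant set entirely by the first
    half-reaction; kcat combines both half-reactions in series.
    """
    needs = {
        "kd_app": ("k1", "k2"),
        "kcat_over_km": ("k1", "k2", "k3"),
        "kcat": ("k3", "k5"),
        "km": ("k1", "k2", "k3", "k5"),
    }
    have = {k: v for k, v in rates.as_dict().items() if v is not None and v > 0}
    out: dict[str, float] = {}
    requested = list(quantities) if quantities is not None else list(needs)
    for name in requested:
        if name not in needs:
            raise ValueError(f"unknown derived quantity {name!r}")
        missing = [lbl for lbl in needs[name] if lbl not in have]
        if missing:
            if quantities is not None:
                raise ValueError(
                    f"cannot compute {name}: rate constant(s) "
                    f"{', '.join(missing)} absent or non-positive"
                )
            continue
        if name == "kd_app":
            out[name] = rates.k2 / rates.k1
        elif name == "kcat_over_km":
            out[name] = rates.k1 * rates.k3 / (rates.k2 + rates.k3) * _PER_UM_TO_PER_M
        elif name == "kcat":
            out[name] = rates.k3 * rates.k5 / (rates.k3 + rates.k5)
        elif name == "km":
            kcat = rates.k3 * rates.k5 / (rates.k3 + rates.k5)
            spec_um = rates.k1 * rates.k3 / (rates.k2 + rates.k3)  # uM^-1 s^-1
            out[name] = kcat / spec_um
    return out
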