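"""Beer-Lambert projection of species concentrations onto absorbance signals.

The nucleobase chromophore travels S -> ES -> P through the mechanism, and
its extinction coefficient changes twice: once on binding (the Michaelis
complex perturbs the base's electronic environment) and once on N-ribosidic
bond cleavage (free nucleobase in solution).  The covalent intermediate E-X
and the sugar-phosphate product Q carry no chromophore.  The four canonical
wavelengths respond with a characteristic sign pattern:

==========  ============  ==============
wavelength  on binding    on cleavage
==========  ============  ==============
251 nm      decrease      increase
264 nm      decrease      decrease
275 nm      unchanged     decrease
286 nm      increase      decrease
==========  ============  ==============

so 275 nm is blind to binding (a pure chemistry channel) and 286 nm reports
both events with opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .schemes import ConcentrationTimecourse, ReactionConditions

__all__ = ["ObservableMap", "Trace", "default_observable_maps", "project_trace"]

#: reference path length (cm) at which the default magnitudes below apply
_REF_PATH = 0.5
#: default substrate-channel response at the reference path (AU/uM);
#: of order epsilon ~ 1.0e4 M^-1 cm^-1 for a pyrimidine nucleotide
_BASE_RESPONSE = 0.0051
#: default magnitude of the binding / cleavage response changes (AU/uM) at the
#: reference path; sets the synthetic signal scale only, never the kinetics
_DELTA_RESPONSE = 0.0018

#: (binding sign, cleavage sign) per canonical wavelength
_SIGNS: dict[int, tuple[int, int]] = {
    251: (-1, +1),
    264: (-1, -1),
    275: (0, -1),
    286: (+1, -1),
}


@dataclass(frozen=True)
class ObservableMap:
    """Per-species absorbance response (AU/uM at the stated path length)."""

    wavelength: float
    response: Mapping[str, float]
    offset: float = 0.0

    def coefficient(self, species: str) -> float:
        return self.response[species]


@dataclass(frozen=True)
class Trace:
    """A time-resolved absorbance trace with its acquisition metadata."""

    time: np.ndarray
    signal: np.ndarray
    wavelength: float
    conditions: ReactionConditions
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays")
        if self.time.size != self.signal.size or self.time.size < 2:
            raise ValueError("time and signal must have equal length >= 2")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("trace time must be strictly increasing")
        if self.time[0] < self.conditions.dead_time - 1e-12:
            raise ValueError(
                f"trace starts at {self.time[0]:.6g} s, before the instrument "
                f"dead time {self.conditions.dead_time:.6g} s"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.time.size)


def default_observable_maps(
    path_length: float = _REF_PATH,
    *,
    base_response: float = _BASE_RESPONSE,
    delta_response: float = _DELTA_RESPONSE,
) -> dict[int, ObservableMap]:
    """Observable maps for the four canonical wavelengths.

    Coefficients scale linearly with ``path_length`` (Beer-Lambert).  The
    chromophore-bearing species are S, ES and P; ES and P coefficients differ
    from the free-substrate coefficient by the signed binding and cleavage
    deltas of the table above.
    """
    if path_length <= 0:
        raise ValueError("path_length must be > 0 cm")
    scale = path_length / _REF_PATH
    base = base_response * scale
    delta = delta_response * scale
    maps: dict[int, ObservableMap] = {}
    for wl, (sign_bind, sign_cleave) in _SIGNS.items():
        response = {
            "E": 0.0,
            "S": base,
            "ES": base + sign_bind * delta,
            "EX": 0.0,
            "P": base + sign_cleave * delta,
            "Q": 0.0,
        }
        maps[wl] = ObservableMap(wavelength=float(wl), response=response)
    return maps


def project_trace(timecourse: ConcentrationTimecourse, omap: ObservableMap) -> Trace:
    """Project a concentration timecourse to a noiseless absorbance trace.

    signal(t) = offset + sum_species response[sp] * concentration[sp](t)
    """
    missing = [sp for sp in timecourse.scheme.species if sp not in omap.response]
    if missing:
        raise KeyError(
            f"observable map at {omap.wavelength:g} nm lacks coefficients for "
            f"species: {', '.join(missing)}"
        )
    signal = np.full(timecourse.time.size, float(omap.offset))
    for sp in timecourse.scheme.species:
        signal = signal + omap.response[sp] * timecourse[sp]
    return Trace(
        time=timecourse.time.copy(),
        signal=signal,
        wavelength=omap.wavelength,
        conditions=timecourse.conditions,
        noise_sigma=0.0,
    )
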