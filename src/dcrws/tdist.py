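"""Argos location-class error model: per-class Student-t parameters.

Argos quality classes 3/2/1/0/A/B carry very different positional errors,
from a few hundred metres (class 3) to tens of kilometres with heavy
tails (class B).  Observation residuals per coordinate are modelled as
``tau * t(nu)``; the defaults below are held fixed during fitting (the
usual DCRWS practice) and can be overridden entry-by-entry from config.

Scales ``tau`` are in degrees and increase monotonically as nominal
Argos quality drops; degrees of freedom ``nu`` are small for the low
classes, giving the heavy tails that make occasional wild class-A/B
fixes cheap to ignore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .argos_io import LOC_CLASSES

# (nu_lon, tau_lon_deg, nu_lat, tau_lat_deg) per class; package defaults
# of the magnitude used in switching-CRW fits to Argos error data
# (class 3 ~ 0.25 km, class B ~ 10 km scale).
_DEFAULT_TABLE = {
    "3": (3.07, 0.00235, 2.08, 0.00184),
    "2": (1.22, 0.00430, 6.31, 0.00655),
    "1": (2.30, 0.01101, 3.90, 0.00826),
    "0": (0.94, 0.06659, 1.66, 0.02000),
    "A": (1.78, 0.07852, 1.98, 0.02973),
    "B": (1.08, 0.10180, 1.22, 0.06004),
}


@dataclass(frozen=True)
class TDistParams:
    """Per-class, per-coordinate t-distribution error parameters."""

    table: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TABLE))

    def __post_init__(self):
        for cls in LOC_CLASSES:
            if cls not in self.table:
                raise ValueError(f"missing t-distribution entry for class {cls}")
            nu_lon, tau_lon, nu_lat, tau_lat = self.table[cls]
            if min(nu_lon, tau_lon, nu_lat, tau_lat) <= 0:
                raise ValueError(f"non-positive t parameter for class {cls}")

    def nu(self, loc_class: str) -> tuple[float, float]:
        """(nu_lon, nu_lat) for a class."""
        e = self._entry(loc_class)
        return e[0], e[2]

    def tau(self, loc_class: str) -> tuple[float, float]:
        """(tau_lon, tau_lat) degrees for a class."""
        e = self._entry(loc_class)
        return e[1], e[3]

    def _entry(self, loc_class: str):
        try:
            return self.table[loc_class]
        except KeyError:
            raise KeyError(f"no t-distribution parameters for Argos class "
                           f"{loc_class!r}") from None

    def arrays(self, loc_classes) -> tuple[np.ndarray, np.ndarray]:
        """(n,2) arrays of nu and tau for a sequence of classes."""
        nu = np.array([self.nu(c) for c in loc_classes], dtype=float)
        tau = np.array([self.tau(c) for c in loc_classes], dtype=float)
        return nu, tau

    def override(self, updates: dict[str, tuple[float, float, float, float]]
                 ) -> "TDistParams":
        table = dict(self.table)
        table.update(updates)
        return TDistParams(table=table)
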