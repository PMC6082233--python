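"""Per-chromosome descriptors: length, arm ratio, centromeric asymmetry, class.

A chromosome with short arm S and long arm L (micrometres) is described by

* total length        CL = S + L (+ satellite, by default),
* arm ratio           r  = L / S                (satellite excluded),
* centromeric asymmetry CA = 100 * (L - S) / (L + S), in percent,

and classified into the morphological classes m / sm / st / t (metacentric,
submetacentric, subtelocentric, telocentric) by half-open arm-ratio bins
with the classical breakpoints 1.7, 3.0 and 7.0.  CA and r carry the same
information (CA = 100 * (r - 1) / (r + 1)); CA is the per-chromosome summand
of the intrachromosomal asymmetry index M_CA.

Satellite policy (configurable): satellites are *included* in total length
(they are chromatin and contribute to TCL) but *excluded* from the arm
ratio and CA, so classification does not flip when a satellite is present.
"""

from __future__ import annotations

from dataclasses import dataclass

from .measurements import ChromosomeMeasurement

#: (label, lower arm-ratio bound) pairs; bins are left-closed, the last is
#: unbounded above.  m: [1, 1.7), sm: [1.7, 3), st: [3, 7), t: [7, inf).
DEFAULT_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("m", 1.0),
    ("sm", 1.7),
    ("st", 3.0),
    ("t", 7.0),
)

#: Canonical rendering order of class labels in karyotype formulas.
CLASS_ORDER = ("m", "m-sat", "sm", "sm-sat", "st", "st-sat", "t", "t-sat")


@dataclass(frozen=True)
class MorphClass:
    """Morphological class of a chromosome: base class plus satellite flag."""

    base: str
    satellited: bool = False

    @property
    def label(self) -> str:
        return f"{self.base}-sat" if self.satellited else self.base

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def chromosome_length(
    c: ChromosomeMeasurement, include_satellite: bool = True
) -> float:
    """Total chromosome length CL in micrometres (satellite included by default)."""
    cl = c.short_arm + c.long_arm
    if include_satellite:
        cl += c.satellite
    return cl


def arm_ratio(c: ChromosomeMeasurement, include_satellite: bool = False) -> float:
    """Arm ratio r = L / S (>= 1); satellite excluded by default.

    With ``include_satellite=True`` the satellite length is added to the arm
    that bears it before taking the ratio.
    """
    s, l = c.short_arm, c.long_arm
    if include_satellite:
        if c.satellite_arm == "short":
            s += c.satellite
        elif c.satellite_arm == "long":
            l += c.satellite
    return max(l, s) / min(l, s)


def centromeric_asymmetry(
    c: ChromosomeMeasurement, include_satellite: bool = False
) -> float:
    """Centromeric asymmetry CA = 100 (L - S)/(L + S), in [0, 100)."""
    r = arm_ratio(c, include_satellite=include_satellite)
    return 100.0 * (r - 1.0) / (r + 1.0)


def classify_ratio(
    r: float, thresholds: tuple[tuple[str, float], ...] = DEFAULT_THRESHOLDS
) -> str:
    """Base class label for an arm ratio ``r`` under left-closed bins."""
    if r < thresholds[0][1]:
        raise ValueError(f"arm ratio {r} below the first class bound")
    label = thresholds[0][0]
    for lab, lower in thresholds:
        if r >= lower:
            label = lab
    return label


def classify(
    c: ChromosomeMeasurement,
    thresholds: tuple[tuple[str, float], ...] = DEFAULT_THRESHOLDS,
    include_satellite: bool = False,
) -> MorphClass:
    """Morphological class of a chromosome from its arm ratio.

    The satellite flag mirrors the presence of a satellite; by default the
    satellite length itself does not enter the ratio.
    """
    r = arm_ratio(c, include_satellite=include_satellite)
    return MorphClass(classify_ratio(r, thresholds), c.satellite_arm != "none")
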