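"""Watchman-style eligibility and device-size selection.

Eligibility requires the maximum appendage length to be at least the
landing-zone diameter, and the diameter to lie in [17, 31] mm (both
bounds inclusive).  A device (21, 24, 27, 30 or 33 mm) is selected so
the landing zone compresses it by 8-20%; when two sizes fit, the larger
is taken.  Compression is computed against the device nominal size,
(device - diameter) / device, by default; the diameter-denominator
convention is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError

__all__ = [
    "DEVICE_SIZES_MM",
    "COMPRESSION_WINDOW",
    "ELIGIBLE_DIAMETER_MM",
    "SizingDecision",
    "assess_eligibility",
    "select_device",
    "size_case",
    "tabulate_eligibility",
]

DEVICE_SIZES_MM = (21, 24, 27, 30, 33)
COMPRESSION_WINDOW = (0.08, 0.20)
ELIGIBLE_DIAMETER_MM = (17.0, 31.0)


@dataclass(frozen=True)
class SizingDecision:
    case_id: str
    strategy: str
    eligible: bool
    ineligibility_reason: str  # diameter_too_small / diameter_too_large /
    #                            length_shorter_than_diameter / none
    device_mm: int | None
    compression_fraction: float | None
    no_feasible_device: bool


def assess_eligibility(diameter_mm: float, length_mm: float) -> tuple[bool, str]:
    """Implantation eligibility from the two landing-zone measurements."""
    if diameter_mm <= 0 or length_mm <= 0:
        raise ParameterError("measurements must be positive")
    if diameter_mm < ELIGIBLE_DIAMETER_MM[0]:
        return False, "diameter_too_small"
    if diameter_mm > ELIGIBLE_DIAMETER_MM[1]:
        return False, "diameter_too_large"
    if length_mm < diameter_mm:
        return False, "length_shorter_than_diameter"
    return True, "none"


def _compression(device: float, diameter: float, denominator: str) -> float:
    if denominator == "device":
        return (device - diameter) / device
    if denominator == "diameter":
        return (device - diameter) / diameter
    raise ParameterError(f"unknown compression denominator '{denominator}'")


def select_device(diameter_mm: float,
                  denominator: str = "device") -> tuple[int | None, float | None]:
    """Largest device whose compression falls in the 8-20% window, or
    (None, None) when no size fits (possible in gaps of the size lattice)."""
    lo, hi = COMPRESSION_WINDOW
    feasible = [(d, _compression(d, diameter_mm, denominator))
                for d in DEVICE_SIZES_MM
                if lo <= _compression(d, diameter_mm, denominator) <= hi]
    if not feasible:
        return None, None
    d, c = max(feasible, key=lambda t: t[0])
    return d, c


def size_case(case_id: str, strategy: str, diameter_mm: float, length_mm: float,
              denominator: str = "device") -> SizingDecision:
    """Full sizing decision for one measured case."""
    eligible, reason = assess_eligibility(diameter_mm, length_mm)
    if not eligible:
        return SizingDecision(case_id, strategy, False, reason, None, None, False)
    device, comp = select_device(diameter_mm, denominator)
    return SizingDecision(case_id, strategy, True, "none", device, comp,
                          device is None)


def tabulate_eligibility(decisions: dict[str, list[SizingDecision]],
                         control: list[SizingDecision]) -> pd.DataFrame:
    """Eligibility agreement of each strategy against Control.

    A false ineligible is a case a strategy rejects but Control accepts;
    a false eligible is the converse.
    """
    ctrl = {d.case_id: d for d in control}
    rows = []
    for strategy, decs in decisions.items():
        ids = {d.case_id for d in decs}
        if ids != set(ctrl):
            raise ParameterError(
                f"strategy '{strategy}' case set differs from Control")
        inel = sum(not d.eligible for d in decs)
        false_inel = sum((not d.eligible) and ctrl[d.case_id].eligible
                         for d in decs)
        false_el = sum(d.eligible and (not ctrl[d.case_id].eligible)
                       for d in decs)
        rows.append({"strategy": strategy, "n": len(decs),
                     "ineligible": inel, "false_ineligible": false_inel,
                     "false_eligible": false_el})
    return pd.DataFrame(rows)
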