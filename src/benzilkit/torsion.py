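"""Torsional potential-energy-profile analysis.

Profiles are grid-sampled relaxed scans over one dihedral period.  Energies
are shifted so the global minimum is zero; extrema are reported at grid
resolution (no interpolation — the published precision is "at about 40 deg"),
and the conformational barrier is E(global max) - E(global min).
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

from .datamodel import InputError, TorsionProfile

HARTREE_TO_KJ_MOL = 2625.50


class Extrema(NamedTuple):
    min_angle: float
    min_energy: float
    max_angle: float
    max_energy: float
    flat: bool


def to_relative(profile: TorsionProfile, unit_in: str = "kJ/mol") -> TorsionProfile:
    """Shift the global minimum to zero, converting hartree input if needed."""
    if unit_in == "hartree":
        energies = [e * HARTREE_TO_KJ_MOL for e in profile.energies]
    elif unit_in == "kJ/mol":
        energies = list(profile.energies)
    else:
        raise InputError(f"unknown energy unit {unit_in!r}")
    if not energies:
        raise InputError("empty torsion profile")
    e_min = min(energies)
    return profile.model_copy(
        update={"energies": tuple(e - e_min for e in energies)}
    )


def find_extrema(profile: TorsionProfile) -> Extrema:
    """Grid-level global minimum and maximum; ties broken by smallest angle.

    A flat profile returns coincident extrema with ``flat=True`` as a warning
    flag rather than an error.
    """
    pairs = list(zip(profile.angles, profile.energies))
    min_a, min_e = min(pairs, key=lambda p: (p[1], p[0]))
    max_a, max_e = max(pairs, key=lambda p: (p[1], -p[0]))
    return Extrema(min_a, min_e, max_a, max_e, flat=(min_e == max_e))


def barrier_height(profile: TorsionProfile) -> float:
    """Conformational barrier: E(global max) - E(global min), >= 0."""
    ext = find_extrema(profile)
    return ext.max_energy - ext.min_energy


def order_barriers(profiles: Mapping[str, TorsionProfile]) -> list[str]:
    """Ids ordered by descending barrier height; ties broken by id."""
    if not profiles:
        raise InputError("no torsion profiles to order")
    heights = {k: barrier_height(p) for k, p in profiles.items()}
    return sorted(heights, key=lambda k: (-heights[k], k))
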