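"""Nonlinear-optical scalar invariants and unit conversion.

Scalars follow the standard quantum-chemistry output conventions:

* first hyperpolarizability beta_total: contract the Kleinman-symmetric
  third-rank tensor to the vector beta_i = beta_iii + beta_ijj + beta_ikk and
  report its Euclidean norm;
* second hyperpolarizability gamma_average: the isotropic fifth-average
  (g_xxxx + g_yyyy + g_zzzz + 2 (g_xxyy + g_xxzz + g_yyzz)) / 5;
* atomic-unit -> esu conversion by the tabulated factors per tensor rank.

The urea reference for first-hyperpolarizability ratios defaults to
0.13e-30 esu, the value consistent with the published fold-enhancements.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import DomainError, InputError

BETA_KEYS = ("xxx", "xxy", "xyy", "yyy", "xxz", "xyz", "yyz", "xzz", "yzz", "zzz")
GAMMA_KEYS = ("xxxx", "yyyy", "zzzz", "xxyy", "xxzz", "yyzz")

#: esu per atomic unit, by tensor rank
AU_TO_ESU = {
    "alpha": 1.4819e-25,
    "beta": 8.6393e-33,
    "gamma": 5.0367e-40,
}

UREA_BETA_ESU = 0.13e-30


def _require_keys(components: Mapping[str, float], keys: Sequence[str], what: str):
    missing = [k for k in keys if k not in components]
    if missing:
        raise InputError(f"{what} components missing: {missing}")


def beta_vector(components: Mapping[str, float]) -> tuple[float, float, float]:
    """(beta_x, beta_y, beta_z) from the 10 Kleinman components (au)."""
    _require_keys(components, BETA_KEYS, "beta")
    c = components
    bx = c["xxx"] + c["xyy"] + c["xzz"]
    by = c["yyy"] + c["xxy"] + c["yzz"]
    bz = c["zzz"] + c["xxz"] + c["yyz"]
    return bx, by, bz


def beta_total(components: Mapping[str, float]) -> float:
    """Norm of the contracted first-hyperpolarizability vector (au)."""
    bx, by, bz = beta_vector(components)
    return math.sqrt(bx * bx + by * by + bz * bz)


def gamma_average(components: Mapping[str, float]) -> float:
    """Isotropic average of the second hyperpolarizability (au); may be
    negative."""
    _require_keys(components, GAMMA_KEYS, "gamma")
    c = components
    return (
        c["xxxx"] + c["yyyy"] + c["zzzz"]
        + 2.0 * (c["xxyy"] + c["xxzz"] + c["yyzz"])
    ) / 5.0


def au_to_esu(value: float, kind: str) -> float:
    """Convert an alpha/beta/gamma scalar from atomic units to esu."""
    try:
        factor = AU_TO_ESU[kind]
    except KeyError:
        raise InputError(
            f"unknown conversion kind {kind!r}; expected one of {sorted(AU_TO_ESU)}"
        ) from None
    return value * factor


def ratio_to_reference(beta_esu: float, reference_esu: float = UREA_BETA_ESU) -> int:
    """Integer fold-enhancement over a reference first hyperpolarizability,
    rounded half away from zero."""
    if reference_esu <= 0:
        raise DomainError(f"reference beta must be positive, got {reference_esu}")
    q = beta_esu / reference_esu
    return int(math.copysign(math.floor(abs(q) + 0.5), q))


def urea_ratio_table(
    nlo_table: pd.DataFrame, reference_esu: float = UREA_BETA_ESU
) -> pd.DataFrame:
    """Fold-enhancement over urea for a series table with a ``beta_1e30_esu``
    column (values in units of 1e-30 esu)."""
    out = nlo_table[["id", "beta_1e30_esu"]].copy()
    out["urea_ratio"] = [
        ratio_to_reference(b * 1e-30, reference_esu) for b in out["beta_1e30_esu"]
    ]
    return out
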