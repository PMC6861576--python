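"""Conceptual-DFT global reactivity descriptors.

From a vertical ionisation potential IP and electron affinity EA (eV):

    chi   = (IP + EA) / 2          electronegativity
    mu    = -chi                   chemical potential
    eta   = (IP - EA) / 2          chemical hardness
    S     = 1 / eta                chemical softness
    omega = mu**2 / (2 eta)        electrophilicity index

Internally everything is full floating point; :func:`rounding_chain_descriptors`
additionally reproduces the legacy report convention in which S and omega are
evaluated from the 3-decimal-rounded chi/mu/eta rather than from full precision
(the convention the published descriptor table evidently follows).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import DomainError, InputError, MoleculeSummary, ReactivityDescriptors


def compute_descriptors(ip: float, ea: float) -> ReactivityDescriptors:
    """All global descriptors from a vertical (IP, EA) pair, full precision.

    Raises :class:`DomainError` when ``ip <= ea`` (hardness would not be
    positive).
    """
    if not ip > ea:
        raise DomainError(
            f"hardness must be positive: need ip > ea, got ip={ip}, ea={ea}"
        )
    chi = (ip + ea) / 2.0
    mu = -chi
    eta = (ip - ea) / 2.0
    return ReactivityDescriptors(
        ip=ip,
        ea=ea,
        chi=chi,
        mu_chem=mu,
        eta=eta,
        s=1.0 / eta,
        omega=mu * mu / (2.0 * eta),
        gap_ipea=ip - ea,
    )


def orbital_gap(e_homo: float, e_lumo: float) -> float:
    """Frontier-orbital gap Eg = E(LUMO) - E(HOMO), always positive."""
    if not e_lumo > e_homo:
        raise DomainError(
            f"e_lumo ({e_lumo}) must lie above e_homo ({e_homo})"
        )
    return e_lumo - e_homo


def _round3(x: Decimal) -> Decimal:
    return x.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)


def rounding_chain_descriptors(ip: float, ea: float) -> dict[str, float]:
    """Descriptors as a descriptor *report* states them: chi, mu, eta rounded
    half-up to 3 decimals, then S and omega derived from those rounded values.

    Decimal arithmetic avoids binary-float artefacts at the half-way cases
    (e.g. chi = 7.2845 -> 7.285).
    """
    if not ip > ea:
        raise DomainError(f"need ip > ea, got ip={ip}, ea={ea}")
    ip_d, ea_d = Decimal(str(ip)), Decimal(str(ea))
    chi = _round3((ip_d + ea_d) / 2)
    eta = _round3((ip_d - ea_d) / 2)
    mu = -chi
    return {
        "ip": ip,
        "ea": ea,
        "chi": float(chi),
        "mu": float(mu),
        "eta": float(eta),
        "s": float(Decimal(1) / eta),
        "omega": float(mu * mu / (2 * eta)),
        "gap_ipea": float(ip_d - ea_d),
    }


def rank_by(
    records: Iterable[tuple[str, float]], descending: bool = True
) -> list[str]:
    """Order ids by value; stable, ties broken lexicographically by id."""
    pairs = list(records)
    ids = [i for i, _ in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate ids in ranking input: {dupes}")
    for i, v in pairs:
        if v != v or v in (float("inf"), float("-inf")):
            raise InputError(f"non-finite value for id {i!r}")
    sign = -1.0 if descending else 1.0
    return [i for i, _ in sorted(pairs, key=lambda p: (sign * p[1], p[0]))]


def descriptor_table(
    molecules: Sequence[MoleculeSummary], printed_style: bool = False
) -> pd.DataFrame:
    """Descriptor table for a molecule series, one row per molecule.

    ``printed_style=True`` uses the rounded-intermediate report convention
    (see :func:`rounding_chain_descriptors`); the default is full precision.
    """
    rows = []
    for mol in molecules:
        if mol.ip_vertical is None or mol.ea_vertical is None:
            raise InputError(f"molecule {mol.id!r} lacks vertical IP/EA")
        if printed_style:
            d = rounding_chain_descriptors(mol.ip_vertical, mol.ea_vertical)
            row = {"id": mol.id, **d}
        else:
            d = compute_descriptors(mol.ip_vertical, mol.ea_vertical)
            row = {
                "id": mol.id,
                "ip": d.ip,
                "ea": d.ea,
                "chi": d.chi,
                "mu": d.mu_chem,
                "eta": d.eta,
                "s": d.s,
                "omega": d.omega,
                "gap_ipea": d.gap_ipea,
            }
        row["orbital_gap"] = orbital_gap(mol.e_homo, mol.e_lumo)
        rows.append(row)
    return pd.DataFrame(rows)
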