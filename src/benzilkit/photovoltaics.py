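"""DSSC sensitizer modelling from TD-DFT excitation summaries.

The screening chain per dye:

    LHE        = 1 - 10**(-f)                light-harvesting efficiency
    E(0,0)     = K / lambda_max              vertical excitation energy (eV)
    E_dye      = -E(HOMO)                    ground-state oxidation energy
    E*_dye     = E_dye - E(0,0)              excited-state oxidation energy
    dG_inject  = E*_dye + E_CB               electron-injection free energy

with E_CB the semiconductor (TiO2) conduction-band energy, -4.00 eV by
default.  A more negative dG_inject means more spontaneous injection.  The
eV.nm conversion constant K defaults to the rounded 1240 used throughout the
source tables; the exact hc/e value is available as ``EV_NM_EXACT``.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .datamodel import DomainError, InputError, MoleculeSummary, PhotovoltaicRecord
from .reactivity import orbital_gap

EV_NM = 1240.0
EV_NM_EXACT = 1239.84
E_CB_TIO2 = -4.00


def light_harvesting_efficiency(f: float) -> float:
    """LHE = 1 - 10**(-f); in [0, 1), strictly increasing in f."""
    if f < 0:
        raise DomainError(f"oscillator strength must be >= 0, got {f}")
    return 1.0 - 10.0 ** (-f)


def vertical_excitation_energy(lambda_nm: float, constant: float = EV_NM) -> float:
    """E(0,0) in eV from the absorption maximum in nm."""
    if lambda_nm <= 0:
        raise DomainError(f"wavelength must be positive, got {lambda_nm}")
    return constant / lambda_nm


def injection_free_energy(
    e_dye: float, e00: float, e_cb: float = E_CB_TIO2
) -> tuple[float, float]:
    """(E*_dye, dG_inject) from the ground-state oxidation energy, vertical
    excitation energy and conduction-band energy."""
    if e00 <= 0:
        raise DomainError(f"excitation energy must be positive, got {e00}")
    e_dye_star = e_dye - e00
    return e_dye_star, e_dye_star + e_cb


def photovoltaic_record(
    molecule: MoleculeSummary,
    e_cb: float = E_CB_TIO2,
    constant: float = EV_NM,
) -> PhotovoltaicRecord:
    """Full screening record for one dye, from its strongest excitation."""
    ex = molecule.strongest_excitation
    e00 = vertical_excitation_energy(ex.lambda_nm, constant)
    e_dye = -molecule.e_homo
    e_dye_star, dg = injection_free_energy(e_dye, e00, e_cb)
    return PhotovoltaicRecord(
        id=molecule.id,
        f=ex.f,
        lhe=light_harvesting_efficiency(ex.f),
        lambda_max_nm=ex.lambda_nm,
        e00=e00,
        e_dye=e_dye,
        e_dye_star=e_dye_star,
        e_cb=e_cb,
        dg_inject=dg,
    )


def photovoltaic_table(
    molecules: Sequence[MoleculeSummary],
    e_cb: float = E_CB_TIO2,
    constant: float = EV_NM,
) -> pd.DataFrame:
    """Screening table for a dye series, one row per molecule."""
    rows = []
    for mol in molecules:
        rec = photovoltaic_record(mol, e_cb=e_cb, constant=constant)
        rows.append(
            {
                "id": rec.id,
                "f": rec.f,
                "lhe": rec.lhe,
                "lambda_max_nm": rec.lambda_max_nm,
                "e00": rec.e00,
                "e_homo": mol.e_homo,
                "e_lumo": mol.e_lumo,
                "gap": orbital_gap(mol.e_homo, mol.e_lumo),
                "e_dye": rec.e_dye,
                "e_dye_star": rec.e_dye_star,
                "e_cb": rec.e_cb,
                "dg_inject": rec.dg_inject,
            }
        )
    return pd.DataFrame(rows)


def select_best_sensitizer(records: Sequence[PhotovoltaicRecord]) -> str:
    """Id with the most negative dG_inject; ties broken by higher LHE, then id."""
    if not records:
        raise InputError("no photovoltaic records to rank")
    best = min(records, key=lambda r: (r.dg_inject, -r.lhe, r.id))
    return best.id
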