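"""Vibrational frequency scaling, band pairing and agreement statistics.

Harmonic DFT wavenumbers are scaled by an empirical factor (0.9613 for
B3LYP-quality harmonics) before comparison with experiment.  Calculated and
observed bands are paired either row-wise from an assignment table
("assigned" mode, the default for curated fixtures) or greedily by nearest
wavenumber within a window ("nearest" mode); agreement is summarised as the
root-mean-square deviation per technique.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import BandPair, CalcMode, DomainError, InputError, ObsBand, StateError

DEFAULT_SCALING = 0.9613
DEFAULT_WINDOW = 30.0


def apply_scaling(
    modes: Sequence[CalcMode], factor: float = DEFAULT_SCALING
) -> list[CalcMode]:
    """Multiply every wavenumber by ``factor`` and set the scaled flag.

    Re-scaling an already scaled list is a :class:`StateError` — the factor is
    meant to be applied exactly once.
    """
    if factor <= 0:
        raise DomainError(f"scaling factor must be positive, got {factor}")
    already = [m for m in modes if m.scaled]
    if already:
        raise StateError(
            f"{len(already)} mode(s) already scaled; refusing to scale twice"
        )
    return [
        m.model_copy(update={"wavenumber": m.wavenumber * factor, "scaled": True})
        for m in modes
    ]


def pair_bands(
    modes: Sequence[CalcMode],
    obs: Sequence[ObsBand],
    mode: str = "assigned",
    window: float = DEFAULT_WINDOW,
) -> list[BandPair]:
    """Pair calculated modes with observed bands.

    ``assigned``: row-wise pairing of equal-length, pre-aligned lists (the
    curated-fixture path).  ``nearest``: greedy matching by ascending
    |calc - obs| within ``window`` cm**-1; each mode and band is used at most
    once, unmatched entries are simply left out.
    """
    if mode == "assigned":
        if len(modes) != len(obs):
            raise InputError(
                "assigned mode needs pre-aligned lists of equal length "
                f"({len(modes)} modes vs {len(obs)} bands)"
            )
        return [
            BandPair(
                calc=m.wavenumber,
                obs=b.wavenumber,
                technique=b.technique,
                assignment=m.assignment,
            )
            for m, b in zip(modes, obs)
        ]
    if mode == "nearest":
        if window <= 0:
            raise DomainError(f"nearest-mode window must be positive, got {window}")
        candidates = sorted(
            (
                (abs(m.wavenumber - b.wavenumber), i, j)
                for i, m in enumerate(modes)
                for j, b in enumerate(obs)
                if abs(m.wavenumber - b.wavenumber) <= window
            ),
        )
        used_m: set[int] = set()
        used_b: set[int] = set()
        pairs = []
        for _, i, j in candidates:
            if i in used_m or j in used_b:
                continue
            used_m.add(i)
            used_b.add(j)
            pairs.append(
                BandPair(
                    calc=modes[i].wavenumber,
                    obs=obs[j].wavenumber,
                    technique=obs[j].technique,
                    assignment=modes[i].assignment,
                )
            )
        pairs.sort(key=lambda p: p.calc)
        return pairs
    raise InputError(f"unknown pairing mode {mode!r}")


def pairs_from_table(table: pd.DataFrame, technique: str) -> list[BandPair]:
    """Row-wise pairs from an assignment table with ``calc`` and
    ``obs_ir``/``obs_raman`` columns; rows lacking either entry are skipped."""
    if technique not in ("IR", "Raman"):
        raise InputError(f"technique must be 'IR' or 'Raman', got {technique!r}")
    col = "obs_ir" if technique == "IR" else "obs_raman"
    pairs = []
    for row in table.itertuples(index=False):
        obs = getattr(row, col)
        if pd.isna(obs):
            continue
        pairs.append(
            BandPair(
                calc=float(row.calc),
                obs=float(obs),
                technique=technique,
                assignment=str(getattr(row, "assignment", "")),
            )
        )
    return pairs


def rmsd(pairs: Sequence[BandPair]) -> float:
    """Root-mean-square deviation between calculated and observed wavenumbers."""
    if not pairs:
        raise InputError("rmsd needs at least one band pair")
    return math.sqrt(
        sum((p.calc - p.obs) ** 2 for p in pairs) / len(pairs)
    )


def rmsd_report(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-molecule, per-technique RMSD summary for assignment tables."""
    rows = []
    for mol_id, table in tables.items():
        for technique in ("IR", "Raman"):
            pairs = pairs_from_table(table, technique)
            if not pairs:
                continue
            rows.append(
                {
                    "id": mol_id,
                    "technique": technique,
                    "n_pairs": len(pairs),
                    "rmsd_cm1": rmsd(pairs),
                }
            )
    return pd.DataFrame(rows)
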