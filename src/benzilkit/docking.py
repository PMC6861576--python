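"""Parsing and summarising ranked docking score tables.

Each receptor-ligand complex carries the server's top conformations with
global energy, attractive/repulsive van-der-Waals terms and atomic contact
energy (ACE).  Scores are opaque "score units"; more negative means more
stabilising throughout.  The rank-1 ACE per complex doubles as the binding
energy fed to the QSAR stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import pydantic

from .datamodel import DockingRow, DockingScoreTable, InputError, SchemaError

LIGANDS = ("BZL", "DMB", "DFB", "DCB", "DBB")


def parse_score_tables(source: str | Path | pd.DataFrame) -> list[DockingScoreTable]:
    """Parse a long-format score CSV (columns receptor, ligand, rank,
    global_energy, attractive_vdw, repulsive_vdw, ace) into one validated
    table per complex block, preserving file order.

    Rank gaps or a block whose rank-1 row does not carry the minimum global
    energy raise :class:`SchemaError` naming the block.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, comment="#")
    if df.empty:
        return []
    required = {"receptor", "ligand", "rank", "global_energy",
                "attractive_vdw", "repulsive_vdw", "ace"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"docking table missing columns: {sorted(missing)}")
    tables = []
    seen = []
    for (receptor, ligand), block in df.groupby(["receptor", "ligand"], sort=False):
        block = block.sort_values("rank")
        try:
            tables.append(
                DockingScoreTable(
                    receptor=str(receptor),
                    ligand=str(ligand),
                    rows=tuple(
                        DockingRow(
                            rank=int(r.rank),
                            global_energy=float(r.global_energy),
                            attractive_vdw=float(r.attractive_vdw),
                            repulsive_vdw=float(r.repulsive_vdw),
                            ace=float(r.ace),
                        )
                        for r in block.itertuples(index=False)
                    ),
                )
            )
        except (pydantic.ValidationError, ValueError) as exc:
            raise SchemaError(f"block {receptor}-{ligand} invalid: {exc}") from exc
        seen.append((receptor, ligand))
    return tables


def load_study_tables() -> list[DockingScoreTable]:
    """The packaged benzil-series docking fixture (15 complexes)."""
    from .io import fixture_path

    return parse_score_tables(fixture_path("docking_scores.csv"))


def top_conformation(table: DockingScoreTable) -> DockingRow:
    """The rank-1 row of a complex block."""
    if not table.rows:
        raise InputError(f"block {table.receptor}-{table.ligand} is empty")
    return table.rows[0]


def best_complex(
    tables: Sequence[DockingScoreTable],
    metric: str = "global_energy",
    statistic: str = "rank1",
) -> tuple[str, float]:
    """(ligand, value) whose chosen statistic of the chosen metric is most
    negative across same-receptor tables; ties broken by ligand id."""
    if not tables:
        raise InputError("no docking tables supplied")
    receptors = {t.receptor for t in tables}
    if len(receptors) > 1:
        raise InputError(f"mixed receptors in input: {sorted(receptors)}")
    if metric not in ("global_energy", "ace"):
        raise InputError(f"unknown metric {metric!r}")
    if statistic not in ("rank1", "min"):
        raise InputError(f"unknown statistic {statistic!r}")

    def value(t: DockingScoreTable) -> float:
        if statistic == "rank1":
            return getattr(top_conformation(t), metric)
        return min(getattr(r, metric) for r in t.rows)

    best = min(tables, key=lambda t: (value(t), t.ligand))
    return best.ligand, value(best)


def binding_energy_vector(
    tables: Sequence[DockingScoreTable], receptor: str
) -> dict[str, float]:
    """Ligand -> rank-1 atomic contact energy for one receptor; this is the
    QSAR response vector.  All five study ligands must be present."""
    by_ligand = {
        t.ligand: t for t in tables if t.receptor == receptor
    }
    missing = [lig for lig in LIGANDS if lig not in by_ligand]
    if missing:
        raise InputError(
            f"receptor {receptor!r}: missing ligand block(s) {missing}"
        )
    return {lig: top_conformation(by_ligand[lig]).ace for lig in LIGANDS}


def ace_summary(tables: Sequence[DockingScoreTable]) -> pd.DataFrame:
    """Per-complex summary showing both the rank-1 and the block-minimum ACE
    (the two readings of 'highest contact energy'), plus rank-1 global energy."""
    rows = []
    for t in tables:
        top = top_conformation(t)
        rows.append(
            {
                "receptor": t.receptor,
                "ligand": t.ligand,
                "global_energy_rank1": top.global_energy,
                "ace_rank1": top.ace,
                "ace_min": min(r.ace for r in t.rows),
            }
        )
    return pd.DataFrame(rows)
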