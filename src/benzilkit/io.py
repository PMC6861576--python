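"""Readers/writers for fixture and report formats, and packaged-data access.

Molecule summaries travel as JSON (schema ``benzilkit.molecule_summary.v1``);
flat tables travel as CSV with ``#`` comment headers.  Written CSV round-trips
to full stored precision (``repr`` floats).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pydantic

from .datamodel import MoleculeSummary, SchemaError

_MOLECULE_IDS = ("BZL", "DMB", "DFB", "DCB", "DBB")
_RECEPTORS = ("3WMT", "2H4Z", "2EEP")


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file by name (e.g. ``benzil_series.json``)."""
    path = Path(str(resources.files("benzilkit").joinpath("data", name)))
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path


def load_molecule_summaries(path: str | Path) -> list[MoleculeSummary]:
    """Load molecule summaries from a schema-v1 JSON file.

    Raises :class:`SchemaError` naming the offending molecule and field on any
    missing mandatory field or invariant breach.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SchemaError(f"{path}: empty file, zero records")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "molecules" not in payload:
        raise SchemaError(f"{path}: missing top-level 'molecules' list")
    records = []
    for i, raw in enumerate(payload["molecules"]):
        label = raw.get("id", f"record {i}") if isinstance(raw, dict) else f"record {i}"
        try:
            records.append(MoleculeSummary.model_validate(raw))
        except pydantic.ValidationError as exc:
            raise SchemaError(f"{path}: molecule {label!r} invalid: {exc}") from exc
    if not records:
        raise SchemaError(f"{path}: zero molecule records")
    return records


def load_benzil_series() -> list[MoleculeSummary]:
    """The packaged five-molecule benzil study series."""
    return load_molecule_summaries(fixture_path("benzil_series.json"))


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a packaged reference CSV (``photovoltaic``, ``reactivity``,
    ``nlo``, ``qsar``, ``qsar_printed_coefficients``, ``docking_scores``)."""
    stem = name if name.endswith(".csv") else f"{name}_reference.csv"
    if name in ("docking_scores", "qsar_printed_coefficients"):
        stem = f"{name}.csv"
    return pd.read_csv(fixture_path(stem), comment="#")


def load_vibrational_table(molecule_id: str) -> pd.DataFrame:
    """Packaged calc/obs vibrational table for one molecule of the series."""
    mol = molecule_id.lower()
    if mol.upper() not in _MOLECULE_IDS:
        raise KeyError(f"no vibrational table for {molecule_id!r}")
    return pd.read_csv(fixture_path(f"vib_{mol}.csv"), comment="#")


def load_torsion_metadata() -> dict:
    """Published torsional barrier heights and extrema angles (metadata only;
    raw scan energies were not published)."""
    return json.loads(fixture_path("torsion_reference.json").read_text())


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    elif isinstance(records, Mapping):
        df = pd.DataFrame([records])
    else:
        rows = list(records)
        if rows and hasattr(rows[0], "model_dump"):
            rows = [r.model_dump() for r in rows]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("cannot write an empty report table")
    return df


def write_report_table(records, path: str | Path, format: str = "csv") -> None:
    """Write a derived table as CSV (round-trip safe) or a Markdown pipe table.

    ``records`` may be a DataFrame, a sequence of mappings or a sequence of
    pydantic models with homogeneous columns.
    """
    df = _records_to_frame(records)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, float_format=None)
    elif format == "markdown":
        path.write_text(to_markdown(df))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV report written by :func:`write_report_table`."""
    return pd.read_csv(path, comment="#")


def to_markdown(df: pd.DataFrame) -> str:
    """Render a DataFrame as a GitHub-style pipe table (no external deps)."""
    cols = [str(c) for c in df.columns]
    cells = [[_fmt(v) for v in row] for row in df.itertuples(index=False)]
    widths = [
        max(len(col), *(len(r[i]) for r in cells)) if cells else len(col)
        for i, col in enumerate(cols)
    ]
    def line(values: Sequence[str]) -> str:
        return "| " + " | ".join(v.ljust(w) for v, w in zip(values, widths)) + " |"
    out = [line(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    out.extend(line(r) for r in cells)
    return "\n".join(out) + "\n"


def _fmt(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return "" if value is None else str(value)


MOLECULE_IDS = _MOLECULE_IDS
RECEPTORS = _RECEPTORS
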