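"""Seeded generators for every input kind the pipeline consumes.

Each generator draws from its own named pseudo-random stream derived from
``(seed, crc32(stream name))``, so adding a generator never perturbs the
output of an existing one, and a fixed seed yields byte-identical output.

The generated conditions mirror the study data: five-ish molecules with
vertical IP in the high-8 eV range sitting above EA near 6 eV, single
dominant UV transitions around 280 nm with oscillator strengths below ~1,
harmonic modes across the mid-IR whose "observed" counterparts are the scaled
wavenumbers plus Gaussian noise of a few cm**-1, cosine torsional wells with
barriers of order 10 kJ/mol, and sorted docking blocks of ten conformations.
"""

from __future__ import annotations

import zlib
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .datamodel import (
    CalcMode,
    DockingRow,
    DockingScoreTable,
    ExcitationRecord,
    InputError,
    MoleculeSummary,
    ObsBand,
    TorsionProfile,
)
from .reactivity import compute_descriptors
from .vibrational import DEFAULT_SCALING


class GeneratorConfig(BaseModel):
    """Knobs for the synthetic-data generators; defaults emulate the study
    conditions (see module docstring)."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_molecules: int = Field(default=5, ge=0)
    ip_range: tuple[float, float] = (7.5, 9.0)
    ea_range: tuple[float, float] = (5.0, 6.5)
    lambda_range_nm: tuple[float, float] = (250.0, 320.0)
    f_range: tuple[float, float] = (0.4, 1.2)
    n_modes: int = Field(default=200, ge=0)
    vib_noise_sigma: float = Field(default=5.0, ge=0)
    torsion_amplitude_range: tuple[float, float] = (5.0, 20.0)
    torsion_periodicities: tuple[int, ...] = (1, 2, 3)
    docking_block_size: int = Field(default=10, ge=1)

    @model_validator(mode="after")
    def _check_ranges(self) -> "GeneratorConfig":
        for name in (
            "ip_range",
            "ea_range",
            "lambda_range_nm",
            "f_range",
            "torsion_amplitude_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if not self.ip_range[0] > self.ea_range[1]:
            raise ValueError(
                "ip_range must lie strictly above ea_range so every draw "
                "satisfies ip > ea"
            )
        return self


def _stream(config: GeneratorConfig, name: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(name.encode())])


class MoleculeSet(NamedTuple):
    molecules: list[MoleculeSummary]
    ground_truth: pd.DataFrame


def generate_molecules(config: GeneratorConfig) -> MoleculeSet:
    """Synthetic molecule summaries plus the descriptor ground truth recorded
    at draw time (for recovery tests)."""
    rng = _stream(config, "molecules")
    molecules = []
    truth_rows = []
    for i in range(config.n_molecules):
        ip = rng.uniform(*config.ip_range)
        ea = rng.uniform(*config.ea_range)
        # frontier orbitals: a plausible Koopmans-like pair, gap 3-5 eV
        e_homo = -rng.uniform(6.0, 7.0)
        e_lumo = e_homo + rng.uniform(3.0, 5.0)
        lam = rng.uniform(*config.lambda_range_nm)
        f = rng.uniform(*config.f_range)
        mol = MoleculeSummary(
            id=f"SYN{i:02d}",
            name=f"synthetic benzil analogue {i}",
            e_homo=e_homo,
            e_lumo=e_lumo,
            ip_vertical=ip,
            ea_vertical=ea,
            excitations=(ExcitationRecord(lambda_nm=lam, f=f),),
            dipole_debye=float(rng.uniform(0.5, 3.5)),
            method_note="synthetic",
        )
        d = compute_descriptors(ip, ea)
        truth_rows.append(
            {
                "id": mol.id,
                "ip": ip,
                "ea": ea,
                "chi": d.chi,
                "eta": d.eta,
                "omega": d.omega,
                "lambda_nm": lam,
                "f": f,
            }
        )
        molecules.append(mol)
    return MoleculeSet(molecules, pd.DataFrame(truth_rows))


class VibrationalSet(NamedTuple):
    modes: list[CalcMode]          # unscaled harmonics
    bands: list[ObsBand]           # obs = scaled calc + N(0, sigma), aligned
    sigma: float
    scaling: float


def generate_vibrational_set(config: GeneratorConfig) -> VibrationalSet:
    """Aligned (modes, bands) where each observed band is the scaled
    calculated wavenumber plus Gaussian noise; assigned-mode pairing then
    estimates sigma via the RMSD."""
    rng = _stream(config, "vibrational")
    n = config.n_modes
    sigma = config.vib_noise_sigma
    wavenumbers = np.sort(rng.uniform(150.0, 3200.0, size=n))
    noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    modes = []
    bands = []
    for i in range(n):
        modes.append(
            CalcMode(
                wavenumber=float(wavenumbers[i]),
                ir_intensity=float(rng.uniform(0, 300)),
                raman_activity=float(rng.uniform(0, 300)),
                assignment="synthetic",
            )
        )
        obs = wavenumbers[i] * DEFAULT_SCALING + noise[i]
        bands.append(
            ObsBand(
                wavenumber=float(max(obs, 1e-6)),
                technique="IR" if i % 2 == 0 else "Raman",
            )
        )
    return VibrationalSet(modes, bands, sigma, DEFAULT_SCALING)


def generate_torsion_profile(
    amplitude: float,
    periodicity: int,
    phase_deg: float,
    grid_step: float = 10.0,
    dihedral_spec: str = "C4-C6-C5-C3",
) -> TorsionProfile:
    """Cosine-well profile E(theta) = A/2 * (1 - cos(k (theta - phase))).

    The phase is snapped to the grid and 180/k must be a grid multiple so
    both extrema land on grid points; the barrier of the returned profile
    then equals ``amplitude`` exactly (to 1e-9).
    """
    if amplitude < 0:
        raise InputError(f"amplitude must be >= 0, got {amplitude}")
    if periodicity < 1:
        raise InputError(f"periodicity must be >= 1, got {periodicity}")
    if grid_step <= 0 or abs(360.0 / grid_step - round(360.0 / grid_step)) > 1e-9:
        raise InputError(f"grid step {grid_step} must divide 360")
    if abs((180.0 / periodicity) / grid_step
           - round((180.0 / periodicity) / grid_step)) > 1e-9:
        raise InputError(
            f"180/periodicity ({180.0 / periodicity}) must be a multiple of "
            f"grid_step ({grid_step}) so both extrema fall on the grid"
        )
    phase = (round(phase_deg / grid_step) * grid_step) % 360.0
    n = int(round(360.0 / grid_step))
    angles = [i * grid_step for i in range(n)]
    energies = [
        amplitude / 2.0 * (1.0 - np.cos(np.radians(periodicity * (a - phase))))
        for a in angles
    ]
    return TorsionProfile(
        dihedral_spec=dihedral_spec,
        angles=tuple(angles),
        energies=tuple(float(e) for e in energies),
        periodic=True,
    )


def generate_torsion_suite(config: GeneratorConfig) -> dict[str, TorsionProfile]:
    """One random cosine-well profile per synthetic molecule."""
    rng = _stream(config, "torsion")
    suite = {}
    for i in range(config.n_molecules):
        amplitude = float(rng.uniform(*config.torsion_amplitude_range))
        periodicity = int(rng.choice(list(config.torsion_periodicities)))
        phase = float(rng.integers(0, 36) * 10.0)
        suite[f"SYN{i:02d}"] = generate_torsion_profile(
            amplitude, periodicity, phase, grid_step=10.0
        )
    return suite


def generate_docking_tables(
    config: GeneratorConfig, receptor: str = "SYNR", ligands: Sequence[str] = None
) -> list[DockingScoreTable]:
    """Sorted synthetic docking blocks (rank-1 global energy minimal)."""
    rng = _stream(config, "docking")
    if ligands is None:
        ligands = [f"SYN{i:02d}" for i in range(max(config.n_molecules, 1))]
    tables = []
    for ligand in ligands:
        glob = np.sort(rng.uniform(-40.0, -10.0, size=config.docking_block_size))
        rows = tuple(
            DockingRow(
                rank=i + 1,
                global_energy=float(glob[i]),
                attractive_vdw=float(rng.uniform(-20.0, -5.0)),
                repulsive_vdw=float(rng.uniform(0.0, 15.0)),
                ace=float(rng.uniform(-12.0, 0.0)),
            )
            for i in range(config.docking_block_size)
        )
        tables.append(DockingScoreTable(receptor=receptor, ligand=ligand, rows=rows))
    return tables


def write_fixture_suite(config: GeneratorConfig, outdir) -> list[str]:
    """Write the full synthetic suite to a directory; returns filenames."""
    from pathlib import Path

    from .io import write_report_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    molset = generate_molecules(config)
    payload = {
        "schema": "benzilkit.molecule_summary.v1",
        "comment": f"synthetic suite, seed {config.seed}",
        "molecules": [m.model_dump() for m in molset.molecules],
    }
    import json

    (outdir / "synthetic_molecules.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    written.append("synthetic_molecules.json")
    if not molset.ground_truth.empty:
        write_report_table(
            molset.ground_truth, outdir / "synthetic_ground_truth.csv"
        )
        written.append("synthetic_ground_truth.csv")

    vib = generate_vibrational_set(config)
    if vib.modes:
        vib_df = pd.DataFrame(
            {
                "calc": [m.wavenumber for m in vib.modes],
                "obs": [b.wavenumber for b in vib.bands],
                "technique": [b.technique for b in vib.bands],
            }
        )
        write_report_table(vib_df, outdir / "synthetic_vibrational.csv")
        written.append("synthetic_vibrational.csv")

    for mol_id, profile in generate_torsion_suite(config).items():
        df = pd.DataFrame(
            {"angle_deg": profile.angles, "energy_kj_mol": profile.energies}
        )
        name = f"synthetic_torsion_{mol_id}.csv"
        write_report_table(df, outdir / name)
        written.append(name)

    docking = generate_docking_tables(config)
    rows = [
        {"receptor": t.receptor, "ligand": t.ligand, **r.model_dump()}
        for t in docking
        for r in t.rows
    ]
    write_report_table(rows, outdir / "synthetic_docking.csv")
    written.append("synthetic_docking.csv")
    return written
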