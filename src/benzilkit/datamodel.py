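"""Typed data model shared by every analysis stage.

All energies are in eV, wavelengths in nm, wavenumbers in cm**-1, dipoles in
Debye and torsional energies in kJ/mol.  Units are part of the schema: loaders
convert on the way in, nothing downstream guesses.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class BenzilkitError(Exception):
    """Base class for every error raised by this package."""


class SchemaError(BenzilkitError):
    """Input file does not match the documented schema."""


class InputError(BenzilkitError):
    """Operation called with inconsistent or incomplete inputs."""


class DomainError(BenzilkitError, ValueError):
    """Numeric argument outside the operation's domain."""


class StateError(BenzilkitError):
    """Operation applied to data in the wrong state (e.g. re-scaling)."""


Technique = Literal["IR", "Raman"]


class ExcitationRecord(BaseModel):
    """One electronic transition: wavelength, oscillator strength and the
    orbital pairs that compose it (weights in percent; minor contributions
    may be omitted, so weights need not sum to 100)."""

    model_config = ConfigDict(frozen=True)

    lambda_nm: float = Field(gt=0)
    f: float = Field(ge=0)
    composition: tuple[tuple[str, str, float], ...] = ()

    @model_validator(mode="after")
    def _check_composition(self) -> "ExcitationRecord":
        total = 0.0
        for donor, acceptor, weight in self.composition:
            if not 0 < weight <= 100:
                raise ValueError(
                    f"composition weight {weight} for {donor}->{acceptor} "
                    "must lie in (0, 100]"
                )
            total += weight
        if total > 100 + 1e-9:
            raise ValueError(f"composition weights sum to {total} > 100")
        return self


class NLOInput(BaseModel):
    """Nonlinear-optical input: either the published scalars (esu, Debye) or
    raw tensor components in atomic units (Kleinman-symmetric beta set of 10,
    six independent gamma components)."""

    model_config = ConfigDict(frozen=True)

    mu_debye: Optional[float] = None
    alpha_esu: Optional[float] = None
    beta_esu: Optional[float] = None
    gamma_esu: Optional[float] = None

    dipole_au: Optional[tuple[float, float, float]] = None
    alpha_au: Optional[dict[str, float]] = None
    beta_au: Optional[dict[str, float]] = None
    gamma_au: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _at_least_one_form(self) -> "NLOInput":
        scalars = (self.mu_debye, self.alpha_esu, self.beta_esu, self.gamma_esu)
        tensors = (self.dipole_au, self.alpha_au, self.beta_au, self.gamma_au)
        if all(v is None for v in scalars) and all(v is None for v in tensors):
            raise ValueError("NLO input needs scalar or tensor data")
        for v in scalars:
            if v is not None and not math.isfinite(v):
                raise ValueError("NLO scalar magnitudes must be finite")
        return self


class CalcMode(BaseModel):
    """One calculated normal mode with its spectral intensities."""

    model_config = ConfigDict(frozen=True)

    wavenumber: float = Field(gt=0)
    ir_intensity: float = Field(default=0.0, ge=0)
    raman_activity: float = Field(default=0.0, ge=0)
    assignment: str = ""
    scaled: bool = False


class ObsBand(BaseModel):
    """One observed IR or Raman band."""

    model_config = ConfigDict(frozen=True)

    wavenumber: float = Field(gt=0)
    technique: Technique


class BandPair(BaseModel):
    """A calculated mode matched to an observed band of one technique."""

    model_config = ConfigDict(frozen=True)

    calc: float = Field(gt=0)
    obs: float = Field(gt=0)
    technique: Technique
    assignment: str = ""


class TorsionProfile(BaseModel):
    """Relaxed potential-energy scan over one dihedral period.

    ``angles`` is a strictly increasing grid in [0, 360) degrees; ``energies``
    are kJ/mol (loaders convert hartree inputs).
    """

    model_config = ConfigDict(frozen=True)

    dihedral_spec: str = ""
    angles: tuple[float, ...]
    energies: tuple[float, ...]
    periodic: bool = True

    @model_validator(mode="after")
    def _check_grid(self) -> "TorsionProfile":
        if len(self.angles) < 3:
            raise ValueError("torsion profile needs at least 3 grid points")
        if len(self.angles) != len(self.energies):
            raise ValueError("angles and energies differ in length")
        for a in self.angles:
            if not 0 <= a < 360:
                raise ValueError(f"angle {a} outside [0, 360)")
        for prev, cur in zip(self.angles, self.angles[1:]):
            if cur <= prev:
                raise ValueError("angle grid must be strictly increasing")
        if not all(math.isfinite(e) for e in self.energies):
            raise ValueError("torsion energies must be finite")
        return self


class MoleculeSummary(BaseModel):
    """One molecule's post-SCF electronic-structure summary.

    ``ip_vertical``/``ea_vertical`` are stored independently of the frontier
    orbital energies: the two need not satisfy Koopmans' relation and both
    families of published values must remain reproducible.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    name: str = ""
    e_homo: float
    e_lumo: float
    ip_vertical: Optional[float] = None
    ea_vertical: Optional[float] = None
    excitations: tuple[ExcitationRecord, ...] = ()
    dipole_debye: Optional[float] = None
    nlo: Optional[NLOInput] = None
    vib_calc: tuple[CalcMode, ...] = ()
    vib_obs: tuple[ObsBand, ...] = ()
    torsion: Optional[TorsionProfile] = None
    method_note: str = ""

    @model_validator(mode="after")
    def _check_invariants(self) -> "MoleculeSummary":
        if not self.e_homo < self.e_lumo:
            raise ValueError(
                f"molecule {self.id!r}: e_homo ({self.e_homo}) must be below "
                f"e_lumo ({self.e_lumo})"
            )
        if (
            self.ip_vertical is not None
            and self.ea_vertical is not None
            and not self.ip_vertical > self.ea_vertical
        ):
            raise ValueError(
                f"molecule {self.id!r}: ip_vertical must exceed ea_vertical"
            )
        return self

    @property
    def strongest_excitation(self) -> ExcitationRecord:
        if not self.excitations:
            raise InputError(f"molecule {self.id!r} has no excitation records")
        return max(self.excitations, key=lambda ex: ex.f)


class ReactivityDescriptors(BaseModel):
    """Conceptual-DFT global reactivity descriptors derived from (IP, EA)."""

    model_config = ConfigDict(frozen=True)

    ip: float
    ea: float
    chi: float
    mu_chem: float
    eta: float
    s: float
    omega: float
    gap_ipea: float


class PhotovoltaicRecord(BaseModel):
    """One dye's DSSC screening quantities."""

    model_config = ConfigDict(frozen=True)

    id: str = ""
    f: float = Field(ge=0)
    lhe: float = Field(ge=0, lt=1)
    lambda_max_nm: float = Field(gt=0)
    e00: float = Field(gt=0)
    e_dye: float
    e_dye_star: float
    e_cb: float = -4.00
    dg_inject: float


class DockingRow(BaseModel):
    """One ranked conformation of a receptor-ligand complex."""

    model_config = ConfigDict(frozen=True)

    rank: int = Field(ge=1)
    global_energy: float
    attractive_vdw: float
    repulsive_vdw: float = Field(ge=0)
    ace: float


class DockingScoreTable(BaseModel):
    """Ranked conformations of one receptor-ligand complex (geometric-docking
    server output: global energy, attractive/repulsive vdW, atomic contact
    energy; score units are the server's own)."""

    model_config = ConfigDict(frozen=True)

    receptor: str
    ligand: str
    rows: tuple[DockingRow, ...]

    @model_validator(mode="after")
    def _check_block(self) -> "DockingScoreTable":
        label = f"{self.receptor}-{self.ligand}"
        ranks = [r.rank for r in self.rows]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"block {label}: ranks must be 1..n without gaps")
        if self.rows:
            energies = [r.global_energy for r in self.rows]
            if min(energies) < energies[0]:
                raise ValueError(
                    f"block {label}: rank 1 must carry the minimum global energy"
                )
        return self


class QsarModel(BaseModel):
    """Fitted linear binding-energy model for one receptor.

    ``coefficients`` holds (b_ip, b_ea, b_s, b_omega, intercept); the design
    is saturated when the number of training molecules equals the number of
    unknowns, in which case the solve is exact interpolation.
    """

    model_config = ConfigDict(frozen=True)

    receptor: str
    coefficients: tuple[float, float, float, float, float]
    design_ids: tuple[str, ...]
    condition_number: float
    exact_fit: bool
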