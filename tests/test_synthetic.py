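"""Synthetic-data generators: determinism, validity, ground-truth recovery."""

import pytest

from benzilkit.datamodel import InputError
from benzilkit.reactivity import compute_descriptors
from benzilkit.synthetic import (
    GeneratorConfig,
    generate_docking_tables,
    generate_molecules,
    generate_torsion_profile,
    generate_torsion_suite,
    generate_vibrational_set,
    write_fixture_suite,
)
from benzilkit.torsion import barrier_height
from benzilkit.vibrational import apply_scaling, pair_bands, rmsd


def test_molecule_generator_is_deterministic_and_valid():
    config = GeneratorConfig(seed=1, n_molecules=5)
    a = generate_molecules(config)
    b = generate_molecules(config)
    assert a.molecules == b.molecules
    assert a.ground_truth.equals(b.ground_truth)
    for mol in a.molecules:
        assert mol.e_homo < mol.e_lumo
        assert mol.ip_vertical > mol.ea_vertical


def test_ground_truth_descriptors_recovered_exactly():
    molset = generate_molecules(GeneratorConfig(seed=3))
    for mol, row in zip(molset.molecules, molset.ground_truth.itertuples(index=False)):
        d = compute_descriptors(mol.ip_vertical, mol.ea_vertical)
        assert d.chi == row.chi and d.eta == row.eta and d.omega == row.omega


def test_zero_molecules_gives_empty_list():
    molset = generate_molecules(GeneratorConfig(seed=0, n_molecules=0))
    assert molset.molecules == []


def test_invalid_ranges_rejected():
    with pytest.raises(ValueError, match="ip_range"):
        GeneratorConfig(ip_range=(6.0, 5.0))
    with pytest.raises(ValueError, match="strictly above"):
        GeneratorConfig(ip_range=(6.0, 7.0), ea_range=(5.0, 6.5))
    with pytest.raises(ValueError):
        GeneratorConfig(vib_noise_sigma=-1.0)


def test_noiseless_vibrational_set_has_zero_rmsd():
    vib = generate_vibrational_set(GeneratorConfig(seed=2, vib_noise_sigma=0.0))
    scaled = apply_scaling(vib.modes, vib.scaling)
    pairs = pair_bands(scaled, vib.bands, mode="assigned")
    assert rmsd(pairs) == pytest.approx(0.0, abs=1e-9)


def test_vibrational_rmsd_within_chi_distribution_bounds():
    vib = generate_vibrational_set(
        GeneratorConfig(seed=7, n_modes=200, vib_noise_sigma=5.0)
    )
    scaled = apply_scaling(vib.modes, vib.scaling)
    value = rmsd(pair_bands(scaled, vib.bands, mode="assigned"))
    assert 4.25 <= value <= 5.75


def test_vibrational_set_deterministic():
    config = GeneratorConfig(seed=11)
    assert generate_vibrational_set(config) == generate_vibrational_set(config)


def test_torsion_profile_barrier_equals_amplitude():
    profile = generate_torsion_profile(16.3175, 2, 130.0, grid_step=10.0)
    assert barrier_height(profile) == pytest.approx(16.3175, abs=1e-9)
    flat = generate_torsion_profile(0.0, 2, 0.0)
    assert barrier_height(flat) == 0.0
    assert generate_torsion_profile(5.0, 1, 40.0) == generate_torsion_profile(5.0, 1, 40.0)


def test_torsion_profile_config_errors():
    with pytest.raises(InputError, match="divide"):
        generate_torsion_profile(5.0, 2, 0.0, grid_step=7.0)
    with pytest.raises(InputError, match="multiple"):
        generate_torsion_profile(5.0, 4, 0.0, grid_step=10.0)  # 45 deg off-grid
    with pytest.raises(InputError):
        generate_torsion_profile(-1.0, 2, 0.0)


def test_docking_generator_blocks_are_valid():
    tables = generate_docking_tables(GeneratorConfig(seed=5, n_molecules=3))
    assert len(tables) == 3
    for t in tables:
        energies = [r.global_energy for r in t.rows]
        assert energies == sorted(energies)


def test_fixture_suite_regenerates_byte_identical(tmp_path):
    config = GeneratorConfig(seed=13, n_molecules=3, n_modes=50)
    dir_a, dir_b = tmp_path / "a", tmp_path / "b"
    names_a = write_fixture_suite(config, dir_a)
    names_b = write_fixture_suite(config, dir_b)
    assert names_a == names_b
    for name in names_a:
        assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()
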