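"""NLO scalar invariants: contraction rules, rotation invariance, esu
conversion and urea fold-enhancements."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from benzilkit.datamodel import DomainError, InputError
from benzilkit.nlo import (
    AU_TO_ESU,
    BETA_KEYS,
    GAMMA_KEYS,
    UREA_BETA_ESU,
    au_to_esu,
    beta_total,
    gamma_average,
    ratio_to_reference,
    urea_ratio_table,
)

AXES = {"x": 0, "y": 1, "z": 2}


def beta_tensor(components):
    """Full Kleinman-symmetric rank-3 tensor from the 10 components."""
    t = np.zeros((3, 3, 3))
    for key, value in components.items():
        idx = tuple(AXES[c] for c in key)
        for perm in set(itertools.permutations(idx)):
            t[perm] = value
    return t


def beta_total_oracle(components):
    """Explicit summation: beta_i = sum_j beta_ijj, then the norm."""
    t = beta_tensor(components)
    vec = np.array([sum(t[i, j, j] for j in range(3)) for i in range(3)])
    return float(np.linalg.norm(vec))


def gamma_components_from_tensor(t):
    return {key: t[tuple(AXES[c] for c in key)] for key in GAMMA_KEYS}


def gamma_average_oracle(t):
    return float(
        sum(t[i, i, j, j] + t[i, j, i, j] + t[i, j, j, i] for i in range(3) for j in range(3))
        / 15.0
    )


def random_symmetric_rank4(rng):
    raw = rng.normal(size=(3, 3, 3, 3))
    t = np.zeros_like(raw)
    for perm in itertools.permutations(range(4)):
        t += np.transpose(raw, perm)
    return t / 24.0


def test_beta_trivial_cases():
    zeros = {k: 0.0 for k in BETA_KEYS}
    assert beta_total(zeros) == 0.0
    single_axis = dict(zeros, xxx=3.0, xyy=4.0)
    assert beta_total(single_axis) == pytest.approx(7.0)


def test_beta_missing_component_rejected():
    with pytest.raises(InputError, match="zzz"):
        beta_total({k: 1.0 for k in BETA_KEYS if k != "zzz"})


def test_beta_matches_explicit_summation_oracle():
    rng = np.random.default_rng(20240917)
    for _ in range(20):
        comps = {k: float(rng.normal(scale=50)) for k in BETA_KEYS}
        assert beta_total(comps) == pytest.approx(
            beta_total_oracle(comps), rel=1e-12
        )


def test_beta_rotation_invariance():
    rng = np.random.default_rng(7)
    for trial in range(10):
        comps = {k: float(rng.normal(scale=10)) for k in BETA_KEYS}
        reference = beta_total(comps)
        rot = Rotation.random(random_state=100 + trial).as_matrix()
        rotated = np.einsum("ia,jb,kc,abc->ijk", rot, rot, rot, beta_tensor(comps))
        rotated_comps = {
            key: rotated[tuple(AXES[c] for c in key)] for key in BETA_KEYS
        }
        assert beta_total(rotated_comps) == pytest.approx(reference, rel=1e-9)


def test_gamma_trivial_cases():
    comps = dict.fromkeys(GAMMA_KEYS, 0.0)
    comps.update(xxxx=5.0, yyyy=5.0, zzzz=5.0)
    assert gamma_average(comps) == pytest.approx(3.0)
    assert gamma_average(dict.fromkeys(GAMMA_KEYS, 2.0)) == pytest.approx(18.0 / 5.0)


def test_gamma_matches_oracle_and_rotation_invariance():
    rng = np.random.default_rng(11)
    for trial in range(10):
        t = random_symmetric_rank4(rng)
        value = gamma_average(gamma_components_from_tensor(t))
        assert value == pytest.approx(gamma_average_oracle(t), rel=1e-9)
        rot = Rotation.random(random_state=200 + trial).as_matrix()
        rotated = np.einsum("ia,jb,kc,ld,abcd->ijkl", rot, rot, rot, rot, t)
        assert gamma_average(
            gamma_components_from_tensor(rotated)
        ) == pytest.approx(value, rel=1e-9)


def test_au_to_esu():
    assert au_to_esu(1.0, "beta") == pytest.approx(8.6393e-33)
    assert au_to_esu(2.0, "alpha") == pytest.approx(2.9638e-25)
    assert au_to_esu(0.0, "gamma") == 0.0
    with pytest.raises(InputError):
        au_to_esu(1.0, "delta")
    assert set(AU_TO_ESU) == {"alpha", "beta", "gamma"}


def test_ratio_rounding_and_domain():
    assert ratio_to_reference(8.295e-30) == 64
    assert ratio_to_reference(1.927e-30) == 15
    assert ratio_to_reference(1.0, 1.0) == 1
    assert ratio_to_reference(0.195e-30) == 2  # half rounds away from zero
    with pytest.raises(DomainError):
        ratio_to_reference(1.0, 0.0)


def test_all_published_urea_ratios(nlo_reference):
    table = urea_ratio_table(nlo_reference, reference_esu=UREA_BETA_ESU)
    assert dict(zip(table["id"], table["urea_ratio"])) == {
        "BZL": 15, "DMB": 31, "DFB": 29, "DCB": 52, "DBB": 64,
    }
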