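"""Linear QSAR of docking binding energy on reactivity descriptors.

The model is the saturated linear form

    BE = b_ip * IP + b_ea * EA + b_s * S + b_omega * omega + intercept

fitted per receptor.  With five training molecules and five unknowns the
system is square: a nonsingular design is solved exactly and the fit
interpolates the training responses.  Overdetermined designs fall back to
least squares.  Chemical potential, electronegativity and hardness are
excluded from the design — they are linear or derived combinations of the
included descriptors.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import InputError, QsarModel

PREDICTORS = ("ip", "ea", "s", "omega")
CONDITION_WARN = 1e8


class SingularDesignError(InputError):
    """Square design matrix is numerically singular."""


def _design_matrix(descriptors: pd.DataFrame) -> np.ndarray:
    missing = [c for c in PREDICTORS if c not in descriptors.columns]
    if missing:
        raise InputError(f"descriptor table missing columns: {missing}")
    X = descriptors.loc[:, list(PREDICTORS)].to_numpy(dtype=float)
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _collinear_columns(A: np.ndarray) -> list[str]:
    # name columns implicated by the null-space direction of a rank-deficient design
    names = list(PREDICTORS) + ["intercept"]
    _, _, vt = np.linalg.svd(A)
    null_vec = np.abs(vt[-1])
    involved = null_vec > 1e-8 * null_vec.max()
    return [n for n, flag in zip(names, involved) if flag]


def fit(
    descriptors: pd.DataFrame,
    response: Sequence[float] | Mapping[str, float],
    receptor: str = "",
) -> QsarModel:
    """Fit the binding-energy model.

    ``descriptors`` needs columns ip, ea, s, omega and (optionally) ``id``;
    ``response`` is a sequence aligned with the rows, or a mapping id->BE.
    Square nonsingular systems are solved exactly; otherwise least squares.
    A condition number above 1e8 emits a warning.
    """
    ids = (
        tuple(str(i) for i in descriptors["id"])
        if "id" in descriptors.columns
        else tuple(str(i) for i in range(len(descriptors)))
    )
    if isinstance(response, Mapping):
        try:
            y = np.array([response[i] for i in ids], dtype=float)
        except KeyError as exc:
            raise InputError(f"response vector missing molecule {exc}") from exc
    else:
        y = np.asarray(list(response), dtype=float)
    A = _design_matrix(descriptors)
    n, p = A.shape
    if len(y) != n:
        raise InputError(f"{n} descriptor rows but {len(y)} responses")
    if n < p:
        raise InputError(
            f"need at least {p} molecules for the {p - 1}-predictor model, got {n}"
        )
    cond = float(np.linalg.cond(A))
    if np.linalg.matrix_rank(A) < p:
        raise SingularDesignError(
            "singular design; collinear columns: " + ", ".join(_collinear_columns(A))
        )
    if cond > CONDITION_WARN:
        warnings.warn(
            f"ill-conditioned QSAR design (condition number {cond:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    if n == p:
        coef = np.linalg.solve(A, y)
        exact = True
    else:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        exact = False
    return QsarModel(
        receptor=receptor,
        coefficients=tuple(float(c) for c in coef),
        design_ids=ids,
        condition_number=cond,
        exact_fit=exact,
    )


def predict(model: QsarModel, descriptors: pd.DataFrame | Sequence[float]) -> np.ndarray:
    """Predicted binding energies: intercept + coefficients . descriptors."""
    if isinstance(descriptors, pd.DataFrame):
        A = _design_matrix(descriptors)
    else:
        row = np.asarray(list(descriptors), dtype=float)
        if row.ndim == 1:
            row = row[None, :]
        A = np.hstack([row, np.ones((row.shape[0], 1))])
    return A @ np.array(model.coefficients)


def compare_signs(
    model: QsarModel, printed: Sequence[float]
) -> pd.DataFrame:
    """Per-coefficient sign comparison against an externally reported
    coefficient 5-tuple.  Purely descriptive: no pass/fail semantics."""
    names = list(PREDICTORS) + ["intercept"]
    printed = list(printed)
    if len(printed) != 5:
        raise InputError("printed coefficient tuple must have 5 entries")
    rows = []
    for name, fitted, ref in zip(names, model.coefficients, printed):
        rows.append(
            {
                "coefficient": name,
                "fitted": fitted,
                "printed": ref,
                "fitted_sign": int(np.sign(fitted)),
                "printed_sign": int(np.sign(ref)),
                "signs_agree": bool(np.sign(fitted) == np.sign(ref)),
            }
        )
    return pd.DataFrame(rows)


def coefficient_report(
    descriptors: pd.DataFrame,
    responses: Mapping[str, Mapping[str, float]],
    printed: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Fit one model per receptor and report coefficients, conditioning and
    (when printed coefficients are supplied) sign agreement and the maximum
    deviation of the printed model's predictions from the responses.

    The printed integer coefficients are compared, never adopted: rounding
    exact-solve coefficients to integers destroys an interpolating fit, so
    the discrepancy is reported as data.
    """
    rows = []
    for receptor, response in responses.items():
        model = fit(descriptors, response, receptor=receptor)
        row = {
            "receptor": receptor,
            **{
                f"b_{name}": c
                for name, c in zip(list(PREDICTORS) + ["intercept"], model.coefficients)
            },
            "condition_number": model.condition_number,
            "exact_fit": model.exact_fit,
            "max_train_residual": float(
                np.max(np.abs(predict(model, descriptors)
                              - np.array([response[i] for i in model.design_ids])))
            ),
        }
        if printed and receptor in printed:
            ref = list(printed[receptor])
            signs = compare_signs(model, ref)
            ref_pred = predict(
                QsarModel(
                    receptor=receptor,
                    coefficients=tuple(float(c) for c in ref),
                    design_ids=model.design_ids,
                    condition_number=model.condition_number,
                    exact_fit=False,
                ),
                descriptors,
            )
            y = np.array([response[i] for i in model.design_ids])
            row["sign_agreement"] = int(signs["signs_agree"].sum())
            row["printed_model_max_abs_error"] = float(np.max(np.abs(ref_pred - y)))
        rows.append(row)
    return pd.DataFrame(rows)
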