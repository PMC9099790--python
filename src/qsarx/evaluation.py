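"""Model evaluation: error metrics, fivefold cross-validation, the frozen
published regression model, and IE%-based screening.

Metrics
-------
For observed ``y`` and predicted ``yhat`` of length n:

* ``MAPE = (100/n) sum |(y_i - yhat_i) / y_i|``  (percent; undefined when
  any ``y_i = 0``)
* ``MSE  = (1/n) sum (y_i - yhat_i)^2``, ``RMSE = sqrt(MSE)``
* ``SD``: sample standard deviation (n-1 denominator) of the residuals
  ``yhat_i - y_i`` about their mean.  This is the only reading of the
  literature's mixed SD formula consistent with SD <= RMSE in reported
  metric sets.

Published model
---------------
The frozen five-term regression predicting inhibition efficiency from
pKa and HSAB descriptors:

    IE% = 812.1748 E_HOMO + 33.1669 dN + 823.4630 E_LUMO
          + 6579.0080 omega + 0.5287 pKa

For fidelity with the source tables, ``omega`` fed to this model must be on
the table-compatible scale (chi/4) — see :mod:`qsarx.descriptors`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .frols import SelectedModel, build_design_matrix, frols_select, predict, resolve_label

__all__ = [
    "Metrics",
    "CVResult",
    "PUBLISHED_COEFFICIENTS",
    "ScreeningThresholds",
    "compute_metrics",
    "fivefold_cv",
    "predict_published",
    "screen",
]

#: Frozen coefficients of the published five-term model (IE% per unit).
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "e_homo": 812.1748,
    "delta_n": 33.1669,
    "e_lumo": 823.4630,
    "omega": 6579.0080,
    "pka": 0.5287,
}


@dataclass(frozen=True)
class Metrics:
    """Error metrics; ``mape`` is NaN when any observed value is zero."""

    mape: float
    sd: float
    mse: float
    rmse: float


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> Metrics:
    """MAPE, residual SD, MSE, and RMSE for a prediction set (n >= 2)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs yhat {yhat.shape}")
    n = y.size
    if n < 2:
        raise ValueError(f"metrics require at least 2 observations, got {n}")
    resid = yhat - y
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    sd = float(np.std(resid, ddof=1))
    if np.any(y == 0):
        warnings.warn("MAPE undefined: some observed values are zero", UserWarning, stacklevel=2)
        mape = float("nan")
    else:
        mape = float(np.mean(np.abs(resid / y)) * 100.0)
    return Metrics(mape=mape, sd=sd, mse=mse, rmse=rmse)


@dataclass
class CVResult:
    """Fivefold cross-validation outcome.

    ``fold_indices[k]`` are the validation rows of fold k (0-based); every
    row appears in exactly one fold.  ``best_index`` is the argmin of
    ``fold_mse`` — that fold's model is the one promoted for prediction.
    """

    fold_models: tuple[SelectedModel, ...]
    fold_mse: np.ndarray
    fold_indices: tuple[np.ndarray, ...]
    seed: int

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fold_mse))

    @property
    def promoted(self) -> SelectedModel:
        return self.fold_models[self.best_index]


def fivefold_cv(
    table: pd.DataFrame,
    seed: int = 0,
    rho: float = 0.005,
    labels: Optional[Sequence[str]] = None,
    n_folds: int = 5,
    **frols_kwargs,
) -> CVResult:
    """Fivefold cross-validation of FROLS model identification.

    Rows are shuffled with a seeded generator and split into ``n_folds``
    near-equal groups; each group serves as the validation set exactly once
    while FROLS fits on the remainder, scored by validation MSE.  The model
    with the lowest validation MSE is ``promoted``.
    """
    table = table.loc[~table["ie_obs"].isna()].reset_index(drop=True)
    n = len(table)
    if n < 2 * n_folds:
        raise ValueError(f"fivefold CV requires at least {2 * n_folds} records with observed IE%, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    models, mses = [], []
    for held_out in folds:
        mask = np.zeros(n, dtype=bool)
        mask[held_out] = True
        D_train = build_design_matrix(table.loc[~mask], labels=labels)
        model = frols_select(D_train, rho=rho, **frols_kwargs)
        val = table.loc[mask]
        yhat = predict(model, val)
        mse = float(np.mean((val["ie_obs"].to_numpy(dtype=float) - yhat) ** 2))
        models.append(model)
        mses.append(mse)
    return CVResult(
        fold_models=tuple(models),
        fold_mse=np.asarray(mses),
        fold_indices=tuple(np.sort(f) for f in folds),
        seed=seed,
    )


def predict_published(
    descriptors: Union[Mapping[str, float], pd.DataFrame],
) -> Union[float, np.ndarray]:
    """Evaluate the frozen published five-term model.

    Accepts a mapping (one compound) or a DataFrame (one row per compound)
    holding pka, e_homo, e_lumo, omega, delta_n (x-symbols accepted).
    ``omega`` must be on the table-compatible (chi/4) scale.  Output is
    unclipped IE%.
    """
    if isinstance(descriptors, pd.DataFrame):
        absent = [k for k in PUBLISHED_COEFFICIENTS if k not in descriptors.columns]
        if absent:
            raise KeyError(f"missing descriptor column(s) for the published model: {absent}")
        vals = descriptors[list(PUBLISHED_COEFFICIENTS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite descriptor values for the published model")
        coef = np.array(list(PUBLISHED_COEFFICIENTS.values()))
        return vals @ coef
    supplied = {resolve_label(k): float(v) for k, v in descriptors.items()}
    total = 0.0
    for term, coef in PUBLISHED_COEFFICIENTS.items():
        if term not in supplied:
            raise KeyError(f"missing descriptor {term!r} for the published model")
        if not np.isfinite(supplied[term]):
            raise ValueError(f"non-finite value for descriptor {term!r}")
        total += coef * supplied[term]
    return total


@dataclass(frozen=True)
class ScreeningThresholds:
    """IE% category boundaries.

    Defaults: predictions above 100% are physically unrealistic and
    excluded; >= 95% is the high-efficiency band used for candidate
    selection; the moderate band's lower edge (84.92%) is the smallest
    efficiency in the published intermediate-performance group.
    """

    unrealistic_above: float = 100.0
    high_at_least: float = 95.0
    moderate_at_least: float = 84.92


def screen(
    predictions: Iterable[Tuple[str, float]],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> pd.DataFrame:
    """Partition predicted efficiencies into screening categories.

    Returns a DataFrame with columns ``name``, ``ie_pred``, ``category``
    where category is one of ``unrealistic`` (> 100), ``high`` (>= 95),
    ``moderate`` (>= 84.92), ``low`` (below the moderate band).
    """
    t = thresholds
    rows = []
    for name, ie in predictions:
        ie = float(ie)
        if ie > t.unrealistic_above:
            cat = "unrealistic"
        elif ie >= t.high_at_least:
            cat = "high"
        elif ie >= t.moderate_at_least:
            cat = "moderate"
        else:
            cat = "low"
        rows.append({"name": name, "ie_pred": ie, "category": cat})
    return pd.DataFrame(rows, columns=["name", "ie_pred", "category"])
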