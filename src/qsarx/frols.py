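"""Linear-in-parameters design matrix and FROLS/ERR sparse term selection.

The response (inhibition efficiency, IE%) is modelled as a static linear
combination of descriptor terms,

    y_i = sum_j beta_j x_{i,j},   i = 1..N,

with no intercept.  The candidate dictionary is the N x M matrix whose
columns are the descriptor terms; the forward regression orthogonal least
squares (FROLS) algorithm selects a sparse subset by repeatedly picking the
candidate with the highest error reduction ratio (ERR),

    ERR_m = (y' p_m)^2 / ((p_m' p_m) (y' y)),

i.e. the fraction of the response's (uncentred) energy the candidate
explains — the squared cosine between y and p_m.  From the second step
onward every remaining candidate is first orthogonalized (classical
Gram-Schmidt, with one reorthogonalization pass for numerical stability)
against the already-selected basis, so each new term contributes information
independent of its predecessors.  Selection stops when the error-to-signal
ratio ESR = 1 - sum(ERR) falls to a threshold ``rho``, when no candidate
offers more than a minimum ERR gain, when ``max_terms`` is reached, or when
every remaining candidate is numerically collinear with the selected set.
Final weights are ordinary least squares on the original (non-orthogonal)
selected columns.

FROLS is greedy: on orthogonal dictionaries it coincides with exhaustive
best-subset selection, but in general the selected k-subset may have a
residual no smaller than the best exhaustive k-subset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.linalg

from .descriptors import (
    IRON_REFERENCE,
    CompoundRecord,
    MetalReference,
    compute_descriptors,
)

__all__ = [
    "CANONICAL_LABELS",
    "X_SYMBOLS",
    "DesignMatrix",
    "SelectedModel",
    "descriptor_table",
    "build_design_matrix",
    "err_ratio",
    "frols_select",
    "estimate_weights",
    "predict",
]

#: Descriptor labels in dictionary order x1..x10.
CANONICAL_LABELS: tuple[str, ...] = (
    "mw", "pka", "logp", "logs", "psa", "alpha",
    "e_homo", "e_lumo", "omega", "delta_n",
)

#: Symbolic aliases x1..x10 for the canonical labels.
X_SYMBOLS: dict[str, str] = {f"x{i + 1}": lab for i, lab in enumerate(CANONICAL_LABELS)}


def resolve_label(label: str) -> str:
    """Map an 'x7'-style symbol or canonical name to the canonical name."""
    lab = label.strip().lower()
    lab = X_SYMBOLS.get(lab, lab)
    if lab not in CANONICAL_LABELS:
        raise KeyError(
            f"unknown descriptor label {label!r}; expected one of "
            f"{CANONICAL_LABELS} or x1..x{len(CANONICAL_LABELS)}"
        )
    return lab


class CollinearityWarning(UserWarning):
    """A candidate term was skipped as numerically collinear."""


@dataclass(frozen=True)
class DesignMatrix:
    """Candidate dictionary: labelled columns plus the observed response."""

    labels: tuple[str, ...]
    columns: np.ndarray  # shape (N, M)
    response: np.ndarray  # shape (N,)

    def __post_init__(self) -> None:
        X = np.asarray(self.columns, dtype=float)
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "columns", X)
        object.__setattr__(self, "response", y)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError(f"design matrix must be N x M with N, M >= 1, got shape {X.shape}")
        if len(self.labels) != X.shape[1]:
            raise ValueError(f"{len(self.labels)} labels for {X.shape[1]} columns")
        if y.shape != (X.shape[0],):
            raise ValueError("response length must match the number of rows")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("design matrix and response must be finite")
        norms = np.linalg.norm(X, axis=0)
        if np.any(norms == 0):
            dead = [self.labels[j] for j in np.flatnonzero(norms == 0)]
            raise ValueError(f"zero-norm candidate column(s): {dead}")
        variances = X.var(axis=0)
        flat = [self.labels[j] for j in np.flatnonzero(variances == 0)
                if self.labels[j] != "intercept"]
        if flat:
            warnings.warn(
                f"zero-variance candidate column(s) retained: {flat}",
                UserWarning,
                stacklevel=3,
            )

    @property
    def n_obs(self) -> int:
        return self.columns.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.columns.shape[1]

    def column(self, label: str) -> np.ndarray:
        if label not in self.labels:
            label = resolve_label(label)
        return self.columns[:, self.labels.index(label)]


@dataclass
class SelectedModel:
    """Result of FROLS term selection.

    ``terms`` are indices into ``design_labels`` in selection order;
    ``err_per_term`` holds each term's ERR measured after orthogonalization
    against its predecessors, so the values sum to SERR <= 1 and the order
    reflects decreasing marginal contribution, not raw ERR.
    """

    design_labels: tuple[str, ...]
    terms: tuple[int, ...]
    weights: np.ndarray
    err_per_term: np.ndarray
    rho: float
    stop_reason: str = "esr"
    skipped_collinear: tuple[int, ...] = field(default_factory=tuple)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.design_labels[j] for j in self.terms)

    @property
    def serr(self) -> float:
        return float(np.sum(self.err_per_term))

    @property
    def esr(self) -> float:
        return 1.0 - self.serr

    def coefficients(self) -> dict[str, float]:
        return {lab: float(w) for lab, w in zip(self.labels, self.weights)}

    def to_json(self) -> str:
        payload = {
            "labels": list(self.design_labels),
            "terms": list(self.terms),
            "weights": [float(w) for w in self.weights],
            "err_per_term": [float(e) for e in self.err_per_term],
            "serr": self.serr,
            "esr": self.esr,
            "rho": self.rho,
            "provenance": {"stop_reason": self.stop_reason,
                           "skipped_collinear": list(self.skipped_collinear)},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SelectedModel":
        d = json.loads(text)
        prov = d.get("provenance", {})
        return cls(
            design_labels=tuple(d["labels"]),
            terms=tuple(d["terms"]),
            weights=np.asarray(d["weights"], dtype=float),
            err_per_term=np.asarray(d["err_per_term"], dtype=float),
            rho=float(d["rho"]),
            stop_reason=prov.get("stop_reason", "unknown"),
            skipped_collinear=tuple(prov.get("skipped_collinear", ())),
        )


def descriptor_table(
    records: Iterable[CompoundRecord],
    metal: MetalReference = IRON_REFERENCE,
    omega_mode: str = "standard",
) -> pd.DataFrame:
    """Assemble the full per-compound descriptor frame.

    ``omega`` and ``delta_n`` are taken from the record when present
    (pre-tabulated or synthetic values) and otherwise derived from the
    frontier-orbital energies via the HSAB operations.
    """
    rows = []
    for rec in records:
        row = {
            "name": rec.name, "mw": rec.mw, "pka": rec.pka, "logp": rec.logp,
            "logs": rec.logs, "psa": rec.psa, "alpha": rec.alpha,
            "e_homo": rec.e_homo, "e_lumo": rec.e_lumo,
        }
        if rec.omega is None or rec.delta_n is None:
            hsab = compute_descriptors(rec, metal=metal, mode=omega_mode)
            row["omega"] = hsab.omega if rec.omega is None else rec.omega
            row["delta_n"] = hsab.delta_n if rec.delta_n is None else rec.delta_n
        else:
            row["omega"] = rec.omega
            row["delta_n"] = rec.delta_n
        row["ie_obs"] = np.nan if rec.ie_obs is None else rec.ie_obs
        rows.append(row)
    return pd.DataFrame(rows, columns=["name", *CANONICAL_LABELS, "ie_obs"])


def build_design_matrix(
    table: Union[pd.DataFrame, Iterable[CompoundRecord]],
    labels: Optional[Sequence[str]] = None,
    *,
    metal: MetalReference = IRON_REFERENCE,
    omega_mode: str = "standard",
    strict: bool = False,
    add_intercept: bool = False,
    standardize: bool = False,
) -> DesignMatrix:
    """Build the candidate dictionary from a descriptor table.

    Parameters
    ----------
    table
        Descriptor DataFrame with an ``ie_obs`` column, or an iterable of
        :class:`~qsarx.descriptors.CompoundRecord` (converted via
        :func:`descriptor_table`).
    labels
        Requested candidate terms, canonical names or x1..x10 symbols, in
        the order the columns should appear.  Defaults to every available
        canonical label.
    strict
        When True, rows without an observed IE% raise instead of being
        dropped with a warning.
    add_intercept
        Opt-in: prepend a constant unit column labelled ``intercept``.
        Off by default — the model family has no constant term.
    standardize
        Opt-in: z-score each candidate column (the response is untouched).
        Off by default — fitted weights are in raw IE%-per-unit scale,
        matching the published coefficients.
    """
    if not isinstance(table, pd.DataFrame):
        table = descriptor_table(table, metal=metal, omega_mode=omega_mode)
    if "ie_obs" not in table.columns:
        raise ValueError("descriptor table has no 'ie_obs' response column")

    missing = table["ie_obs"].isna()
    if missing.any():
        names = (
            table.loc[missing, "name"].astype(str).tolist()
            if "name" in table.columns
            else [f"row {i}" for i in table.index[missing]]
        )
        msg = f"records without observed IE% rejected from the design matrix: {names}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
        table = table.loc[~missing]
    if len(table) == 0:
        raise ValueError("no records with observed IE% remain")

    if labels is None:
        resolved = [lab for lab in CANONICAL_LABELS if lab in table.columns]
    else:
        resolved = [resolve_label(lab) for lab in labels]
    absent = [lab for lab in resolved if lab not in table.columns]
    if absent:
        raise KeyError(f"descriptor table lacks requested column(s): {absent}")

    X = table[resolved].to_numpy(dtype=float)
    y = table["ie_obs"].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # zero-variance columns pass through centred
        X = (X - X.mean(axis=0)) / sd
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        resolved = ["intercept", *resolved]
    return DesignMatrix(labels=tuple(resolved), columns=X, response=y)


def err_ratio(y: np.ndarray, p: np.ndarray) -> float:
    """Error reduction ratio of candidate ``p`` for response ``y``.

    ERR = (y'p)^2 / ((p'p)(y'y)), the squared cosine similarity; lies in
    [0, 1] and is invariant to positive rescaling of either vector.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    yty = float(y @ y)
    ptp = float(p @ p)
    if yty == 0 or ptp == 0:
        raise ZeroDivisionError("ERR undefined for zero-norm input vector")
    ytp = float(y @ p)
    return (ytp * ytp) / (ptp * yty)


def estimate_weights(Z: np.ndarray, y: np.ndarray, rank_tol: float = 1e-10) -> np.ndarray:
    """Least-squares weights for the selected columns.

    Solves ``min ||y - Z beta||`` via QR; the residual is orthogonal to the
    column space of Z.  Raises ``np.linalg.LinAlgError`` naming the offending
    columns when Z is rank deficient (pivoted-QR diagnostic).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1 and Z.shape[1] > 1 and len(np.atleast_1d(y)) != 1:
        Z = Z.T
    y = np.asarray(y, dtype=float)
    _, R, piv = scipy.linalg.qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    ref = diag[0] if diag.size and diag[0] > 0 else 1.0
    deficient = np.flatnonzero(diag < rank_tol * ref)
    if Z.shape[1] > Z.shape[0] or deficient.size:
        bad = sorted(piv[deficient].tolist()) if deficient.size else list(range(Z.shape[1]))
        raise np.linalg.LinAlgError(
            f"rank-deficient selected-term matrix; offending column indices: {bad}"
        )
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return beta


def frols_select(
    D: DesignMatrix,
    rho: float = 0.005,
    max_terms: Optional[int] = None,
    *,
    min_gain: float = 1e-6,
    collinearity_tol: float = 1e-12,
) -> SelectedModel:
    """Sparse term selection by forward regression orthogonal least squares.

    Parameters
    ----------
    D
        Candidate dictionary with response.
    rho
        Error-to-signal stopping threshold, ``0 <= rho < 1``: selection
        stops once ESR = 1 - SERR <= rho.
    max_terms
        Hard cap on the number of selected terms (default: all candidates).
    min_gain
        Selection also stops when the best remaining (orthogonalized)
        candidate would reduce ESR by no more than this; guards against an
        unreachable ``rho`` on noisy data.
    collinearity_tol
        A candidate whose orthogonalized squared norm falls below
        ``collinearity_tol`` times its original squared norm is skipped as
        collinear with the selected set (with a warning).

    Returns
    -------
    SelectedModel
        Selection order, per-term ERR, weights from least squares on the
        original selected columns, and which stopping rule fired
        (``esr`` | ``min_gain`` | ``max_terms`` | ``exhausted``).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if max_terms is None:
        max_terms = D.n_candidates
    if not 1 <= max_terms <= D.n_candidates:
        raise ValueError(f"max_terms must lie in [1, {D.n_candidates}], got {max_terms}")

    X = D.columns
    y = D.response
    yty = float(y @ y)
    if yty == 0:
        raise ValueError("response vector is identically zero")
    orig_sq = np.einsum("ij,ij->j", X, X)

    basis: list[np.ndarray] = []  # orthogonal (unnormalized) selected vectors
    selected: list[int] = []
    errs: list[float] = []
    skipped: set[int] = set()
    remaining = set(range(D.n_candidates))
    stop_reason = "exhausted"

    def orthogonalize(v: np.ndarray) -> np.ndarray:
        # classical Gram-Schmidt with one reorthogonalization pass
        for _ in range(2):
            for q in basis:
                v = v - (v @ q) / (q @ q) * q
        return v

    while remaining and len(selected) < max_terms:
        best_idx, best_err = -1, -1.0
        for m in sorted(remaining):  # ascending index -> deterministic ties
            w = orthogonalize(X[:, m].copy())
            wsq = float(w @ w)
            if wsq < collinearity_tol * orig_sq[m]:
                if m not in skipped:
                    warnings.warn(
                        f"candidate {D.labels[m]!r} skipped: collinear with selected terms",
                        CollinearityWarning,
                        stacklevel=2,
                    )
                    skipped.add(m)
                continue
            err_m = float(w @ y) ** 2 / (wsq * yty)
            if err_m > best_err:
                best_idx, best_err = m, err_m
        if best_idx < 0:
            stop_reason = "exhausted"
            break
        if selected and best_err <= min_gain:
            stop_reason = "min_gain"
            break
        w = orthogonalize(X[:, best_idx].copy())
        basis.append(w)
        selected.append(best_idx)
        errs.append(best_err)
        remaining.discard(best_idx)
        remaining -= skipped
        esr = 1.0 - float(np.sum(errs))
        if esr <= rho:
            stop_reason = "esr"
            break
        if len(selected) == max_terms:
            stop_reason = "max_terms"
        elif not remaining:
            stop_reason = "exhausted"

    if not selected:
        raise ValueError("FROLS selected no terms: every candidate was null or collinear")

    beta = estimate_weights(X[:, selected], y)
    return SelectedModel(
        design_labels=D.labels,
        terms=tuple(selected),
        weights=beta,
        err_per_term=np.asarray(errs),
        rho=rho,
        stop_reason=stop_reason,
        skipped_collinear=tuple(sorted(skipped)),
    )


def predict(model: SelectedModel, D: Union[DesignMatrix, pd.DataFrame]) -> np.ndarray:
    """Model predictions yhat = Z beta on a dictionary or descriptor table.

    Values are returned unclipped; predictions above 100% are flagged by the
    screening step downstream, not here.
    """
    if isinstance(D, DesignMatrix):
        for lab in model.labels:
            if lab not in D.labels:
                raise KeyError(f"design matrix lacks model term {lab!r}")
        Z = np.column_stack([D.column(lab) for lab in model.labels])
    else:
        absent = [lab for lab in model.labels if lab not in D.columns]
        if absent:
            raise KeyError(f"descriptor table lacks model term(s): {absent}")
        Z = D[list(model.labels)].to_numpy(dtype=float)
    return Z @ np.asarray(model.weights, dtype=float)
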