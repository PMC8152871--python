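"""Partial-correlation connectivity: regress-out estimation and group averaging.

For a pair of regions (i, j), all remaining regions (and optional
confounds) are regressed out of both series by ordinary least squares
(always including an intercept), and the partial correlation r is the
Pearson correlation of the two residual series.  In the population this
equals -Omega_ij / sqrt(Omega_ii * Omega_jj) where Omega is the
precision (inverse covariance) matrix; that identity is exposed as
:func:`partial_corr_from_precision` and serves as an independent oracle
for the regress-out path, never as its replacement.

Per-participant matrices are averaged entrywise on the raw r scale (no
Fisher transform by default) into a group matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .roi import RoiTimeSeriesSet

__all__ = [
    "PartialCorrMatrix",
    "ConnectivityError",
    "DegreesOfFreedomWarning",
    "partial_corr_pair",
    "partial_corr_matrix",
    "partial_corr_from_precision",
    "group_average",
    "randomize_series",
]

#: residual degrees of freedom below which estimation warns
MIN_RESIDUAL_DOF = 30


class ConnectivityError(ValueError):
    """Raised for rank-deficient designs or mismatched inputs."""


class DegreesOfFreedomWarning(UserWarning):
    """Few residual degrees of freedom: r estimates will be noisy."""


@dataclass(frozen=True)
class PartialCorrMatrix:
    """Symmetric region x region partial-correlation matrix.

    ``provenance`` is a participant id or group label; ``condition_set``
    tags which task-condition regime the series came from (``easier``,
    ``harder`` or ``combined``).  ``n_participants`` is 1 for a single
    participant and the member count for a group average.
    """

    region_names: tuple[str, ...]
    values: np.ndarray
    provenance: str = ""
    condition_set: str = "combined"
    n_participants: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.region_names)
        if values.shape != (n, n):
            raise ConnectivityError(
                f"matrix shape {values.shape} does not match {n} regions"
            )
        if not np.allclose(values, values.T, atol=1e-10):
            raise ConnectivityError("partial-correlation matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0):
            raise ConnectivityError("diagonal must be 1")
        if np.nanmax(np.abs(values)) > 1 + 1e-9:
            raise ConnectivityError("|r| must not exceed 1")
        object.__setattr__(self, "values", values)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def pair_value(self, region_a: str, region_b: str) -> float:
        i = self.region_names.index(region_a)
        j = self.region_names.index(region_b)
        return float(self.values[i, j])

    def pair_vector(self, pairs) -> np.ndarray:
        """r-values for an iterable of pair labels, in their given order."""
        idx = {name: k for k, name in enumerate(self.region_names)}
        return np.array(
            [self.values[idx[p.region_a], idx[p.region_b]] for p in pairs]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.region_names), columns=list(self.region_names)
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="region")

    @classmethod
    def from_tsv(cls, path, **meta) -> "PartialCorrMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region")
        return cls(tuple(df.columns), df.to_numpy(), **meta)


def _design(others: np.ndarray, confounds: np.ndarray | None, n_t: int) -> np.ndarray:
    cols = [np.ones((n_t, 1)), others.T]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != n_t:
            raise ConnectivityError(
                f"confounds have {confounds.shape[0]} rows, expected {n_t} timepoints"
            )
        cols.append(confounds)
    return np.hstack(cols)


def partial_corr_pair(
    X: np.ndarray,
    i: int,
    j: int,
    confounds: np.ndarray | None = None,
) -> float:
    """Partial correlation of regions i and j given all other regions.

    ``X`` is region x time.  Both series are residualized by OLS on
    [intercept, every other region, confounds]; r is the Pearson
    correlation of the residuals.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConnectivityError("X must be a region x time matrix")
    p, n_t = X.shape
    if i == j:
        raise ConnectivityError("i and j must differ")
    others = np.delete(X, [i, j], axis=0)
    Z = _design(others, confounds, n_t)
    if n_t <= Z.shape[1] + 2:
        raise ConnectivityError(
            f"insufficient timepoints: {n_t} for {Z.shape[1]} regressors"
        )
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ConnectivityError(
            f"rank-deficient regressor matrix for pair ({i}, {j}) — collinear nodes"
        )
    Y = X[[i, j]].T  # (t, 2)
    beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ beta
    denom = np.linalg.norm(resid[:, 0]) * np.linalg.norm(resid[:, 1])
    if denom == 0:
        raise ConnectivityError(f"zero residual variance for pair ({i}, {j})")
    return float(np.clip(resid[:, 0] @ resid[:, 1] / denom, -1.0, 1.0))


def partial_corr_matrix(
    X: np.ndarray | RoiTimeSeriesSet,
    confounds: np.ndarray | None = None,
    region_names: Sequence[str] | None = None,
    provenance: str = "",
    condition_set: str = "combined",
) -> PartialCorrMatrix:
    """Regress-out partial correlation for every region pair.

    Equivalent to calling :func:`partial_corr_pair` per pair, computed
    through per-pair normal equations on the Gram matrix (the Schur
    complement of the "all other regions" block), which is the same OLS
    residual algebra without re-factorizing the design for every pair.
    """
    if isinstance(X, RoiTimeSeriesSet):
        if region_names is None:
            region_names = X.region_names
        if not provenance:
            provenance = X.participant
        X = X.data
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConnectivityError("X must be a region x time matrix")
    p, n_t = X.shape
    if region_names is None:
        region_names = tuple(f"region_{k}" for k in range(p))
    region_names = tuple(region_names)
    if len(region_names) != p:
        raise ConnectivityError(f"{len(region_names)} names for {p} regions")

    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
    n_conf = 0 if confounds is None else confounds.shape[1]
    if n_t <= p + n_conf + 2:
        raise ConnectivityError(
            f"insufficient timepoints: {n_t} for {p} regions + {n_conf} confounds"
        )
    if n_t - p - 2 < MIN_RESIDUAL_DOF:
        warnings.warn(
            f"only {n_t - p - 2} residual degrees of freedom for {p} regions",
            DegreesOfFreedomWarning,
            stacklevel=2,
        )

    # Frisch-Waugh: centering = intercept; projecting out confounds first
    # = including them in every pairwise design.
    Xc = X - X.mean(axis=1, keepdims=True)
    if confounds is not None:
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n_t:
            raise ConnectivityError(
                f"confounds have {C.shape[0]} rows, expected {n_t} timepoints"
            )
        Cc = C - C.mean(axis=0, keepdims=True)
        beta, *_ = np.linalg.lstsq(Cc, Xc.T, rcond=None)
        Xc = Xc - (Cc @ beta).T

    G = Xc @ Xc.T  # Gram matrix of centered (and confound-free) series
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            keep = [k for k in range(p) if k not in (i, j)]
            G_oo = G[np.ix_(keep, keep)]
            G_op = G[np.ix_(keep, [i, j])]
            if keep:
                try:
                    cho = scipy.linalg.cho_factor(G_oo, check_finite=False)
                except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
                    raise ConnectivityError(
                        f"rank-deficient regressor matrix for pair "
                        f"({region_names[i]}, {region_names[j]}) — collinear nodes"
                    ) from exc
                S = G[np.ix_([i, j], [i, j])] - G_op.T @ scipy.linalg.cho_solve(
                    cho, G_op, check_finite=False
                )
            else:
                S = G[np.ix_([i, j], [i, j])]
            denom = np.sqrt(S[0, 0] * S[1, 1])
            if not denom > 0:
                raise ConnectivityError(
                    f"zero residual variance for pair "
                    f"({region_names[i]}, {region_names[j]})"
                )
            out[i, j] = out[j, i] = np.clip(S[0, 1] / denom, -1.0, 1.0)
    return PartialCorrMatrix(
        region_names=region_names,
        values=out,
        provenance=provenance,
        condition_set=condition_set,
    )


def partial_corr_from_precision(
    X: np.ndarray, region_names: Sequence[str] | None = None
) -> PartialCorrMatrix:
    """Oracle route: normalized negative inverse sample covariance.

    Diagnostic cross-check for :func:`partial_corr_matrix`; the two
    agree to numerical precision on well-conditioned inputs.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[0]
    if region_names is None:
        region_names = tuple(f"region_{k}" for k in range(p))
    omega = np.linalg.inv(np.cov(X))
    d = np.sqrt(np.diag(omega))
    r = -omega / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    return PartialCorrMatrix(tuple(region_names), r, provenance="precision-oracle")


def population_partial_corr(precision: np.ndarray) -> np.ndarray:
    """Population partial correlations implied by a precision matrix."""
    omega = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(omega))
    r = -omega / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def group_average(
    matrices: Sequence[PartialCorrMatrix],
    group_label: str = "",
    fisher: bool = False,
) -> PartialCorrMatrix:
    """Entrywise mean of member matrices on the raw r scale.

    ``fisher=True`` averages on the Fisher-z scale and transforms back
    (off by default: group matrices are reported as plain means of r).
    """
    if not matrices:
        raise ConnectivityError("empty matrix list")
    first = matrices[0]
    for m in matrices[1:]:
        if m.region_names != first.region_names:
            raise ConnectivityError(
                f"region-order mismatch: {m.provenance!r} vs {first.provenance!r}"
            )
    stack = np.stack([m.values for m in matrices])
    if fisher:
        z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 1.0)
    condition_sets = {m.condition_set for m in matrices}
    return PartialCorrMatrix(
        region_names=first.region_names,
        values=mean,
        provenance=group_label or "group",
        condition_set=condition_sets.pop() if len(condition_sets) == 1 else "mixed",
        n_participants=len(matrices),
    )


def randomize_series(ts: RoiTimeSeriesSet, seed: int) -> RoiTimeSeriesSet:
    """Permute each region's series over time, independently per region and run.

    Destroys cross-region temporal dependence while preserving each
    region-run multiset of values (the randomized-null control for the
    intergroup similarity statistic).
    """
    rng = np.random.default_rng(seed)
    data = ts.data.copy()
    for sl in ts.run_slices():
        block = data[:, sl]
        for k in range(block.shape[0]):
            block[k] = rng.permutation(block[k])
        data[:, sl] = block
    return replace(ts, data=data)
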