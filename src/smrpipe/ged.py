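"""Generalized eigendecomposition of active/passive covariances.

Spatial filters come from the common-spatial-patterns family problem

    C_passive^-1 C_active W = W Lambda,

whose extreme eigenvectors maximise/minimise the variance ratio between
the motor-imagery ("active") and visual-attention ("passive") states.
Columns with the *smallest* eigenvalues minimise active-state variance
relative to the passive state and are the candidate ERD sources.  The
scalp projection of a filter w is its forward model a = C_active w
(equivalently a column of W^-T up to scale when W is C_passive-
orthonormal).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .preprocess import TrialCovarianceSet

#: shrinkage weight applied to the passive covariance before inversion
DEFAULT_SHRINKAGE = 0.01


@dataclass
class SpatialDecomposition:
    """Eigenvectors (spatial filters), eigenvalues, forward models."""

    W: np.ndarray              # (n_ch, n_comp), columns = filters
    eigenvalues: np.ndarray    # ascending
    A: np.ndarray              # (n_ch, n_comp), columns = forward models
    selected_erd_indices: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))
    fold_id: int | None = None

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def _shrink(C: np.ndarray, gamma: float) -> np.ndarray:
    n = C.shape[0]
    return (1 - gamma) * C + gamma * (np.trace(C) / n) * np.eye(n)


def _sign_normalize(A: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude element is positive."""
    signs = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    return A * signs


def forward_models(W: np.ndarray, C_active: np.ndarray) -> np.ndarray:
    """Forward models A = C_active W, unit-norm and sign-normalised columns."""
    A = C_active @ W
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    return _sign_normalize(A / norms)


def ged(
    C_active: np.ndarray,
    C_passive: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> SpatialDecomposition:
    """Solve C_passive^-1 C_active W = W Lambda.

    The passive covariance receives trace-preserving shrinkage
    ``(1-g) C + g (tr C / n) I`` for invertibility.  Eigenvalues are
    sorted ascending and eigenvectors are scaled to the generalized
    orthonormality ``W^T C_passive W = I`` (so the smallest-eigenvalue
    columns are the candidate ERD filters).
    """
    C_active = np.asarray(C_active, float)
    C_passive = np.asarray(C_passive, float)
    if C_active.shape != C_passive.shape or C_active.ndim != 2:
        raise ValueError("covariances must be square matrices of equal size")
    if not (np.allclose(C_active, C_active.T, atol=1e-8)
            and np.allclose(C_passive, C_passive.T, atol=1e-8)):
        raise ValueError("covariance matrices must be symmetric")
    Cp = _shrink(0.5 * (C_passive + C_passive.T), shrinkage)
    Ca = 0.5 * (C_active + C_active.T)
    try:
        evals, evecs = linalg.eigh(Ca, Cp)
    except linalg.LinAlgError as err:  # pragma: no cover - diagnostic path
        raise ValueError(
            f"generalized eigendecomposition failed ({err}); passive "
            "covariance is not positive definite even after shrinkage"
        ) from err
    # linalg.eigh returns ascending eigenvalues with v^T Cp v = I already
    A_raw = Ca @ evecs
    norms = np.linalg.norm(A_raw, axis=0)
    norms[norms == 0] = 1.0
    A = A_raw / norms
    signs = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    # flip filters together with their forward models so W stays consistent
    return SpatialDecomposition(W=evecs * signs, eigenvalues=evals,
                                A=A * signs)


def _align_to(reference: np.ndarray, A: np.ndarray, W: np.ndarray):
    """Flip columns of (A, W) jointly to correlate positively with reference."""
    signs = np.sign(np.sum(reference * A, axis=0))
    signs[signs == 0] = 1.0
    return A * signs, W * signs


def crossval_ged(
    covs_active: TrialCovarianceSet,
    covs_passive: TrialCovarianceSet,
    k: int = 10,
    seed: int = 0,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> SpatialDecomposition:
    """k-fold cross-validated GED; returns the fold-averaged decomposition.

    Per fold the GED is computed on the mean covariance of the training
    ~90 % of kept trials; fold patterns are sign-aligned to the first
    fold and averaged (arithmetic mean of unit-norm columns, then
    re-normalised).  The fold decompositions are attached as ``folds``
    together with ``fold_test_indices`` for held-out application.
    """
    act_idx = np.flatnonzero(covs_active.keep_mask)
    pas_idx = np.flatnonzero(covs_passive.keep_mask)
    n_min = min(len(act_idx), len(pas_idx))
    if n_min < 2:
        raise ValueError("need at least 2 kept trials per condition")
    if n_min < k:
        warnings.warn(
            f"only {n_min} kept trials; reducing folds from {k} to {n_min}",
            UserWarning, stacklevel=2)
        k = n_min
    rng = np.random.default_rng(seed)
    act_perm = rng.permutation(act_idx)
    pas_perm = rng.permutation(pas_idx)
    act_folds = np.array_split(act_perm, k)
    pas_folds = np.array_split(pas_perm, k)

    folds, test_indices = [], []
    W_sum = A_sum = lam_sum = None
    ref_A = None
    for fold_id, (act_test, pas_test) in enumerate(zip(act_folds, pas_folds)):
        act_train = np.setdiff1d(act_idx, act_test)
        pas_train = np.setdiff1d(pas_idx, pas_test)
        Ca = covs_active.matrices[act_train].mean(axis=0)
        Cp = covs_passive.matrices[pas_train].mean(axis=0)
        dec = ged(Ca, Cp, shrinkage=shrinkage)
        dec.fold_id = fold_id
        if ref_A is None:
            ref_A = dec.A
            A_al, W_al = dec.A, dec.W
        else:
            A_al, W_al = _align_to(ref_A, dec.A, dec.W)
        W_sum = W_al if W_sum is None else W_sum + W_al
        A_sum = A_al if A_sum is None else A_sum + A_al
        lam_sum = dec.eigenvalues if lam_sum is None else lam_sum + dec.eigenvalues
        folds.append(dec)
        test_indices.append({"active": act_test, "passive": pas_test})

    A_mean = A_sum / k
    norms = np.linalg.norm(A_mean, axis=0)
    norms[norms == 0] = 1.0
    mean = SpatialDecomposition(
        W=W_sum / k,
        eigenvalues=lam_sum / k,
        A=_sign_normalize(A_mean / norms),
    )
    mean.folds = folds
    mean.fold_test_indices = test_indices
    return mean


def select_erd_sources(
    decomp: SpatialDecomposition, erdd_per_component: np.ndarray, n: int = 2
) -> np.ndarray:
    """Indices of the ``n`` components with the most negative ERDd.

    Components with non-negative ERDd are never selected; with no
    negative-ERDd component at all an empty selection is returned with a
    warning.  The selection is stored on the decomposition.
    """
    scores = np.asarray(erdd_per_component, float)
    if scores.shape[0] != decomp.n_components:
        raise ValueError("one ERDd score per component is required")
    neg = np.flatnonzero(scores < 0)
    if len(neg) == 0:
        warnings.warn("no component with negative ERDd; empty selection",
                      UserWarning, stacklevel=2)
        decomp.selected_erd_indices = np.array([], dtype=int)
        return decomp.selected_erd_indices
    order = neg[np.argsort(scores[neg])]
    decomp.selected_erd_indices = order[:n]
    return decomp.selected_erd_indices


def pattern_correlations(patterns_by_day: np.ndarray) -> np.ndarray:
    """Cross-day Pearson correlations of forward-model columns.

    ``patterns_by_day`` is (n_days, n_channels), one mean forward model
    per day for one source.  Each day's pattern is first sign-aligned to
    the day-1 pattern (forward-model signs are arbitrary), then the full
    Pearson correlation matrix is returned.
    """
    P = np.asarray(patterns_by_day, float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need patterns for at least 2 days")
    sd = P.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance pattern: correlation undefined")
    centered = P - P.mean(axis=1, keepdims=True)
    ref = centered[0]
    signs = np.sign(centered @ ref)
    signs[signs == 0] = 1.0
    aligned = centered * signs[:, None]
    R = np.corrcoef(aligned)
    np.fill_diagonal(R, 1.0)
    return R


def mean_offdiagonal(R: np.ndarray) -> float:
    """Mean of the off-diagonal entries of a correlation matrix."""
    n = R.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(R[mask].mean())
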