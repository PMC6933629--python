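"""Greedy block-sparse regulator selection for a single target gene.

This is the ARNI step: starting from an intercept-only model of the target
vector y, repeatedly add the candidate regulator whose whole polynomial block
most reduces the least-squares residual, up to L accepted blocks.  The
per-step fit is ordinary least squares on [intercept | selected blocks |
candidate block]; residuals are computed by orthogonal projection onto that
column space, which coincides with the pseudo-inverse solution's residual for
any (possibly rank-deficient) design.

Stopping: the loop ends when L blocks are accepted, candidates run out, the
relative residual improvement falls below ``tol`` (that step is *not*
accepted), or the residual drops below ``tol * ||y||`` (that step *is*
accepted — the target is essentially explained).

Ties: candidates whose residuals agree to within 1e-12 relative resolve to
the lower regulator index, so the selection order is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .basis import DesignBlock
from .errors import ConfigurationError, ValidationError

#: relative residual gap below which two candidates count as tied
TIE_REL_TOL = 1e-12

#: residuals below this fraction of the initial residual are recomputed by
#: explicit projection: the Gram-based fast path loses ~sqrt(eps) precision
#: to cancellation when a candidate (nearly) completes the span of y
REFINE_REL_TOL = 1e-4


@dataclass
class SelectionResult:
    """Outcome of one greedy selection run.

    Attributes
    ----------
    selected
        Regulator indices in acceptance order (length <= L).
    residual_norms
        The intercept-only residual 2-norm followed by the residual after
        each accepted step; non-increasing.
    coefficients
        Fitted per-block coefficient vectors (length P1 each) from the final
        least-squares refit on all accepted blocks, keyed by regulator index.
    """

    selected: list[int]
    residual_norms: list[float]
    coefficients: dict[int, np.ndarray]


def _orthonormal_complement(block: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Orthonormal basis of block's column space modulo span(q).

    Rank-revealing QR with a machine-epsilon-scaled cutoff relative to the
    original block's magnitude, so columns (nearly) inside span(q) — e.g.
    duplicated bootstrap rows or zero-variance genes — are dropped rather
    than amplified.
    """
    z = block - q @ (q.T @ block)
    z -= q @ (q.T @ z)  # second Gram-Schmidt pass for numerical safety
    scale = np.linalg.norm(block)
    if scale == 0.0:
        return np.empty((block.shape[0], 0))
    qz, rz, _ = scipy.linalg.qr(z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rz))
    cutoff = max(block.shape) * np.finfo(float).eps * scale
    keep = int(np.sum(diag > cutoff))
    return qz[:, :keep]


def _candidate_residuals(
    blocks: np.ndarray, q: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Least-squares residual norms of all candidate designs at one step.

    ``blocks`` is (C, M, P).  For candidate j the residual of fitting the
    current residual ``r`` on [existing design | block j] equals
    ``sqrt(r.r - v' G^+ v)`` with Z = block j projected orthogonal to the
    design's orthonormal basis ``q``, G = Z'Z and v = Z'r.  The pseudo-
    inverse is taken by eigendecomposition of the (C, P, P) Gram stack with
    eigenvalues cut off at the machine-epsilon-scaled block magnitude, which
    matches the rank handling of the accepted-design QR update.
    """
    c, m, p = blocks.shape
    flat = blocks.transpose(1, 0, 2).reshape(m, c * p)  # (M, C*P) for one GEMM
    z2 = flat - q @ (q.T @ flat)
    z2 -= q @ (q.T @ z2)
    z = z2.reshape(m, c, p).transpose(1, 0, 2)  # (C, M, P)
    zt = z.transpose(0, 2, 1)
    gram = zt @ z
    v = (zt @ r[:, None])[:, :, 0]  # (C, P)
    eigval, eigvec = np.linalg.eigh(gram)
    scale = np.linalg.norm(blocks, axis=(1, 2))  # per-candidate block norm
    cutoff = (max(m, p) * np.finfo(float).eps * scale) ** 2
    w = (eigvec.transpose(0, 2, 1) @ v[:, :, None])[:, :, 0]
    inv = np.where(
        eigval > cutoff[:, None], 1.0 / np.where(eigval > 0, eigval, 1.0), 0.0
    )
    explained = (w * w * inv).sum(axis=1)
    return np.sqrt(np.maximum(r @ r - explained, 0.0))


def select_regulators(
    y: np.ndarray,
    blocks: Sequence[DesignBlock],
    L: int,
    tol: float = 1e-6,
    compute_coefficients: bool = True,
) -> SelectionResult:
    """Greedily select up to ``L`` regulator blocks explaining ``y``.

    Parameters
    ----------
    y
        Target expression vector, length M'.
    blocks
        One :class:`DesignBlock` per candidate regulator (the target itself
        must already be excluded).
    L
        Maximum number of accepted blocks (ARNI steps).
    tol
        Relative-improvement / relative-residual stopping threshold.
    compute_coefficients
        Skip the final least-squares refit when False (the bootstrap
        pipeline only consumes the selection order).

    Returns
    -------
    SelectionResult
        Selections in acceptance order with the residual trajectory.
    """
    if L < 1:
        raise ConfigurationError(f"L must be >= 1, got {L}")
    if tol <= 0:
        raise ConfigurationError(f"tol must be positive, got {tol}")
    if not blocks:
        raise ValidationError("candidate set must be non-empty")
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValidationError("target vector must be 1-D")
    m = y.shape[0]
    for blk in blocks:
        if blk.columns.shape[0] != m:
            raise ValidationError(
                f"block of regulator {blk.regulator_index} has "
                f"{blk.columns.shape[0]} rows, target has {m}"
            )

    by_index = {blk.regulator_index: blk.columns for blk in blocks}
    if len(by_index) != len(blocks):
        raise ValidationError("duplicate regulator indices among blocks")
    remaining = sorted(by_index)

    y_norm = float(np.linalg.norm(y))
    # intercept-only model: project out the constant column
    q = np.full((m, 1), 1.0 / np.sqrt(m))
    r = y - q @ (q.T @ y)
    r_init = float(np.linalg.norm(r))
    residual_norms = [r_init]
    selected: list[int] = []

    if y_norm == 0.0 or r_init <= tol * y_norm:
        return SelectionResult(selected, residual_norms, {})

    tie_slack = TIE_REL_TOL * r_init
    r_prev = r_init
    while len(selected) < L and remaining:
        resids = _candidate_residuals(
            np.stack([by_index[j] for j in remaining]), q, r
        )
        for k in np.flatnonzero(resids < REFINE_REL_TOL * r_init):
            qk = _orthonormal_complement(by_index[remaining[k]], q)
            r_vec = r - qk @ (qk.T @ r) if qk.shape[1] else r
            resids[k] = float(np.linalg.norm(r_vec))
        # ascending candidate order, strict improvement beyond the tie slack:
        # ties land on the lower regulator index
        best_pos = 0
        for k in range(1, len(remaining)):
            if resids[k] < resids[best_pos] - tie_slack:
                best_pos = k
        best_j = remaining[best_pos]
        best_res = resids[best_pos]
        if (r_prev - best_res) / r_init < tol:
            break  # improvement stop: the triggering step is not accepted
        selected.append(best_j)
        remaining.remove(best_j)
        best_q = _orthonormal_complement(by_index[best_j], q)
        if best_q.shape[1]:
            q = np.hstack([q, best_q])
            r = r - best_q @ (best_q.T @ r)
        r_prev = float(np.linalg.norm(r))
        residual_norms.append(r_prev)
        if r_prev < tol * y_norm:
            break  # target essentially explained

    coefficients = (
        _final_coefficients(y, by_index, selected) if compute_coefficients else {}
    )
    return SelectionResult(selected, residual_norms, coefficients)


def _final_coefficients(
    y: np.ndarray, by_index: dict[int, np.ndarray], selected: list[int]
) -> dict[int, np.ndarray]:
    """Minimum-norm least-squares refit on all accepted blocks, split per block."""
    if not selected:
        return {}
    design = np.hstack(
        [np.ones((y.shape[0], 1))] + [by_index[j] for j in selected]
    )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    out: dict[int, np.ndarray] = {}
    offset = 1
    for j in selected:
        width = by_index[j].shape[1]
        out[j] = beta[offset : offset + width]
        offset += width
    return out
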