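"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most literal route available —
exhaustive enumeration, pseudo-inverse refits, pairwise comparison — so the
implementation under test is checked against an independent derivation, not
against itself.
"""

from __future__ import annotations

import numpy as np

TIE_REL_TOL = 1e-12


def greedy_pinv_selection(
    y: np.ndarray,
    blocks: dict[int, np.ndarray],
    L: int,
    tol: float = 1e-6,
) -> list[int]:
    """Literal greedy selection: full pseudo-inverse refit per candidate.

    At each step every unselected candidate's design
    [intercept | selected blocks | candidate block] is refit from scratch
    with ``np.linalg.pinv``; the argmin residual wins, ties (within 1e-12
    relative of the initial residual) to the lower index.  Stopping matches
    the contract: relative improvement below tol ends the loop without
    accepting; residual below tol * ||y|| ends it after accepting.
    """
    m = y.shape[0]
    remaining = sorted(blocks)
    selected: list[int] = []
    ones = np.ones((m, 1))
    r_init = float(np.linalg.norm(y - ones @ np.linalg.pinv(ones) @ y))
    y_norm = float(np.linalg.norm(y))
    if y_norm == 0.0 or r_init <= tol * y_norm:
        return selected
    slack = TIE_REL_TOL * r_init
    r_prev = r_init
    while len(selected) < L and remaining:
        best_j, best_res = None, np.inf
        for j in remaining:
            design = np.hstack([ones] + [blocks[k] for k in selected] + [blocks[j]])
            fitted = design @ np.linalg.pinv(design) @ y
            res = float(np.linalg.norm(y - fitted))
            if res < best_res - slack:
                best_j, best_res = j, res
        if best_j is None or (r_prev - best_res) / r_init < tol:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        r_prev = best_res
        if best_res < tol * y_norm:
            break
    return selected


def area_score_closed_form(steps: list[int | None], b: int, L: int) -> float:
    """Closed-form area score from per-run selection steps (1-based).

    ``None`` means the regulator was not selected in that run.  Equals
    (1/(L*b)) * sum over runs of (L - step + 1) for selections at step <= L.
    """
    total = sum(L - s + 1 for s in steps if s is not None and s <= L)
    return total / (L * b)


def pairwise_auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Exhaustive pairwise AUROC: wins + half-ties over all true/false pairs."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def prefix_sweep_aupr(labels: np.ndarray) -> float:
    """AUPR by the literal prefix sweep over an already-ordered label vector."""
    n_true = int(labels.sum())
    area = 0.0
    tp = 0
    for q in range(1, len(labels) + 1):
        if labels[q - 1]:
            tp += 1
            area += (tp / q) * (1.0 / n_true)
    return area
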