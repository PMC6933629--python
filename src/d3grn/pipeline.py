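"""The D3GRN driver: bootstrap, per-target selection, area scoring, ranking.

For every target gene and every bootstrap run the expression samples are
resampled with replacement, re-standardized, expanded into per-regulator
polynomial blocks and passed to the greedy selector.  The ordered selections
from all runs form the target's selection trace; the area under each
regulator's cumulative selection-frequency curve (normalised by the step
budget L) is its edge score.

Randomness discipline: a master seed spawns an independent substream per
(target, run) pair, so the score matrix is bit-identical whether targets are
processed serially or in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .arni import select_regulators
from .basis import BasisConfig, DesignBlock, zscore_columns
from .errors import ConfigurationError, ValidationError
from .io import ExpressionMatrix, RankedEdgeList, RegulatorSet


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters.

    Parameters
    ----------
    b
        Number of bootstrap runs per target (default 200).
    L
        Greedy selection steps per run; bounds regulators per run.
    seed
        Master random seed (non-negative integer).
    basis
        Polynomial basis configuration (default degree 5).
    tol
        Stopping tolerance passed to the selector.
    """

    b: int = 200
    L: int = 3
    seed: int = 0
    basis: BasisConfig = field(default_factory=BasisConfig)
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ConfigurationError(f"bootstrap runs b must be >= 1, got {self.b}")
        if self.L < 1:
            raise ConfigurationError(f"ARNI steps L must be >= 1, got {self.L}")
        if not (0 <= int(self.seed) < 2**32):
            raise ConfigurationError("seed must be a non-negative 32-bit integer")


@dataclass
class SelectionTrace:
    """Ordered per-run regulator selections for one target gene."""

    target_index: int
    runs: list[list[int]]

    def __post_init__(self) -> None:
        for i, run in enumerate(self.runs):
            if self.target_index in run:
                raise ValidationError(
                    f"run {i} of target {self.target_index} selected the target itself"
                )
            if len(set(run)) != len(run):
                raise ValidationError(
                    f"run {i} of target {self.target_index} contains duplicates"
                )


@dataclass(frozen=True)
class ScoreMatrix:
    """Area-based edge scores S[regulator, target] with cumulative frequencies.

    ``scores`` has one row per regulator (in ``regulator_indices`` order) and
    one column per gene; ``phi[r, t, l]`` is the fraction of bootstrap runs
    in which regulator r was selected for target t at step <= l+1.
    """

    scores: np.ndarray
    phi: np.ndarray
    regulator_indices: tuple[int, ...]
    gene_names: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        object.__setattr__(self, "regulator_indices", tuple(self.regulator_indices))
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        if np.any(s < 0) or np.any(s > 1):
            raise ValidationError("edge scores must lie in [0, 1]")
        for row, reg in enumerate(self.regulator_indices):
            if s[row, reg] != 0:
                raise ValidationError("self-regulation scores must be zero")


def rng_for_run(seed: int, target: int, run: int) -> np.random.Generator:
    """Deterministic substream for one (target, bootstrap-run) pair."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(int(target), int(run)))
    )


def candidate_regulators(regs: RegulatorSet, target: int) -> list[int]:
    """The regulator indices eligible for ``target`` (self excluded)."""
    return [r for r in regs.indices if r != target]


def bootstrap_resample(
    expr: ExpressionMatrix,
    target: int,
    regs: RegulatorSet,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one bootstrap resample of the target and candidate columns.

    M row indices are drawn uniformly with replacement; the same row multiset
    indexes both the target vector y and the candidate matrix X.
    """
    if not 0 <= target < expr.n_genes:
        raise ValidationError(f"target index {target} out of range")
    cands = candidate_regulators(regs, target)
    idx = rng.integers(0, expr.n_samples, size=expr.n_samples)
    y = expr.values[idx, target]
    x = expr.values[np.ix_(idx, cands)]
    return y, x


def _trace_for_target(
    values: np.ndarray,
    reg_indices: tuple[int, ...],
    target: int,
    config: RunConfig,
) -> SelectionTrace:
    """All bootstrap selections for one target gene."""
    cands = [r for r in reg_indices if r != target]
    if not cands:
        return SelectionTrace(target, [[] for _ in range(config.b)])
    m = values.shape[0]
    cols = np.asarray(cands + [target])
    powers = np.arange(1, config.basis.degree + 1)
    runs: list[list[int]] = []
    for run in range(config.b):
        rng = rng_for_run(config.seed, target, run)
        idx = rng.integers(0, m, size=m)
        sub = zscore_columns(values[np.ix_(idx, cols)])
        y = sub[:, -1]
        tensor = sub[:, :-1].T[:, :, None] ** powers  # (C, M, P) in one shot
        blocks = [DesignBlock(tensor[k], cands[k]) for k in range(len(cands))]
        try:
            result = select_regulators(
                y, blocks, config.L, config.tol, compute_coefficients=False
            )
        except Exception as exc:  # attach target/run context for diagnosis
            raise type(exc)(f"target {target}, run {run}: {exc}") from exc
        runs.append(result.selected)
    return SelectionTrace(target, runs)


def area_score(
    trace: SelectionTrace,
    b: int,
    L: int,
    regulator_indices: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Area-based scores for one target from its selection trace.

    ``phi[r, l]`` is the fraction of the b runs in which regulator r (row
    order follows ``regulator_indices``) was selected at step <= l+1; the
    score is the mean of phi over the L steps, i.e. the area under the
    cumulative selection-frequency curve normalised by L.  A regulator
    selected early contributes to more steps and therefore scores higher
    than one selected late at the same overall frequency.

    Returns
    -------
    (scores, phi)
        ``scores`` of shape (R,), ``phi`` of shape (R, L).
    """
    if len(trace.runs) != b:
        raise ValidationError(
            f"trace has {len(trace.runs)} runs, expected b={b}"
        )
    row_of = {reg: i for i, reg in enumerate(regulator_indices)}
    counts = np.zeros((len(row_of), L))
    for run in trace.runs:
        if len(run) > L:
            raise ValidationError(
                f"run selected {len(run)} regulators, more than L={L}"
            )
        for step, reg in enumerate(run):  # step is 0-based
            counts[row_of[reg], step:] += 1.0
    phi = counts / b
    return phi.mean(axis=1), phi


def run_d3grn(
    expr: ExpressionMatrix,
    regs: RegulatorSet,
    config: RunConfig,
    n_jobs: int = 1,
    progress: Callable[[int], None] | None = None,
) -> ScoreMatrix:
    """Infer the full score matrix: every gene is a target in turn.

    Deterministic given ``config.seed`` regardless of ``n_jobs``.
    ``progress``, if given, is called with each completed target index.
    """
    regs.validate_against(expr)
    n = expr.n_genes
    targets = range(n)
    if n_jobs == 1:
        traces = []
        for t in targets:
            traces.append(_trace_for_target(expr.values, regs.indices, t, config))
            if progress is not None:
                progress(t)
    else:
        traces = Parallel(n_jobs=n_jobs)(
            delayed(_trace_for_target)(expr.values, regs.indices, t, config)
            for t in targets
        )

    n_regs = len(regs.indices)
    scores = np.zeros((n_regs, n))
    phi = np.zeros((n_regs, n, config.L))
    for trace in traces:
        s_col, phi_col = area_score(trace, config.b, config.L, regs.indices)
        scores[:, trace.target_index] = s_col
        phi[:, trace.target_index, :] = phi_col
    return ScoreMatrix(scores, phi, regs.indices, expr.gene_names)


def rank_edges(sm: ScoreMatrix) -> RankedEdgeList:
    """Sort all positive-score pairs into the global edge ranking.

    Descending score; ties break by ascending (regulator index, target
    index).  Zero-score pairs are omitted here but treated as tied-last
    during evaluation.
    """
    entries: list[tuple[float, int, int]] = []
    for row, reg in enumerate(sm.regulator_indices):
        for tgt in range(sm.scores.shape[1]):
            s = sm.scores[row, tgt]
            if s > 0 and reg != tgt:
                entries.append((s, reg, tgt))
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    rows = tuple(
        (sm.gene_names[reg], sm.gene_names[tgt], float(s)) for s, reg, tgt in entries
    )
    return RankedEdgeList(rows)


def auto_steps(n_true_edges: int, n_genes: int) -> int:
    """Step-budget heuristic: twice the verified-interaction density.

    L should sit near the true average regulator count per gene; with a
    gold standard available this is estimated as
    ``round(2 * n_true_edges / n_genes)``, floored at 1.
    """
    if n_genes < 1 or n_true_edges < 0:
        raise ConfigurationError("need n_genes >= 1 and n_true_edges >= 0")
    return max(1, int(np.floor(2.0 * n_true_edges / n_genes + 0.5)))
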