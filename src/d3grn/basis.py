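"""Polynomial basis expansion of regulator expression vectors.

Each candidate regulator contributes a *block* of design columns: the
standardized expression vector raised elementwise to powers 1..P1.  Only
first-order (single-gene) blocks are supported; pairwise and higher-order
interaction bases are deliberately out of scope.  Expression is z-scored per
gene before exponentiation so that fifth powers stay numerically tame; an
intercept is regression plumbing handled by the selection step, not a basis
column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import ExpressionMatrix


@dataclass(frozen=True)
class BasisConfig:
    """Configuration of the basis family.

    Parameters
    ----------
    family
        Basis family; only ``"polynomial"`` is supported.
    degree
        Number of first-order basis functions P1 (powers 1..degree).
        Default 5.
    order
        Interaction order K; only 1 (single-gene terms) is supported —
        higher-order term counts are fixed at zero.
    """

    family: str = "polynomial"
    degree: int = 5
    order: int = 1

    def __post_init__(self) -> None:
        if self.family != "polynomial":
            raise ConfigurationError(f"unsupported basis family {self.family!r}")
        if self.order != 1:
            raise ConfigurationError("only first-order (K=1) bases are supported")
        if self.degree < 1:
            raise ConfigurationError(f"polynomial degree must be >= 1, got {self.degree}")


@dataclass(frozen=True)
class DesignBlock:
    """The M x P1 design columns contributed by one candidate regulator."""

    columns: np.ndarray
    regulator_index: int

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        object.__setattr__(self, "columns", cols)
        if cols.ndim != 2:
            raise ValidationError("design block must be a 2-D matrix")
        if not np.all(np.isfinite(cols)):
            raise ValidationError(
                f"non-finite entry in design block of regulator {self.regulator_index}"
            )


def zscore_columns(values: np.ndarray) -> np.ndarray:
    """Z-score each column; zero-variance columns map to all-zero columns.

    Uses the population standard deviation (ddof=0).  A constant gene carries
    no regulatory signal beyond the intercept, so zeroing it makes the gene
    unselectable rather than producing 0/0.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("cannot standardize non-finite values")
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    centered = values - mean
    out = np.zeros_like(centered)
    nonzero = sd > 0
    out[..., nonzero] = centered[..., nonzero] / sd[nonzero]
    return out


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy of ``expr`` with every gene column z-scored.

    Columns with zero variance become all-zero.  Idempotent up to floating
    tolerance.
    """
    return ExpressionMatrix(
        zscore_columns(expr.values), expr.gene_names, expr.sample_ids
    )


def build_block(
    x_j: np.ndarray, config: BasisConfig, regulator_index: int = -1
) -> DesignBlock:
    """Expand one standardized gene vector into its polynomial design block.

    Column p of the result is ``x_j ** p`` elementwise, p = 1..degree.
    """
    x_j = np.asarray(x_j, dtype=float)
    if x_j.ndim != 1:
        raise ValidationError("regulator vector must be 1-D")
    cols = x_j[:, None] ** np.arange(1, config.degree + 1)
    return DesignBlock(cols, regulator_index)
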