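"""Readers and writers for the DREAM-challenge text dialects.

Expression matrices are tab-separated with a header row of gene names and one
row per sample (DREAM5 style); an optional leading sample-ID column is
supported.  Regulator lists are one gene name per line.  Gold standards and
predictions are three-column TSV ``regulator<TAB>target<TAB>value``.

Gene-name matching is case-sensitive exact match throughout.  Internally all
gene indices are 0-based; user-facing files always carry gene names.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import FormatError, ResolutionError, ValidationError

DEFAULT_MAX_EDGES = 100_000


@dataclass(frozen=True)
class ExpressionMatrix:
    """M samples x N genes of real-valued expression.

    Parameters
    ----------
    values
        ``(M, N)`` float array; every entry must be finite.
    gene_names
        N unique gene identifiers; column order defines the gene index.
    sample_ids
        M sample identifiers (synthesised ordinals when the file has none).
    """

    values: np.ndarray
    gene_names: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        m, n = values.shape
        if m < 2 or n < 2:
            raise FormatError(
                f"expression matrix must be at least 2x2, got {m} samples x {n} genes"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at sample {bad[0] + 1}, "
                f"gene {self.gene_names[bad[1]]!r}"
            )
        if len(self.gene_names) != n:
            raise FormatError(f"{len(self.gene_names)} gene names for {n} columns")
        if len(self.sample_ids) != m:
            raise FormatError(f"{len(self.sample_ids)} sample ids for {m} rows")
        dupes = _duplicates(self.gene_names)
        if dupes:
            raise FormatError(f"duplicate gene names: {sorted(dupes)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def index_of(self, name: str) -> int:
        """0-based column index of ``name``; raises ResolutionError if absent."""
        try:
            return self._name_index[name]
        except AttributeError:
            idx = {g: i for i, g in enumerate(self.gene_names)}
            object.__setattr__(self, "_name_index", idx)
            return self.index_of(name)
        except KeyError:
            raise ResolutionError(f"unknown gene name {name!r}") from None


@dataclass(frozen=True)
class RegulatorSet:
    """Indices of candidate regulator (TF) columns in an ExpressionMatrix.

    Stored 0-based and sorted; when no regulator list is supplied every gene
    is its own candidate regulator (the DREAM4 convention).
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        object.__setattr__(self, "indices", idx)
        if not idx:
            raise ValidationError("regulator set must be non-empty")
        if len(set(idx)) != len(idx):
            raise ValidationError("regulator set contains duplicate indices")
        if idx[0] < 0:
            raise ValidationError("regulator indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, index: int) -> bool:
        return index in set(self.indices)

    @classmethod
    def all_genes(cls, expr: ExpressionMatrix) -> "RegulatorSet":
        return cls(tuple(range(expr.n_genes)))

    def validate_against(self, expr: ExpressionMatrix) -> None:
        if self.indices[-1] >= expr.n_genes:
            raise ValidationError(
                f"regulator index {self.indices[-1]} out of range for "
                f"{expr.n_genes} genes"
            )

    def names(self, expr: ExpressionMatrix) -> tuple[str, ...]:
        return tuple(expr.gene_names[i] for i in self.indices)


@dataclass(frozen=True)
class GoldStandard:
    """Verified true edges plus the admissible candidate pair universe.

    The candidate universe is every ordered (regulator, target) pair with the
    regulator in the TF set and target != regulator; its size is |I|*(N-1).
    """

    true_edges: frozenset[tuple[str, str]]
    regulator_names: tuple[str, ...]
    gene_names: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = set(self.gene_names)
        regs = set(self.regulator_names)
        for reg, tgt in self.true_edges:
            if reg == tgt:
                raise FormatError(f"self-regulation pair {reg!r} in gold standard")
            if reg not in genes or tgt not in genes:
                raise ResolutionError(f"gold-standard gene not in expression: {reg!r}->{tgt!r}")
            if reg not in regs:
                raise ResolutionError(
                    f"gold-standard regulator {reg!r} not in the regulator set"
                )

    @property
    def n_true(self) -> int:
        return len(self.true_edges)

    @property
    def n_candidates(self) -> int:
        return len(self.regulator_names) * (len(self.gene_names) - 1)

    def candidate_universe(self) -> Iterator[tuple[str, str]]:
        """All admissible pairs, regulator-major in gene-index order."""
        for reg in self.regulator_names:
            for tgt in self.gene_names:
                if tgt != reg:
                    yield (reg, tgt)


@dataclass(frozen=True)
class RankedEdgeList:
    """Global edge ranking: (regulator, target, score) with descending score."""

    rows: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        rows = tuple((str(r), str(t), float(s)) for r, t, s in self.rows)
        object.__setattr__(self, "rows", rows)
        seen: set[tuple[str, str]] = set()
        prev = np.inf
        for reg, tgt, score in rows:
            if reg == tgt:
                raise FormatError(f"self-pair {reg!r} in ranking")
            if (reg, tgt) in seen:
                raise FormatError(f"duplicate pair {reg!r}->{tgt!r} in ranking")
            seen.add((reg, tgt))
            if score > prev:
                raise FormatError("ranking scores must be non-increasing")
            prev = score

    def __len__(self) -> int:
        return len(self.rows)

    def pairs(self) -> list[tuple[str, str]]:
        return [(r, t) for r, t, _ in self.rows]


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def read_expression(path: str | os.PathLike, sample_id_column: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix with a gene-name header row.

    Parameters
    ----------
    path
        TSV file: header of gene names, then one numeric row per sample.
    sample_id_column
        If True the first column holds sample identifiers instead of data.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file or blank header")
        header = header_line.rstrip("\r\n").split("\t")
        gene_names = header[1:] if sample_id_column else header
        # header=None: pandas must not mangle duplicate gene names before we see them
        raw = pd.read_csv(fh, sep="\t", header=None, dtype=str, keep_default_na=False)

    if len(gene_names) < 2:
        raise FormatError(f"{path}: need at least 2 gene columns, got {len(gene_names)}")
    dupes = _duplicates(gene_names)
    if dupes:
        raise FormatError(f"{path}: duplicate gene names in header: {sorted(dupes)}")
    n = len(gene_names)
    expected_fields = n + 1 if sample_id_column else n
    if raw.shape[1] != expected_fields:
        raise FormatError(
            f"{path}: data rows have {raw.shape[1]} fields, expected {expected_fields}"
        )
    if raw.shape[0] < 2:
        raise FormatError(f"{path}: need at least 2 sample rows, got {raw.shape[0]}")

    if sample_id_column:
        sample_ids = tuple(raw.iloc[:, 0].astype(str))
        data = raw.iloc[:, 1:]
    else:
        sample_ids = tuple(str(i + 1) for i in range(raw.shape[0]))
        data = raw
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: non-numeric value {data.iat[i, j]!r} at row {i + 2}, "
            f"column {gene_names[j]!r}"
        )
    return ExpressionMatrix(numeric.to_numpy(dtype=float), tuple(gene_names), sample_ids)


def read_regulators(path: str | os.PathLike | None, expr: ExpressionMatrix) -> RegulatorSet:
    """Read a regulator list (one gene name per line) against ``expr``.

    When ``path`` is None every gene is a candidate regulator.
    """
    if path is None:
        return RegulatorSet.all_genes(expr)
    with open(path, "r", encoding="utf-8") as fh:
        names = [line.strip() for line in fh if line.strip()]
    known = set(expr.gene_names)
    missing = sorted(set(names) - known)
    if missing:
        raise ResolutionError(f"regulator names not in expression matrix: {missing}")
    return RegulatorSet(tuple({expr.index_of(n) for n in names}))


def read_gold_standard(
    path: str | os.PathLike, expr: ExpressionMatrix, regs: RegulatorSet
) -> GoldStandard:
    """Read a DREAM gold standard: ``regulator<TAB>target<TAB>label`` lines.

    Label-1 lines form the true-edge set; label-0 lines are ignored (the full
    candidate universe remains the negatives).
    """
    true_edges: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\r\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            reg, tgt, label = fields
            if label not in ("0", "1"):
                raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {label!r}")
            if label == "1":
                if reg == tgt:
                    raise FormatError(f"{path}:{lineno}: self-regulation pair {reg!r}")
                true_edges.add((reg, tgt))
    return GoldStandard(
        frozenset(true_edges),
        regs.names(expr),
        expr.gene_names,
    )


def write_predictions(
    ranking: RankedEdgeList,
    path: str | os.PathLike,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> None:
    """Write up to ``max_edges`` lines ``regulator<TAB>target<TAB>score``.

    Scores are written with full precision (the shortest decimal that
    round-trips the float), so re-reading the file reproduces the ranking
    exactly.
    """
    if max_edges < 1:
        raise ValidationError(f"max_edges must be positive, got {max_edges}")
    with open(path, "w", encoding="utf-8") as fh:
        for reg, tgt, score in ranking.rows[:max_edges]:
            fh.write(f"{reg}\t{tgt}\t{score!r}\n")


def read_predictions(path: str | os.PathLike) -> RankedEdgeList:
    """Read a prediction file written by :func:`write_predictions`."""
    rows: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\r\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                score = float(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                ) from None
            rows.append((fields[0], fields[1], score))
    return RankedEdgeList(tuple(rows))
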