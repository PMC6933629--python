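"""Synthetic gold-standard networks and DREAM4-like expression data.

The generator builds a directed acyclic network (edges only run from lower
to higher gene index, self-regulation excluded) over a designated regulator
subset, then simulates steady-state-like samples: regulator genes draw standard
normal baselines plus a shared per-sample perturbation shift — every sample
emulates one multifactorial perturbation experiment — and each regulated
gene adds its parents' weighted sum passed through a regulatory function,
with additive observation noise on non-regulator genes.

This is a testbed, not a kinetic simulator: no ODE/SDE dynamics, no
knockout or time-series experiment types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import ExpressionMatrix, GoldStandard

REGULATORY_FUNCTIONS = ("linear", "sigmoid", "polynomial")


@dataclass(frozen=True)
class SyntheticNetwork:
    """Ground-truth directed network with edge weights.

    Attributes
    ----------
    n_genes
        Total genes; names are synthesized as G1..GN.
    regulator_indices
        0-based indices of the designated TF subset (the first genes).
    edges
        (regulator, target, weight) triples; regulator < target always
        (DAG by index ordering) and regulator is in the TF subset.
    regulatory_function
        "linear" (identity), "sigmoid" (tanh) or "polynomial"
        (u + 0.25 u^2) applied to each target's weighted regulator sum.
    noise_sd
        SD of the observation noise on non-regulator genes.
    perturbation_sd
        SD of the per-sample scalar shift shared by regulator baselines.
    """

    n_genes: int
    regulator_indices: tuple[int, ...]
    edges: tuple[tuple[int, int, float], ...]
    regulatory_function: str = "linear"
    noise_sd: float = 0.1
    perturbation_sd: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "regulator_indices", tuple(self.regulator_indices))
        object.__setattr__(
            self, "edges", tuple((int(r), int(t), float(w)) for r, t, w in self.edges)
        )
        if self.regulatory_function not in REGULATORY_FUNCTIONS:
            raise ConfigurationError(
                f"unknown regulatory function {self.regulatory_function!r}"
            )
        if self.noise_sd < 0 or self.perturbation_sd < 0:
            raise ConfigurationError("noise_sd and perturbation_sd must be >= 0")
        regs = set(self.regulator_indices)
        seen = set()
        for reg, tgt, _ in self.edges:
            if reg == tgt:
                raise ValidationError(f"self-edge on gene {reg}")
            if reg >= tgt:
                raise ValidationError(
                    f"edge {reg}->{tgt} violates the index (topological) ordering"
                )
            if reg not in regs:
                raise ValidationError(f"edge source {reg} is not a regulator")
            if (reg, tgt) in seen:
                raise ValidationError(f"duplicate edge {reg}->{tgt}")
            seen.add((reg, tgt))

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1}" for i in range(self.n_genes))

    def parents_of(self, target: int) -> list[tuple[int, float]]:
        return [(r, w) for r, t, w in self.edges if t == target]


def generate_network(
    n_genes: int,
    n_regulators: int,
    mean_in_degree: float,
    seed: int,
    max_in_degree: int | None = None,
    regulatory_function: str = "linear",
    noise_sd: float = 0.1,
    perturbation_sd: float = 0.3,
) -> SyntheticNetwork:
    """Sample a random DAG topology with Poisson-with-floor in-degrees.

    The first ``n_regulators`` genes are the TF subset.  Every gene except
    the first regulator receives ``max(1, Poisson(mean_in_degree))`` distinct
    parents drawn uniformly from the regulators with lower index (clipped,
    with a warning, when fewer are available).  Weights are uniform on
    +/-[0.5, 1.5].
    """
    if not 1 <= n_regulators <= n_genes:
        raise ConfigurationError(
            f"need 1 <= n_regulators <= n_genes, got {n_regulators}/{n_genes}"
        )
    if mean_in_degree < 1:
        raise ConfigurationError(f"mean_in_degree must be >= 1, got {mean_in_degree}")
    rng = np.random.default_rng(seed)
    regulators = tuple(range(n_regulators))
    edges: list[tuple[int, int, float]] = []
    clipped = False
    for target in range(n_genes):
        available = [r for r in regulators if r < target]
        want = max(1, int(rng.poisson(mean_in_degree)))
        if max_in_degree is not None:
            want = min(want, max_in_degree)
        if want > len(available):
            clipped = True
            want = len(available)
        if want == 0:
            continue
        parents = rng.choice(len(available), size=want, replace=False)
        for p in sorted(parents):
            weight = rng.uniform(0.5, 1.5) * rng.choice((-1.0, 1.0))
            edges.append((available[p], target, float(weight)))
    if clipped:
        warnings.warn(
            "requested in-degree exceeded the available upstream regulators "
            "for some genes; clipped",
            stacklevel=2,
        )
    return SyntheticNetwork(
        n_genes,
        regulators,
        tuple(edges),
        regulatory_function=regulatory_function,
        noise_sd=noise_sd,
        perturbation_sd=perturbation_sd,
    )


def _apply_function(u: np.ndarray, family: str) -> np.ndarray:
    if family == "linear":
        return u
    if family == "sigmoid":
        return np.tanh(u)
    return u + 0.25 * u**2  # "polynomial": keeps a dominant linear part


def simulate_expression(
    net: SyntheticNetwork, n_samples: int, seed: int
) -> tuple[ExpressionMatrix, GoldStandard]:
    """Simulate multifactorial-perturbation-like samples from the network.

    Every regulator gene draws an i.i.d. standard normal baseline plus its
    own per-sample N(0, perturbation_sd) perturbation (each sample jitters
    every input independently — one multifactorial perturbation experiment).
    Genes with parents receive the regulatory function of their
    unit-norm-weighted parent sum; for a regulated TF that term is averaged
    with its baseline at equal variance, for a non-regulator gene it is the
    whole signal plus N(0, noise_sd) observation noise.  Genes are filled in
    index order, which is a topological order by construction.
    """
    if n_samples < 2:
        raise ValidationError(f"need at least 2 samples, got {n_samples}")
    rng = np.random.default_rng(seed)
    m, n = n_samples, net.n_genes
    values = np.zeros((m, n))
    parents = {t: net.parents_of(t) for t in range(n)}
    is_regulator = set(net.regulator_indices)
    for gene in range(n):
        if gene in is_regulator:
            # baseline + this TF's own multifactorial perturbation; drawn
            # independently per TF so the perturbation is not a global
            # confounder correlating unrelated regulators
            base = rng.standard_normal(m)
            if net.perturbation_sd:
                base = base + rng.normal(0.0, net.perturbation_sd, size=m)
        else:
            base = rng.normal(0.0, net.noise_sd, size=m) if net.noise_sd else 0.0
        if parents[gene]:
            u = np.zeros(m)
            norm = np.sqrt(sum(w * w for _, w in parents[gene]))
            for reg, w in parents[gene]:
                # weights scaled to unit 2-norm per target: gene variance then
                # stays O(1) at any regulatory depth instead of compounding
                # geometrically down TF->TF cascades
                u += (w / norm) * values[:, reg]
            reg_term = _apply_function(u, net.regulatory_function)
            if gene in is_regulator:
                # a regulated TF splits its variance evenly between network
                # regulation and its independent baseline (inputs outside the
                # modelled network): regulation visible enough for in-edge
                # detection, baseline large enough to keep the TF
                # distinguishable from its ancestors
                base = (base + reg_term) / np.sqrt(2.0)
            else:
                base = base + reg_term
        values[:, gene] = base
    names = net.gene_names
    expr = ExpressionMatrix(values, names, tuple(f"S{i + 1}" for i in range(m)))
    gold = GoldStandard(
        frozenset((names[r], names[t]) for r, t, _ in net.edges),
        tuple(names[i] for i in net.regulator_indices),
        names,
    )
    return expr, gold


def write_benchmark(
    net: SyntheticNetwork,
    expr: ExpressionMatrix,
    gold: GoldStandard,
    prefix: str,
) -> tuple[str, str, str]:
    """Write expression/regulators/gold files in the DREAM dialects."""
    expr_path = f"{prefix}_expression.tsv"
    regs_path = f"{prefix}_regulators.txt"
    gold_path = f"{prefix}_goldstandard.tsv"
    with open(expr_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(expr.gene_names) + "\n")
        for row in expr.values:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(regs_path, "w", encoding="utf-8") as fh:
        for name in gold.regulator_names:
            fh.write(name + "\n")
    with open(gold_path, "w", encoding="utf-8") as fh:
        for reg, tgt, _ in net.edges:
            fh.write(f"{expr.gene_names[reg]}\t{expr.gene_names[tgt]}\t1\n")
    return expr_path, regs_path, gold_path
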