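"""Pairwise Mixed Graphical Model estimation: nodewise lasso regressions
combined into an undirected weighted network.

An edge s--j exists when the regression of s on j and the regression of j on
s both (AND rule, default) or either (OR rule) retain a nonzero coefficient
block; the edge weight is the mean of the two directional strengths, each
the mean absolute coefficient over its block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MixedDataset, VariableSpec, center_continuous, continuous_means
from .nodewise import NodewiseModel, fit_node

AND = "AND"
OR = "OR"

#: signs matrix entries: +1 / -1 signed edge, 0 no edge or no sign,
#: NaN = sign undefined (categorical with K > 2, or conflicting directions)
UNDEFINED = float("nan")


@dataclass
class NetworkModel:
    """Aggregated undirected network: symmetric nonnegative ``weights`` with
    zero diagonal, a parallel ``signs`` matrix, the variable specs and the
    underlying nodewise fits."""

    weights: np.ndarray
    signs: np.ndarray
    specs: list[VariableSpec]
    nodewise: list[NodewiseModel]
    aggregation_rule: str = AND
    train_means: np.ndarray | None = None
    fit_config: dict = field(default_factory=dict)
    kind: str = "mgm"

    def __post_init__(self) -> None:
        w = self.weights
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for s in range(self.p):
            for j in range(s + 1, self.p):
                if self.weights[s, j] > 0:
                    out.append((s, j, float(self.weights[s, j])))
        return out

    def node_strength(self) -> np.ndarray:
        """Sum of absolute edge weights per node (degree-weighted centrality)."""
        return self.weights.sum(axis=1)


def _directional_sign(model: NodewiseModel, j: int) -> float:
    """Signed scalar summary of predictor j's block in one nodewise fit.

    Gaussian-gaussian blocks carry their coefficient's sign directly.  Blocks
    touching a binary categorical variable are reduced to level-2-minus-
    level-1 contrasts (the double difference for a binary-binary 2x2 block).
    Any block touching a K>2 categorical variable has no single sign: NaN.
    """
    block = model.coef_blocks[j]
    L = model.predictor_levels[j]
    if model.family == "gaussian":
        if L == 1:
            return float(np.sign(block[0]))
        if L == 2:
            return float(np.sign(block[1] - block[0]))
        return UNDEFINED
    K = model.n_levels
    if K != 2:
        return UNDEFINED
    if L == 1:
        return float(np.sign(block[1, 0] - block[0, 0]))
    if L == 2:
        return float(np.sign(block[1, 1] - block[1, 0] - block[0, 1] + block[0, 0]))
    return UNDEFINED


def _edge_sign(s_sign: float, j_sign: float, s_on: bool, j_on: bool) -> float:
    signs = []
    if s_on:
        signs.append(s_sign)
    if j_on:
        signs.append(j_sign)
    if any(np.isnan(v) for v in signs):
        return UNDEFINED
    nonzero = [v for v in signs if v != 0]
    if not nonzero:
        return 0.0
    if all(v == nonzero[0] for v in nonzero):
        return float(nonzero[0])
    return UNDEFINED


def aggregate_graph(models: list[NodewiseModel], rule: str = AND) -> NetworkModel:
    """Combine the p nodewise neighborhoods into one undirected network.

    Directional strength of j in s's regression is the mean absolute
    coefficient over j's block; under AND both directions must be nonzero for
    an edge, under OR either suffices (the absent direction contributing 0 to
    the mean weight).
    """
    if rule not in (AND, OR):
        raise ValueError(f"rule must be 'AND' or 'OR', got {rule!r}")
    p = len(models)
    specs = []
    for s, m in enumerate(models):
        if m.target != s:
            raise ValueError("models must be ordered by target index")
        specs.append(VariableSpec(
            name=f"V{s}", family=m.family, n_levels=m.n_levels
        ))
    for s, m in enumerate(models):
        for j, L in m.predictor_levels.items():
            exp = models[j].n_levels if models[j].family == "categorical" else 1
            if L != exp:
                raise ValueError(
                    f"inconsistent specs: node {s} saw node {j} with {L} "
                    f"levels, node {j} declares {exp}"
                )

    weights = np.zeros((p, p))
    signs = np.zeros((p, p))
    for s in range(p):
        for j in range(s + 1, p):
            a = models[s].block_strength(j)
            b = models[j].block_strength(s)
            if rule == AND:
                present = a > 0 and b > 0
                w = (a + b) / 2.0 if present else 0.0
            else:
                present = a > 0 or b > 0
                w = (a + b) / 2.0 if present else 0.0
            weights[s, j] = weights[j, s] = w
            if present:
                sg = _edge_sign(
                    _directional_sign(models[s], j),
                    _directional_sign(models[j], s),
                    a > 0, b > 0,
                )
            else:
                sg = 0.0
            signs[s, j] = signs[j, s] = sg
    return NetworkModel(weights=weights, signs=signs, specs=specs,
                        nodewise=models, aggregation_rule=rule)


def fit_mgm(
    d: MixedDataset,
    cv_folds: int = 10,
    rule: str = AND,
    seed: int = 0,
    lambda_path: np.ndarray | None = None,
    selection: str = "min",
    threshold: str = "auto",
) -> NetworkModel:
    """Estimate the full MGM: center continuous columns, fit every node's
    l1 neighborhood regression with CV-selected penalty, and aggregate.
    Deterministic given ``seed``."""
    means = continuous_means(d)
    dc = center_continuous(d, means)
    node_seeds = np.random.SeedSequence(seed).generate_state(d.p) % (2**31 - 1)
    models = [
        fit_node(dc, s, lambda_path=lambda_path, cv_folds=cv_folds,
                 seed=int(node_seeds[s]), selection=selection,
                 threshold=threshold)
        for s in range(d.p)
    ]
    net = aggregate_graph(models, rule=rule)
    net.specs = list(d.specs)
    net.train_means = means
    net.fit_config = {
        "cv_folds": cv_folds, "rule": rule, "seed": seed,
        "selection": selection, "kind": "mgm",
    }
    return net
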