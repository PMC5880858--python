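"""Predictions from fitted nodewise conditionals.

A gaussian node's prediction is the conditional mean
mu = beta0 + sum_j block_j . x_j; a categorical node's is the softmax of the
per-category linear predictors mu_k, with the predicted class the argmax
(ties broken toward the lowest category index).  Because nodes outside a
target's neighborhood have zero blocks, predicting from the neighbors alone
and predicting from all nodes coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data import MixedDataset
from .nodewise import NodewiseModel


def _block_contribution(block: np.ndarray, levels: int, x: np.ndarray) -> np.ndarray:
    """Contribution of one predictor to the linear predictor(s).

    Gaussian predictor (levels == 1): coefficient times value.  Categorical
    predictor: the coefficient column indexed by the observed 1-based code.
    Returns shape (n,) for a gaussian target block and (n, K) otherwise.
    """
    x = np.asarray(x, dtype=float)
    if block.ndim == 1:            # gaussian target
        if levels == 1:
            return block[0] * x
        idx = x.astype(int) - 1
        if np.any((idx < 0) | (idx >= levels)):
            raise ValueError("categorical predictor value outside 1..L")
        return block[idx]
    # categorical target: block is (K, L)
    if levels == 1:
        return np.outer(x, block[:, 0])
    idx = x.astype(int) - 1
    if np.any((idx < 0) | (idx >= levels)):
        raise ValueError("categorical predictor value outside 1..L")
    return block[:, idx].T


def _gather(model: NodewiseModel, predictors: Mapping[int, np.ndarray]):
    """Validate predictor vectors against the model's block map.  Zero blocks
    may be omitted (they drop out of the linear predictor); nonzero blocks
    require a value vector of common length."""
    n = None
    for j, block in model.coef_blocks.items():
        if j in predictors:
            x = np.asarray(predictors[j], dtype=float)
            if x.ndim != 1:
                raise ValueError(f"predictor {j} must be 1-D")
            if n is None:
                n = len(x)
            elif len(x) != n:
                raise ValueError("predictor vectors differ in length")
        elif np.any(block != 0):
            raise ValueError(f"missing values for nonzero predictor block {j}")
    if n is None:
        raise ValueError("no predictor values supplied")
    return n


def predict_gaussian_node(
    model: NodewiseModel, predictors: Mapping[int, np.ndarray]
) -> np.ndarray:
    """Conditional means of a gaussian node given neighbor values.

    ``predictors`` maps node index -> vector of raw values (codes 1..L for
    categorical neighbors).  Pure linear algebra, no randomness.
    """
    if model.family != "gaussian":
        raise ValueError("model is not a gaussian nodewise fit")
    n = _gather(model, predictors)
    mu = np.full(n, float(model.intercepts))
    for j, block in model.coef_blocks.items():
        if j in predictors and np.any(block != 0):
            mu += _block_contribution(block, model.predictor_levels[j],
                                      predictors[j])
    return mu


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with log-sum-exp stabilization (shift-invariant,
    overflow-free for |logits| up to ~700)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict_categorical_node(
    model: NodewiseModel, predictors: Mapping[int, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (n, K) and predicted classes (argmax, ties to the
    lowest category) of a categorical node given neighbor values."""
    if model.family != "categorical":
        raise ValueError("model is not a categorical nodewise fit")
    K = model.n_levels
    n = _gather(model, predictors)
    logits = np.tile(np.asarray(model.intercepts, dtype=float), (n, 1))
    for j, block in model.coef_blocks.items():
        if j in predictors and np.any(block != 0):
            logits += _block_contribution(block, model.predictor_levels[j],
                                          predictors[j])
    probs = softmax(logits)
    classes = np.argmax(probs, axis=1) + 1   # argmax takes the first maximum
    return probs, classes


@dataclass
class NodePrediction:
    node: int
    name: str
    family: str
    observed: np.ndarray
    predicted: np.ndarray            # means (gaussian) or classes (categorical)
    probabilities: np.ndarray | None = None


@dataclass
class PredictionResult:
    nodes: list[NodePrediction]

    def __getitem__(self, i: int) -> NodePrediction:
        return self.nodes[i]

    def __len__(self) -> int:
        return len(self.nodes)


def predict_all(model, d: MixedDataset) -> PredictionResult:
    """Predict every node of ``d`` from the fitted model.

    Cross-sectional networks predict row i of each node from row i of the
    others; lag-1 VAR models predict rows 2..n from rows 1..n-1 (n-1
    predictions per node).  Continuous columns are centered by the model's
    training means so predictions live on the scale the model was fitted on.
    """
    if [s.family for s in d.specs] != [s.family for s in model.specs]:
        raise ValueError("dataset variable families do not match the model")
    means = model.train_means
    if means is None:
        means = np.zeros(d.p)
    centered = d.values - np.asarray(means)[None, :]

    is_var = getattr(model, "kind", "mgm") == "mvar"
    if is_var:
        pred_rows = centered[:-1]
        obs_rows = centered[1:]
    else:
        pred_rows = centered
        obs_rows = centered

    out: list[NodePrediction] = []
    for s, spec in enumerate(d.specs):
        m = model.nodewise[s]
        predictors = {
            j: pred_rows[:, j] for j in m.coef_blocks
        }
        observed = obs_rows[:, s] if not spec.is_categorical else (
            d.values[1:, s] if is_var else d.values[:, s]
        )
        if spec.is_categorical:
            probs, classes = predict_categorical_node(m, predictors)
            out.append(NodePrediction(s, spec.name, spec.family,
                                      observed.astype(int), classes, probs))
        else:
            mu = predict_gaussian_node(m, predictors)
            out.append(NodePrediction(s, spec.name, spec.family, observed, mu))
    return PredictionResult(out)
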