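"""Lag-1 mixed vector autoregression by nodewise regression on a lagged
design.

Every variable at time t is regressed on all p variables (including itself)
at time t-1, with the same l1 machinery as the cross-sectional model.  The
resulting weight matrix is directed: ``weights[i, j]`` is the strength of
lagged variable i on target j, and the diagonal holds self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MixedDataset, VariableSpec, center_continuous, continuous_means
from .mgm import UNDEFINED, _directional_sign
from .nodewise import NodewiseModel, fit_node


@dataclass
class VARModel:
    """Directed lag-1 network.  ``weights[i, j]``: strength of variable i at
    t-1 on variable j at t; no symmetry constraint, diagonal = self-loops."""

    weights: np.ndarray
    signs: np.ndarray
    specs: list[VariableSpec]
    nodewise: list[NodewiseModel]
    train_means: np.ndarray | None = None
    fit_config: dict = field(default_factory=dict)
    kind: str = "mvar"

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for i in range(self.p):
            for j in range(self.p):
                if self.weights[i, j] > 0:
                    out.append((i, j, float(self.weights[i, j])))
        return out

    def node_strength(self) -> np.ndarray:
        """In-strength per target node: total lagged influence received."""
        return self.weights.sum(axis=0)


def lag_design(
    d: MixedDataset, lag: int = 1, breaks: np.ndarray | None = None
) -> tuple[MixedDataset, MixedDataset]:
    """Split a time-ordered dataset into aligned (predictor, response) pairs:
    predictor rows t, response rows t + lag, so n_effective = n - lag.

    ``breaks``, if given, is a per-row block label (e.g. the day of an
    experience-sampling protocol); pairs whose two rows lie in different
    blocks are dropped, so overnight transitions never enter the fit.
    """
    if lag < 1:
        raise ValueError("lag >= 1 required")
    if d.n < lag + 2:
        raise ValueError(f"need at least {lag + 2} rows for lag {lag}, got {d.n}")
    keep = np.arange(d.n - lag)
    if breaks is not None:
        breaks = np.asarray(breaks)
        if len(breaks) != d.n:
            raise ValueError("breaks must have one label per row")
        keep = keep[breaks[keep] == breaks[keep + lag]]
        if len(keep) < 2:
            raise ValueError("fewer than 2 transition pairs remain after breaks")
    pred = MixedDataset(d.values[keep], list(d.specs), dict(d.level_labels))
    resp = MixedDataset(d.values[keep + lag], list(d.specs), dict(d.level_labels))
    return pred, resp


def _lagged_node_dataset(
    pred: MixedDataset, resp: MixedDataset, target: int
) -> MixedDataset:
    """Dataset whose first p columns are the lagged predictors (all nodes,
    including the target's own past) and whose last column is the response;
    fitting that last column then regresses on every lagged column."""
    specs = [
        VariableSpec(name=f"{s.name}_lag1", family=s.family, n_levels=s.n_levels)
        for s in pred.specs
    ]
    tspec = resp.specs[target]
    specs.append(VariableSpec(name=tspec.name, family=tspec.family,
                              n_levels=tspec.n_levels))
    values = np.column_stack([pred.values, resp.values[:, target]])
    return MixedDataset(values, specs, {})


def fit_mvar(
    d: MixedDataset,
    cv_folds: int = 10,
    seed: int = 0,
    lambda_path: np.ndarray | None = None,
    selection: str = "min",
    threshold: str = "auto",
    breaks: np.ndarray | None = None,
) -> VARModel:
    """Estimate the lag-1 VAR: center continuous columns by their full-series
    means, lag the design, and fit each target's regression on all lagged
    variables.  Deterministic given ``seed``."""
    means = continuous_means(d)
    dc = center_continuous(d, means)
    pred, resp = lag_design(dc, lag=1, breaks=breaks)
    node_seeds = np.random.SeedSequence(seed).generate_state(d.p) % (2**31 - 1)

    models: list[NodewiseModel] = []
    p = d.p
    for t in range(p):
        ds = _lagged_node_dataset(pred, resp, t)
        m = fit_node(ds, target=p, lambda_path=lambda_path, cv_folds=cv_folds,
                     seed=int(node_seeds[t]), selection=selection,
                     threshold=threshold)
        # re-key blocks from design indices 0..p-1 (lagged nodes) to node ids
        m.target = t
        models.append(m)

    weights = np.zeros((p, p))
    signs = np.zeros((p, p))
    for j, m in enumerate(models):
        for i in range(p):
            w = m.block_strength(i)
            weights[i, j] = w
            signs[i, j] = _directional_sign(m, i) if w > 0 else 0.0
    return VARModel(
        weights=weights, signs=signs, specs=list(d.specs), nodewise=models,
        train_means=means,
        fit_config={"cv_folds": cv_folds, "seed": seed,
                    "selection": selection, "kind": "mvar"},
    )
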