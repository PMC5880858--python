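"""Per-node predictability measures.

Continuous nodes are scored by explained variance R^2 = 1 - var(yhat - y) /
var(y).  Categorical nodes are scored by classification accuracy (CC), the
accuracy of the intercept-only marginal model (CCmarg = largest category
proportion), and the normalized accuracy nCC = (CC - CCmarg) / (1 - CCmarg),
which removes the accuracy that trivially follows from the marginal: nCC = 0
means the neighbors add nothing, nCC = 1 means perfect prediction.

Measures are computed either within sample (on the fitting data) or on a
held-out split after refitting on the training part only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MixedDataset
from .predict import predict_all

WITHIN_SAMPLE = "within_sample"
HOLDOUT = "holdout"


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Proportion of explained variance, 1 - var(residual)/var(observed).

    Both variances use the same (sample, ddof=1) denominator so the ratio is
    denominator-invariant.  Can exceed [0, 1] only out of sample or without
    an intercept; reported unclipped.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(observed) < 2:
        raise ValueError("need at least 2 observations")
    v = np.var(observed, ddof=1)
    if v == 0:
        raise ValueError("constant node: variance of observed values is zero")
    return float(1.0 - np.var(observed - predicted, ddof=1) / v)


def accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Proportion of correct classifications."""
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if len(observed) == 0:
        raise ValueError("empty class vector")
    return float(np.mean(observed == predicted))


def marginal_accuracy(observed: np.ndarray, K: int) -> tuple[float, np.ndarray]:
    """Relative category frequencies and the accuracy of always predicting
    the modal class (the intercept-only model's accuracy)."""
    observed = np.asarray(observed).astype(int)
    if len(observed) == 0:
        raise ValueError("empty class vector")
    marginals = np.array([np.mean(observed == k) for k in range(1, K + 1)])
    return float(marginals.max()), marginals


def normalized_accuracy(cc: float, cc_marg: float) -> float:
    """Accuracy beyond the marginal model, rescaled to the achievable range.
    May be negative when the model underperforms the marginal; returned
    unclipped."""
    if not 0.0 <= cc_marg < 1.0:
        raise ValueError(
            "degenerate marginal; normalized accuracy undefined for CCmarg = 1"
        )
    return float((cc - cc_marg) / (1.0 - cc_marg))


@dataclass
class NodeMeasures:
    node: int
    name: str
    family: str
    R2: float | None = None
    CC: float | None = None
    CCmarg: float | None = None
    nCC: float | None = None
    marginals: np.ndarray | None = None
    below_marginal: bool = False      # flagged when nCC < 0


@dataclass
class PredictabilityReport:
    nodes: list[NodeMeasures]
    scheme: str
    split: dict = field(default_factory=dict)

    def __getitem__(self, i: int) -> NodeMeasures:
        return self.nodes[i]

    def __len__(self) -> int:
        return len(self.nodes)

    def check_identity(self, atol: float = 1e-12) -> None:
        """nCC * (1 - CCmarg) + CCmarg == CC on every categorical node."""
        for m in self.nodes:
            if m.CC is not None:
                lhs = m.nCC * (1.0 - m.CCmarg) + m.CCmarg
                if abs(lhs - m.CC) > atol:
                    raise AssertionError(
                        f"accuracy identity violated at node {m.name}: "
                        f"{lhs} != {m.CC}"
                    )


def _measures(model, d: MixedDataset, train_marginals: dict | None = None):
    preds = predict_all(model, d)
    out: list[NodeMeasures] = []
    for np_ in preds.nodes:
        m = NodeMeasures(node=np_.node, name=np_.name, family=np_.family)
        if np_.family == "categorical":
            K = model.specs[np_.node].n_levels
            m.CC = accuracy(np_.observed, np_.predicted)
            if train_marginals is not None and np_.node in train_marginals:
                m.marginals = train_marginals[np_.node]
                m.CCmarg = float(m.marginals.max())
            else:
                m.CCmarg, m.marginals = marginal_accuracy(np_.observed, K)
            m.nCC = normalized_accuracy(m.CC, m.CCmarg)
            m.below_marginal = m.nCC < 0
        else:
            m.R2 = r_squared(np_.observed, np_.predicted)
        out.append(m)
    return out


def _refit(model, d: MixedDataset):
    from .mgm import fit_mgm
    from .mvar import fit_mvar
    cfg = dict(model.fit_config)
    kind = cfg.pop("kind", getattr(model, "kind", "mgm"))
    if kind == "mvar":
        return fit_mvar(d, cv_folds=cfg.get("cv_folds", 10),
                        seed=cfg.get("seed", 0),
                        selection=cfg.get("selection", "min"))
    return fit_mgm(d, cv_folds=cfg.get("cv_folds", 10),
                   rule=cfg.get("rule", "AND"), seed=cfg.get("seed", 0),
                   selection=cfg.get("selection", "min"))


def compute_predictability(
    model,
    d: MixedDataset,
    scheme: str = WITHIN_SAMPLE,
    split: float = 0.5,
    seed: int = 0,
) -> PredictabilityReport:
    """Per-node predictability of ``d`` under ``model``.

    ``within_sample`` scores predictions on the data the model was fitted to.
    ``holdout`` refits the model (same configuration) on a training part and
    scores the held-out part: cross-sectional data are split by a seeded
    shuffle, time series by a contiguous first/second cut so temporal order
    survives; marginal accuracies come from the training part, since the
    marginal model is itself fitted on training data.
    """
    if scheme == WITHIN_SAMPLE:
        return PredictabilityReport(nodes=_measures(model, d),
                                    scheme=scheme)
    if scheme != HOLDOUT:
        raise ValueError(f"unknown scheme {scheme!r}")
    if split is None or not 0.0 < split < 1.0:
        raise ValueError("holdout requires a split fraction in (0, 1)")

    n_train = int(round(d.n * split))
    if n_train < 2 or d.n - n_train < 2:
        raise ValueError("split leaves fewer than 2 rows in a part")
    is_var = getattr(model, "kind", "mgm") == "mvar"
    if is_var:
        tr_idx = np.arange(n_train)
        te_idx = np.arange(n_train, d.n)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(d.n)
        tr_idx, te_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    d_train = MixedDataset(d.values[tr_idx], list(d.specs), dict(d.level_labels))
    d_test = MixedDataset(d.values[te_idx], list(d.specs), dict(d.level_labels))
    refit = _refit(model, d_train)

    train_marg = {}
    for j, spec in enumerate(d.specs):
        if spec.is_categorical:
            _, marg = marginal_accuracy(d_train.values[:, j], spec.n_levels)
            train_marg[j] = marg
    nodes = _measures(refit, d_test, train_marginals=train_marg)
    return PredictabilityReport(
        nodes=nodes, scheme=HOLDOUT,
        split={"fraction": split, "seed": seed, "n_train": int(n_train),
               "n_test": int(d.n - n_train),
               "contiguous": bool(is_var)},
    )
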