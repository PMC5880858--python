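"""Serialization of fitted models and predictability reports.

Models round-trip through JSON (weights, signs, per-node selected penalty
and full coefficient blocks, plus a provenance block recording the fit
configuration and package version); reports are written as long-format CSV
(node, family, measure, value, scheme).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import __version__
from .data import VariableSpec
from .mgm import NetworkModel
from .mvar import VARModel
from .nodewise import NodewiseModel
from .predictability import PredictabilityReport


def _sign_out(v: float):
    return "undefined" if np.isnan(v) else int(v)


def _sign_in(v):
    return float("nan") if v == "undefined" else float(v)


def _nodewise_to_dict(m: NodewiseModel) -> dict:
    return {
        "target": m.target,
        "family": m.family,
        "n_levels": m.n_levels,
        "intercepts": np.asarray(m.intercepts).tolist(),
        "coef_blocks": {str(j): b.tolist() for j, b in m.coef_blocks.items()},
        "predictor_levels": {str(j): L for j, L in m.predictor_levels.items()},
        "lambda_selected": m.lambda_selected,
        "lambda_path": np.asarray(m.lambda_path).tolist(),
        "cv_error_path": np.asarray(m.cv_error_path).tolist(),
        "residual_scale": m.residual_scale,
    }


def _nodewise_from_dict(d: dict) -> NodewiseModel:
    return NodewiseModel(
        target=d["target"],
        family=d["family"],
        n_levels=d["n_levels"],
        intercepts=np.asarray(d["intercepts"]),
        coef_blocks={int(j): np.asarray(b) for j, b in d["coef_blocks"].items()},
        lambda_selected=d["lambda_selected"],
        lambda_path=np.asarray(d["lambda_path"]),
        cv_error_path=np.asarray(d["cv_error_path"]),
        residual_scale=d["residual_scale"],
        predictor_levels={int(j): int(L)
                          for j, L in d["predictor_levels"].items()},
    )


def model_to_json(model, path) -> None:
    doc = {
        "kind": model.kind,
        "version": __version__,
        "specs": [s.to_dict() for s in model.specs],
        "weights": model.weights.tolist(),
        "signs": [[_sign_out(v) for v in row] for row in model.signs],
        "train_means": None if model.train_means is None
        else np.asarray(model.train_means).tolist(),
        "fit_config": model.fit_config,
        "nodewise": [_nodewise_to_dict(m) for m in model.nodewise],
    }
    if isinstance(model, NetworkModel):
        doc["aggregation_rule"] = model.aggregation_rule
    with open(path, "w") as fh:
        json.dump(doc, fh)


def model_from_json(path):
    with open(path) as fh:
        doc = json.load(fh)
    specs = [VariableSpec.from_dict(s) for s in doc["specs"]]
    nodewise = [_nodewise_from_dict(m) for m in doc["nodewise"]]
    weights = np.asarray(doc["weights"], dtype=float)
    signs = np.asarray([[_sign_in(v) for v in row] for row in doc["signs"]])
    means = None if doc["train_means"] is None else np.asarray(doc["train_means"])
    if doc["kind"] == "mvar":
        return VARModel(weights=weights, signs=signs, specs=specs,
                        nodewise=nodewise, train_means=means,
                        fit_config=doc["fit_config"])
    return NetworkModel(weights=weights, signs=signs, specs=specs,
                        nodewise=nodewise,
                        aggregation_rule=doc.get("aggregation_rule", "AND"),
                        train_means=means, fit_config=doc["fit_config"])


def report_to_frame(report: PredictabilityReport,
                    measures: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for m in report.nodes:
        avail = {"R2": m.R2, "CC": m.CC, "CCmarg": m.CCmarg, "nCC": m.nCC}
        for name, value in avail.items():
            if value is None:
                continue
            if measures is not None and name not in measures:
                continue
            rows.append({"node": m.node, "name": m.name, "family": m.family,
                         "measure": name, "value": value,
                         "scheme": report.scheme})
    return pd.DataFrame(rows)


def report_to_csv(report: PredictabilityReport, path,
                  measures: list[str] | None = None) -> None:
    report_to_frame(report, measures).to_csv(path, index=False,
                                             float_format="%.10g")
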