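"""Mixed data container with per-variable family metadata and CSV/JSON I/O.

A dataset is an n x p table in which every column is either continuous
("gaussian") or categorical with K >= 2 levels.  Categorical columns hold
1-based integer codes 1..K; string labels in an input CSV are mapped to
codes in order of first appearance and the mapping is retained so files
round-trip.  Missing values are rejected at load: the estimators downstream
define no missing-data mechanism, so silent imputation would change what is
being estimated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GAUSSIAN = "gaussian"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class VariableSpec:
    """Type metadata for one variable: its name, family, and (categorical
    only) the number of categories K."""

    name: str
    family: str
    n_levels: int | None = None

    def __post_init__(self) -> None:
        if self.family not in (GAUSSIAN, CATEGORICAL):
            raise ValueError(
                f"unknown family {self.family!r} for variable {self.name!r}; "
                f"expected 'gaussian' or 'categorical'"
            )
        if self.family == CATEGORICAL:
            if self.n_levels is None or int(self.n_levels) < 2:
                raise ValueError(
                    f"categorical variable {self.name!r} requires n_levels >= 2"
                )
        elif self.n_levels is not None:
            raise ValueError(
                f"gaussian variable {self.name!r} must not define n_levels"
            )

    @property
    def is_categorical(self) -> bool:
        return self.family == CATEGORICAL

    def to_dict(self) -> dict:
        d = {"name": self.name, "family": self.family}
        if self.n_levels is not None:
            d["n_levels"] = int(self.n_levels)
        return d

    @staticmethod
    def from_dict(d: dict) -> "VariableSpec":
        return VariableSpec(
            name=str(d["name"]),
            family=str(d["family"]),
            n_levels=int(d["n_levels"]) if "n_levels" in d else None,
        )


@dataclass
class MixedDataset:
    """Observations x variables with family metadata.

    ``values`` is an (n, p) float array; categorical columns carry integer
    codes in {1, .., K}.  ``level_labels`` optionally records, per categorical
    variable name, the original string labels in code order.
    """

    values: np.ndarray
    specs: list[VariableSpec]
    level_labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        self.validate()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def validate(self) -> None:
        n, p = self.values.shape
        if p != len(self.specs):
            raise ValueError(
                f"{p} columns but {len(self.specs)} variable specs"
            )
        if n < 2:
            raise ValueError("n >= 2 required")
        if p < 2:
            raise ValueError("p >= 2 required")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"missing/non-finite value at row {i}, column {self.specs[j].name!r}"
            )
        for j, spec in enumerate(self.specs):
            if spec.is_categorical:
                col = self.values[:, j]
                codes = np.unique(col)
                if not np.allclose(codes, np.round(codes)):
                    raise ValueError(
                        f"categorical column {spec.name!r} contains non-integer codes"
                    )
                out = (col < 1) | (col > spec.n_levels)
                if out.any():
                    i = int(np.argmax(out))
                    raise ValueError(
                        f"categorical value {col[i]:g} at row {i} of column "
                        f"{spec.name!r} outside 1..{spec.n_levels}"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def copy(self) -> "MixedDataset":
        return replace(self, values=self.values.copy(),
                       specs=list(self.specs),
                       level_labels=dict(self.level_labels))


def load_specs(spec_path) -> list[VariableSpec]:
    with open(spec_path) as fh:
        raw = json.load(fh)
    return [VariableSpec.from_dict(d) for d in raw]


def save_specs(specs: list[VariableSpec], spec_path) -> None:
    with open(spec_path, "w") as fh:
        json.dump([s.to_dict() for s in specs], fh, indent=1)


def load_dataset(data_path, spec_path) -> MixedDataset:
    """Read a CSV (header row required) plus a JSON type spec, validating
    codes, spec/column agreement and completeness.

    Categorical columns may hold arbitrary string labels; these are mapped to
    1-based codes in first-appearance order and the mapping recorded in
    ``level_labels``.
    """
    specs = load_specs(spec_path)
    df = pd.read_csv(data_path, float_precision="round_trip")
    if df.shape[1] != len(specs):
        raise ValueError(
            f"CSV has {df.shape[1]} columns but spec lists {len(specs)} variables"
        )
    if df.shape[0] < 2:
        raise ValueError("n >= 2 required (CSV has fewer than two data rows)")

    values = np.empty(df.shape, dtype=float)
    level_labels: dict[str, list[str]] = {}
    for j, spec in enumerate(specs):
        col = df.iloc[:, j]
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise ValueError(
                f"missing value at row {i}, column {spec.name!r}"
            )
        if spec.is_categorical and not pd.api.types.is_numeric_dtype(col):
            labels: list[str] = []
            codes = np.empty(len(col), dtype=float)
            for i, lab in enumerate(col.astype(str)):
                if lab not in labels:
                    labels.append(lab)
                codes[i] = labels.index(lab) + 1
            if len(labels) > spec.n_levels:
                raise ValueError(
                    f"column {spec.name!r} has {len(labels)} labels but "
                    f"n_levels={spec.n_levels}"
                )
            level_labels[spec.name] = labels
            values[:, j] = codes
        else:
            values[:, j] = pd.to_numeric(col).to_numpy(dtype=float)
    return MixedDataset(values=values, specs=specs, level_labels=level_labels)


def save_dataset(d: MixedDataset, data_path, spec_path=None) -> None:
    """Write the dataset back to CSV (and optionally its spec to JSON) with
    full float precision so finite doubles round-trip bit-exactly."""
    df = d.to_frame()
    df.to_csv(data_path, index=False, float_format="%.17g")
    if spec_path is not None:
        save_specs(d.specs, spec_path)


def continuous_means(d: MixedDataset) -> np.ndarray:
    """Per-column sample means, zero for categorical columns."""
    means = np.zeros(d.p)
    for j, spec in enumerate(d.specs):
        if not spec.is_categorical:
            means[j] = float(np.mean(d.values[:, j]))
    return means


def center_continuous(d: MixedDataset, means: np.ndarray | None = None) -> MixedDataset:
    """Return a copy with every gaussian column shifted to mean zero;
    categorical columns untouched.  Centering removes the intercepts'
    contribution to explained variance.  Idempotent."""
    if means is None:
        means = continuous_means(d)
    out = d.copy()
    out.values = out.values - np.asarray(means)[None, :]
    return out
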