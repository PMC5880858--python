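"""Synthetic data from known network models.

Three generators cover the estimators' ground-truth needs: exact draws from
a Gaussian graphical model given its precision matrix; a Gibbs sampler for
pairwise mixed models (gaussian + categorical nodes) cycling the nodewise
conditionals; and the linear recursion for a stationary lag-1 VAR.  All are
deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CATEGORICAL, GAUSSIAN, MixedDataset, VariableSpec


@dataclass
class SimulationSpec:
    """Ground-truth model for one generator.

    For all-gaussian sampling, ``precision`` is the p x p precision matrix
    (symmetric positive definite; partial correlation of a pair is
    -omega_ij / sqrt(omega_ii * omega_jj)).  For mixed Gibbs sampling,
    ``interactions`` maps node pairs (a, b) with a < b to coupling blocks:
    a scalar theta for gaussian-gaussian (joint term theta * x_a * x_b, i.e.
    theta = -omega_ab), a length-K vector for gaussian-categorical, a
    (K_a, K_b) matrix for categorical-categorical; ``gaussian_precision``
    holds each gaussian node's conditional precision (variance 1/omega) and
    ``thresholds`` each categorical node's per-category base potentials.
    For VAR sampling, ``var_coefs[i, j]`` is the effect of variable i at t-1
    on variable j at t (spectral radius < 1) and ``innovation_sd`` the
    per-variable innovation scale.
    """

    specs: list[VariableSpec]
    n: int
    seed: int = 0
    precision: np.ndarray | None = None
    interactions: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    gaussian_precision: np.ndarray | None = None
    gaussian_intercepts: np.ndarray | None = None
    thresholds: dict[int, np.ndarray] = field(default_factory=dict)
    var_coefs: np.ndarray | None = None
    innovation_sd: np.ndarray | None = None
    burn_in: int = 1000
    thinning: int = 5

    @property
    def p(self) -> int:
        return len(self.specs)


def _check_positive_definite(omega: np.ndarray) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if not np.allclose(omega, omega.T):
        raise ValueError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        raise ValueError("precision matrix is not positive definite") from None
    return omega


def chain_precision(p: int, partial_corr: float) -> np.ndarray:
    """Unit-diagonal precision of a chain graph 1-2-...-p in which every
    adjacent pair has the given partial correlation."""
    omega = np.eye(p)
    for i in range(p - 1):
        omega[i, i + 1] = omega[i + 1, i] = -partial_corr
    return _check_positive_definite(omega)


def ggm_analytic_r2(omega: np.ndarray) -> np.ndarray:
    """Population explained variance of each node given all others:
    R2_s = 1 - 1 / (omega_ss * Sigma_ss) with Sigma the covariance."""
    omega = np.asarray(omega, dtype=float)
    sigma = np.linalg.inv(omega)
    return 1.0 - 1.0 / (np.diag(omega) * np.diag(sigma))


def sample_ggm(spec: SimulationSpec) -> MixedDataset:
    """Exact multivariate-normal draws with the spec's precision matrix."""
    if any(s.is_categorical for s in spec.specs):
        raise ValueError("sample_ggm requires an all-gaussian spec")
    omega = _check_positive_definite(spec.precision)
    sigma = np.linalg.inv(omega)
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(sigma)
    values = rng.standard_normal((spec.n, spec.p)) @ L.T
    if spec.n == 1:
        # container enforces n >= 2 for modeling; single draws are still
        # useful for chaining, so duplicate-guard at the caller
        pass
    return MixedDataset(values, list(spec.specs)) if spec.n >= 2 else \
        _unchecked_dataset(values, spec.specs)


def _unchecked_dataset(values, specs):
    ds = MixedDataset.__new__(MixedDataset)
    ds.values = np.asarray(values, dtype=float)
    ds.specs = list(specs)
    ds.level_labels = {}
    return ds


def _pair_block(spec: SimulationSpec, a: int, b: int):
    """Coupling block of the (unordered) pair, oriented as stored (a < b)."""
    if (a, b) in spec.interactions:
        return np.asarray(spec.interactions[(a, b)], dtype=float), False
    if (b, a) in spec.interactions:
        return np.asarray(spec.interactions[(b, a)], dtype=float), True
    return None, False


def _gibbs_pass(x: np.ndarray, spec: SimulationSpec, rng: np.random.Generator,
                omega_diag: np.ndarray, alpha: np.ndarray) -> None:
    from .predict import softmax
    for s, vs in enumerate(spec.specs):
        if vs.is_categorical:
            K = vs.n_levels
            logits = np.array(spec.thresholds.get(s, np.zeros(K)), dtype=float)
            for t, vt in enumerate(spec.specs):
                if t == s:
                    continue
                block, flipped = _pair_block(spec, min(s, t), max(s, t))
                if block is None:
                    continue
                if vt.is_categorical:
                    B = block if min(s, t) == s else block.T
                    logits = logits + B[:, int(x[t]) - 1]
                else:
                    logits = logits + np.asarray(block).ravel() * x[t]
            probs = softmax(logits[None, :])[0]
            x[s] = rng.choice(K, p=probs) + 1
        else:
            if omega_diag[s] <= 0:
                raise ValueError(
                    f"divergent gaussian conditional at node {vs.name!r}: "
                    f"nonpositive conditional precision"
                )
            drive = alpha[s]
            for t, vt in enumerate(spec.specs):
                if t == s:
                    continue
                block, _ = _pair_block(spec, min(s, t), max(s, t))
                if block is None:
                    continue
                if vt.is_categorical:
                    drive += np.asarray(block).ravel()[int(x[t]) - 1]
                else:
                    drive += float(block) * x[t]
            x[s] = rng.normal(drive / omega_diag[s],
                              1.0 / np.sqrt(omega_diag[s]))


def sample_mgm(spec: SimulationSpec) -> MixedDataset:
    """Gibbs draws from the pairwise mixed model: gaussian nodes from their
    normal conditionals, categorical nodes from their multinomial
    conditionals, with burn-in and thinning."""
    p = spec.p
    rng = np.random.default_rng(spec.seed)
    omega_diag = (np.ones(p) if spec.gaussian_precision is None
                  else np.asarray(spec.gaussian_precision, dtype=float))
    alpha = (np.zeros(p) if spec.gaussian_intercepts is None
             else np.asarray(spec.gaussian_intercepts, dtype=float))
    x = np.zeros(p)
    for s, vs in enumerate(spec.specs):
        x[s] = rng.integers(1, vs.n_levels + 1) if vs.is_categorical else \
            rng.normal()
    for _ in range(spec.burn_in):
        _gibbs_pass(x, spec, rng, omega_diag, alpha)
    rows = np.empty((spec.n, p))
    for i in range(spec.n):
        for _ in range(spec.thinning):
            _gibbs_pass(x, spec, rng, omega_diag, alpha)
        rows[i] = x
    return MixedDataset(rows, list(spec.specs))


def sample_var(spec: SimulationSpec) -> MixedDataset:
    """Stationary lag-1 VAR recursion x_t = B^T x_{t-1} + eps with a 500-step
    burn-in; ``var_coefs[i, j]`` drives target j from lagged i."""
    if any(s.is_categorical for s in spec.specs):
        raise ValueError("sample_var supports gaussian variables only")
    B = np.asarray(spec.var_coefs, dtype=float)
    if B.shape != (spec.p, spec.p):
        raise ValueError("var_coefs must be p x p")
    rho = np.max(np.abs(np.linalg.eigvals(B)))
    if rho >= 1.0:
        raise ValueError(
            f"VAR coefficient matrix has spectral radius {rho:.3f} >= 1; "
            f"the process is not stationary"
        )
    sd = (np.ones(spec.p) if spec.innovation_sd is None
          else np.asarray(spec.innovation_sd, dtype=float))
    rng = np.random.default_rng(spec.seed)
    burn = 500
    x = np.zeros(spec.p)
    rows = np.empty((spec.n, spec.p))
    for t in range(burn + spec.n):
        x = B.T @ x + rng.standard_normal(spec.p) * sd
        if t >= burn:
            rows[t - burn] = x
    return MixedDataset(rows, list(spec.specs))


def gaussian_specs(p: int, prefix: str = "V") -> list[VariableSpec]:
    return [VariableSpec(name=f"{prefix}{j}", family=GAUSSIAN) for j in range(p)]
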