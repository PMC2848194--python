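"""The tanh ("S-shape") transcription-rate model.

A gene's one-step expression change is a saturating function of a weighted
sum of its regulators' current levels:

    dg_i(t+1) = g_i(t+1) - g_i(t)
              = alpha_i * tanh( sum_j w_ji g_j(t) + sum_k w'_ki F_k(t) - beta_i )

|alpha_i| bounds the per-step rate of change, beta_i locates the threshold
at which the tanh crosses zero, and the weights carry the (signed) strength
of each regulator. A single regulator inside the tanh recovers the familiar
one-TF sigmoid model as a special case.

Fitting uses one-step-ahead (teacher-forced) prediction: the model is
evaluated at the *observed* state at time t, and the per-gene lack of fit is
SSE normalised by the gene's sample variance (SSE/Var). Free-running
simulation is available for inspection but is not used in fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import ExpressionDataset


class ModelInputError(ValueError):
    """Raised when the data or parameters are structurally unusable."""


@dataclass
class GeneParameters:
    """Parameters Theta(pi_i) of one target gene.

    ``w`` maps regulator-gene id -> weight; ``w_factor`` maps factor id ->
    weight. Regulators absent from these maps are structurally zero.
    """

    alpha: float
    beta: float
    w: dict[str, float] = field(default_factory=dict)
    w_factor: dict[str, float] = field(default_factory=dict)

    @property
    def regulators(self) -> list[str]:
        return list(self.w) + list(self.w_factor)

    def n_params(self) -> int:
        return 2 + len(self.w) + len(self.w_factor)


def _weighted_sum(params: GeneParameters, state: Mapping[str, float]) -> float:
    s = 0.0
    for rid, weight in {**params.w, **params.w_factor}.items():
        if rid not in state:
            raise ModelInputError(f"state missing regulator {rid!r}")
        s += weight * state[rid]
    return s


def one_step_delta(params: GeneParameters, state: Mapping[str, float]) -> float:
    """Predicted expression change dg_i(t+1) given the state at time t.

    Deterministic; simulator noise is added elsewhere. Bounded by |alpha|.
    """
    u = _weighted_sum(params, state) - params.beta
    return params.alpha * float(np.tanh(u))


def regulator_matrix(
    params: GeneParameters, data: ExpressionDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Stack regulator series into the design used by prediction/fitting.

    Returns ``(X, w)`` where X is (T-1) x p of regulator levels at times
    1..T-1 (columns ordered as ``params.regulators``) and w the matching
    weight vector.
    """
    cols, weights = [], []
    known = set(data.ids)
    for rid, weight in {**params.w, **params.w_factor}.items():
        if rid not in known:
            raise ModelInputError(f"regulator {rid!r} not in dataset")
        cols.append(data.row(rid)[:-1])
        weights.append(weight)
    if cols:
        X = np.column_stack(cols)
    else:
        X = np.zeros((data.n_times - 1, 0))
    return X, np.asarray(weights, dtype=float)


def predict_series(
    params: GeneParameters, data: ExpressionDataset, gene: str
) -> np.ndarray:
    """One-step-ahead predictions ghat_i(2..T), length T-1.

    ghat_i(t+1) = g_i(t) + one_step_delta at the observed state at t.
    """
    if gene not in set(data.ids):
        raise ModelInputError(f"unknown gene {gene!r}")
    if data.n_times < 2:
        raise ModelInputError("need at least 2 time points to predict")
    g = data.row(gene)
    X, w = regulator_matrix(params, data)
    u = X @ w - params.beta
    return g[:-1] + params.alpha * np.tanh(u)


def simulate_free_run(
    params: GeneParameters, data: ExpressionDataset, gene: str
) -> np.ndarray:
    """Free-running trajectory: feed predictions back as the gene's own state.

    Other rows are taken as observed. Offered for inspection only; fitting
    always uses :func:`predict_series` (teacher forcing).
    """
    g_obs = data.row(gene)
    T = data.n_times
    out = np.empty(T)
    out[0] = g_obs[0]
    for t in range(T - 1):
        state = {rid: data.row(rid)[t] for rid in params.regulators}
        if gene in state:
            state[gene] = out[t]  # feed back the simulated level
        out[t + 1] = out[t] + one_step_delta(params, state)
    return out


def sse(params: GeneParameters, data: ExpressionDataset, gene: str) -> float:
    """Sum of squared one-step prediction errors over t = 2..T."""
    g = data.row(gene)
    resid = g[1:] - predict_series(params, data, gene)
    return float(resid @ resid)


def cost(params: GeneParameters, data: ExpressionDataset, gene: str) -> float:
    """The per-gene lack-of-fit E = SSE(g_i) / Var(g_i).

    Var is the unbiased sample variance of the observed row across time.
    """
    v = float(data.var[gene])
    if v <= 0.0:
        raise ModelInputError(f"gene {gene!r} has zero variance; cost undefined")
    return sse(params, data, gene) / v
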