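"""Factor identification.

Factors are nodes that regulate genes inside the network but receive no
incoming links from within it. If every row is nevertheless forced to be
explained from within the network, factor rows cannot be fitted well and
their minimal SSE/Var stands out. The strategy: compute each row's smallest
SSE/Var over all incoming-link sets of size <= l_max (annealing fit per
set), then flag rows whose cost is an upper boxplot outlier
(> Q3 + 1.5 * IQR, Tukey's fence with linear-interpolation quartiles).
Only the upper fence flags: an unusually *good* fit is not lack of fit.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .ga import enumerate_link_sets
from .sa import RANKING_BUDGET, SAConfig, fit_gene

#: guard against intractable enumeration per row
COMBO_WARN_THRESHOLD = 10_000


def min_cost_per_gene(
    data: ExpressionDataset,
    l_max: int = 4,
    sa_cfg: SAConfig | None = None,
    seed: int = 0,
) -> pd.Series:
    """Smallest SSE/Var per row over all within-network link sets.

    Every row (factor designations ignored) is treated as a regulated gene
    whose candidate regulators are all rows including itself (a gene's own
    self-feedback is part of the model class); sets of size 1..l_max are
    enumerated and each is fitted with a reduced annealing budget (this
    step needs a ranking, not final precision). Deterministic given seed.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    sa_cfg = sa_cfg or RANKING_BUDGET
    ids = data.ids
    n_cand = len(ids)
    n_combos = sum(math.comb(n_cand, d) for d in range(1, min(l_max, n_cand) + 1))
    if n_combos > COMBO_WARN_THRESHOLD:
        warnings.warn(
            f"{n_combos} link-set combinations per row; factor scan may be slow",
            stacklevel=2,
        )
    costs = {}
    for ri, rid in enumerate(ids):
        cands = list(ids)
        best = math.inf
        combo_i = 0
        for d in range(1, min(l_max, len(cands)) + 1):
            for combo in enumerate_link_sets(cands, d):
                ss = np.random.SeedSequence(entropy=[seed, 0xFA, ri, combo_i])
                fit = fit_gene(
                    list(combo),
                    data,
                    rid,
                    sa_cfg,
                    seed=int(ss.generate_state(1)[0] % 2**31),
                )
                combo_i += 1
                if fit.energy < best:
                    best = fit.energy
        costs[rid] = best
    return pd.Series(costs, name="min_cost")


def detect_factors(costs: pd.Series, rel_guard: float = 0.05) -> list[str]:
    """Ids whose cost exceeds the upper Tukey fence Q3 + 1.5 * IQR.

    ``rel_guard`` lifts the fence by a fraction of the largest cost so the
    rule stays meaningful when most rows fit essentially perfectly
    (quartiles collapse to ~0 and the bare fence would flag numerical
    residue). Invariant under positive rescaling of all costs; identical
    costs yield an empty set.
    """
    if len(costs) < 4:
        raise ValueError("need at least 4 rows to detect outliers")
    vals = costs.to_numpy(dtype=float)
    q1, q3 = np.percentile(vals, [25, 75])
    fence = q3 + 1.5 * (q3 - q1) + rel_guard * vals.max()
    return [rid for rid, c in costs.items() if c > fence]


def find_factors(
    data: ExpressionDataset,
    l_max: int = 4,
    sa_cfg: SAConfig | None = None,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Convenience wrapper: scan costs, then flag the boxplot outliers."""
    costs = min_cost_per_gene(data, l_max, sa_cfg, seed)
    return detect_factors(costs), costs


def plot_costs(costs: pd.Series, ax=None):
    """Boxplot of per-row minimal SSE/Var with flagged rows annotated."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    ax.boxplot(costs.to_numpy(), tick_labels=["min SSE/Var"])
    for rid in detect_factors(costs):
        ax.annotate(rid, (1.05, costs[rid]), fontsize=9)
    ax.set_ylabel("min SSE/Var")
    return ax
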