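"""Merging two inferred subnetworks into one larger network.

Two subnetworks fitted on the same dataset (sharing factors) are integrated
iteratively: for each gene of the first network, every potential incoming
link from the other network's genes is evaluated by an annealing re-fit of
that gene's augmented link set; the candidate giving the largest decrease
in SSE/Var is provisionally added, and the addition is kept only if the
whole network's AIC/BIC improves (the complexity check). The pass is then
repeated symmetrically for the second network, and the union of the
accepted structures is returned. Each accepted addition strictly improves
the criterion score, so the procedure terminates within the configured
pass budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset
from .ga import StructureFit, gene_score, SSE_FLOOR
from .sa import SAConfig, SEARCH_BUDGET, fit_gene


class MergeError(ValueError):
    pass


@dataclass(frozen=True)
class MergeConfig:
    criterion: str = "aic"
    max_passes: int = 3
    l_max: int = 4
    sa_cfg: SAConfig = SEARCH_BUDGET
    seed: int = 0


def _network_score(fit: StructureFit, data: ExpressionDataset, criterion: str) -> float:
    t_prime = data.n_times - 1
    total = 0.0
    for g in fit.genes:
        total += gene_score(
            fit.sse[g],
            float(data.var[g]),
            len(fit.regulators[g]),
            fit.has_self[g],
            t_prime,
            criterion,
        )
    return total


def _absorb(
    target_net: StructureFit,
    donor_genes: list[str],
    data: ExpressionDataset,
    cfg: MergeConfig,
    pass_i: int,
) -> tuple[StructureFit, bool]:
    """One pass of adding donor-gene links into target_net (at most one
    accepted link per gene). Returns the updated net and whether anything
    was accepted."""
    changed = False
    t_prime = data.n_times - 1
    for gi, gene in enumerate(target_net.genes):
        current = set(target_net.regulators[gene])
        cands = [g for g in donor_genes if g != gene and g not in current]
        if not cands or len(current) >= cfg.l_max:
            continue
        base_energy = target_net.sse[gene] / float(data.var[gene])
        best = None  # (gain, candidate, fit)
        for ci, cand in enumerate(cands):
            regs = list(target_net.regulators[gene]) + [cand]
            if target_net.has_self[gene]:
                regs.append(gene)
            ss = np.random.SeedSequence(entropy=[cfg.seed, 0x3E, pass_i, gi, ci])
            fit = fit_gene(
                regs, data, gene, cfg.sa_cfg,
                seed=int(ss.generate_state(1)[0] % 2**31),
            )
            gain = base_energy - fit.energy
            if best is None or gain > best[0]:
                best = (gain, cand, fit)
        if best is None or best[0] <= 0:
            continue
        _, cand, fit = best
        # complexity check: keep only if the criterion score improves
        var = float(data.var[gene])
        old_term = gene_score(
            target_net.sse[gene], var, len(current), target_net.has_self[gene],
            t_prime, cfg.criterion,
        )
        new_term = gene_score(
            max(fit.sse, SSE_FLOOR), var, len(current) + 1,
            target_net.has_self[gene], t_prime, cfg.criterion,
        )
        if new_term < old_term:
            target_net.regulators[gene] = tuple(list(target_net.regulators[gene]) + [cand])
            target_net.params[gene] = fit.params
            target_net.sse[gene] = fit.sse
            changed = True
    target_net.fitness = _network_score(target_net, data, cfg.criterion)
    return target_net, changed


def _copy(fit: StructureFit) -> StructureFit:
    return StructureFit(
        genes=list(fit.genes),
        factors=list(fit.factors),
        regulators=dict(fit.regulators),
        has_self=dict(fit.has_self),
        params=dict(fit.params),
        sse=dict(fit.sse),
        fitness=fit.fitness,
        criterion=fit.criterion,
    )


def merge(
    net_a: StructureFit,
    net_b: StructureFit,
    data: ExpressionDataset,
    cfg: MergeConfig | None = None,
) -> StructureFit:
    """Merge two subnetworks fitted on the same dataset.

    Returns a network over the union of genes whose per-gene structures are
    the (possibly augmented) structures of the inputs.
    """
    cfg = cfg or MergeConfig()
    known = set(data.ids)
    missing = (set(net_a.genes) | set(net_b.genes)) - known
    if missing:
        raise MergeError(f"genes not present in the shared dataset: {sorted(missing)}")
    a, b = _copy(net_a), _copy(net_b)
    for pass_i in range(cfg.max_passes):
        a, ch_a = _absorb(a, list(net_b.genes), data, cfg, pass_i * 2)
        b, ch_b = _absorb(b, list(net_a.genes), data, cfg, pass_i * 2 + 1)
        if not (ch_a or ch_b):
            break
    # union of the accepted structures
    merged = StructureFit(
        genes=list(dict.fromkeys(a.genes + b.genes)),
        factors=list(dict.fromkeys(a.factors + b.factors)),
        regulators={**b.regulators, **a.regulators},
        has_self={**b.has_self, **a.has_self},
        params={**b.params, **a.params},
        sse={**b.sse, **a.sse},
        fitness=0.0,
        criterion=cfg.criterion,
    )
    merged.fitness = _network_score(merged, data, cfg.criterion)
    return merged
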