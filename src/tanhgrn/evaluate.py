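"""Network-recovery metrics.

Predicted edge sets are scored against ground truth over the candidate set
of all (regulator in genes+factors) -> (target in genes) directed pairs,
self pairs included; factors are never candidate targets. Besides the usual
TPR/TNR/FPR, the modified false positive rate mFPR = FP / (TP + FP) (the
complement of precision) is reported, which separates methods well when
true non-links vastly outnumber links. Sign-aware mode additionally
requires a predicted edge's sign to match the true edge's sign to count as
a true positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Edge = tuple[str, str]  # (regulator, target)


class EvaluationInputError(ValueError):
    pass


@dataclass
class EvaluationReport:
    """Confusion counts and rates over the candidate directed pairs."""

    tp: int
    fp: int
    tn: int
    fn: int
    signed: bool = False

    @property
    def n_candidates(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else 0.0

    @property
    def tnr(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else 0.0

    @property
    def fpr(self) -> float:
        neg = self.tn + self.fp
        return self.fp / neg if neg else 0.0

    @property
    def mfpr(self) -> float:
        pred = self.tp + self.fp
        return self.fp / pred if pred else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "tpr": round(self.tpr, 4), "tnr": round(self.tnr, 4),
            "fpr": round(self.fpr, 4), "mfpr": round(self.mfpr, 4),
            "signed": self.signed,
        }


def candidate_pairs(
    genes: list[str], factors: list[str], include_self: bool = True
) -> list[Edge]:
    """All candidate regulator -> target pairs: (genes + factors) x genes,
    gene self pairs included by default; factors are never targets."""
    pairs = []
    for reg in list(genes) + list(factors):
        for tgt in genes:
            if not include_self and reg == tgt:
                continue
            pairs.append((reg, tgt))
    return pairs


def _edge_map(edges, genes, factors) -> dict[Edge, int]:
    universe = set(genes) | set(factors)
    out: dict[Edge, int] = {}
    for e in edges:
        reg, tgt = e[0], e[1]
        if reg not in universe or tgt not in universe:
            raise EvaluationInputError(f"edge ({reg}, {tgt}) references unknown node")
        if tgt in set(factors):
            raise EvaluationInputError(f"factor {tgt!r} cannot be a target")
        sign = int(np.sign(e[2])) if len(e) > 2 and e[2] is not None else 1
        if len(e) > 3 and e[3] is not None:
            sign = int(e[3])
        out[(reg, tgt)] = sign or 1
    return out


def score(
    truth_edges,
    predicted_edges,
    genes: list[str],
    factors: list[str],
    signed: bool = False,
    include_self: bool = True,
) -> EvaluationReport:
    """Confusion counts over the candidate pairs.

    Edges are (regulator, target[, weight[, sign]]) tuples; when a sign
    column is absent the weight's sign is used. In unsigned mode a
    predicted link with the wrong sign still counts as a true positive.
    """
    t = _edge_map(truth_edges, genes, factors)
    p = _edge_map(predicted_edges, genes, factors)
    tp = fp = tn = fn = 0
    for pair in candidate_pairs(genes, factors, include_self):
        in_t, in_p = pair in t, pair in p
        if in_t and in_p:
            if signed and t[pair] != p[pair]:
                # wrong sign: the true link goes unrecovered; the pair stays
                # on the true-link side so tp+fn = #links, tn+fp = #non-links
                fn += 1
            else:
                tp += 1
        elif in_p:
            fp += 1
        elif in_t:
            fn += 1
        else:
            tn += 1
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn, signed=signed)


def mtpr_star(n_tp: int, n_validated: int, n_predicted: int) -> float:
    """TP over min(validated regulators, total predicted links); 0 when the
    minimum is 0. Used when the validation catalogue is known-incomplete."""
    if min(n_tp, n_validated, n_predicted) < 0:
        raise EvaluationInputError("counts must be non-negative")
    if n_predicted < n_tp:
        raise EvaluationInputError("n_predicted must be >= n_tp")
    denom = min(n_validated, n_predicted)
    return n_tp / denom if denom else 0.0
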