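"""Model / Results interface over the inference pipeline.

`NetworkModel` holds the data and the modelling choices; `fit()` runs the
structure search plus parameter estimation and returns a `NetworkResults`
carrying the inferred structure, per-gene parameter estimates, fit
diagnostics and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .dynamics import GeneParameters, predict_series
from .evaluate import EvaluationReport, score as _score
from .ga import GAConfig, StructureFit, run_ga
from .preprocess import smooth_dataset
from .sa import SAConfig


class NetworkModel:
    """Small gene-network model for time-course expression data.

    Parameters
    ----------
    data : ExpressionDataset
        Genes x time matrix with factor rows designated.
    factors : list of str, optional
        Override the dataset's factor designation.
    l_max : int
        Maximum in-degree per gene.
    criterion : {"aic", "bic"}
        Model-selection criterion for the structure search.
    power_law : float or None
        If set (2 < gamma < 3), restrict the in-degree distribution of the
        structure search to P(k) ~ k^-gamma.
    smooth_width : int or None
        Optional mean-filter width applied before fitting.
    """

    def __init__(
        self,
        data: ExpressionDataset,
        factors: list[str] | None = None,
        l_max: int = 4,
        criterion: str = "aic",
        power_law: float | None = None,
        smooth_width: int | None = None,
    ):
        self.raw_data = data
        self.factors = list(factors if factors is not None else data.factor_ids)
        self.l_max = l_max
        self.criterion = criterion
        self.power_law = power_law
        self.smooth_width = smooth_width
        self.data = smooth_dataset(data, smooth_width) if smooth_width else data

    @classmethod
    def from_tsv(cls, path: str | Path, factors: list[str] | None = None, **kw) -> "NetworkModel":
        return cls(ExpressionDataset.from_tsv(path, factors=factors), **kw)

    def fit(
        self,
        seed: int = 0,
        ga_config: GAConfig | None = None,
        sa_config: SAConfig | None = None,
    ) -> "NetworkResults":
        cfg = ga_config or GAConfig(
            l_max=self.l_max,
            criterion=self.criterion,
            power_law=self.power_law,
            seed=seed,
        )
        fit = run_ga(self.data, self.factors, cfg, sa_config)
        return NetworkResults(model=self, structure=fit, seed=seed)


@dataclass
class NetworkResults:
    """Inferred network: structure, parameters and diagnostics."""

    model: NetworkModel
    structure: StructureFit
    seed: int = 0

    @property
    def fitness(self) -> float:
        return self.structure.fitness

    @property
    def criterion(self) -> str:
        return self.structure.criterion

    def params(self, gene: str) -> GeneParameters:
        return self.structure.params[gene]

    def edges(self) -> list[tuple[str, str, float, int]]:
        return self.structure.edges()

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges(), columns=["regulator", "target", "weight", "sign"]
        )

    def cost_per_gene(self) -> pd.Series:
        var = self.model.data.var
        return pd.Series(
            {g: self.structure.sse[g] / float(var[g]) for g in self.structure.genes},
            name="sse_over_var",
        )

    def predict(self, gene: str) -> np.ndarray:
        """One-step-ahead predicted levels ghat(2..T) for one gene."""
        return predict_series(self.params(gene), self.model.data, gene)

    def evaluate(self, truth_edges, signed: bool = False) -> EvaluationReport:
        return _score(
            truth_edges,
            self.edges(),
            self.structure.genes,
            self.structure.factors,
            signed=signed,
        )

    def summary(self) -> str:
        lines = []
        st = self.structure
        data = self.model.data
        lines.append("Gene network inference (tanh rate model)")
        lines.append("=" * 72)
        lines.append(
            f"genes: {len(st.genes)}  factors: {len(st.factors)}"
            f"  time points: {data.n_times}"
        )
        lines.append(
            f"criterion: {st.criterion.upper()}  score: {st.fitness:.6f}"
            f"  converged: {st.converged}  SA fits: {st.n_fits}"
        )
        lines.append("-" * 72)
        lines.append(
            f"{'gene':<6}{'regulators':<34}{'self':<6}{'alpha':>8}{'beta':>8}{'SSE/Var':>10}"
        )
        var = data.var
        for g in st.genes:
            gp = st.params[g]
            regs = ",".join(
                f"{r}({w:+.2f})" for r, w in {**gp.w, **gp.w_factor}.items() if r != g
            )
            cost = st.sse[g] / float(var[g])
            lines.append(
                f"{g:<6}{regs:<34}{str(st.has_self[g]):<6}"
                f"{gp.alpha:>8.3f}{gp.beta:>8.3f}{cost:>10.4f}"
            )
        lines.append("-" * 72)
        lines.append(f"predicted links: {len(self.edges())}")
        return "\n".join(lines)
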