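"""Time-course expression data container.

Expression matrices are genes x time points on a log-ratio scale (cDNA
microarray convention). Rows are split into ordinary genes and *factors*:
nodes that regulate genes inside the network but receive no incoming links
from within it (external transcription factors or proteins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FACTOR_PREFIX = "#factor:"


class ExpressionDataError(ValueError):
    """Raised for malformed or degenerate expression input."""


@dataclass
class ExpressionDataset:
    """Genes x time expression matrix with factor designations.

    Parameters
    ----------
    frame : DataFrame
        Rows indexed by gene/factor id, columns are time labels. Gene rows
        come first, factor rows last (order is normalised on construction).
    factor_ids : list of str
        Ids of the factor rows (subset of the index).
    """

    frame: pd.DataFrame
    factor_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique()
            raise ExpressionDataError(f"duplicate row id(s): {list(dupes)}")
        unknown = set(self.factor_ids) - set(self.frame.index)
        if unknown:
            raise ExpressionDataError(f"factor id(s) not in matrix: {sorted(unknown)}")
        if self.frame.shape[1] < 3:
            raise ExpressionDataError(
                f"need at least 3 time points, got {self.frame.shape[1]}"
            )
        vals = self.frame.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = self.frame.index[~np.isfinite(vals).all(axis=1)]
            raise ExpressionDataError(f"non-finite values in row(s): {list(bad)}")
        if len(self.factor_ids) > len(self.gene_ids):
            raise ExpressionDataError("more factors than genes")
        # normalise order: genes first, factors last
        order = self.gene_ids + self.factor_ids
        self.frame = self.frame.loc[order].astype(float)
        # row/variance caches: fits hit these thousands of times
        self._rows = {
            rid: np.ascontiguousarray(vals)
            for rid, vals in zip(self.frame.index, self.frame.to_numpy(dtype=float))
        }
        self._var = self.frame.var(axis=1, ddof=1)

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [i for i in self.frame.index if i not in set(self.factor_ids)]

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_genes(self) -> int:
        return len(self.frame) - len(self.factor_ids)

    @property
    def n_factors(self) -> int:
        return len(self.factor_ids)

    @property
    def n_times(self) -> int:
        return self.frame.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def row(self, rid: str) -> np.ndarray:
        return self._rows[rid]

    @property
    def var(self) -> pd.Series:
        """Unbiased per-row sample variance across time (denominator T-1)."""
        return self._var

    def is_factor(self, rid: str) -> bool:
        return rid in set(self.factor_ids)

    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        gene_ids: list[str],
        factor_ids: list[str] | None = None,
        factor_values: np.ndarray | None = None,
        time_labels: list | None = None,
    ) -> "ExpressionDataset":
        factor_ids = list(factor_ids or [])
        values = np.asarray(values, dtype=float)
        if factor_values is not None:
            values = np.vstack([values, np.asarray(factor_values, dtype=float)])
        idx = list(gene_ids) + factor_ids
        if time_labels is None:
            time_labels = list(range(1, values.shape[1] + 1))
        frame = pd.DataFrame(values, index=idx, columns=time_labels)
        return cls(frame, factor_ids)

    @classmethod
    def from_tsv(cls, path: str | Path, factors: list[str] | None = None) -> "ExpressionDataset":
        """Read a TSV expression matrix.

        First column holds the row id; the header row holds time labels.
        Factor rows may be flagged with a ``#factor:`` id prefix, or given
        via the ``factors`` sidecar list.
        """
        path = Path(path)
        rows: list[tuple[str, list[float]]] = []
        factor_ids = list(factors or [])
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            time_labels = header[1:]
            width = len(time_labels)
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                rid = parts[0]
                if rid.startswith(FACTOR_PREFIX):
                    rid = rid[len(FACTOR_PREFIX):]
                    if rid not in factor_ids:
                        factor_ids.append(rid)
                if len(parts) - 1 != width:
                    raise ExpressionDataError(
                        f"{path}:{lineno}: expected {width} values, got {len(parts) - 1}"
                    )
                try:
                    vals = [float(x) for x in parts[1:]]
                except ValueError as exc:
                    raise ExpressionDataError(f"{path}:{lineno}: non-numeric cell ({exc})")
                if any(r[0] == rid for r in rows):
                    raise ExpressionDataError(f"{path}:{lineno}: duplicate id {rid!r}")
                rows.append((rid, vals))
        frame = pd.DataFrame(
            [v for _, v in rows], index=[r for r, _ in rows], columns=time_labels
        )
        return cls(frame, factor_ids)

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix; factor rows carry the ``#factor:`` id prefix."""
        path = Path(path)
        fset = set(self.factor_ids)
        with path.open("w") as fh:
            fh.write("id\t" + "\t".join(str(c) for c in self.frame.columns) + "\n")
            for rid in self.frame.index:
                tag = FACTOR_PREFIX + rid if rid in fset else rid
                vals = "\t".join(repr(float(v)) for v in self.frame.loc[rid])
                fh.write(f"{tag}\t{vals}\n")
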