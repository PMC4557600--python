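"""Core containers: the sample design and the expression matrix.

The experimental unit throughout is a nested replicate design per cell
culture: ``condition in {control, treated}`` x biological replicate x
technical replicate.  The default layout mirrors a two-culture treatment
experiment with three biological and two technical replicates per
(cell_line, condition) cell, i.e. 12 arrays per culture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("control", "treated")

DESIGN_COLUMNS = ["sample_id", "cell_line", "condition", "bio_rep", "tech_rep"]


@dataclass
class SampleDesign:
    """Sample sheet tying every array column to its experimental cell.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per sample with columns ``sample_id``, ``cell_line``,
        ``condition`` ("control"/"treated"), ``bio_rep`` (>= 1) and
        ``tech_rep`` (>= 1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        key = t[["cell_line", "condition", "bio_rep", "tech_rep"]]
        if key.duplicated().any():
            raise ValueError("duplicate (cell_line, condition, bio_rep, tech_rep) combination")
        if (t["bio_rep"] < 1).any() or (t["tech_rep"] < 1).any():
            raise ValueError("bio_rep and tech_rep must be >= 1")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.table["cell_line"].unique())

    def subset(self, cell_line: str) -> "SampleDesign":
        sub = self.table[self.table["cell_line"] == cell_line]
        if sub.empty:
            raise KeyError(f"no samples for cell line {cell_line!r}")
        return SampleDesign(sub)

    def condition_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in design")
        return row["condition"].iloc[0]

    def labels(self, by: str = "condition") -> pd.Series:
        """Per-sample labels indexed by sample_id (``condition`` or ``cell_line``)."""
        if by not in ("condition", "cell_line"):
            raise ValueError("label must be 'condition' or 'cell_line'")
        return self.table.set_index("sample_id")[by]

    @classmethod
    def default_layout(
        cls,
        cell_lines: tuple[str, ...] = ("HN1957", "HN2092"),
        n_bio: int = 3,
        n_tech: int = 2,
    ) -> "SampleDesign":
        """The study layout: 3 biological x 2 technical replicates per cell."""
        rows = []
        for cl in cell_lines:
            for cond in CONDITIONS:
                tag = "C" if cond == "control" else "T"
                for b in range(1, n_bio + 1):
                    for t in range(1, n_tech + 1):
                        tech_tag = chr(ord("A") + t - 1)
                        rows.append(
                            {
                                "sample_id": f"{cl}_{tag}{b}{tech_tag}",
                                "cell_line": cl,
                                "condition": cond,
                                "bio_rep": b,
                                "tech_rep": t,
                            }
                        )
        return cls(pd.DataFrame(rows))


@dataclass
class ExpressionMatrix:
    """Log2-scale feature-by-sample expression values.

    ``values`` rows are features (unique ids in the index), columns are
    sample ids matching a :class:`SampleDesign`.  ``kind`` records whether
    the features are miRNAs or mRNAs.
    """

    values: pd.DataFrame
    kind: str = field(default="mRNA")

    def __post_init__(self) -> None:
        if self.kind not in ("miRNA", "mRNA"):
            raise ValueError(f"kind must be 'miRNA' or 'mRNA', got {self.kind!r}")
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        arr = v.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            bad = v.index[np.argwhere(~np.isfinite(arr))[0][0]]
            raise ValueError(f"non-finite expression value (feature {bad!r})")
        self.values = v.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def check_design(self, design: SampleDesign) -> None:
        """Raise unless the column set equals the design's sample-id set."""
        cols, ids = set(self.sample_ids), set(design.sample_ids)
        if cols != ids:
            extra, miss = sorted(cols - ids), sorted(ids - cols)
            raise ValueError(
                f"matrix/design sample mismatch (matrix-only: {extra}, design-only: {miss})"
            )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.values[sample_ids], self.kind)

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        feature_ids = list(feature_ids)
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[feature_ids], self.kind)
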