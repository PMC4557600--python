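"""Relative quantification of qRT-PCR data by the 2^-ddCt method.

Cycle-threshold (Ct) values are normalized per sample against one or more
reference assays (e.g. U6 snRNA for miRNAs, B2M/ACTB for mRNAs), contrasted
between treated and control biological replicates, and converted to fold
changes via fc = 2^-ddCt.  Spearman rank correlations between miRNA and
mRNA fold-change series provide the interaction-validation statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import SampleDesign

CT_COLUMNS = ["target_id", "sample_id", "replicate", "ct"]


class ConstantVectorError(ValueError):
    """Rank correlation is undefined for a constant vector."""


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold measurements.

    ``records`` holds one row per (target, sample, PCR replicate) with the
    measured ``ct``; ``reference_targets`` names the endogenous-control
    assays used for normalization.
    """

    records: pd.DataFrame
    reference_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        r = self.records.reset_index(drop=True).copy()
        ct = r["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("all Ct values must be finite and > 0")
        if r[["target_id", "sample_id", "replicate"]].duplicated().any():
            raise ValueError("duplicate (target, sample, replicate) measurement")
        if not self.reference_targets:
            raise ValueError("at least one reference target is required")
        targets = set(r["target_id"])
        absent = [t for t in self.reference_targets if t not in targets]
        if absent:
            raise ValueError(f"reference targets not measured: {absent}")
        self.records = r

    @property
    def target_ids(self) -> list[str]:
        return sorted(set(self.records["target_id"]) - set(self.reference_targets))


def _delta_ct(table: CtTable, target: str) -> pd.Series:
    """Per-sample dCt = Ct_target - mean(reference Cts), PCR replicates averaged.

    Averaging the reference Cts on the cycle (log2) scale is equivalent to
    normalizing expression by the geometric mean of the reference assays.
    """
    rec = table.records
    tgt = rec[rec["target_id"] == target]
    if tgt.empty:
        raise KeyError(f"target {target!r} not measured")
    refs = rec[rec["target_id"].isin(table.reference_targets)]
    # mean reference Ct per (sample, replicate); every target well needs one
    ref_mean = refs.groupby(["sample_id", "replicate"])["ct"].agg(["mean", "size"])
    complete = ref_mean[ref_mean["size"] == len(table.reference_targets)]["mean"]
    keyed = tgt.set_index(["sample_id", "replicate"])["ct"]
    missing = keyed.index.difference(complete.index)
    if len(missing):
        s, r = missing[0]
        raise ValueError(
            f"missing reference measurement for sample {s!r} replicate {r} "
            f"(target {target!r})"
        )
    dct = keyed - complete.reindex(keyed.index)
    return dct.groupby(level="sample_id").mean()


def ddct_fold_change(table: CtTable, target: str, design: SampleDesign) -> tuple[float, float]:
    """Treated-vs-control fold change of `target` by 2^-ddCt.

    Returns ``(fc, p)`` where ddCt = mean dCt(treated) - mean dCt(control),
    fc = 2^-ddCt, and p is a two-sided two-sample t-test on the per-sample
    dCt values.
    """
    dct = _delta_ct(table, target)
    cond = design.labels("condition").reindex(dct.index)
    if cond.isna().any():
        bad = dct.index[cond.isna()][0]
        raise KeyError(f"sample {bad!r} not in design")
    treated = dct[cond == "treated"].to_numpy()
    control = dct[cond == "control"].to_numpy()
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(
            f"target {target!r}: need >=2 biological replicates per condition "
            f"(treated={len(treated)}, control={len(control)})"
        )
    ddct = treated.mean() - control.mean()
    fc = float(2.0 ** (-ddct))
    if np.ptp(treated) == 0 and np.ptp(control) == 0:
        p = 1.0 if ddct == 0 else 0.0
    else:
        p = float(stats.ttest_ind(treated, control).pvalue)
    return fc, p


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def count_validated_pairs(pairs, threshold: float = -0.5) -> int:
    """Count miRNA-mRNA pairs whose Spearman rho is at or below `threshold`.

    `pairs` is an iterable of (miRNA, mRNA, rho) triples (or bare rho
    values); a pair validates the assumed repressive interaction when its
    fold-change series anti-correlate at rho <= threshold.
    """
    n = 0
    for item in pairs:
        rho = float(item[2]) if isinstance(item, (tuple, list)) else float(item)
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"rho outside [-1, 1]: {rho}")
        if rho <= threshold:
            n += 1
    return n


class DeltaDeltaCt:
    """2^-ddCt relative-quantification model for a qPCR plate.

    Parameters
    ----------
    ct_table : CtTable
        Measured cycle thresholds including the reference assays.
    design : SampleDesign
        Maps sample ids to treated/control.
    """

    def __init__(self, ct_table: CtTable, design: SampleDesign):
        self.ct_table = ct_table
        self.design = design

    def fit(self, targets: list[str] | None = None) -> "DeltaDeltaCtResults":
        targets = list(targets) if targets is not None else self.ct_table.target_ids
        rows = []
        for t in targets:
            fc, p = ddct_fold_change(self.ct_table, t, self.design)
            rows.append({"target_id": t, "fc": fc, "p": p})
        table = pd.DataFrame(rows).set_index("target_id")
        return DeltaDeltaCtResults(self, table)


class DeltaDeltaCtResults:
    def __init__(self, model: DeltaDeltaCt, table: pd.DataFrame):
        self.model = model
        self.table = table

    def fold_change(self, target: str) -> float:
        return float(self.table.loc[target, "fc"])

    def summary(self) -> str:
        lines = ["2^-ddCt relative quantification",
                 f"reference targets: {', '.join(self.model.ct_table.reference_targets)}",
                 ""]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
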