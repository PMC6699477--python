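"""Relative quantification of qPCR data by the comparative-Ct (2^-ΔΔCt) method.

Per replicate, ΔCt = Ct(target) - Ct(reference); ΔΔCt subtracts the mean
control ΔCt, and the fold change is 2^-ΔΔCt.  The mean control fold change is
1 by construction in ΔCt space.  Mean ± SEM is reported over per-replicate
treatment fold changes (matching the usual MEAN ± S.E.M. presentation), the
log2 fold change is log2 of the mean, and significance is a two-sided
Student's equal-variance t-test on ΔCt values between conditions (the
standard practice; configurable to FC space).  No amplification-efficiency
correction is applied — the model is a pure power of two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "condition", "replicate", "target", "ct_target", "reference", "ct_reference", "assay"]


@dataclass
class ExpressionResult:
    target: str
    fold_changes: list[float]  # per treatment replicate
    mean_fc: float
    sem_fc: float
    log2fc: float
    p_value: float
    n_treatment: int
    n_control: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def stars(self, thresholds: tuple[float, float, float] = (0.05, 0.01, 0.001)) -> str:
        if self.p_value < thresholds[2]:
            return "***"
        if self.p_value < thresholds[1]:
            return "**"
        if self.p_value < thresholds[0]:
            return "*"
        return ""


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(df[col], errors="raise")
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError(f"{col}: Ct values must be finite and > 0")
    bad = set(df["condition"]) - {"treatment", "control"}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}")
    return df


def ddct(table: pd.DataFrame, target: str, test_space: str = "dct") -> ExpressionResult:
    """2^-ΔΔCt relative expression of ``target`` vs the control condition.

    ``test_space`` selects whether the t-test compares ΔCt values (default)
    or per-replicate fold changes.
    """
    validate_ct_table(table)
    sub = table[table["target"] == target]
    if sub.empty:
        raise ValueError(f"target {target!r} not in table")
    treat = sub[sub["condition"] == "treatment"]
    ctrl = sub[sub["condition"] == "control"]
    if len(treat) < 2 or len(ctrl) < 2:
        raise ValueError(f"target {target!r}: need >=2 replicates per condition")
    dct_t = (treat["ct_target"] - treat["ct_reference"]).to_numpy(float)
    dct_c = (ctrl["ct_target"] - ctrl["ct_reference"]).to_numpy(float)
    ddct_t = dct_t - dct_c.mean()
    fc = np.power(2.0, -ddct_t)
    mean_fc = float(fc.mean())
    sem_fc = float(stats.sem(fc, ddof=1)) if len(fc) > 1 else 0.0
    if test_space == "dct":
        a, b = dct_t, dct_c
    elif test_space == "fc":
        a, b = fc, np.power(2.0, -(dct_c - dct_c.mean()))
    else:
        raise ValueError("test_space must be 'dct' or 'fc'")
    if np.var(a) == 0.0 and np.var(b) == 0.0:  # degenerate noise-free input
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        _, p = stats.ttest_ind(a, b, equal_var=True)
    return ExpressionResult(
        target=target,
        fold_changes=[float(x) for x in fc],
        mean_fc=mean_fc,
        sem_fc=sem_fc,
        log2fc=math.log2(mean_fc),
        p_value=float(p),
        n_treatment=len(treat),
        n_control=len(ctrl),
    )


def density_compare(table: pd.DataFrame, target: str = "16S") -> tuple[ExpressionResult, str]:
    """Symbiont-density comparison on a DNA-assay Ct table; the verdict is
    'not significant' when p >= 0.05."""
    dna = table[table["assay"] == "dna"] if "assay" in table.columns else table
    if dna.empty:
        raise ValueError("no DNA-assay rows in table")
    res = ddct(dna, target)
    verdict = "significant" if res.p_value < 0.05 else "not significant"
    return res, verdict


def results_table(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    rows = [
        dict(
            gene=r.target,
            log2fc=round(r.log2fc, 2),
            fc_mean=round(r.mean_fc, 2),
            fc_sem=round(r.sem_fc, 3),
            p_value=r.p_value,
            significance=r.stars(),
        )
        for r in results
    ]
    return pd.DataFrame(rows)
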