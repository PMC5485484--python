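"""Relative quantification from qPCR Ct tables by the 2^-ddCt method.

dCt = Ct_gene - Ct_reference, paired by replicate index within each
condition; ddCt = dCt_treated - mean(dCt_control); fold = 2^-ddCt with
the control folds rescaled to mean 1.  Conditions are compared with a
two-sided Welch (unequal-variance) t-test on the per-replicate folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RelativeExpression", "load_ct_table", "ddct", "replicate_ttest"]

_REQUIRED = ("gene", "role", "condition", "replicate", "ct")


@dataclass
class RelativeExpression:
    gene: str
    reference: str
    dct_control: np.ndarray
    dct_treated: np.ndarray
    ddct: float                  # mean(dCt_treated) - mean(dCt_control)
    folds_control: np.ndarray    # rescaled so their mean is 1
    folds_treated: np.ndarray
    fold_mean: float
    fold_sd: float
    p_value: float


def load_ct_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return df


def _paired_dct(df: pd.DataFrame, gene: str, reference: str, condition: str) -> np.ndarray:
    g = df[(df["gene"] == gene) & (df["condition"] == condition)].set_index("replicate")["ct"]
    r = df[(df["gene"] == reference) & (df["condition"] == condition)].set_index("replicate")["ct"]
    if g.empty or r.empty:
        raise ValueError(f"missing condition {condition!r} for {gene!r} or {reference!r}")
    unpaired = sorted(set(g.index) ^ set(r.index))
    if unpaired:
        raise ValueError(f"unpaired replicates for condition {condition!r}: {unpaired}")
    reps = sorted(g.index)
    return (g.loc[reps] - r.loc[reps]).to_numpy(dtype=float)


def ddct(ct_table: pd.DataFrame, gene: str, reference: str) -> RelativeExpression:
    """Relative expression of ``gene`` against ``reference`` across conditions."""
    df = load_ct_table(ct_table)
    dct_c = _paired_dct(df, gene, reference, "control")
    dct_t = _paired_dct(df, gene, reference, "treated")
    base = dct_c.mean()
    folds_c = np.power(2.0, -(dct_c - base))
    folds_t = np.power(2.0, -(dct_t - base))
    scale = folds_c.mean()          # rescale so the control mean is exactly 1
    folds_c = folds_c / scale
    folds_t = folds_t / scale
    p = replicate_ttest(folds_c, folds_t) if min(len(folds_c), len(folds_t)) >= 2 else np.nan
    return RelativeExpression(
        gene=gene,
        reference=reference,
        dct_control=dct_c,
        dct_treated=dct_t,
        ddct=float(dct_t.mean() - base),
        folds_control=folds_c,
        folds_treated=folds_t,
        fold_mean=float(folds_t.mean()),
        fold_sd=float(folds_t.std(ddof=1)) if len(folds_t) > 1 else 0.0,
        p_value=float(p),
    )


def replicate_ttest(folds_control: np.ndarray, folds_treated: np.ndarray) -> float:
    """Two-sided Welch t-test p-value between replicate fold values."""
    a = np.asarray(folds_control, dtype=float)
    b = np.asarray(folds_treated, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
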