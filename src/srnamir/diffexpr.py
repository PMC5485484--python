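"""RPM normalization, fold changes and the tag-count exact test.

The test is the classic Audic-Claverie conditional: given x tags in a
library of N1 clean reads, the probability of seeing y tags in a second
library of N2 clean reads is

    P(y | x) = (N2/N1)^y * (x+y)! / (x! y!) / (1 + N2/N1)^(x+y+1),

i.e. y | x ~ NegativeBinomial(x+1, N1/(N1+N2)).  Tail masses
C = sum_{k<=y} P(k|x) and D = sum_{k>=y} P(k|x) are accumulated in log
space via log-gamma (D through the complement, never an infinite sum),
and the reported two-sided p-value is min(1, 2 min(C, D)); a one-sided
variant is available.  No multiple-testing correction gates the flags —
the thresholds are raw p <= 0.05 (p <= 0.01 for "significant") combined
with |log2 fold change| >= 1; a Benjamini-Hochberg column is emitted for
reference only.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "normalize",
    "log2_fold_change",
    "ac_pmf",
    "ac_pvalue",
    "expression_table",
    "call_de",
]

RPM_EPSILON = 0.01  # pseudo-RPM replacing zeros in fold-change ratios only


def normalize(count: int, library_total: int) -> float:
    """Reads-per-million: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / library_total * 1e6


def log2_fold_change(rpm_treated: float, rpm_control: float, epsilon: float = RPM_EPSILON) -> float:
    """log2(treated/control) on RPM, zeros floored at ``epsilon`` RPM.

    Antisymmetric under swapping the libraries; 0 when both are zero.
    """
    if rpm_treated < 0 or rpm_control < 0:
        raise ValueError("RPM values must be >= 0")
    if rpm_treated == 0 and rpm_control == 0:
        return 0.0
    return math.log2(max(rpm_treated, epsilon) / max(rpm_control, epsilon))


def _log_pmf(ks: np.ndarray, x: int, log_r: float) -> np.ndarray:
    return (
        ks * log_r
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
        - (x + ks + 1) * np.log1p(np.exp(log_r))
    )


def ac_pmf(x: int, y: int, n1: int, n2: int) -> float:
    """P(y | x) for library totals (n1, n2); evaluated via log-gamma."""
    if x < 0 or y < 0:
        raise ValueError("counts must be >= 0")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be > 0")
    log_r = math.log(n2) - math.log(n1)
    return float(np.exp(_log_pmf(np.array([y], dtype=float), x, log_r)[0]))


def ac_pvalue(x: int, y: int, n1: int, n2: int, two_sided: bool = True) -> tuple[float, float, float]:
    """Tail masses and p-value of the exact test.

    Returns ``(C, D, p)`` with C = P(Y <= y | x), D = P(Y >= y | x)
    (computed as 1 - P(Y < y | x)) and p = min(1, 2 min(C, D)) when
    two-sided, min(C, D) otherwise.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be >= 0")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be > 0")
    log_r = math.log(n2) - math.log(n1)
    logs = _log_pmf(np.arange(y + 1, dtype=float), x, log_r)
    c = float(np.exp(logsumexp(logs)))
    below = float(np.exp(logsumexp(logs[:-1]))) if y > 0 else 0.0
    d = 1.0 - below
    c, d = min(c, 1.0), max(min(d, 1.0), 0.0)
    p = min(1.0, 2.0 * min(c, d)) if two_sided else min(c, d)
    return c, d, p


def expression_table(
    counts: pd.DataFrame | list[tuple[str, int, int]],
    total_treated: int,
    total_control: int,
    two_sided: bool = True,
    swap_totals: bool = False,
) -> pd.DataFrame:
    """Per-miRNA expression statistics for the treated-vs-control contrast.

    ``counts`` rows are (mirna_id, count_treated, count_control); x is
    the treated count with its library total as N1, y the control count
    with N2 (``swap_totals`` flips the binding).  Adds RPM, log2 fold
    change, the exact-test C/D/p and a BH-adjusted column.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(counts, columns=["mirna_id", "count_treated", "count_control"])
    n1, n2 = (total_control, total_treated) if swap_totals else (total_treated, total_control)
    rows = []
    for rec in counts.itertuples(index=False):
        x, y = int(rec.count_treated), int(rec.count_control)
        rpm_t = normalize(x, total_treated)
        rpm_c = normalize(y, total_control)
        c, d, p = ac_pvalue(x, y, n1, n2, two_sided=two_sided)
        rows.append(
            {
                "mirna_id": rec.mirna_id,
                "x": x,
                "y": y,
                "N1": n1,
                "N2": n2,
                "rpm_treated": rpm_t,
                "rpm_control": rpm_c,
                "log2fc": log2_fold_change(rpm_t, rpm_c),
                "C": c,
                "D": d,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_bh"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def call_de(
    table: pd.DataFrame,
    p_de: float = 0.05,
    p_sig: float = 0.01,
    lfc_min: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag differentially expressed miRNAs and tally the calls.

    DE: p <= ``p_de`` and |log2fc| >= ``lfc_min``; significant DE uses
    ``p_sig``.  Up/down by the sign of the fold change.
    """
    df = table.copy()
    lfc_ok = df["log2fc"].abs() >= lfc_min
    df["de"] = (df["p_value"] <= p_de) & lfc_ok
    df["sig"] = (df["p_value"] <= p_sig) & lfc_ok
    df["direction"] = np.where(df["log2fc"] >= lfc_min, "up", np.where(df["log2fc"] <= -lfc_min, "down", "ns"))
    tallies = {
        "n_de": int(df["de"].sum()),
        "n_up": int((df["de"] & (df["direction"] == "up")).sum()),
        "n_down": int((df["de"] & (df["direction"] == "down")).sum()),
        "n_sig": int(df["sig"].sum()),
        "n_sig_up": int((df["sig"] & (df["direction"] == "up")).sum()),
        "n_sig_down": int((df["sig"] & (df["direction"] == "down")).sum()),
    }
    return df, tallies
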