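"""Two-group differential tsRNA expression.

Species passing a low-expression filter are tested with a two-sided
Welch t-test on log2(CPM+1); p-values are Benjamini-Hochberg adjusted
across the tested species and calls are made at q <= fdr with
|log2FC| >= lfc.  A simple transparent test is preferred over a count
model here: group sizes are small (5 vs 5 in the emulated design) and
the dispersion structure of exosomal tsRNA libraries is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import CountMatrix


@dataclass
class DEParams:
    min_cpm: float = 5.0
    min_samples: int | None = None  # default: size of the smaller group
    fdr: float = 0.05
    lfc: float = 1.0
    case_label: str = "case"
    control_label: str = "control"


def filter_low_expression(
    cpm: pd.DataFrame, min_cpm: float = 5.0, min_samples: int | None = None
) -> pd.DataFrame:
    """Keep species with CPM >= min_cpm in >= min_samples samples (>= bounds)."""
    if min_samples is None:
        min_samples = cpm.shape[1]
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return cpm.loc[keep]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped to 1, monotone in p."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_test(matrix: CountMatrix, params: DEParams | None = None) -> pd.DataFrame:
    """Per-species Welch t-test on log2(CPM+1) with BH adjustment.

    Returns a frame indexed by species key with columns mean_cpm_case,
    mean_cpm_control, log2_fold_change, p_value, q_value, call — sorted
    by q then p.  Degenerate species (zero variance in both groups) get
    p = 1 when the means agree and p = 0 (flagged) otherwise.
    """
    params = params or DEParams()
    groups = matrix.groups
    case = [s for s in matrix.samples if groups.get(s) == params.case_label]
    ctrl = [s for s in matrix.samples if groups.get(s) == params.control_label]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"differential expression needs >= 2 samples per group "
            f"(got {len(case)} {params.case_label}, {len(ctrl)} {params.control_label})"
        )
    cpm = matrix.cpm().counts
    min_samples = params.min_samples
    if min_samples is None:
        min_samples = min(len(case), len(ctrl))
    cpm = filter_low_expression(cpm, params.min_cpm, min_samples)
    if cpm.empty:
        return pd.DataFrame(
            columns=[
                "mean_cpm_case", "mean_cpm_control", "log2_fold_change",
                "p_value", "q_value", "call", "degenerate",
            ]
        )

    log_case = np.log2(cpm[case].values + 1.0)
    log_ctrl = np.log2(cpm[ctrl].values + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(
            log_case, log_ctrl, axis=1, equal_var=False
        )
    lfc = log_case.mean(axis=1) - log_ctrl.mean(axis=1)

    var0 = (log_case.var(axis=1) == 0) & (log_ctrl.var(axis=1) == 0)
    equal_means = np.isclose(lfc, 0.0)
    pvals = np.where(var0 & equal_means, 1.0, pvals)
    degenerate = var0 & ~equal_means
    pvals = np.where(degenerate, 0.0, pvals)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    qvals = bh_adjust(pvals)
    res = pd.DataFrame(
        {
            "mean_cpm_case": cpm[case].mean(axis=1),
            "mean_cpm_control": cpm[ctrl].mean(axis=1),
            "log2_fold_change": lfc,
            "p_value": pvals,
            "q_value": qvals,
            "degenerate": degenerate,
        },
        index=cpm.index,
    )
    res["call"] = "ns"
    res.loc[(res.q_value <= params.fdr) & (res.log2_fold_change >= params.lfc), "call"] = "up"
    res.loc[(res.q_value <= params.fdr) & (res.log2_fold_change <= -params.lfc), "call"] = "down"
    return res.sort_values(["q_value", "p_value"], kind="mergesort")


def call_de(results: pd.DataFrame, fdr: float = 0.05, lfc: float = 1.0
            ) -> tuple[list[str], list[str]]:
    """(up, down) species lists at the given thresholds."""
    sig = results[results.q_value <= fdr]
    up = list(sig.index[sig.log2_fold_change >= lfc])
    down = list(sig.index[sig.log2_fold_change <= -lfc])
    return up, down
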