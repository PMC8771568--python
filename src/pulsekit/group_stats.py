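"""Group-level statistics: MFI normalization, 2^-ddCT expression, and
t-test + Benjamini-Hochberg + fold-change discriminant-feature selection.

``mfi_normalize`` expresses a treated mean fluorescence intensity relative
to its own control (control maps to 1). ``ddct_fold_change`` implements the
comparative qPCR method: dCT = CT_target - CT_reference per condition,
ddCT = dCT_treated - dCT_control, fold change = 2^(-ddCT).

``discriminant_features`` reproduces a volcano-style selection on a
features x samples intensity matrix with two groups: per-feature two-sample
t-test on log2 intensities (equal-variance by default, Welch optional),
Benjamini-Hochberg adjustment across all features, and selection iff the
(adjusted, by default) p-value is below the p threshold AND the group ratio
of raw means falls outside the [fc_low, fc_high] band (defaults 0.8/1.25).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def mfi_normalize(treated_mfi: float, control_mfi: float) -> float:
    """Treated MFI over its respective control MFI (control maps to 1)."""
    if control_mfi <= 0:
        raise ValueError("control MFI must be > 0")
    return float(treated_mfi) / float(control_mfi)


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative expression by the comparative 2^-ddCT method."""
    cts = (ct_target_treated, ct_reference_treated,
           ct_target_control, ct_reference_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("CT values must be finite")
    dct_treated = ct_target_treated - ct_reference_treated
    dct_control = ct_target_control - ct_reference_control
    ddct = dct_treated - dct_control
    return float(2.0 ** (-ddct))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(columns, groups: pd.Series):
    labels = pd.Series(groups)
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    cols_a = [c for c in columns if labels[c] == levels[0]]
    cols_b = [c for c in columns if labels[c] == levels[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples per group")
    return levels, cols_a, cols_b


def discriminant_features(
    matrix: pd.DataFrame,
    groups: pd.Series,
    p_threshold: float = 0.05,
    fc_low: float = 0.8,
    fc_high: float = 1.25,
    equal_var: bool = True,
    use_adjusted_p: bool = True,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Volcano-style discriminant selection on a features x samples matrix.

    ``groups`` maps sample (column) name to one of two labels; fold change
    is mean(second level) / mean(first level) on raw intensities. Returns a
    per-feature table with fold_change, p_value, p_adjusted, log2_fc,
    neg_log10_p and the selected flag.
    """
    levels, cols_a, cols_b = _group_columns(matrix.columns, groups)
    a = matrix[cols_a].to_numpy(dtype=float)
    b = matrix[cols_b].to_numpy(dtype=float)
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("intensities must be > 0 for log transformation")
        ta, tb = np.log2(a), np.log2(b)
    else:
        ta, tb = a, b

    res = stats.ttest_ind(ta, tb, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    # identical constant groups: no effect, not an error
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(ta.mean(axis=1), tb.mean(axis=1))
        zerovar = (ta.var(axis=1) == 0) & (tb.var(axis=1) == 0)
        fix = degenerate & same & zerovar
        if fix.any():
            logger.info("%d feature(s) with zero variance and zero mean "
                        "difference: p set to 1", int(fix.sum()))
            p[fix] = 1.0

    fc = b.mean(axis=1) / a.mean(axis=1)
    p_adj = bh_adjust(p)
    p_gate = p_adj if use_adjusted_p else p
    selected = (p_gate < p_threshold) & ((fc <= fc_low) | (fc >= fc_high))

    with np.errstate(divide="ignore"):
        table = pd.DataFrame({
            "feature": matrix.index,
            "fold_change": fc,
            "p_value": p,
            "p_adjusted": p_adj,
            "log2_fc": np.log2(fc),
            "neg_log10_p": -np.log10(p_gate),
            "selected": selected,
        }).set_index("feature")
    table.attrs["group_order"] = tuple(levels)
    table.attrs["p_gate"] = "adjusted" if use_adjusted_p else "raw"
    return table
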