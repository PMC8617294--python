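"""Differential connectivity (DC) analysis.

Per protein, capture intensities between two cellular states are compared
with a two-sided Student t-test on the log10-processed values (DC.p), and a
fold change is computed as the ratio of linear-scale group means. A protein
is DC when DC.p <= dc_alpha (default 0.1). The sign of log10(FC) defines the
"direction" used downstream to stratify enrichment tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ConfigError, InputError, IntensityMatrix, SampleDesign

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keep -log10(p) finite

DC_COLUMNS = [
    "mean_a",
    "mean_b",
    "fold_change",
    "log10_fc",
    "p_value",
    "neg_log10_p",
    "direction",
    "is_dc",
]

__all__ = ["dc_table", "dc_filter", "DC_COLUMNS", "P_FLOOR"]


def dc_table(
    m: IntensityMatrix,
    design: SampleDesign,
    cond_a: str,
    cond_b: str,
    dc_alpha: float = 0.1,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-protein DC statistics for cond_b versus cond_a.

    Parameters
    ----------
    m
        Preprocessed (log10-scale) intensity matrix.
    cond_a, cond_b
        Condition labels; the fold change is mean_b / mean_a on the linear
        scale (means of 10**x over each condition's replicates).
    welch
        Use Welch's unequal-variance t-test instead of the classic
        pooled-variance Student test.

    Returns
    -------
    DataFrame indexed by protein ID with columns ``mean_a``, ``mean_b``,
    ``fold_change``, ``log10_fc``, ``p_value``, ``neg_log10_p``,
    ``direction`` (one of "+", "-", "0") and ``is_dc``.
    """
    if m.scale != "log10":
        raise InputError(f"DC analysis expects log10-scale input, got {m.scale!r}")
    if not (0 < dc_alpha <= 1):
        raise ConfigError(f"dc_alpha must be in (0, 1], got {dc_alpha}")
    a_cols = design.samples_of(cond_a)
    b_cols = design.samples_of(cond_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise InputError("both conditions need >= 2 replicates for DC testing")
    xa = m.values[a_cols].to_numpy(dtype=float)
    xb = m.values[b_cols].to_numpy(dtype=float)
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise InputError("DC input contains missing values; run preprocess first")

    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # near-constant rows trigger scipy's precision-loss warning; the
        # degenerate-row handling below covers them explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xb, xa, axis=1, equal_var=not welch)
        p = np.asarray(res.pvalue, dtype=float)

    # degenerate rows: zero variance in both groups
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    mean_la = xa.mean(axis=1)
    mean_lb = xb.mean(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal = degenerate & (mean_la == mean_lb)
        unequal = degenerate & ~equal
        p[equal] = 1.0
        p[unequal] = 0.0
        if unequal.any():
            log.warning(
                "%d proteins with zero within-group variance and unequal "
                "means: p floored at 0",
                int(unequal.sum()),
            )
        if equal.any():
            log.debug(
                "%d proteins constant across all replicates: p = 1",
                int(equal.sum()),
            )
    p = np.clip(p, 0.0, 1.0)

    mean_a = np.power(10.0, xa).mean(axis=1)
    mean_b = np.power(10.0, xb).mean(axis=1)
    fc = mean_b / mean_a
    log_fc = np.log10(fc)
    direction = np.where(log_fc > 0, "+", np.where(log_fc < 0, "-", "0"))
    tbl = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log10_fc": log_fc,
            "p_value": p,
            "neg_log10_p": -np.log10(np.maximum(p, P_FLOOR)),
            "direction": direction,
            "is_dc": p <= dc_alpha,
        },
        index=m.values.index,
    )
    tbl.index.name = "protein_id"
    return tbl


def dc_filter(table: pd.DataFrame, dc_alpha: float = 0.1) -> set[str]:
    """Return the DC protein set: p_value <= dc_alpha (inclusive threshold).

    The non-DC proteins — those with DC.p strictly greater than the
    threshold — are the ones dropped, so p exactly at the threshold is kept.
    """
    if not (0 < dc_alpha <= 1):
        raise ConfigError(f"dc_alpha must be in (0, 1], got {dc_alpha}")
    return set(table.index[table["p_value"] <= dc_alpha])
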