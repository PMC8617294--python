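"""LFQ preprocessing: within-condition quantile normalization, group-minimum
missing-value imputation, log10 transform.

The processing chain mirrors standard AP-MS label-free workflows: replicate
columns of the same condition are quantile-normalized against each other
(conditions are never pooled, so between-condition differences survive),
missing cells are filled from the minimal raw intensity observed for that
protein within the condition, and everything is log10-transformed for
downstream t-testing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import InputError, IntensityMatrix, SampleDesign

log = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize_within_groups",
    "impute_missing_group_min",
    "preprocess",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A processing step produced or encountered an invalid value."""


def _normalize_group(block: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of one condition, missing-aware.

    Each column's observed values are replaced by the group reference
    distribution (the mean of the per-column empirical quantile functions on
    a common grid) evaluated at the column's own empirical quantiles. Ties
    receive the average of the tied reference quantiles via average ranks.
    Missing cells stay missing. Columns with unequal observed counts are
    handled by linear interpolation of the quantile functions.
    """
    out = block.copy()
    n_cols = block.shape[1]
    obs_sorted = []
    for j in range(n_cols):
        col = block[:, j]
        obs_sorted.append(np.sort(col[~np.isnan(col)]))
    counts = [len(s) for s in obs_sorted]
    grid_size = max(counts)
    if grid_size == 0:
        return out  # all-missing group: nothing to normalize
    grid = np.linspace(0.0, 1.0, grid_size) if grid_size > 1 else np.array([0.5])
    ref = np.zeros(grid_size)
    n_used = 0
    for s in obs_sorted:
        if len(s) == 0:
            continue
        if len(s) == 1:
            ref += np.full(grid_size, s[0])
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, len(s)), s)
        n_used += 1
    ref /= n_used
    for j in range(n_cols):
        col = block[:, j]
        mask = ~np.isnan(col)
        n_obs = int(mask.sum())
        if n_obs == 0:
            continue
        if n_obs == 1:
            # a single observation maps to the reference midpoint
            out[mask, j] = np.interp(0.5, grid, ref) if grid_size > 1 else ref[0]
            continue
        ranks = rankdata(col[mask], method="average")
        q = (ranks - 1.0) / (n_obs - 1.0)
        out[mask, j] = np.interp(q, grid, ref)
    return out


def quantile_normalize_within_groups(
    m: IntensityMatrix, design: SampleDesign
) -> IntensityMatrix:
    """Quantile-normalize replicate columns within each condition.

    Columns belonging to different conditions are never pooled. A condition
    with a single replicate column is returned unchanged (with a warning),
    since a one-column quantile normalization is the identity.
    """
    if m.scale not in ("raw", "normalized"):
        raise InputError(f"expected a linear-scale matrix, got {m.scale!r}")
    design.check_matches(m)
    vals = m.values.to_numpy(dtype=float).copy()
    col_pos = {s: i for i, s in enumerate(m.sample_ids)}
    for condition, samples in design.groups().items():
        samples = [s for s in samples if s in col_pos]
        if not samples:
            continue
        if len(samples) == 1:
            log.warning(
                "condition %r has a single replicate; column left unchanged",
                condition,
            )
            continue
        idx = [col_pos[s] for s in samples]
        vals[:, idx] = _normalize_group(vals[:, idx])
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return m.with_values(out, "normalized")


def impute_missing_group_min(
    m: IntensityMatrix,
    raw: IntensityMatrix,
    design: SampleDesign,
    remap: bool = False,
) -> IntensityMatrix:
    """Fill missing cells from the minimal raw intensity within the condition.

    For a missing cell (protein p, sample s of condition g) the fill value is
    the minimum raw intensity observed for p across g's replicates. If p was
    never observed in g, the fallback is the minimum raw intensity observed
    anywhere in g (over all proteins), and the event is logged.

    With ``remap=True`` the raw fill value is additionally passed through the
    destination column's raw->normalized monotone map (linear interpolation
    between the column's observed raw values and their normalized images).
    The default writes the raw minimum directly, so an imputed cell never
    exceeds the observed raw minimum of its (protein, condition) cell set.
    """
    if m.values.shape != raw.values.shape or list(m.values.index) != list(
        raw.values.index
    ) or list(m.values.columns) != list(raw.values.columns):
        raise InputError("shape/label mismatch between matrix and raw matrix")
    design.check_matches(m)
    vals = m.values.to_numpy(dtype=float).copy()
    raw_vals = raw.values.to_numpy(dtype=float)
    col_pos = {s: i for i, s in enumerate(m.sample_ids)}
    n_fallback = 0
    for condition, samples in design.groups().items():
        idx = [col_pos[s] for s in samples if s in col_pos]
        if not idx:
            continue
        raw_block = raw_vals[:, idx]
        block = vals[:, idx]
        missing = np.isnan(block)
        if not missing.any():
            continue
        finite = np.where(np.isnan(raw_block), np.inf, raw_block)
        row_min = finite.min(axis=1)
        row_min = np.where(np.isinf(row_min), np.nan, row_min)  # all-missing rows
        observed = raw_block[~np.isnan(raw_block)]
        group_min = observed.min() if observed.size else np.nan
        all_missing = np.isnan(row_min)
        if all_missing.any():
            n_fallback += int(all_missing.sum())
            row_min = np.where(all_missing, group_min, row_min)
        maps = None
        if remap:
            maps = []
            for k, j in enumerate(idx):
                r = raw_block[:, k]
                n = block[:, k]
                ok = ~np.isnan(r) & ~np.isnan(n)
                order = np.argsort(r[ok], kind="stable")
                maps.append((r[ok][order], n[ok][order]))
        rows, cols = np.nonzero(missing)
        for p, k in zip(rows, cols):
            fill = row_min[p]
            if np.isnan(fill):
                raise PipelineError(
                    f"no observed raw intensity to impute protein "
                    f"{m.protein_ids[p]!r} in condition {condition!r}"
                )
            if remap and maps is not None and len(maps[k][0]) > 0:
                fill = float(np.interp(fill, maps[k][0], maps[k][1]))
            block[p, k] = fill
        vals[:, idx] = block
    if n_fallback:
        log.warning(
            "imputation fell back to the condition-global raw minimum for "
            "%d all-missing (protein, condition) groups",
            n_fallback,
        )
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(out, scale=m.scale)


def preprocess(
    m: IntensityMatrix, design: SampleDesign, remap_imputed: bool = False
) -> IntensityMatrix:
    """Full chain: quantile-normalize within conditions, impute, log10.

    Zeros must have been declared missing at read time (the proteinGroups
    convention); a non-positive value reaching the log10 step is an error.
    """
    normalized = quantile_normalize_within_groups(m, design)
    filled = impute_missing_group_min(normalized, m, design, remap=remap_imputed)
    vals = filled.values.to_numpy(dtype=float)
    bad = ~(vals > 0) | ~np.isfinite(vals)
    if bad.any():
        p, s = np.argwhere(bad)[0]
        raise PipelineError(
            f"non-positive or non-finite value at protein "
            f"{filled.protein_ids[p]!r}, sample {filled.sample_ids[s]!r} "
            "reached the log10 step (zeros must be declared missing at read time)"
        )
    out = pd.DataFrame(
        np.log10(vals), index=filled.values.index, columns=filled.values.columns
    )
    return filled.with_values(out, "log10")
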