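"""Two-directional Z-transformation (2DIZ) and variance decomposition.

Raw docking scores carry large pocket-intrinsic ("endogenous") components --
free-energy offsets that differ between binding pockets regardless of the
ligand -- plus drug-intrinsic components.  The 2DIZ removes both by
z-scoring each drug column across pockets and then each pocket row across
drugs, leaving a Z'-score in which variation reflects drug effects and
specific drug-pocket interactions.  ``variance_decomposition`` quantifies
that claim with a two-way additive split of the total variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cpi_data import ScoreMatrix, ZMatrix

__all__ = ["VarianceComponents", "twodiz", "variance_decomposition"]


@dataclass(frozen=True)
class VarianceComponents:
    """Shares of total variance from drug (column) main effects, pocket
    (row) main effects, and the residual (interaction + noise)."""

    drug: float
    pocket: float
    residual: float


def _zscore_axis(values: np.ndarray, axis: int, ddof: int) -> np.ndarray:
    """Z-score along ``axis`` using non-NaN moments.

    Slices with < 2 observations become all-NaN (insufficient data);
    zero-variance slices become all-zero so constant pockets can never rank
    as binding hits.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n = np.sum(~np.isnan(values), axis=axis, keepdims=True)
        mean = np.nanmean(values, axis=axis, keepdims=True)
        sd = np.nanstd(values, axis=axis, ddof=ddof, keepdims=True)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    out = np.where(np.isnan(values), np.nan, out)
    out = np.where(n < 2, np.nan, out)
    return out


def twodiz(m: ScoreMatrix, ddof: int = 1) -> ZMatrix:
    """Column-then-row z-score normalization of a raw score matrix.

    Step 1 z-scores every drug column over its non-missing pockets; step 2
    z-scores every pocket row of the step-1 result over its non-missing
    drugs.  Missing entries stay missing.  Columns or rows with fewer than
    two non-missing entries produce missing output (with a warning);
    zero-variance slices produce zeros by convention.
    """
    if ddof not in (0, 1):
        raise ValueError(f"ddof must be 0 or 1, got {ddof}")
    if m.n_pockets < 2 or m.n_drugs < 2:
        raise ValueError(
            f"matrix must be at least 2x2, got {m.n_pockets}x{m.n_drugs}"
        )
    vals = m.values.copy()
    thin_cols = np.sum(~np.isnan(vals), axis=0) < 2
    if thin_cols.any():
        warnings.warn(
            f"{int(thin_cols.sum())} drug column(s) with <2 scores produce "
            "missing output",
            stacklevel=2,
        )
    step1 = _zscore_axis(vals, axis=0, ddof=ddof)
    thin_rows = np.sum(~np.isnan(step1), axis=1) < 2
    if thin_rows.any():
        warnings.warn(
            f"{int(thin_rows.sum())} pocket row(s) with <2 scores produce "
            "missing output",
            stacklevel=2,
        )
    step2 = _zscore_axis(step1, axis=1, ddof=ddof)
    return ZMatrix(
        drug_ids=m.drug_ids,
        pocket_ids=m.pocket_ids,
        values=step2,
        missing=np.isnan(step2),
    )


def variance_decomposition(values: np.ndarray) -> VarianceComponents:
    """Two-way additive variance split of a (possibly incomplete) matrix.

    Row and column main effects are deviations of the non-missing row and
    column means from the grand mean; the residual share is the remainder,
    so the three shares always sum to one.  On complete additive data
    (value = r_i + c_j) the residual share is zero.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(f"need a matrix of at least 2x2, got shape {values.shape}")
    ok = ~np.isnan(values)
    if ok.sum() < 4:
        raise ValueError("too few non-missing entries for a decomposition")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        grand = np.nanmean(values)
        row_means = np.nanmean(values, axis=1)
        col_means = np.nanmean(values, axis=0)
    total_ss = np.nansum((values - grand) ** 2)
    if total_ss == 0:
        return VarianceComponents(drug=0.0, pocket=0.0, residual=0.0)
    row_eff = np.where(np.isnan(row_means), 0.0, row_means - grand)
    col_eff = np.where(np.isnan(col_means), 0.0, col_means - grand)
    pocket_ss = float(np.sum(ok * row_eff[:, None] ** 2))
    drug_ss = float(np.sum(ok * col_eff[None, :] ** 2))
    pocket = pocket_ss / total_ss
    drug = drug_ss / total_ss
    return VarianceComponents(
        drug=drug, pocket=pocket, residual=1.0 - drug - pocket
    )
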