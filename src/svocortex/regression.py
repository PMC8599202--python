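"""Per-parcel ordinary least squares fits.

Each cortical parcel's thickness is regressed on the design matrix; the
coefficient(s) of interest are reported on two scales: ``beta_raw`` in mm
per unit of the predictor, and ``beta_std`` — the standardized coefficient
``beta_raw * sd(x) / sd(y)``, dimensionless and invariant to affine
rescaling of either variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .atlas import ParcelAtlas, ThicknessMatrix, _HEMI_PREFIX

__all__ = ["RegressionResult", "fit_parcel", "fit_lobe", "results_table"]

_PREFIX_HEMI = {v: k for k, v in _HEMI_PREFIX.items()}


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary for one parcel, keyed by variable of interest."""

    parcel_column: str  # e.g. "lh_olfactory_sulcus"
    hemisphere: str
    parcel_id: int | None
    parcel_name: str | None
    lobe: str | None
    beta_raw: dict = field(default_factory=dict)  # mm per predictor unit
    beta_std: dict = field(default_factory=dict)  # dimensionless
    t_stat: dict = field(default_factory=dict)
    p_uncorrected: dict = field(default_factory=dict)  # two-sided parametric
    residual_df: int = 0
    params: pd.Series = None  # all coefficients, for diagnostics
    resid: np.ndarray = field(default=None, repr=False)


def _parcel_meta(column: str, atlas: ParcelAtlas | None):
    prefix, _, snake = column.partition("_")
    hemisphere = _PREFIX_HEMI.get(prefix, prefix)
    if atlas is None:
        return hemisphere, None, None, None
    row = atlas.table[atlas.table["snake"] == snake]
    if row.empty:
        return hemisphere, None, snake, None
    return hemisphere, int(row["id"].iloc[0]), row["name"].iloc[0], row["lobe"].iloc[0]


def fit_parcel(
    y,
    design: pd.DataFrame,
    interest,
    parcel_column: str = "",
    atlas: ParcelAtlas | None = None,
) -> RegressionResult:
    """Ordinary least squares of one parcel's thickness on the design.

    ``interest`` names the design column(s) whose coefficients are reported;
    nuisance coefficients remain available through ``params``.
    """
    if isinstance(interest, str):
        interest = [interest]
    for col in interest:
        if col not in design.columns:
            raise KeyError(f"interest column {col!r} not in design {list(design.columns)}")
    yarr = np.asarray(y, dtype=float)
    n, k = design.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} subjects for a {k}-column design, got {n}")
    res = sm.OLS(yarr, design.to_numpy(dtype=float)).fit()
    params = pd.Series(res.params, index=design.columns)
    tvals = pd.Series(res.tvalues, index=design.columns)
    pvals = pd.Series(res.pvalues, index=design.columns)
    sd_y = float(np.std(yarr, ddof=1))
    hemisphere, pid, name, lobe = _parcel_meta(parcel_column, atlas)
    out = RegressionResult(
        parcel_column=parcel_column,
        hemisphere=hemisphere,
        parcel_id=pid,
        parcel_name=name,
        lobe=lobe,
        residual_df=int(res.df_resid),
        params=params,
        resid=np.asarray(res.resid),
    )
    for col in interest:
        sd_x = float(design[col].std(ddof=1))
        out.beta_raw[col] = float(params[col])
        out.beta_std[col] = float(params[col]) * sd_x / sd_y if sd_y > 0 else np.nan
        out.t_stat[col] = float(tvals[col])
        out.p_uncorrected[col] = float(pvals[col])
    return out


def fit_lobe(
    matrix: ThicknessMatrix,
    design: pd.DataFrame,
    interest,
    atlas: ParcelAtlas | None = None,
) -> list[RegressionResult]:
    """Fit every parcel column of a (lobe-restricted) thickness matrix.

    Columns are fitted in their stored order, which `select_lobe` guarantees
    to be ascending atlas id. Subjects are aligned to the design index.
    """
    vals = matrix.values.loc[design.index]
    return [
        fit_parcel(vals[col], design, interest, parcel_column=col, atlas=atlas)
        for col in vals.columns
    ]


def results_table(results: list[RegressionResult]) -> pd.DataFrame:
    """Flatten results to one row per parcel x variable of interest."""
    rows = []
    for r in results:
        for var in r.beta_raw:
            rows.append(
                {
                    "hemisphere": r.hemisphere,
                    "lobe": r.lobe,
                    "parcel_id": r.parcel_id,
                    "parcel_name": r.parcel_name,
                    "parcel_column": r.parcel_column,
                    "variable": var,
                    "beta_raw": r.beta_raw[var],
                    "beta_std": r.beta_std[var],
                    "t": r.t_stat[var],
                    "p_uncorrected": r.p_uncorrected[var],
                    "residual_df": r.residual_df,
                }
            )
    return pd.DataFrame(rows)
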