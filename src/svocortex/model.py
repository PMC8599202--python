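"""Model/results interface tying scoring, regression and permutation together.

`ParcelThicknessModel` is built from a thickness matrix, scored SVO
profiles and demographics; `fit()` returns a `ParcelThicknessResults`
holding the per-parcel OLS estimates, and `permutation_test()` on the
results adds per-lobe max-t corrected inference.

Example
-------
>>> from svocortex import simulate, model
>>> data = simulate.simulate_dataset(seed=7)
>>> m = model.ParcelThicknessModel.from_choices(
...     data["choices"], data["thickness"], data["demographics"])
>>> res = m.fit()
>>> perm = res.permutation_test(B=1000, seed=7)
>>> perm.flagged(alpha=0.05)  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import HEMISPHERES, ParcelAtlas, ThicknessMatrix, load_atlas
from .design import INTEREST_COLUMNS, build_design
from .permutation import PermutationResult, as_seed_sequence, run_all_lobes
from .regression import RegressionResult, fit_lobe, results_table
from .ring import CONSISTENCY_THRESHOLD, filter_consistent, score_table

__all__ = ["ParcelThicknessModel", "ParcelThicknessResults", "PermutationInference"]


class ParcelThicknessModel:
    """Mass-univariate model of parcel thickness on social preferences.

    Per parcel: ``thickness ~ C + interest + age + gender + avg_thickness``
    where ``interest`` is the SVO angle (``model="angle"``) or the pair
    W_self, W_other (``model="weights"``). One design matrix is kept per
    hemisphere, carrying that hemisphere's average-thickness covariate.
    """

    def __init__(
        self,
        thickness: ThicknessMatrix,
        profiles: pd.DataFrame,
        demographics: pd.DataFrame,
        atlas: ParcelAtlas | None = None,
        model: str = "angle",
        include_age: bool = True,
    ):
        self.atlas = atlas or load_atlas()
        self.model = model
        self.include_age = include_age
        self.interest = INTEREST_COLUMNS[model]
        self.profiles = profiles.reset_index(drop=True)
        self.demographics = demographics
        self.designs = {
            h: build_design(
                self.profiles,
                demographics,
                thickness.hemi_average[h],
                model=model,
                include_age=include_age,
            )
            for h in HEMISPHERES
        }
        self.subjects = self.designs["left"].index
        self.thickness = thickness.reindex(self.subjects)

    @classmethod
    def from_choices(
        cls,
        choices: pd.DataFrame,
        thickness: ThicknessMatrix,
        demographics: pd.DataFrame,
        atlas: ParcelAtlas | None = None,
        model: str = "angle",
        include_age: bool = True,
        consistency_threshold: float = CONSISTENCY_THRESHOLD,
        include_all: bool = False,
        ring=None,
    ) -> "ParcelThicknessModel":
        """Score a raw choice table, apply the consistency filter, build the model.

        ``include_all=True`` skips the exclusion of inconsistent responders
        (subjects with an undefined angle are still dropped, as the angle
        model cannot use them). The exclusion report is kept on the instance
        as ``exclusions``.
        """
        profiles = score_table(choices, ring=ring, threshold=consistency_threshold)
        if include_all:
            kept = profiles[~profiles["degenerate"]].copy()
            report = profiles[profiles["degenerate"]].copy()
        else:
            kept, report = filter_consistent(profiles, consistency_threshold)
        obj = cls(
            thickness,
            kept,
            demographics,
            atlas=atlas,
            model=model,
            include_age=include_age,
        )
        obj.exclusions = report
        obj.all_profiles = profiles
        return obj

    @property
    def nobs(self) -> int:
        return len(self.subjects)

    def fit(self) -> "ParcelThicknessResults":
        """Ordinary least squares for every parcel of both hemispheres."""
        results: list[RegressionResult] = []
        for h in HEMISPHERES:
            sub = self.thickness.subset(self.atlas.columns(h))
            results.extend(fit_lobe(sub, self.designs[h], self.interest, atlas=self.atlas))
        return ParcelThicknessResults(model=self, results=results)


@dataclass
class ParcelThicknessResults:
    """Per-parcel OLS estimates; entry point for permutation inference."""

    model: ParcelThicknessModel
    results: list[RegressionResult]

    @property
    def table(self) -> pd.DataFrame:
        """One row per parcel x variable: beta_raw, beta_std, t, parametric p."""
        return results_table(self.results)

    def permutation_test(
        self, B: int = 5000, seed=None, sidedness: str = "upper"
    ) -> "PermutationInference":
        """Freedman-Lane max-t corrected p-values, per lobe and hemisphere.

        With several variables of interest (weights model) the procedure is
        run once per variable, the other acting as a nuisance covariate.
        """
        blocks: list[PermutationResult] = []
        seeds = as_seed_sequence(seed).spawn(len(self.model.interest))
        for var, ss in zip(self.model.interest, seeds):
            blocks.extend(
                run_all_lobes(
                    self.model.thickness,
                    self.model.atlas,
                    self.model.designs,
                    var,
                    B=B,
                    seed=ss,
                    sidedness=sidedness,
                )
            )
        return PermutationInference(results=self, blocks=blocks, B=B, seed=seed, sidedness=sidedness)

    def adjusted_scatter(self, parcel_column: str, variable: str | None = None) -> pd.DataFrame:
        """Predictor vs thickness residualized on the nuisance covariates.

        One row per included subject; the exported pairs are what a partial
        regression plot for ``variable`` at this parcel would display.
        """
        variable = variable or self.model.interest[0]
        hemi = "left" if parcel_column.startswith("lh_") else "right"
        X = self.model.designs[hemi]
        nuisance = X.drop(columns=[variable])
        y = self.model.thickness.values.loc[X.index, parcel_column].to_numpy(dtype=float)
        Zn = nuisance.to_numpy(dtype=float)
        y_res = y - Zn @ np.linalg.lstsq(Zn, y, rcond=None)[0]
        return pd.DataFrame(
            {
                "participant_id": X.index,
                variable: X[variable].to_numpy(),
                "thickness_residual": y_res,
            }
        )

    def plot_adjusted(self, parcel_column: str, variable: str | None = None, ax=None):
        """Partial-regression scatter for one parcel (requires matplotlib)."""
        import matplotlib.pyplot as plt

        variable = variable or self.model.interest[0]
        data = self.adjusted_scatter(parcel_column, variable)
        if ax is None:
            _, ax = plt.subplots()
        x = data[variable]
        y = data["thickness_residual"]
        ax.scatter(x, y, s=12, alpha=0.7)
        slope, intercept = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, intercept + slope * xs, color="k")
        ax.set_xlabel(variable)
        ax.set_ylabel(f"{parcel_column} thickness (adjusted, mm)")
        return ax

    def summary(self) -> str:
        tab = self.table
        lines = [
            "Parcel-wise thickness regression (OLS)",
            f"  model: {self.model.model}   n = {self.model.nobs}   "
            f"parcels = {len(self.results)}",
            f"  covariates: {list(self.model.designs['left'].columns)}",
            "",
            "Strongest associations per variable (by |t|):",
        ]
        for var, grp in tab.groupby("variable"):
            top = grp.reindex(grp["t"].abs().sort_values(ascending=False).index).head(5)
            lines.append(f"  [{var}]")
            lines.append(
                top[
                    ["hemisphere", "lobe", "parcel_id", "parcel_name", "beta_raw", "beta_std", "t", "p_uncorrected"]
                ].to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)


@dataclass
class PermutationInference:
    """Corrected inference across all lobe x hemisphere families."""

    results: ParcelThicknessResults
    blocks: list[PermutationResult]
    B: int
    seed: object
    sidedness: str

    @property
    def table(self) -> pd.DataFrame:
        """Regression table extended with permutation p-values per parcel."""
        reg = self.results.table
        perm = pd.concat([b.to_frame() for b in self.blocks], ignore_index=True)
        perm = perm.drop(columns=["lobe", "hemisphere", "t"])
        return reg.merge(perm, on=["parcel_column", "variable"], how="left")

    def flagged(self, alpha: float = 0.05) -> pd.DataFrame:
        tab = self.table
        return tab[tab["p_corrected"] <= alpha].reset_index(drop=True)

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            "Freedman-Lane max-t permutation inference",
            f"  B = {self.B}   sidedness = {self.sidedness}   seed = {self.seed}",
            "",
            "Per-lobe summary (max observed t, min corrected p):",
        ]
        for b in self.blocks:
            lines.append(
                f"  {b.interest:10s} {b.hemisphere:5s} {b.lobe:9s} "
                f"max t = {np.nanmax(b.observed_t):7.3f}   "
                f"min p_corrected = {np.nanmin(b.p_corrected):.4f}"
            )
        flg = self.flagged(alpha)
        if flg.empty:
            lines.append(f"\nNo parcel significant at alpha = {alpha}.")
        else:
            lines.append(f"\nParcels significant at alpha = {alpha}:")
            lines.append(
                flg[
                    ["variable", "hemisphere", "lobe", "parcel_id", "parcel_name", "beta_raw", "t", "p_corrected"]
                ].to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)
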