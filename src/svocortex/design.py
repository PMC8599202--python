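"""Design matrices for the per-parcel thickness regressions.

Two model specifications are supported, sharing the nuisance covariates
(age in years, gender coded female = 1, and the whole-hemisphere average
thickness in mm):

* ``angle``   -- thickness ~ C + b1*SVO_angle + b2*age + b3*gender + b4*avg_thickness
* ``weights`` -- thickness ~ C + b5*W_self + b6*W_other + b2*age + b3*gender
  + b4*avg_thickness (age can be dropped for a reduced variant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DesignError", "build_design", "INTEREST_COLUMNS"]

INTEREST_COLUMNS = {"angle": ["svo_angle"], "weights": ["w_self", "w_other"]}


class DesignError(ValueError):
    """Raised for rank-deficient or inconsistent design inputs."""


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = 0
    kept: list[str] = []
    for j, col in enumerate(X.columns):
        r = np.linalg.matrix_rank(arr[:, : j + 1])
        if r == rank:
            raise DesignError(
                f"design matrix is rank deficient: column {col!r} is "
                f"collinear with {kept}"
            )
        rank = r
        kept.append(col)


def build_design(
    profiles: pd.DataFrame,
    demographics: pd.DataFrame,
    hemi_average: pd.Series,
    model: str = "angle",
    include_age: bool = True,
) -> pd.DataFrame:
    """Assemble the subject x covariate design matrix for one hemisphere.

    Parameters
    ----------
    profiles
        Scored (and already consistency-filtered) SVO profiles; must carry
        ``participant_id`` plus ``angle_deg`` (angle model) or
        ``w_self``/``w_other`` (weights model).
    demographics
        ``participant_id``, ``age``, ``gender`` (female = 1).
    hemi_average
        Whole-hemisphere average thickness per subject, indexed by
        participant id — this is hemisphere-specific, so one design is built
        per hemisphere.
    model
        ``"angle"`` or ``"weights"``.
    include_age
        Only consulted for the weights model; ``False`` drops the age column.

    Returns
    -------
    DataFrame indexed by participant id with a leading ``const`` column,
    the interest column(s), then ``age`` (unless dropped), ``gender`` and
    ``avg_thickness``. Raises :class:`DesignError` on subject mismatch or a
    rank-deficient matrix (naming the offending column).
    """
    if model not in INTEREST_COLUMNS:
        raise DesignError(f"unknown model {model!r}; expected 'angle' or 'weights'")
    prof = profiles.set_index("participant_id")
    demo = demographics.set_index("participant_id")

    subjects = prof.index
    for name, idx in (("demographics", demo.index), ("hemisphere averages", hemi_average.index)):
        missing = subjects.difference(idx)
        if len(missing):
            raise DesignError(f"subjects missing from {name}: {list(missing)[:10]}")

    cols = {"const": pd.Series(1.0, index=subjects)}
    if model == "angle":
        if prof["angle_deg"].isna().any():
            bad = prof.index[prof["angle_deg"].isna()].tolist()
            raise DesignError(f"undefined SVO angle for subjects {bad}")
        cols["svo_angle"] = prof["angle_deg"].astype(float)
    else:
        cols["w_self"] = prof["w_self"].astype(float)
        cols["w_other"] = prof["w_other"].astype(float)
    if model == "angle" or include_age:
        cols["age"] = demo.loc[subjects, "age"].astype(float)
    cols["gender"] = demo.loc[subjects, "gender"].astype(float)
    cols["avg_thickness"] = hemi_average.loc[subjects].astype(float)

    X = pd.DataFrame(cols, index=subjects)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise DesignError(f"missing values in design columns {bad}")
    _check_full_rank(X)
    return X
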