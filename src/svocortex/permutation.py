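"""Freedman-Lane residual permutation with per-lobe max-t FWER correction.

For each lobe (the family of tests), the null distribution of the variable
of interest's t-statistic is built by (i) fitting the reduced model without
the variable of interest to every parcel, (ii) permuting the reduced-model
residuals at the subject level — one shared permutation per iteration across
all parcels of the lobe, preserving their spatial dependence — (iii) adding
them back to the reduced fitted values, (iv) refitting the full model and
recording the maximum t across the lobe's parcels, and (v) comparing each
observed t to the null of B maxima:

    p_corrected(parcel) = (1 + #{b : maxT_b >= t_obs}) / (1 + B)

With ``sidedness="upper"`` the signed t is used throughout (a negative
association can only yield p near 1); ``"two_sided"`` uses |t|.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import LOBES, HEMISPHERES, ParcelAtlas, ThicknessMatrix, select_lobe

__all__ = ["PermutationResult", "freedman_lane", "run_all_lobes", "block_seeds"]

_CHUNK = 500  # permutations processed per vectorized block


@dataclass(frozen=True)
class PermutationResult:
    """Max-t permutation inference for one lobe x hemisphere family."""

    lobe: str | None
    hemisphere: str | None
    interest: str
    parcel_columns: tuple
    observed_t: np.ndarray = field(repr=False)
    maxT_null: np.ndarray = field(repr=False)
    p_corrected: np.ndarray = field(repr=False)
    p_uncorrected_perm: np.ndarray = field(repr=False)  # per-parcel, same draws
    B: int = 0
    seed: object = None
    sidedness: str = "upper"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_column": list(self.parcel_columns),
                "lobe": self.lobe,
                "hemisphere": self.hemisphere,
                "variable": self.interest,
                "t": self.observed_t,
                "p_perm_uncorrected": self.p_uncorrected_perm,
                "p_corrected": self.p_corrected,
                "B": self.B,
                "sidedness": self.sidedness,
            }
        )


def _ols_terms(X: np.ndarray):
    """Pseudo-inverse, (X'X)^-1 diagonal and residual df for fast refits."""
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    return pinv, xtx_inv_diag, n - k


def _safe_t(beta_j: np.ndarray, se: np.ndarray) -> np.ndarray:
    """beta/se, mapping a perfectly fitted model (se = 0) to t = 0 when the
    coefficient itself vanishes (outcome explained by the nuisance alone)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_j / se
    degenerate = se < 1e-12
    if np.any(degenerate):
        t = np.where(
            degenerate,
            np.where(np.abs(beta_j) < 1e-8, 0.0, np.sign(beta_j) * np.inf),
            t,
        )
    return t


def _t_matrix(X: np.ndarray, Y: np.ndarray, j: int, pinv, c_jj, df) -> np.ndarray:
    """t-statistics of coefficient ``j`` for every column of Y (n x p)."""
    beta = pinv @ Y  # (k, p)
    resid = Y - X @ beta
    s2 = (resid**2).sum(axis=0) / df
    return _safe_t(beta[j], np.sqrt(s2 * c_jj))


def freedman_lane(
    matrix: ThicknessMatrix | pd.DataFrame | np.ndarray,
    design: pd.DataFrame,
    interest: str,
    B: int = 5000,
    seed=None,
    sidedness: str = "upper",
    exhaustive: bool = False,
    lobe: str | None = None,
    hemisphere: str | None = None,
) -> PermutationResult:
    """Run the residual-permutation max-t procedure on one parcel family.

    Parameters
    ----------
    matrix
        Lobe-restricted thickness values (subjects x parcels); a
        :class:`ThicknessMatrix`, DataFrame or plain array. Rows are aligned
        to the design index when labelled.
    design
        Full design matrix including ``interest``.
    interest
        Single design column whose coefficient is tested (H0: coefficient
        = 0). For models with several variables of interest, call once per
        variable; the others act as nuisance covariates.
    B
        Number of Monte Carlo permutations (ignored when ``exhaustive``).
    seed
        Seed for the permutation stream (int or numpy SeedSequence/Generator).
    sidedness
        ``"upper"`` (signed max t) or ``"two_sided"`` (max |t|).
    exhaustive
        Enumerate all n! subject permutations instead of sampling — exact
        inference, feasible only for tiny n.
    """
    if interest not in design.columns:
        raise KeyError(f"interest column {interest!r} not in design")
    if not exhaustive and B < 1:
        raise ValueError("B must be >= 1")
    if sidedness not in ("upper", "two_sided"):
        raise ValueError(f"sidedness must be 'upper' or 'two_sided', got {sidedness!r}")

    if isinstance(matrix, ThicknessMatrix):
        vals = matrix.values.loc[design.index]
        columns = tuple(vals.columns)
        Y = vals.to_numpy(dtype=float)
    elif isinstance(matrix, pd.DataFrame):
        vals = matrix.loc[design.index]
        columns = tuple(vals.columns)
        Y = vals.to_numpy(dtype=float)
    else:
        Y = np.asarray(matrix, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        columns = tuple(f"col{i}" for i in range(Y.shape[1]))

    X = design.to_numpy(dtype=float)
    n = X.shape[0]
    j = list(design.columns).index(interest)
    pinv, xtx_inv_diag, df = _ols_terms(X)
    c_jj = xtx_inv_diag[j]

    t_obs = _t_matrix(X, Y, j, pinv, c_jj, df)

    # reduced (nuisance-only) model: fitted values and residuals per parcel
    Z = np.delete(X, j, axis=1)
    fitted = Z @ (np.linalg.pinv(Z) @ Y)
    resid = Y - fitted

    stat_obs = np.abs(t_obs) if sidedness == "two_sided" else t_obs

    if exhaustive:
        perm_iter = (np.array(p) for p in itertools.permutations(range(n)))
        B = math.factorial(n)
    else:
        rng = np.random.default_rng(seed)
        perm_iter = (rng.permutation(n) for _ in range(B))

    maxT = np.empty(B)
    exceed_parcel = np.zeros(Y.shape[1], dtype=np.int64)
    done = 0
    while done < B:
        perms = list(itertools.islice(perm_iter, min(_CHUNK, B - done)))
        P = np.stack(perms)  # (b, n)
        Ystar = fitted[None, :, :] + resid[P, :]  # (b, n, p)
        beta = np.einsum("kn,bnp->bkp", pinv, Ystar)
        rstar = Ystar - np.einsum("nk,bkp->bnp", X, beta)
        s2 = (rstar**2).sum(axis=1) / df  # (b, p)
        tstar = _safe_t(beta[:, j, :], np.sqrt(s2 * c_jj))  # (b, p)
        if sidedness == "two_sided":
            tstar = np.abs(tstar)
        maxT[done : done + len(perms)] = tstar.max(axis=1)
        # ties count as exceedances (conservative)
        exceed_parcel += (tstar >= stat_obs[None, :] - 1e-12).sum(axis=0)
        done += len(perms)

    exceed_max = (maxT[:, None] >= stat_obs[None, :] - 1e-12).sum(axis=0)
    p_corr = (1 + exceed_max) / (1 + B)
    p_unc = (1 + exceed_parcel) / (1 + B)
    return PermutationResult(
        lobe=lobe,
        hemisphere=hemisphere,
        interest=interest,
        parcel_columns=columns,
        observed_t=t_obs,
        maxT_null=maxT,
        p_corrected=p_corr,
        p_uncorrected_perm=p_unc,
        B=B,
        seed=seed,
        sidedness=sidedness,
    )


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Wrap an int (or pass through a SeedSequence) for deterministic spawning."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def block_seeds(master_seed, n_blocks: int) -> list[np.random.SeedSequence]:
    """Deterministic per-block sub-seeds spawned from the master seed."""
    return as_seed_sequence(master_seed).spawn(n_blocks)


def run_all_lobes(
    matrix: ThicknessMatrix,
    atlas: ParcelAtlas,
    designs: dict[str, pd.DataFrame],
    interest: str,
    B: int = 5000,
    seed=None,
    sidedness: str = "upper",
) -> list[PermutationResult]:
    """Run the max-t procedure for every lobe of both hemispheres.

    ``designs`` maps hemisphere -> design matrix (each hemisphere's design
    carries its own average-thickness covariate). Sub-seeds are spawned from
    the master seed in the fixed order (left, right) x (frontal, parietal,
    temporal, occipital), so each block is independently reproducible.
    """
    blocks = [(h, lb) for h in HEMISPHERES for lb in LOBES]
    seeds = block_seeds(seed, len(blocks))
    out = []
    for (hemi, lb), ss in zip(blocks, seeds):
        sub = select_lobe(matrix, atlas, lb, hemi)
        out.append(
            freedman_lane(
                sub,
                designs[hemi],
                interest,
                B=B,
                seed=ss,
                sidedness=sidedness,
                lobe=lb,
                hemisphere=hemi,
            )
        )
    return out
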