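"""Ring Measure instrument and social value orientation (SVO) scoring.

The Ring Measure presents 24 forced choices between adjacent points on a
circle of own/other payoffs (radius EUR 15, centred on EUR 15 / EUR 15).
Scoring summarises a participant's choices as a resultant vector in the
self/other payoff plane:

* ``angle_deg`` -- direction of the resultant, rotated so that the sadistic
  pattern (sacrificing own payoff to hurt the other) sits at 0 degrees and
  increasing angle means increasing willingness to trade own money for the
  other's.
* ``vector_length`` -- resultant magnitude per choice, an index of response
  consistency (maximum 1.25 on the default instrument; participants below
  0.625, half the maximum, are excluded as random responders).
* ``w_self`` / ``w_other`` -- normalised weights on own and other's
  outcomes, ``(total - 360) / 60`` on the default instrument, each bounded
  by [-0.5, 0.5].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingDefinition",
    "SVOProfile",
    "InvalidInstrumentError",
    "MalformedResponseError",
    "build_ring",
    "score_choices",
    "score_table",
    "classify",
    "weights_from_totals",
    "filter_consistent",
    "utility_choices",
    "read_choices",
    "write_profiles",
    "export_instrument",
    "CONSISTENCY_THRESHOLD",
    "ROTATION_OFFSET_DEG",
    "CATEGORIES",
]

#: Default consistency cut-off: half the maximum vector length of the
#: default instrument (0.5 * 1.25). Participants strictly below are excluded.
CONSISTENCY_THRESHOLD = 0.625

#: Rotation (degrees) added to the raw resultant angle so that the sadistic
#: pole (raw 225 deg, the -self/-other bisector) maps to 0 deg.
ROTATION_OFFSET_DEG = 135.0

#: The eight motivational categories in order of transformed angle, one per
#: 45-degree sector centred on a pole (sadistic pole at 0 deg).
CATEGORIES = (
    "sadistic",
    "aggressive",
    "competitive",
    "individualistic",
    "prosocial/cooperative",
    "altruistic",
    "martyr",
    "masochistic",
)


class InvalidInstrumentError(ValueError):
    """Raised when ring parameters cannot define a valid instrument."""


class MalformedResponseError(ValueError):
    """Raised when a participant's responses are missing or duplicated."""


def _round_to_cents10(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest EUR 0.10, half away from zero (payoffs >= 0)."""
    return np.floor(np.asarray(x, dtype=float) * 10.0 + 0.5) / 10.0


@dataclass(frozen=True)
class RingDefinition:
    """The payoff circle and the adjacent-pair choices that make up the task.

    ``points`` holds the *displayed* payoffs, i.e. raw circle coordinates
    rounded to the nearest EUR 0.10 -- these are what participants allocate,
    so scoring uses them throughout. ``pairs`` links adjacent point indices
    with wrap-around, so each point appears in exactly two choices.
    """

    radius: float = 15.0
    origin_self: float = 15.0
    origin_other: float = 15.0
    n_points: int = 24
    points: np.ndarray = field(repr=False, default=None)  # (n, 2) displayed
    raw_points: np.ndarray = field(repr=False, default=None)  # (n, 2) exact
    pairs: tuple = field(repr=False, default=None)

    @property
    def point_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_points) * (360.0 / self.n_points)

    @property
    def offsets(self) -> np.ndarray:
        """Displayed payoffs minus the origin, shape (n_points, 2)."""
        return self.points - np.array([self.origin_self, self.origin_other])

    @property
    def max_vector_length(self) -> float:
        """Resultant length per choice of a perfectly consistent responder.

        A grid-aligned consistent responder picks every point on the
        half-circle facing its preferred direction, once from each of its two
        pairs; the doubly-chosen pole point and the never-chosen antipode
        leave a resultant of magnitude 2 * radius (1.25 EUR/choice on the
        default instrument).
        """
        return 2.0 * self.radius / self.n_points

    @property
    def median_total(self) -> tuple[float, float]:
        """Totals of a payoff-median responder: n_points * origin."""
        return (self.n_points * self.origin_self, self.n_points * self.origin_other)

    @property
    def weight_denominator(self) -> float:
        """Maximal self/other total difference: 4 * radius (EUR 60 default)."""
        return 4.0 * self.radius

    def pair_payoffs(self) -> pd.DataFrame:
        """Tidy table of the choice pairs with both options' displayed payoffs."""
        rows = []
        for k, (i, j) in enumerate(self.pairs):
            rows.append(
                {
                    "pair_index": k,
                    "first_self": self.points[i, 0],
                    "first_other": self.points[i, 1],
                    "second_self": self.points[j, 0],
                    "second_other": self.points[j, 1],
                }
            )
        return pd.DataFrame(rows)


def build_ring(
    radius: float = 15.0,
    origin: tuple[float, float] = (15.0, 15.0),
    n_points: int = 24,
) -> RingDefinition:
    """Construct the Ring Measure instrument.

    Point ``k`` sits at angle ``k * 360 / n_points`` degrees on the circle:
    raw payoffs ``(origin_self + r cos, origin_other + r sin)``, displayed to
    the nearest EUR 0.10. Choice ``k`` offers points ``k`` and ``k+1``
    (mod ``n_points``).
    """
    if radius <= 0:
        raise InvalidInstrumentError(f"radius must be positive, got {radius}")
    if n_points < 3:
        raise InvalidInstrumentError(f"need at least 3 points, got {n_points}")
    origin_self, origin_other = float(origin[0]), float(origin[1])
    theta = np.deg2rad(np.arange(n_points) * (360.0 / n_points))
    raw = np.column_stack(
        [origin_self + radius * np.cos(theta), origin_other + radius * np.sin(theta)]
    )
    points = _round_to_cents10(raw)
    pairs = tuple((k, (k + 1) % n_points) for k in range(n_points))
    return RingDefinition(
        radius=radius,
        origin_self=origin_self,
        origin_other=origin_other,
        n_points=n_points,
        points=points,
        raw_points=raw,
        pairs=pairs,
    )


@dataclass(frozen=True)
class SVOProfile:
    """Scored social-preference profile of one participant."""

    participant_id: object
    total_self: float
    total_other: float
    angle_deg: float  # transformed: 0 deg = sadistic; NaN if degenerate
    raw_angle_deg: float  # atan2(other offset, self offset), degrees in [0, 360)
    vector_length: float
    w_self: float
    w_other: float
    category: str
    included: bool
    degenerate: bool = False  # zero resultant: angle undefined


def classify(angle_deg: float) -> str:
    """Map a transformed angle to one of the eight motivational categories.

    Sectors are 45 degrees wide, centred on the poles (sadistic at 0);
    a boundary angle (pole + 22.5) belongs to the lower sector.
    """
    if angle_deg is None or (isinstance(angle_deg, float) and math.isnan(angle_deg)):
        return "undefined"
    a = float(angle_deg) % 360.0
    shifted = (a + 22.5) % 360.0
    q, r = divmod(shifted, 45.0)
    idx = int(q) if r > 0 else (int(q) - 1) % 8
    return CATEGORIES[idx]


def weights_from_totals(
    total_self: float, total_other: float, ring: RingDefinition | None = None
) -> tuple[float, float]:
    """Weights to self and other from summed allocations.

    Each weight is the total allocated minus the payoff-median responder's
    total (EUR 360 on the default instrument), divided by the maximal
    difference between the self and the other's totals (EUR 60), bounding
    both weights by [-0.5, 0.5].
    """
    ring = ring if ring is not None else build_ring()
    med_self, med_other = ring.median_total
    denom = ring.weight_denominator
    return (total_self - med_self) / denom, (total_other - med_other) / denom


def _chosen_point_indices(choices: np.ndarray, ring: RingDefinition) -> np.ndarray:
    pairs = np.asarray(ring.pairs)
    return pairs[np.arange(ring.n_points), choices]


def score_choices(
    choices,
    ring: RingDefinition | None = None,
    threshold: float = CONSISTENCY_THRESHOLD,
    participant_id=None,
) -> SVOProfile:
    """Score one participant's 24 choices into an :class:`SVOProfile`.

    Parameters
    ----------
    choices
        Either a sequence of ``n_points`` values in {0, 1} ordered by pair
        index (0 = first option of the pair, 1 = second), or a DataFrame
        with columns ``pair_index`` and ``chosen``.
    ring
        Instrument definition; defaults to the standard 24-point ring.
    threshold
        Consistency cut-off on vector length; profiles strictly below are
        marked not included.

    Notes
    -----
    The resultant is the sum of the chosen points' payoff offsets from the
    origin. Its direction gives the raw angle (four-quadrant arctangent,
    other-offset over self-offset), rotated by +135 degrees so the sadistic
    pole maps to 0. A zero resultant leaves the angle undefined: the profile
    is flagged ``degenerate`` and excluded.
    """
    ring = ring if ring is not None else build_ring()
    n = ring.n_points
    if isinstance(choices, pd.DataFrame):
        df = choices
        if participant_id is None and "participant_id" in df.columns:
            ids = df["participant_id"].unique()
            if len(ids) != 1:
                raise MalformedResponseError(
                    f"expected one participant, got {len(ids)}"
                )
            participant_id = ids[0]
        idx = df["pair_index"].to_numpy()
        if len(idx) != n or sorted(idx.tolist()) != list(range(n)):
            raise MalformedResponseError(
                f"participant {participant_id!r}: need exactly one choice per "
                f"pair 0..{n - 1}, got pair indices {sorted(idx.tolist())}"
            )
        vec = np.empty(n, dtype=int)
        vec[idx] = df["chosen"].to_numpy(dtype=int)
    else:
        vec = np.asarray(list(choices), dtype=int)
        if vec.shape != (n,):
            raise MalformedResponseError(
                f"participant {participant_id!r}: expected {n} choices, got {vec.shape}"
            )
    if not np.isin(vec, (0, 1)).all():
        raise MalformedResponseError(
            f"participant {participant_id!r}: choices must be 0 (first) or 1 (second)"
        )

    chosen_points = _chosen_point_indices(vec, ring)
    payoffs = ring.points[chosen_points]
    total_self = float(payoffs[:, 0].sum())
    total_other = float(payoffs[:, 1].sum())
    resultant = ring.offsets[chosen_points].sum(axis=0)
    length = float(np.hypot(*resultant)) / n

    w_self, w_other = weights_from_totals(total_self, total_other, ring)

    degenerate = np.hypot(*resultant) < 1e-9
    if degenerate:
        raw_angle = math.nan
        angle = math.nan
        length = 0.0
    else:
        raw_angle = math.degrees(math.atan2(resultant[1], resultant[0])) % 360.0
        angle = (raw_angle + ROTATION_OFFSET_DEG) % 360.0
    included = (not degenerate) and length >= threshold
    return SVOProfile(
        participant_id=participant_id,
        total_self=total_self,
        total_other=total_other,
        angle_deg=angle,
        raw_angle_deg=raw_angle,
        vector_length=length,
        w_self=w_self,
        w_other=w_other,
        category=classify(angle),
        included=included,
        degenerate=bool(degenerate),
    )


def score_table(
    choices: pd.DataFrame,
    ring: RingDefinition | None = None,
    threshold: float = CONSISTENCY_THRESHOLD,
) -> pd.DataFrame:
    """Score a long-format choice table (all participants) into a profile table.

    Input columns: ``participant_id``, ``pair_index``, ``chosen``. Output has
    one row per participant with the :class:`SVOProfile` fields.
    """
    required = {"participant_id", "pair_index", "chosen"}
    missing = required - set(choices.columns)
    if missing:
        raise MalformedResponseError(f"choice table missing columns: {sorted(missing)}")
    rows = []
    for pid, grp in choices.groupby("participant_id", sort=True):
        prof = score_choices(grp, ring=ring, threshold=threshold, participant_id=pid)
        rows.append(prof.__dict__)
    return pd.DataFrame(rows)


def filter_consistent(
    profiles: pd.DataFrame,
    threshold: float = CONSISTENCY_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split profiles into consistent responders and an exclusion report.

    A participant is retained when ``vector_length >= threshold`` (the
    boundary itself is included; only strictly shorter vectors indicate
    unreliable, random-like responding) and the angle is defined.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    ok = (profiles["vector_length"] >= threshold) & ~profiles["degenerate"]
    report = profiles.loc[~ok, ["participant_id", "vector_length", "degenerate"]].copy()
    report["reason"] = np.where(
        report["degenerate"], "zero resultant (angle undefined)", "inconsistent"
    )
    return profiles.loc[ok].copy(), report.reset_index(drop=True)


def utility_choices(ring: RingDefinition, theta_deg: float) -> np.ndarray:
    """Choice vector of a deterministic linear-utility responder.

    For each pair the responder picks the option with the larger projection
    of its displayed payoff offset onto the preferred direction
    ``(cos theta, sin theta)`` (raw-angle convention: 0 deg = pure
    self-maximiser). Ties break to the first option.
    """
    direction = np.array(
        [math.cos(math.radians(theta_deg)), math.sin(math.radians(theta_deg))]
    )
    proj = ring.offsets @ direction
    pairs = np.asarray(ring.pairs)
    return (proj[pairs[:, 1]] > proj[pairs[:, 0]]).astype(int)


# ---------------------------------------------------------------------------
# text I/O


def read_choices(path) -> pd.DataFrame:
    """Read a long-format choice table (CSV/TSV by extension) and validate."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"participant_id", "pair_index", "chosen"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedResponseError(
            f"{path}: choice table missing columns {sorted(missing)}"
        )
    return df


def write_profiles(profiles: pd.DataFrame, path) -> None:
    cols = [
        "participant_id",
        "angle_deg",
        "vector_length",
        "w_self",
        "w_other",
        "category",
        "included",
        "total_self",
        "total_other",
        "raw_angle_deg",
        "degenerate",
    ]
    cols = [c for c in cols if c in profiles.columns]
    profiles[cols].to_csv(path, index=False)


def export_instrument(ring: RingDefinition, path) -> None:
    """Write the 24 choice pairs with both options' displayed payoffs."""
    ring.pair_payoffs().to_csv(path, index=False)
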