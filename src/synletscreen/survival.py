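"""Tumor-growth endpoints: caliper volume, RTV, progression events, KM/log-rank.

Caliper volume uses the ellipsoid approximation 0.5 * length * width^2
(mm^3).  Each animal's volume series is normalized to its treatment-start
(day 0) volume to give the relative tumor volume (RTV); progression is
the first measurement day with RTV at or above a 10x threshold, with
animals that never cross censored at their last measurement (or at a
recorded removal day for non-progression reasons such as death or an
open tumor).  Arms are compared with Kaplan-Meier estimates and the
unweighted (Mantel-Cox) log-rank test via lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synletscreen.errors import ConfigurationError, EndpointError, GroupingError

PROGRESSION_THRESHOLD_RTV = 10.0


@dataclass
class TumorTrajectory:
    """One animal's caliper series: (day, length mm, width mm) triples.

    Days must be strictly increasing and include day 0 (treatment start).
    ``censor_day`` marks removal for a non-progression reason (death,
    open tumor); measurements after it are not expected.
    """

    animal: str
    arm: str
    days: np.ndarray
    lengths_mm: np.ndarray
    widths_mm: np.ndarray
    censor_day: float | None = None
    censor_reason: str | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        self.widths_mm = np.asarray(self.widths_mm, dtype=float)
        if not (self.days.size == self.lengths_mm.size == self.widths_mm.size):
            raise ConfigurationError("days/lengths/widths sizes differ")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ConfigurationError("measurement days must be strictly increasing")
        if np.any(self.lengths_mm <= 0) or np.any(self.widths_mm <= 0):
            raise ConfigurationError("caliper measurements must be positive")

    def volumes(self) -> np.ndarray:
        return caliper_volume(self.lengths_mm, self.widths_mm)


@dataclass
class SurvivalRecord:
    """Progression-free survival outcome for one animal."""

    animal: str
    arm: str
    time: float
    event: bool
    censor_reason: str | None = None


@dataclass
class LogRankResult:
    """Two-sample log-rank comparison plus per-arm KM curves.

    ``curves`` maps arm -> DataFrame with columns ``time`` and
    ``survival`` (the product-limit estimate evaluated at event times).
    """

    statistic: float
    p_value: float
    curves: dict[str, pd.DataFrame]


def caliper_volume(length_mm, width_mm):
    """Ellipsoid tumor volume 0.5 * L * W^2 in mm^3.

    By caliper convention the length is the larger diameter; swapped
    inputs are corrected with a warning rather than rejected.
    """
    length = np.asarray(length_mm, dtype=float)
    width = np.asarray(width_mm, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ConfigurationError("caliper measurements must be positive")
    if np.any(width > length):
        warnings.warn("width > length in caliper data; swapping to the caliper convention")
        length, width = np.maximum(length, width), np.minimum(length, width)
    out = 0.5 * length * width**2
    return float(out) if out.ndim == 0 else out


def rtv_series(t: TumorTrajectory) -> list[tuple[float, float]]:
    """Relative tumor volume per measurement day (RTV(0) = 1 exactly)."""
    if t.days.size == 0 or t.days[0] != 0:
        raise EndpointError(f"animal {t.animal!r}: no day-0 measurement (treatment start)")
    vols = t.volumes()
    if vols[0] <= 0:
        raise EndpointError(f"animal {t.animal!r}: degenerate day-0 volume {vols[0]}")
    rtv = vols / vols[0]
    rtv[0] = 1.0
    return list(zip(t.days.tolist(), rtv.tolist()))


def pfs_event(
    t: TumorTrajectory, threshold: float = PROGRESSION_THRESHOLD_RTV
) -> SurvivalRecord:
    """Progression-free survival outcome: first day with RTV >= threshold.

    No interpolation between visits: the event day is the first observed
    crossing.  Trajectories that never cross are censored at the last
    measurement day, or at the recorded ``censor_day`` when the animal was
    removed for a non-progression reason.
    """
    series = rtv_series(t)
    for day, rtv in series:
        if day > 0 and rtv >= threshold:
            return SurvivalRecord(animal=t.animal, arm=t.arm, time=day, event=True)
    last = t.censor_day if t.censor_day is not None else series[-1][0]
    return SurvivalRecord(
        animal=t.animal, arm=t.arm, time=float(last), event=False,
        censor_reason=t.censor_reason or "no progression",
    )


def records_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal": [r.animal for r in records],
            "arm": [r.arm for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        }
    )


def km_logrank(
    records: list[SurvivalRecord], arms: tuple[str, str] | None = None
) -> LogRankResult:
    """Kaplan-Meier curves per arm and the Mantel-Cox log-rank comparison.

    ``arms`` selects (and orders) the two arms to compare; by default the
    records must contain exactly two arms.  Each arm needs at least one
    record.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = records_frame(records)
    if arms is None:
        found = tuple(pd.unique(df["arm"]))
        if len(found) != 2:
            raise GroupingError(f"expected exactly two arms, found {found}; pass arms=")
        arms = found
    sub = {arm: df[df["arm"] == arm] for arm in arms}
    for arm, part in sub.items():
        if part.empty:
            raise GroupingError(f"arm {arm!r} has no records")
    a, b = arms
    res = logrank_test(
        sub[a]["time"], sub[b]["time"],
        event_observed_A=sub[a]["event"], event_observed_B=sub[b]["event"],
    )
    curves = {}
    for arm in arms:
        kmf = KaplanMeierFitter()
        kmf.fit(sub[arm]["time"], event_observed=sub[arm]["event"], label=arm)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[arm] = sf
    return LogRankResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value), curves=curves
    )


def trajectories_from_table(df: pd.DataFrame) -> list[TumorTrajectory]:
    """Build trajectories from a long caliper table.

    Expected columns: animal, arm, day, length_mm, width_mm and optional
    censor_day / censor_reason (constant within an animal).
    """
    needed = {"animal", "arm", "day", "length_mm", "width_mm"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigurationError(f"caliper table missing column(s): {sorted(missing)}")
    out = []
    for (animal, arm), grp in df.groupby(["animal", "arm"], sort=False):
        grp = grp.sort_values("day")
        censor_day = None
        censor_reason = None
        if "censor_day" in grp.columns and grp["censor_day"].notna().any():
            censor_day = float(grp["censor_day"].dropna().iloc[0])
        if "censor_reason" in grp.columns and grp["censor_reason"].notna().any():
            censor_reason = str(grp["censor_reason"].dropna().iloc[0])
        out.append(
            TumorTrajectory(
                animal=str(animal), arm=str(arm),
                days=grp["day"].to_numpy(float),
                lengths_mm=grp["length_mm"].to_numpy(float),
                widths_mm=grp["width_mm"].to_numpy(float),
                censor_day=censor_day, censor_reason=censor_reason,
            )
        )
    return out


def plot_km(result: LogRankResult, path) -> None:
    """Step-plot the KM curves with the log-rank p in the title."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for arm, curve in result.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=arm)
    ax.set_xlabel("days")
    ax.set_ylabel("progression-free fraction")
    ax.set_ylim(0, 1.05)
    ax.legend()
    ax.set_title(f"log-rank p = {result.p_value:.4g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
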