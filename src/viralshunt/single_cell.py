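"""Single-cell growth rates from mother-machine tracks.

Cells in a mother machine grow exponentially in length, so the per-cell
elongation rate is the slope of an ordinary least-squares regression (with
intercept) of log cell length on time; times are converted from minutes to
hours so rates come out in h^-1.  Quality control mirrors the imaging
pipeline's constraints:

* only the final portion of the experiment is analyzed (default 6 h),
* tracks seen in fewer than ``min_frames`` frames are dropped (default 7),
* tracks whose x-position ever exceeds a chamber-exit threshold are dropped
  (cells sliding out of the field produce artifactual negative rates),
* fits with R^2 below ``r2_min`` are dropped (default 0.95), where R^2 is
  the squared Pearson correlation of the log-length-vs-time fit.

Condition comparisons follow the replicate-level design: a two-way
fixed-effects ANOVA (condition + biological replicate, no interaction) on
the table of replicate mean rates, followed by Tukey's HSD on the condition
means using the ANOVA residual mean square.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellTrack",
    "TrackFilterConfig",
    "GrowthRateRecord",
    "estimate_track_growth_rate",
    "filter_tracks",
    "summarize_conditions",
    "replicate_means_anova",
    "tukey_hsd",
    "doubling_time",
    "percent_change",
]


@dataclass(frozen=True)
class CellTrack:
    """Frames of one tracked cell: time (min), length (um), x-position (um)."""

    track_id: str
    condition: str
    replicate: str
    times_min: np.ndarray
    lengths_um: np.ndarray
    x_um: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        ln = np.asarray(self.lengths_um, dtype=float)
        x = np.asarray(self.x_um, dtype=float)
        if not (t.size == ln.size == x.size):
            raise ValueError("times, lengths, and x must have equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "lengths_um", ln)
        object.__setattr__(self, "x_um", x)

    @property
    def n_frames(self) -> int:
        return self.times_min.size


@dataclass(frozen=True)
class TrackFilterConfig:
    """Quality-control thresholds for track retention."""

    min_frames: int = 7
    r2_min: float = 0.95
    x_max: float = 20.0  # um; 80% of a 25 um chamber, origin at the closed end
    analysis_window: float = 6.0  # h, final window retained

    def __post_init__(self):
        if self.min_frames < 2:
            raise ValueError("min_frames must be >= 2")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must lie in (0, 1]")


@dataclass(frozen=True)
class GrowthRateRecord:
    track_id: str
    condition: str
    replicate: str
    rate: float  # h^-1
    r2: float
    n_frames: int
    rejected_reason: str | None = None  # short_track | low_r2 | chamber_exit


def estimate_track_growth_rate(track: CellTrack) -> tuple[float, float, int]:
    """OLS slope of ln(length) on time in hours: (rate h^-1, R^2, n_frames).

    R^2 is the squared Pearson correlation between ln-length and time,
    which for OLS with intercept equals the coefficient of determination.
    A perfectly constant track is assigned rate 0 and R^2 = 1 by convention
    (the flat fit has zero residual).
    """
    if track.n_frames < 2:
        raise ValueError(f"track {track.track_id}: need >= 2 frames to fit")
    if np.any(track.lengths_um <= 0):
        raise ValueError(f"track {track.track_id}: nonpositive cell length")
    t_h = track.times_min / 60.0
    y = np.log(track.lengths_um)
    if np.ptp(y) == 0.0:
        return 0.0, 1.0, track.n_frames
    slope, _ = np.polyfit(t_h, y, 1)
    r = np.corrcoef(t_h, y)[0, 1]
    return float(slope), float(r * r), track.n_frames


def _crop_to_window(
    tracks: Sequence[CellTrack], window_h: float
) -> list[CellTrack]:
    """Keep only frames in the final ``window_h`` hours of the experiment.

    The window is anchored at the latest frame time over the whole input
    (one experiment's worth of tracks)."""
    if not tracks:
        return []
    t_max = max(tr.times_min[-1] for tr in tracks)
    t_cut = t_max - window_h * 60.0
    out = []
    for tr in tracks:
        keep = tr.times_min >= t_cut
        if not keep.any():
            continue
        out.append(
            replace(
                tr,
                times_min=tr.times_min[keep],
                lengths_um=tr.lengths_um[keep],
                x_um=tr.x_um[keep],
            )
        )
    return out


def filter_tracks(
    tracks: Sequence[CellTrack], cfg: TrackFilterConfig | None = None
) -> tuple[list[GrowthRateRecord], dict[str, int]]:
    """Apply QC and estimate rates; returns (records, rejection tally).

    Filters apply in a fixed order — window crop, frame count, chamber
    exit, regression fit, R^2 — and every record carries at most one
    (first-failing) rejection reason.  Retained records have
    ``rejected_reason is None``.
    """
    cfg = cfg or TrackFilterConfig()
    records: list[GrowthRateRecord] = []
    tally = {"short_track": 0, "chamber_exit": 0, "low_r2": 0, "retained": 0}
    for tr in _crop_to_window(tracks, cfg.analysis_window):
        if tr.n_frames < cfg.min_frames:
            tally["short_track"] += 1
            records.append(
                GrowthRateRecord(
                    tr.track_id, tr.condition, tr.replicate,
                    rate=np.nan, r2=np.nan, n_frames=tr.n_frames,
                    rejected_reason="short_track",
                )
            )
            continue
        if np.any(tr.x_um > cfg.x_max):
            tally["chamber_exit"] += 1
            records.append(
                GrowthRateRecord(
                    tr.track_id, tr.condition, tr.replicate,
                    rate=np.nan, r2=np.nan, n_frames=tr.n_frames,
                    rejected_reason="chamber_exit",
                )
            )
            continue
        rate, r2, n = estimate_track_growth_rate(tr)
        if r2 < cfg.r2_min:
            tally["low_r2"] += 1
            records.append(
                GrowthRateRecord(
                    tr.track_id, tr.condition, tr.replicate,
                    rate=rate, r2=r2, n_frames=n, rejected_reason="low_r2",
                )
            )
            continue
        tally["retained"] += 1
        records.append(
            GrowthRateRecord(tr.track_id, tr.condition, tr.replicate, rate, r2, n)
        )
    return records, tally


def records_frame(records: Iterable[GrowthRateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": r.track_id,
                "condition": r.condition,
                "replicate": r.replicate,
                "rate": r.rate,
                "r2": r.r2,
                "n_frames": r.n_frames,
                "rejected_reason": r.rejected_reason,
            }
            for r in records
        ]
    )


def summarize_conditions(
    records: Iterable[GrowthRateRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled per-condition and per-(condition, replicate) summaries.

    Returns ``(condition_summary, replicate_means)`` where the first pools
    all retained cells per condition (mean, sample SD — 0 for n=1 — and n)
    and the second is the condition x replicate table of mean rates used by
    the replicate-level ANOVA.
    """
    retained = [r for r in records if r.rejected_reason is None]
    if not retained:
        raise ValueError("no retained growth-rate records to summarize")
    df = records_frame(retained)
    cond = (
        df.groupby("condition", sort=False)["rate"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if s.size > 1 else 0.0, n="size")
        .reset_index()
    )
    rep = (
        df.groupby(["condition", "replicate"], sort=False)["rate"]
        .mean()
        .reset_index()
        .rename(columns={"rate": "mean_rate"})
    )
    return cond, rep


def _check_complete(replicate_means: pd.DataFrame) -> tuple[int, int]:
    counts = replicate_means.groupby(["condition", "replicate"]).size()
    c = replicate_means["condition"].nunique()
    r = replicate_means["replicate"].nunique()
    if len(counts) != c * r or (counts != 1).any():
        raise ValueError(
            "replicate-means table must contain exactly one mean per "
            "condition x replicate cell"
        )
    return c, r


def replicate_means_anova(replicate_means: pd.DataFrame) -> pd.DataFrame:
    """Additive two-way fixed-effects ANOVA on replicate mean rates.

    ``replicate_means`` needs columns condition, replicate, mean_rate (one
    row per condition x replicate).  Returns the ANOVA table with sums of
    squares, df, F, and p for both factors; the residual df is
    ``(n_conditions - 1) * (n_replicates - 1)``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    c, r = _check_complete(replicate_means)
    if c < 2 or r < 2:
        raise ValueError("ANOVA needs >= 2 conditions and >= 2 replicates")
    model = smf.ols(
        "mean_rate ~ C(condition) + C(replicate)", data=replicate_means
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return table.rename(
        index={"C(condition)": "condition", "C(replicate)": "replicate",
               "Residual": "residual"}
    )


def tukey_hsd(replicate_means: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Tukey HSD between conditions on replicate means.

    Uses the residual mean square of the additive two-way ANOVA (so the
    replicate blocking is respected) and the studentized range distribution
    with ``(c-1)(r-1)`` degrees of freedom.  With exactly two conditions the
    adjusted p-value coincides with the unadjusted two-sided comparison
    built from the same residual MS.
    """
    c, r = _check_complete(replicate_means)
    if c < 2:
        raise ValueError("Tukey HSD needs at least 2 conditions")
    anova = replicate_means_anova(replicate_means)
    ms_resid = anova.loc["residual", "sum_sq"] / anova.loc["residual", "df"]
    df_resid = anova.loc["residual", "df"]
    means = replicate_means.groupby("condition", sort=False)["mean_rate"].mean()
    se = np.sqrt(ms_resid / r)
    rows = []
    for a, b in itertools.combinations(means.index, 2):
        diff = means[b] - means[a]
        q = abs(diff) / se if se > 0 else 0.0
        p = float(stats.studentized_range.sf(q, c, df_resid)) if se > 0 else 1.0
        rows.append(
            {"group_a": a, "group_b": b, "mean_diff": float(diff),
             "q": float(q), "p_adj": min(max(p, 0.0), 1.0)}
        )
    return pd.DataFrame(rows)


def doubling_time(rate: float) -> float:
    """Doubling time in minutes for an exponential rate in h^-1."""
    if rate <= 0:
        raise ValueError("doubling time requires a positive growth rate")
    return 60.0 * np.log(2.0) / rate


def percent_change(rate_ref: float, rate_new: float) -> float:
    """Percent change of ``rate_new`` relative to ``rate_ref``."""
    if rate_ref <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (rate_new - rate_ref) / rate_ref
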