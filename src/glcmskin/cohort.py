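"""Paired before/after cohort statistics for brightness and GLCM features.

Works from per-patient measurement records — either freshly computed from
images or transcribed clinical tables — and produces cohort summaries: means
and sample standard deviations before and after treatment, mean absolute and
percent changes, per-patient extremes, and per-RGB-channel aggregates.

Percent changes divide the absolute change by the *larger* of the two values
by default (increases are divided by the post value, decreases by the pre
value); this single rule makes the conventional clinical-report percentages
symmetric in before/after.  "before" and "after" denominators are available
as explicit options.

Significance tests (paired t, Wilcoxon signed-rank) are provided as post-hoc
plumbing for exploratory use; they are not part of the measurement model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientRecord",
    "Extreme",
    "CohortSummary",
    "ChannelStats",
    "ChannelSummary",
    "PairedTestReport",
    "percent_change",
    "summarize_cohort",
    "summarize_channels",
    "channel_summary_from_table",
    "paired_tests",
    "load_measurements",
    "packaged_fixture_path",
    "load_packaged_records",
    "load_packaged_channel_table",
    "round_half_up",
]

METRICS = ("brightness", "contrast", "homogeneity")
CHANNELS = ("gray", "R", "G", "B")

_CSV_COLUMNS = ["patient_id", "metric", "channel", "before", "after"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from the midpoint toward +inf in magnitude,
    matching how clinical tables are conventionally printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PatientRecord:
    """Before/after value pairs for one subject, keyed by (metric, channel)."""

    patient_id: int
    values: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def get(self, metric: str, channel: str = "gray") -> tuple[float, float] | None:
        return self.values.get((metric, channel))


@dataclass(frozen=True)
class Extreme:
    patient_id: int
    absolute_change: float
    percent_change: float


@dataclass(frozen=True)
class CohortSummary:
    metric: str
    channel: str
    n: int
    mean_before: float
    mean_after: float
    sd_before: float | None
    sd_after: float | None
    mean_absolute_change: float
    mean_percent_change: float
    largest: Extreme
    smallest: Extreme


@dataclass(frozen=True)
class ChannelStats:
    channel: str
    contrast_before: float
    contrast_after: float
    homogeneity_before: float
    homogeneity_after: float
    #: magnitude of the contrast decrease, before - after
    contrast_decrease: float
    contrast_percent_change: float
    #: homogeneity change, after - before
    homogeneity_increase: float
    homogeneity_percent_change: float


@dataclass(frozen=True)
class ChannelSummary:
    channels: dict[str, ChannelStats]
    #: channel with the largest contrast difference, None on a tie
    largest_contrast_channel: str | None
    tie: bool
    missing_channels: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairedTestReport:
    metric: str
    channel: str
    n: int
    t_statistic: float | None
    t_pvalue: float | None
    wilcoxon_statistic: float | None
    wilcoxon_pvalue: float | None
    degenerate: bool
    note: str = (
        "post-hoc exploratory tests on after-before differences; "
        "not part of the measurement model"
    )


def percent_change(before: float, after: float, convention: str = "larger") -> float:
    """Fractional change |after - before| / denominator.

    convention 'larger' uses max(before, after) (symmetric in the two values);
    'before' and 'after' use the respective measurement.
    """
    if convention == "larger":
        denom = max(before, after)
    elif convention == "before":
        denom = before
    elif convention == "after":
        denom = after
    else:
        raise ValueError("convention must be 'larger', 'before' or 'after'")
    if denom <= 0:
        raise ValueError(f"percent change undefined: non-positive denominator {denom}")
    return abs(after - before) / denom


def _paired_values(records, metric, channel):
    pairs = [(r.patient_id, *r.values[(metric, channel)])
             for r in records if (metric, channel) in r.values]
    if not pairs:
        raise ValueError(f"no records carry metric {metric!r} on channel {channel!r}")
    return pairs


def summarize_cohort(records: list[PatientRecord], metric: str,
                     channel: str = "gray",
                     convention: str = "larger") -> CohortSummary:
    """Cohort means, sample SDs (n-1), mean changes and per-patient extremes.

    Extremes are ranked by the magnitude of the per-patient change; ties break
    toward the lower patient id.  The cohort percent change is the percent
    change of the cohort means.
    """
    pairs = _paired_values(records, metric, channel)
    ids = np.array([p[0] for p in pairs])
    before = np.array([p[1] for p in pairs], dtype=float)
    after = np.array([p[2] for p in pairs], dtype=float)
    n = len(pairs)
    mb, ma = float(before.mean()), float(after.mean())
    sd_b = float(before.std(ddof=1)) if n > 1 else None
    sd_a = float(after.std(ddof=1)) if n > 1 else None

    change = after - before
    absc = np.abs(change)
    # rank by |change|, ties broken toward the lower patient id
    top = int(np.lexsort((ids, -absc))[0])
    bottom = int(np.lexsort((ids, absc))[0])

    def _extreme(k: int) -> Extreme:
        return Extreme(
            patient_id=int(ids[k]),
            absolute_change=float(change[k]),
            percent_change=percent_change(before[k], after[k], convention),
        )

    return CohortSummary(
        metric=metric,
        channel=channel,
        n=n,
        mean_before=mb,
        mean_after=ma,
        sd_before=sd_b,
        sd_after=sd_a,
        mean_absolute_change=ma - mb,
        mean_percent_change=percent_change(mb, ma, convention),
        largest=_extreme(top),
        smallest=_extreme(bottom),
    )


def _channel_stats(channel, cb, ca, hb, ha, convention) -> ChannelStats:
    return ChannelStats(
        channel=channel,
        contrast_before=cb,
        contrast_after=ca,
        homogeneity_before=hb,
        homogeneity_after=ha,
        contrast_decrease=cb - ca,
        contrast_percent_change=percent_change(cb, ca, convention),
        homogeneity_increase=ha - hb,
        homogeneity_percent_change=percent_change(hb, ha, convention),
    )


def _assemble_channel_summary(stats_map: dict[str, ChannelStats],
                              missing: tuple[str, ...]) -> ChannelSummary:
    decreases = {ch: s.contrast_decrease for ch, s in stats_map.items()}
    best = max(decreases.values())
    winners = sorted(ch for ch, d in decreases.items() if d == best)
    tie = len(winners) > 1
    return ChannelSummary(
        channels=stats_map,
        largest_contrast_channel=None if tie else winners[0],
        tie=tie,
        missing_channels=missing,
    )


def summarize_channels(records: list[PatientRecord],
                       convention: str = "larger") -> ChannelSummary:
    """Per-RGB-channel mean contrast/homogeneity before and after, and the
    channel with the largest contrast decrease.  Channels with no data are
    omitted and flagged."""
    stats_map: dict[str, ChannelStats] = {}
    missing: list[str] = []
    for ch in ("R", "G", "B"):
        try:
            c_pairs = _paired_values(records, "contrast", ch)
            h_pairs = _paired_values(records, "homogeneity", ch)
        except ValueError:
            missing.append(ch)
            continue
        cb = float(np.mean([p[1] for p in c_pairs]))
        ca = float(np.mean([p[2] for p in c_pairs]))
        hb = float(np.mean([p[1] for p in h_pairs]))
        ha = float(np.mean([p[2] for p in h_pairs]))
        stats_map[ch] = _channel_stats(ch, cb, ca, hb, ha, convention)
    if not stats_map:
        raise ValueError("no channel data present in any record")
    return _assemble_channel_summary(stats_map, tuple(missing))


def channel_summary_from_table(table: pd.DataFrame,
                               convention: str = "larger") -> ChannelSummary:
    """Build a :class:`ChannelSummary` from a cohort-level means table with
    columns channel, metric, before, after (metrics contrast/homogeneity)."""
    required = {"channel", "metric", "before", "after"}
    if not required.issubset(table.columns):
        raise ValueError(f"channel table must have columns {sorted(required)}")
    stats_map: dict[str, ChannelStats] = {}
    missing: list[str] = []
    for ch in ("R", "G", "B"):
        sub = table[table["channel"] == ch].set_index("metric")
        if not {"contrast", "homogeneity"}.issubset(sub.index):
            missing.append(ch)
            continue
        stats_map[ch] = _channel_stats(
            ch,
            float(sub.loc["contrast", "before"]),
            float(sub.loc["contrast", "after"]),
            float(sub.loc["homogeneity", "before"]),
            float(sub.loc["homogeneity", "after"]),
            convention,
        )
    if not stats_map:
        raise ValueError("channel table contains no usable channel rows")
    return _assemble_channel_summary(stats_map, tuple(missing))


def paired_tests(records: list[PatientRecord], metric: str,
                 channel: str = "gray") -> PairedTestReport:
    """Two-sided paired t and Wilcoxon signed-rank on after-before differences.

    Degenerate difference sets (zero variance, or all zeros for Wilcoxon) are
    flagged rather than reported as spuriously extreme statistics.
    """
    pairs = _paired_values(records, metric, channel)
    if len(pairs) < 3:
        raise ValueError("paired tests need at least 3 complete pairs")
    before = np.array([p[1] for p in pairs], dtype=float)
    after = np.array([p[2] for p in pairs], dtype=float)
    diff = after - before

    degenerate = False
    if np.allclose(diff.std(ddof=1), 0.0):
        t_stat = t_p = None
        degenerate = True
    else:
        t = stats.ttest_rel(after, before)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
    if np.all(diff == 0):
        w_stat = w_p = None
        degenerate = True
    else:
        w = stats.wilcoxon(after, before)
        w_stat, w_p = float(w.statistic), float(w.pvalue)
    return PairedTestReport(
        metric=metric,
        channel=channel,
        n=len(pairs),
        t_statistic=t_stat,
        t_pvalue=t_p,
        wilcoxon_statistic=w_stat,
        wilcoxon_pvalue=w_p,
        degenerate=degenerate,
    )


def load_measurements(path: str | Path) -> list[PatientRecord]:
    """Read a per-patient measurements CSV into validated records.

    Expected header: patient_id, metric, channel, before, after.  Duplicate
    (patient, metric, channel) rows and malformed rows are rejected with the
    offending line named (line numbers count the header as line 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty measurements file") from None
    if list(df.columns) != _CSV_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {_CSV_COLUMNS}, found {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"{path}: no measurement rows")

    records: dict[int, PatientRecord] = {}
    seen: dict[tuple[int, str, str], int] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            pid = int(row["patient_id"])
            metric = str(row["metric"]).strip()
            channel = str(row["channel"]).strip()
            before = float(row["before"])
            after = float(row["after"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {line}: {exc}") from None
        if metric not in METRICS:
            raise ValueError(f"{path}: unknown metric {metric!r} at line {line}")
        if channel not in CHANNELS:
            raise ValueError(f"{path}: unknown channel {channel!r} at line {line}")
        if not (np.isfinite(before) and np.isfinite(after)):
            raise ValueError(f"{path}: non-finite value at line {line}")
        key = (pid, metric, channel)
        if key in seen:
            raise ValueError(
                f"{path}: duplicate (patient {pid}, {metric}, {channel}) at line "
                f"{line} (first seen at line {seen[key]})"
            )
        seen[key] = line
        records.setdefault(pid, PatientRecord(pid)).values[(metric, channel)] = (
            before,
            after,
        )
    return [records[pid] for pid in sorted(records)]


def packaged_fixture_path(name: str) -> Path:
    """Path to a CSV packaged with the library (clinical table transcriptions)."""
    res = importlib.resources.files("glcmskin.data").joinpath(name)
    return Path(str(res))


def load_packaged_records() -> list[PatientRecord]:
    """Merged per-patient records from the packaged brightness, contrast and
    homogeneity tables (12 subjects, grayscale channel)."""
    merged: dict[int, PatientRecord] = {}
    for name in ("table1_brightness.csv", "table2_contrast.csv",
                 "table3_homogeneity.csv"):
        for rec in load_measurements(packaged_fixture_path(name)):
            merged.setdefault(rec.patient_id, PatientRecord(rec.patient_id)).values.update(
                rec.values
            )
    return [merged[pid] for pid in sorted(merged)]


def load_packaged_channel_table() -> pd.DataFrame:
    """Cohort-level per-channel means table (channel, metric, before, after)."""
    return pd.read_csv(packaged_fixture_path("table4_channels.csv"))
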