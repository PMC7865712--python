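"""Longitudinal drug-response analysis: percent change from control.

Each treatment arm (e.g. carfilzomib, bortezomib, vehicle/PBS) contributes a
series of per-timepoint vascular metrics per ROI, anchored by a single
pre-injection *control* record.  Every parameter is unit-normalized as the
percentage difference from its control value,

    Δ%(t) = 100 · (x(t) − x(control)) / x(control),

which makes the five heterogeneous parameters (mean intensity, pixels,
fractions, a dimension) directly comparable on one axis.  Group summaries
are unweighted means of Δ% over post-control timepoints, reported both per
parameter and pooled over all five parameters, together with between-group
ratios.

No hypothesis testing is performed; the analysis is descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .metrics import VesselMetrics

__all__ = [
    "SeriesRecord",
    "percent_change",
    "records_to_frame",
    "build_change_table",
    "summarize_group",
    "render_report",
    "PARAMETERS",
]

PARAMETERS = VesselMetrics.PARAMETERS
CONTROL_LABEL = "control"


@dataclass(frozen=True)
class SeriesRecord:
    """Metrics of one (group, ROI, timepoint) observation."""

    group: str
    timepoint_label: str
    timepoint_minutes: float
    roi_id: str
    metrics: VesselMetrics

    @property
    def is_control(self) -> bool:
        return self.timepoint_label == CONTROL_LABEL


def percent_change(value: float, control: float) -> float:
    """100 · (value − control) / control."""
    if control == 0:
        raise ZeroDivisionError("control value is zero; percent change undefined")
    return 100.0 * (value - control) / control


def records_to_frame(records: list[SeriesRecord]) -> pd.DataFrame:
    """Flatten records into a long-format frame, one row per parameter."""
    rows = []
    for rec in records:
        md = rec.metrics.to_dict()
        for param in PARAMETERS:
            rows.append({
                "group": rec.group,
                "roi_id": rec.roi_id,
                "timepoint_label": rec.timepoint_label,
                "timepoint_minutes": rec.timepoint_minutes,
                "parameter": param,
                "value": md[param],
            })
    return pd.DataFrame(rows)


def build_change_table(records: list[SeriesRecord]) -> pd.DataFrame:
    """Percent change from control for every parameter and timepoint.

    Long format with columns group, roi_id, timepoint_label,
    timepoint_minutes, parameter, percent_change; control rows excluded
    (they are identically 0%).  Every (group, roi) series must contain
    exactly one control record.
    """
    if not records:
        raise ValueError("no records provided")
    frame = records_to_frame(records)
    out_rows = []
    for (group, roi), sub in frame.groupby(["group", "roi_id"], sort=True):
        controls = sub[sub["timepoint_label"] == CONTROL_LABEL]
        if controls.empty:
            raise ValueError(f"series (group={group!r}, roi={roi!r}) has no control record")
        n_ctrl = controls["timepoint_minutes"].nunique()
        if len(controls) != len(PARAMETERS) * n_ctrl or n_ctrl != 1:
            raise ValueError(f"series (group={group!r}, roi={roi!r}) has multiple control records")
        ctrl = controls.set_index("parameter")["value"]
        post = sub[sub["timepoint_label"] != CONTROL_LABEL]
        for _, row in post.iterrows():
            c = ctrl[row["parameter"]]
            if c == 0:
                raise ZeroDivisionError(
                    f"control value of {row['parameter']} is zero in series "
                    f"(group={group!r}, roi={roi!r})"
                )
            out_rows.append({
                "group": group,
                "roi_id": roi,
                "timepoint_label": row["timepoint_label"],
                "timepoint_minutes": row["timepoint_minutes"],
                "parameter": row["parameter"],
                "percent_change": percent_change(row["value"], c),
            })
    table = pd.DataFrame(out_rows)
    return table.sort_values(
        ["group", "roi_id", "parameter", "timepoint_minutes"]
    ).reset_index(drop=True)


def summarize_group(table: pd.DataFrame, parameter: str | None = None) -> pd.DataFrame:
    """Mean percent change per group, with between-group ratios.

    ``parameter=None`` pools all parameters ("all"); otherwise the summary is
    restricted to one parameter.  The ratio column divides each group's mean
    by every other group's mean (index ``group``, columns ``mean_percent_change``
    and ``ratio_vs_<other>``).
    """
    if table.empty:
        raise ValueError("empty change table")
    sel = table if parameter is None else table[table["parameter"] == parameter]
    if sel.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    means = sel.groupby("group")["percent_change"].mean()
    out = means.to_frame("mean_percent_change")
    for other, other_mean in means.items():
        if other_mean != 0:
            out[f"ratio_vs_{other}"] = means / other_mean
    out.insert(0, "parameter", parameter if parameter is not None else "all")
    return out


def render_report(table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """One percent-change line plot per parameter plus the table as CSV.

    x = timepoint (minutes), y = percent change from control, one line per
    group (ROIs averaged).  File names are deterministic; returns the list
    of files written.
    """
    if table.empty:
        raise ValueError("empty change table; nothing to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    csv_path = out_dir / "percent_change.csv"
    table.to_csv(csv_path, index=False)
    written.append(csv_path)

    for param in PARAMETERS:
        sub = table[table["parameter"] == param]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        for group, gsub in sub.groupby("group"):
            curve = gsub.groupby("timepoint_minutes")["percent_change"].mean()
            ax.plot(curve.index, curve.values, marker="o", label=group)
        ax.axhline(0.0, color="0.6", lw=0.8, ls="--")
        ax.set_xlabel("time after injection (min)")
        ax.set_ylabel("change from control (%)")
        ax.set_title(param)
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"percent_change_{param}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
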