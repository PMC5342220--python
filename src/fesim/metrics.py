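"""Tracking-performance metrics: squared tracking error and settling time.

The squared tracking error (STE) is the mean of the squared pointwise
deviation between the achieved trajectory and its target — the desired
trajectory for the PI and open-loop cases, the reference trajectory for
the adaptive controllers.  It is reported in mm^2, the natural scale of
millimeter step commands.

The settling time is the earliest time after which the response stays
within a band (default +/-2%) of the final value for the rest of the
record ("reach and maintain"); a trace that leaves the band again
afterwards has not settled at the earlier crossing.  For the adaptive
controllers settling is naturally measured against the reference
trajectory they chase (same convention as the STE), with the band still
expressed as a fraction of the commanded final value; use
:func:`settling_time_to_target` for that variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricReport",
    "squared_tracking_error",
    "settling_time",
    "settling_time_to_target",
    "summarize",
]

M2_TO_MM2 = 1e6


@dataclass
class MetricReport:
    ste_mm2: float               # mean squared tracking error (mm^2)
    settling_time: float | None  # seconds, None if never settled
    final_error: float           # x - target at the last sample (m)
    band: float = 0.02
    reference_kind: str = "desired"   # which target the STE used


def squared_tracking_error(x, target) -> float:
    """Mean squared pointwise difference between two equal-length series.

    Inputs in meters; the result keeps m^2 (convert with ``M2_TO_MM2``
    for reporting).
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    if x.shape != target.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("series must be equal-length, nonempty 1-D arrays")
    d = target - x
    return float(np.mean(d * d))


def settling_time(x, t, final_value: float, band: float = 0.02) -> float | None:
    """Earliest t* with |x(t) - final_value| <= band*|final_value| for t >= t*.

    Returns ``None`` when the trace never settles within the record.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.size == 0 or x.shape != t.shape:
        raise ValueError("series must be aligned and nonempty")
    if not 0.0 < band < 1.0:
        raise ValueError("band must lie in (0, 1)")
    if final_value == 0.0:
        raise ValueError("final_value must be nonzero")
    outside = np.abs(x - final_value) > band * abs(final_value)
    if not outside.any():
        return float(t[0])
    last = int(np.flatnonzero(outside)[-1])
    if last == x.size - 1:
        return None
    return float(t[last + 1])


def settling_time_to_target(
    x, target, t, final_value: float, band: float = 0.02
) -> float | None:
    """Earliest t* with |x(t) - target(t)| <= band*|final_value| for t >= t*.

    ``target`` may be time-varying (a reference trajectory); the band is
    anchored to the commanded final value.  For a constant target equal
    to ``final_value`` this reduces to :func:`settling_time`.
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.size == 0 or x.shape != t.shape or x.shape != target.shape:
        raise ValueError("series must be aligned and nonempty")
    if not 0.0 < band < 1.0:
        raise ValueError("band must lie in (0, 1)")
    if final_value == 0.0:
        raise ValueError("final_value must be nonzero")
    outside = np.abs(x - target) > band * abs(final_value)
    if not outside.any():
        return float(t[0])
    last = int(np.flatnonzero(outside)[-1])
    if last == x.size - 1:
        return None
    return float(t[last + 1])


def summarize(reports: dict[tuple[str, str], list[MetricReport]]) -> pd.DataFrame:
    """Aggregate per-(controller, trajectory) batches of metric reports.

    Returns a table with mean and standard deviation of the STE and of
    the settling time (settling statistics use only the settled runs).
    """
    if not reports:
        raise ValueError("no reports to summarize")
    rows = []
    for (controller, trajectory), batch in reports.items():
        if not batch:
            continue
        ste = np.array([r.ste_mm2 for r in batch])
        ts = np.array([r.settling_time for r in batch
                       if r.settling_time is not None], dtype=float)
        rows.append({
            "controller": controller,
            "trajectory": trajectory,
            "n": len(batch),
            "ste_mean_mm2": ste.mean(),
            "ste_sd_mm2": ste.std(ddof=0),
            "n_settled": ts.size,
            "ts_mean_s": ts.mean() if ts.size else np.nan,
            "ts_sd_s": ts.std(ddof=0) if ts.size else np.nan,
        })
    return pd.DataFrame(rows)
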