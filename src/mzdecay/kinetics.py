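"""Decay kinetics: net decay, early/late partition, half-lives.

All quantities are differences of log2 expression (i.e. log2 fold
changes).  Net decay is measured against the U1 reference, which stands
in for the maternally provided level X_M.  Half-lives assume first-order
(exponential) decay between the second and third time points of a
series:

    k = -ln(X(t3) / X(t2)) / dt = (log2 X(t2) - log2 X(t3)) * ln(2) / dt
    t_1/2 = ln(2) / k

with dt = 60 minutes between consecutive sampling windows.  A
non-positive k (no decay between t2 and t3) yields an infinite
half-life, reported as such and marked censored, never clipped.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

DT_DEFAULT_MIN = 60.0

_M = "median_{}"


def net_decay(profiles: pd.DataFrame, late: str = "E3") -> pd.Series:
    """Late-minus-U1 log2 difference per gene (late is ``'U3'`` or ``'E3'``)."""
    if late not in ("U3", "E3"):
        raise ValueError(f"late condition must be U3 or E3, got {late!r}")
    return (profiles[_M.format(late)] - profiles[_M.format("U1")]).rename("net_decay")


def fraction_remaining(d):
    """Fraction of the initial signal left after a net decay of ``d`` log2 units."""
    return 2.0 ** np.asarray(d, dtype=float) if np.ndim(d) else float(2.0 ** d)


def percent_remaining(d):
    return 100.0 * fraction_remaining(d)


def percent_reduction(d):
    """Percent of the initial signal lost: 100 * (1 - 2^d)."""
    return 100.0 * (1.0 - fraction_remaining(d))


def partition_early_late(profiles: pd.DataFrame, series: str) -> pd.DataFrame:
    """Split a series' net change into early (t2-t1) and late (t3-t2) parts.

    The two components sum to the series net change exactly.
    """
    if series not in ("U", "E"):
        raise ValueError(f"series must be U or E, got {series!r}")
    t1, t2, t3 = (profiles[_M.format(f"{series}{i}")] for i in (1, 2, 3))
    return pd.DataFrame({"early_decay": t2 - t1, "late_decay": t3 - t2})


def half_life(log2_t2, log2_t3, dt_min: float = DT_DEFAULT_MIN):
    """Decay constant and half-life from two log2 expression values.

    Returns ``(k, t_half)``; both are arrays when the inputs are arrays.
    k <= 0 maps to an infinite half-life.
    """
    if dt_min <= 0:
        raise ValueError(f"dt_min must be positive, got {dt_min}")
    scalar = np.ndim(log2_t2) == 0 and np.ndim(log2_t3) == 0
    drop = np.asarray(log2_t2, dtype=float) - np.asarray(log2_t3, dtype=float)
    k = drop * math.log(2.0) / dt_min
    with np.errstate(divide="ignore"):
        t_half = np.where(drop > 0, dt_min / np.where(drop > 0, drop, 1.0), np.inf)
    if scalar:
        return float(k), float(t_half)
    return k, t_half


def maternal_zygotic_split(profiles: pd.DataFrame) -> pd.DataFrame:
    """Maternal (U3-U1) and zygotic (E3-U3) decay components.

    The two components sum exactly to the embryo net change E3-U1: the
    unfertilized series isolates the maternal machinery, and whatever
    additional divergence embryos show relative to eggs at t3 is
    attributed to net zygotic activity (decay or transcription).
    """
    u1 = profiles[_M.format("U1")]
    u3 = profiles[_M.format("U3")]
    e3 = profiles[_M.format("E3")]
    return pd.DataFrame(
        {"maternal_component": u3 - u1, "zygotic_component": e3 - u3}
    )


# half-life series routing: maternal-decay classes are read off the egg
# series, zygotic-decay classes off the embryo series
_SERIES_FOR_CLASS = {"II": "U", "III": "U", "IV": "E", "V": "E"}


def compute_kinetics(
    profiles: pd.DataFrame,
    class_labels: pd.Series | None = None,
    dt_min: float = DT_DEFAULT_MIN,
    default_series: str = "E",
) -> pd.DataFrame:
    """Full per-gene kinetics table.

    ``class_labels`` (gene -> stability class) routes each gene to the
    series its decay machinery is visible in: classes II/III use U2-U3,
    classes IV/V use E2-E3; other genes fall back to ``default_series``.
    Columns: series_used, net_decay, early_decay, late_decay,
    maternal_component, zygotic_component, k, half_life_min, censored.
    """
    if class_labels is not None:
        series_used = class_labels.reindex(profiles.index).map(_SERIES_FOR_CLASS)
        series_used = series_used.fillna(default_series)
    else:
        series_used = pd.Series(default_series, index=profiles.index)

    out = pd.DataFrame(index=profiles.index)
    out["series_used"] = series_used
    split = maternal_zygotic_split(profiles)

    for series in ("U", "E"):
        mask = series_used == series
        if not mask.any():
            continue
        sub = profiles.loc[mask]
        late = f"{series}3"
        out.loc[mask, "net_decay"] = net_decay(sub, late=late)
        part = partition_early_late(sub, series)
        out.loc[mask, "early_decay"] = part["early_decay"]
        out.loc[mask, "late_decay"] = part["late_decay"]
        k, t_half = half_life(
            sub[_M.format(f"{series}2")].to_numpy(),
            sub[_M.format(f"{series}3")].to_numpy(),
            dt_min=dt_min,
        )
        out.loc[mask, "k"] = k
        out.loc[mask, "half_life_min"] = t_half
    out["maternal_component"] = split["maternal_component"]
    out["zygotic_component"] = split["zygotic_component"]
    out["censored"] = out["k"] <= 0
    return out
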