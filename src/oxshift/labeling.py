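"""13C switch-labeling analysis.

After switching the carbon source to universally labeled 13C glucose
mid-course, each metabolite's isotopologue signals are collapsed into a
labeled and an unlabeled channel — by default a form counts as labeled
only when it carries at least 2 heavy carbons, which excludes natural
abundance and single-carbon exchange artifacts — and the incorporation
rate is estimated as the early-window linear slope of the labeled
fraction. A condition whose rate falls to <= 10% of the control's is
called "order_of_magnitude_lower".

No natural-abundance correction is applied (a documented limitation);
rates are point estimates without an uncertainty model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class LabelingError(ValueError):
    pass


@dataclass
class IsotopologueSeries:
    """Per-metabolite isotopologue intensities over a switch time course.

    ``signals`` maps (time_min, n_labeled) -> intensity a.u. with
    0 <= n_labeled <= n_carbons.
    """

    metabolite: str
    condition: str
    n_carbons: int
    signals: dict[tuple[float, int], float] = field(default_factory=dict)
    switch_time_min: float = 0.0

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise LabelingError("n_carbons must be >= 1")
        for (t, m), v in self.signals.items():
            if not 0 <= m <= self.n_carbons:
                raise LabelingError(
                    f"n_labeled {m} outside 0..{self.n_carbons} at t={t}"
                )
            if v < 0:
                raise LabelingError(f"negative intensity at t={t}, m={m}")

    @property
    def times(self) -> list[float]:
        return sorted({t for (t, _m) in self.signals})


def aggregate_labeled(
    series: IsotopologueSeries, min_labeled_carbons: int = 2
) -> dict[float, tuple[float, float, float]]:
    """Collapse isotopologues to (labeled, unlabeled, labeled fraction)
    per time; forms with >= ``min_labeled_carbons`` heavy carbons count
    as labeled, the rest (including singly labeled) as unlabeled.
    Fraction is NaN when the total pool is zero."""
    if min_labeled_carbons > series.n_carbons:
        raise LabelingError(
            f"min_labeled_carbons {min_labeled_carbons} exceeds "
            f"n_carbons {series.n_carbons}"
        )
    out = {}
    for t in series.times:
        labeled = sum(
            v
            for (tt, m), v in series.signals.items()
            if tt == t and m >= min_labeled_carbons
        )
        unlabeled = sum(
            v
            for (tt, m), v in series.signals.items()
            if tt == t and m < min_labeled_carbons
        )
        total = labeled + unlabeled
        frac = labeled / total if total > 0 else float("nan")
        out[t] = (labeled, unlabeled, frac)
    return out


def incorporation_rate(
    fractions: dict[float, float],
    switch_time_min: float,
    window_min: float = 10.0,
) -> float:
    """OLS slope (per minute) of labeled fraction vs. time over the
    post-switch points within ``window_min`` of the switch. NaN when
    fewer than 2 usable points exist."""
    pts = [
        (t, f)
        for t, f in sorted(fractions.items())
        if switch_time_min <= t <= switch_time_min + window_min and np.isfinite(f)
    ]
    if len(pts) < 2:
        return float("nan")
    t = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if np.unique(t).size < 2:
        return float("nan")
    return float(sps.linregress(t, f).slope)


def compare_incorporation(rate_a: float, rate_b: float) -> tuple[float, bool]:
    """Ratio rate_a / rate_b and the qualitative order-of-magnitude
    call (True iff the ratio is <= 0.1). ``rate_b`` is the control."""
    if not rate_b > 0:
        raise LabelingError(f"control rate must be positive, got {rate_b}")
    ratio = rate_a / rate_b
    return ratio, ratio <= 0.1


def series_from_frame(df, metabolite: str, condition: str = "") -> IsotopologueSeries:
    """Build an IsotopologueSeries from a long table with columns
    metabolite, time_min, n_labeled, signal, n_carbons, switch_time_min
    (and optionally condition)."""
    sub = df[df["metabolite"] == metabolite]
    if "condition" in df.columns and condition:
        sub = sub[sub["condition"] == condition]
    if sub.empty:
        raise LabelingError(f"no rows for metabolite {metabolite!r}")
    signals = {
        (float(r["time_min"]), int(r["n_labeled"])): float(r["signal"])
        for _, r in sub.iterrows()
    }
    return IsotopologueSeries(
        metabolite=metabolite,
        condition=condition,
        n_carbons=int(sub["n_carbons"].iloc[0]),
        signals=signals,
        switch_time_min=float(sub["switch_time_min"].iloc[0]),
    )
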