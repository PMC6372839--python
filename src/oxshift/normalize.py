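"""Metabolomics normalization chain.

For intracellular LC-MS features: the 12C parent signal is divided by
the fully labeled 13C spike-in reference signal (cancelling the
per-injection instrument factor), the ratio is divided by the sample's
OD600 to correct for culture density, each replicate's corrected series
is divided by its own time-zero value, and the log2 of those ratios is
averaged over replicates per time point — conditions processed
independently. Signals below the low-signal floor (default 1e4 a.u., on
either channel) are treated as missing.

Extracellular series skip the OD step: concentrations are per volume,
not per cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from oxshift.data_model import FeatureTable, NormalizedSeries, StudyDesign

logger = logging.getLogger(__name__)

MISSING = float("nan")


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs of the normalization chain.

    ``low_signal_floor`` masks unreliable intensities (applied to both
    channels); ``apply_od_correction`` is true for intracellular data
    only; ``batch_priority`` optionally restricts a feature to one batch
    (multi-iteration merges where one iteration supersedes the others).
    """

    low_signal_floor: float = 1.0e4
    apply_od_correction: bool = True
    baseline_time_min: int = 0
    batch_priority: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.low_signal_floor < 0:
            raise ValueError("low_signal_floor must be non-negative")


def isotope_ratio(parent: float, reference: float, floor: float = 1.0e4) -> float:
    """12C-parent / 13C-reference ratio, or NaN when either channel is
    below the low-signal floor (or the reference is zero)."""
    if np.isnan(parent) or np.isnan(reference):
        return MISSING
    if parent < 0 or reference < 0:
        raise ValueError("channel intensities must be non-negative")
    if parent < floor or reference < floor:
        return MISSING
    if reference == 0.0:
        logger.warning("reference channel is zero with parent %.3g; masking", parent)
        return MISSING
    return parent / reference


def od_correct(ratio: float, od600: float) -> float:
    """Divide an isotope ratio by the sample OD600 (culture density)."""
    if not od600 > 0:
        raise ValueError(f"od600 must be positive, got {od600}")
    if np.isnan(ratio):
        return MISSING
    return ratio / od600


def _corrected_value(
    parent: float, reference: float, od600: float | None, config: NormalizationConfig
) -> float:
    r = isotope_ratio(parent, reference, config.low_signal_floor)
    if config.apply_od_correction:
        if od600 is None:
            raise ValueError("OD correction requested but sample lacks od600")
        r = od_correct(r, od600)
    return r


def corrected_matrix(
    table: FeatureTable, config: NormalizationConfig
) -> "np.ndarray":
    """Feature x sample matrix of ratio- (and OD-) corrected values.

    This is the scale the repeated-measures ANOVA consumes for
    metabolomics; NaN marks masked or absent entries.
    """
    parent = table.channel("parent_12C").to_numpy(dtype=float)
    ref = table.channel("reference_13C").to_numpy(dtype=float)
    out = np.full_like(parent, np.nan)
    for j, meta in enumerate(table.samples):
        for i in range(parent.shape[0]):
            out[i, j] = _corrected_value(parent[i, j], ref[i, j], meta.od600, config)
    return out


def relative_to_baseline(
    table: FeatureTable, config: NormalizationConfig
) -> list[NormalizedSeries]:
    """Per-feature log2 fold changes versus each replicate's own baseline.

    Order of operations follows the ratio-then-log-then-average rule:
    per (feature, condition, replicate, time) the corrected value is
    divided by the same replicate's value at the baseline time, log2 is
    taken, and the arithmetic mean over available replicates is reported
    per time. A replicate missing its baseline contributes nothing; a
    replicate missing a single time point is dropped at that time only.
    Features with no replicate baseline in a condition are excluded with
    a logged reason.
    """
    corrected = corrected_matrix(table, config)
    sample_index = {m.sample_id: j for j, m in enumerate(table.samples)}
    conditions = sorted({m.condition for m in table.samples})
    times = sorted({m.time_min for m in table.samples})
    out: list[NormalizedSeries] = []

    for i, feature in enumerate(table.features):
        priority_batch = config.batch_priority.get(feature)
        for cond in conditions:
            metas = [
                m
                for m in table.samples
                if m.condition == cond
                and (priority_batch is None or m.batch == priority_batch)
            ]
            reps = sorted({m.replicate for m in metas})
            baselines: dict[str, float] = {}
            for m in metas:
                if m.time_min == config.baseline_time_min:
                    baselines[m.replicate] = corrected[i, sample_index[m.sample_id]]
            usable = {
                r: b for r, b in baselines.items() if np.isfinite(b) and b > 0
            }
            if not usable:
                logger.info(
                    "feature %s condition %s: no replicate with a defined "
                    "baseline; excluded",
                    feature,
                    cond,
                )
                continue
            per_rep: dict[tuple[int, str], float] = {}
            for m in metas:
                if m.replicate not in usable:
                    per_rep[(m.time_min, m.replicate)] = MISSING
                    continue
                v = corrected[i, sample_index[m.sample_id]]
                if np.isfinite(v) and v > 0:
                    per_rep[(m.time_min, m.replicate)] = math.log2(
                        v / usable[m.replicate]
                    )
                else:
                    per_rep[(m.time_min, m.replicate)] = MISSING
            mean: dict[int, float] = {}
            n_used: dict[int, int] = {}
            for t in times:
                vals = [
                    per_rep[(t, r)]
                    for r in reps
                    if (t, r) in per_rep and np.isfinite(per_rep[(t, r)])
                ]
                n_used[t] = len(vals)
                mean[t] = float(np.mean(vals)) if vals else MISSING
            out.append(
                NormalizedSeries(
                    feature=feature,
                    condition=cond,
                    per_replicate_log2fc=per_rep,
                    mean_log2fc=mean,
                    n_used=n_used,
                )
            )
    return out


def normalize_metabolomics(
    table: FeatureTable,
    design: StudyDesign,
    config: NormalizationConfig | None = None,
) -> list[NormalizedSeries]:
    """Full chain: isotope ratio -> OD correction (intracellular only)
    -> per-replicate baseline fold change -> log2 -> replicate mean."""
    if config is None:
        intracellular = all(m.compartment == "intracellular" for m in table.samples)
        config = NormalizationConfig(apply_od_correction=intracellular)
    return relative_to_baseline(table, config)
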