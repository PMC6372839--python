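"""In-silico oxygen-shift studies with the statistical structure the
analysis assumes.

The generator emulates a two-condition design (aerobic shift "O2" vs.
anaerobic control "An") sampled at t = 0, 1, 5, 10, 15, 30, 45, 60, 120
minutes with 3 replicates, exponential growth of roughly one doubling
over the 2-h course, impulse-shaped metabolite transients, spike-in
reference channels sharing a per-injection scale factor with the parent
channel, transcript impulses with lagged protein responses, first-order
13C label incorporation after a mid-course switch, and growth-coupled
extracellular product accumulation.

Noise is multiplicative lognormal on intensities (matching the error
structure that ratio normalization assumes) and the per-injection factor
is identical for both channels of a sample, so it cancels exactly in the
parent/reference ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oxshift.data_model import (
    FeatureTable,
    METAB_CHANNELS,
    SampleMeta,
    StudyDesign,
)

DEFAULT_TIMEPOINTS = (0, 1, 5, 10, 15, 30, 45, 60, 120)
DEFAULT_CONDITIONS = ("O2", "An")


class ParameterError(ValueError):
    """A simulation parameter violates its stated domain."""


# ---------------------------------------------------------------------------
# growth


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth OD(t) = od0 * 2^(t / doubling_time_min).

    Defaults give one doubling over the 120-min course from OD 0.35.
    """

    od0: float = 0.35
    doubling_time_min: float = 120.0

    def __post_init__(self) -> None:
        if not self.od0 > 0:
            raise ParameterError(f"od0 must be positive, got {self.od0}")
        if not self.doubling_time_min > 0:
            raise ParameterError(
                f"doubling_time_min must be positive, got {self.doubling_time_min}"
            )

    def od(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.od0 * 2.0 ** (np.asarray(t, dtype=float) / self.doubling_time_min)


def simulate_growth(model: GrowthModel, times) -> np.ndarray:
    """OD600 at each requested time (minutes, non-negative)."""
    t = np.asarray(times, dtype=float)
    if (t < 0).any():
        raise ParameterError("times must be non-negative")
    return np.asarray(model.od(t), dtype=float)


# ---------------------------------------------------------------------------
# impulse kinetics


@dataclass(frozen=True)
class ImpulseParams:
    """Product-of-two-logistics impulse on the log2 fold-change scale.

    A minimal parametric form capturing peak-and-recover,
    depletion-and-recover, and monotone shapes: a rising logistic
    (midpoint t_peak/2, steepness ``rise_rate``) multiplies a falling
    transition from ``h_peak`` toward ``h_final``. The fall midpoint
    sits at t_peak + 4.6/fall_rate, so the fall contributes ~1% at the
    peak and the recovery level is not distorted; the curve is then
    anchored exactly so that f(0) = h0 and f(t_peak_min) = h_peak.
    """

    h0: float = 0.0
    h_peak: float = 0.0
    h_final: float = 0.0
    t_peak_min: float = 15.0
    rise_rate: float = 0.5
    fall_rate: float = 0.15

    def __post_init__(self) -> None:
        if not (self.rise_rate > 0 and self.fall_rate > 0):
            raise ParameterError("rise_rate and fall_rate must be positive")
        if not self.t_peak_min > 0:
            raise ParameterError("t_peak_min must be positive")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def impulse_log2fc(p: ImpulseParams, t) -> float | np.ndarray:
    """Evaluate the impulse log2FC trajectory at time(s) ``t`` (minutes)."""
    tt = np.asarray(t, dtype=float)
    t_on = p.t_peak_min / 2.0
    # logistic(-4.6) ~ 0.01: the fall is negligible at the peak time
    t_off = p.t_peak_min + 4.6 / p.fall_rate

    def raw(x):
        rise = _logistic(p.rise_rate * (x - t_on))
        fall = _logistic(p.fall_rate * (x - t_off))
        return rise * ((p.h_peak - p.h0) - (p.h_peak - p.h_final) * fall)

    g = raw(tt)
    g0 = raw(np.array(0.0))
    gpk = raw(np.array(p.t_peak_min))
    denom = gpk - g0
    # anchor f(0)=h0 and f(t_peak)=h_peak exactly; flat profile -> z=1
    z = denom / (p.h_peak - p.h0) if abs(p.h_peak - p.h0) > 1e-12 else 1.0
    if z == 0.0:
        z = 1.0
    out = p.h0 + (g - g0) / z
    return float(out) if np.isscalar(t) else out


# ---------------------------------------------------------------------------
# noise


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise structure of the LC-MS feature level.

    ``injection_cv`` scales a per-sample lognormal factor shared exactly
    by both channels (so the spike-in ratio cancels it); ``feature_cv``
    is the per-entry lognormal CV. ``detection_floor`` (a.u.) is the
    intensity below which a recorded value is masked as unreliable at
    analysis time — the generator still records the truth so tests can
    inspect sub-floor values.
    """

    injection_cv: float = 0.1
    feature_cv: float = 0.1
    reference_level: float = 1.0e6
    detection_floor: float = 1.0e4

    def __post_init__(self) -> None:
        if self.injection_cv < 0 or self.feature_cv < 0:
            raise ParameterError("noise CVs must be non-negative")
        if self.reference_level <= 0:
            raise ParameterError("reference_level must be positive")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multiplicative factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# design construction


def make_design(
    conditions=DEFAULT_CONDITIONS,
    timepoints=DEFAULT_TIMEPOINTS,
    n_replicates: int = 3,
    assays=("metabolomics_intra",),
    growth: dict[str, GrowthModel] | None = None,
    batch: str = "b1",
    dilution_factor: float = 1.0,
) -> StudyDesign:
    """A fully crossed design: every (condition, time, replicate, assay).

    OD600 recorded per sample from the condition's growth model
    (defaults: od0 0.35, one doubling per 120 min for both arms).
    """
    growth = growth or {c: GrowthModel() for c in conditions}
    reps = [f"r{i + 1}" for i in range(n_replicates)]
    sampling = {}
    for assay in assays:
        compartment = (
            "extracellular" if assay == "metabolomics_extra" else "intracellular"
        )
        for cond in conditions:
            ods = simulate_growth(growth[cond], timepoints)
            for t, od in zip(timepoints, ods):
                for rep in reps:
                    sampling[(cond, int(t), rep, assay)] = SampleMeta(
                        condition=cond,
                        time_min=int(t),
                        replicate=rep,
                        od600=float(od),
                        batch=batch,
                        dilution_factor=dilution_factor,
                        compartment=compartment,
                    )
    return StudyDesign(
        conditions=list(conditions),
        timepoints_min=sorted(int(t) for t in set(timepoints)),
        replicates={c: list(reps) for c in conditions},
        sampling=sampling,
    )


# ---------------------------------------------------------------------------
# metabolomics


def simulate_metabolomics(
    design: StudyDesign,
    profiles: dict[str, dict[str, ImpulseParams]],
    growth: dict[str, GrowthModel],
    noise: NoiseModel,
    seed: int,
    base_levels: dict[str, float] | None = None,
    assay: str = "metabolomics_intra",
) -> FeatureTable:
    """Paired-channel metabolomics intensities for every sampled tuple.

    parent  = base_level * 2^f(t) * OD(t) * injection(sample) * eps
    reference = reference_level    * injection(sample)        * eps'

    with eps, eps' independent unit-mean lognormal (CV ``feature_cv``)
    and the injection factor shared by both channels. Deterministic for
    a given seed.
    """
    rng = np.random.default_rng(seed)
    samples = design.samples(assay)
    features = sorted(profiles)
    for f in features:
        for meta in samples:
            if meta.condition not in profiles[f]:
                raise ParameterError(
                    f"feature {f!r} lacks an impulse profile for sampled "
                    f"condition {meta.condition!r}"
                )
    base_levels = base_levels or {}
    inj = _lognormal_factors(rng, noise.injection_cv, len(samples))
    n_f, n_s = len(features), len(samples)
    eps_parent = _lognormal_factors(rng, noise.feature_cv, (n_f, n_s))
    eps_ref = _lognormal_factors(rng, noise.feature_cv, (n_f, n_s))

    parent = np.empty((n_f, n_s))
    ref = np.empty((n_f, n_s))
    for j, meta in enumerate(samples):
        od = growth[meta.condition].od(meta.time_min)
        for i, f in enumerate(features):
            base = base_levels.get(f, 1.0e6)
            fc = impulse_log2fc(profiles[f][meta.condition], meta.time_min)
            parent[i, j] = base * 2.0**fc * od * inj[j] * eps_parent[i, j]
            ref[i, j] = noise.reference_level * inj[j] * eps_ref[i, j]

    cols = pd.MultiIndex.from_tuples(
        [(m.sample_id, ch) for m in samples for ch in METAB_CHANNELS],
        names=["sample", "channel"],
    )
    data = np.empty((n_f, 2 * n_s))
    data[:, 0::2] = parent
    data[:, 1::2] = ref
    values = pd.DataFrame(data, index=pd.Index(features, name="feature_id"), columns=cols)
    return FeatureTable(values=values, samples=samples, assay=assay)


# ---------------------------------------------------------------------------
# expression (transcript + protein)


@dataclass(frozen=True)
class ExpressionKinetics:
    """Coupled mRNA impulse and first-order protein kinetics for one gene.

    The protein trajectory solves dP/dt = k_translation * M(t)
    - k_degradation * P with M(t) the linear-scale transcript abundance
    and P(0) at the pre-shift steady state k_translation * M(0) /
    k_degradation. In ``degradation_down`` mode the oxygen shift
    multiplies the degradation rate by ``deg_induction_fold`` for t > 0
    (protein loss with flat mRNA cannot arise otherwise).
    """

    mrna_profile: ImpulseParams = field(default_factory=ImpulseParams)
    k_translation: float = 1.0
    k_degradation: float = 0.01
    mode: str = "null"
    deg_induction_fold: float = 4.0
    tpm_base: float = 100.0

    def __post_init__(self) -> None:
        if self.k_degradation <= 0:
            raise ParameterError("k_degradation must be positive")
        if self.mode not in (
            "transcriptional_up",
            "degradation_down",
            "transcript_down_protein_flat",
            "null",
        ):
            raise ParameterError(f"unknown mode {self.mode!r}")


def _protein_trajectory(k: ExpressionKinetics, times: np.ndarray) -> np.ndarray:
    """Fixed-step RK4 solution of the protein ODE on a <=1-min grid."""
    t_end = float(times.max())
    n_steps = int(math.ceil(t_end)) if t_end > 0 else 1
    h = t_end / n_steps if t_end > 0 else 1.0
    grid = np.linspace(0.0, t_end, n_steps + 1)

    def mrna(t):
        return k.tpm_base * 2.0 ** impulse_log2fc(k.mrna_profile, t)

    def kd(t):
        if k.mode == "degradation_down" and t > 0:
            return k.k_degradation * k.deg_induction_fold
        return k.k_degradation

    def dpdt(t, p):
        return k.k_translation * mrna(t) - kd(t) * p

    p = k.k_translation * mrna(0.0) / k.k_degradation
    traj = np.empty(n_steps + 1)
    traj[0] = p
    for i in range(n_steps):
        t = grid[i]
        k1 = dpdt(t, p)
        k2 = dpdt(t + h / 2, p + h / 2 * k1)
        k3 = dpdt(t + h / 2, p + h / 2 * k2)
        k4 = dpdt(t + h, p + h * k3)
        p = p + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        traj[i + 1] = p
    return np.interp(times, grid, traj)


def simulate_expression(
    design: StudyDesign,
    kinetics: dict[str, dict[str, ExpressionKinetics]],
    noise: NoiseModel,
    seed: int,
) -> tuple[FeatureTable, FeatureTable]:
    """Transcript (TPM) and protein (log2 intensity) tables for the design.

    transcript = tpm_base * 2^M(t) * eps (lognormal, CV ``feature_cv``);
    protein = log2 of the ODE solution plus additive Gaussian noise of
    matching magnitude on the log2 scale. Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(kinetics)

    def build(assay: str) -> tuple[list[SampleMeta], np.ndarray]:
        samples = design.samples(assay)
        return samples, np.empty((len(genes), len(samples)))

    t_samples, tpm = build("transcriptomics")
    p_samples, prot = build("proteomics")

    # additive log2 noise sd equivalent to the multiplicative feature CV
    sigma_ln = math.sqrt(math.log1p(noise.feature_cv**2))
    log2_sd = sigma_ln / math.log(2.0)

    # noise-free trajectories per (gene, condition)
    for i, g in enumerate(genes):
        for cond in design.conditions:
            if cond not in kinetics[g]:
                raise ParameterError(
                    f"gene {g!r} lacks kinetics for condition {cond!r}"
                )
        for j, m in enumerate(t_samples):
            kin = kinetics[g][m.condition]
            tpm[i, j] = kin.tpm_base * 2.0 ** impulse_log2fc(
                kin.mrna_profile, m.time_min
            )
        cond_times = {}
        for m in p_samples:
            cond_times.setdefault(m.condition, set()).add(m.time_min)
        traj = {
            cond: dict(
                zip(
                    sorted(ts),
                    _protein_trajectory(
                        kinetics[g][cond], np.asarray(sorted(ts), dtype=float)
                    ),
                )
            )
            for cond, ts in cond_times.items()
        }
        for j, m in enumerate(p_samples):
            prot[i, j] = math.log2(traj[m.condition][m.time_min])

    tpm *= _lognormal_factors(rng, noise.feature_cv, tpm.shape)
    if log2_sd > 0:
        prot += rng.normal(0.0, log2_sd, prot.shape)

    def table(samples, data, assay):
        cols = pd.MultiIndex.from_tuples(
            [(m.sample_id, "abundance") for m in samples],
            names=["sample", "channel"],
        )
        values = pd.DataFrame(
            data, index=pd.Index(genes, name="feature_id"), columns=cols
        )
        return FeatureTable(values=values, samples=samples, assay=assay)

    return table(t_samples, tpm, "transcriptomics"), table(p_samples, prot, "proteomics")


# ---------------------------------------------------------------------------
# 13C switch labeling


def simulate_labeling_switch(
    pool_sizes: dict[str, float],
    turnover: dict[str, float],
    switch_time_min: float,
    carbons: dict[str, int],
    times,
    seed: int,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Isotopologue time series after a 12C -> 13C medium switch.

    The labeled fraction (>= 1 labeled carbon) follows first-order
    incorporation 1 - exp(-k (t - t_switch)) for t >= t_switch and is 0
    before. Labeled mass is spread over isotopologue bins m = 1..C by a
    binomial mixing rule with per-carbon labeling probability equal to
    the labeled fraction, conditioned on m >= 1; the total pool is
    conserved exactly at every time when ``noise_cv`` is 0 (the default
    stated world).

    Returns a long DataFrame with columns metabolite, time_min,
    n_labeled, signal, n_carbons, switch_time_min.
    """
    rng = np.random.default_rng(seed)
    rows = []
    times = np.asarray(times, dtype=float)
    for met in sorted(pool_sizes):
        pool = pool_sizes[met]
        if pool < 0:
            raise ParameterError(f"negative pool for {met!r}")
        k = turnover[met]
        if k < 0:
            raise ParameterError(f"negative turnover for {met!r}")
        c = carbons[met]
        for t in times:
            dt = t - switch_time_min
            frac = 1.0 - math.exp(-k * dt) if (dt >= 0 and k > 0) else 0.0
            signals = np.zeros(c + 1)
            signals[0] = pool * (1.0 - frac)
            if frac > 0:
                q = frac
                pmf = np.array(
                    [math.comb(c, m) * q**m * (1 - q) ** (c - m) for m in range(c + 1)]
                )
                cond = pmf[1:] / pmf[1:].sum()
                signals[1:] = pool * frac * cond
            if noise_cv > 0:
                signals = signals * _lognormal_factors(rng, noise_cv, c + 1)
            for m in range(c + 1):
                rows.append(
                    {
                        "metabolite": met,
                        "time_min": float(t),
                        "n_labeled": m,
                        "signal": float(signals[m]),
                        "n_carbons": c,
                        "switch_time_min": float(switch_time_min),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# extracellular products


def simulate_extracellular(
    export_rate: float, growth: GrowthModel, times
) -> np.ndarray:
    """Accumulated extracellular concentration (mM) of a secreted product.

    The instantaneous export is proportional to cell density, so
    C(t) = rate * od0 * (Td / ln 2) * (2^(t/Td) - 1), which is monotone
    non-decreasing. ``export_rate`` is in mM per OD600 unit per minute.
    """
    if export_rate < 0:
        raise ParameterError("export_rate must be non-negative")
    t = np.asarray(times, dtype=float)
    td = growth.doubling_time_min
    return export_rate * growth.od0 * (td / math.log(2.0)) * (2.0 ** (t / td) - 1.0)
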