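"""Transcript-protein integration and pipeline orchestration.

Per gene, the transcript and protein log2 fold-change time courses are
joined, response peaks located, and a regulation mode assigned:

- ``transcriptional_up``: both layers rise past the "changed" threshold
  and the mRNA peak precedes (or coincides with) the protein peak — the
  canonical transcription-then-translation lag;
- ``post_transcriptional_down``: protein falls past the threshold while
  mRNA stays flat — consistent with protein degradation rather than
  transcriptional control;
- ``transcript_down_protein_flat``: mRNA falls while protein holds —
  slow protein turnover buffering a transcriptional shutdown;
- ``none`` otherwise.

The "changed" threshold defaults to the gene-level fold-change cutoff
(2-fold) and "flat" to the metabolite cutoff (1.5-fold). Transcript
log2FC is computed directly as log2(mean TPM at t / mean TPM at t0) per
condition — a deliberate replacement of count-model fitting with an
explicit, fully owned computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from oxshift import synthetic
from oxshift.data_model import (
    FeatureTable,
    SignificanceThresholds,
    StudyDesign,
    design_to_frame,
    feature_table_to_frame,
    normalized_series_to_frames,
    write_results,
)
from oxshift.normalize import NormalizationConfig, corrected_matrix, normalize_metabolomics
from oxshift.stats import run_stats


@dataclass
class RegulationCall:
    gene: str
    call: str
    mrna_peak_time_min: float | None
    protein_peak_time_min: float | None
    evidence: dict[str, float]


def peak_time(series: dict[int, float]) -> tuple[int, float] | None:
    """Earliest time attaining the maximum |log2FC|; None if all missing."""
    finite = [(t, v) for t, v in sorted(series.items()) if np.isfinite(v)]
    if not finite:
        return None
    best_t, best_v = finite[0]
    for t, v in finite[1:]:
        if abs(v) > abs(best_v):
            best_t, best_v = t, v
    return best_t, best_v


def classify_regulation(
    mrna: dict[int, float],
    protein: dict[int, float],
    up_fc: float = 2.0,
    flat_fc: float = 1.5,
) -> RegulationCall:
    """Assign a regulation mode from paired log2FC series (same grid)."""
    if set(mrna) != set(protein):
        raise ValueError("mRNA and protein series are on different time grids")
    up = math.log2(up_fc)
    flat = math.log2(flat_fc)

    m_vals = [v for v in mrna.values() if np.isfinite(v)]
    p_vals = [v for v in protein.values() if np.isfinite(v)]
    m_peak = peak_time(mrna)
    p_peak = peak_time(protein)

    m_max = max(m_vals) if m_vals else float("nan")
    m_min = min(m_vals) if m_vals else float("nan")
    m_absmax = max(abs(v) for v in m_vals) if m_vals else float("nan")
    p_max = max(p_vals) if p_vals else float("nan")
    p_min = min(p_vals) if p_vals else float("nan")
    p_absmax = max(abs(v) for v in p_vals) if p_vals else float("nan")

    call = "none"
    if (
        m_vals
        and p_vals
        and m_max >= up
        and p_max >= up
        and m_peak is not None
        and p_peak is not None
        and m_peak[0] <= p_peak[0]
    ):
        call = "transcriptional_up"
    elif p_vals and p_min <= -up and m_vals and m_absmax < flat:
        call = "post_transcriptional_down"
    elif m_vals and m_min <= -up and p_vals and p_absmax < flat:
        call = "transcript_down_protein_flat"
    return RegulationCall(
        gene="",
        call=call,
        mrna_peak_time_min=m_peak[0] if m_peak else None,
        protein_peak_time_min=p_peak[0] if p_peak else None,
        evidence={
            "mrna_max_abs_log2fc": m_absmax,
            "protein_max_abs_log2fc": p_absmax,
        },
    )


def detected_genome_coverage(n_detected: int, n_total: int) -> float:
    """Percent of annotated protein-coding genes with measured
    abundances in both layers (e.g. 1565 of 1890 -> 82.8)."""
    if n_total <= 0 or n_detected < 0 or n_detected > n_total:
        raise ValueError("need 0 <= n_detected <= n_total with n_total > 0")
    return 100.0 * n_detected / n_total


def log2fc_series(
    table: FeatureTable, feature: str, condition: str, log_scale: bool = False
) -> dict[int, float]:
    """Per-time log2 fold change vs. t0 from time-point means of a
    single-channel table. ``log_scale`` marks tables already on the log2
    scale (proteins), where the fold change is a difference of means."""
    metas = [m for m in table.samples if m.condition == condition]
    times = sorted({m.time_min for m in metas})
    ch = table.channel("abundance")
    means = {}
    for t in times:
        ids = [m.sample_id for m in metas if m.time_min == t]
        vals = ch.loc[feature, ids].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        means[t] = float(vals.mean()) if vals.size else float("nan")
    base = means.get(0, float("nan"))
    out = {}
    for t in times:
        if not (np.isfinite(means[t]) and np.isfinite(base)):
            out[t] = float("nan")
        elif log_scale:
            out[t] = means[t] - base
        else:
            out[t] = math.log2(means[t] / base) if base > 0 and means[t] > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


def default_demo_config() -> dict:
    """The bundled pure-simulation demo: a metabolite panel containing a
    MEcDP-like transient (45-fold peak at 15 min, near-baseline by 120)
    and a flat upstream feature, plus a small expression panel with one
    gene per regulation mode."""
    return {
        "design": {"n_replicates": 3, "timepoints": list(synthetic.DEFAULT_TIMEPOINTS)},
        "noise": {"injection_cv": 0.1, "feature_cv": 0.1},
        "metabolites": {
            "MEcDP_like": {
                "O2": {"h_peak": math.log2(45.0), "h_final": math.log2(3.0),
                       "t_peak_min": 15.0},
                "An": {},
            },
            "upstream_flat": {"O2": {}, "An": {}},
            "depleted": {
                "O2": {"h_peak": -3.0, "h_final": -1.0, "t_peak_min": 10.0},
                "An": {},
            },
        },
        "genes": {
            "up_gene": {
                "O2": {"mode": "transcriptional_up",
                       "mrna": {"h_peak": 3.8, "h_final": 3.0, "t_peak_min": 15.0,
                                "rise_rate": 1.0},
                       "k_degradation": 0.01},
                "An": {"mode": "null"},
            },
            "deg_gene": {
                "O2": {"mode": "degradation_down", "k_degradation": 0.01,
                       "deg_induction_fold": 6.0},
                "An": {"mode": "null"},
            },
            "shutoff_gene": {
                "O2": {"mode": "transcript_down_protein_flat",
                       "mrna": {"h_peak": -2.5, "h_final": -2.5, "t_peak_min": 15.0},
                       "k_degradation": 0.003},
                "An": {"mode": "null"},
            },
            "null_gene": {"O2": {"mode": "null"}, "An": {"mode": "null"}},
        },
        "thresholds": {"metabolite_fc": 1.5, "gene_fc": 2.0, "fdr": 0.01},
        "fermentation": {
            "glucose_consumed_mM": 10.0,
            "od600_gain": 0.1,
            "volume_l": 1.0,
            "products": {"ethanol": 18.52, "acetate": 0.1, "gluconate": 0.02},
        },
    }


def _impulse_from_cfg(cfg: dict) -> synthetic.ImpulseParams:
    return synthetic.ImpulseParams(**cfg)


def _kinetics_from_cfg(cfg: dict) -> synthetic.ExpressionKinetics:
    cfg = dict(cfg)
    mrna = cfg.pop("mrna", {})
    return synthetic.ExpressionKinetics(
        mrna_profile=_impulse_from_cfg(mrna), **cfg
    )


def run_pipeline(config: dict, seed: int, out_dir=None) -> dict:
    """Simulate a study and run every analysis stage over it.

    Returns a bundle of DataFrames / objects; when ``out_dir`` is given,
    writes all tables as CSV plus a JSON manifest. Identical config and
    seed give identical outputs.
    """
    from oxshift import carbon_balance as cb
    from oxshift import labeling as lab

    noise = synthetic.NoiseModel(**config.get("noise", {}))
    dsn = config.get("design", {})
    growth = {c: synthetic.GrowthModel() for c in synthetic.DEFAULT_CONDITIONS}
    design = synthetic.make_design(
        n_replicates=dsn.get("n_replicates", 3),
        timepoints=tuple(dsn.get("timepoints", synthetic.DEFAULT_TIMEPOINTS)),
        assays=("metabolomics_intra", "transcriptomics", "proteomics"),
        growth=growth,
    )

    profiles = {
        feat: {cond: _impulse_from_cfg(p) for cond, p in by_cond.items()}
        for feat, by_cond in config.get("metabolites", {}).items()
    }
    metab = synthetic.simulate_metabolomics(
        design, profiles, growth, noise, seed=seed
    )

    kinetics = {
        gene: {cond: _kinetics_from_cfg(k) for cond, k in by_cond.items()}
        for gene, by_cond in config.get("genes", {}).items()
    }
    tpm, prot = synthetic.simulate_expression(design, kinetics, noise, seed=seed + 1)

    # normalization + metabolite statistics
    norm_cfg = NormalizationConfig(low_signal_floor=noise.detection_floor)
    series = normalize_metabolomics(metab, design, norm_cfg)
    thr_cfg = config.get("thresholds", {})
    metab_thr = SignificanceThresholds(
        min_abs_fold_change=thr_cfg.get("metabolite_fc", 1.5),
        max_fdr=thr_cfg.get("fdr", 0.01),
    )
    corrected = pd.DataFrame(
        corrected_matrix(metab, norm_cfg),
        index=metab.features,
        columns=[m.sample_id for m in metab.samples],
    )
    fc_lookup = {s.feature: s for s in series if s.condition == "O2"}
    metab_stats = run_stats(
        corrected, design, condition="O2", thr=metab_thr,
        assay="metabolomics_intra", fold_changes=fc_lookup,
    )

    # expression statistics + integration
    gene_thr = SignificanceThresholds(
        min_abs_fold_change=thr_cfg.get("gene_fc", 2.0),
        max_fdr=thr_cfg.get("fdr", 0.01),
    )
    tpm_matrix = tpm.channel("abundance")
    prot_matrix = prot.channel("abundance")
    tpm_stats = run_stats(tpm_matrix, design, condition="O2", thr=gene_thr,
                          assay="transcriptomics")
    prot_stats = run_stats(prot_matrix, design, condition="O2", thr=gene_thr,
                           assay="proteomics")
    calls = []
    for gene in sorted(kinetics):
        m_fc = log2fc_series(tpm, gene, "O2")
        p_fc = log2fc_series(prot, gene, "O2", log_scale=True)
        call = classify_regulation(m_fc, p_fc,
                                   up_fc=thr_cfg.get("gene_fc", 2.0),
                                   flat_fc=thr_cfg.get("metabolite_fc", 1.5))
        call.gene = gene
        calls.append(call)
    calls_df = pd.DataFrame(
        [
            {
                "gene": c.gene,
                "call": c.call,
                "mrna_peak_time_min": c.mrna_peak_time_min,
                "protein_peak_time_min": c.protein_peak_time_min,
                "mrna_max_abs_log2fc": c.evidence["mrna_max_abs_log2fc"],
                "protein_max_abs_log2fc": c.evidence["protein_max_abs_log2fc"],
            }
            for c in calls
        ]
    ).set_index("gene")

    # labeling demo: aerobic incorporation an order of magnitude below control
    label_df = synthetic.simulate_labeling_switch(
        pool_sizes={"IDP_DMADP": 1.0e6},
        turnover={"IDP_DMADP": 0.005},
        switch_time_min=7.0,
        carbons={"IDP_DMADP": 5},
        times=[0, 7, 10, 13, 16, 19, 30, 60],
        seed=seed + 2,
    )
    control_df = synthetic.simulate_labeling_switch(
        pool_sizes={"IDP_DMADP": 1.0e6},
        turnover={"IDP_DMADP": 0.1},
        switch_time_min=7.0,
        carbons={"IDP_DMADP": 5},
        times=[0, 7, 10, 13, 16, 19, 30, 60],
        seed=seed + 3,
    )
    def rate_of(df):
        s = lab.series_from_frame(df, "IDP_DMADP")
        agg = lab.aggregate_labeled(s)
        return lab.incorporation_rate({t: a[2] for t, a in agg.items()},
                                      s.switch_time_min)
    rate_o2, rate_an = rate_of(label_df), rate_of(control_df)
    ratio, omag = lab.compare_incorporation(rate_o2, rate_an)

    # carbon balance
    ferm = config.get("fermentation", {})
    report = cb.balance_report(
        products=ferm.get("products", {}),
        glucose_consumed_mM=ferm.get("glucose_consumed_mM", 10.0),
        od600_gain=ferm.get("od600_gain", 0.0),
        volume_l=ferm.get("volume_l", 1.0),
    )

    bundle = {
        "design": design,
        "metabolomics": metab,
        "transcripts": tpm,
        "proteins": prot,
        "normalized": series,
        "metab_stats": metab_stats,
        "tpm_stats": tpm_stats,
        "prot_stats": prot_stats,
        "regulation_calls": calls_df,
        "labeling": {"rate_O2": rate_o2, "rate_An": rate_an,
                     "ratio": ratio, "order_of_magnitude_lower": omag},
        "carbon_balance": report,
    }

    if out_dir is not None:
        rep_df, mean_df = normalized_series_to_frames(series)
        balance_rows = [
            {"item": name, "mM": e["mM"], "potential": e["potential"],
             "percent": e["percent"]}
            for name, e in report.products.items()
        ]
        balance_rows.append({"item": "biomass", "mM": np.nan, "potential": np.nan,
                             "percent": report.biomass_percent})
        balance_rows.append({"item": "unaccounted", "mM": np.nan, "potential": np.nan,
                             "percent": report.unaccounted_percent})
        tables = {
            "design": design_to_frame(design).set_index("condition"),
            "metabolomics_raw": feature_table_to_frame(metab),
            "transcripts_tpm": feature_table_to_frame(tpm),
            "proteins_log2": feature_table_to_frame(prot),
            "normalized_series": rep_df,
            "normalized_means": mean_df,
            "anova_metabolites": metab_stats,
            "anova_transcripts": tpm_stats,
            "anova_proteins": prot_stats,
            "regulation_calls": calls_df,
            "carbon_balance": pd.DataFrame(balance_rows).set_index("item"),
        }
        bundle["manifest"] = write_results(tables, out_dir)
    return bundle
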