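"""Normalization chain: isotope ratio, OD correction, baseline fold
change, and the chain's exact invariances."""

import math

import numpy as np
import pytest

from oxshift import synthetic
from oxshift.data_model import FeatureTable
from oxshift.normalize import (
    NormalizationConfig,
    isotope_ratio,
    normalize_metabolomics,
    od_correct,
    relative_to_baseline,
)
from oxshift.synthetic import GrowthModel, ImpulseParams, NoiseModel


class TestIsotopeRatio:
    @pytest.mark.parametrize(
        "parent, reference, expected",
        [
            (2.0e6, 1.0e6, 2.0),
            (6.0e6, 3.0e6, 2.0),  # x3 both channels: unchanged
        ],
    )
    def test_arithmetic_and_injection_invariance(self, parent, reference, expected):
        assert isotope_ratio(parent, reference) == pytest.approx(expected)

    def test_low_signal_masked(self):
        """Signals below the 1e4 a.u. reliability floor become missing."""
        assert np.isnan(isotope_ratio(5.0e3, 1.0e6, floor=1e4))
        assert np.isnan(isotope_ratio(1.0e6, 5.0e3, floor=1e4))

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            isotope_ratio(-1.0, 1e6)


class TestOdCorrect:
    def test_divides_by_od(self):
        assert od_correct(2.0, 0.4) == pytest.approx(5.0)
        assert od_correct(2.0, 1.0) == 2.0

    def test_missing_propagates(self):
        assert np.isnan(od_correct(float("nan"), 0.4))

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            od_correct(2.0, 0.0)


def _table_from_corrected(values_by_sample, design):
    """Build a metabolomics table whose parent/reference ratio equals
    the given corrected-value * OD for each sample (reference 1e6)."""
    import pandas as pd

    samples = design.samples("metabolomics_intra")
    cols, data = [], []
    for m in samples:
        cols += [(m.sample_id, "parent_12C"), (m.sample_id, "reference_13C")]
    rows = {}
    for feat, per_sample in values_by_sample.items():
        row = []
        for m in samples:
            v = per_sample[(m.condition, m.time_min, m.replicate)]
            row += [v * m.od600 * 1.0e6, 1.0e6]
        rows[feat] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=pd.MultiIndex.from_tuples(cols, names=["sample", "channel"]))
    df.index.name = "feature_id"
    return FeatureTable(values=df, samples=samples, assay="metabolomics_intra")


class TestRelativeToBaseline:
    def test_ratio_then_log_then_average(self):
        """Two replicates at 4x and 16x baseline average to log2FC 3,
        not log2 of the averaged fold change (~3.32)."""
        design = synthetic.make_design(
            conditions=("O2",), timepoints=(0, 15), n_replicates=2
        )
        vals = {
            "m": {
                ("O2", 0, "r1"): 1.0,
                ("O2", 0, "r2"): 1.0,
                ("O2", 15, "r1"): 4.0,
                ("O2", 15, "r2"): 16.0,
            }
        }
        table = _table_from_corrected(vals, design)
        series = relative_to_baseline(table, NormalizationConfig())[0]
        assert series.mean_log2fc[15] == pytest.approx(3.0, abs=1e-9)
        assert series.mean_log2fc[0] == 0.0
        assert series.per_replicate_log2fc[(15, "r1")] == pytest.approx(2.0)
        assert series.per_replicate_log2fc[(15, "r2")] == pytest.approx(4.0)

    def test_45_fold_peak(self):
        design = synthetic.make_design(
            conditions=("O2",), timepoints=(0, 15), n_replicates=2
        )
        vals = {
            "MEcDP": {
                ("O2", 0, "r1"): 1.0,
                ("O2", 0, "r2"): 1.0,
                ("O2", 15, "r1"): 45.0,
                ("O2", 15, "r2"): 45.0,
            }
        }
        series = relative_to_baseline(
            _table_from_corrected(vals, design), NormalizationConfig()
        )[0]
        assert series.mean_log2fc[15] == pytest.approx(math.log2(45), abs=1e-9)

    def test_missing_cell_drops_replicate_at_that_time_only(self):
        design = synthetic.make_design(
            conditions=("O2",), timepoints=(0, 15, 30), n_replicates=2
        )
        vals = {
            "m": {
                ("O2", 0, "r1"): 1.0,
                ("O2", 0, "r2"): 1.0,
                ("O2", 15, "r1"): 2.0,
                ("O2", 15, "r2"): 1e-9,  # below floor after scaling
                ("O2", 30, "r1"): 4.0,
                ("O2", 30, "r2"): 4.0,
            }
        }
        series = relative_to_baseline(
            _table_from_corrected(vals, design), NormalizationConfig()
        )[0]
        assert series.n_used[15] == 1
        assert series.mean_log2fc[15] == pytest.approx(1.0)
        assert series.n_used[30] == 2  # r2 still contributes elsewhere

    def test_feature_without_baseline_excluded(self):
        design = synthetic.make_design(
            conditions=("O2",), timepoints=(0, 15), n_replicates=2
        )
        vals = {
            "m": {
                ("O2", 0, "r1"): 1e-9,
                ("O2", 0, "r2"): 1e-9,
                ("O2", 15, "r1"): 2.0,
                ("O2", 15, "r2"): 2.0,
            }
        }
        out = relative_to_baseline(
            _table_from_corrected(vals, design), NormalizationConfig()
        )
        assert out == []

    def test_batch_priority_restricts_to_one_batch(self):
        """A feature mapped to a priority batch ignores other iterations
        (the fourth-iteration rule for low-quality early signals)."""
        import pandas as pd

        from oxshift.data_model import SampleMeta, StudyDesign

        sampling = {}
        for batch, rep in (("b1", "r1"), ("b4", "r2")):
            for t in (0, 15):
                m = SampleMeta("O2", t, rep, od600=1.0, batch=batch)
                sampling[("O2", t, rep, "metabolomics_intra")] = m
        design = StudyDesign(
            conditions=["O2"], timepoints_min=[0, 15],
            replicates={"O2": ["r1", "r2"]}, sampling=sampling,
        )
        vals = {
            "HMBDP": {
                ("O2", 0, "r1"): 1.0, ("O2", 15, "r1"): 2.0,   # b1: log2fc 1
                ("O2", 0, "r2"): 1.0, ("O2", 15, "r2"): 8.0,   # b4: log2fc 3
            }
        }
        table = _table_from_corrected(vals, design)
        cfg = NormalizationConfig(batch_priority={"HMBDP": "b4"})
        series = relative_to_baseline(table, cfg)[0]
        assert series.mean_log2fc[15] == pytest.approx(3.0)
        assert series.n_used[15] == 1


class TestFullChainInvariances:
    def test_noise_free_flat_features_are_zero(
        self, o2_design, growth_o2, flat_table
    ):
        for s in normalize_metabolomics(flat_table, o2_design):
            for t, v in s.mean_log2fc.items():
                assert abs(v) < 1e-9

    def test_injected_peak_recovered_exactly_without_noise(
        self, o2_design, growth_o2, noisefree
    ):
        profiles = {
            "m": {"O2": ImpulseParams(h_peak=3.0, h_final=1.0, t_peak_min=30)}
        }
        tab = synthetic.simulate_metabolomics(
            o2_design, profiles, growth_o2, noisefree, seed=0
        )
        series = normalize_metabolomics(tab, o2_design)[0]
        assert series.mean_log2fc[30] == pytest.approx(3.0, abs=1e-9)

    def test_injection_factor_invariance_per_sample(
        self, o2_design, flat_table
    ):
        """Multiplying both channels of one sample by any c > 0 leaves
        every output unchanged."""
        scaled = flat_table.values.copy()
        sid = flat_table.samples[5].sample_id
        scaled[(sid, "parent_12C")] *= 37.5
        scaled[(sid, "reference_13C")] *= 37.5
        table2 = FeatureTable(scaled, flat_table.samples, flat_table.assay)
        a = normalize_metabolomics(flat_table, o2_design)
        b = normalize_metabolomics(table2, o2_design)
        for sa, sb in zip(a, b):
            for t in sa.mean_log2fc:
                assert sa.mean_log2fc[t] == pytest.approx(
                    sb.mean_log2fc[t], abs=1e-12
                )

    def test_growth_proportional_feature_is_flat(
        self, o2_design, growth_o2, flat_table
    ):
        """Generator parent scales with OD; after OD correction and
        baseline division every log2FC is 0 — growth invariance."""
        for s in normalize_metabolomics(flat_table, o2_design):
            assert s.max_abs_log2fc() < 1e-9

    def test_doubling_all_ods_leaves_output_unchanged(self, growth_o2, noisefree):
        profiles = {"m": {"O2": ImpulseParams(h_peak=2.0, t_peak_min=15)}}
        out = []
        for od0 in (0.35, 0.70):
            g = {"O2": GrowthModel(od0=od0)}
            d = synthetic.make_design(conditions=("O2",), growth=g)
            tab = synthetic.simulate_metabolomics(d, profiles, g, noisefree, seed=0)
            out.append(normalize_metabolomics(tab, d)[0])
        for t in out[0].mean_log2fc:
            assert out[0].mean_log2fc[t] == pytest.approx(
                out[1].mean_log2fc[t], abs=1e-12
            )

    def test_extracellular_skips_od_correction(self, noisefree):
        """Extracellular tables are ratio-corrected but never divided by
        OD: a constant extracellular pool stays flat even as OD grows."""
        g = {"O2": GrowthModel()}
        design = synthetic.make_design(
            conditions=("O2",), assays=("metabolomics_extra",), growth=g
        )
        # constant-abundance feature: cancel the generator's OD factor
        profiles = {"m": {"O2": ImpulseParams()}}
        tab = synthetic.simulate_metabolomics(
            design, profiles, g, noisefree, seed=0, assay="metabolomics_extra"
        )
        series = normalize_metabolomics(tab, design)[0]
        # generator parent tracks OD, so without OD correction the series
        # reproduces the growth curve: log2fc(t) = t/Td
        for t, v in series.mean_log2fc.items():
            assert v == pytest.approx(t / 120.0, abs=1e-9)
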