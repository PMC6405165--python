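"""Normalization, QC, plate fusion, ranking, cross-species rescaling, stars."""

import numpy as np
import pandas as pd
import pytest

from fishscreen import (
    ConditionModel,
    IntensityTrace,
    QCParams,
    SimulationConfig,
    aggregate_measurements,
    build_traces,
    compare_groups,
    cross_species_table,
    fuse_plates,
    normalize_trace,
    qc_filter,
    quantify_plate,
    randomize_layout,
    rank_conditions,
    simulate_plate,
    star_label,
    window_means,
)
from fishscreen.errors import FusionError, NormalizationError


def _trace(well="A1", values=(4.0, 8.0), times=(9.0, 11.0), role="test"):
    return IntensityTrace(well=well, condition="c", channel_role=role,
                          times=np.array(times), values=np.array(values))


class TestNormalizeTrace:
    def test_self_normalization_is_one_at_t_norm(self):
        ref = _trace(values=(2.0, 6.0), role="reference")
        norm = normalize_trace(ref, ref, t_norm=9.2)
        assert norm.value_near(9.2) == 1.0
        assert norm.normalized and norm.normalization_time == 9.0

    def test_scalar_division(self):
        test = _trace(values=(4.0, 8.0))
        ref = _trace(values=(2.0, 5.0), role="reference")
        norm = normalize_trace(test, ref, t_norm=9.4)  # nearest time 9.0 -> ref 2.0
        assert np.allclose(norm.values, [2.0, 4.0])

    def test_nearest_timepoint_no_interpolation(self):
        test = _trace(values=(4.0, 8.0))
        ref = _trace(values=(2.0, 4.0), role="reference")
        norm = normalize_trace(test, ref, t_norm=10.5)  # nearest is 11.0 -> 4.0
        assert np.allclose(norm.values, [1.0, 2.0])

    def test_mismatched_well_and_bad_reference_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_trace(_trace(well="A1"), _trace(well="B2", role="reference"), 9.0)
        with pytest.raises(NormalizationError):
            normalize_trace(_trace(), _trace(values=(0.0, 1.0), role="reference"), 9.0)


def test_normalization_cancels_injection_volume(small_plate):
    """Wells of one condition share a programmed brightness ratio but have
    very different injection volumes; normalization recovers the ratio and
    shrinks the between-well spread."""
    config, plate_layout, models, (series, truth) = small_plate
    measurements = quantify_plate(series, "mCherry")
    agg = aggregate_measurements(measurements)
    traces, failures = build_traces(agg, plate_layout, "mCherry",
                                    config.t_end)
    assert failures.empty
    test_rows = traces[(traces["channel_role"] == "test")
                       & (traces["time_hpf"] == config.times[-1])]
    for condition, expected in (("dim", 0.5), ("bright", 2.0)):
        vals = test_rows[test_rows["condition"] == condition]["value"]
        assert vals.mean() == pytest.approx(expected, rel=0.05)
        # raw means vary with volume; normalized values are tight
        raw = agg[(agg["channel"] == "GFP")
                  & (agg["time_hpf"] == config.times[-1])
                  & (agg["well"].isin(test_rows[test_rows["condition"] == condition]["well"]))]
        assert vals.std() / vals.mean() < 0.5 * raw["mean"].std() / raw["mean"].mean()


def test_reference_trace_is_one_at_normalization_time(small_plate):
    config, plate_layout, _, (series, _) = small_plate
    agg = aggregate_measurements(quantify_plate(series, "mCherry"))
    traces, _ = build_traces(agg, plate_layout, "mCherry", 6.0)
    ref = traces[traces["channel_role"] == "reference"]
    t_star = 6.0  # on the acquisition grid
    assert np.allclose(ref[ref["time_hpf"] == t_star]["value"], 1.0)


def test_qc_drops_dead_wells_with_reasons():
    plate_layout = randomize_layout({"c": 10}, seed=2)
    config = SimulationConfig(image_size=64, t_start=2.0, t_end=8.0, t_step=90.0,
                              z_slices=1, channels=("GFP", "mCherry"),
                              background_level=100.0, noise_sd=10.0,
                              embryo_radius=14, injection_volume_cv=0.2,
                              dead_well_fraction=0.4, seed=17)
    models = {"c": ConditionModel(name="c",
                                  brightness={"GFP": 4000.0, "mCherry": 4000.0})}
    series, truth = simulate_plate(config, plate_layout, models)
    agg = aggregate_measurements(quantify_plate(series, "mCherry"))
    kept, dropped = qc_filter(agg, QCParams(min_area=50, min_signal_ratio=2.0),
                              channel="mCherry")
    assert set(dropped["well"]) == truth.dead_wells()
    assert kept == set(truth.wells) - truth.dead_wells()
    assert all("no signal" in r or "area" in r for r in dropped["reason"])


class TestFusePlates:
    @staticmethod
    def _plate_df(scale=1.0, conditions=("ctrl", "x")):
        t = np.arange(5.0, 15.0, 1.0)
        rows = []
        for c in conditions:
            base = 2.0 if c == "ctrl" else 3.0
            for w in range(3):
                for ti in t:
                    rows.append({"well": f"{c}{w}", "condition": c,
                                 "time_hpf": ti, "value": scale * base * (1 + 0.01 * ti)})
        return pd.DataFrame(rows)

    def test_single_plate_identity(self):
        df = self._plate_df()
        fused, factors = fuse_plates({"p1": df}, "ctrl")
        assert factors == {"p1": 1.0}
        assert np.allclose(fused["value"], df["value"])

    def test_constructed_scaling_recovered_exactly(self):
        fused, factors = fuse_plates(
            {"A": self._plate_df(1.0), "B": self._plate_df(2.0)}, "ctrl")
        assert factors["B"] == pytest.approx(0.5, abs=1e-12)
        a = fused[fused["plate"] == "A"].reset_index(drop=True)
        b = fused[fused["plate"] == "B"].reset_index(drop=True)
        assert np.allclose(a["value"], b["value"])

    def test_hidden_factors_recovered_noiseless(self):
        hidden = {"p1": 1.0, "p2": 1.7, "p3": 0.4}
        plates = {n: self._plate_df(f) for n, f in hidden.items()}
        _, factors = fuse_plates(plates, "ctrl")
        for name, f in hidden.items():
            assert abs(factors[name] - 1.0 / f) < 1e-9

    def test_fusion_fixed_point(self):
        plates = {"p1": self._plate_df(1.0), "p2": self._plate_df(1.7)}
        fused, _ = fuse_plates(plates, "ctrl")
        refused, factors2 = fuse_plates(
            {n: g for n, g in fused.groupby("plate")}, "ctrl")
        assert all(abs(s - 1.0) < 1e-9 for s in factors2.values())

    def test_missing_control_names_plate(self):
        with pytest.raises(FusionError, match="p2"):
            fuse_plates({"p1": self._plate_df(),
                         "p2": self._plate_df(conditions=("x",))}, "ctrl")


class TestRankConditions:
    @staticmethod
    def _traces(means):
        rows = []
        for c, m in means.items():
            for w in range(3):
                rows.append({"well": f"{c}{w}", "condition": c,
                             "time_hpf": 10.0, "value": m})
        return pd.DataFrame(rows)

    def test_descending_order(self):
        out = rank_conditions(self._traces({"A": 3.0, "B": 1.0}), 10.0)
        assert list(out["condition"]) == ["A", "B"]
        assert out["n_wells"].tolist() == [3, 3]

    def test_tie_broken_alphabetically(self):
        out = rank_conditions(self._traces({"zed": 2.0, "abc": 2.0}), 10.0)
        assert list(out["condition"]) == ["abc", "zed"]


def test_ranking_recovers_programmed_brightness_order(small_plate):
    config, plate_layout, models, (series, _) = small_plate
    agg = aggregate_measurements(quantify_plate(series, "mCherry"))
    traces, _ = build_traces(agg, plate_layout, "mCherry", config.t_end)
    ranking = rank_conditions(traces, config.t_end)
    assert list(ranking["condition"]) == ["bright", "dim"]
    assert ranking["mean"].iloc[0] == pytest.approx(2.0, rel=0.1)


class TestCrossSpecies:
    CLASSES = {"Venus": "yellow", "YFPx": "yellow", "eGFP": "green",
               "Cloverx": "green", "mRFP1*": "red"}
    NORMALIZERS = {"yellow": "Venus", "green": "eGFP", "red": "mRFP1*"}
    REFS = {"Venus": 1.2, "eGFP": 1.0, "mRFP1*": 1.0, "YFPx": 0.9, "Cloverx": 1.1}

    def test_yellow_normalizer_pinned_to_reference(self):
        means = {"Venus": 3.7, "YFPx": 1.1, "eGFP": 2.0, "mRFP1*": 0.8}
        table, errors = cross_species_table(means, self.REFS, self.CLASSES,
                                            self.NORMALIZERS)
        assert errors == []
        venus = table[table["condition"] == "Venus"]["normalized_internal"].iloc[0]
        assert venus == 1.2  # pinned exactly to the external value

    def test_proportionality_within_class(self):
        means = {"eGFP": 2.0, "Cloverx": 4.0, "Venus": 1.0, "mRFP1*": 1.0}
        table, _ = cross_species_table(means, self.REFS, self.CLASSES,
                                       self.NORMALIZERS)
        by = dict(zip(table["condition"], table["normalized_internal"]))
        assert by["eGFP"] == pytest.approx(self.REFS["eGFP"])
        assert by["Cloverx"] == pytest.approx(2.0 * self.REFS["eGFP"])

    def test_invariance_to_class_rescaling(self):
        means = {"eGFP": 2.0, "Cloverx": 5.0, "Venus": 1.0, "mRFP1*": 1.0}
        scaled = {c: (7.3 * v if self.CLASSES[c] == "green" else v)
                  for c, v in means.items()}
        t1, _ = cross_species_table(means, self.REFS, self.CLASSES, self.NORMALIZERS)
        t2, _ = cross_species_table(scaled, self.REFS, self.CLASSES, self.NORMALIZERS)
        assert np.allclose(t1["normalized_internal"], t2["normalized_internal"])

    def test_missing_normalizer_excludes_class(self):
        means = {"eGFP": 2.0, "Venus": 1.0}  # no red normalizer
        table, errors = cross_species_table(means, self.REFS, self.CLASSES,
                                            self.NORMALIZERS)
        assert any("red" in e for e in errors)
        assert set(table["colour_class"]) == {"green", "yellow"}


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.00005, "****"), (0.0001, "****"), (0.0005, "***"), (0.001, "***"),
        (0.005, "**"), (0.01, "**"), (0.03, "*"), (0.05, "*"), (0.2, "ns"),
    ])
    def test_legend_mapping(self, p, expected):
        assert star_label(p) == expected

    def test_monotone_step_function(self):
        ps = np.logspace(-6, 0, 200)
        order = {"****": 0, "***": 1, "**": 2, "*": 3, "ns": 4}
        labels = [order[star_label(p)] for p in ps]
        assert all(a <= b for a, b in zip(labels, labels[1:]))

    def test_compare_groups(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(3, 1, 40)
        p, stars = compare_groups(a, b)
        assert p <= 0.0001 and stars == "****"
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


def test_window_means_inclusive_bounds():
    rows = [{"well": "A1", "condition": "c", "time_hpf": t, "value": v}
            for t, v in [(22.9, 100.0), (23.0, 1.0), (30.0, 3.0), (30.1, 100.0)]]
    assert window_means(pd.DataFrame(rows)) == {"c": 2.0}
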