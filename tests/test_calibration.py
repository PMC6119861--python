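import numpy as np
import pytest

from cagetime import (CalibrationOffsets, DatasetBundle, NoiseModel,
                      TimeCourse, calibrate_offsets, classify_dataset,
                      classify_series, classify_tss,
                      generate_calibration_series, nested_sampling_logZ)
from cagetime.calibration import median_replicate_sd
from cagetime.evidence import ModelFit, derive_seed, estimate_noise_sd


def _fake_fit(key, logz, tp=55.0):
    name, _, variant = key.partition("_")
    return ModelFit(model=name, variant=variant, logz=logz, logz_err=0.1,
                    param_names=("a",), post_mean=np.array([1.0]),
                    post_sd=np.array([0.1]), tp_mean=tp, tp_sd=3.0)


def _no_offsets():
    return CalibrationOffsets(offsets={}, n_per_model=100, noise=0.3, seed=0)


class TestClassifyTss:
    def test_clear_winner_is_selected(self):
        fits = {"linear": _fake_fit("linear", -10.0),
                "decay": _fake_fit("decay", -12.0),
                "dip": _fake_fit("dip", -15.0),
                "peak_fast": _fake_fit("peak_fast", -3.0)}
        rec = classify_tss(fits, _no_offsets(), margin=1.0)
        assert rec.label == "peak"
        assert rec.tp_mean == 55.0

    def test_margin_not_met_is_unclassified(self):
        fits = {"linear": _fake_fit("linear", -5.0),
                "decay": _fake_fit("decay", -30.0),
                "dip": _fake_fit("dip", -30.0),
                "peak_fast": _fake_fit("peak_fast", -4.6)}
        rec = classify_tss(fits, _no_offsets(), margin=1.0)
        assert rec.label == "unclassified"
        assert rec.reason == "margin not met"
        assert np.isnan(rec.tp_mean)

    def test_missing_fit_is_unclassified_with_reason(self):
        fits = {"linear": _fake_fit("linear", -5.0),
                "peak_fast": _fake_fit("peak_fast", -3.0)}
        rec = classify_tss(fits, _no_offsets(), margin=1.0)
        assert rec.label == "unclassified"
        assert "missing fits" in rec.reason

    def test_peak_variants_collapse_to_the_better_one(self):
        fits = {"linear": _fake_fit("linear", -20.0),
                "decay": _fake_fit("decay", -22.0),
                "dip": _fake_fit("dip", -25.0),
                "peak_fast": _fake_fit("peak_fast", -8.0, tp=40.0),
                "peak_slow": _fake_fit("peak_slow", -5.0, tp=150.0)}
        rec = classify_tss(fits, _no_offsets(), margin=1.0)
        assert rec.label == "peak"
        assert rec.peak_variant == "slow"
        assert rec.tp_mean == 150.0

    def test_offsets_subtracted_only_at_decision_time(self):
        fits = {"linear": _fake_fit("linear", -6.0),
                "decay": _fake_fit("decay", -20.0),
                "dip": _fake_fit("dip", -20.0),
                "peak_fast": _fake_fit("peak_fast", -4.0)}
        offsets = CalibrationOffsets(offsets={"peak_fast": 5.0},
                                     n_per_model=100, noise=0.3, seed=0)
        rec = classify_tss(fits, offsets, margin=1.0)
        # peak's raw 2-nat advantage is wiped out by the 5-nat offset
        assert rec.label == "linear"
        assert fits["peak_fast"].logz == -4.0  # raw value untouched


class TestCalibrateOffsets:
    def test_deterministic_given_seed(self, models300, times12):
        o1 = calibrate_offsets(models300, times12, n_per_model=100,
                               noise=0.3, n_live=100, seed=5)
        o2 = calibrate_offsets(models300, times12, n_per_model=100,
                               noise=0.3, n_live=100, seed=5)
        assert o1.offsets == o2.offsets

    def test_offsets_finite_positive_and_cover_all_complex_models(self, offsets200):
        assert set(offsets200.offsets) == {"decay", "dip", "peak_fast",
                                           "peak_slow"}
        for v in offsets200.offsets.values():
            assert np.isfinite(v)
        # flexible models carry a real advantage on null data
        assert offsets200.offsets["peak_fast"] > 0

    def test_full_sample_consistent_with_independent_halves(self, models300,
                                                            times12, offsets200):
        halves = [calibrate_offsets(models300, times12, n_per_model=100,
                                    noise=0.3, n_live=100, seed=s)
                  for s in (101, 202)]
        for key in offsets200.offsets:
            h = [o.offsets[key] for o in halves]
            spread = abs(h[0] - h[1]) + 0.5
            assert min(h) - spread <= offsets200.offsets[key] <= max(h) + spread

    def test_round_trips_through_json(self, offsets200, tmp_path):
        path = tmp_path / "offsets.json"
        offsets200.to_json(path)
        back = CalibrationOffsets.from_json(path)
        assert back.offsets == offsets200.offsets
        assert back.n_per_model == offsets200.n_per_model

    def test_noise_free_advantage_over_nested_linear_is_nonnegative(
            self, models300, times12):
        """With noise=0, every complex model can express flat (null) data at
        least as well as linear, so its mean evidence advantage is >= 0."""
        rng = np.random.default_rng(8)
        advantages = {k: [] for k in models300 if k != "linear"}
        for i in range(10):
            params = np.array([rng.uniform(0.0, 10.0), 0.0])
            series = generate_calibration_series(models300["linear"], params,
                                                 times12, noise=0.0)
            nm = NoiseModel(estimate_noise_sd(series.values))
            fits = {k: nested_sampling_logZ(sp, series, nm, n_live=100,
                                            seed=derive_seed(3, i, k))
                    for k, sp in models300.items()}
            for k in advantages:
                advantages[k].append(fits[k].logz - fits["linear"].logz)
        for k, a in advantages.items():
            assert np.mean(a) >= 0.0, f"{k} disadvantaged on nested null data"


class TestClassifySeries:
    def test_recovers_a_strong_planted_peak(self, models300, times12, offsets200):
        spec = models300["peak_fast"]
        series = generate_calibration_series(
            spec, np.array([1.0, 7.0, 10.0, 50.0, 0.08, 0.02]), times12, 0.3)
        series.tss_id = "planted"
        rec, fits = classify_series(series, models300, offsets200,
                                    margin=1.0, n_live=100, master_seed=4)
        assert rec.label == "peak"
        assert abs(rec.tp_mean - 60.0) < 15.0
        assert set(rec.corrected_logz) == set(fits)

    def test_invariant_to_replicate_ordering(self, models300, times12, offsets200):
        spec = models300["decay"]
        series = generate_calibration_series(
            spec, np.array([1.0, 6.0, 0.02]), times12, 0.3)
        series.tss_id = "rep-order"
        rec1, _ = classify_series(series, models300, offsets200, master_seed=4)
        series.values = series.values[::-1].copy()
        rec2, _ = classify_series(series, models300, offsets200, master_seed=4)
        assert rec1.label == rec2.label == "decay"
        assert rec1.corrected_logz == rec2.corrected_logz


class TestClassifyDataset:
    def test_empty_bundle_gives_empty_records(self, offsets200):
        bundle = DatasetBundle(dataset_id="DS1", timecourses=[])
        assert classify_dataset(bundle, offsets200) == []

    def test_constant_tss_reported_degenerate(self, offsets200, times12):
        tc = TimeCourse(tss_id="p1", gene_id="g1", biotype="coding",
                        dataset_id="DS1", times=times12,
                        expression=np.full((3, times12.size), 20.0))
        records = classify_dataset(DatasetBundle(dataset_id="DS1",
                                                 timecourses=[tc]), offsets200)
        assert records[0].label == "unclassified"
        assert "degenerate" in records[0].reason

    def test_invariant_to_tss_ordering(self, models300, times12, offsets200):
        rng = np.random.default_rng(12)
        tcs = []
        for i in range(4):
            curve = 15.0 + 40.0 * np.exp(-0.02 * times12) \
                + rng.normal(0, 1.0, size=(3, times12.size))
            tcs.append(TimeCourse(tss_id=f"p{i}", gene_id=f"g{i}",
                                  biotype="coding", dataset_id="DS1",
                                  times=times12,
                                  expression=np.clip(curve, 0, None)))
        fwd = classify_dataset(DatasetBundle(dataset_id="DS1", timecourses=tcs),
                               offsets200, models=models300, master_seed=6)
        rev = classify_dataset(DatasetBundle(dataset_id="DS1",
                                             timecourses=tcs[::-1]),
                               offsets200, models=models300, master_seed=6)
        assert {r.tss_id: r.label for r in fwd} == \
            {r.tss_id: r.label for r in rev}

    def test_classified_fraction_rises_as_noise_falls(self, models300, times12):
        """Sweep replicate noise {0.8, 0.4, 0.1}: lower noise means more
        series carry decisive evidence."""
        fractions = []
        for noise in (0.8, 0.4, 0.1):
            offsets = calibrate_offsets(models300, times12, n_per_model=100,
                                        noise=noise, n_live=100, seed=31)
            rng = np.random.default_rng(13)
            n_classified = 0
            gen = [("decay", models300["decay"]), ("peak", models300["peak_fast"])]
            n_series = 30
            for i in range(n_series):
                cls, spec = gen[i % 2]
                params = rng.uniform(spec.lower, spec.upper)
                series = generate_calibration_series(spec, params, times12, noise)
                series.tss_id = f"s{i}"
                rec, _ = classify_series(series, models300, offsets,
                                         margin=1.0, n_live=100, master_seed=14)
                n_classified += rec.classified
            fractions.append(n_classified / n_series)
        assert fractions[0] < fractions[2]
        assert sorted(fractions) == fractions


def test_median_replicate_sd_matches_construction(times12):
    # replicates at +/-0.3 around a trend, normalized span 10 over range 30
    rng = np.random.default_rng(3)
    tcs = []
    for i in range(5):
        base = np.linspace(10, 40, times12.size)
        expr = np.stack([base, base + 0.9, base - 0.9])
        tcs.append(TimeCourse(tss_id=f"p{i}", gene_id=f"g{i}", biotype="coding",
                              dataset_id="DS1", times=times12, expression=expr))
    bundle = DatasetBundle(dataset_id="DS1", timecourses=tcs)
    # normalized scale multiplies by 10/30, so offsets become 0.3
    assert median_replicate_sd(bundle) == pytest.approx(0.3 * np.sqrt(2 / 3))
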