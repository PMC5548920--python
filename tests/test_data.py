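"""Arbitrary-unit data handling and the shared normalisation rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import relfit as rf
from relfit.data import normalize_simulation_like_data, reference_value
from relfit.exceptions import InputError, NormalizationError


class TestReadDataset:
    def test_valid_file_roundtrip(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "condition,observable,time,replicate,value\n"
            "ctrl,obs1,0.0,r1,2.0\nctrl,obs1,1.0,r1,4.0\nctrl,obs1,2.0,r1,6.0\n"
        )
        ds = rf.read_dataset(p, rf.NormalizationSpec("average"))
        assert len(ds) == 3 and not ds.normalized
        assert ds.values() == pytest.approx([2.0, 4.0, 6.0])

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("condition,observable,time,value\nctrl,obs1,0.0,2.0\n")
        with pytest.raises(InputError, match="replicate"):
            rf.read_dataset(p)

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "condition,observable,time,replicate,value\n"
            "ctrl,obs1,0.0,r1,2.0\nctrl,obs1,0.0,r1,3.0\n"
        )
        with pytest.raises(InputError, match="duplicate"):
            rf.read_dataset(p)

    def test_unparsable_value_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("condition,observable,time,replicate,value\nctrl,obs1,0.0,r1,oops\n")
        with pytest.raises(InputError, match="row 0"):
            rf.read_dataset(p)


class TestReferenceValue:
    @pytest.mark.parametrize(
        "scheme,expected",
        [("average", 4.0), ("max", 6.0), ("none", 1.0)],
    )
    def test_schemes(self, scheme, expected):
        spec = rf.NormalizationSpec(scheme)
        assert reference_value([2.0, 4.0, 6.0], spec) == pytest.approx(expected)

    def test_reference_point_selector(self):
        spec = rf.NormalizationSpec("reference_point", ("ctrl", 0.0))
        ctx = {("ctrl", 0.0): 1}
        assert reference_value([5.0, 2.0, 7.0], spec, ctx) == pytest.approx(2.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(NormalizationError):
            reference_value([0.0, 0.0], rf.NormalizationSpec("average"))

    def test_empty_group_rejected(self):
        with pytest.raises(NormalizationError):
            reference_value([], rf.NormalizationSpec("average"))


class TestNormalizeData:
    def test_average_division(self, simple_dataset):
        out = rf.normalize_data(simple_dataset)
        assert out.normalized
        vals = out.values()
        assert vals[:3] == pytest.approx([0.5, 1.0, 1.5])
        assert vals[3:6] == pytest.approx([0.5, 1.0, 1.5])  # r2 scaled by its own mean

    def test_max_division(self, simple_dataset):
        ds = rf.Dataset(simple_dataset.points, rf.NormalizationSpec("max"))
        out = rf.normalize_data(ds)
        assert out.values()[:3] == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_scheme_none_identity(self, simple_dataset):
        ds = rf.Dataset(simple_dataset.points, rf.NormalizationSpec("none"))
        out = rf.normalize_data(ds)
        assert out.values() == pytest.approx(simple_dataset.values())

    def test_mean_one_invariant_per_group(self, simple_dataset):
        out = rf.normalize_data(simple_dataset)
        vals = out.values()
        for _, idx in out.groups().items():
            assert np.mean(vals[idx]) == pytest.approx(1.0, abs=1e-12)

    def test_double_normalisation_rejected(self, simple_dataset):
        out = rf.normalize_data(simple_dataset)
        with pytest.raises(InputError):
            rf.normalize_data(out)

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(min_value=1e-6, max_value=1e6),
        scheme=st.sampled_from(["average", "max"]),
    )
    def test_scale_invariance_of_replicate_groups(self, scale, scheme):
        """Multiplying one replicate group by c > 0 leaves the output unchanged."""
        points = tuple(
            rf.DataPoint("ctrl", obs, t, rep, v)
            for obs, rep, vals in [
                ("obs1", "r1", [2.0, 4.0, 6.0]),
                ("obs1", "r2", [10.0, 20.0, 30.0]),
                ("obs2", "r1", [1.0, 3.0, 5.0]),
            ]
            for t, v in zip([0.0, 1.0, 2.0], vals)
        )
        base = rf.Dataset(points, rf.NormalizationSpec(scheme))
        scaled_points = tuple(
            rf.DataPoint(p.condition, p.observable, p.time, p.replicate,
                         p.value * scale if (p.observable, p.replicate) == ("obs1", "r1") else p.value)
            for p in base.points
        )
        scaled = rf.Dataset(scaled_points, rf.NormalizationSpec(scheme))
        np.testing.assert_allclose(
            rf.normalize_data(base).values(), rf.normalize_data(scaled).values(), rtol=1e-12
        )


class TestNormalizeSimulationLikeData:
    def test_same_rule_as_data(self, simple_dataset):
        sim = {("ctrl", "obs1", t): v for t, v in zip([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])}
        sim.update({("ctrl", "obs2", t): 1.0 for t in [0.0, 1.0, 2.0]})
        out = normalize_simulation_like_data(sim, simple_dataset)
        assert out[:3] == pytest.approx([0.5, 1.0, 1.5])

    def test_proportional_data_gives_equal_normalisation(self, simple_dataset):
        # data = c * sim  ->  normalised data == normalised sim for any c > 0
        c = 123.4
        sim = {
            (p.condition, p.observable, float(p.time)): p.value / c
            for p in simple_dataset.points
        }
        norm_sim = normalize_simulation_like_data(sim, simple_dataset)
        norm_data = rf.normalize_data(simple_dataset).values()
        np.testing.assert_allclose(norm_sim, norm_data, rtol=1e-12)

    def test_reference_point_selector_divides_by_that_point(self, simple_dataset):
        ds = rf.Dataset(simple_dataset.points, rf.NormalizationSpec("reference_point", ("ctrl", 0.0)))
        sim = {
            (p.condition, p.observable, float(p.time)): 2.0 + p.time
            for p in ds.points
        }
        out = normalize_simulation_like_data(sim, ds)
        assert out[:3] == pytest.approx([1.0, 1.5, 2.0])

    def test_nonpositive_simulated_reference_raises(self, simple_dataset):
        sim = {
            (p.condition, p.observable, float(p.time)): -1.0 for p in simple_dataset.points
        }
        with pytest.raises(NormalizationError):
            normalize_simulation_like_data(sim, simple_dataset)

    def test_missing_simulated_point_rejected(self, simple_dataset):
        with pytest.raises(InputError):
            normalize_simulation_like_data({}, simple_dataset)
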