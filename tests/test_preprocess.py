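from dataclasses import replace

import numpy as np
import pytest

from cytoda import preprocess as pp
from cytoda import synthetic_data as sim
from cytoda.fcs_io import ChannelInfo, EventTable, ValidationError


@pytest.fixture(scope="module")
def preprocessed(small_truth, small_result, small_gating):
    """Run normalize -> gate -> threshold -> debarcode once, keeping the
    index bookkeeping needed to score against per-event truth."""
    table = small_result.table
    normalized, report = pp.normalize_beads(table, small_gating)
    assert report.attrs["n_dropped_events"] == 0
    cf = small_gating.cofactor
    keep = np.ones(table.n_events, bool)
    for name in small_gating.dna_channels:
        v = np.arcsinh(normalized.column(name) / cf)
        keep &= (v >= small_gating.dna_low) & (v <= small_gating.dna_high)
    el = normalized.column("EventLength")
    lo, hi = small_gating.event_length_range
    keep &= (el >= lo) & (el <= hi)
    keep &= ~pp._bead_mask(normalized, small_gating)
    idx = np.flatnonzero(keep)
    gated = normalized.take_events(idx)
    scheme = small_truth.barcode_scheme()
    cutoffs = pp.estimate_barcode_thresholds(gated, scheme)
    assignment, yield_report = pp.debarcode(gated, scheme, cutoffs)
    return {
        "gated": gated,
        "idx": idx,
        "cutoffs": cutoffs,
        "assignment": assignment,
        "yield": yield_report,
        "scheme": scheme,
    }


class TestNormalizeBeads:
    def test_flat_drift_identity(self, small_truth, small_gating):
        truth = replace(
            small_truth,
            drift_profile=sim.FLAT_DRIFT,
            spillover_used=None,
            bead_cv=1e-12,
        )
        res = sim.simulate_experiment(truth)
        out, _ = pp.normalize_beads(res.table, small_gating)
        np.testing.assert_allclose(out.values, res.table.values, atol=1e-9)

    def test_linear_decay_corrected(self, small_gating):
        truth = sim.default_truth(
            n_per_group=(4, 4),
            n_events=2000,
            n_populations=5,
            n_markers=8,
            n_lineage=6,
            spill=0.0,
            drift=sim.DriftProfile(multipliers=(1.0, 0.5)),
            seed=9,
        )
        res = sim.simulate_experiment(truth)

        def interval_cv(table):
            beads = pp._bead_mask(table, small_gating)
            t = table.time
            width = small_gating.bead_interval_seconds
            iv = np.minimum(
                (t / width).astype(int), int(np.ceil(t.max() / width)) - 1
            )
            meds = []
            vals = table.matrix(table.names_for_role("bead"))
            for i in range(iv.max() + 1):
                m = beads & (iv == i)
                if m.sum() >= small_gating.min_beads_per_interval:
                    meds.append(np.median(vals[m], axis=0).mean())
            meds = np.array(meds)
            return meds.std() / meds.mean()

        assert interval_cv(res.table) > 0.15
        out, _ = pp.normalize_beads(res.table, small_gating)
        assert interval_cv(out) < 0.02

    def test_sparse_interval_excluded_and_reported(self):
        # hand-built table: 2 intervals of 100 s, second has only 30 beads
        n1, n2 = 80, 30
        rng = np.random.default_rng(0)
        channels = [
            ChannelInfo(metal="140Ce", role="bead"),
            ChannelInfo(metal="191Ir", marker="DNA1", role="dna"),
            ChannelInfo(metal="Time", role="time"),
        ]
        t = np.concatenate([np.linspace(0, 99, n1), np.linspace(100, 199, n2)])
        vals = np.column_stack(
            [
                rng.lognormal(np.log(500), 0.05, n1 + n2),
                np.full(n1 + n2, 0.1),
                t,
            ]
        )
        table = EventTable(vals, channels)
        gating = pp.GatingConfig(
            dna_channels=("191Ir",),
            bead_channels=["140Ce"],
            bead_interval_seconds=100.0,
            min_beads_per_interval=50,
        )
        out, report = pp.normalize_beads(table, gating)
        assert report.attrs["n_dropped_events"] == n2
        assert bool(report.loc[report["interval"] == 1, "excluded"].iloc[0])
        assert out.n_events == n1

    def test_no_beads_is_error(self, small_gating):
        channels = [
            ChannelInfo(metal="140Ce", role="bead"),
            ChannelInfo(metal="191Ir", marker="DNA1", role="dna"),
            ChannelInfo(metal="Time", role="time"),
        ]
        vals = np.column_stack(
            [np.full(100, 0.1), np.full(100, 300.0), np.linspace(0, 99, 100)]
        )
        with pytest.raises(ValidationError, match="bead"):
            pp.normalize_beads(EventTable(vals, channels), small_gating)


class TestGateSinglets:
    def _table(self, dna, elen):
        channels = [
            ChannelInfo(metal="191Ir", marker="DNA1", role="dna"),
            ChannelInfo(metal="EventLength", role="event_length"),
            ChannelInfo(metal="Time", role="time"),
        ]
        n = len(dna)
        vals = np.column_stack([dna, elen, np.arange(n, dtype=float)])
        return EventTable(vals, channels)

    def test_short_event_removed(self):
        # event length 9 with range [10, 150] must go
        tab = self._table([300.0, 300.0], [9.0, 20.0])
        g = pp.GatingConfig(dna_channels=("191Ir",))
        out = pp.gate_singlets(tab, g)
        assert out.n_events == 1
        assert out.column("EventLength")[0] == 20.0

    def test_dna_negative_removed(self):
        tab = self._table([0.5, 300.0], [20.0, 20.0])
        g = pp.GatingConfig(dna_channels=("191Ir",))
        assert pp.gate_singlets(tab, g).n_events == 1

    def test_all_in_gate_unchanged(self):
        tab = self._table([300.0, 280.0, 310.0], [20.0, 30.0, 40.0])
        g = pp.GatingConfig(dna_channels=("191Ir",))
        out = pp.gate_singlets(tab, g)
        np.testing.assert_array_equal(out.values, tab.values)

    def test_empty_result_warns_not_errors(self):
        tab = self._table([0.5, 0.4], [20.0, 20.0])
        g = pp.GatingConfig(dna_channels=("191Ir",))
        with pytest.warns(UserWarning, match="every event"):
            out = pp.gate_singlets(tab, g)
        assert out.n_events == 0


class TestBarcodeThresholds:
    def test_cutoff_between_modes(self, preprocessed, small_truth):
        # every cutoff must separate arcsinh(off median) from arcsinh(on)
        lo = np.arcsinh(small_truth.barcode_off_median / 5.0)
        hi = np.arcsinh(small_truth.barcode_on_median / 5.0)
        for cut in preprocessed["cutoffs"].values():
            assert lo < cut < hi

    def test_constant_channel_warns(self):
        channels = [
            ChannelInfo(metal="89Y", role="barcode"),
            ChannelInfo(metal="113In", role="barcode"),
            ChannelInfo(metal="Time", role="time"),
        ]
        vals = np.column_stack(
            [np.full(50, 5.0), np.full(50, 5.0), np.arange(50, dtype=float)]
        )
        scheme = pp.BarcodeScheme(
            barcode_channels=["89Y", "113In"],
            codes={"S1": [1, 0], "S2": [0, 1]},
        )
        with pytest.warns(UserWarning, match="unimodal"):
            pp.estimate_barcode_thresholds(EventTable(vals, channels), scheme)

    def test_scaling_shifts_cutoff_monotonically(self):
        rng = np.random.default_rng(1)
        off = rng.lognormal(np.log(1.0), 0.4, 500)
        on = rng.lognormal(np.log(200.0), 0.4, 500)
        v = np.concatenate([off, on])
        cut1, _ = pp._split_1d(np.arcsinh(v / 5.0))
        cut2, _ = pp._split_1d(np.arcsinh(3.0 * v / 5.0))
        assert cut2 > cut1


class TestDebarcode:
    def test_exact_match_assigned(self):
        channels = [
            ChannelInfo(metal="89Y", role="barcode"),
            ChannelInfo(metal="113In", role="barcode"),
            ChannelInfo(metal="Time", role="time"),
        ]
        vals = np.array([[200.0, 1.0, 0.0]])
        scheme = pp.BarcodeScheme(
            barcode_channels=["89Y", "113In"],
            codes={"S1": [1, 0], "S2": [0, 1]},
        )
        cutoffs = {"89Y": 2.0, "113In": 2.0}
        assign, _ = pp.debarcode(EventTable(vals, channels), scheme, cutoffs)
        assert assign[0] == "S1"

    def test_all_on_pattern_unassigned(self):
        channels = [
            ChannelInfo(metal="89Y", role="barcode"),
            ChannelInfo(metal="113In", role="barcode"),
            ChannelInfo(metal="Time", role="time"),
        ]
        vals = np.array([[200.0, 200.0, 0.0]])
        scheme = pp.BarcodeScheme(
            barcode_channels=["89Y", "113In"],
            codes={"S1": [1, 0], "S2": [0, 1]},
        )
        assign, report = pp.debarcode(
            EventTable(vals, channels), scheme, {"89Y": 2.0, "113In": 2.0}
        )
        assert assign[0] == ""
        assert report.attrs["n_unassigned"] == 1

    def test_low_separation_unassigned(self):
        channels = [
            ChannelInfo(metal="89Y", role="barcode"),
            ChannelInfo(metal="113In", role="barcode"),
            ChannelInfo(metal="Time", role="time"),
        ]
        # on/off straddle the cutoffs but with tiny arcsinh separation
        vals = np.array([[11.0, 9.0, 0.0]])
        scheme = pp.BarcodeScheme(
            barcode_channels=["89Y", "113In"],
            codes={"S1": [1, 0], "S2": [0, 1]},
        )
        cut = float(np.arcsinh(10.0 / 5.0))
        assign, _ = pp.debarcode(
            EventTable(vals, channels), scheme, {"89Y": cut, "113In": cut}
        )
        assert assign[0] == ""

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            pp.BarcodeScheme(
                barcode_channels=["a", "b"],
                codes={"S1": [1, 0], "S2": [1, 0]},
            )

    def test_synthetic_run_accuracy(self, preprocessed, small_result):
        tr = small_result.per_event_truth.iloc[preprocessed["idx"]]
        assign = preprocessed["assignment"]
        nond = (~tr.is_doublet.to_numpy()) & (~tr.is_bead.to_numpy())
        correct = assign[nond] == tr.sample_id.to_numpy()[nond]
        assert correct.mean() >= 0.99
        cross = (assign[nond] != "") & ~correct
        assert cross.mean() <= 0.005

    def test_permutation_equivariance(self, preprocessed):
        gated, scheme = preprocessed["gated"], preprocessed["scheme"]
        cutoffs = preprocessed["cutoffs"]
        renamed = {f"X{sid}": code for sid, code in scheme.codes.items()}
        scheme2 = pp.BarcodeScheme(
            barcode_channels=scheme.barcode_channels,
            codes=renamed,
            min_hamming=scheme.min_hamming,
        )
        a1, _ = pp.debarcode(gated, scheme, cutoffs)
        a2, _ = pp.debarcode(gated, scheme2, cutoffs)
        relabeled = np.array(
            [f"X{s}" if s else "" for s in a1], dtype=object
        )
        np.testing.assert_array_equal(relabeled, a2)


class TestSpillover:
    def _bead_table(self, values_by_channel):
        names = list(values_by_channel)
        n = len(next(iter(values_by_channel.values())))
        channels = [ChannelInfo(metal=m, role="marker") for m in names]
        channels.append(ChannelInfo(metal="Time", role="time"))
        vals = np.column_stack(
            [values_by_channel[m] for m in names] + [np.arange(n, dtype=float)]
        )
        return EventTable(vals, channels)

    def test_zero_offtarget_gives_identity(self):
        tabs = {
            "A": self._bead_table({"A": np.full(100, 500.0), "B": np.zeros(100)}),
            "B": self._bead_table({"A": np.zeros(100), "B": np.full(100, 500.0)}),
        }
        S = pp.estimate_spillover(tabs)
        np.testing.assert_array_equal(S.S, np.eye(2))

    def test_known_spill_recovered(self):
        rng = np.random.default_rng(2)
        true = np.array([[1.0, 0.05], [0.02, 1.0]])
        tabs = {}
        for i, name in enumerate(["A", "B"]):
            clean = np.zeros((3000, 2))
            clean[:, i] = rng.lognormal(np.log(500), 0.2, 3000)
            mixed = clean @ true
            tabs[name] = self._bead_table({"A": mixed[:, 0], "B": mixed[:, 1]})
        S = pp.estimate_spillover(tabs)
        np.testing.assert_allclose(S.S, true, atol=0.005)

    def test_unstained_channel_is_error(self):
        tabs = {"A": self._bead_table({"A": np.zeros(10), "B": np.zeros(10)})}
        with pytest.raises(ValidationError, match="median <= 0"):
            pp.estimate_spillover(tabs)


class TestCompensate:
    def _two_channel_table(self, rows):
        channels = [
            ChannelInfo(metal="A", role="marker"),
            ChannelInfo(metal="B", role="marker"),
            ChannelInfo(metal="Time", role="time"),
        ]
        rows = np.asarray(rows, float)
        vals = np.column_stack([rows, np.arange(len(rows), dtype=float)])
        return EventTable(vals, channels)

    def test_identity_noop(self):
        tab = self._two_channel_table([[100.0, 50.0]])
        S = pp.SpilloverMatrix(channels=["A", "B"], S=np.eye(2))
        out = pp.compensate(tab, S)
        np.testing.assert_array_equal(out.values, tab.values)

    def test_printed_two_channel_example(self):
        # S = [[1, 0.1], [0, 1]], observed (100, 110) -> (100, 100)
        tab = self._two_channel_table([[100.0, 110.0]])
        S = pp.SpilloverMatrix(channels=["A", "B"], S=[[1.0, 0.1], [0.0, 1.0]])
        out = pp.compensate(tab, S)
        np.testing.assert_allclose(out.values[0, :2], [100.0, 100.0], atol=1e-9)

    def test_nonnegativity_contract(self):
        tab = self._two_channel_table([[0.0, 5.0]])
        S = pp.SpilloverMatrix(channels=["A", "B"], S=[[1.0, 0.1], [0.0, 1.0]])
        out = pp.compensate(tab, S)
        np.testing.assert_allclose(out.values[0, :2], [0.0, 5.0], atol=1e-9)
        assert out.values.min() >= 0

    def test_nnls_when_inversion_goes_negative(self):
        # observed signal below the spill line: plain inversion would give
        # a negative x[1]; NNLS must clip at the boundary
        tab = self._two_channel_table([[100.0, 2.0]])
        S = pp.SpilloverMatrix(channels=["A", "B"], S=[[1.0, 0.1], [0.0, 1.0]])
        out = pp.compensate(tab, S)
        assert out.values[0, 1] == 0.0
        assert out.values.min() >= 0

    def test_recovery_on_synthetic(self, small_truth, small_result):
        comp = pp.compensate(small_result.table, small_truth.spillover_used)
        idx = [
            small_result.table.channel_index(c)
            for c in small_result.signal_channels
        ]
        est = comp.values[:, idx]
        true = small_result.clean_signal
        nz = true > 1.0
        rel = np.abs(est[nz] - true[nz]) / true[nz]
        assert np.median(rel) < 0.02

    def test_transformed_table_rejected(self, tiny_table):
        trans = pp.transform_arcsinh(tiny_table)
        S = pp.SpilloverMatrix(channels=["M01"], S=np.eye(1))
        with pytest.raises(ValidationError, match="untransformed"):
            pp.compensate(trans, S)


class TestTransform:
    def test_zero_maps_to_zero(self, tiny_table):
        tab = tiny_table.copy()
        tab.values[0, 0] = 0.0
        out = pp.transform_arcsinh(tab)
        assert out.values[0, 0] == 0.0

    def test_closed_form(self, tiny_table):
        tab = tiny_table.copy()
        tab.values[0, 0] = 5.0
        out = pp.transform_arcsinh(tab, pp.TransformConfig(cofactor=5.0))
        assert out.values[0, 0] == pytest.approx(np.arcsinh(1.0))
        assert out.values[0, 0] == pytest.approx(0.881374, abs=1e-6)

    def test_monotone(self):
        v = np.linspace(0, 1000, 101)
        t = np.arcsinh(v / 5.0)
        assert np.all(np.diff(t) > 0)

    def test_double_transform_guard(self, tiny_table):
        once = pp.transform_arcsinh(tiny_table)
        with pytest.raises(ValidationError, match="already transformed"):
            pp.transform_arcsinh(once)

    def test_time_and_length_untouched(self, tiny_table):
        out = pp.transform_arcsinh(tiny_table)
        np.testing.assert_array_equal(out.time, tiny_table.time)
        np.testing.assert_array_equal(
            out.column("EventLength"), tiny_table.column("EventLength")
        )


class TestPipelineConservation:
    def test_five_way_accounting(self, small_truth, small_result, small_gating):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prov = pp.preprocess_pipeline(
                small_result.table,
                small_gating,
                small_truth.barcode_scheme(),
                small_truth.spillover_used,
            )
        parts = (
            prov["n_assigned"]
            + prov["n_unassigned"]
            + prov["n_excluded_by_gate"]
            + prov["n_excluded_interval"]
            + prov["n_bead"]
        )
        assert parts == prov["n_input"]
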