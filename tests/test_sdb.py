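"""AHI / REI, ensemble desaturation averaging, search window and hypoxic burden."""

import math

import numpy as np
import pytest

from hypnodense.core import Hypnogram
from hypnodense.errors import HypnodensityError
from hypnodense.sdb import (
    EnsembleCurve,
    OximetryTrace,
    RespiratoryEvent,
    SearchWindow,
    ahi,
    classify_rem_related_osa,
    ensemble_average_desaturation,
    hypoxic_burden,
    rei,
    search_window,
    validate_events,
)


def _events_every(spacing_s, n, duration_s=20.0, first_start=60.0):
    return [
        RespiratoryEvent("hypopnea", first_start + i * spacing_s, duration_s)
        for i in range(n)
    ]


def _hypnogram_hours(stage="N2", hours=6.0):
    return Hypnogram((stage,) * int(hours * 120))


class TestEventValidation:
    def test_overlap_rejected_and_sorting_applied(self):
        ev = [
            RespiratoryEvent("apnea", 100, 20),
            RespiratoryEvent("hypopnea", 50, 20),
        ]
        out = validate_events(ev)
        assert out[0].start_s == 50
        with pytest.raises(HypnodensityError):
            validate_events(
                [RespiratoryEvent("apnea", 0, 30), RespiratoryEvent("apnea", 20, 30)]
            )

    def test_bad_kind_and_duration_rejected(self):
        with pytest.raises(HypnodensityError):
            RespiratoryEvent("snore", 0, 10)
        with pytest.raises(HypnodensityError):
            RespiratoryEvent("apnea", 0, 0)


class TestAhiRei:
    def test_event_count_over_tst(self):
        hyp = _hypnogram_hours(hours=6.0)
        events = _events_every(300, 60)
        assert ahi(events, hyp).ahi_total == pytest.approx(10.0)

    def test_no_events(self):
        assert ahi([], _hypnogram_hours()).ahi_total == 0.0

    def test_state_split_arithmetic(self):
        # 5 h NREM then 1 h REM; 5 events end in NREM, 10 in REM
        stages = ("N2",) * 600 + ("R",) * 120
        hyp = Hypnogram(stages)
        nrem_events = _events_every(600, 5, first_start=100)
        rem_events = _events_every(300, 10, first_start=5 * 3600 + 10)
        idx = ahi(nrem_events + rem_events, hyp)
        assert idx.ahi_nrem == pytest.approx(1.0)
        assert idx.ahi_rem == pytest.approx(10.0)
        assert idx.ahi_total == pytest.approx(15 / 6)

    def test_rei_and_identity_with_tst(self):
        assert rei(_events_every(100, 60), 8.0) == pytest.approx(7.5)
        hyp = _hypnogram_hours(hours=6.0)
        events = _events_every(300, 60)
        assert rei(events, 6.0) == pytest.approx(ahi(events, hyp).ahi_total)

    def test_rei_scales_with_wake_fraction(self):
        hyp = _hypnogram_hours(hours=6.0)
        events = _events_every(300, 60)
        a = ahi(events, hyp).ahi_total
        assert rei(events, 8.0) == pytest.approx(a * 6.0 / 8.0)
        assert rei(events, 8.0) <= a


def _rect_desat_trace(
    baseline=95.0, depth=4.0, dip_start=300.0, dip_len=30.0,
    total_s=3600.0, rate_hz=1.0,
):
    t = np.arange(0, total_s + 1e-9, 1.0 / rate_hz)
    spo2 = np.full(t.size, baseline)
    spo2[(t >= dip_start) & (t < dip_start + dip_len)] -= depth
    return OximetryTrace(spo2, rate_hz)


class TestEnsembleAverage:
    def test_identical_events_average_to_single_segment(self):
        trace = _rect_desat_trace()
        ev = [RespiratoryEvent("apnea", 280, 15)]  # terminates at 295
        curve = ensemble_average_desaturation(trace, ev, (60, 120))
        assert curve.n_events_used == 1
        nadir_depth = 95.0 - curve.spo2_pct.min()
        assert nadir_depth == pytest.approx(4.0)

    def test_mean_of_two_depths(self):
        t = np.arange(0, 2000.0)
        spo2 = np.full(t.size, 95.0)
        spo2[(t >= 500) & (t < 530)] -= 2.0
        spo2[(t >= 1500) & (t < 1530)] -= 6.0
        trace = OximetryTrace(spo2, 1.0)
        evs = [RespiratoryEvent("apnea", 480, 15), RespiratoryEvent("apnea", 1480, 15)]
        curve = ensemble_average_desaturation(trace, evs, (60, 120))
        assert 95.0 - curve.spo2_pct.min() == pytest.approx(4.0)

    def test_uncovered_events_are_excluded_or_error(self):
        trace = _rect_desat_trace(total_s=600)
        with pytest.raises(HypnodensityError):
            ensemble_average_desaturation(
                trace, [RespiratoryEvent("apnea", 590, 20)], (60, 120)
            )


class TestSearchWindow:
    def _curve(self, lo_s, hi_s, depth=4.0, pre=60, post=120):
        t = np.arange(-pre, post + 1, 1.0)
        y = np.full(t.size, 95.0)
        y[(t >= lo_s) & (t <= hi_s)] -= depth
        return EnsembleCurve(t, y, 10, 0)

    def test_clean_dip_bounds_recovered(self):
        """Dip below baseline from -10 s to +44 s gives the (10, 44) window."""
        w = search_window(self._curve(-10, 44))
        assert w.pre_s == pytest.approx(10.0)
        assert w.post_s == pytest.approx(44.0)
        assert w.width_s == pytest.approx(54.0)
        assert not w.zero_width

    def test_flat_curve_yields_zero_width(self):
        t = np.arange(-60, 121, 1.0)
        w = search_window(EnsembleCurve(t, np.full(t.size, 95.0), 5, 0))
        assert w.zero_width
        assert w.width_s == 0.0

    def test_symmetric_dip_gives_symmetric_window(self):
        w = search_window(self._curve(-30, 30))
        assert w.pre_s == pytest.approx(w.post_s)


class TestHypoxicBurden:
    def test_no_desaturation_gives_zero(self):
        trace = OximetryTrace(np.full(3700, 95.0), 1.0)
        hyp = _hypnogram_hours(hours=1.0)
        hb = hypoxic_burden(
            trace, [RespiratoryEvent("apnea", 280, 15)], hyp, SearchWindow(10, 60)
        )
        assert hb.hb_total == 0.0

    def test_rectangular_closed_form(self):
        """4% deep, 30 s long rectangle on a 95% baseline over 1 h TST:
        area 2.0 %min, HB 2.0 %min/h."""
        trace = _rect_desat_trace(dip_start=300, dip_len=30)
        hyp = _hypnogram_hours(hours=1.0)
        ev = [RespiratoryEvent("apnea", 280, 15)]  # ends 295; dip 300-330
        hb = hypoxic_burden(trace, ev, hyp, SearchWindow(10, 60))
        sample_tol = 4.0 * 1.0 / 60  # one sample width of trapezoid edge
        assert hb.hb_total == pytest.approx(2.0, abs=2 * sample_tol)
        assert hb.per_event_areas.sum() == pytest.approx(2.0, abs=2 * sample_tol)

    def test_doubling_events_doubles_burden(self):
        t = np.arange(0, 3600.0 + 1)
        spo2 = np.full(t.size, 95.0)
        spo2[(t >= 300) & (t < 330)] -= 4.0
        one = OximetryTrace(spo2.copy(), 1.0)
        spo2[(t >= 1300) & (t < 1330)] -= 4.0
        two = OximetryTrace(spo2, 1.0)
        hyp = _hypnogram_hours(hours=1.0)
        ev1 = [RespiratoryEvent("apnea", 280, 15)]
        ev2 = ev1 + [RespiratoryEvent("apnea", 1280, 15)]
        hb1 = hypoxic_burden(one, ev1, hyp, SearchWindow(10, 60))
        hb2 = hypoxic_burden(two, ev2, hyp, SearchWindow(10, 60))
        assert hb2.hb_total == pytest.approx(2 * hb1.hb_total, rel=1e-6)

    def test_sampling_rate_invariance(self):
        hyp = _hypnogram_hours(hours=1.0)
        ev = [RespiratoryEvent("apnea", 280, 15)]
        vals = []
        for rate in (1.0, 10.0):
            trace = _rect_desat_trace(rate_hz=rate)
            hb = hypoxic_burden(trace, ev, hyp, SearchWindow(10, 60))
            vals.append(hb.hb_total)
        assert vals[0] == pytest.approx(vals[1], abs=4.0 * 1.0 / 60)

    def test_area_sum_identity(self):
        trace = _rect_desat_trace()
        hyp = _hypnogram_hours(hours=2.0)
        ev = [RespiratoryEvent("apnea", 280, 15)]
        hb = hypoxic_burden(trace, ev, hyp, SearchWindow(10, 60))
        assert hb.hb_total == pytest.approx(hb.per_event_areas.sum() / 2.0, abs=1e-9)

    def test_event_outside_trace_excluded_and_counted(self):
        trace = _rect_desat_trace(total_s=400)
        hyp = _hypnogram_hours(hours=1.0)
        ev = [
            RespiratoryEvent("apnea", 280, 15),
            RespiratoryEvent("apnea", 380, 15),  # window leaves the trace
        ]
        hb = hypoxic_burden(trace, ev, hyp, SearchWindow(10, 60))
        assert hb.n_events_excluded == 1
        assert hb.per_event_areas.size == 1

    def test_nrem_rem_split_by_termination_state(self):
        stages = ("N2",) * 120 + ("R",) * 120  # 1 h NREM + 1 h REM
        hyp = Hypnogram(stages)
        t = np.arange(0, 7200.0 + 1)
        spo2 = np.full(t.size, 95.0)
        spo2[(t >= 1000) & (t < 1030)] -= 4.0  # NREM event
        spo2[(t >= 5000) & (t < 5030)] -= 4.0  # REM event
        trace = OximetryTrace(spo2, 1.0)
        evs = [RespiratoryEvent("apnea", 980, 15), RespiratoryEvent("apnea", 4980, 15)]
        hb = hypoxic_burden(trace, evs, hyp, SearchWindow(10, 60))
        assert hb.hb_nrem == pytest.approx(hb.hb_rem, rel=1e-6)
        assert hb.hb_total == pytest.approx(hb.hb_nrem, rel=1e-6)  # halves combine

    def test_short_gap_interpolated_long_gap_excludes(self):
        trace = _rect_desat_trace()
        spo2 = trace.spo2_pct.copy()
        spo2[310:312] = np.nan  # 2 s gap inside the dip: bridged
        short = OximetryTrace(spo2, 1.0)
        hyp = _hypnogram_hours(hours=1.0)
        ev = [RespiratoryEvent("apnea", 280, 15)]
        hb = hypoxic_burden(short, ev, hyp, SearchWindow(10, 60))
        assert hb.n_events_excluded == 0
        spo2_long = trace.spo2_pct.copy()
        spo2_long[305:320] = np.nan  # 15 s dropout: event excluded
        long_gap = OximetryTrace(spo2_long, 1.0)
        hb2 = hypoxic_burden(long_gap, ev, hyp, SearchWindow(10, 60))
        assert hb2.n_events_excluded == 1


class TestRemRelatedOsa:
    @pytest.mark.parametrize(
        "ahi_nrem, ahi_rem, rem_min, expected",
        [
            (3.0, 12.0, 45.0, True),
            (3.0, 12.0, 20.0, False),   # too little REM
            (5.0, 12.0, 45.0, False),   # strict "fewer than 5"
            (3.0, 5.0, 30.0, True),     # boundary: >= 5 and >= 30 min
            (3.0, 4.9, 45.0, False),
        ],
    )
    def test_rule_boundaries(self, ahi_nrem, ahi_rem, rem_min, expected):
        from hypnodense.sdb import SdbIndices

        idx = SdbIndices(math.nan, ahi_nrem, ahi_rem)
        assert classify_rem_related_osa(idx, rem_min) is expected
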