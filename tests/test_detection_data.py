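"""Event ingestion, occasion windowing, fusion and naive summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surveydetect import (
    SchemaError,
    ValidationError,
    build_sensor_history,
    build_transect_history,
    combo_label,
    fuse_histories,
    hourly_profile,
    naive_summary,
    read_events,
    stack_histories,
    write_events,
)
from surveydetect.detection_data import DetectionHistory

from conftest import make_history

T0 = pd.Timestamp("2022-11-21 00:00")


def events_frame(records):
    """records: list of (site_id, method, timestamp, detected[, visit])."""
    rows = []
    for r in records:
        site, method, ts, det = r[:4]
        visit = r[4] if len(r) > 4 else pd.NA
        rows.append(
            {"site_id": site, "method": method, "timestamp": pd.Timestamp(ts),
             "detected": bool(det), "visit_index": visit}
        )
    df = pd.DataFrame(rows)
    df["visit_index"] = df["visit_index"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# read/write
# ---------------------------------------------------------------------------

class TestEventIO:
    def test_round_trip_preserves_all_fields(self, tmp_path):
        ev = events_frame(
            [
                ("L01-forest-CT", "CT", "2022-11-28 07:15", 1),
                ("L01-forest-CT", "CT", "2022-12-02 18:40", 0),
                ("L01-forest-PT", "PT", "2022-11-25 08:00", 1, 1),
            ]
        )
        path = tmp_path / "events.csv"
        write_events(ev, path)
        back = read_events(path)
        pd.testing.assert_frame_equal(back, ev)
        # a second round trip is byte-identical
        path2 = tmp_path / "events2.csv"
        write_events(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_unknown_method_is_schema_error_naming_allowed_values(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "site_id,method,timestamp,detected\ns1,CAM,2022-11-21T08:00,1\n"
        )
        with pytest.raises(SchemaError, match="PT.*CT.*PAM"):
            read_events(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site_id,timestamp,detected\ns1,2022-11-21T08:00,1\n")
        with pytest.raises(SchemaError, match="method"):
            read_events(path)

    def test_unparseable_timestamp_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "site_id,method,timestamp,detected\n"
            "s1,CT,2022-11-21T08:00,1\ns1,CT,not-a-time,1\n"
        )
        with pytest.raises(ValidationError, match=r"\[3\]"):
            read_events(path)

    def test_campaign_window_rejects_outside_rows(self, tmp_path):
        ev = events_frame(
            [
                ("s1", "CT", "2022-11-25 08:00", 1),
                ("s1", "CT", "2023-06-01 08:00", 1),
            ]
        )
        path = tmp_path / "events.csv"
        write_events(ev, path)
        with pytest.warns(UserWarning, match="rejected 1 event"):
            kept = read_events(path, campaign=(T0, T0 + pd.Timedelta(days=52)))
        assert len(kept) == 1


# ---------------------------------------------------------------------------
# sensor histories
# ---------------------------------------------------------------------------

def coverage_frame(site, start, days):
    return pd.DataFrame(
        {"site_id": [site], "start": [pd.Timestamp(start)],
         "end": [pd.Timestamp(start) + pd.Timedelta(days=days)]}
    )


class TestSensorHistory:
    def test_single_event_lands_in_its_occasion(self, sites_table):
        sid = "L01-forest-CT"
        ev = events_frame([(sid, "CT", T0 + pd.Timedelta(days=6, hours=3), 1)])
        hist = build_sensor_history(ev, sites_table, coverage_frame(sid, T0, 40))
        assert hist.matrix.loc[sid].tolist() == [0, 1, 0, 0, 0, 0, 0, 0]

    def test_dropout_scores_partial_occasions_by_coverage_rule(self, sites_table):
        # active days 0-11 of 40: occasions 1-2 full, occasion 3 covered 1/5 -> NA
        sid = "L01-forest-PAM"
        ev = events_frame([(sid, "PAM", T0 + pd.Timedelta(days=1, hours=6), 1)])
        hist = build_sensor_history(ev, sites_table, coverage_frame(sid, T0, 11))
        row = hist.matrix.loc[sid]
        assert row.iloc[0] == 1 and row.iloc[1] == 0
        assert row.iloc[2:].isna().all()

    def test_half_covered_occasion_is_scored(self, sites_table):
        # 13 active days: occasion 3 covered 3/5 >= 50% -> scored 0
        sid = "L01-forest-PAM"
        ev = events_frame([(sid, "PAM", T0 + pd.Timedelta(hours=2), 1)])
        hist = build_sensor_history(ev, sites_table, coverage_frame(sid, T0, 13))
        assert hist.matrix.loc[sid].tolist()[:3] == [1, 0, 0]

    def test_empty_events_with_full_coverage_is_all_zero(self, sites_table):
        sid = "L01-forest-CT"
        empty = events_frame([(sid, "CT", T0, 1)]).iloc[:0]
        hist = build_sensor_history(empty, sites_table, coverage_frame(sid, T0, 40))
        assert (hist.matrix.loc[sid] == 0).all()

    def test_translation_invariance(self, sites_table):
        sid = "L01-forest-CT"
        times = [pd.Timedelta(days=d, hours=h) for d, h in [(2, 5), (13, 22), (33, 1)]]
        ev = events_frame([(sid, "CT", T0 + t, 1) for t in times])
        hist = build_sensor_history(ev, sites_table, coverage_frame(sid, T0, 40))
        shift = pd.Timedelta(days=17, hours=7)
        ev2 = ev.copy()
        ev2["timestamp"] = ev2["timestamp"] + shift
        hist2 = build_sensor_history(ev2, sites_table, coverage_frame(sid, T0 + shift, 40))
        pd.testing.assert_frame_equal(hist.matrix, hist2.matrix)

    def test_occasions_partition_the_record(self, sites_table):
        # every event inside coverage falls in exactly one half-open window
        sid = "L01-forest-CT"
        rng = np.random.default_rng(7)
        times = T0 + pd.to_timedelta(np.sort(rng.uniform(0, 40 * 24, 60)), unit="h")
        starts = [T0 + pd.Timedelta(days=5 * k) for k in range(8)]
        counts = np.zeros(len(times), dtype=int)
        for k, s in enumerate(starts):
            inside = (times >= s) & (times < s + pd.Timedelta(days=5))
            counts += inside.astype(int)
        assert (counts == 1).all()

    def test_mixed_methods_rejected(self, sites_table):
        ev = events_frame(
            [("L01-forest-CT", "CT", T0, 1), ("L01-forest-PAM", "PAM", T0, 1)]
        )
        with pytest.raises(ValidationError, match="mixed"):
            build_sensor_history(ev, sites_table, None)


class TestTransectHistory:
    def test_visit_outcomes_become_columns(self, sites_table):
        sid = "L01-forest-PT"
        ev = events_frame(
            [
                (sid, "PT", T0 + pd.Timedelta(days=2, hours=7), 1, 1),
                (sid, "PT", T0 + pd.Timedelta(days=12, hours=9), 0, 2),
                (sid, "PT", T0 + pd.Timedelta(days=25, hours=8), 1, 3),
            ]
        )
        hist = build_transect_history(ev, sites_table)
        assert hist.matrix.loc[sid].tolist() == [1, 0, 1]

    def test_missing_visit_is_na(self, sites_table):
        sid = "L01-forest-PT"
        ev = events_frame(
            [
                (sid, "PT", T0 + pd.Timedelta(days=2, hours=7), 1, 1),
                (sid, "PT", T0 + pd.Timedelta(days=12, hours=9), 0, 2),
            ]
        )
        hist = build_transect_history(ev, sites_table)
        row = hist.matrix.loc[sid]
        assert row.tolist()[:2] == [1, 0] and np.isnan(row.iloc[2])

    def test_close_visits_warn_but_do_not_fail(self, sites_table):
        sid = "L01-forest-PT"
        ev = events_frame(
            [
                (sid, "PT", T0 + pd.Timedelta(days=2), 1, 1),
                (sid, "PT", T0 + pd.Timedelta(days=4), 0, 2),
                (sid, "PT", T0 + pd.Timedelta(days=20), 1, 3),
            ]
        )
        with pytest.warns(UserWarning, match="5"):
            hist = build_transect_history(ev, sites_table)
        assert hist.n_sites == 1

    def test_many_transects_make_one_row_each(self, sites_table):
        evs = []
        for li in range(1, 4):
            for hab in ("forest", "open"):
                sid = f"L{li:02d}-{hab}-PT"
                for vi in range(1, 4):
                    evs.append((sid, "PT", T0 + pd.Timedelta(days=5 * vi), vi % 2, vi))
        hist = build_transect_history(events_frame(evs), sites_table)
        assert hist.n_sites == 6 and hist.n_occasions == 3


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

cell = st.sampled_from([0.0, 1.0, None])
row3 = st.lists(cell, min_size=3, max_size=3)


def has_non_na(rows):
    return all(any(v is not None for v in r) for r in rows)


class TestFusion:
    def test_or_with_na_absorption(self):
        a = make_history([[1, 0, None]], method="CT")
        b = make_history([[0, 0, 1]], method="PAM")
        fused = fuse_histories([a, b])
        assert fused.matrix.iloc[0].tolist() == [1, 0, 1]
        assert fused.covariates["method"].iloc[0] == "CT+PAM"

    def test_all_na_only_when_every_input_na(self):
        a = make_history([[None, 0]], method="CT")
        b = make_history([[None, None]], method="PAM")
        fused = fuse_histories([a, b])
        row = fused.matrix.iloc[0]
        assert np.isnan(row.iloc[0]) and row.iloc[1] == 0

    def test_single_history_is_identity(self):
        a = make_history([[1, 0, None]])
        assert fuse_histories([a]) is a

    def test_no_overlap_is_error(self):
        a = make_history([[1, 0]], method="CT", locations=["L01"])
        b = make_history([[0, 1]], method="PAM", locations=["L02"])
        with pytest.raises(ValidationError, match="overlap"):
            fuse_histories([a, b])

    def test_shorter_history_is_na_padded(self):
        pt = make_history([[1, 0, 0]], method="PT")
        ct = make_history([[0] * 8], method="CT")
        fused = fuse_histories([pt, ct])
        assert fused.matrix.iloc[0].tolist() == [1, 0, 0, 0, 0, 0, 0, 0]

    @settings(max_examples=60, deadline=None)
    @given(a=row3, b=row3)
    def test_commutative_and_idempotent(self, a, b):
        if not has_non_na([a]) or not has_non_na([b]):
            return
        ha = make_history([a], method="CT")
        hb = make_history([b], method="PAM")
        ab = fuse_histories([ha, hb]).matrix.to_numpy()
        ba = fuse_histories([hb, ha]).matrix.to_numpy()
        np.testing.assert_array_equal(ab, ba)
        aa = fuse_histories([ha, make_history([a], method="PAM")]).matrix.to_numpy()
        np.testing.assert_array_equal(aa, np.asarray(
            [[np.nan if v is None else v for v in a]]))

    @settings(max_examples=60, deadline=None)
    @given(a=row3, b=row3, c=row3)
    def test_associative_and_dominant(self, a, b, c):
        if not has_non_na([a, b, c]):
            return
        ha = make_history([a], method="PT")
        hb = make_history([b], method="CT")
        hc = make_history([c], method="PAM")
        abc = fuse_histories([ha, hb, hc]).matrix.to_numpy()
        ab_c = fuse_histories([fuse_histories([ha, hb]), hc]).matrix.to_numpy()
        np.testing.assert_array_equal(abc, ab_c)
        # fused row has at least as many detections as any input row
        for r in (a, b, c):
            arr = np.asarray([np.nan if v is None else v for v in r])
            assert np.nansum(abc) >= np.nansum(arr)

    def test_combo_label_canonical_order(self):
        assert combo_label(["PAM", "PT"]) == "PT+PAM"
        assert combo_label(["CT+PAM", "PT"]) == "PT+CT+PAM"


# ---------------------------------------------------------------------------
# naive summaries and profiles
# ---------------------------------------------------------------------------

class TestNaiveSummary:
    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        rows = rng.choice([0.0, 1.0, None], size=(6, 8), p=[0.4, 0.4, 0.2]).tolist()
        rows = [r if any(v is not None for v in r) else [1.0] + r[1:] for r in rows]
        hist = make_history(rows, method="CT",
                            habitat=["forest"] * 3 + ["open"] * 3)
        summ = naive_summary([hist])
        vals = hist.matrix.to_numpy()
        for hab, sl in (("forest", slice(0, 3)), ("open", slice(3, 6))):
            cells = vals[sl]
            row = summ.rates.query("method=='CT' and habitat==@hab").iloc[0]
            assert row["occasions_total"] == int((~np.isnan(cells)).sum())
            assert row["occasions_detected"] == int(np.nansum(cells))

    def test_printed_style_rate(self):
        # 49 detections of 72 scored occasions -> 68%
        cells = [1.0] * 49 + [0.0] * 23
        rows = [cells[i * 8:(i + 1) * 8] for i in range(9)]
        hist = make_history(rows, method="CT", habitat="forest")
        row = naive_summary([hist]).rates.query("habitat=='forest'").iloc[0]
        assert (row["occasions_detected"], row["occasions_total"]) == (49, 72)
        assert round(row["rate"], 2) == 0.68

    def test_latency_is_first_detection_occasion(self):
        hist = make_history([[0, 0, 1]], method="PT")
        lat = naive_summary([hist]).latency.iloc[0]
        assert lat["latency_mean"] == 3 and lat["latency_min"] == 3

    def test_empty_stratum_reports_zero_counts(self):
        hist = make_history([[1, 0]], method="PAM", habitat="forest")
        row = naive_summary([hist]).rates.query("habitat=='open'").iloc[0]
        assert row["occasions_total"] == 0 and np.isnan(row["rate"])

    def test_overlap_counts_shared_occasions(self):
        a = make_history([[1, 1, 0, 0]], method="PT")
        b = make_history([[1, 0, 1, None]], method="CT")
        ov = naive_summary([a, b]).overlap.iloc[0]
        assert (ov["both"], ov["only_a"], ov["only_b"], ov["shared_cells"]) == (1, 1, 1, 3)


class TestHourlyProfile:
    def test_bins_sum_to_detected_events(self):
        ev = events_frame(
            [
                ("s", "CT", "2022-11-21 05:10", 1),
                ("s", "CT", "2022-11-21 05:50", 1),
                ("s", "CT", "2022-11-22 17:30", 1),
                ("s", "CT", "2022-11-22 09:00", 0),
            ]
        )
        prof = hourly_profile(ev)
        assert prof.loc[5, "CT"] == 2 and prof.loc[17, "CT"] == 1
        assert prof["CT"].sum() == 3

    def test_empty_input_gives_all_zero_histogram(self):
        ev = events_frame([("s", "CT", "2022-11-21 05:10", 0)])
        prof = hourly_profile(ev)
        assert prof.to_numpy().sum() == 0 if prof.size else True


class TestStacking:
    def test_stack_pads_and_warns_on_pseudoreplication(self):
        pt = make_history([[1, 0, 1]], method="PT", locations=["L01"])
        ct = make_history([[0] * 8], method="CT", locations=["L01"])
        fused = fuse_histories([pt, ct])
        with pytest.warns(UserWarning, match="pseudo"):
            stacked = stack_histories([pt, ct, fused])
        assert stacked.n_sites == 3 and stacked.n_occasions == 8
        assert np.isnan(stacked.matrix.loc["L01-forest-PT"].iloc[3:]).all()


class TestHistoryContainer:
    def test_csv_round_trip(self, tmp_path):
        hist = make_history([[1, 0, None], [0, 1, 1]], method="CT")
        path = tmp_path / "h.csv"
        hist.to_csv(path)
        back = DetectionHistory.from_csv(path)
        np.testing.assert_array_equal(back.matrix.to_numpy(), hist.matrix.to_numpy())
        assert list(back.covariates["method"]) == list(hist.covariates["method"])
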