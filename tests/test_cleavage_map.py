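"""Unit and oracle tests for the pseudocount/RCI/median-filter/site-calling chain."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavemap.cleavage_map import (
    CleavageSite,
    apply_pseudocount,
    call_sites,
    compute_rci,
    detect_recognition_sequence,
    filter_by_median,
    top_k_sites,
)
from cleavemap.io_formats import CoverageTrack, SequenceRecord
from cleavemap.synthetic_data import PanelConfig, make_fixture_panel


def _track(values, sid="s1"):
    return CoverageTrack(sid, np.asarray(values))


def brute_force_decisions(raw_values, rci_threshold=3.0):
    """Independent re-implementation with direct loops: returns
    {position: (cov_n, cov_nm1, rci, kept)} for every n in 2..L."""
    v = [1 if x == 0 else x for x in raw_values]
    med = sorted(v)
    L = len(med)
    median = (med[L // 2] if L % 2 else (med[L // 2 - 1] + med[L // 2]) / 2)
    out = {}
    for n in range(2, L + 1):
        cov_n, cov_nm1 = v[n - 1], v[n - 2]
        rci = cov_n / cov_nm1
        kept = cov_n >= median and rci >= rci_threshold
        out[n] = (cov_n, cov_nm1, rci, kept)
    return out


class TestApplyPseudocount:
    @pytest.mark.parametrize(
        "values,expected",
        [([0, 5, 0], [1, 5, 1]), ([3, 4], [3, 4]), ([0, 0, 0], [1, 1, 1])],
    )
    def test_zero_replacement(self, values, expected):
        assert apply_pseudocount(_track(values)).values.tolist() == expected

    def test_idempotent(self, rng):
        track = _track(rng.integers(0, 10, size=50))
        once = apply_pseudocount(track)
        twice = apply_pseudocount(once)
        assert (once.values == twice.values).all()


class TestComputeRci:
    def test_arithmetic(self):
        df = compute_rci(_track([10, 10, 40, 40]))
        assert df["position"].tolist() == [2, 3, 4]
        assert df["rci"].tolist() == [1.0, 4.0, 1.0]

    def test_flat_track_all_ones(self):
        df = compute_rci(_track([1] * 20))
        assert (df["rci"] == 1.0).all()
        assert len(df) == 19

    def test_step_down(self):
        df = compute_rci(_track([100, 1]))
        assert df["rci"].tolist() == [0.01]

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            compute_rci(_track([5, 0, 5]))


class TestFilterByMedian:
    def test_even_length_median_is_mean_of_central_order_statistics(self):
        track = _track([1, 1, 1, 9, 9, 9])  # median 5.0
        df = filter_by_median(compute_rci(track), track)
        assert (df["cov_n"] == 9).all()
        assert len(df) == 3

    def test_boundary_is_inclusive(self):
        track = _track([1, 2, 100])  # median 2
        df = filter_by_median(compute_rci(track), track)
        assert 2 in df["cov_n"].tolist()

    def test_all_equal_keeps_everything(self):
        track = _track([7] * 10)
        df = filter_by_median(compute_rci(track), track)
        assert len(df) == 9

    def test_substrate_mismatch_rejected(self):
        track = _track([5, 5, 5])
        with pytest.raises(ValueError, match="s1"):
            filter_by_median(compute_rci(track), _track([5, 5, 5], sid="other"))


class TestCallSites:
    def _substrate(self, length=40):
        return SequenceRecord("s1", "RNA", "AUGC" * (length // 4))

    def test_threshold_is_inclusive(self):
        sub = self._substrate()
        values = [4] * 40
        values[19] = 12  # rci exactly 3.0 at n=20
        track = apply_pseudocount(_track(values))
        sites = call_sites(filter_by_median(compute_rci(track), track), sub)
        assert [s.position for s in sites] == [20]
        assert sites[0].rci == 3.0
        assert sites[0].window == sub.residues[14:25]
        assert sites[0].window[5] == sub.residues[19]

    def test_just_below_threshold_dropped(self):
        sub = self._substrate()
        values = [100] * 40
        values[19] = 299  # rci 2.99
        track = _track(values)
        sites = call_sites(filter_by_median(compute_rci(track), track), sub)
        assert sites == []

    def test_window_must_fit_in_substrate(self):
        sub = self._substrate()
        values = [4] * 40
        values[3] = 1000  # n=4: passes filters but window needs position -1
        values[37] = 1000  # n=38: window needs position 43
        track = _track(values)
        sites = call_sites(filter_by_median(compute_rci(track), track), sub)
        assert sites == []


class TestTopK:
    def _site(self, rci, sid="a", pos=100):
        return CleavageSite(sid, pos, 10, 2, rci, "GUACAAAGCAU")

    def test_largest_k_in_descending_order(self):
        sites = [self._site(float(r)) for r in range(3, 15)]
        top = top_k_sites(sites, k=10)
        assert [s.rci for s in top] == list(range(14, 4, -1))
        assert [s.rank for s in top] == list(range(1, 11))

    def test_fewer_than_k_returns_all(self):
        sites = [self._site(5.0), self._site(4.0), self._site(3.0)]
        assert len(top_k_sites(sites, k=10)) == 3

    def test_tie_broken_by_substrate_then_position(self):
        tie = [self._site(5.0, sid="b", pos=10), self._site(5.0, sid="a", pos=20),
               self._site(5.0, sid="a", pos=5)]
        top = top_k_sites(tie, k=3)
        assert [(s.substrate_id, s.position) for s in top] == [("a", 5), ("a", 20), ("b", 10)]


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force_on_random_tracks(self, rng):
        """Pseudocount, RCI value and kept/dropped decision agree with direct loops."""
        for _ in range(200):
            L = int(rng.integers(2, 201))
            raw = rng.integers(0, 30, size=L)
            if rng.random() < 0.3:
                raw[rng.random(L) < 0.5] = 0
            expected = brute_force_decisions(raw.tolist())

            track = apply_pseudocount(_track(raw))
            df = compute_rci(track)
            kept_threshold = {
                int(r.position)
                for r in filter_by_median(df, track).itertuples()
                if r.rci >= 3.0
            }
            for row in df.itertuples():
                n = int(row.position)
                cov_n, cov_nm1, rci, kept_expected = expected[n]
                assert row.cov_n == cov_n and row.cov_nm1 == cov_nm1
                assert row.rci == rci
                assert (n in kept_threshold) == kept_expected

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=60))
    def test_pipeline_matches_brute_force_for_arbitrary_tracks(self, raw):
        expected = brute_force_decisions(raw)
        track = apply_pseudocount(_track(raw))
        df = compute_rci(track)
        kept = set(filter_by_median(df, track).loc[lambda d: d["rci"] >= 3.0, "position"])
        for row in df.itertuples():
            n = int(row.position)
            cov_n, cov_nm1, rci, decision = expected[n]
            assert (row.cov_n, row.cov_nm1, row.rci) == (cov_n, cov_nm1, rci)
            assert (n in kept) == decision

    def test_median_filter_and_threshold_commute(self, rng):
        for _ in range(50):
            raw = rng.integers(0, 20, size=int(rng.integers(5, 100)))
            track = apply_pseudocount(_track(raw))
            df = compute_rci(track)
            a = filter_by_median(df, track)
            a = a[a["rci"] >= 3.0]
            b = df[df["rci"] >= 3.0]
            b = filter_by_median(b, track)
            assert a.reset_index(drop=True).equals(b.reset_index(drop=True))


class TestDetect:
    def test_end_to_end_recovery_on_default_panel(self, default_panel):
        substrates, tracks, manifest = default_panel
        report = detect_recognition_sequence([s.record for s in substrates], tracks)
        motif = report["motif"]
        assert motif["recognition_sequence"] == "UACAAA"
        assert motif["recognition_with_cut"] == "U^ACAAA"
        assert motif["consensus"][4:10] == "UACAAA"
        # every top window is centred on a planted site
        planted = {
            (sid, n)
            for sid, info in manifest["substrates"].items()
            for n, _ in info["planted_sites"]
        }
        for s in report["top_sites"]:
            assert (s["substrate_id"], s["position"]) in planted

    def test_report_is_deterministic(self, default_panel):
        substrates, tracks, _ = default_panel
        records = [s.record for s in substrates]
        r1 = detect_recognition_sequence(records, tracks)
        r2 = detect_recognition_sequence(records, tracks)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_no_passing_sites_gives_null_consensus(self):
        sub = SequenceRecord("s1", "RNA", "ACGU" * 10)
        track = _track([5] * 40)
        report = detect_recognition_sequence([sub], [track])
        assert report["n_sites"] == 0
        assert report["motif"] is None

    def test_unknown_substrate_in_coverage_is_fatal(self):
        sub = SequenceRecord("s1", "RNA", "ACGU" * 10)
        with pytest.raises(ValueError, match="ghost"):
            detect_recognition_sequence([sub], [_track([1] * 40, sid="ghost")])

    def test_length_mismatch_is_fatal(self):
        sub = SequenceRecord("s1", "RNA", "ACGU" * 10)
        with pytest.raises(ValueError, match="length"):
            detect_recognition_sequence([sub], [_track([1] * 39)])
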