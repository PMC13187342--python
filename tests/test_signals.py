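"""Synthetic-session generator: determinism, planted effects, bookkeeping."""

import numpy as np
import pytest

from tuslab.errors import ValidationError
from tuslab.session_io import read_session, write_session
from tuslab.signals import (
    Block,
    ParticipantSpec,
    Peak,
    default_schedule,
    generate_session,
    validate_schedule,
)

FAST = dict(eeg_rate=512.0)


def fast_schedule(block=60.0):
    return default_schedule(block_duration=block, gap=10.0)


class TestSchedule:
    def test_default_schedule_sham_precedes_active(self):
        blocks = default_schedule()
        for day in ("GPi_day", "Ventricle_day"):
            day_blocks = [b for b in blocks if b.day == day]
            sham = next(b for b in day_blocks if b.condition == "sham")
            active = next(b for b in day_blocks if b.condition == "active")
            assert sham.start < active.start

    def test_active_without_sham_rejected(self):
        blocks = [Block("GPi_day", "active", "rest", 0.0, 60.0)]
        with pytest.raises(ValidationError, match="sham"):
            validate_schedule(blocks)

    def test_overlap_rejected(self):
        blocks = [
            Block("GPi_day", "sham", "rest", 0.0, 60.0),
            Block("GPi_day", "active", "rest", 30.0, 60.0),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            validate_schedule(blocks)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            validate_schedule([])


class TestGenerateSession:
    def test_deterministic_given_seed(self):
        s1, _ = generate_session(ParticipantSpec(seed=5, **FAST), fast_schedule())
        s2, _ = generate_session(ParticipantSpec(seed=5, **FAST), fast_schedule())
        for ch in s1.channels:
            assert np.array_equal(s1.channels[ch], s2.channels[ch])

    def test_sample_counts_match_rates(self):
        sched = fast_schedule()
        s, _ = generate_session(ParticipantSpec(seed=0, **FAST), sched)
        duration = max(b.end for b in sched) + 5.0
        assert s.channels["Left_0-2"].size == int(duration * 250)
        assert s.channels["C3Cz"].size == int(duration * 512)

    def test_no_suppression_plants_zero_change_on_average(self):
        # the booked truth uses realised carrier variances, so individual
        # entries fluctuate around zero; the planted effect is zero in
        # expectation and small per entry at this block length
        vals = []
        for seed in range(4):
            spec = ParticipantSpec(seed=seed, suppression={}, gain_sd=0.0, **FAST)
            _, gt = generate_session(spec, fast_schedule(120.0))
            t = gt.band_table.drop_duplicates(["channel", "band", "day"])
            vals.extend(t.true_rel_reduction_pct[t.band != "tremor"])
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 1.5
        assert np.max(np.abs(vals)) < 10.0

    def test_isolated_component_power_ratio_is_factor_squared(self):
        # single beta peak, negligible background, frozen gain
        s = 0.8
        spec = ParticipantSpec(
            seed=2, aperiodic_offset=1e-6, noise_sd=1e-6, gain_sd=0.0,
            peaks={g: (Peak(17.0, 0.5, 3.0),) for g in
                   ("stn_left", "stn_right", "m1_left", "m1_right")},
            suppression={("stn_left", "low_beta", "GPi_day"): s},
            **FAST,
        )
        _, gt = generate_session(spec, fast_schedule())
        t = gt.band_table
        sel = (t.channel == "Left_0-2") & (t.band == "low_beta") & (
            t.day == "GPi_day"
        )
        sham = t[sel & (t.condition == "sham")].band_power.iloc[0]
        active = t[sel & (t.condition == "active")].band_power.iloc[0]
        assert active / sham == pytest.approx(s**2, rel=0.05)

    def test_planted_band_power_matches_welch_measurement(self):
        """Power bookkeeping: generator-declared band power agrees with a
        direct Welch measurement of the generated samples within 5%."""
        from tuslab.ephys import WelchConfig, band_power, preprocess, welch_psd

        spec = ParticipantSpec(seed=3, gain_sd=0.0, **FAST)
        sched = fast_schedule(120.0)
        sess, gt = generate_session(spec, sched)
        block = sess.rest_block("GPi_day", "sham")
        x = preprocess(sess.block_samples("Left_0-2", block), 250.0)
        psd = welch_psd(x, 250.0, WelchConfig(normalise=False))
        measured = band_power(psd, "beta")
        t = gt.band_table
        declared = t[
            (t.channel == "Left_0-2") & (t.band == "beta")
            & (t.day == "GPi_day") & (t.condition == "sham")
        ].band_power.iloc[0]
        assert measured == pytest.approx(declared, rel=0.05)

    def test_full_coupling_correlates_left_gains(self):
        spec = ParticipantSpec(seed=4, ipsilateral_coupling=1.0, **FAST)
        _, gt = generate_session(spec, fast_schedule())
        g = gt.gain_table
        stn = g[g.channel == "Left_0-2"].sort_values("block").mean_sq_gain
        m1 = g[g.channel == "C3Cz"].sort_values("block").mean_sq_gain
        assert np.corrcoef(stn, m1)[0, 1] ** 2 > 0.99

    def test_day_drift_scales_second_day(self):
        spec = ParticipantSpec(seed=6, suppression={}, day_drift=1.5,
                               gain_sd=0.0, **FAST)
        _, gt = generate_session(spec, fast_schedule())
        t = gt.band_table
        sel = (t.channel == "Left_0-2") & (t.band == "beta") & (
            t.condition == "sham"
        )
        p1 = t[sel & (t.day == "GPi_day")].band_power.iloc[0]
        p2 = t[sel & (t.day == "Ventricle_day")].band_power.iloc[0]
        # amplitude drift 1.5 -> power drift 2.25 on the oscillatory part
        assert p2 > p1

    def test_tremor_component_lands_in_tremor_band(self):
        spec = ParticipantSpec(seed=7, tremor=(5.0, 1.0), **FAST)
        _, gt = generate_session(spec, fast_schedule())
        t = gt.band_table
        no_tremor_spec = ParticipantSpec(seed=7, tremor=None, **FAST)
        _, gt0 = generate_session(no_tremor_spec, fast_schedule())
        p = t[(t.channel == "Left_0-2") & (t.band == "tremor")].band_power.mean()
        p0 = gt0.band_table[
            (gt0.band_table.channel == "Left_0-2")
            & (gt0.band_table.band == "tremor")
        ].band_power.mean()
        assert p > 2 * p0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError, match="suppression"):
            ParticipantSpec(suppression={("stn_left", "beta", "GPi_day"): 1.5})
        with pytest.raises(ValidationError, match="coupling"):
            ParticipantSpec(ipsilateral_coupling=1.2)
        with pytest.raises(ValidationError, match="tremor"):
            ParticipantSpec(tremor=(9.0, 1.0))


class TestSessionIO:
    def test_round_trip_exact(self, tmp_path):
        sess, _ = generate_session(ParticipantSpec(seed=8, **FAST), fast_schedule())
        write_session(sess, tmp_path / "session")
        back = read_session(tmp_path / "session")
        for ch in sess.channels:
            assert np.array_equal(back.channels[ch], sess.channels[ch])
            assert back.rates[ch] == sess.rates[ch]
        for stream in sess.sync_events:
            assert np.allclose(back.sync_events[stream], sess.sync_events[stream])
        assert back.blocks == sess.blocks

    def test_missing_channel_named(self, tmp_path):
        import json

        sess, _ = generate_session(ParticipantSpec(seed=8, **FAST), fast_schedule())
        write_session(sess, tmp_path / "session")
        header = json.loads((tmp_path / "session.json").read_text())
        header["channels"] = [
            c for c in header["channels"] if c["name"] != "C4Cz"
        ]
        (tmp_path / "session.json").write_text(json.dumps(header))
        with pytest.raises(ValidationError, match="C4Cz"):
            read_session(tmp_path / "session")

    def test_truncated_payload_length_mismatch(self, tmp_path):
        sess, _ = generate_session(ParticipantSpec(seed=8, **FAST), fast_schedule())
        write_session(sess, tmp_path / "session")
        payload = (tmp_path / "session.bin").read_bytes()
        (tmp_path / "session.bin").write_bytes(payload[: len(payload) // 2])
        with pytest.raises(ValidationError, match="length mismatch"):
            read_session(tmp_path / "session")

    def test_malformed_header_rejected(self, tmp_path):
        (tmp_path / "bad.json").write_text("{not json")
        (tmp_path / "bad.bin").write_bytes(b"")
        with pytest.raises(ValidationError, match="malformed"):
            read_session(tmp_path / "bad")
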