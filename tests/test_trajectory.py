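"""Geometry and sampling-law tests for the double-spiral trajectories."""

import numpy as np
import pytest

import spiralscan as ss
from spiralscan.trajectory import driving_waveforms


def _params(pattern, n_points=8192, n_turns=16, **kw):
    return ss.SpiralParams(pattern=pattern, fov_diameter=2.0, n_points=n_points,
                           n_turns=n_turns, **kw)


@pytest.mark.parametrize("pattern", ["AS", "FS", "AFS"])
class TestFrameStructure:
    def test_arrays_and_timing(self, pattern):
        p = _params(pattern)
        tr = ss.make_trajectory(p)
        assert len(tr.x) == len(tr.y) == len(tr.t) == len(tr.segment) == p.n_points
        # pulses arrive at exactly the repetition rate
        assert np.allclose(np.diff(tr.t), 1.0 / p.prf, rtol=0, atol=1e-15)
        assert p.frame_rate * p.n_points == p.prf

    def test_radius_bounds_and_rim_visit(self, pattern):
        tr = ss.make_trajectory(_params(pattern))
        R = tr.params.radius
        assert tr.r.max() <= R + 1e-9
        assert np.isclose(tr.r.max(), R)  # every pattern reaches the rim
        # first sample starts at the centre (within one angular step)
        assert tr.r[0] <= R * 2 * np.pi * tr.params.n_turns / len(tr.r)

    def test_constant_angular_rate_within_segments(self, pattern):
        tr = ss.make_trajectory(_params(pattern))
        dth = np.diff(tr.theta)
        same_seg = tr.segment[:-1] == tr.segment[1:]
        for lab in np.unique(tr.segment):
            sel = same_seg & (tr.segment[:-1] == lab)
            inc = dth[sel]
            assert np.allclose(inc, inc[0], rtol=1e-9)

    def test_continuity_no_flyback(self, pattern):
        tr = ss.make_trajectory(_params(pattern))
        steps = tr.step_lengths()
        assert steps.max() <= 4 * np.median(steps)
        # junction gaps are ordinary steps, not jumps
        assert tr.junction_gaps().max() <= steps.max() + 1e-12

    def test_even_point_budget_required(self, pattern):
        with pytest.raises(ValueError, match="even"):
            _params(pattern, n_points=4097)


class TestRadialSamplingLaws:
    def test_archimedes_central_fraction(self):
        tr = ss.make_trajectory(_params("AS", n_points=4096))
        frac = np.count_nonzero(tr.r <= tr.params.radius / 16) / 4096
        assert abs(frac - 1 / 16) <= 2 / 4096

    def test_archimedes_max_gap_at_rim(self):
        tr = ss.make_trajectory(_params("AS", n_points=4096))
        out = tr.segment == "AS_out"
        steps = np.hypot(np.diff(tr.x[out]), np.diff(tr.y[out]))
        assert np.argmax(steps) == len(steps) - 1  # arc step r*dtheta peaks at r=R

    def test_fermat_central_fraction_and_monotone(self):
        tr = ss.make_trajectory(_params("FS", n_points=4096))
        frac = np.count_nonzero(tr.r <= tr.params.radius / 16) / 4096
        assert abs(frac - 1 / 256) <= 2 / 4096
        out = tr.r[tr.segment == "FS_out"]
        assert (np.diff(out) >= -1e-12).all()

    def test_fermat_equal_area_annuli_uniform(self):
        n = 4096
        tr = ss.make_trajectory(_params("FS", n_points=n))
        R = tr.params.radius
        edges = R * np.sqrt(np.linspace(0, 1, 17))  # 16 equal-area annuli
        counts, _ = np.histogram(tr.r, bins=edges)
        expect = n / 16
        assert (np.abs(counts - expect) <= 4 * np.sqrt(expect)).all()

    @pytest.mark.parametrize("n_points", [1024, 8192, 65536])
    def test_point_fraction_law_brute_force(self, n_points):
        """AS cumulative fraction -> rho/R, FS -> (rho/R)^2, within 2/n."""
        for pattern, law in (("AS", lambda u: u), ("FS", lambda u: u**2)):
            tr = ss.make_trajectory(_params(pattern, n_points=n_points))
            R = tr.params.radius
            for u in (0.1, 0.25, 0.5, 1 / 16, 0.75):
                frac = np.count_nonzero(tr.r <= u * R) / n_points
                assert abs(frac - law(u)) <= 2 / n_points

    def test_compound_is_mean_of_both_laws(self):
        tr = ss.make_trajectory(_params("AFS", n_points=8192))
        frac = np.count_nonzero(tr.r <= tr.params.radius / 16) / 8192
        assert abs(frac - (1 / 16 + 1 / 256) / 2) <= 2 / 8192

    def test_compound_between_pure_patterns(self):
        trs = {p: ss.make_trajectory(_params(p, n_points=16384)) for p in ("AS", "FS", "AFS")}
        R = trs["AS"].params.radius
        for f in (1 / 256, 1 / 64, 1 / 16, 1 / 4, 1 / 2):
            rho = R * np.sqrt(f)
            fr = {p: np.count_nonzero(t.r <= rho) / t.n_points for p, t in trs.items()}
            assert fr["FS"] < fr["AFS"] < fr["AS"]


class TestCompoundComposition:
    def test_equal_pass_split_and_labels(self):
        tr = ss.make_trajectory(_params("AFS", n_points=8192))
        labels, counts = np.unique(tr.segment, return_counts=True)
        assert set(labels) == {"AS_out", "FS_in"}
        assert (counts == 4096).all()

    def test_junction_matched_at_rim(self):
        tr = ss.make_trajectory(_params("AFS"))
        b = tr.segment_boundaries()[0]
        assert np.isclose(tr.r[b], tr.params.radius)
        assert tr.junction_gaps()[0] <= tr.step_lengths().max()

    def test_four_pass_composition(self):
        tr = ss.make_trajectory(
            _params("AFS", n_points=8192, composition="as_roundtrip_fs_roundtrip")
        )
        labels, counts = np.unique(tr.segment, return_counts=True)
        assert set(labels) == {"AS_out", "AS_in", "FS_out", "FS_in"}
        assert (counts == 2048).all()
        with pytest.raises(ValueError, match="divisible by 4"):
            _params("AFS", n_points=4098, composition="as_roundtrip_fs_roundtrip")


class TestDrivingWaveforms:
    def test_amplitude_envelope_linear_on_as_outward(self):
        tr = ss.make_trajectory(_params("AS", n_points=4096))
        wf = driving_waveforms(tr)
        amp = np.hypot(wf.x, wf.y)
        out = tr.segment == "AS_out"
        # r(t) is linear in t on the outward pass
        coeffs = np.polyfit(wf.t[out], amp[out], 1)
        assert np.allclose(amp[out], np.polyval(coeffs, wf.t[out]), atol=1e-9)

    @pytest.mark.parametrize("pattern", ["AS", "FS", "AFS"])
    def test_junction_jump_small(self, pattern):
        wf = driving_waveforms(ss.make_trajectory(_params(pattern)))
        assert wf.max_junction_ratio <= 2.0 + 1e-6

    def test_reverse_involution(self, default_afs):
        rev2 = default_afs.reversed().reversed()
        assert np.array_equal(rev2.x, default_afs.x)
        assert np.array_equal(rev2.y, default_afs.y)
        assert np.array_equal(rev2.segment, default_afs.segment)


def test_csv_round_trip(tmp_path):
    tr = ss.make_trajectory(_params("AFS", n_points=2048))
    path = tmp_path / "traj.csv"
    tr.to_csv(path)
    back = ss.ScanTrajectory.from_csv(path)
    assert back.params == tr.params
    assert np.allclose(back.x, tr.x)
    assert (back.segment == tr.segment).all()


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ss.SpiralParams(pattern="XX")
    with pytest.raises(ValueError):
        ss.SpiralParams(pattern="AS", fov_diameter=-1)
    with pytest.raises(ValueError):
        ss.SpiralParams(pattern="AS", n_turns=0)
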