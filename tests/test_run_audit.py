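"""Landmark location and one-way-trip classification (the correction process)."""

import numpy as np
import pytest

from dfekit.deposition_io import CVTrajectory, FESProfile
from dfekit.fes_reconstruction import average_fes, primitive_fes
from dfekit.run_audit import (
    AuditError,
    Landmarks,
    audit_ensemble,
    classify_run,
    iterate_audit,
    locate_landmarks,
    summarize_verdicts,
)

from conftest import make_constant_profile


def well_profile(r0=5.0, depth=8.0, plateau_start=7.0, lo=0.0, hi=12.0, n=241):
    """Parabolic well at r0 rising to a flat plateau at 0."""
    grid = np.linspace(lo, hi, n)
    width = plateau_start - r0
    g = np.where(
        np.abs(grid - r0) < width,
        -depth + depth * ((grid - r0) / width) ** 2,
        0.0,
    )
    return FESProfile(grid=grid, energies=g, kind="averaged")


def traj(values, run_id="t"):
    values = np.asarray(values, dtype=float)
    return CVTrajectory(run_id=run_id, times=np.arange(len(values), dtype=float), values=values)


class TestLocateLandmarks:
    def test_parabolic_well_to_plateau(self):
        profile = well_profile()
        lm = locate_landmarks(profile, smooth_window=1)
        assert lm.r0 == pytest.approx(5.0, abs=0.05)
        # no interior maximum: first point risen to within 0.1 of the plateau
        assert 6.5 <= lm.rb <= 7.2
        assert lm.g_min == pytest.approx(-8.0, abs=0.01)

    def test_two_maxima_takes_smaller_cv(self):
        grid = np.linspace(0.0, 10.0, 201)
        g = -8.0 * np.exp(-((grid - 3.0) ** 2)) + 2.0 * np.exp(-((grid - 5.0) ** 2) / 0.1)
        g += 1.0 * np.exp(-((grid - 8.0) ** 2) / 0.1)
        profile = FESProfile(grid=grid, energies=g, kind="averaged")
        lm = locate_landmarks(profile, smooth_window=1)
        assert lm.rb == pytest.approx(5.0, abs=0.1)

    def test_monotone_profiles_have_no_bound_state(self):
        grid = np.linspace(0, 10, 101)
        with pytest.raises(AuditError, match="no bound state"):
            locate_landmarks(FESProfile(grid=grid, energies=grid * 0.5, kind="averaged"))
        with pytest.raises(AuditError, match="no bound state"):
            locate_landmarks(FESProfile(grid=grid, energies=-grid * 0.5, kind="averaged"))

    def test_inner_wall_diagnostic(self):
        profile = well_profile()
        lm = locate_landmarks(profile, smooth_window=1)
        assert lm.inner_wall is not None and lm.inner_wall < lm.r0
        # the profile rises 4 kcal/mol above the minimum at the inner wall
        g_at = np.interp(lm.inner_wall, profile.grid, profile.energies)
        assert g_at >= lm.g_min + 4.0 - 0.2

    def test_split_half_stability_on_benchmark(self, benchmark_primitives):
        """r0 from disjoint 25-replica halves agrees within one grid spacing."""
        half1 = average_fes(benchmark_primitives[:25])
        half2 = average_fes(benchmark_primitives[25:])
        lm1, lm2 = locate_landmarks(half1), locate_landmarks(half2)
        spacing = max(half1.profile.spacing, half2.profile.spacing)
        assert abs(lm1.r0 - lm2.r0) <= spacing + 1e-12


LM = Landmarks(r0=5.0, rb=7.0, g_min=-8.0)


class TestClassifyRun:
    def test_monotone_exit_is_one_way(self):
        vd = classify_run(traj(np.linspace(4.5, 12.0, 100)), None, LM)
        assert vd.category == "one_way" and vd.action == "keep"
        assert vd.evidence.return_events == 0
        assert vd.evidence.first_crossing_time is not None

    def test_cross_and_return_is_multi_trip(self):
        values = np.concatenate([np.linspace(5, 9, 40), np.linspace(9, 5, 40)])
        vd = classify_run(traj(values), None, LM)
        assert vd.category == "multi_trip" and vd.action == "reject"
        assert vd.evidence.return_events == 1

    def test_drift_below_r0_is_invasion(self):
        values = np.linspace(5.0, -0.0 + 0.0, 50) * 0 + np.linspace(5.0, 0.0, 50)
        vd = classify_run(traj(values), None, LM)
        assert vd.category == "invasion" and vd.action == "reject"
        assert vd.evidence.min_cv < LM.r0 - 4.0

    def test_bound_oscillation_is_incomplete(self):
        rng = np.random.default_rng(0)
        values = 5.5 + 0.8 * np.sin(np.linspace(0, 20, 300)) + 0.05 * rng.standard_normal(300)
        vd = classify_run(traj(values), None, LM)
        assert vd.category == "incomplete" and vd.action == "extend"

    def test_hysteresis_suppresses_boundary_jitter(self):
        # dips to rb - 0.3 after crossing: inside the 0.5 A hysteresis band
        values = np.concatenate([np.linspace(5, 7.5, 30), [6.7, 7.4, 6.8], np.linspace(7.5, 12, 30)])
        vd = classify_run(traj(values), None, LM, hysteresis=0.5)
        assert vd.category == "one_way"
        vd_tight = classify_run(traj(values), None, LM, hysteresis=0.1)
        assert vd_tight.category == "multi_trip"

    def test_invariant_to_uniform_time_rescaling(self):
        rng = np.random.default_rng(11)
        values = np.cumsum(rng.standard_normal(200) * 0.3) + 5.0
        t1 = traj(values)
        t2 = CVTrajectory(run_id="t", times=t1.times * 7.3, values=values)
        v1, v2 = classify_run(t1, None, LM), classify_run(t2, None, LM)
        assert v1.category == v2.category
        assert v1.evidence.return_events == v2.evidence.return_events


def test_all_one_way_keeps_everything():
    profile = well_profile()
    runs = [
        (traj(np.linspace(4.0 + 0.1 * i, 12.0, 80), run_id=f"r{i}"), None)
        for i in range(4)
    ]
    ens_profile = profile
    from dfekit.fes_reconstruction import EnsembleFES

    ens = EnsembleFES(profile=ens_profile, member_ids=[f"r{i}" for i in range(4)])
    verdicts, kept = audit_ensemble(runs, ens)
    assert kept == [f"r{i}" for i in range(4)]
    assert summarize_verdicts(verdicts)["one_way"] == 4


def test_injected_multi_trip_runs_are_rejected(benchmark_replicas, benchmark_primitives):
    """Two synthetic multi-trip replicas injected into a healthy toy ensemble
    are exactly the ones flagged multi-trip among the injected set."""
    ens = average_fes(benchmark_primitives[:20])
    base = [(t, p) for (s, t), p in zip(benchmark_replicas[:20], benchmark_primitives[:20])]
    t_grid = np.linspace(0.0, 3000.0, 500)
    multi1 = CVTrajectory("bad-multi-1", t_grid,
                          np.concatenate([np.linspace(2.5, 15, 250), np.linspace(15, 2.5, 250)]))
    multi2 = CVTrajectory("bad-multi-2", t_grid,
                          2.5 + 13.0 * np.abs(np.sin(np.linspace(0, 6, 500))))
    verdicts, kept = audit_ensemble(base + [(multi1, None), (multi2, None)], ens)
    by_id = {v.run_id: v for v in verdicts}
    assert by_id["bad-multi-1"].category == "multi_trip"
    assert by_id["bad-multi-2"].category == "multi_trip"
    assert not {"bad-multi-1", "bad-multi-2"} & set(kept)


def test_injected_invasion_recognized_for_interior_well():
    """A run drifting >4 Å below r0 without exiting is an invasion (needs a
    bound state far enough from the origin for the rule to be reachable)."""
    profile = well_profile(r0=7.0, plateau_start=9.0, hi=16.0)
    from dfekit.fes_reconstruction import EnsembleFES

    ens = EnsembleFES(profile=profile, member_ids=["a", "b", "c"])
    t_grid = np.linspace(0.0, 3000.0, 400)
    runs = [
        (CVTrajectory("a", t_grid, np.linspace(6.5, 15.5, 400)), None),
        (CVTrajectory("b", t_grid, np.linspace(7.0, 15.9, 400)), None),
        (CVTrajectory("c", t_grid, np.linspace(7.0, 2.5, 400)), None),  # drifts to r0-4.5
    ]
    verdicts, kept = audit_ensemble(runs, ens)
    by_id = {v.run_id: v for v in verdicts}
    assert by_id["c"].category == "invasion" and by_id["c"].action == "reject"
    assert kept == ["a", "b"]


def test_iterate_audit_reaches_fixed_point(benchmark_replicas, benchmark_primitives):
    runs = [(t, p) for (s, t), p in zip(benchmark_replicas[:20], benchmark_primitives[:20])]
    verdicts, kept, averaged, iters = iterate_audit(runs)
    assert 1 <= iters <= 5
    assert set(kept) == {v.run_id for v in verdicts if v.action == "keep"}
    # re-running the audit on the final average changes nothing
    verdicts2, kept2 = audit_ensemble(runs, averaged)
    assert kept2 == kept


def test_verdict_action_consistency_enforced():
    from dfekit.run_audit import RunEvidence, RunVerdict

    ev = RunEvidence(None, 5.0, 0, 0.0)
    with pytest.raises(ValueError, match="requires action"):
        RunVerdict(run_id="x", category="multi_trip", action="keep", evidence=ev)
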