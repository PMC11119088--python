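"""Generative respondent model: closed forms, calibration shape, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from flankit.engine import run_session
from flankit.enums import Condition, Congruency, Direction, Phase, Preference, Response
from flankit.respondent import (
    CALIBRATIONS,
    ChildProfile,
    RespondentParams,
    fit_respondent,
    make_cohort,
    make_responder,
    sample_enjoyment,
    sample_preference,
    sample_response,
)
from flankit.schedule import TaskConfig, TrialSpec

CONG = TrialSpec(index=0, phase=Phase.TEST, congruency=Congruency.CONGRUENT,
                 target_direction=Direction.LEFT)
INCONG = TrialSpec(index=1, phase=Phase.TEST, congruency=Congruency.INCONGRUENT,
                   target_direction=Direction.RIGHT)


def _profile(**overrides):
    params = dict(t0_ms=250.0, mu=math.log(800.0), sigma=0.4, delta_incong=0.2,
                  err_cong=0.1, err_incong=0.25, lapse=0.02)
    params.update(overrides)
    return ChildProfile(
        child_id="x", age_years=4, params=RespondentParams(**params),
        ability_z=0.0, verbal_score=10.0, matrix_score=10.0, enjoyment_bias=2.0,
    )


def test_error_free_child_is_always_correct(rng):
    prof = _profile(err_cong=0.0, err_incong=0.0, lapse=0.0)
    for spec in (CONG, INCONG):
        for _ in range(50):
            response, rt = sample_response(prof, spec, math.inf, rng)
            assert response is Response(spec.target_direction.value)
            assert rt is not None and rt > prof.params.t0_ms


def test_window_below_t0_forces_omission(rng):
    prof = _profile(lapse=0.0)
    for _ in range(100):
        response, rt = sample_response(prof, CONG, prof.params.t0_ms - 1, rng)
        assert response is Response.NONE and rt is None


def test_rt_present_iff_response_and_within_window(rng):
    prof = _profile()
    for _ in range(500):
        response, rt = sample_response(prof, INCONG, 1200.0, rng)
        assert (response is Response.NONE) == (rt is None)
        if rt is not None:
            assert rt <= 1200.0


def test_congruency_rt_gap_matches_lognormal_closed_form(rng):
    """Monte-Carlo means against exp(mu)(e^delta - 1)e^(sigma^2/2)."""
    prof = _profile(err_cong=0.0, err_incong=0.0, lapse=0.0)
    p = prof.params
    n = 100_000
    rts = {}
    for spec in (CONG, INCONG):
        rts[spec.congruency] = np.array(
            [sample_response(prof, spec, math.inf, rng)[1] for _ in range(n)]
        )
    gap = rts[Congruency.INCONGRUENT].mean() - rts[Congruency.CONGRUENT].mean()
    expected = math.exp(p.mu) * (math.exp(p.delta_incong) - 1.0) * math.exp(p.sigma**2 / 2)
    # MC standard error of the gap is ~2 ms at this n
    assert gap == pytest.approx(expected, abs=8.0)


def test_omission_probability_nonincreasing_in_window(rng):
    prof = _profile()
    windows = [600.0, 900.0, 1300.0, 2000.0, 4000.0]
    rates = []
    for w in windows:
        misses = sum(
            sample_response(prof, CONG, w, rng)[0] is Response.NONE for _ in range(4000)
        )
        rates.append(misses / 4000)
    # allow tiny MC wiggle on an otherwise monotone curve
    assert all(a >= b - 0.02 for a, b in zip(rates, rates[1:]))


def test_cohort_reproducible_and_stream_stable():
    a = make_cohort(n=20, seed=11)
    b = make_cohort(n=20, seed=11)
    assert a == b
    # growing the cohort never perturbs existing children
    bigger = make_cohort(n=25, seed=11)
    assert bigger[:20] == a


def test_cohort_age_mix_default_6_6_8():
    ages = [p.age_years for p in make_cohort(n=20, seed=0)]
    assert sorted(set(ages)) == [3, 4, 5]
    assert [ages.count(a) for a in (3, 4, 5)] == [6, 6, 8]


def test_bad_age_mix_rejected():
    with pytest.raises(ValueError):
        make_cohort(n=10, age_mix={3: 0.5, 4: 0.2}, seed=0)


def test_age_presets_monotone():
    """Older preset rows are faster and less error-prone."""
    cal = CALIBRATIONS["preschool2024"]
    p3, p4, p5 = (cal.age_params[a] for a in (3, 4, 5))
    assert p3.mu > p4.mu > p5.mu
    assert p3.lapse > p4.lapse > p5.lapse
    five = make_cohort(n=200, age_mix={3: 0.0, 4: 0.0, 5: 1.0}, seed=2)
    three = make_cohort(n=200, age_mix={3: 1.0, 4: 0.0, 5: 0.0}, seed=2)
    assert np.mean([p.params.mu for p in five]) < np.mean([p.params.mu for p in three])


def test_enjoyment_favors_gamified(rng):
    prof = _profile()
    n = 10_000
    ga = np.array([sample_enjoyment(prof, Condition.GAMIFIED, rng) for _ in range(n)])
    trad = np.array([sample_enjoyment(prof, Condition.TRADITIONAL, rng) for _ in range(n)])
    assert set(np.unique(ga)) <= {1, 2, 3, 4, 5}
    assert ga.mean() > trad.mean() + 0.5


def test_zero_bias_gives_identical_rating_distribution(rng):
    from dataclasses import replace

    prof = replace(_profile(), enjoyment_bias=0.0)
    n = 20_000
    ga = np.array([sample_enjoyment(prof, Condition.GAMIFIED, rng) for _ in range(n)])
    trad = np.array([sample_enjoyment(prof, Condition.TRADITIONAL, rng) for _ in range(n)])
    assert abs(ga.mean() - trad.mean()) < 0.06


def test_preference_default_probabilities(rng):
    prof = _profile()
    n = 10_000
    choices = [sample_preference(prof, rng) for _ in range(n)]
    ga_share = sum(c is Preference.GA for c in choices) / n
    assert ga_share == pytest.approx(0.80, abs=0.02)


def test_parameter_recovery_within_three_se(rng):
    """Closed-form MLE on 10^4 unlimited-window trials recovers the truth."""
    prof = _profile(lapse=0.0)
    p = prof.params
    rows = []
    for i in range(10_000):
        spec = CONG if i % 3 else INCONG  # 2:1 congruent mix
        response, rt = sample_response(prof, spec, math.inf, rng)
        outcome = (
            "CORRECT" if response is Response(spec.target_direction.value) else "COMMISSION"
        )
        rows.append({"congruency": spec.congruency.value, "outcome": outcome, "rt_ms": rt})
    fit = fit_respondent(pd.DataFrame(rows), t0_ms=p.t0_ms)
    assert abs(fit.mu - p.mu) < 3 * fit.se_mu
    assert abs(fit.sigma - p.sigma) < 3 * fit.se_sigma
    assert abs(fit.delta_incong - p.delta_incong) < 3 * fit.se_delta
    assert abs(fit.err_cong - p.err_cong) < 3 * fit.se_err_cong
    assert abs(fit.err_incong - p.err_incong) < 3 * fit.se_err_incong


def test_session_level_conflict_pattern(rng):
    """Pooled over many simulated sessions: slower and less accurate under
    incongruent flankers whenever delta > 0 and err_incong > err_cong."""
    from flankit.scoring import metrics_frame

    cohort = make_cohort(n=40, seed=5)
    cfg = TaskConfig(condition=Condition.TRADITIONAL)
    sessions = [
        run_session(cfg, responder=make_responder(p), rng=np.random.default_rng(100 + i),
                    child_id=p.child_id, age_years=p.age_years)
        for i, p in enumerate(cohort)
    ]
    m = metrics_frame(sessions)
    assert m["acc_congruent"].mean() > m["acc_incongruent"].mean()
    assert m["rt_incongruent_ms"].mean() > m["rt_congruent_ms"].mean()
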