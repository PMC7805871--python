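"""Unit and property tests of the winding-filament muscle-tendon unit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wfhankle import (InputDomainError, MuscleParams, ParameterError,
                      advance_state, ce_velocity, contractile_force,
                      force_length, history_dependence, init_state,
                      oracle_advance, run_isometric, run_ramp_hold,
                      select_damping)
from wfhankle.muscle import DEFAULT_DT, MuscleState

SETTLED = dict(deadline=None, derandomize=True, max_examples=100)


# ---------------------------------------------------------------- force_length

@pytest.mark.parametrize("rel_length, expected", [
    (1.0, 1.0),                 # plateau at optimal length
    (1.5, 0.0),                 # parabola root at +fl_width strain
    (0.5, 0.0),                 # symmetric root
    (1.25, 0.75),               # halfway down the descending limb
    (0.75, 0.75),               # mirrored ascending limb
])
def test_force_length_parabola(posterior, rel_length, expected):
    assert force_length(rel_length * posterior.L0, posterior) == pytest.approx(expected)


@given(strain=st.floats(0.0, 0.99))
@settings(**SETTLED)
def test_force_length_bounded_and_symmetric(posterior, strain):
    up = force_length(posterior.L0 * (1 + strain), posterior)
    down = force_length(posterior.L0 * (1 - strain), posterior)
    assert 0.0 <= up <= 1.0
    assert down == pytest.approx(up, abs=1e-9)


def test_force_length_rejects_nonpositive_length(posterior):
    with pytest.raises(InputDomainError):
        force_length(0.0, posterior)


# ------------------------------------------------------------ contractile_force

def test_contractile_force_table_values(posterior):
    assert contractile_force(1.0, posterior.L0, posterior) == pytest.approx(1654.0)
    assert contractile_force(0.44, posterior.L0, posterior) == pytest.approx(727.76)
    assert contractile_force(0.0, 1.3 * posterior.L0, posterior) == 0.0


def test_contractile_force_rejects_bad_activation(posterior):
    with pytest.raises(ParameterError):
        contractile_force(1.2, posterior.L0, posterior)


# ---------------------------------------------------------------- ce_velocity

def _state(params, Xm, Xp, Xts):
    return MuscleState(t=0.0, Xm=Xm, Xce=0.0, Xp=Xp, Xts=Xts, vce=0.0,
                       Fce=0.0, Fts=params.kts * Xts,
                       Fss=params.kss * (Xm - Xp), act=0.0)


def test_ce_velocity_worked_example(posterior):
    # kss*(Xm-Xp)=155.9 N, Fce=0, Cce=57 -> 155.9/57
    s = _state(posterior, posterior.L0, posterior.L0 - 0.1, 0.0)
    assert ce_velocity(s, 0.0, 57.0, posterior) == pytest.approx(2.7351, abs=1e-4)


def test_ce_velocity_balanced_superposition(posterior):
    Fce = 300.0
    dx = 2 * Fce / posterior.kss
    s = _state(posterior, posterior.L0, posterior.L0 - dx, 0.5)
    assert ce_velocity(s, Fce, posterior.Cce_s, posterior) == pytest.approx(0.0, abs=1e-12)


@given(xts=st.floats(0, 5), delta=st.floats(0, 3), dx=st.floats(-1, 1),
       fce=st.floats(0, 2000))
@settings(**SETTLED)
def test_ce_velocity_titin_terms_cancel(posterior, xts, delta, dx, fce):
    """The titin force appears in both superposed balances with opposite
    sign, so the CE velocity cannot depend on it."""
    a = _state(posterior, posterior.L0, posterior.L0 - dx, xts)
    b = _state(posterior, posterior.L0, posterior.L0 - dx, xts + delta)
    va = ce_velocity(a, fce, 57.0, posterior)
    vb = ce_velocity(b, fce, 57.0, posterior)
    assert va == pytest.approx(vb, rel=1e-12, abs=1e-12)
    closed = (posterior.kss * dx - 2 * fce) / 57.0
    assert va == pytest.approx(closed, rel=1e-12, abs=1e-9)


def test_ce_velocity_rejects_bad_damping(posterior):
    s = _state(posterior, posterior.L0, posterior.L0, 0.0)
    with pytest.raises(ParameterError):
        ce_velocity(s, 0.0, 0.0, posterior)


# -------------------------------------------------------------- select_damping

def test_select_damping_directions(anterior, posterior):
    assert select_damping(+1.0, anterior) == 97.0
    assert select_damping(-1.0, posterior) == 57.0
    assert select_damping(0.0, posterior) == posterior.Cce_l  # tie -> lengthening


# ------------------------------------------------------------------ init/advance

def test_init_state_rest(posterior):
    s = init_state(posterior, posterior.L0)
    assert s.Fss == 0.0 and s.Fts == 0.0 and s.Xts == 0.0 and s.vce == 0.0
    with pytest.raises(InputDomainError):
        init_state(posterior, -1.0)


def test_passive_fixed_point(posterior):
    """Without drive and at constant length the rest state is invariant."""
    s = init_state(posterior, posterior.L0)
    for _ in range(10_000):
        s = advance_state(s, posterior.L0, 0.0, DEFAULT_DT, posterior)
    assert s.Xce == 0.0 and s.Xp == posterior.L0 and s.Xts == 0.0
    assert s.Fss == 0.0 and s.Fts == 0.0


def test_isometric_steady_state_force_doubling(posterior):
    """An activation step at constant length drives the output force to twice
    the contractile force (titin carries an equal share at equilibrium)."""
    trace = run_isometric(posterior, 1.0, posterior.L0, duration=8.0)
    Fce = contractile_force(1.0, posterior.L0, posterior)
    assert trace["Fss_N"].iloc[-1] / (2 * Fce) == pytest.approx(1.0, abs=1e-3)


def test_isometric_trace_monotone_development(posterior):
    trace = run_isometric(posterior, 0.6, posterior.L0, duration=4.0)
    diffs = np.diff(trace["Fss_N"].to_numpy())
    assert diffs.min() > -1e-9 * posterior.P0


def test_isometric_linear_in_activation(posterior):
    lo = run_isometric(posterior, 0.3, posterior.L0, 6.0)["Fss_N"].iloc[-1]
    hi = run_isometric(posterior, 0.6, posterior.L0, 6.0)["Fss_N"].iloc[-1]
    assert hi / lo == pytest.approx(2.0, rel=1e-6)


def test_zero_activation_trace_is_zero(posterior):
    trace = run_isometric(posterior, 0.0, posterior.L0, 1.0)
    assert np.all(trace["Fss_N"].to_numpy() == 0.0)


def test_advance_state_rejects_bad_dt(posterior):
    s = init_state(posterior, posterior.L0)
    with pytest.raises(ParameterError):
        advance_state(s, posterior.L0, 0.5, 0.0, posterior)


def test_titin_strain_never_negative(posterior):
    """Large active shortening pushes titin to slack but never below."""
    trace, _ = run_ramp_hold(posterior, 0.8, posterior.L0 * 1.1, velocity=10.0,
                             amplitude=-0.2 * posterior.L0, hold=1.0)
    assert trace["Xts_cm"].min() >= 0.0


# ---------------------------------------------------------------- ramp-hold

def test_ramp_hold_requires_velocity(posterior):
    with pytest.raises(ParameterError):
        run_ramp_hold(posterior, 0.5, posterior.L0, velocity=0.0, amplitude=1.0, hold=1.0)


def test_ramp_hold_zero_amplitude_matches_isometric(posterior):
    trace, post = run_ramp_hold(posterior, 0.5, posterior.L0, velocity=1.0,
                                amplitude=0.0, hold=1.5, settle=2.0)
    iso = run_isometric(posterior, 0.5, posterior.L0, 3.5)
    n = min(len(trace), len(iso))
    assert np.allclose(trace["Fss_N"].to_numpy()[:n], iso["Fss_N"].to_numpy()[:n])


def test_stretch_enhances_and_shortening_depresses(posterior):
    grid = history_dependence(posterior, act=0.5, amplitude_fracs=(0.05,))
    stretch = grid[grid.protocol == "stretch"].iloc[0]
    shorten = grid[grid.protocol == "shorten"].iloc[0]
    assert stretch.post_force_N > stretch.isometric_N
    assert shorten.post_force_N < shorten.isometric_N


# ---------------------------------------------------------------- oracle

def test_oracle_refinement_one_is_exact(posterior):
    s = init_state(posterior, posterior.L0)
    a = advance_state(s, posterior.L0 + 0.05, 0.7, DEFAULT_DT, posterior)
    b = oracle_advance(s, posterior.L0 + 0.05, 0.7, DEFAULT_DT, posterior, refinement=1)
    assert a == b


def test_oracle_fixed_point_any_refinement(posterior):
    s = init_state(posterior, posterior.L0)
    for refinement in (1, 7, 50):
        out = oracle_advance(s, posterior.L0, 0.0, DEFAULT_DT, posterior, refinement)
        assert out.Fss == 0.0 and out.Xts == 0.0


def test_oracle_rejects_bad_refinement(posterior):
    s = init_state(posterior, posterior.L0)
    with pytest.raises(ParameterError):
        oracle_advance(s, posterior.L0, 0.0, DEFAULT_DT, posterior, refinement=0)


# ---------------------------------------------------------------- params

def test_params_validation():
    with pytest.raises(ParameterError):
        MuscleParams(name="bad", P0=-1.0, kts=1.0, kss=1.0, Cce_l=1.0,
                     Cce_s=1.0, L0=30.0)
    with pytest.raises(ParameterError):
        MuscleParams(name="bad", P0=1.0, kts=1.0, kss=1.0, Cce_l=1.0,
                     Cce_s=1.0, L0=30.0, fl_width=0.0)
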