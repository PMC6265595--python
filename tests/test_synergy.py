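"""Force singular points, torque-sign sectors, and synergy weights."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armstat import (
    ArmGeometry,
    ForceSpec,
    JointConfiguration,
    OnBoundary,
    characteristic_angles,
    classify_sector,
    force_singular_points,
    joint_torques,
    synergy_profile,
    synergy_weights,
)

PI = math.pi

nondegenerate_joints = st.builds(
    JointConfiguration,
    alpha_s=st.floats(0.0, PI * 0.999),
    alpha_e=st.floats(0.05, PI * 0.95),
)


def _ca(alpha_s, alpha_e):
    return characteristic_angles(ArmGeometry(), JointConfiguration(alpha_s, alpha_e))


def test_fsp_known_configuration():
    assert force_singular_points(_ca(0.0, PI / 2)) == pytest.approx(
        [PI / 4, PI / 2, 5 * PI / 4, 3 * PI / 2], abs=1e-12
    )


def test_fsp_collapse_when_elbow_extended():
    """With the elbow fully extended both torques change sign together:
    only two singular points remain and the profile is degenerate."""
    ca = _ca(0.0, 0.0)
    assert force_singular_points(ca) == pytest.approx([0.0, PI], abs=1e-12)
    profile = synergy_profile(ca)
    assert profile.degenerate
    assert len(profile.sectors) == 2
    assert all(s.klass == "TCD" for s in profile.sectors)
    assert profile.w_tod == pytest.approx(0.0, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(joints=nondegenerate_joints)
def test_torques_vanish_at_singular_points(joints):
    """Defining property: one torque is zero at each FSP."""
    geom = ArmGeometry()
    ca = characteristic_angles(geom, joints)
    for theta in force_singular_points(ca):
        tq = joint_torques(ca, ForceSpec(1.0, theta), geom)
        assert min(abs(tq.m_s), abs(tq.m_e)) < 1e-12


def test_sector_classification_around_the_cycle():
    """Sign analysis for the right-angle-elbow end-point: TOD between
    gamma_s and gamma_e, TCD between gamma_e and gamma_s + pi."""
    ca = _ca(0.0, PI / 2)  # gamma_s = pi/4, gamma_e = pi/2
    tod = classify_sector(ca, (PI / 4 + PI / 2) / 2)
    assert (tod.label, tod.klass) == ("Ms+Me-", "TOD")
    assert (tod.shoulder_muscle, tod.elbow_muscle) == ("flexor", "extensor")
    tcd = classify_sector(ca, (PI / 2 + 5 * PI / 4) / 2)
    assert (tcd.label, tcd.klass) == ("Ms+Me+", "TCD")
    assert (tcd.shoulder_muscle, tcd.elbow_muscle) == ("flexor", "flexor")
    both_neg = classify_sector(ca, (3 * PI / 2 + 2 * PI + PI / 4) / 2)
    assert (both_neg.label, both_neg.klass) == ("Ms-Me-", "TCD")


def test_classification_matches_torque_signs():
    geom = ArmGeometry()
    ca = _ca(0.3, 1.1)
    for theta in np.linspace(0.01, 2 * PI - 0.01, 57):
        try:
            sector = classify_sector(ca, theta)
        except OnBoundary:
            continue
        tq = joint_torques(ca, ForceSpec(1.0, theta), geom)
        expected = f"Ms{'+' if tq.m_s > 0 else '-'}Me{'+' if tq.m_e > 0 else '-'}"
        assert sector.label == expected


def test_on_boundary_signal():
    ca = _ca(0.0, PI / 2)
    with pytest.raises(OnBoundary):
        classify_sector(ca, ca.gamma_s)


def test_extended_elbow_is_all_coinciding():
    ca = _ca(0.5, 0.0)
    for theta in (ca.gamma_s + 0.3, ca.gamma_s + 2.0, ca.gamma_s + 4.0):
        assert classify_sector(ca, theta).klass == "TCD"


@pytest.mark.parametrize(
    "alpha_e, w_tcd",
    [(0.0, 1.0), (PI / 2, 0.75)],
)
def test_weights_known_values(alpha_e, w_tcd):
    got_tcd, got_tod = synergy_weights(_ca(0.3, alpha_e))
    assert got_tcd == pytest.approx(w_tcd, abs=1e-12)
    assert got_tod == pytest.approx(1 - w_tcd, abs=1e-12)


def test_weight_limit_at_complete_flexion():
    """w_TCD converges to 0.5 as the elbow approaches complete flexion."""
    from armstat import CharacteristicAngles

    ca = CharacteristicAngles(gamma_s=PI / 2, gamma_e=PI, h_s=0.0)
    assert synergy_weights(ca) == pytest.approx((0.5, 0.5), abs=1e-12)
    # and continuously from the geometric route just short of the limit
    w_tcd, _ = synergy_weights(_ca(0.0, PI * 0.9999))
    assert w_tcd == pytest.approx(0.5, abs=1e-4)


@settings(derandomize=True, max_examples=200)
@given(joints=nondegenerate_joints)
def test_weight_invariants(joints):
    """Weights sum to one, TCD predominates everywhere, and for equal
    segments w_TOD = alpha_e / 2pi independent of the shoulder angle."""
    ca = characteristic_angles(ArmGeometry(), joints)
    w_tcd, w_tod = synergy_weights(ca)
    assert w_tcd + w_tod == pytest.approx(1.0, abs=1e-12)
    assert 0.5 <= w_tcd <= 1.0 + 1e-12
    assert w_tod == pytest.approx(joints.alpha_e / (2 * PI), abs=1e-10)


def test_weight_monotone_in_elbow_angle():
    w = [synergy_weights(_ca(0.4, a))[0] for a in np.linspace(0.0, 0.95 * PI, 30)]
    assert all(a > b for a, b in zip(w, w[1:]))


def test_sector_measure_matches_closed_form():
    """Numerically integrating sector membership over 10^4 directions
    reproduces the closed-form weights."""
    geom = ArmGeometry()
    ca = _ca(0.6, 1.3)
    thetas = (np.arange(10_000) + 0.5) * (2 * PI / 10_000)
    signs_s = np.sign(np.sin(thetas - ca.gamma_s))
    signs_e = np.sign(np.sin(thetas - ca.gamma_e))
    w_tcd_num = np.mean(signs_s == signs_e)
    w_tcd, w_tod = synergy_weights(ca)
    assert w_tcd_num == pytest.approx(w_tcd, abs=2 / 10_000)


def test_sector_widths_and_profile_structure():
    """Four half-open sectors partition the cycle; each TOD sector has
    width equal to the torque-phase lag, and the shoulder flexor onset
    (gamma_s) precedes the elbow flexor onset (gamma_e)."""
    ca = _ca(0.2, 1.0)
    profile = synergy_profile(ca)
    assert len(profile.sectors) == 4
    widths = [s.width for s in profile.sectors]
    assert sum(widths) == pytest.approx(2 * PI, abs=1e-12)
    tod_widths = [s.width for s in profile.sectors if s.klass == "TOD"]
    assert tod_widths == pytest.approx([ca.lag, ca.lag], abs=1e-12)
    assert ca.gamma_s < ca.gamma_e  # shoulder flexors activate first
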