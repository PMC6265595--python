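"""Torque sinusoids and the two independent statics oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armstat import (
    ArmGeometry,
    ForceSpec,
    JointConfiguration,
    characteristic_angles,
    jacobian_transpose_check,
    joint_torques,
    torque_wave,
    virtual_work_residual,
)

PI = math.pi

valid_joints = st.builds(
    JointConfiguration,
    alpha_s=st.floats(0.0, PI * 0.999),
    alpha_e=st.floats(0.0, PI * 0.95),
)
forces = st.builds(
    ForceSpec, f=st.floats(0.0, 3.0), theta=st.floats(0.0, 2 * PI, exclude_max=True)
)


def _fit_sinusoid(theta, samples):
    """Least-squares fit of A sin(theta - phi); returns (A, phi mod 2pi)."""
    design = np.column_stack([np.sin(theta), np.cos(theta)])
    (a, b), *_ = np.linalg.lstsq(design, samples, rcond=None)
    return math.hypot(a, b), math.atan2(-b, a) % (2 * PI)


def test_right_angle_configuration_torques(geom):
    """Backward-pointing force at the (0, pi/2) end-point loads both
    flexors equally: M_s = M_e = 0.5 for a unit force."""
    ca = characteristic_angles(geom, JointConfiguration(0.0, PI / 2))
    tq = joint_torques(ca, ForceSpec(f=1.0, theta=PI), geom)
    assert tq.m_s == pytest.approx(0.5, abs=1e-12)
    assert tq.m_e == pytest.approx(0.5, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(joints=valid_joints, f=st.floats(0.0, 3.0))
def test_torque_zeros_and_peaks_at_phase_angles(joints, f):
    """M_s vanishes at theta = gamma_s and peaks at gamma_s + pi/2."""
    geom = ArmGeometry()
    ca = characteristic_angles(geom, joints)
    assert joint_torques(ca, ForceSpec(f, ca.gamma_s), geom).m_s == pytest.approx(
        0.0, abs=1e-12
    )
    peak = joint_torques(ca, ForceSpec(f, ca.gamma_s + PI / 2), geom).m_s
    assert peak == pytest.approx(f * ca.h_s, abs=1e-12)


def test_wave_amplitudes_and_lag(geom):
    """Extended arm: shoulder peak 2FL, elbow peak FL; right-angle elbow:
    the shoulder wave leads the elbow wave by exactly alpha_e / 2."""
    ca_ext = characteristic_angles(geom, JointConfiguration(0.4, 0.0))
    wave = torque_wave(ca_ext, f=1.0, geom=geom, n_samples=1000)
    assert wave.peak_m_s == pytest.approx(1.0, abs=1e-5)  # 2FL
    assert wave.peak_m_e == pytest.approx(0.5, abs=1e-5)  # FL

    ca = characteristic_angles(geom, JointConfiguration(0.0, PI / 2))
    wave = torque_wave(ca, f=1.0, geom=geom, n_samples=1000)
    _, phi_s = _fit_sinusoid(wave.theta_samples, wave.m_s_samples)
    _, phi_e = _fit_sinusoid(wave.theta_samples, wave.m_e_samples)
    assert (phi_e - phi_s) % (2 * PI) == pytest.approx(PI / 4, abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(joints=valid_joints, f=st.floats(0.1, 3.0))
def test_sinusoid_fit_recovers_amplitude_and_phase(joints, f):
    """The sampled waves are exact sinusoids whose fitted amplitude and
    phase recover (F h_s, gamma_s) and (F L_e, gamma_e)."""
    geom = ArmGeometry()
    ca = characteristic_angles(geom, joints)
    wave = torque_wave(ca, f=f, geom=geom, n_samples=256)
    amp_s, phi_s = _fit_sinusoid(wave.theta_samples, wave.m_s_samples)
    amp_e, phi_e = _fit_sinusoid(wave.theta_samples, wave.m_e_samples)
    assert amp_s == pytest.approx(f * ca.h_s, abs=1e-9)
    assert amp_e == pytest.approx(f * geom.l_e, abs=1e-9)
    assert math.cos(phi_s - ca.gamma_s) == pytest.approx(1.0, abs=1e-9)
    assert math.cos(phi_e - ca.gamma_e) == pytest.approx(1.0, abs=1e-9)
    # residual from the fitted sinusoid is numerically zero
    fit = amp_s * np.sin(wave.theta_samples - phi_s)
    assert np.max(np.abs(fit - wave.m_s_samples)) < 1e-9


def test_equal_flexor_extensor_half_cycles(geom):
    """Each torque is positive on exactly half of the force cycle."""
    ca = characteristic_angles(geom, JointConfiguration(0.7, 0.9))
    wave = torque_wave(ca, f=1.0, geom=geom, n_samples=10_000)
    for samples in (wave.m_s_samples, wave.m_e_samples):
        frac_pos = np.mean(samples > 0)
        assert frac_pos == pytest.approx(0.5, abs=2 / 10_000)
        signs = np.sign(samples[np.abs(samples) > 1e-12])
        assert np.sum(np.diff(signs) != 0) in (1, 2)  # two sign changes per cycle


def test_elbow_amplitude_constant_shoulder_amplitude_decreasing(geom):
    """max|M_e| = F L_e everywhere; max|M_s| strictly decreases with the
    elbow angle at fixed force."""
    peaks_s = []
    for alpha_e in np.arange(10) * PI / 10:
        ca = characteristic_angles(geom, JointConfiguration(0.2, alpha_e))
        wave = torque_wave(ca, f=1.0, geom=geom, n_samples=1000)
        assert wave.peak_m_e == pytest.approx(0.5, abs=1e-5)
        peaks_s.append(wave.peak_m_s)
    assert all(a > b for a, b in zip(peaks_s, peaks_s[1:]))


def test_virtual_work_residual_quadratic_convergence(geom):
    """The finite-difference work residual is a second-order remainder:
    halving delta shrinks it about four-fold, and it is tiny at delta=1e-4."""
    joints = JointConfiguration(0.9, 1.1)
    force = ForceSpec(f=1.3, theta=2.0)
    assert virtual_work_residual(joints, force, geom, delta=1e-4) < 1e-6
    r1 = virtual_work_residual(joints, force, geom, delta=1e-3)
    r2 = virtual_work_residual(joints, force, geom, delta=5e-4)
    assert 3.5 <= r1 / r2 <= 4.5


def test_virtual_work_residual_zero_force(geom):
    assert virtual_work_residual(
        JointConfiguration(0.5, 0.5), ForceSpec(f=0.0, theta=1.0), geom
    ) == pytest.approx(0.0, abs=1e-15)


@settings(derandomize=True, max_examples=300)
@given(
    joints=valid_joints,
    force=forces,
    l_s=st.floats(0.2, 0.8),
    l_e=st.floats(0.2, 0.8),
)
def test_jacobian_transpose_agreement(joints, force, l_s, l_e):
    """The sinusoid torques coincide with J^T F for any lengths, angles
    and force."""
    geom = ArmGeometry(l_s, l_e)
    if (
        math.hypot(
            l_s * math.cos(joints.alpha_s)
            + l_e * math.cos(joints.alpha_s + joints.alpha_e),
            l_s * math.sin(joints.alpha_s)
            + l_e * math.sin(joints.alpha_s + joints.alpha_e),
        )
        < 1e-6
    ):
        return  # end-point at the shoulder axis: gamma_s undefined
    assert jacobian_transpose_check(joints, force, geom) < 1e-10


def test_wave_rejects_tiny_sampling(geom):
    ca = characteristic_angles(geom, JointConfiguration(0.1, 0.1))
    with pytest.raises(ValueError):
        torque_wave(ca, n_samples=3)
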