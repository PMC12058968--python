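"""Synthetic StateRecords realizing each state's defining signature.

These records are constructed, not simulated: static metrics are drawn
inside the region that defines each state, and the MSD/OCF curves are
closed-form signatures of the corresponding dynamics (free-ABP-like decay
for disperse, slowed reorientation for persistent worms, orbital
plateau-oscillation for rotary worms), with optional multiplicative noise.
The dynamic flags (crossover, oscillation) are then computed by the same
estimators used on simulated data, so a recovered label exercises the whole
decision path.  Used for classifier validation; synthetic by construction.
"""

from __future__ import annotations

import math

import numpy as np

from .params import SimParams
from .observables import CurveWithError, abp_msd, abp_ocf
from .classify import (
    ClassifierThresholds,
    StateRecord,
    detect_oscillation,
    estimate_crossover,
)

__all__ = ["synthetic_state_record", "SYNTHETIC_LABELS"]

SYNTHETIC_LABELS = (
    "disperse",
    "multiple_worm",
    "line",
    "persistent_worm",
    "rotary_worm",
    "aster",
    "trans_worm_line",
    "trans_persistent_rotary",
)


def _curve(t: np.ndarray, values: np.ndarray, rng: np.random.Generator,
           noise: float) -> CurveWithError:
    v = values.copy()
    if noise > 0:
        v[1:] = v[1:] * (1.0 + noise * rng.standard_normal(len(v) - 1))
    return CurveWithError(t, v, np.zeros_like(t), np.ones_like(t))


def _slowed_abp_msd(p: SimParams, t: np.ndarray, dr_eff: float) -> np.ndarray:
    """Free-ABP MSD with an effective reorientation rate dr_eff; the
    ballistic-to-diffusive crossover scales with 1/dr_eff."""
    return (4.0 * p.D * t
            + 2.0 * p.v0**2 / dr_eff**2 * (dr_eff * t - 1.0 + np.exp(-dr_eff * t)))


def synthetic_state_record(label: str, rng: np.random.Generator,
                           params: SimParams | None = None,
                           noise: float = 0.01,
                           thresholds: ClassifierThresholds | None = None,
                           ) -> StateRecord:
    """One synthetic record whose metrics realize ``label``'s signature.

    Static metrics are drawn with a margin from the decision boundaries;
    dynamic metrics come from running the crossover/oscillation estimators
    on the constructed curves.
    """
    if label not in SYNTHETIC_LABELS:
        raise ValueError(f"unknown label {label!r}")
    p = params or SimParams(N=100, Phi=0.025)
    th = thresholds or ClassifierThresholds()
    L = p.L
    t = np.arange(0.0, 200.0 + 1e-9, 0.5)

    # defaults: no cluster signal
    psi = float(rng.uniform(0.02, 0.8 * th.psi_lo))
    s_c = float(rng.uniform(0.0, 0.8 * th.s_lo))
    line_fraction = 0.0
    radial = float(rng.uniform(-0.3, 0.3))
    asym = float(rng.uniform(0.3, 0.9))

    msd_vals = abp_msd(p, t)
    ocf_vals = abp_ocf(p, t)

    if label == "disperse":
        pass
    elif label == "aster":
        s_c = float(rng.uniform(1.3 * th.s_lo, 0.45 * L))
        radial = float(rng.uniform(-1.0, 1.2 * th.radial_in))
        # nearly arrested cluster: tiny slow diffusion, frozen orientations
        msd_vals = 4 * 1e-3 * t
        ocf_vals = np.exp(-t / 500.0)
    elif label == "multiple_worm":
        psi = float(rng.uniform(1.1 * th.psi_hi, 0.98))
        s_c = float(rng.uniform(0.5, 0.8 * th.s_lo))
        line_fraction = float(rng.uniform(0.0, 0.8 * th.intermittent_lo))
        msd_vals = _slowed_abp_msd(p, t, 0.02)  # ballistic through the window
        ocf_vals = np.exp(-0.02 * t)
    elif label == "line":
        psi = float(rng.uniform(1.1 * th.psi_hi, 0.98))
        s_c = float(rng.uniform(0.55 * L, 0.9 * L))
        line_fraction = 1.0
        msd_vals = _slowed_abp_msd(p, t, 0.01)
        ocf_vals = np.exp(-0.01 * t)
    elif label == "trans_worm_line":
        psi = float(rng.uniform(1.1 * th.psi_hi, 0.98))
        s_c = float(rng.uniform(1.3 * th.s_lo, 0.45 * L))
        line_fraction = float(rng.uniform(1.5 * th.intermittent_lo,
                                          0.9 * th.intermittent_hi))
        msd_vals = _slowed_abp_msd(p, t, 0.05)
        ocf_vals = np.exp(-0.05 * t)
    elif label == "persistent_worm":
        psi = float(rng.uniform(1.1 * th.psi_hi, 0.98))
        s_c = float(rng.uniform(1.3 * th.s_lo, 0.45 * L))
        asym = float(rng.uniform(0.75, 0.98))
        dr_eff = float(rng.uniform(0.2, 0.5))  # slower reorientation than ABP
        msd_vals = _slowed_abp_msd(p, t, dr_eff)
        ocf_vals = np.exp(-dr_eff * t)
    elif label == "rotary_worm":
        psi = float(rng.uniform(1.1 * th.psi_hi, 0.98))
        s_c = float(rng.uniform(1.3 * th.s_lo, 0.45 * L))
        asym = float(rng.uniform(0.02, 0.3))
        # orbiting cluster: plateau with persistent oscillation plus a slow
        # center-of-rotation drift keeping the curve positive
        a = float(rng.uniform(2.0, 6.0))
        period = float(rng.uniform(4.0, 20.0))
        omega = 2 * math.pi / period
        msd_vals = 4 * 5e-3 * t + 2 * a**2 * (1 - np.cos(omega * t))
        ocf_vals = np.cos(omega * t) * np.exp(-t / 400.0)
    else:  # trans_persistent_rotary
        psi = float(rng.uniform(1.1 * th.psi_hi, 0.98))
        s_c = float(rng.uniform(1.3 * th.s_lo, 0.45 * L))
        asym = float(rng.uniform(0.3, 0.7))
        if rng.random() < 0.5:
            # crossover earlier than a standard ABP's, no oscillation
            dr_eff = float(rng.uniform(3.0, 8.0))
            msd_vals = _slowed_abp_msd(p, t, dr_eff)
            ocf_vals = np.exp(-dr_eff * t)
        else:
            # damped oscillation on top of late (sub-)diffusion
            a = float(rng.uniform(2.0, 5.0))
            period = float(rng.uniform(4.0, 10.0))
            omega = 2 * math.pi / period
            damp = np.exp(-t / period)
            msd_vals = (4 * 5.0 * t
                        + 2 * a**2 * (1 - np.cos(omega * t)) * damp)
            ocf_vals = np.cos(omega * t) * damp

    msd_curve = _curve(t, msd_vals, rng, noise)
    ocf_curve = _curve(t, ocf_vals, rng, noise)
    abp_curve = CurveWithError(t, abp_msd(p, t), np.zeros_like(t), np.ones_like(t))

    record = StateRecord(
        params=p, init_kind="synthetic", seed=0,
        psi_mean=psi, s_c_mean=s_c, s_mean=s_c, line_fraction=line_fraction,
        radial_order_mean=radial, asymmetry_mean=asym, n_clusters_mean=1.0,
        msd_curve=msd_curve, ocf_curve=ocf_curve,
        msd_uniform=msd_curve, ocf_uniform=ocf_curve,
    )
    record.crossover = estimate_crossover(msd_curve, th.slope_diffusive)
    record.abp_crossover = estimate_crossover(abp_curve, th.slope_diffusive)
    record.oscillation, record.oscillation_period = detect_oscillation(
        msd_curve, ocf_curve, th)
    return record
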