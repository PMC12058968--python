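"""Six-state classification of runs and (R, T0) state-diagram sweeps.

A run is summarized by static metrics (time-averaged polar order Psi,
average cluster size S_c, system size S, radial orientation order,
asymmetry) and dynamic metrics (MSD/OCF, ballistic-to-diffusive crossover
time, oscillation signature).  The decision rule assigns one of

    disperse, multiple_worm, line, persistent_worm, rotary_worm, aster,

plus two transition states (multiple-worm <-> line intermittency and the
persistent <-> rotary crossover).  The numeric thresholds separating the
static groupings are configurable; the dynamic split compares against a
standard ABP's crossover computed with the same estimator on the analytic
curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .params import SimParams
from .state import Trajectory
from . import observables as obs
from .observables import CurveWithError

__all__ = [
    "ClassifierThresholds",
    "StateRecord",
    "StateDiagram",
    "LABELS",
    "analyze",
    "estimate_crossover",
    "detect_oscillation",
    "classify",
    "sweep",
]

LABELS = (
    "disperse",
    "multiple_worm",
    "line",
    "persistent_worm",
    "rotary_worm",
    "aster",
    "trans_worm_line",
    "trans_persistent_rotary",
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable decision boundaries (box-size L enters separately).

    psi_lo / psi_hi split low / high polar order; s_lo (in sigma) splits
    small from extended clusters; radial_in is the outward radial-order
    value below which a low-Psi compact grouping counts as an aster.
    The intermittency band applies to the fraction of frames whose largest
    cluster extent exceeds L/2 (the per-frame line criterion).  Oscillations require the OCF to dip below ocf_depth
    with a dominant spectral peak >= spectral_ratio times the background,
    or >= 2 MSD local maxima past the plateau onset.
    """

    psi_lo: float = 0.3
    psi_hi: float = 0.6
    s_lo: float = 5.0
    radial_in: float = -0.5
    intermittent_lo: float = 0.05
    intermittent_hi: float = 0.95
    slope_diffusive: float = 1.5
    ocf_depth: float = -0.1
    spectral_ratio: float = 3.0
    msd_peak_prominence: float = 0.1


@dataclass
class StateRecord:
    """Per-run summary consumed by :func:`classify`."""

    params: SimParams
    init_kind: str
    seed: int
    psi_mean: float
    s_c_mean: float
    s_mean: float
    line_fraction: float  # fraction of frames whose largest cluster spans > L/2
    radial_order_mean: float
    asymmetry_mean: float
    n_clusters_mean: float
    msd_curve: CurveWithError
    ocf_curve: CurveWithError
    msd_uniform: CurveWithError
    ocf_uniform: CurveWithError
    crossover: float | None = None
    abp_crossover: float | None = None
    oscillation: bool = False
    oscillation_period: float | None = None
    label: str | None = None
    unclassifiable: bool = False


# ---------------------------------------------------------------------------
# dynamic-signature estimators
# ---------------------------------------------------------------------------

def loglog_slope(lags: np.ndarray, values: np.ndarray,
                 points_per_decade: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Local log-log slope by centered differences.

    The curve is first thinned to at most ``points_per_decade`` log-spaced
    lags; on a uniform lag grid the late-time log spacing shrinks toward
    zero and centered differences would amplify sampling noise without this.
    """
    ok = (lags > 0) & (values > 0)
    t_all = lags[ok]
    y_all = values[ok]
    if t_all.size < 3:
        raise ValueError("curve too short for slope estimation")
    decades = math.log10(t_all[-1] / t_all[0])
    n_target = max(3, int(points_per_decade * decades) + 1)
    targets = np.logspace(math.log10(t_all[0]), math.log10(t_all[-1]), n_target)
    idx = np.unique(np.searchsorted(t_all, targets).clip(0, t_all.size - 1))
    t = np.log(t_all[idx])
    y = np.log(y_all[idx])
    return t_all[idx], np.gradient(y, t)


def estimate_crossover(curve: CurveWithError,
                       slope_threshold: float = 1.5) -> float | None:
    """First lag where the local log-log MSD slope drops below the threshold
    and stays below it for a decade (or to the end of the curve); None if the
    curve never leaves the ballistic regime.  The curve must span at least
    two decades of lag."""
    lags, slope = loglog_slope(curve.lags, curve.mean)
    if lags[-1] / lags[0] < 100.0 * (1 - 1e-9):
        raise ValueError("crossover estimation needs >= 2 decades of lag")
    below = slope < slope_threshold
    for k in range(len(lags)):
        if not below[k]:
            continue
        if 10.0 * lags[k] > lags[-1] * (1 + 1e-9):
            break  # cannot confirm persistence over a full decade
        window = (lags >= lags[k]) & (lags <= 10.0 * lags[k] * (1 + 1e-9))
        if np.all(below[window]):
            return float(lags[k])
    return None


def _dominant_period(t: np.ndarray, y: np.ndarray,
                     spectral_ratio: float) -> float | None:
    """Period of the dominant nonzero-frequency peak of a uniformly sampled
    signal, if it stands >= spectral_ratio above the median background."""
    if len(t) < 8:
        return None
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-6):
        raise ValueError("oscillation detection requires uniform sampling")
    yz = y - y.mean()
    power = np.abs(np.fft.rfft(yz)) ** 2
    freqs = np.fft.rfftfreq(len(yz), d=dt)
    power[0] = 0.0
    k = int(np.argmax(power))
    if k == 0:
        return None
    background = np.median(power[1:])
    if background <= 0 or power[k] < spectral_ratio * background:
        return None
    # quadratic interpolation around the peak for sub-bin frequency
    if 1 <= k < len(power) - 1:
        a, b, c = power[k - 1], power[k], power[k + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    f = freqs[k] + shift * (freqs[1] - freqs[0])
    return 1.0 / f if f > 0 else None


def detect_oscillation(msd_curve: CurveWithError, ocf_curve: CurveWithError,
                       thresholds: ClassifierThresholds = ClassifierThresholds(),
                       ) -> tuple[bool, float | None]:
    """Flag rotary-worm dynamics: an OCF that swings negative with a dominant
    spectral peak, or an MSD with repeated local maxima about a plateau.
    Returns (flag, dominant period or None)."""
    t = ocf_curve.lags
    y = ocf_curve.mean
    pos = t > 0
    period = _dominant_period(t[pos], y[pos], thresholds.spectral_ratio)
    ocf_flag = (y.min() < thresholds.ocf_depth) and period is not None

    m = msd_curve.mean
    msd_flag = False
    if m.max() > 0 and len(m) >= 8:
        plateau = float(np.median(m[-max(2, len(m) // 4):]))
        onset_idx = np.flatnonzero(m >= 0.5 * plateau)
        if len(onset_idx):
            tail = m[onset_idx[0]:]
            peaks, _ = find_peaks(
                tail, prominence=thresholds.msd_peak_prominence * plateau)
            msd_flag = len(peaks) >= 2
            if msd_flag and period is None and len(peaks) >= 2:
                tt = msd_curve.lags[onset_idx[0]:]
                period = float(np.mean(np.diff(tt[peaks])))
    return (ocf_flag or msd_flag), period


# ---------------------------------------------------------------------------
# trajectory -> StateRecord
# ---------------------------------------------------------------------------

def analyze(traj: Trajectory, thresholds: ClassifierThresholds = ClassifierThresholds(),
            init_kind: str = "unknown", cluster_eps: float = 1.5,
            max_uniform_lags: int = 400) -> StateRecord:
    """Compute every static and dynamic metric of a trajectory.

    Static metrics are averaged over collection frames.  Two MSD/OCF
    samplings are produced: log-spaced lags for crossover slopes and a
    uniform-lag grid for spectral oscillation detection.
    """
    p = traj.params
    L = p.L
    f = traj.n_frames

    psis = np.empty(f)
    s_cs = np.empty(f)
    s_max = np.empty(f)  # largest single-cluster extent per frame
    s_sys = np.empty(f)
    radials = np.empty(f)
    asyms = np.full(f, np.nan)
    n_clusters = np.empty(f)
    for k in range(f):
        pos = traj.pos[k]
        phi = traj.phi[k]
        psis[k] = obs.polar_order(phi)
        lab = obs.find_clusters(pos, L, eps=cluster_eps, t=float(traj.times[k]))
        s_cs[k] = obs.cluster_size(lab, pos, L)
        s_max[k] = max(
            obs.cluster_size(
                obs.ClusterLabeling(lab.t, np.zeros(np.sum(lab.labels == c), int),
                                    lab.coms[c:c + 1], 1),
                pos[lab.labels == c], L)
            for c in range(lab.n_clusters))
        s_sys[k] = obs.system_size(pos, L)
        radials[k] = obs.radial_order(pos, phi, lab, L)
        n_clusters[k] = lab.n_clusters
        frame_asym = [obs.asymmetry(pos[lab.labels == c], L)
                      for c in range(lab.n_clusters)
                      if np.sum(lab.labels == c) >= 2]
        frame_asym = [a for a in frame_asym if not math.isnan(a)]
        if frame_asym:
            asyms[k] = float(np.mean(frame_asym))

    msd_log = obs.msd(traj)
    ocf_log = obs.ocf(traj)
    stride = max(1, (f - 1) // max_uniform_lags)
    uniform = np.arange(0, f, stride)
    msd_uni = obs.msd(traj, uniform)
    ocf_uni = obs.ocf(traj, uniform)

    record = StateRecord(
        params=p, init_kind=init_kind, seed=p.seed,
        psi_mean=float(psis.mean()),
        s_c_mean=float(s_cs.mean()),
        s_mean=float(s_sys.mean()),
        line_fraction=float(np.mean(s_max > L / 2)),
        radial_order_mean=float(np.nanmean(radials)),
        asymmetry_mean=float(np.nanmean(asyms)) if np.any(np.isfinite(asyms)) else float("nan"),
        n_clusters_mean=float(n_clusters.mean()),
        msd_curve=msd_log, ocf_curve=ocf_log,
        msd_uniform=msd_uni, ocf_uniform=ocf_uni,
    )
    try:
        record.crossover = estimate_crossover(msd_log, thresholds.slope_diffusive)
        abp_curve, _ = obs.abp_baselines(p, msd_log.lags)
        record.abp_crossover = estimate_crossover(abp_curve, thresholds.slope_diffusive)
    except ValueError:
        record.crossover = None
        record.abp_crossover = None
    record.oscillation, record.oscillation_period = detect_oscillation(
        msd_uni, ocf_uni, thresholds)
    return record


# ---------------------------------------------------------------------------
# decision rule
# ---------------------------------------------------------------------------

def classify(record: StateRecord,
             thresholds: ClassifierThresholds = ClassifierThresholds()) -> str:
    """Assign a state label from the stored metrics (pure function).

    Static split first (polar order vs cluster/system size, aster via
    inward radial order), then the worm family is divided by dynamics:
    persistent worms keep a ballistic-to-diffusive crossover later than a
    standard ABP's, rotary worms never turn diffusive but oscillate, and
    runs with an early crossover or mixed signatures are the
    persistent/rotary transition state.  Records matching no rule raise
    (flagged unclassifiable), never a silent default.
    """
    th = thresholds
    psi = record.psi_mean
    s_c = record.s_c_mean
    L = record.params.L

    label: str | None = None
    if psi < th.psi_lo and s_c > th.s_lo and record.radial_order_mean < th.radial_in:
        label = "aster"
    elif psi < th.psi_lo and s_c <= th.s_lo:
        label = "disperse"
    elif psi >= th.psi_hi and s_c > L / 2:
        label = "line"
    elif psi >= th.psi_hi and th.intermittent_lo < record.line_fraction < th.intermittent_hi:
        label = "trans_worm_line"
    elif psi >= th.psi_hi and s_c <= th.s_lo:
        label = "multiple_worm"
    else:
        xo = record.crossover
        abp_xo = record.abp_crossover
        if xo is not None and abp_xo is not None and xo > abp_xo and not record.oscillation:
            label = "persistent_worm"
        elif xo is None and record.oscillation:
            label = "rotary_worm"
        elif xo is not None and (record.oscillation or (abp_xo is not None and xo <= abp_xo)):
            label = "trans_persistent_rotary"
    if label is None:
        record.unclassifiable = True
        raise ValueError(
            "record does not match any state rule; flagged for manual review "
            f"(Psi={psi:.3f}, S_c={s_c:.3f}, crossover={record.crossover}, "
            f"oscillation={record.oscillation})")
    record.label = label
    return label


# ---------------------------------------------------------------------------
# state-diagram sweep
# ---------------------------------------------------------------------------

@dataclass
class StateDiagram:
    """Multiset of labels per (R, T0) cell over runs and initializations."""

    R_values: tuple
    T0_values: tuple
    entries: list = field(default_factory=list)  # dicts: R, T0, init, seed, label/error

    def counts(self, R: float, T0: float) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            if e["R"] == R and e["T0"] == T0 and "label" in e:
                out[e["label"]] = out.get(e["label"], 0) + 1
        return out

    def to_dict(self) -> dict:
        return {"R_values": list(self.R_values), "T0_values": list(self.T0_values),
                "entries": self.entries}


def sweep(base_params: SimParams, R_values, T0_values, inits, seeds,
          thresholds: ClassifierThresholds = ClassifierThresholds(),
          done: dict | None = None, progress: bool = False) -> StateDiagram:
    """Run simulate -> analyze -> classify over an (R, T0) grid.

    ``inits`` is a sequence of InitialCondition objects; every (R, T0, init,
    seed) combination is one independent run.  ``done`` maps completed keys
    (R, T0, init.kind, seed) to labels and lets an interrupted sweep resume.
    Failed runs are recorded with their error message, never dropped.
    """
    from .dynamics import run_simulation

    diagram = StateDiagram(tuple(R_values), tuple(T0_values))
    done = done or {}
    for R in R_values:
        for T0 in T0_values:
            for init in inits:
                for seed in seeds:
                    key = (R, T0, init.kind, seed)
                    entry = {"R": R, "T0": T0, "init": init.kind, "seed": seed}
                    if key in done:
                        entry["label"] = done[key]
                        diagram.entries.append(entry)
                        continue
                    params = base_params.replace(R=R, T0=T0, seed=seed)
                    try:
                        traj = run_simulation(params, init)
                        record = analyze(traj, thresholds, init_kind=init.kind)
                        entry["label"] = classify(record, thresholds)
                        entry["psi"] = record.psi_mean
                        entry["s_c"] = record.s_c_mean
                    except Exception as err:  # recorded, not dropped
                        entry["error"] = f"{type(err).__name__}: {err}"
                    if progress:
                        print(f"R={R} T0={T0} init={init.kind} seed={seed} -> "
                              f"{entry.get('label', entry.get('error'))}",
                              flush=True)
                    diagram.entries.append(entry)
    return diagram
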