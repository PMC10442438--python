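"""Intrinsic membrane properties and short-term synaptic dynamics from
whole-cell sweeps.

Protocols mirror standard slice-physiology practice: a 5 mV / 1 s seal test
and -110 +/- 30 mV voltage steps (10 mV increments) for passive properties,
a 0-300 pA / 1 s current ramp for rheobase and spike threshold, 0-300 pA /
2 s current steps (20 pA increments) for the F-I relation, and paired or
10-pulse optogenetic stimulation (2 ms pulses, 50 ms interval) for
short-term plasticity.

Passive-property extraction fits the seal-test current transient with
``I(t) = A exp(-t/tau) + I_ss`` (relative to the pre-step holding current).
For a single-compartment RC cell accessed through a series resistance Rs,
``I(0) = dV/Rs``, ``I_ss = dV/(Rs+Rm)`` and ``tau = Cm * Rs*Rm/(Rs+Rm)``,
which inverts to Rs, Rm and Cm. Input resistance is the slope of the
steady-state I-V relation over subthreshold voltage steps. PSC amplitudes
are measured from a local baseline (mean of the 5 ms before each pulse) to
the extremum inside a 40 ms post-pulse window, so a response riding on the
previous pulse's decay is still referenced correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, ParameterError, ProtocolError

__all__ = [
    "EphysSweepSet",
    "IntrinsicProperties",
    "SynapticDynamics",
    "seal_test_properties",
    "iv_input_resistance",
    "ramp_rheobase",
    "fi_curve",
    "intrinsic_properties",
    "paired_pulse_ratio",
    "train_dynamics",
]


@dataclass
class EphysSweepSet:
    """A set of sweeps from one protocol.

    ``response`` is (n_sweeps, n_samples): current (pA) in voltage clamp,
    voltage (mV) in current clamp. ``meta`` carries protocol parameters
    (step values, pulse times, command amplitudes...).
    """

    time: np.ndarray
    response: np.ndarray
    protocol: str
    rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.response = np.atleast_2d(np.asarray(self.response, float))
        if self.response.shape[1] != len(self.time):
            raise ProtocolError("response and time lengths differ")
        if self.rate <= 0:
            raise ParameterError("sampling rate must be positive")


@dataclass
class IntrinsicProperties:
    membrane_resistance_mohm: float = np.nan   # Rm from the seal test
    series_resistance_mohm: float = np.nan
    membrane_capacitance_pf: float = np.nan
    input_resistance_mohm: float = np.nan      # slope of the I-V relation
    rheobase_pa: float = np.nan
    spike_threshold_mv: float = np.nan
    fi_currents_pa: np.ndarray | None = None
    fi_rates_hz: np.ndarray | None = None


@dataclass
class SynapticDynamics:
    amplitudes_pa: np.ndarray        # per-pulse, magnitudes
    normalized: np.ndarray           # amplitudes / amplitude of pulse 1
    peak_latencies_s: np.ndarray     # pulse onset -> PSC peak
    ppr: float = np.nan              # amplitude 2 / amplitude 1


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------

def _step_edges(sweeps: EphysSweepSet) -> tuple[int, int]:
    on = sweeps.meta.get("step_onset_s", 0.1)
    dur = sweeps.meta.get("step_duration_s", 1.0)
    i0 = int(round(on * sweeps.rate))
    i1 = int(round((on + dur) * sweeps.rate))
    return i0, min(i1, sweeps.response.shape[1])


def seal_test_properties(sweeps: EphysSweepSet) -> tuple[float, float, float]:
    """(Rs, Rm, Cm) in (MOhm, MOhm, pF) from a voltage-clamp seal test.

    Fits the on-transient of the step current with a single exponential plus
    plateau and inverts the RC-through-Rs circuit equations. The command
    step amplitude (mV) is read from ``meta['step_mv']`` (default 5).
    """
    if sweeps.protocol != "seal_test":
        raise ProtocolError("expected a seal_test sweep set")
    dv = float(sweeps.meta.get("step_mv", 5.0)) * 1e-3  # V
    i0, i1 = _step_edges(sweeps)
    resp = sweeps.response.mean(axis=0) * 1e-12  # A
    base = resp[max(0, i0 - int(0.02 * sweeps.rate)):i0].mean() if i0 else 0.0
    seg = resp[i0:i1] - base
    t = (np.arange(len(seg))) / sweeps.rate

    i_ss = seg[int(len(seg) * 0.8):].mean()
    a0 = max(seg[0] - i_ss, 1e-15)
    # crude tau from the 1/e crossing for the initial guess
    below = np.flatnonzero(seg - i_ss < a0 / np.e)
    tau0 = t[below[0]] if len(below) else 1e-3
    tau0 = max(tau0, 1.0 / sweeps.rate)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    popt, _ = curve_fit(model, t, seg, p0=(a0, tau0, i_ss),
                        maxfev=20000)
    a, tau, c = popt
    i_peak = a + c                      # extrapolated I(0) = dV / Rs
    if i_peak <= 0 or c <= 0:
        raise DataError("seal-test transient has no measurable response")
    rs = dv / i_peak                    # Ohm
    rm = dv / c - rs
    if rm <= 0:
        raise DataError("non-physical membrane resistance from seal test")
    cm = tau * (rs + rm) / (rs * rm)    # F
    return rs / 1e6, rm / 1e6, cm * 1e12


def iv_input_resistance(sweeps: EphysSweepSet) -> float:
    """Input resistance (MOhm): slope of the steady-state I-V relation.

    Voltage steps are read from ``meta['step_values_mv']``; steady-state
    current is the mean over the last 20% of each step.
    """
    if sweeps.protocol != "iv_steps":
        raise ProtocolError("expected an iv_steps sweep set")
    steps = np.asarray(sweeps.meta["step_values_mv"], float)
    if len(steps) != sweeps.response.shape[0]:
        raise ProtocolError("one command step per sweep required")
    i0, i1 = _step_edges(sweeps)
    tail = slice(i0 + int((i1 - i0) * 0.8), i1)
    i_ss = sweeps.response[:, tail].mean(axis=1)  # pA
    slope = np.polyfit(steps, i_ss, 1)[0]         # pA / mV
    if slope <= 0:
        raise DataError("non-positive I-V slope")
    return 1000.0 / slope                         # MOhm


def ramp_rheobase(
    sweeps: EphysSweepSet, dvdt_threshold_mv_ms: float = 20.0
) -> tuple[float, float]:
    """(rheobase pA, spike threshold mV) from a current ramp.

    The threshold is the membrane potential at the first crossing of the
    dV/dt criterion; the rheobase is the commanded ramp current at that
    sample. Both are NaN when no spike occurs.
    """
    if sweeps.protocol != "ramp":
        raise ProtocolError("expected a ramp sweep set")
    ramp = np.asarray(sweeps.meta["command_pa"], float)
    i0, i1 = _step_edges(sweeps)
    if np.any(np.diff(ramp[i0:i1]) < 0):
        raise ProtocolError("ramp command must be non-decreasing")
    v = sweeps.response[0]
    dvdt = np.diff(v) * sweeps.rate / 1000.0  # mV/ms
    idx = np.flatnonzero(dvdt[i0:i1] >= dvdt_threshold_mv_ms)
    if len(idx) == 0:
        return np.nan, np.nan
    i = i0 + int(idx[0])
    return float(ramp[i]), float(v[i])


def fi_curve(sweeps: EphysSweepSet) -> tuple[np.ndarray, np.ndarray]:
    """(injected currents pA, firing rates Hz) from 2 s current steps.

    Spikes are counted as upward crossings of ``meta['spike_detect_mv']``
    (default 0 mV) during the step.
    """
    if sweeps.protocol != "fi_steps":
        raise ProtocolError("expected an fi_steps sweep set")
    steps = np.asarray(sweeps.meta["step_values_pa"], float)
    thr = float(sweeps.meta.get("spike_detect_mv", 0.0))
    dur = float(sweeps.meta.get("step_duration_s", 2.0))
    i0, i1 = _step_edges(sweeps)
    rates = np.empty(len(steps))
    for k, sweep in enumerate(sweeps.response):
        seg = sweep[i0:i1]
        crossings = np.sum((seg[1:] >= thr) & (seg[:-1] < thr))
        rates[k] = crossings / dur
    return steps, rates


def intrinsic_properties(protocols: dict) -> IntrinsicProperties:
    """Combine whichever protocols are present into one property record.

    ``protocols`` maps protocol name -> :class:`EphysSweepSet`; any of
    ``seal_test``, ``iv_steps``, ``ramp``, ``fi_steps`` may be given.
    """
    props = IntrinsicProperties()
    if "seal_test" in protocols:
        rs, rm, cm = seal_test_properties(protocols["seal_test"])
        props.series_resistance_mohm = rs
        props.membrane_resistance_mohm = rm
        props.membrane_capacitance_pf = cm
    if "iv_steps" in protocols:
        props.input_resistance_mohm = iv_input_resistance(protocols["iv_steps"])
    if "ramp" in protocols:
        props.rheobase_pa, props.spike_threshold_mv = ramp_rheobase(protocols["ramp"])
    if "fi_steps" in protocols:
        props.fi_currents_pa, props.fi_rates_hz = fi_curve(protocols["fi_steps"])
    return props


# ---------------------------------------------------------------------------
# synaptic dynamics
# ---------------------------------------------------------------------------

def _psc_amplitudes(
    sweeps: EphysSweepSet,
    pulse_times: np.ndarray,
    sign: int,
    baseline_s: float = 0.005,
    search_s: float = 0.040,
) -> tuple[np.ndarray, np.ndarray]:
    trace = sweeps.response.mean(axis=0)
    rate = sweeps.rate
    amps = np.empty(len(pulse_times))
    lats = np.empty(len(pulse_times))
    for k, tp in enumerate(pulse_times):
        ip = int(round(tp * rate))
        b0 = max(0, ip - int(round(baseline_s * rate)))
        base = trace[b0:ip].mean() if ip > b0 else trace[ip]
        seg = trace[ip:ip + int(round(search_s * rate)) + 1]
        if len(seg) == 0:
            raise DataError("pulse window falls outside the sweep")
        dev = sign * (seg - base)
        j = int(np.argmax(dev))
        amps[k] = dev[j]
        lats[k] = j / rate
    return amps, lats


def _response_sign(sweeps: EphysSweepSet, sign: int | None) -> int:
    if sign is not None:
        return sign
    # EPSCs at -70 mV are inward (negative); IPSCs at 0 mV outward (positive)
    kind = sweeps.meta.get("psc_kind", "EPSC")
    return -1 if kind.upper() == "EPSC" else +1


def paired_pulse_ratio(
    sweeps: EphysSweepSet,
    pulse_times,
    sign: int | None = None,
    noise_floor_pa: float = 1.0,
) -> SynapticDynamics:
    """Paired-pulse ratio A2/A1 from two stimulation pulses.

    A PPR below 1 indicates short-term depression. Amplitudes are magnitudes
    measured from each pulse's local pre-pulse baseline; an undetectable
    first response raises.
    """
    pulse_times = np.asarray(pulse_times, float)
    if len(pulse_times) != 2:
        raise ParameterError("paired-pulse analysis needs exactly 2 pulses")
    amps, lats = _psc_amplitudes(sweeps, pulse_times, _response_sign(sweeps, sign))
    if amps[0] <= noise_floor_pa:
        raise DataError("first-pulse response below the noise floor; PPR undefined")
    return SynapticDynamics(amplitudes_pa=amps, normalized=amps / amps[0],
                            peak_latencies_s=lats, ppr=float(amps[1] / amps[0]))


def train_dynamics(
    sweeps: EphysSweepSet,
    pulse_times,
    sign: int | None = None,
    noise_floor_pa: float = 1.0,
) -> SynapticDynamics:
    """Ten-pulse train amplitudes normalized to the first pulse."""
    pulse_times = np.asarray(pulse_times, float)
    if len(pulse_times) != 10:
        raise ParameterError("train analysis needs exactly 10 pulses")
    amps, lats = _psc_amplitudes(sweeps, pulse_times, _response_sign(sweeps, sign))
    if amps[0] <= noise_floor_pa:
        raise DataError("first-pulse response below the noise floor")
    norm = amps / amps[0]
    return SynapticDynamics(amplitudes_pa=amps, normalized=norm,
                            peak_latencies_s=lats, ppr=float(norm[1]))
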