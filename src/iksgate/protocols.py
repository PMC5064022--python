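"""Voltage-clamp protocols and macroscopic-current synthesis.

Protocols are ordered piecewise-constant voltage segments, grouped into
sweeps.  Driving a gating scheme through a protocol yields a
:class:`Recording`: per-sweep time, voltage and current traces, where the
macroscopic current is ``I = Gmax * Popen * (V - Erev)`` with ``Popen`` the
summed occupancy of the conducting states.  Outward current is positive, so
tail currents at -120 mV (below the K+ reversal potential) are inward
(negative), as in the experiments these protocols mirror.

Presets cover the standard two-electrode voltage-clamp repertoire for the
slow delayed rectifier: repetitive +40 mV test pulses, an activation
current-voltage family with -120 mV tails, deactivation tail families, a
long closed-state rest at the holding potential, subthreshold conditioning
trains, and the six-sweep activation family used for model simulations
(-40..+60 mV, 5 s, tail -120 mV).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gating import (
    ConfigurationError,
    GatingScheme,
    OccupancyTrace,
    _evolve,
    scheme_to_dict,
    steady_state,
)

__all__ = [
    "Segment",
    "VoltageProtocol",
    "SimulationSettings",
    "SweepTrace",
    "Recording",
    "PROTOCOL_NAMES",
    "preset_protocol",
    "simulate_recording",
    "open_probability",
]


@dataclass(frozen=True)
class Segment:
    duration_s: float
    voltage_mV: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("segment duration must be positive")


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered piecewise-constant voltage segments, grouped into sweeps.

    ``test_segment`` / ``tail_segment`` index the segment within each sweep
    holding the variable test voltage and the fixed tail step, when the
    protocol has them.  ``carry_over`` keeps the channel occupancy across
    sweeps (repetitive and conditioning protocols); otherwise each sweep
    restarts from the holding-potential steady state.
    """

    name: str
    sweeps: tuple[tuple[Segment, ...], ...]
    dt_s: float = 1e-3
    holding_mV: float = -80.0
    carry_over: bool = False
    test_segment: int | None = None
    tail_segment: int | None = None

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ConfigurationError("protocol needs at least one sweep")
        shortest = min(seg.duration_s for sweep in self.sweeps for seg in sweep)
        if self.dt_s > shortest:
            raise ConfigurationError(
                f"sampling interval {self.dt_s} s exceeds the shortest segment ({shortest} s)"
            )

    @property
    def test_voltages(self) -> np.ndarray:
        if self.test_segment is None:
            raise ConfigurationError(f"protocol {self.name!r} has no test segment")
        return np.array([sweep[self.test_segment].voltage_mV for sweep in self.sweeps])

    def segment_start_s(self, sweep_index: int, segment_index: int) -> float:
        return float(
            sum(seg.duration_s for seg in self.sweeps[sweep_index][:segment_index])
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "dt_s": self.dt_s,
            "holding_mV": self.holding_mV,
            "carry_over": self.carry_over,
            "test_segment": self.test_segment,
            "tail_segment": self.tail_segment,
            "sweeps": [
                [[seg.duration_s, seg.voltage_mV] for seg in sweep] for sweep in self.sweeps
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "VoltageProtocol":
        sweeps = tuple(
            tuple(Segment(d, v) for d, v in sweep) for sweep in doc["sweeps"]
        )
        return cls(
            name=doc["name"],
            sweeps=sweeps,
            dt_s=doc.get("dt_s", 1e-3),
            holding_mV=doc.get("holding_mV", -80.0),
            carry_over=doc.get("carry_over", False),
            test_segment=doc.get("test_segment"),
            tail_segment=doc.get("tail_segment"),
        )


PROTOCOL_NAMES = (
    "repetitive_40",
    "activation_iv",
    "deactivation_tails",
    "rest_hold",
    "conditioning",
    "fig9",
)


def preset_protocol(name: str, **overrides) -> VoltageProtocol:
    """Build one of the packaged protocols; overrides are explicit keywords.

    Every preset exposes its voltages and durations as keyword arguments, so
    nothing can be changed silently; unknown keywords raise ``TypeError``.
    """
    builders = {
        "repetitive_40": _repetitive_40,
        "activation_iv": _activation_iv,
        "deactivation_tails": _deactivation_tails,
        "rest_hold": _rest_hold,
        "conditioning": _conditioning,
        "fig9": _fig9,
    }
    if name not in builders:
        raise ConfigurationError(
            f"unknown protocol {name!r}; choose from {', '.join(PROTOCOL_NAMES)}"
        )
    return builders[name](**overrides)


def _step_family(
    name: str,
    test_voltages: Sequence[float],
    hold_s: float,
    pulse_s: float,
    tail_s: float,
    tail_mV: float,
    holding_mV: float,
    dt_s: float,
) -> VoltageProtocol:
    sweeps = tuple(
        (Segment(hold_s, holding_mV), Segment(pulse_s, float(v)), Segment(tail_s, tail_mV))
        for v in test_voltages
    )
    return VoltageProtocol(
        name=name,
        sweeps=sweeps,
        dt_s=dt_s,
        holding_mV=holding_mV,
        test_segment=1,
        tail_segment=2,
    )


def _fig9(
    test_voltages: Sequence[float] = (-40, -20, 0, 20, 40, 60),
    hold_s: float = 0.5,
    pulse_s: float = 5.0,
    tail_s: float = 2.0,
    tail_mV: float = -120.0,
    holding_mV: float = -80.0,
    dt_s: float = 1e-3,
) -> VoltageProtocol:
    """Six 5 s steps -40..+60 mV in 20 mV increments, tails at -120 mV."""
    return _step_family("fig9", test_voltages, hold_s, pulse_s, tail_s, tail_mV, holding_mV, dt_s)


def _activation_iv(
    test_voltages: Sequence[float] = (-100, -80, -60, -40, -20, 0, 20, 40, 60),
    hold_s: float = 0.5,
    pulse_s: float = 10.0,
    tail_s: float = 2.0,
    tail_mV: float = -120.0,
    holding_mV: float = -80.0,
    dt_s: float = 1e-3,
) -> VoltageProtocol:
    """Nine 10 s steps -100..+60 mV in 20 mV increments, tails at -120 mV."""
    return _step_family(
        "activation_iv", test_voltages, hold_s, pulse_s, tail_s, tail_mV, holding_mV, dt_s
    )


def _deactivation_tails(
    tail_voltages: Sequence[float] = (-140, -120, -100, -80, -60, -40),
    hold_s: float = 0.5,
    prepulse_mV: float = -20.0,
    prepulse_s: float = 5.0,
    tail_s: float = 3.0,
    holding_mV: float = -80.0,
    dt_s: float = 1e-3,
) -> VoltageProtocol:
    """5 s prepulse to -20 mV, then tails from -140 to -40 mV."""
    sweeps = tuple(
        (Segment(hold_s, holding_mV), Segment(prepulse_s, prepulse_mV), Segment(tail_s, float(v)))
        for v in tail_voltages
    )
    return VoltageProtocol(
        name="deactivation_tails",
        sweeps=sweeps,
        dt_s=dt_s,
        holding_mV=holding_mV,
        test_segment=2,
        tail_segment=2,
    )


def _repetitive_40(
    n_pulses: int = 10,
    pulse_s: float = 7.0,
    pulse_mV: float = 40.0,
    period_s: float = 30.0,
    holding_mV: float = -80.0,
    dt_s: float = 1e-3,
) -> VoltageProtocol:
    """Repetitive 7 s pulses to +40 mV applied every 30 s from -80 mV."""
    if period_s <= pulse_s:
        raise ConfigurationError("inter-pulse period must exceed the pulse duration")
    sweep = (Segment(pulse_s, pulse_mV), Segment(period_s - pulse_s, holding_mV))
    return VoltageProtocol(
        name="repetitive_40",
        sweeps=(sweep,) * n_pulses,
        dt_s=dt_s,
        holding_mV=holding_mV,
        carry_over=True,
        test_segment=0,
    )


def _rest_hold(
    rest_s: float = 270.0,
    pulse_s: float = 7.0,
    pulse_mV: float = 40.0,
    tail_s: float = 2.0,
    tail_mV: float = -120.0,
    holding_mV: float = -80.0,
    dt_s: float = 1e-3,
) -> VoltageProtocol:
    """4.5 min rest at the holding potential, then one +40 mV test pulse."""
    sweep = (Segment(rest_s, holding_mV), Segment(pulse_s, pulse_mV), Segment(tail_s, tail_mV))
    return VoltageProtocol(
        name="rest_hold",
        sweeps=(sweep,),
        dt_s=dt_s,
        holding_mV=holding_mV,
        carry_over=True,
        test_segment=1,
        tail_segment=2,
    )


def _conditioning(
    frequency_Hz: float = 2.0,
    train_s: float = 60.0,
    prepulse_s: float = 0.3,
    prepulse_mV: float = -40.0,
    test_s: float = 5.0,
    test_mV: float = 0.0,
    tail_s: float = 2.0,
    tail_mV: float = -120.0,
    holding_mV: float = -80.0,
    dt_s: float = 1e-3,
) -> VoltageProtocol:
    """300 ms subthreshold prepulse train (use-dependence), then a test pulse."""
    period = 1.0 / frequency_Hz
    if period <= prepulse_s:
        raise ConfigurationError("conditioning frequency too high for the prepulse duration")
    n = int(round(frequency_Hz * train_s))
    train = (Segment(prepulse_s, prepulse_mV), Segment(period - prepulse_s, holding_mV))
    final = (Segment(test_s, test_mV), Segment(tail_s, tail_mV))
    return VoltageProtocol(
        name=f"conditioning_{frequency_Hz:g}Hz",
        sweeps=(train,) * n + (final,),
        dt_s=dt_s,
        holding_mV=holding_mV,
        carry_over=True,
    )


# ---------------------------------------------------------------------------
# Current synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationSettings:
    """Conductance scaling for macroscopic-current synthesis.

    ``gmax_uS`` is the maximal whole-cell conductance (microsiemens) and
    ``erev_mV`` the reversal potential.  With ``normalize`` set, currents are
    divided by the largest absolute current of the recording, mimicking the
    normalized presentation used when channel counts are unknown.
    """

    gmax_uS: float = 1.0
    erev_mV: float = -90.0
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.gmax_uS <= 0:
            raise ValueError("Gmax must be positive")
        if not (-150.0 < self.erev_mV < 0.0):
            raise ValueError("Erev outside the plausible K+ range (-150, 0) mV")


@dataclass
class SweepTrace:
    time_s: np.ndarray
    voltage_mV: np.ndarray
    current_uA: np.ndarray
    open_prob: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.voltage_mV) == len(self.current_uA) == len(self.open_prob) == n):
            raise ValueError("sweep arrays must have equal length")


@dataclass
class Recording:
    """Per-sweep traces plus metadata sufficient to regenerate them."""

    protocol: VoltageProtocol
    sweeps: list[SweepTrace]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "sweep_id": i,
                    "time_s": sw.time_s,
                    "voltage_mV": sw.voltage_mV,
                    "current_uA": sw.current_uA,
                }
            )
            for i, sw in enumerate(self.sweeps)
        ]
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_metadata(self, path: str | Path) -> None:
        doc = dict(self.metadata)
        doc["protocol"] = self.protocol.to_dict()
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def scheme_fingerprint(scheme: GatingScheme) -> str:
    """Stable content hash of a scheme definition (for provenance metadata)."""
    canon = json.dumps(scheme_to_dict(scheme), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sweep_grid(sweep: tuple[Segment, ...], dt: float):
    """Per-segment sample counts; durations are snapped to the dt grid."""
    counts = []
    for seg in sweep:
        n = int(round(seg.duration_s / dt))
        if n < 1 or abs(n * dt - seg.duration_s) > 1e-9 * max(1.0, seg.duration_s):
            raise ConfigurationError(
                f"segment duration {seg.duration_s} s is not a multiple of dt={dt} s"
            )
        counts.append(n)
    return counts


def simulate_recording(
    scheme: GatingScheme,
    protocol: VoltageProtocol,
    settings: SimulationSettings | None = None,
    initial: np.ndarray | None = None,
) -> Recording:
    """Noiseless macroscopic currents for a scheme driven through a protocol.

    Each sweep starts from the steady state at the holding potential (or from
    ``initial`` on the first sweep) unless the protocol carries occupancy
    over, and the current is ``Gmax * Popen * (V - Erev)`` in microamperes
    for Gmax in microsiemens and voltages in millivolts.
    """
    settings = settings or SimulationSettings()
    cond = scheme.conducting_indices
    if not cond:
        raise ConfigurationError("scheme has no conducting state; cannot synthesize current")

    p_hold = steady_state(scheme, protocol.holding_mV)
    p = np.asarray(initial, dtype=float) if initial is not None else p_hold
    if len(p) != scheme.n_states:
        raise ValueError("initial occupancy length must match the scheme")

    dt = protocol.dt_s
    sweeps: list[SweepTrace] = []
    for sweep in protocol.sweeps:
        if not protocol.carry_over and sweeps:
            p = p_hold
        counts = _sweep_grid(sweep, dt)
        n_total = sum(counts) + 1
        t = np.arange(n_total) * dt
        v = np.empty(n_total)
        occ = np.empty((n_total, scheme.n_states))
        v[0] = sweep[0].voltage_mV
        occ[0] = p
        k = 1
        for seg, n in zip(sweep, counts):
            local = np.arange(1, n + 1) * dt
            occ[k : k + n] = _evolve(scheme, seg.voltage_mV, p, local)
            v[k : k + n] = seg.voltage_mV
            p = occ[k + n - 1]
            k += n
        popen = occ[:, list(cond)].sum(axis=1)
        current = settings.gmax_uS * popen * (v - settings.erev_mV) * 1e-3
        sweeps.append(SweepTrace(t, v, current, popen))

    if settings.normalize:
        peak = max(np.abs(sw.current_uA).max() for sw in sweeps)
        if peak > 0:
            for sw in sweeps:
                sw.current_uA = sw.current_uA / peak

    metadata = {
        "scheme": scheme.name,
        "scheme_sha256": scheme_fingerprint(scheme),
        "settings": {
            "gmax_uS": settings.gmax_uS,
            "erev_mV": settings.erev_mV,
            "normalize": settings.normalize,
        },
        "noise": None,
        "seed": None,
    }
    return Recording(protocol=protocol, sweeps=sweeps, metadata=metadata)


def open_probability(trace: OccupancyTrace, scheme: GatingScheme) -> np.ndarray:
    """Summed conducting-state occupancy of a trace, bounded in [0, 1]."""
    if trace.labels != scheme.labels:
        raise ValueError("trace state labels do not match the scheme")
    cond = list(scheme.conducting_indices)
    po = trace.probabilities[:, cond].sum(axis=1)
    return np.clip(po, 0.0, 1.0)
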