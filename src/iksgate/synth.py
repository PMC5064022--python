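"""Seeded synthetic datasets with the statistical structure of TEVC data.

Everything here is a pure function of (parameters, seed): noisy voltage-clamp
recordings (additive Gaussian current noise, ohmic leak, and an optional slow
endogenous-current contaminant activating at high potentials), Hill-shaped
concentration-response tables with multiplicative replicate scatter, and
wash-in time courses simulated from the explicit ligand-binding expansion of
a gating scheme under repetitive pulsing.

The noise magnitudes are synthetic-fixture choices (the recordings they
emulate report none); they approximate the replicate scatter visible in
published concentration-response data without claiming its exact value.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fitting import DoseResponseTable, exp_fit, hill_model
from .gating import BindingSpec, GatingScheme, augment_with_binding, steady_state
from .protocols import (
    Recording,
    SimulationSettings,
    VoltageProtocol,
    preset_protocol,
    simulate_recording,
)

__all__ = [
    "NoiseModel",
    "WashinTrace",
    "default_binding_specs",
    "synth_recording",
    "synth_dose_response",
    "synth_washin",
    "washin_tau_table",
]

#: Closed states of the packaged IKs scheme: the binding-competent set.
IKS_CLOSED_STATES = ("C1", "C2", "C3", "C2s")
#: Default association rate (1/M/s) and dissociation constant (M) for the
#: ligand-binding extension; Kd is the wild-type IC50 surrogate.
DEFAULT_KON = 1.0e4
DEFAULT_KD = 78.4e-9


@dataclass(frozen=True)
class NoiseModel:
    """Additive recording noise: Gaussian current noise, ohmic leak, and an
    optional slow contaminant current activating above a voltage threshold
    (first-order onset, emulating endogenous oocyte currents elicited by long
    pulses at high potentials)."""

    sigma_uA: float = 0.0
    g_leak_uS: float = 0.0
    e_leak_mV: float = 0.0
    contaminant_uA: float = 0.0
    contaminant_threshold_mV: float = 40.0
    contaminant_tau_s: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_uA < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.g_leak_uS < 0:
            raise ValueError("leak conductance must be nonnegative")

    def as_dict(self) -> dict:
        return {
            "sigma_uA": self.sigma_uA,
            "g_leak_uS": self.g_leak_uS,
            "e_leak_mV": self.e_leak_mV,
            "contaminant_uA": self.contaminant_uA,
            "contaminant_threshold_mV": self.contaminant_threshold_mV,
            "contaminant_tau_s": self.contaminant_tau_s,
        }


def _contaminant(noise: NoiseModel, t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """First-order activating contaminant within supra-threshold segments."""
    out = np.zeros_like(t)
    if noise.contaminant_uA == 0.0:
        return out
    above = v >= noise.contaminant_threshold_mV
    if not above.any():
        return out
    # time since entry into each contiguous supra-threshold stretch
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1) + 1
    starts = ([0] if above[0] else []) + list(edges)
    for s in starts:
        e = s
        while e < len(above) and above[e]:
            e += 1
        tloc = t[s:e] - t[s]
        out[s:e] = noise.contaminant_uA * (1.0 - np.exp(-tloc / noise.contaminant_tau_s))
    return out


def synth_recording(
    scheme: GatingScheme,
    protocol: VoltageProtocol,
    settings: SimulationSettings | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    initial: np.ndarray | None = None,
) -> Recording:
    """A noisy recording: model current + leak + contaminant + Gaussian noise.

    With all noise terms zero the output is bit-identical to
    :func:`iksgate.protocols.simulate_recording`.
    """
    if seed < 0:
        raise ValueError("seed must be a nonnegative integer")
    noise = noise or NoiseModel()
    rec = simulate_recording(scheme, protocol, settings, initial=initial)
    rng = np.random.default_rng(seed)
    for sw in rec.sweeps:
        extra = noise.g_leak_uS * (sw.voltage_mV - noise.e_leak_mV) * 1e-3
        extra = extra + _contaminant(noise, sw.time_s, sw.voltage_mV)
        if noise.sigma_uA > 0:
            extra = extra + rng.normal(0.0, noise.sigma_uA, size=len(sw.time_s))
        if np.any(extra != 0.0):
            sw.current_uA = sw.current_uA + extra
    rec.metadata["noise"] = noise.as_dict()
    rec.metadata["seed"] = int(seed)
    return rec


def synth_dose_response(
    ic50_M: float,
    hill: float,
    concentrations_M: Sequence[float],
    sigma_rel: float = 0.03,
    n_replicates: int = 5,
    seed: int = 0,
) -> DoseResponseTable:
    """Hill-distributed fractional responses with multiplicative scatter.

    Each replicate is ``Hill(C) * (1 + N(0, sigma_rel))``, clipped to
    [0, 1.1]; deterministic for a fixed seed.
    """
    if ic50_M <= 0 or hill <= 0:
        raise ValueError("IC50 and Hill coefficient must be positive")
    conc = np.asarray(concentrations_M, dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration list")
    rng = np.random.default_rng(seed)
    clean = hill_model(conc, ic50_M, hill)
    resp = clean[:, None] * np.ones((1, n_replicates))
    if sigma_rel > 0:
        resp = resp * (1.0 + rng.normal(0.0, sigma_rel, size=resp.shape))
    resp = np.clip(resp, 0.0, 1.1)
    return DoseResponseTable(conc, resp)


def default_binding_specs(
    concentrations_M: Sequence[float],
    kon: float = DEFAULT_KON,
    kd_M: float = DEFAULT_KD,
    competent: tuple[str, ...] = IKS_CLOSED_STATES,
) -> list[BindingSpec]:
    """One BindingSpec per concentration with koff = kon * Kd."""
    return [
        BindingSpec(kon=kon, koff=kon * kd_M, concentration=float(c), competent=competent)
        for c in concentrations_M
    ]


@dataclass
class WashinTrace:
    """Wash-in time course at one drug concentration."""

    concentration_M: float
    recording: Recording
    pulse_time_s: np.ndarray
    norm_end_amplitude: np.ndarray
    binding: BindingSpec = field(repr=False, default=None)


def synth_washin(
    scheme: GatingScheme,
    binding_specs: Sequence[BindingSpec],
    hold_mV: float = -80.0,
    pulse_protocol: VoltageProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    dt_s: float = 5e-3,
    settings: SimulationSettings | None = None,
    end_window_s: float = 0.05,
    min_pulses: int = 10,
    max_total_s: float = 1800.0,
) -> list[WashinTrace]:
    """Wash-in under repetitive pulsing, one trace per binding spec.

    The drug is applied at t=0 with the channel equilibrated drug-free at the
    holding potential; pulsing then proceeds (by default 7 s to +40 mV every
    30 s) while the bound fraction builds up.  End-of-pulse current
    amplitudes, normalized to the first pulse, form the wash-in time course.

    Recording length adapts to the expected pseudo-first-order binding time
    constant (about five time constants, clamped so every trace has at least
    ``min_pulses`` pulses and at most ``max_total_s`` seconds), as an
    experimenter would record until inhibition approaches steady state.
    """
    out: list[WashinTrace] = []
    seeds = np.random.SeedSequence(seed).generate_state(max(len(binding_specs), 1)) % (2**31)
    for spec, sub_seed in zip(binding_specs, seeds):
        augmented = augment_with_binding(scheme, spec)
        if pulse_protocol is None:
            period = 30.0
            tau_pred = 1.0 / max(spec.kon * spec.concentration + spec.koff, 1e-9)
            total = min(max_total_s, max(min_pulses * period, 5.0 * tau_pred))
            proto = preset_protocol(
                "repetitive_40",
                n_pulses=int(np.ceil(total / period)),
                holding_mV=hold_mV,
                dt_s=dt_s,
            )
        else:
            proto = pulse_protocol
        # drug-free equilibrium at the hold embedded in the unbound copy
        p0 = np.zeros(augmented.n_states)
        p0[: scheme.n_states] = steady_state(scheme, hold_mV)
        rec = synth_recording(
            augmented, proto, settings=settings, noise=noise, seed=int(sub_seed), initial=p0
        )
        seg = proto.test_segment if proto.test_segment is not None else 0
        times, amps = [], []
        t_global = 0.0
        for i, sw in enumerate(rec.sweeps):
            start = proto.segment_start_s(i, seg)
            stop = start + proto.sweeps[i][seg].duration_s
            m = (sw.time_s > stop - end_window_s) & (sw.time_s <= stop + 1e-12)
            amps.append(float(sw.current_uA[m].mean()))
            times.append(t_global + stop)
            t_global += float(sw.time_s[-1])
        amps = np.asarray(amps)
        norm = amps / amps[0] if amps[0] != 0 else amps
        out.append(
            WashinTrace(
                concentration_M=spec.concentration,
                recording=rec,
                pulse_time_s=np.asarray(times),
                norm_end_amplitude=norm,
                binding=spec,
            )
        )
    return out


def washin_tau_table(washes: Sequence[WashinTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Exponential wash-in time constants per concentration."""
    conc, taus = [], []
    for w in washes:
        fit = exp_fit(w.pulse_time_s, w.norm_end_amplitude, kind="inhibition")
        conc.append(w.concentration_M)
        taus.append(fit.params.get("tau_s", np.nan))
    return np.asarray(conc), np.asarray(taus)
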