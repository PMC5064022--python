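"""Voltage-dependent Markov models of ion-channel gating.

This module represents a channel gating scheme as a labelled continuous-time
Markov chain whose transition rates depend exponentially on the reduced
membrane potential ``phi = V*F/(R*T)``.  It builds the generator (Q) matrix,
solves for stationary occupancies, propagates the master equation
``dp/dt = p @ Q`` under constant voltage, and applies state-dependent drug
modifications: either as a rate-law override on a fully drug-bound scheme, or
as an explicit ligand-binding expansion that doubles the state space.

The packaged preset is a six-state model of the slow delayed-rectifier
potassium current IKs (Kv7.1/KCNE1): three closed states C1, C2, C3, two open
states O1, O2, and a stable ("inactivated") closed state C2s reached from C2.
A gating-modifier drug (an adamantane compound) is modelled as slowing the
exit rate from C2s (``rho``) 100-fold, trapping channels closed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "ConfigurationError",
    "NonUniqueSteadyStateError",
    "PhysConstants",
    "RateLaw",
    "State",
    "Transition",
    "GatingScheme",
    "DrugConfig",
    "BindingSpec",
    "OccupancyTrace",
    "evaluate_rate",
    "build_generator",
    "steady_state",
    "propagate",
    "apply_drug_config",
    "augment_with_binding",
    "DRUG_FREE",
    "AC1_BOUND",
    "iks_scheme",
    "scheme_to_dict",
    "scheme_from_dict",
    "load_scheme",
    "save_scheme",
]

# Probabilities in (-NEG_CLIP, 0) are rounded to 0 and the row renormalized;
# anything more negative indicates a solver failure and raises.
NEG_CLIP = 1e-12
ROW_SUM_TOL = 1e-7


class ConfigurationError(ValueError):
    """A scheme, drug config or binding spec is internally inconsistent."""


class NonUniqueSteadyStateError(RuntimeError):
    """The generator has no one-dimensional null space (disconnected chain)."""


@dataclass(frozen=True)
class PhysConstants:
    """Physical constants entering the reduced potential phi = V*F/(R*T).

    F is the Faraday constant (C/mol), R the gas constant (J/mol/K) and T the
    absolute temperature (K).  The default temperature, 293.15 K (20 degrees
    C), is typical for oocyte recordings at room temperature.
    """

    F: float = 96485.33212
    R: float = 8.31446261815324
    T: float = 293.15

    def __post_init__(self) -> None:
        if not (self.F > 0 and self.R > 0 and self.T > 0):
            raise ValueError("F, R and T must all be strictly positive")

    def phi(self, v_mV: float) -> float:
        """Dimensionless reduced potential for a membrane voltage in mV."""
        v_mV = np.asarray(v_mV, dtype=float)
        if not np.all(np.isfinite(v_mV)):
            raise ValueError("membrane voltage must be finite")
        return (v_mV * 1e-3) * self.F / (self.R * self.T)


@dataclass(frozen=True)
class RateLaw:
    """Exponentially voltage-dependent rate: amplitude * exp(charge * phi).

    ``amplitude`` is the rate at 0 mV in 1/s; ``charge`` is the effective
    valence multiplying phi (0 for voltage-independent transitions).
    """

    amplitude: float
    charge: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("rate-law amplitude must be nonnegative")

    def __call__(self, v_mV: float, constants: PhysConstants) -> float:
        return float(self.amplitude * np.exp(self.charge * constants.phi(v_mV)))


def evaluate_rate(law: RateLaw, v_mV: float, constants: PhysConstants) -> float:
    """Rate of ``law`` at membrane voltage ``v_mV`` (mV), in 1/s."""
    return law(v_mV, constants)


@dataclass(frozen=True)
class State:
    label: str
    conducting: bool = False


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    law: RateLaw

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ConfigurationError(
                f"self-transition {self.source!r} -> {self.target!r} is not allowed"
            )


@dataclass(frozen=True)
class GatingScheme:
    """A labelled Markov gating scheme with voltage-dependent transitions."""

    name: str
    states: tuple[State, ...]
    transitions: tuple[Transition, ...]
    constants: PhysConstants = field(default_factory=PhysConstants)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("state labels must be unique")
        index = set(labels)
        seen: set[tuple[str, str]] = set()
        for tr in self.transitions:
            if tr.source not in index or tr.target not in index:
                raise ConfigurationError(
                    f"transition {tr.source!r}->{tr.target!r} references unknown state"
                )
            pair = (tr.source, tr.target)
            if pair in seen:
                raise ConfigurationError(f"duplicate transition {pair[0]!r}->{pair[1]!r}")
            seen.add(pair)

    # -- lookups -----------------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state {label!r}") from None

    @property
    def conducting_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.states) if s.conducting)

    def transition(self, source: str, target: str) -> Transition:
        for tr in self.transitions:
            if tr.source == source and tr.target == target:
                return tr
        raise ConfigurationError(f"no transition {source!r}->{target!r} in scheme {self.name!r}")


@dataclass(frozen=True)
class DrugConfig:
    """Rate-law overrides representing a drug-bound channel configuration.

    Each entry replaces the rate law of one existing transition, identified by
    its (source, target) labels.
    """

    overrides: tuple[tuple[str, str, RateLaw], ...] = ()


#: The IKs preset's C2s -> C2 exit rate in the drug-free configuration.
DRUG_FREE = DrugConfig((("C2s", "C2", RateLaw(10.0, 0.0)),))
#: Fully drug-bound configuration: C2s -> C2 slowed 100-fold (10 -> 0.1 /s).
AC1_BOUND = DrugConfig((("C2s", "C2", RateLaw(0.1, 0.0)),))


@dataclass(frozen=True)
class BindingSpec:
    """Explicit ligand-binding expansion of a gating scheme.

    Association proceeds at ``kon * concentration`` from every
    binding-competent state to its drug-bound twin and dissociation at
    ``koff`` back.  The bound copy of the scheme carries ``bound_config``
    (for the IKs preset, the 100-fold slowed C2s exit).
    """

    kon: float  # 1/(M*s)
    koff: float  # 1/s
    concentration: float  # M
    competent: tuple[str, ...]
    bound_config: DrugConfig = AC1_BOUND
    bound_suffix: str = ":AC"

    def __post_init__(self) -> None:
        if self.kon < 0 or self.koff < 0 or self.concentration < 0:
            raise ValueError("kon, koff and concentration must be nonnegative")

    @property
    def kd(self) -> float:
        if self.kon <= 0:
            raise ValueError("Kd undefined for kon = 0")
        return self.koff / self.kon


@dataclass
class OccupancyTrace:
    """State-occupancy time course under a (piecewise-)constant voltage."""

    time_s: np.ndarray
    probabilities: np.ndarray  # (n_times, n_states)
    voltage_mV: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        dev = np.abs(self.probabilities.sum(axis=1) - 1.0).max()
        if dev > 1e-9:
            raise RuntimeError(f"occupancy rows deviate from probability 1 by {dev:.2e}")


# ---------------------------------------------------------------------------
# Generator matrix and solvers
# ---------------------------------------------------------------------------

def build_generator(scheme: GatingScheme, v_mV: float) -> np.ndarray:
    """Generator (Q) matrix at constant voltage; rows sum to zero.

    Entry (i, j), i != j, holds the i->j rate in 1/s; the diagonal is the
    negative row sum, so the master equation reads ``dp/dt = p @ Q`` for a
    row vector p of state probabilities.
    """
    n = scheme.n_states
    idx = {lab: i for i, lab in enumerate(scheme.labels)}
    q = np.zeros((n, n))
    for tr in scheme.transitions:
        q[idx[tr.source], idx[tr.target]] = tr.law(v_mV, scheme.constants)
    q[np.diag_indices(n)] = -q.sum(axis=1)
    return q


def steady_state(scheme: GatingScheme, v_mV: float) -> np.ndarray:
    """Stationary occupancy vector p with p @ Q = 0 and sum(p) = 1."""
    q = build_generator(scheme, v_mV)
    ns = null_space(q.T)
    if ns.shape[1] != 1:
        raise NonUniqueSteadyStateError(
            f"generator null space has dimension {ns.shape[1]} "
            f"(scheme {scheme.name!r} at {v_mV} mV); the chain must have a "
            "single recurrent communicating class"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if p.min() < -1e-10:
        raise NonUniqueSteadyStateError(
            f"stationary vector has negative entry {p.min():.2e}"
        )
    p = np.clip(p, 0.0, None)
    return p / p.sum()


@lru_cache(maxsize=512)
def _eigensystem(scheme: GatingScheme, v_mV: float):
    """Eigendecomposition of Q^T, or None when too ill-conditioned to trust."""
    q = build_generator(scheme, v_mV)
    w, vec = np.linalg.eig(q.T)
    try:
        vec_inv = np.linalg.inv(vec)
    except np.linalg.LinAlgError:
        return None
    scale = max(1.0, np.abs(q).max())
    resid = np.abs(vec @ np.diag(w) @ vec_inv - q.T).max() / scale
    if resid > 1e-9 or np.linalg.cond(vec) > 1e10:
        return None
    return w, vec, vec_inv


def _evolve(scheme: GatingScheme, v_mV: float, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Occupancies at the given times for constant voltage, exactly (expm)."""
    eig = _eigensystem(scheme, v_mV)
    if eig is not None:
        w, vec, vec_inv = eig
        coeff = vec_inv @ p0
        out = (vec @ (np.exp(np.outer(w, times)) * coeff[:, None])).T
        out = np.ascontiguousarray(out.real)
    else:
        # Fallback: per-step matrix exponential, exact at the grid times even
        # when the spectrum is defective.
        q = build_generator(scheme, v_mV)
        out = np.empty((len(times), len(p0)))
        p = p0
        prev_t = None
        prop = None
        last = 0.0
        for k, t in enumerate(times):
            step = t - last
            if prev_t is None or abs(step - prev_t) > 1e-15:
                prop = expm(q * step)
                prev_t = step
            p = p @ prop
            out[k] = p
            last = t
    return _guard(out)


def _guard(probs: np.ndarray) -> np.ndarray:
    """Clip tiny negative round-off, renormalize rows, reject real violations."""
    low = probs.min()
    if low < -NEG_CLIP:
        raise RuntimeError(f"occupancy went negative by {low:.2e}; solver failure")
    probs = np.clip(probs, 0.0, None)
    sums = probs.sum(axis=1)
    dev = np.abs(sums - 1.0).max()
    if dev > ROW_SUM_TOL:
        raise RuntimeError(f"occupancy rows deviate from 1 by {dev:.2e}; solver failure")
    return probs / sums[:, None]


def propagate(
    scheme: GatingScheme,
    p0: Sequence[float],
    v_mV: float,
    duration_s: float,
    dt_s: float,
) -> OccupancyTrace:
    """Solve dp/dt = p @ Q at constant voltage over [0, duration].

    The output grid is 0, dt, 2*dt, ..., plus the exact end point when the
    duration is not a multiple of dt.  Propagation is by matrix exponential
    (eigendecomposition when well-conditioned), hence exact at the grid times
    up to round-off.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.ndim != 1 or len(p0) != scheme.n_states:
        raise ValueError("p0 length must match the number of states")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"p0 must sum to 1 (got {p0.sum():.12f})")
    if duration_s < 0:
        raise ValueError("duration must be nonnegative")
    if dt_s <= 0:
        raise ValueError("dt must be positive")

    if duration_s == 0:
        times = np.array([0.0])
        probs = p0[None, :].copy()
    else:
        n = int(np.floor(duration_s / dt_s + 1e-9))
        times = np.arange(n + 1) * dt_s
        if times[-1] < duration_s - 1e-12:
            times = np.append(times, duration_s)
        probs = np.empty((len(times), scheme.n_states))
        probs[0] = p0
        probs[1:] = _evolve(scheme, v_mV, p0, times[1:])
    return OccupancyTrace(
        time_s=times,
        probabilities=probs,
        voltage_mV=np.full(len(times), float(v_mV)),
        labels=scheme.labels,
    )


# ---------------------------------------------------------------------------
# Drug configurations and ligand binding
# ---------------------------------------------------------------------------

def apply_drug_config(scheme: GatingScheme, config: DrugConfig) -> GatingScheme:
    """New scheme with the configured rate laws replaced; input untouched."""
    by_pair = {(src, tgt): law for src, tgt, law in config.overrides}
    existing = {(tr.source, tr.target) for tr in scheme.transitions}
    unknown = set(by_pair) - existing
    if unknown:
        src, tgt = sorted(unknown)[0]
        raise ConfigurationError(f"drug config names unknown transition {src!r}->{tgt!r}")
    if not by_pair:
        return scheme
    new_transitions = tuple(
        replace(tr, law=by_pair.get((tr.source, tr.target), tr.law))
        for tr in scheme.transitions
    )
    return replace(scheme, transitions=new_transitions)


def augment_with_binding(scheme: GatingScheme, spec: BindingSpec) -> GatingScheme:
    """Double the state space into unbound + drug-bound copies.

    Binding-competent unbound states gain an edge ``kon * C`` to their bound
    twin and the twin an edge ``koff`` back; all other cross-copy transitions
    are absent.  The bound copy carries ``spec.bound_config``.
    """
    labels = set(scheme.labels)
    unknown = [lab for lab in spec.competent if lab not in labels]
    if unknown:
        raise ConfigurationError(f"binding-competent labels not in scheme: {unknown}")
    if not spec.competent and spec.concentration > 0:
        raise ConfigurationError("no binding-competent states but concentration > 0")

    bound = apply_drug_config(scheme, spec.bound_config)
    suf = spec.bound_suffix
    states = scheme.states + tuple(
        State(s.label + suf, s.conducting) for s in bound.states
    )
    transitions = list(scheme.transitions)
    transitions += [
        Transition(tr.source + suf, tr.target + suf, tr.law) for tr in bound.transitions
    ]
    kon_c = spec.kon * spec.concentration
    for lab in spec.competent:
        transitions.append(Transition(lab, lab + suf, RateLaw(kon_c, 0.0)))
        transitions.append(Transition(lab + suf, lab, RateLaw(spec.koff, 0.0)))
    return GatingScheme(
        name=f"{scheme.name}+binding",
        states=states,
        transitions=tuple(transitions),
        constants=scheme.constants,
    )


# ---------------------------------------------------------------------------
# Serialization and packaged presets
# ---------------------------------------------------------------------------

def scheme_to_dict(scheme: GatingScheme) -> dict:
    return {
        "name": scheme.name,
        "constants": {"F": scheme.constants.F, "R": scheme.constants.R, "T": scheme.constants.T},
        "states": [{"label": s.label, "conducting": s.conducting} for s in scheme.states],
        "transitions": [
            {
                "source": tr.source,
                "target": tr.target,
                "amplitude": tr.law.amplitude,
                "charge": tr.law.charge,
            }
            for tr in scheme.transitions
        ],
    }


def scheme_from_dict(doc: Mapping) -> GatingScheme:
    constants = PhysConstants(**doc.get("constants", {}))
    states = tuple(State(s["label"], bool(s.get("conducting", False))) for s in doc["states"])
    transitions = tuple(
        Transition(t["source"], t["target"], RateLaw(t["amplitude"], t.get("charge", 0.0)))
        for t in doc["transitions"]
    )
    return GatingScheme(doc["name"], states, transitions, constants)


def save_scheme(scheme: GatingScheme, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scheme_to_dict(scheme), indent=2) + "\n")


def load_scheme(path: str | Path) -> GatingScheme:
    return scheme_from_dict(json.loads(Path(path).read_text()))


def iks_scheme(drug: str = "free", temperature_K: float | None = None) -> GatingScheme:
    """The packaged six-state IKs scheme.

    ``drug`` selects the configuration: "free" (C2s exit rho = 10/s) or
    "bound" (rho = 0.1/s, the fully gating-modifier-bound channel).
    """
    fname = {"free": "iks_drug_free.json", "bound": "iks_ac1_bound.json"}.get(drug)
    if fname is None:
        raise ConfigurationError(f"unknown drug configuration {drug!r}; use 'free' or 'bound'")
    text = resources.files("iksgate.schemes").joinpath(fname).read_text()
    scheme = scheme_from_dict(json.loads(text))
    if temperature_K is not None:
        scheme = replace(scheme, constants=replace(scheme.constants, T=temperature_K))
    return scheme
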