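"""Electrophysiology curve fitting and derived metrics.

The four fit families used to analyse macroscopic recordings:

* Hill concentration-response, ``I_drug/I_max = 1 / (1 + (C/IC50)**H)``,
  fitted with IC50 in log10 space;
* Boltzmann activation, ``A = A_min + (A_max - A_min) / (1 + exp((V50 - V)/k))``;
* single exponential, ``y = A0 + A * exp(-t/tau)``, for activation and
  deactivation kinetics;
* ordinary least squares of log10(tau) on log10(concentration) for wash-in
  time constants (a slope near -1 indicates pseudo-first-order binding).

Plus the two trace-level metrics: fractional end-of-pulse inhibition and
tail-current activation curves (initial tail amplitudes normalized to the
maximum across sweeps).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .gating import ConfigurationError
from .protocols import Recording

__all__ = [
    "DoseResponseTable",
    "FitResult",
    "hill_model",
    "boltzmann_model",
    "exponential_model",
    "hill_fit",
    "boltzmann_fit",
    "exp_fit",
    "linear_log_fit",
    "end_pulse_inhibition",
    "tail_activation_curve",
    "activation_tau_table",
    "deactivation_tau",
]


@dataclass
class DoseResponseTable:
    """Concentrations (M) with replicate fractional responses I_drug/I_max."""

    concentrations_M: np.ndarray
    responses: np.ndarray  # shape (n_concentrations, n_replicates)

    def __post_init__(self) -> None:
        self.concentrations_M = np.asarray(self.concentrations_M, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[0] != len(self.concentrations_M):
            raise ValueError("one response row per concentration required")
        if np.any(self.concentrations_M <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.responses.min() < -0.1 or self.responses.max() > 1.1:
            raise ValueError("responses outside the plausible range [-0.1, 1.1]")

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.repeat(self.concentrations_M, self.responses.shape[1])
        return c, self.responses.ravel()

    def to_csv(self, path: str | Path) -> None:
        c, r = self.flat()
        rep = np.tile(np.arange(self.responses.shape[1]), len(self.concentrations_M))
        pd.DataFrame(
            {"concentration_M": c, "replicate": rep, "response": r}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseTable":
        df = pd.read_csv(path)
        for col in ("concentration_M", "replicate", "response"):
            if col not in df.columns:
                raise ValueError(f"dose-response CSV is missing column {col!r}")
        piv = df.pivot_table(
            index="concentration_M", columns="replicate", values="response", sort=True
        )
        return cls(piv.index.to_numpy(), piv.to_numpy())


@dataclass
class FitResult:
    """Fitted parameters with uncertainties for one of the fit families."""

    family: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    rss: float
    converged: bool
    n: int
    tags: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "family": self.family,
            "params": self.params,
            "stderr": self.stderr,
            "rss": self.rss,
            "converged": self.converged,
            "n": self.n,
            "tags": self.tags,
        }
        text = json.dumps(doc, indent=2, default=float) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def hill_model(concentration_M, ic50_M, hill):
    """Fractional remaining current 1 / (1 + (C/IC50)**H)."""
    c = np.asarray(concentration_M, dtype=float)
    return 1.0 / (1.0 + (c / ic50_M) ** hill)


def boltzmann_model(v_mV, v_half_mV, k_mV, a_max=1.0, a_min=0.0):
    v = np.asarray(v_mV, dtype=float)
    return a_min + (a_max - a_min) / (1.0 + np.exp((v_half_mV - v) / k_mV))


def exponential_model(t_s, a0, a, tau_s):
    t = np.asarray(t_s, dtype=float)
    return a0 + a * np.exp(-t / tau_s)


def _run_minimize(residual, params, restarts=3, jitter=0.3, rng_seed=0):
    """lmfit least squares with a few jittered restarts before giving up."""
    rng = np.random.default_rng(rng_seed)
    best = None
    for attempt in range(restarts):
        p = params.copy()
        if attempt:
            for par in p.values():
                if par.vary:
                    span = abs(par.value) if par.value != 0 else 1.0
                    par.value = par.value + rng.normal(0.0, jitter * span)
                    if par.min is not None and np.isfinite(par.min):
                        par.value = max(par.value, par.min + 1e-12)
                    if par.max is not None and np.isfinite(par.max):
                        par.value = min(par.value, par.max - 1e-12)
        try:
            out = lmfit.minimize(residual, p, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
        if out.success and out.errorbars:
            return out, True
    if best is None:
        return None, False
    return best, bool(best.success)


# ---------------------------------------------------------------------------
# Fitters
# ---------------------------------------------------------------------------

def hill_fit(table: DoseResponseTable, fix_hill: float | None = None) -> FitResult:
    """Fit the Hill equation; IC50 is searched in log space over 10 pM-1 mM.

    The Hill coefficient is free (bounded to [0.2, 5]) unless ``fix_hill``
    pins it.  By construction the fitted curve passes through 0.5 at
    C = IC50.
    """
    c, y = table.flat()
    if len(np.unique(table.concentrations_M)) < 3:
        raise ValueError("hill_fit needs at least 3 distinct concentrations")
    if table.concentrations_M.max() / table.concentrations_M.min() < 10:
        raise ValueError("concentrations must span at least one decade")

    # midpoint heuristic: log-interpolate the 0.5 crossing of the means
    means = table.responses.mean(axis=1)
    order = np.argsort(table.concentrations_M)
    logc = np.log10(table.concentrations_M[order])
    m = means[order]
    start = float(np.interp(0.5, m[::-1], logc[::-1])) if (m.min() < 0.5 < m.max()) else float(
        np.median(logc)
    )

    # molar-scale default search window, widened when the data use other units
    lo = min(-11.0, float(np.log10(table.concentrations_M.min())) - 2.0)
    hi = max(-3.0, float(np.log10(table.concentrations_M.max())) + 2.0)
    params = lmfit.Parameters()
    params.add("log10_ic50", value=float(np.clip(start, lo, hi)), min=lo, max=hi)
    if fix_hill is None:
        params.add("hill", value=1.0, min=0.2, max=5.0)
    else:
        params.add("hill", value=float(fix_hill), vary=False)

    def residual(p):
        return hill_model(c, 10.0 ** p["log10_ic50"], p["hill"]) - y

    out, ok = _run_minimize(residual, params)
    if out is None:
        return FitResult("hill", {}, {}, math.inf, False, len(y))
    log_ic50 = out.params["log10_ic50"]
    ic50 = 10.0 ** log_ic50.value
    se_ic50 = (
        math.log(10.0) * ic50 * log_ic50.stderr if log_ic50.stderr is not None else None
    )
    h = out.params["hill"]
    return FitResult(
        family="hill",
        params={"ic50_M": ic50, "hill": h.value},
        stderr={"ic50_M": se_ic50, "hill": h.stderr},
        rss=float(out.chisqr),
        converged=ok,
        n=len(y),
        tags={"hill_fixed": fix_hill is not None},
    )


def boltzmann_fit(voltages_mV, amplitudes) -> FitResult:
    """Fit a Boltzmann activation curve; needs at least 5 voltage points."""
    v = np.asarray(voltages_mV, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if len(v) < 5:
        raise ValueError("boltzmann_fit needs at least 5 voltage points")
    if not np.all(np.isfinite(y)):
        raise ValueError("amplitudes must be finite")

    half = 0.5 * (y.max() + y.min())
    order = np.argsort(v)
    v_half0 = float(np.interp(half, y[order], v[order])) if y.max() > y.min() else float(np.median(v))
    params = lmfit.Parameters()
    params.add("v_half_mV", value=v_half0)
    params.add("k_mV", value=10.0, min=1e-3)
    params.add("a_max", value=float(y.max()))
    params.add("a_min", value=float(y.min()))

    def residual(p):
        return boltzmann_model(v, p["v_half_mV"], p["k_mV"], p["a_max"], p["a_min"]) - y

    out, ok = _run_minimize(residual, params)
    if out is None:
        return FitResult("boltzmann", {}, {}, math.inf, False, len(y))
    pr = out.params
    return FitResult(
        family="boltzmann",
        params={k: pr[k].value for k in ("v_half_mV", "k_mV", "a_max", "a_min")},
        stderr={k: pr[k].stderr for k in ("v_half_mV", "k_mV", "a_max", "a_min")},
        rss=float(out.chisqr),
        converged=ok,
        n=len(y),
    )


def exp_fit(
    time_s,
    signal,
    window: tuple[float, float] | None = None,
    kind: str | None = None,
) -> FitResult:
    """Fit ``y = A0 + A*exp(-t/tau)`` over an optional time window.

    Time is shifted so the window starts at t=0.  A practically flat trace
    (or a fit that cannot converge) is returned flagged, not raised.  The
    result's tag records whether the relaxation looks like activation
    (magnitude growing) or deactivation unless ``kind`` is given.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signal, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    if len(t) < 10:
        raise ValueError("exp_fit needs at least 10 samples in the window")
    ts = t - t[0]

    span = float(np.ptp(y))
    inferred = "activation" if abs(y[-1]) >= abs(y[0]) else "deactivation"
    tags = {"kind": kind or inferred, "t0_s": float(t[0])}
    if span == 0.0:
        return FitResult(
            "exponential", {"a0": float(y[0]), "a": 0.0, "tau_s": math.nan},
            {}, 0.0, False, len(y), tags | {"flat": True},
        )

    # 1/e-crossing heuristic for the initial time constant
    target = y[-1] + (y[0] - y[-1]) / math.e
    cross = np.nonzero((y - target) * (y[0] - target) <= 0)[0]
    tau0 = float(ts[cross[0]]) if len(cross) and ts[cross[0]] > 0 else float(ts[-1] / 3.0)

    params = lmfit.Parameters()
    params.add("a0", value=float(y[-1]))
    params.add("a", value=float(y[0] - y[-1]))
    params.add("tau_s", value=tau0, min=1e-9)

    def residual(p):
        return exponential_model(ts, p["a0"], p["a"], p["tau_s"]) - y

    out, ok = _run_minimize(residual, params)
    if out is None:
        return FitResult("exponential", {}, {}, math.inf, False, len(y), tags)
    pr = out.params
    return FitResult(
        family="exponential",
        params={"a0": pr["a0"].value, "a": pr["a"].value, "tau_s": pr["tau_s"].value},
        stderr={k: pr[k].stderr for k in ("a0", "a", "tau_s")},
        rss=float(out.chisqr),
        converged=ok,
        n=len(y),
        tags=tags,
    )


def linear_log_fit(concentrations_M, taus_s) -> FitResult:
    """OLS of log10(tau) on log10(concentration): slope m and intercept b."""
    c = np.asarray(concentrations_M, dtype=float)
    tau = np.asarray(taus_s, dtype=float)
    if len(c) < 3:
        raise ValueError("linear_log_fit needs at least 3 points")
    if np.any(c <= 0) or np.any(tau <= 0):
        raise ValueError("concentrations and time constants must be positive")
    res = stats.linregress(np.log10(c), np.log10(tau))
    rss = float(np.sum((np.log10(tau) - (res.slope * np.log10(c) + res.intercept)) ** 2))
    return FitResult(
        family="loglinear",
        params={"m": res.slope, "b": res.intercept},
        stderr={"m": res.stderr, "b": res.intercept_stderr},
        rss=rss,
        converged=True,
        n=len(c),
        tags={"r_value": res.rvalue},
    )


# ---------------------------------------------------------------------------
# Trace-level metrics
# ---------------------------------------------------------------------------

def _segment_window(recording: Recording, sweep_index: int, segment_index: int):
    proto = recording.protocol
    start = proto.segment_start_s(sweep_index, segment_index)
    stop = start + proto.sweeps[sweep_index][segment_index].duration_s
    return start, stop


def end_pulse_inhibition(
    control: Recording,
    drug: Recording,
    pulse_index: int = 0,
    window_s: float = 0.05,
    segment_index: int | None = None,
) -> float:
    """Percent reduction of the mean current over the last ``window_s`` of a pulse.

    ``100 * (1 - I_drug / I_control)`` for the designated sweep's test
    segment; both recordings must come from the same protocol structure.
    """
    if control.protocol.to_dict()["sweeps"] != drug.protocol.to_dict()["sweeps"]:
        raise ValueError("control and drug recordings use different protocols")
    seg = segment_index if segment_index is not None else control.protocol.test_segment
    if seg is None:
        raise ConfigurationError("protocol does not designate a test segment")
    start, stop = _segment_window(control, pulse_index, seg)

    def _end_mean(rec: Recording) -> float:
        sw = rec.sweeps[pulse_index]
        m = (sw.time_s > stop - window_s) & (sw.time_s <= stop + 1e-12)
        return float(sw.current_uA[m].mean())

    i_ctrl = _end_mean(control)
    i_drug = _end_mean(drug)
    if abs(i_ctrl) < 1e-12:
        raise ZeroDivisionError("control end-pulse current is ~0; inhibition undefined")
    return 100.0 * (1.0 - i_drug / i_ctrl)


def tail_activation_curve(
    recording: Recording,
    method: str = "settle",
    settle_s: float = 0.005,
    peak_window_s: float = 0.05,
) -> pd.DataFrame:
    """Initial tail amplitudes per sweep, normalized to the maximum.

    ``method="settle"`` reads the current at the first sample at least
    ``settle_s`` after the tail step (letting the instantaneous jump settle);
    ``method="peak"`` takes the extremum within ``peak_window_s``.  The
    output column ``norm`` has maximum exactly 1.
    """
    proto = recording.protocol
    if proto.tail_segment is None:
        raise ConfigurationError(f"protocol {proto.name!r} has no tail segment")
    if method not in ("settle", "peak"):
        raise ValueError("method must be 'settle' or 'peak'")
    amps = []
    for i, sw in enumerate(recording.sweeps):
        start, stop = _segment_window(recording, i, proto.tail_segment)
        if method == "settle":
            j = int(np.searchsorted(sw.time_s, start + settle_s))
            amps.append(sw.current_uA[j])
        else:
            m = (sw.time_s >= start + 1e-12) & (sw.time_s <= start + peak_window_s)
            seg = sw.current_uA[m]
            amps.append(seg[np.argmax(np.abs(seg))])
    amps = np.asarray(amps)
    ref = amps[np.argmax(np.abs(amps))]
    norm = amps / ref if ref != 0 else amps
    return pd.DataFrame(
        {
            "voltage_mV": proto.test_voltages,
            "tail_uA": amps,
            "norm": norm,
        }
    )


def activation_tau_table(recording: Recording, exclude_s: float = 0.2) -> pd.DataFrame:
    """Single-exponential activation time constants per test voltage.

    The fit window is the test-pulse segment with its first ``exclude_s``
    removed: the sigmoidal onset of the slow delayed rectifier makes a single
    exponential a late-time description only.
    """
    proto = recording.protocol
    if proto.test_segment is None:
        raise ConfigurationError("protocol does not designate a test segment")
    rows = []
    for i, sw in enumerate(recording.sweeps):
        start, stop = _segment_window(recording, i, proto.test_segment)
        fit = exp_fit(sw.time_s, sw.current_uA, window=(start + exclude_s, stop), kind="activation")
        rows.append(
            {
                "voltage_mV": proto.sweeps[i][proto.test_segment].voltage_mV,
                "tau_s": fit.params.get("tau_s", np.nan),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def deactivation_tau(
    recording: Recording, sweep_index: int, exclude_s: float = 0.01
) -> FitResult:
    """Single-exponential fit of the tail-current decay of one sweep."""
    proto = recording.protocol
    if proto.tail_segment is None:
        raise ConfigurationError(f"protocol {proto.name!r} has no tail segment")
    sw = recording.sweeps[sweep_index]
    start, stop = _segment_window(recording, sweep_index, proto.tail_segment)
    return exp_fit(sw.time_s, sw.current_uA, window=(start + exclude_s, stop), kind="deactivation")
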