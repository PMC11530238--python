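"""Patch-clamp current-family quantification.

Implements the standard inside-out voltage-step analysis for a
Ca2+-activated, outwardly rectifying channel: leak subtraction against a
0-Ca2+ family, extraction of instantaneous (I_inst), steady-state (I_SS)
and tail currents from configurable windows, normalized I–V and G–V
curves (tail-based or steady-state/(V − V_rev)), the instantaneous
current fraction I_inst/I_SS, wash-out fraction remaining, and a Boltzmann
fit used for synthetic parameter-recovery checks.

Sign convention: voltages in mV, currents in pA, time in ms (wash
timecourses in s).
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Protocol",
    "Sweep",
    "CurrentFamily",
    "AnalysisWindows",
    "SweepFeatures",
    "CurveSet",
    "WashTimecourse",
    "BoltzmannFit",
    "parse_sweeps",
    "write_sweeps",
    "leak_subtract",
    "sweep_features",
    "inst_fraction",
    "build_iv",
    "build_gv",
    "normalize_curves",
    "wash_fraction_remaining",
    "fit_boltzmann",
]

#: Exclusion threshold from standard practice: patches with very large
#: currents produce substantial voltage errors and are discarded.
MAX_CURRENT_PA = 5000.0


@dataclass(frozen=True)
class Condition:
    """Recording condition: intracellular Ca2+ (µM), icilin (µM), construct."""

    ca_uM: float = 0.0
    icilin_uM: float = 0.0
    construct: str = "WT"

    def label(self) -> str:
        return f"{self.construct}/Ca{self.ca_uM:g}uM/icilin{self.icilin_uM:g}uM"


@dataclass
class Protocol:
    """Voltage-step protocol of a current family."""

    holding_V: float = -60.0
    step_Vs: tuple[float, ...] = tuple(np.arange(-100.0, 161.0, 20.0))
    step_duration: float = 200.0  # ms
    tail_V: float = -60.0
    tail_duration: float = 50.0  # ms
    sample_rate: float = 10.0  # kHz
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        vs = tuple(float(v) for v in self.step_Vs)
        if list(vs) != sorted(set(vs)):
            raise ValueError("step_Vs must be strictly increasing")
        self.step_Vs = vs
        if self.step_duration <= 0 or self.tail_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("durations and sample rate must be positive")

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1.0 / self.sample_rate

    def time_base(self) -> np.ndarray:
        """Times (ms) covering step + tail; t=0 is step onset."""
        n = int(round((self.step_duration + self.tail_duration) * self.sample_rate))
        return np.arange(n) * self.dt


@dataclass
class Sweep:
    """One voltage step: time base (ms, t=0 at step onset) and current (pA)."""

    step_V: float
    time: np.ndarray
    current: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape or self.time.ndim != 1:
            raise ValueError("time and current must be matching 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time base must be strictly increasing")


@dataclass
class CurrentFamily:
    """A protocol plus one sweep per step voltage."""

    protocol: Protocol
    sweeps: dict[float, Sweep]

    def __post_init__(self) -> None:
        missing = [v for v in self.protocol.step_Vs if v not in self.sweeps]
        if missing:
            raise ValueError(f"missing sweeps for step voltages {missing}")
        times = [self.sweeps[v].time for v in self.protocol.step_Vs]
        for t in times[1:]:
            if t.shape != times[0].shape or not np.allclose(t, times[0]):
                raise ValueError("all sweeps must share the time base")

    def max_abs_current(self) -> float:
        return max(float(np.max(np.abs(s.current))) for s in self.sweeps.values())


@dataclass
class AnalysisWindows:
    """Measurement windows (ms).  Defaults: 2 ms capacitive settle, I_inst
    over [2, 5] ms after step onset, I_SS over the last 10 ms of the step,
    tails over [2, 5] ms after repolarisation."""

    settle: float = 2.0
    inst_window: tuple[float, float] = (2.0, 5.0)
    ss_window_len: float = 10.0
    tail_window: tuple[float, float] = (2.0, 5.0)
    noise_floor_sd_mult: float = 5.0

    def __post_init__(self) -> None:
        if self.inst_window[0] < self.settle:
            raise ValueError("inst_window must start at or after the settle period")
        if self.inst_window[1] <= self.inst_window[0]:
            raise ValueError("inst_window must have positive length")
        if self.ss_window_len <= 0:
            raise ValueError("ss_window_len must be positive")


@dataclass
class SweepFeatures:
    """Extracted currents for one sweep (pA)."""

    step_V: float
    I_inst: float
    I_SS: float
    I_tail: float
    noise_sd: float
    reliable: bool = True


@dataclass
class CurveSet:
    """An I–V or G–V relation with its normalization record."""

    kind: str  # "IV" or "GV"
    points: dict[float, float]
    source: str = "steady_state"  # or "tail"
    normalization: dict | None = None
    excluded: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("IV", "GV"):
            raise ValueError(f"unknown curve kind {self.kind!r}")

    @property
    def voltages(self) -> np.ndarray:
        return np.array(sorted(self.points))

    @property
    def values(self) -> np.ndarray:
        return np.array([self.points[v] for v in sorted(self.points)])


@dataclass
class WashTimecourse:
    """Current at a fixed probe voltage versus time (s) around agonist removal."""

    times: np.ndarray
    currents: np.ndarray
    removal_time: float
    probe_V: float = 160.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


# ------------------------------- I/O -------------------------------------

def write_sweeps(family: CurrentFamily, path: str | Path) -> None:
    """Write a family as a delimited table: time column + one column per step."""
    cols = {"time_ms": family.sweeps[family.protocol.step_Vs[0]].time}
    for v in family.protocol.step_Vs:
        cols[f"{v:g}mV"] = family.sweeps[v].current
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def parse_sweeps(table: str | Path | io.StringIO, protocol: Protocol) -> CurrentFamily:
    """Parse a delimited sweep table (time + one column per step voltage)."""
    df = pd.read_csv(table)
    if "time_ms" not in df.columns:
        raise ValueError("sweep table must have a 'time_ms' column")
    time = df["time_ms"].to_numpy(dtype=float)
    sweeps = {}
    for v in protocol.step_Vs:
        col = f"{v:g}mV"
        if col not in df.columns:
            raise ValueError(
                f"sweep table lacks column {col!r} for step voltage {v:g} mV"
            )
        sweeps[v] = Sweep(step_V=v, time=time, current=df[col].to_numpy(dtype=float))
    extra = set(df.columns) - {"time_ms"} - {f"{v:g}mV" for v in protocol.step_Vs}
    if extra:
        raise ValueError(f"sweep table has columns not in the protocol: {sorted(extra)}")
    return CurrentFamily(protocol=protocol, sweeps=sweeps)


# --------------------------- computations --------------------------------

def leak_subtract(family: CurrentFamily, leak_family: CurrentFamily) -> CurrentFamily:
    """Pointwise subtraction of the 0-Ca2+ leak family, voltage by voltage."""
    if tuple(family.protocol.step_Vs) != tuple(leak_family.protocol.step_Vs):
        raise ValueError("protocol step voltages differ between family and leak family")
    out = {}
    for v in family.protocol.step_Vs:
        s, l = family.sweeps[v], leak_family.sweeps[v]
        if s.time.shape != l.time.shape:
            raise ValueError(f"time base mismatch at {v:g} mV")
        out[v] = Sweep(step_V=v, time=s.time, current=s.current - l.current)
    return CurrentFamily(protocol=family.protocol, sweeps=out)


def _window_mean(sweep: Sweep, lo: float, hi: float) -> float:
    # half-open [lo, hi) so a window ending at the step edge never captures
    # the first post-step sample
    mask = (sweep.time >= lo) & (sweep.time < hi)
    if not np.any(mask):
        raise ValueError(f"window [{lo}, {hi}) ms outside the sweep time base")
    return float(np.mean(sweep.current[mask]))


def sweep_features(
    sweep: Sweep, windows: AnalysisWindows | None = None, step_duration: float = 200.0
) -> SweepFeatures:
    """I_inst, I_SS and I_tail as window means of the trace."""
    w = windows or AnalysisWindows()
    I_inst = _window_mean(sweep, w.inst_window[0], w.inst_window[1])
    I_SS = _window_mean(sweep, step_duration - w.ss_window_len, step_duration)
    t0 = step_duration
    has_tail = np.any(sweep.time >= t0 + w.tail_window[0])
    I_tail = (
        _window_mean(sweep, t0 + w.tail_window[0], t0 + w.tail_window[1])
        if has_tail
        else float("nan")
    )
    # noise from detrended steady-state segment
    mask = (sweep.time >= step_duration - w.ss_window_len) & (sweep.time < step_duration)
    seg = sweep.current[mask]
    noise_sd = float(np.std(seg - np.polyval(np.polyfit(np.arange(len(seg)), seg, 1), np.arange(len(seg))))) if len(seg) > 2 else 0.0
    reliable = abs(I_SS) > w.noise_floor_sd_mult * noise_sd
    return SweepFeatures(
        step_V=sweep.step_V,
        I_inst=I_inst,
        I_SS=I_SS,
        I_tail=I_tail,
        noise_sd=noise_sd,
        reliable=reliable,
    )


def inst_fraction(features: SweepFeatures) -> float:
    """Fraction of current that activates instantaneously, I_inst / I_SS.

    Returns NaN (flagged undefined) when |I_SS| is below the noise floor.
    """
    if not features.reliable or features.I_SS == 0.0:
        warnings.warn(
            f"I_SS below noise floor at {features.step_V:g} mV; "
            "instantaneous fraction undefined",
            stacklevel=2,
        )
        return float("nan")
    return features.I_inst / features.I_SS


def build_iv(
    family: CurrentFamily, windows: AnalysisWindows | None = None
) -> CurveSet:
    """Steady-state I–V relation of a family."""
    pts = {}
    for v in family.protocol.step_Vs:
        f = sweep_features(family.sweeps[v], windows, family.protocol.step_duration)
        pts[v] = f.I_SS
    return CurveSet(kind="IV", points=pts, source="steady_state")


def build_gv(
    family: CurrentFamily,
    source: str = "tail",
    Vrev: float = 0.0,
    windows: AnalysisWindows | None = None,
) -> CurveSet:
    """Conductance–voltage relation.

    ``tail`` mode uses tail amplitudes measured at the fixed tail voltage:
    the driving force is the same constant for every point, so dividing by
    it only sets the scale/sign and tails remain directly proportional to
    conductance at step end.  ``steady_state`` mode computes
    G = I_SS / (V − V_rev), excluding the point at V = V_rev.
    """
    if source not in ("tail", "steady_state"):
        raise ValueError(f"unknown G–V source {source!r}")
    pts, excluded = {}, []
    for v in family.protocol.step_Vs:
        f = sweep_features(family.sweeps[v], windows, family.protocol.step_duration)
        if source == "tail":
            if family.protocol.tail_V == Vrev:
                raise ValueError("tail voltage equals reversal potential: no driving force")
            pts[v] = f.I_tail / (family.protocol.tail_V - Vrev)
        else:
            if v == Vrev:
                excluded.append(v)
                continue
            pts[v] = f.I_SS / (v - Vrev)
    return CurveSet(kind="GV", points=pts, source=source, excluded=excluded)


def normalize_curves(
    curves: dict[str, CurveSet],
    reference_key: str,
    reference_V: float = 160.0,
) -> dict[str, CurveSet]:
    """Divide every curve of a cell by the value of the reference curve at
    the reference voltage (the fixed recording condition each cell must
    include), so the reference point maps to exactly 1.0."""
    if reference_key not in curves:
        raise ValueError(
            f"reference condition {reference_key!r} absent; have {sorted(curves)}"
        )
    ref_curve = curves[reference_key]
    if reference_V not in ref_curve.points:
        raise ValueError(f"reference voltage {reference_V:g} mV absent from reference curve")
    ref_val = ref_curve.points[reference_V]
    if ref_val == 0.0:
        raise ValueError("reference value is zero; cannot normalize")
    out = {}
    for key, c in curves.items():
        if c.normalization is not None:
            out[key] = c  # idempotent: already normalized
            continue
        out[key] = replace(
            c,
            points={v: val / ref_val for v, val in c.points.items()},
            normalization={
                "reference_condition": reference_key,
                "reference_V": reference_V,
                "reference_value": ref_val,
            },
        )
    return out


def wash_fraction_remaining(
    tc: WashTimecourse, delay: float = 14.0
) -> float:
    """Current remaining ``delay`` s after agonist removal over the current
    immediately before removal, after baseline subtraction."""
    t_probe = tc.removal_time + delay
    if tc.times[-1] < t_probe or tc.times[0] > tc.removal_time:
        raise ValueError(
            f"timecourse [{tc.times[0]:g}, {tc.times[-1]:g}] s does not span "
            f"removal + {delay:g} s"
        )
    before = float(np.interp(tc.removal_time, tc.times, tc.currents)) - tc.baseline
    after = float(np.interp(t_probe, tc.times, tc.currents)) - tc.baseline
    if before == 0.0:
        raise ValueError("zero pre-removal current")
    return after / before


@dataclass
class BoltzmannFit:
    """Result of a two-state Boltzmann fit G(V) = G_max / (1 + exp((V_half − V)/slope))."""

    V_half: float
    slope: float
    G_max: float
    converged: bool
    rmse: float
    message: str = ""


def fit_boltzmann(gv: CurveSet) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a G–V relation.

    Initialisation is data-driven and deterministic: G_max from the maximum,
    V_half from the half-maximum crossing, slope from the 25–75% span.
    A flat curve (dynamic range below 5% of its maximum) is flagged
    non-converged rather than fitted.
    """
    V, G = gv.voltages, gv.values
    if len(V) < 5:
        raise ValueError("at least 5 points are required for a Boltzmann fit")
    gspan = float(G.max() - G.min())
    if G.max() == 0 or gspan < 0.05 * abs(G.max()):
        return BoltzmannFit(
            V_half=float("nan"), slope=float("nan"), G_max=float(G.max()),
            converged=False, rmse=float("nan"), message="flat curve",
        )

    def model(v, vhalf, slope, gmax):
        return gmax / (1.0 + np.exp((vhalf - v) / slope))

    g_max0 = float(G.max())
    v_half0 = float(V[np.argmin(np.abs(G - g_max0 / 2.0))])
    slope0 = max((float(V.max()) - float(V.min())) / 10.0, 1.0)
    try:
        popt, _ = curve_fit(
            model, V, G, p0=[v_half0, slope0, g_max0], maxfev=10000
        )
    except RuntimeError as exc:
        return BoltzmannFit(
            V_half=float("nan"), slope=float("nan"), G_max=float("nan"),
            converged=False, rmse=float("nan"), message=str(exc),
        )
    resid = G - model(V, *popt)
    return BoltzmannFit(
        V_half=float(popt[0]),
        slope=float(popt[1]),
        G_max=float(popt[2]),
        converged=True,
        rmse=float(np.sqrt(np.mean(resid**2))),
    )
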