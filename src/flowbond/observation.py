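"""From bead trajectories to corrected, specific-only survival curves.

The observational unit is an *arrest*: a bead whose displacement stays below
a threshold (0.5 um) over a forward-looking detection window (200 ms).  The
window makes short arrests invisible and biases apparent durations, which is
undone by the correction

    d_true = d_app + dt_window - 2 * dx_threshold / u_p,

where ``u_p`` is the unbound bead velocity.  Corrected durations feed an
empirical survival curve with binomial per-point uncertainty; curves are
renormalized with a linear extrapolation of the early (< 0.5 s) surviving
count to time zero, and purged of nonspecific arrests by the two-component
mixture identity

    s_spec = (s_obs - p_ns * s_ns) / (1 - p_ns).

Right-censored arrests (still arrested when the record ends) are handled by
Kaplan-Meier risk-set reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinetics import BondLaw, SurvivalCurve, survival as law_survival

__all__ = [
    "Trajectory",
    "ArrestEvent",
    "ArrestSet",
    "NonspecificModel",
    "detect_arrests",
    "correct_duration",
    "build_survival",
    "extrapolate_true_count",
    "renormalize_to_true_count",
    "binding_frequency",
    "subtract_nonspecific",
    "specific_survival_pipeline",
    "specific_fraction",
    "mean_off_rate",
]


@dataclass
class Trajectory:
    """A tracked bead: (time, x) samples at nominally uniform frame spacing."""

    bead_id: str
    times: np.ndarray  # s
    x: np.ndarray  # um, along-flow position
    pixel_size: float = 0.5  # um
    position_resolution: float = 40.0  # nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.times.shape != self.x.shape or self.times.ndim != 1:
            raise ValueError("times and x must be 1-d arrays of equal length")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if len(dt) and np.ptp(dt) > np.median(dt):
            raise ValueError("trajectory frames must be uniformly spaced")

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class ArrestEvent:
    """One detected bead arrest."""

    start_time: float
    apparent_duration: float
    corrected_duration: float | None = None
    shear_rate: float | None = None
    censored: bool = False


@dataclass
class ArrestSet:
    """Arrests from one experimental condition plus the scanned path length."""

    events: list[ArrestEvent]
    total_path_length: float  # mm
    label: str = ""

    def __post_init__(self) -> None:
        if not self.total_path_length > 0:
            raise ValueError("total_path_length must be positive")

    def durations(self, corrected: bool = True) -> np.ndarray:
        if corrected:
            return np.array([e.corrected_duration for e in self.events], dtype=float)
        return np.array([e.apparent_duration for e in self.events], dtype=float)

    def censored_flags(self) -> np.ndarray:
        return np.array([e.censored for e in self.events], dtype=bool)


@dataclass
class NonspecificModel:
    """Pooled nonspecific share of arrests and their survival curve."""

    p_ns: float
    ns_survival: SurvivalCurve | BondLaw

    def __post_init__(self) -> None:
        if not 0 <= self.p_ns < 1:
            raise ValueError("p_ns must lie in [0, 1)")


def detect_arrests(
    traj: Trajectory,
    displacement_threshold: float = 0.5,
    window: float = 0.2,
    u_p: float | None = None,
) -> list[ArrestEvent]:
    """Detect arrests with the forward-window displacement criterion.

    A frame *qualifies* when the displacement over the following ``window``
    is below ``displacement_threshold``; maximal runs of qualifying frames
    become events.  The apparent duration spans the first to last qualifying
    frame; runs reaching the end of the evaluable record are flagged
    censored.  If ``u_p`` (um/s) is given, corrected durations are filled via
    :func:`correct_duration`.
    """
    frame = traj.frame_interval
    w = int(round(window / frame))
    n = len(traj.times)
    if n <= w or w < 1:
        raise ValueError("trajectory shorter than the detection window")
    disp = np.abs(traj.x[w:] - traj.x[:-w])
    qualifies = disp < displacement_threshold  # indices 0 .. n-1-w
    events: list[ArrestEvent] = []
    i = 0
    m = len(qualifies)
    while i < m:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and qualifies[j + 1]:
            j += 1
        d_app = float(traj.times[j] - traj.times[i])
        ev = ArrestEvent(
            start_time=float(traj.times[i]),
            apparent_duration=d_app,
            censored=(j == m - 1),
        )
        if u_p is not None:
            ev.corrected_duration = correct_duration(
                d_app, window=window, threshold=displacement_threshold, u_p=u_p
            )
        events.append(ev)
        i = j + 1
    return events


def correct_duration(
    d_app: float, window: float = 0.2, threshold: float = 0.5, u_p: float = 22.5
) -> float:
    """True arrest duration d_true = d_app + window - 2 * threshold / u_p."""
    if not u_p > 0:
        raise ValueError("u_p must be positive")
    return d_app + window - 2.0 * threshold / u_p


def build_survival(
    durations: Sequence[float],
    grid: Sequence[float],
    censored: Sequence[bool] | None = None,
) -> SurvivalCurve:
    """Empirical survivor function on ``grid`` with binomial uncertainty.

    Without censoring this is the plain fraction of durations exceeding each
    grid time.  With censoring flags, the Kaplan-Meier estimator (reduced
    risk set after each censoring time) is used instead.  The per-point SD is
    sqrt(s (1 - s) / N) with N the total event count.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one duration")
    grid = np.asarray(grid, dtype=float)
    n = d.size
    if censored is not None and np.any(censored):
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter()
        kmf.fit(d, event_observed=~np.asarray(censored, dtype=bool))
        s = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    else:
        s = (d[None, :] > grid[:, None]).mean(axis=1)
    sd = np.sqrt(np.clip(s * (1.0 - s), 0.0, None) / n)
    return SurvivalCurve(times=grid, survival=s, sd=sd, n_total=n)


def extrapolate_true_count(
    curve: SurvivalCurve, cutoff: float = 0.5, t_min: float = 0.0
) -> float:
    """Extrapolate the early surviving count linearly to time zero.

    Fits an ordinary least-squares line through (t, s(t) * N) for t_min <=
    t <= ``cutoff`` and returns its intercept: the estimated true number of
    arrests, including those too short to detect.  ``t_min`` excludes grid
    times below the detection floor, where the empirical curve is flat by
    construction rather than by physics.
    """
    if curve.n_total is None:
        raise ValueError("curve must carry n_total to extrapolate counts")
    mask = (curve.times <= cutoff) & (curve.times >= t_min)
    if mask.sum() < 2:
        raise ValueError("need at least two points in the extrapolation window")
    t = curve.times[mask]
    counts = curve.survival[mask] * curve.n_total
    slope, intercept = np.polyfit(t, counts, 1)
    return float(intercept)


def renormalize_to_true_count(
    curve: SurvivalCurve, cutoff: float = 0.5, t_min: float = 0.0
) -> SurvivalCurve:
    """Rescale a curve so that the extrapolated time-zero count has survival 1."""
    n0 = extrapolate_true_count(curve, cutoff=cutoff, t_min=t_min)
    counts = curve.survival * curve.n_total
    s = np.clip(counts / n0, 0.0, 1.0)
    sd = np.sqrt(np.clip(s * (1.0 - s), 0.0, None) / n0)
    return SurvivalCurve(times=curve.times, survival=s, sd=sd, n_total=n0)


def binding_frequency(n_events: int, path_length: float) -> tuple[float, float]:
    """Binding frequency per mm and its Poisson SD, sqrt(N) / L."""
    if not path_length > 0:
        raise ValueError("path_length must be positive")
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    return n_events / path_length, float(np.sqrt(n_events)) / path_length


def subtract_nonspecific(observed: SurvivalCurve, ns: NonspecificModel) -> SurvivalCurve:
    """Remove the nonspecific mixture component from an observed curve.

    s_spec(t) = (s_obs(t) - p_ns * s_ns(t)) / (1 - p_ns), clamped to [0, 1];
    the underlying event count is scaled by (1 - p_ns).
    """
    if ns.p_ns >= 1:
        raise ValueError("p_ns must be < 1")
    t = observed.times
    if isinstance(ns.ns_survival, BondLaw):
        s_ns = law_survival(ns.ns_survival, t)
    else:
        s_ns = ns.ns_survival.evaluate(t)
    s_spec = np.clip((observed.survival - ns.p_ns * s_ns) / (1.0 - ns.p_ns), 0.0, 1.0)
    n = None if observed.n_total is None else observed.n_total * (1.0 - ns.p_ns)
    sd = None
    if n:
        sd = np.sqrt(np.clip(s_spec * (1.0 - s_spec), 0.0, None) / n)
    return SurvivalCurve(times=t, survival=s_spec, sd=sd, n_total=n)


def specific_fraction(fold_increase: float) -> float:
    """Fraction of arrests that are specific, from the frequency fold-increase
    of coated over control beads: (fold - 1) / fold."""
    if fold_increase < 1:
        raise ValueError("fold_increase must be >= 1")
    return (fold_increase - 1.0) / fold_increase


def specific_survival_pipeline(
    durations: Sequence[float],
    ns: NonspecificModel | None,
    grid: Sequence[float],
    detection_floor: float = 0.0,
    censored: Sequence[bool] | None = None,
    cutoff: float = 0.5,
) -> tuple[SurvivalCurve, SurvivalCurve]:
    """Corrected durations -> specific-only survival curves.

    Builds the empirical curve from detected arrests, then removes the
    nonspecific mixture component (``ns`` holds the *detected-event*
    nonspecific share and the control curve measured under the same
    detection window).  Returns two curves:

    * the *conditional* curve -- survival relative to the detected events,
      i.e. conditional on lasting past ``detection_floor``; feed this to
      :func:`~flowbond.kinetics.fit_bond_law` with
      ``condition_at=detection_floor`` to fit without truncation bias;
    * the *renormalized* curve -- rescaled by the linear early-count
      extrapolation so survival refers to the estimated true arrest count,
      including arrests too short to detect (for plotting and frequencies).
    """
    grid = np.asarray(grid, dtype=float)
    curve = build_survival(durations, grid, censored=censored)
    if ns is not None and ns.p_ns > 0:
        curve = subtract_nonspecific(curve, ns)
    renorm = renormalize_to_true_count(curve, cutoff=cutoff, t_min=detection_floor)
    return curve, renorm


def mean_off_rate(curve_or_law, horizon: float = 0.5) -> float:
    """Average dissociation rate over [0, horizon]: -ln s(horizon) / horizon."""
    if isinstance(curve_or_law, BondLaw):
        s = law_survival(curve_or_law, horizon)
    else:
        s = curve_or_law.evaluate(horizon)
    if s <= 0:
        raise ValueError("survival at the horizon must be positive")
    return float(-np.log(s) / horizon)
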