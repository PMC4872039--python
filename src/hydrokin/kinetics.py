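"""Hydration/conformation state kinetics.

Snapshots of a trajectory are classified into discrete conformational and
hydration states from the gauge distance d and the region-integrated solvent
charge Q. Snapshots falling between the state boxes are labelled
``boundary`` and then assigned to the temporally nearest classified
snapshot. Residence times of the resulting dwell segments are fitted with an
exponential model: the probability that a dwell in state A (ending in state
B) has terminated by time t is 1 − exp(−t/τ_AB), so 1/τ_AB is the A→B rate
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BOUNDARY",
    "StateSeries",
    "DwellRecord",
    "RateEstimate",
    "HS1Thresholds",
    "classify_hs1",
    "classify_hs2",
    "classify_hs1_series",
    "classify_hs2_series",
    "resolve_boundaries",
    "extract_dwells",
    "fit_rate",
    "transition_stats",
    "fit_all_rates",
]

BOUNDARY = "boundary"


@dataclass
class StateSeries:
    """Per-frame categorical labels on a uniform time grid (ps)."""

    times: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.times) != len(self.labels):
            raise ValueError("times and labels must have equal length")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("StateSeries requires uniform time spacing")
            if steps[0] <= 0:
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("dt undefined for a series with < 2 samples")
        return float(self.times[1] - self.times[0])

    def runs(self) -> list[tuple[str, int, int]]:
        """Maximal constant-label runs as (label, start_idx, stop_idx_excl)."""
        labels = self.labels
        if len(labels) == 0:
            return []
        change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [len(labels)]))
        return [(str(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


@dataclass(frozen=True)
class DwellRecord:
    """One maximal residence segment in a state."""

    state: str
    start: float  # ps
    end: float  # ps
    duration: float  # ps
    successor: str | None  # state entered at `end`; None if censored


@dataclass
class RateEstimate:
    """Fitted mean residence time τ_AB and rate 1/τ_AB for a state pair."""

    pair: tuple[str, str]
    tau: float  # ps
    n_dwells: int
    t_min: float
    tau_closed_form: float  # mean(t_res) − t_min (truncated-exponential MLE)
    residual_norm: float

    @property
    def rate(self) -> float:
        return 1.0 / self.tau


# ---------------------------------------------------------------------------
# Classification

@dataclass(frozen=True)
class HS1Thresholds:
    """State boxes for the hydrophobic pocket: jaw distance d (Å) vs Q (e).

    Defaults: wet open (d > 7, Q > 8), wet half-open (5 < d < 7, Q > 8),
    dry half-open (5 < d < 7, Q < 4), closed (d < 5, Q < 4); anything that
    falls in no box (including values exactly on a threshold) is boundary.
    """

    d_closed: float = 5.0
    d_open: float = 7.0
    q_dry: float = 4.0
    q_wet: float = 8.0


def classify_hs1(d: float, q: float, thresholds: HS1Thresholds = HS1Thresholds()) -> str:
    t = thresholds
    if d > t.d_open and q > t.q_wet:
        return "wet_open"
    if t.d_closed < d < t.d_open and q > t.q_wet:
        return "wet_half_open"
    if t.d_closed < d < t.d_open and q < t.q_dry:
        return "dry_half_open"
    if d < t.d_closed and q < t.q_dry:
        return "closed"
    return BOUNDARY


def classify_hs1_series(
    times, d, q, thresholds: HS1Thresholds = HS1Thresholds()
) -> StateSeries:
    labels = np.array([classify_hs1(di, qi, thresholds) for di, qi in zip(d, q)])
    return StateSeries(times=np.asarray(times, dtype=float), labels=labels)


def classify_hs2(
    q: float, levels: tuple[float, ...] = (30.0, 40.0, 50.0), half_width: float = 5.0
) -> str:
    """Water-occupancy state of the hydrophilic crevice from Q alone.

    Q plateaus near 10 e per resident water; the default levels 30/40/50 e
    correspond to 3, 4 and 5 waters. Q is assigned to the nearest level
    within ±half_width (upper edges belong to the higher level); outside
    every bin it is boundary.
    """
    levels = tuple(sorted(levels))
    if q < levels[0] - half_width or q > levels[-1] + half_width:
        return BOUNDARY
    nearest = min(range(len(levels)), key=lambda i: (abs(q - levels[i]), -i))
    n_waters = int(round(levels[nearest] / 10.0))
    return f"{n_waters}w"


def classify_hs2_series(
    times, q, levels: tuple[float, ...] = (30.0, 40.0, 50.0), half_width: float = 5.0
) -> StateSeries:
    labels = np.array([classify_hs2(qi, levels, half_width) for qi in q])
    return StateSeries(times=np.asarray(times, dtype=float), labels=labels)


# ---------------------------------------------------------------------------
# Boundary resolution and dwell extraction

def resolve_boundaries(series: StateSeries) -> StateSeries:
    """Assign each boundary snapshot the label of the temporally nearest
    classified snapshot; ties go to the earlier side. Idempotent."""
    labels = np.asarray(series.labels).copy()
    classified = np.nonzero(labels != BOUNDARY)[0]
    if len(classified) == 0:
        raise ValueError("series contains no classified snapshots")
    boundary = np.nonzero(labels == BOUNDARY)[0]
    if len(boundary) == 0:
        return StateSeries(series.times, labels)
    # For each boundary index, nearest classified index; tie -> earlier.
    pos = np.searchsorted(classified, boundary)
    left = classified[np.clip(pos - 1, 0, len(classified) - 1)]
    right = classified[np.clip(pos, 0, len(classified) - 1)]
    dist_left = np.where(pos > 0, boundary - left, np.iinfo(np.int64).max)
    dist_right = np.where(pos < len(classified), right - boundary, np.iinfo(np.int64).max)
    take_left = dist_left <= dist_right
    source = np.where(take_left, left, right)
    labels[boundary] = labels[source]
    return StateSeries(series.times, labels)


def extract_dwells(
    series: StateSeries,
    t_min: float = 5.0,
    include_censored: bool = False,
    include_short: bool = False,
) -> list[DwellRecord]:
    """Dwell segments usable for residence-time fitting.

    A run of L consecutive snapshots at spacing dt counts as a residence of
    duration L·dt. By default the first and last runs (censored: their true
    start/end is unobserved) are dropped, as are runs with duration ≤ t_min
    (residence times of more than t_min enter the frequency distribution).
    Transition tallies are unaffected by either filter — use
    :func:`transition_stats` for those.
    """
    if BOUNDARY in series.labels:
        raise ValueError("resolve_boundaries must be applied before dwell extraction")
    runs = series.runs()
    if not runs:
        return []
    dt = series.dt if len(series) > 1 else 0.0
    records: list[DwellRecord] = []
    for k, (label, a, b) in enumerate(runs):
        censored = k == 0 or k == len(runs) - 1
        if censored and not include_censored:
            continue
        duration = (b - a) * dt
        if duration <= t_min and not include_short:
            continue
        successor = runs[k + 1][0] if k + 1 < len(runs) else None
        records.append(
            DwellRecord(
                state=label,
                start=float(series.times[a]),
                end=float(series.times[a] + duration),
                duration=float(duration),
                successor=successor,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Rate fitting

def _cdf_model(t, tau):
    return 1.0 - np.exp(-t / tau)


def fit_rate(
    durations,
    t_min: float = 5.0,
    pair: tuple[str, str] = ("A", "B"),
    method: str = "ls_cdf",
) -> RateEstimate:
    """Fit the mean residence time τ_AB from dwell durations.

    Default estimator: unweighted least squares of the empirical CDF of
    (t_res − t_min), evaluated at the observed dwell times (Hazen plotting
    positions (i − 1/2)/n), against 1 − exp(−t/τ). The closed-form
    truncated-exponential MLE, mean(t_res) − t_min, is always reported as a
    diagnostic and is the estimator when ``method="mean"``. Deterministic
    given the dwell set.
    """
    t = np.sort(np.asarray(durations, dtype=float)) - t_min
    if len(t) < 5:
        raise ValueError(f"need >= 5 dwell records to fit a rate, got {len(t)}")
    if np.any(t < 0):
        raise ValueError("dwell durations below t_min in fit set")
    closed_form = float(np.mean(t))
    if method == "mean":
        tau = closed_form
        resid = float(np.linalg.norm(_cdf_model(t, tau) - _ecdf(t)))
    elif method == "ls_cdf":
        ecdf = _ecdf(t)
        try:
            popt, _ = curve_fit(
                _cdf_model, t, ecdf, p0=[max(closed_form, 1e-6)],
                bounds=(1e-9, np.inf),
            )
            tau = float(popt[0])
        except RuntimeError as exc:
            raise RuntimeError(
                f"CDF fit did not converge (closed-form estimate: "
                f"{closed_form:.3g} ps)"
            ) from exc
        resid = float(np.linalg.norm(_cdf_model(t, tau) - ecdf))
    else:
        raise ValueError(f"unknown method {method!r}")
    if tau <= 0:
        raise RuntimeError("fitted tau is non-positive")
    return RateEstimate(
        pair=pair,
        tau=tau,
        n_dwells=len(t),
        t_min=t_min,
        tau_closed_form=closed_form,
        residual_norm=resid,
    )


def _ecdf(sorted_t: np.ndarray) -> np.ndarray:
    n = len(sorted_t)
    return (np.arange(1, n + 1) - 0.5) / n


def fit_all_rates(
    series: StateSeries, t_min: float = 5.0, min_dwells: int = 5, method: str = "ls_cdf"
) -> dict[tuple[str, str], RateEstimate]:
    """Fit τ_AB for every (state, successor) pair with enough dwells."""
    dwells = extract_dwells(series, t_min=t_min)
    by_pair: dict[tuple[str, str], list[float]] = {}
    for d in dwells:
        if d.successor is not None:
            by_pair.setdefault((d.state, d.successor), []).append(d.duration)
    out = {}
    for pair, durations in sorted(by_pair.items()):
        if len(durations) >= min_dwells:
            out[pair] = fit_rate(durations, t_min=t_min, pair=pair, method=method)
    return out


def transition_stats(series: StateSeries):
    """Transition counts and state populations of a resolved series.

    Returns ``(counts, populations)``: counts maps (A, B) to the number of
    A→B label changes; populations maps each state to its snapshot fraction
    (fractions sum to 1).
    """
    if BOUNDARY in series.labels:
        raise ValueError("resolve_boundaries must be applied before transition_stats")
    labels = np.asarray(series.labels)
    counts: dict[tuple[str, str], int] = {}
    change = np.nonzero(labels[1:] != labels[:-1])[0]
    for i in change:
        key = (str(labels[i]), str(labels[i + 1]))
        counts[key] = counts.get(key, 0) + 1
    states, tallies = np.unique(labels, return_counts=True)
    populations = {str(s): float(c) / len(labels) for s, c in zip(states, tallies)}
    return counts, populations
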