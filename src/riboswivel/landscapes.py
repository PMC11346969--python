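"""Relative free-energy landscapes, state assignment and transit times.

A landscape is a 2-D histogram over two reaction coordinates with the
bin occupancy normalised to the modal bin; the relative free energy is
Delta G* = -ln(count / max count) in units of kT (Boltzmann constant 1
at the simulation temperature), so the modal bin sits at 0 and empty
bins are masked.

Translocation states are assigned from the head-swivel angle:
PRE (0 deg), a 10 deg waypoint, INT2 (16 deg), INT3 (22.6 deg) for
forward swivel, and a 13 deg intermediate on the way back to
POST (0 deg) for reverse swivel.  Transit times are first-passage frame
counts to each destination threshold, summarised as mean +/- sample SD
across trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Landscape2D",
    "StateThresholds",
    "TransitSummary",
    "make_landscape",
    "assign_state",
    "transit_times",
    "relative_transit",
]


@dataclass
class Landscape2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    occupancy: np.ndarray      # counts / max counts, modal bin = 1
    delta_g: np.ndarray        # -ln occupancy; NaN on empty bins

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        import json

        with open(path, "w") as fh:
            fh.write("# Delta G* (kT) matrix; rows = x bins, cols = y bins; NaN = unsampled\n")
            fh.write("# bin edges: " + json.dumps(
                {"x_edges": self.x_edges.tolist(), "y_edges": self.y_edges.tolist()}) + "\n")
            np.savetxt(fh, self.delta_g, delimiter=",", fmt="%.6g")


def make_landscape(x, y, x_edges, y_edges) -> Landscape2D:
    """Normalised-occupancy landscape from two reaction-coordinate series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("reaction-coordinate series must have equal length")
    counts, xe, ye = np.histogram2d(x, y, bins=[np.asarray(x_edges), np.asarray(y_edges)])
    if counts.sum() == 0:
        raise ValueError("no samples fall inside the landscape range")
    occ = counts / counts.max()
    with np.errstate(divide="ignore"):
        dg = np.where(counts > 0, -np.log(np.where(occ > 0, occ, 1.0)), np.nan)
    return Landscape2D(xe, ye, counts.astype(np.int64), occ, dg)


@dataclass
class StateThresholds:
    """Head-swivel angles (degrees) defining the translocation states."""

    pre: float = 0.0
    ten_degree: float = 10.0
    int2: float = 16.0
    int3: float = 22.6
    post: float = 0.0
    reverse_intermediate: float = 13.0

    def __post_init__(self):
        if not (self.pre < self.ten_degree < self.int2 < self.int3):
            raise ValueError("forward thresholds must be ordered pre < 10 < INT2 < INT3")

    def forward_targets(self) -> dict[str, float]:
        return {"10deg": self.ten_degree, "INT2": self.int2, "INT3": self.int3}

    def reverse_targets(self) -> dict[str, float]:
        return {"13deg": self.reverse_intermediate, "POST": self.post}


FORWARD_LABELS = ["PRE", "10deg", "INT2", "INT3"]
REVERSE_LABELS = ["INT3", "13deg", "POST"]


def assign_state(
    swivel: np.ndarray,
    thresholds: StateThresholds | None = None,
    direction: str = "forward",
    hysteresis: float = 1.0,
) -> list[str]:
    """Per-frame state labels from the swivel series with hysteresis.

    Forward: the label advances when the swivel reaches the next
    threshold and only falls back when it drops more than the hysteresis
    band below the current one (avoiding label chatter from noise).
    Reverse runs symmetrically from INT3 down to POST.
    """
    thr = thresholds or StateThresholds()
    swivel = np.asarray(swivel, dtype=float)
    if direction == "forward":
        levels = [thr.pre, thr.ten_degree, thr.int2, thr.int3]
        labels = FORWARD_LABELS
        up = True
    elif direction == "reverse":
        levels = [thr.int3, thr.reverse_intermediate, thr.post]
        labels = REVERSE_LABELS
        up = False
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")
    out = []
    level = 0
    for s in swivel:
        if up:
            while level + 1 < len(levels) and s >= levels[level + 1]:
                level += 1
            while level > 0 and s < levels[level] - hysteresis:
                level -= 1
        else:
            while level + 1 < len(levels) and s <= levels[level + 1]:
                level += 1
            while level > 0 and s > levels[level] + hysteresis:
                level -= 1
        out.append(labels[level])
    return out


@dataclass
class TransitSummary:
    """First-passage statistics across trajectories, in frames."""

    direction: str
    per_trajectory: dict[str, list[float]] = field(default_factory=dict)
    n_trajectories: int = 0
    n_not_reaching: dict[str, int] = field(default_factory=dict)
    sd_mode: str = "sample"

    def mean(self, transition: str) -> float:
        v = self.per_trajectory[transition]
        return float(np.mean(v)) if v else float("nan")

    def sd(self, transition: str) -> float:
        v = self.per_trajectory[transition]
        if len(v) < 2:
            return float("nan")
        return float(np.std(v, ddof=1 if self.sd_mode == "sample" else 0))

    def as_rows(self):
        for tr in self.per_trajectory:
            yield {
                "transition": tr,
                "mean_frames": self.mean(tr),
                "sd_frames": self.sd(tr),
                "n_reaching": len(self.per_trajectory[tr]),
                "n_not_reaching": self.n_not_reaching.get(tr, 0),
            }


def _first_passage(series: np.ndarray, threshold: float, forward: bool):
    hit = (series >= threshold) if forward else (series <= threshold)
    idx = np.flatnonzero(hit)
    return int(idx[0]) if len(idx) else None


def transit_times(
    swivel_series: list[np.ndarray],
    thresholds: StateThresholds | None = None,
    direction: str = "forward",
    sd_mode: str = "sample",
) -> TransitSummary:
    """First frame reaching each destination state, per trajectory.

    Trajectories that never reach a destination are flagged, counted,
    and excluded from that transition's mean.  Per trajectory the
    first-passage frames are non-decreasing along nested targets.
    """
    if not swivel_series:
        raise ValueError("at least one trajectory required")
    thr = thresholds or StateThresholds()
    forward = direction == "forward"
    targets = thr.forward_targets() if forward else thr.reverse_targets()
    names = [("PRE->" if forward else "INT3->") + k for k in targets]
    summary = TransitSummary(direction=direction,
                             per_trajectory={nm: [] for nm in names},
                             n_trajectories=len(swivel_series),
                             n_not_reaching={nm: 0 for nm in names},
                             sd_mode=sd_mode)
    for series in swivel_series:
        series = np.asarray(series, dtype=float)
        for nm, level in zip(names, targets.values()):
            fp = _first_passage(series, level, forward)
            if fp is None:
                summary.n_not_reaching[nm] += 1
            else:
                summary.per_trajectory[nm].append(fp)
    return summary


def relative_transit(
    variant: TransitSummary,
    reference: TransitSummary,
    transition: str,
) -> dict[str, float]:
    """Variant/reference transit-time ratio with propagated uncertainty.

    Returns the ratio of means as a percentage, the derived
    "percent faster" value (1 - ratio) x 100, and first-order
    error-propagated SDs for both.
    """
    tv, tr = variant.mean(transition), reference.mean(transition)
    sv, sr = variant.sd(transition), reference.sd(transition)
    if not np.isfinite(tr) or tr == 0:
        raise ValueError("reference mean transit time is zero or undefined")
    ratio = tv / tr
    if np.isfinite(sv) and np.isfinite(sr) and tv != 0:
        sd_ratio = abs(ratio) * np.sqrt((sv / tv) ** 2 + (sr / tr) ** 2)
    else:
        sd_ratio = float("nan")
    return {
        "ratio_pct": 100.0 * ratio,
        "ratio_pct_sd": 100.0 * sd_ratio,
        "percent_faster": 100.0 * (1.0 - ratio),
        "percent_faster_sd": 100.0 * sd_ratio,
    }
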