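"""Gait event detection from the combined CoP, step segmentation, and
two-window time normalization.

Heel strikes and toe-offs are read off the "butterfly" of the combined
center-of-pressure trajectory: every double-stance phase shows up as a rapid,
near-linear transfer of the CoP from the trailing to the leading foot
(forward in AP, laterally in ML), separated by slow single-stance segments.
Events are localized by fitting straight lines to the single-stance and
transfer segments of the AP CoP and intersecting them, which needs no
amplitude threshold in physical units and is robust to broadband measurement
noise; the direction of the ML transfer labels the landing side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

logger = logging.getLogger("gaitfpc")

LEFT = "left"
RIGHT = "right"


def other_side(side: str) -> str:
    return LEFT if side == RIGHT else RIGHT


class EventDetectionError(RuntimeError):
    """Raised when no credible gait events can be extracted."""


# ---------------------------------------------------------------------------
# Event table
# ---------------------------------------------------------------------------

@dataclass
class GaitEventTable:
    """Per-side heel-strike and toe-off sample indices at sampling rate fs."""

    fs: float
    heel_strikes: dict[str, np.ndarray]  # side -> sorted sample indices
    toe_offs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for d in (self.heel_strikes, self.toe_offs):
            for side in (LEFT, RIGHT):
                d[side] = np.asarray(d.get(side, []), dtype=np.int64)
                if np.any(np.diff(d[side]) <= 0):
                    raise ValueError(f"{side} events not strictly increasing")

    def times(self, events: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {s: v / self.fs for s, v in events.items()}

    def merged_heel_strikes(self) -> tuple[np.ndarray, list[str]]:
        """All heel strikes in time order with their sides.

        Raises a diagnostic error if sides do not alternate.
        """
        samples = np.concatenate([self.heel_strikes[LEFT], self.heel_strikes[RIGHT]])
        sides = [LEFT] * len(self.heel_strikes[LEFT]) + [RIGHT] * len(self.heel_strikes[RIGHT])
        order = np.argsort(samples, kind="stable")
        samples = samples[order]
        sides = [sides[k] for k in order]
        bad = [int(samples[k]) for k in range(1, len(sides)) if sides[k] == sides[k - 1]]
        if bad:
            raise EventDetectionError(
                f"heel-strike sides do not alternate; offending samples: {bad}"
            )
        return samples, sides

    def to_json(self, path) -> None:
        payload = {
            "fs": self.fs,
            "heel_strikes": {
                s: {"sample": v.tolist(), "time_s": (v / self.fs).tolist()}
                for s, v in self.heel_strikes.items()
            },
            "toe_offs": {
                s: {"sample": v.tolist(), "time_s": (v / self.fs).tolist()}
                for s, v in self.toe_offs.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GaitEventTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            fs=payload["fs"],
            heel_strikes={s: np.array(v["sample"]) for s, v in payload["heel_strikes"].items()},
            toe_offs={s: np.array(v["sample"]) for s, v in payload["toe_offs"].items()},
        )


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _fit_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line y = a + b t (closed form, no polyfit overhead)."""
    tm = t.mean()
    ym = y.mean()
    dt = t - tm
    denom = np.dot(dt, dt)
    b = np.dot(dt, y - ym) / denom
    return ym - b * tm, b


def detect_events_from_cop(
    cop_ap: np.ndarray,
    cop_ml: np.ndarray,
    fs: float,
    min_step_time: float = 0.3,
    smooth_window: float = 0.025,
) -> GaitEventTable:
    """Detect heel strikes and toe-offs from the combined CoP butterfly.

    Parameters
    ----------
    cop_ap, cop_ml : array
        Combined CoP, anterior-posterior and mediolateral (m), same length.
    fs : float
        Sampling rate (Hz).
    min_step_time : float
        Minimum plausible step duration (s); nearer transfer candidates are
        merged, keeping the stronger one.
    smooth_window : float
        Savitzky-Golay window (s) for pre-smoothing.

    Returns
    -------
    GaitEventTable
        Heel strike = onset of a rapid CoP transfer (intersection of the
        preceding single-stance line with the transfer ramp); toe-off = its
        completion. Sides follow the ML transfer direction (ML positive =
        right).
    """
    cop_ap = np.asarray(cop_ap, float)
    cop_ml = np.asarray(cop_ml, float)
    if cop_ap.shape != cop_ml.shape:
        raise ValueError("cop_ap and cop_ml must have the same length")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = cop_ap.size
    win = max(5, int(round(smooth_window * fs)) | 1)
    if n <= win + 2:
        raise EventDetectionError("signal too short for event detection")
    if np.ptp(cop_ap) == 0 and np.ptp(cop_ml) == 0:
        raise EventDetectionError("constant CoP: no gait events present")

    ap_s = savgol_filter(cop_ap, win, 2)
    ml_s = savgol_filter(cop_ml, win, 2)
    # run finding tolerates (and benefits from) heavier smoothing: event
    # localization below fits lines to the raw signal away from the blurred
    # knees, so the extra smoothing costs no timing accuracy
    win_h = max(win, int(round(0.04 * fs)) | 1)
    v = np.gradient(savgol_filter(cop_ap, win_h, 2)) * fs

    lo, hi = np.percentile(v, [5.0, 95.0])
    if hi - lo <= 0:
        raise EventDetectionError("no CoP velocity spread: no gait events present")
    # Double-stance transfers are the minority phase with the extreme slope;
    # forward walking puts them on the positive side, a time-reversed record
    # on the negative side.
    if abs(hi) >= abs(lo):
        supra = v > lo + 0.5 * (hi - lo)
    else:
        supra = v < hi + 0.5 * (lo - hi)

    # contiguous supra-threshold runs
    edges = np.flatnonzero(np.diff(supra.astype(np.int8)))
    starts = edges[supra[edges + 1]] + 1
    stops = edges[~supra[edges + 1]] + 1  # exclusive
    if supra[0]:
        starts = np.r_[0, starts]
    if supra[-1]:
        stops = np.r_[stops, n]
    runs = [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= 3]
    if not runs:
        raise EventDetectionError("no CoP transfer candidates found")

    # merge candidates closer than min_step_time, keeping the stronger ramp
    min_gap = int(round(min_step_time * fs))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][0] < min_gap:
            prev = merged[-1]
            strength = lambda r: np.abs(v[r[0]:r[1]]).max()
            if strength(run) > strength(prev):
                merged[-1] = run
        else:
            merged.append(run)
    runs = merged
    if len(runs) < 3:
        raise EventDetectionError(f"fewer than 3 steps detected ({len(runs)} transfers)")

    guard = win_h // 2 + 2
    t = np.arange(n) / fs
    records = []  # (hs_sample | None, to_sample | None, side, strength)
    for k, (a, b) in enumerate(runs):
        prev_stop = runs[k - 1][1] if k > 0 else 0
        next_start = runs[k + 1][0] if k + 1 < len(runs) else n
        ra, rb = a + guard, b - guard
        if rb - ra < 3:  # keep at least the central third of the ramp
            ra, rb = a + (b - a) // 3, b - (b - a) // 3
        if rb - ra < 2:
            continue
        a_r, b_r = _fit_line(t[ra:rb], cop_ap[ra:rb])

        # landing side from the ML plateau shift (medians are robust to noise)
        ml_pre = ml_s[max(prev_stop + guard, 0):max(a - guard, 1)]
        ml_post = ml_s[min(b + guard, n - 1):max(next_start - guard, b + guard + 1)]
        if ml_pre.size < 3 or ml_post.size < 3:
            ml_pre = ml_s[max(a - guard, 0):max(a - guard + 1, 1)]
            ml_post = ml_s[min(b + guard, n - 1):min(b + guard + 1, n)]
        new_side = RIGHT if np.median(ml_post) - np.median(ml_pre) > 0 else LEFT

        def _intersect(seg_a, seg_b, ramp=(a_r, b_r)):
            """Knee = intersection of a stance line and the ramp line."""
            if seg_b - seg_a < 3:
                return None, None
            al, bl = _fit_line(t[seg_a:seg_b], cop_ap[seg_a:seg_b])
            if abs(ramp[1] - bl) <= 1e-12:
                return None, None
            s = int(round((al - ramp[0]) / (ramp[1] - bl) * fs))
            return (s, (al, bl)) if 0 <= s < n else (None, None)

        hs_sample, _ = _intersect(prev_stop + guard, a - guard)
        to_sample, _ = _intersect(b + guard, next_start - guard)

        # refinement: with knee estimates in hand, refit on wider, tighter
        # windows (the raw signal is not blurred, so only a small margin is
        # needed around the knees)
        m = 2
        if hs_sample is not None and to_sample is not None and to_sample - hs_sample >= m * 2 + 4:
            ramp2 = _fit_line(t[hs_sample + m:to_sample - m + 1],
                              cop_ap[hs_sample + m:to_sample - m + 1])
            s, _ = _intersect(prev_stop + m, hs_sample - m + 1, ramp2)
            if s is not None:
                hs_sample = s
            s, _ = _intersect(to_sample + m, next_start - m + 1, ramp2)
            if s is not None:
                to_sample = s
        if hs_sample is not None or to_sample is not None:
            records.append([hs_sample, to_sample, new_side,
                            float(np.abs(v[a:b]).max())])

    # transfers must alternate sides; a same-side neighbor pair means a
    # spurious (weak) transfer or a missed one in between -- drop the weaker
    changed = True
    while changed and len(records) > 1:
        changed = False
        for k in range(len(records) - 1):
            if records[k][2] == records[k + 1][2]:
                weak = k if records[k][3] <= records[k + 1][3] else k + 1
                logger.warning(
                    "dropping non-alternating transfer near sample %s (side %s)",
                    records[weak][0] if records[weak][0] is not None else records[weak][1],
                    records[weak][2],
                )
                del records[weak]
                changed = True
                break

    hs = {LEFT: [], RIGHT: []}
    to = {LEFT: [], RIGHT: []}
    for hs_sample, to_sample, side, _ in records:
        if hs_sample is not None:
            hs[side].append(hs_sample)
        if to_sample is not None:
            to[other_side(side)].append(to_sample)

    table = GaitEventTable(
        fs=fs,
        heel_strikes={s: np.array(sorted(hs[s]), dtype=np.int64) for s in (LEFT, RIGHT)},
        toe_offs={s: np.array(sorted(to[s]), dtype=np.int64) for s in (LEFT, RIGHT)},
    )
    n_hs = sum(len(x) for x in table.heel_strikes.values())
    if n_hs < 3:
        raise EventDetectionError(f"fewer than 3 heel strikes detected ({n_hs})")
    table.merged_heel_strikes()  # raises on non-alternating sides
    return table


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class StepWindow:
    """One step, heel strike to contralateral heel strike (samples)."""

    start: int
    toe_off: int  # contralateral toe-off ending the double stance
    end: int
    side_leading: str  # foot that struck at `start`
    fs: float

    @property
    def side_trailing(self) -> str:
        return other_side(self.side_leading)

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.fs

    @property
    def ds_duration_s(self) -> float:
        return (self.toe_off - self.start) / self.fs


def segment_steps(events: GaitEventTable, n_samples: int | None = None) -> list[StepWindow]:
    """Cut the recording into steps with their double-/single-stance split.

    Steps missing the contralateral toe-off are dropped with a warning.
    """
    samples, sides = events.merged_heel_strikes()
    windows: list[StepWindow] = []
    for i in range(len(samples) - 1):
        start, end = int(samples[i]), int(samples[i + 1])
        if n_samples is not None and end >= n_samples:
            break
        trailing = other_side(sides[i])
        cand = events.toe_offs[trailing]
        inside = cand[(cand > start) & (cand < end)]
        if inside.size != 1:
            logger.warning(
                "step %d (samples %d-%d) dropped: %d toe-offs of %s foot inside",
                i, start, end, inside.size, trailing,
            )
            continue
        windows.append(StepWindow(start, int(inside[0]), end, sides[i], events.fs))
    return windows


# ---------------------------------------------------------------------------
# Two-window time normalization
# ---------------------------------------------------------------------------

@dataclass
class StrideMatrix:
    """Phase-normalized per-step signal matrices (steps x J).

    The phase grid runs 0-100% from heel strike to contralateral heel strike;
    the first ``j_ds`` samples cover the double stance, the remaining ``j_ss``
    the single stance, each sub-window resampled to a fixed sample count so
    that j = 100% is exactly the contralateral heel strike.
    """

    channels: dict[str, np.ndarray]
    j_ds: int
    j_ss: int
    windows: list[StepWindow]
    fs: float

    @property
    def n_steps(self) -> int:
        return len(self.windows)

    @property
    def J(self) -> int:
        return self.j_ds + self.j_ss

    @property
    def ds_fraction(self) -> float:
        """Mean fraction of step time spent in double stance."""
        return float(np.mean([w.ds_duration_s / w.duration_s for w in self.windows]))

    @property
    def phase(self) -> np.ndarray:
        """Phase in % of step at each grid sample (heel strike = 0 is the
        open end of the grid; 100% = contralateral heel strike); the
        double-stance sub-window is placed at its mean fractional duration."""
        f = self.ds_fraction
        ds = f * np.arange(1, self.j_ds + 1) / self.j_ds
        ss = f + (1.0 - f) * np.arange(1, self.j_ss + 1) / self.j_ss
        return 100.0 * np.concatenate([ds, ss])

    def sides_leading(self) -> list[str]:
        return [w.side_leading for w in self.windows]


def grid_times(window: StepWindow, j_ds: int, j_ss: int) -> np.ndarray:
    """Absolute sample positions (fractional) of the normalized grid.

    Each sub-window grid is right-anchored: the double-stance points cover
    ``(HS, TO]`` and the single-stance points ``(TO, next HS]``, so the last
    grid sample (j = 100%) is exactly the contralateral heel strike and the
    heel-strike instant itself belongs to one step only (it closes the
    preceding step).
    """
    ds = window.start + (window.toe_off - window.start) * np.arange(1, j_ds + 1) / j_ds
    ss = window.toe_off + (window.end - window.toe_off) * np.arange(1, j_ss + 1) / j_ss
    return np.concatenate([ds, ss])


def time_normalize(
    signals,
    windows: list[StepWindow],
    j_ds: int = 20,
    j_ss: int = 80,
    fs: float | None = None,
    method: str = "linear",
) -> StrideMatrix:
    """Resample each step onto the fixed two-window phase grid.

    ``signals`` is a mapping (or DataFrame) of equally-sampled channels.
    Sub-windows shorter than 2 samples are dropped with a warning.
    """
    if j_ds < 2 or j_ss < 2:
        raise ValueError("j_ds and j_ss must both be >= 2")
    if method not in ("linear", "cubic"):
        raise ValueError(f"unknown interpolation method {method!r}")
    if hasattr(signals, "columns"):  # DataFrame
        signals = {c: signals[c].to_numpy() for c in signals.columns}
    n = len(next(iter(signals.values())))

    kept: list[StepWindow] = []
    for w in windows:
        if w.toe_off - w.start < 2 or w.end - w.toe_off < 2 or w.end >= n:
            logger.warning("step at sample %d dropped: sub-window too short", w.start)
            continue
        kept.append(w)
    if not kept:
        raise ValueError("no usable steps to normalize")
    if fs is None:
        fs = kept[0].fs

    pos = np.stack([grid_times(w, j_ds, j_ss) for w in kept])  # (n_steps, J)
    if method == "linear":
        i0 = np.floor(pos).astype(np.int64)
        i0 = np.clip(i0, 0, n - 2)
        frac = pos - i0
        channels = {
            name: (1.0 - frac) * np.asarray(x, float)[i0] + frac * np.asarray(x, float)[i0 + 1]
            for name, x in signals.items()
        }
    else:
        from scipy.interpolate import CubicSpline

        channels = {}
        for name, x in signals.items():
            x = np.asarray(x, float)
            rows = np.empty_like(pos)
            for r, w in enumerate(kept):
                sl = slice(w.start, w.end + 1)
                cs = CubicSpline(np.arange(w.start, w.end + 1), x[sl])
                rows[r] = cs(pos[r])
            channels[name] = rows
    return StrideMatrix(channels=channels, j_ds=j_ds, j_ss=j_ss, windows=kept, fs=fs)
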