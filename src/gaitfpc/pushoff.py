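"""Correlation of foot-placement errors with subsequent push-off kinetics.

For every phase sample j of the corrective step, the kinetic time series F
(combined AP GRF, trailing-leg AP GRF, or trailing-leg sagittal ankle
moment) is regressed on the foot-placement error of the preceding step:

    F_{i+1}(j) = beta_eps(j) * eps_FP_i + eps_{i+1}(j)

The full-stride view splices the same-step series (phases before the heel
strike that defines the error) and the next-step series (phases after it),
so the field covers one complete stride around the error. Phases where the
trailing leg is in swing carry an identically zero signal and are masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .events import StrideMatrix, other_side

logger = logging.getLogger("gaitfpc")

PRE_HS = "pre_hs"
DOUBLE_STANCE = "double_stance"
POST_DS = "post_ds"

LAGS = ("next_step", "same_step", "full_stride")


class UndefinedCorrelationError(ValueError):
    """The error vector has no variance: correlations are undefined."""


def trailing_channel(stride: StrideMatrix, base: str = "grf_ap") -> np.ndarray:
    """Per-step rows of the trailing leg's channel.

    The trailing leg of a step is the one whose heel strike opened the
    previous step, i.e. the contralateral of the step's leading foot.
    """
    rows = {s: stride.channels[f"{base}_{s}{_unit_suffix(base)}"] for s in ("left", "right")}
    sides = stride.sides_leading()
    return np.stack([rows[other_side(s)][i] for i, s in enumerate(sides)])


def leading_channel(stride: StrideMatrix, base: str = "grf_ap") -> np.ndarray:
    """Per-step rows of the leading (stance) leg's channel.

    In the full-stride view of a correction, the leg that pushes off during
    the next step's double stance is this step's leading/stance leg; its
    pre-heel-strike kinetics are these rows.
    """
    rows = {s: stride.channels[f"{base}_{s}{_unit_suffix(base)}"] for s in ("left", "right")}
    sides = stride.sides_leading()
    return np.stack([rows[s][i] for i, s in enumerate(sides)])


def _unit_suffix(base: str) -> str:
    return {"grf_ap": "_N", "ankle_moment": "_Nm", "heel_ap": "_m"}[base]


def _pair(errors: np.ndarray, kinetics: np.ndarray, lag: str,
          kinetics_pre: np.ndarray | None = None):
    """Align error i with the kinetic rows of the requested lag.

    ``errors`` and ``kinetics`` are indexed by the same step i (the error
    belongs to the placement closing step i). Steps with NaN errors (e.g.
    the other foot's placements) are dropped; the last step is dropped for
    the next-step pairing. For the full-stride view, ``kinetics_pre``
    supplies the pre-heel-strike rows (the push-off leg followed through
    step i, where it is the stance leg); it defaults to ``kinetics``.
    """
    errors = np.asarray(errors, float)
    n, J = kinetics.shape
    if errors.shape != (n,):
        raise ValueError("errors must align with the kinetic step rows")
    if lag not in LAGS:
        raise ValueError(f"lag must be one of {LAGS}")
    if lag == "same_step":
        e, K = errors, kinetics if kinetics_pre is None else kinetics_pre
    else:
        e = errors[:-1]
        K = kinetics[1:]
        if lag == "full_stride":
            pre = kinetics if kinetics_pre is None else kinetics_pre
            K = np.hstack([pre[:-1], K])
    valid = ~np.isnan(e)
    return e[valid], K[valid]


def _phase_labels(stride_like, lag: str) -> list[str]:
    j_ds, j_ss = stride_like.j_ds, stride_like.j_ss
    nxt = [DOUBLE_STANCE] * j_ds + [POST_DS] * j_ss
    if lag == "full_stride":
        return [PRE_HS] * (j_ds + j_ss) + nxt
    if lag == "same_step":
        return [PRE_HS] * (j_ds + j_ss)
    return nxt


@dataclass
class CorrelationField:
    """Phase-dependent Pearson correlation and regression slope."""

    signal_id: str
    lag: str
    r: np.ndarray              # (Jf,) Pearson r, NaN where masked
    slope: np.ndarray          # (Jf,) signal units per m
    n_pairs: int
    mask: np.ndarray           # (Jf,) True where the signal has no variance
    phase_labels: list[str]
    j_ds: int
    j_ss: int

    def fisher_z(self) -> np.ndarray:
        z = np.full_like(self.r, np.nan)
        ok = ~self.mask
        z[ok] = np.arctanh(np.clip(self.r[ok], -1 + 1e-12, 1 - 1e-12))
        return z


def correlate_errors_kinetics(
    errors: np.ndarray,
    kinetics: np.ndarray,
    lag: str = "full_stride",
    signal_id: str = "",
    j_ds: int | None = None,
    j_ss: int | None = None,
    kinetics_pre: np.ndarray | None = None,
) -> CorrelationField:
    """Pearson r and OLS slope of the kinetic series on the errors, per phase.

    ``kinetics`` rows are step-indexed like ``errors`` (NaN errors dropped);
    the pairing follows ``lag``: ``next_step`` pairs eps_i with F_{i+1},
    ``same_step`` with F_i, ``full_stride`` concatenates both so the field
    spans a stride with the error-defining heel strike in the middle
    (``kinetics_pre`` carries the pre-heel-strike rows of the push-off leg).
    """
    e, K = _pair(errors, kinetics, lag, kinetics_pre)
    if e.size < 3:
        raise ValueError("need at least 3 valid error/kinetics pairs")
    if np.ptp(e) == 0:
        raise UndefinedCorrelationError(
            "foot-placement errors have zero variance; correlation undefined"
        )
    ed = e - e.mean()
    Kd = K - K.mean(axis=0)
    se = float(ed @ ed)
    sk = np.einsum("ij,ij->j", Kd, Kd)
    cross = ed @ Kd
    scale = np.max(sk) if np.max(sk) > 0 else 1.0
    mask = sk <= 1e-24 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cross / np.sqrt(se * sk)
        slope = cross / se
    r[mask] = np.nan
    slope[mask] = np.nan
    if j_ds is None or j_ss is None:
        raise ValueError("j_ds and j_ss are required to label phases")
    labels = _phase_labels(_Grid(j_ds, j_ss), lag)
    return CorrelationField(signal_id=signal_id, lag=lag, r=r, slope=slope,
                            n_pairs=int(e.size), mask=mask, phase_labels=labels,
                            j_ds=j_ds, j_ss=j_ss)


@dataclass
class _Grid:
    j_ds: int
    j_ss: int


@dataclass
class ExtremeContrast:
    """Mean kinetic curves of the k most positive / most negative errors."""

    k: int
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    idx_pos: np.ndarray        # step indices (into the valid pairs' step ids)
    idx_neg: np.ndarray
    phase_labels: list[str]


def extreme_error_contrast(
    errors: np.ndarray,
    kinetics: np.ndarray,
    k: int = 10,
    lag: str = "full_stride",
    j_ds: int | None = None,
    j_ss: int | None = None,
    kinetics_pre: np.ndarray | None = None,
) -> ExtremeContrast:
    """Average the kinetic rows of the k most positive and k most negative
    foot-placement errors (disjoint sets; ties broken by step order)."""
    errors = np.asarray(errors, float)
    step_ids = np.arange(errors.size)
    e, K = _pair(errors, kinetics, lag, kinetics_pre)
    # surviving step indices, mirroring _pair's dropping rules
    if lag == "same_step":
        cand = step_ids
        ev = errors
    else:
        cand = step_ids[:-1]
        ev = errors[:-1]
    cand = cand[~np.isnan(ev)]
    if k < 1:
        raise ValueError("k must be >= 1")
    if e.size < 2 * k:
        raise ValueError(
            f"need at least 2k={2 * k} valid pairs, have {e.size}; reduce k"
        )
    order = np.argsort(e, kind="stable")
    neg_sel, pos_sel = order[:k], order[-k:]
    if np.ptp(e) == 0:
        logger.warning("all foot-placement errors equal; extreme sets are arbitrary")
    if e[order[k - 1]] == e[order[k]] or e[order[-k]] == e[order[-k - 1]]:
        logger.warning("ties at the extreme-error cutoffs; broken by step order")
    labels = _phase_labels(_Grid(j_ds, j_ss), lag) if j_ds and j_ss else []
    return ExtremeContrast(k=k, mean_pos=K[pos_sel].mean(axis=0),
                           mean_neg=K[neg_sel].mean(axis=0),
                           idx_pos=cand[pos_sel], idx_neg=cand[neg_sel],
                           phase_labels=labels)
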