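"""Phase-dependent linear foot-placement model.

At every phase sample j of the step, the de-meaned anterior-posterior foot
placement FP_i (the AP distance between trailing and leading foot at the
heel strike closing step i) is regressed on the de-meaned CoM states at that
phase:

    FP_i = beta_pos(j) * CoM_pos_i(j) + beta_vel(j) * CoM_vel_i(j) + eps_i(j)

with CoM_pos expressed relative to the stance (trailing) foot and no
intercept (all variables are de-meaned per participant, foot and condition).
The residual at j = 100% is the foot-placement error eps_FP_i: positive
means the foot landed further forward than the linear prediction from the
CoM states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import StrideMatrix, other_side


def compute_com_states(
    stride: StrideMatrix,
    com_pos: str = "com_pos_ap_m",
    com_vel: str = "com_vel_ap_mps",
    stance_foot_ap: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CoM AP position relative to the stance (leading-at-start, trailing-at-
    placement) foot, and AP velocity, on the stride grid.

    ``stance_foot_ap`` may be an (n_steps,) or (n_steps, J) reference; by
    default it is the heel trajectory of each step's stance foot taken from
    the heel channels.
    """
    pos = stride.channels[com_pos]
    vel = stride.channels[com_vel]
    if stance_foot_ap is None:
        heel = {s: stride.channels[f"heel_ap_{s}_m"] for s in ("left", "right")}
        rows = np.arange(stride.n_steps)
        sides = stride.sides_leading()
        stance_foot_ap = np.stack([heel[sides[i]][i] for i in rows])
    stance_foot_ap = np.asarray(stance_foot_ap, float)
    if stance_foot_ap.ndim == 1:
        stance_foot_ap = stance_foot_ap[:, None]
    if stance_foot_ap.shape[0] != pos.shape[0]:
        raise ValueError("one stance-foot reference required per step")
    return pos - stance_foot_ap, vel


def compute_foot_placement(
    heel_ap_leading: np.ndarray,
    heel_ap_trailing: np.ndarray,
) -> np.ndarray:
    """De-meaned AP foot placement: leading minus trailing heel at heel strike.

    One value per step; de-meaning enforces the zero intercept of the model.
    """
    lead = np.asarray(heel_ap_leading, float)
    trail = np.asarray(heel_ap_trailing, float)
    if lead.shape != trail.shape or lead.ndim != 1:
        raise ValueError("need one leading and one trailing heel position per step")
    if lead.size < 3:
        raise ValueError("need at least 3 steps to de-mean and fit")
    fp = lead - trail
    return fp - fp.mean()


def foot_placement_from_stride(stride: StrideMatrix) -> np.ndarray:
    """De-meaned FP per step, read off the heel channels at j = 100%.

    The foot landing at the step's closing heel strike is the contralateral
    (trailing-side label) foot of the step; the step's own leading foot is
    the stance/trailing foot of the new placement.
    """
    heel = {s: stride.channels[f"heel_ap_{s}_m"] for s in ("left", "right")}
    sides = stride.sides_leading()
    lead_new = np.array([heel[other_side(s)][i, -1] for i, s in enumerate(sides)])
    trail_new = np.array([heel[s][i, -1] for i, s in enumerate(sides)])
    return compute_foot_placement(lead_new, trail_new)


@dataclass
class FootPlacementFit:
    """Per-phase OLS fit of FP on the two CoM states (no intercept)."""

    phase: np.ndarray          # % of step
    beta_pos: np.ndarray       # (J,) dimensionless
    beta_vel: np.ndarray       # (J,) s
    r_squared: np.ndarray      # (J,) in [0, 1]
    p_values: np.ndarray       # (J,) F-test of the two-predictor model
    residuals: np.ndarray      # (n_steps, J) m
    fp: np.ndarray             # (n_steps,) de-meaned FP
    degenerate: np.ndarray     # (J,) bool, rank-deficient predictor pair
    n_steps: int


def fit_fpm(
    fp: np.ndarray,
    com_pos: np.ndarray,
    com_vel: np.ndarray,
    phase: np.ndarray | None = None,
) -> FootPlacementFit:
    """Fit the foot-placement model independently at every phase sample.

    Inputs are de-meaned internally across steps (per phase for the states);
    a rank-deficient predictor pair at a phase is flagged and its
    coefficients set to NaN rather than silently zeroed.
    """
    fp = np.asarray(fp, float)
    P = np.asarray(com_pos, float)
    V = np.asarray(com_vel, float)
    n, J = P.shape
    if fp.shape != (n,) or V.shape != (n, J):
        raise ValueError("fp, com_pos and com_vel must share the step dimension")
    if n < 3:
        raise ValueError("need at least 3 steps to fit")
    if np.isnan(fp).any() or np.isnan(P).any() or np.isnan(V).any():
        raise ValueError("missing values: drop incomplete steps before fitting")
    y = fp - fp.mean()
    Pd = P - P.mean(axis=0)
    Vd = V - V.mean(axis=0)

    s11 = np.einsum("ij,ij->j", Pd, Pd)
    s22 = np.einsum("ij,ij->j", Vd, Vd)
    s12 = np.einsum("ij,ij->j", Pd, Vd)
    c1 = Pd.T @ y
    c2 = Vd.T @ y
    det = s11 * s22 - s12**2
    degenerate = det <= 1e-12 * np.maximum(s11 * s22, 1e-300)
    safe = np.where(degenerate, 1.0, det)
    b1 = (s22 * c1 - s12 * c2) / safe
    b2 = (s11 * c2 - s12 * c1) / safe
    b1[degenerate] = np.nan
    b2[degenerate] = np.nan

    pred = Pd * b1[None, :] + Vd * b2[None, :]
    resid = y[:, None] - pred
    ss_tot = float(y @ y)
    if ss_tot == 0:
        r2 = np.zeros(J)
        pvals = np.ones(J)
        resid = np.zeros_like(resid)
    else:
        ss_res = np.einsum("ij,ij->j", resid, resid)
        r2 = np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (r2 / 2.0) / np.maximum((1.0 - r2) / max(n - 2, 1), 1e-300)
        pvals = stats.f.sf(f, 2, n - 2)
    r2[degenerate] = np.nan
    pvals[degenerate] = np.nan
    resid[:, degenerate] = np.nan
    if phase is None:
        phase = 100.0 * np.arange(1, J + 1) / J
    return FootPlacementFit(phase=np.asarray(phase, float), beta_pos=b1, beta_vel=b2,
                            r_squared=r2, p_values=pvals, residuals=resid, fp=y,
                            degenerate=degenerate, n_steps=n)


def fit_fpm_from_stride(stride: StrideMatrix, step_subset: np.ndarray | None = None) -> FootPlacementFit:
    """Convenience wrapper: extract FP and CoM states from a StrideMatrix
    (optionally a boolean subset of steps, e.g. one placing foot) and fit."""
    P, V = compute_com_states(stride)
    fpv = foot_placement_from_stride(stride)
    if step_subset is not None:
        P, V = P[step_subset], V[step_subset]
        heel = {s: stride.channels[f"heel_ap_{s}_m"] for s in ("left", "right")}
        sides = [s for s, keep in zip(stride.sides_leading(), step_subset) if keep]
        idx = np.flatnonzero(step_subset)
        lead_new = np.array([heel[other_side(s)][i, -1] for i, s in zip(idx, sides)])
        trail_new = np.array([heel[s][i, -1] for i, s in zip(idx, sides)])
        fpv = compute_foot_placement(lead_new, trail_new)
    return fit_fpm(fpv, P, V, phase=stride.phase)


def foot_placement_errors(fit: FootPlacementFit) -> np.ndarray:
    """Foot-placement error per step: the model residual at j = 100% (m).

    Positive = foot placed further forward than the CoM-state prediction.
    """
    return fit.residuals[:, -1]


def summarize_errors(errors: np.ndarray) -> dict:
    """Sample moments, Gaussian MLE fit and a Shapiro-Wilk normality test."""
    e = np.asarray(errors, float)
    if e.size < 3:
        raise ValueError("need at least 3 errors to summarize")
    mu, sigma_ml = stats.norm.fit(e)
    out = {
        "mean": float(e.mean()),
        "sd": float(e.std(ddof=1)),
        "gaussian_mu": float(mu),
        "gaussian_sigma": float(sigma_ml),
        "degenerate": bool(np.ptp(e) == 0),
    }
    if out["degenerate"]:
        out["shapiro_stat"] = np.nan
        out["shapiro_p"] = np.nan
    else:
        stat, p = stats.shapiro(e)
        out["shapiro_stat"] = float(stat)
        out["shapiro_p"] = float(p)
    return out
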