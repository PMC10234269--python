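"""Synthetic treadmill-gait generator with full ground truth.

The generator emulates exactly the statistical structure the downstream
analysis assumes:

* heel-strike CoM states (AP position relative to the stance foot, and AP
  velocity) follow a stationary first-order step-to-step map;
* anterior-posterior foot placement is a linear function of those states
  plus an exactly Gaussian error ``eps_fp ~ N(0, sigma_fp^2)``;
* the kinetic channels of the *next* step (trailing-leg AP GRF, trailing-leg
  sagittal ankle moment, and through summation the combined AP GRF) are a
  baseline profile plus a phase-dependent feedback gain times the preceding
  foot-placement error, plus smooth Gaussian noise;
* the combined CoP alternates mediolaterally between the feet with a sharp
  linear transfer during every double stance (the "butterfly"), and drifts
  backward at belt speed under the stance foot, so heel strikes and toe-offs
  are detectable without ground truth.

Per-leg GRF and ankle moment are identically zero during that leg's swing,
and the combined AP GRF is the exact sum of the per-leg channels.

Step timing is metronome-regular: the emulated protocol paced walking with a
metronome, and regular timing keeps the two-window normalization exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov
from scipy.ndimage import gaussian_filter1d

from .events import LEFT, RIGHT, GaitEventTable

GRAVITY = 9.81  # m/s^2

#: analysis signal identifiers
COMBINED_GRF = "combined_ap_grf"
TRAILING_GRF = "trailing_ap_grf"
TRAILING_MOMENT = "trailing_ankle_moment"
KINETIC_SIGNALS = (COMBINED_GRF, TRAILING_GRF, TRAILING_MOMENT)


def belt_speed(leg_length: float, speed_coefficient: float) -> float:
    """Treadmill belt speed ``c * sqrt(g * l)`` (m/s).

    ``c = 0.4`` is the normal-walking condition, ``c = 0.2`` the slow one.
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    if speed_coefficient < 0:
        raise ValueError("speed_coefficient must be non-negative")
    return speed_coefficient * math.sqrt(GRAVITY * leg_length)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_state_map() -> np.ndarray:
    return np.array([[0.15, 0.05], [0.10, 0.20]])


@dataclass
class GeneratorConfig:
    """All tunables of the synthetic trial generator.

    Gain profiles are callables of the normalized double-stance coordinate
    ``u in [0, 1)`` returning the feedback gain (signal units per metre of
    foot-placement error); scalars are promoted to the default smooth shape
    ``peak * (0.4 + 0.6 sin(pi u))`` whose floor keeps the feedback active
    across the whole double stance. ``beta_pos_true`` / ``beta_vel_true``
    may be scalars (phase-constant, the default) or callables of the step
    fraction ``x in [0, 1]``.
    """

    n_strides: int = 200
    fs: float = 200.0
    step_time: float = 0.55          # s; metronome-imposed
    ds_fraction: float = 0.2         # fraction of step time in double stance
    leg_length: float = 0.9          # m
    speed_coefficient: float = 0.4   # 0.4 normal, 0.2 slow
    beta_pos_true: object = 1.2      # dimensionless
    beta_vel_true: object = 0.35     # s
    sigma_fp: float = 0.010          # m, SD of foot-placement error
    com_state_map: np.ndarray = field(default_factory=_default_state_map)
    state_noise_sd: tuple = (0.008, 0.025)      # (m, m/s) step-to-step innovation
    com_traj_noise_sd: tuple = (0.004, 0.012)   # within-step, tapered to 0 at HS
    gain_trailing_grf: object = 400.0           # N/m (peak)
    gain_ankle_moment: object = 220.0           # N*m/m (peak)
    gain_leading_grf: object = 0.0
    sigma_eta_grf: float = 8.0       # N, per-leg smooth kinetic noise
    sigma_eta_moment: float = 5.5    # N*m
    noise_fwhm: float = 10.0         # % of step phase
    step_width: float = 0.10         # m, ML distance between foot CoP lines
    cop_roll_length: float = 0.18    # m, heel-to-toe CoP travel in single stance
    cop_noise_sd: float = 0.001      # m, broadband CoP measurement noise
    condition: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 3:
            raise ValueError("n_strides must be >= 3")
        if not 0.0 < self.ds_fraction < 0.5:
            raise ValueError("ds_fraction must lie in (0, 0.5)")
        for name in ("sigma_fp", "sigma_eta_grf", "sigma_eta_moment", "cop_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.step_time * self.fs < 20:
            raise ValueError("step_time * fs must give at least 20 samples per step")
        A = np.asarray(self.com_state_map, float)
        if A.shape != (2, 2):
            raise ValueError("com_state_map must be 2x2")
        if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
            raise ValueError("com_state_map must have spectral radius < 1")

    # -- derived quantities -------------------------------------------------
    @property
    def belt_speed(self) -> float:
        return belt_speed(self.leg_length, self.speed_coefficient)

    @property
    def samples_per_step(self) -> int:
        return int(round(self.step_time * self.fs))

    @property
    def ds_samples(self) -> int:
        return max(2, int(round(self.ds_fraction * self.samples_per_step)))

    def beta_curves(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """True coefficient curves over step fractions ``x``."""
        bp = self.beta_pos_true(x) if callable(self.beta_pos_true) else np.full_like(x, float(self.beta_pos_true))
        bv = self.beta_vel_true(x) if callable(self.beta_vel_true) else np.full_like(x, float(self.beta_vel_true))
        return np.asarray(bp, float), np.asarray(bv, float)

    def gain_curve(self, which: str, u: np.ndarray) -> np.ndarray:
        """Feedback gain over the double-stance coordinate ``u in [0, 1)``."""
        g = {TRAILING_GRF: self.gain_trailing_grf,
             TRAILING_MOMENT: self.gain_ankle_moment,
             "leading_ap_grf": self.gain_leading_grf}[which]
        if callable(g):
            return np.asarray(g(u), float)
        return float(g) * (0.4 + 0.6 * np.sin(np.pi * u))


def normal_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**{"condition": "normal", "speed_coefficient": 0.4, **overrides})


def slow_config(**overrides) -> GeneratorConfig:
    """Slow-walking condition: half the belt-speed coefficient, longer steps,
    larger foot-placement error SD (slow walking is more variable)."""
    defaults = dict(condition="slow", speed_coefficient=0.2, step_time=0.7,
                    ds_fraction=0.25, sigma_fp=0.014)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


# ---------------------------------------------------------------------------
# Trial container
# ---------------------------------------------------------------------------

@dataclass
class TrialTruth:
    events: GaitEventTable
    fp_errors: np.ndarray          # eps_fp for the placement ending step i, i = 0..N-1
    com_hs_states: np.ndarray      # (N, 2) stance-relative (pos, vel) at each placement
    step_sides: list[str]          # leading side of step i, i = 0..N-1
    gain_samples: dict             # per-signal gain over the double-stance samples
    beta_samples: tuple            # (beta_pos, beta_vel) over the within-step sample grid


@dataclass
class SyntheticTrial:
    signals: pd.DataFrame          # time-indexed columns, data_io schema
    fs: float
    condition: str
    leg_length: float
    truth: TrialTruth
    participant: str = "synthetic"

    @property
    def n_steps(self) -> int:
        return len(self.truth.step_sides)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def smooth_noise(rng: np.random.Generator, shape: tuple, fwhm_samples: float) -> np.ndarray:
    """Unit-variance Gaussian noise with the given FWHM smoothness along the
    last axis (stationary: generated on a padded grid and cropped)."""
    if fwhm_samples <= 0:
        return rng.standard_normal(shape)
    sg = fwhm_samples / 2.3548200450309493
    pad = int(math.ceil(4 * sg)) + 1
    padded = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    sm = gaussian_filter1d(padded, sg, axis=-1, mode="constant")
    # exact unit-variance normalization via the discrete kernel norm
    impulse = np.zeros(2 * pad + shape[-1])
    impulse[impulse.size // 2] = 1.0
    kernel = gaussian_filter1d(impulse, sg, mode="constant")
    norm = math.sqrt(float(np.sum(kernel**2)))
    return sm[..., pad:pad + shape[-1]] / norm


# ---------------------------------------------------------------------------
# Baseline kinetic profiles (N and N*m); x = step fraction, u = DS fraction
# ---------------------------------------------------------------------------

def _mu_trailing_grf(u: np.ndarray) -> np.ndarray:
    return 40.0 * np.cos(np.pi * u / 2) ** 2 + 55.0 * np.sin(np.pi * u)


def _mu_leading_grf(x: np.ndarray) -> np.ndarray:
    return -45.0 * np.sin(np.pi * x) * (1.0 - x) + 40.0 * x**3


def _mu_trailing_moment(u: np.ndarray) -> np.ndarray:
    return 60.0 * np.cos(np.pi * u / 2) ** 2 + 30.0 * np.sin(np.pi * u)


def _mu_leading_moment(x: np.ndarray) -> np.ndarray:
    return -10.0 * np.sin(np.pi * x) * (1.0 - x) + 60.0 * x**2


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------

def simulate_trial(config: GeneratorConfig, seed: int | None = None) -> SyntheticTrial:
    """Generate one synthetic trial; deterministic given config and seed.

    Step ``k`` (k = 0..N-1, N = 2 n_strides) runs from heel strike ``k`` at
    sample ``k n_s`` to heel strike ``k+1``; its within-step samples occupy
    ``k n_s + 1 .. (k+1) n_s`` (the heel-strike sample closes the preceding
    step and carries that step's end-of-step CoM state). The left foot leads
    even steps.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_s = config.samples_per_step
    ds_n = config.ds_samples
    N = 2 * config.n_strides          # steps inside the trial
    v = config.belt_speed
    T = config.step_time
    fs = config.fs
    sl_bar = v * T                    # mean step length keeps treadmill stationarity

    # --- step-to-step heel-strike states (stationary AR(1)) ---------------
    A = np.asarray(config.com_state_map, float)
    Q = np.diag(np.square(config.state_noise_sd))
    if np.any(np.diag(Q) > 0):
        P_stat = solve_discrete_lyapunov(A, Q)
    else:
        P_stat = np.zeros((2, 2))
    z = np.empty((N + 1, 2))
    L = np.linalg.cholesky(P_stat + 1e-18 * np.eye(2))
    z[0] = L @ rng.standard_normal(2)
    w = rng.standard_normal((N, 2)) * np.asarray(config.state_noise_sd)
    for k in range(N):
        z[k + 1] = A @ z[k] + w[k]

    # --- foot placements ---------------------------------------------------
    x = np.arange(1, n_s + 1) / n_s   # within-step fractions (0, 1]
    x_to = ds_n / n_s
    bp, bv = config.beta_curves(x)
    if np.any(bp == 0) or np.any(bv == 0):
        raise ValueError("true coefficient curves must be nonzero at every phase")
    B_pos, B_vel = bp[-1], bv[-1]
    eps = rng.standard_normal(N) * config.sigma_fp
    fp_dev = B_pos * z[1:, 0] + B_vel * z[1:, 1] + eps   # de-meaned FP of step k
    x_land = np.empty(N + 1)
    x_land[0] = 0.0
    x_land[1:] = np.cumsum(fp_dev)   # x_{k+1} = x_k + fp_dev_k  (mean SL = v*T)

    # --- per-step geometry -------------------------------------------------
    steps = np.arange(N)
    lead_stance = x_land[steps, None] - v * x[None, :] * T             # leading heel
    x_prev = np.r_[-sl_bar, x_land[:N - 1]]                            # virtual step -1
    uu = (x[None, ds_n:] - x_to) / (1.0 - x_to)
    s_swing = 3 * uu**2 - 2 * uu**3
    swing_from = x_prev - v * (T + x_to * T)
    heel_trail = np.empty((N, n_s))
    heel_trail[:, :ds_n] = x_prev[:, None] - v * (T + x[None, :ds_n] * T)
    heel_trail[:, ds_n:] = swing_from[:, None] + (x_land[1:N + 1, None] - swing_from[:, None]) * s_swing

    # --- CoM ---------------------------------------------------------------
    f_scale = bp[-1] / bp
    h_scale = bv[-1] / bv
    p_mean = sl_bar * (-0.4 + 1.0 * x)               # stance-relative mean path
    v_mean = 0.05 * np.sin(2 * np.pi * x)            # treadmill-frame oscillation
    taper = np.cos(np.pi * x / 2)                    # kills trajectory noise at HS
    fwhm_s = config.noise_fwhm / 100.0 * n_s
    xi_p = smooth_noise(rng, (N, n_s), fwhm_s) * config.com_traj_noise_sd[0] * taper
    xi_v = smooth_noise(rng, (N, n_s), fwhm_s) * config.com_traj_noise_sd[1] * taper
    com_rel = p_mean[None, :] + z[1:N + 1, 0:1] * f_scale[None, :] + xi_p
    com_pos = lead_stance + com_rel
    com_vel = v_mean[None, :] + z[1:N + 1, 1:2] * h_scale[None, :] + xi_v

    # --- CoP ---------------------------------------------------------------
    sign = np.where(steps % 2 == 0, -1.0, 1.0)       # left leads even steps; right = +
    half_w = config.step_width / 2.0
    u_ds = x[:ds_n] / x_to                            # DS transfer coordinate (0, 1]
    cop_ml = np.empty((N, n_s))
    cop_ml[:, :ds_n] = sign[:, None] * half_w * (2.0 * u_ds[None, :] - 1.0)
    cop_ml[:, ds_n:] = sign[:, None] * half_w
    r0, L_roll = 0.02, config.cop_roll_length
    cop_from = x_prev - v * T + L_roll               # trailing toe at HS
    cop_to = x_land[:N] - v * x_to * T + r0          # leading heel region at TO
    cop_ap = np.empty((N, n_s))
    cop_ap[:, :ds_n] = cop_from[:, None] + (cop_to - cop_from)[:, None] * u_ds[None, :]
    roll = r0 + (L_roll - r0) * (x[ds_n:] - x_to) / (1.0 - x_to)
    cop_ap[:, ds_n:] = lead_stance[:, ds_n:] + roll[None, :]

    # --- kinetics ----------------------------------------------------------
    # trailing-leg support: samples strictly before toe-off (force is zero at
    # the toe-off sample and throughout the swing)
    u_sup = np.arange(1, ds_n) / ds_n
    g_grf = config.gain_curve(TRAILING_GRF, u_sup)
    g_mom = config.gain_curve(TRAILING_MOMENT, u_sup)
    g_lead = config.gain_curve("leading_ap_grf", u_sup)
    eps_prev = np.r_[0.0, eps[:N - 1]]               # error being corrected in step k

    def _kinetic(mu_ds, mu_full, gain_ds, gain_lead_ds, sd):
        full = mu_full(x)[None, :] + np.zeros((N, 1))
        full[:, :ds_n - 1] += gain_lead_ds[None, :] * eps_prev[:, None]
        full += smooth_noise(rng, (N, n_s), fwhm_s) * sd
        trail = np.zeros((N, n_s))
        trail[:, :ds_n - 1] = (mu_ds(u_sup)[None, :]
                               + gain_ds[None, :] * eps_prev[:, None]
                               + smooth_noise(rng, (N, ds_n - 1), fwhm_s) * sd)
        return trail, full

    grf_trail, grf_lead_m = _kinetic(_mu_trailing_grf, _mu_leading_grf, g_grf, g_lead,
                                     config.sigma_eta_grf)
    mom_trail, mom_lead_m = _kinetic(_mu_trailing_moment, _mu_leading_moment, g_mom,
                                     np.zeros(ds_n - 1), config.sigma_eta_moment)

    # --- route leading/trailing rows to left/right channels ----------------
    even = (steps % 2 == 0)[:, None]

    def _by_side(lead_rows, trail_rows):
        return (np.where(even, lead_rows, trail_rows),
                np.where(even, trail_rows, lead_rows))

    heel_l, heel_r = _by_side(lead_stance, heel_trail)
    grf_l, grf_r = _by_side(grf_lead_m, grf_trail)
    mom_l, mom_r = _by_side(mom_lead_m, mom_trail)

    # --- flatten; sample 0 is the end of a virtual preceding step ----------
    p_end = 0.6 * sl_bar
    v_end = 0.05 * math.sin(2 * math.pi)
    first = {
        "heel_l": 0.0, "heel_r": -sl_bar - v * T,
        "com_pos": (-sl_bar - v * T) + p_end + z[0, 0],
        "com_vel": v_end + z[0, 1],
        "cop_ap": -sl_bar - v * T + L_roll, "cop_ml": half_w,
        "grf_l": 0.0, "grf_r": _mu_leading_grf(np.array([1.0]))[0],
        "mom_l": 0.0, "mom_r": _mu_leading_moment(np.array([1.0]))[0],
    }

    def _flat(m, first_val):
        return np.r_[first_val, m.reshape(-1)]

    n_total = N * n_s + 1
    cop_ap_f = _flat(cop_ap, first["cop_ap"]) + rng.standard_normal(n_total) * config.cop_noise_sd
    cop_ml_f = _flat(cop_ml, first["cop_ml"]) + rng.standard_normal(n_total) * config.cop_noise_sd
    grf_l_f = _flat(grf_l, first["grf_l"])
    grf_r_f = _flat(grf_r, first["grf_r"])
    time = np.arange(n_total) / fs
    signals = pd.DataFrame({
        "time_s": time,
        "cop_ap_m": cop_ap_f,
        "cop_ml_m": cop_ml_f,
        "grf_ap_left_N": grf_l_f,
        "grf_ap_right_N": grf_r_f,
        "grf_ap_combined_N": grf_l_f + grf_r_f,
        "ankle_moment_left_Nm": _flat(mom_l, first["mom_l"]),
        "ankle_moment_right_Nm": _flat(mom_r, first["mom_r"]),
        "com_pos_ap_m": _flat(com_pos, first["com_pos"]),
        "com_vel_ap_mps": _flat(com_vel, first["com_vel"]),
        "heel_ap_left_m": _flat(heel_l, first["heel_l"]),
        "heel_ap_right_m": _flat(heel_r, first["heel_r"]),
    })

    hs_samples = np.arange(N + 1) * n_s
    hs_sides = [LEFT if k % 2 == 0 else RIGHT for k in range(N + 1)]
    to_samples = np.arange(N) * n_s + ds_n
    to_sides = [RIGHT if k % 2 == 0 else LEFT for k in range(N)]  # trailing foot
    events = GaitEventTable(
        fs=fs,
        heel_strikes={s: hs_samples[[k for k, sd in enumerate(hs_sides) if sd == s]]
                      for s in (LEFT, RIGHT)},
        toe_offs={s: to_samples[[k for k, sd in enumerate(to_sides) if sd == s]]
                  for s in (LEFT, RIGHT)},
    )
    truth = TrialTruth(
        events=events,
        fp_errors=eps,
        com_hs_states=np.column_stack([p_end + z[1:N + 1, 0], v_end + z[1:N + 1, 1]]),
        step_sides=hs_sides[:N],
        gain_samples={TRAILING_GRF: g_grf, TRAILING_MOMENT: g_mom,
                      COMBINED_GRF: g_grf + g_lead, "leading_ap_grf": g_lead},
        beta_samples=(bp, bv),
    )
    return SyntheticTrial(signals=signals, fs=fs, condition=config.condition,
                          leg_length=config.leg_length, truth=truth)


# ---------------------------------------------------------------------------
# Closed-form correlation target
# ---------------------------------------------------------------------------

def expected_correlation_profile(
    config: GeneratorConfig,
    signal: str,
    j_ds: int = 20,
    j_ss: int = 80,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected next-step error-kinetics correlation on the normalized grid.

    Returns ``(r_star, mask)`` of length ``j_ds + j_ss``; ``r_star(j) =
    g(j) sigma_fp / sqrt(g(j)^2 sigma_fp^2 + sigma_noise(j)^2)``, evaluated
    with the same sampling and linear interpolation as the analysis pipeline
    so that finite-n estimates converge to it. ``mask`` marks phases where
    the signal is structurally zero (trailing-leg swing).
    """
    if signal not in KINETIC_SIGNALS:
        raise ValueError(f"unknown kinetic signal {signal!r}")
    n_s, ds_n = config.samples_per_step, config.ds_samples
    u_sup = np.arange(1, ds_n) / ds_n
    # per-sample gain and noise SD at within-step sample positions 1..n_s
    g = np.zeros(n_s)
    sd = np.zeros(n_s)
    if signal == TRAILING_GRF:
        g[:ds_n - 1] = config.gain_curve(TRAILING_GRF, u_sup)
        sd[:ds_n - 1] = config.sigma_eta_grf
    elif signal == TRAILING_MOMENT:
        g[:ds_n - 1] = config.gain_curve(TRAILING_MOMENT, u_sup)
        sd[:ds_n - 1] = config.sigma_eta_moment
    else:  # combined: trailing + leading legs, both noisy, both possibly gained
        g[:ds_n - 1] = (config.gain_curve(TRAILING_GRF, u_sup)
                        + config.gain_curve("leading_ap_grf", u_sup))
        sd[:] = config.sigma_eta_grf          # leading leg loaded all step
        sd[:ds_n - 1] = math.sqrt(2.0) * config.sigma_eta_grf
    # linear interpolation onto the two-window grid, as time_normalize does
    pos_ds = ds_n * np.arange(1, j_ds + 1) / j_ds
    pos_ss = ds_n + (n_s - ds_n) * np.arange(1, j_ss + 1) / j_ss
    pos = np.r_[pos_ds, pos_ss]
    samples = np.arange(1, n_s + 1)
    gi = np.interp(pos, samples, g)
    sdi = np.interp(pos, samples, sd)
    denom = np.sqrt(gi**2 * config.sigma_fp**2 + sdi**2)
    if np.all(denom == 0):
        raise ValueError("degenerate variance: sigma_fp and kinetic noise both zero")
    mask = denom == 0
    r = np.zeros_like(denom)
    r[~mask] = gi[~mask] * config.sigma_fp / denom[~mask]
    return r, mask
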