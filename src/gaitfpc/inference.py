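"""Group-level aggregation and 1D permutation cluster inference.

Per-participant correlation curves are aggregated by Fisher's r-to-z
transform (atanh), averaging in z-space and back-transforming, which keeps
the group mean inside (-1, 1) and makes the per-phase sampling distribution
approximately normal. Phase-dependent effects are tested SPM-style on the
whole 1D field: a pointwise one-sample (or paired) t statistic across
participants, a cluster-forming threshold at the pointwise two-sided alpha
quantile, and family-wise cluster p-values from the sign-flip permutation
null distribution of the maximum cluster mass. Cluster-level inference
respects the smoothness of the field: contiguous supra-threshold runs are
tested as units, not samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("gaitfpc")


# ---------------------------------------------------------------------------
# Fisher aggregation
# ---------------------------------------------------------------------------

def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| >= 1 clipped to 1 - 1e-12 (with a warning)."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) == 1):
        warnings.warn("|r| = 1 clipped to 1 - 1e-12 before atanh", stacklevel=2)
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r)


def fisher_mean(r_values, axis: int = 0) -> np.ndarray:
    """Group-mean correlation: tanh(mean(atanh(r))) along ``axis``.

    NaN entries (masked phases) are ignored; an all-NaN phase stays NaN.
    """
    r = np.asarray(r_values, float)
    if r.size == 0:
        raise ValueError("fisher_mean of empty input")
    z = fisher_z(np.where(np.isnan(r), 0.0, r))
    z[np.isnan(r)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.tanh(np.nanmean(z, axis=axis))


# ---------------------------------------------------------------------------
# Pointwise t field
# ---------------------------------------------------------------------------

def spm_t_field(data: np.ndarray, design: str = "one_sample",
                data2: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise t statistic across participants at each phase sample.

    ``design='one_sample'`` tests the mean of ``data`` (participants x J)
    against zero; ``design='paired'`` tests ``data - data2``. Returns
    ``(t, zero_variance_flag)``: phases with zero between-participant
    variance get t = +/-inf (0 if the mean is also zero) and are flagged.
    """
    X = np.asarray(data, float)
    if design == "paired":
        if data2 is None:
            raise ValueError("paired design needs data2")
        X = X - np.asarray(data2, float)
    elif design != "one_sample":
        raise ValueError(f"unknown design {design!r}")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    m = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    flag = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[flag] = np.where(m[flag] == 0, 0.0, np.inf * np.sign(m[flag]))
    return t, flag


# ---------------------------------------------------------------------------
# Permutation cluster inference
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start: int                 # first supra-threshold phase index (inclusive)
    end: int                   # last supra-threshold phase index (inclusive)
    stat: float                # cluster mass: sum of |t| over the run
    p_value: float


@dataclass
class ClusterResult:
    t: np.ndarray
    threshold: float
    clusters: list[Cluster]
    alpha: float
    n_permutations: int
    exhaustive: bool

    @property
    def any_significant(self) -> bool:
        return any(c.p_value <= self.alpha for c in self.clusters)

    def report(self, phase: np.ndarray | None = None) -> str:
        lines = [f"cluster-forming |t| threshold: {self.threshold:.4f} "
                 f"(alpha={self.alpha}, {self.n_permutations} permutations"
                 f"{', exhaustive' if self.exhaustive else ''})"]
        if not self.clusters:
            lines.append("no supra-threshold clusters")
        for c in self.clusters:
            if phase is not None:
                span = f"[{phase[c.start]:.1f}%, {phase[c.end]:.1f}%]"
            else:
                span = f"[{c.start}, {c.end}]"
            lines.append(f"cluster {span}: mass={c.stat:.3f}, p={c.p_value:.4f}")
        return "\n".join(lines)


def _cluster_masses(supra: np.ndarray, absu: np.ndarray) -> list[tuple[int, int, float]]:
    """(start, end, mass) of each contiguous True run of ``supra``."""
    out = []
    j = 0
    J = supra.size
    while j < J:
        if supra[j]:
            start = j
            while j + 1 < J and supra[j + 1]:
                j += 1
            out.append((start, j, float(absu[start:j + 1].sum())))
        j += 1
    return out


def _max_masses(T: np.ndarray, thr: float) -> np.ndarray:
    """Maximum cluster mass per row of a (B, J) t-field array (0 if none)."""
    A = np.abs(T)
    S = A > thr
    B, J = S.shape
    out = np.zeros(B)
    # cumulative-sum trick: mass of each run = csum at run end - csum at start
    pad = np.zeros((B, 1), bool)
    Sp = np.hstack([pad, S, pad])
    d = np.diff(Sp.astype(np.int8), axis=1)
    csum = np.concatenate([np.zeros((B, 1)), np.cumsum(A * S, axis=1)], axis=1)
    for b in range(B):
        starts = np.flatnonzero(d[b] == 1)
        ends = np.flatnonzero(d[b] == -1)
        if starts.size:
            out[b] = np.max(csum[b, ends] - csum[b, starts])
    return out


def permutation_cluster_inference(
    data: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: int | None = None,
    data2: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    threshold: float | None = None,
) -> ClusterResult:
    """Sign-flip permutation test of a 1D field's deviation from zero.

    One-sample (or paired, via ``data2``) design over participants x J
    curves. Clusters are contiguous runs of ``|t|`` above the pointwise
    two-sided ``alpha`` t quantile (masked phases are excluded and break
    contiguity); each observed cluster's family-wise p-value is the fraction
    of permutation maximum cluster masses at least as large. If fewer than
    ``n_permutations`` distinct sign patterns exist, they are enumerated
    exhaustively instead (logged). Deterministic given ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    X = np.asarray(data, float)
    if data2 is not None:
        X = X - np.asarray(data2, float)
    n, J = X.shape
    if n < 3:
        raise ValueError("need at least 3 participants")
    if mask is not None:
        keep = ~np.asarray(mask, bool)
    else:
        keep = ~np.any(np.isnan(X), axis=0)
    Xv = X[:, keep]
    if Xv.shape[1] == 0:
        raise ValueError("all phases masked")
    # map valid-column indices back to original phase indices; a gap in the
    # original grid must break cluster contiguity
    orig_idx = np.flatnonzero(keep)
    breaks = np.flatnonzero(np.diff(orig_idx) > 1)

    t_obs, _ = spm_t_field(Xv)
    if threshold is None:
        threshold = float(stats.t.ppf(1 - alpha / 2, n - 1))

    absu = np.abs(t_obs)
    supra = absu > threshold
    segments = np.split(np.arange(Xv.shape[1]), breaks + 1)
    observed: list[tuple[int, int, float]] = []
    for seg in segments:
        if seg.size == 0:
            continue
        for s, e, m in _cluster_masses(supra[seg], absu[seg]):
            observed.append((int(orig_idx[seg[s]]), int(orig_idx[seg[e]]), m))

    exhaustive = 2**n <= n_permutations
    if exhaustive:
        logger.info("enumerating all %d sign patterns exhaustively", 2**n)
        bits = np.arange(2**n)
        S = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
    else:
        rng = np.random.default_rng(seed)
        S = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    B = S.shape[0]
    sumsq = np.einsum("ij,ij->j", Xv, Xv)
    M = (S @ Xv) / n
    V = np.maximum((sumsq[None, :] - n * M**2) / (n - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = M / np.sqrt(V / n)
    T[~np.isfinite(T)] = 0.0
    # break contiguity across masked gaps by zeroing a virtual boundary:
    # compute max masses segment-wise and take the row-wise maximum
    max_mass = np.zeros(B)
    for seg in segments:
        if seg.size:
            max_mass = np.maximum(max_mass, _max_masses(T[:, seg], threshold))

    clusters = []
    for s, e, m in observed:
        if exhaustive:
            p = float(np.mean(max_mass >= m))
        else:
            p = float((1 + np.sum(max_mass >= m)) / (B + 1))
        clusters.append(Cluster(start=s, end=e, stat=m, p_value=p))
    clusters.sort(key=lambda c: c.start)
    return ClusterResult(t=t_obs if keep.all() else _expand(t_obs, keep),
                         threshold=threshold, clusters=clusters, alpha=alpha,
                         n_permutations=B, exhaustive=exhaustive)


def _expand(values: np.ndarray, keep: np.ndarray) -> np.ndarray:
    out = np.full(keep.size, np.nan)
    out[keep] = values
    return out


# ---------------------------------------------------------------------------
# Group field
# ---------------------------------------------------------------------------

@dataclass
class GroupField:
    """Group aggregation of per-participant correlation curves."""

    signal_id: str
    mean_r: np.ndarray             # back-transformed group mean per phase
    z: np.ndarray                  # (n_participants, J) Fisher z curves
    mask: np.ndarray               # phases masked for all participants
    cluster_result: ClusterResult | None
    alpha: float

    @property
    def n_participants(self) -> int:
        return self.z.shape[0]


def group_correlation_field(
    signal_id: str,
    z_curves: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> GroupField:
    """Aggregate per-participant z curves and run cluster inference.

    ``z_curves`` is participants x J in Fisher-z units (per-foot curves
    should already be averaged in z-space so participants are the
    independent unit); NaN marks masked phases.
    """
    z = np.asarray(z_curves, float)
    mask = np.all(np.isnan(z), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = np.tanh(np.nanmean(z, axis=0))
    mean_r[mask] = np.nan
    usable = ~np.any(np.isnan(z), axis=0)
    result = None
    if usable.any():
        result = permutation_cluster_inference(
            z, alpha=alpha, n_permutations=n_permutations, seed=seed, mask=~usable
        )
    return GroupField(signal_id=signal_id, mean_r=mean_r, z=z, mask=mask,
                      cluster_result=result, alpha=alpha)
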