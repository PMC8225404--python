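"""Two-state autoregressive hidden semi-Markov segmentation of wrist trajectories.

The observation model is a state-conditional AR(1) on per-frame displacement
vectors (positions are differenced once so the process is stationary within a
state).  State dwell times follow a shifted negative-binomial distribution
truncated at a configurable maximum, which keeps duration-explicit Viterbi
decoding tractable.  States strictly alternate (two-state swap transition
matrix).  State 0 is "rest", state 1 is "move"; after fitting, the state with
the smaller innovation-covariance trace is relabelled "rest".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special, stats

REST, MOVE = 0, 1
STATE_NAMES = ("rest", "move")


class SingularModelError(ValueError):
    """Raised when the trajectory cannot support a two-state model."""


@dataclass
class WristTrajectory:
    """Per-frame 2D wrist keypoint path with tracking confidence.

    Pixel convention: image coordinates, y increases downward ("up" on screen
    is decreasing y).  ``frame_rate`` is in frames per second.
    """

    frame_rate: float
    positions: np.ndarray  # (n_frames, 2) float, pixels
    confidence: np.ndarray  # (n_frames,) in [0, 1]
    wrist_side: str = "contralateral"  # or "ipsilateral"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_frames, 2)")
        if len(self.positions) != len(self.confidence):
            raise ValueError("positions and confidence must have equal length")
        finite = np.isfinite(self.confidence)
        if np.any((self.confidence[finite] < 0) | (self.confidence[finite] > 1)):
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def displacements(self) -> np.ndarray:
        """Per-frame displacement vectors, shape (n_frames - 1, 2)."""
        return np.diff(self.positions, axis=0)


@dataclass
class HSMMParams:
    """Parameters of the two-state AR(1) hidden semi-Markov model.

    ``ar`` holds one 2x2 AR coefficient matrix per state; ``innovation_cov``
    one 2x2 innovation covariance per state.  ``dwell_r`` / ``dwell_p`` are
    negative-binomial parameters of the dwell length minus one (so dwells are
    supported on {1, 2, ...}); mean dwell is ``1 + r (1 - p) / p``.
    """

    ar: np.ndarray  # (2, 2, 2)
    innovation_cov: np.ndarray  # (2, 2, 2)
    dwell_r: np.ndarray  # (2,)
    dwell_p: np.ndarray  # (2,)
    init_prob: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    max_dwell: int = 300

    def __post_init__(self) -> None:
        self.ar = np.asarray(self.ar, dtype=float)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        self.dwell_r = np.asarray(self.dwell_r, dtype=float)
        self.dwell_p = np.asarray(self.dwell_p, dtype=float)
        self.init_prob = np.asarray(self.init_prob, dtype=float)
        for s in range(2):
            cov = self.innovation_cov[s]
            if not np.all(np.linalg.eigvalsh(cov) > 0):
                raise SingularModelError(f"state {s} innovation covariance not positive definite")
        if np.any(self.dwell_r <= 0) or np.any((self.dwell_p <= 0) | (self.dwell_p >= 1)):
            raise ValueError("dwell parameters must satisfy r > 0, 0 < p < 1")
        if self.max_dwell < 1:
            raise ValueError("max_dwell must be >= 1")

    def mean_dwell(self) -> np.ndarray:
        return 1.0 + self.dwell_r * (1.0 - self.dwell_p) / self.dwell_p

    def dwell_log_pmf(self) -> np.ndarray:
        """Log pmf over dwell lengths 1..max_dwell, renormalised after truncation.

        Returns array (2, max_dwell); entry [s, d-1] is log P(dwell = d | s).
        """
        d = np.arange(1, self.max_dwell + 1)
        out = np.empty((2, self.max_dwell))
        for s in range(2):
            lp = stats.nbinom.logpmf(d - 1, self.dwell_r[s], self.dwell_p[s])
            out[s] = lp - special.logsumexp(lp)
        return out

    def dwell_log_sf(self) -> np.ndarray:
        """Log survival log P(dwell >= d) for d = 1..max_dwell under the truncated pmf."""
        lpmf = self.dwell_log_pmf()
        rev = np.flip(np.logaddexp.accumulate(np.flip(lpmf, axis=1), axis=1), axis=1)
        return rev


@dataclass
class StateSequence:
    """Per-frame move/rest labels for one trajectory."""

    labels: np.ndarray  # (n_frames,) int, REST or MOVE
    frame_rate: float
    posterior: Optional[np.ndarray] = None
    source: str = "fitted"  # or "ground-truth"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isin(self.labels, [REST, MOVE])):
            raise ValueError("labels must be 0 (rest) or 1 (move)")


def _interpolate_low_confidence(traj: WristTrajectory, threshold: float = 0.4) -> np.ndarray:
    """Positions with low-confidence / non-finite frames linearly interpolated."""
    pos = traj.positions.copy()
    bad = (~np.isfinite(pos).all(axis=1)) | (traj.confidence < threshold)
    if bad.all():
        raise SingularModelError("no usable frames: all positions low-confidence or non-finite")
    if bad.any():
        idx = np.arange(len(pos))
        for k in range(2):
            pos[bad, k] = np.interp(idx[bad], idx[~bad], pos[~bad, k])
    return pos


def emission_loglik(params: HSMMParams, displacements: np.ndarray) -> np.ndarray:
    """Log-likelihood of each displacement under each state, shape (2, T).

    The first displacement is scored against a zero-mean Gaussian with the
    state's innovation covariance (no AR predecessor).
    """
    disp = np.asarray(displacements, dtype=float)
    T = len(disp)
    ll = np.empty((2, T))
    for s in range(2):
        cov = params.innovation_cov[s]
        resid = np.empty_like(disp)
        resid[0] = disp[0]
        resid[1:] = disp[1:] - disp[:-1] @ params.ar[s].T
        ll[s] = stats.multivariate_normal(mean=np.zeros(2), cov=cov).logpdf(resid)
    return ll


def segmentation_log_prob(params: HSMMParams, displacements: np.ndarray, labels: np.ndarray) -> float:
    """Joint log-probability of one alternating labelling of the displacements.

    Interior segments are scored with the (truncated, renormalised) dwell pmf;
    the final segment — cut off by the end of the sequence — with the dwell
    survival function.  Non-alternating labellings score ``-inf``.
    """
    labels = np.asarray(labels, dtype=int)
    ll = emission_loglik(params, displacements)
    T = ll.shape[1]
    if len(labels) != T:
        raise ValueError("labels length must match number of displacements")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [T]))
    seg_states = labels[starts]
    if np.any(seg_states[1:] == seg_states[:-1]):
        return -np.inf
    lpmf = params.dwell_log_pmf()
    lsf = params.dwell_log_sf()
    total = np.log(params.init_prob[seg_states[0]])
    for i, (a, b, s) in enumerate(zip(starts, ends, seg_states)):
        d = b - a
        if d > params.max_dwell:
            return -np.inf
        total += ll[s, a:b].sum()
        total += lsf[s, d - 1] if i == len(starts) - 1 else lpmf[s, d - 1]
    return float(total)


def viterbi_decode(params: HSMMParams, displacements: np.ndarray) -> tuple[np.ndarray, float]:
    """MAP alternating segmentation by duration-explicit Viterbi.

    Returns (labels over displacements, joint log-probability).  The final
    segment is duration-censored (scored with the dwell survival function).
    """
    ll = emission_loglik(params, displacements)
    T = ll.shape[1]
    if T < 1:
        raise ValueError("sequence shorter than minimum dwell support")
    D = min(params.max_dwell, T)
    lpmf = params.dwell_log_pmf()
    lsf = params.dwell_log_sf()
    logpi = np.log(params.init_prob)
    cum = np.concatenate([np.zeros((2, 1)), np.cumsum(ll, axis=1)], axis=1)  # (2, T+1)

    V = np.full((T, 2), -np.inf)
    back = np.zeros((T, 2), dtype=int)  # chosen dwell length ending at t
    for t in range(T):
        dmax = min(D, t + 1)
        d = np.arange(1, dmax + 1)
        for s in range(2):
            seg = cum[s, t + 1] - cum[s, t + 1 - d]
            prev = np.where(t - d >= 0, V[t - d, 1 - s], logpi[s])
            cand = seg + lpmf[s, d - 1] + prev
            j = int(np.argmax(cand))
            V[t, s] = cand[j]
            back[t, s] = d[j]

    # censored final segment
    best = (-np.inf, 0, 0)
    d = np.arange(1, D + 1)
    for s in range(2):
        seg = cum[s, T] - cum[s, T - d]
        prev = np.where(T - 1 - d >= 0, V[T - 1 - d, 1 - s], logpi[s])
        cand = seg + lsf[s, d - 1] + prev
        j = int(np.argmax(cand))
        if cand[j] > best[0]:
            best = (float(cand[j]), s, int(d[j]))

    score, s, dlen = best
    labels = np.empty(T, dtype=int)
    t = T - 1
    labels[t - dlen + 1 : t + 1] = s
    t -= dlen
    s = 1 - s
    while t >= 0:
        dlen = back[t, s]
        labels[t - dlen + 1 : t + 1] = s
        t -= dlen
        s = 1 - s
    return labels, score


def decode_states(params: HSMMParams, trajectory: WristTrajectory) -> StateSequence:
    """MAP move/rest labelling of a trajectory under fitted parameters.

    Labels are decoded on the displacement sequence; the first frame inherits
    the label of the first displacement so the output matches the trajectory
    length.
    """
    if trajectory.n_frames < 2:
        raise ValueError("trajectory shorter than minimum dwell support")
    pos = _interpolate_low_confidence(trajectory)
    disp = np.diff(pos, axis=0)
    labels, _ = viterbi_decode(params, disp)
    frame_labels = np.concatenate(([labels[0]], labels))
    return StateSequence(labels=frame_labels, frame_rate=trajectory.frame_rate, source="fitted")


def _fit_nbinom(dwells: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood negative-binomial fit to dwell lengths (shifted by 1)."""
    k = np.asarray(dwells, dtype=float) - 1.0
    n = len(k)
    kbar = k.mean()
    if kbar <= 1e-9:  # all dwells of length 1
        return 1.0, 1.0 - 1e-6

    def nll(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + kbar)
        return -float(
            np.sum(special.gammaln(k + r)) - n * special.gammaln(r)
            + n * r * np.log(p) + np.sum(k) * np.log1p(-p)
        )

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-2), np.log(1e3)), method="bounded")
    r = float(np.exp(res.x))
    p = r / (r + kbar)
    return r, float(p)


def _mstep(disp: np.ndarray, labels: np.ndarray, max_dwell: int, prev: Optional[HSMMParams]) -> HSMMParams:
    ar = np.zeros((2, 2, 2))
    cov = np.zeros((2, 2, 2))
    dwell_r = np.zeros(2)
    dwell_p = np.zeros(2)

    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    seg_states = labels[starts]
    seg_lens = ends - starts

    for s in range(2):
        sel = labels == s
        # AR pairs: consecutive displacements both in state s
        pair = sel[1:] & sel[:-1]
        if pair.sum() >= 8:
            X = disp[:-1][pair]
            Y = disp[1:][pair]
            A, *_ = np.linalg.lstsq(X, Y, rcond=None)
            ar[s] = A.T
            resid = Y - X @ A
        elif prev is not None:
            ar[s] = prev.ar[s]
            resid = None
        else:
            ar[s] = np.zeros((2, 2))
            resid = disp[sel]
        # innovation covariance from residuals plus segment-first frames
        first_idx = starts[seg_states == s]
        firsts = disp[first_idx] if len(first_idx) else np.empty((0, 2))
        if resid is not None:
            R = np.vstack([resid, firsts]) if len(firsts) else resid
        else:
            R = firsts
        if len(R) >= 4:
            cov[s] = (R.T @ R) / len(R) + 1e-10 * np.eye(2)
        elif prev is not None:
            cov[s] = prev.innovation_cov[s]
        else:
            raise SingularModelError(f"too few frames assigned to state {s}")
        if np.trace(cov[s]) < 1e-12:
            raise SingularModelError(f"state {s} has (near-)zero innovation variance")

        lens = seg_lens[seg_states == s]
        if len(lens) >= 2:
            dwell_r[s], dwell_p[s] = _fit_nbinom(np.minimum(lens, max_dwell))
        elif prev is not None:
            dwell_r[s], dwell_p[s] = prev.dwell_r[s], prev.dwell_p[s]
        else:
            m = float(lens.mean()) if len(lens) else 2.0
            dwell_r[s], dwell_p[s] = 1.0, 1.0 / max(m, 1.0 + 1e-6)

    return HSMMParams(ar=ar, innovation_cov=cov, dwell_r=dwell_r, dwell_p=dwell_p,
                      init_prob=np.array([0.5, 0.5]), max_dwell=max_dwell)


def _relabel_rest_low_variance(params: HSMMParams) -> tuple[HSMMParams, bool]:
    """Enforce the convention that 'rest' is the state with smaller innovation trace."""
    if np.trace(params.innovation_cov[REST]) <= np.trace(params.innovation_cov[MOVE]):
        return params, False
    flip = HSMMParams(
        ar=params.ar[::-1].copy(),
        innovation_cov=params.innovation_cov[::-1].copy(),
        dwell_r=params.dwell_r[::-1].copy(),
        dwell_p=params.dwell_p[::-1].copy(),
        init_prob=params.init_prob[::-1].copy(),
        max_dwell=params.max_dwell,
    )
    return flip, True


def fit_arhsmm(
    trajectory: WristTrajectory,
    init_seed: int = 0,
    max_iter: int = 30,
    tol: float = 1e-6,
    max_dwell: int = 300,
    return_history: bool = False,
):
    """Fit the two-state AR(1) HSMM by segmental (Viterbi) EM.

    The E-step is MAP segmentation; the M-step re-estimates AR coefficients
    and innovation covariances by least squares and dwell parameters by
    negative-binomial maximum likelihood.  The tracked objective is the joint
    log-probability of the decoded segmentation, which is nondecreasing across
    iterations.  A non-convergence warning is emitted if the objective is
    still improving after ``max_iter`` iterations.
    """
    if trajectory.n_frames < 200:
        raise ValueError("need at least 200 frames to fit the model")
    pos = _interpolate_low_confidence(trajectory)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite positions remain after interpolation")
    disp = np.diff(pos, axis=0)
    raw_speed = np.linalg.norm(disp, axis=1)
    if raw_speed.std() < 1e-9:
        raise SingularModelError("constant (or uniformly drifting) trajectory")
    # smooth speed before clustering so brief within-movement pauses (e.g. the
    # turnaround of an out-and-back reach) do not fragment the initial labels
    kernel = np.ones(7) / 7.0
    speed = np.convolve(raw_speed, kernel, mode="same")

    # init: 2-means on (smoothed) frame speed, rest = lower-speed cluster
    rng = np.random.default_rng(init_seed)
    centers = np.sort(rng.choice(speed, size=2, replace=False))
    if centers[0] == centers[1]:
        centers = np.array([speed.min(), speed.max()])
    for _ in range(50):
        assign = (np.abs(speed[:, None] - centers[None, :])).argmin(axis=1)
        new = np.array([
            speed[assign == j].mean() if np.any(assign == j) else centers[j] for j in range(2)
        ])
        if np.allclose(new, centers):
            break
        centers = new
    order = np.argsort(centers)
    labels = np.argsort(order)[assign]  # 0 = lower speed = rest

    if len(np.unique(labels)) < 2:
        raise SingularModelError("speed clustering collapsed to one state")

    params = _mstep(disp, labels, max_dwell, prev=None)
    prev_score = -np.inf
    converged = False
    history: list[float] = []
    for _ in range(max_iter):
        labels, score = viterbi_decode(params, disp)
        history.append(score)
        if len(np.unique(labels)) < 2:
            break  # one state explains everything; keep current params
        params = _mstep(disp, labels, max_dwell, prev=params)
        if score - prev_score < tol and np.isfinite(prev_score):
            converged = True
            break
        prev_score = score
    if not converged:
        warnings.warn("EM did not converge within max_iter; returning best iterate", stacklevel=2)
    params, _ = _relabel_rest_low_variance(params)
    if return_history:
        return params, history
    return params
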