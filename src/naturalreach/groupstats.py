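"""Group-level aggregation, bootstrap baseline masking, and standard tests.

Aggregation is median over events within subject, then mean over subjects.
Significance masking compares every time–frequency bin against a bootstrap
null built from baseline time points of the group spectrogram (per
frequency), with two-sided p-values and Benjamini–Hochberg FDR correction
across all bins of the region.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .spectral import BASELINE_WINDOW


def aggregate(per_subject_event_planes: dict[str, np.ndarray]) -> np.ndarray:
    """Median over events within each subject, then mean across subjects.

    ``per_subject_event_planes`` maps subject id to an (n_events, n_freqs,
    n_times) stack of baseline-subtracted planes for one region.  Subjects
    with no events for the region are skipped with a warning.
    """
    medians = []
    for subject, planes in per_subject_event_planes.items():
        planes = np.asarray(planes, dtype=float)
        if planes.ndim != 3 or planes.shape[0] == 0:
            warnings.warn(f"subject {subject!r} has no events for this region; skipped", stacklevel=2)
            continue
        medians.append(np.median(planes, axis=0))
    if not medians:
        raise ValueError("no subject contributed events")
    return np.mean(medians, axis=0)


def bootstrap_baseline_mask(
    group_plane: np.ndarray,
    times: np.ndarray,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    per_subject_event_planes: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask non-significant bins of a group spectrogram against a baseline null.

    When ``per_subject_event_planes`` (the same event stacks that produced the
    group plane) is given, the null is ``n_boot`` re-aggregations — median
    over events, mean over subjects — of baseline bins resampled per event
    and frequency, i.e. the null distribution of the aggregate statistic
    itself.  Without the stacks, the null falls back to resampling the group
    plane's own baseline values per frequency (coarser: its tail resolution
    is limited by the number of baseline time points).

    Each bin gets a two-sided p-value with a +1/(n+1) continuity correction;
    Benjamini–Hochberg correction runs across all bins of the plane, and bins
    with corrected p > alpha are set to 0.  Returns (masked plane, raw
    two-sided p-values).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    group_plane = np.asarray(group_plane, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not sel.any():
        raise ValueError("baseline window absent from time grid")
    rng = np.random.default_rng(seed)
    n_freq, n_time = group_plane.shape

    if per_subject_event_planes is not None:
        subject_nulls = []
        for subject in sorted(per_subject_event_planes):
            planes = np.asarray(per_subject_event_planes[subject], dtype=float)
            if planes.ndim != 3 or planes.shape[0] == 0:
                continue
            base = planes[:, :, sel]  # (n_ev, n_freq, n_base)
            n_ev, _, n_base = base.shape
            idx = rng.integers(0, n_base, size=(n_boot, n_ev))
            # resampled[b, ev, f] = base[ev, f, idx[b, ev]]
            resampled = base[
                np.arange(n_ev)[None, :, None],
                np.arange(n_freq)[None, None, :],
                idx[:, :, None],
            ]
            subject_nulls.append(np.median(resampled, axis=1))  # (n_boot, n_freq)
        if not subject_nulls:
            raise ValueError("no usable event stacks for the bootstrap null")
        null = np.mean(subject_nulls, axis=0).T  # (n_freq, n_boot)
    else:
        base = group_plane[:, sel]
        idx = rng.integers(0, base.shape[1], size=n_boot)
        null = base[:, idx]  # (n_freq, n_boot)

    obs = group_plane[:, :, None]  # (n_freq, n_time, 1)
    ge = (null[:, None, :] >= obs).sum(axis=2)
    le = (null[:, None, :] <= obs).sum(axis=2)
    p_hi = (ge + 1.0) / (n_boot + 1.0)
    p_lo = (le + 1.0) / (n_boot + 1.0)
    pvals = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))

    reject = benjamini_hochberg(pvals.ravel(), alpha=alpha).reshape(pvals.shape)
    masked = np.where(reject, group_plane, 0.0)
    return masked, pvals


def benjamini_hochberg(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-up BH procedure; returns a boolean rejection vector."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        reject[order[: kmax + 1]] = True
    return reject


def kruskal_wallis_bands(values: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way Kruskal–Wallis H test across groups of band-power values.

    Returns (H, p).  Fully tied data (every observation identical) yields
    H = 0, p = 1 instead of an error.
    """
    groups = [np.asarray(v, dtype=float) for v in values]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need at least 2 groups with at least 1 observation each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
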