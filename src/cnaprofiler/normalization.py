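"""Profile centering and noise estimation for aCGH log2 ratios.

Segment calling assumes the copy-neutral state of each sample sits at
log2 = 0 and needs a per-sample noise scale for the interval score.  Two
robust estimators provide this:

* ``estimate_noise_sd`` — a derivative-based spread estimate: the median
  absolute first difference of the profile scaled to be consistent for
  Gaussian noise (the DLRS idea).  First differences cancel any
  piecewise-constant copy-number signal except at its breakpoints, so the
  estimate ignores aberrations as long as breakpoints are sparse.
* ``center_profile`` — mode centering: shift the profile so the peak of a
  Gaussian-kernel density estimate of its values (the copy-neutral
  majority population) lands on zero.
* ``iterative_recenter`` — call-aware refinement: alternate aberration
  calling with re-centering on the probes outside called segments, so a
  large aberrant fraction cannot drag the baseline.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import optimize, stats

__all__ = ["center_profile", "estimate_noise_sd", "iterative_recenter"]

# Phi^-1(0.75): MAD -> sd consistency factor for Gaussian noise
_MAD_TO_SD = 0.6744897501960817


def estimate_noise_sd(profile, chromosomes=None) -> float:
    """Robust per-sample noise sigma from median absolute first differences.

    sigma_hat = median(|v[i+1] - v[i]|) / (0.6745 * sqrt(2)), over
    consecutive non-missing pairs; with ``chromosomes`` given, pairs never
    straddle a chromosome boundary.  The sqrt(2) removes the variance
    doubling of differencing.
    """
    v = np.asarray(profile, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing values to estimate noise")
    if chromosomes is None:
        chrom = np.zeros(len(v))
    else:
        chrom = np.asarray(chromosomes)
        if len(chrom) != len(v):
            raise ValueError("chromosomes must align with the profile")
    diffs = []
    for c in _unique_in_order(chrom):
        vals = v[(chrom == c) & ok]
        if len(vals) >= 2:
            diffs.append(np.abs(np.diff(vals)))
    if not diffs:
        raise ValueError("no chromosome holds 2 non-missing values")
    d = np.concatenate(diffs)
    return float(np.median(d) / (_MAD_TO_SD * math.sqrt(2)))


def _unique_in_order(values):
    """Unique values in order of first appearance."""
    seen, out = set(), []
    for x in values:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def center_profile(profile) -> tuple[np.ndarray, float]:
    """Shift a profile so the mode of its value density sits at zero.

    The shift is the argmax of a Gaussian KDE with Silverman bandwidth,
    located on a grid and polished with a bounded scalar optimizer; for the
    copy-neutral majority of probes the density peak is the neutral level.
    Returns ``(profile - shift, shift)``.
    """
    v = np.asarray(profile, dtype=float)
    vals = v[~np.isnan(v)]
    if len(vals) < 10:
        raise ValueError("need at least 10 non-missing values to center")
    if np.ptp(vals) == 0:
        shift = float(vals[0])
        return v - shift, shift
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), 1024)
    dens = kde(grid)
    k = int(np.argmax(dens))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda x: -kde(x)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-9},
        )
        shift = float(res.x)
        if kde(shift)[0] < dens[k]:
            shift = float(grid[k])
    else:
        shift = float(grid[k])
    return v - shift, shift


def iterative_recenter(
    profile,
    probe_map,
    score_threshold: float = 4.0,
    min_abs_log2: float = 0.2,
    max_iter: int = 10,
    tol: float = 1e-4,
    sigma: float | None = None,
) -> np.ndarray:
    """Center a profile while ignoring its own called aberrations.

    Starts from mode centering, then repeats {call aberrations; subtract
    the median of probes outside called segments} until the incremental
    shift falls below ``tol`` or ``max_iter`` is reached.  The result is
    invariant to adding a constant to the input.  If every probe ends up
    inside a called segment the mode-centered profile is returned with a
    warning.
    """
    from .segmentation import call_aberrations  # local import: avoid cycle

    centered, _ = center_profile(profile)
    if not math.isfinite(tol):
        return centered
    for _ in range(max_iter):
        sd = sigma if sigma is not None else estimate_noise_sd(
            centered, probe_map["chromosome"].to_numpy()
        )
        if sd <= 0:
            break  # noise-free and already centered: nothing to refine
        segs = call_aberrations(
            centered, probe_map, sd,
            score_threshold=score_threshold, min_abs_log2=min_abs_log2,
        )
        mask = np.zeros(len(centered), dtype=bool)
        for s in segs:
            mask[s.first_probe : s.last_probe + 1] = True
        outside = centered[~mask & ~np.isnan(centered)]
        if len(outside) == 0:
            warnings.warn("every probe sits in a called segment; keeping mode centering")
            return centered
        shift = float(np.median(outside))
        centered = centered - shift
        if abs(shift) < tol:
            break
    return centered
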