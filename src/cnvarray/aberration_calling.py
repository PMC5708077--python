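"""Per-sample QC and aberration calling from log2-ratio profiles.

QC uses the derivative log ratio spread (DLRS): the robust spread of
consecutive-probe log2-ratio differences within each chromosome, divided
by sqrt(2). For i.i.d. Gaussian probe noise of sd sigma the differences
have sd sigma*sqrt(2), so DLRS estimates sigma directly. Arrays pass QC
when DLRS < 0.30 (vendor recommendation; well-behaved arrays typically
land in the 0.11-0.17 band).

Aberrations are called with a z-type interval score

    score(i..j) = |mean(r_i..r_j)| * sqrt(N) / sigma

mirroring the user-facing contract of threshold-based interval-scoring
segmentation on Agilent platforms (threshold 6.0 by default). The exact
vendor algorithm is proprietary; here the maximal-scoring interval per
chromosome is found by exhaustive search over all O(n^2) intervals,
extracted greedily, and the flanks re-searched until no interval reaches
the threshold. Emitted calls must then pass an aberration filter:

* standard filter    — >= 3 probes and |mean log2| >= 0.25
* correlation filter — >= 2 probes and |mean log2| >= 0.5
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CnvCall, LogRatioProfile, ProbeMap

__all__ = [
    "DLRS_QC_BOUND",
    "CallingParams",
    "compute_dlrs",
    "qc_pass",
    "interval_score",
    "call_aberrations",
]

DLRS_QC_BOUND = 0.30

# (min_probes, min |mean log2|) per aberration filter
_FILTERS = {"standard": (3, 0.25), "correlation": (2, 0.5)}


@dataclass(frozen=True)
class CallingParams:
    """Aberration-calling parameters.

    sigma is the per-sample noise scale used by the interval score; when
    None it defaults to the sample's DLRS estimate. filter_mode selects
    the aberration filter; min_probes/min_abs_mean override its defaults
    when given explicitly.
    """

    score_threshold: float = 6.0
    sigma: float | None = None
    filter_mode: str = "standard"
    min_probes: int | None = None
    min_abs_mean: float | None = None

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if self.filter_mode not in _FILTERS:
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.min_probes is not None and self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.min_abs_mean is not None and self.min_abs_mean < 0:
            raise ValueError("min_abs_mean must be >= 0")

    @property
    def effective_min_probes(self) -> int:
        return self.min_probes if self.min_probes is not None else _FILTERS[self.filter_mode][0]

    @property
    def effective_min_abs_mean(self) -> float:
        return self.min_abs_mean if self.min_abs_mean is not None else _FILTERS[self.filter_mode][1]


def compute_dlrs(profile: LogRatioProfile, robust: bool = True) -> float:
    """Derivative log ratio spread of one profile.

    Differences are taken between consecutive probes within each
    chromosome (never across chromosome boundaries); their spread is
    IQR/1.349 when ``robust`` (default) or the plain sd otherwise, and is
    divided by sqrt(2) so the result estimates the per-probe noise sd.
    """
    pm = profile.probe_map
    diffs = []
    for chrom in pm.chroms:
        r = profile.ratios[pm.slice_of(chrom)]
        if r.size >= 2:
            diffs.append(np.diff(r))
    if not diffs:
        raise ValueError("DLRS undefined: no chromosome has >= 2 probes")
    d = np.concatenate(diffs)
    if robust:
        q75, q25 = np.percentile(d, [75, 25])
        spread = (q75 - q25) / 1.349
    else:
        spread = float(np.std(d, ddof=1))
    return float(spread) / np.sqrt(2.0)


def qc_pass(dlrs: float, bound: float = DLRS_QC_BOUND) -> bool:
    """QC pass iff DLRS is strictly below the bound (default 0.30)."""
    return dlrs < bound


def interval_score(ratios: np.ndarray, sigma: float) -> float:
    """z-type score of one interval: |mean| * sqrt(N) / sigma."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("interval must be non-empty")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(abs(ratios.mean()) * np.sqrt(ratios.size) / sigma)


def _best_interval(r: np.ndarray, sigma: float) -> tuple[int, int, float]:
    """Maximal-scoring interval of ``r`` (indices inclusive) and its score.

    Exhaustive over all O(n^2) intervals; ties broken by longer interval,
    then leftmost start, so extraction is deterministic.
    """
    n = r.size
    prefix = np.concatenate([[0.0], np.cumsum(r)])
    # sums[i, j] = r[i] + ... + r[j] for j >= i
    sums = prefix[np.newaxis, 1:] - prefix[: n, np.newaxis]
    lengths = np.arange(n)[np.newaxis, :] - np.arange(n)[:, np.newaxis] + 1
    valid = lengths >= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.abs(sums) / (sigma * np.sqrt(np.where(valid, lengths, 1)))
    scores[~valid] = -np.inf
    best = scores.max()
    ii, jj = np.nonzero(scores >= best - 1e-12 * max(1.0, best))
    # prefer longer, then leftmost
    order = np.lexsort((ii, -(jj - ii)))
    k = order[0]
    return int(ii[k]), int(jj[k]), float(scores[ii[k], jj[k]])


def _greedy_extract(r: np.ndarray, sigma: float, threshold: float) -> list[tuple[int, int, float]]:
    """Greedy maximal-interval decomposition of one chromosome's ratios."""
    out: list[tuple[int, int, float]] = []
    stack = [(0, r.size)]  # half-open index segments
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        i, j, score = _best_interval(r[lo:hi], sigma)
        if score < threshold:
            continue
        out.append((lo + i, lo + j, score))
        stack.append((lo, lo + i))
        stack.append((lo + j + 1, hi))
    return sorted(out)


def call_aberrations(
    profile: LogRatioProfile,
    probe_map: ProbeMap | None = None,
    params: CallingParams | None = None,
) -> list[CnvCall]:
    """Call gain/loss aberrations in one sample.

    Returns disjoint intervals per chromosome whose score reaches the
    threshold, found by greedy extraction of the best-scoring interval
    with recursion on the flanks; each call must additionally pass the
    active aberration filter. Calls are sorted by (chromosome order,
    start).
    """
    params = params or CallingParams()
    pm = probe_map if probe_map is not None else profile.probe_map
    if pm is not profile.probe_map and pm.n_probes != profile.ratios.size:
        raise ValueError("probe map does not match profile")
    sigma = params.sigma
    if sigma is None:
        if profile.dlrs is None:
            profile.dlrs = compute_dlrs(profile)
        sigma = profile.dlrs
    if sigma is None or sigma <= 0:
        raise ValueError("sigma must be positive (noiseless profile: pass sigma explicitly)")

    min_probes = params.effective_min_probes
    min_abs_mean = params.effective_min_abs_mean
    calls: list[CnvCall] = []
    for chrom in pm.chroms:
        sl = pm.slice_of(chrom)
        r = profile.ratios[sl]
        if r.size == 0:
            continue
        pos = pm.positions[chrom]
        for i, j, score in _greedy_extract(r, sigma, params.score_threshold):
            n = j - i + 1
            mean = float(r[i : j + 1].mean())
            if n < min_probes or abs(mean) < min_abs_mean or mean == 0.0:
                continue
            calls.append(
                CnvCall(
                    sample_id=profile.sample_id,
                    chromosome=chrom,
                    start=int(pos[i]),
                    stop=int(pos[j]) + 1,
                    n_probes=n,
                    mean_log2=mean,
                    score=score,
                    kind="gain" if mean > 0 else "loss",
                )
            )
    return calls
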