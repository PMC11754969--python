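"""Extraction of the 20-feature HRV battery from a single phase's RRI series.

Time domain (6): mean RRI, SDNN, RMSSD, pNN50, triangular index (TRI) and
TINN.  Frequency domain (7): log band powers (VLF/LF/HF/total, natural log
of power in s^2), normalized LF/HF power and the LF/HF ratio, from a Welch
periodogram of the cubic-spline-resampled (4 Hz) tachogram.  Nonlinear (7,
from 5 method families): approximate and sample entropy (m=2, r=0.2*SD),
detrended fluctuation exponents alpha1 (boxes 4-16) and alpha2 (17-64),
Grassberger-Procaccia correlation dimension, and the Poincare descriptors
SD1/SD2.

Conventions applied throughout (documented in docs/methods.md):

* sample standard deviation (ddof=1) wherever an SD is reported;
* SD1 = RMSSD / sqrt(2) and SD2 = sqrt(2*SDNN^2 - SD1^2), which makes the
  Poincare identities exact rather than asymptotic;
* degenerate (zero-variance) series yield entropies 0 and CorDim 0; a
  sample entropy with no template matches is reported as NaN and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist

from .cohort import RRISeries
from .errors import InsufficientDataError, QualityError

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_DOMAINS",
    "EntropyParams",
    "correct_artifacts",
    "time_domain_features",
    "spectral_features",
    "approximate_entropy",
    "sample_entropy",
    "dfa",
    "correlation_dimension",
    "poincare",
    "extract_features",
    "extract_cohort_features",
]

#: Canonical feature ordering used by every downstream table.
FEATURE_NAMES: tuple[str, ...] = (
    "mean_rri", "sdnn", "rmssd", "pnn50", "tri", "tinn",
    "log_vlf", "log_lf", "log_hf", "log_tot", "lf_nu", "hf_nu", "lf_hf",
    "sd1", "sd2", "apen", "sampen", "alpha1", "alpha2", "cordim",
)

#: Analysis-domain membership of each feature (time / frequency / nonlinear).
FEATURE_DOMAINS: dict[str, str] = {
    "mean_rri": "time", "sdnn": "time", "rmssd": "time",
    "pnn50": "time", "tri": "time", "tinn": "time",
    "log_vlf": "frequency", "log_lf": "frequency", "log_hf": "frequency",
    "log_tot": "frequency", "lf_nu": "frequency", "hf_nu": "frequency",
    "lf_hf": "frequency",
    "sd1": "nonlinear", "sd2": "nonlinear", "apen": "nonlinear",
    "sampen": "nonlinear", "alpha1": "nonlinear", "alpha2": "nonlinear",
    "cordim": "nonlinear",
}

#: Method families in the nonlinear domain (Poincare, ApEn, SampEn, DFA, CorDim).
NONLINEAR_FAMILIES: dict[str, str] = {
    "sd1": "poincare", "sd2": "poincare", "apen": "apen", "sampen": "sampen",
    "alpha1": "dfa", "alpha2": "dfa", "cordim": "cordim",
}

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

_HIST_BIN_S = 1.0 / 128.0  # geometric-feature histogram bin width


@dataclass(frozen=True)
class EntropyParams:
    """Embedding dimension and tolerance for ApEn/SampEn.

    The tolerance is ``r_factor`` times the sample SD of the analysed
    segment.
    """

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")


# ---------------------------------------------------------------------------
# artifact correction
# ---------------------------------------------------------------------------

def correct_artifacts(
    intervals_ms: np.ndarray,
    dev_threshold: float = 0.25,
    window: int = 11,
    max_flag_fraction: float = 0.30,
) -> tuple[np.ndarray, int]:
    """Flag ectopic/artifactual beats and replace them by spline interpolation.

    A beat is flagged when it deviates from the running median (centred
    window of ``window`` beats) by more than ``dev_threshold`` as a fraction
    of that median.  Flagged beats are replaced by a piecewise cubic spline
    over beat index fitted to the unflagged beats.  Returns the corrected
    series and the number of corrections.

    Raises :class:`QualityError` when more than ``max_flag_fraction`` of
    beats are flagged.
    """
    x = np.asarray(intervals_ms, dtype=float)
    if x.size < window:
        raise InsufficientDataError(
            f"artifact correction needs >= {window} beats, got {x.size}"
        )
    med = signal.medfilt(x, kernel_size=window)
    # medfilt zero-pads the edges; recompute edge medians over the available window
    half = window // 2
    for i in range(half):
        med[i] = np.median(x[: i + half + 1])
        med[-(i + 1)] = np.median(x[-(i + half + 1):])
    flagged = np.abs(x - med) > dev_threshold * med
    n_flagged = int(flagged.sum())
    if n_flagged == 0:
        return x.copy(), 0
    if n_flagged > max_flag_fraction * x.size:
        raise QualityError(
            f"{n_flagged} of {x.size} beats flagged as artifacts "
            f"(> {max_flag_fraction:.0%}); series rejected"
        )
    idx = np.arange(x.size)
    good = ~flagged
    spline = CubicSpline(idx[good], x[good])
    corrected = x.copy()
    corrected[flagged] = spline(idx[flagged])
    return corrected, n_flagged


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def _triangular_fit(counts: np.ndarray, centers: np.ndarray) -> float:
    """Baseline width (ms) of the least-squares triangular fit to the RRI
    histogram; exhaustive search of the (N, M) corner positions on the bin
    grid."""
    nz = np.nonzero(counts)[0]
    if nz.size <= 1:
        return 0.0
    peak = int(np.argmax(counts))
    y = float(counts[peak])
    lo_candidates = range(0, peak)          # N strictly left of the mode
    hi_candidates = range(peak + 1, len(counts))
    best = (math.inf, 0.0)
    for i in lo_candidates:
        for j in hi_candidates:
            tri = np.zeros_like(counts, dtype=float)
            left = slice(i, peak + 1)
            tri[left] = y * (centers[left] - centers[i]) / (centers[peak] - centers[i])
            right = slice(peak, j + 1)
            tri[right] = y * (centers[j] - centers[right]) / (centers[j] - centers[peak])
            tri[peak] = y
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0]:
                best = (err, float(centers[j] - centers[i]))
    return best[1]


def time_domain_features(intervals_ms: np.ndarray) -> dict[str, float]:
    """Mean RRI (s), SDNN, RMSSD (ms), pNN50 (%), TRI and TINN (ms)."""
    x = np.asarray(intervals_ms, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("time-domain features need >= 2 intervals")
    d = np.diff(x)
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    pnn50 = float(100.0 * np.mean(np.abs(d) > 50.0))
    # geometric features on a 1/128 s histogram aligned to the bin grid
    bw = _HIST_BIN_S * 1000.0
    lo = math.floor(x.min() / bw) * bw
    hi = math.ceil(x.max() / bw) * bw
    if hi <= lo:
        hi = lo + bw
    edges = np.arange(lo, hi + bw / 2, bw)
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    tri = float(x.size / counts.max())
    tinn = _triangular_fit(counts.astype(float), centers)
    return {
        "mean_rri": float(np.mean(x) / 1000.0),
        "sdnn": sdnn,
        "rmssd": rmssd,
        "pnn50": pnn50,
        "tri": tri,
        "tinn": tinn,
    }


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def resample_tachogram(
    intervals_ms: np.ndarray, fs: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling of the RR tachogram to an equidistant grid.

    The k-th interval is anchored at its end time t_k = sum(RR_1..RR_k); the
    spline is evaluated every 1/fs s between the first and last beat.
    Returns (times_s, rri_s).
    """
    x = np.asarray(intervals_ms, dtype=float) / 1000.0
    t = np.cumsum(x)
    if t[-1] - t[0] < 10.0:
        raise InsufficientDataError("tachogram shorter than 10 s cannot be resampled")
    spline = CubicSpline(t, x)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    return grid, spline(grid)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs < band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def spectral_features(
    intervals_ms: np.ndarray,
    fs: float = 4.0,
    window_s: float = 150.0,
) -> dict[str, float]:
    """Welch-periodogram band powers of the resampled tachogram.

    The mean-removed 4 Hz tachogram is analysed with Hann windows of
    ``window_s`` seconds and 50% overlap; band powers (s^2) are trapezoidal
    integrals of the PSD over VLF [0, 0.04), LF [0.04, 0.15) and
    HF [0.15, 0.4) Hz.  Absolute powers are returned as natural logs.
    """
    x = np.asarray(intervals_ms, dtype=float)
    if x.sum() / 1000.0 < 60.0:
        raise InsufficientDataError("spectral features need >= 60 s of data")
    _, y = resample_tachogram(x, fs=fs)
    y = y - y.mean()
    nperseg = int(round(window_s * fs))
    if y.size < nperseg:
        warnings.warn(
            f"series shorter than one {window_s:.0f}-s Welch window; "
            "using a single-segment periodogram",
            stacklevel=2,
        )
        nperseg = y.size
    freqs, psd = signal.welch(
        y, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )
    vlf = _band_power(freqs, psd, VLF_BAND)
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND)
    tot = vlf + lf + hf
    if hf <= 0.0:
        raise InsufficientDataError("zero HF power: LF/HF undefined")
    with np.errstate(divide="ignore"):
        out = {
            "log_vlf": float(np.log(vlf)) if vlf > 0 else -np.inf,
            "log_lf": float(np.log(lf)) if lf > 0 else -np.inf,
            "log_hf": float(np.log(hf)),
            "log_tot": float(np.log(tot)),
        }
    out["lf_nu"] = float(100.0 * lf / (lf + hf))
    out["hf_nu"] = float(100.0 - out["lf_nu"])
    out["lf_hf"] = float(lf / hf)
    return out


# ---------------------------------------------------------------------------
# nonlinear: entropies
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * delay
    idx = np.arange(m) * delay + np.arange(n)[:, None]
    return x[idx]


def _cheb_counts(templates: np.ndarray, r: float) -> np.ndarray:
    """Number of templates within Chebyshev distance r of each template
    (self-matches included)."""
    # max over embedding dimensions of pairwise |differences|
    d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
    return (d <= r).sum(axis=1)


def approximate_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Approximate entropy, Pincus definition (self-matches included).

    ApEn(m, r) = Phi_m(r) - Phi_{m+1}(r), with Phi_m the mean log fraction
    of templates within tolerance r = r_factor * SD(x).  A zero-variance
    series returns 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    m = params.m
    if x.size < m + 2:
        raise InsufficientDataError(f"ApEn needs >= {m + 2} points, got {x.size}")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    r = params.r_factor * sd

    def phi(mm: int) -> float:
        tpl = _embed(x, mm)
        counts = _cheb_counts(tpl, r)
        return float(np.mean(np.log(counts / tpl.shape[0])))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> float:
    """Sample entropy (Richman-Moorman), self-matches excluded.

    SampEn = -ln(A/B) where B and A count template pairs within tolerance at
    lengths m and m+1 (the same N-m templates are used for both lengths).
    Returns 0 for a zero-variance series and NaN (an explicit
    undefined-value flag) when no matches exist at either length.
    """
    x = np.asarray(x, dtype=float)
    m = params.m
    if x.size < m + 2:
        raise InsufficientDataError(f"SampEn needs >= {m + 2} points, got {x.size}")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    r = params.r_factor * sd
    tpl_m = _embed(x, m)[:-1]          # N - m templates for both lengths
    tpl_m1 = _embed(x, m + 1)
    db = np.abs(tpl_m[:, None, :] - tpl_m[None, :, :]).max(axis=2)
    da = np.abs(tpl_m1[:, None, :] - tpl_m1[None, :, :]).max(axis=2)
    iu = np.triu_indices(tpl_m.shape[0], k=1)
    b = int((db[iu] <= r).sum())
    a = int((da[iu] <= r).sum())
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# nonlinear: DFA
# ---------------------------------------------------------------------------

def dfa_fluctuations(x: np.ndarray, box_sizes: np.ndarray) -> np.ndarray:
    """Root-mean-square fluctuation F(n) of the integrated, per-box linearly
    detrended series, for each box size n (non-overlapping boxes, leftover
    tail discarded)."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    out = np.empty(box_sizes.size)
    for i, n in enumerate(box_sizes):
        n = int(n)
        n_boxes = y.size // n
        seg = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n, dtype=float)
        # per-box least-squares line via closed-form regression
        tm = t.mean()
        denom = np.sum((t - tm) ** 2)
        slope = (seg @ (t - tm)) / denom
        inter = seg.mean(axis=1) - slope * tm
        resid = seg - (inter[:, None] + slope[:, None] * t)
        out[i] = np.sqrt(np.mean(resid ** 2))
    return out


def dfa(x: np.ndarray, short_range: tuple[int, int] = (4, 16),
        long_range: tuple[int, int] = (17, 64)) -> tuple[float, float]:
    """Detrended fluctuation exponents alpha1 (short boxes) and alpha2 (long).

    Each exponent is the least-squares slope of log F(n) versus log n over
    every integer box size in its range.
    """
    x = np.asarray(x, dtype=float)
    min_len = 2 * long_range[1] + 2
    if x.size < min_len:
        raise InsufficientDataError(
            f"DFA needs >= {min_len} beats to populate n={long_range[1]} boxes, "
            f"got {x.size}"
        )
    if np.std(x) == 0:
        return 0.0, 0.0

    def slope(rng: tuple[int, int]) -> float:
        sizes = np.arange(rng[0], rng[1] + 1)
        f = dfa_fluctuations(x, sizes)
        good = f > 0
        if good.sum() < 2:
            return 0.0
        return float(np.polyfit(np.log(sizes[good]), np.log(f[good]), 1)[0])

    return slope(short_range), slope(long_range)


# ---------------------------------------------------------------------------
# nonlinear: correlation dimension
# ---------------------------------------------------------------------------

def correlation_sums(
    x: np.ndarray, embed_m: int, delay: int, radii: np.ndarray
) -> np.ndarray:
    """Grassberger-Procaccia correlation sum C(r): the fraction of distinct
    embedded-vector pairs closer (Euclidean) than each radius."""
    emb = _embed(np.asarray(x, dtype=float), embed_m, delay)
    d = pdist(emb)
    return np.searchsorted(np.sort(d), radii, side="left") / d.size


def correlation_dimension(
    x: np.ndarray, embed_m: int = 10, delay: int = 1, n_radii: int = 30
) -> float:
    """Correlation dimension via the Grassberger-Procaccia slope.

    The series is delay-embedded, pairwise distances are summarised as C(r)
    on a log-spaced radius grid spanning the distance range, and the
    dimension is the least-squares slope of log C(r) vs log r over the
    middle third of radii with 0 < C(r) < 1.  A constant series returns 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < embed_m * delay + 50:
        raise InsufficientDataError(
            f"correlation dimension needs >= {embed_m * delay + 50} points"
        )
    if np.std(x) == 0:
        return 0.0
    emb = _embed(x, embed_m, delay)
    d = pdist(emb)
    d = d[d > 0]
    if d.size == 0:
        return 0.0
    # anchor the grid at the 5th-percentile distance: near-recurrences in
    # periodic orbits otherwise collapse the usable scaling range
    lo = np.percentile(d, 5)
    radii = np.logspace(np.log10(lo), np.log10(d.max()), n_radii)
    c = np.searchsorted(np.sort(d), radii, side="left") / d.size
    valid = np.nonzero((c > 0) & (c < 1))[0]
    if valid.size < 3:
        return 0.0
    third = valid.size // 3
    mid = valid[third: valid.size - third] if valid.size >= 6 else valid
    return float(np.polyfit(np.log(radii[mid]), np.log(c[mid]), 1)[0])


# ---------------------------------------------------------------------------
# nonlinear: Poincare
# ---------------------------------------------------------------------------

def poincare(intervals_ms: np.ndarray) -> tuple[float, float]:
    """Poincare-plot dispersions SD1 (perpendicular to the identity line)
    and SD2 (along it).

    SD1 is computed as RMSSD/sqrt(2) and SD2 from the variance
    decomposition SD2^2 = 2*SDNN^2 - SD1^2, which makes both classical
    Poincare identities hold exactly under the sample-SD convention.
    """
    x = np.asarray(intervals_ms, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("Poincare descriptors need >= 3 intervals")
    d = np.diff(x)
    sd1 = float(np.sqrt(np.mean(d ** 2) / 2.0))
    sdnn = float(np.std(x, ddof=1))
    sd2_sq = 2.0 * sdnn ** 2 - sd1 ** 2
    return sd1, float(np.sqrt(max(sd2_sq, 0.0)))


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

def extract_features(
    rri: RRISeries | np.ndarray,
    entropy_params: EntropyParams = EntropyParams(),
    correct: bool = False,
) -> pd.Series:
    """Compute the canonical 20-feature vector for one phase.

    Accepts an :class:`RRISeries` or a bare interval array (ms).  With
    ``correct=True`` the automated artifact rule is applied first.  Returns
    a :class:`pandas.Series` indexed by :data:`FEATURE_NAMES`; an undefined
    sample entropy is reported as NaN.
    """
    if isinstance(rri, RRISeries):
        x = rri.intervals_ms
        context = f"{rri.participant_id}/v{rri.visit}/{rri.phase}"
    else:
        x = np.asarray(rri, dtype=float)
        context = "series"
    if correct:
        x, _ = correct_artifacts(x)
    try:
        out: dict[str, float] = {}
        out.update(time_domain_features(x))
        try:
            out.update(spectral_features(x))
        except InsufficientDataError:
            if np.std(x) > 0:
                raise
            # zero-variance series: band powers undefined, flagged as NaN
            for k in ("log_vlf", "log_lf", "log_hf", "log_tot",
                      "lf_nu", "hf_nu", "lf_hf"):
                out[k] = float("nan")
        sd1, sd2 = poincare(x)
        out["sd1"], out["sd2"] = sd1, sd2
        out["apen"] = approximate_entropy(x, entropy_params)
        out["sampen"] = sample_entropy(x, entropy_params)
        out["alpha1"], out["alpha2"] = dfa(x)
        out["cordim"] = correlation_dimension(x)
    except (InsufficientDataError, QualityError) as exc:
        raise type(exc)(f"{context}: {exc}") from exc
    return pd.Series([out[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES))


def extract_cohort_features(
    cohort,
    entropy_params: EntropyParams = EntropyParams(),
    correct: bool = True,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per (participant, visit, phase).

    Series failing quality screening are skipped with a warning; undefined
    sample entropies stay NaN for listwise handling downstream.
    """
    rows = []
    meta = []
    skipped = 0
    for s in cohort:
        try:
            feats = extract_features(s, entropy_params=entropy_params, correct=correct)
        except (QualityError, InsufficientDataError) as exc:
            warnings.warn(f"skipping series {s.key()}: {exc}", stacklevel=2)
            skipped += 1
            continue
        meta.append((s.participant_id, s.group, s.visit, s.phase))
        rows.append(feats)
    if not rows:
        raise InsufficientDataError("no series survived feature extraction")
    df = pd.DataFrame(
        meta, columns=["participant", "group", "visit", "phase"]
    ).join(pd.DataFrame(rows).reset_index(drop=True))
    if skipped:
        warnings.warn(f"{skipped} series skipped during extraction", stacklevel=2)
    return df
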