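"""Automated detection of transduction coverage signatures.

The detector formalizes the visual vocabulary used to read paired
coverage tracks: an induced prophage (or packaging-competent island) is a
sharply bounded high-coverage plateau in the VLP sample; specialized
transduction adds short declining host-DNA flanks next to such a plateau;
lateral transduction adds a one-sided decaying staircase spanning
hundreds of kbp; generalized transduction shows pac-site edges (vertical
coverage rise, slow decline downstream) without an induction plateau;
GTA-like packaging shows smooth genome-wide unevenness without sharp
edges.  Classification runs per contig on the normalized VLP track, with
the whole-community track used only as an assembly-sanity (evenness)
check and for the contamination rank screen.

Fold-change thresholds act on normalized (per-million) depths, so calls
are invariant under rescaling of sequencing effort; absolute coverage
gates act on raw depths and only control the ``confident`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .segmentation import binary_segmentation, estimate_noise_variance
from .tracks import CoverageTrack, NormalizedTrack, PairedCoverage, normalize_track

__all__ = [
    "DetectorParams",
    "Segment",
    "ElementCall",
    "PatternCall",
    "EvennessReport",
    "contig_baseline",
    "wgs_evenness",
    "segment_log_coverage",
    "edge_sharpness",
    "fit_decay_slope",
    "call_pac_sites",
    "estimate_headful_size",
    "estimate_transduction_frequency",
    "unevenness_ratio",
    "call_patterns",
    "MODE_PRECEDENCE",
]

MODE_PRECEDENCE = (
    "specialized",
    "lateral",
    "induction",
    "generalized",
    "gta_like",
    "unknown",
    "standard",
)


@dataclass
class DetectorParams:
    """Tunable thresholds of the pattern detector.

    Fold thresholds are unitless ratios of normalized depth over the
    contig baseline; coverage gates (``min_*_cov``) are raw ×fold read
    coverage.  Defaults reflect the magnitudes seen in the model systems:
    induced prophages sit orders of magnitude above baseline, genuine
    weak generalized signals peak around 10-fold, lateral decay spans
    several hundred kbp, and prophage induction remains recognizable down
    to ~20× plateau coverage.
    """

    pseudocount: float = 1.0            # normalized-depth units, for all log transforms
    min_plateau: int = 5_000            # bp
    max_plateau: int = 200_000          # bp
    induction_fold: float = 10.0        # plateau over baseline
    edge_window: int = 500              # bp, sharpness window
    edge_fold: float = 5.0              # sharp-edge threshold
    flank_fold: float = 3.0             # flank over baseline
    min_flank_extent: int = 1_000       # bp, shortest credible flank
    lateral_min_extent: int = 100_000   # bp, one-sided flank => lateral
    unevenness_fold: float = 5.0        # generalized unevenness threshold
    gta_min_unevenness: float = 2.0
    smooth_window: int = 10_000         # bp, for evenness/unevenness
    flank_smooth_window: int = 500      # bp, light smoothing for edges/flanks
    min_induction_cov: float = 20.0     # raw x-fold gate for confident plateaus
    min_flank_cov: float = 150.0        # raw x-fold gate for confident flanks
    min_gta_cov: float = 20.0           # raw mean gate for gta-like calls
    wgs_cv_max: float = 0.5
    segmentation_penalty: float = 30.0
    min_segment_bins: int = 3
    headful_scale: int = 44_000         # bp, decay-window scale for pac checks
    pac_max_slope: float = -0.01        # log2-fold per 10 kbp; must decay below this
    plateau_max_abs_slope: float = 0.05  # log2-fold per 10 kbp; plateaus are level
    edge_end_margin: int = 2_500        # bp; ignore edge candidates this close to contig ends
    flank_floor_quantile: float = 0.10  # reference level for flank walks

    def __post_init__(self) -> None:
        if self.min_plateau >= self.max_plateau:
            raise ValueError("min_plateau must be < max_plateau")
        for name in ("induction_fold", "edge_fold", "flank_fold", "unevenness_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must be > 1")


@dataclass
class Segment:
    """A segment of the VLP log-coverage segmentation, with features."""

    start: int            # bp, inclusive
    end: int              # bp, exclusive
    start_bin: int
    end_bin: int
    mean_vlp_norm: float
    fold_over_baseline: float
    left_edge_fold: float
    right_edge_fold: float
    decay_slope: float    # log2-fold per 10 kbp
    decay_r2: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ElementCall:
    """One detected mobilized element on a contig."""

    kind: str
    start: int
    end: int
    plateau_mean_norm: float = 0.0
    plateau_mean_raw: float = 0.0
    flanks: list[dict] = field(default_factory=list)
    frequency_ratio: Optional[float] = None
    headful: Optional[float] = None
    flags: set = field(default_factory=set)


@dataclass
class PatternCall:
    """Per-contig transduction verdict."""

    contig_id: str
    mode: str
    elements: list[ElementCall] = field(default_factory=list)
    pac_positions: list[int] = field(default_factory=list)
    headful_estimate: Optional[float] = None
    frequency_ratio: Optional[float] = None
    unevenness: float = 1.0
    baseline: float = 0.0
    wgs_cv: float = 0.0
    qc_flags: set = field(default_factory=set)

    @property
    def confident(self) -> bool:
        return not (self.qc_flags & {"low_coverage", "flank_below_gate"})


@dataclass
class EvennessReport:
    contig_id: str
    cv: float
    passed: bool


# ---------------------------------------------------------------------------
# helpers


def _as_norm(track: CoverageTrack) -> NormalizedTrack:
    return track if isinstance(track, NormalizedTrack) else normalize_track(track)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if w <= 1 or x.size == 0:
        return np.asarray(x, dtype=float).copy()
    cs = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(x.size)
    lo = np.maximum(0, idx - w // 2)
    hi = np.minimum(x.size, idx + w // 2 + 1)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _bins(track: CoverageTrack, bp: int) -> int:
    return max(1, int(round(bp / track.bin_size)))


# ---------------------------------------------------------------------------
# feature operations


def contig_baseline(vlp: CoverageTrack, params: DetectorParams | None = None) -> float:
    """Robust base level of the normalized VLP track.

    Median of the bins at or below the 90th percentile — robust against
    one large induced prophage occupying up to ~10% of the contig.
    """
    params = params or DetectorParams()
    x = _as_norm(vlp).norm_depths
    if x.size == 0:
        raise ValueError("empty track")
    thr = np.percentile(x, params.baseline_percentile if hasattr(params, "baseline_percentile") else 90.0)
    low = x[x <= thr]
    return float(np.median(low)) if low.size else float(np.median(x))


def wgs_evenness(wgs: CoverageTrack, params: DetectorParams | None = None) -> EvennessReport:
    """Coefficient of variation of the smoothed whole-community track.

    Even whole-community coverage is evidence of correct assembly; a high
    CV suggests a chimeric contig whose VLP pattern cannot be trusted.
    Failing contigs are still processed, only flagged.
    """
    params = params or DetectorParams()
    t = _as_norm(wgs)
    sm = _moving_average(t.norm_depths, _bins(t, params.smooth_window))
    mean = sm.mean()
    cv = float(sm.std() / mean) if mean > 0 else 0.0
    return EvennessReport(t.contig_id, cv, cv <= params.wgs_cv_max)


def edge_sharpness(
    track: CoverageTrack,
    boundary: int,
    edge_window: int | None = None,
    pseudocount: float = 1.0,
) -> tuple[float, bool]:
    """Fold change of mean depth across a boundary (after / before).

    Returns ``(fold, truncated)``; ``truncated`` is set when the boundary
    lies within one window of a contig end, in which case the fold is
    computed over the available bins.
    """
    t = _as_norm(track)
    w = _bins(t, edge_window or 500)
    b = int(boundary // t.bin_size)
    if not 0 <= b <= t.n_bins:
        raise ValueError("boundary outside contig")
    x = t.norm_depths
    lo = max(0, b - w)
    hi = min(t.n_bins, b + w)
    truncated = (b - lo < w) or (hi - b < w)
    before = x[lo:b].mean() if b > lo else 0.0
    after = x[b:hi].mean() if hi > b else 0.0
    return float((after + pseudocount) / (before + pseudocount)), truncated


def fit_decay_slope(
    track: CoverageTrack,
    interval: tuple[int, int],
    pseudocount: float = 1.0,
    *,
    reverse: bool = False,
) -> tuple[float, float]:
    """Least-squares decay slope of log2 coverage over an interval.

    Returns ``(slope, r2)`` with slope in log2-fold per 10 kbp measured
    *away* from the interval's reference edge (its left end, or its right
    end with ``reverse=True``); negative slope means decaying coverage.
    An all-zero interval returns ``(nan, nan)``.
    """
    t = _as_norm(track)
    b0, b1 = int(interval[0] // t.bin_size), int(-(-interval[1] // t.bin_size))
    x = t.norm_depths[b0:b1]
    if x.size < 2:
        return float("nan"), float("nan")
    if np.all(x == 0):
        return float("nan"), float("nan")
    y = np.log2(x + pseudocount)
    if reverse:
        y = y[::-1]
    if np.allclose(y, y[0]):
        return 0.0, 0.0
    pos = np.arange(y.size) * t.bin_size
    res = stats.linregress(pos, y)
    return float(res.slope * 10_000), float(res.rvalue**2)


def segment_log_coverage(
    vlp: CoverageTrack,
    params: DetectorParams | None = None,
    baseline: float | None = None,
) -> list[Segment]:
    """Change-point segmentation of log2(normalized VLP depth + pseudocount).

    Segments tile the contig; each is annotated with its mean normalized
    depth, fold over the contig baseline, edge sharpness at both
    boundaries and its internal decay slope.
    """
    params = params or DetectorParams()
    t = _as_norm(vlp)
    if baseline is None:
        baseline = contig_baseline(t, params)
    pc = params.pseudocount
    y = np.log2(t.norm_depths + pc)
    breaks = binary_segmentation(
        y,
        penalty=params.segmentation_penalty,
        min_size=params.min_segment_bins,
        sigma2=max(estimate_noise_variance(y), 0.01),
    )
    segments = []
    a = 0
    for b in breaks:
        start, end = a * t.bin_size, min(b * t.bin_size, t.contig_length)
        mean_norm = float(t.norm_depths[a:b].mean())
        lfold, _ = edge_sharpness(t, start, params.edge_window, pc)
        rfold, _ = edge_sharpness(t, end, params.edge_window, pc)
        slope, r2 = fit_decay_slope(t, (start, end), pc)
        segments.append(
            Segment(
                start=start, end=end, start_bin=a, end_bin=b,
                mean_vlp_norm=mean_norm,
                fold_over_baseline=(mean_norm + pc) / (baseline + pc),
                left_edge_fold=lfold,
                right_edge_fold=1.0 / rfold if rfold > 0 else float("inf"),
                decay_slope=slope, decay_r2=r2,
            )
        )
        a = b
    return segments


def estimate_transduction_frequency(plateau_mean: float, flank_max: float) -> float:
    """Transducing-particle frequency ratio N (meaning 1:N), 2 significant figures.

    The plateau coverage measures particles carrying the mobile element
    itself; the flank maximum measures particles carrying adjacent host
    DNA, so their ratio estimates how rare transducing particles are.
    """
    if flank_max <= 0:
        raise ValueError("flank_max must be > 0 (use the detection floor for a lower bound)")
    n = plateau_mean / flank_max
    if n <= 0 or not math.isfinite(n):
        return float("nan")
    digits = -int(math.floor(math.log10(abs(n)))) + 1
    return float(round(n, digits))


def unevenness_ratio(
    track: CoverageTrack,
    smooth_window: int = 10_000,
    pseudocount: float = 1.0,
) -> float:
    """Max/min ratio of the smoothed, pseudocount-floored normalized track."""
    t = _as_norm(track)
    sm = _moving_average(t.norm_depths, _bins(t, smooth_window))
    floored = np.maximum(sm, pseudocount)
    return float(floored.max() / floored.min())


def _directional_edge_folds(t: NormalizedTrack, params: DetectorParams):
    """Per-boundary upward fold for rightward ('+') and leftward ('-') rises."""
    pc = params.pseudocount
    # no pre-smoothing: the window means already average noise, and
    # smoothing would blur the edge position by half a smoothing window
    x = t.norm_depths
    w = _bins(t, params.edge_window)
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    b = np.arange(1, n)
    lo = np.maximum(0, b - w)
    hi = np.minimum(n, b + w)
    before = (cs[b] - cs[lo]) / (b - lo)
    after = (cs[hi] - cs[b]) / (hi - b)
    up_right = (after + pc) / (before + pc)
    return b, up_right, x


def call_pac_sites(track: CoverageTrack, params: DetectorParams | None = None) -> list[int]:
    """Positions of packaging-initiation (pac) sites on a VLP track.

    A pac site is a vertical coverage rise (edge fold at or above the
    sharp-edge threshold) followed by a declining staircase over at least
    two headful scales downstream; candidate edges within one headful of
    a stronger one are suppressed.  Rises facing either direction are
    detected.
    """
    params = params or DetectorParams()
    t = _as_norm(track)
    b, up_right, _ = _directional_edge_folds(t, params)
    candidates = []  # (fold, boundary_bin, direction)
    for direction, fold in (("right", up_right), ("left", 1.0 / up_right)):
        above = fold >= params.edge_fold
        if not np.any(above):
            continue
        w = _bins(t, params.edge_window)
        for i in np.flatnonzero(above):
            lo, hi = max(0, i - w), min(fold.size, i + w + 1)
            if fold[i] == fold[lo:hi].max():
                candidates.append((float(fold[i]), int(b[i]), direction))
    # strongest first; suppress within one headful scale
    candidates.sort(key=lambda c: (-c[0], c[1]))
    kept: list[tuple[int, str]] = []
    min_gap = params.headful_scale
    for foldv, bb, direction in candidates:
        pos = bb * t.bin_size
        # coverage ramps at linear-contig ends are not packaging edges
        if pos < params.edge_end_margin or pos > t.contig_length - params.edge_end_margin:
            continue
        if any(abs(pos - p) < min_gap for p, _ in kept):
            continue
        span = 2 * params.headful_scale
        if direction == "right":
            iv = (pos, min(pos + span, t.contig_length))
            slope, _ = fit_decay_slope(t, iv, params.pseudocount)
        else:
            iv = (max(0, pos - span), pos)
            slope, _ = fit_decay_slope(t, iv, params.pseudocount, reverse=True)
        if np.isfinite(slope) and slope <= params.pac_max_slope:
            kept.append((pos, direction))
    return sorted(p for p, _ in kept)


def estimate_headful_size(
    track: CoverageTrack,
    interval: tuple[int, int],
    params: DetectorParams | None = None,
) -> float:
    """Dominant step period (bp) of a packaging staircase, or NaN.

    Uses the autocorrelation of the first difference of log2 coverage
    within the interval: processive headful packaging leaves equally
    spaced, equally sized (in log space) downward steps, so the
    difference signal is an impulse train whose autocorrelation peaks at
    the headful size.  Returns NaN, signalling no periodicity above the
    noise floor, when no significant peak exists.
    """
    params = params or DetectorParams()
    t = _as_norm(track)
    b0, b1 = int(interval[0] // t.bin_size), int(-(-interval[1] // t.bin_size))
    x = t.norm_depths[b0:b1]
    if x.size < 30:
        return float("nan")
    pc = params.pseudocount
    # analyse only the well-covered part: once depth falls into the noise
    # floor the log signal is step-free and only adds noise
    floor = max(3 * pc, 0.02 * x.max())
    covered = np.flatnonzero(_moving_average(x, 5) >= floor)
    if covered.size >= 30:
        x = x[: covered[-1] + 1]
    y = np.log2(x + pc)
    d = np.diff(y)
    if d.size < 20 or np.allclose(d, 0):
        return float("nan")
    d = d - d.mean()
    ac = np.correlate(d, d, mode="full")[d.size - 1 :]
    min_lag = max(5, _bins(t, 1_000))
    max_lag = d.size // 2
    if max_lag <= min_lag:
        return float("nan")
    window = ac[min_lag:max_lag]
    peak_i = int(np.argmax(window)) + min_lag
    med = float(np.median(window))
    mad = float(np.median(np.abs(window - med)))
    if mad <= 0:
        return float("nan")
    z = (ac[peak_i] - med) / (1.4826 * mad)
    if z < 5.0:
        return float("nan")
    # prefer the fundamental over a harmonic (octave error): if a
    # sub-multiple lag carries a comparable peak, take the smallest one
    best = peak_i
    for k in (4, 3, 2):
        cand = int(round(peak_i / k))
        if cand < min_lag:
            continue
        lo, hi = max(min_lag, cand - 2), cand + 3
        local = int(np.argmax(ac[lo:hi])) + lo
        if ac[local] >= 0.5 * ac[peak_i]:
            best = local
            break
    return float(best * t.bin_size)


# ---------------------------------------------------------------------------
# classification cascade


def _merge_plateaus(
    segments: list[Segment],
    params: DetectorParams,
    baseline: float,
) -> list[tuple[int, int]]:
    """Candidate plateau intervals: runs of adjacent same-level segments.

    Adjacent segments are grouped while their mean depths stay within one
    sharp-edge fold of each other (a plateau is internally level; its
    boundaries are the sharp edges).  A group qualifies as a plateau
    candidate when its overall mean is at least ``induction_fold`` over
    the contig baseline; declining flanks and staircases fail either the
    grouping or the later edge/flatness criteria.
    """
    pc = params.pseudocount
    groups: list[list[Segment]] = [[segments[0]]]
    for seg in segments[1:]:
        prev = groups[-1][-1]
        hi = max(prev.mean_vlp_norm, seg.mean_vlp_norm) + pc
        lo = min(prev.mean_vlp_norm, seg.mean_vlp_norm) + pc
        if hi / lo < params.edge_fold:
            groups[-1].append(seg)
        else:
            groups.append([seg])
    intervals = []
    for g in groups:
        length = g[-1].end - g[0].start
        mean = sum(s.mean_vlp_norm * s.length for s in g) / length
        if (mean + pc) / (baseline + pc) >= params.induction_fold:
            intervals.append((g[0].start, g[-1].end))
    return intervals


def _analyse_flank(
    t: NormalizedTrack,
    raw_sm: np.ndarray,
    norm_sm: np.ndarray,
    edge_bin: int,
    side: str,
    baseline: float,
    params: DetectorParams,
    blocked: Sequence[tuple[int, int]],
) -> dict | None:
    """Walk outward from a plateau edge while coverage stays above the
    flank threshold; returns flank features or None if no flank."""
    pc = params.pseudocount
    thr = params.flank_fold * (baseline + pc) - pc
    guard = _bins(t, params.flank_smooth_window)
    n = t.n_bins
    blocked_bins = [(s // t.bin_size, -(-e // t.bin_size)) for s, e in blocked]

    def in_blocked(i):
        return any(s <= i < e for s, e in blocked_bins)

    step = 1 if side == "right" else -1
    i = edge_bin + step * guard
    last_good = None
    truncated = False
    while 0 <= i < n:
        if in_blocked(i):
            break
        if norm_sm[i] < thr:
            break
        last_good = i
        i += step
    if i < 0 or i >= n:
        truncated = True
    if last_good is None:
        return None
    if side == "right":
        b0, b1 = edge_bin + guard, last_good + 1
        extent = (last_good + 1 - edge_bin) * t.bin_size
        iv = (b0 * t.bin_size, b1 * t.bin_size)
        slope, r2 = fit_decay_slope(t, iv, pc)
    else:
        b0, b1 = last_good, edge_bin - guard + 1
        extent = (edge_bin + 1 - last_good) * t.bin_size
        iv = (b0 * t.bin_size, b1 * t.bin_size)
        slope, r2 = fit_decay_slope(t, iv, pc, reverse=True)
    if b1 <= b0:
        return None
    return {
        "side": side,
        "extent": int(extent),
        "interval": iv,
        "max_norm": float(norm_sm[b0:b1].max()),
        "max_raw": float(raw_sm[b0:b1].max()),
        "slope": slope,
        "r2": r2,
        "truncated": truncated,
    }


def call_patterns(
    paired: PairedCoverage,
    params: DetectorParams | None = None,
) -> PatternCall:
    """Classify one contig's paired coverage into a transduction mode.

    Decision cascade: (1) whole-community evenness (flag only);
    (2) induction plateaus: sharply bounded high-fold segments of
    plateau-like length; (3) specialized: plateau plus short declining
    flank(s) well below the plateau; (4) lateral: plateau plus a
    one-sided decaying flank spanning at least ``lateral_min_extent``;
    (5) generalized: pac-site calls with strong unevenness but no
    plateau; (6) GTA-like: smooth unevenness with no sharp edges;
    (7) standard: flat/low VLP coverage; anything else is ``unknown``.
    The contig-level mode is the highest-precedence element call.
    """
    params = params or DetectorParams()
    pc = params.pseudocount
    wgs_n = _as_norm(paired.wgs)
    vlp_n = _as_norm(paired.vlp)
    even = wgs_evenness(wgs_n, params)
    baseline = contig_baseline(vlp_n, params)
    qc: set = set()
    if not even.passed:
        qc.add("wgs_uneven")

    segments = segment_log_coverage(vlp_n, params, baseline=baseline)
    plateau_ivs = [
        (s, e) for s, e in _merge_plateaus(segments, params, baseline)
        if params.min_plateau <= e - s <= params.max_plateau
    ]

    norm_sm = _moving_average(vlp_n.norm_depths, _bins(vlp_n, params.flank_smooth_window))
    raw_sm = _moving_average(vlp_n.depths, _bins(vlp_n, params.flank_smooth_window))
    elements: list[ElementCall] = []

    confirmed: list[ElementCall] = []
    for s, e in plateau_ivs:
        b0, b1 = s // vlp_n.bin_size, -(-e // vlp_n.bin_size)
        lfold, ltrunc = edge_sharpness(vlp_n, s, params.edge_window, pc)
        rfold, rtrunc = edge_sharpness(vlp_n, e, params.edge_window, pc)
        rfold = 1.0 / rfold if rfold > 0 else float("inf")
        left_ok = lfold >= params.edge_fold or (ltrunc and s <= params.edge_window)
        right_ok = rfold >= params.edge_fold or (rtrunc and e >= vlp_n.contig_length - params.edge_window)
        if not (left_ok and right_ok):
            continue
        # a truncated decaying staircase is not a plateau: require flatness
        slope, _r2 = fit_decay_slope(vlp_n, (s, e), pc)
        if np.isfinite(slope) and abs(slope) > params.plateau_max_abs_slope:
            continue
        el = ElementCall(kind="induction", start=int(s), end=int(e))
        el.plateau_mean_norm = float(vlp_n.norm_depths[b0:b1].mean())
        el.plateau_mean_raw = float(vlp_n.depths[b0:b1].mean())
        if ltrunc or rtrunc or s == 0 or e >= vlp_n.contig_length:
            el.flags.add("truncated_at_end")
        if el.plateau_mean_raw < params.min_induction_cov:
            el.flags.add("low_coverage")
        confirmed.append(el)

    # reference level for flank walks: the low quantile / smoothed minimum
    # stay near the true background even when a lateral staircase covers
    # most of the contig (the sub-90th-percentile median does not)
    sm10 = _moving_average(vlp_n.norm_depths, _bins(vlp_n, params.smooth_window))
    flank_floor = min(
        baseline,
        float(np.quantile(vlp_n.norm_depths, params.flank_floor_quantile)),
        float(sm10.min()),
    )
    for el in confirmed:
        s, e = el.start, el.end
        b0, b1 = s // vlp_n.bin_size, -(-e // vlp_n.bin_size)
        others = [(o.start, o.end) for o in confirmed if o is not el]
        spec_sides, lateral_sides = [], []
        for side, edge_bin in (("left", b0), ("right", b1 - 1)):
            flank = _analyse_flank(
                vlp_n, raw_sm, norm_sm, edge_bin, side, flank_floor, params, others,
            )
            if flank is None:
                continue
            if flank["max_norm"] > el.plateau_mean_norm / 10:
                # plateau bleed or adjacent element, not a low-frequency flank
                continue
            el.flanks.append(flank)
            if flank["extent"] >= params.lateral_min_extent and flank["slope"] < 0:
                lateral_sides.append(flank)
            elif flank["extent"] >= params.min_flank_extent:
                spec_sides.append(flank)
        if lateral_sides:
            el.kind = "lateral"
            best = max(lateral_sides, key=lambda f: f["max_norm"])
            el.frequency_ratio = estimate_transduction_frequency(
                el.plateau_mean_norm, best["max_norm"]
            )
            el.headful = estimate_headful_size(vlp_n, best["interval"], params)
            if best["truncated"]:
                el.flags.add("truncated_at_end")
        elif spec_sides:
            el.kind = "specialized"
            best = max(spec_sides, key=lambda f: f["max_norm"])
            el.frequency_ratio = estimate_transduction_frequency(
                el.plateau_mean_norm, best["max_norm"]
            )
            if all(f["max_raw"] < params.min_flank_cov for f in spec_sides):
                el.flags.add("flank_below_gate")
        elements.append(el)

    call = PatternCall(
        contig_id=paired.contig_id,
        mode="standard",
        elements=elements,
        baseline=baseline,
        wgs_cv=even.cv,
        qc_flags=qc,
    )
    call.unevenness = unevenness_ratio(vlp_n, params.smooth_window, pc)

    if elements:
        for el in elements:
            call.qc_flags |= el.flags
        kinds = {el.kind for el in elements}
        call.mode = next(m for m in MODE_PRECEDENCE if m in kinds)
        for m in MODE_PRECEDENCE:
            els = [el for el in elements if el.kind == m and el.frequency_ratio]
            if els:
                call.frequency_ratio = els[0].frequency_ratio
                break
        headfuls = [el.headful for el in elements if el.headful and np.isfinite(el.headful)]
        if headfuls:
            call.headful_estimate = float(np.median(headfuls))
        return call

    # no plateau: generalized / GTA-like / standard / unknown
    pac = call_pac_sites(vlp_n, params)
    unev = call.unevenness
    b, up_right, _ = _directional_edge_folds(vlp_n, params)
    margin_bins = _bins(vlp_n, params.edge_end_margin)
    interior = (b >= margin_bins) & (b <= vlp_n.n_bins - margin_bins)
    if np.any(interior):
        ur = up_right[interior]
        max_edge = float(np.maximum(ur, 1.0 / ur).max())
    else:
        max_edge = 1.0
    mean_raw = float(vlp_n.depths.mean())
    max_raw_sm = float(raw_sm.max()) if raw_sm.size else 0.0

    if pac and unev >= params.unevenness_fold:
        call.mode = "generalized"
        call.pac_positions = pac
        if max_raw_sm < params.min_induction_cov:
            call.qc_flags.add("low_coverage")
        # headful from the strongest site's downstream staircase
        heads = []
        bounds = pac + [vlp_n.contig_length]
        for i, p in enumerate(pac):
            h = estimate_headful_size(vlp_n, (p, bounds[i + 1]), params)
            if np.isfinite(h):
                heads.append(h)
        if heads:
            call.headful_estimate = float(np.median(heads))
    elif not pac and unev >= params.gta_min_unevenness and max_edge < params.edge_fold:
        if mean_raw >= params.min_gta_cov:
            call.mode = "gta_like"
        else:
            call.mode = "standard"
    elif unev < params.gta_min_unevenness:
        call.mode = "standard"
    else:
        call.mode = "unknown"
    return call
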