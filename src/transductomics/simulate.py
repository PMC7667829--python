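"""Mechanistic simulator of DNA packaging into virus-like particles.

The simulator draws individual packaged DNA fragments for every
transduction mode with a characteristic coverage signature:

* **prophage induction** — particles carrying the excised phage genome,
  producing a sharply bounded coverage plateau over the prophage;
* **specialized transduction** — rare imprecise-excision particles that
  keep part of the phage genome and carry adjacent host DNA; the flank
  extent is drawn uniformly up to a maximum set by the capsid capacity,
  giving a finite flank with linearly declining expected coverage;
* **lateral / generalized transduction** — processive headful packaging
  from an initiation (*pac*) site: a particle carries the k-th headful
  ``[s + (k-1)H, s + kH)`` with geometric probability
  ``P(k) = q^(k-1) (1-q)``, producing the decaying coverage staircase;
* **GTA-like packaging** — fixed-size quasi-random fragments whose start
  density may follow a smooth positive bias field, optionally depleted
  over the GTA's own gene cluster.

Besides sampled fragments the module provides the closed-form expected
coverage for the same model, a whole-community (WGS) track generator with
an optional origin-of-replication gradient and Poisson noise, and named
ground-truthed fixtures that emulate the classical model systems
(λ, P22, P1, PBSX, enterococcal prophages) plus a synthetic community.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .tracks import CoverageTrack, NormalizedTrack, PairedCoverage, _bin_widths, _n_bins

__all__ = [
    "ProphageElement",
    "PacSite",
    "GTAParams",
    "GenomeModel",
    "FragmentSet",
    "TruthLabel",
    "simulate_fragments",
    "expected_coverage",
    "fragments_to_coverage",
    "simulate_wgs_track",
    "make_fixture",
    "load_model_yaml",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = (
    "lambda_like",
    "p22_like",
    "p1_like",
    "pbsx_like",
    "faecalis_like",
    "community_like",
)


@dataclass
class ProphageElement:
    """An integrated prophage (or prophage-like island) and its packaging rates.

    Rates are relative weights in the particle-type distribution of the
    genome: a pool of ``n`` particles contains on average
    ``n * rate / total_rate`` particles of each type.
    """

    start: int
    end: int
    induction_rate: float = 1.0
    #: probability that an induction particle is an imprecise-excision
    #: (specialized transducing) particle.
    specialized_rate: float = 0.0
    #: capsid capacity in bp; also the headful size of the element's
    #: packaging machinery.  Defaults to the element length.
    capsid_capacity: Optional[int] = None
    #: maximum host-DNA flank extent of a specialized particle (bp);
    #: bounded by the capsid capacity minus retained phage DNA.
    max_flank: Optional[int] = None
    #: probability a specialized particle extends over the LEFT edge.
    side_bias: float = 0.5
    #: relative weight of in-situ (lateral) headful initiation at one edge.
    lateral_rate: float = 0.0
    lateral_direction: str = "right"
    #: per-headful continuation probability of the lateral machinery.
    continuation_prob: float = 0.5
    element_id: str = "prophage"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.element_id}: empty interval")
        if self.capsid_capacity is None:
            self.capsid_capacity = self.end - self.start
        if self.max_flank is None:
            self.max_flank = self.capsid_capacity // 2
        if not 0.0 <= self.specialized_rate <= 1.0:
            raise ValueError(f"{self.element_id}: specialized_rate outside [0, 1]")
        if self.capsid_capacity <= 0:
            raise ValueError(f"{self.element_id}: capsid_capacity must be > 0")
        if self.max_flank > self.capsid_capacity:
            raise ValueError(f"{self.element_id}: max_flank exceeds capsid capacity")
        if self.lateral_rate > 0 and not 0.0 < self.continuation_prob < 1.0:
            raise ValueError(f"{self.element_id}: continuation_prob must be in (0, 1)")
        if self.lateral_direction not in ("left", "right"):
            raise ValueError(f"{self.element_id}: lateral_direction must be left/right")


@dataclass
class PacSite:
    """A packaging-initiation site on the host genome."""

    position: int
    initiation_rate: float = 1.0
    headful: int = 44_000
    continuation_prob: float = 0.5
    direction: str = "right"
    site_id: str = "pac"

    def __post_init__(self) -> None:
        if self.headful <= 0:
            raise ValueError(f"{self.site_id}: headful must be > 0")
        if not 0.0 < self.continuation_prob < 1.0:
            raise ValueError(f"{self.site_id}: continuation_prob must be in (0, 1)")
        if self.direction not in ("left", "right"):
            raise ValueError(f"{self.site_id}: direction must be left/right")


@dataclass
class GTAParams:
    """Gene-transfer-agent-like random packaging of fixed-size fragments."""

    fragment_size: int = 13_000
    #: relative weight of the GTA channel in the particle-type distribution.
    rate: float = 1.0
    #: smooth positive per-bin start-rate multiplier (mean 1), or None for flat.
    bias_field: Optional[np.ndarray] = None
    #: bin width in bp of the bias field grid.
    bias_bin: int = 1_000
    #: interval with reduced packaging rate (the GTA's own gene cluster).
    self_exclusion: Optional[tuple[int, int]] = None
    self_exclusion_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.fragment_size <= 0:
            raise ValueError("fragment_size must be > 0")
        if self.bias_field is not None:
            self.bias_field = np.asarray(self.bias_field, dtype=float)
            if np.any(self.bias_field < 0):
                raise ValueError("bias_field must be non-negative")
            m = self.bias_field.mean()
            if m <= 0:
                raise ValueError("bias_field must have positive mean")
            self.bias_field = self.bias_field / m


@dataclass
class GenomeModel:
    """Layout of mobile elements on one (model) genome/contig."""

    genome_length: int
    circular: bool = False
    prophages: list[ProphageElement] = field(default_factory=list)
    pac_sites: list[PacSite] = field(default_factory=list)
    gta: Optional[GTAParams] = None
    ori_position: int = 0
    contig_id: str = "contig"

    def __post_init__(self) -> None:
        for p in self.prophages:
            if not (0 <= p.start < p.end <= self.genome_length):
                raise ValueError(
                    f"{self.contig_id}/{p.element_id}: interval outside genome"
                )
        for s in self.pac_sites:
            if not 0 <= s.position < self.genome_length:
                raise ValueError(
                    f"{self.contig_id}/{s.site_id}: pac position outside genome"
                )

    def channel_weights(self) -> list[tuple[str, int, float]]:
        """(kind, element index, weight) for every particle-type channel."""
        channels: list[tuple[str, int, float]] = []
        for i, p in enumerate(self.prophages):
            if p.induction_rate > 0:
                channels.append(("induction", i, p.induction_rate))
            if p.lateral_rate > 0:
                channels.append(("lateral", i, p.lateral_rate))
        for j, s in enumerate(self.pac_sites):
            if s.initiation_rate > 0:
                channels.append(("pac", j, s.initiation_rate))
        if self.gta is not None and self.gta.rate > 0:
            channels.append(("gta", 0, self.gta.rate))
        return channels


@dataclass
class FragmentSet:
    """Packaged DNA intervals with per-fragment provenance.

    ``starts`` lie in ``[0, genome_length)``; on circular genomes ``ends``
    may exceed ``genome_length``, meaning the fragment wraps the origin.
    """

    genome_length: int
    circular: bool
    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray  # provenance "mode:element_id" per fragment

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        if np.any(self.ends <= self.starts):
            raise ValueError("empty fragment")
        if np.any(self.starts < 0) or np.any(self.starts >= self.genome_length):
            raise ValueError("fragment start outside genome")
        if not self.circular and np.any(self.ends > self.genome_length):
            raise ValueError("fragment end outside linear genome")

    def __len__(self) -> int:
        return self.starts.shape[0]

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def subsample(self, fraction: float, seed: int) -> "FragmentSet":
        """Binomial thinning of the particle pool (models read downsampling)."""
        rng = np.random.default_rng(seed)
        keep = rng.random(len(self)) < fraction
        return FragmentSet(
            self.genome_length, self.circular,
            self.starts[keep], self.ends[keep], self.labels[keep],
        )

    def to_bed(self, path: str | Path, contig_id: str = "contig") -> None:
        """Write fragments as BED6 (provenance in the name column)."""
        with open(path, "w") as fh:
            for s, e, lab in zip(self.starts, self.ends, self.labels):
                if e <= self.genome_length:
                    fh.write(f"{contig_id}\t{s}\t{e}\t{lab}\t0\t+\n")
                else:  # wrapped fragment: two BED lines
                    fh.write(f"{contig_id}\t{s}\t{self.genome_length}\t{lab}\t0\t+\n")
                    fh.write(f"{contig_id}\t0\t{e - self.genome_length}\t{lab}\t0\t+\n")


@dataclass
class TruthLabel:
    """Ground truth for one simulated contig (detector test scaffolding)."""

    contig_id: str
    mode: str  # contig-level mode (highest-precedence element)
    elements: list[dict] = field(default_factory=list)
    contamination: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# fragment sampling


def _truncate_linear(starts, ends, genome_length):
    starts = np.clip(starts, 0, genome_length)
    ends = np.clip(ends, 0, genome_length)
    keep = ends > starts
    return starts[keep], ends[keep], keep


def simulate_fragments(model: GenomeModel, n_particles: int, seed: int) -> FragmentSet:
    """Draw ``n_particles`` packaged fragments from the model's particle-type mix.

    Each particle is one of: an induced-phage-genome particle (the exact
    prophage interval), an imprecise-excision particle (capsid-capacity
    fragment spanning one prophage edge, flank extent uniform on
    ``[0, max_flank)``), a lateral/generalized headful (the k-th headful
    downstream of the initiation point, ``k`` geometric), or a GTA
    fragment (fixed size, start drawn from the bias field).  Circular
    genomes wrap; linear genomes truncate fragments at the ends.
    """
    if n_particles <= 0:
        raise ValueError("n_particles must be > 0")
    channels = model.channel_weights()
    if not channels:
        raise ValueError("model has no active packaging channel")
    rng = np.random.default_rng(seed)
    weights = np.array([w for _, _, w in channels], dtype=float)
    counts = rng.multinomial(n_particles, weights / weights.sum())

    L = model.genome_length
    all_starts: list[np.ndarray] = []
    all_ends: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []

    def emit(starts, ends, label):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if model.circular:
            # normalize starts into [0, L); ends may exceed L (wrap)
            shift = starts % L
            ends = ends + (shift - starts)
            starts = shift
            keep = ends > starts
            starts, ends = starts[keep], ends[keep]
        else:
            starts, ends, keep = _truncate_linear(starts, ends, L)
        if starts.size:
            all_starts.append(starts)
            all_ends.append(ends)
            all_labels.append(np.full(starts.size, label, dtype=object))

    for (kind, idx, _), c in zip(channels, counts):
        if c == 0:
            continue
        if kind == "induction":
            p = model.prophages[idx]
            spec = rng.random(c) < p.specialized_rate
            n_spec = int(spec.sum())
            n_phage = c - n_spec
            if n_phage:
                emit(
                    np.full(n_phage, p.start),
                    np.full(n_phage, p.end),
                    f"phage:{p.element_id}",
                )
            if n_spec:
                G = p.capsid_capacity
                extent = rng.integers(0, max(p.max_flank, 1), size=n_spec)
                left = rng.random(n_spec) < p.side_bias
                starts = np.where(left, p.start - extent, p.end + extent - G)
                ends = starts + G
                emit(starts, ends, f"specialized:{p.element_id}")
        elif kind in ("lateral", "pac"):
            if kind == "lateral":
                p = model.prophages[idx]
                H = p.capsid_capacity
                q = p.continuation_prob
                direction = p.lateral_direction
                origin = p.end if direction == "right" else p.start
                label = f"lateral:{p.element_id}"
            else:
                s = model.pac_sites[idx]
                H, q, direction, origin = s.headful, s.continuation_prob, s.direction, s.position
                label = f"generalized:{s.site_id}"
            k = rng.geometric(1.0 - q, size=c)  # P(k) = q^(k-1)(1-q), k >= 1
            if direction == "right":
                starts = origin + (k - 1) * H
                ends = starts + H
            else:
                ends = origin - (k - 1) * H
                starts = ends - H
            emit(starts, ends, label)
        else:  # gta
            g = model.gta
            F = g.fragment_size
            dens = _gta_start_density(model)
            starts = _sample_from_density(rng, dens, c, L)
            emit(starts, starts + F, "gta:gta")

    return FragmentSet(
        genome_length=L,
        circular=model.circular,
        starts=np.concatenate(all_starts),
        ends=np.concatenate(all_ends),
        labels=np.concatenate(all_labels),
    )


def _gta_start_density(model: GenomeModel) -> np.ndarray:
    """Per-base GTA fragment-start density (sums to 1) on the genome."""
    g = model.gta
    L = model.genome_length
    if g.bias_field is None:
        dens = np.ones(L)
    else:
        # piecewise-constant per bias bin, resampled to base resolution
        idx = np.minimum(np.arange(L) // g.bias_bin, g.bias_field.size - 1)
        dens = g.bias_field[idx].astype(float).copy()
    if g.self_exclusion is not None:
        s, e = g.self_exclusion
        dens[s:e] *= g.self_exclusion_factor
    return dens / dens.sum()


def _sample_from_density(rng, dens, n, L):
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    return np.searchsorted(cdf, rng.random(n), side="left").astype(np.int64)


# ---------------------------------------------------------------------------
# coverage


def fragments_to_coverage(
    fragments: FragmentSet,
    genome_length: int | None = None,
    bin_size: int = 100,
    circular: bool | None = None,
    *,
    contig_id: str = "contig",
    total_mapped: float | None = None,
    source: str = "vlp",
) -> CoverageTrack:
    """Exact per-base fragment-overlap counts, averaged into bins."""
    L = genome_length if genome_length is not None else fragments.genome_length
    circ = circular if circular is not None else fragments.circular
    diff = np.zeros(L + 1)
    starts, ends = fragments.starts, fragments.ends
    wrap = ends > L
    if np.any(wrap):
        if not circ:
            raise ValueError("wrapped fragments on a linear genome")
        # a wrapped fragment [s, e) covers [s, L) plus [0, e - L)
        np.add.at(diff, starts[wrap], 1.0)
        diff[L] -= int(wrap.sum())
        diff[0] += int(wrap.sum())
        np.add.at(diff, ends[wrap] - L, -1.0)
    inb = ~wrap
    np.add.at(diff, starts[inb], 1.0)
    np.add.at(diff, ends[inb], -1.0)
    per_base = np.cumsum(diff[:-1])
    return _bin_per_base(
        per_base, L, bin_size, contig_id,
        total_mapped if total_mapped is not None else float(len(fragments)),
        source,
    )


def _bin_per_base(per_base, L, bin_size, contig_id, total_mapped, source):
    n = _n_bins(L, bin_size)
    pad = n * bin_size - L
    mass = np.concatenate([per_base, np.zeros(pad)]).reshape(n, bin_size).sum(axis=1)
    depths = mass / _bin_widths(L, bin_size)
    return CoverageTrack(
        contig_id=contig_id, contig_length=L, bin_size=bin_size,
        depths=depths, total_mapped=total_mapped, source=source,
    )


def expected_coverage(
    model: GenomeModel,
    n_particles: int,
    bin_size: int = 100,
    *,
    contig_id: str | None = None,
    total_mapped: float | None = None,
) -> CoverageTrack:
    """Closed-form expected per-base coverage of the particle pool, binned.

    The expectation mirrors :func:`simulate_fragments` exactly: induced
    plateau at the induction particle count; specialized flank at
    distance ``d`` from the prophage edge decaying as
    ``P(extent > d) = (max_flank - 1 - d) / max_flank``; headful channels
    decaying as ``q**floor(d / H)`` downstream of the initiation point
    (wrapped on circular genomes); GTA coverage as the start-density
    convolved with the fragment length.
    """
    channels = model.channel_weights()
    L = model.genome_length
    exp = np.zeros(L)
    if channels:
        weights = np.array([w for _, _, w in channels], dtype=float)
        weights = weights / weights.sum()
        for (kind, idx, _), w in zip(channels, weights):
            n_ch = n_particles * w
            if kind == "induction":
                p = model.prophages[idx]
                exp[p.start : p.end] += n_ch * (1.0 - p.specialized_rate)
                n_spec = n_ch * p.specialized_rate
                if n_spec > 0 and p.max_flank > 0:
                    _add_specialized_expectation(exp, p, n_spec, model)
            elif kind in ("lateral", "pac"):
                if kind == "lateral":
                    p = model.prophages[idx]
                    H, q = p.capsid_capacity, p.continuation_prob
                    direction = p.lateral_direction
                    origin = p.end if direction == "right" else p.start
                else:
                    s = model.pac_sites[idx]
                    H, q, direction, origin = (
                        s.headful, s.continuation_prob, s.direction, s.position,
                    )
                _add_headful_expectation(exp, L, model.circular, origin, direction, H, q, n_ch)
            else:
                g = model.gta
                dens = _gta_start_density(model)
                exp += n_ch * _box_coverage(dens, g.fragment_size, model.circular)
    return _bin_per_base(
        exp, L, bin_size,
        contig_id if contig_id is not None else model.contig_id,
        total_mapped if total_mapped is not None else float(n_particles),
        "vlp",
    )


def _add_specialized_expectation(exp, p: ProphageElement, n_spec: float, model: GenomeModel):
    L = model.genome_length
    G, M = p.capsid_capacity, p.max_flank
    d = np.arange(M)
    p_cover_flank = (M - 1 - d) / M  # P(extent > d), extent ~ UniformInt[0, M)
    for side, w_side, edge in (("left", p.side_bias, p.start), ("right", 1 - p.side_bias, p.end)):
        if w_side <= 0:
            continue
        # host flank
        if side == "left":
            pos = edge - 1 - d
        else:
            pos = edge + d
        contrib = n_spec * w_side * p_cover_flank
        _scatter(exp, pos, contrib, L, model.circular)
        # retained phage DNA adjacent to the chosen edge
        dd = np.arange(min(G, p.end - p.start))
        p_cover_in = np.minimum(1.0, (G - dd) / M)  # P(extent < G - dd)
        if side == "left":
            pos_in = p.start + dd
        else:
            pos_in = p.end - 1 - dd
        _scatter(exp, pos_in, n_spec * w_side * p_cover_in, L, model.circular)


def _scatter(exp, pos, contrib, L, circular):
    if circular:
        np.add.at(exp, pos % L, contrib)
    else:
        ok = (pos >= 0) & (pos < L)
        np.add.at(exp, pos[ok], contrib[ok])


def _add_headful_expectation(exp, L, circular, origin, direction, H, q, n_ch):
    # The k-th headful covers exactly the distances d in [(k-1)H, kH), so
    # P(a particle covers distance d) = P(k = d//H + 1) = q**(d//H) * (1-q).
    # On circular genomes distances wrap; extend until the tail is negligible.
    if circular:
        n_headfuls = int(np.ceil(np.log(1e-9) / np.log(q))) + 1
        max_d = max(L, n_headfuls * H)
    else:
        max_d = L
    d = np.arange(max_d, dtype=np.int64)
    contrib = n_ch * np.power(q, d // H) * (1.0 - q)
    if direction == "right":
        pos = origin + d
    else:
        pos = origin - 1 - d
    _scatter(exp, pos, contrib, L, circular)


def _box_coverage(dens: np.ndarray, F: int, circular: bool) -> np.ndarray:
    """P(a fragment covers base x) for start density ``dens`` and length F."""
    L = dens.size
    if circular:
        Fc = min(F, L)
        # coverage at x = sum of dens over starts s in (x - Fc, x], wrapped
        ext = np.concatenate([dens[L - Fc:], dens])  # index s + Fc, s in [-Fc, L)
        cs = np.concatenate([[0.0], np.cumsum(ext)])
        x = np.arange(L)
        cov = cs[x + Fc + 1] - cs[x + 1]
        if F >= L:
            cov += float(F // L - 1) + 0.0  # full extra laps cover every base
        return cov
    cs = np.concatenate([[0.0], np.cumsum(dens)])
    x = np.arange(L)
    lo = np.maximum(0, x - F + 1)
    return cs[x + 1] - cs[lo]


def simulate_wgs_track(
    genome_length: int,
    mean_depth: float,
    *,
    bin_size: int = 100,
    ori_gradient: float = 1.0,
    ori_position: int = 0,
    circular: bool = False,
    noise: bool = True,
    seed: int = 0,
    contig_id: str = "contig",
    total_mapped: float = 1e6,
) -> CoverageTrack:
    """Whole-community coverage: even, with an optional ori→terminus gradient.

    The expected depth follows a log-linear ramp spanning ``ori_gradient``
    fold between the replication origin and the terminus, rescaled to the
    requested genome-wide mean.  With ``noise`` on, each bin is drawn as
    ``Poisson(expected depth)``, so the per-bin variance equals the mean.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if ori_gradient < 1:
        raise ValueError("ori_gradient must be >= 1")
    n = _n_bins(genome_length, bin_size)
    centers = (np.arange(n) + 0.5) * bin_size
    if circular:
        dist = np.minimum(
            np.abs(centers - ori_position),
            genome_length - np.abs(centers - ori_position),
        )
        max_dist = genome_length / 2
    else:
        dist = np.abs(centers - ori_position)
        max_dist = max(ori_position, genome_length - ori_position)
    t = dist / max_dist if max_dist > 0 else np.zeros(n)
    shape = np.power(ori_gradient, 1.0 - t)
    widths = _bin_widths(genome_length, bin_size)
    shape_mean = float(shape @ widths / genome_length)
    expected = mean_depth * shape / shape_mean
    if noise:
        rng = np.random.default_rng(seed)
        depths = rng.poisson(expected).astype(float)
    else:
        depths = expected
    return CoverageTrack(
        contig_id=contig_id, contig_length=genome_length, bin_size=bin_size,
        depths=depths, total_mapped=total_mapped, source="whole",
    )


# ---------------------------------------------------------------------------
# model / fixture configuration


def _model_from_dict(cfg: dict, contig_id: str = "contig", rng: np.random.Generator | None = None) -> GenomeModel:
    prophages = [
        ProphageElement(
            start=p["start"], end=p["end"],
            induction_rate=p.get("induction_rate", 1.0),
            specialized_rate=p.get("specialized_rate", 0.0),
            capsid_capacity=p.get("capsid_capacity"),
            max_flank=p.get("max_flank"),
            side_bias=p.get("side_bias", 0.5),
            lateral_rate=p.get("lateral_rate", 0.0),
            lateral_direction=p.get("lateral_direction", "right"),
            continuation_prob=p.get("continuation_prob", 0.5),
            element_id=p.get("id", f"prophage{i}"),
        )
        for i, p in enumerate(cfg.get("prophages", []))
    ]
    pac_sites = [
        PacSite(
            position=s["position"],
            initiation_rate=s.get("initiation_rate", 1.0),
            headful=s.get("headful", 44_000),
            continuation_prob=s.get("continuation_prob", 0.5),
            direction=s.get("direction", "right"),
            site_id=s.get("id", f"pac{j}"),
        )
        for j, s in enumerate(cfg.get("pac_sites", []))
    ]
    gta = None
    if "gta" in cfg and cfg["gta"] is not None:
        g = cfg["gta"]
        bias = None
        bias_bin = g.get("bias_bin", 1000)
        excl = None
        excl_factor = 0.2
        if g.get("self_exclusion"):
            excl = (g["self_exclusion"]["start"], g["self_exclusion"]["end"])
            excl_factor = g["self_exclusion"].get("factor", 0.2)
        if "bias_fold" in g and g["bias_fold"] > 1:
            if rng is None:
                rng = np.random.default_rng(0)
            fold = g["bias_fold"]
            bias = _smooth_bias_field(
                rng,
                n_bins=_n_bins(cfg["genome_length"], bias_bin),
                fold=fold,
                length_scale_bins=max(1, g.get("bias_length_scale", 50_000) // bias_bin),
            )
            if excl is not None:
                # fold the self-exclusion dip into the field, then rescale in
                # log space so the overall max/min ratio stays exactly `fold`
                bias[excl[0] // bias_bin : -(-excl[1] // bias_bin)] *= excl_factor
                logb = np.log(bias)
                s = (logb - logb.min()) / (logb.max() - logb.min())
                bias = np.power(fold, s)
                excl = None
        gta = GTAParams(
            fragment_size=g.get("fragment_size", 13_000),
            rate=g.get("rate", 1.0),
            bias_field=bias,
            bias_bin=bias_bin,
            self_exclusion=excl,
            self_exclusion_factor=excl_factor,
        )
    return GenomeModel(
        genome_length=cfg["genome_length"],
        circular=cfg.get("circular", False),
        prophages=prophages,
        pac_sites=pac_sites,
        gta=gta,
        ori_position=cfg.get("ori_position", 0),
        contig_id=contig_id,
    )


def _smooth_bias_field(rng, n_bins: int, fold: float, length_scale_bins: int) -> np.ndarray:
    """Smooth positive field whose max/min ratio equals ``fold`` exactly."""
    raw = rng.standard_normal(n_bins)
    kernel = np.exp(-0.5 * (np.arange(-3 * length_scale_bins, 3 * length_scale_bins + 1) / length_scale_bins) ** 2)
    kernel /= kernel.sum()
    # circular smoothing keeps the field continuous across the origin
    smooth = np.real(np.fft.ifft(np.fft.fft(raw) * np.fft.fft(kernel, n_bins)))
    s = (smooth - smooth.min()) / (smooth.max() - smooth.min())
    return np.power(fold, s)


def load_model_yaml(path: str | Path, seed: int = 0) -> GenomeModel:
    """Load a single genome model from a YAML description."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _model_from_dict(cfg, contig_id=cfg.get("id", "contig"), rng=np.random.default_rng(seed))


def _fixture_config(name: str) -> dict:
    ref = importlib.resources.files("transductomics") / "fixtures" / f"{name}.yaml"
    if not ref.is_file():
        raise ValueError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")
    return yaml.safe_load(ref.read_text())


def _simulate_contig(
    cfg: dict,
    contig_id: str,
    seed: int,
    bin_size: int,
) -> tuple[PairedCoverage, GenomeModel, FragmentSet | None]:
    rng = np.random.default_rng(seed)
    model = _model_from_dict(cfg, contig_id=contig_id, rng=rng)
    L = model.genome_length
    wgs_cfg = cfg.get("wgs", {})
    wgs = simulate_wgs_track(
        L,
        wgs_cfg.get("mean_depth", 100.0),
        bin_size=bin_size,
        ori_gradient=wgs_cfg.get("ori_gradient", 1.0),
        ori_position=cfg.get("ori_position", 0),
        circular=model.circular,
        noise=wgs_cfg.get("noise", True),
        seed=int(rng.integers(2**31)),
        contig_id=contig_id,
    )
    n_particles = int(cfg.get("n_particles", 0))
    frags = None
    if n_particles > 0 and model.channel_weights():
        frags = simulate_fragments(model, n_particles, seed=int(rng.integers(2**31)))
        vlp = fragments_to_coverage(
            frags, bin_size=bin_size, contig_id=contig_id, total_mapped=1e6,
        )
    elif cfg.get("vlp_mirror_wgs_depth"):
        # seeded contamination: VLP reads are a scaled-down copy of the
        # whole-community profile (cellular DNA surviving purification)
        target = float(cfg["vlp_mirror_wgs_depth"])
        scale = target / max(wgs.mean_depth(), 1e-9)
        vlp_depths = np.random.default_rng(int(rng.integers(2**31))).poisson(
            np.maximum(wgs.depths * scale, 0.0)
        ).astype(float)
        vlp = CoverageTrack(
            contig_id=contig_id, contig_length=L, bin_size=bin_size,
            depths=vlp_depths, total_mapped=1e6, source="vlp",
        )
    else:
        flat = float(cfg.get("vlp_flat_depth", 0.0))
        if flat > 0:
            vlp_depths = np.random.default_rng(int(rng.integers(2**31))).poisson(
                np.full(_n_bins(L, bin_size), flat)
            ).astype(float)
        else:
            vlp_depths = np.zeros(_n_bins(L, bin_size))
        vlp = CoverageTrack(
            contig_id=contig_id, contig_length=L, bin_size=bin_size,
            depths=vlp_depths, total_mapped=1e6, source="vlp",
        )
    return PairedCoverage(contig_id, wgs=wgs, vlp=vlp), model, frags


_MODE_PRECEDENCE = ["specialized", "lateral", "induction", "generalized", "gta_like", "unknown", "standard"]


def _truth_from_model(contig_id: str, cfg: dict, model: GenomeModel, seed: int) -> TruthLabel:
    elements = []
    modes = set()
    n_particles = cfg.get("n_particles", 0)
    channels = model.channel_weights()
    total_w = sum(w for _, _, w in channels) or 1.0
    for p in model.prophages:
        if p.induction_rate <= 0:
            continue
        el = {
            "mode": "induction",
            "start": p.start,
            "end": p.end,
            "element_id": p.element_id,
        }
        if p.specialized_rate > 0:
            el["mode"] = "specialized"
            # observed plateau:flank frequency ratio; flank max sits at the
            # prophage edge where P(extent > 0) ~ 1
            per_side = p.specialized_rate * max(p.side_bias, 1 - p.side_bias)
            el["frequency_ratio"] = (1 - p.specialized_rate) / per_side
            el["max_flank"] = p.max_flank
        if p.lateral_rate > 0:
            el["mode"] = "lateral"
            n_ind = n_particles * p.induction_rate / total_w
            n_lat = n_particles * p.lateral_rate / total_w
            first_headful = n_lat * (1 - p.continuation_prob)
            el["frequency_ratio"] = n_ind * (1 - p.specialized_rate) / first_headful
            el["lateral_direction"] = p.lateral_direction
            el["headful"] = p.capsid_capacity
        modes.add(el["mode"])
        elements.append(el)
    if model.pac_sites:
        modes.add("generalized")
        elements.append({
            "mode": "generalized",
            "pac_positions": [s.position for s in model.pac_sites],
            "headful": model.pac_sites[0].headful,
        })
    if model.gta is not None and model.gta.rate > 0:
        modes.add("gta_like")
        el = {"mode": "gta_like", "fragment_size": model.gta.fragment_size}
        if "gta" in cfg and cfg["gta"] and "bias_fold" in cfg["gta"]:
            el["bias_fold"] = cfg["gta"]["bias_fold"]
        elements.append(el)
    mode = "standard"
    for m in _MODE_PRECEDENCE:
        if m in modes:
            mode = m
            break
    return TruthLabel(
        contig_id=contig_id,
        mode=mode,
        elements=elements,
        contamination=bool(cfg.get("vlp_mirror_wgs_depth")),
        seed=seed,
    )


def make_fixture(
    name: str,
    seed: int = 0,
    *,
    bin_size: int = 100,
    return_fragments: bool = False,
    counts: dict | None = None,
):
    """Build a named ground-truthed fixture.

    Returns ``(pairs, truths)`` — a list of :class:`PairedCoverage` and a
    matching list of :class:`TruthLabel` — or, with
    ``return_fragments=True``, ``(pairs, truths, fragments)`` where
    ``fragments`` maps contig id to its sampled :class:`FragmentSet`.
    For ``community_like``, ``counts`` overrides the per-mode contig
    counts of the fixture configuration.
    """
    if name == "community_like":
        return _make_community(
            seed, bin_size=bin_size, return_fragments=return_fragments, counts=counts,
        )
    cfg = _fixture_config(name)
    rng = np.random.default_rng(seed)
    pairs, truths, frag_map = [], [], {}
    for i, contig_cfg in enumerate(cfg["contigs"]):
        contig_id = contig_cfg.get("id", f"{name}_{i}")
        sub_seed = int(rng.integers(2**31))
        pair, model, frags = _simulate_contig(contig_cfg, contig_id, sub_seed, bin_size)
        pairs.append(pair)
        truths.append(_truth_from_model(contig_id, contig_cfg, model, sub_seed))
        frag_map[contig_id] = frags
    if return_fragments:
        return pairs, truths, frag_map
    return pairs, truths


def _make_community(
    seed: int,
    *,
    bin_size: int = 100,
    return_fragments: bool = False,
    counts: dict | None = None,
):
    """Synthetic community: >= 50 contigs mixing every mode plus seeded
    cellular-DNA contamination contigs.

    Transduced contigs are genuinely VLP-enriched (their whole-community
    abundance is assigned monotonically in their expected VLP coverage),
    which is the biological assumption behind the rank screen; the seeded
    contamination contigs violate it by construction.
    """
    cfg = _fixture_config("community_like")
    rng = np.random.default_rng(seed)
    contigs: list[dict] = []

    def u(lo, hi):
        return float(rng.uniform(lo, hi))

    def ui(lo, hi):
        return int(rng.integers(lo, hi))

    counts = {**cfg["counts"], **(counts or {})}
    for _ in range(counts["standard"]):
        contigs.append({
            "genome_length": ui(40_000, 300_000),
            "wgs": {"mean_depth": u(100, 300), "ori_gradient": u(1.0, 1.3)},
            "vlp_flat_depth": float(rng.choice([0.0, u(2, 4)])),
            "_mode": "standard",
        })
    for _ in range(counts["contamination"]):
        contigs.append({
            "genome_length": ui(60_000, 300_000),
            "wgs": {"mean_depth": u(500, 1000), "ori_gradient": u(1.0, 1.3)},
            "vlp_mirror_wgs_depth": u(6, 15),
            "_mode": "standard",
        })
    for _ in range(counts["induction"]):
        L = ui(120_000, 400_000)
        width = ui(20_000, 60_000)
        start = ui(20_000, L - width - 20_000)
        contigs.append({
            "genome_length": L,
            "wgs": {"mean_depth": u(40, 90), "ori_gradient": u(1.0, 1.3)},
            "n_particles": ui(3_000, 30_000),
            "prophages": [{"start": start, "end": start + width,
                           "induction_rate": 1.0}],
            "_mode": "induction",
        })
    for _ in range(counts["specialized"]):
        L = ui(250_000, 450_000)
        width = ui(35_000, 55_000)
        start = ui(60_000, L - width - 60_000)
        contigs.append({
            "genome_length": L,
            "wgs": {"mean_depth": u(40, 90), "ori_gradient": u(1.0, 1.3)},
            "n_particles": ui(200_000, 400_000),
            "prophages": [{"start": start, "end": start + width,
                           "induction_rate": 1.0,
                           "specialized_rate": 2e-3,
                           "capsid_capacity": width,
                           "max_flank": ui(15_000, 25_000),
                           "side_bias": 0.5}],
            "_mode": "specialized",
        })
    for _ in range(counts["lateral"]):
        L = ui(400_000, 650_000)
        width = ui(35_000, 50_000)
        start = ui(20_000, 60_000)
        q = u(0.5, 0.65)
        ratio = u(200, 500)
        contigs.append({
            "genome_length": L,
            "wgs": {"mean_depth": u(40, 90), "ori_gradient": u(1.0, 1.3)},
            "n_particles": ui(150_000, 300_000),
            "prophages": [{"start": start, "end": start + width,
                           "induction_rate": 1.0,
                           "capsid_capacity": width,
                           "lateral_rate": 1.0 / (ratio * (1 - q)),
                           "lateral_direction": "right",
                           "continuation_prob": q}],
            "_mode": "lateral",
        })
    for _ in range(counts["generalized"]):
        L = ui(350_000, 700_000)
        H = 44_000
        n_sites = ui(2, 4)
        gap = (L - 100_000) // n_sites
        positions = [50_000 + j * gap + ui(0, max(1, gap - 2 * H)) for j in range(n_sites)]
        contigs.append({
            "genome_length": L,
            "wgs": {"mean_depth": u(40, 90), "ori_gradient": u(1.0, 1.3)},
            "n_particles": ui(10_000, 40_000),
            "pac_sites": [{"position": int(p), "headful": H,
                           "continuation_prob": u(0.6, 0.75),
                           "direction": "right"} for p in positions],
            "_mode": "generalized",
        })
    for _ in range(counts["gta_like"]):
        L = ui(200_000, 500_000)
        F = 13_000
        mean_depth = u(200, 1500)
        contigs.append({
            "genome_length": L,
            "wgs": {"mean_depth": u(40, 90), "ori_gradient": u(1.0, 1.3)},
            "n_particles": int(mean_depth * L / F),
            "gta": {"fragment_size": F, "bias_fold": u(5, 25),
                    "bias_length_scale": 50_000},
            "_mode": "gta_like",
        })

    # simulate every contig first to learn its realised VLP mean coverage
    pairs, truths, frag_map = [], [], {}
    order = rng.permutation(len(contigs))
    for rank_i, idx in enumerate(order):
        c = contigs[idx]
        contig_id = f"ctg_{rank_i:04d}"
        sub_seed = int(rng.integers(2**31))
        pair, model, frags = _simulate_contig(c, contig_id, sub_seed, bin_size)
        truth = _truth_from_model(contig_id, c, model, sub_seed)
        pairs.append(pair)
        truths.append(truth)
        frag_map[contig_id] = frags

    # re-draw whole-community depths of transduced contigs monotonically in
    # their VLP coverage so that genuine carriage is VLP-enriched in rank
    transduced = [
        (i, pairs[i].vlp.mean_depth()) for i, t in enumerate(truths)
        if t.mode != "standard"
    ]
    transduced.sort(key=lambda x: -x[1])
    lo, hi = 30.0, 95.0
    for j, (i, _) in enumerate(transduced):
        target = hi - (hi - lo) * j / max(len(transduced) - 1, 1)
        old = pairs[i].wgs
        new_wgs = simulate_wgs_track(
            old.contig_length, target, bin_size=bin_size,
            ori_gradient=1.2, circular=False, noise=True,
            seed=int(rng.integers(2**31)), contig_id=old.contig_id,
        )
        pairs[i] = PairedCoverage(old.contig_id, wgs=new_wgs, vlp=pairs[i].vlp)

    if return_fragments:
        return pairs, truths, frag_map
    return pairs, truths
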