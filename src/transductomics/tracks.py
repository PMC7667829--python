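"""Binned read-coverage tracks for paired whole-community / VLP samples.

A :class:`CoverageTrack` is the package's basic container: mean per-base
read depth in fixed-width bins along one contig, for one read set
(``whole`` community metagenome or purified ``vlp`` fraction).  Tracks are
produced from coordinate-sorted SAM/BAM alignments, per-base depth TSVs
(``samtools depth`` style) or bedGraph files, paired across the two
samples on contig identity, normalized to depth per million mapped reads,
and written back out as bedGraph for genome-browser inspection.

Coordinates are 0-based half-open throughout, as in BED/bedGraph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "CoverageTrack",
    "NormalizedTrack",
    "PairedCoverage",
    "load_depth",
    "read_fai",
    "filter_contigs",
    "normalize_track",
    "pair_tracks",
    "write_track",
]

#: contigs shorter than this are discarded by default; patterns that span
#: hundreds of kbp cannot be recognised on short contigs.
DEFAULT_MIN_CONTIG_LENGTH = 40_000

#: default bin width in bp (browser-style mean-per-window coverage).
DEFAULT_BIN_SIZE = 100


def _n_bins(contig_length: int, bin_size: int) -> int:
    return -(-contig_length // bin_size)


def _bin_widths(contig_length: int, bin_size: int) -> np.ndarray:
    """True bp width of every bin; the last bin may be partial."""
    n = _n_bins(contig_length, bin_size)
    widths = np.full(n, bin_size, dtype=float)
    rem = contig_length - (n - 1) * bin_size
    widths[-1] = rem
    return widths


@dataclass
class CoverageTrack:
    """Mean per-base depth in fixed-width bins along one contig.

    Parameters
    ----------
    contig_id : str
        Reference contig name.
    contig_length : int
        Contig length in bp.
    bin_size : int
        Bin width in bp.  The last bin covers the remainder and its depth
        is averaged over its true width.
    depths : ndarray of float
        Mean per-base depth per bin, length ``ceil(contig_length / bin_size)``.
    total_mapped : float
        Mapped-read count of the *whole sample* the track was derived
        from (the per-million normalization denominator).
    source : {"whole", "vlp"}
        Which read set the track belongs to.
    """

    contig_id: str
    contig_length: int
    bin_size: int
    depths: np.ndarray
    total_mapped: float
    source: str = "vlp"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.contig_length < 1:
            raise ValueError("contig_length must be >= 1")
        expected = _n_bins(self.contig_length, self.bin_size)
        if self.depths.shape != (expected,):
            raise ValueError(
                f"{self.contig_id}: expected {expected} bins for length "
                f"{self.contig_length} at bin {self.bin_size}, got {self.depths.shape}"
            )
        if np.any(self.depths < 0):
            raise ValueError(f"{self.contig_id}: negative depths")
        if self.source not in ("whole", "vlp"):
            raise ValueError("source must be 'whole' or 'vlp'")

    @property
    def n_bins(self) -> int:
        return self.depths.shape[0]

    def bin_widths(self) -> np.ndarray:
        return _bin_widths(self.contig_length, self.bin_size)

    def mean_depth(self) -> float:
        """Length-weighted mean per-base depth of the contig."""
        return float(self.depths @ self.bin_widths() / self.contig_length)

    def base_mass(self) -> float:
        """Total aligned bases represented by the track."""
        return float(self.depths @ self.bin_widths())

    def rebin(self, bin_size: int) -> "CoverageTrack":
        """Re-bin to a coarser bin width (must be a multiple of the current one)."""
        if bin_size % self.bin_size:
            raise ValueError("new bin_size must be a multiple of the current bin_size")
        if bin_size == self.bin_size:
            return replace(self, depths=self.depths.copy())
        mass = self.depths * self.bin_widths()
        n_new = _n_bins(self.contig_length, bin_size)
        factor = bin_size // self.bin_size
        pad = n_new * factor - self.n_bins
        mass = np.concatenate([mass, np.zeros(pad)])
        new_mass = mass.reshape(n_new, factor).sum(axis=1)
        new_depths = new_mass / _bin_widths(self.contig_length, bin_size)
        return CoverageTrack(
            contig_id=self.contig_id,
            contig_length=self.contig_length,
            bin_size=bin_size,
            depths=new_depths,
            total_mapped=self.total_mapped,
            source=self.source,
        )


@dataclass
class NormalizedTrack(CoverageTrack):
    """A coverage track with depths additionally expressed per million mapped reads."""

    norm_depths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.norm_depths is None:
            raise ValueError("norm_depths required")
        self.norm_depths = np.asarray(self.norm_depths, dtype=float)
        if self.norm_depths.shape != self.depths.shape:
            raise ValueError("norm_depths must match depths in shape")

    def mean_norm_depth(self) -> float:
        return float(self.norm_depths @ self.bin_widths() / self.contig_length)


@dataclass
class PairedCoverage:
    """Whole-community and VLP tracks for the same contig, binned identically."""

    contig_id: str
    wgs: CoverageTrack
    vlp: CoverageTrack

    def __post_init__(self) -> None:
        if self.wgs.contig_id != self.contig_id or self.vlp.contig_id != self.contig_id:
            raise ValueError("track contig_ids disagree with pair contig_id")
        if self.wgs.contig_length != self.vlp.contig_length:
            raise ValueError(f"{self.contig_id}: contig_length mismatch between samples")
        if self.wgs.bin_size != self.vlp.bin_size:
            raise ValueError(f"{self.contig_id}: bin_size mismatch between samples")


def read_fai(path: str | Path) -> dict[str, int]:
    """Read contig lengths from a FASTA index (``samtools faidx`` output)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: not a .fai file (line {line!r})")
            lengths[parts[0]] = int(parts[1])
    return lengths


def _bin_base_interval(mass: np.ndarray, start: int, end: int, bin_size: int) -> None:
    """Add ``end - start`` aligned bases of the interval [start, end) to per-bin mass."""
    b0 = start // bin_size
    b1 = (end - 1) // bin_size
    if b0 == b1:
        mass[b0] += end - start
        return
    mass[b0] += (b0 + 1) * bin_size - start
    mass[b1] += end - b1 * bin_size
    if b1 - b0 > 1:
        mass[b0 + 1 : b1] += bin_size


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".bam", ".cram"):
        return "alignment"
    if suffix == ".sam":
        return "alignment"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track") or line.startswith("browser"):
                continue
            if line.startswith("@HD") or line.startswith("@SQ"):
                return "alignment"
            parts = line.split("\t")
            if len(parts) == 3:
                try:
                    int(parts[1]), float(parts[2])
                    return "depth-tsv"
                except ValueError:
                    break
            if len(parts) >= 4:
                try:
                    int(parts[1]), int(parts[2]), float(parts[3])
                    return "bedgraph"
                except ValueError:
                    break
            break
    raise ValueError(
        f"{path}: unrecognised coverage input (expected SAM/BAM alignment, "
        "3-column per-base depth TSV, or 4-column bedGraph)"
    )


def _load_alignment(
    path: Path,
    bin_size: int,
    source: str,
    min_mapq: int,
) -> list[CoverageTrack]:
    mode = "rb" if path.suffix.lower() in (".bam", ".cram") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        header = af.header.to_dict()
        so = header.get("HD", {}).get("SO", "unknown")
        if so not in ("coordinate", "unsorted", "unknown") or so == "unsorted":
            raise ValueError(
                f"{path}: alignment is not coordinate-sorted (SO:{so}); "
                "run `samtools sort` first"
            )
        if mode == "rb" and not af.has_index():
            raise ValueError(
                f"{path}: BAM file has no index; run `samtools index` first"
            )
        refs = list(af.references)
        lengths = dict(zip(refs, af.lengths))
        masses = {
            name: np.zeros(_n_bins(lengths[name], bin_size)) for name in refs
        }
        total_mapped = 0
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            # mapq-0 (ambiguous, randomly placed) reads are kept by default so
            # that multi-mapping reads contribute exactly once.
            if read.mapping_quality < min_mapq:
                continue
            total_mapped += 1
            mass = masses[read.reference_name]
            for start, end in read.get_blocks():
                _bin_base_interval(mass, start, end, bin_size)
    tracks = []
    for name in refs:
        widths = _bin_widths(lengths[name], bin_size)
        tracks.append(
            CoverageTrack(
                contig_id=name,
                contig_length=lengths[name],
                bin_size=bin_size,
                depths=masses[name] / widths,
                total_mapped=total_mapped,
                source=source,
            )
        )
    return tracks


def _finish_depth_tracks(
    mass_by_contig: dict[str, np.ndarray],
    lengths: dict[str, int],
    bin_size: int,
    source: str,
    total_mapped: float | None,
) -> list[CoverageTrack]:
    # Depth files carry no library size; default to the identity denominator
    # (norm == raw depth).  All fold-based decisions are scale-invariant, so
    # only callers comparing absolute norm values across samples need to
    # supply the true mapped-read counts.
    if total_mapped is None:
        total_mapped = 1e6
    tracks = []
    for name, length in lengths.items():
        mass = mass_by_contig.get(name)
        if mass is None:
            mass = np.zeros(_n_bins(length, bin_size))
        tracks.append(
            CoverageTrack(
                contig_id=name,
                contig_length=length,
                bin_size=bin_size,
                depths=mass / _bin_widths(length, bin_size),
                total_mapped=total_mapped,
                source=source,
            )
        )
    return tracks


def _load_depth_tsv(
    path: Path,
    bin_size: int,
    source: str,
    lengths: dict[str, int] | None,
    total_mapped: float | None,
) -> list[CoverageTrack]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "pos", "depth"],
        dtype={"contig": str, "pos": np.int64, "depth": float},
    )
    if lengths is None:
        lengths = {c: int(g["pos"].max()) for c, g in df.groupby("contig", sort=False)}
    mass_by_contig: dict[str, np.ndarray] = {}
    for contig, g in df.groupby("contig", sort=False):
        if contig not in lengths:
            raise ValueError(f"{path}: contig {contig!r} absent from contig-length index")
        n = _n_bins(lengths[contig], bin_size)
        mass = np.zeros(n)
        pos0 = g["pos"].to_numpy() - 1  # 1-based positions
        if pos0.min() < 0 or pos0.max() >= lengths[contig]:
            raise ValueError(f"{path}: position outside contig {contig!r}")
        np.add.at(mass, pos0 // bin_size, g["depth"].to_numpy())
        mass_by_contig[contig] = mass
    return _finish_depth_tracks(mass_by_contig, lengths, bin_size, source, total_mapped)


def _load_bedgraph(
    path: Path,
    bin_size: int,
    source: str,
    lengths: dict[str, int] | None,
    total_mapped: float | None,
) -> list[CoverageTrack]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "depth"])
    if lengths is None:
        lengths = {c: int(g["end"].max()) for c, g in df.groupby("contig", sort=False)}
    mass_by_contig = {}
    for contig, g in df.groupby("contig", sort=False):
        if contig not in lengths:
            raise ValueError(f"{path}: contig {contig!r} absent from contig-length index")
        n = _n_bins(lengths[contig], bin_size)
        mass = np.zeros(n)
        for start, end, depth in zip(g["start"], g["end"], g["depth"]):
            end = min(end, lengths[contig])
            if end > start:
                # spread depth x width base mass over the covered bins
                tmp_start, tmp_end = int(start), int(end)
                b0 = tmp_start // bin_size
                b1 = (tmp_end - 1) // bin_size
                if b0 == b1:
                    mass[b0] += depth * (tmp_end - tmp_start)
                else:
                    mass[b0] += depth * ((b0 + 1) * bin_size - tmp_start)
                    mass[b1] += depth * (tmp_end - b1 * bin_size)
                    if b1 - b0 > 1:
                        mass[b0 + 1 : b1] += depth * bin_size
        mass_by_contig[contig] = mass
    return _finish_depth_tracks(mass_by_contig, lengths, bin_size, source, total_mapped)


def load_depth(
    path: str | Path,
    bin_size: int = DEFAULT_BIN_SIZE,
    *,
    source: str = "vlp",
    fai: str | Path | dict[str, int] | None = None,
    total_mapped: float | None = None,
    min_mapq: int = 0,
) -> list[CoverageTrack]:
    """Load binned coverage tracks from an alignment or a depth file.

    Parameters
    ----------
    path
        SAM/BAM alignment (coordinate-sorted; BAM additionally indexed),
        3-column per-base depth TSV (contig, 1-based position, depth) or
        bedGraph file.
    bin_size
        Bin width in bp; mean per-base depth is computed within each bin,
        the last partial bin over its true width.
    source
        ``"whole"`` or ``"vlp"``; stored on every track.
    fai
        FASTA index path or ``{contig: length}`` mapping used as the
        contig-length authority for depth/bedGraph inputs (alignments
        carry their own header).  Contigs listed here but absent from the
        file get explicit all-zero tracks.
    total_mapped
        Sample-wide mapped-read count.  Counted from the file for
        alignments; for depth inputs it defaults to the total aligned-base
        mass of the file.
    min_mapq
        Minimum mapping quality; the default 0 keeps ambiguous,
        randomly-placed multi-mappers.

    Returns
    -------
    list of CoverageTrack, one per reference contig (zero-depth contigs included).
    """
    path = Path(path)
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lengths = None
    if fai is not None:
        lengths = dict(fai) if isinstance(fai, dict) else read_fai(fai)
    fmt = _sniff_format(path)
    if fmt == "alignment":
        tracks = _load_alignment(path, bin_size, source, min_mapq)
        if total_mapped is not None:
            tracks = [replace(t, total_mapped=total_mapped) for t in tracks]
        return tracks
    if fmt == "depth-tsv":
        return _load_depth_tsv(path, bin_size, source, lengths, total_mapped)
    return _load_bedgraph(path, bin_size, source, lengths, total_mapped)


def filter_contigs(
    tracks: Iterable[CoverageTrack],
    min_length: int = DEFAULT_MIN_CONTIG_LENGTH,
) -> list[CoverageTrack]:
    """Keep contigs with ``contig_length >= min_length`` (stable order).

    The boundary is inclusive: a contig of exactly ``min_length`` bp is
    retained, shorter ones are discarded.
    """
    return [t for t in tracks if t.contig_length >= min_length]


def normalize_track(track: CoverageTrack) -> NormalizedTrack:
    """Attach depth-per-million-mapped-reads to a track.

    ``norm_depths[i] = depths[i] * 1e6 / total_mapped``; raw depths are
    preserved so that absolute coverage gates remain applicable.
    """
    if isinstance(track, NormalizedTrack):
        return track
    if track.total_mapped <= 0:
        raise ValueError(
            f"{track.contig_id}: cannot normalize with total_mapped == 0"
        )
    return NormalizedTrack(
        contig_id=track.contig_id,
        contig_length=track.contig_length,
        bin_size=track.bin_size,
        depths=track.depths,
        total_mapped=track.total_mapped,
        source=track.source,
        norm_depths=track.depths * 1e6 / track.total_mapped,
    )


def pair_tracks(
    wgs: Sequence[CoverageTrack],
    vlp: Sequence[CoverageTrack],
) -> list[PairedCoverage]:
    """Pair whole-community and VLP tracks on contig identity.

    Contigs present in only one sample are reported via a warning and
    excluded.  Both sets must be binned identically.
    """
    wgs_by_id = {t.contig_id: t for t in wgs}
    vlp_by_id = {t.contig_id: t for t in vlp}
    bin_sizes = {t.bin_size for t in wgs} | {t.bin_size for t in vlp}
    if len(bin_sizes) > 1:
        raise ValueError(f"bin_size mismatch across samples: {sorted(bin_sizes)}")
    only_wgs = sorted(set(wgs_by_id) - set(vlp_by_id))
    only_vlp = sorted(set(vlp_by_id) - set(wgs_by_id))
    if only_wgs or only_vlp:
        warnings.warn(
            "contigs present in only one sample were excluded: "
            f"whole-only={only_wgs} vlp-only={only_vlp}",
            stacklevel=2,
        )
    pairs = []
    for t in wgs:
        if t.contig_id in vlp_by_id:
            pairs.append(PairedCoverage(t.contig_id, wgs=t, vlp=vlp_by_id[t.contig_id]))
    return pairs


def write_track(track: CoverageTrack, path: str | Path, *, normalized: bool = False) -> None:
    """Write a track as 0-based half-open bedGraph.

    Runs of adjacent equal-value bins are merged into one line; an
    all-zero track still produces a single explicit zero line so that a
    write/load round trip reconstructs the contig.
    """
    values = track.norm_depths if normalized and isinstance(track, NormalizedTrack) else track.depths
    path = Path(path)
    with open(path, "w") as fh:
        start_bin = 0
        current = values[0]
        for i in range(1, track.n_bins + 1):
            if i == track.n_bins or values[i] != current:
                start = start_bin * track.bin_size
                end = min(i * track.bin_size, track.contig_length)
                fh.write(f"{track.contig_id}\t{start}\t{end}\t{current:g}\n")
                if i < track.n_bins:
                    start_bin = i
                    current = values[i]
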