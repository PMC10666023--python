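"""Strand-specific coverage tracks and hotspot-centered profiles.

The analysis path mirrors the standard treatment of resection end-mapping
data: bin mapped end positions into strand-specific coverage vectors,
normalize to reads per million mapped reads (RPM), then average signal
across hotspots after *co-orienting* — bottom-strand (leftward resection)
signal is flipped across the hotspot center so that both resection
directions superimpose on one positive-distance axis. Averaged profiles
are smoothed with a unit-sum Hann window (151 bp for 1-bp profiles), a
background estimated 2,500 bp from the center is subtracted, and the
profile is normalized to the resection-endpoint peak on (100, 2500] bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import BOTTOM, TOP, EndMap, GenomeSpec, HotspotSet
from .tracks_io import AnalysisConfig

logger = logging.getLogger("dsbend")


@dataclass
class StrandTrack:
    """Per-chromosome strand-split coverage vectors.

    ``top`` and ``bottom`` map chromosome name to a vector of length
    ``ceil(length / bin_size)`` holding raw counts or, after
    :func:`rpm_normalize`, RPM values.
    """

    genome: GenomeSpec
    bin_size: int
    top: dict[str, np.ndarray]
    bottom: dict[str, np.ndarray]
    n_mapped: int
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for name, length in self.genome.chroms.items():
            want = -(-length // self.bin_size)
            for vecs in (self.top, self.bottom):
                if name not in vecs or len(vecs[name]) != want:
                    raise ValueError(f"track vector for {name!r} has wrong length")

    def combined(self) -> dict[str, np.ndarray]:
        """Top + bottom per chromosome (both resection directions pooled)."""
        return {c: self.top[c] + self.bottom[c] for c in self.genome.chroms}

    def total(self) -> float:
        return float(sum(self.top[c].sum() + self.bottom[c].sum()
                         for c in self.genome.chroms))

    @classmethod
    def zeros(cls, genome: GenomeSpec, bin_size: int, dtype=np.float64,
              n_mapped: int = 0, normalized: bool = False) -> "StrandTrack":
        make = lambda: {c: np.zeros(-(-l // bin_size), dtype=dtype)
                        for c, l in genome.chroms.items()}
        return cls(genome=genome, bin_size=bin_size, top=make(), bottom=make(),
                   n_mapped=n_mapped, normalized=normalized)

    @classmethod
    def average(cls, tracks: list["StrandTrack"]) -> "StrandTrack":
        """Arithmetic mean of replicate tracks (same genome/bin/normalization).

        Replicates are averaged after RPM normalization, so each library
        contributes equally regardless of depth.
        """
        if not tracks:
            raise ValueError("no tracks to average")
        ref = tracks[0]
        for t in tracks[1:]:
            if (t.genome.chroms != ref.genome.chroms or t.bin_size != ref.bin_size
                    or t.normalized != ref.normalized):
                raise ValueError("replicate tracks must share genome, bin and normalization")
        k = len(tracks)
        out = cls.zeros(ref.genome, ref.bin_size,
                        n_mapped=round(sum(t.n_mapped for t in tracks) / k),
                        normalized=ref.normalized)
        for c in ref.genome.chroms:
            out.top[c] = sum(t.top[c] for t in tracks) / k
            out.bottom[c] = sum(t.bottom[c] for t in tracks) / k
        return out

    @classmethod
    def pool(cls, tracks: list["StrandTrack"]) -> "StrandTrack":
        """Sum raw-count replicate tracks (for peak calling on pooled reads)."""
        if not tracks:
            raise ValueError("no tracks to pool")
        if any(t.normalized for t in tracks):
            raise ValueError("pool operates on raw-count tracks")
        ref = tracks[0]
        out = cls.zeros(ref.genome, ref.bin_size,
                        n_mapped=sum(t.n_mapped for t in tracks), normalized=False)
        for c in ref.genome.chroms:
            out.top[c] = sum(t.top[c] for t in tracks)
            out.bottom[c] = sum(t.bottom[c] for t in tracks)
        return out


@dataclass
class CoorientedProfile:
    """Mean signal versus distance from the hotspot center.

    ``distances`` runs from ``-flank`` to ``+flank`` in profile-bin steps
    and is symmetric about 0. When ``combined`` is set, ``values`` holds
    top-aligned plus flipped-bottom signal, so positive distances read as
    resection-endpoint distance from the break in nt.
    """

    distances: np.ndarray
    values: np.ndarray
    n_hotspots: int
    combined: bool
    top: np.ndarray | None = None
    bottom_flipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_hotspots <= 0:
            raise ValueError("n_hotspots must be positive")
        if len(self.distances) != len(self.values):
            raise ValueError("distances and values must have equal length")

    def value_at(self, distance: int) -> float:
        i = int(np.searchsorted(self.distances, distance))
        if i >= len(self.distances) or self.distances[i] != distance:
            raise ValueError(f"profile does not cover distance {distance}")
        return float(self.values[i])


def bin_coverage(ends: EndMap, genome: GenomeSpec, bin_size: int = 1) -> StrandTrack:
    """Bin end records into a strand-split coverage track of raw counts.

    Each record increments bin ``floor(pos / bin_size)`` on its strand;
    total bin mass equals the record count exactly.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    ends.validate(genome)
    track = StrandTrack.zeros(genome, bin_size, dtype=np.float64,
                              n_mapped=ends.n_mapped, normalized=False)
    for chrom in genome.chroms:
        sel = ends.chrom == chrom
        if not sel.any():
            continue
        bins = ends.pos[sel] // bin_size
        strands = ends.strand[sel]
        nb = len(track.top[chrom])
        track.top[chrom] += np.bincount(bins[strands == TOP], minlength=nb).astype(float)
        track.bottom[chrom] += np.bincount(bins[strands == BOTTOM], minlength=nb).astype(float)
    logger.info("bin_coverage: %d records, bin %d bp", ends.n_mapped, bin_size)
    return track


def rpm_normalize(track: StrandTrack) -> StrandTrack:
    """Scale a raw-count track to reads per million mapped reads.

    Refuses to normalize twice (no silent rescaling) and errors on an
    empty library.
    """
    if track.normalized:
        raise ValueError("track is already RPM-normalized")
    if track.n_mapped <= 0:
        raise ValueError("cannot RPM-normalize a track with n_mapped == 0")
    scale = 1e6 / track.n_mapped
    out = StrandTrack.zeros(track.genome, track.bin_size, n_mapped=track.n_mapped,
                            normalized=True)
    for c in track.genome.chroms:
        out.top[c] = track.top[c] * scale
        out.bottom[c] = track.bottom[c] * scale
    return out


def hann_window(window_bins: int) -> np.ndarray:
    """Unit-sum Hann taper w[k] = 0.5 (1 - cos(2 pi k / (M-1))), k = 0..M-1."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window_bins == 1:
        return np.ones(1)
    w = np.hanning(window_bins)
    return w / w.sum()


def hann_smooth(values: np.ndarray, window_bins: int) -> np.ndarray:
    """Smooth a vector with a unit-sum Hann window, reflecting at the edges.

    The unit-sum window preserves the local mean and reflection padding
    preserves constants; output length equals input length. ``window_bins``
    must be odd and no longer than the vector.
    """
    values = np.asarray(values, dtype=np.float64)
    if window_bins > len(values):
        raise ValueError("window longer than input vector")
    w = hann_window(window_bins)
    if window_bins == 1:
        return values.copy()
    pad = window_bins // 2
    padded = np.pad(values, pad, mode="reflect")
    return np.convolve(padded, w, mode="valid")


def _profile_sums(track: StrandTrack, hotspots: HotspotSet, cfg: AnalysisConfig,
                  per_hotspot: bool = False, weights: np.ndarray | None = None):
    """Gather top / flipped-bottom windows around each usable hotspot.

    Returns (distances, top, bottom_flipped, n_used) where the arrays are
    either means across hotspots or, with ``per_hotspot``, stacked rows.
    """
    if track.bin_size != cfg.profile_bin_bp:
        raise ValueError("track bin size must equal cfg.profile_bin_bp")
    if len(hotspots) == 0:
        raise ValueError("hotspot set is empty")
    if cfg.profile_flank_bp % track.bin_size != 0:
        raise ValueError("profile_flank_bp must be a multiple of the bin size")
    fb = cfg.profile_flank_bp // track.bin_size
    n_off = 2 * fb + 1
    rows_top, rows_bot = [], []
    top_sum = np.zeros(n_off)
    bot_sum = np.zeros(n_off)
    wsum = 0.0
    n_used = n_skipped = 0
    for i in range(len(hotspots)):
        chrom = hotspots.chrom[i]
        c = int(hotspots.center[i]) // track.bin_size
        nb = len(track.top[chrom])
        if c - fb < 0 or c + fb >= nb:
            n_skipped += 1
            continue
        wt = 1.0 if weights is None else float(weights[i])
        t = track.top[chrom][c - fb:c + fb + 1]
        b = track.bottom[chrom][c - fb:c + fb + 1][::-1]  # flip: bottom at -d
        if per_hotspot:
            rows_top.append(t)
            rows_bot.append(b)
        else:
            top_sum += wt * t
            bot_sum += wt * b
            wsum += wt
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable hotspots (all windows cross chromosome edges)")
    if n_skipped:
        logger.info("cooriented_average: skipped %d edge hotspots", n_skipped)
    distances = np.arange(-fb, fb + 1) * track.bin_size
    if per_hotspot:
        return distances, np.vstack(rows_top), np.vstack(rows_bot), n_used
    return distances, top_sum / wsum, bot_sum / wsum, n_used


def cooriented_average(track: StrandTrack, hotspots: HotspotSet, cfg: AnalysisConfig,
                       combine: bool = True, weight_by_heat: bool = False) -> CoorientedProfile:
    """Average signal across hotspots after co-orienting the strands.

    For each hotspot the top-strand signal is taken at offsets
    ``d in [-flank, +flank]`` and the bottom-strand signal at ``-d``
    (flipped), then averaged across hotspots — unweighted by default, so
    each hotspot contributes equally; ``weight_by_heat`` weights by heat
    instead. Hotspot windows crossing a chromosome edge are skipped (and
    counted in the log), not zero-padded. With ``combine`` the flipped
    bottom is added to the top.
    """
    weights = hotspots.heat if weight_by_heat else None
    distances, top, bot, n_used = _profile_sums(track, hotspots, cfg, weights=weights)
    values = top + bot if combine else top
    return CoorientedProfile(distances=distances, values=values, n_hotspots=n_used,
                             combined=combine, top=top, bottom_flipped=bot)


def cooriented_matrix(track: StrandTrack, hotspots: HotspotSet, cfg: AnalysisConfig,
                      lo_bp: int | None = None, hi_bp: int | None = None):
    """Per-hotspot combined co-oriented windows, one row per usable hotspot.

    Optionally restricted to offsets ``[lo_bp, hi_bp]`` — the bootstrap in
    :func:`dsbend.resection.compare_resection` only needs the positive
    side plus smoothing margin. Returns ``(distances, matrix)``.
    """
    distances, top_rows, bot_rows, _ = _profile_sums(track, hotspots, cfg,
                                                     per_hotspot=True)
    mat = top_rows + bot_rows
    if lo_bp is not None or hi_bp is not None:
        lo = -cfg.profile_flank_bp if lo_bp is None else lo_bp
        hi = cfg.profile_flank_bp if hi_bp is None else hi_bp
        keep = (distances >= lo) & (distances <= hi)
        distances, mat = distances[keep], mat[:, keep]
    return distances, mat


def smooth_profile(profile: CoorientedProfile, window_bins: int) -> CoorientedProfile:
    """Hann-smooth a profile's values (and strand components if present)."""
    return CoorientedProfile(
        distances=profile.distances,
        values=hann_smooth(profile.values, window_bins),
        n_hotspots=profile.n_hotspots,
        combined=profile.combined,
        top=None if profile.top is None else hann_smooth(profile.top, window_bins),
        bottom_flipped=(None if profile.bottom_flipped is None
                        else hann_smooth(profile.bottom_flipped, window_bins)),
    )


def normalize_to_resection_peak(profile: CoorientedProfile,
                                cfg: AnalysisConfig) -> CoorientedProfile:
    """Background-subtract and scale a profile to its resection peak.

    Subtracts the value at ``+background_offset_bp`` (the co-oriented
    side), divides by the maximum over ``(core_exclusion_bp,
    background_offset_bp]``, and clamps negatives to zero, so the output
    peaks at exactly 1 inside that window and is 0 at the background
    offset. Errors when no resection signal survives subtraction.
    """
    if not profile.combined:
        raise ValueError("peak normalization expects a combined profile")
    bg = profile.value_at(cfg.background_offset_bp)
    shifted = profile.values - bg
    window = (profile.distances > cfg.core_exclusion_bp) \
        & (profile.distances <= cfg.background_offset_bp)
    if not window.any():
        raise ValueError("profile does not cover the resection window")
    peak = shifted[window].max()
    if peak <= 0:
        raise ValueError("no resection signal above background")
    values = np.clip(shifted / peak, 0.0, None)
    return CoorientedProfile(distances=profile.distances, values=values,
                             n_hotspots=profile.n_hotspots, combined=True)
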