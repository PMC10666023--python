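"""DSB peak calling and hotspot-class overlap accounting.

A deliberately minimal, fully specified caller: slide a fixed window
(default 1,000 bp, half-window step) along each chromosome over the
combined-strand raw counts, test each window's count against a Poisson
null with the genome-wide mean rate, Benjamini–Hochberg adjust across all
windows, and merge significant windows within a gap. It is not a
reimplementation of any published caller; it exists to support overlap
accounting between genotypes and hotspot catalogs on equal footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .genome import GenomeSpec, HotspotSet
from .signal import StrandTrack

logger = logging.getLogger("dsbend")


@dataclass(frozen=True)
class Peak:
    """A called peak: merged significant windows with a summit."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float  # -log10 adjusted p
    fold_enrichment: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError("peak start must precede end")
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak")
        if self.score < 0:
            raise ValueError("score must be non-negative")


@dataclass(frozen=True)
class OverlapSummary:
    """Counts of peaks overlapping PRDM9-directed vs default hotspots.

    A peak may overlap both catalogs; the accounting identity
    ``n_overlap_prdm9 + n_overlap_default - n_overlap_both + n_neither
    == n_peaks`` always holds.
    """

    genotype: str
    n_peaks: int
    n_overlap_prdm9: int
    n_overlap_default: int
    n_overlap_both: int
    n_neither: int

    def __post_init__(self) -> None:
        if (self.n_overlap_prdm9 + self.n_overlap_default - self.n_overlap_both
                + self.n_neither != self.n_peaks):
            raise ValueError("overlap accounting identity violated")

    def _frac(self, k: int) -> float:
        return k / self.n_peaks if self.n_peaks else 0.0

    @property
    def frac_prdm9(self) -> float:
        return self._frac(self.n_overlap_prdm9)

    @property
    def frac_default(self) -> float:
        return self._frac(self.n_overlap_default)

    @property
    def frac_both(self) -> float:
        return self._frac(self.n_overlap_both)

    @property
    def frac_neither(self) -> float:
        return self._frac(self.n_neither)


def window_pvalues(track: StrandTrack, window: int = 1000):
    """Per-window Poisson upper-tail p-values on combined-strand counts.

    Windows start every ``window / 2`` bp. Returns
    ``(chroms, starts, counts, pvals)`` as flat arrays across the genome.
    """
    if track.normalized:
        raise ValueError("peak calling operates on raw-count tracks")
    bin_size = track.bin_size
    if window % bin_size != 0 or (window // 2) % bin_size != 0:
        raise ValueError("window and window/2 must be multiples of the bin size")
    wb = window // bin_size
    sb = wb // 2
    total = track.total()
    rate = total / track.genome.total_length  # reads per bp
    mu = rate * window
    combined = track.combined()
    chroms_out, starts_out, counts_out = [], [], []
    for chrom, vec in combined.items():
        nb = len(vec)
        if nb < wb:
            continue
        cum = np.concatenate([[0.0], np.cumsum(vec)])
        starts = np.arange(0, nb - wb + 1, sb)
        counts = cum[starts + wb] - cum[starts]
        chroms_out.append(np.full(len(starts), chrom, dtype=object))
        starts_out.append(starts * bin_size)
        counts_out.append(counts)
    if not chroms_out:
        return (np.array([], dtype=object), np.array([], dtype=int),
                np.array([]), np.array([]))
    chroms = np.concatenate(chroms_out)
    starts = np.concatenate(starts_out)
    counts = np.concatenate(counts_out)
    pvals = stats.poisson.sf(counts - 1, mu) if mu > 0 else np.ones_like(counts)
    return chroms, starts, counts, pvals


def call_peaks(track: StrandTrack, window: int = 1000, q_threshold: float = 0.01,
               merge_gap: int = 500) -> list[Peak]:
    """Call peaks from a combined-strand raw-count track.

    Windows with BH-adjusted Poisson p below ``q_threshold`` are merged
    when within ``merge_gap`` bp. The summit is the maximum-signal bin of
    the merged interval, the score is ``-log10`` of the best adjusted p,
    and fold enrichment is the merged-interval read rate over the
    genome-wide background rate. An empty track yields an empty list.
    """
    chroms, starts, counts, pvals = window_pvalues(track, window)
    if len(pvals) == 0 or track.total() == 0:
        return []
    qvals = stats.false_discovery_control(pvals, method="bh")
    sig = qvals < q_threshold
    if not sig.any():
        return []
    rate = track.total() / track.genome.total_length
    combined = track.combined()
    bin_size = track.bin_size
    peaks: list[Peak] = []
    for chrom in track.genome.chroms:
        sel = sig & (chroms == chrom)
        if not sel.any():
            continue
        s = np.sort(starts[sel])
        q = qvals[sel][np.argsort(starts[sel])]
        # merge windows into intervals closer than merge_gap
        merged: list[list] = []  # [start, end, best_q]
        for st, qq in zip(s, q):
            en = st + window
            if merged and st - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], en)
                merged[-1][2] = min(merged[-1][2], qq)
            else:
                merged.append([int(st), int(en), float(qq)])
        vec = combined[chrom]
        for st, en, best_q in merged:
            en = min(en, track.genome.chroms[chrom])
            b0, b1 = st // bin_size, -(-en // bin_size)
            local = vec[b0:b1]
            summit_bin = b0 + int(np.argmax(local))
            summit = min(summit_bin * bin_size + bin_size // 2, en - 1)
            n_reads = float(local.sum())
            fold = (n_reads / (en - st)) / rate if rate > 0 else np.inf
            score = float(-np.log10(max(best_q, 1e-300)))
            peaks.append(Peak(chrom, st, en, summit, score, fold))
    logger.info("call_peaks: %d peaks from %d windows", len(peaks), len(pvals))
    return peaks


def _overlaps_any(peaks: list[Peak], hotspots: HotspotSet, halfwidth: int) -> np.ndarray:
    """Boolean per peak: any bp intersection with center +/- halfwidth.

    Hotspot intervals have fixed width, so sorted interval starts suffice:
    a peak [ps, pe) overlaps some hotspot iff a hotspot start lies in
    (ps - 2 * halfwidth, pe).
    """
    out = np.zeros(len(peaks), dtype=bool)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in set(hotspots.chrom):
        sel = hotspots.chrom == chrom
        by_chrom[chrom] = np.sort(hotspots.center[sel] - halfwidth)
    for i, pk in enumerate(peaks):
        starts = by_chrom.get(pk.chrom)
        if starts is None:
            continue
        lo = np.searchsorted(starts, pk.start - 2 * halfwidth, side="right")
        hi = np.searchsorted(starts, pk.end, side="left")
        out[i] = hi > lo
    return out


def overlap_with_hotspots(peaks: list[Peak], prdm9: HotspotSet, default: HotspotSet,
                          halfwidth: int = 1000, genotype: str = "") -> OverlapSummary:
    """Tabulate peak overlap with the two hotspot catalogs.

    Hotspot intervals are ``center ± halfwidth``; any bp of intersection
    counts, and a peak may count in both catalogs.
    """
    in_p = _overlaps_any(peaks, prdm9, halfwidth)
    in_d = _overlaps_any(peaks, default, halfwidth)
    return OverlapSummary(
        genotype=genotype,
        n_peaks=len(peaks),
        n_overlap_prdm9=int(in_p.sum()),
        n_overlap_default=int(in_d.sum()),
        n_overlap_both=int((in_p & in_d).sum()),
        n_neither=int((~in_p & ~in_d).sum()),
    )


def interval_signal(track: StrandTrack, interval: tuple[str, int, int]) -> float:
    """Total combined-strand signal over a genomic interval.

    Sums the bins whose start falls inside ``[start, end)``; with an
    RPM-normalized track the result is interval RPM (as used for PAR
    signal summaries). Out-of-bounds intervals raise.
    """
    chrom, start, end = interval
    if chrom not in track.genome:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not (0 <= start < end <= track.genome.chroms[chrom]):
        raise ValueError(f"interval {interval} out of bounds")
    b0 = start // track.bin_size
    b1 = -(-end // track.bin_size)
    vec = track.top[chrom][b0:b1] + track.bottom[chrom][b0:b1]
    return float(vec.sum())


# ---------------------------------------------------------------------------
# peak BED I/O (BED5 + fold-enrichment column)

def write_peaks_bed(peaks: list[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak_{i + 1}\t"
                     f"{pk.score:.6g}\t{pk.fold_enrichment:.6g}\t{pk.summit}\n")


def read_peaks_bed(path: str | Path, genome: GenomeSpec) -> list[Peak]:
    peaks: list[Peak] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "track")):
            continue
        fields = raw.split("\t")
        if len(fields) != 7:
            raise ValueError(f"{path}:{ln}: expected 7 fields")
        chrom, start, end, _name, score, fold, summit = fields
        if chrom not in genome:
            raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
        peaks.append(Peak(chrom, int(start), int(end), int(summit),
                          float(score), float(fold)))
    return peaks
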