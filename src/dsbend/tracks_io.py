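"""File formats and run configuration.

The pipeline touches only plain-text genomic formats: BED6 for end
records, TSV for hotspot catalogs and genome descriptions, bedGraph for
strand-split coverage tracks. All intervals are 0-based half-open;
single-position records occupy width-1 intervals. BED strand "+" maps to
the top strand (rightward resection endpoints) and "-" to the bottom.

:class:`AnalysisConfig` collects the analysis constants: the 151-bp
Hann smoothing window for 1-bp profiles (51 bins for display-binned
tracks), the 2,500-bp background offset, the 100-bp hotspot-core
exclusion, and the 100-bp resection histogram bin.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .genome import CHAR_STRANDS, STRAND_CHARS, BOTTOM, TOP, EndMap, GenomeSpec, HotspotSet

if TYPE_CHECKING:  # pragma: no cover
    from .signal import StrandTrack

logger = logging.getLogger("dsbend")


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants of the end-signal analysis.

    hann_window_bp
        Hann smoothing window applied to 1-bp profiles (odd, bp).
    hann_window_bins
        Hann window in bins for display-binned tracks (odd).
    profile_bin_bp
        Bin size of tracks feeding hotspot-centered profiles.
    display_bin_bp
        Bin size for browser-style plots (10 bp for default-hotspot
        close-ups, 40 bp for PAR-scale views).
    background_offset_bp
        Distance from the hotspot center whose signal estimates the
        background to subtract (bp).
    core_exclusion_bp
        Offsets at or below this are zeroed before resection estimation,
        removing the central recombination-intermediate signal.
    resection_bin_bp
        Width of resection-length histogram bins.
    profile_flank_bp
        Half-width of hotspot-centered profiles.
    hotspot_halfwidth_bp
        Half-width of hotspot intervals for overlap counting.
    resection_min_signal_frac
        Minimum ratio of background-subtracted to raw window signal for a
        resection distribution to count as non-degenerate; background-only
        libraries fall far below it.
    """

    hann_window_bp: int = 151
    hann_window_bins: int = 51
    profile_bin_bp: int = 1
    display_bin_bp: int = 10
    background_offset_bp: int = 2500
    core_exclusion_bp: int = 100
    resection_bin_bp: int = 100
    profile_flank_bp: int = 5000
    hotspot_halfwidth_bp: int = 1000
    resection_min_signal_frac: float = 0.1

    def __post_init__(self) -> None:
        for name in ("hann_window_bp", "hann_window_bins"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3 (got {w})")
        if not (0 < self.core_exclusion_bp < self.background_offset_bp
                <= self.profile_flank_bp):
            raise ValueError("need 0 < core_exclusion_bp < background_offset_bp"
                             " <= profile_flank_bp")
        span = self.background_offset_bp - self.core_exclusion_bp
        if span % self.resection_bin_bp != 0:
            raise ValueError("resection_bin_bp must divide the (core, background] span")
        if self.profile_bin_bp < 1 or self.display_bin_bp < 1:
            raise ValueError("bin sizes must be >= 1 bp")
        if not (0 <= self.resection_min_signal_frac < 1):
            raise ValueError("resection_min_signal_frac must lie in [0, 1)")

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)!r}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Parse a flat key=value config; unknown keys raise (guards typos)."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            caster = float if key == "resection_min_signal_frac" else int
            kwargs[key] = caster(val)
        return cls(**kwargs)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


# ---------------------------------------------------------------------------
# genome description

def write_genome(genome: GenomeSpec, path: str | Path) -> None:
    """Write a genome TSV: one ``chrom<TAB>length`` line per chromosome,
    plus an optional ``#PAR`` line."""
    lines = [f"{c}\t{l}" for c, l in genome.chroms.items()]
    if genome.par is not None:
        c, s, e = genome.par
        lines.append(f"#PAR\t{c}\t{s}\t{e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genome(path: str | Path) -> GenomeSpec:
    chroms: dict[str, int] = {}
    par = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if fields[0] == "#PAR":
            if len(fields) != 4:
                raise ValueError(f"{path}:{ln}: malformed #PAR line")
            par = (fields[1], int(fields[2]), int(fields[3]))
        elif line.startswith("#"):
            continue
        else:
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>length'")
            chroms[fields[0]] = int(fields[1])
    return GenomeSpec(chroms=chroms, par=par)


# ---------------------------------------------------------------------------
# end records (BED6)

def write_endmap_bed(ends: EndMap, path: str | Path) -> None:
    """Write end records as BED6; each record is a width-1 interval and
    "+" denotes the top strand."""
    with open(path, "w") as fh:
        for i in range(len(ends)):
            p = ends.pos[i]
            fh.write(f"{ends.chrom[i]}\t{p}\t{p + 1}\t.\t0\t"
                     f"{STRAND_CHARS[int(ends.strand[i])]}\n")


def read_endmap_bed(path: str | Path, genome: GenomeSpec) -> EndMap:
    """Read BED6 end records, validating positions against the genome.

    Malformed lines, unknown chromosomes and out-of-bounds positions raise
    with the offending line number or coordinate.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[int] = []
    n_lines = 0
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        fields = raw.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{ln}: expected BED6 (6 tab-separated fields)")
        chrom, start, _end, _name, _score, strand = fields[:6]
        if chrom not in genome:
            raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
        if strand not in CHAR_STRANDS:
            raise ValueError(f"{path}:{ln}: strand must be '+' or '-'")
        try:
            pos = int(start)
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: non-integer start {start!r}") from err
        if not (0 <= pos < genome.chroms[chrom]):
            raise ValueError(f"{path}:{ln}: position {chrom}:{pos} out of bounds")
        chroms.append(chrom)
        poss.append(pos)
        strands.append(CHAR_STRANDS[strand])
        n_lines += 1
    logger.info("read_endmap_bed: %d records from %s", n_lines, path)
    return EndMap(np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
                  np.array(strands, dtype=np.uint8))


# ---------------------------------------------------------------------------
# hotspot catalogs

def write_hotspots(hotspots: HotspotSet, path: str | Path) -> None:
    """Write a hotspot TSV: chrom, center, heat, class."""
    with open(path, "w") as fh:
        fh.write("chrom\tcenter\theat\tclass\n")
        for i in range(len(hotspots)):
            fh.write(f"{hotspots.chrom[i]}\t{hotspots.center[i]}\t"
                     f"{hotspots.heat[i]:.17g}\t{hotspots.hclass[i]}\n")


def read_hotspots(path: str | Path, genome: GenomeSpec) -> HotspotSet:
    chroms: list[str] = []
    centers: list[int] = []
    heats: list[float] = []
    classes: list[str] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if fields[0] == "chrom":  # header
            continue
        if len(fields) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
        chrom, center_s, heat_s, cls = fields
        if chrom not in genome:
            raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
        try:
            center, heat = int(center_s), float(heat_s)
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: malformed numeric field") from err
        if not (0 <= center < genome.chroms[chrom]):
            raise ValueError(f"{path}:{ln}: center {chrom}:{center} out of bounds")
        if heat < 0:
            raise ValueError(f"{path}:{ln}: negative heat {heat}")
        if cls not in ("prdm9", "default"):
            raise ValueError(f"{path}:{ln}: unknown hotspot class {cls!r}")
        chroms.append(chrom)
        centers.append(center)
        heats.append(heat)
        classes.append(cls)
    logger.info("read_hotspots: %d hotspots from %s", len(centers), path)
    return HotspotSet(np.array(chroms, dtype=object), np.array(centers, dtype=np.int64),
                      np.array(heats), np.array(classes, dtype=object))


def write_hotspots_bed(hotspots: HotspotSet, path: str | Path, halfwidth: int,
                       genome: GenomeSpec | None = None) -> None:
    """Write hotspot intervals (center ± halfwidth) as BED, clipped to the
    genome when one is given."""
    with open(path, "w") as fh:
        for i in range(len(hotspots)):
            c = hotspots.chrom[i]
            start = max(0, int(hotspots.center[i]) - halfwidth)
            end = int(hotspots.center[i]) + halfwidth
            if genome is not None:
                end = min(end, genome.chroms[c])
            fh.write(f"{c}\t{start}\t{end}\t{hotspots.hclass[i]}\t"
                     f"{hotspots.heat[i]:.6g}\t.\n")


# ---------------------------------------------------------------------------
# bedGraph tracks

def write_bedgraph(track: "StrandTrack", strand: int, path: str | Path) -> None:
    """Write one strand of a coverage track as bedGraph.

    Zero bins are omitted; runs of equal values are merged into single
    intervals. A comment header records ``n_mapped``, ``bin_size`` and the
    normalization flag so the track round-trips.
    """
    vectors = track.top if strand == TOP else track.bottom
    with open(path, "w") as fh:
        fh.write(f"# dsbend bedgraph strand={STRAND_CHARS[strand]} "
                 f"bin_size={track.bin_size} n_mapped={track.n_mapped} "
                 f"normalized={int(track.normalized)}\n")
        for chrom, vec in vectors.items():
            nz = np.flatnonzero(vec)
            if len(nz) == 0:
                continue
            # merge consecutive equal-value bins
            breaks = np.flatnonzero((np.diff(nz) != 1)
                                    | (np.diff(vec[nz]) != 0)) + 1
            for seg in np.split(nz, breaks):
                start = int(seg[0]) * track.bin_size
                end = min((int(seg[-1]) + 1) * track.bin_size, track.genome.chroms[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\t{vec[seg[0]]:.10g}\n")


def read_bedgraph_pair(prefix: str | Path, genome: GenomeSpec) -> "StrandTrack":
    """Read ``<prefix>.top.bedgraph`` / ``<prefix>.bottom.bedgraph`` back
    into a StrandTrack (inverse of the coverage CLI output)."""
    from .signal import StrandTrack  # deferred: avoid import cycle

    meta: dict[str, int] = {}

    def read_one(path: Path) -> dict[str, np.ndarray]:
        header = path.read_text().splitlines()
        if not header or not header[0].startswith("# dsbend bedgraph"):
            raise ValueError(f"{path}: missing dsbend bedgraph header")
        for tok in header[0].split():
            k, _, v = tok.partition("=")
            if k in ("bin_size", "n_mapped", "normalized"):
                meta[k] = int(v)
        bin_size = meta["bin_size"]
        vecs = {c: np.zeros(-(-l // bin_size)) for c, l in genome.chroms.items()}
        for ln, raw in enumerate(header[1:], start=2):
            if not raw.strip():
                continue
            chrom, start, end, value = raw.split("\t")
            if chrom not in genome:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            b0, b1 = int(start) // bin_size, -(-int(end) // bin_size)
            vecs[chrom][b0:b1] = float(value)
        return vecs

    top = read_one(Path(f"{prefix}.top.bedgraph"))
    bottom = read_one(Path(f"{prefix}.bottom.bedgraph"))
    return StrandTrack(genome=genome, bin_size=meta["bin_size"], top=top, bottom=bottom,
                       n_mapped=meta["n_mapped"], normalized=bool(meta["normalized"]))
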