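"""Coordinate-frame containers for DSB end-mapping data.

Everything downstream — coverage tracks, hotspot-centered profiles, peak
calls — lives in the coordinate frame defined by a :class:`GenomeSpec`:
a set of named chromosomes with lengths and, optionally, a pseudoautosomal
region (PAR) interval where per-kb DSB activity is expected to be unusually
high in males.

Positions are 0-based throughout; intervals are half-open ``[start, end)``.
Strand is encoded as ``TOP`` (reads mapping to the plus strand, marking
rightward resection endpoints) and ``BOTTOM`` (minus strand, leftward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

TOP: int = 0
BOTTOM: int = 1

STRAND_CHARS = {TOP: "+", BOTTOM: "-"}
CHAR_STRANDS = {"+": TOP, "-": BOTTOM}

HOTSPOT_CLASSES = ("prdm9", "default")


@dataclass(frozen=True)
class GenomeSpec:
    """Named chromosome lengths plus an optional PAR interval.

    Parameters
    ----------
    chroms
        Mapping of chromosome name to length in bp. Order is preserved and
        defines the canonical chromosome order for all outputs.
    par
        Optional ``(chrom, start, end)`` 0-based half-open interval marking
        the pseudoautosomal region. Must lie within its chromosome.
    """

    chroms: dict[str, int]
    par: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if not self.chroms:
            raise ValueError("GenomeSpec requires at least one chromosome")
        for name, length in self.chroms.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.par is not None:
            chrom, start, end = self.par
            if chrom not in self.chroms:
                raise ValueError(f"PAR chromosome {chrom!r} not in genome")
            if not (0 <= start < end <= self.chroms[chrom]):
                raise ValueError(f"PAR interval {self.par} outside chromosome bounds")

    @property
    def total_length(self) -> int:
        return sum(self.chroms.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms


@dataclass(frozen=True)
class Hotspot:
    """A single DSB hotspot: a center position with a relative heat."""

    chrom: str
    center: int
    heat: float
    hclass: str

    def __post_init__(self) -> None:
        if self.heat < 0:
            raise ValueError("hotspot heat must be non-negative")
        if self.hclass not in HOTSPOT_CLASSES:
            raise ValueError(f"hotspot class must be one of {HOTSPOT_CLASSES}")


@dataclass
class HotspotSet:
    """DSB hotspot catalog held as parallel arrays.

    ``hclass`` distinguishes PRDM9-directed hotspots from "default"
    (promoter/CpG-island) hotspots used when PRDM9 targeting is absent.
    """

    chrom: np.ndarray  # str
    center: np.ndarray  # int64
    heat: np.ndarray  # float64
    hclass: np.ndarray  # str, values in HOTSPOT_CLASSES

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.center = np.asarray(self.center, dtype=np.int64)
        self.heat = np.asarray(self.heat, dtype=np.float64)
        self.hclass = np.asarray(self.hclass, dtype=object)
        n = len(self.center)
        if not (len(self.chrom) == len(self.heat) == len(self.hclass) == n):
            raise ValueError("HotspotSet arrays must have equal length")
        if n and (self.heat < 0).any():
            raise ValueError("hotspot heats must be non-negative")
        if n:
            bad = set(self.hclass) - set(HOTSPOT_CLASSES)
            if bad:
                raise ValueError(f"unknown hotspot classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.center)

    def __iter__(self) -> Iterator[Hotspot]:
        for i in range(len(self)):
            yield Hotspot(self.chrom[i], int(self.center[i]), float(self.heat[i]), self.hclass[i])

    @classmethod
    def empty(cls) -> "HotspotSet":
        return cls(np.array([], dtype=object), np.array([], dtype=np.int64),
                   np.array([], dtype=np.float64), np.array([], dtype=object))

    @classmethod
    def concat(cls, sets: list["HotspotSet"]) -> "HotspotSet":
        if not sets:
            return cls.empty()
        return cls(
            np.concatenate([s.chrom for s in sets]),
            np.concatenate([s.center for s in sets]),
            np.concatenate([s.heat for s in sets]),
            np.concatenate([s.hclass for s in sets]),
        )

    def subset(self, mask: np.ndarray) -> "HotspotSet":
        return HotspotSet(self.chrom[mask], self.center[mask], self.heat[mask], self.hclass[mask])

    def validate(self, genome: GenomeSpec) -> None:
        """Check every center lies within its chromosome."""
        for i in range(len(self)):
            c = self.chrom[i]
            if c not in genome:
                raise ValueError(f"hotspot on unknown chromosome {c!r}")
            if not (0 <= self.center[i] < genome.chroms[c]):
                raise ValueError(
                    f"hotspot center {c}:{self.center[i]} outside chromosome bounds")

    def in_par(self, genome: GenomeSpec) -> np.ndarray:
        """Boolean mask of hotspots whose center lies inside the PAR."""
        mask = np.zeros(len(self), dtype=bool)
        if genome.par is None or len(self) == 0:
            return mask
        chrom, start, end = genome.par
        on = self.chrom == chrom
        mask[on] = (self.center[on] >= start) & (self.center[on] < end)
        return mask


@dataclass
class EndMap:
    """Mapped, blunted DNA-end records: (chrom, 0-based position, strand).

    The raw input of the pipeline. Top-strand records mark rightward
    resection endpoints, bottom-strand records leftward ones; reads near
    hotspot centers may instead derive from recombination intermediates
    (the "central signal").
    """

    chrom: np.ndarray  # str
    pos: np.ndarray  # int64
    strand: np.ndarray  # uint8, TOP or BOTTOM

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=np.uint8)
        if not (len(self.chrom) == len(self.pos) == len(self.strand)):
            raise ValueError("EndMap arrays must have equal length")
        if len(self.strand) and not np.isin(self.strand, [TOP, BOTTOM]).all():
            raise ValueError("strand values must be TOP (0) or BOTTOM (1)")

    @property
    def n_mapped(self) -> int:
        return len(self.pos)

    def __len__(self) -> int:
        return len(self.pos)

    @classmethod
    def empty(cls) -> "EndMap":
        return cls(np.array([], dtype=object), np.array([], dtype=np.int64),
                   np.array([], dtype=np.uint8))

    @classmethod
    def concat(cls, maps: list["EndMap"]) -> "EndMap":
        if not maps:
            return cls.empty()
        return cls(
            np.concatenate([m.chrom for m in maps]),
            np.concatenate([m.pos for m in maps]),
            np.concatenate([m.strand for m in maps]),
        )

    def validate(self, genome: GenomeSpec) -> None:
        for name in set(self.chrom):
            if name not in genome:
                raise ValueError(f"end record on unknown chromosome {name!r}")
            sel = self.chrom == name
            p = self.pos[sel]
            if len(p) and (p.min() < 0 or p.max() >= genome.chroms[name]):
                raise ValueError(f"end position outside chromosome {name!r}")
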