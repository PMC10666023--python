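"""Synthetic generator of resected meiotic DSB read ends.

Emulates the statistical structure that strand-specific DSB end-mapping
(exonuclease-blunted end sequencing) assumes: DSBs form at hotspots with
probability proportional to hotspot heat; 5'->3' resection places the top
strand endpoint to the right of the break and the bottom strand endpoint
to the left, at distances drawn from a gamma distribution; a fraction of
hotspot reads instead reports recombination intermediates near the center
("central signal"); and a uniform genome-wide background accounts for
DSB-independent library material.

Genotype presets bundle the parameter contrasts of interest:

``wildtype``
    PRDM9-directed hotspots dominate, the PAR is strongly boosted, mean
    resection 800 nt (gamma shape 16, scale 50).
``ankrd31_null_like``
    Elevated default-hotspot usage, no PAR boost, mean resection 700 nt
    (shape 14, scale 50) — a ~100 nt decrease versus wildtype.
``ea_like``
    Wildtype-like landscape with an intermediate PAR boost.
``spo11_null``
    Background only: no programmed DSBs at all.

All randomness comes from one ``numpy.random.default_rng`` seeded per
call; identical seeds give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import BOTTOM, TOP, EndMap, GenomeSpec, HotspotSet

_FRACTION_TOL = 1e-9

PRESET_NAMES = ("wildtype", "ankrd31_null_like", "ea_like", "spo11_null")


@dataclass(frozen=True)
class GenotypeParams:
    """Generative parameters for one genotype.

    Fractions partition reads into PRDM9-hotspot, default-hotspot and
    background categories and must sum to 1. ``frac_central`` is the
    probability that a hotspot-assigned read reports a recombination
    intermediate (uniform within ``center ± central_halfwidth``) rather
    than a resection endpoint. Resection lengths in nt are
    ``Gamma(resection_shape, resection_scale)`` so the mean resection
    length is ``shape * scale``. ``par_boost`` multiplies the selection
    heat of hotspots inside the PAR; 0 removes PAR signal entirely.
    """

    total_reads: int = 250_000
    frac_prdm9: float = 0.75
    frac_default: float = 0.05
    frac_background: float = 0.20
    frac_central: float = 0.15
    resection_shape: float = 16.0
    resection_scale: float = 50.0
    dsb_jitter_sd: float = 50.0
    central_halfwidth: float = 100.0
    par_boost: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_prdm9, self.frac_default, self.frac_background, self.frac_central)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("all fractions must lie in [0, 1]")
        s = self.frac_prdm9 + self.frac_default + self.frac_background
        if abs(s - 1.0) > _FRACTION_TOL:
            raise ValueError(f"category fractions must sum to 1 (got {s!r})")
        if self.resection_shape <= 0 or self.resection_scale <= 0:
            raise ValueError("gamma resection parameters must be positive")
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")
        if self.dsb_jitter_sd < 0 or self.central_halfwidth < 0:
            raise ValueError("jitter sd and central halfwidth must be non-negative")
        if self.par_boost < 0:
            raise ValueError("par_boost must be non-negative")

    @property
    def mean_resection(self) -> float:
        """Expected resection length in nt (gamma mean, shape * scale)."""
        return self.resection_shape * self.resection_scale

    def replace(self, **kwargs) -> "GenotypeParams":
        return dataclasses.replace(self, **kwargs)

    def to_file(self, path: str | Path) -> None:
        """Serialize as a flat ``key = value`` text file."""
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "GenotypeParams":
        """Parse a flat key=value file; unknown keys are an error."""
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}")
            kwargs[key] = int(val) if key in ("total_reads", "seed") else float(val)
        return cls(**kwargs)


def genotype_preset(name: str) -> GenotypeParams:
    """Return the parameter bundle for a named genotype preset.

    Raises ``ValueError`` listing valid names if ``name`` is unknown.
    """
    if name == "wildtype":
        return GenotypeParams()
    if name == "ankrd31_null_like":
        return GenotypeParams(frac_prdm9=0.45, frac_default=0.35, frac_background=0.20,
                              resection_shape=14.0, par_boost=0.0)
    if name == "ea_like":
        return GenotypeParams(frac_prdm9=0.72, frac_default=0.08, frac_background=0.20,
                              par_boost=5.0)
    if name == "spo11_null":
        return GenotypeParams(frac_prdm9=0.0, frac_default=0.0, frac_background=1.0,
                              frac_central=0.0)
    raise ValueError(f"unknown genotype preset {name!r}; valid: {', '.join(PRESET_NAMES)}")


def example_genome() -> GenomeSpec:
    """Small multi-chromosome genome with a PAR, used by examples and tests.

    35 Mb total: three autosomes plus a short sex chromosome carrying a
    700 kb PAR near its distal end (the mouse PAR is ~700 kb).
    """
    return GenomeSpec(
        chroms={"chr1": 12_000_000, "chr2": 10_000_000, "chr3": 8_000_000,
                "chrX": 5_000_000},
        par=("chrX", 4_200_000, 4_900_000),
    )


def example_catalog(genome: GenomeSpec | None = None, n_prdm9: int = 180,
                    n_default: int = 90, n_par: int = 5,
                    min_spacing: int = 20_000, heat_shape: float = 2.5,
                    seed: int = 11) -> tuple[HotspotSet, HotspotSet]:
    """Standard study catalog at mouse-like hotspot density.

    Scaled to the 35 Mb example genome, ~270 hotspots reproduce the
    genome-average spacing of real catalogs (one hotspot per ~130-190 kb),
    so a PAR-length window holds only a handful of hotspots. Because the
    PAR is intrinsically hotspot-carrying - its high per-kb DSB activity
    is the reason for ``par_boost`` - the catalog guarantees it ``n_par``
    PRDM9-class hotspots (the genome-average expectation for its length)
    rather than leaving their presence to chance.

    Returns ``(prdm9, default)`` hotspot sets.
    """
    if genome is None:
        genome = example_genome()
    prdm9 = simulate_hotspots(genome, n_prdm9, heat_shape=heat_shape,
                              hclass="prdm9", min_spacing=min_spacing, seed=seed)
    if n_par > 0 and genome.par is not None:
        chrom, start, end = genome.par
        par_genome = GenomeSpec(chroms={chrom: end - start})
        spacing = min((end - start) // max(n_par, 1) // 2, min_spacing)
        par_hs = simulate_hotspots(par_genome, n_par, heat_shape=heat_shape,
                                   hclass="prdm9", min_spacing=spacing,
                                   seed=seed + 101)
        par_hs = HotspotSet(par_hs.chrom, par_hs.center + start, par_hs.heat,
                            par_hs.hclass)
        prdm9 = HotspotSet.concat([prdm9, par_hs])
    default = simulate_hotspots(genome, n_default, heat_shape=heat_shape,
                                hclass="default", min_spacing=min_spacing,
                                seed=seed + 1)
    return prdm9, default


def _allocate_counts(rng: np.random.Generator, lengths: np.ndarray, capacity: np.ndarray,
                     n: int) -> np.ndarray:
    """Multinomial allocation over chromosomes, repaired to respect capacity."""
    if capacity.sum() < n:
        raise ValueError("genome too small: cannot place hotspots at this spacing")
    counts = rng.multinomial(n, lengths / lengths.sum())
    # move surplus from over-capacity chromosomes to ones with headroom
    for _ in range(len(lengths) * 2 + 1):
        over = counts - capacity
        surplus = int(over[over > 0].sum())
        if surplus == 0:
            break
        counts = np.minimum(counts, capacity)
        room = capacity - counts
        order = np.argsort(-room)
        for i in order:
            take = min(surplus, int(room[i]))
            counts[i] += take
            surplus -= take
            if surplus == 0:
                break
    if (counts > capacity).any() or counts.sum() != n:
        raise ValueError("genome too small: cannot place hotspots at this spacing")
    return counts


def simulate_hotspots(genome: GenomeSpec, n: int, heat_shape: float = 2.5,
                      hclass: str = "prdm9", min_spacing: int = 10_000,
                      seed: int = 0) -> HotspotSet:
    """Draw a synthetic hotspot catalog.

    Centers are uniform per chromosome subject to a pairwise minimum
    spacing (enforced exactly via the order-statistics spacing transform);
    heats are Gamma(``heat_shape``, scale 1), a heavy-tailed spectrum like
    observed hotspot heat maps.

    Parameters
    ----------
    n
        Number of hotspots. ``n * min_spacing`` must be smaller than the
        genome length.
    hclass
        Class label applied to all hotspots ("prdm9" or "default").
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return HotspotSet.empty()
    if min_spacing < 0:
        raise ValueError("min_spacing must be non-negative")
    if n * min_spacing >= genome.total_length:
        raise ValueError("genome too small: n * min_spacing exceeds genome length")
    rng = np.random.default_rng(seed)
    names = list(genome.chroms)
    lengths = np.array([genome.chroms[c] for c in names], dtype=float)
    if min_spacing > 0:
        capacity = np.floor((lengths - 1) / min_spacing).astype(int) + 1
    else:
        capacity = np.full(len(names), n, dtype=int)
    counts = _allocate_counts(rng, lengths, capacity, n)

    chroms: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    for name, length, k in zip(names, lengths, counts):
        if k == 0:
            continue
        # sample k sorted uniforms on the shrunken interval, then re-inflate:
        # guarantees pairwise spacing >= min_spacing with uniform placement
        span = length - (k - 1) * min_spacing
        u = np.sort(rng.random(int(k))) * span
        pos = np.floor(u).astype(np.int64) + min_spacing * np.arange(int(k), dtype=np.int64)
        chroms.append(np.full(int(k), name, dtype=object))
        centers.append(pos)
    heat = rng.gamma(heat_shape, 1.0, size=n)
    hs = HotspotSet(np.concatenate(chroms), np.concatenate(centers), heat,
                    np.full(n, hclass, dtype=object))
    hs.validate(genome)
    return hs


def _clip_to_chroms(genome: GenomeSpec, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    lens = np.fromiter((genome.chroms[c] for c in chrom), dtype=np.int64, count=len(chrom))
    return np.clip(pos, 0, lens - 1)


def simulate_end_reads(genome: GenomeSpec, hotspots: HotspotSet,
                       params: GenotypeParams) -> EndMap:
    """Simulate one genotype's mapped end records.

    Reads are partitioned multinomially into the prdm9 / default /
    background categories. Hotspot-assigned reads select a hotspot of the
    matching class with probability proportional to heat (PAR hotspots
    multiplied by ``par_boost``); the DSB center is the hotspot center
    plus Gaussian jitter. With probability ``frac_central`` a read is a
    central recombination-intermediate signal (fair-coin strand, uniform
    within ``± central_halfwidth``); otherwise it is a resection endpoint:
    fair-coin strand, length ``l ~ Gamma(shape, scale)``, position
    ``center + l`` on the top strand, ``center - l`` on the bottom.
    Background reads are uniform over the genome. Positions are clipped to
    chromosome bounds. Deterministic for a fixed ``params.seed``.
    """
    if len(hotspots) == 0 and params.frac_background != 1.0:
        raise ValueError("hotspot set may be empty only when frac_background == 1")
    rng = np.random.default_rng(params.seed)
    n_p, n_d, n_b = rng.multinomial(
        params.total_reads,
        [params.frac_prdm9, params.frac_default, params.frac_background])

    parts: list[EndMap] = []
    par_mask_all = hotspots.in_par(genome) if len(hotspots) else None
    for cls_name, n_class in (("prdm9", int(n_p)), ("default", int(n_d))):
        if n_class == 0:
            continue
        cls_mask = hotspots.hclass == cls_name
        sub = hotspots.subset(cls_mask)
        if len(sub) == 0:
            raise ValueError(f"no {cls_name} hotspots available but frac_{cls_name} > 0")
        w = sub.heat.copy()
        if genome.par is not None and params.par_boost != 1.0:
            w[par_mask_all[cls_mask]] *= params.par_boost
        total_w = w.sum()
        if total_w <= 0:
            raise ValueError(f"total selection heat for class {cls_name!r} is zero")
        idx = rng.choice(len(sub), size=n_class, p=w / total_w)
        centers = sub.center[idx].astype(float)
        if params.dsb_jitter_sd > 0:
            centers = centers + rng.normal(0.0, params.dsb_jitter_sd, n_class)
        central = rng.random(n_class) < params.frac_central
        strand = rng.integers(0, 2, n_class).astype(np.uint8)
        lengths = rng.gamma(params.resection_shape, params.resection_scale, n_class)
        pos = np.where(strand == TOP, centers + lengths, centers - lengths)
        if central.any():
            upos = centers + rng.uniform(-params.central_halfwidth,
                                         params.central_halfwidth, n_class)
            pos = np.where(central, upos, pos)
        pos = np.rint(pos).astype(np.int64)
        chrom = sub.chrom[idx]
        pos = _clip_to_chroms(genome, chrom, pos)
        parts.append(EndMap(chrom, pos, strand))

    if n_b > 0:
        names = list(genome.chroms)
        lengths = np.array([genome.chroms[c] for c in names], dtype=float)
        counts = rng.multinomial(int(n_b), lengths / lengths.sum())
        bg_chrom = np.concatenate([np.full(int(k), c, dtype=object)
                                   for c, k in zip(names, counts)]) if n_b else np.array([], dtype=object)
        bg_pos = np.concatenate([rng.integers(0, genome.chroms[c], int(k))
                                 for c, k in zip(names, counts)]).astype(np.int64)
        bg_strand = rng.integers(0, 2, int(n_b)).astype(np.uint8)
        parts.append(EndMap(bg_chrom, bg_pos, bg_strand))

    ends = EndMap.concat(parts)
    ends.validate(genome)
    return ends
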