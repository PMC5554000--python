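"""Synthetic hybrid genomes, meioses and return-to-growth (RTG) tetrads.

The simulator emulates the statistical structure of a tetrad-sequencing study
of a hybrid yeast: eight chromosomes totalling ~12 Mb, dense heterozygous
markers (~200 bp median spacing), crossovers (COs) placed by a stationary
gamma renewal process (shape ``k`` models interference, ``k = 1`` is a
Poisson process), CO-associated and non-crossover (NCO) conversion tracts
with right-skewed lengths, a recombination coldspot arm, and a pericentromeric
halo where no event may convert markers.

Return-to-growth is modelled mechanistically: a first meiotic prophase
recombines the four chromatids, the cell then aborts meiosis and segregates
mitotically, retaining one chromatid per homolog under the constraint that
centromeres stay heterozygous, and the resulting diploid undergoes a second,
complete meiosis.  Prophase single COs thereby become double COs or loss-of-
heterozygosity (LOH) tracts, and prophase conversions become 4:0 tracts, all
of which are exported as ground-truth events for caller validation.

Every public entry point takes an explicit seed; per-tetrad substreams are
derived deterministically from it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import RecombEvent
from .markers import MarkerMap

_BASES = np.array(list("ACGT"))


# ----------------------------------------------------------------------------------
# genome model
# ----------------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes, centromeres and special regions of the model genome.

    ``excluded_regions`` are masked from marker placement and analysis
    (subtelomere-style); ``coldspots`` carry markers but no recombination
    event may initiate inside them.  All intervals are 0-based half-open.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, int]
    excluded_regions: tuple[tuple[str, int, int], ...] = ()
    coldspots: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, L in self.chromosomes:
            if L <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            cen = self.centromeres.get(name)
            if cen is None or not (0 <= cen <= L):
                raise ValueError(f"centromere of {name} missing or out of bounds")
        for kind, regions in (("excluded", self.excluded_regions), ("coldspot", self.coldspots)):
            for chrom, start, end in regions:
                if chrom not in lengths:
                    raise ValueError(f"{kind} region on unknown chromosome {chrom}")
                if not (0 <= start < end <= lengths[chrom]):
                    raise ValueError(f"{kind} region ({chrom}, {start}, {end}) out of bounds")

    # -- derived quantities -------------------------------------------------------
    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(L for _, L in self.chromosomes)

    def regions_on(self, chrom: str, kind: str = "coldspot") -> list[tuple[int, int]]:
        regions = self.coldspots if kind == "coldspot" else self.excluded_regions
        return [(s, e) for c, s, e in regions if c == chrom]

    def coldspot_mass(self) -> int:
        return sum(e - s for _, s, e in self.coldspots)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c for c, _ in self.chromosomes],
                "length": [L for _, L in self.chromosomes],
                "centromere": [self.centromeres[c] for c, _ in self.chromosomes],
            }
        )


#: default genome: 8 chromosomes, 12 Mb total, one 1-Mb coldspot left arm
_DEFAULT_CHROMS: tuple[tuple[str, int], ...] = (
    ("chrA", 1_050_000),
    ("chrB", 1_300_000),
    ("chrC", 1_800_000),
    ("chrD", 1_550_000),
    ("chrE", 1_600_000),
    ("chrF", 1_750_000),
    ("chrG", 1_350_000),
    ("chrH", 1_600_000),
)
_DEFAULT_CENTROMERES: dict[str, int] = {
    "chrA": 480_000,
    "chrB": 600_000,
    "chrC": 1_050_000,
    "chrD": 700_000,
    "chrE": 750_000,
    "chrF": 820_000,
    "chrG": 610_000,
    "chrH": 730_000,
}


def default_genome() -> GenomeModel:
    """The default 12-Mb, 8-chromosome hybrid genome with a 1-Mb coldspot arm."""
    return GenomeModel(
        chromosomes=_DEFAULT_CHROMS,
        centromeres=dict(_DEFAULT_CENTROMERES),
        coldspots=(("chrC", 0, 1_000_000),),
    )


def build_genome(config: Mapping) -> GenomeModel:
    """Build a :class:`GenomeModel` from a plain configuration mapping.

    Expected keys: ``chromosomes`` (list of ``[name, length]``),
    ``centromeres`` (mapping), optional ``excluded_regions`` and ``coldspots``
    (lists of ``[chrom, start, end]``).  An empty/missing config yields
    :func:`default_genome`.
    """
    if not config:
        return default_genome()
    chroms = tuple((str(n), int(L)) for n, L in config["chromosomes"])
    centromeres = {str(k): int(v) for k, v in config.get("centromeres", {}).items()}
    if not centromeres:  # default: mid-chromosome
        centromeres = {n: L // 2 for n, L in chroms}
    as_regions = lambda key: tuple(
        (str(c), int(s), int(e)) for c, s, e in config.get(key, [])
    )
    return GenomeModel(chroms, centromeres, as_regions("excluded_regions"), as_regions("coldspots"))


# ----------------------------------------------------------------------------------
# simulation parameters
# ----------------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Tunable parameters of the meiosis / RTG simulator.

    ``co_per_meiosis_mean`` is the calibration target for the expected number
    of COs per meiosis over the analyzed (non-coldspot) genome; when set, the
    gamma renewal scale is rescaled internally so the realized rate matches
    while the shape ``gamma_shape_k`` (interference strength) is preserved.
    Set it to ``None`` to use ``gamma_scale_theta`` (kb) literally.

    Conversion tract lengths are lognormal, parameterized by their median (kb)
    and a log-sd of ``tract_log_sd``.  ``rtg_probability`` is the per-tetrad
    chance that the tetrad derives from an RTG diploid rather than a direct
    meiosis.  ``centromere_halo_bp`` is the pericentromeric radius kept free
    of conversion tracts so that centromere-linked markers stay heterozygous.
    """

    co_per_meiosis_mean: float | None = 19.9
    nco_per_meiosis_mean: float = 5.6
    gamma_shape_k: float = 1.47
    gamma_scale_theta: float = 187.0
    co_tract_median_kb: float = 2.9
    nco_tract_median_kb: float = 2.2
    tract_log_sd: float = 0.8
    obligate_co: bool = False
    rtg_probability: float = 0.0
    na_rate: float = 0.0
    centromere_halo_bp: int = 5_000
    #: optional site-specific homing-endonuclease hotspot, modeled after the
    #: meiotic homing of an intein-encoded endonuclease: (chrom, pos_bp,
    #: cut_probability, carrier_parent 0/1).  With the given probability per
    #: meiosis, one chromatid carrying the empty allele is cut at the locus
    #: and converted toward the carrier, with or without an associated CO.
    homing_hotspot: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.co_per_meiosis_mean is not None and self.co_per_meiosis_mean < 0:
            raise ValueError("co_per_meiosis_mean must be >= 0")
        if self.nco_per_meiosis_mean < 0:
            raise ValueError("nco_per_meiosis_mean must be >= 0")
        if self.gamma_shape_k <= 0 or self.gamma_scale_theta <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if not 0 <= self.rtg_probability <= 1:
            raise ValueError("rtg_probability must lie in [0, 1]")
        if not 0 <= self.na_rate < 1:
            raise ValueError("na_rate must lie in [0, 1)")
        if min(self.co_tract_median_kb, self.nco_tract_median_kb) < 0:
            raise ValueError("tract medians must be >= 0")

    # -- derived ------------------------------------------------------------------
    def mean_tract_bp(self, which: str = "co") -> float:
        med = self.co_tract_median_kb if which == "co" else self.nco_tract_median_kb
        return med * 1000.0 * math.exp(self.tract_log_sd**2 / 2.0)

    def analyzed_mass_bp(self, genome: GenomeModel) -> float:
        """Genome mass where a CO may initiate and convert markers."""
        mass = float(genome.total_length - genome.coldspot_mass())
        halo = self.centromere_halo_bp
        for chrom, L in genome.chromosomes:
            cen = genome.centromeres[chrom]
            lo, hi = max(0, cen - halo), min(L, cen + halo)
            # subtract halo, minus any part already inside a coldspot
            overlap = sum(
                max(0, min(hi, e) - max(lo, s)) for s, e in genome.regions_on(chrom)
            )
            mass -= (hi - lo) - overlap
            mass -= self.mean_tract_bp("co")  # tract-overlap thinning around the halo
        return max(mass, 1.0)

    def renewal_scale_bp(self, genome: GenomeModel) -> float:
        """Gamma renewal scale in bp, calibrated to ``co_per_meiosis_mean``."""
        if self.co_per_meiosis_mean is None:
            return self.gamma_scale_theta * 1000.0
        if self.co_per_meiosis_mean == 0:
            return math.inf
        return self.analyzed_mass_bp(genome) / (self.gamma_shape_k * self.co_per_meiosis_mean)

    # -- IO -----------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimParams":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


# ----------------------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------------------


@dataclass
class TetradGenotypes:
    """Genotypes of the four spores of one tetrad over a marker map."""

    marker_map: MarkerMap
    codes: np.ndarray  # (n_markers, 4) int8, 0=P1 1=P2 -1=NA
    name: str = "tetrad"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.marker_map), 4):
            raise ValueError("codes must be (n_markers, 4)")

    def chrom_codes(self, chrom: str) -> np.ndarray:
        a, b = self.marker_map.chrom_range(chrom)
        return self.codes[a:b]

    def to_tsv(self, path: str | Path) -> None:
        lab = np.array(["NA", "P1", "P2"], dtype=object)
        frame = self.marker_map.frame[["chrom", "pos"]].copy()
        for s in range(4):
            frame[f"{self.name}_s{s + 1}"] = lab[self.codes[:, s] + 1]
        frame.to_csv(path, sep="\t", index=False)


@dataclass
class TruthEventSet:
    """Ground-truth simulated events, with exact coordinates and provenance.

    Provenance values: ``meiosis`` (events of the final meiosis),
    ``rtg_prophase`` (raw prophase events of the aborted first meiosis) and
    ``rtg`` (the observable signatures those prophase events leave in the
    retained diploid: LOH tracts, short 4:0 tracts, double-CO points).
    """

    events: list[RecombEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def select(self, cls: str | None = None, provenance: str | None = None) -> list[RecombEvent]:
        return [
            e
            for e in self.events
            if (cls is None or e.cls == cls) and (provenance is None or e.provenance == provenance)
        ]

    def per_chrom_counts(self, cls: str, provenance: str | None = None) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.select(cls, provenance):
            out[e.chrom] = out.get(e.chrom, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        from .events import events_to_frame

        return events_to_frame(self.events)


# ----------------------------------------------------------------------------------
# marker placement
# ----------------------------------------------------------------------------------


def place_markers(
    genome: GenomeModel, median_spacing_bp: int = 196, seed: int = 0
) -> MarkerMap:
    """Scatter heterozygous markers along the genome.

    Inter-marker gaps are i.i.d. Uniform(0.5 s, 1.5 s) with s the requested
    median spacing, so both the median and the mean of the realized spacing
    match the request (real marker maps are more skewed; see the methods
    note).  No marker falls inside an excluded region; a chromosome shorter
    than the spacing still receives one mid-chromosome marker.
    """
    if median_spacing_bp < 1:
        raise ValueError("median_spacing_bp must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    for chrom, L in genome.chromosomes:
        n_est = int(L / median_spacing_bp * 1.2) + 8
        gaps = rng.uniform(0.5 * median_spacing_bp, 1.5 * median_spacing_bp, size=n_est)
        pos = np.cumsum(gaps)
        while pos[-1] < L:  # pragma: no cover - generous overdraw above
            extra = rng.uniform(0.5 * median_spacing_bp, 1.5 * median_spacing_bp, size=n_est)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = pos[pos < L].astype(np.int64)
        for s, e in genome.regions_on(chrom, "excluded"):
            pos = pos[(pos < s) | (pos >= e)]
        pos = np.unique(pos)
        if pos.size == 0:
            warnings.warn(f"no marker fits on {chrom}; placing one at midpoint")
            pos = np.array([L // 2], dtype=np.int64)
        a1 = rng.integers(0, 4, size=pos.size)
        a2 = (a1 + rng.integers(1, 4, size=pos.size)) % 4
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "allele_P1": _BASES[a1],
                    "allele_P2": _BASES[a2],
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    return MarkerMap(frame, [c for c, _ in genome.chromosomes])


# ----------------------------------------------------------------------------------
# meiosis engine
# ----------------------------------------------------------------------------------


def _stationary_renewal(
    rng: np.random.Generator, length_bp: float, shape: float, scale_bp: float
) -> np.ndarray:
    """Points of a stationary gamma renewal process on [0, length_bp).

    The process is started 50 mean intervals before the origin so the first
    point on the chromosome follows the equilibrium interval distribution and
    the marginal point density is uniform (no edge artifact).
    """
    if not math.isfinite(scale_bp):
        return np.array([])
    mean = shape * scale_bp
    t = -50.0 * mean
    pts: list[float] = []
    while t < length_bp:
        t += rng.gamma(shape, scale_bp)
        if 0.0 <= t < length_bp:
            pts.append(t)
    return np.asarray(pts)


def _in_any(x: float, regions: Sequence[tuple[int, int]]) -> bool:
    return any(s <= x < e for s, e in regions)


def _overlaps_any(a: float, b: float, regions: Sequence[tuple[int, int]]) -> bool:
    return any(a < e and s < b for s, e in regions)


def _tract(rng: np.random.Generator, center: float, median_kb: float, log_sd: float, L: int):
    length = median_kb * 1000.0 * math.exp(log_sd * rng.standard_normal())
    a = max(0.0, center - length / 2.0)
    b = min(float(L), center + length / 2.0)
    return a, b


def _meiosis_core(
    genome: GenomeModel,
    markers: MarkerMap,
    params: SimParams,
    rng: np.random.Generator,
    homologs: tuple[np.ndarray, np.ndarray] | None = None,
    provenance: str = "meiosis",
) -> tuple[np.ndarray, list[RecombEvent]]:
    """One meiosis on a diploid with homolog marker sequences H0, H1.

    Returns the (4, n_markers) chromatid origin matrix and the truth events.
    For a fresh hybrid diploid the homologs are the pure parental sequences;
    for the second meiosis after RTG they are the retained mosaics.
    """
    n = len(markers)
    if homologs is None:
        H0 = np.zeros(n, dtype=np.int8)
        H1 = np.ones(n, dtype=np.int8)
    else:
        H0, H1 = (np.asarray(h, dtype=np.int8) for h in homologs)
    origins = np.vstack([H0, H0, H1, H1]).astype(np.int8)

    scale_bp = params.renewal_scale_bp(genome)
    analyzed_total = params.analyzed_mass_bp(genome)
    events: list[RecombEvent] = []

    for chrom, L in genome.chromosomes:
        a0, b0 = markers.chrom_range(chrom)
        pos = markers.positions(chrom)
        sub = origins[:, a0:b0]
        cold = genome.regions_on(chrom, "coldspot")
        cen = genome.centromeres[chrom]
        halo = (cen - params.centromere_halo_bp, cen + params.centromere_halo_bp)

        def draw_cos() -> list[tuple[float, float, float]]:
            out = []
            for x in _stationary_renewal(rng, L, params.gamma_shape_k, scale_bp):
                if _in_any(x, cold):
                    continue
                ta, tb = _tract(rng, x, params.co_tract_median_kb, params.tract_log_sd, L)
                if _overlaps_any(ta, tb, [halo]):
                    continue
                out.append((x, ta, tb))
            return out

        cos = draw_cos()
        if params.obligate_co and not cos:
            cos = draw_cos()  # single redraw; may legitimately stay empty

        for x, ta, tb in cos:
            i = int(rng.integers(0, 2))
            j = int(rng.integers(2, 4))
            m0 = int(np.searchsorted(pos, ta))
            m1 = int(np.searchsorted(pos, tb))
            # local content of the two involved chromatids before the exchange;
            # after earlier exchanges they may locally carry the same parent,
            # in which case the crossover is genotype-silent (recorded as
            # visible=False in the truth set)
            ci = sub[i, m0:m1].copy()
            cj = sub[j, m0:m1].copy()
            visible = bool(m1 < pos.size and sub[i, m1] != sub[j, m1])
            # reciprocal exchange: swap distal segments of chromatids i and j
            tmp = sub[i, m0:].copy()
            sub[i, m0:] = sub[j, m0:]
            sub[j, m0:] = tmp
            # heteroduplex resolution: the tract is converted to one strand's
            # content, chosen uniformly, so it segregates 3:1 where the two
            # strands differed
            tract = ci if rng.integers(0, 2) == 0 else cj
            sub[i, m0:m1] = tract
            sub[j, m0:m1] = tract
            events.append(
                RecombEvent(
                    cls="CO",
                    chrom=chrom,
                    start=ta,
                    end=tb,
                    point=x,
                    spores=(i, j),
                    n_markers=int((ci != cj).sum()),
                    visible=visible,
                    provenance=provenance,
                )
            )

        # NCOs: uniform over the analyzed fraction of this chromosome
        chrom_mass = L - sum(e - s for s, e in cold)
        lam = params.nco_per_meiosis_mean * chrom_mass / max(analyzed_total, 1.0)
        for _ in range(rng.poisson(lam)):
            for _try in range(200):
                x = float(rng.uniform(0, L))
                ta, tb = _tract(rng, x, params.nco_tract_median_kb, params.tract_log_sd, L)
                if not _in_any(x, cold) and not _overlaps_any(ta, tb, [halo]):
                    break
            else:  # pragma: no cover - chromosome fully cold
                continue
            r = int(rng.integers(0, 4))
            q = int(rng.integers(2, 4)) if r < 2 else int(rng.integers(0, 2))
            m0 = int(np.searchsorted(pos, ta))
            m1 = int(np.searchsorted(pos, tb))
            donor = sub[q, m0:m1].copy()  # donor is a chromatid of the other homolog
            n_conv = int((sub[r, m0:m1] != donor).sum())
            sub[r, m0:m1] = donor
            events.append(
                RecombEvent(
                    cls="NCO",
                    chrom=chrom,
                    start=ta,
                    end=tb,
                    point=x,
                    spores=(r,),
                    n_markers=n_conv,
                    visible=n_conv > 0,
                    provenance=provenance,
                )
            )

    if params.homing_hotspot is not None:
        _apply_homing(genome, markers, params, rng, origins, events, provenance)
    return origins, events


def _apply_homing(genome, markers, params, rng, origins, events, provenance) -> None:
    """Site-specific homing: cut one empty-allele chromatid, convert toward
    the carrier allele, with or without an associated crossover."""
    chrom, hx, prob, carrier = params.homing_hotspot
    if rng.random() >= prob:
        return
    a0, b0 = markers.chrom_range(chrom)
    if a0 == b0:
        return
    pos = markers.positions(chrom)
    sub = origins[:, a0:b0]
    idx = min(int(np.searchsorted(pos, hx)), pos.size - 1)
    empty_rows = np.flatnonzero(sub[:, idx] != carrier)
    carrier_rows = np.flatnonzero(sub[:, idx] == carrier)
    if not empty_rows.size or not carrier_rows.size:
        return  # locus already fixed; nothing to home into
    r = int(rng.choice(empty_rows))
    q = int(rng.choice(carrier_rows))
    ta, tb = _tract(rng, float(hx), params.co_tract_median_kb, params.tract_log_sd,
                    genome.chrom_lengths[chrom])
    m0 = int(np.searchsorted(pos, ta))
    m1 = int(np.searchsorted(pos, tb))
    with_co = bool(rng.integers(0, 2))
    if with_co:
        tmp = sub[r, m0:].copy()
        sub[r, m0:] = sub[q, m0:]
        sub[q, m0:] = tmp
    donor = sub[q, m0:m1].copy() if not with_co else sub[r, m0:m1].copy()
    sub[r, m0:m1] = donor
    sub[q, m0:m1] = donor
    events.append(
        RecombEvent(
            cls="CO" if with_co else "NCO",
            chrom=chrom,
            start=ta,
            end=tb,
            point=float(hx),
            spores=(r, q) if with_co else (r,),
            n_markers=m1 - m0,
            provenance=provenance,
        )
    )


def simulate_meiosis(
    genome: GenomeModel,
    markers: MarkerMap,
    params: SimParams,
    seed: int,
    homologs: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[TetradGenotypes, TruthEventSet]:
    """Simulate one complete meiosis and return the tetrad plus truth events.

    ``homologs`` optionally supplies mosaic homolog sequences (marker-length
    int8 arrays of parental origins) instead of the pure parental haplotypes;
    this is how the post-RTG meiosis is run, and it is handy for hand-built
    scenarios in tests.
    """
    rng = np.random.default_rng(seed)
    origins, events = _meiosis_core(genome, markers, params, rng, homologs)
    tet = TetradGenotypes(markers, origins.T.copy())
    return tet, TruthEventSet(events)


# ----------------------------------------------------------------------------------
# return-to-growth
# ----------------------------------------------------------------------------------


def _retain_rtg_diploid(
    genome: GenomeModel,
    markers: MarkerMap,
    origins: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mitotic segregation after an aborted meiosis.

    Per chromosome, one chromatid per homolog is retained, chosen uniformly
    among those whose centromere-proximal origin matches each parent, so
    centromeres stay heterozygous.
    """
    n = origins.shape[1]
    Ha = np.empty(n, dtype=np.int8)
    Hb = np.empty(n, dtype=np.int8)
    for chrom, L in genome.chromosomes:
        a0, b0 = markers.chrom_range(chrom)
        if a0 == b0:
            continue
        pos = markers.positions(chrom)
        cen_idx = int(np.argmin(np.abs(pos - genome.centromeres[chrom])))
        vals = origins[:, a0:b0][:, cen_idx]
        p1_rows = np.flatnonzero(vals == 0)
        p2_rows = np.flatnonzero(vals == 1)
        if p1_rows.size and p2_rows.size:
            c1 = int(rng.choice(p1_rows))
            c2 = int(rng.choice(p2_rows))
        else:  # degenerate: conversion covered the centromere marker
            c1, c2 = 0, 2
        Ha[a0:b0] = origins[c1, a0:b0]
        Hb[a0:b0] = origins[c2, a0:b0]
    return Ha, Hb


def _rtg_truth_signatures(
    genome: GenomeModel,
    markers: MarkerMap,
    Ha: np.ndarray,
    Hb: np.ndarray,
    loh_threshold_bp: float = 10_000.0,
) -> list[RecombEvent]:
    """Observable signatures the RTG diploid will leave in the final tetrad.

    Homozygous runs become 4:0 tracts (LOH when their midpoint-convention
    span exceeds the threshold); marker boundaries where both homologs switch
    parent inside heterozygous sequence become double COs.  Coordinates use
    the same midpoint convention as the event caller so truth and calls are
    directly comparable.
    """
    events: list[RecombEvent] = []
    for chrom, L in genome.chromosomes:
        a0, b0 = markers.chrom_range(chrom)
        if b0 - a0 < 2:
            continue
        pos = markers.positions(chrom)
        ha, hb = Ha[a0:b0], Hb[a0:b0]
        hom = ha == hb
        n = hom.size
        # homozygous runs
        edges = np.flatnonzero(np.diff(hom.astype(np.int8)) != 0) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [n]])
        for s, e in zip(starts, ends):
            if not hom[s]:
                continue
            left = 0.0 if s == 0 else (pos[s - 1] + pos[s]) / 2.0
            right = float(L) if e == n else (pos[e - 1] + pos[e]) / 2.0
            size = right - left
            touch_l, touch_r = s == 0, e == n
            is_loh = size > loh_threshold_bp
            # a short homozygous run flanked by heterozygous sequence is a
            # retained prophase conversion; when both homologs switch parent
            # across it, it is the 4:0 tract of a double CO, otherwise a
            # plain 4:0 NCO tract
            cls = "LOH" if is_loh else "GC40"
            if not is_loh and not touch_l and not touch_r and ha[s - 1] != ha[e]:
                cls = "doubleCO"
            events.append(
                RecombEvent(
                    cls=cls,
                    chrom=chrom,
                    start=left,
                    end=right,
                    point=(left + right) / 2.0,
                    spores=(0, 1, 2, 3),
                    n_markers=int(e - s),
                    segregation="4:0",
                    retained_parent="P1" if ha[s] == 0 else "P2",
                    telomeric=bool(touch_l or touch_r) if is_loh else False,
                    lohips=(0 if not is_loh else 2 - int(touch_l) - int(touch_r)),
                    provenance="rtg",
                )
            )
        # tractless double COs: both homologs switch at the same marker
        # boundary within heterozygous sequence
        both_switch = (np.diff(ha) != 0) & (np.diff(hb) != 0) & ~hom[:-1] & ~hom[1:]
        for m in np.flatnonzero(both_switch):
            x = (pos[m] + pos[m + 1]) / 2.0
            events.append(
                RecombEvent(
                    cls="doubleCO",
                    chrom=chrom,
                    start=x,
                    end=x,
                    point=x,
                    spores=(0, 1, 2, 3),
                    provenance="rtg",
                )
            )
    return events


def simulate_rtg_then_meiosis(
    genome: GenomeModel,
    markers: MarkerMap,
    params: SimParams,
    seed: int,
) -> tuple[TetradGenotypes, TruthEventSet]:
    """Aborted meiosis, return to growth, then a second complete meiosis.

    Stage 1 simulates a meiotic prophase event set exactly as
    :func:`simulate_meiosis`; stage 2 retains one chromatid per homolog per
    chromosome with heterozygous centromeres; stage 3 runs a full meiosis on
    the retained diploid.  The truth set contains the raw prophase events
    (``rtg_prophase``), their observable signatures in the diploid (``rtg``:
    LOH, short 4:0 tracts, double COs) and the final-meiosis events
    (``meiosis``).
    """
    rng = np.random.default_rng(seed)
    origins1, ev1 = _meiosis_core(genome, markers, params, rng, provenance="rtg_prophase")
    Ha, Hb = _retain_rtg_diploid(genome, markers, origins1, rng)
    derived = _rtg_truth_signatures(genome, markers, Ha, Hb)
    origins2, ev2 = _meiosis_core(genome, markers, params, rng, homologs=(Ha, Hb))
    tet = TetradGenotypes(markers, origins2.T.copy())
    return tet, TruthEventSet(ev1 + derived + ev2)


# ----------------------------------------------------------------------------------
# degradation and batch simulation
# ----------------------------------------------------------------------------------


def degrade_genotypes(tetrad: TetradGenotypes, na_rate: float, seed: int) -> TetradGenotypes:
    """Replace each genotype independently by NA with probability ``na_rate``."""
    if not 0 <= na_rate < 1:
        raise ValueError("na_rate must lie in [0, 1)")
    codes = tetrad.codes.copy()
    if na_rate > 0:
        rng = np.random.default_rng(seed)
        codes[rng.random(codes.shape) < na_rate] = -1
    return TetradGenotypes(tetrad.marker_map, codes, tetrad.name)


def simulate_tetrads(
    genome: GenomeModel,
    markers: MarkerMap,
    params: SimParams,
    n_tetrads: int,
    seed: int,
) -> list[tuple[TetradGenotypes, TruthEventSet]]:
    """Simulate a cohort of tetrads, each meiotic or RTG-derived.

    Each tetrad draws an independent substream from the master seed and is an
    RTG tetrad with probability ``params.rtg_probability``; genotypes are
    degraded at ``params.na_rate`` afterwards.
    """
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_tetrads):
        sub = int(master.integers(0, 2**31 - 1))
        is_rtg = master.random() < params.rtg_probability
        sim = simulate_rtg_then_meiosis if is_rtg else simulate_meiosis
        tet, truth = sim(genome, markers, params, sub)
        tet.name = f"tetrad{i + 1}"
        if params.na_rate > 0:
            tet = degrade_genotypes(tet, params.na_rate, sub ^ 0x5EED)
        out.append((tet, truth))
    return out
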