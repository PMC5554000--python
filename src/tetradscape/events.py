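"""Recombination event calling from tetrad segregation patterns.

Given the four-spore genotypes of one tetrad over a marker map, this module
reads the allelic segregation pattern marker by marker and classifies it into
the canonical tetrad event classes:

* ``CO_plain`` - a reciprocal phase switch between two 2:2 segments involving
  two spores, with no detectable conversion tract;
* ``CO_with_GC31`` - a crossover whose 3:1 conversion tract covers enough
  markers to be seen;
* ``NCO_31`` - a 3:1 conversion tract flanked by identical 2:2 phases;
* ``doubleCO`` / ``doubleCO_with_GC40`` - two crossovers at the same location
  involving all four chromatids (the tetrad signature of a pre-meiotic
  crossover followed by a second meiosis);
* ``NCO_40`` - a short 4:0 conversion tract;
* ``LOH`` - a 4:0 tract larger than the loss-of-heterozygosity threshold
  (default 10 kb), the signature of a region homozygosed before the final
  meiosis.  Each internal LOH has two initiation points (LOHips), a tract
  touching an analyzed chromosome end has one.

Tract coordinates use the midpoint convention: a tract runs from the midpoint
between the last non-converted marker and the first converted one to the
midpoint between the last converted marker and the next non-converted one;
tracts touching the analyzed boundary extend to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: event classes carrying a crossover (used by rate accounting downstream)
CO_CLASSES = ("CO_plain", "CO_with_GC31")
DOUBLE_CO_CLASSES = ("doubleCO", "doubleCO_with_GC40")


@dataclass
class RecombEvent:
    """One called (or simulated truth) recombination event.

    ``start``/``end`` delimit the tract in bp (0-based half-open, midpoint
    convention); ``point`` is the point estimate used for densities and
    interference (tract midpoint, or the inter-anchor midpoint for tractless
    COs).  ``spores`` are the 0-based spore indices switching phase or
    carrying the conversion.  ``lohips`` counts LOH initiation points (2 for
    an internal LOH, 1 when the tract touches one analyzed boundary).
    """

    cls: str
    chrom: str
    start: float
    end: float
    point: float
    spores: tuple[int, ...] = ()
    n_markers: int = 0
    segregation: str = ""
    retained_parent: str = ""
    telomeric: bool = False
    lohips: int = 0
    tetrad: str = ""
    provenance: str = "called"
    #: truth-set bookkeeping: False when a simulated exchange was locally
    #: genotype-silent (the involved chromatids carried the same parent)
    visible: bool = True

    @property
    def size_bp(self) -> float:
        return self.end - self.start


def event_size(event: RecombEvent) -> float:
    """Tract size in bp under the midpoint convention."""
    return event.size_bp


@dataclass(frozen=True)
class Segment:
    """A maximal run of markers with a constant spore-origin 4-tuple."""

    chrom: str
    start_idx: int  # first marker index (within chromosome block)
    end_idx: int  # exclusive
    pattern: tuple[int, int, int, int]

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def n_p2(self) -> int:
        return int(sum(self.pattern))

    @property
    def segregation(self) -> str:
        return f"{4 - self.n_p2}:{self.n_p2}"

    @property
    def is_anchor(self) -> bool:
        return self.n_p2 == 2

    @property
    def is_40(self) -> bool:
        return self.n_p2 in (0, 4)

    @property
    def is_31(self) -> bool:
        return self.n_p2 in (1, 3)

    @property
    def retained_parent(self) -> str:
        if self.n_p2 == 0:
            return "P1"
        if self.n_p2 == 4:
            return "P2"
        return "P1" if self.n_p2 == 1 else "P2"  # majority parent for 3:1


def drop_na_markers(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove markers where any spore is NA.

    Returns the filtered (n, 4) matrix and the integer indices kept.
    """
    codes = np.asarray(codes)
    keep = np.flatnonzero((codes >= 0).all(axis=1))
    return codes[keep], keep


def segment_chromosome(codes: np.ndarray, chrom: str = "") -> list[Segment]:
    """Run-length encode an NA-free (n, 4) genotype block into segments."""
    codes = np.asarray(codes, dtype=np.int8)
    n = codes.shape[0]
    if n == 0:
        return []
    change = np.flatnonzero(np.any(codes[1:] != codes[:-1], axis=1)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return [
        Segment(chrom, int(s), int(e), tuple(int(v) for v in codes[s]))
        for s, e in zip(starts, ends)
    ]


def _hamming(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, tuple[int, ...]]:
    diff = tuple(i for i in range(4) if a[i] != b[i])
    return len(diff), diff


def _tract_bounds(
    seg: Segment, pos: np.ndarray, chrom_start: float, chrom_end: float
) -> tuple[float, float]:
    left = (
        chrom_start
        if seg.start_idx == 0
        else (pos[seg.start_idx - 1] + pos[seg.start_idx]) / 2.0
    )
    right = (
        chrom_end
        if seg.end_idx == len(pos)
        else (pos[seg.end_idx - 1] + pos[seg.end_idx]) / 2.0
    )
    return float(left), float(right)


def call_events(
    segments: Sequence[Segment],
    pos: np.ndarray,
    *,
    chrom: str,
    chrom_start: float = 0.0,
    chrom_end: float | None = None,
    min_gc_markers: int = 3,
    loh_threshold_bp: float = 10_000.0,
) -> list[RecombEvent]:
    """Classify the segments of one analyzed block into recombination events.

    Consecutive non-2:2 segments between two 2:2 anchors form one cluster.
    The total phase change between the anchors determines the crossover
    content of the cluster (0 spores switching: none; 2: one CO; 4: a double
    CO); each non-2:2 segment covering at least ``min_gc_markers`` markers
    additionally yields a conversion-tract record.  4:0 tracts larger than
    ``loh_threshold_bp`` (midpoint convention) are emitted as LOH and
    suppress phase-change calls across them, since the flanking phases of a
    homozygosed region are unrelated.  Boundary-touching clusters are
    classified against their single inner anchor.
    """
    if chrom_end is None:
        chrom_end = float(pos[-1]) if len(pos) else chrom_start
    if len(pos) < 2:
        warnings.warn(f"{chrom}: fewer than 2 markers; no events called")
        return []

    events: list[RecombEvent] = []

    def tract_record(seg: Segment) -> tuple[float, float, float]:
        a, b = _tract_bounds(seg, pos, chrom_start, chrom_end)
        return a, b, b - a

    def emit_gc(seg: Segment, cls: str, anchor: tuple[int, ...] | None = None) -> None:
        a, b, _ = tract_record(seg)
        if seg.is_31 and anchor is not None:
            # the conversion recipient is the spore deviating from the anchor
            spores = tuple(i for i in range(4) if seg.pattern[i] != anchor[i])
        else:
            spores = _minority_spores(seg)
        events.append(
            RecombEvent(
                cls=cls,
                chrom=chrom,
                start=a,
                end=b,
                point=(a + b) / 2.0,
                spores=spores,
                n_markers=seg.n_markers,
                segregation="4:0" if seg.is_40 else "3:1",
                retained_parent=seg.retained_parent,
            )
        )

    def emit_loh(seg: Segment) -> None:
        a, b, size = tract_record(seg)
        touch_l = seg.start_idx == 0
        touch_r = seg.end_idx == len(pos)
        events.append(
            RecombEvent(
                cls="LOH",
                chrom=chrom,
                start=a,
                end=b,
                point=(a + b) / 2.0,
                spores=(0, 1, 2, 3),
                n_markers=seg.n_markers,
                segregation="4:0",
                retained_parent=seg.retained_parent,
                telomeric=touch_l or touch_r,
                lohips=2 - int(touch_l) - int(touch_r),
            )
        )

    def _minority_spores(seg: Segment) -> tuple[int, ...]:
        if seg.is_40:
            return (0, 1, 2, 3)
        minority = 1 if seg.n_p2 == 1 else 0
        return tuple(i for i, v in enumerate(seg.pattern) if v == minority)

    anchors = [k for k, s in enumerate(segments) if s.is_anchor]

    def classify_cluster(left: Segment | None, mids: list[Segment], right: Segment | None) -> None:
        anchor = left.pattern if left is not None else (right.pattern if right is not None else None)
        gc31 = [m for m in mids if m.is_31 and m.n_markers >= min_gc_markers]
        loh = [m for m in mids if m.is_40 and tract_record(m)[2] > loh_threshold_bp]
        gc40 = [
            m
            for m in mids
            if m.is_40 and m.n_markers >= min_gc_markers and m not in loh
        ]
        for m in loh:
            emit_loh(m)
        if left is None or right is None or loh:
            # boundary cluster, or phase information interrupted by an LOH:
            # conversion tracts are reported but no phase-change call is made
            for m in gc31:
                emit_gc(m, "NCO_31", anchor)
            for m in gc40:
                emit_gc(m, "NCO_40", anchor)
            return
        n_switch, switching = _hamming(left.pattern, right.pattern)
        if n_switch == 0:
            for m in gc31:
                emit_gc(m, "NCO_31", anchor)
            for m in gc40:
                emit_gc(m, "NCO_40", anchor)
        elif n_switch == 2:
            if gc31:
                a = min(_tract_bounds(m, pos, chrom_start, chrom_end)[0] for m in gc31)
                b = max(_tract_bounds(m, pos, chrom_start, chrom_end)[1] for m in gc31)
                nm = sum(m.n_markers for m in gc31)
                events.append(
                    RecombEvent(
                        cls="CO_with_GC31",
                        chrom=chrom,
                        start=a,
                        end=b,
                        point=(a + b) / 2.0,
                        spores=switching,
                        n_markers=nm,
                        segregation="3:1",
                        retained_parent=gc31[0].retained_parent,
                    )
                )
            else:
                x = (pos[left.end_idx - 1] + pos[right.start_idx]) / 2.0
                events.append(
                    RecombEvent(
                        cls="CO_plain", chrom=chrom, start=x, end=x, point=x, spores=switching
                    )
                )
            for m in gc40:
                emit_gc(m, "NCO_40", anchor)
        else:  # n_switch == 4
            if gc40:
                a = min(_tract_bounds(m, pos, chrom_start, chrom_end)[0] for m in gc40)
                b = max(_tract_bounds(m, pos, chrom_start, chrom_end)[1] for m in gc40)
                nm = sum(m.n_markers for m in gc40)
                events.append(
                    RecombEvent(
                        cls="doubleCO_with_GC40",
                        chrom=chrom,
                        start=a,
                        end=b,
                        point=(a + b) / 2.0,
                        spores=(0, 1, 2, 3),
                        n_markers=nm,
                        segregation="4:0",
                        retained_parent=gc40[0].retained_parent,
                    )
                )
            else:
                x = (pos[left.end_idx - 1] + pos[right.start_idx]) / 2.0
                events.append(
                    RecombEvent(
                        cls="doubleCO", chrom=chrom, start=x, end=x, point=x, spores=(0, 1, 2, 3)
                    )
                )
            for m in gc31:
                emit_gc(m, "NCO_31", anchor)

    if not anchors:
        # whole block is non-2:2 (e.g. chromosome-wide LOH)
        classify_cluster(None, list(segments), None)
        return events

    classify_cluster(None, list(segments[: anchors[0]]), segments[anchors[0]])
    for k0, k1 in zip(anchors, anchors[1:]):
        classify_cluster(segments[k0], list(segments[k0 + 1 : k1]), segments[k1])
    classify_cluster(segments[anchors[-1]], list(segments[anchors[-1] + 1 :]), None)
    return events


def call_tetrad(
    tetrad,
    *,
    chrom_lengths: Mapping[str, int] | None = None,
    exclusion_regions: Iterable[tuple[str, int, int]] | None = None,
    min_gc_markers: int = 3,
    loh_threshold_bp: float = 10_000.0,
) -> list[RecombEvent]:
    """Call all events of one tetrad (a :class:`~tetradscape.simulate.TetradGenotypes`).

    Markers with any NA spore are disregarded first.  Exclusion regions split
    a chromosome into independently analyzed blocks whose boundaries behave
    like chromosome ends (no event is called across them, and boundary-
    touching 4:0 tracts are telomeric with respect to the block).
    """
    mm = tetrad.marker_map
    chrom_lengths = dict(chrom_lengths or {})
    exclusions = list(exclusion_regions or [])
    out: list[RecombEvent] = []
    for chrom in mm.chroms():
        a0, b0 = mm.chrom_range(chrom)
        codes, keep = drop_na_markers(tetrad.codes[a0:b0])
        pos_all = mm.positions(chrom)[keep]
        L = float(chrom_lengths.get(chrom, pos_all[-1] + 1 if len(pos_all) else 0.0))
        # split into analyzed blocks at exclusion boundaries
        bounds = [0.0, L]
        for c, s, e in exclusions:
            if c == chrom:
                bounds.extend([float(s), float(e)])
        bounds = sorted(set(bounds))
        blocks = [
            (bounds[i], bounds[i + 1])
            for i in range(len(bounds) - 1)
            if not any(c == chrom and s <= bounds[i] and bounds[i + 1] <= e for c, s, e in exclusions)
        ]
        for lo, hi in blocks:
            sel = (pos_all >= lo) & (pos_all < hi)
            if sel.sum() < 2:
                continue
            pos = pos_all[sel]
            segs = segment_chromosome(codes[sel], chrom)
            for ev in call_events(
                segs,
                pos,
                chrom=chrom,
                chrom_start=lo,
                chrom_end=hi,
                min_gc_markers=min_gc_markers,
                loh_threshold_bp=loh_threshold_bp,
            ):
                ev.tetrad = tetrad.name
                out.append(ev)
    return out


# ----------------------------------------------------------------------------------
# pooled-heterozygosity LOH detection (independent cross-check of the caller)
# ----------------------------------------------------------------------------------


def detect_loh_pooled(tetrad, min_tract_bp: float = 10_000.0) -> list[tuple[str, float, float]]:
    """Detect LOH tracts by pooling the four spores per marker.

    Emulates calling heterozygous sites on the merged reads of all four
    spores: a marker where both parental origins appear is heterozygous;
    maximal runs of single-origin markers spanning more than ``min_tract_bp``
    are reported.  Intended as an independent cross-validation of the LOH
    calls of :func:`call_tetrad`.
    """
    mm = tetrad.marker_map
    out: list[tuple[str, float, float]] = []
    for chrom in mm.chroms():
        a0, b0 = mm.chrom_range(chrom)
        codes, keep = drop_na_markers(tetrad.codes[a0:b0])
        if codes.shape[0] == 0:
            continue
        pos = mm.positions(chrom)[keep]
        hom = codes.min(axis=1) == codes.max(axis=1)
        edges = np.flatnonzero(np.diff(hom.astype(np.int8)) != 0) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [hom.size]])
        for s, e in zip(starts, ends):
            if hom[s] and pos[e - 1] - pos[s] > min_tract_bp:
                out.append((chrom, float(pos[s]), float(pos[e - 1])))
    return out


# ----------------------------------------------------------------------------------
# event table IO
# ----------------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "tetrad",
    "chrom",
    "cls",
    "start",
    "end",
    "point",
    "spores",
    "n_markers",
    "segregation",
    "retained_parent",
    "telomeric",
    "lohips",
    "provenance",
    "visible",
]


def events_to_frame(events: Iterable[RecombEvent]) -> pd.DataFrame:
    rows = [
        {
            **{k: getattr(e, k) for k in _EVENT_COLUMNS if k != "spores"},
            "spores": ",".join(str(s) for s in e.spores),
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def frame_to_events(frame: pd.DataFrame) -> list[RecombEvent]:
    events = []
    for r in frame.itertuples(index=False):
        d = r._asdict()
        spores = tuple(int(s) for s in str(d.pop("spores")).split(",") if s not in ("", "nan"))
        d["retained_parent"] = "" if pd.isna(d.get("retained_parent")) else str(d["retained_parent"])
        d["segregation"] = "" if pd.isna(d.get("segregation")) else str(d["segregation"])
        d["tetrad"] = "" if pd.isna(d.get("tetrad")) else str(d["tetrad"])
        events.append(RecombEvent(spores=spores, **{k: d[k] for k in d}))
    return events


def write_events_tsv(events: Iterable[RecombEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "tetrad": str})
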