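"""Separation of meiotic from RTG-derived events and rate accounting.

A tetrad from a cell that underwent return-to-growth (RTG) before its final
meiosis carries signatures of the aborted first meiosis: double COs, short
4:0 conversion tracts, and large loss-of-heterozygosity (LOH) tracts.  The
accounting implemented here converts called event counts into per-meiosis and
per-RTG recombination rates:

* each double CO corresponds to one CO of the aborted prophase;
* each internal LOH tract has two borders (LOH initiation points, LOHips),
  each border marking one prophase CO, hence two COs per internal tract;
* a telomere-proximal LOH tract has a single border, hence one CO;
* short 4:0 tracts are prophase NCOs.

Meiotic COs inside LOH regions are invisible (the region is homozygous), so
the per-meiosis CO rate includes an extrapolated correction assuming a
homogeneous recombination rate.  Detected per-RTG counts underestimate the
true prophase activity because only two of the four prophase chromatids are
retained; the conventional correction factor is 2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import CO_CLASSES, DOUBLE_CO_CLASSES, RecombEvent

#: fraction of the extrapolated in-LOH COs that the caller actually detects
#: (odd numbers of COs inside an LOH shift its borders and are counted as
#: LOHips; even numbers are invisible)
DEFAULT_LOH_CO_DETECTABILITY = 100.0 / 190.0


@dataclass
class EventLedger:
    """Aggregated event counts over a cohort of tetrads."""

    co_plain: int = 0
    co_with_gc31: int = 0
    nco_31: int = 0
    double_co: int = 0
    double_co_with_gc40: int = 0
    nco_40_short: int = 0
    loh_internal: int = 0
    loh_telomeric: int = 0
    genome_size_bp: float = 0.0
    loh_cumulative_bp: float = 0.0
    n_tetrads: int = 0
    n_tetrads_with_rtg: int = 0

    def __post_init__(self) -> None:
        for name in (
            "co_plain",
            "co_with_gc31",
            "nco_31",
            "double_co",
            "double_co_with_gc40",
            "nco_40_short",
            "loh_internal",
            "loh_telomeric",
            "n_tetrads",
            "n_tetrads_with_rtg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_tetrads and self.loh_cumulative_bp > self.genome_size_bp * self.n_tetrads:
            raise ValueError("cumulative LOH exceeds total analyzed genome")

    @property
    def lohips(self) -> int:
        """LOH initiation points: two per internal tract, one per telomeric."""
        return 2 * self.loh_internal + self.loh_telomeric

    @property
    def n_single_cos(self) -> int:
        """Detected single meiotic COs (with and without visible GC tract)."""
        return self.co_plain + self.co_with_gc31

    @property
    def n_double_cos(self) -> int:
        return self.double_co + self.double_co_with_gc40

    @classmethod
    def from_events(
        cls,
        events: Iterable[RecombEvent] | pd.DataFrame,
        n_tetrads: int,
        genome_size_bp: float,
    ) -> "EventLedger":
        """Build a ledger from a called event list or concatenated table.

        A tetrad is flagged "with RTG" when it carries at least one double CO
        or one LOH tract.
        """
        if isinstance(events, pd.DataFrame):
            frame = events
        else:
            from .events import events_to_frame

            frame = events_to_frame(list(events))
        counts = frame["cls"].value_counts().to_dict() if len(frame) else {}
        loh = frame[frame["cls"] == "LOH"] if len(frame) else pd.DataFrame()
        telomeric = int(loh["telomeric"].sum()) if len(loh) else 0
        rtg_classes = ("LOH",) + DOUBLE_CO_CLASSES
        with_rtg = (
            frame.loc[frame["cls"].isin(rtg_classes), "tetrad"].nunique() if len(frame) else 0
        )
        return cls(
            co_plain=counts.get("CO_plain", 0),
            co_with_gc31=counts.get("CO_with_GC31", 0),
            nco_31=counts.get("NCO_31", 0),
            double_co=counts.get("doubleCO", 0),
            double_co_with_gc40=counts.get("doubleCO_with_GC40", 0),
            nco_40_short=counts.get("NCO_40", 0),
            loh_internal=int(len(loh)) - telomeric,
            loh_telomeric=telomeric,
            genome_size_bp=float(genome_size_bp),
            loh_cumulative_bp=float((loh["end"] - loh["start"]).sum()) if len(loh) else 0.0,
            n_tetrads=int(n_tetrads),
            n_tetrads_with_rtg=int(with_rtg),
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["lohips"] = self.lohips
        return d


@dataclass(frozen=True)
class RateReport:
    """Per-meiosis and per-RTG recombination rates."""

    co_per_meiosis: float
    nco_per_meiosis: float
    co_per_rtg: float  # NaN when no RTG tetrad observed
    nco_per_rtg: float
    estimated_cos_in_loh: float
    detected_cos_in_loh: float
    co_per_mb: float
    rtg_correction_factor: float = 2.0 / 3.0
    co_per_rtg_corrected: float = float("nan")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ----------------------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------------------


def classify_40_tracts(
    sizes_bp: Sequence[float], threshold_bp: float = 10_000.0
) -> tuple[list[float], list[float]]:
    """Split 4:0 tract sizes into short (meiotic conversion) and large (LOH).

    Strictly larger than the threshold counts as large; a tract of exactly
    the threshold size is short.
    """
    sizes = [float(s) for s in sizes_bp]
    if any(s <= 0 for s in sizes):
        raise ValueError("tract sizes must be > 0")
    short = [s for s in sizes if s <= threshold_bp]
    large = [s for s in sizes if s > threshold_bp]
    return short, large


def count_rtg_cos(ledger: EventLedger) -> int:
    """Total COs attributable to the aborted pre-RTG meiosis.

    One per double CO, two per internal LOH tract, one per telomeric LOH
    tract - algebraically ``double_co + lohips``.
    """
    return ledger.n_double_cos + 2 * ledger.loh_internal + ledger.loh_telomeric


def estimate_cos_in_loh(n_cos_observed: float, non_loh_bp: float, loh_bp: float) -> float:
    """Extrapolate observed COs into LOH territory at a homogeneous rate."""
    if non_loh_bp <= 0:
        raise ValueError("non_loh_bp must be > 0")
    if loh_bp < 0:
        raise ValueError("loh_bp must be >= 0")
    return n_cos_observed * loh_bp / non_loh_bp


def rtg_underestimation_correction(observed: float, factor: float = 2.0 / 3.0) -> float:
    """Correct a per-RTG count for the two retained chromatids out of four.

    Only a fraction ``factor`` (conventionally 2/3) of prophase events leaves
    a detectable signature in the single daughter cell analyzed; the
    corrected estimate is ``observed / factor``.  Reported alongside the
    observed value, never substituted for it.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must lie in (0, 1]")
    return observed / factor


def meiotic_rates(
    ledger: EventLedger,
    loh_co_estimate_detected: float | None = None,
    *,
    non_loh_bp: float | None = None,
    detectability: float = DEFAULT_LOH_CO_DETECTABILITY,
    rtg_correction_factor: float = 2.0 / 3.0,
) -> RateReport:
    """Compute per-meiosis and per-RTG recombination rates from a ledger.

    ``loh_co_estimate_detected`` is the number of single COs assumed to hide
    inside LOH regions yet still contribute to the meiotic map; when not
    supplied it defaults to the homogeneous-rate extrapolation times a
    detectability fraction.  Per-RTG rates assume exactly one RTG per flagged
    tetrad and are NaN when the cohort has none.
    """
    if ledger.n_tetrads <= 0:
        raise ValueError("ledger must contain at least one tetrad")
    if non_loh_bp is None:
        non_loh_bp = ledger.genome_size_bp * ledger.n_tetrads - ledger.loh_cumulative_bp
    estimated = (
        estimate_cos_in_loh(ledger.n_single_cos, non_loh_bp, ledger.loh_cumulative_bp)
        if non_loh_bp > 0
        else 0.0
    )
    detected = (
        loh_co_estimate_detected if loh_co_estimate_detected is not None else estimated * detectability
    )
    co_per_meiosis = (ledger.n_single_cos + detected) / ledger.n_tetrads
    nco_per_meiosis = ledger.nco_31 / ledger.n_tetrads
    if ledger.n_tetrads_with_rtg > 0:
        co_per_rtg = count_rtg_cos(ledger) / ledger.n_tetrads_with_rtg
        nco_per_rtg = ledger.nco_40_short / ledger.n_tetrads_with_rtg
        co_per_rtg_corrected = rtg_underestimation_correction(co_per_rtg, rtg_correction_factor)
    else:
        co_per_rtg = nco_per_rtg = co_per_rtg_corrected = float("nan")
    co_per_mb = (
        co_per_meiosis / (ledger.genome_size_bp / 1e6) if ledger.genome_size_bp > 0 else float("nan")
    )
    return RateReport(
        co_per_meiosis=co_per_meiosis,
        nco_per_meiosis=nco_per_meiosis,
        co_per_rtg=co_per_rtg,
        nco_per_rtg=nco_per_rtg,
        estimated_cos_in_loh=estimated,
        detected_cos_in_loh=detected,
        co_per_mb=co_per_mb,
        rtg_correction_factor=rtg_correction_factor,
        co_per_rtg_corrected=co_per_rtg_corrected,
    )


def ledger_per_tetrad(events_frame: pd.DataFrame) -> pd.DataFrame:
    """One row of class counts per tetrad (for the ledger TSV output)."""
    if not len(events_frame):
        return pd.DataFrame()
    tab = events_frame.pivot_table(
        index="tetrad", columns="cls", aggfunc="size", fill_value=0
    ).reset_index()
    tab.columns.name = None
    return tab
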