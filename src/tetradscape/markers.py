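"""Marker selection and spore genotype assignment.

This module turns variant summary tables of the two parents of a hybrid
diploid into a :class:`MarkerMap` of reliable heterozygous markers, assigns a
parental origin (P1/P2/NA) to each marker in each sequenced spore, and applies
the population-level marker filters (missingness, segregation balance,
subtelomeric exclusion) to the resulting genotype matrix.

Genotypes are encoded as ``int8``: ``0`` = P1, ``1`` = P2, ``-1`` = NA.
Variant tables use 1-based positions (VCF convention); everything downstream
is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

P1: int = 0
P2: int = 1
NA: int = -1

CODE_LABELS = {0: "P1", 1: "P2", -1: "NA"}
LABEL_CODES = {v: k for k, v in CODE_LABELS.items()}

#: columns expected in a variant summary table (TSV or parsed VCF)
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "allele",
    "coverage",
    "mapping_quality",
    "allele_frequency",
    "near_indel_bp",
]


class MarkerMap:
    """Ordered genomic markers with the parental allele at each site.

    The coordinate backbone of the whole pipeline: simulation, genotype
    matrices and event calls all index into one map.  Positions are 0-based
    and strictly increasing within each chromosome.

    Parameters
    ----------
    frame:
        DataFrame with columns ``chrom, pos, allele_P1, allele_P2``.
    chrom_order:
        Chromosome ordering; defaults to order of first appearance.
    """

    def __init__(self, frame: pd.DataFrame, chrom_order: Sequence[str] | None = None):
        required = {"chrom", "pos", "allele_P1", "allele_P2"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"marker frame missing columns: {sorted(missing)}")
        frame = frame.copy()
        if chrom_order is None:
            chrom_order = list(dict.fromkeys(frame["chrom"].astype(str)))
        frame["chrom"] = pd.Categorical(
            frame["chrom"].astype(str), categories=list(chrom_order), ordered=True
        )
        if frame["chrom"].isna().any():
            raise ValueError("marker frame contains chromosomes not in chrom_order")
        frame = frame.reset_index(drop=True).sort_values(["chrom", "pos"], kind="mergesort")
        #: positional indices of the input rows in map order, for realigning
        #: arrays that were built against the unsorted input
        self.input_order: np.ndarray = frame.index.to_numpy()
        frame = frame.reset_index(drop=True)
        if frame.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in marker map")
        if (frame["allele_P1"].astype(str) == frame["allele_P2"].astype(str)).any():
            raise ValueError("marker with identical parental alleles")
        self._frame = frame
        self.chrom_order: list[str] = list(chrom_order)
        codes = frame["chrom"].cat.codes.to_numpy()
        self._ranges: dict[str, tuple[int, int]] = {}
        for i, c in enumerate(self.chrom_order):
            idx = np.flatnonzero(codes == i)
            if idx.size:
                self._ranges[c] = (int(idx[0]), int(idx[-1]) + 1)

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MarkerMap({len(self)} markers, {len(self.chroms())} chromosomes)"

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def chroms(self) -> list[str]:
        """Chromosomes that actually carry markers, in map order."""
        return [c for c in self.chrom_order if c in self._ranges]

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Row range ``[start, stop)`` of a chromosome (``(0, 0)`` if empty)."""
        return self._ranges.get(chrom, (0, 0))

    def positions(self, chrom: str) -> np.ndarray:
        a, b = self.chrom_range(chrom)
        return self._frame["pos"].to_numpy()[a:b]

    # -- IO -----------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self._frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, chrom_order: Sequence[str] | None = None) -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}), chrom_order)


# ----------------------------------------------------------------------------------
# parental marker selection
# ----------------------------------------------------------------------------------


def _check_sorted(tab: pd.DataFrame, name: str) -> None:
    grp = tab.groupby("chrom", sort=False)["pos"]
    if (grp.diff().dropna() <= 0).any():
        raise ValueError(f"{name} variant table is not sorted by position within chromosome")


def _passes_parent_filters(
    tab: pd.DataFrame,
    min_coverage: float,
    max_coverage: float,
    min_mapping_quality: float,
    af_tol: float,
    indel_exclusion_bp: float,
) -> pd.Series:
    af = tab["allele_frequency"].to_numpy(dtype=float)
    near = tab.get("near_indel_bp")
    near = (
        np.full(len(tab), np.inf)
        if near is None
        else near.fillna(np.inf).to_numpy(dtype=float)
    )
    ok = (
        (tab["coverage"] >= min_coverage)
        & (tab["coverage"] <= max_coverage)
        & (tab["mapping_quality"] >= min_mapping_quality)
        & ((np.abs(af) <= af_tol) | (np.abs(af - 1.0) <= af_tol))
        & (near > indel_exclusion_bp)
    )
    return pd.Series(np.asarray(ok), index=tab.index)


def select_parental_markers(
    p1_variants: pd.DataFrame,
    p2_variants: pd.DataFrame,
    *,
    min_coverage: float = 50,
    max_coverage: float = 300,
    min_mapping_quality: float = 100,
    af_tol: float = 1e-9,
    indel_exclusion_bp: float = 10,
    chrom_order: Sequence[str] | None = None,
) -> MarkerMap:
    """Select reliable heterozygous markers from the two parental variant tables.

    A position is retained when the parents carry *different* alleles and, in
    **both** parents: coverage lies in ``[min_coverage, max_coverage]``
    (inclusive), mapping quality is ``>= min_mapping_quality``, the allele
    frequency equals 0 or 1 (within ``af_tol``), and the site is more than
    ``indel_exclusion_bp`` away from the nearest indel.

    Input positions are 1-based; the returned :class:`MarkerMap` is 0-based.
    """
    for tab, name in ((p1_variants, "P1"), (p2_variants, "P2")):
        missing = {"chrom", "pos", "allele"} - set(tab.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
        _check_sorted(tab, name)

    merged = p1_variants.merge(
        p2_variants, on=["chrom", "pos"], suffixes=("_p1", "_p2"), how="inner"
    )
    if merged.empty:
        warnings.warn("no shared positions between parental tables; empty marker map")
        return MarkerMap(
            pd.DataFrame(columns=["chrom", "pos", "allele_P1", "allele_P2"]), chrom_order or []
        )

    def side(suffix: str) -> pd.DataFrame:
        cols = {f"{c}_{suffix}": c for c in VARIANT_COLUMNS[2:] if f"{c}_{suffix}" in merged}
        return merged[list(cols)].rename(columns=cols)

    ok = (
        (merged["allele_p1"].astype(str) != merged["allele_p2"].astype(str))
        & _passes_parent_filters(
            side("p1"), min_coverage, max_coverage, min_mapping_quality, af_tol, indel_exclusion_bp
        )
        & _passes_parent_filters(
            side("p2"), min_coverage, max_coverage, min_mapping_quality, af_tol, indel_exclusion_bp
        )
    )
    kept = merged.loc[ok]
    frame = pd.DataFrame(
        {
            "chrom": kept["chrom"].astype(str),
            "pos": kept["pos"].astype(int) - 1,  # to 0-based
            "allele_P1": kept["allele_p1"].astype(str),
            "allele_P2": kept["allele_p2"].astype(str),
        }
    )
    if frame.empty:
        warnings.warn("all shared positions failed the parental filters; empty marker map")
    return MarkerMap(frame, chrom_order)


# ----------------------------------------------------------------------------------
# spore genotype assignment
# ----------------------------------------------------------------------------------


def assign_spore_genotypes(
    spore_variants: pd.DataFrame,
    marker_map: MarkerMap,
    spore_mean_coverage: float,
    *,
    min_coverage_fraction: float = 0.25,
    min_mapping_quality: float = 100,
    af_tol: float = 1e-9,
) -> np.ndarray:
    """Assign a parental origin to each marker of one spore.

    At each marker the origin is P1 or P2 when the observed allele equals the
    corresponding parental allele *and* coverage is strictly greater than
    ``min_coverage_fraction`` of the spore's mean coverage *and* mapping
    quality is strictly greater than ``min_mapping_quality`` *and* the allele
    frequency is 0 or 1.  Everything else (including markers absent from the
    spore table) is NA.

    Returns an ``int8`` column aligned with ``marker_map``.
    """
    if spore_mean_coverage <= 0:
        raise ValueError("spore_mean_coverage must be positive")
    tab = spore_variants.copy()
    tab["pos"] = tab["pos"].astype(int) - 1  # to 0-based, matching the map
    merged = marker_map.frame.merge(tab, on=["chrom", "pos"], how="left")

    af = merged["allele_frequency"].to_numpy(dtype=float)
    reliable = (
        (merged["coverage"] > min_coverage_fraction * spore_mean_coverage)
        & (merged["mapping_quality"] > min_mapping_quality)
        & ((np.abs(af) <= af_tol) | (np.abs(af - 1.0) <= af_tol))
    )
    allele = merged["allele"].astype(str)
    out = np.full(len(marker_map), NA, dtype=np.int8)
    out[np.asarray(reliable & (allele == merged["allele_P1"].astype(str)))] = P1
    out[np.asarray(reliable & (allele == merged["allele_P2"].astype(str)))] = P2
    return out


# ----------------------------------------------------------------------------------
# genotype matrix and population-level filters
# ----------------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Markers x spores matrix of parental origins, spores grouped in tetrads.

    ``codes`` is ``int8`` with values 0 (P1), 1 (P2), -1 (NA); the column
    count must be a multiple of 4 (four spores per tetrad).
    """

    marker_map: MarkerMap
    codes: np.ndarray
    spore_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.marker_map):
            raise ValueError("codes must be (n_markers, n_spores)")
        if self.codes.shape[1] % 4 != 0:
            raise ValueError("spore count must be a multiple of 4 (tetrads)")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1}")
        if not self.spore_names:
            self.spore_names = [
                f"t{i // 4 + 1}_s{i % 4 + 1}" for i in range(self.codes.shape[1])
            ]
        if len(self.spore_names) != self.codes.shape[1]:
            raise ValueError("spore_names length mismatch")

    @property
    def n_tetrads(self) -> int:
        return self.codes.shape[1] // 4

    def tetrad_codes(self, i: int) -> np.ndarray:
        """(n_markers, 4) view of tetrad ``i``."""
        return self.codes[:, 4 * i : 4 * i + 4]

    def iter_tetrads(self) -> Iterator[tuple[str, np.ndarray]]:
        for i in range(self.n_tetrads):
            name = self.spore_names[4 * i].rsplit("_", 1)[0]
            yield name, self.tetrad_codes(i)

    # -- IO -------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        lab = np.array(["NA", "P1", "P2"], dtype=object)  # index by code+1
        frame = pd.DataFrame(
            lab[self.codes + 1], columns=self.spore_names, index=self.marker_map.frame.index
        )
        out = pd.concat([self.marker_map.frame[["chrom", "pos"]], frame], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, marker_map: MarkerMap) -> "GenotypeMatrix":
        tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        spores = [c for c in tab.columns if c not in ("chrom", "pos")]
        codes = np.empty((len(tab), len(spores)), dtype=np.int8)
        for j, s in enumerate(spores):
            codes[:, j] = tab[s].map(LABEL_CODES).to_numpy(dtype=np.int8)
        return cls(marker_map, codes, spores)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_dropped_na: int
    n_dropped_balance: int
    n_dropped_excluded: int
    n_retained: int


def _in_regions(marker_map: MarkerMap, regions: Iterable[tuple[str, int, int]]) -> np.ndarray:
    """Boolean mask of markers falling inside any 0-based half-open region."""
    mask = np.zeros(len(marker_map), dtype=bool)
    pos = marker_map.frame["pos"].to_numpy()
    for chrom, start, end in regions:
        a, b = marker_map.chrom_range(str(chrom))
        if a == b:
            continue
        sub = pos[a:b]
        mask[a:b] |= (sub >= start) & (sub < end)
    return mask


def filter_matrix(
    matrix: GenotypeMatrix,
    na_spore_fraction: float = 0.30,
    balance_low: float = 0.30,
    balance_high: float = 0.70,
    exclusion_regions: Iterable[tuple[str, int, int]] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop unreliable markers from the population genotype matrix.

    Rules (evaluated per marker, independent of row order):

    * NA fraction across spores ``>= na_spore_fraction`` (inclusive);
    * non-NA P1 fraction strictly above ``balance_high`` or strictly below
      ``balance_low`` (unbalanced segregation across the population);
    * position inside a user-supplied exclusion region (e.g. subtelomeres).

    Returns the filtered matrix plus per-rule drop counts.  The operation is
    idempotent: all statistics are per-marker, so re-filtering the output is a
    no-op.
    """
    codes = matrix.codes
    n_spores = codes.shape[1]
    na_frac = (codes == NA).sum(axis=1) / n_spores
    drop_na = na_frac >= na_spore_fraction

    non_na = (codes != NA).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p1_frac = np.where(non_na > 0, (codes == P1).sum(axis=1) / np.maximum(non_na, 1), np.nan)
    drop_bal = (p1_frac > balance_high) | (p1_frac < balance_low)
    drop_bal &= ~drop_na  # attribute each marker to the first rule that hits

    drop_exc = (
        _in_regions(matrix.marker_map, exclusion_regions) if exclusion_regions else
        np.zeros(len(matrix.marker_map), dtype=bool)
    )
    drop_exc &= ~(drop_na | drop_bal)

    keep = ~(drop_na | drop_bal | drop_exc)
    if not keep.any():
        warnings.warn("all markers dropped by filters; empty matrix")
    new_map = MarkerMap(
        matrix.marker_map.frame.loc[keep].reset_index(drop=True),
        matrix.marker_map.chrom_order,
    )
    out = GenotypeMatrix(new_map, codes[keep], list(matrix.spore_names))
    report = FilterReport(
        n_input=len(matrix.marker_map),
        n_dropped_na=int(drop_na.sum()),
        n_dropped_balance=int(drop_bal.sum()),
        n_dropped_excluded=int(drop_exc.sum()),
        n_retained=int(keep.sum()),
    )
    return out, report


@dataclass(frozen=True)
class MatrixSummary:
    n_markers: int
    median_spacing_bp: float
    n_gaps_over_threshold: int
    per_chrom_counts: dict[str, int]
    gap_threshold_bp: int = 5000


def matrix_summary(
    source: GenotypeMatrix | MarkerMap, gap_threshold_bp: int = 5000
) -> MatrixSummary:
    """Marker count, median inter-marker distance and large-gap count."""
    mm = source.marker_map if isinstance(source, GenotypeMatrix) else source
    gaps: list[np.ndarray] = []
    per_chrom: dict[str, int] = {}
    for chrom in mm.chroms():
        pos = mm.positions(chrom)
        per_chrom[chrom] = int(pos.size)
        if pos.size >= 2:
            gaps.append(np.diff(pos))
    allg = np.concatenate(gaps) if gaps else np.array([], dtype=float)
    return MatrixSummary(
        n_markers=len(mm),
        median_spacing_bp=float(np.median(allg)) if allg.size else float("nan"),
        n_gaps_over_threshold=int((allg > gap_threshold_bp).sum()),
        per_chrom_counts=per_chrom,
        gap_threshold_bp=gap_threshold_bp,
    )


# ----------------------------------------------------------------------------------
# variant table IO
# ----------------------------------------------------------------------------------


def read_variants_table(path: str | Path) -> pd.DataFrame:
    """Read a variant summary TSV (columns of :data:`VARIANT_COLUMNS`)."""
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "allele"} - set(tab.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return tab


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    """Parse a minimal VCF into a variant summary table.

    Uses the ``DP``, ``MQ`` and ``AF`` INFO fields; the reported allele is ALT
    when AF is ~1 and REF when AF is ~0.  ``near_indel_bp`` is the distance to
    the nearest indel record in the same file (``inf`` if none).
    """
    from cyvcf2 import VCF  # optional dependency

    snps: list[tuple] = []
    indels: dict[str, list[int]] = {}
    for rec in VCF(str(path)):
        alt = rec.ALT[0] if rec.ALT else rec.REF
        if len(rec.REF) != 1 or len(alt) != 1:
            indels.setdefault(rec.CHROM, []).append(rec.POS)
            continue
        info = dict(rec.INFO)
        af = float(info.get("AF", np.nan))
        snps.append(
            (
                rec.CHROM,
                rec.POS,
                alt if af >= 0.5 else rec.REF,
                float(info.get("DP", np.nan)),
                float(info.get("MQ", np.nan)),
                af,
            )
        )
    tab = pd.DataFrame(
        snps, columns=["chrom", "pos", "allele", "coverage", "mapping_quality", "allele_frequency"]
    )
    near = np.full(len(tab), np.inf)
    for chrom, positions in indels.items():
        arr = np.sort(np.asarray(positions))
        sel = np.flatnonzero(tab["chrom"].to_numpy() == chrom)
        if not sel.size:
            continue
        p = tab["pos"].to_numpy()[sel]
        idx = np.searchsorted(arr, p)
        left = np.abs(p - arr[np.clip(idx - 1, 0, arr.size - 1)])
        right = np.abs(arr[np.clip(idx, 0, arr.size - 1)] - p)
        near[sel] = np.minimum(left, right)
    tab["near_indel_bp"] = near
    return tab


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED file into (chrom, start, end) tuples."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    return [(str(r[0]), int(r[1]), int(r[2])) for r in tab.itertuples(index=False)]
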