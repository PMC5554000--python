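"""Genome-wide recombination landscape statistics.

Crossover density tracks, hotspot calling under a randomization null,
crossover interference via gamma fits to inter-CO distances, the
chromosome-size regression (obligate-CO intercept), E0 chromosome counts and
the gene-proximal cross-dataset hotspot comparison.

Crossover interference is quantified by fitting pooled inter-CO distances to
a gamma distribution: the shape ``k`` estimates interference strength
(``k = 1`` is a no-interference Poisson process; larger ``k`` means more
evenly spaced COs) and the scale ``θ`` the inverse CO rate.  Distances are
handled in kb throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import CO_CLASSES, DOUBLE_CO_CLASSES
from .simulate import GenomeModel

#: classes whose point estimates enter CO density / hotspot tracks; double
#: COs and LOH borders carry pre-RTG crossovers and are included by default
MEIOTIC_CO_CLASSES = CO_CLASSES
ALL_CO_CLASSES = CO_CLASSES + DOUBLE_CO_CLASSES


# ----------------------------------------------------------------------------------
# result containers
# ----------------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit with goodness-of-fit tests."""

    shape_k: float
    scale_theta: float
    n_observations: int
    ks_stat_vs_exponential: float = float("nan")
    ks_p_vs_exponential: float = float("nan")
    ks_stat_vs_reference_shape: float = float("nan")
    ks_p_vs_reference_shape: float = float("nan")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class HotspotCall:
    chrom: str
    start: int
    end: int
    co_count: int
    empirical_p: float
    is_hotspot: bool


@dataclass(frozen=True)
class ChromRegression:
    slope: float  # COs per Mb
    intercept: float  # COs at zero length
    r_squared: float
    per_chrom: pd.DataFrame  # columns: chrom, length_mb, mean_cos

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }


# ----------------------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------------------


def co_points(
    events: pd.DataFrame, classes: Sequence[str] = ALL_CO_CLASSES, include_lohips: bool = True
) -> pd.DataFrame:
    """Extract CO point estimates (tetrad, chrom, point) from an event table.

    With ``include_lohips`` the borders of internal and telomeric LOH tracts
    are added as crossover points of the aborted pre-RTG meiosis (two per
    internal tract, one per telomeric tract at the non-boundary border).
    """
    rows = events.loc[events["cls"].isin(classes), ["tetrad", "chrom", "point"]]
    parts = [rows]
    if include_lohips:
        loh = events[events["cls"] == "LOH"]
        if len(loh):
            internal = loh[loh["lohips"] == 2]
            telo = loh[loh["lohips"] == 1]
            parts.append(internal[["tetrad", "chrom", "start"]].rename(columns={"start": "point"}))
            parts.append(internal[["tetrad", "chrom", "end"]].rename(columns={"end": "point"}))
            if len(telo):
                inner = np.where(telo["telomeric"] & (telo["start"] <= 0), telo["end"], telo["start"])
                parts.append(
                    pd.DataFrame(
                        {"tetrad": telo["tetrad"], "chrom": telo["chrom"], "point": inner}
                    )
                )
    return pd.concat(parts, ignore_index=True)


def _analyzed_segments(genome: GenomeModel) -> list[tuple[str, int, int]]:
    """Chromosome intervals minus excluded regions (coldspots stay analyzed)."""
    out = []
    for chrom, L in genome.chromosomes:
        cuts = [0, L]
        for s, e in genome.regions_on(chrom, "excluded"):
            cuts.extend([s, e])
        cuts = sorted(set(cuts))
        for a, b in zip(cuts, cuts[1:]):
            mid = (a + b) / 2
            if not any(s <= mid < e for s, e in genome.regions_on(chrom, "excluded")):
                out.append((chrom, a, b))
    return out


# ----------------------------------------------------------------------------------
# density and hotspots
# ----------------------------------------------------------------------------------


def co_density(
    points: pd.DataFrame,
    genome: GenomeModel,
    window_bp: int = 5_000,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Per-window CO counts along the genome.

    ``points`` must have columns ``chrom`` and ``point``.  Windows are
    ``window_bp`` wide every ``step_bp`` (default: non-overlapping), clipped
    at chromosome ends; windows overlapping an excluded region are flagged.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    step = step_bp or window_bp
    rows = []
    for chrom, L in genome.chromosomes:
        pts = np.sort(points.loc[points["chrom"] == chrom, "point"].to_numpy(dtype=float))
        starts = np.arange(0, L, step)
        ends = np.minimum(starts + window_bp, L)
        counts = np.searchsorted(pts, ends) - np.searchsorted(pts, starts)
        excl = genome.regions_on(chrom, "excluded")
        masked = [any(s0 < e and s < e0 for s, e in excl) for s0, e0 in zip(starts, ends)]
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "count": counts, "masked": masked}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _window_index(genome: GenomeModel, window_bp: int) -> tuple[dict[str, int], int]:
    """Global offset of each chromosome's first window, and total windows."""
    offsets: dict[str, int] = {}
    total = 0
    for chrom, L in genome.chromosomes:
        offsets[chrom] = total
        total += int(np.ceil(L / window_bp))
    return offsets, total


def randomization_null_max_counts(
    n_cos: int,
    genome: GenomeModel,
    window_bp: int = 5_000,
    n_randomizations: int = 100_000,
    seed: int = 0,
    chunk: int = 2_000,
) -> np.ndarray:
    """Null distribution of the maximum window count.

    Each randomization places ``n_cos`` points uniformly over the analyzed
    (non-excluded) genome and records the maximum count over all disjoint
    ``window_bp`` windows.  Returns the ``n_randomizations`` maxima.
    """
    segs = _analyzed_segments(genome)
    seg_len = np.array([e - s for _, s, e in segs], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    offsets, total_windows = _window_index(genome, window_bp)
    seg_chrom = [c for c, _, _ in segs]
    seg_start = np.array([s for _, s, _ in segs], dtype=float)
    seg_window0 = np.array([offsets[c] for c in seg_chrom])

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_randomizations, dtype=np.int32)
    done = 0
    while done < n_randomizations:
        m = min(chunk, n_randomizations - done)
        u = rng.random((m, n_cos)) * cum[-1]
        seg_idx = np.searchsorted(cum, u, side="right") - 1
        pos = seg_start[seg_idx] + (u - cum[seg_idx])
        widx = seg_window0[seg_idx] + (pos // window_bp).astype(np.int64)
        for r in range(m):
            counts = np.bincount(widx[r], minlength=total_windows)
            maxima[done + r] = counts.max()
        done += m
    return maxima


def randomization_null_tail(
    n_cos: int,
    genome: GenomeModel,
    threshold: int = 7,
    window_bp: int = 5_000,
    n_randomizations: int = 100_000,
    seed: int = 0,
) -> float:
    """P(any window holds >= threshold COs) under the uniform-placement null."""
    maxima = randomization_null_max_counts(n_cos, genome, window_bp, n_randomizations, seed)
    return float((maxima >= threshold).mean())


def call_hotspots(
    points: pd.DataFrame,
    genome: GenomeModel,
    threshold: int = 7,
    window_bp: int = 5_000,
    n_randomizations: int = 100_000,
    seed: int = 0,
    p_cutoff: float = 0.02,
    family_wise: bool = True,
) -> list[HotspotCall]:
    """Call CO hotspots against a uniform randomization null.

    Disjoint windows with ``co_count >= threshold`` are candidates.  The null
    places the same number of COs uniformly over the analyzed genome
    ``n_randomizations`` times.  With ``family_wise`` (default) a candidate's
    empirical p is the fraction of randomizations whose *maximum* window
    count reaches its observed count (the stricter, genome-wide reading);
    otherwise the per-window count distribution is used.
    """
    if n_randomizations < 100:
        warnings.warn("fewer than 100 randomizations: empirical p-values are unstable")
    dens = co_density(points, genome, window_bp)
    n_cos = int(len(points))
    if n_cos < 1:
        raise ValueError("hotspot calling needs at least one CO")
    candidates = dens[dens["count"] >= threshold]
    if candidates.empty:
        return []
    if family_wise:
        maxima = randomization_null_max_counts(
            n_cos, genome, window_bp, n_randomizations, seed
        )
        tail = lambda c: float((maxima >= c).mean())
    else:
        segs = _analyzed_segments(genome)
        rng = np.random.default_rng(seed)
        seg_len = np.array([e - s for _, s, e in segs], dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        offsets, total_windows = _window_index(genome, window_bp)
        all_counts = np.zeros((n_randomizations, 0))
        # per-window null: pool counts over all windows and randomizations
        pooled = []
        seg_start = np.array([s for _, s, _ in segs], dtype=float)
        seg_window0 = np.array([offsets[c] for c, _, _ in segs])
        for _ in range(n_randomizations):
            u = rng.random(n_cos) * cum[-1]
            si = np.searchsorted(cum, u, side="right") - 1
            pos = seg_start[si] + (u - cum[si])
            widx = seg_window0[si] + (pos // window_bp).astype(np.int64)
            pooled.append(np.bincount(widx, minlength=total_windows))
        counts = np.concatenate(pooled)
        tail = lambda c: float((counts >= c).mean())
    out = []
    for r in candidates.itertuples(index=False):
        p = tail(int(r.count))
        out.append(
            HotspotCall(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                co_count=int(r.count),
                empirical_p=p,
                is_hotspot=p < p_cutoff,
            )
        )
    return out


# ----------------------------------------------------------------------------------
# interference
# ----------------------------------------------------------------------------------


def inter_co_distances(points: pd.DataFrame) -> np.ndarray:
    """Pooled distances (kb) between consecutive COs, per tetrad and chromosome.

    ``points`` needs columns ``tetrad``, ``chrom``, ``point``.  Chromosomes
    with fewer than two COs in a tetrad contribute nothing.
    """
    dists = []
    for _, grp in points.groupby(["tetrad", "chrom"], sort=False):
        p = np.sort(grp["point"].to_numpy(dtype=float))
        if p.size >= 2:
            dists.append(np.diff(p) / 1000.0)
    return np.concatenate(dists) if dists else np.array([])


def fit_gamma(
    distances_kb: Sequence[float],
    reference_shape: float = 1.0,
    extra_reference_shape: float | None = None,
    min_observations: int = 30,
) -> GammaFit:
    """Maximum-likelihood gamma fit to inter-CO distances (kb).

    Also runs a Kolmogorov-Smirnov test of the data against a gamma with
    ``reference_shape`` and scale matched to the sample mean; with the
    default shape of 1 this is the test against a no-interference
    (exponential) model.  ``extra_reference_shape`` adds a second KS test,
    e.g. against another species' fitted shape.
    """
    x = np.asarray(distances_kb, dtype=float)
    if x.size < min_observations:
        raise ValueError(f"need at least {min_observations} observations, got {x.size}")
    if (x <= 0).any():
        raise ValueError("distances must be > 0")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: gamma shape diverges")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    mean = x.mean()
    ks0 = stats.kstest(x, stats.gamma(a=reference_shape, scale=mean / reference_shape).cdf)
    if extra_reference_shape is not None:
        ks1 = stats.kstest(
            x, stats.gamma(a=extra_reference_shape, scale=mean / extra_reference_shape).cdf
        )
        extra = (float(ks1.statistic), float(ks1.pvalue))
    else:
        extra = (float("nan"), float("nan"))
    return GammaFit(
        shape_k=float(shape),
        scale_theta=float(scale),
        n_observations=int(x.size),
        ks_stat_vs_exponential=float(ks0.statistic),
        ks_p_vs_exponential=float(ks0.pvalue),
        ks_stat_vs_reference_shape=extra[0],
        ks_p_vs_reference_shape=extra[1],
    )


def fit_gamma_loh_sizes(loh_sizes_kb: Sequence[float], min_observations: int = 30) -> GammaFit:
    """Gamma fit to LOH tract sizes (kb); no reference-shape test by default.

    LOH sizes following approximately the same gamma law as inter-CO
    distances is evidence of their (aborted-)meiotic origin.
    """
    x = np.asarray(loh_sizes_kb, dtype=float)
    if x.size < min_observations:
        raise ValueError(f"need at least {min_observations} observations, got {x.size}")
    if (x <= 0).any():
        raise ValueError("sizes must be > 0")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample: gamma shape diverges")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return GammaFit(shape_k=float(shape), scale_theta=float(scale), n_observations=int(x.size))


# ----------------------------------------------------------------------------------
# chromosome-level summaries
# ----------------------------------------------------------------------------------


def chrom_regression(
    per_chrom_mean_cos: Mapping[str, float], chrom_lengths_mb: Mapping[str, float]
) -> ChromRegression:
    """OLS of mean COs per meiosis on chromosome length (Mb)."""
    chroms = [c for c in chrom_lengths_mb if c in per_chrom_mean_cos]
    if len(chroms) < 3:
        raise ValueError("regression needs at least 3 chromosomes")
    x = np.array([chrom_lengths_mb[c] for c in chroms], dtype=float)
    y = np.array([per_chrom_mean_cos[c] for c in chroms], dtype=float)
    res = stats.linregress(x, y)
    per_chrom = pd.DataFrame({"chrom": chroms, "length_mb": x, "mean_cos": y})
    return ChromRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        per_chrom=per_chrom,
    )


def e0_counts(
    points: pd.DataFrame, tetrads: Sequence[str], chromosomes: Sequence[str]
) -> pd.DataFrame:
    """Per-chromosome counts of tetrads segregating without any crossover.

    ``points`` are CO point estimates with ``tetrad`` and ``chrom`` columns;
    a (tetrad, chromosome) pair with no point is an E0 chromosome.
    """
    counts = points.groupby(["tetrad", "chrom"]).size() if len(points) else pd.Series(dtype=int)
    rows = []
    for chrom in chromosomes:
        e0 = sum(1 for t in tetrads if counts.get((t, chrom), 0) == 0)
        rows.append(
            {
                "chrom": chrom,
                "n_e0": e0,
                "n_tetrads": len(tetrads),
                "e0_fraction": e0 / len(tetrads) if tetrads else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------------------
# cross-dataset gene-proximal comparison
# ----------------------------------------------------------------------------------


def gene_proximal_cos(
    points_a: pd.DataFrame,
    points_b: pd.DataFrame,
    ortholog_pairs: pd.DataFrame,
    window_bp: int = 10_000,
) -> tuple[pd.DataFrame, float]:
    """Compare CO counts near ortholog pairs between two datasets.

    ``ortholog_pairs`` has columns ``gene, chrom_a, start_a, end_a, chrom_b,
    start_b, end_b`` (gene intervals in each dataset's coordinates).  For
    each pair, COs within a ``window_bp`` window centered on the gene are
    counted in each dataset and a 2x2 Fisher exact test (near-gene vs
    elsewhere, dataset A vs B) is run.  Returns the per-pair table and the
    R-squared of the cross-dataset linear regression of the counts; R-squared
    near zero means the hotspot landscape is not conserved.
    """
    total_a, total_b = len(points_a), len(points_b)
    rows = []
    for r in ortholog_pairs.itertuples(index=False):
        counts = []
        for pts, chrom, s, e in (
            (points_a, r.chrom_a, r.start_a, r.end_a),
            (points_b, r.chrom_b, r.start_b, r.end_b),
        ):
            if pd.isna(chrom):
                counts = None
                break
            center = (s + e) / 2.0
            lo, hi = center - window_bp / 2.0, center + window_bp / 2.0
            sel = pts[(pts["chrom"] == chrom) & (pts["point"] >= lo) & (pts["point"] < hi)]
            counts.append(int(len(sel)))
        if counts is None:
            warnings.warn(f"gene {r.gene} absent in one dataset; skipped")
            continue
        na, nb = counts
        table = [[na, total_a - na], [nb, total_b - nb]]
        _, p = stats.fisher_exact(table)
        rows.append({"gene": r.gene, "cos_a": na, "cos_b": nb, "fisher_p": float(p)})
    tab = pd.DataFrame(rows)
    if len(tab) >= 3 and tab["cos_a"].var() > 0 and tab["cos_b"].var() > 0:
        res = stats.linregress(tab["cos_a"], tab["cos_b"])
        r2 = float(res.rvalue**2)
    else:
        r2 = 1.0 if len(tab) and (tab["cos_a"] == tab["cos_b"]).all() else float("nan")
    return tab, r2
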