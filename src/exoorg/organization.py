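"""Positional organization of factors around their motifs.

This module holds the biology-facing computations: co-occupancy
classification of two factors' location lists (40-bp midpoint rule),
motif-anchored strand-separated composite tag profiles, cross-link-point
estimation from composite peak pairs, occupancy quantification in
factor-specific windows (GATA1 -25..+25, TAL1 -40..+30 relative to the
motif reference point), occupancy-sorted heatmap matrices, per-position
sequence composition panels, homotypic clustering of binding locations
(<500 bp, median coordinate), and cluster-vs-expression comparison.

Anchors are oriented reference points: a minus-strand anchor flips offsets
and swaps strands, so "upstream" always means 5' on the motif strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TagTrack

#: factor-specific occupancy windows (upstream, downstream) in bp
DEFAULT_OCCUPANCY_WINDOWS = {"GATA1": (25, 25), "TAL1": (40, 30)}

#: strand-specific sort windows for the four consensus composite peaks
PEAK_SORT_WINDOWS = {
    "sense1": ("+", -25, 0),       # plus-strand peak of the upstream pair
    "sense2": ("+", 0, 25),        # plus-strand peak of the downstream pair
    "antisense1": ("-", -25, 5),   # minus-strand peak of the upstream pair
    "antisense2": ("-", 5, 25),    # minus-strand peak of the downstream pair
}


def _anchor_frame(anchors) -> pd.DataFrame:
    df = anchors if isinstance(anchors, pd.DataFrame) else pd.DataFrame(anchors)
    if "strand" not in df.columns and "motif_strand" in df.columns:
        df = df.rename(columns={"motif_strand": "strand"})
    if "point" not in df.columns:
        for alt in ("midpoint", "ref_point"):
            if alt in df.columns:
                df = df.rename(columns={alt: "point"})
                break
    if "strand" not in df.columns:
        df = df.assign(strand="+")
    return df[["chrom", "point", "strand"]]


# -- co-occupancy --------------------------------------------------------


@dataclass
class CooccupancyResult:
    cobound: pd.DataFrame       # one row per matched (first, second) pair
    first_only: pd.DataFrame
    second_only: pd.DataFrame

    @property
    def venn_counts(self) -> dict[str, int]:
        return {"cobound": len(self.cobound),
                "first_only": len(self.first_only),
                "second_only": len(self.second_only)}


def classify_cooccupancy(first_locs: pd.DataFrame, second_locs: pd.DataFrame,
                         max_dist: int = 40) -> CooccupancyResult:
    """One-to-one nearest-first matching of two location lists.

    Midpoints within ``max_dist`` bp (inclusive) are cobound; candidate
    pairs are matched globally by ascending distance (ties by coordinate).
    """
    a = first_locs.reset_index(drop=True)
    b = second_locs.reset_index(drop=True)
    cands = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        ai = np.flatnonzero((a["chrom"] == chrom).to_numpy())
        bi = np.flatnonzero((b["chrom"] == chrom).to_numpy())
        am = a.loc[ai, "midpoint"].to_numpy()
        bm = b.loc[bi, "midpoint"].to_numpy()
        order = np.argsort(bm, kind="stable")
        bm_sorted, bi_sorted = bm[order], bi[order]
        for i, m in zip(ai, am):
            lo = np.searchsorted(bm_sorted, m - max_dist, side="left")
            hi = np.searchsorted(bm_sorted, m + max_dist, side="right")
            for j in range(lo, hi):
                cands.append((abs(int(bm_sorted[j]) - int(m)), int(m),
                              int(bm_sorted[j]), i, int(bi_sorted[j])))
    cands.sort()
    used_a, used_b = set(), set()
    rows = []
    for dist, am, bm_, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append({"chrom": a.at[i, "chrom"], "first_midpoint": am,
                     "second_midpoint": bm_, "distance": dist,
                     "first_index": i, "second_index": j})
    cobound = pd.DataFrame(
        rows, columns=["chrom", "first_midpoint", "second_midpoint",
                       "distance", "first_index", "second_index"])
    return CooccupancyResult(
        cobound=cobound,
        first_only=a.loc[sorted(set(a.index) - used_a)].reset_index(drop=True),
        second_only=b.loc[sorted(set(b.index) - used_b)].reset_index(drop=True),
    )


# -- composite profiles & cross-link estimation --------------------------


@dataclass
class CompositeProfile:
    """Strand-separated mean tag density around oriented anchors."""
    offsets: np.ndarray
    plus_density: np.ndarray    # tags per anchor per bp, motif-strand sense
    minus_density: np.ndarray
    n_anchors: int
    smoothing_window: int

    def density(self, strand: str) -> np.ndarray:
        return self.plus_density if strand == "+" else self.minus_density

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets,
                             "plus": self.plus_density,
                             "minus": self.minus_density})


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def composite_profile(track: TagTrack, anchors, flank: int = 100,
                      smooth: int = 5) -> CompositeProfile:
    """Average strand-separated tag density at offsets around anchors.

    For minus-strand anchors offsets are negated and strands swapped before
    accumulation, so the profile reads in motif-strand orientation.  Each
    strand is then smoothed with a centered moving average of ``smooth`` bp.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    df = _anchor_frame(anchors)
    n = 2 * flank + 1
    acc = {"+": np.zeros(n), "-": np.zeros(n)}
    for _, row in df.iterrows():
        point, anchor_strand = int(row["point"]), row["strand"]
        for strand in ("+", "-"):
            pos, cnt = track.positions_counts(row["chrom"], strand)
            lo, hi = np.searchsorted(pos, [point - flank, point + flank + 1])
            if hi <= lo:
                continue
            offs = pos[lo:hi] - point
            c = cnt[lo:hi]
            if anchor_strand == "-":
                offs = -offs
                out_strand = "-" if strand == "+" else "+"
            else:
                out_strand = strand
            np.add.at(acc[out_strand], offs + flank, c)
    n_anchors = max(len(df), 1)
    return CompositeProfile(
        offsets=np.arange(-flank, flank + 1),
        plus_density=_moving_average(acc["+"] / n_anchors, smooth),
        minus_density=_moving_average(acc["-"] / n_anchors, smooth),
        n_anchors=len(df),
        smoothing_window=smooth,
    )


@dataclass(frozen=True)
class CrosslinkEstimate:
    offset: float        # peak-pair midpoint relative to the reference point
    separation: int      # minus-peak offset - plus-peak offset
    intensity: float     # mean height of the two paired maxima


def _local_maxima(y: np.ndarray, min_height: float) -> list[int]:
    idx = np.flatnonzero((y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:])) + 1
    return [int(i) for i in idx if y[i] >= min_height]


def estimate_crosslinks(profile: CompositeProfile, max_pairs: int = 2,
                        d_min: int = -5, d_max: int = 25,
                        target_separation: int = 12,
                        min_height_frac: float = 0.1
                        ) -> list[CrosslinkEstimate]:
    """Infer cross-link points from a composite profile.

    Local maxima are found independently on the plus and minus densities
    (above ``min_height_frac`` of the global maximum); plus/minus maxima are
    paired one-to-one by the peak-pair separation rule, preferring
    separations near ``target_separation`` and higher intensity.  Each pair's
    midpoint estimates a cross-link offset.  Up to ``max_pairs`` estimates
    are returned by descending intensity; an empty list means no pairable
    maxima.
    """
    plus, minus = profile.plus_density, profile.minus_density
    floor = min_height_frac * max(plus.max(), minus.max(), 1e-12)
    pmax = _local_maxima(plus, floor)
    mmax = _local_maxima(minus, floor)
    offs = profile.offsets
    cands = []
    for i in pmax:
        for j in mmax:
            d = int(offs[j] - offs[i])
            if d_min <= d <= d_max:
                intensity = (plus[i] + minus[j]) / 2.0
                cands.append((abs(d - target_separation), -intensity,
                              int(offs[i]), i, j, d))
    cands.sort()
    used_p, used_m = set(), set()
    picks = []
    for _, neg_int, _, i, j, d in cands:
        if i in used_p or j in used_m:
            continue
        used_p.add(i)
        used_m.add(j)
        picks.append(CrosslinkEstimate(
            offset=(float(offs[i]) + float(offs[j])) / 2.0,
            separation=d, intensity=-neg_int))
        if len(picks) == max_pairs:
            break
    return sorted(picks, key=lambda e: -e.intensity)


# -- occupancy & heatmaps ------------------------------------------------


def occupancy_table(tracks: dict[str, TagTrack], anchors,
                    windows: dict[str, tuple[int, int]] | None = None
                    ) -> pd.DataFrame:
    """Per-anchor tag counts (both strands) in each factor's strand-oriented
    occupancy window (upstream, downstream) around the reference point."""
    windows = windows or DEFAULT_OCCUPANCY_WINDOWS
    df = _anchor_frame(anchors)
    out = df.copy()
    for factor, track in tracks.items():
        up, down = windows.get(factor, (25, 25))
        counts = []
        for _, row in df.iterrows():
            p = int(row["point"])
            if row["strand"] == "+":
                lo, hi = p - up, p + down
            else:
                lo, hi = p - down, p + up
            counts.append(track.count_in(row["chrom"], lo, hi + 1))
        out[factor] = counts
    return out


@dataclass
class HeatmapResult:
    order: np.ndarray           # anchor row order (indices into anchors)
    offsets: np.ndarray
    plus_matrix: np.ndarray     # (n_anchors, 2*flank+1), motif-strand sense
    minus_matrix: np.ndarray
    sort_keys: np.ndarray


def heatmap_matrix(track: TagTrack, anchors, flank: int = 100,
                   sort_key: str = "occupancy",
                   occupancy: np.ndarray | None = None) -> HeatmapResult:
    """Anchor-per-row strand-separated tag matrices, sorted descending.

    ``sort_key`` is "occupancy" (requires ``occupancy`` or uses total tags
    in +-flank) or one of the four composite-peak windows
    (sense1/sense2/antisense1/antisense2).  Ties keep coordinate order.
    """
    df = _anchor_frame(anchors)
    n = 2 * flank + 1
    plus_m = np.zeros((len(df), n))
    minus_m = np.zeros((len(df), n))
    for r, (_, row) in enumerate(df.iterrows()):
        point, anchor_strand = int(row["point"]), row["strand"]
        for strand in ("+", "-"):
            pos, cnt = track.positions_counts(row["chrom"], strand)
            lo, hi = np.searchsorted(pos, [point - flank, point + flank + 1])
            if hi <= lo:
                continue
            offs = pos[lo:hi] - point
            c = cnt[lo:hi]
            if anchor_strand == "-":
                offs, out_strand = -offs, ("-" if strand == "+" else "+")
            else:
                out_strand = strand
            target = plus_m if out_strand == "+" else minus_m
            np.add.at(target[r], offs + flank, c)
    if sort_key == "occupancy":
        keys = (np.asarray(occupancy, dtype=float) if occupancy is not None
                else plus_m.sum(axis=1) + minus_m.sum(axis=1))
    elif sort_key in PEAK_SORT_WINDOWS:
        strand, lo_off, hi_off = PEAK_SORT_WINDOWS[sort_key]
        mat = plus_m if strand == "+" else minus_m
        sel = (np.arange(-flank, flank + 1) >= lo_off) & \
              (np.arange(-flank, flank + 1) <= hi_off)
        keys = mat[:, sel].sum(axis=1)
    else:
        raise ValueError(
            f"unknown sort key {sort_key!r}; options: occupancy, "
            f"{', '.join(PEAK_SORT_WINDOWS)}")
    order = np.argsort(-keys, kind="stable")
    return HeatmapResult(order=order, offsets=np.arange(-flank, flank + 1),
                         plus_matrix=plus_m[order], minus_matrix=minus_m[order],
                         sort_keys=keys[order])


# -- sequence composition ------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def _anchor_sequence(genome, chrom, point, strand, lo_off, hi_off):
    """Motif-strand sequence covering offsets [lo_off, hi_off]; None at edges."""
    seq = genome[chrom]
    if strand == "+":
        lo, hi = point + lo_off, point + hi_off + 1
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi]
    lo, hi = point - hi_off, point - lo_off + 1
    if lo < 0 or hi > len(seq):
        return None
    return seq[lo:hi].translate(_RC)[::-1]


def sequence_composition(anchors, genome: dict[str, str],
                         window: tuple[int, int] = (-18, 3),
                         strata: np.ndarray | None = None):
    """Per-offset A/C/G/T frequencies on the motif strand.

    Returns a DataFrame (offset x base) or, with ``strata`` (one label per
    anchor), a dict of such tables per stratum.  Edge anchors are skipped;
    the skip count is attached as ``.attrs['n_skipped']``.
    """
    df = _anchor_frame(anchors)
    lo_off, hi_off = window
    labels = (np.zeros(len(df), dtype=int) if strata is None
              else np.asarray(strata))
    tables = {}
    skipped = 0
    for label in np.unique(labels):
        counts = np.zeros((hi_off - lo_off + 1, 4))
        for (_, row), lab in zip(df.iterrows(), labels):
            if lab != label:
                continue
            s = _anchor_sequence(genome, row["chrom"], int(row["point"]),
                                 row["strand"], lo_off, hi_off)
            if s is None:
                skipped += 1
                continue
            for k, base in enumerate(s):
                if base in "ACGT":
                    counts[k, "ACGT".index(base)] += 1
        totals = counts.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1
        tab = pd.DataFrame(counts / totals, columns=list("ACGT"),
                           index=pd.Index(range(lo_off, hi_off + 1),
                                          name="offset"))
        tab.attrs["n_skipped"] = skipped
        tables[label] = tab
    if strata is None:
        return tables[0]
    return tables


def four_color_matrix(anchors, genome: dict[str, str], flank: int = 25
                      ) -> np.ndarray:
    """Per-anchor base codes (A=0, C=1, G=2, T=3, other=-1) over +-flank,
    motif-strand oriented; edge anchors yield rows of -1."""
    df = _anchor_frame(anchors)
    out = np.full((len(df), 2 * flank + 1), -1, dtype=np.int8)
    for r, (_, row) in enumerate(df.iterrows()):
        s = _anchor_sequence(genome, row["chrom"], int(row["point"]),
                             row["strand"], -flank, flank)
        if s is None:
            continue
        for k, base in enumerate(s):
            if base in "ACGT":
                out[r, k] = "ACGT".index(base)
    return out


# -- homotypic clustering ------------------------------------------------


@dataclass
class Cluster:
    chrom: str
    member_ids: list[int]       # indices into the location table
    coordinate: int             # median member midpoint


@dataclass
class HomotypicClusterSet:
    clusters: list[Cluster]
    noncluster_ids: list[int]
    n_locations: int

    @property
    def n_clustered(self) -> int:
        return sum(len(c.member_ids) for c in self.clusters)

    @property
    def frac_clustered(self) -> float:
        return self.n_clustered / self.n_locations if self.n_locations else 0.0

    @property
    def locations_per_cluster(self) -> float:
        return (self.n_clustered / len(self.clusters)
                if self.clusters else float("nan"))


def _median_coord(mids: np.ndarray) -> int:
    mids = np.sort(mids)
    n = len(mids)
    if n % 2:
        return int(mids[n // 2])
    return int(np.round((mids[n // 2 - 1] + mids[n // 2]) / 2.0))


def find_clusters(locations: pd.DataFrame, max_gap: int = 500
                  ) -> HomotypicClusterSet:
    """Homotypic clusters by single-linkage chaining of adjacent midpoints.

    Adjacent locations closer than ``max_gap`` bp (strict) chain into one
    cluster whose coordinate is the median member midpoint (even sizes:
    rounded mean of the central two).  Isolated locations are nonclusters.
    """
    locs = locations.reset_index(drop=True)
    clusters, single = [], []
    for chrom, grp in locs.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()[np.argsort(grp["midpoint"].to_numpy(),
                                              kind="stable")]
        mids = locs.loc[idx, "midpoint"].to_numpy()
        breaks = np.flatnonzero(np.diff(mids) >= max_gap) + 1
        for block in np.split(np.arange(len(idx)), breaks):
            members = idx[block]
            if len(members) >= 2:
                clusters.append(Cluster(chrom, [int(i) for i in members],
                                        _median_coord(mids[block])))
            else:
                single.extend(int(i) for i in members)
    return HomotypicClusterSet(clusters, sorted(single), len(locs))


@dataclass
class ExpressionComparison:
    statistic: float            # Mann-Whitney U
    p_value: float
    cluster_values: np.ndarray
    noncluster_values: np.ndarray
    cluster_genes: list[str]
    noncluster_genes: list[str]

    @property
    def medians(self) -> tuple[float, float]:
        return (float(np.median(self.cluster_values)),
                float(np.median(self.noncluster_values)))

    @property
    def means(self) -> tuple[float, float]:
        return (float(np.mean(self.cluster_values)),
                float(np.mean(self.noncluster_values)))


def nearest_tss_gene(chrom: str, coord: int, tss: pd.DataFrame) -> str | None:
    """Gene with the TSS nearest to a coordinate (ties: lower TSS)."""
    sub = tss[tss["chrom"] == chrom]
    if not len(sub):
        return None
    d = np.abs(sub["tss"].to_numpy() - coord)
    order = np.lexsort((sub["tss"].to_numpy(), d))
    return str(sub.iloc[order[0]]["gene"])


def expression_by_cluster(cluster_set: HomotypicClusterSet,
                          locations: pd.DataFrame, tss: pd.DataFrame,
                          expression: pd.DataFrame) -> ExpressionComparison:
    """Two-sided Mann-Whitney U of nearest-gene expression change,
    cluster locations versus noncluster locations."""
    locs = locations.reset_index(drop=True)
    expr = expression.set_index("gene")["log2fc"]

    def values_for(points):
        genes, vals = [], []
        for chrom, coord in points:
            g = nearest_tss_gene(chrom, coord, tss)
            if g is not None and g in expr.index:
                genes.append(g)
                vals.append(float(expr[g]))
        return genes, np.array(vals)

    cl_points = [(c.chrom, c.coordinate) for c in cluster_set.clusters]
    nc_points = [(locs.at[i, "chrom"], int(locs.at[i, "midpoint"]))
                 for i in cluster_set.noncluster_ids]
    cl_genes, cl_vals = values_for(cl_points)
    nc_genes, nc_vals = values_for(nc_points)
    if not len(cl_vals) or not len(nc_vals):
        import warnings

        warnings.warn("empty group; expression comparison skipped")
        return ExpressionComparison(float("nan"), float("nan"),
                                    cl_vals, nc_vals, cl_genes, nc_genes)
    u, p = stats.mannwhitneyu(cl_vals, nc_vals, alternative="two-sided")
    return ExpressionComparison(float(u), float(p), cl_vals, nc_vals,
                                cl_genes, nc_genes)
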