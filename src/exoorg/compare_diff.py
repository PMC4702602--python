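"""ChIP-exo vs ChIP-seq concordance and differential-occupancy kinetics.

Concordance: location midpoints within 40 bp (an 80-bp window) count as
shared, with per-category motif fractions; occupancy consistency is the
Spearman correlation of log10 tag counts in 400-bp windows; a composite exo
profile around seq-only midpoints (20-bp smoothing) checks whether sub-
threshold exo signal is nonetheless centered there.

Kinetics: per-location occupancy counts are total-tag normalized across
time points, converted to log2 fold changes for the stated ratios, and
k-means clustered (k=6); clusters ranked by mean late/early fold change are
grouped into increased / unchanged / decreased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io_formats import TagTrack
from .organization import CompositeProfile, composite_profile


@dataclass
class OverlapSummary:
    n_exo: int
    n_seq: int
    n_exo_shared: int           # exo locations with >=1 seq midpoint in range
    n_seq_shared: int           # seq locations with >=1 exo midpoint in range
    n_exo_only: int
    n_seq_only: int
    motif_fraction: dict[str, float]
    exo_only: pd.DataFrame
    seq_only: pd.DataFrame


def _shared_mask(locs: pd.DataFrame, others: pd.DataFrame, dist: int
                 ) -> np.ndarray:
    mask = np.zeros(len(locs), dtype=bool)
    for chrom, grp in locs.groupby("chrom", sort=False):
        om = np.sort(others.loc[others["chrom"] == chrom, "midpoint"].to_numpy())
        if not len(om):
            continue
        mids = grp["midpoint"].to_numpy()
        lo = np.searchsorted(om, mids - dist, side="left")
        hi = np.searchsorted(om, mids + dist, side="right")
        mask[locs.index.get_indexer(grp.index)] = hi > lo
    return mask


def _motif_fraction(locs: pd.DataFrame, hits: pd.DataFrame, dist: int) -> float:
    if not len(locs):
        return float("nan")
    return float(_shared_mask(
        locs, hits.rename(columns={"ref_point": "midpoint"}), dist).mean())


def overlap_locations(exo_locs: pd.DataFrame, seq_locs: pd.DataFrame,
                      midpoint_dist: int = 40,
                      motif_hits: pd.DataFrame | None = None,
                      motif_dist: int = 40) -> OverlapSummary:
    """Overlap of exo and seq location lists by the 40-bp midpoint rule.

    Counting is done in both directions (each seq location with >= 1 exo
    midpoint in range, and vice versa), as several exo peak pairs can share
    one broad seq interval.  With ``motif_hits``, the fraction of locations
    carrying a motif reference point within ``motif_dist`` is reported per
    category.
    """
    exo = exo_locs.reset_index(drop=True)
    seq = seq_locs.reset_index(drop=True)
    exo_shared = _shared_mask(exo, seq, midpoint_dist)
    seq_shared = _shared_mask(seq, exo, midpoint_dist)
    exo_only = exo.loc[~exo_shared].reset_index(drop=True)
    seq_only = seq.loc[~seq_shared].reset_index(drop=True)
    motif_fraction = {}
    if motif_hits is not None and len(motif_hits):
        motif_fraction = {
            "exo_shared": _motif_fraction(exo.loc[exo_shared], motif_hits,
                                          motif_dist),
            "seq_shared": _motif_fraction(seq.loc[seq_shared], motif_hits,
                                          motif_dist),
            "exo_only": _motif_fraction(exo_only, motif_hits, motif_dist),
            "seq_only": _motif_fraction(seq_only, motif_hits, motif_dist),
        }
    return OverlapSummary(
        n_exo=len(exo), n_seq=len(seq),
        n_exo_shared=int(exo_shared.sum()), n_seq_shared=int(seq_shared.sum()),
        n_exo_only=len(exo_only), n_seq_only=len(seq_only),
        motif_fraction=motif_fraction, exo_only=exo_only, seq_only=seq_only,
    )


def correlate_occupancy(track_a: TagTrack, track_b: TagTrack,
                        anchors: pd.DataFrame, window: int = 400,
                        pseudocount: float = 1.0, bins: int = 50):
    """Spearman correlation of log10 tag counts around anchor midpoints.

    Counts (both strands) are taken in a ``window``-bp window centered on
    each midpoint, log10-transformed with a pseudocount.  Returns
    (rho, per-anchor table, binned 2-D density table)."""
    if len(anchors) < 3:
        raise ValueError("need >= 3 anchors for a correlation")
    half = window // 2
    rows = []
    for _, row in anchors.iterrows():
        mid = int(row["midpoint"])
        ca = track_a.count_in(row["chrom"], mid - half, mid + half + 1)
        cb = track_b.count_in(row["chrom"], mid - half, mid + half + 1)
        rows.append((np.log10(ca + pseudocount), np.log10(cb + pseudocount)))
    table = pd.DataFrame(rows, columns=["log10_a", "log10_b"])
    rho = float(stats.spearmanr(table["log10_a"], table["log10_b"]).statistic)
    h, xe, ye = np.histogram2d(table["log10_a"], table["log10_b"], bins=bins)
    density = pd.DataFrame(h, index=pd.Index(xe[:-1], name="log10_a"),
                           columns=pd.Index(ye[:-1], name="log10_b"))
    return rho, table, density


def seq_only_profile(exo_track: TagTrack, seq_only_midpoints: pd.DataFrame,
                     flank: int = 200, smooth: int = 20):
    """Composite exo tag profile around seq-only midpoints (20-bp smoothing).

    Returns (profile, centered, mode_offset): ``centered`` is whether the
    combined-density mode falls within +-10 bp of the midpoints.
    """
    anchors = seq_only_midpoints.copy()
    if "strand" not in anchors.columns:
        anchors["strand"] = "+"
    profile = composite_profile(exo_track, anchors, flank=flank, smooth=smooth)
    combined = profile.plus_density + profile.minus_density
    mode_offset = int(profile.offsets[int(np.argmax(combined))])
    return profile, abs(mode_offset) <= 10, mode_offset


def differential_occupancy(tracks: dict[str, TagTrack],
                           locations: pd.DataFrame,
                           ratios: list[tuple[str, str]] | None = None,
                           count_halfwidth: int = 25,
                           pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-location log2 fold changes of occupancy between time points.

    Counts (both strands, +-count_halfwidth of the midpoint) are scaled so
    total tag counts are equal across time points, then
    log2((a + pc) / (b + pc)) is taken for each (a, b) ratio.  Default
    ratios compare every later time point with every earlier one.
    """
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need >= 2 time points")
    totals = {t: tracks[t].total for t in names}
    if any(v == 0 for v in totals.values()):
        zero = [t for t, v in totals.items() if v == 0]
        raise ValueError(f"zero-total track(s): {zero}")
    mean_total = np.mean(list(totals.values()))
    scales = {t: mean_total / totals[t] for t in names}
    counts = {}
    for t in names:
        c = []
        for _, row in locations.iterrows():
            mid = int(row["midpoint"])
            c.append(tracks[t].count_in(row["chrom"], mid - count_halfwidth,
                                        mid + count_halfwidth + 1))
        counts[t] = np.asarray(c, dtype=float) * scales[t]
    if ratios is None:
        ratios = [(b, a) for i, a in enumerate(names)
                  for b in names[i + 1:]]
    out = locations[["chrom", "midpoint"]].reset_index(drop=True)
    for num, den in ratios:
        out[f"log2fc_{num}_vs_{den}"] = np.log2(
            (counts[num] + pseudocount) / (counts[den] + pseudocount))
    return out


@dataclass
class KineticClassAssignment:
    assignments: pd.DataFrame       # cluster (1..k by rank) and group per row
    cluster_means: pd.DataFrame     # per ranked cluster, mean log2FC vector
    key_column: str


def kinetic_classes(log2fc: pd.DataFrame, k: int = 6, seed: int = 0,
                    key_column: str | None = None,
                    n_init: int = 10) -> KineticClassAssignment:
    """k-means kinetic classes on log2 fold-change vectors.

    Clusters are relabeled 1..k by descending mean of ``key_column`` (the
    late/early fold change; defaults to the last log2fc column) and grouped
    into increased (top 2), unchanged (middle 2) and decreased (bottom 2).
    """
    fc_cols = [c for c in log2fc.columns if c.startswith("log2fc_")]
    if not fc_cols:
        raise ValueError("no log2fc_* columns found")
    X = log2fc[fc_cols].to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("log2 fold changes must be finite")
    if len(X) < k:
        raise ValueError(f"fewer locations ({len(X)}) than clusters ({k})")
    key_column = key_column or fc_cols[-1]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    raw = km.labels_
    means = pd.DataFrame(km.cluster_centers_, columns=fc_cols)
    rank_order = np.argsort(-means[key_column].to_numpy(), kind="stable")
    rank_of = {int(raw_label): r + 1 for r, raw_label in enumerate(rank_order)}
    ranked = np.array([rank_of[int(l)] for l in raw])
    third = k // 3
    groups = np.where(ranked <= third, "increased",
                      np.where(ranked <= 2 * third, "unchanged", "decreased"))
    assignments = log2fc.copy()
    assignments["cluster"] = ranked
    assignments["group"] = groups
    cluster_means = means.iloc[rank_order].reset_index(drop=True)
    cluster_means.index = pd.RangeIndex(1, k + 1, name="cluster")
    return KineticClassAssignment(assignments, cluster_means, key_column)
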