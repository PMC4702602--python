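"""Synthetic ChIP-exo / ChIP-seq / input data with known ground truth.

The generator encodes the structural model the analysis is built to recover:
lambda exonuclease stops ~6 bp 5' of each protein-DNA cross-link, so a single
cross-link produces a plus-strand 5'-end peak 6 bp to its left and a
minus-strand peak 6 bp to its right (~12 bp apart).  GATA1 cross-links at the
two edges of the WGATAA element (offsets -8/+8 from the motif reference point,
major/minor), TAL1 at two points upstream (-21/-13, flanking the partial
E-box of the composite TG[N7-8]WGATAA element).  ChIP-seq tags instead start
at random sonication breakpoints of fragments overlapping the site.

Site occupancies are lognormal (heavy-tailed, as in sorted occupancy
heatmaps); background is strand-independent uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import TagTrack

#: motif-strand offset of the reference base (the 5th base, index 4, of
#: WGATAA) -- all cross-link offsets are defined relative to this point.
WGATAA_REF_INDEX = 4

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CrossLinkModel:
    """Cross-link geometry of one factor around the motif reference point.

    ``crosslink_offsets`` is a list of (offset_bp, weight) pairs; offsets are
    motif-strand coordinates relative to the reference point.  The exonuclease
    stops ``exo_stop_offset`` bp 5' of the cross-link on each strand, with
    rounded-Gaussian jitter of ``jitter_sd`` bp.
    """

    factor_name: str
    crosslink_offsets: list[tuple[int, float]]
    exo_stop_offset: int = 6
    jitter_sd: float = 1.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        w = sum(w for _, w in self.crosslink_offsets)
        if not np.isclose(w, 1.0):
            raise ValueError("cross-link weights must sum to 1")
        if self.exo_stop_offset < 0:
            raise ValueError("exo_stop_offset must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def gata1_model(major_weight: float = 0.75, **kw) -> CrossLinkModel:
    """GATA1: cross-links at the motif edges, major at -8, minor at +8."""
    return CrossLinkModel(
        "GATA1", [(-8, major_weight), (8, 1.0 - major_weight)], **kw
    )


def tal1_model(distal_weight: float = 0.5, downstream_weight: float = 0.0, **kw):
    """TAL1: two upstream cross-links at -21 and -13; an optional minor
    downstream cross-link (+14) is off by default."""
    offsets = [
        (-21, distal_weight * (1 - downstream_weight)),
        (-13, (1 - distal_weight) * (1 - downstream_weight)),
    ]
    if downstream_weight > 0:
        offsets.append((14, downstream_weight))
    return CrossLinkModel("TAL1", offsets, **kw)


@dataclass
class SiteSpec:
    """How many sites of each class to embed and their spacing/occupancy."""

    n_cobound: int = 0
    n_gata_only: int = 0
    n_tal_only: int = 0
    spacer_lengths: tuple[int, ...] = (7, 8)
    occupancy_log_mean: float = 3.0
    occupancy_log_sd: float = 1.0
    min_site_separation: int = 600

    def __post_init__(self) -> None:
        if min(self.n_cobound, self.n_gata_only, self.n_tal_only) < 0:
            raise ValueError("site counts must be >= 0")
        if any(s < 0 for s in self.spacer_lengths):
            raise ValueError("spacer lengths must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_cobound + self.n_gata_only + self.n_tal_only


TRUTH_COLUMNS = [
    "site_id", "chrom", "motif_start", "motif_end", "motif_strand",
    "site_class", "spacer_length", "wgataa_start", "ref_point",
    "occ_GATA1", "occ_TAL1", "strength",
]


def generate_genome(length: int, gc_fraction: float = 0.42, seed: int = 0,
                    chrom: str = "chrSim") -> dict[str, str]:
    """Random i.i.d. genome with the stated GC fraction."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
         (1 - gc_fraction) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return {chrom: bases.tobytes().decode("ascii")}


def _ref_point(start: int, end: int, strand: str) -> int:
    """Genomic coordinate of the WGATAA reference base (motif index 4)."""
    if strand == "+":
        return start + WGATAA_REF_INDEX
    return end - 1 - WGATAA_REF_INDEX


def _scrub(seq: list[str], pattern: str, rng) -> None:
    """Destroy every occurrence of a dinucleotide in a mutable window."""
    alphabet = "ACGT"
    for i in range(len(seq) - 1):
        while seq[i] + seq[i + 1] == pattern:
            seq[i + 1] = alphabet[rng.integers(4)]


def embed_sites(genome: dict[str, str], spec: SiteSpec, seed: int = 0):
    """Plant cobound / GATA1-only / TAL1-only sites into a genome.

    Cobound sites carry the composite element TG[Ns]WGATAA; GATA1-only sites
    carry WGATAA with the upstream TG scrubbed out of the 1-12 bp band;
    TAL1-only sites carry a CAGMTG E-box with no WGATAA within 40 bp.  Sites
    land on either strand with equal probability at >= ``min_site_separation``
    spacing.  Returns the modified genome and the truth table.
    """
    rng = np.random.default_rng(seed)
    (chrom, seq), = genome.items()
    seq = list(seq)
    n = spec.n_total
    if n == 0:
        return {chrom: "".join(seq)}, pd.DataFrame(columns=TRUTH_COLUMNS)

    margin = 100
    sep = spec.min_site_separation
    slots = np.arange(margin, len(seq) - margin - 40, sep)
    if len(slots) < n:
        raise ValueError(
            f"genome too short: {len(slots)} slots of {sep} bp for {n} sites "
            "(min_site_separation constraint)"
        )
    positions = np.sort(rng.choice(slots, size=n, replace=False))
    classes = (["cobound"] * spec.n_cobound + ["gata_only"] * spec.n_gata_only
               + ["tal_only"] * spec.n_tal_only)
    rng.shuffle(classes)

    # shared site strength couples GATA1 and TAL1 occupancy at cobound sites
    strengths = rng.lognormal(spec.occupancy_log_mean, spec.occupancy_log_sd, n)

    rows = []
    for i, (pos, cls, strength) in enumerate(zip(positions, classes, strengths)):
        strand = "+" if rng.random() < 0.5 else "-"
        w = "AT"[rng.integers(2)]
        wgataa = w + "GATAA"
        spacer_len = None
        if cls == "cobound":
            spacer_len = int(spec.spacer_lengths[rng.integers(len(spec.spacer_lengths))])
            spacer = "".join("ACGT"[j] for j in rng.integers(0, 4, spacer_len))
            _scrub_list = list(spacer)
            _scrub(_scrub_list, "TG", rng)
            element = "TG" + "".join(_scrub_list) + wgataa
        elif cls == "gata_only":
            element = wgataa
        else:  # tal_only: CAGMTG E-box, no WGATAA nearby
            m = "AC"[rng.integers(2)]
            element = "CAG" + m + "TG"
        placed = element if strand == "+" else revcomp(element)
        start, end = int(pos), int(pos) + len(element)
        seq[start:end] = list(placed)

        if cls == "cobound":
            wg_start = start + len(element) - 6 if strand == "+" else start
        elif cls == "gata_only":
            wg_start = start
        else:
            wg_start = None

        if cls in ("cobound", "gata_only"):
            # WGATAA genome span (the anchor element for the reference point)
            wg_end = wg_start + 6
            # no spurious upstream TG within 1-12 bp of the motif at
            # gata_only sites, and none nearer than the planted one at
            # cobound sites
            if cls == "gata_only":
                if strand == "+":
                    lo = max(0, wg_start - 14)
                    window = seq[lo:wg_start]
                    _scrub(window, "TG", rng)
                    seq[lo:wg_start] = window
                else:
                    hi = min(len(seq), wg_end + 14)
                    window = seq[wg_end:hi]
                    _scrub(window, "CA", rng)
                    seq[wg_end:hi] = window
            ref = _ref_point(wg_start, wg_end, strand)
        else:
            # E-box midpoint stands in as the anchor; remove any WGATAA
            # (either strand) within 40 bp
            center = (start + end) // 2
            lo, hi = max(0, center - 43), min(len(seq), center + 43)
            window = "".join(seq[lo:hi])
            for probe_w in "AT":
                for probe in (probe_w + "GATAA", revcomp(probe_w + "GATAA")):
                    j = window.find(probe)
                    while j != -1:
                        if not (start - lo <= j < end - lo):
                            seq[lo + j + 2] = "ACGT"[rng.integers(4)]
                            window = "".join(seq[lo:hi])
                            j = window.find(probe)
                        else:
                            j = window.find(probe, j + 1)
            ref = center
            wg_start = -1

        occ_g = strength if cls in ("cobound", "gata_only") else 0.0
        occ_t = strength * np.exp(rng.normal(0, 0.3)) if cls in ("cobound", "tal_only") else 0.0
        rows.append({
            "site_id": f"site{i:05d}", "chrom": chrom,
            "motif_start": start, "motif_end": end, "motif_strand": strand,
            "site_class": cls, "spacer_length": spacer_len,
            "wgataa_start": wg_start, "ref_point": int(ref),
            "occ_GATA1": occ_g, "occ_TAL1": occ_t, "strength": strength,
        })
    return {chrom: "".join(seq)}, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _site_tag_counts(occ: np.ndarray, mean_tags_per_site: float, rng):
    occ = np.asarray(occ, dtype=float)
    mean_occ = occ[occ > 0].mean() if (occ > 0).any() else 1.0
    lam = mean_tags_per_site * occ / mean_occ
    return rng.poisson(lam)


def simulate_exo_tags(genome, truth: pd.DataFrame, model: CrossLinkModel,
                      mean_tags_per_site: float = 50, seed: int = 0,
                      occupancy_column: str | None = None) -> TagTrack:
    """Place strand-separated ChIP-exo 5' ends around truth-site cross-links.

    Each bound molecule draws one cross-link by weight; the exonuclease stop
    puts a plus-strand 5' end ``exo_stop_offset`` bp to the genomic left of
    the cross-link and a minus-strand 5' end the same distance to the right,
    each with independent rounded-Gaussian jitter.  Minus-strand motifs
    mirror all offsets through the reference-point mapping.  Uniform
    background is added at ``model.background_rate`` per bp per strand.
    Returns the track; dropped out-of-bounds tags are counted in
    ``track.n_dropped``.
    """
    if mean_tags_per_site <= 0:
        raise ValueError("mean_tags_per_site must be positive")
    rng = np.random.default_rng(seed)
    (chrom, seq), = genome.items()
    L = len(seq)
    track = TagTrack({chrom: L}, name=f"exo_{model.factor_name}",
                     factor=model.factor_name)
    occ_col = occupancy_column or f"occ_{model.factor_name}"
    offsets = np.array([o for o, _ in model.crosslink_offsets])
    weights = np.array([w for _, w in model.crosslink_offsets])
    dropped = 0
    if len(truth):
        counts = _site_tag_counts(truth[occ_col].to_numpy(), mean_tags_per_site, rng)
        for (_, site), n_mol in zip(truth.iterrows(), counts):
            if n_mol == 0 or site[occ_col] <= 0:
                continue
            sign = 1 if site.motif_strand == "+" else -1
            xl_off = rng.choice(offsets, size=n_mol, p=weights)
            xl = site.ref_point + sign * xl_off
            for strand_sign, strand in ((-1, "+"), (1, "-")):
                stops = xl + strand_sign * model.exo_stop_offset
                if model.jitter_sd > 0:
                    stops = stops + np.rint(
                        rng.normal(0, model.jitter_sd, n_mol)).astype(int)
                for p in stops:
                    if 0 <= p < L:
                        track.add(chrom, strand, int(p))
                    else:
                        dropped += 1
    if model.background_rate > 0:
        for strand in ("+", "-"):
            n_bg = rng.poisson(model.background_rate * L)
            for p in rng.integers(0, L, n_bg):
                track.add(chrom, strand, int(p))
    track.n_dropped = dropped
    return track


def simulate_seq_tags(genome, truth: pd.DataFrame, fragment_mean: float = 200,
                      fragment_sd: float = 50, mean_tags_per_site: float = 50,
                      background_rate: float = 0.0, seed: int = 0,
                      occupancy_column: str = "occ_GATA1") -> TagTrack:
    """ChIP-seq tags: 5' ends at sonication breakpoints of fragments
    overlapping each site, giving broad unimodal strand densities."""
    if fragment_mean <= 0:
        raise ValueError("fragment_mean must be positive")
    rng = np.random.default_rng(seed)
    (chrom, seq), = genome.items()
    L = len(seq)
    track = TagTrack({chrom: L}, name="seq", factor=occupancy_column[4:])
    dropped = 0
    if len(truth):
        counts = _site_tag_counts(truth[occupancy_column].to_numpy(),
                                  mean_tags_per_site, rng)
        for (_, site), n_mol in zip(truth.iterrows(), counts):
            if n_mol == 0 or site[occupancy_column] <= 0:
                continue
            center = site.ref_point
            frag_len = np.maximum(
                20, rng.normal(fragment_mean, fragment_sd, n_mol)).astype(int)
            left = center - rng.integers(0, frag_len)  # uniform overlap
            right = left + frag_len - 1
            strands = rng.random(n_mol) < 0.5
            for fl, fr, plus in zip(left, right, strands):
                p, strand = (int(fl), "+") if plus else (int(fr), "-")
                if 0 <= p < L:
                    track.add(chrom, strand, p)
                else:
                    dropped += 1
    if background_rate > 0:
        for strand in ("+", "-"):
            n_bg = rng.poisson(background_rate * L)
            for p in rng.integers(0, L, n_bg):
                track.add(chrom, strand, int(p))
    track.n_dropped = dropped
    return track


def simulate_input_track(length: int, rate: float, seed: int = 0,
                         chrom: str = "chrSim") -> TagTrack:
    """Uniform Poisson input control: ``rate`` expected tags per bp per strand."""
    rng = np.random.default_rng(seed)
    track = TagTrack({chrom: length}, name="input")
    for strand in ("+", "-"):
        n = rng.poisson(rate * length)
        for p in rng.integers(0, length, n):
            track.add(chrom, strand, int(p))
    return track


def simulate_annotation(genome, truth: pd.DataFrame, n_genes: int = 100,
                        effect_log2fc_cobound: float = 2.0,
                        noise_sd: float = 0.5, seed: int = 0):
    """TSS and expression tables: genes nearest a cobound site respond.

    TSS positions are spread uniformly over the genome; each gene's log2
    expression fold change is N(effect, noise_sd) if it is the nearest gene
    to some cobound truth site and N(0, noise_sd) otherwise.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    (chrom, seq), = genome.items()
    tss_pos = np.sort(rng.choice(len(seq), size=n_genes, replace=False))
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    tss = pd.DataFrame({"gene": genes, "chrom": chrom, "tss": tss_pos,
                        "strand": rng.choice(["+", "-"], n_genes)})
    responsive = set()
    cobound = truth[truth.site_class == "cobound"] if len(truth) else truth
    for _, site in cobound.iterrows():
        responsive.add(int(np.argmin(np.abs(tss_pos - site.ref_point))))
    log2fc = rng.normal(0.0, noise_sd, n_genes)
    for i in responsive:
        log2fc[i] = rng.normal(effect_log2fc_cobound, noise_sd)
    expr = pd.DataFrame({"gene": genes, "log2fc": log2fc})
    return tss, expr
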