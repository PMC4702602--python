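"""IUPAC and PWM motif scanning with exact p-values, motif centering,
TG-spacing analysis, and E-box composition classification.

A scan reports hits on both strands; minus-strand hits are matches of the
reverse complement on the forward sequence.  Every hit carries a strand-aware
*reference point*: for the WGATAA element this is its 5th base (0-based index
4), and all cross-link offsets and occupancy windows in the pipeline are
defined relative to it.  PWM p-values are exact tail probabilities of the
log-odds score under the background base distribution, computed by dynamic
programming over a discretized score grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import WGATAA_REF_INDEX, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

HIT_COLUMNS = ["chrom", "start", "end", "strand", "score", "p_value",
               "ref_point"]


def _validate_iupac(consensus: str) -> str:
    consensus = consensus.upper()
    bad = [c for c in consensus if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC letters {bad} in {consensus!r}")
    return consensus


def _ref_points(start, end, strand, ref_index):
    """Strand-aware reference coordinate of hits (vectorized)."""
    return np.where(np.asarray(strand) == "+",
                    np.asarray(start) + ref_index,
                    np.asarray(end) - 1 - ref_index)


def _encode(seq: str) -> np.ndarray:
    code = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[np.frombuffer(seq.encode(), dtype=np.uint8)
             == ord(b)] = i
    return code


def scan_iupac(genome: dict[str, str], consensus: str,
               ref_index: int | None = None) -> pd.DataFrame:
    """All exact matches of an IUPAC consensus on both strands.

    score = motif length; p_value = (product of allowed-letter counts)/4^L,
    the chance of a match at a fixed position/strand of random sequence.
    """
    consensus = _validate_iupac(consensus)
    L = len(consensus)
    if ref_index is None:
        ref_index = WGATAA_REF_INDEX if L == 6 else L // 2
    p_match = float(np.prod([len(IUPAC[c]) for c in consensus]) / 4.0**L)
    allowed = [
        np.array([_BASE_INDEX[b] for b in IUPAC[c]], dtype=np.int8)
        for c in consensus
    ]
    rows = []
    for chrom in sorted(genome):
        code = _encode(genome[chrom])
        n = len(code) - L + 1
        if n <= 0:
            continue
        for strand in ("+", "-"):
            letters = allowed if strand == "+" else [
                np.array([3 - b for b in a], dtype=np.int8)
                for a in allowed[::-1]
            ]
            ok = np.ones(n, dtype=bool)
            for i, a in enumerate(letters):
                ok &= np.isin(code[i:i + n], a)
            for s in np.flatnonzero(ok):
                rows.append((chrom, int(s), int(s) + L, strand, float(L),
                             p_match, 0))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(hits):
        hits["ref_point"] = _ref_points(hits["start"], hits["end"],
                                        hits["strand"], ref_index)
    return hits.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


@dataclass
class Pwm:
    """Position weight matrix with background model and log-odds scoring."""

    motif_id: str
    matrix: np.ndarray          # (L, 4) per-position base probabilities
    background: np.ndarray = None
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (L, 4)")
        if self.matrix.shape[0] < 2:
            raise ValueError("PWM length must be >= 2")
        if not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("PWM rows must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = (self.matrix + self.pseudocount)
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    @classmethod
    def from_iupac(cls, consensus: str, pseudocount: float = 1e-3,
                   motif_id: str | None = None) -> "Pwm":
        """Uniform-over-allowed-letters matrix from an IUPAC consensus."""
        consensus = _validate_iupac(consensus)
        mat = np.zeros((len(consensus), 4))
        for i, c in enumerate(consensus):
            for b in IUPAC[c]:
                mat[i, _BASE_INDEX[b]] = 1.0 / len(IUPAC[c])
        return cls(motif_id or consensus, mat, pseudocount=pseudocount)

    @classmethod
    def from_text(cls, path, motif_id: str | None = None) -> "Pwm":
        """Read a simple 4-column probability matrix (one row per position)."""
        mat = np.loadtxt(path)
        return cls(motif_id or str(path), np.atleast_2d(mat))

    def reverse_complement(self) -> np.ndarray:
        """Log-odds matrix scoring the minus strand on the forward sequence."""
        return self.log_odds[::-1, ::-1]


_PVAL_BIN = 0.01  # log-odds discretization for the exact-p-value DP


def _score_distribution(log_odds: np.ndarray, background: np.ndarray,
                        bin_width: float = _PVAL_BIN):
    """Exact distribution of the integer-binned score under the background.

    Returns (lo, probs) where probs[i] = P(binned score == lo + i).
    """
    scaled = np.rint(log_odds / bin_width).astype(np.int64)
    probs = np.array([1.0])
    lo = 0
    for row in scaled:
        rmin, rmax = int(row.min()), int(row.max())
        new = np.zeros(len(probs) + rmax - rmin)
        for b in range(4):
            shift = int(row[b]) - rmin
            new[shift:shift + len(probs)] += background[b] * probs
        probs = new
        lo += rmin
    return lo, probs


def pwm_pvalue(pwm: Pwm, score: float) -> float:
    """Exact P(score' >= score) for a random background sequence."""
    lo, probs = _score_distribution(pwm.log_odds, pwm.background)
    sf = np.cumsum(probs[::-1])[::-1]
    # bin the query score the same way window scores are binned
    q = int(np.rint(score / _PVAL_BIN))
    idx = q - lo
    if idx <= 0:
        return 1.0
    if idx >= len(sf):
        return 0.0
    return float(sf[idx])


def _window_scores(code: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Binned integer log-odds score of every window (NaN-free; windows with
    non-ACGT bases score -inf)."""
    L = len(log_odds)
    n = len(code) - L + 1
    scaled = np.rint(log_odds / _PVAL_BIN).astype(np.int64)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(L):
        window = code[i:i + n]
        valid &= window >= 0
        scores += scaled[i, np.clip(window, 0, 3)]
    return np.where(valid, scores, np.iinfo(np.int64).min)


def scan_pwm(genome: dict[str, str], pwm: Pwm, p_max: float = 1e-3,
             ref_index: int | None = None) -> pd.DataFrame:
    """PWM hits on both strands with exact p_value < p_max."""
    if not (0.0 < p_max <= 1.0):
        raise ValueError("p_max must be in (0, 1]")
    L = pwm.length
    if ref_index is None:
        ref_index = WGATAA_REF_INDEX if L == 6 else L // 2
    lo, probs = _score_distribution(pwm.log_odds, pwm.background)
    sf = np.cumsum(probs[::-1])[::-1]

    def pvalue_of(binned: np.ndarray) -> np.ndarray:
        idx = np.clip(binned - lo, 0, len(sf) - 1)
        p = sf[idx]
        p[binned - lo <= 0] = 1.0
        return p

    matrices = {"+": pwm.log_odds, "-": pwm.reverse_complement()}
    rows = []
    for chrom in sorted(genome):
        code = _encode(genome[chrom])
        if len(code) < L:
            continue
        for strand, lo_mat in matrices.items():
            binned = _window_scores(code, lo_mat)
            ok = binned > np.iinfo(np.int64).min
            pvals = np.ones(len(binned))
            pvals[ok] = pvalue_of(binned[ok])
            # p_max = 1 means "report every scorable window"
            keep = ok if p_max >= 1.0 else (ok & (pvals < p_max))
            hit_idx = np.flatnonzero(keep)
            for s in hit_idx:
                rows.append((chrom, int(s), int(s) + L, strand,
                             float(binned[s] * _PVAL_BIN), float(pvals[s]), 0))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(hits):
        hits["ref_point"] = _ref_points(hits["start"], hits["end"],
                                        hits["strand"], ref_index)
    return hits.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def center_on_motif(locations: pd.DataFrame, hits: pd.DataFrame,
                    max_dist: int = 40) -> pd.DataFrame:
    """Move each location midpoint to the most significant motif within
    ``max_dist`` bp (ties: nearest, then lower coordinate); locations with
    no eligible hit are flagged motif-less and left unmoved."""
    out = locations.copy().reset_index(drop=True)
    out["has_motif"] = False
    out["motif_strand"] = "."
    out["motif_p"] = np.nan
    out["motif_start"] = -1
    for chrom, grp in out.groupby("chrom", sort=False):
        h = hits[hits["chrom"] == chrom]
        if not len(h):
            continue
        refs = h["ref_point"].to_numpy()
        order = np.argsort(refs, kind="stable")
        refs_sorted = refs[order]
        for i in grp.index:
            mid = out.at[i, "midpoint"]
            lo = np.searchsorted(refs_sorted, mid - max_dist, side="left")
            hi = np.searchsorted(refs_sorted, mid + max_dist, side="right")
            if hi <= lo:
                continue
            cand = h.iloc[order[lo:hi]].assign(
                _dist=lambda d: np.abs(d["ref_point"] - mid))
            best = cand.sort_values(["p_value", "_dist", "ref_point"],
                                    kind="stable").iloc[0]
            out.at[i, "midpoint"] = int(best["ref_point"])
            out.at[i, "has_motif"] = True
            out.at[i, "motif_strand"] = best["strand"]
            out.at[i, "motif_p"] = best["p_value"]
            out.at[i, "motif_start"] = int(best["start"])
    return out


@dataclass
class TgScanResult:
    """Upstream-TG scan: overall distance histogram plus per-site distances."""
    histogram: pd.Series                  # distance -> occurrence count
    per_site: list[list[int]]             # distances found per site
    site_index: list                      # location-table index per entry
    n_skipped: int

    def presence(self, distances=(7, 8, 9)) -> np.ndarray:
        want = set(distances)
        return np.array([bool(want & set(d)) for d in self.per_site])


def _motif_bounds(row) -> tuple[int, int]:
    start = int(row["motif_start"])
    return start, start + 6


def tg_distance_histogram(sites: pd.DataFrame, genome: dict[str, str],
                          scan_range: tuple[int, int] = (1, 20)
                          ) -> TgScanResult:
    """Frequencies of upstream-TG distances from WGATAA on the motif strand.

    Distance = number of bases between the G of TG and the first base of
    WGATAA (TG[N_d]WGATAA).  All occurrences within ``scan_range`` are
    recorded per site.  Sites too close to a chromosome edge are skipped.
    """
    d_lo, d_hi = scan_range
    counts: dict[int, int] = {d: 0 for d in range(d_lo, d_hi + 1)}
    per_site, site_index = [], []
    n_skipped = 0
    for i, row in sites.iterrows():
        if not row.get("has_motif", True) or row["motif_strand"] not in "+-":
            continue
        seq = genome[row["chrom"]]
        start, end = _motif_bounds(row)
        found = []
        scanned_any = False
        for d in range(d_lo, d_hi + 1):
            if row["motif_strand"] == "+":
                j = start - d - 2
                if j < 0:
                    break  # clipped at the chromosome edge
                scanned_any = True
                if seq[j:j + 2] == "TG":
                    found.append(d)
            else:
                j = end + d
                if j + 2 > len(seq):
                    break
                scanned_any = True
                if seq[j:j + 2] == "CA":
                    found.append(d)
        if not scanned_any:
            n_skipped += 1
            continue
        for d in found:
            counts[d] += 1
        per_site.append(found)
        site_index.append(i)
    return TgScanResult(pd.Series(counts).sort_index(), per_site,
                        site_index, n_skipped)


def choose_tg(distances: list[int], band: tuple[int, int] = (7, 8)
              ) -> int | None:
    """Pick the TG occurrence closest to the expected spacing band
    (ties toward the smaller distance)."""
    if not distances:
        return None

    def penalty(d):
        if band[0] <= d <= band[1]:
            return 0
        return min(abs(d - band[0]), abs(d - band[1]))

    return sorted(distances, key=lambda d: (penalty(d), d))[0]


@dataclass
class EboxComposition:
    """ZZNNTG composition of chosen upstream-TG sites."""
    zz_counts: pd.Series            # ZZ dinucleotide -> count
    nn_counts_ca: pd.Series         # NN within ZZ=CA -> count
    frac_full_ebox: float           # CANNTG fraction
    frac_ma_or_bg: float            # MA / BG dimorphism (IUPAC M, B)
    n_sites: int
    n_excluded: int


def classify_ebox(sites: pd.DataFrame, genome: dict[str, str],
                  tg_distance_col: str = "tg_distance") -> EboxComposition:
    """Read the 4 bases 5' of each chosen TG as ZZNN and tabulate.

    ``sites`` must carry motif coordinates/strand and a per-site chosen TG
    distance (``tg_distance``); sites with insufficient flank are excluded
    and counted.
    """
    zz: dict[str, int] = {}
    nn_ca: dict[str, int] = {}
    n_full = n_mabg = n_used = n_excl = 0
    for _, row in sites.iterrows():
        d = row[tg_distance_col]
        if d is None or (isinstance(d, float) and np.isnan(d)):
            continue
        d = int(d)
        seq = genome[row["chrom"]]
        start, end = _motif_bounds(row)
        if row["motif_strand"] == "+":
            j = start - d - 2          # start of TG
            if j - 4 < 0:
                n_excl += 1
                continue
            zznn = seq[j - 4:j]
        else:
            j = end + d                # start of CA (= TG on motif strand)
            if j + 6 > len(seq):
                n_excl += 1
                continue
            zznn = revcomp(seq[j + 2:j + 6])
        z2, n2 = zznn[:2], zznn[2:]
        zz[z2] = zz.get(z2, 0) + 1
        n_used += 1
        if z2 == "CA":
            nn_ca[n2] = nn_ca.get(n2, 0) + 1
            n_full += 1
        if (z2[1] == "A" and z2[0] in IUPAC["M"]) or \
           (z2[1] == "G" and z2[0] in IUPAC["B"]):
            n_mabg += 1
    return EboxComposition(
        zz_counts=pd.Series(zz).sort_values(ascending=False),
        nn_counts_ca=pd.Series(nn_ca).sort_values(ascending=False),
        frac_full_ebox=n_full / n_used if n_used else float("nan"),
        frac_ma_or_bg=n_mabg / n_used if n_used else float("nan"),
        n_sites=n_used, n_excluded=n_excl,
    )
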