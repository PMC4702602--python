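# exoorg

Analysis of ChIP-exo data for the positional organization of
transcription-factor complexes around their DNA motifs, built around the
GATA1/TAL1 erythroid system.

In ChIP-exo, a 5'→3' lambda exonuclease digests immunoprecipitated chromatin
up to ~6 bp 5' of each protein–DNA cross-link, so a single cross-link leaves
a plus-strand peak of tag 5' ends ~6 bp to its left and a minus-strand peak
~6 bp to its right — a *peak pair* separated by ~12 bp whose midpoint
estimates the cross-link position to a few bp. `exoorg` implements the full
analysis chain that exploits this geometry:

- **peakcalling** — per-strand Gaussian smoothing (σ = 5 bp), exclusion-zone
  (10 bp) peak picking, plus/minus pairing with separation d = minus − plus
  ∈ [−5, +25] bp, blacklist filtering, exact-binomial enrichment against an
  input control (fold > 2, Benjamini–Hochberg q < 0.05), 40-bp
  cross-condition union, and 100-bp intersection with an external event list
  (e.g. MultiGPS output).
- **motifscan** — IUPAC and PWM scanning on both strands with exact p-values
  (dynamic programming over the discretized log-odds score; p < 10⁻³
  default), motif-centering of binding locations (≤ 40 bp), upstream-TG
  spacing analysis of the composite TG[N₇₋₈]WGATAA element, and E-box
  (ZZNNTG) composition classification.
- **organization** — GATA1/TAL1 co-occupancy (midpoints ≤ 40 bp),
  motif-anchored strand-separated composite profiles (5-bp moving average),
  cross-link-point estimation from composite peak pairs, occupancy windows
  (GATA1 −25..+25, TAL1 −40..+30 around the WGATAA reference point),
  occupancy-sorted heatmap matrices, sequence-composition panels, homotypic
  clustering (< 500 bp, median coordinate) and cluster-vs-expression
  comparison (Mann–Whitney).
- **compare_diff** — ChIP-exo/ChIP-seq concordance (40-bp midpoint rule,
  Spearman correlation of log₁₀ counts in 400-bp windows, composite exo
  signal around seq-only locations), and differential-occupancy kinetics
  (total-tag normalization, log₂ fold changes across activation time
  points, k-means k = 6 grouped into increased/unchanged/decreased).
- **simdata** — a synthetic-data generator emitting genomes with embedded
  cobound / GATA1-only / TAL1-only sites, strand-separated ChIP-exo tags
  under an explicit cross-link model (GATA1 at −8/+8 from the WGATAA
  reference base, TAL1 at −21/−13), sonication-breakpoint ChIP-seq tags,
  Poisson input controls, and TSS/expression tables — all with ground-truth
  tables for recovery testing.
- **io_formats** — tag BED (5'-end extraction), FASTA, interval and
  location-table readers/writers; 0-based half-open coordinates throughout.

## Worked example

Simulate a dataset, call peak pairs, and recover the GATA1 cross-link
geometry:

```python
import numpy as np
from exoorg import simdata, peakcalling, organization

genome = simdata.generate_genome(300_000, gc_fraction=0.42, seed=1)
spec = simdata.SiteSpec(n_cobound=150, n_gata_only=100, min_site_separation=600)
genome, truth = simdata.embed_sites(genome, spec, seed=2)

model = simdata.gata1_model(background_rate=1e-4)   # cross-links at -8/+8
chip = simdata.simulate_exo_tags(genome, truth, model, mean_tags_per_site=50, seed=3)

peaks = peakcalling.call_peaks_track(chip, sigma=5, exclusion=10)
pairs = peakcalling.pair_peaks(peaks[("chrSim", "+")], peaks[("chrSim", "-")])
seps, counts = np.unique([p.separation for p in pairs], return_counts=True)
print("pairs:", len(pairs), "modal separation:", seps[np.argmax(counts)])

anchors = truth.rename(columns={"ref_point": "point", "motif_strand": "strand"})
profile = organization.composite_profile(chip, anchors, flank=60, smooth=5)
for est in organization.estimate_crosslinks(profile, max_pairs=2):
    print(f"cross-link at {est.offset:+.1f} bp, pair separation "
          f"{est.separation} bp, intensity {est.intensity:.2f}")
```

Output:

```
pairs: 429 modal separation: 12
cross-link at -8.0 bp, pair separation 12 bp, intensity 7.40
cross-link at +8.0 bp, pair separation 12 bp, intensity 2.44
```

The modal plus/minus separation of 12 bp is twice the 6-bp exonuclease stop
offset; the two composite peak-pair midpoints sit at −8 and +8 bp from the
WGATAA reference base (16 bp apart), with the −8 pair the stronger — the
double-peak-pair signature of GATA1 cross-linking at both edges of its
motif.

A `exoorg` console script exposes the same chain from the shell
(`exoorg simulate`, `callpairs`, `consolidate`, `organize`, `compare`,
`kinetics`, `validate`); run `exoorg --help` for options.

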