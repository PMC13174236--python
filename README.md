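# hicrearr

Interpretation of genomic rearrangements from Hi-C contact maps — the
analysis chain used to find and interpret oncogene-activating structural
variants (SVs) in tumor biopsies, including formalin-fixed paraffin-embedded
(FFPE) material where long-read and optical genome mapping (OGM) assays are
not feasible.

A rearrangement junction appears in a binned Hi-C matrix as a right-angled
"corner" of elevated inter-locus contact counts that decays with distance
from the junction along the direction encoded by the breakend strands (side
`+`: the derivative allele retains coordinates ≤ the breakpoint, `-`:
retains ≥). `hicrearr` implements:

- **Contact matrices** (`hicrearr.matrix`): sparse binned matrices from
  pairs, square-root vanilla-coverage balancing
  (w<sub>i</sub> = 1/√(Σ<sub>j</sub> c<sub>ij</sub>), balanced value
  w<sub>i</sub> c<sub>ij</sub> w<sub>j</sub>), expected contact vs distance,
  triplet-text and pairs-text I/O.
- **Breakpoint harmonization** (`hicrearr.breakpoints`): union-merge of two
  SV caller outputs (duplicates within 1 Mb on both anchors collapse to the
  preferred caller), automatic exclusion of intra-chromosomal `+/-` calls
  within 5 Mb of the diagonal (TAD-indistinguishable, unless coverage
  indicates amplification), and an automated accept/adjust/reject review
  that scores each call's corner contrast, distance decay (Spearman of
  signal vs derivative distance), anchor placement (snapped to the signal
  step) and strand/quadrant consistency against a reference panel.
- **Topology** (`hicrearr.topology`): A/B compartment scores (leading
  eigenvector of the Pearson correlation of the observed/expected matrix at
  100 kb, per chromosome, sign-flipped so positive correlates with an
  active-chromatin H3K27ac track), insulation scores (10 kb bins, 100 kb
  sliding diamond, log2 of the chromosome mean) with gradients, TAD
  boundaries as prominent insulation minima, and a donut-filter loop caller
  with Poisson tests and Benjamini-Hochberg control (max loop distance 5 Mb).
- **Rearrangement interpretation** (`hicrearr.rearrange`): Hi-C coverage
  copy-number segmentation (25 kb / 500 kb), reconstruction of derivative
  assemblies by chaining reviewed junctions into oriented segments with
  exact coordinate maps, contact matrices over assembly coordinates,
  virtual 4C (fixed viewpoint ± 1 bin, observed values normalized by unique
  valid pairs), and neo-loop detection (loops whose anchors map to
  different assembly segments, i.e. exist only on the derivative allele).
- **Enrichment** (`hicrearr.enrichment`): CTCF motif enrichment at
  boundaries/anchors and convergence at loop anchors, aggregate peak
  analysis (APA), H3K27ac signal at anchors, and A/A compartment-pair
  enrichment of neo-loop anchors — each against chromosome-matched random
  loci with empirical p = (1 + #{replicates ≥ observed}) / (1 + R).
- **Differential topology** (`hicrearr.differential`): cross-sample track
  correlation, 50 kb binned Jaccard similarity of boundary/loop sets,
  differential compartments (median A/B assignment per group, Mann-Whitney
  U on label-discordant bins, Benjamini-Hochberg), per-locus differential
  insulation, Fisher's exact test on boundary/loop-anchor presence, and
  compartment PCA. Samples enter group tests only above 10 M unique valid
  pairs.
- **OGM concordance and locus analysis** (`hicrearr.concordance`):
  comparability filter (inter-chromosomal, or intra > 5 Mb), unique
  OGM↔Hi-C event matching within 1 Mb per anchor (strand-concordant
  candidates preferred, then minimal distance sum), breakend orientation
  filters for cis juxtaposition to an intact locus, per-patient
  deduplication, and 50 kb / 10 kb sliding-window breakpoint density.
- **Synthetic data** (`hicrearr.simulate`): a generator with planted,
  exactly-known truth — power-law contact decay, plaid compartments, TAD
  blocks, focal loops, SV corner wedges decaying with derivative distance,
  CNV, Poisson/negative-binomial noise — plus emulated caller and OGM call
  sets with jitter, misses and false positives. Every downstream stage is
  testable without external data.

## Worked example

Simulate a tumor-like sample with five planted translocations, emulate two
noisy SV callers, merge and review:

```python
from hicrearr import toy_layout
from hicrearr.simulate import default_config, random_svs, simulate_hic, emulate_caller_calls
from hicrearr.matrix import balance_sqrt_vc
from hicrearr.breakpoints import merge_calls, exclude_near_diagonal, review_and_adjust

layout = toy_layout()                      # 4 chromosomes x 10 Mb
svs = random_svs(layout, 5, seed=8)
mats, truth = simulate_hic(default_config(seed=8, svs=svs), resolutions=(100_000,))
matrix = balance_sqrt_vc(mats[100_000])
c1 = emulate_caller_calls(truth, "breakfinder-like", jitter_sd=100_000,
                          miss_rate=0.1, n_false_positives=3, seed=1)
c2 = emulate_caller_calls(truth, "eaglec-like", jitter_sd=100_000,
                          miss_rate=0.1, n_false_positives=3, seed=2)
merged = exclude_near_diagonal(merge_calls(c1.calls, c2.calls, layout), matrix)
for c in review_and_adjust(matrix, merged):
    m = c.metrics
    print(f"{c.chrom_a}:{c.pos_a:,}({c.side_a}) <-> {c.chrom_b}:{c.pos_b:,}({c.side_b})"
          f"  {c.status} contrast={m.contrast:.1f} decay={m.decay_fit:+.2f}")
```

Output:

```
chr1:4,000,000(+) <-> chr2:4,500,000(+)  adjusted contrast=26.9 decay=-0.56
chr1:4,326,307(+) <-> chr2:7,491,787(-)  rejected contrast=1.6 decay=-0.09
chr1:7,491,028(-) <-> chr4:9,616,571(-)  rejected contrast=1.4 decay=-0.18
chr1:8,300,000(-) <-> chr3:4,500,000(-)  adjusted contrast=11.2 decay=-0.80
chr1:9,349,510(-) <-> chr3:9,674,359(+)  rejected contrast=1.1 decay=-0.16
chr1:9,769,059(+) <-> chr2:1,340,416(+)  rejected contrast=1.1 decay=-0.36
chr2:1,100,000(+) <-> chr4:3,000,000(+)  adjusted contrast=35.0 decay=-0.44
chr2:7,503,646(+) <-> chr3:198,225(+)  rejected contrast=1.4 decay=+0.01
chr3:6,000,000(-) <-> chr4:2,000,000(-)  adjusted contrast=50.2 decay=-0.85
chr3:6,924,593(-) <-> chr3:8,912,094(+)  rejected contrast=1.4 decay=-0.07
```

Four of the five planted junctions are accepted with anchors snapped to the
100 kb bin of the true breakpoint (status `adjusted`: the jittered caller
positions were moved to the signal step); every emulated false positive is
rejected by the corner-contrast and decay criteria. The fifth planted
junction was missed by both emulated callers in this draw, so it never
reaches review — the recall/precision of the whole chain is quantified in
`scripts/acceptance.py`. A `hicrearr` command-line interface wraps these
stages (`hicrearr simulate`, `callmerge`, `review`, `topology`, `cnv`,
`assemble`, `v4c`, `neoloops`, `enrich`, `concord`, `density`,
`orient-filter`, `run-sample`, `run-cohort`).

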