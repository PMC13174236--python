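"""Cross-sample similarity and group-difference statistics.

Samples enter group comparisons only when their informative depth exceeds
10 million unique valid pairs. Compartment differences are found by median
A/B assignment per group, Mann-Whitney U tests on label-discordant bins and
Benjamini-Hochberg control; insulation comparisons at targeted positions
are per-locus Mann-Whitney tests without multiplicity adjustment;
boundary/loop-anchor presence is compared with Fisher's exact test on
per-bin presence/absence contingency tables (boundaries at 100 kb bins,
loop anchors at 50 kb). Significance thresholds follow q (or p) < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, pearsonr
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .genome import BinIndex, GenomeLayout
from .tracks import BinnedTrack

__all__ = [
    "UVP_MIN",
    "Sample",
    "SampleGroup",
    "track_correlation",
    "binned_jaccard",
    "mann_whitney",
    "benjamini_hochberg",
    "differential_compartments",
    "differential_insulation",
    "differential_presence",
    "compartment_pca",
]

log = logging.getLogger(__name__)

#: inclusion threshold on unique valid pairs (strictly greater-than)
UVP_MIN = 10_000_000


@dataclass
class Sample:
    sample_id: str
    compartments: BinnedTrack | None = None
    insulation: BinnedTrack | None = None
    boundaries: list = field(default_factory=list)   # (chrom, pos)
    loops: list = field(default_factory=list)        # (chrom, posA, posB)
    uvp: int = 0


@dataclass
class SampleGroup:
    label: str
    members: list[Sample]

    def included(self) -> list[Sample]:
        return [m for m in self.members if m.uvp > UVP_MIN]


def track_correlation(a: BinnedTrack, b: BinnedTrack, mask=None) -> float:
    """Pearson correlation over jointly defined, unmasked bins."""
    x, y = a.values, b.values
    if mask:
        x = a.mask_intervals(mask).values
        y = b.mask_intervals(mask).values
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly defined bins")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        log.warning("track_correlation: constant input, correlation undefined")
        return np.nan
    return float(pearsonr(x[ok], y[ok]).statistic)


def _to_bin_set(features, bins: BinIndex) -> set[int]:
    out: set[int] = set()
    for f in features:
        if len(f) == 2:
            out.add(bins.bin_id(f[0], int(f[1])))
        else:  # loop: both anchors
            out.add(bins.bin_id(f[0], int(f[1])))
            out.add(bins.bin_id(f[0], int(f[2])))
    return out


def binned_jaccard(
    features_a, features_b, layout: GenomeLayout, bin_size: int = 50_000
) -> float:
    """Jaccard similarity of the bin-id sets of two feature collections.

    Empty-vs-empty is defined as 1 (identical absence of features).
    """
    bins = BinIndex(layout, bin_size)
    sa, sb = _to_bin_set(features_a, bins), _to_bin_set(features_b, bins)
    union = sa | sb
    if not union:
        log.warning("binned_jaccard: both feature sets empty; defining similarity = 1")
        return 1.0
    return len(sa & sb) / len(union)


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U p-value (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, q >= p elementwise)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def _median_scores(samples: list[Sample], n_bins: int) -> np.ndarray:
    mat = np.vstack([s.compartments.values for s in samples])
    with np.errstate(invalid="ignore"):
        return np.nanmedian(mat, axis=0)


def differential_compartments(
    group_a: SampleGroup,
    group_b: SampleGroup,
    candidate_bins=None,
    alpha: float = 0.05,
    min_members: int = 3,
) -> pd.DataFrame:
    """Bins whose median A/B assignment differs between groups, tested by
    Mann-Whitney on per-sample scores with BH correction.

    ``candidate_bins`` restricts testing (e.g. promoter-bearing unmasked
    bins); default is every bin with defined scores in both groups.
    """
    a = group_a.included()
    b = group_b.included()
    if len(a) < min_members or len(b) < min_members:
        raise ValueError(
            f"each group needs >= {min_members} included members "
            f"(got {len(a)} and {len(b)})"
        )
    bins = a[0].compartments.bins
    med_a = _median_scores(a, bins.n_bins)
    med_b = _median_scores(b, bins.n_bins)
    if candidate_bins is None:
        candidate_bins = np.flatnonzero(np.isfinite(med_a) & np.isfinite(med_b))
    rows = []
    for bin_id in candidate_bins:
        ma, mb = med_a[bin_id], med_b[bin_id]
        if not (np.isfinite(ma) and np.isfinite(mb)):
            continue
        lab_a = "A" if ma > 0 else "B"
        lab_b = "A" if mb > 0 else "B"
        if lab_a == lab_b:
            continue
        xs = np.array([s.compartments.values[bin_id] for s in a])
        ys = np.array([s.compartments.values[bin_id] for s in b])
        xs, ys = xs[np.isfinite(xs)], ys[np.isfinite(ys)]
        if len(xs) == 0 or len(ys) == 0:
            continue
        chrom, start, end = bins.bin_interval(int(bin_id))
        rows.append(
            {
                "bin": int(bin_id), "chrom": chrom, "start": start, "end": end,
                "medianA": ma, "medianB": mb, "labelA": lab_a, "labelB": lab_b,
                "p": mann_whitney(xs, ys),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["bin", "chrom", "start", "end", "medianA", "medianB",
                 "labelA", "labelB", "p"],
    )
    if len(df):
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def differential_insulation(
    group_a: SampleGroup,
    group_b: SampleGroup,
    positions,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position two-sided Mann-Whitney on per-sample insulation scores.

    Targeted positions (e.g. CTCF motif bins) are tested without multiplicity
    adjustment; a position is skipped when scores are missing in more than
    half of either group.
    """
    a = group_a.included()
    b = group_b.included()
    rows = []
    for chrom, pos in positions:
        xs = np.array(
            [s.insulation.values[s.insulation.bins.bin_id(chrom, pos)] for s in a]
        )
        ys = np.array(
            [s.insulation.values[s.insulation.bins.bin_id(chrom, pos)] for s in b]
        )
        if np.isnan(xs).mean() > 0.5 or np.isnan(ys).mean() > 0.5:
            log.info("differential_insulation: skipping %s:%d (missing scores)", chrom, pos)
            continue
        xs, ys = xs[np.isfinite(xs)], ys[np.isfinite(ys)]
        p = mann_whitney(xs, ys)
        rows.append(
            {
                "chrom": chrom, "pos": pos,
                "medianA": float(np.median(xs)), "medianB": float(np.median(ys)),
                "p": p, "significant": p < alpha,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "medianA", "medianB", "p", "significant"]
    )


def differential_presence(
    group_a: SampleGroup,
    group_b: SampleGroup,
    feature: str = "boundary",
    alpha: float = 0.05,
    bin_size: int | None = None,
) -> pd.DataFrame:
    """Fisher's exact test on per-bin feature presence between groups.

    Presence = the sample has >= 1 boundary (100 kb bins) or loop anchor
    (50 kb bins) in the bin; only bins present in at least one included
    sample are reported.
    """
    if feature not in ("boundary", "loop-anchor"):
        raise ValueError("feature must be 'boundary' or 'loop-anchor'")
    bin_size = bin_size or (100_000 if feature == "boundary" else 50_000)
    a = group_a.included()
    b = group_b.included()
    if not a or not b:
        return pd.DataFrame(
            columns=["bin", "chrom", "start", "end", "presentA", "presentB",
                     "nA", "nB", "p", "significant"]
        )
    layout = (a[0].compartments or a[0].insulation).bins.layout if (
        a[0].compartments or a[0].insulation
    ) else None
    if layout is None:
        raise ValueError("samples carry no track to infer the genome layout from")
    bins = BinIndex(layout, bin_size)

    def sample_bins(s: Sample) -> set[int]:
        feats = s.boundaries if feature == "boundary" else s.loops
        return _to_bin_set(feats, bins)

    sets_a = [sample_bins(s) for s in a]
    sets_b = [sample_bins(s) for s in b]
    all_bins = sorted(set().union(*sets_a, *sets_b))
    rows = []
    for bin_id in all_bins:
        ka = sum(bin_id in s for s in sets_a)
        kb = sum(bin_id in s for s in sets_b)
        table = [[ka, len(a) - ka], [kb, len(b) - kb]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        chrom, start, end = bins.bin_interval(bin_id)
        rows.append(
            {
                "bin": bin_id, "chrom": chrom, "start": start, "end": end,
                "presentA": ka, "presentB": kb, "nA": len(a), "nB": len(b),
                "p": p, "significant": p < alpha,
            }
        )
    return pd.DataFrame(
        rows, columns=["bin", "chrom", "start", "end", "presentA", "presentB",
                       "nA", "nB", "p", "significant"]
    )


def compartment_pca(
    profiles: list[BinnedTrack],
    mask=None,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of per-sample compartment scores over shared unmasked bins.

    Returns (sample coordinates, explained variance ratios).
    """
    if len(profiles) < 3:
        raise ValueError("PCA needs at least 3 samples")
    vals = [
        (p.mask_intervals(mask).values if mask else p.values) for p in profiles
    ]
    mat = np.vstack(vals)
    ok = np.all(np.isfinite(mat), axis=0)
    mat = mat[:, ok]
    k = min(n_components, len(profiles) - 1, mat.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(mat)
    return coords, pca.explained_variance_ratio_
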