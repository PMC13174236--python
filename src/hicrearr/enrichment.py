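"""Feature-enrichment statistics against chromosome-matched random controls.

Every permutation result carries its replicate distribution and an empirical
p-value with the +1/+1 finite-sample correction:
p = (1 + #{replicates >= observed}) / (1 + R). Random loci are drawn
uniformly per chromosome (matched to the chromosomes of the observed
features), excluding masked intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout
from .matrix import ContactMatrix
from .topology import CompartmentProfile
from .tracks import BinnedTrack

__all__ = [
    "EnrichmentResult",
    "motif_enrichment",
    "loop_convergence",
    "apa",
    "anchor_track_signal",
    "compartment_pair_enrichment",
]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    observed: float
    replicates: np.ndarray
    p: float
    n_features: int
    n_random: int
    seed: int

    @property
    def ratio(self) -> float:
        m = float(np.mean(self.replicates)) if len(self.replicates) else np.nan
        return self.observed / m if m else np.inf


def _upper_p(observed: float, reps: np.ndarray) -> float:
    return float((1 + np.sum(reps >= observed)) / (1 + len(reps)))


def _allowed_intervals(layout: GenomeLayout, chrom: str, mask) -> list[tuple[int, int]]:
    length = layout.length_of(chrom)
    blocked = sorted(
        (max(0, s), min(length, e)) for c, s, e in (mask or []) if c == chrom
    )
    out = []
    cur = 0
    for s, e in blocked:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out or [(0, length)]


def _draw_positions(rng, layout, chrom: str, size: int, mask) -> np.ndarray:
    ivs = _allowed_intervals(layout, chrom, mask)
    lens = np.array([e - s for s, e in ivs], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    u = rng.uniform(0, cum[-1], size)
    k = np.searchsorted(cum, u, side="right") - 1
    return (np.array([ivs[i][0] for i in k]) + (u - cum[k])).astype(np.int64)


def motif_enrichment(
    features,
    motifs,
    layout: GenomeLayout,
    window: int = 25_000,
    replicates: int = 1_000,
    mask=None,
    seed: int = 0,
) -> EnrichmentResult:
    """Fraction of features with >= 1 motif within ``window`` bp, versus
    chromosome-matched uniform random positions.

    ``features`` are (chrom, pos) or (chrom, start, end); ``motifs`` are BED6
    rows (midpoints used).
    """
    feats = [(f[0], int(f[1]), int(f[1]) + 1) if len(f) == 2 else (f[0], int(f[1]), int(f[2]))
             for f in features]
    if not feats:
        log.warning("motif_enrichment: no features; result undefined")
        return EnrichmentResult(np.nan, np.array([]), np.nan, 0, 0, seed)
    mids: dict[str, np.ndarray] = {}
    for m in motifs:
        mids.setdefault(m[0], []).append((int(m[1]) + int(m[2])) // 2)
    mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}

    def hits(chrom_arr, start_arr, end_arr) -> np.ndarray:
        out = np.zeros(len(chrom_arr), dtype=bool)
        for c in set(chrom_arr):
            m = mids.get(c)
            if m is None or not len(m):
                continue
            sel = np.asarray([x == c for x in chrom_arr])
            lo = np.searchsorted(m, np.asarray(start_arr)[sel] - window, side="left")
            hi = np.searchsorted(m, np.asarray(end_arr)[sel] + window, side="right")
            out[sel] = hi > lo
        return out

    chroms = [f[0] for f in feats]
    starts = [f[1] for f in feats]
    ends = [f[2] for f in feats]
    widths = np.asarray(ends) - np.asarray(starts)
    observed = float(np.mean(hits(chroms, starts, ends)))
    rng = np.random.default_rng(seed)
    reps = np.empty(replicates)
    by_chrom: dict[str, np.ndarray] = {}
    for c in set(chroms):
        sel = np.flatnonzero(np.asarray([x == c for x in chroms]))
        by_chrom[c] = sel
    for r in range(replicates):
        rs = np.empty(len(feats), dtype=np.int64)
        for c, sel in by_chrom.items():
            rs[sel] = _draw_positions(rng, layout, c, len(sel), mask)
        reps[r] = float(np.mean(hits(chroms, rs, rs + widths)))
    return EnrichmentResult(observed, reps, _upper_p(observed, reps), len(feats), len(feats), seed)


def loop_convergence(loops, motifs, anchor_width: int = 10_000) -> dict:
    """CTCF orientation bookkeeping at loop anchors.

    Returns fractions of loops with any motif in either anchor, with a motif
    in each anchor, and - among the latter - with a convergent orientation
    ("+" motif at the left anchor and "-" at the right, by coordinate).
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for m in motifs:
        by_chrom.setdefault(m[0], []).append(((int(m[1]) + int(m[2])) // 2, m[5]))

    def strands_at(chrom: str, pos: int) -> set[str]:
        return {
            s for p, s in by_chrom.get(chrom, [])
            if pos <= p < pos + anchor_width
        }

    n = n_any = n_each = n_conv = 0
    for lp in loops:
        chrom, pa, pb = (lp.chrom, lp.pos_a, lp.pos_b) if hasattr(lp, "chrom") else lp[:3]
        if pa > pb:
            pa, pb = pb, pa
        sa, sb = strands_at(chrom, pa), strands_at(chrom, pb)
        n += 1
        if sa or sb:
            n_any += 1
        if sa and sb:
            n_each += 1
            if "+" in sa and "-" in sb:
                n_conv += 1
    return {
        "n_loops": n,
        "any_anchor": n_any / n if n else np.nan,
        "each_anchor": n_each / n if n else np.nan,
        "convergent_of_each": n_conv / n_each if n_each else np.nan,
    }


def apa(
    matrix: ContactMatrix,
    anchor_pairs,
    flank: int = 100_000,
    min_distance: int = 300_000,
    corner: int = 5,
    oe: bool = True,
) -> tuple[np.ndarray, float]:
    """Aggregate peak analysis: element-wise mean of balanced/uvp windows
    centered on qualifying anchor pairs.

    Pairs closer than ``min_distance`` are excluded (all pairs excluded is an
    error). The center score is the central pixel over the mean of the
    lower-left corner block (``corner`` x ``corner``). With ``oe`` (default),
    each window pixel is divided by the distance-decay expectation before
    aggregation, so the score is ~1 for anchor pairs with no punctate
    enrichment; ``oe=False`` aggregates plain balanced/uvp values.
    """
    from .matrix import expected_by_distance

    bins = matrix.bins
    res = bins.resolution
    f = flank // res
    size = 2 * f + 1
    w = matrix.require_weights()
    sym = matrix.symmetric()
    uvp = max(matrix.uvp, 1)
    exp_cache: dict[str, np.ndarray] = {}
    stack = []
    for chrom, pa, pb in anchor_pairs:
        if pa > pb:
            pa, pb = pb, pa
        if pb - pa < min_distance:
            continue
        lo, hi = bins.chrom_span(chrom)
        ba = lo + int(pa) // res
        bb = lo + int(pb) // res
        if ba - f < lo or bb + f >= hi:
            continue
        rows = np.arange(ba - f, ba + f + 1)
        cols = np.arange(bb - f, bb + f + 1)
        win = np.asarray(sym[rows][:, cols].todense(), dtype=float)
        win = win * w[rows, None] * w[None, cols] / uvp
        if oe:
            if chrom not in exp_cache:
                exp_cache[chrom] = expected_by_distance(matrix, chrom) / uvp
            exp = exp_cache[chrom]
            d = np.abs(cols[None, :] - rows[:, None])
            with np.errstate(invalid="ignore", divide="ignore"):
                win = win / exp[np.minimum(d, len(exp) - 1)]
        stack.append(win)
    if not stack:
        raise ValueError("no qualifying anchor pairs for APA")
    with np.errstate(invalid="ignore"):
        agg = np.nanmean(np.stack(stack), axis=0)
        # center = mean of the central 3x3 block: loops are focal but not
        # single-pixel at finite resolution, and the block mean is far less
        # noisy than one sparse pixel
        center = np.nanmean(agg[f - 1:f + 2, f - 1:f + 2])
        bg = np.nanmean(agg[size - corner:, :corner])
    score = float(center / bg) if bg and np.isfinite(bg) else np.inf
    return agg, score


def anchor_track_signal(
    anchors,
    track: BinnedTrack,
    flank: int = 100_000,
    end_margin: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Mean track signal within ``flank`` of each anchor, excluding anchors
    within ``end_margin`` of chromosome ends; returns per-anchor means and
    the cohort mean."""
    bins = track.bins
    res = bins.resolution
    out = []
    for chrom, pos in anchors:
        length = bins.layout.length_of(chrom)
        if pos < end_margin or pos > length - end_margin:
            continue
        lo, hi = bins.chrom_span(chrom)
        b0 = max(lo, lo + (int(pos) - flank) // res)
        b1 = min(hi, lo + (int(pos) + flank) // res + 1)
        with np.errstate(invalid="ignore"):
            out.append(float(np.nanmean(track.values[b0:b1])))
    if not out:
        log.warning("anchor_track_signal: all anchors excluded")
        return np.array([]), np.nan
    arr = np.asarray(out)
    return arr, float(np.nanmean(arr))


def compartment_pair_enrichment(
    anchor_pairs,
    profile: CompartmentProfile,
    replicates: int = 1_000,
    seed: int = 0,
) -> tuple[EnrichmentResult, dict]:
    """Fraction of anchor pairs with both anchors in the active (A) compartment,
    versus chromosome-matched random anchor pairs.

    Anchors are labeled A when the compartment score is > 0, B otherwise;
    pairs with an anchor in a masked/undefined bin are dropped (counted in
    the state table under ``dropped``).
    """
    bins = profile.track.bins
    scores = profile.track.values

    def label(chrom: str, pos: int):
        v = scores[bins.bin_id(chrom, int(pos))]
        if np.isnan(v):
            return None
        return "A" if v > 0 else "B"

    states = {"AA": 0, "AB": 0, "BB": 0, "dropped": 0}
    kept_pairs = []
    for ca, pa, cb, pb in anchor_pairs:
        la, lb = label(ca, pa), label(cb, pb)
        if la is None or lb is None:
            states["dropped"] += 1
            continue
        states["".join(sorted(la + lb))] += 1
        kept_pairs.append((ca, cb))
    n = len(kept_pairs)
    if n == 0:
        return EnrichmentResult(np.nan, np.array([]), np.nan, 0, 0, seed), states
    observed = states["AA"] / n
    # per-chromosome pools of defined bin labels
    pool: dict[str, np.ndarray] = {}
    for chrom in bins.layout.names:
        lo, hi = bins.chrom_span(chrom)
        v = scores[lo:hi]
        pool[chrom] = (v[np.isfinite(v)] > 0)
    rng = np.random.default_rng(seed)
    reps = np.empty(replicates)
    ca_list = [p[0] for p in kept_pairs]
    cb_list = [p[1] for p in kept_pairs]
    for r in range(replicates):
        la = np.array([pool[c][rng.integers(len(pool[c]))] for c in ca_list])
        lb = np.array([pool[c][rng.integers(len(pool[c]))] for c in cb_list])
        reps[r] = float(np.mean(la & lb))
    result = EnrichmentResult(observed, reps, _upper_p(observed, reps), n, n, seed)
    return result, states
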