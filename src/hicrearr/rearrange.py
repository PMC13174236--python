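"""Rearrangement interpretation: Hi-C copy number, derivative assemblies,
assembled matrices, virtual 4C, and cross-junction (neo-)loop detection.

A derivative (rearranged) chromosome is modeled as an ordered chain of
oriented reference segments joined at reviewed breakpoint junctions. The
contact matrix over assembly coordinates is the reference matrix re-indexed
through the segment coordinate maps; loops whose anchors fall in different
segments of the assembly are neo-loops - contacts that exist only on the
derivative allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .breakpoints import BreakpointCall
from .genome import BinIndex, GenomeLayout
from .matrix import ContactMatrix, balance_sqrt_vc
from .topology import LoopCall, detect_loops
from .tracks import BinnedTrack

__all__ = [
    "CNVSegment",
    "Segment",
    "Assembly",
    "AssembledMatrix",
    "NeoLoop",
    "coverage_cnv",
    "reconstruct_assembly",
    "assembled_matrix",
    "virtual_4c",
    "detect_neoloops",
]

log = logging.getLogger(__name__)


# ------------------------------------------------------------------ CNV

@dataclass(frozen=True)
class CNVSegment:
    chrom: str
    start: int
    end: int
    ratio: float    # coverage relative to genome median


def _binary_segmentation(x: np.ndarray, min_seg: int, penalty: float) -> list[int]:
    """Changepoints of a least-squares binary segmentation (recursive)."""
    cps: list[int] = []

    def sse(c1, c2, cn1, cn2):
        n = cn2 - cn1
        s = c2 - c1
        return 0.0 if n == 0 else -(s * s) / n

    csum = np.concatenate([[0.0], np.cumsum(x)])

    def rec(a: int, b: int) -> None:
        n = b - a
        if n < 2 * min_seg:
            return
        total = sse(csum[a], csum[b], a, b)
        ts = np.arange(a + min_seg, b - min_seg + 1)
        left = -((csum[ts] - csum[a]) ** 2) / (ts - a)
        right = -((csum[b] - csum[ts]) ** 2) / (b - ts)
        k = int(np.argmin(left + right))
        gain = total - (left[k] + right[k])
        if gain > penalty:
            t = int(ts[k])
            cps.append(t)
            rec(a, t)
            rec(t, b)

    rec(0, len(x))
    return sorted(cps)


def coverage_cnv(
    matrix: ContactMatrix,
    min_seg: int = 5,
    sensitivity: float = 10.0,
) -> list[CNVSegment]:
    """Copy-ratio segments from median-normalized per-bin Hi-C coverage.

    Per-chromosome binary segmentation minimizing within-segment squared
    error; a split is accepted when its SSE gain exceeds
    ``sensitivity * sigma^2 * log(n)`` with sigma estimated from successive
    differences. Ratios are relative to the genome-median bin coverage, so
    they are invariant to global depth.
    """
    marg = matrix.marginals().astype(float)
    positive = marg[marg > 0]
    med = np.median(positive) if positive.size else 0.0
    segments: list[CNVSegment] = []
    bins = matrix.bins
    for chrom in bins.layout.names:
        lo, hi = bins.chrom_span(chrom)
        x = marg[lo:hi]
        length = bins.layout.length_of(chrom)
        if med <= 0 or not (x > 0).any():
            segments.append(CNVSegment(chrom, 0, length, 0.0))
            continue
        r = x / med
        diffs = np.diff(r)
        sigma = np.median(np.abs(diffs)) / 0.6745 / np.sqrt(2) if diffs.size else 0.0
        penalty = sensitivity * max(sigma, 1e-9) ** 2 * np.log(max(len(r), 2))
        cps = _binary_segmentation(r, min_seg, penalty)
        edges = [0] + cps + [len(r)]
        for a, b in zip(edges, edges[1:]):
            start = a * bins.resolution
            end = min(b * bins.resolution, length)
            segments.append(CNVSegment(chrom, start, end, float(np.mean(r[a:b]))))
    return segments


# ------------------------------------------------------------- assemblies

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int      # half-open reference interval
    end: int
    orientation: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Assembly:
    segments: list[Segment]
    junctions: list[BreakpointCall]

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def _offsets(self) -> list[int]:
        off = [0]
        for s in self.segments:
            off.append(off[-1] + s.length)
        return off

    def to_reference(self, asm_pos: int) -> tuple[str, int]:
        """Map an assembly bp position to (chrom, reference bp)."""
        off = self._offsets()
        if not 0 <= asm_pos < off[-1]:
            raise ValueError(f"assembly position {asm_pos} out of range")
        k = int(np.searchsorted(off, asm_pos, side="right") - 1)
        seg = self.segments[k]
        local = asm_pos - off[k]
        if seg.orientation == FORWARD:
            return seg.chrom, seg.start + local
        return seg.chrom, seg.end - 1 - local

    def from_reference(self, chrom: str, pos: int) -> int:
        """Map (chrom, reference bp) to the assembly position (first segment hit)."""
        off = self._offsets()
        for k, seg in enumerate(self.segments):
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                local = (
                    pos - seg.start if seg.orientation == FORWARD else seg.end - 1 - pos
                )
                return off[k] + local
        raise ValueError(f"{chrom}:{pos} not covered by the assembly")

    def segment_of(self, asm_pos: int) -> int:
        off = self._offsets()
        return int(np.searchsorted(off, asm_pos, side="right") - 1)


def _cnv_bound(cnv, chrom: str, pos: int, direction: int) -> int | None:
    """Nearest CNV changepoint strictly beyond ``pos`` in ``direction``."""
    edges = sorted(
        {s.start for s in cnv if s.chrom == chrom}
        | {s.end for s in cnv if s.chrom == chrom}
    )
    if direction > 0:
        nxt = [e for e in edges if e > pos]
        return nxt[0] if nxt else None
    prv = [e for e in edges if e < pos]
    return prv[-1] if prv else None


def reconstruct_assembly(
    calls: list[BreakpointCall],
    layout: GenomeLayout,
    cnv: list[CNVSegment] | None = None,
    flank: int = 4_000_000,
    region: tuple[str, int, int] | None = None,
) -> Assembly:
    """Chain reviewed junctions into an oriented derivative assembly.

    Terminal segment extent is bounded by the chromosome end, the nearest
    CNV changepoint, or the flank cap, whichever comes first; middle
    segments run between consecutive junctions, whose sides must agree on
    the retained direction (conflicts raise with the offending junction).
    With no calls, the assembly is the queried reference window.
    """
    if not calls:
        if region is None:
            raise ValueError("region required when no breakpoints are given")
        chrom, start, end = region
        return Assembly([Segment(chrom, start, end, FORWARD)], [])
    ends_seen: set = set()
    for c in calls:
        for key in ((c.chrom_a, c.pos_a, c.side_a), (c.chrom_b, c.pos_b, c.side_b)):
            if key in ends_seen:
                raise ValueError(f"conflicting junction reuse at {key}")
            ends_seen.add(key)
    cnv = cnv or []

    def bound(chrom: str, pos: int, direction: int) -> int:
        cap = pos + direction * flank
        cp = _cnv_bound(cnv, chrom, pos, direction)
        if direction > 0:
            limit = min(layout.length_of(chrom), cap)
            if cp is not None:
                limit = min(limit, cp)
            return max(limit, pos + 1)
        limit = max(0, cap)
        if cp is not None:
            limit = max(limit, cp)
        return min(limit, pos - 1)

    segments: list[Segment] = []
    first = calls[0]
    if first.side_a == "+":
        segments.append(Segment(first.chrom_a, bound(first.chrom_a, first.pos_a, -1),
                                first.pos_a, FORWARD))
    else:
        segments.append(Segment(first.chrom_a, first.pos_a,
                                bound(first.chrom_a, first.pos_a, +1), REVERSE))
    for k, call in enumerate(calls):
        cB, pB, sB = call.chrom_b, call.pos_b, call.side_b
        if k + 1 < len(calls):
            nxt = calls[k + 1]
            cA, pA, sA = nxt.chrom_a, nxt.pos_a, nxt.side_a
            if cA != cB:
                raise ValueError(
                    f"junctions {k} and {k + 1} do not share a chromosome "
                    f"({cB} vs {cA})"
                )
            if sB == "-" and sA == "+" and pA > pB:
                segments.append(Segment(cB, pB, pA, FORWARD))
            elif sB == "+" and sA == "-" and pA < pB:
                segments.append(Segment(cB, pA, pB, REVERSE))
            else:
                raise ValueError(
                    f"conflicting junction chain between calls {k} and {k + 1}: "
                    f"sides ({sB},{sA}) positions ({pB},{pA})"
                )
        else:
            if sB == "-":
                segments.append(Segment(cB, pB, bound(cB, pB, +1), FORWARD))
            else:
                segments.append(Segment(cB, bound(cB, pB, -1), pB, REVERSE))
    return Assembly(segments, list(calls))


@dataclass
class AssembledMatrix:
    matrix: ContactMatrix           # over assembly coordinates
    assembly: Assembly
    bin_map: np.ndarray             # assembly bin -> reference global bin id
    segment_of_bin: np.ndarray
    source_bins: BinIndex


def assembled_matrix(
    matrix: ContactMatrix,
    assembly: Assembly,
    cnv: list[CNVSegment] | None = None,
) -> AssembledMatrix:
    """Re-index a reference contact matrix into assembly coordinates.

    Segment bounds are snapped outward to the bin grid; balancing is
    recomputed on the assembled matrix. With ``cnv``, values are divided by
    the copy-ratio product of the two bins.
    """
    bins = matrix.bins
    res = bins.resolution
    bin_map: list[int] = []
    seg_of: list[int] = []
    for k, seg in enumerate(assembly.segments):
        lo, _ = bins.chrom_span(seg.chrom)
        b0 = seg.start // res
        b1 = -(-seg.end // res)
        ids = np.arange(lo + b0, lo + b1)
        if seg.orientation == REVERSE:
            ids = ids[::-1]
        bin_map.extend(int(i) for i in ids)
        seg_of.extend([k] * len(ids))
    bin_map_arr = np.asarray(bin_map, dtype=np.int64)
    if bin_map_arr.size and (bin_map_arr.max() >= bins.n_bins or bin_map_arr.min() < 0):
        raise ValueError("assembly maps outside the matrix")
    sym = matrix.symmetric()
    sub = np.asarray(sym[bin_map_arr][:, bin_map_arr].todense(), dtype=float)
    if cnv:
        ratio = np.ones(len(bin_map_arr))
        for k, gb in enumerate(bin_map_arr):
            chrom, start, _ = bins.bin_interval(int(gb))
            for s in cnv:
                if s.chrom == chrom and s.start <= start < s.end and s.ratio > 0:
                    ratio[k] = s.ratio
                    break
        sub = sub / (ratio[:, None] * ratio[None, :])
    n = len(bin_map_arr)
    layout = GenomeLayout(("assembly",), (max(n, 1) * res,))
    abins = BinIndex(layout, res)
    counts = sp.csr_matrix(np.triu(sub))
    out = ContactMatrix(abins, counts, uvp=matrix.uvp)
    out = balance_sqrt_vc(out)
    return AssembledMatrix(out, assembly, bin_map_arr, np.asarray(seg_of), bins)


# ------------------------------------------------------------- virtual 4C

def virtual_4c(
    matrix: ContactMatrix,
    viewpoint,
    window: int = 0,
    balanced: bool = True,
    scale: float = 1.0,
) -> BinnedTrack:
    """Fixed-viewpoint interaction profile, depth-normalized across samples.

    ``viewpoint`` is (chrom, pos), (chrom, start, end) or a global bin id;
    ``window`` widens the viewpoint by that many bins on each side and the
    profile is the mean over viewpoint rows. Raw (observed) values are
    divided by the sample's uvp (times ``scale``); balanced sqrt-VC values
    are already depth-invariant and are returned as-is. In both modes,
    jointly scaling counts and uvp leaves the track unchanged.
    """
    bins = matrix.bins
    if isinstance(viewpoint, int):
        vbins = [viewpoint]
    elif len(viewpoint) == 2:
        vbins = [bins.bin_id(viewpoint[0], int(viewpoint[1]))]
    else:
        chrom, start, end = viewpoint
        vbins = list(
            range(bins.bin_id(chrom, int(start)), bins.bin_id(chrom, int(end) - 1) + 1)
        )
    lo = max(0, min(vbins) - window)
    hi = min(bins.n_bins, max(vbins) + window + 1)
    rows = np.arange(lo, hi)
    sym = matrix.symmetric()
    block = np.asarray(sym[rows].todense(), dtype=float)
    if balanced:
        w = matrix.require_weights()
        block = block * w[rows, None] * w[None, :]
    with np.errstate(invalid="ignore"):
        prof = np.nanmean(block, axis=0) if len(rows) > 1 else block[0]
    if balanced:
        norm = 1.0
    elif matrix.uvp <= 0:
        log.warning("virtual_4c: uvp is 0; returning unnormalized profile")
        norm = 1.0
    else:
        norm = matrix.uvp
    values = prof * scale / norm
    if np.all(np.isnan(values)):
        log.warning("virtual_4c: viewpoint has no coverage; all-missing track")
    return BinnedTrack(bins, values, label="virtual_4c")


# -------------------------------------------------------------- neo-loops

@dataclass(frozen=True)
class NeoLoop:
    asm_pos_a: int
    asm_pos_b: int
    ref_a: tuple[str, int]
    ref_b: tuple[str, int]
    crosses_junction: bool
    enrichment: float
    p: float
    q: float


def detect_neoloops(
    assembled: AssembledMatrix,
    max_distance: int = 5_000_000,
    fold: float = 2.0,
    fdr: float = 0.05,
    **loop_kwargs,
) -> list[NeoLoop]:
    """Loop calling on the assembled matrix with junction-crossing annotation.

    Anchors are mapped back to reference coordinates; a call whose anchors
    fall in different assembly segments crosses a junction (a neo-loop).
    """
    res = assembled.matrix.bins.resolution
    loops = detect_loops(
        assembled.matrix, max_distance=max_distance, fold=fold, fdr=fdr, **loop_kwargs
    )
    out = []
    for lp in loops:
        ba, bb = lp.pos_a // res, lp.pos_b // res
        ga, gb = int(assembled.bin_map[ba]), int(assembled.bin_map[bb])
        ca, sa, _ = assembled.source_bins.bin_interval(ga)
        cb, sb_, _ = assembled.source_bins.bin_interval(gb)
        out.append(
            NeoLoop(
                asm_pos_a=lp.pos_a,
                asm_pos_b=lp.pos_b,
                ref_a=(ca, sa),
                ref_b=(cb, sb_),
                crosses_junction=(
                    int(assembled.segment_of_bin[ba]) != int(assembled.segment_of_bin[bb])
                ),
                enrichment=lp.enrichment,
                p=lp.p,
                q=lp.q,
            )
        )
    return out
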