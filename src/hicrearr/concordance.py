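"""OGM vs Hi-C structural-variant concordance and locus breakpoint density.

Cross-platform comparison keeps only events both technologies can see
(inter-chromosomal, or intra-chromosomal larger than 5 Mb), then matches
each OGM event to a unique Hi-C event whose anchors fall within 1 Mb on the
corresponding chromosomes, preferring strand-concordant candidates and then
the smallest summed anchor distance. The locus utilities implement
orientation-based breakpoint filtering (keeping events compatible with cis
juxtaposition to an intact gene), per-patient deduplication, and
sliding-window breakpoint density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genome import GenomeLayout

__all__ = [
    "SVEvent",
    "MatchResult",
    "canonical_event",
    "filter_comparable",
    "match_events",
    "orientation_filter",
    "dedup_per_patient",
    "sliding_density",
]

log = logging.getLogger(__name__)

COMPARABLE_MIN_SIZE = 5_000_000


@dataclass(frozen=True)
class SVEvent:
    chrom_a: str
    pos_a: int
    side_a: str
    chrom_b: str
    pos_b: int
    side_b: str
    source: str = ""
    patient_id: str | None = None

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def size(self) -> int | None:
        return abs(self.pos_b - self.pos_a) if self.is_intra else None


def canonical_event(ev: SVEvent, layout: GenomeLayout) -> SVEvent:
    ka = (layout.names.index(ev.chrom_a), ev.pos_a)
    kb = (layout.names.index(ev.chrom_b), ev.pos_b)
    if ka <= kb:
        return ev
    return replace(
        ev,
        chrom_a=ev.chrom_b, pos_a=ev.pos_b, side_a=ev.side_b,
        chrom_b=ev.chrom_a, pos_b=ev.pos_a, side_b=ev.side_a,
    )


def filter_comparable(events: list[SVEvent]) -> list[SVEvent]:
    """Keep inter-chromosomal events and intra-chromosomal events > 5 Mb."""
    return [
        e for e in events
        if not e.is_intra or e.size > COMPARABLE_MIN_SIZE
    ]


@dataclass
class MatchResult:
    matched: list[tuple[SVEvent, SVEvent, tuple[int, int], bool]]
    unmatched_first: list[SVEvent]
    unmatched_second: list[SVEvent]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def _strand_match(a: SVEvent, b: SVEvent) -> bool:
    return a.side_a == b.side_a and a.side_b == b.side_b


def match_events(
    ogm: list[SVEvent],
    hic: list[SVEvent],
    layout: GenomeLayout,
    radius: int = 1_000_000,
) -> MatchResult:
    """Unique OGM-to-Hi-C event matching within a per-anchor radius.

    A candidate pair requires both anchor distances <= ``radius`` on matching
    chromosomes (after canonical anchor ordering). Assignment is globally
    optimal and deterministic: maximal number of matched pairs, then maximal
    number of strand-concordant pairs, then minimal total anchor distance.
    """
    key = lambda e: (
        layout.names.index(e.chrom_a), e.pos_a,
        layout.names.index(e.chrom_b), e.pos_b, e.side_a, e.side_b, e.source,
    )
    o = sorted((canonical_event(e, layout) for e in ogm), key=key)
    h = sorted((canonical_event(e, layout) for e in hic), key=key)
    no, nh = len(o), len(h)
    if no == 0 or nh == 0:
        return MatchResult([], list(o), list(h))
    strand_penalty = 2.0 * radius * (min(no, nh) + 1) + 1.0
    unmatched_cost = strand_penalty + 2.0 * radius + 1.0
    forbid = (no + nh) * (unmatched_cost + strand_penalty) + 1.0
    size = no + nh
    cost = np.full((size, size), forbid)
    for i, a in enumerate(o):
        for j, b in enumerate(h):
            if a.chrom_a != b.chrom_a or a.chrom_b != b.chrom_b:
                continue
            da, db = abs(a.pos_a - b.pos_a), abs(a.pos_b - b.pos_b)
            if da <= radius and db <= radius:
                cost[i, j] = da + db + (0.0 if _strand_match(a, b) else strand_penalty)
    for i in range(no):
        cost[i, nh + i] = unmatched_cost
    for j in range(nh):
        cost[no + j, j] = unmatched_cost
        for i in range(no):
            cost[no + j, nh + i] = 0.0
    rows, cols = linear_sum_assignment(cost)
    matched = []
    used_o: set[int] = set()
    used_h: set[int] = set()
    for r, c in zip(rows, cols):
        if r < no and c < nh and cost[r, c] < forbid and cost[r, c] < unmatched_cost:
            a, b = o[r], h[c]
            matched.append(
                (a, b, (abs(a.pos_a - b.pos_a), abs(a.pos_b - b.pos_b)),
                 _strand_match(a, b))
            )
            used_o.add(r)
            used_h.add(c)
    return MatchResult(
        matched,
        [e for i, e in enumerate(o) if i not in used_o],
        [e for j, e in enumerate(h) if j not in used_h],
    )


# ------------------------------------------------------ locus-level filters

def _in_locus(chrom: str, pos: int, locus) -> bool:
    lc, ls, le = locus
    return chrom == lc and ls <= pos < le


def orientation_filter(
    events: list[SVEvent],
    locus: tuple[str, int, int],
    keep_rules: list[tuple[str, str, int]],
    partner_outside: bool = True,
) -> list[SVEvent]:
    """Keep events whose in-locus breakend satisfies any keep rule.

    A rule is (side, comparator, position) with comparator "<" or ">";
    e.g. ("-", "<", 127738251) keeps "-"-strand breakends left of the gene.
    With ``partner_outside``, the partner breakend must lie outside the
    locus (events entirely inside the locus are dropped).
    """
    def rule_ok(side: str, pos: int) -> bool:
        for r_side, cmp_, r_pos in keep_rules:
            if side == r_side and (pos < r_pos if cmp_ == "<" else pos > r_pos):
                return True
        return False

    out = []
    for e in events:
        a_in = _in_locus(e.chrom_a, e.pos_a, locus)
        b_in = _in_locus(e.chrom_b, e.pos_b, locus)
        if not (a_in or b_in):
            continue
        if partner_outside and a_in and b_in:
            continue
        candidates = []
        if a_in:
            candidates.append((e.side_a, e.pos_a))
        if b_in:
            candidates.append((e.side_b, e.pos_b))
        if any(rule_ok(side, pos) for side, pos in candidates):
            out.append(e)
    return out


def _gene_distance(e: SVEvent, gene: tuple[str, int, int]) -> tuple[int, int]:
    """(distance to gene interval, breakend position) of the closest breakend
    on the gene's chromosome; inside the interval counts as 0."""
    gc, gs, ge = gene
    best = None
    for chrom, pos in ((e.chrom_a, e.pos_a), (e.chrom_b, e.pos_b)):
        if chrom != gc:
            continue
        d = 0 if gs <= pos < ge else (gs - pos if pos < gs else pos - ge + 1)
        if best is None or (d, pos) < best:
            best = (d, pos)
    return best if best is not None else (np.iinfo(np.int64).max, 0)


def dedup_per_patient(
    events: list[SVEvent],
    gene: tuple[str, int, int],
) -> list[SVEvent]:
    """One event per patient: the one closest to the gene interval.

    Ties break deterministically by ascending breakend position; events
    without a patient id pass through ungrouped (with a warning).
    """
    by_patient: dict[str, list[SVEvent]] = {}
    out = []
    for e in events:
        if e.patient_id is None:
            log.warning("dedup_per_patient: event without patient id passes through")
            out.append(e)
        else:
            by_patient.setdefault(e.patient_id, []).append(e)
    for pid in sorted(by_patient):
        out.append(min(by_patient[pid], key=lambda e: _gene_distance(e, gene)))
    return out


def sliding_density(
    positions,
    window: int = 50_000,
    step: int = 10_000,
    extent: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Count positions in half-open sliding windows [s, s + window).

    Returns (window starts, counts). The extent defaults to the span of the
    positions; at step == window the counts partition the events.
    """
    pos = np.sort(np.asarray(list(positions), dtype=np.int64))
    if extent is None:
        if len(pos) == 0:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        extent = (int(pos[0]), int(pos[-1]) + 1)
    start, end = extent
    starts = np.arange(start, max(end - window, start) + 1, step, dtype=np.int64)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    return starts, (hi - lo).astype(np.int64)
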