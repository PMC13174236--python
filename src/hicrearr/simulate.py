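"""Synthetic Hi-C generator with planted, exactly-known truth.

The generator emulates the statistical structure of binned tumor Hi-C data:
power-law contact decay within chromosomes, a small constant inter-chromosome
background, plaid A/B compartment signal, TAD blocks, punctate loops,
rearrangement "corner" signal decaying with derivative-chromosome distance in
the direction of the breakend sides, copy-number scaling of bin coverage, and
Poisson (optionally overdispersed) counting noise. Companion generators
emulate caller output (jitter, misses, false positives), orthogonal OGM call
sets, and ChIP-like/CTCF/blacklist annotation tracks.

Counts are sampled per cell from the rate field, then expanded into a pair
stream with uniform positions inside each base-resolution bin so the same
draw can be binned at any coarser (or the base) resolution with consistent
unique-valid-pair bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .breakpoints import BreakpointCall, canonical_call
from .genome import BinIndex, GenomeLayout, toy_layout
from .matrix import ContactMatrix, pairs_to_matrix
from .tracks import BinnedTrack

__all__ = [
    "PlantedSV",
    "SimulationConfig",
    "SimTruth",
    "EmulatedCallSet",
    "default_config",
    "simulate_hic",
    "simulate_pairs",
    "plant_rearranged_pairs",
    "synth_tracks",
    "emulate_caller_calls",
    "emulate_ogm_calls",
    "random_svs",
    "synth_compartment_scores",
    "synth_insulation_scores",
]


@dataclass(frozen=True)
class PlantedSV:
    """A rearrangement junction between two stranded breakends.

    Side "+" means the derivative allele retains coordinates <= position on
    that breakend's chromosome; "-" retains coordinates >= position.
    """

    chrom_a: str
    pos_a: int
    side_a: str
    chrom_b: str
    pos_b: int
    side_b: str
    clonal_fraction: float = 1.0
    #: loops that exist only on the derivative allele: (ref posA, ref posB,
    #: fold) with anchors on the retained side of each breakend; the fold
    #: multiplies the junction-proximity signal focally
    neo_loops: tuple = ()

    def __post_init__(self) -> None:
        if self.side_a not in "+-" or self.side_b not in "+-":
            raise ValueError("sides must be '+' or '-'")
        if not 0 < self.clonal_fraction <= 1:
            raise ValueError("clonal fraction must be in (0, 1]")


@dataclass
class SimulationConfig:
    layout: GenomeLayout = field(default_factory=toy_layout)
    depth: int = 2_000_000
    decay_exponent: float = -1.0
    base_resolution: int = 10_000
    compartment_block: int = 1_000_000    # alternating A/B block size
    compartment_phase: int = 0            # 0: first block is A; 1: first is B
    plaid_strength: float = 0.3
    trans_loops: tuple = ()               # (chromA, posA, chromB, posB, fold)
    tads: tuple = ()                      # (chrom, start, end)
    tad_factor: float = 2.0
    loops: tuple = ()                     # (chrom, posA, posB, fold)
    svs: tuple = ()                       # PlantedSV
    cnvs: tuple = ()                      # (chrom, start, end, copy ratio)
    mask_intervals: tuple = ()            # blacklist (chrom, start, end)
    trans_fraction: float = 0.1           # share of background mass inter-chrom
    overdispersion: float = 0.0           # 0 = Poisson; >0 = gamma-Poisson
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.decay_exponent >= 0:
            raise ValueError("decay exponent must be negative")
        for chrom, start, end in self.tads:
            if not (chrom in self.layout and 0 <= start < end <= self.layout.length_of(chrom)):
                raise ValueError(f"TAD interval {(chrom, start, end)} outside layout")
        for chrom, a, b, fold in self.loops:
            if fold <= 1:
                raise ValueError("loop fold enrichment must be > 1")
            if not (chrom in self.layout and 0 <= a < b < self.layout.length_of(chrom)):
                raise ValueError(f"loop {(chrom, a, b)} outside layout")
        for chrom, start, end, ratio in self.cnvs:
            if ratio <= 0 or not (0 <= start < end <= self.layout.length_of(chrom)):
                raise ValueError(f"bad CNV segment {(chrom, start, end, ratio)}")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default desk-scale study conditions: 4 x 10 Mb genome, 2 M pairs.

    Chromosome 1 carries a run of seven contiguous TADs (six internal
    boundaries); chromosome 2 carries three convergent-CTCF loops at 0.3-1 Mb
    anchor distance; a 200 kb blacklist interval sits on chromosome 3.
    """
    tads = tuple(
        ("chr1", 1_000_000 + k * 600_000, 1_000_000 + (k + 1) * 600_000)
        for k in range(7)
    )
    loops = (
        ("chr2", 2_000_000, 2_500_000, 8.0),
        ("chr2", 4_000_000, 4_800_000, 8.0),
        ("chr2", 6_000_000, 6_400_000, 8.0),
    )
    cfg = SimulationConfig(
        tads=tads,
        loops=loops,
        mask_intervals=(("chr3", 5_000_000, 5_200_000),),
        seed=seed,
    )
    return replace(cfg, **overrides)


@dataclass
class SimTruth:
    """Planted ground truth, with accessors used by recovery tests."""

    config: SimulationConfig

    @property
    def layout(self) -> GenomeLayout:
        return self.config.layout

    def compartment_labels(self, resolution: int) -> BinnedTrack:
        """A-compartment indicator (1.0 = A, 0.0 = B) at ``resolution``."""
        bins = BinIndex(self.layout, resolution)
        chrom, start = bins.bin_starts()
        labels = (
            (start // self.config.compartment_block + self.config.compartment_phase)
            % 2 == 0
        ).astype(float)
        return BinnedTrack(bins, labels, label="A_label")

    @property
    def tad_internal_boundaries(self) -> list[tuple[str, int]]:
        """Positions where one planted TAD ends exactly where the next begins."""
        out = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.config.tads:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if e1 == s2:
                    out.append((chrom, e1))
        return out

    @property
    def loops(self) -> tuple:
        return self.config.loops

    @property
    def svs(self) -> tuple:
        return self.config.svs

    @property
    def cnvs(self) -> tuple:
        return self.config.cnvs

    @property
    def mask_intervals(self) -> tuple:
        return self.config.mask_intervals


# --------------------------------------------------------------- rate fields

def _cnv_factor(config: SimulationConfig, chrom: str, n: int) -> np.ndarray:
    res = config.base_resolution
    f = np.ones(n)
    for c, start, end, ratio in config.cnvs:
        if c == chrom:
            b0, b1 = start // res, -(-end // res)
            f[b0:b1] = ratio
    return f


def _labels(config: SimulationConfig, chrom: str, n: int) -> np.ndarray:
    res = config.base_resolution
    starts = np.arange(n) * res
    return (starts // config.compartment_block + config.compartment_phase) % 2 == 0


def _apply_focal(rate: np.ndarray, bi: int, bj: int, fold: float,
                 symmetric_fold: bool = False) -> None:
    """Multiply a focal 5x5 footprint (full fold at the apex, decaying by
    Chebyshev ring) into ``rate`` in place."""
    na, nb = rate.shape
    for da in range(-2, 3):
        for db in range(-2, 3):
            i, j = bi + da, bj + db
            if 0 <= i < na and 0 <= j < nb:
                w = 0.5 ** max(abs(da), abs(db))
                rate[i, j] *= 1.0 + (fold - 1.0) * w
                if symmetric_fold and 0 <= j < na and 0 <= i < nb:
                    rate[j, i] *= 1.0 + (fold - 1.0) * w


def _intra_rate(config: SimulationConfig, chrom: str) -> np.ndarray:
    """Upper-triangle background rate field for one chromosome (base bins)."""
    res = config.base_resolution
    n = -(-config.layout.length_of(chrom) // res)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    rate = (d + 1.0) ** config.decay_exponent
    lab = _labels(config, chrom, n)
    same = lab[:, None] == lab[None, :]
    rate *= np.where(same, 1.0 + config.plaid_strength, 1.0 - config.plaid_strength)
    for c, start, end in config.tads:
        if c == chrom:
            b0, b1 = start // res, -(-end // res)
            rate[b0:b1, b0:b1] *= config.tad_factor
    for c, a, b, fold in config.loops:
        if c == chrom:
            # focal enrichment with shoulders, as punctate loops present at
            # finite resolution: full fold at the apex, decaying by ring
            _apply_focal(rate, a // res, b // res, fold, symmetric_fold=True)
    cf = _cnv_factor(config, chrom, n)
    # cis contacts need both loci on the same molecule: the rate scales with
    # the smaller copy ratio of the two bins (trans contacts scale with the
    # product, see _inter_rate)
    rate *= np.minimum(cf[:, None], cf[None, :])
    return np.triu(rate)


def _inter_rate(config: SimulationConfig, chrom_a: str, chrom_b: str,
                level: float) -> np.ndarray:
    res = config.base_resolution
    na = -(-config.layout.length_of(chrom_a) // res)
    nb = -(-config.layout.length_of(chrom_b) // res)
    la, lb = _labels(config, chrom_a, na), _labels(config, chrom_b, nb)
    same = la[:, None] == lb[None, :]
    rate = level * np.where(
        same, 1.0 + config.plaid_strength, 1.0 - config.plaid_strength
    )
    rate *= _cnv_factor(config, chrom_a, na)[:, None]
    rate *= _cnv_factor(config, chrom_b, nb)[None, :]
    for ca, pa, cb, pb, fold in config.trans_loops:
        if (ca, cb) == (chrom_a, chrom_b):
            _apply_focal(rate, pa // res, pb // res, fold)
        elif (cb, ca) == (chrom_a, chrom_b):
            _apply_focal(rate, pb // res, pa // res, fold)
    return rate


def _sv_rate(config: SimulationConfig, sv: PlantedSV) -> tuple[str, str, np.ndarray]:
    """Cross-locus wedge rate on the (chromA, chromB) block, upper triangle
    when intra-chromosomal. Rate at derivative distance dA+dB matches the
    intra background coefficient so junction-adjacent signal is continuous."""
    res = config.base_resolution
    na = -(-config.layout.length_of(sv.chrom_a) // res)
    nb = -(-config.layout.length_of(sv.chrom_b) // res)
    ba, bb = sv.pos_a // res, sv.pos_b // res
    ia = np.arange(na)
    ib = np.arange(nb)
    da = np.abs(ia - ba).astype(float)
    db = np.abs(ib - bb).astype(float)
    keep_a = (ia <= ba) if sv.side_a == "+" else (ia >= ba)
    keep_b = (ib <= bb) if sv.side_b == "+" else (ib >= bb)
    wedge = (da[:, None] + db[None, :] + 1.0) ** config.decay_exponent
    wedge *= keep_a[:, None] * keep_b[None, :]
    wedge *= sv.clonal_fraction
    for pa, pb, fold in sv.neo_loops:
        _apply_focal(wedge, pa // res, pb // res, fold)
    if sv.chrom_a == sv.chrom_b:
        # fold both orientations of the wedge into the upper triangle
        wedge = (
            np.triu(wedge, k=1) + np.triu(wedge.T, k=1)
            + np.diag(np.diag(wedge))
        )
    return sv.chrom_a, sv.chrom_b, wedge


def _sample_block(rng: np.random.Generator, rate: np.ndarray,
                  overdispersion: float) -> np.ndarray:
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = np.where(rate > 0, rate * rng.gamma(shape, overdispersion, rate.shape), 0.0)
    else:
        lam = rate
    return rng.poisson(lam)


def _block_to_pairs(rng: np.random.Generator, counts: np.ndarray,
                    ca: int, cb: int, res: int):
    i, j = np.nonzero(counts)
    if len(i) == 0:
        return None
    reps = counts[i, j].astype(np.int64)
    bi = np.repeat(i, reps)
    bj = np.repeat(j, reps)
    pa = bi * res + rng.integers(0, res, len(bi))
    pb = bj * res + rng.integers(0, res, len(bj))
    return (
        np.full(len(bi), ca, dtype=np.int64), pa.astype(np.int64),
        np.full(len(bj), cb, dtype=np.int64), pb.astype(np.int64),
    )


def _background_scale(
    config: SimulationConfig, intra_rates: dict[str, np.ndarray] | None = None
) -> tuple[float, float]:
    """Global rate scale and inter-chromosome level hitting the target depth."""
    if intra_rates is None:
        intra_rates = {c: _intra_rate(config, c) for c in config.layout.names}
    intra_mass = sum(r.sum() for r in intra_rates.values())
    names = config.layout.names
    # inter level chosen so trans_fraction of background mass is trans
    res = config.base_resolution
    nb = [-(-l // res) for l in config.layout.lengths]
    cross_cells = sum(
        nb[i] * nb[j] for i in range(len(names)) for j in range(i + 1, len(names))
    )
    if config.trans_fraction > 0 and cross_cells > 0:
        level = (
            config.trans_fraction / (1.0 - config.trans_fraction)
            * intra_mass / cross_cells
        )
    else:
        level = 0.0
    total = intra_mass + level * cross_cells
    scale = config.depth / total if total > 0 else 0.0
    return scale, level


def simulate_pairs(config: SimulationConfig):
    """Sample the full pair stream (reference coordinates).

    Returns (chromA index, posA, chromB index, posB) arrays. Background and
    rearrangement pairs are drawn from independent child seeds, so a config
    without SVs reproduces the background stream of one with SVs.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    bg_seed, sv_seed = ss.spawn(2)
    rng_bg = np.random.default_rng(bg_seed)
    intra_rates = {c: _intra_rate(config, c) for c in config.layout.names}
    scale, level = _background_scale(config, intra_rates)
    res = config.base_resolution
    names = config.layout.names
    chunks = []
    for ci, chrom in enumerate(names):
        counts = _sample_block(
            rng_bg, scale * intra_rates[chrom], config.overdispersion
        )
        chunk = _block_to_pairs(rng_bg, counts, ci, ci, res)
        if chunk:
            chunks.append(chunk)
    for ci in range(len(names)):
        for cj in range(ci + 1, len(names)):
            counts = _sample_block(
                rng_bg,
                scale * _inter_rate(config, names[ci], names[cj], level),
                config.overdispersion,
            )
            chunk = _block_to_pairs(rng_bg, counts, ci, cj, res)
            if chunk:
                chunks.append(chunk)
    sv_chunk = plant_rearranged_pairs(config, scale, seed=sv_seed)
    if sv_chunk is not None:
        chunks.append(sv_chunk)
    if not chunks:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z, z
    return tuple(np.concatenate([c[k] for c in chunks]) for k in range(4))


def plant_rearranged_pairs(config: SimulationConfig, scale: float, seed=None):
    """Sample the SV ("corner") pairs only, mapped to reference coordinates.

    Pairs are generated on the derivative chromosome (rate decays with
    derivative distance dA + dB from the junction), restricted to the retained
    side of each breakend, then expressed in reference coordinates.
    """
    svs = config.svs
    if not svs:
        return None
    # overlapping derivative definitions: the same breakend reused
    ends = [(sv.chrom_a, sv.pos_a, sv.side_a) for sv in svs] + [
        (sv.chrom_b, sv.pos_b, sv.side_b) for sv in svs
    ]
    if len(set(ends)) != len(ends):
        raise ValueError("overlapping derivative definitions: breakend reused")
    rng = np.random.default_rng(seed)
    res = config.base_resolution
    idx = {n: i for i, n in enumerate(config.layout.names)}
    chunks = []
    for sv in svs:
        ca, cb, wedge = _sv_rate(config, sv)
        counts = _sample_block(rng, scale * wedge, config.overdispersion)
        chunk = _block_to_pairs(rng, counts, idx[ca], idx[cb], res)
        if chunk:
            chunks.append(chunk)
    if not chunks:
        return None
    return tuple(np.concatenate([c[k] for c in chunks]) for k in range(4))


def simulate_hic(
    config: SimulationConfig,
    resolutions: tuple[int, ...] = (10_000, 25_000, 100_000, 500_000),
) -> tuple[dict[int, ContactMatrix], SimTruth]:
    """Simulate one sample; returns {resolution: matrix} and the truth record."""
    pairs = simulate_pairs(config)
    matrices = {}
    for res in resolutions:
        bins = BinIndex(config.layout, res)
        matrices[res] = pairs_to_matrix(pairs, bins)
    return matrices, SimTruth(config)


# ------------------------------------------------------------- annotations

def synth_tracks(
    truth: SimTruth,
    track_resolution: int = 100_000,
    n_background_motifs: int = 50,
    h3k27ac_strength: float = 1.0,
    seed: int = 0,
):
    """Companion annotations: H3K27ac-like track, CTCF motif BED6 rows, blacklist.

    H3K27ac is positive-mean in A-label bins and near zero in B bins. CTCF
    motifs are planted at every TAD boundary (random strand), convergently at
    loop anchors ("+" at the left anchor, "-" at the right), plus uniform
    background motifs. The blacklist reproduces the configured mask intervals.
    """
    rng = np.random.default_rng(seed)
    labels = truth.compartment_labels(track_resolution)
    a = labels.values > 0.5
    vals = np.where(
        a,
        rng.normal(h3k27ac_strength, 0.3 * h3k27ac_strength, labels.bins.n_bins),
        np.abs(rng.normal(0.0, 0.05, labels.bins.n_bins)),
    )
    h3k27ac = BinnedTrack(labels.bins, np.clip(vals, 0, None), label="H3K27ac")

    motifs: list[tuple[str, int, int, str, float, str]] = []
    for chrom, pos in truth.tad_internal_boundaries:
        strand = "+" if rng.random() < 0.5 else "-"
        motifs.append((chrom, pos - 10, pos + 9, "ctcf_boundary", 0.0, strand))
    for chrom, pa, pb, _fold in truth.loops:
        motifs.append((chrom, pa, pa + 19, "ctcf_loop", 0.0, "+"))
        motifs.append((chrom, pb, pb + 19, "ctcf_loop", 0.0, "-"))
    names = truth.layout.names
    for _ in range(n_background_motifs):
        c = names[rng.integers(len(names))]
        p = int(rng.integers(0, truth.layout.length_of(c) - 20))
        strand = "+" if rng.random() < 0.5 else "-"
        motifs.append((c, p, p + 19, "ctcf_bg", 0.0, strand))
    motifs.sort(key=lambda m: (names.index(m[0]), m[1]))
    blacklist = [tuple(iv) for iv in truth.mask_intervals]
    return h3k27ac, motifs, blacklist


# --------------------------------------------------------- emulated callers

@dataclass
class EmulatedCallSet:
    caller: str
    calls: list[BreakpointCall]
    truth_index: list  # per call: planted-SV index, or None for false positives
    jitter_sd: float
    n_false_positives: int
    miss_rate: float

    def __post_init__(self) -> None:
        if self.jitter_sd < 0 or not 0 <= self.miss_rate <= 1:
            raise ValueError("jitter sd must be >= 0 and miss rate in [0, 1]")


def _jitter_pos(rng, pos: int, sd: float, length: int) -> int:
    if sd == 0:
        return pos
    return int(np.clip(pos + rng.normal(0, sd), 0, length - 1))


def random_svs(
    layout: GenomeLayout,
    n: int,
    seed: int = 0,
    inter_only: bool = True,
    min_gap: int = 300_000,
    end_margin: int = 1_000_000,
    clonal_fraction: float = 1.0,
) -> tuple[PlantedSV, ...]:
    """Draw ``n`` planted SVs with breakends spread over the genome.

    Breakends on each chromosome keep at least ``min_gap`` bp separation
    (stick-breaking construction) and stay ``end_margin`` bp from chromosome
    ends; partners and sides are random. ``inter_only`` keeps all junctions
    inter-chromosomal (the near-diagonal exclusion rule is exercised by its
    own dedicated fixtures).
    """
    rng = np.random.default_rng(seed)
    names = list(layout.names)
    if inter_only and len(names) < 2:
        raise ValueError("inter-chromosomal SVs need at least two chromosomes")
    # spread 2n breakend slots evenly over chromosomes, then pair the two
    # most-loaded chromosomes at each step (always feasible when inter-only)
    load = {c: 0 for c in names}
    for k in range(2 * n):
        load[names[k % len(names)]] += 1
    pairs: list[tuple[str, str]] = []
    for _ in range(n):
        ranked = sorted(names, key=lambda c: (-load[c], rng.random()))
        ca = ranked[0]
        cb = next(c for c in ranked[1:] if not inter_only or c != ca) if (
            inter_only or len(ranked) > 1
        ) else ca
        if not inter_only and rng.random() < 1.0 / len(names):
            cb = ca
        load[ca] -= 1
        load[cb] -= 1
        pairs.append((ca, cb))
    need = {c: sum(p.count(c) for p in pairs) for c in names}
    positions: dict[str, list[int]] = {}
    for c in names:
        m = need[c]
        if m == 0:
            positions[c] = []
            continue
        span = layout.length_of(c) - 2 * end_margin - (m - 1) * min_gap
        if span <= 0:
            raise ValueError(f"cannot place {m} breakends on {c} with the stated gaps")
        raw = np.sort(rng.uniform(0, span, m))
        pos = [int(end_margin + raw[i] + i * min_gap) for i in range(m)]
        rng.shuffle(pos)
        positions[c] = pos
    svs = []
    for ca, cb in pairs:
        pa = positions[ca].pop()
        pb = positions[cb].pop()
        sa = "+" if rng.random() < 0.5 else "-"
        sb = "+" if rng.random() < 0.5 else "-"
        if (names.index(ca), pa) > (names.index(cb), pb):
            (ca, pa, sa), (cb, pb, sb) = (cb, pb, sb), (ca, pa, sa)
        svs.append(
            PlantedSV(ca, pa, sa, cb, pb, sb, clonal_fraction=clonal_fraction)
        )
    return tuple(svs)


def emulate_caller_calls(
    truth: SimTruth,
    caller: str = "emulated",
    jitter_sd: float = 100_000,
    miss_rate: float = 0.0,
    n_false_positives: int = 0,
    fp_exclusion: int = 2_000_000,
    seed: int = 0,
) -> EmulatedCallSet:
    """Emulate an SV caller on the planted truth.

    Each planted SV is emitted with probability 1 - miss_rate with Gaussian
    anchor jitter (truncated to the chromosome); false positives are placed
    uniformly at random with random sides, rejected only if they mimic a
    jittered version of a specific truth call (both anchors within
    ``fp_exclusion`` of the same planted SV's anchors).
    """
    rng = np.random.default_rng(seed)
    layout = truth.layout
    calls: list[BreakpointCall] = []
    origin: list = []
    for k, sv in enumerate(truth.svs):
        if rng.random() < miss_rate:
            continue
        call = BreakpointCall(
            sv.chrom_a,
            _jitter_pos(rng, sv.pos_a, jitter_sd, layout.length_of(sv.chrom_a)),
            sv.side_a,
            sv.chrom_b,
            _jitter_pos(rng, sv.pos_b, jitter_sd, layout.length_of(sv.chrom_b)),
            sv.side_b,
            caller=caller,
        )
        calls.append(canonical_call(call, layout))
        origin.append(k)
    names = list(layout.names)
    n_fp = 0
    while n_fp < n_false_positives:
        ca, cb = (names[rng.integers(len(names))] for _ in range(2))
        pa = int(rng.integers(0, layout.length_of(ca)))
        pb = int(rng.integers(0, layout.length_of(cb)))
        if ca == cb and abs(pb - pa) < 200_000:
            continue
        mimics = any(
            _pair_mimics(sv, ca, pa, cb, pb, fp_exclusion) for sv in truth.svs
        )
        if mimics:
            continue
        sa = "+" if rng.random() < 0.5 else "-"
        sb = "+" if rng.random() < 0.5 else "-"
        call = canonical_call(
            BreakpointCall(ca, pa, sa, cb, pb, sb, caller=caller), layout
        )
        calls.append(call)
        origin.append(None)
        n_fp += 1
    return EmulatedCallSet(
        caller, calls, origin, jitter_sd, n_false_positives, miss_rate
    )


def _pair_mimics(sv: PlantedSV, ca: str, pa: int, cb: str, pb: int, radius: int) -> bool:
    direct = (
        sv.chrom_a == ca and sv.chrom_b == cb
        and abs(sv.pos_a - pa) <= radius and abs(sv.pos_b - pb) <= radius
    )
    swapped = (
        sv.chrom_a == cb and sv.chrom_b == ca
        and abs(sv.pos_a - pb) <= radius and abs(sv.pos_b - pa) <= radius
    )
    return direct or swapped


def emulate_ogm_calls(
    truth: SimTruth,
    jitter_sd: float = 50_000,
    miss_rate: float = 0.0,
    n_false_positives: int = 0,
    seed: int = 0,
):
    """Emulate an optical-genome-mapping SV call set (independent errors).

    Returns a list of :class:`hicrearr.concordance.SVEvent` with sizes filled
    in for intra-chromosomal events, plus the per-event truth indices.
    """
    from .concordance import SVEvent

    calls = emulate_caller_calls(
        truth,
        caller="ogm",
        jitter_sd=jitter_sd,
        miss_rate=miss_rate,
        n_false_positives=n_false_positives,
        seed=seed,
    )
    events = [
        SVEvent(
            c.chrom_a, c.pos_a, c.side_a, c.chrom_b, c.pos_b, c.side_b,
            source="ogm",
        )
        for c in calls.calls
    ]
    return events, calls.truth_index


# -------------------------------------------- cohort-level profile emulation

def synth_compartment_scores(
    truth: SimTruth,
    n_samples: int,
    noise_sd: float = 0.15,
    amplitude: float = 0.5,
    flip_intervals: tuple = (),
    seed: int = 0,
) -> list[BinnedTrack]:
    """Per-sample compartment score tracks: +/- amplitude by truth label plus
    Gaussian sampling noise; ``flip_intervals`` invert the label for this
    group (a planted group-level compartment difference)."""
    rng = np.random.default_rng(seed)
    labels = truth.compartment_labels(100_000)
    base = np.where(labels.values > 0.5, amplitude, -amplitude)
    res = labels.bins.resolution
    base = base.copy()
    for chrom, start, end in flip_intervals:
        lo, _ = labels.bins.chrom_span(chrom)
        base[lo + start // res: lo + -(-end // res)] *= -1.0
    return [
        BinnedTrack(
            labels.bins,
            base + rng.normal(0, noise_sd, labels.bins.n_bins),
            label=f"compartment_s{k}",
        )
        for k in range(n_samples)
    ]


def synth_insulation_scores(
    truth: SimTruth,
    n_samples: int,
    noise_sd: float = 0.1,
    boundary_depth: float = 1.0,
    shift_intervals: tuple = (),
    resolution: int = 10_000,
    seed: int = 0,
) -> list[BinnedTrack]:
    """Per-sample log2 insulation tracks: dips of ``boundary_depth`` at planted
    TAD boundaries plus noise; ``shift_intervals`` are (chrom, start, end,
    delta) group-level shifts."""
    rng = np.random.default_rng(seed)
    bins = BinIndex(truth.layout, resolution)
    base = np.zeros(bins.n_bins)
    for chrom, pos in truth.tad_internal_boundaries:
        b = bins.bin_id(chrom, min(pos, truth.layout.length_of(chrom) - 1))
        base[max(0, b - 1): b + 2] -= boundary_depth
    for chrom, start, end, delta in shift_intervals:
        lo, _ = bins.chrom_span(chrom)
        base[lo + start // resolution: lo + -(-end // resolution)] += delta
    return [
        BinnedTrack(
            bins,
            base + rng.normal(0, noise_sd, bins.n_bins),
            label=f"insulation_s{k}",
        )
        for k in range(n_samples)
    ]
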