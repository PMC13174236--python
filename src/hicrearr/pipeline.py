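"""Per-sample and cohort orchestration with machine-readable JSON reports.

A single master seed fans out to every stochastic stage through a
deterministic derivation, so identical configs produce byte-identical
reports. Stage failures are recorded in the report and dependent stages
are skipped rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import breakpoints as bp
from .differential import (
    Sample,
    SampleGroup,
    binned_jaccard,
    compartment_pca,
    differential_compartments,
    differential_insulation,
    differential_presence,
)
from .enrichment import motif_enrichment
from .genome import GenomeLayout, toy_layout
from .matrix import balance_sqrt_vc
from .rearrange import (
    assembled_matrix,
    coverage_cnv,
    detect_neoloops,
    reconstruct_assembly,
    virtual_4c,
)
from .simulate import (
    default_config,
    emulate_caller_calls,
    random_svs,
    simulate_hic,
    synth_compartment_scores,
    synth_insulation_scores,
    synth_tracks,
)
from .topology import compartment_scores, detect_loops, insulation_profile, tad_boundaries

__all__ = ["parse_config", "derive_seed", "run_sample", "run_cohort", "write_report"]

log = logging.getLogger(__name__)


def parse_config(path) -> dict:
    """Flat key=value config text; '#' starts a comment; values are parsed as
    int, float, or bool where possible."""
    cfg: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value")
        key, val = (s.strip() for s in line.split("=", 1))
        cfg[key] = _parse_value(val)
    return cfg


def _parse_value(val: str):
    low = val.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            continue
    return val


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def _stage(report: dict, name: str):
    report["stages"][name] = {"status": "ok"}
    return report["stages"][name]


def run_sample(config: dict, sample_id: str = "sample") -> dict:
    """Simulate one sample and run the per-sample analysis chain.

    Stages: simulate -> caller emulation + merge/review -> topology ->
    CNV -> assembly/virtual-4C/neo-loops -> enrichment. Stage toggles are
    config keys ``stage_<name>`` (default on).
    """
    seed = int(config.get("seed", 0))
    depth = int(config.get("depth", 2_000_000))
    n_svs = int(config.get("n_svs", 10))
    jitter = float(config.get("jitter_sd", 100_000))
    miss = float(config.get("miss_rate", 0.1))
    n_fp = int(config.get("n_false_positives", 5))
    report: dict = {
        "sample_id": sample_id,
        "config": {k: config[k] for k in sorted(config)},
        "stages": {},
    }
    layout = toy_layout()
    on = lambda name: bool(config.get(f"stage_{name}", True))
    if not any(on(s) for s in ("simulate", "review", "topology", "cnv", "assembly", "enrichment")):
        return report

    svs = random_svs(layout, n_svs, seed=derive_seed(seed, "svs")) if n_svs else ()
    cfg = default_config(seed=derive_seed(seed, "hic"), svs=svs, depth=depth)
    st = _stage(report, "simulate")
    mats, truth = simulate_hic(cfg, resolutions=(10_000, 25_000, 100_000))
    h3k, motifs, blacklist = synth_tracks(truth, seed=derive_seed(seed, "tracks"))
    st["uvp"] = mats[10_000].uvp
    st["n_planted_svs"] = len(svs)

    accepted: list = []
    if on("review"):
        st = _stage(report, "review")
        try:
            m100 = balance_sqrt_vc(mats[100_000])
            c1 = emulate_caller_calls(
                truth, "breakfinder-like", jitter_sd=jitter, miss_rate=miss,
                n_false_positives=n_fp, seed=derive_seed(seed, "caller1"),
            )
            c2 = emulate_caller_calls(
                truth, "eaglec-like", jitter_sd=jitter, miss_rate=miss,
                n_false_positives=n_fp, seed=derive_seed(seed, "caller2"),
            )
            merged = bp.merge_calls(c1.calls, c2.calls, layout)
            merged = bp.exclude_near_diagonal(merged, m100)
            reviewed = bp.review_and_adjust(m100, merged)
            accepted = [
                c for c in reviewed if c.status in (bp.ACCEPTED, bp.ADJUSTED)
            ]
            st.update(
                n_caller1=len(c1.calls), n_caller2=len(c2.calls),
                n_merged=len(merged),
                n_excluded=sum(c.status == bp.EXCLUDED for c in reviewed),
                n_rejected=sum(c.status == bp.REJECTED for c in reviewed),
                n_accepted=len(accepted),
            )
        except Exception as e:  # pragma: no cover - defensive
            st["status"] = "failed"
            st["error"] = str(e)

    if on("topology"):
        st = _stage(report, "topology")
        try:
            m100 = balance_sqrt_vc(mats[100_000])
            prof = compartment_scores(
                m100, h3k27ac=h3k, mask_intervals=truth.mask_intervals
            )
            m10 = balance_sqrt_vc(mats[10_000])
            ins = insulation_profile(m10)
            bounds = tad_boundaries(ins, prominence=float(config.get("prominence", 0.4)))
            loops = detect_loops(m10)
            st.update(
                n_boundaries=len(bounds),
                n_loops=len(loops),
                flipped={k: bool(v) for k, v in prof.flipped.items()},
            )
            report["_topology"] = (prof, ins, bounds, loops)
        except Exception as e:  # pragma: no cover
            st["status"] = "failed"
            st["error"] = str(e)

    if on("cnv"):
        st = _stage(report, "cnv")
        segs = coverage_cnv(mats[25_000])
        st["n_segments"] = len(segs)

    if on("assembly"):
        st = _stage(report, "assembly")
        if not accepted:
            st["status"] = "skipped"
            st["reason"] = "no accepted breakpoints"
        else:
            try:
                call = next(c for c in accepted if c.chrom_a != c.chrom_b)
            except StopIteration:
                call = accepted[0]
            try:
                m10 = balance_sqrt_vc(mats[10_000])
                asm = reconstruct_assembly([call], layout)
                am = assembled_matrix(m10, asm)
                neoloops = detect_neoloops(am)
                v4c = virtual_4c(
                    m10, (call.chrom_a, max(0, call.pos_a - 10_000)), window=1
                )
                st.update(
                    n_segments=len(asm.segments),
                    assembly_length=asm.length,
                    n_neoloops=len(neoloops),
                    n_cross_junction=sum(n.crosses_junction for n in neoloops),
                    v4c_defined_bins=int(np.isfinite(v4c.values).sum()),
                )
            except Exception as e:
                st["status"] = "failed"
                st["error"] = str(e)

    if on("enrichment") and "_topology" in report:
        st = _stage(report, "enrichment")
        _, _, bounds, _ = report["_topology"]
        if bounds:
            res = motif_enrichment(
                bounds, motifs, layout,
                replicates=int(config.get("replicates", 200)),
                seed=derive_seed(seed, "enrichment"),
            )
            st.update(observed=res.observed, p=res.p)
        else:
            st["status"] = "skipped"
            st["reason"] = "no boundaries"

    report.pop("_topology", None)
    return report


def run_cohort(config: dict) -> dict:
    """Cohort-level comparative statistics on emulated per-sample profiles.

    Two groups of per-sample compartment and insulation tracks are generated
    from the same planted truth; group B carries the configured planted
    differences. Differential stages require >= 2 groups with enough
    included members and are skipped (with a reason) otherwise.
    """
    seed = int(config.get("seed", 0))
    n_per_group = int(config.get("n_per_group", 6))
    noise = float(config.get("profile_noise", 0.15))
    report: dict = {"config": {k: config[k] for k in sorted(config)}, "stages": {}}
    truth_cfg = default_config(seed=derive_seed(seed, "cohort-truth"))
    from .simulate import SimTruth

    truth = SimTruth(truth_cfg)
    flip = (("chr3", 2_000_000, 3_000_000),)
    shift = (("chr1", 2_780_000, 2_830_000, float(config.get("insulation_shift", -0.5))),)
    comp_a = synth_compartment_scores(
        truth, n_per_group, noise_sd=noise, seed=derive_seed(seed, "compA")
    )
    comp_b = synth_compartment_scores(
        truth, n_per_group, noise_sd=noise, flip_intervals=flip,
        seed=derive_seed(seed, "compB"),
    )
    ins_a = synth_insulation_scores(
        truth, n_per_group, seed=derive_seed(seed, "insA")
    )
    ins_b = synth_insulation_scores(
        truth, n_per_group, shift_intervals=shift, seed=derive_seed(seed, "insB")
    )
    boundaries = truth.tad_internal_boundaries
    loops = [(c, a, b) for c, a, b, _ in truth.loops]
    group_a = SampleGroup(
        "A",
        [
            Sample(f"A{k}", comp_a[k], ins_a[k], list(boundaries), list(loops),
                   uvp=20_000_000)
            for k in range(n_per_group)
        ],
    )
    group_b = SampleGroup(
        "B",
        [
            Sample(f"B{k}", comp_b[k], ins_b[k], list(boundaries), list(loops),
                   uvp=20_000_000)
            for k in range(n_per_group)
        ],
    )
    st = _stage(report, "similarity")
    st["jaccard_boundaries_AB"] = binned_jaccard(
        boundaries, boundaries, truth.layout, bin_size=50_000
    )
    st["n_samples"] = 2 * n_per_group

    st = _stage(report, "pca")
    all_profiles = [s.compartments for s in group_a.members + group_b.members]
    if len(all_profiles) < 3:
        st["status"] = "skipped"
        st["reason"] = "fewer than 3 samples"
    else:
        coords, var = compartment_pca(all_profiles)
        st["explained_variance"] = [float(v) for v in var]
        margin = float(
            coords[:n_per_group, 0].mean() - coords[n_per_group:, 0].mean()
        )
        st["group_separation_pc1"] = abs(margin)

    st = _stage(report, "differential_compartments")
    if min(len(group_a.included()), len(group_b.included())) < 3:
        st["status"] = "skipped"
        st["reason"] = "group below minimum size"
    else:
        dc = differential_compartments(group_a, group_b)
        st["n_tested"] = int(len(dc))
        st["n_significant"] = int(dc["significant"].sum()) if len(dc) else 0

    st = _stage(report, "differential_insulation")
    di = differential_insulation(group_a, group_b, [("chr1", 2_800_000)])
    st["n_tested"] = int(len(di))
    st["n_significant"] = int(di["significant"].sum()) if len(di) else 0

    st = _stage(report, "differential_presence")
    dp = differential_presence(group_a, group_b, feature="boundary")
    st["n_tested"] = int(len(dp))
    st["n_significant"] = int(dp["significant"].sum()) if len(dp) else 0
    return report
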