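"""End-to-end pipeline: qc -> select -> draft -> fragments -> merge -> polish.

All stage parameters and every random seed live in :class:`PipelineConfig`
(round-trippable to YAML).  Child seeds for the simulator, the draft
subsampler and the fragment subsampler are spawned deterministically from
the one master seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from . import draft as draft_mod
from . import fragments as frag_mod
from . import merge as merge_mod
from . import polish as polish_mod
from .core import ReadRecord
from .draft import Contig
from .primers import PrimerPair, select_reads
from .readqc import RunStats, filter_reads
from .simulate import ErrorModel, SimulationRun, simulate_run

log = logging.getLogger("ipcrseq")


@dataclass
class PipelineConfig:
    seed: int = 0
    # --- simulation (the synthetic run geometry) ---
    flank5_len: int = 3000
    transgene_len: int = 6168
    flank3_len: int = 3000
    p35s_offset: int = 2750
    p35s_len: int = 350
    background_len: int = 60000
    n_molecules: int = 20000
    target_fraction: float = 0.1
    frag_mean: float = 6000.0
    frag_sd: float = 600.0
    p_circularize: float = 0.9
    exo_efficiency: float = 0.99
    sub_rate: float = 0.03
    ins_rate: float = 0.015
    del_rate: float = 0.015
    mean_read_len: float = 1879.0
    read_len_sd: float = 1200.0
    n_reads: int = 2000
    # --- qc ---
    min_q: float = 10.0
    # --- primer selection ---
    min_len: int = 1000
    min_matches: int = 18
    # --- draft assembly ---
    draft_n: int = 300
    draft_iterations: int = 10
    overlap_k: int = 15
    min_overlap: int = 300
    min_overlap_identity: float = 0.80
    # --- fragment assembly ---
    frag_reads: int = 500
    fragment_size: int = 200
    debruijn_k: int = 21
    # at the pipeline's ~50-100x fragment depth, coincidentally repeated
    # error k-mers survive a count-2 filter and shred the graph; 4 separates
    # true k-mers (>=10 clean copies) from them
    min_kmer_count: int = 4
    # --- merge & polish ---
    min_join_overlap: int = 50
    polish_rounds: int = 5
    map_k: int = 15
    map_band: int = 200
    map_min_identity: float = 0.80

    def error_model(self) -> ErrorModel:
        return ErrorModel(
            sub_rate=self.sub_rate,
            ins_rate=self.ins_rate,
            del_rate=self.del_rate,
            mean_read_len=self.mean_read_len,
            read_len_sd=self.read_len_sd,
        )

    def child_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        sim, draft, frag = ss.spawn(3)
        return {
            "sim": int(sim.generate_state(1)[0] % (2**31)),
            "draft": int(draft.generate_state(1)[0] % (2**31)),
            "frag": int(frag.generate_state(1)[0] % (2**31)),
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    qc_stats: RunStats
    passed: list[ReadRecord]
    selected: list[ReadRecord]
    draft_contigs: list[Contig]
    oriented: list[Contig]
    unitigs: list[Contig]
    extended: list[Contig]
    merged: str
    polished: str
    profile: polish_mod.DepthProfile
    junction: Optional[polish_mod.JunctionCall]


def run_pipeline(
    reads: list[ReadRecord],
    known_seed: str,
    cfg: PipelineConfig,
    plant_reference: str | None = None,
    transgene_reference: str | None = None,
) -> PipelineResult:
    """The full analysis on an arbitrary read set.

    ``known_seed`` is the screening-element sequence spanning the primer
    sites.  The optional references are only used for junction calling.
    """
    seeds = cfg.child_seeds()
    passed, stats = filter_reads(reads, min_q=cfg.min_q)
    log.info("qc: %d/%d reads passed (%.1f%%)", stats.n_passed, stats.n_total, stats.pass_fraction)
    selected = select_reads(
        passed, PrimerPair(), min_len=cfg.min_len, min_matches=cfg.min_matches
    )
    log.info("primer selection: %d reads", len(selected))

    collections = draft_mod.iterate_draft(
        selected,
        n=cfg.draft_n,
        iterations=cfg.draft_iterations,
        rng=seeds["draft"],
        k=cfg.overlap_k,
        min_overlap=cfg.min_overlap,
        min_identity=cfg.min_overlap_identity,
    )
    two = draft_mod.pick_two_longest_distinct(collections)
    oriented = [draft_mod.orient_contig(c, known_seed) for c in two]
    log.info("draft: %d contig(s) selected, lengths %s", len(oriented), [len(c) for c in oriented])

    frag_sample = frag_mod.sample_reads(selected, n=cfg.frag_reads, rng=seeds["frag"])
    frags = frag_mod.split_into_fragments(frag_sample, cfg.fragment_size, cfg.debruijn_k)
    unitigs = frag_mod.debruijn_assemble(frags, k=cfg.debruijn_k, min_kmer_count=cfg.min_kmer_count)
    log.info("fragment assembly: %d unitigs", len(unitigs))

    extended = [merge_mod.extend_contig(c, unitigs) for c in oriented]
    if len(extended) == 2:
        merged = merge_mod.join_contigs(
            extended[0], extended[1], known_seed, min_overlap=cfg.min_join_overlap
        )
    else:
        merged = extended[0].seq
    merged, _seed_iv = merge_mod.rotate_to_locus(merged, known_seed)
    log.info("merged sequence: %d bp", len(merged))

    # 0.80 mapping identity keeps junction-straddling reads (forced full-
    # length alignments near 0.75) from voting at low-depth fringes
    map_kwargs = dict(k=cfg.map_k, band=cfg.map_band, min_identity=cfg.map_min_identity)
    alignments = polish_mod.map_reads(selected, merged, **map_kwargs)
    polished, profile = polish_mod.pileup_consensus(
        alignments, selected, merged, max_rounds=cfg.polish_rounds, map_kwargs=map_kwargs
    )
    log.info("polished consensus: %d bp", len(polished))

    junction = None
    if plant_reference and transgene_reference:
        junction = polish_mod.locate_junction(polished, plant_reference, transgene_reference)
    return PipelineResult(
        qc_stats=stats,
        passed=passed,
        selected=selected,
        draft_contigs=[c for coll in collections for c in coll],
        oriented=oriented,
        unitigs=unitigs,
        extended=extended,
        merged=merged,
        polished=polished,
        profile=profile,
        junction=junction,
    )


def run_end_to_end(cfg: PipelineConfig) -> tuple[SimulationRun, PipelineResult]:
    """Simulate a run under ``cfg`` and analyse it."""
    seeds = cfg.child_seeds()
    sim = simulate_run(
        seed=seeds["sim"],
        flank5_len=cfg.flank5_len,
        transgene_len=cfg.transgene_len,
        flank3_len=cfg.flank3_len,
        p35s_offset=cfg.p35s_offset,
        p35s_len=cfg.p35s_len,
        background_len=cfg.background_len,
        n_molecules=cfg.n_molecules,
        target_fraction=cfg.target_fraction,
        frag_mean=cfg.frag_mean,
        frag_sd=cfg.frag_sd,
        p_circularize=cfg.p_circularize,
        exo_efficiency=cfg.exo_efficiency,
        model=cfg.error_model(),
        n_reads=cfg.n_reads,
    )
    locus = sim.locus
    plant = locus.seq[: locus.junction5]
    transgene = locus.seq[locus.junction5 : locus.junction3]
    result = run_pipeline(
        sim.reads, sim.p35s, cfg, plant_reference=plant, transgene_reference=transgene
    )
    return sim, result
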