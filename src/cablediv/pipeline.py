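"""End-to-end orchestration: curation → clustering → delineation → biogeography.

Stage order follows the curation narrative of the source protocol: reference
screen first, then the conserved-region check, then tree building and the
monophyly filter, and the length cutoff last (the monophyly tree is built before
short sequences are dropped, so fragments still inform the topology). A flag
moves the length filter ahead of the tree for sensitivity analysis.

Every stage logs its input/output counts; given the same inputs and config the
run is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import pandas as pd

from . import biogeo, delineate, phylo
from .delineate import (
    CONSERVED_VIOLATION, OFF_CLADE, RETAINED, SCREEN_REJECTED, TOO_SHORT,
    CurationReport, DelineationSummary, GenusCluster, SpeciesClade,
)
from .identity import IdentityMatrix, identity_matrix, screen_references
from .seqio import SequenceRecord, SiteMetadata

logger = logging.getLogger("cablediv.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage thresholds in one flat, serialisable object."""

    screen_cutoff: float = 92.0
    min_len: int = 800
    min_rep_len: int = 1200
    full_len: int = 1450
    species_cutoff: float = 98.7
    genus_cutoff: float = 94.5
    genus_tolerance: float = 0.0
    species_linkage: str = "complete"   # or "single"
    genus_linkage: str = "min"          # or "mean"
    conserved_min_conservation: float = 0.95
    conserved_min_run: int = 10
    conserved_max_violations: int = 5
    tree_correction: str = "jc"         # distance correction for NJ trees
    identity_method: str = "fast"       # or "exact"
    length_filter_first: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (self.screen_cutoff, self.species_cutoff, self.genus_cutoff):
            if not 0 < c <= 100:
                raise ValueError("cutoffs must lie in (0, 100]")
        if self.species_cutoff <= self.genus_cutoff:
            raise ValueError("species cutoff must exceed the genus cutoff")

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class PipelineResult:
    report: CurationReport
    clades: list[SpeciesClade]
    clusters: list[GenusCluster]
    summary: DelineationSummary
    biogeo_summary: Optional[biogeo.BiogeoSummary]
    identity: Optional[IdentityMatrix]
    monophyly_tree: Optional[dendropy.Tree]
    genus_tree: Optional[dendropy.Tree]
    assignments: pd.DataFrame
    stage_counts: list[tuple[str, int, int]]  # (stage, n_in, n_retained)


def _log_stage(stage: str, n_in: int, n_out: int,
               counts: list[tuple[str, int, int]]) -> None:
    counts.append((stage, n_in, n_out))
    logger.info("[%s] %d -> %d", stage, n_in, n_out)


def run_pipeline(
    records: Sequence[SequenceRecord],
    metadata: Sequence[SiteMetadata],
    config: PipelineConfig = PipelineConfig(),
    queries: Sequence[SequenceRecord] = (),
    outgroup: Optional[SequenceRecord] = None,
    whitelist: Sequence[str] = (),
    external_tree: Optional[dendropy.Tree] = None,
) -> PipelineResult:
    """Run the full delineation pipeline.

    ``queries`` are the trusted reference sequences used both for the identity
    screen and as monophyly seeds; ``outgroup`` is the rooting sequence, which
    bypasses all filters and only participates in trees. An ``external_tree``
    (e.g. from a maximum-likelihood program) replaces the internal NJ tree for
    the monophyly stage when given.

    An empty survivor set at any stage yields an explicit empty result rather
    than an error.
    """
    if len(queries) == 0:
        raise ValueError("run_pipeline needs at least one trusted query sequence")
    stage_counts: list[tuple[str, int, int]] = []
    report = CurationReport()
    method = config.identity_method
    records = [r for r in records if outgroup is None or r.id != outgroup.id]

    def empty_result() -> PipelineResult:
        summary = delineate.summarize([], [], None, report)
        return PipelineResult(
            report=report, clades=[], clusters=[], summary=summary,
            biogeo_summary=None, identity=None, monophyly_tree=None,
            genus_tree=None, assignments=pd.DataFrame(
                columns=["record_id", "clade_id", "cluster_id",
                         "representative", "valid_clade"]),
            stage_counts=stage_counts,
        )

    # --- stage 1: reference identity screen -------------------------------
    screen = screen_references(records, queries, cutoff=config.screen_cutoff,
                               whitelist=whitelist, method=method)
    keep_ids = {s.record_id for s in screen if s.retained}
    survivors = [r for r in records if r.id in keep_ids]
    for r in records:
        if r.id not in keep_ids:
            report.set(r, SCREEN_REJECTED)
    _log_stage("screen", len(records), len(survivors), stage_counts)
    if not survivors:
        return empty_result()

    # --- optional early length filter --------------------------------------
    if config.length_filter_first:
        survivors, removed, _ = delineate.filter_length(survivors, config.min_len)
        for r in removed:
            report.set(r, TOO_SHORT)
        _log_stage("length(early)", len(survivors) + len(removed), len(survivors),
                   stage_counts)
        if not survivors:
            return empty_result()

    # --- stage 2: conserved-region violations ------------------------------
    profile = delineate.build_conserved_profile(
        survivors,
        min_conservation=config.conserved_min_conservation,
        min_run=config.conserved_min_run,
    )
    survivors, flagged = delineate.flag_conserved_violations(
        survivors, profile, max_violations=config.conserved_max_violations
    )
    for r in flagged:
        report.set(r, CONSERVED_VIOLATION)
    _log_stage("conserved", len(survivors) + len(flagged), len(survivors),
               stage_counts)
    if not survivors:
        return empty_result()

    # all-vs-all identities over the curated candidates (plus outgroup),
    # computed once and sliced by the downstream stages
    pool = survivors + ([outgroup] if outgroup is not None else [])
    im_full = identity_matrix(pool, method=method)

    # --- stage 3: tree + monophyly filter ----------------------------------
    monophyly_tree = None
    if outgroup is not None and len(survivors) >= 2:
        if external_tree is not None:
            monophyly_tree = external_tree
        else:
            dm = phylo.to_distances(im_full, correction=config.tree_correction)
            monophyly_tree = phylo.nj_tree(dm)
        seed_ids = {q.id for q in queries} & {r.id for r in survivors}
        if seed_ids:
            retained_ids, removed_ids = delineate.monophyly_filter(
                monophyly_tree, seed_ids, outgroup.id
            )
            next_surv = [r for r in survivors if r.id in retained_ids]
            for r in survivors:
                if r.id in removed_ids:
                    report.set(r, OFF_CLADE)
            survivors = next_surv
    _log_stage("monophyly", stage_counts[-1][2], len(survivors), stage_counts)
    if not survivors:
        return empty_result()

    # --- stage 4: length cutoff --------------------------------------------
    if not config.length_filter_first:
        survivors, removed, _ = delineate.filter_length(survivors, config.min_len)
        for r in removed:
            report.set(r, TOO_SHORT)
        _log_stage("length", len(survivors) + len(removed), len(survivors),
                   stage_counts)
        if not survivors:
            return empty_result()
    for r in survivors:
        report.set(r, RETAINED)

    # --- stage 5: species-level clades -------------------------------------
    im = im_full.subset([r.id for r in survivors])
    groups = delineate.cluster_species(im, cutoff=config.species_cutoff,
                                       linkage=config.species_linkage)
    clades = delineate.finalize_clades(groups, survivors,
                                       min_rep_len=config.min_rep_len)
    valid = [c for c in clades if c.valid]
    _log_stage("species_clades", len(survivors), len(valid), stage_counts)

    # --- stage 6: genus-level clusters --------------------------------------
    clusters: list[GenusCluster] = []
    genus_tree = None
    if outgroup is not None and len(valid) >= 2:
        reps = sorted(c.representative_id for c in valid)
        rep_im = im_full.subset(reps + [outgroup.id])
        if len(reps) + 1 >= 3:
            dm = phylo.to_distances(rep_im, correction=config.tree_correction)
            genus_tree = phylo.nj_tree(dm)
            clusters = delineate.cluster_genus(
                genus_tree, rep_im, outgroup.id, valid,
                guide_cutoff=config.genus_cutoff,
                tolerance=config.genus_tolerance,
                linkage=config.genus_linkage,
            )
    elif len(valid) == 1:
        only = valid[0]
        clusters = [GenusCluster(
            cluster_id="G1", clade_ids=frozenset({only.clade_id}),
            representative_ids=frozenset({only.representative_id}),
            monophyletic=True, min_intra_identity=100.0,
            max_external_identity=0.0,
        )]
    _log_stage("genus_clusters", len(valid), len(clusters), stage_counts)

    # --- stage 7: summaries + biogeography ----------------------------------
    summary = delineate.summarize(clades, clusters, im, report)
    assignments = delineate.assignments_table(clades, clusters)
    bio = None
    if len(metadata) > 0 and not assignments.empty:
        bio = biogeo.site_summary(assignments, survivors, metadata)
    return PipelineResult(
        report=report, clades=clades, clusters=clusters, summary=summary,
        biogeo_summary=bio, identity=im, monophyly_tree=monophyly_tree,
        genus_tree=genus_tree, assignments=assignments,
        stage_counts=stage_counts,
    )


def write_outputs(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    """Write the standard output bundle (TSV/CSV/JSON/Newick) to a directory."""
    from . import seqio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    result.summary.to_json(out / "summary.json")
    result.assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    result.report.counts_by_source().to_csv(out / "accounting.tsv", sep="\t")
    if result.identity is not None:
        result.identity.to_csv(out / "identity_matrix.csv")
    if result.monophyly_tree is not None:
        seqio.write_newick(result.monophyly_tree, out / "monophyly_tree.nwk")
    if result.genus_tree is not None:
        seqio.write_newick(result.genus_tree, out / "genus_tree.nwk")
    if result.biogeo_summary is not None:
        result.biogeo_summary.to_json(out / "biogeo.json")
        result.biogeo_summary.per_site_table().to_csv(
            out / "site_composition.csv", index=False
        )
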