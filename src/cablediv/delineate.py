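"""Curation filters and the two-level taxon delineation.

The delineation follows the three-step convention for 16S rRNA taxon calling:

1. candidate sequences are curated (identity screen, conserved-region check,
   monophyly against a rooted tree, 800 bp length cutoff);
2. species-level clades are formed by complete-linkage clustering of pairwise
   identities at the conventional 98.7% cutoff, a clade being *valid* only when it
   contains at least one nearly complete (≥1,200 bp) sequence;
3. genus-level clusters are delineated over the clade representatives by a
   monophyletic decomposition of the rooted tree guided by the 94.5% identity
   cutoff, so every cluster is a clade of the tree by construction.

Complete linkage is used for step 2 because it guarantees that every pair of
sequences inside a species-level clade meets the identity cutoff; single linkage is
available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import phylo
from .identity import IdentityMatrix, bases_intersect, pair_identity
from .seqio import SequenceRecord, ungapped_length

# curation statuses (one per record; a record has exactly one)
RETAINED = "retained"
TOO_SHORT = "too_short"
CONSERVED_VIOLATION = "conserved_violation"
OFF_CLADE = "off_clade"
SCREEN_REJECTED = "screen_rejected"

STATUSES = (RETAINED, TOO_SHORT, CONSERVED_VIOLATION, OFF_CLADE, SCREEN_REJECTED)

NEARLY_COMPLETE_LEN = 1200
FULL_LENGTH_LEN = 1450


@dataclass
class CurationReport:
    """Per-record curation status plus per-source accounting.

    Statuses partition the input: every record id appears exactly once, and the
    per-source accounting rows sum to the input sizes.
    """

    status: dict[str, str] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)

    def set(self, record: SequenceRecord, status: str) -> None:
        if status not in STATUSES:
            raise ValueError(f"unknown curation status {status!r}")
        self.status[record.id] = status
        self.source[record.id] = record.source

    def counts_by_source(self) -> pd.DataFrame:
        """Source × status count table with row totals (filter-accounting style)."""
        df = pd.DataFrame(
            {"source": [self.source[i] for i in self.status],
             "status": [self.status[i] for i in self.status]}
        )
        if df.empty:
            return pd.DataFrame(columns=list(STATUSES) + ["total"])
        tab = df.pivot_table(index="source", columns="status", aggfunc="size",
                             fill_value=0)
        for st in STATUSES:
            if st not in tab.columns:
                tab[st] = 0
        tab = tab[list(STATUSES)]
        tab["total"] = tab.sum(axis=1)
        return tab

    def n_with_status(self, status: str) -> int:
        return sum(1 for s in self.status.values() if s == status)


# ---------------------------------------------------------------------------
# Length filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthFlags:
    nearly_complete: bool  # ≥ 1,200 bp
    full_length: bool      # ≥ 1,450 bp


def filter_length(
    records: Sequence[SequenceRecord], min_len: int = 800
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict[str, LengthFlags]]:
    """Drop sequences shorter than ``min_len`` (inclusive cutoff).

    Also annotates each record as nearly complete (≥1,200 bp) and/or full length
    (≥1,450 bp), the thresholds used downstream for clade validity.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    retained, removed = [], []
    flags: dict[str, LengthFlags] = {}
    for rec in records:
        L = ungapped_length(rec)
        flags[rec.id] = LengthFlags(L >= NEARLY_COMPLETE_LEN, L >= FULL_LENGTH_LEN)
        (retained if L >= min_len else removed).append(rec)
    return retained, removed, flags


# ---------------------------------------------------------------------------
# Conserved-region filter
# ---------------------------------------------------------------------------

@dataclass
class ConservedProfile:
    """Per-position consensus of a trusted alignment with conservation weights.

    A column is *conserved* when at least ``min_conservation`` of the profile rows
    carry a base compatible with the column consensus.
    """

    consensus: str
    conservation: np.ndarray  # per-column agreement fraction among covering rows
    min_conservation: float = 0.95
    #: Number of profile rows. The effective conservation threshold is
    #: min(min_conservation, 1 − 1/coverage): a single aberrant sequence in a
    #: small panel must not be able to demote the very column it violates.
    n_rows: int = 0
    #: Per-column number of rows actually covering the column (fragments do not
    #: vote on regions they never reach). None means full coverage everywhere.
    coverage: Optional[np.ndarray] = None
    #: Minimum length of a run of conserved columns for the run to count as a
    #: conserved *region*. Isolated invariant columns inside variable regions are
    #: not conserved regions of the gene and alignment jitter around them would
    #: otherwise masquerade as violations.
    min_run: int = 10

    def __post_init__(self) -> None:
        if len(self.consensus) == 0:
            raise ValueError("empty conserved profile")
        if len(self.consensus) != len(self.conservation):
            raise ValueError("profile consensus/conservation length mismatch")

    @property
    def conserved_columns(self) -> np.ndarray:
        """Columns lying in a conserved region (high-conservation run ≥ min_run)."""
        L = len(self.consensus)
        cov = (self.coverage if self.coverage is not None
               else np.full(L, max(self.n_rows, 1)))
        thresh = np.full(L, self.min_conservation)
        np.minimum(thresh, 1.0 - 1.0 / np.maximum(cov, 1), out=thresh)
        # a column needs meaningful coverage before it can count as conserved
        min_cov = max(2, self.n_rows // 2) if self.n_rows else 2
        high = (self.conservation >= thresh - 1e-12) & (cov >= min_cov)
        out = np.zeros_like(high)
        i = 0
        n = len(high)
        while i < n:
            if high[i]:
                j = i
                while j < n and high[j]:
                    j += 1
                if j - i >= self.min_run:
                    out[i:j] = True
                i = j
            else:
                i += 1
        return out


def _alignment_columns(record_seq: str, consensus: str):
    """Yield (record_symbol_or_None, consensus_index) columns of an infix
    alignment of the record against the consensus.

    Consensus terminal overhangs are free and never yielded, so a fragment is not
    penalised for the regions it simply does not cover.
    """
    import edlib

    from .identity import _EDLIB_EQUALITIES

    res = edlib.align(record_seq, consensus, task="path", mode="HW",
                      additionalEqualities=_EDLIB_EQUALITIES)
    ti = res["locations"][0][0]
    qi = 0
    num = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            num = num * 10 + int(ch)
            continue
        if ch in "=XM":
            for k in range(num):
                yield record_seq[qi + k], ti + k
            qi += num
            ti += num
        elif ch == "I":  # record-only column, no consensus coordinate
            qi += num
        elif ch == "D":  # gap in the record at a consensus column
            for k in range(num):
                yield None, ti + k
            ti += num
        num = 0


def build_conserved_profile(
    references: Sequence[SequenceRecord],
    min_conservation: float = 0.95,
    min_run: int = 10,
) -> ConservedProfile:
    """Estimate a conserved-region profile from trusted reference sequences.

    The longest reference is the coordinate backbone; every reference is aligned
    to it and per-column agreement with the majority base is tallied. Gaps count
    as disagreement, so indel-prone columns are never marked conserved.
    """
    if len(references) == 0:
        raise ValueError("cannot build a conserved profile from zero references")
    backbone = max(references, key=lambda r: (len(r.residues), r.id))
    L = len(backbone.residues)
    counts = {b: np.zeros(L, dtype=np.int32) for b in "ACGT"}
    other = np.zeros(L, dtype=np.int32)  # ambiguity codes, rare
    n_rows = len(references)
    symbols_per_ref: list[dict[int, Optional[str]]] = []
    for ref in references:
        cols: dict[int, Optional[str]] = {}
        if ref.id == backbone.id:
            for i, b in enumerate(ref.residues):
                cols[i] = b
        else:
            for sym, ti in _alignment_columns(ref.residues, backbone.residues):
                cols[ti] = sym
        symbols_per_ref.append(cols)
        for ti, sym in cols.items():
            if sym in counts:
                counts[sym][ti] += 1
            elif sym is not None:
                other[ti] += 1
    stacked = np.vstack([counts[b] for b in "ACGT"])
    maj_idx = stacked.argmax(axis=0)
    consensus = "".join("ACGT"[k] for k in maj_idx)
    conservation = np.zeros(L)
    coverage = np.zeros(L, dtype=np.int32)
    for cols in symbols_per_ref:
        if not cols:
            continue
        covered = sorted(cols)
        lo, hi = covered[0], covered[-1]
        coverage[lo:hi + 1] += 1  # internal gaps count as covering (and failing)
        for ti, sym in cols.items():
            if sym is not None and bases_intersect(sym, consensus[ti]):
                conservation[ti] += 1
    conservation /= np.maximum(coverage, 1)
    return ConservedProfile(consensus, conservation, min_conservation, n_rows,
                            coverage, min_run)


def count_conserved_violations(
    record: SequenceRecord,
    profile: ConservedProfile,
    conserved: Optional[np.ndarray] = None,
) -> int:
    """Number of conserved profile columns where the record has a gap or an
    incompatible base (consensus overhangs not covered by the record are free)."""
    if conserved is None:
        conserved = profile.conserved_columns
    n = 0
    for sym, ti in _alignment_columns(record.residues, profile.consensus):
        if not conserved[ti]:
            continue
        if sym is None or not bases_intersect(sym, profile.consensus[ti]):
            n += 1
    return n


def count_conserved_violations_exact(
    record: SequenceRecord,
    profile: ConservedProfile,
    conserved: Optional[np.ndarray] = None,
) -> int:
    """Violation count from the exact affine semi-global alignment.

    The affine gap penalty does not trade clustered substitutions for indel
    pairs the way a unit-cost path can, so this count is free of alignment
    jitter; it is used to re-verify records the fast count would flag.
    Terminal columns where the record carries an end gap are free.
    """
    from .identity import align_pair

    if conserved is None:
        conserved = profile.conserved_columns
    aln = align_pair(record, SequenceRecord("__consensus__", profile.consensus))
    rec_cols = [i for i, c in enumerate(aln.aligned_a) if c != "-"]
    first, last = rec_cols[0], rec_cols[-1]
    ti = 0
    n = 0
    for k, (x, y) in enumerate(zip(aln.aligned_a, aln.aligned_b)):
        if y == "-":
            continue
        if first <= k <= last and conserved[ti] and (
            x == "-" or not bases_intersect(x, y)
        ):
            n += 1
        ti += 1
    return n


def flag_conserved_violations(
    records: Sequence[SequenceRecord],
    profile: ConservedProfile,
    max_violations: int = 5,
    verify_exact: bool = True,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (retained, flagged) by the conserved-region rule.

    A record is flagged when it has more than ``max_violations`` violating
    conserved columns — the operational form of removing sequences with indels
    and mutations in conserved regions of the gene. Records the fast count
    would flag are re-verified with the exact affine alignment (``verify_exact``)
    so that unit-cost alignment jitter cannot cause false removals.
    """
    retained, flagged = [], []
    conserved = profile.conserved_columns
    for rec in records:
        bad = count_conserved_violations(rec, profile, conserved) > max_violations
        if bad and verify_exact:
            bad = count_conserved_violations_exact(rec, profile, conserved) > max_violations
        (flagged if bad else retained).append(rec)
    return retained, flagged


# ---------------------------------------------------------------------------
# Monophyly filter
# ---------------------------------------------------------------------------

def monophyly_filter(
    tree: dendropy.Tree, seed_ids: set[str], outgroup: str
) -> tuple[set[str], set[str]]:
    """Keep only leaves descending from the MRCA of trusted seed sequences.

    The tree is rooted on the outgroup; retained = all leaves under the seed
    MRCA, removed = every other non-outgroup leaf.
    """
    leaves = phylo.tree_leaf_labels(tree)
    missing = set(seed_ids) - leaves
    if missing:
        raise KeyError(f"seed id(s) not in tree: {sorted(missing)}")
    q = phylo.root_and_query(tree, outgroup, set(seed_ids))
    retained = set(q.mrca_leaves)
    removed = leaves - retained - {outgroup}
    return retained, removed


# ---------------------------------------------------------------------------
# Species-level clades
# ---------------------------------------------------------------------------

def cluster_species(
    im: IdentityMatrix, cutoff: float = 98.7, linkage: str = "complete"
) -> list[set[str]]:
    """Agglomerative clustering of records at the species-level identity cutoff.

    Works on distances 100 − identity, cutting at 100 − cutoff. Merges are
    processed smallest-distance-first; equal distances are broken by the
    lexicographically smallest (sorted) pair of cluster labels, a cluster's label
    being the smallest record id it contains. With complete linkage (default)
    every within-clade pair meets the cutoff.
    """
    if linkage not in ("complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(im.ids)
    thresh = 100.0 - cutoff
    labels = list(im.ids)
    members: list[set[str]] = [{rid} for rid in im.ids]
    D = (100.0 - im.values).astype(float)
    np.fill_diagonal(D, np.inf)
    active = list(range(n))
    comb = np.maximum if linkage == "complete" else np.minimum
    while len(active) > 1:
        sub = D[np.ix_(active, active)]
        dmin = sub.min()
        if dmin > thresh:
            break
        best = None
        for ai, aj in np.argwhere(sub <= dmin + 1e-12):
            if ai >= aj:
                continue
            i, j = active[ai], active[aj]
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, (i, j))
        i, j = best[1]
        # Lance–Williams update into slot i
        row = comb(D[i, :], D[j, :])
        D[i, :] = row
        D[:, i] = row
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        members[i] |= members[j]
        labels[i] = min(labels[i], labels[j])
        active.remove(j)
    return sorted((members[i] for i in active), key=lambda s: min(s))


@dataclass(frozen=True)
class SpeciesClade:
    clade_id: str
    member_ids: frozenset[str]
    representative_id: str
    valid: bool      # contains a nearly complete (≥ min_rep_len) member
    singleton: bool  # exactly one member

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a clade member")


def finalize_clades(
    groups: Sequence[set[str]],
    records: Sequence[SequenceRecord],
    min_rep_len: int = NEARLY_COMPLETE_LEN,
) -> list[SpeciesClade]:
    """Attach representatives and validity flags to raw identity groups.

    The representative is the longest member (ties: lexicographically smallest
    id); a group is a valid species-level clade only if its longest member is at
    least ``min_rep_len`` (nearly complete).
    """
    by_id = {r.id: r for r in records}
    clades: list[SpeciesClade] = []
    ordered = sorted(groups, key=lambda g: min(g))
    width = max(3, len(str(len(ordered))))
    for k, group in enumerate(ordered, start=1):
        if not group:
            raise ValueError("empty species group")
        rep = min(group, key=lambda rid: (-ungapped_length(by_id[rid]), rid))
        valid = ungapped_length(by_id[rep]) >= min_rep_len
        clades.append(
            SpeciesClade(
                clade_id=f"C{k:0{width}d}",
                member_ids=frozenset(group),
                representative_id=rep,
                valid=valid,
                singleton=(len(group) == 1),
            )
        )
    return clades


# ---------------------------------------------------------------------------
# Genus-level clusters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenusCluster:
    cluster_id: str
    clade_ids: frozenset[str]          # species-level clade ids
    representative_ids: frozenset[str]  # the representatives the tree was built on
    monophyletic: bool
    min_intra_identity: float   # minimum pairwise identity inside the cluster
    max_external_identity: float  # maximum identity from a member to a non-member


def cluster_genus(
    tree: dendropy.Tree,
    im: IdentityMatrix,
    outgroup: str,
    clades: Sequence[SpeciesClade],
    guide_cutoff: float = 94.5,
    tolerance: float = 0.0,
    linkage: str = "min",
) -> list[GenusCluster]:
    """Delineate genus-level clusters by monophyletic threshold decomposition.

    The tree over valid-clade representatives is rooted on the outgroup and
    walked in preorder: a node's leaf set becomes one cluster as soon as its
    linkage identity (mean or min of pairwise identities among its leaves) is at
    least ``guide_cutoff − tolerance``; otherwise its children are descended
    into. Every cluster is therefore monophyletic by construction. The tolerance
    admits the sub-cutoff pairs that manual, topology-led cluster calling
    accepts; with the default 0 the identity guide is applied strictly.
    """
    if linkage not in ("mean", "min"):
        raise ValueError(f"unknown linkage {linkage!r}")
    rep_to_clade = {c.representative_id: c.clade_id for c in clades}
    rooted = phylo.root_on_outgroup(tree, outgroup)
    ingroup = phylo.ingroup_root(rooted, outgroup)
    leaves_in_tree = phylo.leaf_labels(ingroup)
    missing = leaves_in_tree - set(im.ids)
    if missing:
        raise ValueError(f"tree leaves absent from identity matrix: {sorted(missing)}")
    link = im.mean_pairwise if linkage == "mean" else im.min_pairwise

    groups: list[set[str]] = []

    def visit(node: dendropy.Node) -> None:
        lab = phylo.leaf_labels(node)
        if len(lab) == 1 or link(sorted(lab)) >= guide_cutoff - tolerance:
            groups.append(lab)
            return
        for child in node.child_nodes():
            visit(child)

    visit(ingroup)

    all_reps = sorted(leaves_in_tree)
    clusters: list[GenusCluster] = []
    for k, grp in enumerate(groups, start=1):
        inside = sorted(grp)
        outside = [r for r in all_reps if r not in grp]
        max_ext = max(
            (im.get(a, b) for a in inside for b in outside), default=0.0
        )
        clusters.append(
            GenusCluster(
                cluster_id=f"G{k}",
                clade_ids=frozenset(rep_to_clade.get(r, r) for r in grp),
                representative_ids=frozenset(grp),
                monophyletic=True,
                min_intra_identity=im.min_pairwise(inside),
                max_external_identity=float(max_ext),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

@dataclass
class DelineationSummary:
    n_groups: int                 # raw identity groups (valid + invalid)
    n_valid_clades: int
    n_invalid_groups: int
    n_genus_clusters: int
    n_singletons: int             # valid clades with exactly one member
    min_intra_cluster_identity: float
    max_inter_cluster_identity: float
    per_source: pd.DataFrame

    def to_json(self, path=None) -> str:
        payload = {
            "n_groups": self.n_groups,
            "n_valid_clades": self.n_valid_clades,
            "n_invalid_groups": self.n_invalid_groups,
            "n_genus_clusters": self.n_genus_clusters,
            "n_singletons": self.n_singletons,
            "min_intra_cluster_identity": self.min_intra_cluster_identity,
            "max_inter_cluster_identity": self.max_inter_cluster_identity,
            "per_source": self.per_source.to_dict() if len(self.per_source) else {},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarize(
    clades: Sequence[SpeciesClade],
    clusters: Sequence[GenusCluster],
    im: Optional[IdentityMatrix],
    report: CurationReport,
) -> DelineationSummary:
    """Counts of clades/clusters/singletons plus identity extremes.

    The intra extreme is the smallest pairwise identity inside any genus-level
    cluster; the inter extreme is the largest identity between members of
    different clusters (both over clade representatives).
    """
    valid = [c for c in clades if c.valid]
    min_intra = min((g.min_intra_identity for g in clusters), default=0.0)
    max_inter = max((g.max_external_identity for g in clusters), default=0.0)
    return DelineationSummary(
        n_groups=len(clades),
        n_valid_clades=len(valid),
        n_invalid_groups=len(clades) - len(valid),
        n_genus_clusters=len(clusters),
        n_singletons=sum(1 for c in valid if c.singleton),
        min_intra_cluster_identity=min_intra,
        max_inter_cluster_identity=max_inter,
        per_source=report.counts_by_source(),
    )


def assignments_table(
    clades: Sequence[SpeciesClade], clusters: Sequence[GenusCluster]
) -> pd.DataFrame:
    """Long-format record → clade → cluster assignment table."""
    clade_to_cluster: dict[str, str] = {}
    for g in clusters:
        for cid in g.clade_ids:
            clade_to_cluster[cid] = g.cluster_id
    rows = []
    for clade in clades:
        for rid in sorted(clade.member_ids):
            rows.append(
                {
                    "record_id": rid,
                    "clade_id": clade.clade_id,
                    "cluster_id": clade_to_cluster.get(clade.clade_id, ""),
                    "representative": rid == clade.representative_id,
                    "valid_clade": clade.valid,
                }
            )
    return pd.DataFrame(rows)
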