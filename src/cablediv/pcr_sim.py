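"""In-silico twin of the nested PCR + Sanger consensus protocol.

Only sequence-level feasibility is modelled: a primer anneals where at most
``max_mismatch`` of its positions are IUPAC-incompatible with the template and its
3'-terminal bases (``anchor3`` of them) are all compatible. Annealing temperatures,
cycle counts and polymerase chemistry are deliberately out of scope — this module
answers "could these primers produce this amplicon", not "how efficiently".

Coordinates are 0-based half-open on the plus strand of the template; amplicons
are reported on the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .identity import align_pair, bases_intersect, percent_identity, reverse_complement
from .seqio import PrimerRecord, SequenceRecord


@dataclass(frozen=True)
class PrimerSite:
    primer_name: str
    strand: str  # "plus" | "minus"
    start: int   # 0-based half-open on the plus strand
    end: int
    mismatches: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    fwd_site: PrimerSite
    rev_site: PrimerSite
    residues: str
    round: str  # "pcr1" | "pcr2"

    def __len__(self) -> int:
        return len(self.residues)


class UnmergeableFragmentsError(ValueError):
    """Raised when PCR fragments share no qualifying overlap."""


@dataclass(frozen=True)
class ConsensusAssembly:
    fragment_ids: tuple[str, ...]
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


def _count_mismatches(window: str, primer: str, anchor_left: bool,
                      max_mismatch: int, anchor3: int) -> Optional[int]:
    """Mismatch count of a primer against a template window, or None if the
    site fails the mismatch budget or the 3' anchor.

    ``anchor_left`` marks sites where the primer's 3' end maps to the *start* of
    the plus-strand window (minus-strand sites).
    """
    n = len(primer)
    mism = 0
    for k in range(n):
        if not bases_intersect(window[k], primer[k]):
            anchor_pos = k < anchor3 if anchor_left else k >= n - anchor3
            if anchor_pos:
                return None
            mism += 1
            if mism > max_mismatch:
                return None
    return mism


def find_primer_sites(
    template: SequenceRecord,
    primer: PrimerRecord,
    max_mismatch: int = 0,
    anchor3: int = 3,
) -> list[PrimerSite]:
    """All annealing sites of a primer on both strands of a template.

    Degenerate primer codes match by IUPAC set intersection (e.g. M matches A or
    C). A site is reported when at most ``max_mismatch`` columns are incompatible
    and all ``anchor3`` 3'-terminal primer bases are compatible — extension
    cannot start from a mismatched 3' end.
    """
    plen = len(primer.sequence)
    tseq = template.residues
    if plen >= len(tseq):
        raise ValueError("primer must be shorter than the template")
    sites: list[PrimerSite] = []
    rc = reverse_complement(primer.sequence)
    for start in range(len(tseq) - plen + 1):
        window = tseq[start:start + plen]
        m = _count_mismatches(window, primer.sequence, False, max_mismatch, anchor3)
        if m is not None:
            sites.append(PrimerSite(primer.name, "plus", start, start + plen, m))
        m = _count_mismatches(window, rc, True, max_mismatch, anchor3)
        if m is not None:
            sites.append(PrimerSite(primer.name, "minus", start, start + plen, m))
    return sites


def amplify(
    template: SequenceRecord,
    fwd: PrimerRecord,
    rev: PrimerRecord,
    min_len: int = 100,
    max_len: int = 2500,
    max_mismatch: int = 0,
    anchor3: int = 3,
    round_tag: str = "pcr1",
) -> list[Amplicon]:
    """Enumerate the products a primer pair can make from a template.

    Every plus-strand forward site combined with every minus-strand reverse site
    downstream of it yields the spanned plus-strand subsequence, kept when its
    length falls within [min_len, max_len]. Deterministic order: by product
    start, then end.
    """
    fwd_sites = [s for s in find_primer_sites(template, fwd, max_mismatch, anchor3)
                 if s.strand == "plus"]
    rev_sites = [s for s in find_primer_sites(template, rev, max_mismatch, anchor3)
                 if s.strand == "minus"]
    products: list[Amplicon] = []
    for fs in sorted(fwd_sites, key=lambda s: (s.start, s.end)):
        for rs in sorted(rev_sites, key=lambda s: (s.start, s.end)):
            if rs.start < fs.end:
                continue
            length = rs.end - fs.start
            if not (min_len <= length <= max_len):
                continue
            products.append(
                Amplicon(
                    template_id=template.id,
                    fwd_site=fs,
                    rev_site=rs,
                    residues=template.residues[fs.start:rs.end],
                    round=round_tag,
                )
            )
    return products


def _merge_two(
    cons: str, votes: list[dict[str, int]], frag: str,
    min_overlap: int, min_overlap_identity: float,
) -> tuple[str, list[dict[str, int]]] | None:
    """Merge a fragment into a growing consensus by best semi-global overlap.

    Returns the extended consensus and per-column vote tallies, or None when the
    aligned overlap is shorter than ``min_overlap`` or below the identity bound.
    Conflicting overlap columns are resolved by majority vote; ties become N.
    """
    aln = align_pair(
        SequenceRecord("cons", cons), SequenceRecord("frag", frag)
    )
    pairs = [(x, y) for x, y in zip(aln.aligned_a, aln.aligned_b)]
    overlap_cols = [(x, y) for x, y in pairs if x != "-" and y != "-"]
    if len(overlap_cols) < min_overlap:
        return None
    ident = 100.0 * sum(bases_intersect(x, y) for x, y in overlap_cols) / len(overlap_cols)
    if ident < min_overlap_identity:
        return None
    merged: list[dict[str, int]] = []
    ci = 0
    for x, y in pairs:
        if x != "-":
            col = votes[ci]
            ci += 1
        else:
            col = {}
        if y != "-":
            col = dict(col)
            col[y] = col.get(y, 0) + 1
        merged.append(col)
    out_votes = [c for c in merged if c]
    cons_chars = []
    for col in out_votes:
        top = max(col.values())
        winners = sorted(b for b, v in col.items() if v == top)
        cons_chars.append(winners[0] if len(winners) == 1 else "N")
    return "".join(cons_chars), out_votes


def merge_fragments(
    fragments: Sequence[tuple[str, str]],
    min_overlap: int = 50,
    min_overlap_identity: float = 99.0,
) -> ConsensusAssembly:
    """Assemble (id, sequence) fragments into one consensus by overlap merging."""
    if not fragments:
        raise UnmergeableFragmentsError("no fragments to merge")
    ids = tuple(fid for fid, _ in fragments)
    first = fragments[0][1]
    cons = first
    votes: list[dict[str, int]] = [{b: 1} for b in first]
    for fid, frag in fragments[1:]:
        res = _merge_two(cons, votes, frag, min_overlap, min_overlap_identity)
        if res is None:
            raise UnmergeableFragmentsError(
                f"fragments have no overlap of >= {min_overlap} columns at "
                f">= {min_overlap_identity}% identity: {list(ids)}"
            )
        cons, votes = res
    return ConsensusAssembly(fragment_ids=ids, residues=cons)


def nested_consensus(
    template: SequenceRecord,
    pcr1: tuple[PrimerRecord, PrimerRecord],
    pcr2_pairs: Sequence[tuple[PrimerRecord, PrimerRecord]],
    min_overlap: int = 50,
    min_overlap_identity: float = 99.0,
    pcr1_bounds: tuple[int, int] = (800, 2000),
    pcr2_bounds: tuple[int, int] = (200, 2000),
) -> ConsensusAssembly:
    """Two-round amplification followed by overlap-merge consensus assembly.

    Round one amplifies the (near) complete gene with the outer primer pair;
    round two re-amplifies each first-round product with every nested pair; the
    second-round fragments are then merged into a single consensus. Fragments
    are merged in template order (leftmost start first).
    """
    fwd1, rev1 = pcr1
    products1 = amplify(template, fwd1, rev1, *pcr1_bounds, round_tag="pcr1")
    fragments: list[tuple[int, str, str]] = []
    for pi, prod in enumerate(products1):
        prod_rec = SequenceRecord(f"{template.id}.p1.{pi}", prod.residues)
        for fwd2, rev2 in pcr2_pairs:
            for ai, amp in enumerate(
                amplify(prod_rec, fwd2, rev2, *pcr2_bounds, round_tag="pcr2")
            ):
                fid = f"{template.id}.{fwd2.name}-{rev2.name}.{pi}.{ai}"
                fragments.append(
                    (prod.fwd_site.start + amp.fwd_site.start, fid, amp.residues)
                )
    if not fragments:
        raise UnmergeableFragmentsError(
            f"no second-round products for template {template.id}"
        )
    fragments.sort(key=lambda t: (t[0], t[1]))
    return merge_fragments(
        [(fid, seq) for _, fid, seq in fragments],
        min_overlap=min_overlap,
        min_overlap_identity=min_overlap_identity,
    )


def sites_to_bed(sites: Sequence[PrimerSite], template_id: str, path) -> None:
    """Write primer sites as a BED-like TSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "template": template_id,
                "start": s.start,
                "end": s.end,
                "primer": s.primer_name,
                "strand": "+" if s.strand == "plus" else "-",
                "mismatches": s.mismatches,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)
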