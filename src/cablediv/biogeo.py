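"""Salinity classification and per-site diversity / co-occurrence summaries.

Sites are binned into the four salinity categories used for sediment habitats:
freshwater (S < 0.5), brackish (0.5 ≤ S < 30), marine (30 ≤ S ≤ 36) and
hypersaline (S > 36). Per-site composition tables report which species-level
clades and genus-level clusters co-occur where, how many sites harbour more than
one cluster, and which clades are "endemic" (found at a single site only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .seqio import SequenceRecord, SiteMetadata

FRESHWATER = "freshwater"
BRACKISH = "brackish"
MARINE = "marine"
HYPERSALINE = "hypersaline"

CATEGORIES = (FRESHWATER, BRACKISH, MARINE, HYPERSALINE)

#: Key used for records whose site cannot be resolved against the metadata.
UNSITED = "unsited"


def classify_salinity(s: float) -> str:
    """Bin a practical salinity into one of the four habitat categories.

    Boundaries are inclusive exactly as conventionally defined: 0.5 is brackish,
    30 and 36 are marine, anything above 36 is hypersaline.
    """
    if s < 0:
        raise ValueError(f"negative salinity: {s}")
    if s < 0.5:
        return FRESHWATER
    if s < 30.0:
        return BRACKISH
    if s <= 36.0:
        return MARINE
    return HYPERSALINE


@dataclass
class SiteComposition:
    site_id: str
    category: Optional[str]               # None for the unsited bucket
    clade_counts: dict[str, int] = field(default_factory=dict)
    cluster_set: set[str] = field(default_factory=set)

    @property
    def n_sequences(self) -> int:
        return sum(self.clade_counts.values())

    @property
    def n_clades(self) -> int:
        return len(self.clade_counts)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_set)


@dataclass
class BiogeoSummary:
    compositions: dict[str, SiteComposition]
    n_sites: int                       # sites with >= 1 resolvable record
    n_multi_cluster_sites: int         # >= 2 genus-level clusters
    n_multi_clade_sites: int           # >= 2 species-level clades
    n_rich_sites: int                  # >= min_rich_clades species-level clades
    min_rich_clades: int
    clades_per_site: dict[str, int]    # site -> number of clades present
    endemic_clades: list[str]          # clades found at exactly one site
    n_unsited_records: int

    def per_site_table(self) -> pd.DataFrame:
        rows = []
        for comp in self.compositions.values():
            rows.append(
                {
                    "site_id": comp.site_id,
                    "salinity_category": comp.category or "",
                    "n_sequences": comp.n_sequences,
                    "n_clades": comp.n_clades,
                    "n_clusters": comp.n_clusters,
                    "clusters": ",".join(sorted(comp.cluster_set)),
                }
            )
        return pd.DataFrame(rows).sort_values("site_id").reset_index(drop=True)

    def to_json(self, path=None) -> str:
        payload = {
            "n_sites": self.n_sites,
            "n_multi_cluster_sites": self.n_multi_cluster_sites,
            "n_multi_clade_sites": self.n_multi_clade_sites,
            "n_rich_sites": self.n_rich_sites,
            "min_rich_clades": self.min_rich_clades,
            "n_endemic_clades": len(self.endemic_clades),
            "endemic_clades": sorted(self.endemic_clades),
            "n_unsited_records": self.n_unsited_records,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def site_summary(
    assignments: pd.DataFrame,
    records: Sequence[SequenceRecord],
    metadata: Sequence[SiteMetadata],
    min_rich_clades: int = 4,
) -> BiogeoSummary:
    """Per-site clade/cluster composition and co-occurrence statistics.

    ``assignments`` is the record → clade → cluster table produced by the
    delineation stage (columns record_id, clade_id, cluster_id). Records whose
    site id does not resolve in the metadata are tallied in a separate
    "unsited" bucket rather than silently dropped, so sequence counts are
    conserved.
    """
    meta_by_id = {m.site_id: m for m in metadata}
    rec_by_id = {r.id: r for r in records}
    comps: dict[str, SiteComposition] = {}
    unsited = 0
    for _, row in assignments.iterrows():
        rec = rec_by_id.get(row["record_id"])
        if rec is None:
            continue
        site = rec.site_id if rec.site_id in meta_by_id else None
        if site is None:
            unsited += 1
            key, cat = UNSITED, None
        else:
            key, cat = site, classify_salinity(meta_by_id[site].salinity)
        comp = comps.setdefault(key, SiteComposition(site_id=key, category=cat))
        comp.clade_counts[row["clade_id"]] = comp.clade_counts.get(row["clade_id"], 0) + 1
        if row["cluster_id"]:
            comp.cluster_set.add(row["cluster_id"])

    real = {k: c for k, c in comps.items() if k != UNSITED}
    clade_sites: dict[str, set[str]] = {}
    for sid, comp in real.items():
        for cid in comp.clade_counts:
            clade_sites.setdefault(cid, set()).add(sid)
    endemic = sorted(cid for cid, sites in clade_sites.items() if len(sites) == 1)

    return BiogeoSummary(
        compositions=comps,
        n_sites=len(real),
        n_multi_cluster_sites=sum(1 for c in real.values() if c.n_clusters >= 2),
        n_multi_clade_sites=sum(1 for c in real.values() if c.n_clades >= 2),
        n_rich_sites=sum(1 for c in real.values() if c.n_clades >= min_rich_clades),
        min_rich_clades=min_rich_clades,
        clades_per_site={sid: c.n_clades for sid, c in real.items()},
        endemic_clades=endemic,
        n_unsited_records=unsited,
    )
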