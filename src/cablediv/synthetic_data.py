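"""Synthetic 16S datasets with the statistical structure the delineation assumes.

The generator emits a two-level genus/species radiation: a random root gene is
evolved down a genus → species → individual tree with per-branch substitution
counts calibrated so that realized pairwise identities straddle the two taxonomic
cutoffs (within species above 98.7%, between species of one genus between 94.5%
and 98.7%, between genera below 94.5%), plus an outgroup and optional off-clade
contaminants, short fragments and conserved-region violators. Primer annealing
windows (27F at the 5' end, 1492R at the 3' end, and internal family-specific
DSBB windows) are copied into every sequence verbatim and masked from mutation,
as are a set of internal conserved blocks that stand in for the conserved regions
of the real gene.

Realized identities are re-measured on the emitted records and the draw is
rejected and resampled (bounded attempts) when any pair violates its band, so
datasets are guaranteed to respect the separations the cutoffs require.

All randomness flows from a single integer seed through one generator stream;
the same spec and seed reproduce byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from . import identity as _identity
from .seqio import SequenceRecord, SiteMetadata, packaged_primers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}

#: Default divergence bands (pairwise substitution proportions). Chosen once to
#: straddle the 98.7% species and 94.5% genus cutoffs with at least one identity
#: point of margin on either side.
D_WITHIN_SPECIES = 0.005
D_BETWEEN_SPECIES = 0.025
D_BETWEEN_GENERA = 0.100
D_OFFCLADE = 0.18
D_OUTGROUP = 0.25

#: Species counts per genus-level cluster in the packaged survey-scale scenario
#: (90 species over six clusters), and how many of each cluster's species are
#: singletons (38 singletons in total; the deep-sea-like cluster carries most).
SURVEY_SPECIES_PER_GENUS = (14, 3, 1, 2, 35, 35)
SURVEY_SINGLETONS_PER_GENUS = (2, 1, 0, 1, 20, 14)


@dataclass(frozen=True)
class RadiationSpec:
    """Parameters of one synthetic radiation; defaults are the packaged
    survey-scale scenario (6 genera, 90 species, 38 singleton clades)."""

    seed: int = 0
    root_length: int = 1500
    n_genera: int = 6
    species_per_genus: tuple[int, ...] = SURVEY_SPECIES_PER_GENUS
    singletons_per_genus: tuple[int, ...] = SURVEY_SINGLETONS_PER_GENUS
    seqs_per_species_default: int = 2
    d_within_species: float = D_WITHIN_SPECIES
    d_between_species: float = D_BETWEEN_SPECIES
    d_between_genera: float = D_BETWEEN_GENERA
    d_offclade: float = D_OFFCLADE
    d_outgroup: float = D_OUTGROUP
    #: Fraction of unmasked sites that are evolutionarily variable. Substitutions
    #: and indels only ever hit variable sites, which are laid out as contiguous
    #: windows in the middle of each unmasked stretch — emulating the alternation
    #: of conserved regions and hypervariable regions (V1–V9) of the real gene
    #: that the conserved-region filter relies on.
    variable_fraction: float = 0.30
    indel_rate: float = 0.0
    n_offclade: int = 0
    n_short: int = 0
    n_conserved_violators: int = 0
    band_margin: float = 0.3      # identity points of slack demanded at each cutoff
    max_attempts: int = 100
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.species_per_genus) != self.n_genera:
            raise ValueError("species_per_genus length must equal n_genera")
        if len(self.singletons_per_genus) != self.n_genera:
            raise ValueError("singletons_per_genus length must equal n_genera")
        if not (
            self.d_within_species
            < (100 - 98.7) / 100
            < self.d_between_species
            < (100 - 94.5) / 100
            < self.d_between_genera
            < self.d_offclade
        ):
            raise ValueError("divergence bands must straddle the 98.7/94.5 cutoffs")
        for p in (self.d_within_species, self.d_between_species,
                  self.d_between_genera, self.d_offclade, self.indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("divergences and rates must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return int(sum(self.species_per_genus))

    @property
    def n_singletons(self) -> int:
        return int(sum(self.singletons_per_genus))


def survey_spec(seed: int = 0, **overrides) -> RadiationSpec:
    """The packaged scenario mirroring the published headline structure."""
    return RadiationSpec(seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Planted labels for every emitted record."""

    genus: dict[str, str]
    species: dict[str, str]
    artifact: dict[str, str]          # none | offclade | short | conserved_violation
    query_ids: list[str]              # one trusted reference per genus
    outgroup_id: str
    primer_windows: list[tuple[int, int, str]]
    conserved_mask: np.ndarray        # True where mutation is masked
    true_tree: Optional[dendropy.Tree] = None

    def in_clade_ids(self) -> list[str]:
        return [rid for rid, tag in self.artifact.items()
                if tag in ("none", "short", "conserved_violation")
                and rid != self.outgroup_id]


def _resolve_degenerate(seq: str) -> str:
    """Replace degenerate codes by the alphabetically first base they denote."""
    from .seqio import IUPAC_SETS

    return "".join(min(IUPAC_SETS[c]) for c in seq)


def _primer_layout(L: int) -> tuple[list[tuple[int, int, str]], np.ndarray]:
    """Primer windows and the full mutation mask (primers + conserved blocks)."""
    primers = {p.name: p for p in packaged_primers()}
    p27 = _resolve_degenerate(primers["27F"].sequence)
    p1492_rc = _identity.reverse_complement(_resolve_degenerate(primers["1492R"].sequence))
    p280 = _resolve_degenerate(primers["DSBB280wF"].sequence)
    p1297_rc = _identity.reverse_complement(
        _resolve_degenerate(primers["DSBB+1297R"].sequence)
    )
    win1297 = int(round(L * 1279 / 1500))
    windows = [
        (0, len(p27), "27F"),
        (int(round(L * 260 / 1500)), int(round(L * 260 / 1500)) + len(p280), "DSBB280wF"),
        (win1297, win1297 + len(p1297_rc), "DSBB+1297R"),
        (L - len(p1492_rc), L, "1492R"),
    ]
    mask = np.zeros(L, dtype=bool)
    for s, e, _ in windows:
        mask[s:e] = True
    # internal conserved blocks standing in for the gene's conserved regions
    block_len = max(10, L // 50)
    for frac in (0.07, 0.21, 0.34, 0.43, 0.54, 0.64, 0.74, 0.90):
        s = int(L * frac)
        mask[s:s + block_len] = True
    return windows, mask


def _variable_sites(mask: np.ndarray, fraction: float) -> np.ndarray:
    """Contiguous variable windows centred in each unmasked stretch.

    Keeps invariant margins flanking every masked block, so conserved regions
    form long uninterrupted runs as in the real gene.
    """
    L = mask.size
    variable: list[np.ndarray] = []
    i = 0
    while i < L:
        if not mask[i]:
            j = i
            while j < L and not mask[j]:
                j += 1
            w = int(round((j - i) * fraction))
            lo = i + (j - i - w) // 2
            if w > 0:
                variable.append(np.arange(lo, lo + w))
            i = j
        else:
            i += 1
    if not variable:
        raise ValueError("no variable sites available")
    return np.concatenate(variable)


def _planted_sequences(L: int, windows, rng) -> np.ndarray:
    """Random root sequence with the primer windows planted verbatim."""
    primers = {p.name: p for p in packaged_primers()}
    root = rng.integers(0, 4, size=L).astype(np.uint8)
    texts = {
        "27F": _resolve_degenerate(primers["27F"].sequence),
        "DSBB280wF": _resolve_degenerate(primers["DSBB280wF"].sequence),
        "DSBB+1297R": _identity.reverse_complement(
            _resolve_degenerate(primers["DSBB+1297R"].sequence)
        ),
        "1492R": _identity.reverse_complement(
            _resolve_degenerate(primers["1492R"].sequence)
        ),
    }
    for s, e, name in windows:
        root[s:e] = [_CODE[c] for c in texts[name]]
    return root


def _mutate(seq: np.ndarray, n_sub: int, free_sites: np.ndarray, rng) -> np.ndarray:
    """Copy with ``n_sub`` substitutions at distinct unmasked sites."""
    out = seq.copy()
    if n_sub <= 0:
        return out
    sites = rng.choice(free_sites, size=min(n_sub, free_sites.size), replace=False)
    shifts = rng.integers(1, 4, size=sites.size).astype(np.uint8)
    out[sites] = (out[sites] + shifts) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def _apply_indels(seq: np.ndarray, rate: float, free: np.ndarray, rng) -> np.ndarray:
    """Scatter single-event indels (geometric length, mean 3) at unmasked sites."""
    if rate <= 0:
        return seq
    n_events = rng.binomial(free.size, rate)
    if n_events == 0:
        return seq
    out = seq
    for _ in range(n_events):
        pos = int(rng.choice(free))
        length = int(rng.geometric(1.0 / 3.0))
        if rng.random() < 0.5:  # deletion
            out = np.concatenate([out[:pos], out[pos + length:]])
        else:                   # insertion
            ins = rng.integers(0, 4, size=length).astype(np.uint8)
            out = np.concatenate([out[:pos], ins, out[pos:]])
    return out


def _band_check(records, truth: GroundTruth, spec: RadiationSpec) -> bool:
    """True when every realized pairwise identity respects its divergence band."""
    in_clade = [r for r in records if truth.artifact.get(r.id) == "none"
                and r.id != truth.outgroup_id]
    if len(in_clade) < 2:
        return True
    im = _identity.identity_matrix(in_clade, method="fast")
    m = spec.band_margin
    lo_species, hi_genus = 98.7, 94.5
    for i, a in enumerate(in_clade):
        for j in range(i + 1, len(in_clade)):
            b = in_clade[j]
            pid = im.values[i, j]
            if truth.species[a.id] == truth.species[b.id]:
                if pid < lo_species + m:
                    return False
            elif truth.genus[a.id] == truth.genus[b.id]:
                if not (hi_genus + m <= pid <= lo_species - m):
                    return False
            else:
                if pid > hi_genus - m:
                    return False
    return True


def _build_true_tree(spec: RadiationSpec, ids_by_species: dict[tuple[int, int], list[str]],
                     outgroup_id: str) -> dendropy.Tree:
    b_ind = spec.d_within_species / 2
    b_sp = (spec.d_between_species - spec.d_within_species) / 2
    b_gen = (spec.d_between_genera - spec.d_between_species) / 2
    genus_parts = []
    for gi in range(spec.n_genera):
        sp_parts = []
        for si in range(spec.species_per_genus[gi]):
            tips = ids_by_species[(gi, si)]
            if len(tips) == 1:
                sp_parts.append(f"{tips[0]}:{b_ind + b_sp}")
            else:
                inner = ",".join(f"{t}:{b_ind}" for t in tips)
                sp_parts.append(f"({inner}):{b_sp}")
        if len(sp_parts) == 1:
            genus_parts.append(f"{sp_parts[0].rsplit(':', 1)[0]}:"
                               f"{float(sp_parts[0].rsplit(':', 1)[1]) + b_gen}")
        else:
            genus_parts.append(f"({','.join(sp_parts)}):{b_gen}")
    ingroup = f"({','.join(genus_parts)})" if len(genus_parts) > 1 else genus_parts[0]
    newick = f"({ingroup}:0.0,{outgroup_id}:{spec.d_outgroup});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def simulate_radiation(spec: RadiationSpec) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate the radiation described by ``spec``; deterministic given its seed.

    Raises ``RuntimeError`` when the divergence bands cannot be realised within
    the bounded number of resampling attempts.
    """
    L = spec.root_length
    windows, mask = _primer_layout(L)
    free = np.flatnonzero(~mask)
    b_ind = int(round(spec.d_within_species / 2 * L))
    b_sp = int(round((spec.d_between_species - spec.d_within_species) / 2 * L))
    b_gen = int(round((spec.d_between_genera - spec.d_between_species) / 2 * L))
    b_off = int(round((spec.d_offclade - spec.d_between_genera / 2) * L))
    b_out = int(round((spec.d_outgroup - spec.d_between_genera / 2) * L))

    variable = _variable_sites(mask, spec.variable_fraction)
    master = np.random.default_rng(spec.seed)
    for attempt in range(spec.max_attempts):
        rng = np.random.default_rng(master.integers(0, 2**31))
        root = _planted_sequences(L, windows, rng)
        records: list[SequenceRecord] = []
        genus_of: dict[str, str] = {}
        species_of: dict[str, str] = {}
        artifact: dict[str, str] = {}
        query_ids: list[str] = []
        ids_by_species: dict[tuple[int, int], list[str]] = {}
        for gi in range(spec.n_genera):
            genus_anc = _mutate(root, b_gen, variable, rng)
            glabel = f"G{gi + 1}"
            n_single = spec.singletons_per_genus[gi]
            for si in range(spec.species_per_genus[gi]):
                sp_anc = _mutate(genus_anc, b_sp, variable, rng)
                slabel = f"{glabel}.S{si + 1:02d}"
                n_seqs = 1 if si < n_single else spec.seqs_per_species_default
                tip_ids = []
                for k in range(n_seqs):
                    tip = _mutate(sp_anc, b_ind, variable, rng)
                    tip = _apply_indels(tip, spec.indel_rate, variable, rng)
                    rid = f"g{gi + 1}_s{si + 1:02d}_i{k + 1}"
                    records.append(
                        SequenceRecord(rid, _to_str(tip), source=spec.source)
                    )
                    genus_of[rid] = glabel
                    species_of[rid] = slabel
                    artifact[rid] = "none"
                    tip_ids.append(rid)
                ids_by_species[(gi, si)] = tip_ids
            # trusted reference: first individual of the genus's last species
            # (multi-sequence species where available)
            query_ids.append(ids_by_species[(gi, spec.species_per_genus[gi] - 1)][0])
        for k in range(spec.n_offclade):
            tip = _mutate(root, b_off, variable, rng)
            rid = f"offclade_{k + 1}"
            records.append(SequenceRecord(rid, _to_str(tip), source=spec.source))
            genus_of[rid] = species_of[rid] = "OFFCLADE"
            artifact[rid] = "offclade"
        out_tip = _mutate(root, b_out, variable, rng)
        outgroup_id = "outgroup"
        records.append(SequenceRecord(outgroup_id, _to_str(out_tip), source=spec.source))
        genus_of[outgroup_id] = species_of[outgroup_id] = "OUTGROUP"
        artifact[outgroup_id] = "outgroup"

        truth = GroundTruth(
            genus=genus_of, species=species_of, artifact=artifact,
            query_ids=query_ids, outgroup_id=outgroup_id,
            primer_windows=windows, conserved_mask=mask,
            true_tree=_build_true_tree(spec, ids_by_species, outgroup_id),
        )
        if _band_check(records, truth, spec):
            return records, truth
    raise RuntimeError(
        f"divergence bands unattainable after {spec.max_attempts} attempts; "
        "widen the bands or enlarge the sequence"
    )


def inject_artifacts(
    records: Sequence[SequenceRecord],
    truth: GroundTruth,
    spec: RadiationSpec,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Plant curation artifacts into clean in-clade records.

    Truncates ``n_short`` records to random lengths in [300, 799] and deletes a
    20 bp window spanning a conserved block from ``n_conserved_violators``
    records; ground truth is tagged accordingly. Trusted queries and the
    outgroup are never touched.
    """
    n_art = spec.n_short + spec.n_conserved_violators
    if n_art == 0:
        return list(records), truth
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(0, 2**31) + 1)
    eligible = [r.id for r in records
                if truth.artifact.get(r.id) == "none" and r.id not in truth.query_ids]
    if n_art > len(eligible):
        raise ValueError(
            f"requested {n_art} artifact records but only {len(eligible)} eligible"
        )
    victims = list(rng.choice(eligible, size=n_art, replace=False))
    short_ids = set(victims[:spec.n_short])
    viol_ids = set(victims[spec.n_short:])
    # deletion window: interior of an internal conserved block
    mask = truth.conserved_mask
    runs = []
    in_run = False
    for i, m in enumerate(mask):
        if m and not in_run:
            start, in_run = i, True
        elif not m and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(mask)))
    internal = [r for r in runs if r[0] > 50 and r[1] < len(mask) - 50 and r[1] - r[0] >= 15]
    out: list[SequenceRecord] = []
    artifact = dict(truth.artifact)
    for rec in records:
        if rec.id in short_ids:
            L = int(rng.integers(300, 800))
            out.append(dataclasses.replace(rec, residues=rec.residues[:L]))
            artifact[rec.id] = "short"
        elif rec.id in viol_ids:
            s, e = internal[int(rng.integers(0, len(internal)))]
            cut = s + 3
            out.append(dataclasses.replace(
                rec, residues=rec.residues[:cut] + rec.residues[cut + 20:]
            ))
            artifact[rec.id] = "conserved_violation"
        else:
            out.append(rec)
    new_truth = dataclasses.replace(truth, artifact=artifact)
    return out, new_truth


# ---------------------------------------------------------------------------
# Site metadata
# ---------------------------------------------------------------------------

#: Home salinity category per genus in the survey-scale scenario: one freshwater
#: genus, two brackish ones, two marine ones and one broadly tolerant genus.
_GENUS_HOME = ("freshwater", "brackish", "brackish", "marine", "marine", "broad")

_CATEGORY_SALINITY = {
    "freshwater": (0.05, 0.45),
    "brackish": (2.0, 25.0),
    "marine": (30.0, 36.0),
    "hypersaline": (37.0, 45.0),
}


def make_metadata(
    spec: RadiationSpec,
    truth: GroundTruth,
    scenario: str = "survey",
) -> tuple[list[SiteMetadata], dict[str, str]]:
    """Synthesise sampling sites and assign every in-clade record to one.

    Sites span all four salinity categories. The ``survey`` scenario places
    each genus in its home category, keeps most species endemic to a single
    site, and plants one brackish site hosting species from three different
    genus-level clusters (the observed co-occurrence pattern at low-sulfide
    estuarine sites). Deterministic given the spec seed.
    """
    if scenario not in ("survey", "uniform"):
        raise ValueError(f"unknown metadata scenario {scenario!r}")
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(0, 2**31) + 2)
    layout = [("F", "freshwater", 3), ("B", "brackish", 4),
              ("M", "marine", 4), ("H", "hypersaline", 1)]
    sites: list[SiteMetadata] = []
    by_cat: dict[str, list[str]] = {}
    for prefix, cat, n in layout:
        lo, hi = _CATEGORY_SALINITY[cat]
        for k in range(n):
            sid = f"{prefix}{k + 1}"
            sites.append(
                SiteMetadata(
                    site_id=sid,
                    location_name=f"Synthetic {cat} site {k + 1}",
                    latitude=float(np.round(rng.uniform(-60, 60), 4)),
                    longitude=float(np.round(rng.uniform(-180, 180), 4)),
                    habitat=f"synthetic {cat} sediment",
                    salinity=float(np.round(rng.uniform(lo, hi), 1)),
                    water_depth_m=float(np.round(rng.uniform(0.3, 50), 1)),
                    sulfide_class=str(rng.choice(["low", "high"])),
                )
            )
            by_cat.setdefault(cat, []).append(sid)

    # species -> site
    species_ids = sorted({truth.species[rid] for rid in truth.in_clade_ids()})
    genus_idx = {f"G{i + 1}": i for i in range(spec.n_genera)}
    species_site: dict[str, str] = {}
    counters: dict[str, int] = {}
    hub = by_cat["brackish"][0]  # the planted multi-cluster site
    for sp in species_ids:
        g = sp.split(".")[0]
        gi = genus_idx.get(g, 0)
        home = _GENUS_HOME[gi] if scenario == "survey" and gi < len(_GENUS_HOME) \
            else "marine"
        if home == "broad":
            pool = by_cat["marine"] + by_cat["brackish"] + by_cat["hypersaline"]
        else:
            pool = by_cat[home]
        k = counters.get(g, 0)
        counters[g] = k + 1
        # first species of the two brackish genera and of the broad genus meet
        # at the hub site, giving >= 3 clusters at one site
        if scenario == "survey" and k == 0 and gi in (1, 2, 5):
            species_site[sp] = hub
        else:
            species_site[sp] = pool[k % len(pool)]
    assignment = {
        rid: species_site[truth.species[rid]] for rid in truth.in_clade_ids()
    }
    return sites, assignment


def attach_sites(
    records: Sequence[SequenceRecord], assignment: dict[str, str]
) -> list[SequenceRecord]:
    """Copies of the records with ``site_id`` filled from an assignment map."""
    return [
        dataclasses.replace(r, site_id=assignment.get(r.id, r.site_id))
        for r in records
    ]


def survey_dataset(
    seed: int = 0, **overrides
) -> tuple[list[SequenceRecord], list[SiteMetadata], GroundTruth, RadiationSpec]:
    """One-call convenience: records (with sites), metadata, truth, spec."""
    spec = survey_spec(seed=seed, **overrides)
    records, truth = simulate_radiation(spec)
    records, truth = inject_artifacts(records, truth, spec)
    sites, assignment = make_metadata(spec, truth)
    return attach_sites(records, assignment), sites, truth, spec
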