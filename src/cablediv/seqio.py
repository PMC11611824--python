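"""Readers/writers for the standard formats the pipeline touches, plus core record types.

FASTA goes through :mod:`Bio.SeqIO`, Newick through :mod:`dendropy`, tabular metadata
through :mod:`pandas`. All residues are normalised to uppercase IUPAC DNA on input
(``U`` is mapped to ``T``), so every downstream module can assume a single alphabet.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Valid IUPAC nucleotide one-letter codes (no gap characters).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: Map from IUPAC code to the set of unambiguous bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SOURCES = ("enrichment", "literature", "silva", "genbank", "synthetic")
SULFIDE_CLASSES = ("low", "high", "unknown")

_METADATA_COLUMNS = [
    "site_id", "location_name", "latitude", "longitude",
    "habitat", "salinity", "water_depth_m", "sulfide_class",
]


class SeqFormatError(ValueError):
    """Raised for malformed sequence, metadata or tree input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single 16S rRNA gene sequence with provenance.

    ``source`` tags where the sequence came from (laboratory enrichment,
    literature compilation, SILVA, GenBank or the synthetic generator);
    ``site_id`` optionally links the record to a sampling site.
    """

    id: str
    residues: str
    source: str = "synthetic"
    site_id: Optional[str] = None
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqFormatError(f"invalid record id: {self.id!r}")
        if self.source not in SOURCES:
            raise SeqFormatError(f"unknown source {self.source!r} for record {self.id}")
        if len(self.residues) < 1:
            raise SeqFormatError(f"record {self.id} has an empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in IUPAC_CODES:
                raise SeqFormatError(
                    f"record {self.id}: non-IUPAC character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def ungapped_length(record: SequenceRecord) -> int:
    """Length of the record's residues (records never store gaps)."""
    return len(record.residues)


@dataclass(frozen=True)
class SiteMetadata:
    """One sampling site: coordinates, habitat, salinity, depth, sulfide class."""

    site_id: str
    location_name: str
    latitude: float
    longitude: float
    habitat: str
    salinity: float
    water_depth_m: float
    sulfide_class: str = "unknown"

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise SeqFormatError(f"site {self.site_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise SeqFormatError(f"site {self.site_id}: longitude {self.longitude} out of range")
        if self.salinity < 0:
            raise SeqFormatError(f"site {self.site_id}: negative salinity {self.salinity}")
        if self.water_depth_m < 0:
            raise SeqFormatError(f"site {self.site_id}: negative water depth")
        if self.sulfide_class not in SULFIDE_CLASSES:
            raise SeqFormatError(
                f"site {self.site_id}: sulfide class must be one of {SULFIDE_CLASSES}"
            )


@dataclass(frozen=True)
class PrimerRecord:
    """A PCR primer written 5'→3'; may contain degenerate IUPAC codes."""

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqFormatError(f"primer {self.name}: empty sequence")
        for pos, ch in enumerate(self.sequence):
            if ch not in IUPAC_CODES:
                raise SeqFormatError(
                    f"primer {self.name}: non-IUPAC character {ch!r} at position {pos}"
                )
        if self.orientation not in ("forward", "reverse"):
            raise SeqFormatError(f"primer {self.name}: bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_residues(raw: str) -> str:
    """Uppercase and map RNA ``U`` to ``T``."""
    return raw.upper().replace("U", "T")


def read_fasta(path, source: str = "synthetic", site_id: Optional[str] = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Duplicate ids and non-IUPAC characters are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqFormatError(f"duplicate record id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=normalize_residues(str(rec.seq)),
                source=source,
                site_id=site_id,
                description=rec.description if rec.description != rec.id else None,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_metadata(path) -> list[SiteMetadata]:
    """Read a tab-separated site-metadata table (one row per sampling site).

    The header must contain all declared columns; numeric fields are parsed with
    ``.`` as decimal separator. Unknown sulfide class should be written "unknown".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SeqFormatError(f"metadata file {path}: missing required column(s) {missing}")
    sites: list[SiteMetadata] = []
    for i, row in df.iterrows():
        try:
            sites.append(
                SiteMetadata(
                    site_id=row["site_id"],
                    location_name=row["location_name"],
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    habitat=row["habitat"],
                    salinity=float(row["salinity"]),
                    water_depth_m=float(row["water_depth_m"]),
                    sulfide_class=row["sulfide_class"] or "unknown",
                )
            )
        except ValueError as exc:
            raise SeqFormatError(f"metadata file {path}, data row {i + 1}: {exc}") from exc
    return sites


def write_metadata(sites: Iterable[SiteMetadata], path) -> None:
    pd.DataFrame([s.__dict__ for s in sites], columns=_METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_primers(path) -> list[PrimerRecord]:
    """Read a primer table (TSV: name, sequence, orientation)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("name", "sequence", "orientation"):
        if col not in df.columns:
            raise SeqFormatError(f"primer file {path}: missing required column {col!r}")
    return [
        PrimerRecord(row["name"], normalize_residues(row["sequence"]), row["orientation"])
        for _, row in df.iterrows()
    ]


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("cablediv").joinpath("data").joinpath(name)))


def packaged_sites() -> list[SiteMetadata]:
    """The packaged sampling-site table of the ten enrichment sites."""
    return read_metadata(_data_path("enrichment_sites.tsv"))


def packaged_primers() -> list[PrimerRecord]:
    """The packaged nested-PCR primer set (universal + Desulfobulbaceae-specific)."""
    return read_primers(_data_path("nested_pcr_primers.tsv"))


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(source) -> dendropy.Tree:
    """Parse a Newick tree from a string or file path; leaf labels must be unique."""
    text = source
    p = Path(str(source))
    if "\n" not in str(source) and p.exists():
        text = p.read_text()
    try:
        tree = dendropy.Tree.get(
            data=str(text), schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise SeqFormatError(f"invalid Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise SeqFormatError(f"duplicate leaf labels in Newick input: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialise a tree to Newick; writes to ``path`` when given, returns the string."""
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True)
    if path is not None:
        Path(str(path)).write_text(text)
    return text
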