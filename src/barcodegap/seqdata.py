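"""Aligned sequence data, species metadata, and alignment-level statistics.

The central container is :class:`LocusAlignment`, an immutable equal-length
gapped nucleotide alignment for one barcode locus (ITS, matK, rbcL,
trnH-psbA or similar), keyed by accession identifiers.  Accession-level
metadata (species assignment, collection region, GPS coordinates) lives in
:class:`SpeciesMap`.  All downstream analyses — distance partitioning, tree
building, diagnostic-character discovery — consume these two objects.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LocusAlignment",
    "SpeciesRecord",
    "SpeciesMap",
    "SiteStats",
    "Haplotype",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "site_statistics",
    "collapse_haplotypes",
    "check_58s_motif",
    "concatenate_loci",
]

# Unambiguous nucleotide states; everything else (N, R, Y, ... and '-') is
# treated as missing when counting variation.
_CANONICAL = frozenset("ACGT")
_IUPAC = frozenset("ACGTUNRYSWKMBDHV-")

#: 5.8S motif diagnostic of plant nuclear ribosomal ITS sequences.
PLANT_58S_MOTIF = "GAATTGCAGAATCC"
#: Variant of the motif generally found in fungi (contamination signal).
FUNGAL_58S_MOTIF = "GAATTGCAGAATTC"


class AlignmentError(ValueError):
    """Raised when sequences do not form a valid equal-length alignment."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the IUPAC set."""


@dataclass(frozen=True)
class LocusAlignment:
    """An equal-length gapped nucleotide alignment for one locus.

    Parameters
    ----------
    locus_name:
        Name of the barcode locus (e.g. ``"ITS"``).
    ids:
        Accession identifiers, unique, in file order.
    seqs:
        Upper-case sequences over ``ACGTUN``, IUPAC ambiguity codes and
        ``-``; all of identical length.
    """

    locus_name: str
    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    #: Original column indices (1-based) retained through column filtering
    #: such as complete deletion; ``None`` means the identity mapping.
    column_origin: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs length mismatch")
        if len(self.ids) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = [i for i in self.ids if list(self.ids).count(i) > 1]
            raise AlignmentError(f"duplicate accession ids: {sorted(set(dupes))}")
        length = len(self.seqs[0])
        if length < 1:
            raise AlignmentError("zero-length alignment")
        for acc, s in zip(self.ids, self.seqs):
            if len(s) != length:
                raise AlignmentError(
                    f"sequence length mismatch for {acc}: {len(s)} != {length}"
                )
            bad = set(s) - _IUPAC
            if bad:
                raise AlphabetError(f"illegal characters in {acc}: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def sequence(self, accession: str) -> str:
        return self.seqs[self.ids.index(accession)]

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n, length) array of single characters."""
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype="S1"
        ).reshape(self.n, self.length).astype("U1")

    def select_columns(self, cols: Sequence[int]) -> "LocusAlignment":
        """Return a sub-alignment keeping columns ``cols`` (0-based, in order)."""
        cols = list(cols)
        if not cols:
            raise AlignmentError("no columns selected")
        origin = self.column_origin or tuple(range(1, self.length + 1))
        seqs = tuple("".join(s[c] for c in cols) for s in self.seqs)
        return LocusAlignment(
            self.locus_name, self.ids, seqs, tuple(origin[c] for c in cols)
        )

    def subset(self, accessions: Iterable[str]) -> "LocusAlignment":
        """Return a sub-alignment restricted to ``accessions`` (given order)."""
        accessions = list(accessions)
        seqs = tuple(self.sequence(a) for a in accessions)
        return LocusAlignment(self.locus_name, tuple(accessions), seqs, self.column_origin)


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    region: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    section: str | None = None


class SpeciesMap:
    """Accession → (species, region, GPS, section) lookup table."""

    def __init__(self, entries: Mapping[str, SpeciesRecord]):
        for acc, rec in entries.items():
            if not rec.species:
                raise ValueError(f"empty species name for accession {acc}")
        self._entries = dict(entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, accession: str) -> SpeciesRecord:
        try:
            return self._entries[accession]
        except KeyError:
            raise KeyError(f"accession {accession!r} missing from species map") from None

    def accessions(self) -> list[str]:
        return list(self._entries)

    def species_of(self, accession: str) -> str:
        return self[accession].species

    def species_names(self, accessions: Iterable[str] | None = None) -> list[str]:
        """Distinct species names, in first-seen order."""
        accs = list(accessions) if accessions is not None else self.accessions()
        seen: dict[str, None] = {}
        for a in accs:
            seen.setdefault(self[a].species, None)
        return list(seen)

    def members(self, species: str, accessions: Iterable[str] | None = None) -> list[str]:
        accs = list(accessions) if accessions is not None else self.accessions()
        return [a for a in accs if self[a].species == species]

    def validate_alignment(self, aln: LocusAlignment) -> None:
        missing = [a for a in aln.ids if a not in self]
        if missing:
            raise KeyError(f"accessions missing from species map: {missing}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpeciesMap":
        entries = {}
        for _, row in df.iterrows():
            lat = row.get("lat")
            lon = row.get("lon")
            entries[str(row["accession_id"])] = SpeciesRecord(
                species=str(row["species"]),
                region=None if pd.isna(row.get("region")) else str(row["region"]),
                latitude=None if pd.isna(lat) else float(lat),
                longitude=None if pd.isna(lon) else float(lon),
                section=None if pd.isna(row.get("section")) else str(row["section"]),
            )
        return cls(entries)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpeciesMap":
        """Read a species map from CSV/TSV with columns
        ``accession_id, species[, region, lat, lon, section]``."""
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accession_id": acc,
                "species": r.species,
                "region": r.region,
                "lat": r.latitude,
                "lon": r.longitude,
                "section": r.section,
            }
            for acc, r in self._entries.items()
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SiteStats:
    """Alignment-level variability summary.

    ``pct_variable`` and ``pct_pic`` are percentages of total alignment
    columns; ``mean_length`` averages ungapped (biological) sequence lengths.
    """

    n_sequences: int
    mean_length: float
    n_variable: int
    n_parsimony_informative: int
    pct_variable: float
    pct_pic: float


@dataclass(frozen=True)
class Haplotype:
    sequence: str
    accessions: tuple[str, ...]
    species: frozenset[str]


def read_aligned_fasta(path: str | Path | io.TextIOBase, locus_name: str) -> LocusAlignment:
    """Read an aligned multi-FASTA file into a :class:`LocusAlignment`.

    The accession id is the first whitespace-delimited token of each header.
    All records must have identical length.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return LocusAlignment(locus_name, ids, seqs)


def write_aligned_fasta(aln: LocusAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=a, description="") for a, s in zip(aln.ids, aln.seqs)]
    SeqIO.write(records, str(path), "fasta")


def _column_state_counts(col: np.ndarray) -> dict[str, int]:
    states, counts = np.unique(col, return_counts=True)
    return {s: int(c) for s, c in zip(states, counts) if s in _CANONICAL}


def site_statistics(aln: LocusAlignment) -> SiteStats:
    """Per-column variability statistics.

    A column is *variable* if at least two distinct unambiguous states
    (A/C/G/T) occur; *parsimony informative* if at least two states each
    occur in at least two sequences.  Gaps and ambiguity codes are treated
    as missing.
    """
    if aln.n < 2:
        raise AlignmentError("site statistics need at least 2 sequences")
    arr = aln.to_array()
    n_variable = 0
    n_pic = 0
    for j in range(aln.length):
        counts = _column_state_counts(arr[:, j])
        if len(counts) >= 2:
            n_variable += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                n_pic += 1
    ungapped = [len(s.replace("-", "")) for s in aln.seqs]
    return SiteStats(
        n_sequences=aln.n,
        mean_length=float(np.mean(ungapped)),
        n_variable=n_variable,
        n_parsimony_informative=n_pic,
        pct_variable=100.0 * n_variable / aln.length,
        pct_pic=100.0 * n_pic / aln.length,
    )


def collapse_haplotypes(aln: LocusAlignment, species: SpeciesMap) -> list[Haplotype]:
    """Group accessions sharing identical (case-folded) aligned sequences.

    Returns haplotypes in order of first occurrence; every accession belongs
    to exactly one group.  Haplotypes shared between species (the ``species``
    set having >1 member) are direct evidence against barcode-based
    discrimination.
    """
    species.validate_alignment(aln)
    groups: dict[str, list[str]] = {}
    for acc, seq in zip(aln.ids, aln.seqs):
        groups.setdefault(seq.upper(), []).append(acc)
    return [
        Haplotype(seq, tuple(accs), frozenset(species.species_of(a) for a in accs))
        for seq, accs in groups.items()
    ]


def check_58s_motif(sequence: str) -> str:
    """Classify a sequence by its 5.8S rDNA motif.

    Returns ``"plant"`` if the angiosperm motif ``GAATTGCAGAATCC`` is present
    (forward strand, gaps removed), ``"fungal_variant"`` if only the fungal
    variant ``GAATTGCAGAATTC`` is present, else ``"absent"``.  Used as a
    pass/fail screen against fungal contamination of ITS amplicons; when both
    motifs occur, the plant call takes precedence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper().replace("-", "")
    if PLANT_58S_MOTIF in s:
        return "plant"
    if FUNGAL_58S_MOTIF in s:
        return "fungal_variant"
    return "absent"


def concatenate_loci(
    alns: Sequence[LocusAlignment],
    species: SpeciesMap,
    min_loci: int | None = None,
) -> tuple[LocusAlignment, dict[str, tuple[int, int]]]:
    """Concatenate loci over the accessions present in every input locus.

    Multilocus barcode analysis restricts to accessions sequenced at all
    loci, concatenating their aligned sequences in the given locus order.

    Returns
    -------
    (alignment, partitions):
        The concatenated alignment (name joins input names with ``+``) and a
        dict mapping locus name to its half-open 0-based column interval.
    """
    if len(alns) < 2:
        raise AlignmentError("concatenation needs at least 2 loci")
    common = [a for a in alns[0].ids if all(a in aln.ids for aln in alns[1:])]
    if not common:
        raise AlignmentError("no accession present in all loci")
    for aln in alns:
        species.validate_alignment(aln)
    name = "+".join(a.locus_name for a in alns)
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for aln in alns:
        partitions[aln.locus_name] = (offset, offset + aln.length)
        offset += aln.length
    seqs = tuple(
        "".join(aln.sequence(acc) for aln in alns) for acc in common
    )
    return LocusAlignment(name, tuple(common), seqs), partitions
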