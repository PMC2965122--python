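"""Character-based species identification.

A *simple* diagnostic character is a nucleotide state at a single position
fixed in all accessions of one species and absent from every other
accession at that position.  A *compound* character is a combination of
states at two or more positions, each individually shared with other
species, whose joint pattern occurs only in the target species.  Positions
are reported in the coordinates of a designated reference sequence aligned
with the data (e.g. position 1 = start of ITS1, or the first base of a
coding region's start codon), so characters are portable across studies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .seqdata import LocusAlignment, SpeciesMap

__all__ = [
    "ReferencePositionMap",
    "DiagnosticCharacter",
    "map_to_reference",
    "find_simple_diagnostics",
    "find_compound_diagnostics",
    "verify_character",
]

logger = logging.getLogger(__name__)

_STATES = frozenset("ACGT")


@dataclass(frozen=True)
class ReferencePositionMap:
    """Bidirectional map between alignment columns and reference positions.

    ``col_to_ref[j]`` gives the 1-based reference position of 0-based
    alignment column ``j``, or ``None`` where the reference has a gap or
    lies before the coordinate origin.
    """

    reference_id: str
    col_to_ref: tuple[int | None, ...]

    def ref_to_col(self, position: int) -> int:
        for j, p in enumerate(self.col_to_ref):
            if p == position:
                return j
        raise KeyError(f"reference position {position} not present in alignment")


@dataclass(frozen=True)
class DiagnosticCharacter:
    """A species-diagnostic nucleotide pattern.

    ``sites`` holds ``(reference position, state)`` pairs — one pair for a
    simple character, two or more for a compound one.  ``support`` is the
    number of species accessions carrying the full pattern;
    ``n_missing_elsewhere`` counts non-member accessions with missing data
    at one or more of the sites (they cannot be confirmed to lack it).
    """

    species: str
    kind: str  # "simple" | "compound"
    sites: tuple[tuple[int, str], ...]
    support: int
    n_missing_elsewhere: int = 0

    def format_sites(self) -> str:
        return ";".join(f"{p}-{s}" for p, s in self.sites)


def map_to_reference(
    aln: LocusAlignment, reference_id: str, origin_offset: int = 1
) -> ReferencePositionMap:
    """Number alignment columns by the reference sequence's coordinates.

    ``origin_offset`` is the 1-based position *within the ungapped
    reference* that becomes coordinate 1 (e.g. the first base of ITS1 when
    the reference includes flanking sequence).  Columns where the reference
    has a gap, or that precede the origin, carry no coordinate.
    """
    if reference_id not in aln.ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    ref = aln.sequence(reference_id)
    ungapped_len = len(ref.replace("-", ""))
    if not (1 <= origin_offset <= ungapped_len):
        raise ValueError(
            f"origin_offset {origin_offset} outside reference length {ungapped_len}"
        )
    col_to_ref: list[int | None] = []
    ref_pos = 0  # 1-based position in ungapped reference
    for c in ref:
        if c == "-":
            col_to_ref.append(None)
        else:
            ref_pos += 1
            coord = ref_pos - origin_offset + 1
            col_to_ref.append(coord if coord >= 1 else None)
    return ReferencePositionMap(reference_id, tuple(col_to_ref))


def _species_fixed_state(
    aln: LocusAlignment, members: list[str], col: int
) -> str | None:
    """The single unambiguous state shared by all member accessions at a
    column, or None if any member is missing/ambiguous or states differ."""
    states = {aln.sequence(a)[col] for a in members}
    if len(states) == 1:
        (s,) = states
        if s in _STATES:
            return s
    return None


def find_simple_diagnostics(
    aln: LocusAlignment,
    species_map: SpeciesMap,
    refmap: ReferencePositionMap,
    min_accessions: int = 3,
) -> list[DiagnosticCharacter]:
    """Single-position diagnostic characters for every qualifying species.

    Only species with at least ``min_accessions`` accessions are scanned
    (fixation within a species is not credible on fewer).  A position
    qualifies when all member accessions share one unambiguous state and no
    non-member accession shows that state there; non-members with a gap or
    ambiguity at the position do not block the character but are counted in
    ``n_missing_elsewhere``.  Positions lacking a reference coordinate
    (reference gap) are skipped.
    """
    species_map.validate_alignment(aln)
    out: list[DiagnosticCharacter] = []
    data_ids = [a for a in aln.ids if a != refmap.reference_id]
    for sp in species_map.species_names(data_ids):
        members = species_map.members(sp, data_ids)
        if len(members) < min_accessions:
            logger.info("species %s skipped: %d < %d accessions", sp, len(members), min_accessions)
            continue
        others = [a for a in data_ids if a not in members]
        for col in range(aln.length):
            pos = refmap.col_to_ref[col]
            if pos is None:
                continue
            state = _species_fixed_state(aln, members, col)
            if state is None:
                continue
            other_states = [aln.sequence(a)[col] for a in others]
            if any(s == state for s in other_states):
                continue
            missing = sum(1 for s in other_states if s not in _STATES)
            out.append(
                DiagnosticCharacter(
                    species=sp,
                    kind="simple",
                    sites=((pos, state),),
                    support=len(members),
                    n_missing_elsewhere=missing,
                )
            )
    return out


def find_compound_diagnostics(
    aln: LocusAlignment,
    species_map: SpeciesMap,
    refmap: ReferencePositionMap,
    k_max: int = 3,
    min_accessions: int = 3,
    max_combinations: int = 200_000,
) -> list[DiagnosticCharacter]:
    """Minimal multi-position diagnostic combinations (k = 2..k_max).

    Candidate positions for a species are those where it is fixed for one
    unambiguous state but that state also occurs elsewhere (individually
    non-diagnostic).  A k-combination is reported when no non-member
    accession carries the full state pattern and no proper subset is itself
    diagnostic (minimality).  Non-members missing data at some site are
    treated as not carrying the pattern but counted.  If the number of
    combinations for a species exceeds ``max_combinations`` the search stops
    early with a warning, returning the combinations examined so far.
    """
    species_map.validate_alignment(aln)
    out: list[DiagnosticCharacter] = []
    data_ids = [a for a in aln.ids if a != refmap.reference_id]
    for sp in species_map.species_names(data_ids):
        members = species_map.members(sp, data_ids)
        if len(members) < min_accessions:
            continue
        others = [a for a in data_ids if a not in members]
        # Fixed-but-shared positions, with per-other-accession state columns.
        candidates: list[tuple[int, str]] = []  # (column, fixed state)
        for col in range(aln.length):
            if refmap.col_to_ref[col] is None:
                continue
            state = _species_fixed_state(aln, members, col)
            if state is None:
                continue
            if any(aln.sequence(a)[col] == state for a in others):
                candidates.append((col, state))
        # Precompute, per (other accession, candidate): exact state match and
        # missing-data flags, so each combination check is a vectorized AND.
        match = np.array(
            [
                [aln.sequence(a)[c] == s for c, s in candidates]
                for a in others
            ],
            dtype=bool,
        ).reshape(len(others), len(candidates))
        miss = np.array(
            [
                [aln.sequence(a)[c] not in _STATES for c, _ in candidates]
                for a in others
            ],
            dtype=bool,
        ).reshape(len(others), len(candidates))
        match_or_miss = match | miss
        minimal: list[tuple[int, ...]] = []
        budget = max_combinations
        truncated = False
        for k in range(2, k_max + 1):
            for combo in itertools.combinations(range(len(candidates)), k):
                budget -= 1
                if budget < 0:
                    truncated = True
                    break
                if any(set(m) <= set(combo) for m in minimal):
                    continue  # a proper subset already diagnostic
                idx = list(combo)
                full = match[:, idx].all(axis=1)
                if full.any():
                    continue
                cols = [candidates[c][0] for c in combo]
                states = [candidates[c][1] for c in combo]
                missing = int((match_or_miss[:, idx].all(axis=1) & ~full).sum())
                minimal.append(combo)
                out.append(
                    DiagnosticCharacter(
                        species=sp,
                        kind="compound",
                        sites=tuple(
                            (refmap.col_to_ref[c], st) for c, st in zip(cols, states)
                        ),
                        support=len(members),
                        n_missing_elsewhere=missing,
                    )
                )
            if truncated:
                logger.warning(
                    "compound search for %s truncated at %d combinations", sp, max_combinations
                )
                break
    return out


def verify_character(
    char: DiagnosticCharacter,
    aln: LocusAlignment,
    species_map: SpeciesMap,
    refmap: ReferencePositionMap,
) -> bool:
    """Re-check a character (including externally supplied ones, e.g.
    disjunctive compounds) against the raw alignment: every member accession
    carries all listed states and no non-member carries the full pattern."""
    data_ids = [a for a in aln.ids if a != refmap.reference_id]
    members = species_map.members(char.species, data_ids)
    others = [a for a in data_ids if a not in members]
    cols = [refmap.ref_to_col(p) for p, _ in char.sites]
    states = [s for _, s in char.sites]
    for a in members:
        if [aln.sequence(a)[c] for c in cols] != states:
            return False
    for a in others:
        if [aln.sequence(a)[c] for c in cols] == states:
            return False
    return True
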