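"""In-silico PCR-RFLP typing of ITS amplicons.

Digestion scans one strand for every (possibly overlapping) match of the
enzyme's IUPAC recognition pattern and cuts at ``match_start +
cut_offset``; both enzymes used in the study (HaeIII GG^CC, HinfI G^ANTC)
have palindromic sites, so single-strand scanning finds every cut.
Fragments below the gel detection limit are discarded before band
patterns are compared, rank-paired by size, against the reference
profile database within a relative sizing tolerance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .datamodel_io import (
    IUPAC_DNA,
    FragmentProfile,
    ReferenceProfileDB,
    RestrictionEnzyme,
    Sequence,
)

__all__ = [
    "HAEIII",
    "HINFI",
    "DEFAULT_ENZYMES",
    "ProfileMatch",
    "digest",
    "bin_fragments",
    "match_profile",
    "type_collection",
]

# REBASE-standard definitions; overridable by passing other enzymes.
HAEIII = RestrictionEnzyme("HaeIII", "GGCC", 2)
HINFI = RestrictionEnzyme("HinfI", "GANTC", 1)
DEFAULT_ENZYMES = (HAEIII, HINFI)

#: Gel detection limit (bp): smaller fragments do not resolve on the gel.
DEFAULT_DETECTION_LIMIT = 80

#: Default per-band relative sizing tolerance (gel estimate error ~10%).
DEFAULT_REL_TOL = 0.10


@dataclass(frozen=True)
class ProfileMatch:
    """Outcome of matching observed band patterns against the references."""

    species: str
    subgroup: str
    score: float
    matched: bool


def _pattern_regex(recognition: str) -> re.Pattern[str]:
    # lookahead makes overlapping matches visible
    body = "".join(
        c if len(IUPAC_DNA[c]) == 1 else "[" + "".join(sorted(IUPAC_DNA[c])) + "]"
        for c in recognition
    )
    return re.compile(f"(?=({body}))")


def cut_positions(seq: Sequence, enzyme: RestrictionEnzyme) -> list[int]:
    """Cut coordinates on the scanned strand, ascending; ends excluded."""
    rx = _pattern_regex(enzyme.recognition)
    cuts = {
        m.start() + enzyme.cut_offset
        for m in rx.finditer(seq.residues)
    }
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(seq: Sequence, enzyme: RestrictionEnzyme) -> FragmentProfile:
    """Digest ``seq`` with ``enzyme``; fragment lengths sum to ``len(seq)``."""
    cuts = cut_positions(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentProfile(enzyme.name, fragments)


def bin_fragments(profile: FragmentProfile, detection_limit: int) -> FragmentProfile:
    """Drop fragments strictly below the gel detection limit.

    Fragments exactly at the limit are kept: the reference table reports
    80-bp bands while excluding only those *smaller* than 80 bp.
    """
    if detection_limit <= 0:
        raise ValueError("detection_limit must be positive")
    kept = tuple(f for f in profile.fragments if f >= detection_limit)
    return FragmentProfile(profile.enzyme, kept, detection_limit=detection_limit)


def _pattern_deviation(observed: tuple[int, ...], reference: tuple[int, ...],
                       rel_tol: float) -> float:
    """Total absolute band deviation, or inf if the patterns do not pair."""
    if len(observed) != len(reference):
        return float("inf")
    obs = sorted(observed, reverse=True)
    ref = sorted(reference, reverse=True)
    total = 0.0
    for o, r in zip(obs, ref):
        if abs(o - r) > rel_tol * r:
            return float("inf")
        total += abs(o - r)
    return total


def match_profile(observed: Iterable[FragmentProfile], refdb: ReferenceProfileDB,
                  rel_tol: float = DEFAULT_REL_TOL) -> ProfileMatch:
    """Assign the observed binned band patterns to a reference entry.

    A (species, subgroup) matches iff, for every one of its enzymes, band
    counts agree and each observed band lies within ``rel_tol`` of its
    rank-paired reference band. Among multiple matches the entry with the
    smallest summed deviation wins; ties break by database order.
    """
    by_enzyme: dict[str, FragmentProfile] = {}
    for prof in observed:
        if prof.enzyme in by_enzyme:
            raise ValueError(f"duplicate observed profile for {prof.enzyme}")
        by_enzyme[prof.enzyme] = prof
    unknown = set(by_enzyme) - set(refdb.enzymes)
    if unknown:
        raise ValueError(f"enzyme(s) {sorted(unknown)} absent from reference DB")

    best: ProfileMatch | None = None
    best_key: tuple[float, int] | None = None
    for order, (species, subgroup) in enumerate(refdb.groups()):
        patterns = refdb.patterns_for(species, subgroup)
        total = 0.0
        for enzyme, ref_pattern in patterns.items():
            if enzyme not in by_enzyme:
                raise ValueError(f"no observed profile for enzyme {enzyme}")
            total += _pattern_deviation(by_enzyme[enzyme].fragments,
                                        ref_pattern, rel_tol)
        key = (total, order)
        if best_key is None or key < best_key:
            best_key = key
            best = ProfileMatch(species, subgroup, total,
                                matched=total != float("inf"))
    assert best is not None
    return best


def type_collection(
    seqs: Iterable[Sequence],
    enzymes: Iterable[RestrictionEnzyme] = DEFAULT_ENZYMES,
    refdb: ReferenceProfileDB | None = None,
    detection_limit: int = DEFAULT_DETECTION_LIMIT,
    rel_tol: float = DEFAULT_REL_TOL,
) -> dict[str, ProfileMatch]:
    """Digest, bin, and match every sequence; one :class:`ProfileMatch` each."""
    if refdb is None:
        from .datamodel_io import load_reference_profiles

        refdb = load_reference_profiles()
    enzymes = tuple(enzymes)
    out: dict[str, ProfileMatch] = {}
    for seq in seqs:
        profiles = [bin_fragments(digest(seq, enz), detection_limit)
                    for enz in enzymes]
        out[seq.seq_id] = match_profile(profiles, refdb, rel_tol)
    return out
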