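"""ITS-based species assignment and the G/A genotype-group call.

Species are assigned by deterministic global pairwise alignment of the
query ITS amplicon against a reference panel, applying the standard
barcoding acceptance rule (>= 97% identity and >= 95% coverage). Within
*Kluyveromyces marxianus* a single diagnostic G/A polymorphism in the
ITS1-5.8S-ITS2 region splits the strains into two genotype groups
(G = Group I, A = Group II); the site is located in a multiple alignment
via a configurable flanking motif because its absolute coordinate
depends on the reference panel.

Scoring is fixed at match +1, mismatch -1, gap -2 (linear). Identity is
computed end-gap-free (terminal gap columns excluded) so that coverage
remains meaningful for partial amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence as TypingSequence

from Bio import Align

from .datamodel_io import Sequence

__all__ = [
    "MATCH_SCORE",
    "MISMATCH_SCORE",
    "GAP_SCORE",
    "PairwiseAlignment",
    "IdentityHit",
    "AlignedBlock",
    "SnpGroup",
    "SnpGroupCall",
    "align_pair",
    "classify_species",
    "multiple_align",
    "call_snp_group",
]

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -2


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences with identity/coverage summaries."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage: float


@dataclass(frozen=True)
class IdentityHit:
    """Best panel hit for a query, with the acceptance decision."""

    query_id: str
    ref_id: str
    ref_species: str
    identity: float
    coverage: float
    assigned: bool


class SnpGroup(Enum):
    I = "I"
    II = "II"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SnpGroupCall:
    strain_id: str
    allele: str  # "G", "A", or "other"
    group: SnpGroup


@dataclass(frozen=True)
class AlignedBlock:
    """A multiple alignment: equal-length gapped rows keyed by sequence id."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows differ in length")

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def align_pair(a: Sequence, b: Sequence) -> PairwiseAlignment:
    """Globally align two sequences; deterministic for given inputs.

    Identity counts matching columns over the end-gap-trimmed region;
    coverage is the fraction of query (``a``) residues inside that region.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner().align(a.residues, b.residues)[0]
    sa, sb = aln[0], aln[1]
    cols = [i for i in range(len(sa)) if sa[i] != "-" and sb[i] != "-"]
    if not cols:
        start, end = 0, 0
        identity = 0.0
        coverage = 0.0
    else:
        start, end = cols[0], cols[-1] + 1
        matches = sum(1 for i in range(start, end)
                      if sa[i] == sb[i] and sa[i] != "-")
        identity = matches / (end - start)
        coverage = sum(1 for i in range(start, end) if sa[i] != "-") / len(a)
    return PairwiseAlignment(sa, sb, float(aln.score), identity, coverage)


def classify_species(
    query: Sequence,
    panel: TypingSequence[tuple[Sequence, str]],
    min_identity: float = 0.97,
    min_coverage: float = 0.95,
) -> IdentityHit:
    """Assign ``query`` to the best panel species if it clears the thresholds.

    The best hit is by identity, ties broken by higher coverage then panel
    order. The returned hit carries ``assigned=False`` (with the best-hit
    diagnostics) when identity or coverage falls below the rule.
    """
    if not panel:
        raise ValueError("reference panel is empty")
    best: tuple[float, float, int] | None = None
    best_hit: IdentityHit | None = None
    for order, (ref, species) in enumerate(panel):
        aln = align_pair(query, ref)
        key = (aln.identity, aln.coverage, -order)
        if best is None or key > best:
            best = key
            best_hit = IdentityHit(query.seq_id, ref.seq_id, species,
                                   aln.identity, aln.coverage, assigned=False)
    assert best_hit is not None
    assigned = (best_hit.identity >= min_identity
                and best_hit.coverage >= min_coverage)
    return IdentityHit(best_hit.query_id, best_hit.ref_id, best_hit.ref_species,
                       best_hit.identity, best_hit.coverage, assigned)


# --------------------------------------------------------------------------
# center-star multiple alignment
# --------------------------------------------------------------------------

def multiple_align(seqs: TypingSequence[Sequence]) -> AlignedBlock:
    """Center-star progressive multiple alignment.

    The center is the sequence maximizing the summed pairwise alignment
    score to all others (ties: first in input order); every other sequence
    is aligned to the center and the pairwise gap patterns are merged
    ("once a gap, always a gap"). De-gapping any output row recovers the
    corresponding input exactly.
    """
    if len(seqs) < 2:
        raise ValueError("multiple alignment needs at least 2 sequences")
    aligner = _aligner()
    n = len(seqs)
    scores = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(seqs[i].residues, seqs[j].residues)
            scores[i][j] = scores[j][i] = s
    center = max(range(n), key=lambda i: (sum(scores[i]), -i))

    center_row = seqs[center].residues  # gains gaps as rows are merged
    merged: dict[int, str] = {center: center_row}

    for i in range(n):
        if i == center:
            continue
        aln = aligner.align(seqs[center].residues, seqs[i].residues)[0]
        ac, ai = aln[0], aln[1]
        # merge the (ac, ai) pair into the running block via the center row
        p = q = 0
        ops: list[tuple[bool, bool]] = []  # (advance master, advance pair)
        master = merged[center]
        while p < len(master) or q < len(ac):
            cm = master[p] if p < len(master) else None
            cp = ac[q] if q < len(ac) else None
            if cm is not None and cp is not None:
                if cm == "-" and cp != "-":
                    ops.append((True, False))
                    p += 1
                elif cp == "-" and cm != "-":
                    ops.append((False, True))
                    q += 1
                else:  # both gap (independent insertions) or same residue
                    ops.append((True, True))
                    p += 1
                    q += 1
            elif cm is not None:
                ops.append((True, False))
                p += 1
            else:
                ops.append((False, True))
                q += 1
        new_merged: dict[int, str] = {}
        for idx, row in merged.items():
            pos = 0
            chars = []
            for take_m, _ in ops:
                if take_m:
                    chars.append(row[pos])
                    pos += 1
                else:
                    chars.append("-")
            new_merged[idx] = "".join(chars)
        pos = 0
        chars = []
        for _, take_p in ops:
            if take_p:
                chars.append(ai[pos])
                pos += 1
            else:
                chars.append("-")
        new_merged[i] = "".join(chars)
        merged = new_merged

    ids = tuple(s.seq_id for s in seqs)
    rows = tuple(merged[i] for i in range(n))
    return AlignedBlock(ids, rows)


# --------------------------------------------------------------------------
# diagnostic SNP call
# --------------------------------------------------------------------------

def locate_snp_column(block: AlignedBlock, motif: str) -> int:
    """Alignment column of the residue immediately after ``motif``.

    The motif is searched in each de-gapped row in order; the first row
    containing it anchors the column. Raises if no row carries the motif.
    """
    motif = motif.upper()
    for i, row in enumerate(block.rows):
        degapped = row.replace("-", "")
        hit = degapped.find(motif)
        if hit < 0 or hit + len(motif) >= len(degapped):
            continue
        target = hit + len(motif)  # de-gapped index of the diagnostic residue
        count = -1
        for col, ch in enumerate(row):
            if ch != "-":
                count += 1
                if count == target:
                    return col
    raise ValueError(
        f"flanking motif {motif!r} not found in any of the "
        f"{len(block.ids)} rows searched: {list(block.ids)}"
    )


def call_snp_group(block: AlignedBlock, motif: str | None = None,
                   site: int | None = None) -> list[SnpGroupCall]:
    """Read the diagnostic allele per strain: G -> Group I, A -> Group II.

    Either an explicit 0-based alignment ``site`` or a flanking ``motif``
    (the 8-bp run immediately 5' of the polymorphism) must be given.
    Gaps or other residues at the site yield an 'unknown' group.
    """
    if site is None:
        if motif is None:
            raise ValueError("either a site index or a flanking motif is required")
        site = locate_snp_column(block, motif)
    if not 0 <= site < len(block.rows[0]):
        raise ValueError(f"site column {site} outside alignment of width "
                         f"{len(block.rows[0])}")
    calls = []
    for strain_id, row in zip(block.ids, block.rows):
        ch = row[site]
        if ch == "G":
            calls.append(SnpGroupCall(strain_id, "G", SnpGroup.I))
        elif ch == "A":
            calls.append(SnpGroupCall(strain_id, "A", SnpGroup.II))
        else:
            calls.append(SnpGroupCall(strain_id, "other", SnpGroup.UNKNOWN))
    return calls
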