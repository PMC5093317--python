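"""Domain types, packaged study tables, and FASTA/TSV/Newick input-output.

The package revolves around a small set of containers describing a yeast
isolate collection from a spontaneously fermented milk: isolate metadata,
ITS amplicon sequences, restriction-fragment profiles, multilocus
microsatellite genotypes, optical-density phenotype matrices, and
qualitative trait tables (invasiveness, oxidative-stress resistance,
hyphae formation, antifungal MICs).

Four tables from the source study ship with the package as tab-delimited
fixtures (strain identities, per-strain RFLP band patterns plus the
distilled reference profile database, qualitative traits, and the MIC
panel). A SHA-256 checksum guards each transcription.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_DNA",
    "Sequence",
    "IsolateRecord",
    "RestrictionEnzyme",
    "FragmentProfile",
    "ReferenceProfileDB",
    "MultilocusGenotype",
    "PhyloNode",
    "PhyloTree",
    "PhenotypeMatrix",
    "GrowthCall",
    "Censoring",
    "MICResult",
    "QualTraitTable",
    "PhytateResult",
    "read_fasta",
    "write_fasta",
    "write_newick",
    "load_table_fixtures",
    "load_reference_profiles",
    "read_genotype_table",
    "read_phenotype_table",
]

#: IUPAC nucleotide ambiguity codes mapped to the bases they stand for.
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_SEQ_ALPHABET = frozenset("ACGTN")


# --------------------------------------------------------------------------
# sequence & isolate types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.seq_id!r}: empty residues")
        bad = set(self.residues) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.seq_id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IsolateRecord:
    """Identity metadata of one isolate: species, medium, sample origin."""

    strain_id: str
    species: str
    isolation_medium: str
    sample_origin: str  # "original" or "maintained"
    accession: str = ""

    def __post_init__(self) -> None:
        if self.sample_origin not in ("original", "maintained"):
            raise ValueError(
                f"{self.strain_id}: sample_origin must be 'original' or "
                f"'maintained', got {self.sample_origin!r}"
            )


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: IUPAC recognition pattern + cut offset.

    ``cut_offset`` is the distance from the start of the recognition match
    to the cut position on the scanned strand.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        bad = set(self.recognition) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"enzyme {self.name}: non-IUPAC codes {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"enzyme {self.name}: cut_offset {self.cut_offset} outside "
                f"pattern of length {len(self.recognition)}"
            )


@dataclass(frozen=True)
class FragmentProfile:
    """Restriction fragment lengths for one enzyme, sorted descending.

    ``detection_limit`` is None for a raw in-silico digest (fragments then
    sum to the parent length) and set to the gel detection limit once
    sub-threshold bands have been discarded.
    """

    enzyme: str
    fragments: tuple[int, ...]
    detection_limit: int | None = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragments):
            raise ValueError(f"{self.enzyme}: fragment lengths must be positive")
        object.__setattr__(self, "fragments",
                           tuple(sorted(self.fragments, reverse=True)))

    @property
    def binned(self) -> bool:
        return self.detection_limit is not None


@dataclass(frozen=True)
class ReferenceProfileDB:
    """Reference band patterns keyed by (species, subgroup, enzyme)."""

    entries: tuple[tuple[str, str, str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        keys = [(sp, sub, enz) for sp, sub, enz, _ in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (species, subgroup, enzyme) entries")
        if any(not pat for *_, pat in self.entries):
            raise ValueError("empty reference pattern")

    @property
    def enzymes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, _, enz, _ in self.entries:
            if enz not in seen:
                seen.append(enz)
        return tuple(seen)

    def groups(self) -> list[tuple[str, str]]:
        """(species, subgroup) pairs in database order."""
        seen: list[tuple[str, str]] = []
        for sp, sub, _, _ in self.entries:
            if (sp, sub) not in seen:
                seen.append((sp, sub))
        return seen

    def patterns_for(self, species: str, subgroup: str) -> dict[str, tuple[int, ...]]:
        return {enz: pat for sp, sub, enz, pat in self.entries
                if (sp, sub) == (species, subgroup)}


@dataclass(frozen=True)
class MultilocusGenotype:
    """One strain's microsatellite profile: locus -> unordered allele pair.

    Missing loci are simply absent from ``genotype``; the declared panel is
    supplied at distance-computation time.
    """

    strain_id: str
    genotype: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for locus, pair in self.genotype.items():
            if len(pair) != 2 or any(int(a) <= 0 for a in pair):
                raise ValueError(
                    f"{self.strain_id}/{locus}: allele lengths must be a "
                    f"positive pair, got {pair!r}"
                )

    def loci(self) -> frozenset[str]:
        return frozenset(self.genotype)


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

class PhyloNode:
    """Tree node with parent link, branch length to parent, and children."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["PhyloNode"] | None = None):
        self.name = name
        self.length = float(length)
        self.children: list[PhyloNode] = []
        self.parent: PhyloNode | None = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "PhyloNode") -> None:
        child.parent = self
        self.children.append(child)

    def remove_child(self, child: "PhyloNode") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloNode({self.name!r}, {self.length:g}, {len(self.children)} ch)"


class PhyloTree:
    """Weighted tree with labelled leaves; optionally rooted.

    An unrooted tree is represented with a trifurcating (or higher-degree)
    top node; a rooted tree has a bifurcating root. ``degenerate`` flags a
    zero-diameter tree that was rooted arbitrarily.
    """

    def __init__(self, root: PhyloNode, rooted: bool = False,
                 degenerate: bool = False):
        self.root = root
        self.rooted = rooted
        self.degenerate = degenerate

    def nodes(self) -> list[PhyloNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    # -- distances ---------------------------------------------------------

    def leaf_distances(self) -> tuple[list[str], "pd.DataFrame"]:
        """All pairwise leaf-to-leaf path lengths (root contributes nothing)."""
        import numpy as np

        leaves = sorted(self.leaf_names())
        idx = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def walk(node: PhyloNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            per_child = []
            for child in node.children:
                sub = {k: v + child.length for k, v in walk(child).items()}
                per_child.append(sub)
            for i, sub_i in enumerate(per_child):
                for sub_j in per_child[i + 1:]:
                    for a, da in sub_i.items():
                        for b, db in sub_j.items():
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
                below.update({k: v for sub in per_child for k, v in sub.items()})
            return below

        walk(self.root)
        return leaves, pd.DataFrame(d, index=leaves, columns=leaves)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: PhyloNode) -> str:
            if node.is_leaf:
                if not node.name:
                    raise ValueError("unlabeled leaf cannot be serialized")
                return f"{node.name}:{float(node.length)!r}"
            inner = ",".join(fmt(c) for c in node.children)
            label = node.name or ""
            return f"({inner}){label}:{float(node.length)!r}"

        if self.root.is_leaf:
            raise ValueError("tree must have at least 2 leaves")
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner}){self.root.name or ''};"

    def copy(self) -> "PhyloTree":
        def clone(node: PhyloNode) -> PhyloNode:
            new = PhyloNode(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted,
                         degenerate=self.degenerate)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Serialize ``tree`` to a Newick file with full-precision branch lengths."""
    if len(tree.leaves()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    Path(path).write_text(tree.to_newick() + "\n")


# --------------------------------------------------------------------------
# phenotype-side types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeMatrix:
    """Strain x condition optical-density matrix (OD630 scale).

    ``od`` holds the per-cell mean over replicate cultures and
    ``replicate_count`` the number of replicates behind each cell.
    """

    od: pd.DataFrame
    replicate_count: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.od.values < 0).any():
            raise ValueError("negative OD readings")
        if self.od.shape != self.replicate_count.shape:
            raise ValueError("od and replicate_count shapes differ")

    @property
    def strains(self) -> list[str]:
        return list(self.od.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.od.columns)


class GrowthCall(Enum):
    """Categorical growth call from a microplate OD reading."""

    NEGATIVE = 0
    INHIBITED = 1
    POSITIVE = 2

    def __lt__(self, other: "GrowthCall") -> bool:
        return self.value < other.value


class Censoring(Enum):
    EXACT = "exact"
    ABOVE_MAX = "above_max"
    BELOW_MIN = "below_min"


@dataclass(frozen=True)
class MICResult:
    """Minimum inhibitory concentration, possibly censored at the range ends."""

    drug: str
    mic: float | None
    censoring: Censoring

    def __post_init__(self) -> None:
        if self.censoring is Censoring.ABOVE_MAX and self.mic is not None:
            raise ValueError("above_max implies an undetermined MIC")
        if self.censoring is not Censoring.ABOVE_MAX and self.mic is None:
            raise ValueError(f"{self.drug}: MIC value required unless above_max")


@dataclass(frozen=True)
class QualTraitTable:
    """Qualitative traits of one strain: oxidative-stress halo distance,
    agar invasiveness grade, and hyphae formation per medium.

    ``hyphae`` maps condition name to True (+), False (-), or None (n.d.).
    """

    strain_id: str
    h2o2_distance: float
    invasiveness: int
    border: bool = False
    hyphae: Mapping[str, bool | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.invasiveness <= 4:
            raise ValueError(f"{self.strain_id}: invasiveness grade outside 0..4")
        if self.h2o2_distance < 0:
            raise ValueError(f"{self.strain_id}: negative H2O2 distance")


@dataclass(frozen=True)
class PhytateResult:
    """Phytate (IP6) degradation outcome for one strain."""

    strain_id: str
    ip6_initial: float
    ip6_final: float
    percent_degraded: float


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into :class:`Sequence` records.

    Residues are uppercased and U is mapped to T. Empty files, duplicate
    record ids, and non-IUPAC characters are rejected with a message naming
    the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[Sequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("U", "T")
        bad = set(residues) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        out.append(Sequence(rec.id, residues))
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    records = [SeqRecord(_BioSeq(s.residues), id=s.seq_id, description="")
               for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# packaged fixtures
# --------------------------------------------------------------------------

_FIXTURE_SHA256 = {
    "table1_isolates.tsv":
        "2f28867b6e79df1e46bfc00a4e4bc2103b761e22fbf430ded26461e0bd5de295",
    "table2_reference_profiles.tsv":
        "8f7b7adbc521014eda4ea4e27aa2c309eede4433a326ea17ee677ff6f4497291",
    "table2_rflp.tsv":
        "9daaaa380871500752f0a86ea8ec8cbeafb8af9e7b7ac79b3787cdd439faec6b",
    "table3_traits.tsv":
        "abc8220e0aedc9feb1765a8e6e719ea14e6bd3fd4151e84069689b4829594812",
    "table4_mic.tsv":
        "a9911bf3b0414ab70e43c2c0deda86102f0eb000f9c8bf3315e28f1c2caec25c",
}

_HYPHAE_COLS = ("hyphae_ypd27", "hyphae_ypd37", "hyphae_ynb27",
                "hyphae_ynb37", "hyphae_rpmi37")


def _fixture_text(name: str) -> str:
    data = (resources.files("fermentype") / "fixtures" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(
            f"fixture {name} checksum mismatch: transcription corrupted "
            f"({digest} != {_FIXTURE_SHA256[name]})"
        )
    return data.decode("utf-8")


def _fixture_frame(name: str) -> pd.DataFrame:
    from io import StringIO

    return pd.read_csv(StringIO(_fixture_text(name)), sep="\t", dtype=str)


def parse_fragments(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in str(text).split(","))


def load_reference_profiles() -> ReferenceProfileDB:
    """The distilled band-pattern database (species/subgroup x enzyme)."""
    df = _fixture_frame("table2_reference_profiles.tsv").fillna("")
    entries = tuple(
        (r.species, r.subgroup, r.enzyme, parse_fragments(r.fragments))
        for r in df.itertuples()
    )
    return ReferenceProfileDB(entries)


def _parse_mic_cell(drug: str, cell: str) -> MICResult:
    cell = cell.strip()
    if cell.endswith("**"):
        return MICResult(drug, float(cell[:-2]), Censoring.BELOW_MIN)
    if cell.endswith("*"):
        # growth at the highest tested concentration: MIC not determined
        return MICResult(drug, None, Censoring.ABOVE_MAX)
    return MICResult(drug, float(cell), Censoring.EXACT)


def load_table_fixtures() -> tuple[
    list[IsolateRecord],
    ReferenceProfileDB,
    list[QualTraitTable],
    dict[str, dict[str, MICResult]],
]:
    """Load the packaged study tables.

    Returns the 52 isolate records, the reference profile database, the
    qualitative trait table (one row per strain; n.d. cells as missing),
    and the 9-strain MIC panel as strain -> drug -> :class:`MICResult`.
    """
    t1 = _fixture_frame("table1_isolates.tsv")
    isolates = [
        IsolateRecord(r.strain_id, r.species, r.isolation_medium,
                      r.sample_origin, r.accession)
        for r in t1.itertuples()
    ]
    if len({rec.strain_id for rec in isolates}) != len(isolates):
        raise RuntimeError("duplicate strain ids in isolate fixture")

    refdb = load_reference_profiles()

    t3 = _fixture_frame("table3_traits.tsv")
    traits = []
    for r in t3.itertuples():
        grade_text = r.invasive
        border = grade_text.endswith("b")
        grade = int(grade_text.rstrip("b"))
        hyphae = {
            col: None if getattr(r, col) == "n.d." else getattr(r, col) == "+"
            for col in _HYPHAE_COLS
        }
        traits.append(QualTraitTable(r.strain_id, float(r.h2o2_mm), grade,
                                     border, hyphae))

    t4 = _fixture_frame("table4_mic.tsv")
    mic_panel = {
        r.strain_id: {
            "fluconazole": _parse_mic_cell("fluconazole", r.fluconazole),
            "clotrimazole": _parse_mic_cell("clotrimazole", r.clotrimazole),
            "amphotericin_b": _parse_mic_cell("amphotericin_b", r.amphotericin_b),
        }
        for r in t4.itertuples()
    }
    return isolates, refdb, traits, mic_panel


def load_rflp_table() -> pd.DataFrame:
    """Per-strain band patterns (species, strain_id, haeiii, hinfi)."""
    return _fixture_frame("table2_rflp.tsv")


# --------------------------------------------------------------------------
# user-facing tabular inputs
# --------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> tuple[list[MultilocusGenotype], list[str]]:
    """Read a microsatellite genotype TSV.

    Layout: a ``strain_id`` column followed by two columns per locus named
    ``<locus>_a1`` and ``<locus>_a2``; blank cells mark missing loci.
    Returns the genotypes and the locus panel in column order.
    """
    df = pd.read_csv(path, sep="\t")
    if "strain_id" not in df.columns:
        raise ValueError(f"{path}: missing 'strain_id' column")
    panel: list[str] = []
    for col in df.columns:
        if col.endswith("_a1"):
            locus = col[:-3]
            if f"{locus}_a2" not in df.columns:
                raise ValueError(f"{path}: locus {locus} lacks an _a2 column")
            panel.append(locus)
    genos = []
    for _, row in df.iterrows():
        geno: dict[str, tuple[int, int]] = {}
        for locus in panel:
            a1, a2 = row[f"{locus}_a1"], row[f"{locus}_a2"]
            if pd.isna(a1) or pd.isna(a2):
                continue
            geno[locus] = (int(a1), int(a2))
        genos.append(MultilocusGenotype(str(row["strain_id"]), geno))
    return genos, panel


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a strain x condition OD table (first column = strain ids).

    Replicate columns may be suffixed ``_r1``, ``_r2``, ...; they are
    returned as-is for :func:`fermentype.phenotype_stats.assemble_matrix`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty phenotype table")
    return df
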