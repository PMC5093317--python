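"""Seeded generators emulating the study's data-generating conditions.

Every generator is deterministic under a fixed seed and produces inputs
with the statistical structure its consuming stage assumes:

* ``gen_its`` builds ITS-like amplicons constructively: restriction
  sites are planted so that each sequence's binned HaeIII/HinfI digest
  reproduces its species' reference band pattern, and *K. marxianus*
  sequences carry the diagnostic G (Group I) or A (Group II) allele
  directly after a configurable flanking motif. Group II differs from
  Group I by a 20-bp shift of one HinfI site (140-bp vs 120-bp band).
* ``gen_microsat`` draws multilocus genotypes from K ancestral
  allele-frequency pools over disjoint-leaning allele ranges, with
  optional mosaic (mixed-ancestry) strains.
* ``gen_phenotypes`` produces OD matrices as baseline + per-species and
  per-genotype-group mean shifts (in noise-SD units) + truncated
  Gaussian noise, in duplicate replicates.
* ``gen_mic_series`` produces OD-vs-concentration series following a
  decreasing Hill curve with strain-specific IC50, including both
  censoring regimes.

Default strain counts mirror the study collection (29 *K. marxianus*
split 12/17 into Groups I/II, 10 *S. cerevisiae*, 12 *P. fermentans*,
1 *K. unispora*).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .datamodel_io import MultilocusGenotype, PhenotypeMatrix, Sequence
from .phenotype_stats import assemble_matrix
from .rflp_typing import DEFAULT_DETECTION_LIMIT, HAEIII, HINFI, bin_fragments, digest
from .datamodel_io import Censoring, MICResult

__all__ = [
    "SPECIES_KM",
    "SPECIES_SC",
    "SPECIES_PF",
    "SPECIES_KU",
    "GeneratorConfig",
    "ItsDataset",
    "MicrosatDataset",
    "PhenotypeDataset",
    "MicSeries",
    "gen_its",
    "gen_microsat",
    "gen_phenotypes",
    "gen_mic_series",
]

SPECIES_KM = "Kluyveromyces marxianus"
SPECIES_SC = "Saccharomyces cerevisiae"
SPECIES_PF = "Pichia fermentans"
SPECIES_KU = "Kazachstania unispora"

#: Reference binned band patterns each synthetic amplicon must reproduce.
TARGET_PATTERNS: dict[tuple[str, str], dict[str, tuple[int, ...]]] = {
    (SPECIES_KM, "I"): {"HaeIII": (655, 80), "HinfI": (240, 185, 120, 80)},
    (SPECIES_KM, "II"): {"HaeIII": (655, 80), "HinfI": (240, 185, 140, 80)},
    (SPECIES_SC, ""): {"HaeIII": (320, 230, 180, 150), "HinfI": (365, 155)},
    (SPECIES_PF, ""): {"HaeIII": (340, 80), "HinfI": (250, 200)},
    (SPECIES_KU, ""): {"HaeIII": (550, 150), "HinfI": (370,)},
}

MICROSAT_LOCI = ("C3", "C4", "C5", "C6", "C8", "C11", "SCYOR267c",
                 "YKL172w", "SCAAT1", "SCAAT3", "SCAAT5", "YPL3")

#: Phenotype condition panel: carbon sources, temperatures, pH, ox bile,
#: ethanol, lactic acid, and osmotic-stress glucose levels.
CONDITIONS = (
    "glucose", "sucrose", "lactose", "maltose", "mannitol", "arabinose",
    "xylose", "galactose",
    "4C", "27C", "37C", "40C", "42C", "46C", "48C",
    "pH4.8", "pH3", "pH2",
    "bile0.5", "bile1", "bile2",
    "ethanol1", "ethanol6", "ethanol12",
    "lactic1", "lactic6", "lactic12",
    "glucose50", "glucose60",
)

#: Conditions carrying each species' planted mean shift (disjoint blocks).
DEFAULT_SPECIES_SIGNATURES: dict[str, tuple[str, ...]] = {
    SPECIES_KM: ("lactose", "40C", "42C", "arabinose", "xylose"),
    SPECIES_SC: ("glucose50", "glucose60", "ethanol6", "ethanol12", "maltose"),
    SPECIES_PF: ("lactic6", "lactic12", "37C", "sucrose", "galactose"),
    SPECIES_KU: ("glucose50", "glucose60"),
}

#: Genotype-group shifts within K. marxianus, in the reported directions.
DEFAULT_GROUP_SIGNATURES: dict[str, tuple[str, ...]] = {
    "I": ("42C", "46C", "pH3", "xylose", "lactic1", "lactic6",
          "glucose50", "glucose60"),
    "II": ("sucrose", "lactose"),
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world; defaults mirror the study shape."""

    seed: int = 17
    # --- ITS sequences ---
    n_group1: int = 12
    n_group2: int = 17
    n_scerevisiae: int = 10
    n_pfermentans: int = 12
    n_kunispora: int = 1
    its_length: int | None = None  # None: shortest length fitting the patterns
    snp_flank_motif: str = "TTGCAGCT"
    its_mutation_rate: float = 0.005  # substitutions/site outside sites & motif
    detection_limit: int = DEFAULT_DETECTION_LIMIT
    # --- microsatellites ---
    microsat_panel: tuple[str, ...] = MICROSAT_LOCI
    n_pools: int = 2
    n_per_pool: int = 10
    n_mosaic: int = 0
    mosaic_weights: tuple[float, ...] | None = None  # None: uniform over pools
    alleles_per_locus: int = 4
    pool_offset: int = 20  # bp shift between pool allele ranges
    # --- phenotypes ---
    conditions: tuple[str, ...] = CONDITIONS
    baseline_od: float = 0.5
    noise_sd: float = 0.1
    species_effect_sd: float = 2.5  # planted species shifts, in SD units
    group_effect_sd: float = 2.0  # planted genotype-group shifts, in SD units
    species_effects: Mapping[str, Mapping[str, float]] | None = None
    group_effects: Mapping[str, Mapping[str, float]] | None = None
    n_replicates: int = 2  # duplicate cultures
    # --- MIC series ---
    mic_concentrations: tuple[float, ...] = (0.06, 0.12, 0.25, 0.5, 1.0, 2.0, 4.0)
    mic_hill_slope: float = 4.0
    mic_top_od: float = 0.8
    mic_noise_sd: float = 0.0
    mic_n_series: int = 27
    mic_growth_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.mic_noise_sd < 0:
            raise ValueError("noise SD cannot be negative")
        if self.mosaic_weights is not None:
            if abs(sum(self.mosaic_weights) - 1.0) > 1e-9:
                raise ValueError("mosaic mixing weights must sum to 1")
            if len(self.mosaic_weights) != self.n_pools:
                raise ValueError("one mixing weight per pool required")


# ==========================================================================
# ITS sequence construction
# ==========================================================================

_BASES = np.array(list("ACGT"))
# per enzyme: overlap-aware regex, cut offset, match window around the cut
_SITE_RX = {
    "HaeIII": (re.compile(r"(?=(GGCC))"), 2, -2, 2),
    "HinfI": (re.compile(r"(?=(GA[ACGT]TC))"), 1, -1, 4),
}


def _chunk_deficit(deficit: int) -> list[int]:
    """Split a length deficit into sub-detection-limit filler fragments.

    Chunks lie in [24, 79]: large enough to host restriction sites with
    margins, small enough to vanish below the 80-bp gel detection limit.
    """
    if deficit == 0:
        return []
    if deficit < 24:
        raise ValueError(f"unfillable deficit {deficit} (< 24 bp)")
    chunks: list[int] = []
    d = deficit
    while d > 158:
        chunks.append(79)
        d -= 79
    if d > 79:
        chunks.extend([d // 2, d - d // 2])
    else:
        chunks.append(d)
    return chunks


def _random_site_free(length: int, rng: np.random.Generator) -> list[str]:
    seq = list(rng.choice(_BASES, size=length))
    for _ in range(200):
        text = "".join(seq)
        hits = [m.start() for rx, *_ in _SITE_RX.values()
                for m in rx.finditer(text)]
        if not hits:
            return seq
        for h in hits:
            seq[h + int(rng.integers(0, 4))] = str(rng.choice(_BASES))
    raise RuntimeError("could not build a site-free background")


def _expected_cuts(text: str) -> dict[str, set[int]]:
    out = {}
    for name, (rx, off, _, _) in _SITE_RX.items():
        out[name] = {m.start() + off for m in rx.finditer(text)
                     if 0 < m.start() + off < len(text)}
    return out


@dataclass
class ItsTemplate:
    residues: str
    protected: frozenset[int]
    targets: dict[str, tuple[int, ...]]
    allele_pos: int | None = None
    moved_cut: int | None = None  # HinfI cut distinguishing Km groups


def _plan_layout(hae: tuple[int, ...], hinf: tuple[int, ...],
                 rng: np.random.Generator, its_length: int | None,
                 glue_after: int | None = None,
                 glue_filler: int | None = None) -> tuple[int, list[int], list[int], int | None]:
    """Choose a total length and compatible cut positions for both enzymes.

    Returns (L, haeIII cuts, hinfI cuts, position of the cut directly after
    the ``glue_after`` fragment, if requested). ``glue_after``/``glue_filler``
    keep a named fragment immediately followed by a specific filler so the
    cut between them can later be shifted.
    """
    sums = (sum(hae), sum(hinf))
    if its_length is not None:
        if its_length < max(sums):
            raise ValueError(
                f"fragments exceeding its_length: patterns need >= {max(sums)} bp"
            )
        L = its_length
    else:
        L = max(sums)
        if any(0 < L - s < 24 for s in sums):
            L += 24
    deficits = (L - sums[0], L - sums[1])
    if any(0 < d < 24 for d in deficits):
        raise ValueError(f"its_length {L} leaves an unfillable deficit")
    hae_items: list[object] = list(hae) + _chunk_deficit(deficits[0])
    hinf_fill = _chunk_deficit(deficits[1])
    if glue_filler is not None:
        if glue_filler not in hinf_fill:
            raise ValueError("glue filler not available from the deficit")
        hinf_fill.remove(glue_filler)
    hinf_items: list[object] = [
        (glue_after, glue_filler) if f == glue_after and glue_filler is not None
        else f
        for f in hinf
    ] + hinf_fill

    def flatten(items: list[object]) -> list[int]:
        out: list[int] = []
        for it in items:
            if isinstance(it, tuple):
                out.extend(it)
            else:
                out.append(it)
        return out

    for _ in range(500):
        rng.shuffle(hae_items)
        rng.shuffle(hinf_items)
        hae_frags = flatten(hae_items)
        hinf_frags = flatten(hinf_items)
        hae_cuts = list(np.cumsum(hae_frags)[:-1])
        hinf_cuts = list(np.cumsum(hinf_frags)[:-1])
        all_cuts = sorted(hae_cuts + hinf_cuts)
        if any(c < 6 or c > L - 6 for c in all_cuts):
            continue
        if any(b - a < 7 for a, b in zip(all_cuts, all_cuts[1:])):
            continue
        moved = None
        if glue_filler is not None:
            pos = 0
            for it in hinf_items:
                if isinstance(it, tuple):
                    moved = pos + it[0]
                    break
                pos += it
        return L, [int(c) for c in hae_cuts], [int(c) for c in hinf_cuts], moved
    raise RuntimeError("no compatible site layout found")


def _plant_sites(seq: list[str], hae_cuts: list[int], hinf_cuts: list[int],
                 rng: np.random.Generator) -> set[int]:
    protected: set[int] = set()
    for c in hae_cuts:
        seq[c - 2:c + 2] = list("GGCC")
        protected.update(range(c - 2, c + 2))
    for c in hinf_cuts:
        site = ["G", "A", str(rng.choice(_BASES)), "T", "C"]
        seq[c - 1:c + 4] = site
        protected.update(range(c - 1, c + 4))
    return protected


def _clean_spurious(seq: list[str], hae_cuts: set[int], hinf_cuts: set[int],
                    protected: set[int], rng: np.random.Generator) -> None:
    """Mutate unprotected bases until no unintended sites remain."""
    windows = {"HaeIII": (hae_cuts, -2, 2), "HinfI": (hinf_cuts, -1, 4)}
    for _ in range(500):
        text = "".join(seq)
        cuts = _expected_cuts(text)
        bad: list[tuple[int, int]] = []
        for name, (want, lo, hi) in windows.items():
            for c in cuts[name] - want:
                bad.append((c + lo, c + hi))
        if not bad:
            return
        for lo, hi in bad:
            candidates = [p for p in range(max(0, lo), min(len(seq), hi))
                          if p not in protected]
            if not candidates:
                raise RuntimeError("spurious site inside protected region")
            p = candidates[int(rng.integers(0, len(candidates)))]
            choices = [b for b in "ACGT" if b != seq[p]]
            seq[p] = choices[int(rng.integers(0, 3))]
    raise RuntimeError("spurious sites persisted")


def _verify_template(residues: str, targets: dict[str, tuple[int, ...]],
                     detection_limit: int) -> bool:
    s = Sequence("t", residues)
    for enz in (HAEIII, HINFI):
        binned = bin_fragments(digest(s, enz), detection_limit)
        if tuple(sorted(binned.fragments, reverse=True)) != \
                tuple(sorted(targets[enz.name], reverse=True)):
            return False
    return True


def _place_motif(seq: list[str], protected: set[int], motif: str, allele: str,
                 reserve: tuple[int, int] | None) -> int:
    """Plant motif+allele in the largest unconstrained interval; returns
    the motif start position."""
    L = len(seq)
    blocked = sorted(protected)
    intervals: list[tuple[int, int]] = []
    prev = 0
    for p in blocked + [L]:
        if p > prev:
            intervals.append((prev, p))
        prev = max(prev, p + 1)
    if reserve is not None:
        trimmed = []
        for lo, hi in intervals:
            if hi <= reserve[0] or lo >= reserve[1]:
                trimmed.append((lo, hi))
            else:
                if reserve[0] - lo > 0:
                    trimmed.append((lo, reserve[0]))
                if hi - reserve[1] > 0:
                    trimmed.append((reserve[1], hi))
        intervals = trimmed
    need = len(motif) + 1 + 12  # motif + allele + 6-bp margins
    usable = [(hi - lo, lo, hi) for lo, hi in intervals if hi - lo >= need]
    if not usable:
        raise RuntimeError("no room for the SNP flanking motif")
    _, lo, hi = max(usable)
    start = (lo + hi - len(motif) - 1) // 2
    seq[start:start + len(motif)] = list(motif)
    seq[start + len(motif)] = allele
    protected.update(range(start, start + len(motif) + 1))
    return start


def _dedup_motif(seq: list[str], motif: str, keep_start: int,
                 protected: set[int], rng: np.random.Generator) -> None:
    for _ in range(50):
        text = "".join(seq)
        extras = [m.start() for m in re.finditer(f"(?={motif})", text)
                  if m.start() != keep_start]
        if not extras:
            return
        for e in extras:
            cands = [p for p in range(e, e + len(motif)) if p not in protected]
            if not cands:
                raise RuntimeError("duplicate motif inside protected region")
            p = cands[int(rng.integers(0, len(cands)))]
            choices = [b for b in "ACGT" if b != seq[p]]
            seq[p] = choices[int(rng.integers(0, 3))]
    raise RuntimeError("could not deduplicate motif")


def _build_template(hae: tuple[int, ...], hinf: tuple[int, ...],
                    rng: np.random.Generator, detection_limit: int,
                    its_length: int | None, motif: str | None = None,
                    allele: str = "A", glue_after: int | None = None,
                    glue_filler: int | None = None) -> ItsTemplate:
    targets = {"HaeIII": tuple(f for f in hae if f >= detection_limit),
               "HinfI": tuple(f for f in hinf if f >= detection_limit)}
    last_err: Exception | None = None
    for _ in range(20):
        try:
            L, hae_cuts, hinf_cuts, moved = _plan_layout(
                hae, hinf, rng, its_length, glue_after, glue_filler)
            seq = _random_site_free(L, rng)
            protected = _plant_sites(seq, hae_cuts, hinf_cuts, rng)
            allele_pos = None
            if motif is not None:
                reserve = (moved - 26, moved + 6) if moved is not None else None
                start = _place_motif(seq, protected, motif, allele, reserve)
                allele_pos = start + len(motif)
            _clean_spurious(seq, set(hae_cuts), set(hinf_cuts), protected, rng)
            if motif is not None:
                _dedup_motif(seq, motif, allele_pos - len(motif), protected, rng)
                _clean_spurious(seq, set(hae_cuts), set(hinf_cuts), protected, rng)
            residues = "".join(seq)
            if not _verify_template(residues, targets, detection_limit):
                raise RuntimeError("digest verification failed")
            return ItsTemplate(residues, frozenset(protected), targets,
                               allele_pos, moved)
        except RuntimeError as err:  # retry with a fresh layout
            last_err = err
    raise RuntimeError(f"template construction failed: {last_err}")


def _derive_group1(template: ItsTemplate, rng: np.random.Generator,
                   detection_limit: int) -> ItsTemplate:
    """Group I template from the Group II one: shift the diagnostic HinfI
    cut 20 bp upstream (140-bp band -> 120-bp band) and set the G allele."""
    assert template.moved_cut is not None and template.allele_pos is not None
    p = template.moved_cut
    seq = list(template.residues)
    protected = set(template.protected)
    # erase the old site, plant the shifted one
    protected.difference_update(range(p - 1, p + 4))
    for q in range(p - 1, p + 4):
        seq[q] = str(rng.choice(_BASES))
    new_cut = p - 20
    seq[new_cut - 1:new_cut + 4] = ["G", "A", str(rng.choice(_BASES)), "T", "C"]
    protected.update(range(new_cut - 1, new_cut + 4))
    seq[template.allele_pos] = "G"
    targets = {"HaeIII": template.targets["HaeIII"],
               "HinfI": tuple(sorted(
                   (120 if f == 140 else f for f in template.targets["HinfI"]),
                   reverse=True))}
    text = "".join(seq)
    hae_cuts = {c for c in _expected_cuts(template.residues)["HaeIII"]}
    hinf_cuts = (_expected_cuts(template.residues)["HinfI"] - {p}) | {new_cut}
    _clean_spurious(seq, hae_cuts, hinf_cuts, protected, rng)
    residues = "".join(seq)
    if not _verify_template(residues, targets, detection_limit):
        raise RuntimeError("group-I template derivation failed verification")
    return ItsTemplate(residues, frozenset(protected), targets,
                       template.allele_pos, new_cut)


def _mutate_copy(template: ItsTemplate, rate: float,
                 rng: np.random.Generator) -> str:
    """Copy with random substitutions outside sites and motif; any
    substitution that would create a new restriction site is reverted."""
    seq = list(template.residues)
    if rate <= 0:
        return template.residues
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    expected = _expected_cuts(template.residues)
    for p in hits:
        p = int(p)
        if p in template.protected:
            continue
        old = seq[p]
        choices = [b for b in "ACGT" if b != old]
        seq[p] = choices[int(rng.integers(0, 3))]
        lo, hi = max(0, p - 5), min(len(seq), p + 6)
        window = "".join(seq[lo:hi])
        created = False
        for name, (rx, off, _, _) in _SITE_RX.items():
            for m in rx.finditer(window):
                if lo + m.start() + off not in expected[name]:
                    created = True
        if created:
            seq[p] = old
    return "".join(seq)


@dataclass
class ItsDataset:
    """Synthetic ITS amplicons with truth labels and a classification panel."""

    records: list[tuple[Sequence, str, str | None]]  # (seq, species, group)
    panel: list[tuple[Sequence, str]]  # one reference per species
    snp_motif: str
    templates: dict[tuple[str, str], ItsTemplate] = field(default_factory=dict)


def gen_its(config: GeneratorConfig) -> ItsDataset:
    """Generate the synthetic ITS collection; see the module docstring."""
    rng = np.random.default_rng(config.seed)
    dl = config.detection_limit

    km2 = _build_template(
        TARGET_PATTERNS[(SPECIES_KM, "II")]["HaeIII"] ,
        # unbinned plan: the 90-bp deficit splits 45+45 so the 140-bp
        # fragment can sit directly before a 45-bp filler (shiftable cut)
        (240, 185, 140, 80), rng, dl, config.its_length,
        motif=config.snp_flank_motif, allele="A",
        glue_after=140, glue_filler=45,
    )
    km1 = _derive_group1(km2, rng, dl)
    sc = _build_template((320, 230, 180, 150), (365, 155), rng, dl,
                         config.its_length)
    pf = _build_template((340, 80), (250, 200), rng, dl, config.its_length)
    ku = _build_template((550, 150), (370,), rng, dl, config.its_length)
    templates = {(SPECIES_KM, "I"): km1, (SPECIES_KM, "II"): km2,
                 (SPECIES_SC, ""): sc, (SPECIES_PF, ""): pf,
                 (SPECIES_KU, ""): ku}

    plan = [
        (SPECIES_KM, "I", km1, "KmI", config.n_group1),
        (SPECIES_KM, "II", km2, "KmII", config.n_group2),
        (SPECIES_SC, None, sc, "Sc", config.n_scerevisiae),
        (SPECIES_PF, None, pf, "Pf", config.n_pfermentans),
        (SPECIES_KU, None, ku, "Ku", config.n_kunispora),
    ]
    records = []
    for species, group, template, prefix, count in plan:
        for i in range(count):
            residues = _mutate_copy(template, config.its_mutation_rate, rng)
            seq = Sequence(f"{prefix}-{i + 1:02d}", residues)
            records.append((seq, species, group))
    panel = [
        (Sequence("ref_Km", km1.residues), SPECIES_KM),
        (Sequence("ref_Sc", sc.residues), SPECIES_SC),
        (Sequence("ref_Pf", pf.residues), SPECIES_PF),
        (Sequence("ref_Ku", ku.residues), SPECIES_KU),
    ]
    return ItsDataset(records, panel, config.snp_flank_motif, templates)


# ==========================================================================
# microsatellite genotypes
# ==========================================================================

@dataclass
class MicrosatDataset:
    genotypes: list[MultilocusGenotype]
    labels: dict[str, str]  # strain -> pool label or "mosaic"
    panel: tuple[str, ...]
    pool_freqs: list[dict[str, tuple[np.ndarray, np.ndarray]]]


def gen_microsat(config: GeneratorConfig) -> MicrosatDataset:
    """Draw multilocus genotypes from K ancestral allele-frequency pools."""
    if config.n_pools < 1 or (config.n_mosaic and config.n_pools < 2):
        raise ValueError("mosaic strains need at least 2 ancestry pools")
    if not config.microsat_panel:
        raise ValueError("empty microsatellite panel")
    rng = np.random.default_rng(config.seed + 1)
    panel = tuple(config.microsat_panel)

    pool_freqs: list[dict[str, tuple[np.ndarray, np.ndarray]]] = []
    for k in range(config.n_pools):
        freqs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for li, locus in enumerate(panel):
            base = 100 + 15 * li + k * config.pool_offset
            alleles = np.array([base + 2 * j
                                for j in range(config.alleles_per_locus)])
            p = rng.dirichlet(np.ones(config.alleles_per_locus))
            freqs[locus] = (alleles, p)
        pool_freqs.append(freqs)

    def draw(freqs: dict[str, tuple[np.ndarray, np.ndarray]],
             locus: str) -> int:
        alleles, p = freqs[locus]
        return int(rng.choice(alleles, p=p))

    genotypes: list[MultilocusGenotype] = []
    labels: dict[str, str] = {}
    for k in range(config.n_pools):
        for i in range(config.n_per_pool):
            sid = f"P{k + 1}S{i + 1:02d}"
            geno = {locus: (draw(pool_freqs[k], locus),
                            draw(pool_freqs[k], locus))
                    for locus in panel}
            genotypes.append(MultilocusGenotype(sid, geno))
            labels[sid] = f"pool{k + 1}"
    weights = (np.full(config.n_pools, 1.0 / config.n_pools)
               if config.mosaic_weights is None
               else np.asarray(config.mosaic_weights))
    for i in range(config.n_mosaic):
        sid = f"M{i + 1:02d}"
        geno = {}
        for locus in panel:
            k = int(rng.choice(config.n_pools, p=weights))
            geno[locus] = (draw(pool_freqs[k], locus),
                           draw(pool_freqs[k], locus))
        genotypes.append(MultilocusGenotype(sid, geno))
        labels[sid] = "mosaic"
    return MicrosatDataset(genotypes, labels, panel, pool_freqs)


# ==========================================================================
# phenotype matrices
# ==========================================================================

@dataclass
class PhenotypeDataset:
    matrix: PhenotypeMatrix
    labels: pd.DataFrame  # strain_id, species, group
    raw: pd.DataFrame  # long-form replicate readings


def _default_species_effects(config: GeneratorConfig) -> dict[str, dict[str, float]]:
    return {sp: {c: config.species_effect_sd for c in conds}
            for sp, conds in DEFAULT_SPECIES_SIGNATURES.items()}


def _default_group_effects(config: GeneratorConfig) -> dict[str, dict[str, float]]:
    return {g: {c: config.group_effect_sd for c in conds}
            for g, conds in DEFAULT_GROUP_SIGNATURES.items()}


def gen_phenotypes(config: GeneratorConfig) -> PhenotypeDataset:
    """OD matrix = baseline + planted mean shifts (in SD units) + noise.

    Each (strain, condition) cell gets ``n_replicates`` replicate readings
    truncated at zero; the returned matrix holds their means.
    """
    rng = np.random.default_rng(config.seed + 2)
    species_effects = (config.species_effects
                       if config.species_effects is not None
                       else _default_species_effects(config))
    group_effects = (config.group_effects
                     if config.group_effects is not None
                     else _default_group_effects(config))

    strains: list[tuple[str, str, str | None]] = []
    for prefix, species, group, count in (
        ("KmI", SPECIES_KM, "I", config.n_group1),
        ("KmII", SPECIES_KM, "II", config.n_group2),
        ("Sc", SPECIES_SC, None, config.n_scerevisiae),
        ("Pf", SPECIES_PF, None, config.n_pfermentans),
        ("Ku", SPECIES_KU, None, config.n_kunispora),
    ):
        strains.extend((f"{prefix}-{i + 1:02d}", species, group)
                       for i in range(count))

    rows = []
    for sid, species, group in strains:
        for cond in config.conditions:
            shift = species_effects.get(species, {}).get(cond, 0.0)
            if group is not None:
                shift += group_effects.get(group, {}).get(cond, 0.0)
            mean = config.baseline_od + shift * config.noise_sd
            for _ in range(config.n_replicates):
                od = max(0.0, mean + rng.normal(0.0, config.noise_sd))
                rows.append({"strain": sid, "condition": cond, "od": od})
    raw = pd.DataFrame(rows)
    matrix = assemble_matrix(raw)
    labels = pd.DataFrame(
        [{"strain_id": s, "species": sp, "group": g or ""}
         for s, sp, g in strains]
    ).set_index("strain_id")
    return PhenotypeDataset(matrix, labels, raw)


# ==========================================================================
# MIC series
# ==========================================================================

@dataclass
class MicSeries:
    strain_id: str
    drug: str
    series: dict[float, float]  # concentration -> mean OD (possibly noisy)
    truth: MICResult
    ic50: float


def gen_mic_series(config: GeneratorConfig) -> list[MicSeries]:
    """Decreasing Hill dose-response series with strain-specific IC50.

    IC50 values are drawn log-uniformly over an interval extending one
    dilution step beyond both ends of the tested range, so the collection
    includes exact calls and both censoring regimes. The true MIC is read
    off the noiseless curve at the growth threshold.
    """
    rng = np.random.default_rng(config.seed + 3)
    concs = tuple(sorted(config.mic_concentrations))
    if len(concs) < 2:
        raise ValueError("need at least 2 concentrations")
    drugs = ("fluconazole", "clotrimazole", "amphotericin_b")
    lo, hi = concs[0] / 8.0, concs[-1] * 8.0

    out: list[MicSeries] = []
    for i in range(config.mic_n_series):
        drug = drugs[i % len(drugs)]
        ic50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        def od_clean(c: float) -> float:
            return config.mic_top_od / (1.0 + (c / ic50) ** config.mic_hill_slope)

        thr = config.mic_growth_threshold
        clean = [od_clean(c) for c in concs]
        if clean[-1] > thr:
            truth = MICResult(drug, None, Censoring.ABOVE_MAX)
        elif clean[0] <= thr:
            truth = MICResult(drug, concs[0], Censoring.BELOW_MIN)
        else:
            mic = next(c for c, o in zip(concs, clean) if o <= thr)
            truth = MICResult(drug, mic, Censoring.EXACT)
        series = {
            c: max(0.0, o + (rng.normal(0.0, config.mic_noise_sd)
                             if config.mic_noise_sd > 0 else 0.0))
            for c, o in zip(concs, clean)
        }
        out.append(MicSeries(f"syn{i + 1:03d}", drug, series, truth, ic50))
    return out
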