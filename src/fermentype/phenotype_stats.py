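"""Phenotype computation: growth calls, PCA, permutational ANOVA,
rank-sum comparisons, MIC calling, phytate arithmetic, trait summaries.

Microplate OD630 readings are categorized with fixed thresholds
(< 0.2 negative, 0.2-0.4 inhibited, > 0.4 positive growth; the closed
interval is assigned to INHIBITED). Multivariate structure is assessed by
PCA on the standardized strain x condition matrix and by a permutational
ANOVA (pseudo-F from Anderson's partitioning of pairwise squared
distances, Euclidean by default, with a seeded permutation null). Group
contrasts use the Wilcoxon rank-sum test, exact by enumeration for small
untied samples and a tie- and continuity-corrected normal approximation
otherwise. Broth-microdilution series are reduced to a minimum
inhibitory concentration with censoring at either end of the tested
range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata

from .datamodel_io import (
    Censoring,
    GrowthCall,
    MICResult,
    PhenotypeMatrix,
    PhytateResult,
    QualTraitTable,
)

__all__ = [
    "NEGATIVE_BELOW",
    "POSITIVE_ABOVE",
    "PermanovaResult",
    "RankSumResult",
    "PCAResult",
    "call_growth",
    "assemble_matrix",
    "standardize",
    "pca",
    "permanova",
    "ranksum",
    "compare_genotype_groups",
    "significance_stars",
    "call_mic",
    "phytate_percent",
    "summarize_traits",
    "round_half_up",
]

NEGATIVE_BELOW = 0.2
POSITIVE_ABOVE = 0.4


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_permutations + 1)
        if not lo <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [{lo}, 1]")


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum W of the first group
    p_value: float
    method: str  # "exact" or "normal_approx"


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


# --------------------------------------------------------------------------
# growth calls & matrix assembly
# --------------------------------------------------------------------------

def call_growth(od: float, negative_below: float = NEGATIVE_BELOW,
                positive_above: float = POSITIVE_ABOVE) -> GrowthCall:
    """Categorize one OD reading; boundary values fall in INHIBITED."""
    if od < 0:
        raise ValueError(f"negative OD reading: {od}")
    if od < negative_below:
        return GrowthCall.NEGATIVE
    if od <= positive_above:
        return GrowthCall.INHIBITED
    return GrowthCall.POSITIVE


def assemble_matrix(raw: pd.DataFrame) -> PhenotypeMatrix:
    """Collapse replicate readings into a strain x condition mean matrix.

    ``raw`` is long-form with columns ``strain``, ``condition``, ``od``
    (one row per replicate culture). Every (strain, condition) pair must
    have at least one replicate.
    """
    required = {"strain", "condition", "od"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw readings need columns {sorted(required)}")
    strains = list(dict.fromkeys(raw["strain"]))
    conditions = list(dict.fromkeys(raw["condition"]))
    counts = raw.pivot_table(index="strain", columns="condition", values="od",
                             aggfunc="count").reindex(index=strains,
                                                      columns=conditions)
    missing = [(s, c) for s in strains for c in conditions
               if pd.isna(counts.loc[s, c])]
    if missing:
        raise ValueError(f"missing replicate readings for cells: {missing}")
    means = raw.pivot_table(index="strain", columns="condition", values="od",
                            aggfunc="mean").reindex(index=strains,
                                                    columns=conditions)
    means.index.name = means.columns.name = None
    counts.index.name = counts.columns.name = None
    return PhenotypeMatrix(means, counts.astype(int))


def standardize(m: PhenotypeMatrix | pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-sample-SD columns; constant columns are dropped."""
    df = m.od if isinstance(m, PhenotypeMatrix) else m
    sd = df.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant condition columns: {constant}")
        df = df.drop(columns=constant)
        sd = sd.drop(constant)
    return (df - df.mean(axis=0)) / sd


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

def pca(standardized: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal components of a standardized matrix via SVD.

    Loadings are orthonormal; explained-variance fractions are
    non-increasing and sum to at most 1. Sign convention: each loading's
    largest-magnitude element is positive.
    """
    X = np.asarray(standardized, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int(np.sum(S > tol))
    k = rank if n_components is None else n_components
    if k > rank:
        warnings.warn(f"n_components={k} exceeds rank {rank}; truncating")
        k = rank
    evr = (S**2 / np.sum(S**2))[:k]
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for c in range(k):
        pivot = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[pivot, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{c + 1}" for c in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=standardized.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=standardized.columns,
                              columns=comp_names),
        explained_variance_ratio=evr,
    )


# --------------------------------------------------------------------------
# permutational ANOVA
# --------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(data: pd.DataFrame | np.ndarray,
              labels: TypingSequence[str],
              n_permutations: int = 999,
              seed: int | None = None,
              metric: str = "euclidean",
              exhaustive: bool = False) -> PermanovaResult:
    """Permutational multivariate ANOVA on pairwise distances.

    ``data`` is a samples x features matrix (distances are computed with
    ``metric``; Euclidean by default, 'braycurtis' available) or an
    already-square distance matrix. The pseudo-F statistic partitions the
    pairwise squared distances into between- and within-group sums of
    squares; the p-value is ``(count of permuted F >= observed F + 1) /
    (n_permutations + 1)`` with label permutations drawn from the stated
    seed, which is mandatory. With ``exhaustive=True`` (samples <= 8) all
    relabelings are enumerated instead and the p-value is the exact
    fraction of permutations, identity included, with F >= observed.
    """
    if seed is None and not exhaustive:
        raise ValueError("a seed is required for the permutation null")
    X = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    n = labels.size
    if X.shape == (n, n) and np.allclose(X, X.T) and np.allclose(np.diag(X), 0):
        d = X
    else:
        if X.shape[0] != n:
            raise ValueError("labels length does not match data rows")
        d = squareform(pdist(X, metric=metric))
    d2 = d**2

    uniq, codes = np.unique(labels, return_counts=False), None
    codes = np.searchsorted(uniq, labels)
    n_groups = uniq.size
    if n_groups < 2:
        raise ValueError("permanova needs at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"group(s) with fewer than 2 members: {small}")

    f_obs = _pseudo_f(d2, codes, n_groups)
    if exhaustive:
        from itertools import permutations as _perms
        from math import factorial

        if n > 8:
            raise ValueError("exhaustive enumeration limited to 8 samples")
        count_ge = sum(
            _pseudo_f(d2, codes[list(perm)], n_groups) >= f_obs - 1e-12
            for perm in _perms(range(n))
        )
        total = factorial(n)
        return PermanovaResult(float(f_obs), count_ge / total, total,
                               seed if seed is not None else 0)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _pseudo_f(d2, codes[perm], n_groups) >= f_obs:
            count_ge += 1
    p = (count_ge + 1) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed)


# --------------------------------------------------------------------------
# Wilcoxon rank-sum
# --------------------------------------------------------------------------

def ranksum(group_a: TypingSequence[float],
            group_b: TypingSequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test (statistic = rank sum of group A).

    Exact by enumeration of all C(n, nA) rank assignments when the
    combined sample has at most 20 observations and no ties; otherwise a
    normal approximation with midranks, tie correction, and continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, na, nb = pooled.size, a.size, b.size
    ranks = rankdata(pooled)
    w = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < n

    if n <= 20 and not has_ties:
        obs_dev = abs(w - mu)
        count = 0
        total = 0
        for combo in combinations(range(1, n + 1), na):
            total += 1
            if abs(sum(combo) - mu) >= obs_dev - 1e-9:
                count += 1
        return RankSumResult(w, count / total, "exact")

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = (na * nb / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankSumResult(w, 1.0, "normal_approx")
    z = max(0.0, (abs(w - mu) - 0.5) / math.sqrt(var))
    p = min(1.0, 2.0 * norm.sf(z))
    return RankSumResult(w, p, "normal_approx")


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_genotype_groups(matrix: PhenotypeMatrix | pd.DataFrame,
                            group_map: Mapping[str, str],
                            bh_correction: bool = False) -> pd.DataFrame:
    """Per-condition rank-sum comparison between two genotype groups.

    ``group_map`` assigns each strain to one of two labels (e.g. "I" and
    "II"). Raw p-values are starred at 0.05/0.01/0.001 with no
    multiplicity correction by default; Benjamini-Hochberg adjusted
    p-values can be added as an extra column.
    """
    df = matrix.od if isinstance(matrix, PhenotypeMatrix) else matrix
    df = df.loc[[s for s in df.index if s in group_map]]
    groups = sorted(set(group_map[s] for s in df.index))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1, g2 = groups
    idx1 = [s for s in df.index if group_map[s] == g1]
    idx2 = [s for s in df.index if group_map[s] == g2]

    rows = []
    for cond in df.columns:
        res = ranksum(df.loc[idx1, cond].values, df.loc[idx2, cond].values)
        m1, m2 = df.loc[idx1, cond].mean(), df.loc[idx2, cond].mean()
        direction = f"{g1}>{g2}" if m1 > m2 else (f"{g2}>{g1}" if m2 > m1 else "=")
        rows.append({"condition": cond, "W": res.statistic,
                     "p_value": res.p_value, "method": res.method,
                     "stars": significance_stars(res.p_value),
                     "direction": direction})
    out = pd.DataFrame(rows).set_index("condition")
    if bh_correction:
        p = out["p_value"].values
        order = np.argsort(p)
        adj = np.empty_like(p)
        m = p.size
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, p[i] * m / (rank_pos + 1))
            adj[i] = running
        out["p_bh"] = adj
    return out


# --------------------------------------------------------------------------
# MIC calling
# --------------------------------------------------------------------------

def call_mic(drug: str,
             series: Mapping[float, float] | Iterable[tuple[float, float]],
             growth_threshold: float = 0.2) -> MICResult:
    """Reduce an OD-vs-concentration series to a MIC with censoring.

    Growth at a concentration means OD > ``growth_threshold``. The MIC is
    the lowest concentration with no growth at it nor at any higher
    concentration. Growth at the highest concentration censors the call
    above the range; no growth anywhere censors it below, flagged at the
    lowest tested concentration. A mapping is sorted by concentration; an
    explicit pair sequence must already be ascending and duplicate-free.
    """
    if isinstance(series, Mapping):
        items = sorted(series.items())
    else:
        items = [(float(c), float(o)) for c, o in series]
        concs = [c for c, _ in items]
        if any(c2 <= c1 for c1, c2 in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly ascending "
                             "and duplicate-free")
    if len(items) < 2:
        raise ValueError("need at least 2 concentrations")
    growth = [od > growth_threshold for _, od in items]
    if growth[-1]:
        return MICResult(drug, None, Censoring.ABOVE_MAX)
    # lowest concentration from which growth never resumes
    k = len(items) - 1
    while k > 0 and not growth[k - 1]:
        k -= 1
    mic = items[k][0]
    if k == 0:
        return MICResult(drug, mic, Censoring.BELOW_MIN)
    return MICResult(drug, mic, Censoring.EXACT)


# --------------------------------------------------------------------------
# phytate degradation
# --------------------------------------------------------------------------

def phytate_percent(ip6_initial: float, ip6_final: float,
                    strain_id: str = "") -> PhytateResult:
    """Percent IP6 degraded: 100 * (initial - final) / initial, clipped at 0."""
    if ip6_initial <= 0:
        raise ValueError("initial IP6 concentration must be positive")
    if ip6_final < 0:
        raise ValueError("final IP6 concentration cannot be negative")
    percent = 100.0 * (ip6_initial - ip6_final) / ip6_initial
    if percent < 0:
        warnings.warn(f"{strain_id or 'sample'}: final IP6 exceeds initial; "
                      "reporting 0% degradation")
        percent = 0.0
    return PhytateResult(strain_id, ip6_initial, ip6_final, percent)


# --------------------------------------------------------------------------
# qualitative trait summaries
# --------------------------------------------------------------------------

def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_traits(table: TypingSequence[QualTraitTable],
                     species_map: Mapping[str, str],
                     h2o2_resistant_mm: float = 5.0,
                     invasive_above_grade: int = 1) -> dict[str, dict]:
    """Per-species summaries of hyphae formation, invasiveness, and
    oxidative-stress resistance.

    Hyphae percentage counts strains with at least one positive medium
    over strains with at least one readable (non-missing) hyphae cell.
    Invasiveness is summarized as the percentage of strains per grade and
    the percentage above ``invasive_above_grade``. H2O2-resistant strains
    are those with a halo distance at or below ``h2o2_resistant_mm``.
    Percentages are rounded half-up to integers.
    """
    missing = [t.strain_id for t in table if t.strain_id not in species_map]
    if missing:
        raise ValueError(f"species_map lacks strains: {missing}")
    by_species: dict[str, list[QualTraitTable]] = {}
    for t in table:
        by_species.setdefault(species_map[t.strain_id], []).append(t)

    out: dict[str, dict] = {}
    for species, rows in by_species.items():
        readable = [t for t in rows
                    if any(v is not None for v in t.hyphae.values())]
        positive = [t for t in readable
                    if any(v is True for v in t.hyphae.values())]
        hyphae_pct = (round_half_up(100.0 * len(positive) / len(readable))
                      if readable else None)
        n = len(rows)
        grade_counts: dict[int, int] = {}
        for t in rows:
            grade_counts[t.invasiveness] = grade_counts.get(t.invasiveness, 0) + 1
        invasive_pct = {g: round_half_up(100.0 * c / n)
                        for g, c in sorted(grade_counts.items())}
        above = sum(1 for t in rows if t.invasiveness > invasive_above_grade)
        resistant = [t.strain_id for t in rows
                     if t.h2o2_distance <= h2o2_resistant_mm]
        out[species] = {
            "n_strains": n,
            "hyphae_percent": hyphae_pct,
            "invasiveness_percent_by_grade": invasive_pct,
            "invasive_above_grade_percent": round_half_up(100.0 * above / n),
            "h2o2_resistant_strains": resistant,
        }
    return out
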