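"""Repertoire feature quantification.

Four features characterise and compare repertoires here:

* **V-gene usage** — the frequency of each V gene among a repertoire's
  clonotypes, counted *unweighted* (each clonotype counts once regardless
  of its clonal size, so differing sequencing depths and count definitions
  between bulk and single-cell libraries do not distort the profile).
  Profiles are compared pairwise by Pearson correlation over the union of
  genes, absent genes imputed as 0.
* **CDR3 overlap** — the Jaccard index J(A,B) = |A∩B| / |A∪B| on the sets
  of unique CDR3 amino-acid sequences of two repertoires.
* **Evenness profile** — Hill diversity D_alpha(f) = (Σ f_i^alpha)^(1/(1-alpha))
  of the clonal frequency distribution f, evaluated on a grid of alpha in
  [0, 10] and normalised by the clonotype count n to give evenness
  E = D/n in (0, 1]; alpha = 1 uses the Shannon limit exp(-Σ f_i ln f_i).
* **Light-chain coherence (LCC)** — among unordered pairs of cells with the
  same heavy V gene and identical CDRH3 amino-acid sequence (but distinct
  computed clonotypes, within a donor), the percentage sharing the light
  V gene.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Repertoire, SingleCellRepertoire, HEAVY

__all__ = [
    "GeneUsageProfile",
    "PairwiseMatrix",
    "EvennessProfile",
    "LccResult",
    "gene_usage",
    "usage_correlation",
    "jaccard_overlap",
    "evenness_profile",
    "hill_diversity",
    "light_chain_coherence_within",
    "light_chain_coherence_across",
    "default_alpha_grid",
]


@dataclass
class GeneUsageProfile:
    sample_id: str
    frequencies: dict[str, float]

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.frequencies.values()):
            raise ValueError("negative gene frequency")

    @property
    def unique_gene_count(self) -> int:
        return len(self.frequencies)


@dataclass
class PairwiseMatrix:
    """Symmetric sample-by-sample matrix for a pairwise metric.

    Undefined entries (zero-variance Pearson, empty-set Jaccard) are NaN,
    never silently 0.
    """

    metric: str  # 'pearson_usage' | 'jaccard_cdr3'
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Tidy long format over unordered pairs (a < b)."""
        rows = []
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                rows.append(
                    {"sample_a": a, "sample_b": self.labels[j],
                     "metric": self.metric, "value": self.values[i, j]}
                )
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "metric", "value"])


@dataclass
class EvennessProfile:
    alpha_grid: np.ndarray
    D_values: np.ndarray
    n: int

    @property
    def E_values(self) -> np.ndarray:
        return self.D_values / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha": self.alpha_grid, "D": self.D_values, "E": self.E_values}
        )


@dataclass
class LccResult:
    scope: str  # 'within_donor' | 'across_donors'
    n_cells_evaluated: int
    n_eligible_pairs: int
    n_coherent_pairs: int

    @property
    def coherence_pct(self) -> float:
        """Percentage of eligible pairs sharing the light V gene; NaN when
        no eligible pairs exist."""
        if self.n_eligible_pairs == 0:
            return float("nan")
        return 100.0 * self.n_coherent_pairs / self.n_eligible_pairs


def gene_usage(rep: Repertoire, chain: str = HEAVY) -> GeneUsageProfile:
    """Unweighted V-gene usage: each clonotype counts once, sizes ignored."""
    genes = [ct.v_gene for ct in rep.iter_chain(chain)]
    if not genes:
        raise ValueError(f"repertoire {rep.sample_id} has no {chain} clonotypes")
    n = len(genes)
    counts: dict[str, int] = {}
    for g in genes:
        counts[g] = counts.get(g, 0) + 1
    return GeneUsageProfile(
        sample_id=rep.sample_id,
        frequencies={g: c / n for g, c in sorted(counts.items())},
    )


def _pair_pearson(a: dict[str, float], b: dict[str, float], support: str) -> float:
    if support == "union":
        genes = sorted(set(a) | set(b))
    elif support == "intersection":
        genes = sorted(set(a) & set(b))
    else:
        raise ValueError(f"unknown support {support!r}")
    if len(genes) < 2:
        return float("nan")
    x = np.array([a.get(g, 0.0) for g in genes])
    y = np.array([b.get(g, 0.0) for g in genes])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # zero variance: correlation undefined
    return float(np.corrcoef(x, y)[0, 1])


def usage_correlation(
    profiles: list[GeneUsageProfile], support: str = "union"
) -> PairwiseMatrix:
    """Pairwise Pearson correlation of gene-usage profiles.

    Each pair is correlated over the union of its genes with absent genes
    imputed 0 (``support='intersection'`` restricts to shared genes).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    k = len(profiles)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = _pair_pearson(profiles[i].frequencies, profiles[j].frequencies, support)
            mat[i, j] = mat[j, i] = r
    return PairwiseMatrix(
        metric="pearson_usage",
        labels=[p.sample_id for p in profiles],
        values=mat,
    )


def jaccard_overlap(A: set, B: set) -> float:
    """Jaccard overlap |A∩B| / |A∪B|; NaN when both sets are empty."""
    union = len(A | B)
    if union == 0:
        return float("nan")
    return len(A & B) / union


def default_alpha_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 10.0 + 1e-9, 0.1), 10)


def hill_diversity(f, alpha: float) -> float:
    """Hill diversity D_alpha of a frequency distribution.

    Zero entries are dropped first (richness counts only observed clones);
    alpha = 1 is evaluated as the Shannon limit exp(-Σ f_i ln f_i).
    """
    f = np.asarray(f, dtype=float)
    f = f[f > 0]
    if f.size == 0:
        raise ValueError("empty frequency distribution")
    if not math.isclose(float(f.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("frequencies must sum to 1")
    if math.isclose(alpha, 1.0, abs_tol=1e-12):
        return float(np.exp(-np.sum(f * np.log(f))))
    return float(np.sum(f**alpha) ** (1.0 / (1.0 - alpha)))


def evenness_profile(
    rep: Repertoire, alpha_grid=None, chain: str | None = HEAVY
) -> EvennessProfile:
    """Hill-diversity evenness profile E(alpha) = D(alpha)/n over an alpha grid."""
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if np.any(alpha_grid < 0) or np.any(alpha_grid > 10):
        raise ValueError("alpha grid must lie within [0, 10]")
    f = np.asarray(rep.frequencies(chain), dtype=float)
    D = np.array([hill_diversity(f, a) for a in alpha_grid])
    return EvennessProfile(alpha_grid=alpha_grid, D_values=D, n=int((f > 0).sum()))


# ---------------------------------------------------------------------------
# Light chain coherence
# ---------------------------------------------------------------------------

def _cells_by_heavy_group(screp: SingleCellRepertoire):
    groups: dict[tuple[str, str], list] = {}
    for cell in screp.cells:
        groups.setdefault((cell.heavy.v_gene, cell.heavy.cdr3_aa), []).append(cell)
    return groups


def light_chain_coherence_within(screp: SingleCellRepertoire) -> LccResult:
    """Within-donor LCC over cell pairs with the same heavy V gene and
    identical CDRH3 amino-acid sequence but different heavy clonotypes."""
    eligible = coherent = 0
    cells_involved: set[str] = set()
    for _, cells in _cells_by_heavy_group(screp).items():
        for a, b in itertools.combinations(cells, 2):
            if a.heavy.clonotype_key == b.heavy.clonotype_key:
                continue
            eligible += 1
            cells_involved.update((a.cell_id, b.cell_id))
            if a.light.v_gene == b.light.v_gene:
                coherent += 1
    return LccResult(
        scope="within_donor",
        n_cells_evaluated=len(cells_involved),
        n_eligible_pairs=eligible,
        n_coherent_pairs=coherent,
    )


def light_chain_coherence_across(
    repA: SingleCellRepertoire, repB: SingleCellRepertoire
) -> LccResult:
    """Across-donor LCC: cross-donor cell pairs with matching heavy V gene
    and CDRH3 (no different-clonotype requirement; cross-donor cells are
    clonally unrelated by construction)."""
    groupsA = _cells_by_heavy_group(repA)
    groupsB = _cells_by_heavy_group(repB)
    eligible = coherent = 0
    cells_involved: set[tuple[str, str]] = set()
    for key in set(groupsA) & set(groupsB):
        for a in groupsA[key]:
            for b in groupsB[key]:
                eligible += 1
                cells_involved.update({(repA.donor, a.cell_id), (repB.donor, b.cell_id)})
                if a.light.v_gene == b.light.v_gene:
                    coherent += 1
    return LccResult(
        scope="across_donors",
        n_cells_evaluated=len(cells_involved),
        n_eligible_pairs=eligible,
        n_coherent_pairs=coherent,
    )
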