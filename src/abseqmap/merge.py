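"""Cumulative merging of single-cell technical replicates.

Merging emulates increased sampling depth: cells from k replicates are
pooled (barcodes prefixed per replicate so droplets never collide),
clonotypes are rebuilt with sizes recounted from the pooled barcodes, and
the merged repertoire's unique-CDRH3 set is exactly the union of the
members' sets. The depth-overlap curve measures how the CDRH3 Jaccard
overlap with a deep bulk repertoire grows as replicates are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellRecord, Repertoire, SingleCellRepertoire
from .features import jaccard_overlap

__all__ = ["MergePlan", "merge_cumulative", "depth_overlap_curve"]


@dataclass(frozen=True)
class MergePlan:
    """A random replicate ordering: the first k entries are merged."""

    replicate_ids: tuple[str, ...]
    k: int
    seed: int

    def __post_init__(self):
        if not 1 <= self.k <= len(self.replicate_ids):
            raise ValueError(f"k={self.k} out of range for {len(self.replicate_ids)} replicates")
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise ValueError("replicate ids must be distinct")


def _plan(replicates, k, seed) -> MergePlan:
    ids = [rep.replicate_id or rep.sample_id for rep in replicates]
    order = np.random.default_rng(seed).permutation(len(ids))
    return MergePlan(tuple(ids[i] for i in order), k, seed)


def merge_cumulative(
    replicates: list[SingleCellRepertoire], k: int, seed: int = 0,
    plan: MergePlan | None = None,
) -> SingleCellRepertoire:
    """Merge k randomly selected technical replicates into one repertoire.

    All replicates must share donor and method. Cell barcodes are prefixed
    with their replicate id so pooled droplets stay distinct; clonotype
    sizes are recomputed as distinct pooled barcodes.
    """
    if not 1 <= k <= len(replicates):
        raise ValueError(f"k={k} out of range for {len(replicates)} replicates")
    donors = {rep.donor for rep in replicates}
    if len(donors) != 1:
        raise ValueError("replicates must share a donor")
    if any(rep.method != "single_cell" for rep in replicates):
        raise ValueError("replicates must be single-cell repertoires")
    if plan is None:
        plan = _plan(replicates, k, seed)
    by_id = {rep.replicate_id or rep.sample_id: rep for rep in replicates}
    cells: list[CellRecord] = []
    for rid in plan.replicate_ids[:k]:
        rep = by_id[rid]
        for cell in rep.cells:
            cells.append(
                CellRecord(cell_id=f"{rid}+{cell.cell_id}", heavy=cell.heavy, light=cell.light)
            )
    base = replicates[0]
    return SingleCellRepertoire.from_cells(
        cells,
        sample_id=f"{base.donor}_merged_k{k}",
        donor=base.donor,
        isotype_or_subset=base.isotype_or_subset,
        metadata={"merge_plan": plan},
    )


def depth_overlap_curve(
    bulk: Repertoire,
    replicates: list[SingleCellRepertoire],
    seeds: list[int],
) -> pd.DataFrame:
    """CDRH3 Jaccard overlap with bulk as replicates are cumulatively merged.

    For each seed a random replicate ordering is drawn once; for
    k = 1..len(replicates) the first k replicates are merged and
    J(bulk CDRH3 set, merged CDRH3 set) recorded. Returns a tidy table
    (k, seed, jaccard).
    """
    bulk_set = bulk.cdr3_set()
    rows = []
    for seed in seeds:
        plan_full = _plan(replicates, len(replicates), seed)
        for k in range(1, len(replicates) + 1):
            plan = MergePlan(plan_full.replicate_ids, k, seed)
            merged = merge_cumulative(replicates, k, plan=plan)
            rows.append(
                {"k": k, "seed": seed, "jaccard": jaccard_overlap(bulk_set, merged.cdr3_set())}
            )
    return pd.DataFrame(rows, columns=["k", "seed", "jaccard"])
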