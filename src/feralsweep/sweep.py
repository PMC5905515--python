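"""Sweep calling: joint top-5% thresholds, region merging, candidate genes.

A window is called a sweep in the target population when BOTH its F_ST
(target vs reference) and its log2 Hp-ratio reach the genome-wide top-5%
cutoffs of their own distributions.  Contiguous or overlapping called windows
are merged into regions; genes overlapping a region or its 15-kb flanks are
the candidate genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation

logger = logging.getLogger(__name__)

FLANK = 15_000
QUANTILE = 0.95
MIN_WINDOWS = 20


@dataclass(frozen=True)
class SweepThresholds:
    fst_cutoff: float
    hp_ratio_cutoff: float
    quantile: float = QUANTILE


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    member_windows: list[int]
    peak_fst: float
    peak_log2_hp_ratio: float
    flank_start: int = 0
    flank_end: int = 0


@dataclass
class CandidateGeneSet:
    population: str
    genes: dict[str, list[int]] = field(default_factory=dict)  # gene_id -> region idx

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes)


def _top_cutoff(values: np.ndarray, quantile: float) -> float:
    """Smallest value among the ceil((1-quantile)*N) highest-ranked windows."""
    finite = np.sort(values[np.isfinite(values)])
    # small epsilon guards the ceiling against float artifacts of (1 - q)
    n_top = math.ceil((1.0 - quantile) * len(values) - 1e-9)
    has_inf = np.isinf(values).sum()
    if n_top <= has_inf:
        # +inf sentinels alone fill the top set; any finite value is below them
        return float("inf")
    cutoff = finite[len(finite) - (n_top - has_inf)]
    if (values >= cutoff).all():
        warnings.warn("all windows tie at the selection boundary")
    return float(cutoff)


def compute_thresholds(stats: pd.DataFrame, quantile: float = QUANTILE) -> SweepThresholds:
    """Top-5% cutoffs for F_ST and log2 Hp-ratio from non-excluded windows.

    Rank-based: the ceil((1-quantile)*N) highest windows are selected per
    statistic and the cutoff is the smallest selected value, so boundary ties
    are included.
    """
    usable = stats.loc[~stats["excluded"]]
    if len(usable) < MIN_WINDOWS:
        raise ValueError(
            f"only {len(usable)} non-excluded windows; need >= {MIN_WINDOWS} "
            "to set sweep thresholds"
        )
    return SweepThresholds(
        fst_cutoff=_top_cutoff(usable["fst"].to_numpy(float), quantile),
        hp_ratio_cutoff=_top_cutoff(usable["log2_hp_ratio"].to_numpy(float), quantile),
        quantile=quantile,
    )


def call_sweep_windows(stats: pd.DataFrame, thresholds: SweepThresholds) -> pd.DataFrame:
    """Non-excluded windows whose F_ST AND Hp log-ratio reach their cutoffs."""
    fst = stats["fst"].to_numpy(float)
    hpr = stats["log2_hp_ratio"].to_numpy(float)
    called = (~stats["excluded"].to_numpy()
              & (fst >= thresholds.fst_cutoff)
              & (hpr >= thresholds.hp_ratio_cutoff))
    return stats.loc[called]


def merge_regions(called: pd.DataFrame, chrom_lengths: dict[str, int] | None = None,
                  flank: int = FLANK) -> list[SweepRegion]:
    """Union overlapping/book-ended called windows per chromosome, then apply
    flanks clipped to [0, chromosome length)."""
    regions: list[SweepRegion] = []
    if len(called) == 0:
        return regions
    called = called.sort_values(["chrom", "start"])
    cur = None
    for idx, row in called.iterrows():
        if (cur is not None and row["chrom"] == cur.chrom and row["start"] <= cur.end):
            cur.end = max(cur.end, int(row["end"]))
            cur.member_windows.append(int(idx))
            cur.peak_fst = max(cur.peak_fst, float(row["fst"]))
            cur.peak_log2_hp_ratio = max(cur.peak_log2_hp_ratio,
                                         float(row["log2_hp_ratio"]))
        else:
            if cur is not None:
                regions.append(cur)
            cur = SweepRegion(str(row["chrom"]), int(row["start"]), int(row["end"]),
                              [int(idx)], float(row["fst"]),
                              float(row["log2_hp_ratio"]))
    regions.append(cur)
    for r in regions:
        limit = (chrom_lengths or {}).get(r.chrom)
        r.flank_start = max(0, r.start - flank)
        r.flank_end = r.end + flank if limit is None else min(r.end + flank, limit)
    return regions


def candidate_genes(regions: list[SweepRegion], genes: GeneAnnotation,
                    population: str = "") -> CandidateGeneSet:
    """Genes overlapping (>= 1 bp) any region's flanked interval."""
    region_chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in genes}
    unmatched = region_chroms - gene_chroms
    if regions and len(genes) and unmatched:
        warnings.warn(f"no annotation on chromosomes: {sorted(unmatched)}")
    out = CandidateGeneSet(population)
    for i, r in enumerate(regions):
        for g in genes:
            if g.chrom == r.chrom and g.start < r.flank_end and g.end > r.flank_start:
                out.genes.setdefault(g.gene_id, []).append(i)
    return out


def overlap_candidate_sets(sets: dict[str, CandidateGeneSet],
                           named_combinations: dict[str, list[str]] | None = None
                           ) -> pd.DataFrame:
    """Venn-partition counts over >= 2 candidate-gene sets.

    One row per non-empty membership class (e.g. ``PT&OL``), plus optional
    named intersections (e.g. semi-feral = PT & OL).
    """
    if len(sets) < 2:
        raise ValueError("need at least two candidate sets")
    pops = sorted(sets)
    membership: dict[frozenset, set] = {}
    universe = set().union(*(sets[p].gene_ids for p in pops))
    for gene in universe:
        key = frozenset(p for p in pops if gene in sets[p].gene_ids)
        membership.setdefault(key, set()).add(gene)
    rows = []
    for r in range(1, len(pops) + 1):
        for combo in combinations(pops, r):
            genes_here = membership.get(frozenset(combo), set())
            rows.append({"class": "&".join(combo), "exclusive_count": len(genes_here)})
    for name, members in (named_combinations or {}).items():
        inter = set.intersection(*(sets[p].gene_ids for p in members))
        rows.append({"class": name, "exclusive_count": len(inter)})
    return pd.DataFrame(rows)
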