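"""Core in-memory containers shared by every pipeline stage.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted on ingest and converted back in written reports.  Genotypes are
stored as alt-allele dosages in ``{0, 1, 2}`` with ``-1`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class VariantTable:
    """Biallelic SNP sites x samples with alt-allele dosage genotypes.

    Attributes
    ----------
    chrom : np.ndarray of str, one entry per site
    pos : np.ndarray of int, 0-based site positions (VCF POS - 1)
    ref, alt : np.ndarray of single-character allele strings
    dosages : int8 array, shape (n_sites, n_samples); -1 encodes missing
    samples : list of unique sample identifiers, column order of ``dosages``
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("sample identifiers must be unique")
        if self.dosages.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 (missing)")
        self._sort_sites()

    def _sort_sites(self) -> None:
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.alt = self.alt[order]
            self.dosages = self.dosages[order]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids) -> np.ndarray:
        """Column indices of the given samples, in the given order."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)

    def take_sites(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        return VariantTable(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx],
            self.dosages[idx], list(self.samples),
        )

    def chrom_lengths(self) -> dict[str, int]:
        """Smallest per-chromosome lengths covering every site (max pos + 1)."""
        out: dict[str, int] = {}
        for c in dict.fromkeys(self.chrom):
            out[str(c)] = int(self.pos[self.chrom == c].max()) + 1
        return out


@dataclass
class PopulationMap:
    """sample -> breed, breed -> analysis group (group defaults to breed)."""

    sample_to_breed: dict[str, str]
    breed_to_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for breed in set(self.sample_to_breed.values()):
            self.breed_to_group.setdefault(breed, breed)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.breed_to_group.values()))

    def group_samples(self, group: str) -> list[str]:
        """Samples whose breed maps to ``group`` (or whose breed IS ``group``)."""
        hits = [
            s for s, b in self.sample_to_breed.items()
            if self.breed_to_group.get(b) == group or b == group
        ]
        if not hits:
            raise KeyError(f"no samples for population/group {group!r}")
        return hits


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )


@dataclass
class GeneAnnotation:
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)
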