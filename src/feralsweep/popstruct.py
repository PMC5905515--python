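"""Population structure and linkage utilities.

Distance matrices (genome-wide Weir-Cockerham F_ST, allele-sharing, mean
|dAF|), neighbor-joining trees (via scikit-bio, Newick out), EIGENSOFT-style
genotype PCA, and linkage disequilibrium: two-locus EM haplotype frequencies,
D / D' / r-squared, PLINK-style ``--indep-pairwise`` pruning and distance-
binned r-squared decay curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj

from .datatypes import MISSING, VariantTable
from .windows import allele_counts, wc_components, fst_from_components

logger = logging.getLogger(__name__)

EM_TOL = 1e-10
EM_MAX_ITER = 1000


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix must have zero diagonal")


@dataclass
class LDStats:
    hap_freqs: np.ndarray  # [f_RR, f_RA, f_AR, f_AA] over (locus1, locus2) alleles
    D: float
    d_prime: float
    r2: float


# ---------------------------------------------------------------------------
# distances and trees

def fst_distance_matrix(vt: VariantTable, pops: dict[str, list[str]]) -> DistanceMatrix:
    """Pairwise genome-wide Weir-Cockerham F_ST (ratio of averages over all
    sites); negatives clamped to 0 for use as distances."""
    labels = list(pops)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    for name, members in pops.items():
        if len(members) < 2:
            raise ValueError(f"population {name!r} has fewer than 2 samples")
    idx = {k: vt.sample_indices(v) for k, v in pops.items()}
    m = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, tot = wc_components(vt.dosages[:, idx[labels[i]]],
                                   vt.dosages[:, idx[labels[j]]])
            fst = fst_from_components(a, tot)
            m[i, j] = m[j, i] = max(0.0, fst) if np.isfinite(fst) else 0.0
    return DistanceMatrix(labels, m)


def allele_sharing_distance(vt: VariantTable, samples: list[str]) -> DistanceMatrix:
    """d(i, j) = sum over sites non-missing in both of |dosage_i - dosage_j|."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    d = vt.dosages[:, vt.sample_indices(samples)].astype(float)
    d[d == MISSING] = np.nan
    n = len(samples)
    m = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(d[:, i:i + 1] - d[:, i + 1:])
        m[i, i + 1:] = np.nansum(diff, axis=0)
    m += m.T
    return DistanceMatrix(samples, m)


def allele_freq_distance(vt: VariantTable, pops: dict[str, list[str]]) -> DistanceMatrix:
    """Mean over sites of |alt_freq_A - alt_freq_B| (average delta-AF)."""
    labels = list(pops)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    freqs = {}
    for name, members in pops.items():
        alt, nchrom = allele_counts(vt.dosages[:, vt.sample_indices(members)])
        with np.errstate(invalid="ignore"):
            freqs[name] = np.where(nchrom > 0, alt / np.maximum(nchrom, 1), np.nan)
    m = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = np.abs(freqs[labels[i]] - freqs[labels[j]])
            m[i, j] = m[j, i] = float(np.nanmean(diff))
    return DistanceMatrix(labels, m)


def neighbor_joining(dm: DistanceMatrix):
    """Saitou-Nei neighbor joining; returns an skbio TreeNode (Newick via
    ``str(tree)`` or ``tree.write``)."""
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(SkbioDM(dm.matrix, ids=dm.labels))


# ---------------------------------------------------------------------------
# PCA

def pca_genotypes(vt: VariantTable, samples: list[str], n_components: int = 10
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """EIGENSOFT-style genotype PCA.

    Sites are mean-centered and scaled by sqrt(p(1-p)); missing dosages are
    mean-imputed per site.  Returns per-sample coordinates and the explained
    variance fraction per component.  Sign convention: the largest-magnitude
    sample loading on each component is positive.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    d = vt.dosages[:, vt.sample_indices(samples)].astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=1)
    p_hat = mean / 2.0
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    poly = scale > 0
    if not poly.any():
        raise ValueError("no polymorphic sites: PCA undefined")
    d = d[poly]
    d = np.where(np.isnan(d), mean[poly, None], d)
    x = (d - mean[poly, None]) / scale[poly, None]  # sites x samples
    total_var = np.var(x, axis=1, ddof=1).sum()
    if total_var == 0:
        raise ValueError("all samples identical: PCA undefined")
    # SVD of samples x sites
    u, s, _ = np.linalg.svd(x.T - x.T.mean(axis=0), full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    for c in range(k):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] *= -1
    explained = (s[:k] ** 2) / (s ** 2).sum()
    df = pd.DataFrame(coords, index=samples,
                      columns=[f"PC{i + 1}" for i in range(k)])
    return df, explained


# ---------------------------------------------------------------------------
# two-locus EM and LD

def em_haplotype_freq(counts: np.ndarray, tol: float = EM_TOL,
                      max_iter: int = EM_MAX_ITER) -> np.ndarray:
    """ML two-locus haplotype frequencies from a 3x3 unphased genotype table.

    ``counts[i, j]`` is the number of individuals carrying i alt alleles at
    locus 1 and j at locus 2.  Only the double heterozygote has ambiguous
    phase; EM splits it between cis (RR/AA) and trans (RA/AR) resolutions.
    Returns ``[f_RR, f_RA, f_AR, f_AA]`` (R = ref, A = alt allele).
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (3, 3) or (c < 0).any():
        raise ValueError("counts must be a non-negative 3x3 table")
    n = c.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    # unambiguous haplotype counts: genotype (i,j) contributes known gametes
    # except (1,1).  Count of R/A at each locus per genotype is fixed.
    base = np.zeros(4)  # RR, RA, AR, AA
    for i in range(3):
        for j in range(3):
            if (i, j) == (1, 1):
                continue
            ni = c[i, j]
            h1 = [2 - i, i]  # copies of (R, A) at locus 1
            h2 = [2 - j, j]
            if i == 1 and j != 1:
                base[0 if j == 0 else 1] += ni  # R_ paired with known locus2
                base[2 if j == 0 else 3] += ni
            elif j == 1 and i != 1:
                base[0 if i == 0 else 2] += ni
                base[1 if i == 0 else 3] += ni
            else:  # both homozygous
                hap = (0 if i == 0 else 2) + (0 if j == 0 else 1)
                base[hap] += 2 * ni
    dh = c[1, 1]
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = base.copy()
        new[0] += dh * w
        new[3] += dh * w
        new[1] += dh * (1 - w)
        new[2] += dh * (1 - w)
        new /= 2.0 * n
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def hap_log_likelihood(counts: np.ndarray, f: np.ndarray) -> float:
    """Observed-data log-likelihood of a 3x3 genotype table under haplotype
    frequencies ``f = [RR, RA, AR, AA]`` with random mating."""
    c = np.asarray(counts, dtype=float)
    ll = 0.0
    probs = {
        (0, 0): f[0] ** 2, (0, 1): 2 * f[0] * f[1], (0, 2): f[1] ** 2,
        (1, 0): 2 * f[0] * f[2], (1, 1): 2 * f[0] * f[3] + 2 * f[1] * f[2],
        (1, 2): 2 * f[1] * f[3],
        (2, 0): f[2] ** 2, (2, 1): 2 * f[2] * f[3], (2, 2): f[3] ** 2,
    }
    for (i, j), p in probs.items():
        if c[i, j] > 0:
            ll += c[i, j] * np.log(max(p, 1e-300))
    return float(ll)


def ld_pair(hap_freqs: np.ndarray) -> LDStats:
    """D, D' and r-squared from 4 haplotype frequencies [RR, RA, AR, AA]."""
    f = np.asarray(hap_freqs, dtype=float)
    pA = f[2] + f[3]  # alt freq locus 1
    pB = f[1] + f[3]  # alt freq locus 2
    qA, qB = 1.0 - pA, 1.0 - pB
    if min(pA, qA, pB, qB) <= 0:
        return LDStats(f, float("nan"), float("nan"), float("nan"))
    D = f[3] - pA * pB
    d_max = min(pA * qB, qA * pB) if D > 0 else min(pA * pB, qA * qB)
    d_prime = abs(D) / d_max if d_max > 0 else float("nan")
    r2 = D * D / (pA * qA * pB * qB)
    return LDStats(f, float(D), float(d_prime), float(r2))


def genotype_pair_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """3x3 joint genotype table for two dosage vectors, ignoring missing."""
    ok = (gi != MISSING) & (gj != MISSING)
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi[ok], gj[ok]), 1)
    return counts


def r2_between_sites(gi: np.ndarray, gj: np.ndarray) -> float:
    counts = genotype_pair_counts(gi, gj)
    if counts.sum() == 0:
        return float("nan")
    return ld_pair(em_haplotype_freq(counts)).r2


def ld_decay(vt: VariantTable, pop: list[str], max_dist: int = 100_000,
             bin_edges=None, min_maf: float = 0.1, missing_cutoff: float = 0.2,
             max_pairs: int = 50_000, seed: int = 0) -> pd.DataFrame:
    """Mean r-squared of intra-chromosomal SNP pairs binned by distance.

    Sites first pass the MAF and per-site missingness filters; pairs within
    ``max_dist`` are subsampled to ``max_pairs`` with the stated seed.
    Empty bins report NaN, not zero.
    """
    if bin_edges is None:
        bin_edges = list(range(0, max_dist + 1, 1000))
    d = vt.dosages[:, vt.sample_indices(pop)]
    alt, nchrom = allele_counts(d)
    with np.errstate(invalid="ignore"):
        f = np.where(nchrom > 0, alt / np.maximum(nchrom, 1), 0.0)
    maf = np.minimum(f, 1.0 - f)
    miss = (d == MISSING).mean(axis=1)
    keep = np.flatnonzero((maf >= min_maf) & (miss <= missing_cutoff))

    pairs = []
    for c in dict.fromkeys(vt.chrom[keep]):
        sel = keep[vt.chrom[keep] == c]
        pos = vt.pos[sel]
        for ii in range(len(sel)):
            hi = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            for jj in range(ii + 1, hi):
                pairs.append((sel[ii], sel[jj]))
    rng = np.random.default_rng(seed)
    if len(pairs) > max_pairs:
        chosen = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(chosen)]

    edges = np.asarray(bin_edges)
    sums = np.zeros(len(edges) - 1)
    ns = np.zeros(len(edges) - 1, dtype=int)
    for i, j in pairs:
        dist = abs(int(vt.pos[j]) - int(vt.pos[i]))
        b = np.searchsorted(edges, dist, side="right") - 1
        if b < 0 or b >= len(sums):
            continue
        r2 = r2_between_sites(d[i], d[j])
        if np.isfinite(r2):
            sums[b] += r2
            ns[b] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:],
        "mean_r2": mean_r2, "n_pairs": ns,
    })


def ld_prune(vt: VariantTable, pop: list[str] | None = None,
             window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.2) -> np.ndarray:
    """PLINK ``--indep-pairwise``-style pruning; returns retained site indices.

    Within each sliding window of ``window_snps`` sites (advancing
    ``step_snps``) the later-position member of any pair with r-squared above
    ``r2_max`` is removed; removals accumulate globally.
    """
    samples = pop if pop is not None else vt.samples
    d = vt.dosages[:, vt.sample_indices(samples)]
    removed = np.zeros(vt.n_sites, dtype=bool)
    for c in dict.fromkeys(vt.chrom):
        chrom_idx = np.flatnonzero(vt.chrom == c)
        start = 0
        while start < len(chrom_idx):
            win = chrom_idx[start:start + window_snps]
            live = [s for s in win if not removed[s]]
            changed = True
            while changed:
                changed = False
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        i, j = live[a], live[b]
                        r2 = r2_between_sites(d[i], d[j])
                        if np.isfinite(r2) and r2 > r2_max:
                            removed[j] = True
                            live.pop(b)
                            changed = True
                            break
                    if changed:
                        break
            if start + window_snps >= len(chrom_idx):
                break
            start += step_snps
    return np.flatnonzero(~removed)
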