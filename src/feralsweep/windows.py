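"""Sliding-window population-genetic statistics.

The genome is tiled with 30-kb windows advancing in 15-kb steps (defaults).
For a target and a reference population each window receives:

* Weir & Cockerham (1984) F_ST, accumulated as a ratio of averages
  (sum of per-site ``a`` components over sum of ``a + b + c``);
* pooled heterozygosity ``H_P = 2 * sum(p) * sum(q) / (sum(p) + sum(q))**2``
  over the major (p) and minor (q) allele frequencies of every SNP site in
  the window, computed per population;
* the heterozygosity-loss statistic ``log2(H_P|ref / H_P|target)``;
* nucleotide diversity pi, Watterson's theta and Tajima's D for the target;
* SNP density, a low-variant exclusion flag, and genome-wide Z-scores.

Windows with fewer than ``min_variants`` (default 50) cohort SNPs are flagged
excluded and take no part in Z-scores or sweep thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, VariantTable

logger = logging.getLogger(__name__)

#: default scan geometry and exclusion rule
WINDOW_SIZE = 30_000
STEP = 15_000
MIN_VARIANTS = 50


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int
    index: int = 0


def make_windows(chrom_lengths: dict[str, int], window_size: int = WINDOW_SIZE,
                 step: int = STEP) -> list[Window]:
    """Tile each chromosome with half-overlapping windows.

    Starts run 0, step, 2*step, ... while ``start < length``; the terminal
    window is truncated at the chromosome end.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if step > window_size:
        raise ValueError("step must not exceed window_size")
    windows: list[Window] = []
    idx = 0
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            warnings.warn(f"chromosome {chrom} has length {length}; no windows made")
            continue
        start = 0
        while start < length:
            windows.append(Window(str(chrom), start, min(start + window_size, length), idx))
            idx += 1
            start += step
    return windows


# ---------------------------------------------------------------------------
# per-site frequency machinery

def allele_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt-allele count, non-missing allele count) for a dosage
    submatrix of shape (sites, samples)."""
    called = dosages != MISSING
    n_chrom = 2 * called.sum(axis=1)
    alt = np.where(called, dosages, 0).sum(axis=1)
    return alt.astype(np.int64), n_chrom.astype(np.int64)


def site_frequencies(vt: VariantTable, pop: list[str]) -> pd.DataFrame:
    """Major/minor allele frequencies per site within one population.

    Returns columns ``p`` (major), ``q`` (minor), ``alt_freq``, ``n_chrom``;
    sites with zero non-missing calls carry NaN frequencies and ``usable``
    False so downstream statistics can skip them.
    """
    if not pop:
        raise ValueError("population sample set is empty")
    d = vt.dosages[:, vt.sample_indices(pop)]
    alt, n_chrom = allele_counts(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
    p = np.maximum(alt_freq, 1.0 - alt_freq)
    q = np.minimum(alt_freq, 1.0 - alt_freq)
    return pd.DataFrame({
        "p": p, "q": q, "alt_freq": alt_freq,
        "n_chrom": n_chrom, "usable": n_chrom > 0,
    })


def pooled_heterozygosity(p: np.ndarray, q: np.ndarray) -> float:
    """``H_P = 2 * sum(p) * sum(q) / (sum(p) + sum(q))**2`` over window sites.

    ``p`` are major-allele and ``q`` minor-allele frequencies; NaN rows
    (no-call sites) are ignored.  Returns NaN when no site is usable.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    ok = ~np.isnan(p)
    if not ok.any():
        return float("nan")
    sp, sq = p[ok].sum(), q[ok].sum()
    return float(2.0 * sp * sq / (sp + sq) ** 2)


def hp_log_ratio(hp_ref: float, hp_target: float) -> float:
    """``log2(hp_ref / hp_target)``; positive means heterozygosity loss in the
    target.  A zero target yields +inf (infinite-loss sentinel)."""
    if np.isnan(hp_ref) or np.isnan(hp_target):
        return float("nan")
    if hp_target == 0.0:
        return float("-inf") if hp_ref == 0.0 else float("inf")
    return float(np.log2(hp_ref / hp_target))


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST

def wc_components(dosA: np.ndarray, dosB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) variance components for two populations.

    Returns arrays ``a`` (between-population) and ``a + b + c`` (total);
    sites where either population has no genotyped individual, or fewer than
    two overall, contribute zero to both.
    """
    r = 2.0
    comps = []
    for d in (dosA, dosB):
        called = d != MISSING
        n = called.sum(axis=1).astype(float)           # individuals
        alt = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h = np.where(n > 0, (np.where(called, d, 0) == 1).sum(axis=1)
                         / np.maximum(n, 1), np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    nt = n1 + n2
    ok = (n1 > 0) & (n2 > 0) & (nt > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = nt / r
        nc = (nt - (n1 ** 2 + n2 ** 2) / nt) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / nt
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / nt
        inner = p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r
        a = n_bar / nc * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = n_bar / (n_bar - 1.0) * (inner - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar))
        c = h_bar / 2.0
        total = a + b + c
    a = np.where(ok, a, 0.0)
    total = np.where(ok, total, 0.0)
    return np.nan_to_num(a), np.nan_to_num(total)


def fst_from_components(a: np.ndarray, total: np.ndarray) -> float:
    """Ratio-of-averages aggregation; NaN when no site carries information."""
    denom = float(np.sum(total))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(a) / denom)


def fst_window(vt: VariantTable, popA: list[str], popB: list[str],
               window: Window) -> float:
    """Weir-Cockerham F_ST between two populations over one window's sites.

    Raw (possibly slightly negative) value; callers clamp to [0, 1] for
    reports.
    """
    idx = sites_in_window(vt, window)
    if idx.size == 0:
        return float("nan")
    dA = vt.dosages[np.ix_(idx, vt.sample_indices(popA))]
    dB = vt.dosages[np.ix_(idx, vt.sample_indices(popB))]
    a, total = wc_components(dA, dB)
    return fst_from_components(a, total)


def sites_in_window(vt: VariantTable, window: Window) -> np.ndarray:
    on_chrom = np.flatnonzero(vt.chrom == window.chrom)
    pos = vt.pos[on_chrom]
    lo = np.searchsorted(pos, window.start, side="left")
    hi = np.searchsorted(pos, window.end, side="left")
    return on_chrom[lo:hi]


# ---------------------------------------------------------------------------
# diversity statistics

def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i ** power for i in range(1, n)))


def _pi_sum(alt_freq: np.ndarray, n_chrom: np.ndarray) -> float:
    """Sum over sites of the unbiased per-site heterozygosity
    ``2*p*q*k/(k-1)`` (expected pairwise differences)."""
    ok = n_chrom > 1
    f, k = alt_freq[ok], n_chrom[ok].astype(float)
    return float(np.sum(2.0 * f * (1.0 - f) * k / (k - 1.0)))


def nucleotide_diversity(vt: VariantTable, pop: list[str], window: Window) -> float:
    """pi per bp: average pairwise differences in the window / window length."""
    length = window.end - window.start
    if length <= 0:
        raise ValueError("window has zero length")
    idx = sites_in_window(vt, window)
    if idx.size == 0:
        return 0.0
    alt, n_chrom = allele_counts(vt.dosages[np.ix_(idx, vt.sample_indices(pop))])
    with np.errstate(invalid="ignore"):
        f = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), 0.0)
    return _pi_sum(f, n_chrom) / length


def watterson_theta(vt: VariantTable, pop: list[str], window: Window) -> float:
    """theta_W per bp: S / (a_{k-1} * L) with S the segregating sites within
    the population and k the (mean, rounded) non-missing allele count."""
    length = window.end - window.start
    if length <= 0:
        raise ValueError("window has zero length")
    idx = sites_in_window(vt, window)
    if idx.size == 0:
        return 0.0
    alt, n_chrom = allele_counts(vt.dosages[np.ix_(idx, vt.sample_indices(pop))])
    seg = (alt > 0) & (alt < n_chrom)
    S = int(seg.sum())
    if S == 0:
        return 0.0
    k = int(round(n_chrom[n_chrom > 1].mean()))
    return S / (_harmonic(k) * length)


def tajimas_d(vt: VariantTable, pop: list[str], window: Window) -> float:
    """Tajima's (1989) D for the population's window sites; NaN when S = 0."""
    idx = sites_in_window(vt, window)
    if idx.size == 0:
        return float("nan")
    alt, n_chrom = allele_counts(vt.dosages[np.ix_(idx, vt.sample_indices(pop))])
    return _tajima_from_counts(alt, n_chrom)


def _tajima_from_counts(alt: np.ndarray, n_chrom: np.ndarray) -> float:
    seg = (alt > 0) & (alt < n_chrom)
    S = int(seg.sum())
    if S == 0 or not (n_chrom > 1).any():
        return float("nan")
    n = int(round(n_chrom[n_chrom > 1].mean()))
    if n < 4:
        return float("nan")
    with np.errstate(invalid="ignore"):
        f = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), 0.0)
    pi = _pi_sum(f, n_chrom)
    a1, a2 = _harmonic(n), _harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return float("nan")
    return float((pi - S / a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# window-table assembly

def exclude_low_variant_windows(stats: pd.DataFrame,
                                min_variants: int = MIN_VARIANTS) -> pd.DataFrame:
    """Flag (never drop) windows with fewer than ``min_variants`` SNPs."""
    out = stats.copy()
    out["excluded"] = out["n_variants"] < min_variants
    return out


def z_transform(values) -> np.ndarray:
    """Standardize to mean 0, sample (n-1) sd 1; errors on constant input."""
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError("need at least two finite values to Z-transform")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: cannot Z-transform")
    return (x - finite.mean()) / sd


def scan_windows(vt: VariantTable, target: list[str], reference: list[str],
                 chrom_lengths: dict[str, int] | None = None,
                 window_size: int = WINDOW_SIZE, step: int = STEP,
                 min_variants: int = MIN_VARIANTS) -> pd.DataFrame:
    """Full per-window statistics table for one target-vs-reference scan.

    Columns: chrom, start, end, n_variants, fst, hp_target, hp_ref,
    log2_hp_ratio, pi, theta_w, tajima_d, snp_density, excluded, z_fst, z_hp.
    ``fst`` is clamped to [0, 1]; ``fst_raw`` keeps the unclamped value.
    Z-scores are computed over non-excluded finite windows only.
    """
    if chrom_lengths is None:
        chrom_lengths = vt.chrom_lengths()
    windows = make_windows(chrom_lengths, window_size, step)

    ti = vt.sample_indices(target)
    ri = vt.sample_indices(reference)
    # precompute per-site quantities once, aggregate per window
    ft = site_frequencies(vt, target)
    fr = site_frequencies(vt, reference)
    a_comp, tot_comp = wc_components(vt.dosages[:, ti], vt.dosages[:, ri])
    alt_t, nchrom_t = allele_counts(vt.dosages[:, ti])

    rows = []
    for w in windows:
        idx = sites_in_window(vt, w)
        nvar = int(idx.size)
        length = w.end - w.start
        if nvar:
            hp_t = pooled_heterozygosity(ft["p"].values[idx], ft["q"].values[idx])
            hp_r = pooled_heterozygosity(fr["p"].values[idx], fr["q"].values[idx])
            fst_raw = fst_from_components(a_comp[idx], tot_comp[idx])
            with np.errstate(invalid="ignore"):
                af = np.where(nchrom_t[idx] > 0,
                              alt_t[idx] / np.maximum(nchrom_t[idx], 1), 0.0)
            pi = _pi_sum(af, nchrom_t[idx]) / length
            seg = (alt_t[idx] > 0) & (alt_t[idx] < nchrom_t[idx])
            S = int(seg.sum())
            kk = nchrom_t[idx][nchrom_t[idx] > 1]
            theta = (S / (_harmonic(int(round(kk.mean()))) * length)
                     if S and kk.size else 0.0)
            taj = _tajima_from_counts(alt_t[idx], nchrom_t[idx])
        else:
            hp_t = hp_r = fst_raw = taj = float("nan")
            pi = theta = 0.0
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "n_variants": nvar,
            "fst_raw": fst_raw,
            "fst": float(np.clip(fst_raw, 0.0, 1.0)) if np.isfinite(fst_raw) else fst_raw,
            "hp_target": hp_t, "hp_ref": hp_r,
            "log2_hp_ratio": hp_log_ratio(hp_r, hp_t),
            "pi": pi, "theta_w": theta, "tajima_d": taj,
            "snp_density": nvar / (length / 1000.0),
        })
    stats = exclude_low_variant_windows(pd.DataFrame(rows), min_variants)

    for col, zcol in (("fst", "z_fst"), ("log2_hp_ratio", "z_hp")):
        vals = stats[col].to_numpy(dtype=float)
        usable = ~stats["excluded"].to_numpy() & np.isfinite(vals)
        z = np.full(len(stats), np.nan)
        if usable.sum() >= 2 and vals[usable].std(ddof=1) > 0:
            z[usable] = z_transform(vals[usable])
        else:
            logger.warning("not enough usable windows to Z-transform %s", col)
        stats[zcol] = z
    n_exc = int(stats["excluded"].sum())
    if n_exc:
        logger.info("%d windows excluded (<%d variants)", n_exc, min_variants)
    return stats
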