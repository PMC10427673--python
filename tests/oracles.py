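"""Independent brute-force reference implementations used only by tests.

Each oracle takes a deliberately naive route (exact rational arithmetic,
explicit loops, generic library fits) so it shares no code path with the
package implementation it checks.
"""

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational enumeration of the conditional Hardy-Weinberg test."""
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    n_r = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_r == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        hom_r = (n_r - h) // 2
        hom_c = n - h - hom_r
        return Fraction(
            factorial(n) * 2 ** h * factorial(n_r) * factorial(2 * n - n_r),
            factorial(hom_r) * factorial(h) * factorial(hom_c) * factorial(2 * n),
        )

    obs = prob(n_Aa)
    total = Fraction(0)
    for h in range(n_r % 2, n_r + 1, 2):
        p = prob(h)
        if p <= obs:
            total += p
    return float(min(total, Fraction(1)))


def naive_impute(dosages: np.ndarray) -> np.ndarray:
    d = dosages.copy()
    for j in range(d.shape[1]):
        col = d[:, j]
        mean = np.nanmean(col) if np.isfinite(col).any() else 0.0
        col[np.isnan(col)] = mean
    return d


def naive_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared correlation via the textbook sums-of-products formula."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx = (x * x).sum() - sx * sx / n
    syy = (y * y).sum() - sy * sy / n
    sxy = (x * y).sum() - sx * sy / n
    return (sxy * sxy) / (sxx * syy)


def clump_greedy_trace(table, geno, r2_cutoff=0.1, window_kb=250.0):
    """Explicit-loop replay of greedy p-value clumping; returns index SNP ids
    sorted by (chrom, pos, id)."""
    d = naive_impute(geno.dosages)
    col = {s: k for k, s in enumerate(geno.snp_meta["snp_id"])}
    records = [
        dict(snp_id=row.snp_id, chrom=str(row.chrom), pos=float(row.pos), p=float(row.p))
        for row in table.itertuples()
    ]
    order = sorted(records, key=lambda r: (r["p"], r["chrom"], r["pos"], r["snp_id"]))
    assigned = set()
    indices = []
    w = window_kb * 1000.0
    for rec in order:
        if rec["snp_id"] in assigned:
            continue
        indices.append(rec)
        assigned.add(rec["snp_id"])
        for other in records:
            if other["snp_id"] in assigned or other["chrom"] != rec["chrom"]:
                continue
            if not (rec["pos"] - w <= other["pos"] < rec["pos"] + w):
                continue
            r2 = naive_r2(d[:, col[rec["snp_id"]]], d[:, col[other["snp_id"]]])
            if r2 >= r2_cutoff:
                assigned.add(other["snp_id"])
    indices.sort(key=lambda r: (r["chrom"], r["pos"], r["snp_id"]))
    return [r["snp_id"] for r in indices]


def latent_threshold_adjacent_r2(maf_a: float, maf_b: float, rho: float,
                                 n: int, seed: int) -> float:
    """Brute-force simulation of the latent AR(1) thresholding model for one
    adjacent SNP pair, returning the sample genotype r^2."""
    rng = np.random.default_rng(seed)
    dos = np.zeros((n, 2))
    for _ in range(2):  # two haplotypes
        za = rng.standard_normal(n)
        zb = rho * za + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        from scipy.stats import norm
        dos[:, 0] += za < norm.ppf(maf_a)
        dos[:, 1] += zb < norm.ppf(maf_b)
    return naive_r2(dos[:, 0], dos[:, 1])
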