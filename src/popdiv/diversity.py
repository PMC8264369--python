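"""Missing-data-aware diversity and differentiation estimators.

Nucleotide diversity counts allele-pair mismatches and comparisons per site
and divides the summed mismatches by the summed comparisons over the region
(ratio of sums, never a mean of per-site ratios), so invariant sites and
missing calls are handled without bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from popdiv.variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiversityStats:
    ho: float
    he: float
    pi: float
    n_samples: int
    n_sites_used: int


@dataclass
class FstResult:
    fst: float
    numerator_sum: float
    denominator_sum: float
    n_sites_used: int
    estimator: str


def site_mismatch_counts(calls: np.ndarray) -> tuple[int, int]:
    """Allele-pair (mismatches, comparisons) at one site.

    With ``n`` non-missing allele copies of which ``k`` carry the alt allele:
    comparisons = n(n-1)/2 and mismatches = k(n-k). Fewer than two copies
    gives (0, 0).
    """
    calls = np.asarray(calls)
    called = calls != MISSING
    n = 2 * int(called.sum())
    if n < 2:
        return 0, 0
    k = int(calls[called].sum())
    return k * (n - k), n * (n - 1) // 2


def _counts_block(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-site (allele copies n, alt copies k) over sample rows."""
    called = dosages != MISSING
    n = 2 * called.sum(axis=0)
    k = np.where(called, dosages, 0).sum(axis=0)
    return n.astype(np.int64), k.astype(np.int64)


def pi_over_region(
    matrix: GenotypeMatrix,
    samples: list[str] | None = None,
    region: tuple[str, int, int] | None = None,
) -> float:
    """Nucleotide diversity over a region: sum(diffs) / sum(comparisons).

    All sites in the region contribute comparisons — variant and invariant
    alike. Returns NaN when no site yields a comparison.
    """
    idx = matrix.sample_indices(samples)
    mask = matrix.site_mask_in_region(region)
    dos = matrix.dosages[np.ix_(idx, np.flatnonzero(mask))]
    n, k = _counts_block(dos)
    usable = n >= 2
    comps = (n[usable] * (n[usable] - 1) // 2).sum()
    if comps == 0:
        logger.warning("pi_over_region: no usable sites in region %s", region)
        return math.nan
    diffs = (k[usable] * (n[usable] - k[usable])).sum()
    return float(diffs / comps)


def het_stats(
    matrix: GenotypeMatrix,
    samples: list[str] | None = None,
    unbiased: bool = False,
) -> DiversityStats:
    """Observed/expected heterozygosity over variant sites.

    Per site: ho = het calls / non-missing calls and he = 2*p*(1-p) with p the
    alt-allele frequency; H_O and H_E are unweighted means over variant sites
    with at least two non-missing calls. ``unbiased`` applies the n/(n-1)
    small-sample correction to he (n = allele copies).
    """
    idx = matrix.sample_indices(samples)
    var = np.flatnonzero(matrix.is_variant)
    if len(var) == 0:
        raise ValueError("het_stats requires at least one variant site")
    dos = matrix.dosages[np.ix_(idx, var)]
    called = dos != MISSING
    n_calls = called.sum(axis=0)
    ok = n_calls >= 2
    if not ok.any():
        raise ValueError("no variant site has >= 2 non-missing calls")
    dos = dos[:, ok]
    called = called[:, ok]
    n_calls = n_calls[ok]

    het = ((dos == 1) & called).sum(axis=0)
    ho_site = het / n_calls
    n_copies = 2 * n_calls
    p = np.where(called, dos, 0).sum(axis=0) / n_copies
    he_site = 2.0 * p * (1.0 - p)
    if unbiased:
        he_site = he_site * n_copies / (n_copies - 1)

    pi = pi_over_region(matrix, samples=samples)
    return DiversityStats(
        ho=float(ho_site.mean()),
        he=float(he_site.mean()),
        pi=pi,
        n_samples=len(idx),
        n_sites_used=int(ok.sum()),
    )


def _hudson_site_terms(
    n1: np.ndarray, k1: np.ndarray, n2: np.ndarray, k2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator; usable mask requires n >= 2 per pop."""
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(usable, k1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(usable, k2 / np.maximum(n2, 1), 0.0)
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den, usable


def _wc_site_terms(
    n1: np.ndarray, k1: np.ndarray, h1: np.ndarray, n2: np.ndarray, k2: np.ndarray, h2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) a and a+b+c variance components, two populations.

    Sample sizes are in diploid individuals; h is the count of heterozygous
    individuals per site.
    """
    r = 2.0
    ni1 = n1 / 2.0
    ni2 = n2 / 2.0
    usable = (ni1 >= 1) & (ni2 >= 1) & (ni1 + ni2 > 2)
    ni1 = np.maximum(ni1, 1e-12)
    ni2 = np.maximum(ni2, 1e-12)
    p1 = k1 / np.maximum(n1, 1)
    p2 = k2 / np.maximum(n2, 1)
    hf1 = h1 / np.maximum(ni1, 1e-12)
    hf2 = h2 / np.maximum(ni2, 1e-12)

    n_bar = (ni1 + ni2) / r
    n_c = (r * n_bar - (ni1**2 + ni2**2) / (r * n_bar)) / (r - 1)
    p_bar = (ni1 * p1 + ni2 * p2) / (r * n_bar)
    s2 = (ni1 * (p1 - p_bar) ** 2 + ni2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (ni1 * hf1 + ni2 * hf2) / (r * n_bar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
        abc = a + b + c
    return a, abc, usable & np.isfinite(a) & np.isfinite(abc)


def fst_pair(
    matrix: GenotypeMatrix,
    pop_a: list[str],
    pop_b: list[str],
    region: tuple[str, int, int] | None = None,
    estimator: str = "hudson",
) -> FstResult:
    """Pairwise F_ST between two sample subsets as a ratio of sums.

    Hudson (default): per-site N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1), F_ST = sum(N)/sum(D). The Weir-Cockerham option
    uses sum(a)/sum(a+b+c) with the 1984 two-population components. Only
    variant sites contribute. Returns NaN F_ST when the denominator sum is 0.
    """
    if estimator not in ("hudson", "weir_cockerham"):
        raise ValueError(f"unknown estimator: {estimator}")
    ia = matrix.sample_indices(pop_a)
    ib = matrix.sample_indices(pop_b)
    mask = matrix.site_mask_in_region(region) & matrix.is_variant
    cols = np.flatnonzero(mask)
    da = matrix.dosages[np.ix_(ia, cols)]
    db = matrix.dosages[np.ix_(ib, cols)]
    n1, k1 = _counts_block(da)
    n2, k2 = _counts_block(db)

    if estimator == "hudson":
        num, den, usable = _hudson_site_terms(n1, k1, n2, k2)
    else:
        h1 = ((da == 1)).sum(axis=0)
        h2 = ((db == 1)).sum(axis=0)
        num, den, usable = _wc_site_terms(n1, k1, h1, n2, k2, h2)

    num_sum = float(num[usable].sum())
    den_sum = float(den[usable].sum())
    if den_sum == 0.0:
        logger.warning("fst_pair: zero denominator sum (region %s)", region)
        fst = math.nan
    else:
        fst = num_sum / den_sum
    return FstResult(
        fst=fst,
        numerator_sum=num_sum,
        denominator_sum=den_sum,
        n_sites_used=int(usable.sum()),
        estimator=estimator,
    )


def diversity_table(
    matrix: GenotypeMatrix,
    populations: dict[str, list[str]],
    unbiased_he: bool = False,
):
    """Per-population H_O/H_E/pi summary as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for name, samples in populations.items():
        stats = het_stats(matrix, samples=samples, unbiased=unbiased_he)
        rows.append(
            {
                "population": name,
                "n_samples": stats.n_samples,
                "ho": stats.ho,
                "he": stats.he,
                "pi": stats.pi,
                "n_sites": stats.n_sites_used,
            }
        )
    return pd.DataFrame(rows)
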