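"""Joint F_ST / pi-ratio sliding-window selective-sweep scan.

Windows are half-open 0-based internally (reports convert to 1-based
inclusive). Per window we compute pi for each pool (ratio of sums), Hudson
F_ST, and the weedy/cultivated pi ratio; windows in the joint top tail of
both distributions are selected and merged into sweep regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from popdiv.diversity import _counts_block, _hudson_site_terms
from popdiv.variant_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int
    truncated: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class WindowStat:
    window: Window
    pi_w: float
    pi_c: float
    fst: float
    pi_ratio: float  # may be +inf
    n_variant_sites: int
    usable: bool


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    windows: list[Window] = field(default_factory=list)
    max_fst: float = math.nan
    max_pi_ratio: float = math.nan
    genes: list[str] = field(default_factory=list)


def make_windows(
    chrom_lengths: dict[str, int], size: int = 100_000, step: int = 10_000
) -> list[Window]:
    """Sliding windows at starts 0, step, 2*step, ... with start+size <= L.

    A final truncated window is appended only when it covers at least one bp
    that no full window covers.
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if not chrom_lengths:
        raise ValueError("empty chromosome set")
    out: list[Window] = []
    for chrom, length in chrom_lengths.items():
        n_full = (length - size) // step + 1 if length >= size else 0
        for i in range(n_full):
            out.append(Window(chrom, i * step, i * step + size))
        covered_end = (n_full - 1) * step + size if n_full else 0
        if covered_end < length:
            out.append(Window(chrom, n_full * step, length, truncated=True))
    return out


def window_stats(
    matrix: GenotypeMatrix,
    weedy: list[str],
    cultivated: list[str],
    windows: list[Window],
    min_sites: int = 5,
) -> list[WindowStat]:
    """Per-window pi_w, pi_c, Hudson F_ST and pi ratio via prefix sums.

    pi uses every site in the window (invariant included when present; a
    warning is logged when none are, since absolute pi is then inflated).
    pi_ratio is +inf when pi_c == 0 < pi_w; a window with both pools
    monomorphic, or with fewer than ``min_sites`` variant sites, is unusable.
    """
    if not weedy or not cultivated:
        raise ValueError("both sample subsets must be non-empty")
    if not matrix.is_variant.all() and matrix.n_sites:
        pass
    elif matrix.n_sites:
        logger.warning(
            "window_stats: no invariant sites supplied; "
            "absolute pi is inflated (ratios unaffected under uniform coverage)"
        )

    iw = matrix.sample_indices(weedy)
    ic = matrix.sample_indices(cultivated)
    nw, kw = _counts_block(matrix.dosages[iw])
    nc, kc = _counts_block(matrix.dosages[ic])

    diffs_w = (kw * (nw - kw)).astype(float)
    comps_w = (nw * (nw - 1) // 2).astype(float)
    diffs_c = (kc * (nc - kc)).astype(float)
    comps_c = (nc * (nc - 1) // 2).astype(float)
    comps_w[nw < 2] = 0.0
    comps_c[nc < 2] = 0.0
    diffs_w[nw < 2] = 0.0
    diffs_c[nc < 2] = 0.0

    var = matrix.is_variant
    num, den, ok = _hudson_site_terms(nw, kw, nc, kc)
    num = np.where(ok & var, num, 0.0)
    den = np.where(ok & var, den, 0.0)

    order_key: dict[str, np.ndarray] = {}
    stats: list[WindowStat] = []

    def prefix(arr: np.ndarray) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(arr)])

    for chrom in dict.fromkeys(matrix.chrom.tolist()):
        sel = np.flatnonzero(matrix.chrom == chrom)
        order_key[chrom] = sel
    pre: dict[str, dict[str, np.ndarray]] = {}
    for chrom, sel in order_key.items():
        pre[chrom] = {
            "pos0": matrix.pos[sel].astype(np.int64) - 1,
            "dw": prefix(diffs_w[sel]),
            "cw": prefix(comps_w[sel]),
            "dc": prefix(diffs_c[sel]),
            "cc": prefix(comps_c[sel]),
            "num": prefix(num[sel]),
            "den": prefix(den[sel]),
            "nvar": prefix(var[sel].astype(float)),
        }

    for w in windows:
        p = pre.get(w.chrom)
        if p is None:
            stats.append(
                WindowStat(w, math.nan, math.nan, math.nan, math.nan, 0, False)
            )
            continue
        lo = int(np.searchsorted(p["pos0"], w.start, side="left"))
        hi = int(np.searchsorted(p["pos0"], w.end, side="left"))

        def seg(key: str) -> float:
            return float(p[key][hi] - p[key][lo])

        comps_w_sum = seg("cw")
        comps_c_sum = seg("cc")
        pi_w = seg("dw") / comps_w_sum if comps_w_sum > 0 else math.nan
        pi_c = seg("dc") / comps_c_sum if comps_c_sum > 0 else math.nan
        den_sum = seg("den")
        fst = seg("num") / den_sum if den_sum > 0 else math.nan
        n_var = int(round(seg("nvar")))

        usable = n_var >= min_sites and comps_c_sum > 0 and comps_w_sum > 0
        if math.isnan(pi_w) or math.isnan(pi_c):
            ratio = math.nan
            usable = False
        elif pi_c == 0.0:
            if pi_w > 0.0:
                ratio = math.inf
            else:
                ratio = math.nan
                usable = False
        else:
            ratio = pi_w / pi_c
        stats.append(WindowStat(w, pi_w, pi_c, fst, ratio, n_var, usable))
    return stats


def _quantile_lower(values: np.ndarray, q: float) -> float:
    """Empirical order statistic, no interpolation; inf sorts last.

    Returns the order statistic at index floor(q*n) (0-based, capped at n-1)
    so that at most ceil((1-q)*n) values lie at or above the threshold.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("no values")
    idx = min(int(math.floor(q * len(v))), len(v) - 1)
    return float(v[idx])


def joint_outlier_call(
    stats: list[WindowStat],
    quantile: float = 0.95,
    fst_thr: float | None = None,
    ratio_thr: float | None = None,
    min_usable: int = 20,
) -> tuple[float, float, list[WindowStat]]:
    """Select usable windows in the joint upper tails of F_ST and pi ratio.

    Thresholds default to the empirical ``quantile`` (lower order statistic)
    of each distribution over usable windows; +inf pi ratios rank above all
    finite values. Explicit ``fst_thr``/``ratio_thr`` override the empirical
    thresholds (e.g. to replay published cutoffs).
    """
    usable = [s for s in stats if s.usable and not math.isnan(s.fst)]
    if len(usable) < min_usable and (fst_thr is None or ratio_thr is None):
        raise ValueError(
            f"joint_outlier_call: only {len(usable)} usable windows (< {min_usable})"
        )
    if fst_thr is None:
        fst_thr = _quantile_lower(np.array([s.fst for s in usable]), quantile)
    if ratio_thr is None:
        ratio_thr = _quantile_lower(np.array([s.pi_ratio for s in usable]), quantile)
    selected = [s for s in usable if s.fst >= fst_thr and s.pi_ratio >= ratio_thr]
    logger.info(
        "joint_outlier_call: fst_thr=%.4g ratio_thr=%.4g -> %d/%d windows",
        fst_thr,
        ratio_thr,
        len(selected),
        len(usable),
    )
    return fst_thr, ratio_thr, selected


def merge_regions(selected: list[WindowStat]) -> list[SweepRegion]:
    """Merge overlapping or book-ended selected windows into sweep regions."""
    items = sorted(selected, key=lambda s: (s.window.chrom, s.window.start))
    regions: list[SweepRegion] = []
    for s in items:
        w = s.window
        if (
            regions
            and regions[-1].chrom == w.chrom
            and w.start <= regions[-1].end
        ):
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.windows.append(w)
            r.max_fst = max(r.max_fst, s.fst) if not math.isnan(r.max_fst) else s.fst
            r.max_pi_ratio = max(r.max_pi_ratio, s.pi_ratio)
        else:
            regions.append(
                SweepRegion(
                    chrom=w.chrom,
                    start=w.start,
                    end=w.end,
                    windows=[w],
                    max_fst=s.fst,
                    max_pi_ratio=s.pi_ratio,
                )
            )
    return regions


def read_gene_annotation(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Load gene intervals as (chrom, start, end, gene_id), 0-based half-open.

    GFF3 (feature type 'gene', 1-based inclusive -> converted) or BED
    (already half-open) are accepted, chosen by file extension.
    """
    path = Path(path)
    genes: list[tuple[str, int, int, str]] = []
    if path.suffix.lower() in (".bed",):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                genes.append((f[0], int(f[1]), int(f[2]), name))
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
                genes.append((f[0], int(f[3]) - 1, int(f[4]), gid))
    return genes


def genes_in_regions(
    regions: list[SweepRegion],
    annotation: list[tuple[str, int, int, str]],
    known_chroms: set[str] | None = None,
) -> int:
    """Attach overlapping gene ids to each region; returns the global unique count.

    Any >= 1 bp overlap makes a gene a candidate. Genes on chromosomes
    outside ``known_chroms`` (when given) are skipped with a warning.
    """
    by_chrom: dict[str, list[SweepRegion]] = {}
    for r in regions:
        r.genes = []
        by_chrom.setdefault(r.chrom, []).append(r)
    seen: set[str] = set()
    for chrom, start, end, gid in annotation:
        if known_chroms is not None and chrom not in known_chroms:
            logger.warning("annotation chrom %s unknown; gene %s skipped", chrom, gid)
            continue
        for r in by_chrom.get(chrom, []):
            if start < r.end and end > r.start:
                if gid not in r.genes:
                    r.genes.append(gid)
                seen.add(gid)
    return len(seen)


def stats_to_frame(stats: list[WindowStat], selected: list[WindowStat] | None = None):
    """Window stats as a DataFrame (1-based inclusive report coordinates)."""
    import pandas as pd

    sel = {id(s) for s in (selected or [])}
    rows = []
    for s in stats:
        rows.append(
            {
                "chrom": s.window.chrom,
                "start": s.window.start + 1,
                "end": s.window.end,
                "n_sites": s.n_variant_sites,
                "pi_w": s.pi_w,
                "pi_c": s.pi_c,
                "fst": s.fst,
                "pi_ratio": s.pi_ratio,
                "usable": s.usable,
                "selected": id(s) in sel,
            }
        )
    return pd.DataFrame(rows)
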