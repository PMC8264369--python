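"""VCF-backed genotype matrices and site filtering.

Genotypes are stored as alt-allele dosages (0/1/2) with ``MISSING = -1``.
Invariant sites (``ALT = .``) can be carried alongside variant sites so that
downstream diversity estimators can count comparisons at monomorphic
positions.  Site order is strictly increasing by position within each
chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call in dosage arrays.
MISSING: int = -1

#: Sentinel for an absent per-genotype integer annotation (DP/GQ/RGQ).
NO_ANNOT: int = -1

_QUAL_KEYS = ("QUAL", "QD", "FS", "MQ", "SOR")


class VcfParseError(ValueError):
    """Raised when a VCF body line cannot be parsed; message names the line."""


class InputError(ValueError):
    """Raised for unusable inputs (e.g. a VCF with zero samples)."""


@dataclass
class FilterConfig:
    """Thresholds for hard site filters and analysis-site selection.

    Variant-site hard filters use strict inequalities (a site with
    ``QUAL == qual_min`` passes); invariant-genotype filters mask individual
    calls rather than dropping the site.
    """

    qual_min: float = 30.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    sor_max: float = 3.0
    invariant_dp_min: int = 5
    invariant_gq_min: int = 40
    maf_min: float = 0.05
    site_missing_max: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.site_missing_max <= 1.0:
            raise ValueError(
                f"site_missing_max must be in [0, 1], got {self.site_missing_max}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with per-site metadata.

    Attributes
    ----------
    sample_ids
        Ordered sample names; one row of ``dosages`` per sample.
    chrom, pos
        Per-site chromosome and 1-based position. Within each chromosome
        positions are strictly increasing.
    is_variant
        True for variant (biallelic SNP) columns, False for invariant ones.
    ref, alt
        Allele strings; ``alt`` is ``""`` for invariant sites.
    dosages
        ``(n_samples, n_sites)`` int8 array of alt-allele dosages with
        ``MISSING`` sentinel. Invariant columns hold only 0 or MISSING.
    site_quals
        Mapping of QUAL/QD/FS/MQ/SOR to per-site float arrays (NaN = absent).
    gt_depth, gt_qual
        Optional ``(n_samples, n_sites)`` arrays of per-genotype DP and the
        best of GQ/RGQ, with ``NO_ANNOT`` where absent.
    meta
        Free-form provenance (filter removal counts etc.).
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    is_variant: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    site_quals: dict[str, np.ndarray] = field(default_factory=dict)
    gt_depth: np.ndarray | None = None
    gt_qual: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_samples, n_sites = self.dosages.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match dosage rows")
        for arr in (self.chrom, self.pos, self.is_variant, self.ref, self.alt):
            if len(arr) != n_sites:
                raise ValueError("site metadata length does not match dosage columns")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def sample_indices(self, samples: Sequence[str] | None) -> np.ndarray:
        """Map sample names to row indices (all samples when None)."""
        if samples is None:
            return np.arange(self.n_samples)
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return np.asarray([lookup[s] for s in samples], dtype=int)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to site columns ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            is_variant=self.is_variant[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosages=self.dosages[:, idx],
            site_quals={k: v[idx] for k, v in self.site_quals.items()},
            gt_depth=None if self.gt_depth is None else self.gt_depth[:, idx],
            gt_qual=None if self.gt_qual is None else self.gt_qual[:, idx],
            meta=dict(self.meta),
        )

    def take_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(samples)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            is_variant=self.is_variant,
            ref=self.ref,
            alt=self.alt,
            dosages=self.dosages[idx],
            site_quals=dict(self.site_quals),
            gt_depth=None if self.gt_depth is None else self.gt_depth[idx],
            gt_qual=None if self.gt_qual is None else self.gt_qual[idx],
            meta=dict(self.meta),
        )

    def site_mask_in_region(self, region: tuple[str, int, int] | None) -> np.ndarray:
        """Boolean mask of sites inside ``(chrom, start, end)``.

        Regions are half-open on 0-based coordinates; a site at 1-based
        position ``p`` is inside iff ``start <= p - 1 < end``.
        """
        if region is None:
            return np.ones(self.n_sites, dtype=bool)
        chrom, start, end = region
        return (self.chrom == chrom) & (self.pos - 1 >= start) & (self.pos - 1 < end)

    def missing_rate_per_sample(self) -> np.ndarray:
        """Fraction of MISSING calls per sample (reported, never filtered on)."""
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.dosages == MISSING).mean(axis=1)


def _prevalidate_vcf_text(path: str | Path) -> int:
    """Cheap structural scan; raises VcfParseError naming the offending line."""
    n_samples = 0
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                n_samples = max(0, len(cols) - 9)
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[1])
            except ValueError:
                raise VcfParseError(
                    f"{path}: line {lineno}: POS is not an integer: {fields[1]!r}"
                ) from None
    return n_samples


def read_vcf(path: str | Path, keep_invariant: bool = True) -> GenotypeMatrix:
    """Read a multi-sample VCF 4.x into a :class:`GenotypeMatrix`.

    Biallelic SNP records become variant columns; records with ``ALT = .``
    become invariant columns when ``keep_invariant`` is set, otherwise they
    are skipped. Multi-allelic records are dropped (counted in ``meta``).
    """
    n_samples = _prevalidate_vcf_text(path)
    if n_samples == 0:
        raise InputError(f"{path}: VCF has zero samples")

    vcf = VCF(str(path))
    samples = list(vcf.samples)

    chroms: list[str] = []
    positions: list[int] = []
    is_variant: list[bool] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_cols: list[np.ndarray] = []
    qual_cols: dict[str, list[float]] = {k: [] for k in _QUAL_KEYS}
    depth_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    any_depth = False
    any_gq = False
    n_multiallelic = 0

    for rec in vcf:
        alt_alleles = rec.ALT
        if len(alt_alleles) > 1:
            n_multiallelic += 1
            continue
        invariant = len(alt_alleles) == 0
        if invariant and not keep_invariant:
            continue

        geno = rec.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(n_samples, dtype=np.int8)
        for i, g in enumerate(geno):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                dos[i] = MISSING
            else:
                dos[i] = sum(alleles)

        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        is_variant.append(not invariant)
        refs.append(rec.REF)
        alts.append("" if invariant else alt_alleles[0])
        dosage_cols.append(dos)

        qual_cols["QUAL"].append(np.nan if rec.QUAL is None else float(rec.QUAL))
        for key in ("QD", "FS", "MQ", "SOR"):
            v = rec.INFO.get(key)
            qual_cols[key].append(np.nan if v is None else float(v))

        def _fmt(key: str):
            try:
                return rec.format(key)
            except KeyError:  # tag not declared in header
                return None

        dp = _fmt("DP")
        gq = _fmt("GQ")
        rgq = _fmt("RGQ")
        dcol = np.full(n_samples, NO_ANNOT, dtype=np.int32)
        qcol = np.full(n_samples, NO_ANNOT, dtype=np.int32)
        if dp is not None:
            valid = dp[:, 0] >= 0
            dcol[valid] = dp[valid, 0]
            any_depth = True
        for arr in (gq, rgq):
            if arr is not None:
                valid = arr[:, 0] >= 0
                qcol[valid] = np.maximum(qcol[valid], arr[valid, 0])
                any_gq = True
        depth_cols.append(dcol)
        gq_cols.append(qcol)

    n_sites = len(positions)
    mat = GenotypeMatrix(
        sample_ids=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        is_variant=np.asarray(is_variant, dtype=bool),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        dosages=(
            np.stack(dosage_cols, axis=1)
            if n_sites
            else np.zeros((n_samples, 0), dtype=np.int8)
        ),
        site_quals={k: np.asarray(v, dtype=float) for k, v in qual_cols.items()},
        gt_depth=np.stack(depth_cols, axis=1) if (n_sites and any_depth) else None,
        gt_qual=np.stack(gq_cols, axis=1) if (n_sites and any_gq) else None,
        meta={"n_multiallelic_dropped": n_multiallelic},
    )
    logger.info(
        "read %d samples x %d sites from %s (%d multi-allelic records dropped)",
        n_samples,
        n_sites,
        path,
        n_multiallelic,
    )
    return mat


def apply_hard_filters(matrix: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Apply GATK-style hard filters.

    Variant sites are removed when ``QUAL < qual_min``, ``QD < qd_min``,
    ``FS > fs_max``, ``MQ < mq_min`` or ``SOR > sor_max``. An absent
    annotation never fires its rule. Invariant-site genotypes are set
    MISSING when ``DP < invariant_dp_min`` or when the best of GQ/RGQ is
    present but below ``invariant_gq_min``; the site itself is retained.
    """
    q = matrix.site_quals
    nan_ok = np.zeros(matrix.n_sites, dtype=bool)

    def fails(key: str, thr: float, low_is_bad: bool) -> np.ndarray:
        vals = q.get(key)
        if vals is None:
            return nan_ok
        with np.errstate(invalid="ignore"):
            bad = (vals < thr) if low_is_bad else (vals > thr)
        return bad & ~np.isnan(vals)

    bad_variant = (
        fails("QUAL", cfg.qual_min, True)
        | fails("QD", cfg.qd_min, True)
        | fails("FS", cfg.fs_max, False)
        | fails("MQ", cfg.mq_min, True)
        | fails("SOR", cfg.sor_max, False)
    ) & matrix.is_variant

    keep = ~bad_variant
    out = matrix.take_sites(np.flatnonzero(keep))

    n_masked = 0
    inv = ~out.is_variant
    if inv.any():
        bad_geno = np.zeros(out.dosages.shape, dtype=bool)
        if out.gt_depth is not None:
            bad_geno |= (out.gt_depth != NO_ANNOT) & (out.gt_depth < cfg.invariant_dp_min)
        if out.gt_qual is not None:
            bad_geno |= (out.gt_qual != NO_ANNOT) & (out.gt_qual < cfg.invariant_gq_min)
        bad_geno &= inv[None, :]
        bad_geno &= out.dosages != MISSING
        n_masked = int(bad_geno.sum())
        if n_masked:
            out.dosages = out.dosages.copy()
            out.dosages[bad_geno] = MISSING

    out.meta["hard_filter_sites_removed"] = int(bad_variant.sum())
    out.meta["invariant_genotypes_masked"] = n_masked
    logger.info(
        "hard filters removed %d variant sites, masked %d invariant genotypes",
        int(bad_variant.sum()),
        n_masked,
    )
    return out


def site_allele_counts(
    dosages: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (non-missing allele copies, alt-allele copies) for a dosage block."""
    called = dosages != MISSING
    n_copies = 2 * called.sum(axis=0)
    alt_copies = np.where(called, dosages, 0).sum(axis=0)
    return n_copies, alt_copies


def select_analysis_sites(matrix: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Keep variant sites passing missingness and MAF rules.

    A variant site is retained when its missing-call fraction is
    ``<= site_missing_max`` and its minor allele frequency (over non-missing
    allele copies) is ``>= maf_min``. Invariant sites pass through untouched.
    Idempotent.
    """
    var = matrix.is_variant
    dos = matrix.dosages
    n_copies, alt_copies = site_allele_counts(dos)
    miss_frac = (dos == MISSING).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_copies > 0, alt_copies / np.maximum(n_copies, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)

    all_missing = var & (n_copies == 0)
    keep = ~var | (
        (miss_frac <= cfg.site_missing_max) & (n_copies > 0) & (maf >= cfg.maf_min)
    )
    out = matrix.take_sites(np.flatnonzero(keep))
    out.meta["maf_missing_sites_removed"] = int((~keep).sum())
    out.meta["all_missing_sites_removed"] = int(all_missing.sum())
    logger.info(
        "analysis-site selection removed %d variant sites (%d were all-missing)",
        int((~keep).sum()),
        int(all_missing.sum()),
    )
    return out


def _format_float(x: float) -> str:
    s = f"{x:.6g}"
    return s


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as an uncompressed VCF 4.2 file.

    ``read_vcf(write_vcf(m))`` round-trips dosages, coordinates and the
    variant/invariant split. MISSING calls are emitted as ``./.``.
    """
    path = Path(path)
    chrom_order = list(dict.fromkeys(matrix.chrom.tolist()))
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popdiv\n")
        for c in chrom_order:
            cmax = int(matrix.pos[matrix.chrom == c].max()) if matrix.n_sites else 1
            fh.write(f"##contig=<ID={c},length={cmax + 1000}>\n")
        for key in ("QD", "FS", "MQ", "SOR"):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##FORMAT=<ID=RGQ,Number=1,Type=Integer,Description="Reference GQ">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(matrix.n_sites):
            variant = bool(matrix.is_variant[j])
            ref = matrix.ref[j] or "N"
            alt = matrix.alt[j] if variant else "."
            qual_arr = matrix.site_quals.get("QUAL")
            qual = "."
            if qual_arr is not None and not np.isnan(qual_arr[j]):
                qual = _format_float(float(qual_arr[j]))
            info_parts = []
            for key in ("QD", "FS", "MQ", "SOR"):
                vals = matrix.site_quals.get(key)
                if vals is not None and not np.isnan(vals[j]):
                    info_parts.append(f"{key}={_format_float(float(vals[j]))}")
            info = ";".join(info_parts) if info_parts else "."

            has_dp = matrix.gt_depth is not None and np.any(
                matrix.gt_depth[:, j] != NO_ANNOT
            )
            has_gq = matrix.gt_qual is not None and np.any(
                matrix.gt_qual[:, j] != NO_ANNOT
            )
            fmt = "GT" + (":DP" if has_dp else "") + (":RGQ" if has_gq else "")
            calls = []
            for i in range(matrix.n_samples):
                parts = [gt_code[int(matrix.dosages[i, j])]]
                if has_dp:
                    d = int(matrix.gt_depth[i, j])
                    parts.append("." if d == NO_ANNOT else str(d))
                if has_gq:
                    g = int(matrix.gt_qual[i, j])
                    parts.append("." if g == NO_ANNOT else str(g))
                calls.append(":".join(parts))
            fh.write(
                f"{matrix.chrom[j]}\t{int(matrix.pos[j])}\t.\t{ref}\t{alt}\t"
                f"{qual}\t.\t{info}\t{fmt}\t" + "\t".join(calls) + "\n"
            )
    return path


def read_populations(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a sample->population TSV (columns: sample_id, population[, group])."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = list(df.columns)
    if "sample_id" not in cols or "population" not in cols:
        raise InputError(
            f"{path}: population table needs 'sample_id' and 'population' columns"
        )
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = {
            "population": row["population"],
            "group": row.get("group", row["population"]),
        }
    return out


def samples_in_population(
    populations: dict[str, dict[str, str]], name: str
) -> list[str]:
    return [s for s, info in populations.items() if info["population"] == name]
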