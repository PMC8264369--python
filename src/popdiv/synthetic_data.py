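"""Synthetic genotype fixtures with known truth.

Two diverged pools (high-diversity "weedy", bottlenecked "cultivated") are
drawn from the Balding-Nichols model, whose drift parameter F equals the
expected Hudson F_ST between pools — giving an analytic surface for estimator
checks. Feral samples mix the two pools allele-by-allele. Sweep intervals
push cultivated allele frequencies toward fixation. A separate founder-mosaic
generator produces distance-decaying LD (BN sites are independent), and a
masking step emulates heavy per-site missingness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from popdiv.variant_io import MISSING, GenotypeMatrix, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    n_weedy: int = 20
    n_cultivated: int = 20
    n_feral: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000}
    )
    n_variant_sites: int = 5_000
    n_invariant_sites: int = 0
    f_weedy: float = 0.05
    f_cultivated: float = 0.25
    sweep_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    sweep_floor: float = 0.98
    feral_alphas: list[float] = field(default_factory=list)  # cultivated fraction
    founder_count: int = 8
    switch_rate: float = 1e-5  # per bp
    missing_max: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_weedy, self.n_cultivated) <= 0:
            raise ValueError("pool sizes must be positive")
        for f in (self.f_weedy, self.f_cultivated):
            if not 0.0 < f < 1.0:
                raise ValueError("drift parameters must lie in (0, 1)")
        if self.n_feral and len(self.feral_alphas) != self.n_feral:
            raise ValueError("feral_alphas must have one entry per feral sample")
        if any(not 0.0 <= a <= 1.0 for a in self.feral_alphas):
            raise ValueError("feral alphas must lie in [0, 1]")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")
        if not 0.0 <= self.missing_max <= 1.0:
            raise ValueError("missing_max must lie in [0, 1]")


@dataclass
class FreqSim:
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    p_ancestral: np.ndarray
    pool_freqs: dict[str, np.ndarray]


@dataclass
class SimTruth:
    sample_ids: list[str]
    labels: list[str]  # weedy / cultivated / feral
    q_true: np.ndarray  # (n, 2): columns (cultivated, weedy)
    p_ancestral: np.ndarray
    pool_freqs: dict[str, np.ndarray]
    sweep_intervals: list[tuple[str, int, int]]
    seed: int


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # independent, reproducible streams per stage (stable hash: crc32)
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(stream.encode())])
    )


def _site_layout(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Variant positions spread over chromosomes proportionally to length."""
    total = sum(cfg.chrom_lengths.values())
    chroms: list[str] = []
    positions: list[int] = []
    remaining = cfg.n_variant_sites
    items = list(cfg.chrom_lengths.items())
    for i, (chrom, length) in enumerate(items):
        n = (
            remaining
            if i == len(items) - 1
            else int(round(cfg.n_variant_sites * length / total))
        )
        n = min(n, remaining, length)
        remaining -= n
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        chroms.extend([chrom] * n)
        positions.extend(pos.tolist())
    return np.asarray(chroms, dtype=object), np.asarray(positions, dtype=np.int64)


def simulate_frequencies(cfg: SimConfig) -> FreqSim:
    """Ancestral frequencies U(0.05, 0.95) and Balding-Nichols pool frequencies.

    Pool frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F), independently per pool,
    so E[freq] = p and the expected Hudson F_ST between two pools with common
    F equals F.
    """
    rng = _rng(cfg, "frequencies")
    chrom, pos = _site_layout(cfg, rng)
    p = rng.uniform(0.05, 0.95, size=len(pos))
    pools: dict[str, np.ndarray] = {}
    for name, f in (("weedy", cfg.f_weedy), ("cultivated", cfg.f_cultivated)):
        a = p * (1 - f) / f
        b = (1 - p) * (1 - f) / f
        pools[name] = rng.beta(a, b)
    return FreqSim(chrom=chrom, pos=pos, p_ancestral=p, pool_freqs=pools)


def plant_sweeps(freqs: FreqSim, cfg: SimConfig) -> FreqSim:
    """Push cultivated frequencies inside sweep intervals toward fixation.

    At each site in a sweep interval the cultivated frequency of the locally
    major allele is raised to at least ``sweep_floor``; weedy is untouched.
    """
    pc = freqs.pool_freqs["cultivated"].copy()
    for chrom, start, end in cfg.sweep_intervals:
        if chrom not in cfg.chrom_lengths:
            raise ValueError(f"sweep interval on unknown chromosome {chrom}")
        if start < 0 or end > cfg.chrom_lengths[chrom] or start >= end:
            raise ValueError(f"sweep interval outside genome: {chrom}:{start}-{end}")
        mask = (freqs.chrom == chrom) & (freqs.pos - 1 >= start) & (freqs.pos - 1 < end)
        major_alt = pc[mask] >= 0.5
        pc[mask] = np.where(
            major_alt,
            np.maximum(pc[mask], cfg.sweep_floor),
            np.minimum(pc[mask], 1.0 - cfg.sweep_floor),
        )
    out = dict(freqs.pool_freqs)
    out["cultivated"] = pc
    return FreqSim(
        chrom=freqs.chrom,
        pos=freqs.pos,
        p_ancestral=freqs.p_ancestral,
        pool_freqs=out,
    )


def _sample_names(cfg: SimConfig) -> tuple[list[str], list[str]]:
    ids = (
        [f"W{i + 1:03d}" for i in range(cfg.n_weedy)]
        + [f"C{i + 1:03d}" for i in range(cfg.n_cultivated)]
        + [f"F{i + 1:03d}" for i in range(cfg.n_feral)]
    )
    labels = (
        ["weedy"] * cfg.n_weedy
        + ["cultivated"] * cfg.n_cultivated
        + ["feral"] * cfg.n_feral
    )
    return ids, labels


def _invariant_layout(cfg: SimConfig, variant_chrom, variant_pos) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced invariant positions per chromosome, skipping collisions."""
    total = sum(cfg.chrom_lengths.values())
    chroms: list[str] = []
    positions: list[int] = []
    taken = {
        (c, int(p)) for c, p in zip(variant_chrom.tolist(), variant_pos.tolist())
    }
    remaining = cfg.n_invariant_sites
    items = list(cfg.chrom_lengths.items())
    for i, (chrom, length) in enumerate(items):
        n = (
            remaining
            if i == len(items) - 1
            else int(round(cfg.n_invariant_sites * length / total))
        )
        n = min(n, remaining)
        remaining -= n
        if n == 0:
            continue
        grid = np.unique(np.linspace(1, length, n, dtype=np.int64))
        for p in grid.tolist():
            q = p
            while (chrom, q) in taken and q < length:
                q += 1
            if (chrom, q) in taken:
                continue
            taken.add((chrom, q))
            chroms.append(chrom)
            positions.append(q)
    return np.asarray(chroms, dtype=object), np.asarray(positions, dtype=np.int64)


def sample_genotypes(freqs: FreqSim, cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw diploid dosages from pool frequencies; append invariant sites.

    Weedy/cultivated dosages ~ Binomial(2, pool freq). Each feral allele comes
    from the cultivated pool with probability alpha, the weedy pool otherwise;
    the true Q row is (alpha, 1 - alpha).
    """
    rng = _rng(cfg, "genotypes")
    ids, labels = _sample_names(cfg)
    m = len(freqs.pos)
    pw = freqs.pool_freqs["weedy"]
    pc = freqs.pool_freqs["cultivated"]

    rows = []
    q_rows = []
    for lab, sid in zip(labels, ids):
        if lab == "weedy":
            rows.append(rng.binomial(2, pw).astype(np.int8))
            q_rows.append((0.0, 1.0))
        elif lab == "cultivated":
            rows.append(rng.binomial(2, pc).astype(np.int8))
            q_rows.append((1.0, 0.0))
        else:
            alpha = cfg.feral_alphas[int(sid[1:]) - 1]
            dos = np.zeros(m, dtype=np.int8)
            for _ in range(2):  # one draw per allele copy
                from_c = rng.random(m) < alpha
                p_allele = np.where(from_c, pc, pw)
                dos += (rng.random(m) < p_allele).astype(np.int8)
            rows.append(dos)
            q_rows.append((alpha, 1.0 - alpha))
    dosages = np.stack(rows, axis=0)

    chrom = freqs.chrom
    pos = freqs.pos
    is_variant = np.ones(m, dtype=bool)
    if cfg.n_invariant_sites > 0:
        ic, ip = _invariant_layout(cfg, chrom, pos)
        chrom = np.concatenate([chrom, ic])
        pos = np.concatenate([pos, ip])
        is_variant = np.concatenate([is_variant, np.zeros(len(ip), dtype=bool)])
        dosages = np.concatenate(
            [dosages, np.zeros((len(ids), len(ip)), dtype=np.int8)], axis=1
        )
    # sort by chromosome (input order) then position
    chrom_rank = {c: i for i, c in enumerate(cfg.chrom_lengths)}
    order = np.lexsort((pos, np.asarray([chrom_rank[c] for c in chrom])))
    chrom = chrom[order]
    pos = pos[order]
    is_variant = is_variant[order]
    dosages = dosages[:, order]

    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[_rng(cfg, "alleles").integers(0, 4, size=len(pos))]
    alt = np.where(is_variant, np.where(ref == "A", "G", "A"), "").astype(object)

    n_sites = len(pos)
    matrix = GenotypeMatrix(
        sample_ids=ids,
        chrom=chrom,
        pos=pos,
        is_variant=is_variant,
        ref=ref,
        alt=alt,
        dosages=dosages,
        site_quals={
            "QUAL": np.full(n_sites, 100.0),
            "QD": np.where(is_variant, 20.0, np.nan),
            "FS": np.where(is_variant, 5.0, np.nan),
            "MQ": np.where(is_variant, 60.0, np.nan),
            "SOR": np.where(is_variant, 1.0, np.nan),
        },
        gt_depth=np.full(dosages.shape, 20, dtype=np.int32),
        gt_qual=np.full(dosages.shape, 60, dtype=np.int32),
    )
    truth = SimTruth(
        sample_ids=ids,
        labels=labels,
        q_true=np.asarray(q_rows),
        p_ancestral=freqs.p_ancestral,
        pool_freqs=freqs.pool_freqs,
        sweep_intervals=list(cfg.sweep_intervals),
        seed=cfg.seed,
    )
    return matrix, truth


def simulate_ld_haplotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Founder-mosaic diploids with distance-decaying LD.

    Per pool, ``founder_count`` haplotypes are drawn site-wise Bernoulli; each
    sample haplotype copies a founder, switching to a uniformly chosen founder
    between adjacent sites with probability 1 - exp(-switch_rate * gap).
    Larger switch rates shorten the LD scale.
    """
    if cfg.founder_count < 2:
        raise ValueError("founder_count must be >= 2")
    if cfg.switch_rate < 0:
        raise ValueError("switch_rate must be >= 0")
    rng = _rng(cfg, "ld")
    chrom, pos = _site_layout(cfg, rng)
    ids, labels = _sample_names(cfg)
    m = len(pos)
    p_site = rng.uniform(0.1, 0.9, size=m)

    dosages = np.zeros((len(ids), m), dtype=np.int8)
    pool_of = {"weedy": [], "cultivated": [], "feral": []}
    for i, lab in enumerate(labels):
        pool_of[lab].append(i)
    pool_of["cultivated"].extend(pool_of.pop("feral"))  # ferals ride along

    for pool, members in pool_of.items():
        if not members:
            continue
        founders = (rng.random((cfg.founder_count, m)) < p_site).astype(np.int8)
        for i in members:
            hap_sum = np.zeros(m, dtype=np.int8)
            for _ in range(2):
                hap_sum += _mosaic_haplotype(
                    founders, chrom, pos, cfg.switch_rate, rng
                )
            dosages[i] = hap_sum

    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, size=m)]
    alt = np.where(ref == "A", "G", "A").astype(object)
    matrix = GenotypeMatrix(
        sample_ids=ids,
        chrom=chrom,
        pos=pos,
        is_variant=np.ones(m, dtype=bool),
        ref=ref,
        alt=alt,
        dosages=dosages,
        site_quals={
            "QUAL": np.full(m, 100.0),
            "QD": np.full(m, 20.0),
            "FS": np.full(m, 5.0),
            "MQ": np.full(m, 60.0),
            "SOR": np.full(m, 1.0),
        },
    )
    truth = SimTruth(
        sample_ids=ids,
        labels=labels,
        q_true=np.asarray(
            [(1.0, 0.0) if lab != "weedy" else (0.0, 1.0) for lab in labels]
        ),
        p_ancestral=p_site,
        pool_freqs={},
        sweep_intervals=[],
        seed=cfg.seed,
    )
    return matrix, truth


def _mosaic_haplotype(
    founders: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    kf, m = founders.shape
    hap = np.empty(m, dtype=np.int8)
    current = int(rng.integers(0, kf))
    prev_chrom = None
    prev_pos = 0
    for j in range(m):
        if chrom[j] != prev_chrom:
            current = int(rng.integers(0, kf))
        else:
            gap = int(pos[j] - prev_pos)
            if rho > 0 and rng.random() < 1.0 - np.exp(-rho * gap):
                current = int(rng.integers(0, kf))
        hap[j] = founders[current, j]
        prev_chrom = chrom[j]
        prev_pos = pos[j]
    return hap


def inject_missingness(matrix: GenotypeMatrix, cfg: SimConfig) -> GenotypeMatrix:
    """Mask calls i.i.d. with a per-site rate ~ U(0, missing_max)."""
    if cfg.missing_max == 0.0:
        return matrix
    rng = _rng(cfg, "missing")
    rates = rng.uniform(0.0, cfg.missing_max, size=matrix.n_sites)
    mask = rng.random(matrix.dosages.shape) < rates[None, :]
    dosages = matrix.dosages.copy()
    dosages[mask] = MISSING
    out = dataclasses.replace(matrix, dosages=dosages)
    out.meta = dict(matrix.meta)
    out.meta["injected_missing_calls"] = int(mask.sum())
    return out


def write_fixture(
    matrix: GenotypeMatrix, truth: SimTruth, out_dir: str | Path, cfg: SimConfig | None = None
) -> dict[str, Path]:
    """Emit the VCF, population TSV, true Q table, sweep BED and config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "genotypes.vcf",
        "populations": out_dir / "populations.tsv",
        "q_true": out_dir / "q_true.tsv",
        "sweeps_bed": out_dir / "sweeps_true.bed",
        "config": out_dir / "sim_config.json",
    }
    write_vcf(matrix, paths["vcf"])
    with open(paths["populations"], "wt") as fh:
        fh.write("sample_id\tpopulation\tgroup\n")
        for sid, lab in zip(truth.sample_ids, truth.labels):
            fh.write(f"{sid}\t{lab}\t{lab}\n")
    with open(paths["q_true"], "wt") as fh:
        for sid, row in zip(truth.sample_ids, truth.q_true):
            fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(paths["sweeps_bed"], "wt") as fh:
        for chrom, start, end in truth.sweep_intervals:
            fh.write(f"{chrom}\t{start}\t{end}\tsweep\n")
    if cfg is not None:
        with open(paths["config"], "wt") as fh:
            json.dump(dataclasses.asdict(cfg), fh, indent=2, default=str)
    return paths
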