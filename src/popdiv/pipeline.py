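"""End-to-end orchestration: filter -> diversity -> LD -> structure -> phylo -> sweep.

Every stage writes its output with a provenance header (config hash, seed,
in/out counts) so stages can be re-run and audited independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from popdiv import diversity, ld_decay, phylo, popstruct, sweep_scan, variant_io
from popdiv.synthetic_data import SimTruth
from popdiv.variant_io import FilterConfig, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    populations: str = ""
    qmatrix: str = ""
    annotation: str = ""
    out_dir: str = "popdiv_out"
    exclude_samples: list[str] = field(default_factory=list)
    weedy_population: str = "weedy"
    cultivated_population: str = "cultivated"
    filter: FilterConfig = field(default_factory=FilterConfig)
    window_size: int = 100_000
    window_step: int = 10_000
    sweep_quantile: float = 0.95
    min_sites_per_window: int = 5
    fst_threshold: float | None = None
    ratio_threshold: float | None = None
    ld_max_dist: int = 300_000
    ld_bin_width: int = 1_000
    ld_subsample: int = 7
    group_threshold: float = 0.80
    bootstrap_replicates: int = 100
    pca_components: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fcfg = FilterConfig(**raw.pop("filter", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(filter=fcfg, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RecoveryReport:
    fst_bias: float
    pi_bias: dict[str, float]
    sweep_sensitivity: float
    sweep_precision: float  # NaN when nothing was called
    group_assignment_accuracy: float
    half_decay_bp: float


def _provenance(cfg: PipelineConfig, stage: str, **counts) -> str:
    parts = [f"# stage={stage}", f"config_hash={cfg.config_hash()}", f"seed={cfg.seed}"]
    parts += [f"{k}={v}" for k, v in counts.items()]
    return " ".join(parts) + "\n"


def _write_with_header(df, path: Path, header: str) -> None:
    with open(path, "wt") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order; returns a result bundle of in-memory objects.

    A failing stage aborts with the stage name; outputs written so far are
    preserved in ``out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"out_dir": out}
    stage = "load"
    try:
        matrix = variant_io.read_vcf(cfg.vcf, keep_invariant=True)
        pops = variant_io.read_populations(cfg.populations)
        if cfg.exclude_samples:
            keep = [s for s in matrix.sample_ids if s not in set(cfg.exclude_samples)]
            logger.info(
                "excluding %d samples: %s", len(cfg.exclude_samples), cfg.exclude_samples
            )
            matrix = matrix.take_samples(keep)
            pops = {s: v for s, v in pops.items() if s in set(keep)}

        stage = "filter"
        matrix = variant_io.apply_hard_filters(matrix, cfg.filter)
        matrix = variant_io.select_analysis_sites(matrix, cfg.filter)
        variant_io.write_vcf(matrix, out / "filtered.vcf")
        results["matrix"] = matrix

        weedy = [
            s
            for s in matrix.sample_ids
            if pops.get(s, {}).get("population") == cfg.weedy_population
        ]
        cultivated = [
            s
            for s in matrix.sample_ids
            if pops.get(s, {}).get("population") == cfg.cultivated_population
        ]

        stage = "diversity"
        div = diversity.diversity_table(
            matrix, {cfg.weedy_population: weedy, cfg.cultivated_population: cultivated}
        )
        _write_with_header(
            div,
            out / "diversity.tsv",
            _provenance(cfg, stage, n_sites=matrix.n_sites),
        )
        fst = diversity.fst_pair(matrix, weedy, cultivated)
        results["diversity"] = div
        results["fst"] = fst
        (out / "fst.txt").write_text(
            _provenance(cfg, stage)
            + f"fst\t{fst.fst:.6f}\nn_sites\t{fst.n_sites_used}\n"
        )

        stage = "ld"
        rng = np.random.default_rng(cfg.seed)
        curves = {}
        for name, pool in ((cfg.weedy_population, weedy), (cfg.cultivated_population, cultivated)):
            subset = pool
            if cfg.ld_subsample and len(pool) > cfg.ld_subsample:
                subset = list(
                    rng.choice(pool, size=cfg.ld_subsample, replace=False)
                )
            curve = ld_decay.ld_decay_curve(
                matrix, samples=subset, max_dist=cfg.ld_max_dist, bin_width=cfg.ld_bin_width
            )
            curves[name] = curve
            _write_with_header(
                curve.to_frame(),
                out / f"ld_{name}.tsv",
                _provenance(cfg, stage, pool=name, n_samples=len(subset)),
            )
        results["ld_curves"] = curves

        stage = "structure"
        if cfg.qmatrix:
            qmat = popstruct.read_qmatrix(cfg.qmatrix, sample_ids=matrix.sample_ids)
            assign = popstruct.assign_groups(qmat, threshold=cfg.group_threshold)
            results["assignment"] = assign
            with open(out / "groups.tsv", "wt") as fh:
                fh.write(_provenance(cfg, stage, n_assigned=assign.n_assigned))
                fh.write("sample_id\tlabel\n")
                for sid, lab in zip(assign.sample_ids, assign.labels):
                    fh.write(f"{sid}\t{lab}\n")
        pca = popstruct.pca_genotypes(matrix, n_components=cfg.pca_components)
        results["pca"] = pca
        with open(out / "pca.tsv", "wt") as fh:
            fh.write(_provenance(cfg, stage, n_components=len(pca.pct_variance)))
            fh.write(
                "sample_id\t"
                + "\t".join(f"PC{i + 1}" for i in range(pca.coordinates.shape[1]))
                + "\n"
            )
            for sid, row in zip(pca.sample_ids, pca.coordinates):
                fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
        np.savetxt(
            out / "pca_pct_variance.tsv", pca.pct_variance, fmt="%.4f"
        )

        stage = "phylo"
        tree = phylo.bootstrap_supports(
            matrix, replicates=cfg.bootstrap_replicates, seed=cfg.seed
        )
        (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
        results["tree"] = tree

        stage = "sweep"
        chrom_lengths = {
            c: int(matrix.pos[matrix.chrom == c].max())
            for c in dict.fromkeys(matrix.chrom.tolist())
        }
        windows = sweep_scan.make_windows(
            chrom_lengths, size=cfg.window_size, step=cfg.window_step
        )
        stats = sweep_scan.window_stats(
            matrix, weedy, cultivated, windows, min_sites=cfg.min_sites_per_window
        )
        fst_thr, ratio_thr, selected = sweep_scan.joint_outlier_call(
            stats,
            quantile=cfg.sweep_quantile,
            fst_thr=cfg.fst_threshold,
            ratio_thr=cfg.ratio_threshold,
        )
        regions = sweep_scan.merge_regions(selected)
        results["window_stats"] = stats
        results["selected_windows"] = selected
        results["regions"] = regions
        results["thresholds"] = (fst_thr, ratio_thr)
        _write_with_header(
            sweep_scan.stats_to_frame(stats, selected),
            out / "window_stats.tsv",
            _provenance(
                cfg,
                stage,
                fst_thr=f"{fst_thr:.4f}",
                ratio_thr=f"{ratio_thr:.4f}",
                n_selected=len(selected),
                n_regions=len(regions),
            ),
        )
        with open(out / "sweep_regions.bed", "wt") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tsweep\t{r.max_fst:.4f}\n")

        if cfg.annotation:
            genes = sweep_scan.read_gene_annotation(cfg.annotation)
            n_unique = sweep_scan.genes_in_regions(
                regions, genes, known_chroms=set(chrom_lengths)
            )
            results["n_candidate_genes"] = n_unique
            with open(out / "candidate_genes.tsv", "wt") as fh:
                fh.write(_provenance(cfg, stage, n_unique_genes=n_unique))
                fh.write("chrom\tstart\tend\tgenes\n")
                for r in regions:
                    fh.write(
                        f"{r.chrom}\t{r.start + 1}\t{r.end}\t{','.join(r.genes)}\n"
                    )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def compare_to_truth(results: dict, truth: SimTruth) -> RecoveryReport:
    """Score a synthetic-run result bundle against generator truth."""
    matrix: GenotypeMatrix = results["matrix"]
    if set(matrix.sample_ids) - set(truth.sample_ids):
        raise ValueError("result sample set does not match truth")

    by_label: dict[str, list[str]] = {}
    for sid, lab in zip(truth.sample_ids, truth.labels):
        if sid in set(matrix.sample_ids):
            by_label.setdefault(lab, []).append(sid)

    fst = results["fst"].fst
    fst_bias = math.nan
    if truth.pool_freqs:
        # parametric truth: Hudson ratio-of-sums on the exact pool frequencies
        p1 = truth.pool_freqs["weedy"]
        p2 = truth.pool_freqs["cultivated"]
        num = ((p1 - p2) ** 2).sum()
        den = (p1 * (1 - p2) + p2 * (1 - p1)).sum()
        if den > 0 and not math.isnan(fst):
            fst_bias = fst - float(num / den)
    pi_bias: dict[str, float] = {}
    for lab in ("weedy", "cultivated"):
        if lab in by_label:
            est = diversity.pi_over_region(matrix, samples=by_label[lab])
            if truth.pool_freqs:
                p = truth.pool_freqs[lab]
                # expected pi at a BN site is 2p(1-p); invariant sites dilute
                true_pi = float(2 * (p * (1 - p)).sum() / matrix.n_sites)
                pi_bias[lab] = est - true_pi
            else:
                pi_bias[lab] = est

    regions = results.get("regions", [])
    called = [(r.chrom, r.start, r.end) for r in regions]
    planted = truth.sweep_intervals
    if planted:
        hit = sum(
            1
            for (pc, ps, pe) in planted
            if any(c == pc and _interval_overlap((ps, pe), (s, e)) > 0 for c, s, e in called)
        )
        sensitivity = hit / len(planted)
    else:
        sensitivity = math.nan
    called_len = sum(e - s for _, s, e in called)
    if called_len > 0:
        overlap = 0
        for c, s, e in called:
            for pc, ps, pe in planted:
                if c == pc:
                    overlap += _interval_overlap((s, e), (ps, pe))
        precision = overlap / called_len
    else:
        precision = math.nan

    accuracy = math.nan
    if "assignment" in results:
        assign = results["assignment"]
        idx = {s: i for i, s in enumerate(truth.sample_ids)}
        correct = 0
        for sid, lab in zip(assign.sample_ids, assign.labels):
            row = truth.q_true[idx[sid]]
            expected = (
                f"group_{int(np.argmax(row)) + 1}"
                if row.max() >= assign.threshold
                else popstruct.MOSAIC
            )
            correct += lab == expected
        accuracy = correct / len(assign.sample_ids)

    half = math.nan
    curves = results.get("ld_curves", {})
    if "cultivated" in curves:
        try:
            half = ld_decay.half_decay_distance(curves["cultivated"])
        except ValueError:
            pass

    report = RecoveryReport(
        fst_bias=fst_bias,
        pi_bias=pi_bias,
        sweep_sensitivity=sensitivity,
        sweep_precision=precision,
        group_assignment_accuracy=accuracy,
        half_decay_bp=half,
    )
    return report
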