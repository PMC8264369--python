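"""Population structure: admixture-coefficient group assignment and PCA."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from popdiv.variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

MOSAIC = "MOSAIC"


@dataclass
class QMatrix:
    """Per-sample admixture coefficients over K ancestral components."""

    sample_ids: list[str]
    q: np.ndarray  # (n_samples, K)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.sample_ids):
            raise ValueError("q must be (n_samples, K)")
        if self.q.shape[1] < 1:
            raise ValueError("K must be >= 1")
        if np.any(self.q < -1e-9) or np.any(self.q > 1 + 1e-9):
            raise ValueError("admixture coefficients must lie in [0, 1]")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            bad = np.flatnonzero(~np.isclose(self.q.sum(axis=1), 1.0, atol=1e-6))
            raise ValueError(
                f"Q rows must sum to 1 (violations at rows {bad[:5].tolist()})"
            )

    @property
    def k(self) -> int:
        return self.q.shape[1]


@dataclass
class GroupAssignment:
    sample_ids: list[str]
    labels: list[str]  # "group_<k>" (1-based) or MOSAIC
    threshold: float
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return sum(1 for lab in self.labels if lab != MOSAIC)

    @property
    def n_mosaic(self) -> int:
        return sum(1 for lab in self.labels if lab == MOSAIC)


@dataclass
class PcaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_components)
    pct_variance: np.ndarray


def read_qmatrix(path: str | Path, sample_ids: list[str] | None = None) -> QMatrix:
    """Read a whitespace-delimited Q table.

    Accepts the bare ADMIXTURE ``.Q`` dialect (K numeric columns, requires
    ``sample_ids``) and the variant with a leading sample-id column.
    """
    rows: list[list[str]] = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
    if not rows:
        raise ValueError(f"{path}: empty Q table")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_ids = not _is_number(rows[0][0])
    if has_ids:
        ids = [r[0] for r in rows]
        q = np.array([[float(x) for x in r[1:]] for r in rows])
    else:
        if sample_ids is None:
            ids = [f"sample_{i + 1}" for i in range(len(rows))]
        else:
            if len(sample_ids) != len(rows):
                raise ValueError(
                    f"{path}: {len(rows)} Q rows but {len(sample_ids)} sample ids"
                )
            ids = list(sample_ids)
        q = np.array([[float(x) for x in r] for r in rows])
    return QMatrix(sample_ids=ids, q=q)


def assign_groups(qmat: QMatrix, threshold: float = 0.80) -> GroupAssignment:
    """Assign each sample to its argmax component iff that entry >= threshold.

    Samples whose largest coefficient falls below the threshold are labelled
    MOSAIC. The rule is >=: a coefficient exactly at the threshold assigns.
    """
    labels = []
    for row in qmat.q:
        k = int(np.argmax(row))
        labels.append(f"group_{k + 1}" if row[k] >= threshold else MOSAIC)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    logger.info(
        "assign_groups: %d assigned, %d mosaic (threshold %.2f)",
        sum(v for k_, v in counts.items() if k_ != MOSAIC),
        counts.get(MOSAIC, 0),
        threshold,
    )
    return GroupAssignment(
        sample_ids=list(qmat.sample_ids),
        labels=labels,
        threshold=threshold,
        counts=counts,
    )


def pca_genotypes(
    matrix: GenotypeMatrix,
    samples: list[str] | None = None,
    n_components: int = 10,
    scaling: str = "patterson",
) -> PcaResult:
    """PCA of the variant-dosage matrix.

    Missing calls are mean-imputed per site before centering; Patterson
    scaling divides each centered column by sqrt(p(1-p)). Sites monomorphic
    in the subset carry no information and are dropped. pct_variance is the
    percent of total variance captured by each returned component.
    """
    if scaling not in ("patterson", "unit"):
        raise ValueError(f"unknown scaling: {scaling}")
    idx = matrix.sample_indices(samples)
    if len(idx) < 2:
        raise ValueError("PCA needs >= 2 samples")
    cols = np.flatnonzero(matrix.is_variant)
    dos = matrix.dosages[np.ix_(idx, cols)].astype(float)
    dos[dos == MISSING] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(dos, axis=0)
    keep = ~np.isnan(col_mean)
    p = col_mean / 2.0
    if scaling == "patterson":
        keep &= (p > 0) & (p < 1)
    if keep.sum() < 2:
        raise ValueError("PCA needs >= 2 informative variant sites")
    dos = dos[:, keep]
    col_mean = col_mean[keep]
    p = p[keep]

    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(col_mean, inds[1])
    x = dos - col_mean
    if scaling == "patterson":
        x = x / np.sqrt(p * (1.0 - p))

    n = x.shape[0]
    max_k = min(n - 1, x.shape[1])
    if n_components > max_k:
        logger.warning(
            "n_components clipped from %d to %d", n_components, max_k
        )
        n_components = max_k

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    lam = s**2 / (n - 1)
    total = lam.sum()
    coords = u[:, :n_components] * s[:n_components]
    pct = 100.0 * lam[:n_components] / total if total > 0 else np.zeros(n_components)
    sub_ids = [matrix.sample_ids[i] for i in idx]
    return PcaResult(sample_ids=sub_ids, coordinates=coords, pct_variance=pct)
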