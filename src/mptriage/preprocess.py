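"""Normalization and quality filters for the log2 expression matrix.

Three stages, applied in order:

1. :func:`normalize` — per-chip median alignment (each array shifted so its
   median matches the grand median of array medians); optional per-gene
   median centering for fold-change reporting.
2. :func:`detect_outlier_samples` — pairwise-Pearson rule: an array is an
   outlier when at least 90% of its correlations with other arrays fall below
   the global threshold mean - 2*SD of all pairwise correlations.  PCA sample
   coordinates are emitted for visual QC only; no removal is based on them.
3. :func:`filter_noisy_genes` — duplicate-CV rule: for every duplicate pair
   (same group and time) the coefficient of variation of the two replicate
   intensities is computed on the linear scale; a gene is kept only if at
   least 16 of its pairs have CV below 50% (thresholds configurable).

The CV is computed on de-logged intensities by default because a coefficient
of variation of log-scale values is not scale-invariant; ``cv_scale="log2"``
reproduces the alternative reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

#: fraction of an array's correlations that must be sub-threshold to flag it
OUTLIER_FRACTION = 0.9

REASON_LOW_CORRELATION = "low_correlation"
REASON_ZERO_VARIANCE = "zero_variance"


@dataclass
class FilterReport:
    """What the preprocessing filters removed and why."""

    removed_samples: dict[str, float] = field(default_factory=dict)
    removal_reasons: dict[str, str] = field(default_factory=dict)
    genes_before: int = 0
    genes_after: int = 0
    pass_counts: pd.Series | None = None
    n_pairs: int = 0
    skipped_conditions: list[tuple[str, int]] = field(default_factory=list)
    correlation_threshold: float | None = None
    pca_coordinates: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "removed_samples": self.removed_samples,
            "removal_reasons": self.removal_reasons,
            "genes_before": self.genes_before,
            "genes_after": self.genes_after,
            "n_pairs": self.n_pairs,
            "skipped_conditions": [list(c) for c in self.skipped_conditions],
            "correlation_threshold": self.correlation_threshold,
        }


def _check_finite(matrix: pd.DataFrame) -> None:
    bad = ~np.isfinite(matrix.to_numpy())
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value at gene {matrix.index[gi]!r}, sample {matrix.columns[si]!r}"
        )


def normalize(ds: ExpressionDataset, per_gene: bool = False) -> ExpressionDataset:
    """Median-align arrays; optionally center each gene at its median.

    Per-chip: every array is shifted so its median equals the grand median of
    array medians, removing chip-level intensity offsets.  Per-gene centering
    (off by default) subtracts each gene's median across arrays; the
    downstream ANOVA is location-invariant within gene, so centering only
    matters for exported fold-changes.
    """
    _check_finite(ds.matrix)
    medians = ds.matrix.median(axis=0)
    target = float(np.median(medians.to_numpy()))
    out = ds.matrix - (medians - target)
    if per_gene:
        out = out.sub(out.median(axis=1), axis=0)
    return ExpressionDataset(out, list(ds.samples))


def detect_outlier_samples(ds: ExpressionDataset) -> FilterReport:
    """Flag arrays whose pairwise Pearson correlations are globally poor.

    The threshold theta = mean - 2*SD is computed over all n(n-1)/2 pairwise
    correlations; an array is flagged when >= 90% of its n-1 correlations fall
    below theta.  Arrays with zero variance (Pearson undefined) are flagged
    with a distinct reason code.  PCA coordinates of all arrays (first two
    components) are attached for diagnostic plotting.
    """
    if ds.n_samples < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    _check_finite(ds.matrix)
    X = ds.matrix.to_numpy()
    sds = X.std(axis=0)
    zero_var = sds == 0.0
    report = FilterReport(genes_before=ds.n_genes, genes_after=ds.n_genes)

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    valid = ~zero_var
    iu = np.triu_indices(ds.n_samples, k=1)
    pair_vals = corr[iu]
    pair_ok = valid[iu[0]] & valid[iu[1]]
    vals = pair_vals[pair_ok]
    if vals.size:
        theta = float(vals.mean() - 2.0 * vals.std(ddof=1))
    else:
        theta = float("nan")
    report.correlation_threshold = theta

    for j, sid in enumerate(ds.sample_ids):
        if zero_var[j]:
            report.removed_samples[sid] = 1.0
            report.removal_reasons[sid] = REASON_ZERO_VARIANCE
            continue
        others = corr[j, valid]
        others = others[~np.isnan(others)]
        if others.size == 0:
            continue
        frac_low = float(np.mean(others < theta))
        if frac_low >= OUTLIER_FRACTION:
            report.removed_samples[sid] = frac_low
            report.removal_reasons[sid] = REASON_LOW_CORRELATION

    # diagnostic PCA of samples (genes as features), centered per gene
    centered = (X - X.mean(axis=1, keepdims=True)).T
    n_comp = min(2, centered.shape[0], centered.shape[1])
    _, _, vt = np.linalg.svd(centered - centered.mean(axis=0), full_matrices=False)
    coords = (centered - centered.mean(axis=0)) @ vt[:n_comp].T
    report.pca_coordinates = pd.DataFrame(
        coords, index=ds.sample_ids, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    return report


def remove_outlier_samples(ds: ExpressionDataset) -> tuple[ExpressionDataset, FilterReport]:
    """Run :func:`detect_outlier_samples` and drop the flagged arrays."""
    report = detect_outlier_samples(ds)
    return ds.drop_samples(report.removed_samples), report


def duplicate_cv_table(ds: ExpressionDataset, cv_scale: str = "linear") -> pd.DataFrame:
    """Per-gene CV% for every complete duplicate pair.

    Columns are (group, time) pairs with exactly two replicates.  On the
    linear scale values are de-logged (2**x) first; the two-replicate sample
    SD uses the n-1 denominator, i.e. SD = |x1 - x2| / sqrt(2).
    """
    if cv_scale not in ("linear", "log2"):
        raise ValueError(f"cv_scale must be 'linear' or 'log2', got {cv_scale!r}")
    cols = {}
    for group, t, ids in ds.duplicate_pairs():
        if len(ids) != 2:
            continue
        pair = ds.matrix[ids].to_numpy()
        if cv_scale == "linear":
            pair = np.power(2.0, pair)
        mean = pair.mean(axis=1)
        sd = np.abs(pair[:, 0] - pair[:, 1]) / np.sqrt(2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = 100.0 * sd / mean
        cv = np.where(mean > 0, cv, np.inf)
        cols[(group, t)] = cv
    return pd.DataFrame(cols, index=ds.genes)


def filter_noisy_genes(
    ds: ExpressionDataset,
    cv_threshold: float = 50.0,
    min_pass_pairs: int = 16,
    cv_scale: str = "linear",
) -> tuple[ExpressionDataset, FilterReport]:
    """Keep genes whose duplicate CV is below ``cv_threshold`` in at least
    ``min_pass_pairs`` replicate pairs.

    A pair passes when CV% < threshold and its mean intensity is positive.
    Conditions without exactly two replicates are skipped and recorded in the
    report.  If fewer than ``min_pass_pairs`` complete pairs exist at all the
    rule is unsatisfiable and a ``ValueError`` is raised.
    """
    report = FilterReport(genes_before=ds.n_genes)
    complete = []
    for group, t, ids in ds.duplicate_pairs():
        if len(ids) == 2:
            complete.append((group, t))
        else:
            report.skipped_conditions.append((group, t))
    report.n_pairs = len(complete)
    if len(complete) < min_pass_pairs:
        raise ValueError(
            f"only {len(complete)} complete duplicate pairs available; "
            f"cannot require {min_pass_pairs} passing pairs"
        )
    cv = duplicate_cv_table(ds, cv_scale=cv_scale)
    passes = (cv < cv_threshold).sum(axis=1)
    report.pass_counts = passes
    keep = passes[passes >= min_pass_pairs].index
    report.genes_after = len(keep)
    return ds.subset_genes(keep), report
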