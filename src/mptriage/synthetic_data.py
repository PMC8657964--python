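"""Synthetic microarray generator with planted drug-response gene classes.

Generates log2 expression data under the study design (four groups, eight
time points, duplicate arrays, 60 samples) with known ground truth so every
downstream stage — outlier removal, the duplicate-CV noise filter, the
ANOVA/Tukey contrasts, and the SEMP/CPMP/ICMP set algebra — can be scored
against planted labels.

Planted profiles (relative to the untreated sham group S-EtOH, at the active
time points only):

========  =========  ========  =======
class     SCI-EtOH   SCI-MP    S-MP
========  =========  ========  =======
CPMP      +/- delta  restored  flat     (injury effect, drug restores)
ICMP      +/- delta  +/- delta flat     (injury effect, drug cannot restore)
SEMP      flat       +/- delta flat     (no injury effect, drug perturbs)
========  =========  ========  =======

The shift sign is drawn once per gene and kept across its active times, so
both over- and under-expression profiles are exercised.  Noise genes get a
replicate standard deviation large enough that the linear-scale duplicate CV
exceeds the 50% filter threshold in most pairs; outlier arrays are replaced
wholesale by an independent draw with the same marginal distribution, which
destroys their correlation with every other array without changing scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    ExpressionDataset,
    POST_INJURY_TIMES,
    full_design_annotations,
)

CLASS_LABELS = ("SEMP", "CPMP", "ICMP")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Sizes default to a desk-scale array (2,000 probes) with the planted-class
    and noise settings used throughout the validation suite: 50 genes per
    class, a 2.0 log2-unit effect, and 0.2 log2 units of replicate noise.

    Attributes
    ----------
    n_genes
        Total number of probe sets.
    n_planted_per_class
        Planted genes for each of SEMP, CPMP and ICMP.
    n_noise_genes
        High-variance probes meant to fail the duplicate-CV filter.
    n_outlier_samples
        Arrays replaced by independent draws (uncorrelated with peers).
    effect_size
        Planted shift magnitude delta, in log2 units.
    replicate_sd
        Replicate noise SD for ordinary genes, log2 units.
    noise_replicate_sd
        Replicate noise SD for planted noise genes, log2 units.  The default
        2.5 puts the expected linear duplicate CV well above 50%.
    baseline_mean, baseline_sd
        Per-gene baseline expression is drawn once from
        N(baseline_mean, baseline_sd^2) and shared across all conditions.
    active_times
        Post-injury times (h) at which planted effects are switched on.
    rng_seed
        Seed for the single random generator used throughout.
    """

    n_genes: int = 2000
    n_planted_per_class: int = 50
    n_noise_genes: int = 100
    n_outlier_samples: int = 0
    effect_size: float = 2.0
    replicate_sd: float = 0.2
    noise_replicate_sd: float = 2.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    active_times: tuple[int, ...] = POST_INJURY_TIMES
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_planted_per_class < 0:
            raise ValueError("n_planted_per_class must be non-negative")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be non-negative")
        if self.n_outlier_samples < 0:
            raise ValueError("n_outlier_samples must be non-negative")
        if 3 * self.n_planted_per_class + self.n_noise_genes > self.n_genes:
            raise ValueError(
                "n_genes too small: 3 * n_planted_per_class + n_noise_genes "
                f"= {3 * self.n_planted_per_class + self.n_noise_genes} exceeds "
                f"n_genes = {self.n_genes}"
            )
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be > 0")
        if self.noise_replicate_sd <= 0:
            raise ValueError("noise_replicate_sd must be > 0")
        bad = set(self.active_times) - set(POST_INJURY_TIMES)
        if bad:
            raise ValueError(f"active_times outside the post-injury design: {sorted(bad)}")


@dataclass
class GroundTruth:
    """Planted labels: per-gene class, shift sign and active times, plus outlier arrays."""

    labels: pd.Series  # gene_id -> {SEMP, CPMP, ICMP, noise, null}
    signs: pd.Series  # gene_id -> {-1, 0, +1}
    active_times: tuple[int, ...]
    outlier_samples: list[str] = field(default_factory=list)

    def genes_of(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.labels.index,
                "label": self.labels.to_numpy(),
                "sign": self.signs.to_numpy(),
                "active_times": [
                    ",".join(map(str, self.active_times)) if lab in CLASS_LABELS else ""
                    for lab in self.labels
                ],
            }
        )


def _planted_shift_matrix(
    labels: np.ndarray, signs: np.ndarray, delta: float
) -> dict[str, np.ndarray]:
    """Per-group additive shift (active times only), one entry per gene."""
    shift = signs * delta
    zeros = np.zeros_like(shift)
    sci_etoh = np.where(np.isin(labels, ("CPMP", "ICMP")), shift, zeros)
    sci_mp = np.where(np.isin(labels, ("ICMP", "SEMP")), shift, zeros)
    return {
        "S-EtOH": zeros,
        "S-MP": zeros,
        "SCI-EtOH": sci_etoh,
        "SCI-MP": sci_mp,
    }


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one synthetic study under ``config``.

    Deterministic for a fixed ``rng_seed``.  Returns the 60-sample dataset and
    the ground truth needed to score recovery downstream.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    # label assignment: planted classes first, then noise, rest null
    labels = np.full(n, "null", dtype=object)
    pos = 0
    for lab in CLASS_LABELS:
        labels[pos : pos + config.n_planted_per_class] = lab
        pos += config.n_planted_per_class
    labels[pos : pos + config.n_noise_genes] = "noise"

    signs = np.where(np.isin(labels, CLASS_LABELS), rng.choice([-1, 1], size=n), 0)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    shifts = _planted_shift_matrix(labels, signs, config.effect_size)
    rep_sd = np.where(labels == "noise", config.noise_replicate_sd, config.replicate_sd)

    annotations = full_design_annotations()
    cols = {}
    for ann in annotations:
        mean = baseline.copy()
        if ann.time_h in config.active_times:
            mean = mean + shifts[ann.group]
        cols[ann.sample_id] = mean + rng.normal(0.0, rep_sd, size=n)
    matrix = pd.DataFrame(cols, index=genes)

    outliers: list[str] = []
    if config.n_outlier_samples:
        if config.n_outlier_samples > len(annotations):
            raise ValueError("n_outlier_samples exceeds the number of arrays")
        picked = rng.choice(len(annotations), size=config.n_outlier_samples, replace=False)
        for idx in sorted(picked):
            sid = annotations[idx].sample_id
            fresh = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
            matrix[sid] = fresh + rng.normal(0.0, rep_sd, size=n)
            outliers.append(sid)

    truth = GroundTruth(
        labels=pd.Series(labels, index=genes),
        signs=pd.Series(signs, index=genes),
        active_times=tuple(config.active_times),
        outlier_samples=outliers,
    )
    return ExpressionDataset(matrix, annotations), truth
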