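"""Per-timepoint four-group ANOVA, BH FDR gate, and Tukey HSD contrast sets.

At each post-injury time t the four groups (S-EtOH, S-MP, SCI-EtOH, SCI-MP)
are compared gene-by-gene with a one-way ANOVA; raw p-values are adjusted by
Benjamini-Hochberg across genes within the time point, and genes with
adjusted p <= fdr_alpha proceed to Tukey's honest significant difference for
the four contrasts of interest:

    A: SCI-EtOH vs S-EtOH   (injury response, untreated)
    B: SCI-MP  vs SCI-EtOH  (treatment response in the injured)
    C: SCI-MP  vs S-EtOH    (residual injury effect under treatment)
    D: S-MP    vs S-EtOH    (drug response in shams)

The Tukey p-value uses the studentized-range distribution with k = 4 groups
and the pooled-residual degrees of freedom; with unequal group sizes the
Tukey-Kramer standard error is used.  Membership in the DEG sets A_t..D_t
requires both the FDR gate and contrast p <= tukey_alpha (inclusive, per the
significance convention p <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset, GROUPS, POST_INJURY_TIMES

#: contrast label -> (test group, reference group)
CONTRASTS: dict[str, tuple[str, str]] = {
    "A": ("SCI-EtOH", "S-EtOH"),
    "B": ("SCI-MP", "SCI-EtOH"),
    "C": ("SCI-MP", "S-EtOH"),
    "D": ("S-MP", "S-EtOH"),
}
CONTRAST_LABELS = tuple(CONTRASTS)


@dataclass
class DEGQuad:
    """The four differentially-expressed gene sets at one time point."""

    time_h: int
    A: set[str] = field(default_factory=set)
    B: set[str] = field(default_factory=set)
    C: set[str] = field(default_factory=set)
    D: set[str] = field(default_factory=set)

    def __getitem__(self, label: str) -> set[str]:
        return getattr(self, label)

    def to_dict(self) -> dict:
        return {
            "time_h": self.time_h,
            **{lab: sorted(self[lab]) for lab in CONTRAST_LABELS},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DEGQuad":
        return cls(time_h=d["time_h"], **{lab: set(d[lab]) for lab in CONTRAST_LABELS})


def _group_blocks(ds: ExpressionDataset, time_h: int) -> dict[str, np.ndarray]:
    """Gene x replicate value blocks for all four groups at one time point."""
    if time_h not in POST_INJURY_TIMES:
        raise ValueError(
            f"four-group comparison requires a post-injury time point, got {time_h} h"
        )
    blocks = {}
    for group in GROUPS:
        vals = ds.values_for(group, time_h)
        if vals.shape[1] < 2:
            raise ValueError(
                f"group {group} has {vals.shape[1]} replicate(s) at {time_h} h; need >= 2"
            )
        blocks[group] = vals
    return blocks


def anova_per_gene(
    ds: ExpressionDataset, time_h: int, fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """One-way four-group ANOVA per gene with a BH gate at one time point.

    Returns a DataFrame indexed by gene with columns ``anova_F``, ``anova_p``,
    ``anova_fdr`` and boolean ``gate`` (adjusted p <= fdr_alpha), plus the
    contrast mean differences ``log2fc_A`` .. ``log2fc_D``.
    """
    blocks = _group_blocks(ds, time_h)
    ns = np.array([b.shape[1] for b in blocks.values()])
    N, k = int(ns.sum()), len(blocks)
    means = {g: b.mean(axis=1) for g, b in blocks.items()}
    grand = sum(b.sum(axis=1) for b in blocks.values()) / N
    ss_between = sum(
        n_i * (means[g] - grand) ** 2 for (g, _), n_i in zip(blocks.items(), ns)
    )
    ss_within = sum(((b - means[g][:, None]) ** 2).sum(axis=1) for g, b in blocks.items())
    df_b, df_w = k - 1, N - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ms_b / ms_w
    p = np.where(
        ms_w > 0,
        stats.f.sf(np.where(ms_w > 0, F, 0.0), df_b, df_w),
        # zero residual variance: significant iff the group means differ at all
        np.where(ss_between > 0, 0.0, 1.0),
    )
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "anova_F": F,
            "anova_p": p,
            "anova_fdr": fdr,
            "gate": fdr <= fdr_alpha,
        },
        index=ds.genes,
    )
    for lab, (test, ref) in CONTRASTS.items():
        out[f"log2fc_{lab}"] = means[test] - means[ref]
    out["_ms_within"] = ms_w
    out["_df_within"] = df_w
    return out


@lru_cache(maxsize=None)
def _tukey_critical_q(k: int, df: float, alpha: float) -> float:
    """Critical studentized-range value: sf(q_crit) = alpha for k groups, df."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_contrasts(
    ds: ExpressionDataset,
    time_h: int,
    stats_df: pd.DataFrame,
    tukey_alpha: float = 0.05,
    exact_p: bool = True,
) -> pd.DataFrame:
    """Add Tukey HSD p-values and significance flags for the gated genes.

    For each of the four contrasts the studentized-range statistic is
    q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j)) and the
    p-value the upper tail of the studentized range with k = 4 and the
    residual degrees of freedom (Tukey-Kramer form; reduces to the classical
    balanced formula when n_i = n_j).  Genes failing the ANOVA gate keep NaN
    Tukey p-values.  A gene with zero pooled variance gets p = 0 where the
    contrast means differ and p = 1 where they coincide, with a reason flag.

    Significance (``in_A`` .. ``in_D``) is decided by comparing q against the
    cached critical value q_crit with sf(q_crit) = tukey_alpha, which is
    equivalent to p <= tukey_alpha but needs one distribution evaluation per
    design instead of one per gene.  With ``exact_p=False`` the per-gene
    p-values are skipped entirely (left NaN) — useful in large simulation
    studies where only set membership matters.
    """
    blocks = _group_blocks(ds, time_h)
    n_by_group = {g: b.shape[1] for g, b in blocks.items()}
    k = len(blocks)
    out = stats_df.copy()
    gate = out["gate"].to_numpy()
    ms_w = out["_ms_within"].to_numpy()
    df_w = out["_df_within"].to_numpy()
    out["tukey_degenerate"] = gate & (ms_w == 0.0)
    crit = {
        df: _tukey_critical_q(k, float(df), tukey_alpha) for df in np.unique(df_w[gate])
    } if gate.any() else {}
    for lab, (test, ref) in CONTRASTS.items():
        diff = np.abs(out[f"log2fc_{lab}"].to_numpy())
        se = np.sqrt(
            np.maximum(ms_w, 0.0) / 2.0 * (1.0 / n_by_group[test] + 1.0 / n_by_group[ref])
        )
        p = np.full(len(out), np.nan)
        sig = np.zeros(len(out), dtype=bool)
        ok = gate & (se > 0)
        if ok.any():
            q = diff[ok] / se[ok]
            q_crit = np.array([crit[df] for df in df_w[ok]])
            sig[ok] = q >= q_crit
            if exact_p:
                p[ok] = stats.studentized_range.sf(q, k, df_w[ok])
        degen = gate & (se == 0)
        p[degen] = np.where(diff[degen] > 0, 0.0, 1.0)
        sig[degen] = diff[degen] > 0
        out[f"tukey_p_{lab}"] = p
        out[f"in_{lab}"] = sig
    return out


def build_deg_quad(stats_df: pd.DataFrame, time_h: int) -> DEGQuad:
    """Assemble the A/B/C/D gene sets from a completed stats table."""
    quad = DEGQuad(time_h=time_h)
    for lab in CONTRAST_LABELS:
        col = f"in_{lab}"
        if col not in stats_df:
            raise ValueError(f"stats table lacks column {col}; run tukey_contrasts first")
        members = stats_df.index[stats_df[col].fillna(False).astype(bool)]
        setattr(quad, lab, set(members))
    return quad


def differential_at_time(
    ds: ExpressionDataset,
    time_h: int,
    fdr_alpha: float = 0.05,
    tukey_alpha: float = 0.05,
    exact_p: bool = True,
) -> tuple[pd.DataFrame, DEGQuad]:
    """ANOVA gate + Tukey contrasts + DEG quad for one time point."""
    table = anova_per_gene(ds, time_h, fdr_alpha=fdr_alpha)
    table = tukey_contrasts(ds, time_h, table, tukey_alpha=tukey_alpha, exact_p=exact_p)
    return table, build_deg_quad(table, time_h)


def differential_all_times(
    ds: ExpressionDataset,
    times: tuple[int, ...] = POST_INJURY_TIMES,
    fdr_alpha: float = 0.05,
    tukey_alpha: float = 0.05,
    exact_p: bool = True,
) -> tuple[dict[int, pd.DataFrame], dict[int, DEGQuad]]:
    tables: dict[int, pd.DataFrame] = {}
    quads: dict[int, DEGQuad] = {}
    for t in times:
        tables[t], quads[t] = differential_at_time(
            ds, t, fdr_alpha=fdr_alpha, tukey_alpha=tukey_alpha, exact_p=exact_p
        )
    return tables, quads
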