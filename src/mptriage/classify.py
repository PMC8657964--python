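"""Set-algebra classification of genes into SEMP, CPMP and ICMP.

A gene's membership pattern across the four per-timepoint DEG sets
(A: injury effect, B: treatment effect in the injured, C: residual effect
under treatment, D: drug effect in shams) determines its class:

    SEMP  (side effect):  not A, B, C, not D  — unchanged by injury alone,
                          perturbed once the drug is given
    CPMP  (competence):   A, B, not C, not D  — changed by injury, restored
                          to sham level by the drug
    ICMP  (incapability): A, not B, C, not D  — changed by injury and still
                          changed after treatment

Equivalently, with X, Y, Z ranging over {A, B, C} (all distinct):
class = (X_t ∩ Y_t ∩ D_t^c) − Z_t, where the complement of D is taken within
the tested-gene universe.  Both routes are implemented; their equivalence is
an internal invariant.  Time points are treated independently; for reporting,
they are pooled into the four phases 2~6 h, 8 h, 12 h and 24~48 h by union
within class.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dataset import ExpressionDataset, GROUPS, POST_INJURY_TIMES
from .differential import DEGQuad

GENE_CLASSES = ("SEMP", "CPMP", "ICMP")
UNCLASSIFIED = "unclassified"

#: reporting phases -> the time points they pool
PHASES: dict[str, tuple[int, ...]] = {
    "2~6 h": (2, 4, 6),
    "8 h": (8,),
    "12 h": (12,),
    "24~48 h": (24, 48),
}

SignificancePattern = namedtuple("SignificancePattern", ["a", "b", "c", "d"])

#: class -> required (a, b, c, d) significance pattern
CLASS_PATTERNS: dict[str, SignificancePattern] = {
    "SEMP": SignificancePattern(False, True, True, False),
    "CPMP": SignificancePattern(True, True, False, False),
    "ICMP": SignificancePattern(True, False, True, False),
}


def classify_gene(pattern: SignificancePattern) -> str:
    """Map one significance pattern to its gene class (or ``unclassified``)."""
    for cls, req in CLASS_PATTERNS.items():
        if tuple(map(bool, pattern)) == req:
            return cls
    return UNCLASSIFIED


def classify_by_set_algebra(
    quad: DEGQuad, universe: Iterable[str]
) -> dict[str, set[str]]:
    """Class gene sets at one time point via the intersection/complement route.

    ``universe`` is the tested-gene universe (genes surviving the noise
    filter); the complement of D is taken within it.  DEG sets containing
    genes outside the universe are rejected.
    """
    universe = set(universe)
    for lab in "ABCD":
        extra = quad[lab] - universe
        if extra:
            raise ValueError(
                f"DEG set {lab} at {quad.time_h} h contains genes outside the "
                f"tested universe, e.g. {sorted(extra)[:3]}"
            )
    d_comp = universe - quad.D
    return {
        "SEMP": (quad.B & quad.C & d_comp) - quad.A,
        "CPMP": (quad.A & quad.B & d_comp) - quad.C,
        "ICMP": (quad.A & quad.C & d_comp) - quad.B,
    }


@dataclass(frozen=True)
class ClassAssignment:
    gene_id: str
    time_h: int
    gene_class: str


def assignments_from_quads(
    quads: Mapping[int, DEGQuad], universe: Iterable[str]
) -> list[ClassAssignment]:
    """Classified genes for every time point (unclassified genes omitted)."""
    universe = set(universe)
    out: list[ClassAssignment] = []
    for t in sorted(quads):
        sets = classify_by_set_algebra(quads[t], universe)
        for cls in GENE_CLASSES:
            for g in sorted(sets[cls]):
                out.append(ClassAssignment(g, t, cls))
    return out


@dataclass
class PhaseSummary:
    phase: str
    genes: dict[str, set[str]]

    def counts(self) -> dict[str, int]:
        return {cls: len(self.genes[cls]) for cls in GENE_CLASSES}


def aggregate_phases(
    assignments: Sequence[ClassAssignment],
    analyzed_times: Iterable[int] = POST_INJURY_TIMES,
) -> list[PhaseSummary]:
    """Pool per-timepoint class sets into reporting phases by union.

    ``analyzed_times`` are the time points the upstream analysis covered;
    every phase time point must be among them (a phase may still come out
    empty when nothing classified there).  A gene classified differently at
    two time points of one phase is counted in each respective class set
    (deduplicated within class).
    """
    analyzed = set(analyzed_times)
    for phase, phase_times in PHASES.items():
        missing = [t for t in phase_times if t not in analyzed]
        if missing:
            raise ValueError(
                f"phase {phase!r} needs time point(s) {missing} which were not analyzed"
            )
    out = []
    for phase, phase_times in PHASES.items():
        genes: dict[str, set[str]] = {cls: set() for cls in GENE_CLASSES}
        for a in assignments:
            if a.time_h in phase_times:
                genes[a.gene_class].add(a.gene_id)
        out.append(PhaseSummary(phase=phase, genes=genes))
    return out


def phase_summary_table(summaries: Sequence[PhaseSummary]) -> pd.DataFrame:
    """Counts per class x phase, phases as columns."""
    return pd.DataFrame(
        {s.phase: {cls: len(s.genes[cls]) for cls in GENE_CLASSES} for s in summaries}
    ).loc[list(GENE_CLASSES)]


def assignments_table(assignments: Sequence[ClassAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in assignments],
            "time_h": [a.time_h for a in assignments],
            "gene_class": [a.gene_class for a in assignments],
        }
    )


def export_profiles(
    ds: ExpressionDataset, assignments: Sequence[ClassAssignment]
) -> pd.DataFrame:
    """Log2 fold-change of each group vs S-EtOH for every classified gene.

    One row per (gene, time point, group); used for QC plots of the
    class-mean profiles.
    """
    rows = []
    classified = sorted({a.gene_id for a in assignments})
    cls_at = {(a.gene_id, a.time_h): a.gene_class for a in assignments}
    for t in sorted({a.time_h for a in assignments}):
        ref = ds.matrix[ds.columns_for("S-EtOH", t)].mean(axis=1)
        for group in GROUPS:
            cols = ds.columns_for(group, t)
            if not cols:
                continue
            fc = ds.matrix[cols].mean(axis=1) - ref
            for g in classified:
                cls = cls_at.get((g, t))
                if cls is None:
                    continue
                rows.append(
                    {
                        "gene_id": g,
                        "time_h": t,
                        "group": group,
                        "gene_class": cls,
                        "log2fc_vs_S_EtOH": float(fc.loc[g]),
                    }
                )
    return pd.DataFrame(rows)


def class_mean_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean |log2FC| profile per (class, group, time) over classified genes."""
    if profiles.empty:
        return pd.DataFrame(
            columns=["gene_class", "group", "time_h", "mean_abs_log2fc"]
        )
    out = (
        profiles.assign(abs_fc=profiles["log2fc_vs_S_EtOH"].abs())
        .groupby(["gene_class", "group", "time_h"], as_index=False)["abs_fc"]
        .mean()
        .rename(columns={"abs_fc": "mean_abs_log2fc"})
    )
    return out


def plot_class_profiles(profiles: pd.DataFrame, path: str) -> None:
    """Static QC plot: class-mean |log2FC| per group over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"SEMP": "#8B5A2B", "CPMP": "#1f77b4", "ICMP": "#d4a017"}
    means = class_mean_profiles(profiles)
    fig, axes = plt.subplots(1, len(GROUPS), figsize=(4 * len(GROUPS), 3), sharey=True)
    for ax, group in zip(axes, GROUPS):
        for cls in GENE_CLASSES:
            sub = means[(means["gene_class"] == cls) & (means["group"] == group)]
            if not sub.empty:
                sub = sub.sort_values("time_h")
                ax.plot(sub["time_h"], sub["mean_abs_log2fc"], marker="o",
                        color=colors[cls], label=cls)
        ax.set_title(group)
        ax.set_xlabel("time (h)")
    axes[0].set_ylabel("mean |log2FC| vs S-EtOH")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
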