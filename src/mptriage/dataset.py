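"""Expression dataset container for the injury x medication time-course design.

The experimental layout is a 2x2 factorial (injury: sham vs. SCI; medication:
vehicle EtOH vs. methylprednisolone MP) sampled at 0, 2, 4, 6, 8, 12, 24 and
48 h post-injury with two biological replicates per condition.  At 0 h only
the two untreated groups (S-EtOH, SCI-EtOH) exist, so the full design has
4 groups x 7 times x 2 replicates + 2 groups x 1 time x 2 replicates
= 60 arrays.

The matrix is a pandas DataFrame of log2 intensities with genes as rows and
sample IDs as columns; sample metadata lives in :class:`SampleAnnotation`
records kept in column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_TIMES = (0, 2, 4, 6, 8, 12, 24, 48)
POST_INJURY_TIMES = (2, 4, 6, 8, 12, 24, 48)
GROUPS = ("S-EtOH", "S-MP", "SCI-EtOH", "SCI-MP")
#: groups present at the 0 h baseline (sham and injured, both untreated)
BASELINE_GROUPS = ("S-EtOH", "SCI-EtOH")


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one array: factor levels plus replicate index."""

    sample_id: str
    injury: str  # "sham" | "SCI"
    medication: str  # "EtOH" | "MP"
    time_h: int
    replicate: int

    def __post_init__(self) -> None:
        if self.injury not in ("sham", "SCI"):
            raise ValueError(f"injury must be 'sham' or 'SCI', got {self.injury!r}")
        if self.medication not in ("EtOH", "MP"):
            raise ValueError(
                f"medication must be 'EtOH' or 'MP', got {self.medication!r}"
            )
        if self.time_h not in VALID_TIMES:
            raise ValueError(f"time_h must be one of {VALID_TIMES}, got {self.time_h}")

    @property
    def group(self) -> str:
        """Combined group label, e.g. ``SCI-MP`` or ``S-EtOH``."""
        prefix = "S" if self.injury == "sham" else "SCI"
        return f"{prefix}-{self.medication}"


class ExpressionDataset:
    """A log2 gene x sample matrix together with its sample annotations.

    Parameters
    ----------
    matrix
        DataFrame indexed by gene ID with one column per sample ID, values on
        the log2 scale.
    samples
        One :class:`SampleAnnotation` per matrix column, in column order.
    """

    def __init__(self, matrix: pd.DataFrame, samples: Sequence[SampleAnnotation]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if list(matrix.columns) != ids:
            raise ValueError("matrix columns do not match sample annotations")
        if matrix.index.has_duplicates:
            dup = matrix.index[matrix.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        keys = [(s.injury, s.medication, s.time_h, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (injury, medication, time, replicate) sample")
        self.matrix = matrix
        self.samples = samples
        self._by_id = {s.sample_id: s for s in samples}

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def annotation(self, sample_id: str) -> SampleAnnotation:
        return self._by_id[sample_id]

    def sample_table(self) -> pd.DataFrame:
        """Sample sheet as a DataFrame (one row per array)."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "injury": [s.injury for s in self.samples],
                "medication": [s.medication for s in self.samples],
                "time_h": [s.time_h for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    # -- design queries ----------------------------------------------------

    def columns_for(self, group: str, time_h: int) -> list[str]:
        """Sample IDs belonging to one (group, time) condition."""
        return [s.sample_id for s in self.samples if s.group == group and s.time_h == time_h]

    def times(self) -> list[int]:
        return sorted({s.time_h for s in self.samples})

    def values_for(self, group: str, time_h: int) -> np.ndarray:
        """Gene x replicate value block for one condition."""
        cols = self.columns_for(group, time_h)
        return self.matrix[cols].to_numpy()

    def duplicate_pairs(self) -> list[tuple[str, int, list[str]]]:
        """Conditions with their replicate sample IDs, ordered by (group, time).

        A condition with a replicate count other than 2 is still returned;
        callers decide how to treat incomplete pairs.
        """
        out: list[tuple[str, int, list[str]]] = []
        for group in GROUPS:
            for t in self.times():
                cols = self.columns_for(group, t)
                if cols:
                    out.append((group, t, cols))
        return out

    # -- derived datasets --------------------------------------------------

    def drop_samples(self, sample_ids: Iterable[str]) -> "ExpressionDataset":
        drop = set(sample_ids)
        keep = [s for s in self.samples if s.sample_id not in drop]
        return ExpressionDataset(self.matrix[[s.sample_id for s in keep]], keep)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.matrix.loc[list(genes)], self.samples)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.matrix.copy(), list(self.samples))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionDataset({self.n_genes} genes x {self.n_samples} samples)"


def full_design_annotations() -> list[SampleAnnotation]:
    """The 60-array layout: all four groups at 2..48 h plus untreated groups at 0 h."""
    out = []
    for group in GROUPS:
        injury = "sham" if group.startswith("S-") else "SCI"
        medication = group.split("-")[1]
        times = VALID_TIMES if group in BASELINE_GROUPS else POST_INJURY_TIMES
        for t in times:
            for rep in (1, 2):
                out.append(
                    SampleAnnotation(
                        sample_id=f"{group}_{t}h_rep{rep}",
                        injury=injury,
                        medication=medication,
                        time_h=t,
                        replicate=rep,
                    )
                )
    return out
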