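"""Core domain containers.

Genomic CpG sites are keyed by ``(chromosome, position)`` throughout the
package; both strands of a CpG dinucleotide collapse onto the position of the
forward-strand cytosine. Tabular data live in pandas objects indexed by a
two-level (chrom, pos) MultiIndex so that set operations between profiles,
reference models and atlases are plain index intersections.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd


class CpGSite(NamedTuple):
    """One CpG dinucleotide: chromosome label + 0-based forward-strand position."""

    chrom: str
    pos: int

    def __str__(self) -> str:  # "chr1:12345" notation used by the TSV readers
        return f"{self.chrom}:{self.pos}"

    @classmethod
    def parse(cls, text: str) -> "CpGSite":
        chrom, _, pos = text.rpartition(":")
        if not chrom:
            raise ValueError(f"cannot parse CpG site {text!r}; expected 'chrom:pos'")
        position = int(pos)
        if position < 0:
            raise ValueError(f"negative CpG position in {text!r}")
        return cls(chrom, position)


def sites_index(sites: Iterable[tuple[str, int]]) -> pd.MultiIndex:
    """Build the canonical (chrom, pos) MultiIndex from site tuples."""
    return pd.MultiIndex.from_tuples(list(sites), names=["chrom", "pos"])


@dataclasses.dataclass
class MethylationProfile:
    """Sparse per-site methylation of one sample or one cell-type aggregate.

    ``beta`` holds the methylated fraction in [0, 1] and ``coverage`` the
    supporting read count (>= 1); both share one (chrom, pos) index.
    """

    beta: pd.Series
    coverage: pd.Series

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.coverage.index):
            raise ValueError("beta and coverage must share one site index")
        b = self.beta.to_numpy(dtype=float)
        if b.size and (np.nanmin(b) < 0 or np.nanmax(b) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        c = self.coverage.to_numpy()
        if c.size and c.min() < 1:
            raise ValueError("coverage must be >= 1 at every retained site")

    @classmethod
    def from_mappings(
        cls,
        beta: Mapping[tuple[str, int], float],
        coverage: Mapping[tuple[str, int], int] | None = None,
    ) -> "MethylationProfile":
        idx = sites_index(beta.keys())
        b = pd.Series([beta[s] for s in beta], index=idx, dtype=float)
        if coverage is None:
            c = pd.Series(1, index=idx, dtype=int)
        else:
            c = pd.Series([coverage[s] for s in beta], index=idx, dtype=int)
        return cls(beta=b, coverage=c)

    @property
    def sites(self) -> pd.MultiIndex:
        return self.beta.index

    def __len__(self) -> int:
        return len(self.beta)


@dataclasses.dataclass
class Fragment:
    """One long read: id, mapping info, and per-CpG methylation calls.

    ``calls`` maps the CpG position (on ``chrom``) to a methylation call in
    [0, 1] — typically binary for a single molecule, fractional when the
    caller emits confidences.
    """

    read_id: str
    chrom: str
    mapq: int
    calls: dict[int, float]

    def __post_init__(self) -> None:
        if not self.calls:
            raise ValueError(f"fragment {self.read_id}: calls must be non-empty")
        if self.mapq < 0:
            raise ValueError(f"fragment {self.read_id}: mapq must be >= 0")
        for pos, val in self.calls.items():
            if not (0.0 <= val <= 1.0):
                raise ValueError(
                    f"fragment {self.read_id}: call {val} at {self.chrom}:{pos} "
                    "outside [0, 1]"
                )

    @property
    def sites(self) -> list[CpGSite]:
        return [CpGSite(self.chrom, p) for p in self.calls]


INELIGIBLE = "ineligible"
UNASSIGNED = "unassigned"


@dataclasses.dataclass
class AssignmentResult:
    """Cell-type-of-origin call for one fragment.

    ``label`` is a cell-type name, ``"unassigned"`` (scored but the ratio
    rule was not met) or ``"ineligible"`` (pre-scoring filters failed, with
    ``reason`` one of ``non_autosomal`` / ``mapq`` / ``min_overlap``).
    """

    read_id: str
    label: str
    scores: dict[str, float] = dataclasses.field(default_factory=dict)
    n_overlap: dict[str, int] = dataclasses.field(default_factory=dict)
    reason: str | None = None

    @property
    def eligible(self) -> bool:
        return self.label != INELIGIBLE


@dataclasses.dataclass
class AgePrediction:
    """Grid-search age estimate with its full score curve."""

    age_estimate: float
    score_at_max: float
    n_sites_used: int
    score_curve: pd.Series  # index: grid age, values: log-probability score

    def deviation(self, chronological_age: float) -> float:
        """Age deviation: predicted epigenetic age minus chronological age."""
        return self.age_estimate - chronological_age


@dataclasses.dataclass
class ReferenceAgingDataset:
    """Cohort methylation matrix with known ages.

    ``betas`` is samples x sites (NaN allowed for per-site missingness),
    columns a (chrom, pos) MultiIndex; ``ages`` aligns with ``betas.index``.
    """

    betas: pd.DataFrame
    ages: pd.Series

    def __post_init__(self) -> None:
        self.ages = self.ages.reindex(self.betas.index)
        if self.ages.isna().any():
            missing = self.ages[self.ages.isna()].index.tolist()
            raise ValueError(f"samples without ages: {missing[:5]}")
        a = self.ages.to_numpy(dtype=float)
        if a.size and (a.min() < 0 or a.max() > 120):
            raise ValueError("ages must lie in [0, 120] years")
        vals = self.betas.to_numpy(dtype=float)
        if vals.size:
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.betas)

    @property
    def sites(self) -> pd.MultiIndex:
        return self.betas.columns


@dataclasses.dataclass
class AtlasSampleSet:
    """Per-sample methylation with cell-type labels, input to marker finding.

    ``betas``/``coverage``: samples x sites; ``labels`` maps sample id to its
    cell-type group (e.g. "myeloid" / "lymphocyte").
    """

    betas: pd.DataFrame
    coverage: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.betas.index.equals(self.coverage.index) or not self.betas.columns.equals(
            self.coverage.columns
        ):
            raise ValueError("betas and coverage must be aligned")
        self.labels = self.labels.reindex(self.betas.index)
        if self.labels.isna().any():
            raise ValueError("every sample needs a cell-type label")
        vals = self.betas.to_numpy(dtype=float)
        if vals.size:
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.labels.unique())
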