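"""Fragment-level cell-type-of-origin assignment and profile aggregation.

Each long-read fragment is scored against every cell type in the marker
atlas with the similarity likelihood

    L(type) = sum over overlapping marker CpGs of (1 - |r_k - c_k|)

where r_k is the fragment's methylation call and c_k the atlas mean for that
type. L lies in [0, n_overlap]; a perfect match gives L = n_overlap. A
fragment is assigned to a type whose score is at least ``ratio`` (default
1/0.95, i.e. about 1.053x) times every other type's score; otherwise it is
"unassigned". Fragments failing the eligibility filters (autosomal only,
MAPQ >= 20, >= 5 overlapping marker CpGs per cell type) are "ineligible".
Assigned fragments pile up into per-type methylation profiles that feed the
epigenetic age predictor.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import NoEligibleFragmentsError, NoSharedSitesError
from .types import (
    INELIGIBLE,
    UNASSIGNED,
    AssignmentResult,
    Fragment,
    MethylationProfile,
    sites_index,
)

logger = logging.getLogger(__name__)

DEFAULT_RATIO = 1.0 / 0.95  # the published cutoff, ~1.053x
DEFAULT_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


def fragment_likelihood(
    fragment: Fragment, atlas: pd.DataFrame, cell_type: str
) -> tuple[float, int]:
    """Likelihood score and overlap count of one fragment against one type.

    Returns (0.0, 0) when the fragment covers no atlas marker for the type.
    """
    if cell_type not in atlas.columns:
        raise KeyError(f"unknown cell type {cell_type!r}; atlas has {list(atlas.columns)}")
    col = atlas[cell_type]
    score = 0.0
    n = 0
    for pos, r in fragment.calls.items():
        key = (fragment.chrom, pos)
        try:
            c = col.at[key]
        except KeyError:
            continue
        if pd.isna(c):
            continue
        score += 1.0 - abs(r - float(c))
        n += 1
    return score, n


class FragmentCellTypeClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based cell-type-of-origin classifier for long-read fragments.

    Parameters
    ----------
    atlas : pandas.DataFrame
        Markers x cell types mean-beta table, indexed (chrom, pos); at least
        two cell-type columns.
    min_overlap : int, default 5
        Minimum overlapping marker CpGs required against every cell type's
        marker set before a fragment may be scored.
    ratio : float, default 1/0.95
        A type wins only if its score is >= ratio x every other type's score
        (when another score is 0, the winner's score must be positive).
    min_mapq : int, default 20
        Mapping-quality eligibility threshold.
    autosomes : tuple of str
        Chromosome allow-list; default chr1..chr22 (human).

    Attributes
    ----------
    classes_ : ndarray of cell-type labels (after :meth:`fit`).
    """

    def __init__(
        self,
        atlas: pd.DataFrame | None = None,
        min_overlap: int = 5,
        ratio: float = DEFAULT_RATIO,
        min_mapq: int = 20,
        autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES,
    ):
        self.atlas = atlas
        self.min_overlap = min_overlap
        self.ratio = ratio
        self.min_mapq = min_mapq
        self.autosomes = autosomes

    def fit(self, X=None, y=None) -> "FragmentCellTypeClassifier":
        """Validate the atlas; no free parameters are learned."""
        if self.atlas is None or self.atlas.shape[1] < 2:
            raise ValueError("an atlas with >= 2 cell-type columns is required")
        self.classes_ = np.asarray(list(self.atlas.columns))
        # plain-dict views of the atlas columns: fragment scoring is a tight
        # per-call loop and pandas label lookups dominate otherwise
        self._atlas_maps_ = {
            ct: self.atlas[ct].dropna().to_dict() for ct in self.atlas.columns
        }
        return self

    def _likelihood(self, fragment: Fragment, cell_type: str) -> tuple[float, int]:
        cmap = self._atlas_maps_[cell_type]
        score = 0.0
        n = 0
        chrom = fragment.chrom
        for pos, r in fragment.calls.items():
            c = cmap.get((chrom, pos))
            if c is None:
                continue
            score += 1.0 - abs(r - c)
            n += 1
        return score, n

    # ------------------------------------------------------------ assignment
    def assign_one(self, fragment: Fragment) -> AssignmentResult:
        """Filter, score against every cell type, and apply the ratio rule."""
        atlas = self.atlas
        if fragment.chrom not in self.autosomes:
            return AssignmentResult(fragment.read_id, INELIGIBLE, reason="non_autosomal")
        if fragment.mapq < self.min_mapq:
            return AssignmentResult(fragment.read_id, INELIGIBLE, reason="mapq")

        scores: dict[str, float] = {}
        overlaps: dict[str, int] = {}
        for ct in atlas.columns:
            L, n = self._likelihood(fragment, ct)
            scores[ct] = L
            overlaps[ct] = n
        if any(n < self.min_overlap for n in overlaps.values()):
            return AssignmentResult(
                fragment.read_id,
                INELIGIBLE,
                scores=scores,
                n_overlap=overlaps,
                reason="min_overlap",
            )

        label = UNASSIGNED
        for ct, L in scores.items():
            others = [scores[s] for s in scores if s != ct]
            if L > 0 and all(L >= self.ratio * Ls for Ls in others):
                label = ct
                break
        return AssignmentResult(
            fragment.read_id, label, scores=scores, n_overlap=overlaps
        )

    def assign(self, fragments: list[Fragment]) -> list[AssignmentResult]:
        results = [self.assign_one(f) for f in fragments]
        counts = defaultdict(int)
        for r in results:
            counts[r.label if r.eligible else f"{INELIGIBLE}:{r.reason}"] += 1
        logger.info("fragment assignment attrition: %s", dict(counts))
        return results

    def predict(self, X: list[Fragment]) -> np.ndarray:
        """Labels only (cell type, 'unassigned' or 'ineligible')."""
        return np.asarray([self.assign_one(f).label for f in X])

    def decision_function(self, X: list[Fragment]) -> np.ndarray:
        """Score difference L(classes_[0]) - L(classes_[1]) for two-type atlases."""
        if len(self.classes_) != 2:
            raise ValueError("decision_function requires exactly two cell types")
        a, b = self.classes_
        out = np.empty(len(X))
        for i, frag in enumerate(X):
            la, _ = self._likelihood(frag, a)
            lb, _ = self._likelihood(frag, b)
            out[i] = la - lb
        return out


# ------------------------------------------------------ functional wrappers
def assign_fragment(
    fragment: Fragment,
    atlas: pd.DataFrame,
    min_overlap: int = 5,
    ratio: float = DEFAULT_RATIO,
    min_mapq: int = 20,
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES,
) -> AssignmentResult:
    clf = FragmentCellTypeClassifier(
        atlas=atlas,
        min_overlap=min_overlap,
        ratio=ratio,
        min_mapq=min_mapq,
        autosomes=autosomes,
    ).fit()
    return clf.assign_one(fragment)


def aggregate_profiles(
    fragments: list[Fragment],
    results: list[AssignmentResult],
    cell_type: str,
    min_coverage: int = 1,
) -> MethylationProfile:
    """Pile assigned fragments up into a per-site methylation profile.

    Coverage at a site is the number of labeled fragments covering it; beta
    is the mean of their calls. Sites below ``min_coverage`` are dropped.
    """
    if len(fragments) != len(results):
        raise ValueError("fragments and results must correspond one-to-one")
    sums: dict[tuple[str, int], float] = defaultdict(float)
    counts: dict[tuple[str, int], int] = defaultdict(int)
    n_used = 0
    for frag, res in zip(fragments, results):
        if res.label != cell_type:
            continue
        n_used += 1
        for pos, call in frag.calls.items():
            key = (frag.chrom, pos)
            sums[key] += call
            counts[key] += 1
    if n_used == 0:
        logger.warning("no fragments labeled %r; empty profile", cell_type)
        empty = pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"])
        return MethylationProfile(
            beta=pd.Series(dtype=float, index=empty),
            coverage=pd.Series(dtype=int, index=empty),
        )
    keys = sorted(k for k in counts if counts[k] >= min_coverage)
    idx = sites_index(keys)
    beta = pd.Series([sums[k] / counts[k] for k in keys], index=idx, dtype=float)
    cov = pd.Series([counts[k] for k in keys], index=idx, dtype=int)
    return MethylationProfile(beta=beta, coverage=cov)


def cell_type_proportions(results: list[AssignmentResult]) -> dict[str, float]:
    """Fractions of eligible fragments per label (cell types + unassigned)."""
    eligible = [r for r in results if r.eligible]
    if not eligible:
        raise NoEligibleFragmentsError("no prediction-eligible fragments")
    counts = defaultdict(int)
    for r in eligible:
        counts[r.label] += 1
    total = len(eligible)
    return {label: counts[label] / total for label in sorted(counts)}


def profile_concordance(
    profile: MethylationProfile, atlas: pd.DataFrame, cell_type: str
) -> float:
    """Median |profile beta - atlas mean beta| over shared marker sites."""
    if cell_type not in atlas.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    shared = profile.sites.intersection(atlas.index)
    if len(shared) == 0:
        raise NoSharedSitesError("profile and atlas share no sites")
    diff = (profile.beta.loc[shared] - atlas.loc[shared, cell_type]).abs()
    return float(diff.median())
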