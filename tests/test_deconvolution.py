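"""Fragment cell-type assignment, aggregation, and concordance."""

import numpy as np
import pandas as pd
import pytest

import longreadage as lra
from longreadage.deconvolution import DEFAULT_RATIO
from longreadage.types import INELIGIBLE, UNASSIGNED, sites_index


def _atlas(rows):
    """Atlas from (pos, mean_m, mean_l) rows, all on chr1."""
    idx = sites_index([("chr1", p) for p, _, _ in rows])
    return pd.DataFrame(
        {"myeloid": [m for _, m, _ in rows], "lymphocyte": [l for _, _, l in rows]},
        index=idx,
    )


@pytest.fixture
def small_atlas():
    return _atlas([(10, 0.1, 0.9), (20, 0.9, 0.1), (30, 0.2, 0.8), (40, 0.8, 0.2), (50, 0.1, 0.9)])


class TestFragmentLikelihood:
    def test_perfect_match_equals_overlap_count(self, small_atlas):
        calls = {p: small_atlas.loc[("chr1", p), "myeloid"] for p, *_ in [(10,), (20,), (30,), (40,), (50,)]}
        frag = lra.Fragment("r1", "chr1", 60, calls)
        L, n = lra.fragment_likelihood(frag, small_atlas, "myeloid")
        assert n == 5
        assert L == pytest.approx(5.0)

    def test_maximal_mismatch_scores_zero(self):
        atlas = _atlas([(10, 0.0, 1.0), (20, 0.0, 1.0), (30, 0.0, 1.0), (40, 0.0, 1.0)])
        frag = lra.Fragment("r1", "chr1", 60, {10: 1.0, 20: 1.0, 30: 1.0, 40: 1.0})
        L, n = lra.fragment_likelihood(frag, atlas, "myeloid")
        assert (L, n) == (0.0, 4)

    def test_no_overlap_returns_zero_zero(self, small_atlas):
        frag = lra.Fragment("r1", "chr1", 60, {999: 1.0})
        assert lra.fragment_likelihood(frag, small_atlas, "myeloid") == (0.0, 0)

    def test_unknown_cell_type_raises(self, small_atlas):
        frag = lra.Fragment("r1", "chr1", 60, {10: 1.0})
        with pytest.raises(KeyError, match="unknown cell type"):
            lra.fragment_likelihood(frag, small_atlas, "erythroid")

    def test_matches_elementwise_oracle(self, rng):
        # 50 random fragments vs a random 2-type atlas; oracle is a plain
        # python loop over shared positions
        positions = list(range(100, 300, 2))
        atlas = pd.DataFrame(
            {
                "myeloid": rng.random(len(positions)),
                "lymphocyte": rng.random(len(positions)),
            },
            index=sites_index([("chr1", p) for p in positions]),
        )
        for i in range(50):
            npos = rng.integers(3, 15)
            pos = rng.choice(positions, size=npos, replace=False)
            calls = {int(p): float(rng.random()) for p in pos}
            frag = lra.Fragment(f"r{i}", "chr1", 60, calls)
            for ct in ("myeloid", "lymphocyte"):
                L, n = lra.fragment_likelihood(frag, atlas, ct)
                want = sum(
                    1 - abs(v - atlas.loc[("chr1", p), ct]) for p, v in calls.items()
                )
                assert L == pytest.approx(want, rel=1e-12)
                assert n == len(calls)
                assert 0.0 <= L <= n


class TestAssignFragment:
    def test_ratio_cutoff_met(self, small_atlas, monkeypatch):
        # L_myeloid = 4.5 vs 4.0: 4.5 >= (1/0.95)*4.0 = 4.2105 -> myeloid
        clf = lra.FragmentCellTypeClassifier(atlas=small_atlas).fit()
        monkeypatch.setattr(
            clf, "_likelihood",
            lambda frag, ct: (4.5, 5) if ct == "myeloid" else (4.0, 5),
        )
        res = clf.assign_one(lra.Fragment("r1", "chr1", 60, {10: 1.0}))
        assert res.label == "myeloid"

    def test_just_under_cutoff_unassigned(self, small_atlas, monkeypatch):
        clf = lra.FragmentCellTypeClassifier(atlas=small_atlas).fit()
        monkeypatch.setattr(
            clf, "_likelihood",
            lambda frag, ct: (4.2, 5) if ct == "myeloid" else (4.0, 5),
        )
        res = clf.assign_one(lra.Fragment("r1", "chr1", 60, {10: 1.0}))
        assert res.label == UNASSIGNED

    def test_low_mapq_ineligible(self, small_atlas):
        frag = lra.Fragment("r1", "chr1", 10, {10: 0.1, 20: 0.9, 30: 0.2, 40: 0.8, 50: 0.1})
        res = lra.assign_fragment(frag, small_atlas)
        assert res.label == INELIGIBLE and res.reason == "mapq"

    def test_sex_chromosome_ineligible(self, small_atlas):
        frag = lra.Fragment("r1", "chrX", 60, {10: 0.1})
        res = lra.assign_fragment(frag, small_atlas)
        assert res.label == INELIGIBLE and res.reason == "non_autosomal"

    def test_insufficient_overlap_ineligible(self, small_atlas):
        frag = lra.Fragment("r1", "chr1", 60, {10: 0.1, 20: 0.9})
        res = lra.assign_fragment(frag, small_atlas)
        assert res.label == INELIGIBLE and res.reason == "min_overlap"

    def test_zero_other_score_requires_positive_self(self):
        atlas = _atlas([(p, 0.0, 1.0) for p in (10, 20, 30, 40, 50)])
        # calls exactly matching myeloid -> L_lymphocyte = 0, L_myeloid = 5
        frag = lra.Fragment("r1", "chr1", 60, {p: 0.0 for p in (10, 20, 30, 40, 50)})
        res = lra.assign_fragment(frag, atlas)
        assert res.label == "myeloid"
        assert res.scores["lymphocyte"] == 0.0

    def test_partition_conservation(self, sim_atlas):
        cfg, _, truth = sim_atlas
        cfg = lra.SimulationConfig(seed=5, n_fragments=500, ineligible_fraction=0.2)
        frags, _ = lra.simulate_fragments(cfg, truth)
        clf = lra.FragmentCellTypeClassifier(atlas=truth).fit()
        results = clf.assign(frags)
        n_inel = sum(r.label == INELIGIBLE for r in results)
        n_unas = sum(r.label == UNASSIGNED for r in results)
        n_types = sum(r.label in truth.columns for r in results)
        assert n_inel + n_unas + n_types == len(frags)

    def test_raising_ratio_never_assigns_more(self, sim_atlas):
        _, _, truth = sim_atlas
        cfg = lra.SimulationConfig(seed=6, n_fragments=800, ineligible_fraction=0.0,
                                   cpgs_per_read=8, atlas_within_sd=0.15)
        frags, _ = lra.simulate_fragments(cfg, truth)
        counts = []
        for ratio in (1.0, DEFAULT_RATIO, 1.25, 2.0):
            clf = lra.FragmentCellTypeClassifier(atlas=truth, ratio=ratio).fit()
            labels = clf.predict(frags)
            counts.append(int(np.isin(labels, truth.columns).sum()))
        assert counts == sorted(counts, reverse=True)


class TestAggregateProfiles:
    def _labeled(self, frags, label):
        return [
            lra.AssignmentResult(f.read_id, label, scores={"myeloid": 1.0, "lymphocyte": 0.5})
            for f in frags
        ]

    def test_mean_of_calls(self):
        frags = [
            lra.Fragment("r1", "chr1", 60, {100: 1.0}),
            lra.Fragment("r2", "chr1", 60, {100: 1.0}),
            lra.Fragment("r3", "chr1", 60, {100: 0.0}),
        ]
        prof = lra.aggregate_profiles(frags, self._labeled(frags, "myeloid"), "myeloid")
        assert prof.beta[("chr1", 100)] == pytest.approx(2 / 3)
        assert prof.coverage[("chr1", 100)] == 3

    def test_min_coverage_excludes_singletons(self):
        frags = [
            lra.Fragment("r1", "chr1", 60, {100: 1.0, 200: 1.0}),
            lra.Fragment("r2", "chr1", 60, {100: 0.0}),
        ]
        prof = lra.aggregate_profiles(
            frags, self._labeled(frags, "myeloid"), "myeloid", min_coverage=2
        )
        assert ("chr1", 200) not in prof.sites
        assert ("chr1", 100) in prof.sites

    def test_zero_labeled_fragments_warns_and_returns_empty(self, caplog):
        frags = [lra.Fragment("r1", "chr1", 60, {100: 1.0})]
        with caplog.at_level("WARNING"):
            prof = lra.aggregate_profiles(frags, self._labeled(frags, "myeloid"), "lymphocyte")
        assert len(prof) == 0
        assert "no fragments labeled" in caplog.text

    def test_matches_groupby_mean_oracle(self, rng, sim_atlas):
        _, _, truth = sim_atlas
        cfg = lra.SimulationConfig(seed=8, n_fragments=500, ineligible_fraction=0.0)
        frags, labels = lra.simulate_fragments(cfg, truth)
        results = [
            lra.AssignmentResult(f.read_id, lab, scores={"myeloid": 1.0, "lymphocyte": 0.0})
            for f, lab in zip(frags, labels)
        ]
        prof = lra.aggregate_profiles(frags, results, "myeloid")
        # oracle: pandas groupby over the flattened (site, call) incidence
        records = [
            (f.chrom, p, v)
            for f, lab in zip(frags, labels)
            if lab == "myeloid"
            for p, v in f.calls.items()
        ]
        oracle = (
            pd.DataFrame(records, columns=["chrom", "pos", "call"])
            .groupby(["chrom", "pos"])["call"]
            .agg(["mean", "count"])
        )
        assert len(prof) == len(oracle)
        assert np.allclose(prof.beta.to_numpy(), oracle["mean"].to_numpy())
        assert (prof.coverage.to_numpy() == oracle["count"].to_numpy()).all()
        assert prof.beta.between(0, 1).all()
        assert prof.coverage.sum() == len(records)

    def test_mismatched_lengths_raise(self):
        frags = [lra.Fragment("r1", "chr1", 60, {100: 1.0})]
        with pytest.raises(ValueError, match="one-to-one"):
            lra.aggregate_profiles(frags, [], "myeloid")


class TestCellTypeProportions:
    def test_counting(self):
        results = [
            lra.AssignmentResult("r1", "myeloid"),
            lra.AssignmentResult("r2", "myeloid"),
            lra.AssignmentResult("r3", "lymphocyte"),
            lra.AssignmentResult("r4", UNASSIGNED),
        ]
        fracs = lra.cell_type_proportions(results)
        assert fracs == {"lymphocyte": 0.25, "myeloid": 0.5, UNASSIGNED: 0.25}
        assert sum(fracs.values()) == pytest.approx(1.0)

    def test_all_ineligible_raises(self):
        results = [lra.AssignmentResult("r1", INELIGIBLE, reason="mapq")]
        with pytest.raises(lra.NoEligibleFragmentsError):
            lra.cell_type_proportions(results)


class TestProfileConcordance:
    def test_identical_profile_scores_zero(self, small_atlas):
        prof = lra.MethylationProfile(
            beta=small_atlas["myeloid"].copy(),
            coverage=pd.Series(5, index=small_atlas.index, dtype=int),
        )
        assert lra.profile_concordance(prof, small_atlas, "myeloid") == 0.0

    def test_single_site_median(self):
        atlas = _atlas([(10, 0.7, 0.2)])
        prof = lra.MethylationProfile(
            beta=pd.Series([0.2], index=sites_index([("chr1", 10)])),
            coverage=pd.Series([3], index=sites_index([("chr1", 10)])),
        )
        assert lra.profile_concordance(prof, atlas, "myeloid") == pytest.approx(0.5)

    def test_no_shared_sites_raises(self, small_atlas):
        prof = lra.MethylationProfile(
            beta=pd.Series([0.5], index=sites_index([("chr9", 1)])),
            coverage=pd.Series([3], index=sites_index([("chr9", 1)])),
        )
        with pytest.raises(lra.NoSharedSitesError):
            lra.profile_concordance(prof, small_atlas, "myeloid")

    def test_aggregate_closer_to_generating_type(self, sim_atlas):
        _, _, truth = sim_atlas
        cfg = lra.SimulationConfig(seed=9, n_fragments=2000, ineligible_fraction=0.0)
        frags, _ = lra.simulate_fragments(cfg, truth)
        clf = lra.FragmentCellTypeClassifier(atlas=truth).fit()
        results = clf.assign(frags)
        prof = lra.aggregate_profiles(frags, results, "myeloid", min_coverage=3)
        own = lra.profile_concordance(prof, truth, "myeloid")
        other = lra.profile_concordance(prof, truth, "lymphocyte")
        assert own < other
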