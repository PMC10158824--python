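import math

import numpy as np
import pytest
import scipy.stats as sps

from domfact import stats
from domfact.content import DomainHit, content_of
from domfact.formats import AnnotationSet
from domfact.stats import (
    SpeciesSummary,
    ordinal_positions,
    paired_ttest,
    pgls_fit,
    round_half_away,
    spearman,
)


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [
            (4462 / 1233, 1, 3.6),
            (100 * 1243 / 3987, 1, 31.2),
            (-0.7333, 1, -0.7),
            (11.867, 1, 11.9),
            (0.25, 1, 0.3),  # half away from zero, not banker's
            (-0.25, 1, -0.3),
            (2.5, 0, 3.0),
        ],
    )
    def test_half_away_from_zero(self, value, decimals, expected):
        assert round_half_away(value, decimals) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            round_half_away(float("nan"))


class TestSummaryArithmetic:
    def test_ratio_and_percentages(self):
        s = SpeciesSummary(
            "x", n_orthologs=1000, potential_md=446, potential_ad=123,
            md_annotation=171, md_gene_prediction=137, md_undetermined=97,
            true_md=41, ad_annotation=72, ad_isoform=12, true_ad=39)
        assert s.ratio_md_ad == round_half_away(446 / 123, 1)
        assert s.pct_true_md == round_half_away(100 * 41 / 446, 1)
        assert s.pct_true_ad == round_half_away(100 * 39 / 123, 1)

    def test_zero_denominators_give_na(self):
        s = SpeciesSummary("x")
        assert s.ratio_md_ad is None
        assert s.pct_true_md is None
        assert s.pct_orthologs_with_events is None

    def test_summarize_matches_truth_counts(self, recovery_dataset):
        from domfact.events import detect_events
        from domfact.factcheck import fact_check_all
        from domfact.synthetic import PLANT_TRUTH

        ds = recovery_dataset
        pairs = ds.build_pairs()
        events = [e for p in pairs for e in detect_events(p, ds.clans)]
        verdicts = fact_check_all(events, ds.check_resources())
        summaries = stats.summarize(verdicts, pairs)
        tot = summaries["Total"]
        n_md_true = sum(
            1 for t in ds.truth
            if dict(PLANT_TRUTH[t.planted_class]).get("MD") == "true_MD"
            and t.direction == "MD")
        assert tot.true_md == n_md_true
        # partition identity per species and in total
        for s in summaries.values():
            assert s.potential_md == (s.md_annotation + s.md_gene_prediction
                                      + s.md_undetermined + s.md_switching
                                      + s.true_md)
            assert s.potential_ad == (s.ad_annotation + s.ad_isoform
                                      + s.ad_switching + s.true_ad)


class TestOrdinalPositions:
    def _content(self, pid, fams):
        hits, pos = [], 1
        for f in fams:
            hits.append(DomainHit(family=f, start=pos, end=pos + 59))
            pos += 80
        return content_of(AnnotationSet(pid, hits=hits))

    def _verdict(self, ref_fams, ortho_fams, unit_fam, direction="MD"):
        from domfact.events import OrthologPair, detect_events
        from domfact.factcheck import fact_check_one

        def ann(pid, fams):
            hits, pos = [], 1
            for f in fams:
                hits.append(DomainHit(family=f, start=pos, end=pos + 59))
                pos += 80
            return AnnotationSet(pid, hits=hits)

        pair = OrthologPair(ref_ann=ann("R1", ref_fams),
                            ortho_ann=ann("O1", ortho_fams), species="sp")
        ev = next(e for e in detect_events(pair)
                  if e.direction == direction and str(e.unit) == unit_fam)
        from domfact.factcheck import CheckResources
        res = CheckResources(scan_hits={
            "R1": [DomainHit(family=f, start=1, end=60) for f in ref_fams],
            "O1": [DomainHit(family=f, start=1, end=60) for f in ortho_fams]})
        v = fact_check_one(ev, res)
        contents = {"R1": self._content("R1", ref_fams),
                    "O1": self._content("O1", ortho_fams)}
        return v, contents

    def test_first_unit_is_n_terminal(self):
        v, c = self._verdict(["PF00001", "PF00002", "PF00003"],
                             ["PF00002", "PF00003"], "PF00001")
        counts = ordinal_positions([v], c)
        assert counts["MD"]["N_terminal"] == 1

    def test_middle_unit_is_internal(self):
        v, c = self._verdict(["PF00001", "PF00002", "PF00003"],
                             ["PF00001", "PF00003"], "PF00002")
        assert ordinal_positions([v], c)["MD"]["internal"] == 1

    def test_last_of_two_is_c_terminal(self):
        v, c = self._verdict(["PF00001", "PF00002"], ["PF00001", "PF00003"],
                             "PF00002")
        assert ordinal_positions([v], c)["MD"]["C_terminal"] == 1

    def test_single_unit_protein_excluded(self):
        v, c = self._verdict(["PF00001", "PF00002"], ["PF00001"], "PF00002")
        counts = ordinal_positions([v], c)
        assert sum(counts["MD"].values()) == 0  # ortholog has only one unit

    def test_error_verdicts_ignored(self):
        v, c = self._verdict(["PF00001", "PF00002", "PF00003"],
                             ["PF00002", "PF00003"], "PF00001")
        v.klass = "annotation_inconsistent_ortho"
        assert sum(ordinal_positions([v], c)["MD"].values()) == 0


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman([1, 2, 3, 5, 9], [10, 20, 22, 30, 80])
        assert r.estimate == pytest.approx(1.0)
        assert r.p_value == pytest.approx(0.0)

    def test_agrees_with_scipy_on_tied_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.std(sps.rankdata(x)) == 0 or np.std(sps.rankdata(y)) == 0:
                continue
            ours = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert ours.estimate == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman(x, y).estimate
        assert spearman(np.exp(x), y).estimate == pytest.approx(base)
        assert spearman(x**3, y).estimate == pytest.approx(base)

    def test_exact_permutation_small_n(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        r_exact = spearman(x, y, exact=True)
        assert 0 <= r_exact.p_value <= 1
        with pytest.raises(ValueError):
            spearman(list(range(11)), list(range(11)), exact=True)

    def test_constant_vector_is_na(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r.estimate)


class TestPairedT:
    def test_closed_form_three_pairs(self):
        # differences 1, 2, 3: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641
        r = paired_ttest([2, 4, 6], [1, 2, 3])
        assert r.estimate == pytest.approx(2 * math.sqrt(3), abs=1e-6)
        assert r.df == 2

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=15), rng.normal(size=15)
        ours = paired_ttest(a, b)
        ref = sps.ttest_rel(a, b)
        assert ours.estimate == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_identical_vectors_convention(self):
        r = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.estimate == 0.0 and r.p_value == 1.0

    def test_constant_nonzero_difference_is_na(self):
        r = paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isnan(r.estimate)


class TestPGLS:
    def test_lambda_zero_equals_ols_on_equal_tip_heights(self, pgls_setup):
        dist, species, x, V = pgls_setup
        rng = np.random.default_rng(3)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.1, len(x))
        ours = pgls_fit(dist, y, species=species, lam=0.0)
        lr = sps.linregress(x, y)
        assert ours.extra["slope"] == pytest.approx(lr.slope, rel=1e-8)
        assert ours.extra["intercept"] == pytest.approx(lr.intercept, rel=1e-8)
        assert ours.estimate == pytest.approx(lr.rvalue**2, rel=1e-8)

    def test_star_tree_pgls_equals_ols_for_any_lambda(self):
        # equal tip heights and no shared branches: the covariance is a
        # scalar matrix whatever lambda is, so PGLS collapses to OLS
        tips = [f"S{i}:1.0" for i in range(10)] + ["REF:1.0"]
        tree = stats.load_tree("(" + ",".join(tips) + ");")
        dist = stats.patristic_distances(tree, "REF")
        sp = dist.species
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, len(sp))  # distance to REF is constant on a star
        y = 1.0 + 0.7 * x + rng.normal(0, 0.3, len(sp))
        lr = sps.linregress(x, y)
        for lam in (0.0, 0.5, 1.0):
            r = pgls_fit(dist, y, species=sp, lam=lam, x=x)
            assert r.extra["slope"] == pytest.approx(lr.slope, rel=1e-10)
            assert r.extra["intercept"] == pytest.approx(lr.intercept, rel=1e-10)
            assert r.estimate == pytest.approx(lr.rvalue**2, rel=1e-10)

    def test_ml_lambda_beats_fixed_candidates(self, pgls_setup):
        dist, species, x, V = pgls_setup
        L = np.linalg.cholesky(V)
        y = 0.5 + 3.0 * x + L @ np.random.default_rng(7).normal(0, 0.5, len(x))
        ml = pgls_fit(dist, y, species=species)
        for lam in (0.0, 0.5, 1.0):
            fixed = pgls_fit(dist, y, species=species, lam=lam)
            assert ml.extra["loglik"] >= fixed.extra["loglik"] - 1e-6

    def test_singular_covariance_raises(self):
        tree = stats.load_tree("((A:0.0,B:0.0):1.0,(C:1.0,REF:1.0):0.5);")
        dist = stats.patristic_distances(tree, "REF")
        with pytest.raises(ValueError, match="patristic|singular"):
            pgls_fit(dist, [1.0, 2.0, 3.0], species=["A", "B", "C"])

    def test_length_mismatch_and_nonfinite_rejected(self, pgls_setup):
        dist, species, x, V = pgls_setup
        with pytest.raises(ValueError):
            pgls_fit(dist, [1.0, 2.0], species=species)
        bad = np.ones(len(species))
        bad[0] = np.nan
        with pytest.raises(ValueError):
            pgls_fit(dist, bad, species=species)
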