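import numpy as np
import pandas as pd
import pytest

import epiprog as ep


class TestMakeAnnotation:
    def test_deterministic_under_seed(self):
        a1, c1 = ep.make_annotation(50, seed=7)
        a2, c2 = ep.make_annotation(50, seed=7)
        pd.testing.assert_frame_equal(a1.df, a2.df)
        pd.testing.assert_frame_equal(c1, c2)

    def test_construction_guarantees(self, small_annotation):
        ann, cat = small_annotation
        assert ann.df["gene_id"].nunique() == 200
        assert set(ann.df["strand"]) == {"+", "-"}
        hits = ep.assign_region(cat, ann)
        prom = hits[hits["region"] == "promoter"].groupby("gene_id").size()
        body = hits[hits["region"] == "body"].groupby("gene_id").size()
        assert (prom.reindex(ann.gene_ids).fillna(0) >= 6).all()
        assert (body.reindex(ann.gene_ids).fillna(0) >= 6).all()

    def test_minus_strand_promoter_near_tx_end(self, small_annotation):
        ann, cat = small_annotation
        hits = ep.assign_region(cat, ann)
        minus = ann.df[ann.df["strand"] == "-"].iloc[0]
        prom = hits[(hits["gene_id"] == minus["gene_id"]) & (hits["region"] == "promoter")]
        # on the - strand the TSS sits at the high-coordinate end
        assert (np.abs(prom["pos"] - minus["tss"]) <= 500).all()
        assert prom["pos"].mean() > (minus["start"] + minus["end"]) / 2

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            ep.make_annotation(10, cpg_spacing=400, min_cpg=6)


class TestSimulateCounts:
    def test_deterministic_under_seed(self, small_annotation):
        ann, _ = small_annotation
        c1 = ep.simulate_counts(ann, ["A", "B"], seed=5)
        c2 = ep.simulate_counts(ann, ["A", "B"], seed=5)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)

    def test_null_group_means_ratio_near_one(self, small_annotation):
        ann, _ = small_annotation
        cm = ep.simulate_counts(ann, ["A", "B"], reps_per_group=6, seed=6)
        a = cm.counts[cm.group_samples("A")].mean(axis=1)
        b = cm.counts[cm.group_samples("B")].mean(axis=1)
        ratio = (b + 1) / (a + 1)
        # aggregate over 200 genes: log-ratio centered at 0
        assert abs(np.log2(ratio).mean()) < 0.15

    def test_planted_fold_change_recovered_in_aggregate(self):
        # 2^3 = 8 with NB noise at reps=3: aggregate mean ratio of the
        # planted set within the Monte-Carlo band implied by NB variance
        ann, _ = ep.make_annotation(400, seed=8)
        truth = ep.make_planted_truth(list(ann.gene_ids), ["B"], n_coupled=80,
                                      n_decoy=0, log2fc=3.0, seed=9)
        cm = ep.simulate_counts(ann, ["A", "B"], baseline_mean=100.0,
                                planted=truth, seed=10)
        up = truth.coupled[truth.coupled["log2fc"] > 0]["gene_id"]
        a = cm.counts.loc[up, cm.group_samples("A")].mean(axis=1)
        b = cm.counts.loc[up, cm.group_samples("B")].mean(axis=1)
        mean_ratio = (b / a.clip(lower=1)).mean()
        assert 6.0 < mean_ratio < 10.7


class TestSimulateMethylome:
    def test_deterministic_under_seed(self, small_annotation):
        ann, cat = small_annotation
        m1 = ep.simulate_methylome(ann, cat, ["A", "B"], seed=11)
        m2 = ep.simulate_methylome(ann, cat, ["A", "B"], seed=11)
        pd.testing.assert_frame_equal(m1.meth, m2.meth)
        pd.testing.assert_frame_equal(m1.coverage, m2.coverage)

    def test_null_pooled_difference_centered_at_zero(self, small_annotation):
        ann, cat = small_annotation
        m = ep.simulate_methylome(ann, cat, ["A", "B"], seed=12)
        fa = m.meth[m.group_samples("A")].sum(axis=1) / m.coverage[m.group_samples("A")].sum(axis=1)
        fb = m.meth[m.group_samples("B")].sum(axis=1) / m.coverage[m.group_samples("B")].sum(axis=1)
        assert abs((fb - fa).mean()) < 0.01

    def test_planted_shift_recovered(self, two_group_pipeline):
        truth = two_group_pipeline["truth"]
        meth = two_group_pipeline["meth"]
        ann = two_group_pipeline["annotation"]
        cat = two_group_pipeline["catalogue"]
        hits = ep.assign_region(cat, ann)
        planted = truth.coupled.set_index("gene_id")
        shifts = []
        for gene, row in planted.iterrows():
            sites = hits[(hits["gene_id"] == gene) & (hits["region"] == row["region"])]["site_index"]
            ma = meth.meth.loc[sites, meth.group_samples("A")].sum().sum()
            ca = meth.coverage.loc[sites, meth.group_samples("A")].sum().sum()
            mb = meth.meth.loc[sites, meth.group_samples("B")].sum().sum()
            cb = meth.coverage.loc[sites, meth.group_samples("B")].sum().sum()
            shifts.append(100 * (mb / cb - ma / ca) - row["meth_shift"])
        # beta-binomial tolerance at coverage 30, reps 3, >=6 sites per region
        assert abs(np.mean(shifts)) < 3.0
        assert max(abs(s) for s in shifts) < 15.0


class TestSimulateCohort:
    def _sig(self):
        up = frozenset({(f"u{i}", "") for i in range(8)})
        down = frozenset({(f"d{i}", "") for i in range(8)})
        return ep.Signature("toy", up, down)

    def test_deterministic_under_seed(self):
        c1 = ep.simulate_cohort(50, self._sig(), beta_per_sd=0.5, seed=3)
        c2 = ep.simulate_cohort(50, self._sig(), beta_per_sd=0.5, seed=3)
        pd.testing.assert_series_equal(c1.time, c2.time)
        pd.testing.assert_frame_equal(c1.matrix, c2.matrix)

    def test_empty_signature_rejected(self):
        empty = ep.Signature("none", frozenset(), frozenset())
        with pytest.raises(ValueError, match="empty"):
            ep.simulate_cohort(50, empty, beta_per_sd=0.5, seed=3)

    def test_null_effect_logrank_p_uniform(self):
        # with no planted hazard the median split should be null: p-values
        # roughly uniform across replicate seeds
        ps = []
        for s in range(40):
            coh = ep.simulate_cohort(120, self._sig(), beta_per_sd=0.0, seed=1000 + s)
            z = ep.zscore(coh.matrix)
            score = ep.signature_score(z, self._sig())["combined_score"]
            groups = ep.dichotomize_median(score)
            res, _ = ep.km_logrank(groups, coh.time, coh.event)
            ps.append(res.p_logrank)
        assert 0.2 < np.mean(ps) < 0.8
        assert min(ps) < 0.5 < max(ps)

    def test_censoring_rate_matches_target(self):
        coh = ep.simulate_cohort(4000, self._sig(), beta_per_sd=0.4,
                                 censor_rate=0.3, seed=17)
        observed = 1.0 - coh.event.mean()
        assert abs(observed - 0.3) < 0.03

    def test_hazard_coefficient_recovered(self):
        # Monte-Carlo oracle: Cox on the continuous score recovers the
        # planted log-hazard within +/-0.15 in >=90% of replicates
        b = np.log(1.49)
        ok = 0
        for s in range(40):
            coh = ep.simulate_cohort(700, self._sig(), beta_per_sd=b, seed=2000 + s)
            fit = ep.cox_fit(coh.covariates["signature_score"], coh.time, coh.event)
            ok += abs(fit.beta - b) <= 0.15
        assert ok >= 36
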