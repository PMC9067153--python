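import numpy as np
import pandas as pd
import pytest

import epiprog as ep
from epiprog.integrate import VALID_MODES


def _region_calls(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "region", "n_dmc", "n_cpg_tested",
                 "meth_diff_summary", "direction", "discordant"],
    )


def _call(gene, region, diff, discordant=False):
    return [gene, region, 3, 6, diff, "hyper" if diff > 0 else "hypo", discordant]


class TestDirectionRules:
    @pytest.mark.parametrize(
        "expr,region,diff,expected_mode",
        [
            ("up", "promoter", -40.0, "promoter-hypo-up"),
            ("down", "promoter", +40.0, "promoter-hyper-down"),
            ("up", "body", +40.0, "body-hyper-up"),
            ("down", "body", -40.0, "body-hypo-down"),
            ("up", "promoter", +40.0, None),   # concordant promoter: rejected
            ("down", "body", +40.0, None),     # anti-correlated body: rejected
        ],
    )
    def test_mode_pairing(self, expr, region, diff, expected_mode):
        de = {"gA": expr}
        rc = _region_calls([_call("gA", region, diff)])
        out = ep.integrate(de, rc, ("A", "B"))
        if expected_mode is None:
            assert len(out) == 0
        else:
            assert list(out["mode"]) == [expected_mode]

    def test_discordant_region_skipped_by_default(self):
        de = {"gA": "up"}
        rc = _region_calls([_call("gA", "promoter", -40.0, discordant=True)])
        assert len(ep.integrate(de, rc, ("A", "B"))) == 0
        out = ep.integrate(de, rc, ("A", "B"), skip_discordant=False)
        assert len(out) == 1

    def test_comparison_mismatch_rejected(self):
        de = pd.DataFrame({"gene_id": ["gA"], "log2fc": [3.0], "p_raw": [0.001],
                           "p_adj": [0.001], "direction": ["up"]})
        de.attrs["comparison"] = ("A", "B")
        rc = _region_calls([_call("gA", "promoter", -40.0)])
        rc.attrs["comparison"] = ("A", "C")
        with pytest.raises(ValueError, match="comparison"):
            ep.integrate(de, rc, ("A", "B"))


class TestExcludeDual:
    def test_both_regions_large_shift_excluded(self):
        rc = _region_calls([_call("gA", "promoter", 30.0), _call("gA", "body", -25.0)])
        excluded, side = ep.exclude_dual(rc)
        assert excluded == {"gA"}
        assert set(side["gene_id"]) == {"gA"}

    def test_single_region_kept(self):
        rc = _region_calls([_call("gA", "promoter", 30.0)])
        excluded, _ = ep.exclude_dual(rc)
        assert excluded == set()

    def test_one_region_over_threshold_suffices(self):
        rc = _region_calls([_call("gA", "promoter", 26.0), _call("gA", "body", 15.0)])
        excluded, _ = ep.exclude_dual(rc)
        assert excluded == {"gA"}

    def test_threshold_is_strict(self):
        rc = _region_calls([_call("gA", "promoter", 20.0), _call("gA", "body", -20.0)])
        excluded, _ = ep.exclude_dual(rc)
        assert excluded == set()

    def test_between_regions_rule(self):
        rc = _region_calls([_call("gA", "promoter", 30.0), _call("gA", "body", 25.0)])
        assert ep.exclude_dual(rc, rule="either")[0] == {"gA"}
        assert ep.exclude_dual(rc, rule="between")[0] == set()

    def test_small_dual_gene_eligible_for_both_modes(self):
        # both calls <= 20 points: the gene stays and may integrate through
        # both its promoter and its body
        de = {"gA": "up"}
        rc = _region_calls([_call("gA", "promoter", -18.0), _call("gA", "body", 15.0)])
        out = ep.integrate(de, rc, ("A", "B"))
        assert sorted(out["mode"]) == ["body-hyper-up", "promoter-hypo-up"]


def brute_force_integrate(de, region_calls, threshold=20.0):
    """Independent set-algebra oracle: DE genes joined to region calls under
    the four direction rules, minus discordant regions and dual-region
    exclusions."""
    by_gene = {}
    for _, r in region_calls.iterrows():
        by_gene.setdefault(r["gene_id"], []).append(r)
    excluded = set()
    for g, calls in by_gene.items():
        regions = {c["region"] for c in calls}
        if {"promoter", "body"} <= regions:
            if max(abs(c["meth_diff_summary"]) for c in calls) > threshold:
                excluded.add(g)
    out = set()
    for g, d in de.items():
        if g in excluded or g not in by_gene:
            continue
        for c in by_gene[g]:
            if c["discordant"]:
                continue
            mode = VALID_MODES.get((c["region"], c["direction"], d))
            if mode:
                out.add((g, mode))
    return out


def test_matches_set_algebra_oracle_on_random_inputs():
    rng = np.random.default_rng(61)
    for _ in range(30):
        genes = [f"g{i}" for i in range(30)]
        de = {g: rng.choice(["up", "down"]) for g in rng.choice(genes, 15, replace=False)}
        rows = []
        for g in rng.choice(genes, 20, replace=False):
            for region in rng.choice(["promoter", "body"], rng.integers(1, 3), replace=False):
                diff = float(rng.normal(0, 30))
                rows.append([g, region, 3, 6, diff,
                             "hyper" if diff > 0 else "hypo", bool(rng.random() < 0.15)])
        rc = _region_calls(rows)
        got = set(zip(*(ep.integrate(de, rc, ("A", "B"))[c] for c in ("gene_id", "mode"))))
        assert got == brute_force_integrate(de, rc)


def test_output_subset_of_de_and_region_genes(two_group_pipeline):
    res = two_group_pipeline["result"]
    de_genes = set(res.de[res.de["direction"] != "ns"]["gene_id"])
    region_genes = set(res.region_calls["gene_id"])
    excluded, _ = ep.exclude_dual(res.region_calls)
    out_genes = set(res.integrated["gene_id"])
    assert out_genes <= (de_genes & region_genes) - excluded


def test_decoy_discordant_genes_never_integrated(two_group_pipeline):
    truth = two_group_pipeline["truth"]
    res = two_group_pipeline["result"]
    decoys = set(truth.decoys["gene_id"])
    assert decoys, "fixture must plant decoys"
    assert not (set(res.integrated["gene_id"]) & decoys)


def test_planted_modes_recovered_correctly(two_group_pipeline):
    truth = two_group_pipeline["truth"]
    res = two_group_pipeline["result"]
    planted = truth.coupled.set_index("gene_id")["mode"]
    hit = res.integrated.set_index("gene_id")["mode"]
    shared = planted.index.intersection(hit.index)
    # most planted genes come through, each with its planted mode
    assert len(shared) / len(planted) >= 0.7
    assert (hit.loc[shared] == planted.loc[shared]).all()
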