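import numpy as np
import pandas as pd
import pytest

import epiprog as ep


@pytest.fixture(scope="session")
def small_annotation():
    """200 genes on 2 chromosomes with their CpG catalogue."""
    return ep.make_annotation(200, seed=101)


@pytest.fixture(scope="session")
def two_group_pipeline(small_annotation):
    """A planted two-group dataset run end-to-end, shared across tests.

    24 coupled genes (the four modes in equal parts) and 8 discordant
    decoys among 200 genes, triplicates, coverage 30.
    """
    ann, cat = small_annotation
    truth = ep.make_planted_truth(
        list(ann.gene_ids), affected_groups=["B"], n_coupled=24, n_decoy=8, seed=102
    )
    counts = ep.simulate_counts(ann, ["A", "B"], planted=truth, seed=103)
    meth = ep.simulate_methylome(ann, cat, ["A", "B"], planted=truth, seed=104)
    result = ep.run_comparison(counts, meth, ann, "A", "B")
    return {"truth": truth, "counts": counts, "meth": meth, "annotation": ann,
            "catalogue": cat, "result": result}


@pytest.fixture(scope="session")
def progression_pipeline():
    """A four-line progression dataset with planted archetypes, run through
    all signature-informing comparisons."""
    lines = ep.ProgressionLines()
    groups = [lines.parental, lines.premalignant, lines.nonmetastatic, lines.metastatic]
    ann, cat = ep.make_annotation(300, seed=201)
    truth = ep.make_progression_truth(list(ann.gene_ids), n_per_archetype=12, seed=202)
    counts = ep.simulate_counts(ann, groups, planted=truth, seed=203)
    meth = ep.simulate_methylome(ann, cat, groups, planted=truth, seed=204)
    results, sigs = ep.run_progression(counts, meth, ann, lines=lines)
    return {"truth": truth, "results": results, "signatures": sigs, "lines": lines}


def random_integrated_lists(rng, comparisons, n_genes=40):
    """Random per-comparison integrated frames for set-algebra tests."""
    genes = [f"g{i}" for i in range(n_genes)]
    out = {}
    for comp in comparisons:
        chosen = rng.choice(genes, size=rng.integers(5, n_genes), replace=False)
        direction = rng.choice(["up", "down"], size=len(chosen))
        region = rng.choice(["promoter", "body"], size=len(chosen))
        mode = [
            {"up": {"promoter": "promoter-hypo-up", "body": "body-hyper-up"},
             "down": {"promoter": "promoter-hyper-down", "body": "body-hypo-down"}}[d][r]
            for d, r in zip(direction, region)
        ]
        df = pd.DataFrame(
            {
                "gene_id": chosen,
                "group_a": comp[0],
                "group_b": comp[1],
                "expr_direction": direction,
                "region": region,
                "meth_direction": [m.split("-")[1] for m in mode],
                "mode": mode,
                "log2fc": rng.normal(0, 3, len(chosen)),
                "meth_diff_summary": rng.normal(0, 40, len(chosen)),
            }
        )
        out[comp] = df
    return out
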