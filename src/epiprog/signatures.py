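"""Progression gene signatures by set algebra over per-comparison
integrated gene lists.

The four-line progression design (parental melanocytes -> premalignant ->
nonmetastatic melanoma -> metastatic melanoma; by default labelled
``melan-a, 4C, 4C11-, 4C11+``) defines three signatures:

* **malignancy** — genes altered, with the same expression direction, in
  every derived line relative to the parental line;
* **EMT** — genes consistently elevated (or reduced) in the two
  mesenchymal-like lines (4C, 4C11-) relative to both differentiated
  lines (melan-a, 4C11+);
* **metastasis** — genes altered in the metastatic line relative to all
  three others, and (by default) in no other comparison.

Membership requires the same expression direction in every supporting
comparison; each member records its direction, mode and the comparisons
that support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "Signature",
    "ProgressionLines",
    "malignancy_signature",
    "emt_signature",
    "metastasis_signature",
]

Comparison = tuple[str, str]

DEFAULT_LINES = ("melan-a", "4C", "4C11-", "4C11+")


@dataclass(frozen=True)
class ProgressionLines:
    """The four cell lines of the progression model, in order."""

    parental: str = DEFAULT_LINES[0]
    premalignant: str = DEFAULT_LINES[1]
    nonmetastatic: str = DEFAULT_LINES[2]
    metastatic: str = DEFAULT_LINES[3]


@dataclass(frozen=True)
class Signature:
    """A named up/down gene set; members are (gene_id, mode) pairs and
    ``support`` maps gene_id -> the comparisons backing its membership."""

    name: str
    up_genes: frozenset[tuple[str, str]]
    down_genes: frozenset[tuple[str, str]]
    support: Mapping[str, tuple[Comparison, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        up_ids = {g for g, _ in self.up_genes}
        down_ids = {g for g, _ in self.down_genes}
        if up_ids & down_ids:
            raise ValueError(f"genes in both up and down sets: {sorted(up_ids & down_ids)[:5]}")

    @property
    def up_ids(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.up_genes)

    @property
    def down_ids(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.down_genes)

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "direction": d, "mode": m,
             "region": m.split("-")[0] if m else "",
             "support": ";".join(f"{a}->{b}" for a, b in self.support.get(g, ()))}
            for s, d in ((self.up_genes, "up"), (self.down_genes, "down"))
            for g, m in sorted(s)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "direction", "region", "mode", "support"])


def _per_gene_direction(frame: pd.DataFrame) -> dict[str, str]:
    return dict(zip(frame["gene_id"], frame["expr_direction"]))


def _mode_of(frame: pd.DataFrame, gene: str) -> str:
    sub = frame[frame["gene_id"] == gene]
    return "" if len(sub) == 0 else sub["mode"].iloc[0]


def _require(integrated: Mapping[Comparison, pd.DataFrame], comps: Sequence[Comparison]) -> None:
    missing = [c for c in comps if c not in integrated]
    if missing:
        raise KeyError(f"missing comparison(s): {missing}")


def malignancy_signature(
    integrated: Mapping[Comparison, pd.DataFrame],
    lines: ProgressionLines = ProgressionLines(),
) -> Signature:
    """Genes altered with the same direction in all three derived lines
    relative to the parental line."""
    p = lines.parental
    comps = [(p, lines.premalignant), (p, lines.nonmetastatic), (p, lines.metastatic)]
    _require(integrated, comps)
    dirs = [_per_gene_direction(integrated[c]) for c in comps]
    common = set(dirs[0]) & set(dirs[1]) & set(dirs[2])
    up, down, support = set(), set(), {}
    mode_frame = integrated[comps[0]]  # parental vs premalignant
    for g in common:
        ds = {d[g] for d in dirs}
        if len(ds) != 1:
            continue
        mode = _mode_of(mode_frame, g)
        (up if ds.pop() == "up" else down).add((g, mode))
        support[g] = tuple(comps)
    return Signature("malignancy", frozenset(up), frozenset(down), support)


def emt_signature(
    integrated: Mapping[Comparison, pd.DataFrame],
    lines: ProgressionLines = ProgressionLines(),
) -> Signature:
    """Genes separating the mesenchymal-like pair from both differentiated
    lines: up members are up in 4C and 4C11- vs melan-a AND down in 4C11+
    vs each mesenchymal line; down members mirror-imaged."""
    p, pre, non, met = lines.parental, lines.premalignant, lines.nonmetastatic, lines.metastatic
    comps = [(p, pre), (p, non), (pre, met), (non, met)]
    _require(integrated, comps)
    d_p_pre, d_p_non, d_pre_met, d_non_met = [_per_gene_direction(integrated[c]) for c in comps]
    up, down, support = set(), set(), {}
    mode_frame = integrated[(p, pre)]
    candidates = set(d_p_pre) & set(d_p_non) & set(d_pre_met) & set(d_non_met)
    for g in candidates:
        pattern = (d_p_pre[g], d_p_non[g], d_pre_met[g], d_non_met[g])
        if pattern == ("up", "up", "down", "down"):
            up.add((g, _mode_of(mode_frame, g)))
        elif pattern == ("down", "down", "up", "up"):
            down.add((g, _mode_of(mode_frame, g)))
        else:
            continue
        support[g] = tuple(comps)
    return Signature("EMT", frozenset(up), frozenset(down), support)


def metastasis_signature(
    integrated: Mapping[Comparison, pd.DataFrame],
    lines: ProgressionLines = ProgressionLines(),
    exclusive: bool = True,
) -> Signature:
    """Genes altered with the same direction in the metastatic line
    relative to all three other lines; with ``exclusive`` (default), genes
    also appearing in the parental-vs-premalignant or
    parental-vs-nonmetastatic lists are dropped (the "only in the
    metastatic line" clause)."""
    p, pre, non, met = lines.parental, lines.premalignant, lines.nonmetastatic, lines.metastatic
    comps = [(p, met), (pre, met), (non, met)]
    _require(integrated, comps)
    dirs = [_per_gene_direction(integrated[c]) for c in comps]
    elsewhere: set[str] = set()
    if exclusive:
        for c in [(p, pre), (p, non)]:
            if c in integrated:
                elsewhere |= set(integrated[c]["gene_id"])
    up, down, support = set(), set(), {}
    mode_frame = integrated[(p, met)]
    for g in set(dirs[0]) & set(dirs[1]) & set(dirs[2]):
        if g in elsewhere:
            continue
        ds = {d[g] for d in dirs}
        if len(ds) != 1:
            continue
        (up if ds.pop() == "up" else down).add((g, _mode_of(mode_frame, g)))
        support[g] = tuple(comps)
    return Signature("metastasis", frozenset(up), frozenset(down), support)
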