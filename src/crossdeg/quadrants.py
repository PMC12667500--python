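"""Join per-species DEG calls through the ortholog map and partition the
overlapping DEGs into four direction-concordance quadrants.

Quadrants classify an ortholog pair that is differentially expressed in
both species by the pair of directions: Q1 up/up, Q2 A-down/B-up, Q3
down/down, Q4 A-up/B-down.  Directions come from the DEG call, never from
a raw fold-change sign, so the two always agree by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .io import OrthologMap

log = logging.getLogger(__name__)

_QUADRANT_OF = {("up", "up"): "Q1", ("down", "up"): "Q2",
                ("down", "down"): "Q3", ("up", "down"): "Q4"}

OVERLAP_COLUMNS = ["gene_a", "gene_b", "log2fc_a", "log2fc_b",
                   "direction_a", "direction_b"]


def join_orthologs(
    degs_a: tuple[set[str], set[str]],
    degs_b: tuple[set[str], set[str]],
    omap: OrthologMap,
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
) -> pd.DataFrame:
    """Ortholog pairs that are DEGs in both species (any direction).

    ``degs_a``/``degs_b`` are (up, down) sets from :func:`call_degs`;
    ``de_a``/``de_b`` are the full DE tables they derive from.  Unmapped
    DEGs and pairs significant in only one species are excluded (counts
    logged).
    """
    up_a, down_a = degs_a
    up_b, down_b = degs_b
    all_a, all_b = up_a | down_a, up_b | down_b
    for name, degs, table in (("A", all_a, de_a), ("B", all_b, de_b)):
        missing = degs - set(table.index)
        if missing:
            raise ValidationError(
                f"species-{name} DEG {sorted(missing)[0]!r} absent from its DE table"
            )
    unmapped = len(all_a - set(omap.a_to_b)) + len(all_b - set(omap.b_to_a))
    rows = []
    single = 0
    for a, b in omap.pairs:
        in_a, in_b = a in all_a, b in all_b
        if in_a and in_b:
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "log2fc_a": float(de_a.loc[a, "log2fc"]),
                    "log2fc_b": float(de_b.loc[b, "log2fc"]),
                    "direction_a": "up" if a in up_a else "down",
                    "direction_b": "up" if b in up_b else "down",
                }
            )
        elif in_a or in_b:
            single += 1
    log.info(
        "ortholog join: %d overlapping pairs, %d singly-significant pairs, "
        "%d unmapped DEGs", len(rows), single, unmapped,
    )
    return pd.DataFrame(rows, columns=OVERLAP_COLUMNS)


@dataclass
class QuadrantPartition:
    """Disjoint, exhaustive split of the overlap table into Q1..Q4."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {q: len(self.tables[q]) for q in ("Q1", "Q2", "Q3", "Q4")}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pairs(self, quadrant: str) -> set[tuple[str, str]]:
        t = self.tables[quadrant]
        return set(zip(t["gene_a"], t["gene_b"]))


def quadrant_partition(overlap: pd.DataFrame) -> QuadrantPartition:
    """Assign every overlapping DEG pair to its quadrant.

    Raises if any row carries direction ``none`` (the join should have
    excluded it).  The four tables are disjoint and exhaustive; their sizes
    sum to the overlap count.
    """
    labels = []
    for _, row in overlap.iterrows():
        key = (row["direction_a"], row["direction_b"])
        if key not in _QUADRANT_OF:
            raise ValidationError(
                f"pair ({row['gene_a']!r}, {row['gene_b']!r}) has directions {key}; "
                "only definite up/down pairs belong in the overlap"
            )
        labels.append(_QUADRANT_OF[key])
    overlap = overlap.assign(quadrant=labels) if len(overlap) else overlap.assign(quadrant=pd.Series(dtype=str))
    tables = {
        q: overlap[overlap["quadrant"] == q].drop(columns="quadrant").reset_index(drop=True)
        for q in ("Q1", "Q2", "Q3", "Q4")
    }
    part = QuadrantPartition(tables=tables)
    assert part.total == len(overlap), "quadrants must partition the overlap"
    return part


def species_specific_sets(
    degs_a: tuple[set[str], set[str]],
    degs_b: tuple[set[str], set[str]],
    omap: OrthologMap,
) -> tuple[set[str], set[str]]:
    """DEGs private to one species.

    A species-B DEG is B-specific when its one-to-one partner is not an
    A DEG, or when it has no partner at all (and symmetrically for A).
    """
    all_a = degs_a[0] | degs_a[1]
    all_b = degs_b[0] | degs_b[1]
    a_specific = {g for g in all_a if omap.a_to_b.get(g) not in all_b}
    b_specific = {g for g in all_b if omap.b_to_a.get(g) not in all_a}
    return a_specific, b_specific
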