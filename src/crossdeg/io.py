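"""Readers and writers for every on-disk artifact the pipeline touches.

All tables are UTF-8, tab-separated with a header row; missing values are
rendered as ``NA``; floats are written with 6 significant digits.  Readers
validate strictly and raise :class:`~crossdeg.errors.ValidationError` /
:class:`~crossdeg.errors.ParseError` naming the offending location rather
than silently coercing.

Gene identifiers are opaque strings throughout: cross-species comparison
happens only through the :class:`OrthologMap`, never by name equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

#: canonical condition labels; common synonyms are normalized on read
CONDITIONS = ("control", "treated")
_CONDITION_ALIASES = {
    "control": "control",
    "ctrl": "control",
    "treated": "treated",
    "24hpn": "treated",
}

NA_REP = "NA"
FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Nonnegative integer gene-by-sample table plus per-sample metadata.

    ``counts`` is genes x samples; ``meta`` is indexed by sample id with
    columns ``species``, ``condition`` (one of ``control``/``treated``) and
    ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r} in count matrix")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))
            if bad.size:
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count for gene {c.index[i]!r}, sample {c.columns[j]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for gene {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        missing = set(c.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(
                f"sample {sorted(missing)[0]!r} missing from metadata"
            )
        for col in ("species", "condition", "replicate"):
            if col not in self.meta.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        self.meta = self.meta.loc[list(c.columns)].copy()
        norm = []
        for sid, cond in self.meta["condition"].items():
            key = str(cond).strip().lower()
            if key not in _CONDITION_ALIASES:
                raise ValidationError(
                    f"sample {sid!r} has unknown condition {cond!r}; "
                    f"expected one of {sorted(set(_CONDITION_ALIASES))}"
                )
            norm.append(_CONDITION_ALIASES[key])
        self.meta["condition"] = norm

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def condition_of(self, sample: str) -> str:
        return str(self.meta.loc[sample, "condition"])


def read_count_table(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (genes in rows) and its sample metadata."""
    path, meta_path = Path(path), Path(meta_path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        counts = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric count entry ({exc})") from exc
    if counts.isna().to_numpy().any():
        i, j = np.argwhere(counts.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing/NaN count for gene {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}"
        )
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise ValidationError(f"{meta_path}: duplicate sample id {dup!r}")
    try:
        return CountMatrix(counts=counts, meta=meta)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_count_table(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    cm.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Ortholog map
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    """One-to-one ortholog pairs; each identifier appears in at most one pair."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b in self.pairs:
            if a in seen_a:
                raise ValidationError(f"ortholog id {a!r} mapped twice")
            if b in seen_b:
                raise ValidationError(f"ortholog id {b!r} mapped twice")
            seen_a.add(a)
            seen_b.add(b)
        self.a_to_b = dict(self.pairs)
        self.b_to_a = {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of (species-A gene, species-B gene) pairs."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{ln}: expected 2 tab-separated columns")
            pairs.append((fields[0], fields[1]))
    return OrthologMap(pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in omap.pairs:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Annotations (GMT)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """term id -> (term name, member gene set), plus an optional universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValidationError(f"term {tid!r} has an empty member set")

    def restricted(self, background: set[str]) -> "AnnotationSet":
        """Intersect every term with ``background``; empty terms are dropped."""
        terms = {}
        for tid, (name, members) in self.terms.items():
            kept = members & background
            if kept:
                terms[tid] = (name, frozenset(kept))
        return AnnotationSet(terms=terms, universe=frozenset(background))


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read a GMT file: term id, description, then member genes, tab-separated."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{ln}: GMT line needs >= 3 tab-separated fields"
                )
            tid, name, members = fields[0], fields[1], fields[2:]
            if tid in terms:
                raise ParseError(f"{path}:{ln}: duplicate term id {tid!r}")
            terms[tid] = (name, frozenset(m for m in members if m))
    return AnnotationSet(terms=terms)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(annotations.terms):
            name, members = annotations.terms[tid]
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Edge list
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Undirected simple edges stored canonically (lexicographic order)."""

    edges: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_pairs(cls, pairs) -> "EdgeList":
        canon: set[tuple[str, str]] = set()
        dropped = 0
        for a, b in pairs:
            if a == b:
                dropped += 1
                continue
            canon.add((a, b) if a <= b else (b, a))
        if dropped:
            log.warning("dropped %d self-loop edge(s)", dropped)
        return cls(edges=sorted(canon))

    def __len__(self) -> int:
        return len(self.edges)


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a >=2-column TSV of gene pairs; extra columns (scores) are ignored."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{ln}: expected >= 2 tab-separated columns")
            pairs.append((fields[0], fields[1]))
    return EdgeList.from_pairs(pairs)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in edges.edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a result table as TSV: NA for missing, 6 significant digits."""
    df.to_csv(
        path,
        sep="\t",
        na_rep=NA_REP,
        float_format=FLOAT_FMT,
        index=index_label is not None,
        index_label=index_label,
    )


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], index_col=index_col)
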