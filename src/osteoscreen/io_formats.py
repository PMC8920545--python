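"""Readers and writers for the pipeline's external formats.

Every format is plain text (UTF-8, Unix newlines): expression and metadata
tables are tab-separated, gene sets use the MSigDB GMT dialect with an
optional category sidecar, protein interaction networks are two- or
three-column edge lists, and term-to-gene annotations are two-column tables.
All parsers validate their invariants (unique identifiers, aligned samples,
canonical undirected edges) and fail loudly with the offending identifier
in the message; all writers are repr-faithful so that a read/write
round-trip is the identity.

Gene identifiers are treated as case-sensitive HGNC-style symbols; no alias
or ID-mapping layer is applied. Expression matrices are stored genes-as-rows
(index = gene symbol, columns = sample ids) on the log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GENE_SET_CATEGORIES",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_annotation",
    "write_annotation",
    "write_table",
    "validate_expression",
]

#: Allowed category tags for gene sets. "other" is the fallback used when a
#: set is absent from the category sidecar.
GENE_SET_CATEGORIES = frozenset(
    {
        "transcription_factor",
        "differentiation",
        "development",
        "proliferation",
        "signaling",
        "other",
    }
)

METADATA_COLUMNS = ("group", "day", "batch")
GROUPS = ("control", "induced")


@dataclass
class GeneSetCollection:
    """Named gene sets with one category tag per set.

    ``sets`` maps a unique set name to its deduplicated member symbols
    (insertion order preserved); ``categories`` maps each set name to one of
    :data:`GENE_SET_CATEGORIES`.
    """

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))
        for name in self.sets:
            cat = self.categories.setdefault(name, "other")
            if cat not in GENE_SET_CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> list[str]:
        return list(self.sets[name])

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name in self.sets:
            cat = self.categories.get(name, "other")
            counts[cat] = counts.get(cat, 0) + 1
        return counts

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            categories={n: self.categories.get(n, "other") for n in names},
        )


# ---------------------------------------------------------------------------
# expression + metadata


def validate_expression(expr: pd.DataFrame, meta: pd.DataFrame | None = None) -> None:
    """Check ExpressionMatrix (and optionally SampleMetadata) invariants."""
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier {dup!r} in expression matrix")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier {dup!r} in expression matrix")
    if expr.isna().any().any():
        gene = expr.index[expr.isna().any(axis=1)][0]
        raise ValueError(f"missing values in expression matrix (gene {gene!r})")
    if meta is not None:
        missing = [s for s in expr.columns if s not in meta.index]
        if missing:
            raise ValueError(f"sample {missing[0]!r} absent from metadata")
        sub = meta.loc[list(expr.columns)]
        bad = sub.index[(sub["group"] == "control") & (sub["day"] != 0)]
        if len(bad):
            raise ValueError(
                f"control sample {bad[0]!r} has nonzero day; controls are day 0"
            )


def read_expression(
    path: str | Path, metadata_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a log2 expression table plus its sample metadata.

    The expression file is tab-separated with gene symbols in the first
    column and sample ids in the header. The metadata file has columns
    sample_id/group/day/batch. Returns ``(expr, meta)`` with the metadata
    rows aligned to the matrix's sample order.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier {dup!r} in {path}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        mask = values.isna() & raw.notna()
        if not mask.any().any():  # genuinely missing cell
            mask = values.isna()
        gene = mask.any(axis=1).idxmax()
        sample = mask.loc[gene].idxmax()
        raise ValueError(
            f"non-numeric value {raw.loc[gene, sample]!r} at gene {gene!r}, "
            f"sample {sample!r} in {path}"
        )
    expr = values.astype(float)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id",) + METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata file {metadata_path} lacks column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample {dup!r} in metadata")
    meta = meta.set_index("sample_id")
    meta["day"] = meta["day"].astype(int)
    if (meta["day"] < 0).any():
        bad = meta.index[meta["day"] < 0][0]
        raise ValueError(f"negative day for sample {bad!r}")
    unknown = set(meta["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label {sorted(unknown)[0]!r} in metadata")
    validate_expression(expr, meta)
    meta = meta.loc[list(expr.columns)]
    return expr, meta


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr = expr.copy()
    expr.index.name = expr.index.name or "gene"
    expr.to_csv(path, sep="\t", lineterminator="\n")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(
    path: str | Path, categories_path: str | Path | None = None
) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB member...).

    Sets with an empty member list are rejected with a warning and the rest
    of the file is processed; duplicate set names are a hard error. Category
    tags come from an optional two-column sidecar table (set_name TAB
    category); sets not listed there default to "other".
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line")
            name = fields[0]
            members = list(dict.fromkeys(g for g in fields[2:] if g.strip()))
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} in {path}")
            if not members:
                warnings.warn(
                    f"gene set {name!r} has no members; skipped", stacklevel=2
                )
                continue
            sets[name] = members
    categories: dict[str, str] = {}
    if categories_path is not None:
        cat = pd.read_csv(categories_path, sep="\t")
        if not {"set_name", "category"} <= set(cat.columns):
            raise ValueError(
                f"category sidecar {categories_path} needs columns set_name, category"
            )
        for _, row in cat.iterrows():
            if row["set_name"] in sets:
                categories[str(row["set_name"])] = str(row["category"])
    return GeneSetCollection(sets=sets, categories=categories)


def write_gmt(
    collection: GeneSetCollection,
    path: str | Path,
    categories_path: str | Path | None = None,
    description: str = "na",
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
    if categories_path is not None:
        rows = [
            {"set_name": n, "category": collection.categories.get(n, "other")}
            for n in collection.sets
        ]
        pd.DataFrame(rows).to_csv(
            categories_path, sep="\t", index=False, lineterminator="\n"
        )


# ---------------------------------------------------------------------------
# edge lists


def _canonical_edges(rows: Iterable[tuple[str, str, float]]) -> pd.DataFrame:
    best: dict[tuple[str, str], float] = {}
    for a, b, w in rows:
        if a == b:
            warnings.warn(f"self-loop on {a!r} dropped", stacklevel=3)
            continue
        if not (0.0 <= w <= 1.0):
            raise ValueError(f"edge weight {w} for ({a}, {b}) outside [0, 1]")
        key = (a, b) if a < b else (b, a)
        if key not in best or w > best[key]:
            best[key] = w
    edges = pd.DataFrame(
        [(a, b, w) for (a, b), w in best.items()],
        columns=["gene_a", "gene_b", "weight"],
    )
    return edges.sort_values(["gene_a", "gene_b"], ignore_index=True)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a 2- or 3-column undirected edge list into canonical form.

    Edges are canonicalized to lexicographic pair order; duplicate undirected
    edges collapse keeping the maximum weight; self-loops are dropped with a
    warning. Missing weights default to 1.0.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            w = 1.0
            if len(fields) == 3 and fields[2].strip():
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from exc
            rows.append((fields[0], fields[1], w))
    return _canonical_edges(rows)


def edge_list_from_pairs(
    pairs: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float]]
) -> pd.DataFrame:
    """Build a canonical edge-list frame from in-memory pairs."""
    rows = []
    for pair in pairs:
        if len(pair) == 2:
            a, b = pair
            rows.append((a, b, 1.0))
        else:
            rows.append(tuple(pair))
    return _canonical_edges(rows)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# term -> gene annotation tables (GO-style, flat)


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column term TAB gene table into term -> members."""
    table = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    out: dict[str, list[str]] = {}
    for term, sub in table.groupby("term", sort=False):
        out[str(term)] = list(dict.fromkeys(sub["gene"]))
    return out


def write_annotation(annotation: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term, genes in annotation.items():
            for g in genes:
                fh.write(f"{term}\t{g}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a results table as UTF-8 TSV with full float precision."""
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
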