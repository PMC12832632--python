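"""Set-based isolation of condition-specific gene programs.

Builds a gene-by-context module-membership atlas from per-context module
assignments, derives shared and regeneration-specific gene sets, partitions
identifiers into species-specific versus ortholog-annotated classes,
standardizes raw exported gene names, and summarizes protein-protein
interaction edge tables.

"Present at a timepoint" pools over cell-types: a gene counts as present at a
timepoint if it belongs to any (non-grey) module in any cell-type there.  The
per-cell-type stratification is retained in the atlas for drill-down.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MembershipAtlas",
    "GeneSetReport",
    "PPISummary",
    "classify_condition",
    "build_membership_atlas",
    "derive_gene_sets",
    "partition_by_prefix",
    "standardize_symbols",
    "summarize_ppi",
]

GREY = "grey"


def classify_condition(timepoint: str) -> str:
    """Classify a timepoint label as ``"regeneration"`` (post-injury, DPI
    suffix) or ``"control"`` (uninjured)."""
    return "regeneration" if timepoint.strip().lower().endswith("dpi") else "control"


@dataclass
class MembershipAtlas:
    """Gene-by-context module membership, stratified by timepoint.

    ``entries`` has columns ``gene``, ``timepoint``, ``celltype``, ``module``;
    grey-labelled entries are excluded, and ``(gene, timepoint, celltype)``
    is unique.  ``condition_class`` maps each timepoint to ``"control"`` or
    ``"regeneration"``.
    """

    entries: pd.DataFrame
    condition_class: dict[str, str]

    def __post_init__(self) -> None:
        required = {"gene", "timepoint", "celltype", "module"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"atlas entries missing columns: {sorted(missing)}")
        if (self.entries["module"] == GREY).any():
            raise ValueError("grey-labelled entries must be excluded from the atlas")
        dup = self.entries.duplicated(subset=["gene", "timepoint", "celltype"])
        if dup.any():
            first = self.entries[dup].iloc[0]
            raise ValueError(
                "duplicate atlas entry for "
                f"({first['gene']}, {first['timepoint']}, {first['celltype']})"
            )
        unknown = set(self.entries["timepoint"]) - set(self.condition_class)
        if unknown:
            raise ValueError(f"timepoints without a condition class: {sorted(unknown)}")

    @property
    def regeneration_timepoints(self) -> list[str]:
        return [t for t, c in self.condition_class.items() if c == "regeneration"]

    @property
    def control_timepoints(self) -> list[str]:
        return [t for t, c in self.condition_class.items() if c == "control"]

    def genes_at(self, timepoint: str) -> set[str]:
        return set(self.entries.loc[self.entries["timepoint"] == timepoint, "gene"])


@dataclass
class GeneSetReport:
    """Derived gene sets: regeneration-wide, control-wide, shared across all
    regeneration stages, regeneration-specific, and the identifier partition
    of the regeneration-specific set."""

    all_regen: set[str]
    all_control: set[str]
    shared_all_stages: set[str]
    regen_specific: set[str]
    amex_genes: list[str]
    ortholog_genes: list[str]

    def sizes(self) -> dict[str, int]:
        return {
            "all_regen": len(self.all_regen),
            "all_control": len(self.all_control),
            "shared_all_stages": len(self.shared_all_stages),
            "regen_specific": len(self.regen_specific),
            "amex_genes": len(self.amex_genes),
            "ortholog_genes": len(self.ortholog_genes),
        }


def build_membership_atlas(
    assignments: Iterable,
    condition_classes: dict[str, str] | None = None,
) -> MembershipAtlas:
    """Compile per-context module assignments into a membership atlas.

    ``assignments`` is an iterable of :class:`regenhubnet.netcore.ModuleAssignment`
    (each carrying a ``(celltype, condition)`` context); grey entries are
    dropped.  ``condition_classes`` maps condition labels to
    ``"control"``/``"regeneration"``; by default labels are classified by
    their DPI suffix via :func:`classify_condition`.
    """
    rows = []
    classes: dict[str, str] = {}
    for assignment in assignments:
        celltype, condition = assignment.context
        if condition_classes is not None:
            if condition not in condition_classes:
                raise ValueError(f"context condition {condition!r} has no condition class")
            classes[condition] = condition_classes[condition]
        else:
            classes[condition] = classify_condition(condition)
        for gene, module in assignment.labels.items():
            if module == GREY:
                continue
            rows.append((gene, condition, celltype, module))
    entries = pd.DataFrame(rows, columns=["gene", "timepoint", "celltype", "module"])
    return MembershipAtlas(entries=entries, condition_class=classes)


def derive_gene_sets(atlas: MembershipAtlas, amex_prefix: str = "AMEX60DD") -> GeneSetReport:
    """Derive the shared / control / regeneration-specific gene sets.

    ``regen_specific`` contains genes that belong to at least one module in a
    regeneration timepoint and to none in any control timepoint.
    ``shared_all_stages`` is the intersection over all regeneration
    timepoints of the per-timepoint (cell-type-pooled) gene sets.
    """
    regen_tps = atlas.regeneration_timepoints
    control_tps = atlas.control_timepoints
    if not regen_tps:
        raise ValueError("atlas has no regeneration timepoints")

    per_tp = {tp: atlas.genes_at(tp) for tp in set(regen_tps) | set(control_tps)}
    all_regen: set[str] = set().union(*(per_tp[tp] for tp in regen_tps))
    all_control: set[str] = set().union(*(per_tp[tp] for tp in control_tps)) if control_tps else set()
    if not control_tps:
        logger.warning("no control contexts in atlas: regen_specific equals all_regen")
    shared = set(per_tp[regen_tps[0]])
    for tp in regen_tps[1:]:
        shared &= per_tp[tp]
    regen_specific = all_regen - all_control
    ordered = sorted(regen_specific)
    amex, ortholog = partition_by_prefix(ordered, prefix=amex_prefix)
    return GeneSetReport(
        all_regen=all_regen,
        all_control=all_control,
        shared_all_stages=shared,
        regen_specific=regen_specific,
        amex_genes=amex,
        ortholog_genes=ortholog,
    )


def partition_by_prefix(
    genes: Sequence[str], prefix: str = "AMEX60DD"
) -> tuple[list[str], list[str]]:
    """Split genes into (prefix-matched, remainder), preserving input order.

    The match is case-sensitive, separating species-specific identifiers
    (e.g. ``AMEX60DD_000123``) from ortholog-annotated symbols.
    """
    amex = [g for g in genes if g.startswith(prefix)]
    ortholog = [g for g in genes if not g.startswith(prefix)]
    return amex, ortholog


_TAXON_SUFFIX = re.compile(r"_([A-Z]+)$")


def standardize_symbols(raw: Sequence[str]) -> list[str | None]:
    """Standardize raw exported gene names to bare upper-case symbols.

    Rules: split on ``"|"`` and take the first non-empty field, strip
    whitespace, remove a trailing ``_<TAXON>`` suffix when the suffix is
    fully alphabetic and upper-case (e.g. ``_XENLA``), then upper-case the
    result.  Empty raw names are recorded as ``None`` (missing), never
    silently dropped.
    """
    out: list[str | None] = []
    for name in raw:
        fields = [f.strip() for f in str(name).split("|")]
        symbol = next((f for f in fields if f), None)
        if symbol is None:
            out.append(None)
            continue
        symbol = _TAXON_SUFFIX.sub("", symbol)
        out.append(symbol.upper())
    return out


@dataclass
class PPISummary:
    """Thresholded, deduplicated undirected PPI edge list with degree classes.

    ``high_connectivity`` holds nodes with degree > 10; ``low_connectivity``
    holds nodes with degree in 1..3.
    """

    edges: pd.DataFrame  # columns: node1, node2, combined_score
    degree: dict[str, int]
    threshold: float
    high_connectivity: list[str] = field(default_factory=list)
    low_connectivity: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.degree)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def summarize_ppi(
    edge_table: pd.DataFrame | str,
    threshold: float = 0.40,
) -> PPISummary:
    """Filter and summarize a STRING-style exported PPI edge table.

    Keeps undirected pairs with combined confidence score >= ``threshold``
    (inclusive), deduplicating ``(A, B)``/``(B, A)`` by maximum score.  The
    0-999 score dialect is detected (any score > 1) and divided by 1000.
    Accepts a DataFrame or a TSV path with columns ``node1``, ``node2``,
    ``combined_score`` (``#node1``/``protein1`` style headers accepted).
    """
    if isinstance(edge_table, (str, bytes)) or hasattr(edge_table, "read"):
        df = pd.read_csv(edge_table, sep="\t")
    else:
        df = edge_table.copy()
    df.columns = [str(c).lstrip("#").strip() for c in df.columns]
    colmap = {}
    for want, aliases in {
        "node1": ("node1", "protein1", "proteinA", "a"),
        "node2": ("node2", "protein2", "proteinB", "b"),
        "combined_score": ("combined_score", "score", "combined score"),
    }.items():
        for a in aliases:
            if a in df.columns:
                colmap[a] = want
                break
        else:
            raise ValueError(f"edge table lacks a {want!r} column (has {list(df.columns)})")
    df = df.rename(columns=colmap)[["node1", "node2", "combined_score"]]

    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = scores.isna() | df["node1"].isna() | df["node2"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # 1-based, after the header line
        raise ValueError(f"malformed PPI edge row at line {line}")
    if (scores > 1.0).any():  # 0-999 STRING dialect
        scores = scores / 1000.0
    df["combined_score"] = scores

    df = df[df["combined_score"] >= threshold].copy()
    pairs = [tuple(sorted((str(a), str(b)))) for a, b in zip(df["node1"], df["node2"])]
    df["node1"] = [p[0] for p in pairs]
    df["node2"] = [p[1] for p in pairs]
    df = (
        df.groupby(["node1", "node2"], as_index=False)["combined_score"]
        .max()
        .sort_values(["node1", "node2"])
        .reset_index(drop=True)
    )

    degree: dict[str, int] = {}
    for n1, n2 in zip(df["node1"], df["node2"]):
        degree[n1] = degree.get(n1, 0) + 1
        degree[n2] = degree.get(n2, 0) + 1
    high = sorted(n for n, d in degree.items() if d > 10)
    low = sorted(n for n, d in degree.items() if 1 <= d <= 3)
    return PPISummary(
        edges=df,
        degree=degree,
        threshold=threshold,
        high_connectivity=high,
        low_connectivity=low,
    )
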