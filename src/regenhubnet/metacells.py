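"""KNN metacell aggregation within annotation groups.

Correlation estimates on sparse single-cell profiles are noisy; aggregating
each cell with its k-1 nearest transcriptomic neighbours (within the same
annotated cell-type) into a "metacell" averages that noise out before
network construction.  Candidate metacells are formed around every cell of a
group, visited in a seed-determined random order, and accepted greedily iff
their member overlap with every previously accepted metacell stays within
``max_shared`` (a per-pair cap).  Neighbour search runs in a truncated
principal-component embedding of the group's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .synthdata import ExpressionSection

logger = logging.getLogger(__name__)

__all__ = ["MetacellParams", "MetacellMatrix", "build_metacells", "normalize_metacells"]


@dataclass(frozen=True)
class MetacellParams:
    """Metacell construction parameters.

    ``k`` cells per metacell (the seed cell plus its k-1 nearest neighbours);
    ``max_shared`` caps the member overlap between any two accepted metacells
    and is clamped below ``k``; ``n_components`` sets the PCA embedding
    dimensionality used for the neighbour search.
    """

    k: int = 25
    max_shared: int = 30
    n_components: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.max_shared < 0:
            raise ValueError("max_shared must be >= 0")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")

    @property
    def effective_max_shared(self) -> int:
        # overlap of k would duplicate a metacell entirely; cap below k
        return min(self.max_shared, self.k - 1)


@dataclass
class MetacellMatrix:
    """Aggregated metacell-by-gene expression with member provenance.

    ``values`` holds per-gene sums over each metacell's ``k`` member cells;
    ``members`` lists source cell ids per metacell; all members of a metacell
    share the ``group`` annotation.  ``skipped_groups`` records annotation
    groups too small to form any metacell.
    """

    values: np.ndarray
    genes: tuple[str, ...]
    members: list[list[str]]
    group: list[str]
    source_section: str
    normalized: bool = False
    zero_metacells: list[int] = field(default_factory=list)
    skipped_groups: list[str] = field(default_factory=list)

    @property
    def n_metacells(self) -> int:
        return self.values.shape[0]

    def subset_group(self, group: str) -> "MetacellMatrix":
        idx = [i for i, g in enumerate(self.group) if g == group]
        return MetacellMatrix(
            values=self.values[idx],
            genes=self.genes,
            members=[self.members[i] for i in idx],
            group=[group] * len(idx),
            source_section=self.source_section,
            normalized=self.normalized,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.genes))


def _group_metacells(
    expr: np.ndarray, cell_ids: list[str], params: MetacellParams, rng: np.random.Generator
) -> tuple[np.ndarray, list[list[int]]]:
    """Greedy seed-ordered metacell selection within one annotation group."""
    n = expr.shape[0]
    n_comp = min(params.n_components, n - 1, expr.shape[1])
    centred = expr - expr.mean(axis=0, keepdims=True)
    if n_comp >= 2 and np.any(centred):
        emb = PCA(n_components=n_comp, svd_solver="full").fit_transform(centred)
    else:
        emb = centred  # identical (or too few) cells: trivial embedding
    nn = NearestNeighbors(n_neighbors=params.k).fit(emb)
    _, neigh = nn.kneighbors(emb)

    order = rng.permutation(n)
    accepted: list[list[int]] = []
    accepted_sets: list[frozenset[int]] = []
    cap = params.effective_max_shared
    for i in order:
        candidate = neigh[i].tolist()
        cset = frozenset(candidate)
        if all(len(cset & prev) <= cap for prev in accepted_sets):
            accepted.append(candidate)
            accepted_sets.append(cset)
    values = np.stack([expr[m].sum(axis=0) for m in accepted]) if accepted else np.empty((0, expr.shape[1]))
    return values, accepted


def build_metacells(section: ExpressionSection, params: MetacellParams) -> MetacellMatrix:
    """Aggregate a section's cells into metacells per annotation group.

    Groups with fewer than ``k`` cells yield no metacells and are flagged in
    ``skipped_groups`` with a logged warning.  Deterministic given
    ``params.seed``.
    """
    if section.n_cells == 0 or section.n_genes == 0:
        raise ValueError("section expression matrix is empty")
    groups = section.cells["celltype"].unique().tolist()
    if not groups:
        raise ValueError("section has no annotation groups")

    rng = np.random.default_rng(params.seed)
    all_values: list[np.ndarray] = []
    all_members: list[list[str]] = []
    all_groups: list[str] = []
    skipped: list[str] = []
    for g in groups:
        mask = (section.cells["celltype"] == g).to_numpy()
        ids = section.cells.loc[mask, "cell_id"].tolist()
        if len(ids) < params.k:
            logger.warning(
                "group %r in section %r has %d cells < k=%d; skipped",
                g, section.condition, len(ids), params.k,
            )
            skipped.append(g)
            continue
        values, member_idx = _group_metacells(section.values[mask], ids, params, rng)
        all_values.append(values)
        all_members.extend([[ids[j] for j in m] for m in member_idx])
        all_groups.extend([g] * values.shape[0])

    values = np.concatenate(all_values, axis=0) if all_values else np.empty((0, section.n_genes))
    return MetacellMatrix(
        values=values,
        genes=tuple(section.genes),
        members=all_members,
        group=all_groups,
        source_section=section.condition,
        skipped_groups=skipped,
    )


def normalize_metacells(m: MetacellMatrix) -> MetacellMatrix:
    """Library-size-normalize metacells to the median total, then log1p.

    Each row is scaled so its total equals the median metacell total (totals
    are equal after scaling, before the log); all-zero rows are left as zeros
    and flagged in ``zero_metacells``.
    """
    if (m.values < 0).any():
        raise ValueError("metacell values must be non-negative before normalization")
    totals = m.values.sum(axis=1)
    zero_rows = np.flatnonzero(totals == 0).tolist()
    nonzero = totals > 0
    scaled = m.values.astype(float).copy()
    if nonzero.any():
        target = float(np.median(totals[nonzero]))
        scaled[nonzero] = scaled[nonzero] * (target / totals[nonzero])[:, None]
    if zero_rows:
        logger.warning("%d all-zero metacells left unscaled", len(zero_rows))
    return MetacellMatrix(
        values=np.log1p(scaled),
        genes=m.genes,
        members=m.members,
        group=m.group,
        source_section=m.source_section,
        normalized=True,
        zero_metacells=zero_rows,
        skipped_groups=m.skipped_groups,
    )
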