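"""Weighted co-expression network construction for one (cell-type, condition)
context.

The pipeline mirrors the single-cell WGCNA workflow: genes detected in at
least a ``fraction`` of the group's cells are retained; the soft-threshold
power beta is chosen as the lowest candidate whose network satisfies an
approximate scale-free topology (signed fit index R^2 >= 0.80, with contexts
that never qualify excluded from downstream analysis); the adjacency
``a_ij = ((1 + cor)/2)^beta`` (signed) or ``|cor|^beta`` (unsigned) is turned
into a topological overlap matrix (TOM); and modules are detected by
average-linkage hierarchical clustering of ``1 - TOM`` with a deterministic
branch-cutting variant, a minimum module size, and an eigengene-correlation
merge step.  Genes left unassigned carry the reserved label ``"grey"``.

The :class:`CoexpressionNetwork` model class bundles these steps; its
:meth:`~CoexpressionNetwork.fit` returns a :class:`CoexpressionResults`
object carrying the selected power, the per-power scale-free scan, module
assignments, eigengenes, kME and hub extraction, plus a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from . import modulestats
from .metacells import MetacellMatrix
from .synthdata import ExpressionSection

logger = logging.getLogger(__name__)

__all__ = [
    "EXCLUDED",
    "NetworkParams",
    "AdjacencyMatrix",
    "ScaleFreeFit",
    "TOMatrix",
    "ModuleAssignment",
    "filter_genes_by_fraction",
    "compute_adjacency",
    "scale_free_fit",
    "scan_soft_powers",
    "select_soft_power",
    "compute_tom",
    "detect_modules",
    "CoexpressionNetwork",
    "CoexpressionResults",
]

GREY = "grey"


class _Excluded:
    """Distinguished outcome for contexts where no candidate power reaches
    the scale-free fit threshold."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "EXCLUDED"

    def __bool__(self) -> bool:
        return False


EXCLUDED = _Excluded()


@dataclass(frozen=True)
class NetworkParams:
    """Network construction parameters (field-standard defaults)."""

    fraction: float = 0.05
    power_candidates: tuple[int, ...] = tuple(range(1, 31))
    r2_threshold: float = 0.80
    network_type: str = "signed"
    min_module_size: int = 30
    merge_cut: float = 0.25
    n_bins: int = 10
    deep_split: int = 2
    cut_quantile: float = 0.995
    kme_assign: float = 0.70
    kme_stay: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie strictly in (0, 1)")
        pc = self.power_candidates
        if not pc or any(p <= 0 for p in pc) or any(nxt <= prev for prev, nxt in zip(pc, pc[1:])):
            raise ValueError("power_candidates must be strictly increasing positive integers")
        # r2_threshold is deliberately unconstrained: values above 1 are
        # unattainable by design (forcing exclusion), values <= 0 accept any
        # candidate, giving the lowest power
        if self.network_type not in ("signed", "unsigned"):
            raise ValueError("network_type must be 'signed' or 'unsigned'")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must lie in 0..4")


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded gene-gene adjacency, symmetric with unit diagonal."""

    values: np.ndarray
    genes: tuple[str, ...]
    power: int
    network_type: str

    @property
    def connectivity(self) -> np.ndarray:
        """Per-gene connectivity k_i = sum_{j != i} a_ij."""
        return self.values.sum(axis=0) - np.diag(self.values)


@dataclass
class ScaleFreeFit:
    """Signed scale-free topology fit of a network's degree distribution."""

    r_squared: float
    slope: float
    mean_connectivity: float
    connectivity: np.ndarray


@dataclass
class TOMatrix:
    """Topological overlap matrix: similarity combining direct adjacency and
    shared-neighbour weight; ``1 - values`` is the clustering dissimilarity."""

    values: np.ndarray
    genes: tuple[str, ...]


@dataclass
class ModuleAssignment:
    """Gene-to-module labels for one (cell-type, condition) context; the
    reserved label ``"grey"`` marks unassigned genes."""

    labels: dict[str, str]
    context: tuple[str, str]

    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.labels.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()) - {GREY})

    @property
    def n_grey(self) -> int:
        return sum(1 for v in self.labels.values() if v == GREY)


# ---------------------------------------------------------------------------
# operations


def filter_genes_by_fraction(m, group: str | None = None, fraction: float = 0.05) -> list[str]:
    """Genes with nonzero expression in at least ``fraction`` of the group's
    cells (boundary inclusive), input order preserved.

    ``m`` may be an :class:`ExpressionSection` (cells of ``group`` are used)
    or a :class:`MetacellMatrix` (metacells of ``group``).
    """
    if isinstance(m, ExpressionSection):
        if group is None:
            mask = np.ones(m.n_cells, dtype=bool)
        else:
            mask = (m.cells["celltype"] == group).to_numpy()
            if not mask.any():
                raise ValueError(f"annotation group {group!r} is empty or absent")
        values = m.values[mask]
        genes = list(m.genes)
    elif isinstance(m, MetacellMatrix):
        sub = m.subset_group(group) if group is not None else m
        if sub.n_metacells == 0:
            raise ValueError(f"annotation group {group!r} is empty or absent")
        values = sub.values
        genes = list(sub.genes)
    else:
        raise TypeError("expected an ExpressionSection or MetacellMatrix")
    detected = (values > 0).mean(axis=0)
    return [g for g, d in zip(genes, detected) if d >= fraction]


def _pearson(values: np.ndarray, genes) -> np.ndarray:
    sd = values.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant gene(s) not allowed in correlation: {[genes[i] for i in constant[:5]]}"
        )
    cor = np.corrcoef(values, rowvar=False)
    return np.clip(cor, -1.0, 1.0)


def _extract_matrix(expr) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(expr, MetacellMatrix):
        return expr.values, tuple(expr.genes)
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), tuple(map(str, expr.columns))
    raise TypeError("expected a MetacellMatrix or a sample x gene DataFrame")


def compute_adjacency(expr, power: int, network_type: str = "signed") -> AdjacencyMatrix:
    """Soft-thresholded adjacency from Pearson correlation over samples.

    signed: ``a_ij = ((1 + cor)/2)^power``; unsigned: ``a_ij = |cor|^power``;
    the diagonal is forced to 1.  Requires >= 3 samples, >= 2 genes, and no
    constant genes.
    """
    values, genes = _extract_matrix(expr)
    if values.shape[0] < 3:
        raise ValueError("adjacency needs at least 3 samples (metacells)")
    if values.shape[1] < 2:
        raise ValueError("adjacency needs at least 2 genes")
    cor = _pearson(values, genes)
    if network_type == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    elif network_type == "unsigned":
        adj = np.abs(cor) ** power
    else:
        raise ValueError("network_type must be 'signed' or 'unsigned'")
    np.fill_diagonal(adj, 1.0)
    return AdjacencyMatrix(values=adj, genes=genes, power=power, network_type=network_type)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Signed scale-free topology fit index of the connectivity distribution.

    Connectivity values are binned into ``n_bins`` equal-width bins;
    ``log10(mean frequency per bin)`` is regressed on ``log10(mean k per
    bin)`` over non-empty bins, and the index is ``-sign(slope) * R^2`` so
    decreasing (scale-free-like) degree laws score positively.
    """
    k = adj.connectivity
    counts, edges = np.histogram(k, bins=n_bins)
    bin_idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    n = k.size
    for b in range(n_bins):
        in_bin = bin_idx == b
        if not in_bin.any():
            continue
        mean_k = k[in_bin].mean()
        freq = in_bin.sum() / n
        if mean_k > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 2:
        raise ValueError("scale-free fit needs at least 2 non-empty connectivity bins")
    fit = linregress(xs, ys)
    r2 = fit.rvalue**2
    signed = -np.sign(fit.slope) * r2 if fit.slope != 0 else 0.0
    return ScaleFreeFit(
        r_squared=float(signed),
        slope=float(fit.slope),
        mean_connectivity=float(k.mean()),
        connectivity=k,
    )


def scan_soft_powers(expr, params: NetworkParams = NetworkParams()) -> pd.DataFrame:
    """Evaluate the scale-free fit for every candidate power.

    Returns a table with columns ``power``, ``r_squared``, ``slope``,
    ``mean_connectivity``.
    """
    values, genes = _extract_matrix(expr)
    cor = _pearson(values, genes)
    rows = []
    for power in params.power_candidates:
        if params.network_type == "signed":
            adj_values = ((1.0 + cor) / 2.0) ** power
        else:
            adj_values = np.abs(cor) ** power
        np.fill_diagonal(adj_values, 1.0)
        adj = AdjacencyMatrix(adj_values, genes, power, params.network_type)
        try:
            fit = scale_free_fit(adj, params.n_bins)
        except ValueError:
            rows.append((power, np.nan, np.nan, float(adj.connectivity.mean())))
            continue
        rows.append((power, fit.r_squared, fit.slope, fit.mean_connectivity))
    return pd.DataFrame(rows, columns=["power", "r_squared", "slope", "mean_connectivity"])


def select_soft_power(expr, params: NetworkParams = NetworkParams()):
    """Lowest candidate power whose signed fit index reaches the threshold.

    Candidates are evaluated in increasing order; if none qualifies, the
    distinguished outcome :data:`EXCLUDED` is returned (and logged) — that
    context is excluded from downstream network analysis.
    """
    scan = scan_soft_powers(expr, params)
    qualifying = scan[scan["r_squared"] >= params.r2_threshold]
    if qualifying.empty:
        logger.warning(
            "no candidate power reaches R^2 >= %.2f (best %.3f); context excluded",
            params.r2_threshold,
            np.nanmax(scan["r_squared"].to_numpy()) if len(scan) else np.nan,
        )
        return EXCLUDED
    return int(qualifying.iloc[0]["power"])


def compute_tom(adj: AdjacencyMatrix) -> TOMatrix:
    """Topological overlap of a weighted network.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    for i != j, with ``k_i = sum_{u != i} a_iu``; the diagonal is 1.
    """
    a = adj.values
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=0) - np.diag(a)
    # with unit diagonal, (A @ A)_ij counts a_ii*a_ij + a_ij*a_jj = 2 a_ij extra
    shared = a @ a - 2.0 * a
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    assert (denom > 0).all(), "TOM denominator must be positive for valid adjacency"
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMatrix(values=tom, genes=adj.genes)


# ---------------------------------------------------------------------------
# module detection


def _gap_threshold(deep_split: int) -> float:
    # deeper splitting tolerates smaller height gaps (0.25 .. 0.05)
    return 0.25 - 0.05 * deep_split


def _split_tree(node, gap_threshold: float) -> list:
    """Top-down recursive branch splitting: a merge is undone when its height
    exceeds both children's internal heights by more than ``gap_threshold``.
    Returns the surviving subtree nodes."""
    if node.is_leaf():
        return [node]
    child_top = max(node.left.dist, node.right.dist)
    if node.dist - child_top > gap_threshold:
        return _split_tree(node.left, gap_threshold) + _split_tree(node.right, gap_threshold)
    return [node]


def _initial_branches(link: np.ndarray, cut_height: float) -> list:
    """Subtrees of the dendrogram whose merge height is <= cut_height and
    whose parent merges above it (the clusters of a height cut)."""
    root, nodes = to_tree(link, rd=True)
    branches = []

    def walk(node):
        if node.dist <= cut_height:
            branches.append(node)
            return
        if node.is_leaf():
            branches.append(node)
            return
        walk(node.left)
        walk(node.right)

    walk(root)
    return branches


def detect_modules(
    tom: TOMatrix,
    params: NetworkParams = NetworkParams(),
    expr=None,
    context: tuple[str, str] = ("all", "all"),
) -> ModuleAssignment:
    """Detect co-expression modules from a topological overlap matrix.

    Average-linkage hierarchical clustering on ``1 - TOM``; the dendrogram is
    cut at an adaptively chosen fraction of the maximum merge height
    (candidate fractions from 0.90 up to ``cut_quantile`` are scanned and
    the cut that yields the most clusters of at least ``min_module_size``
    genes — ties broken toward more assigned genes — is kept; background
    genes merge in a near-flat plateau just below the root, so a fixed
    fraction is brittle across datasets), branches are then recursively
    split where the merge-height gap exceeds a ``deep_split``-controlled
    threshold.

    When ``expr`` (a sample x gene frame) is given, cluster cores are then
    completed by eigengene proximity, as in the ecosystem's dynamic branch
    cut: unassigned genes whose correlation with a core's eigengene reaches
    ``kme_assign`` join that core, core genes whose own-module kME falls
    below ``kme_stay`` are released to grey, modules whose eigengenes
    correlate at ``>= 1 - merge_cut`` are merged, and only then are clusters
    smaller than ``min_module_size`` greyed.  Without ``expr`` the
    completion and merge stages are skipped and the size filter applies to
    the raw clusters.  Labels are deterministic: "M1", "M2", ... ordered by
    descending module size, ties broken by the lexicographically smallest
    member gene.  An all-grey outcome is valid.
    """
    genes = list(tom.genes)
    n = len(genes)
    if n < 2:
        return ModuleAssignment(labels={g: GREY for g in genes}, context=context)
    dissim = 1.0 - tom.values
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = linkage(condensed, method="average")
    heights = link[:, 2]
    max_height = float(heights.max())
    gap = _gap_threshold(params.deep_split)
    # smaller cores are admitted when kME completion can grow them later
    core_min = params.min_module_size if expr is None else max(6, params.min_module_size // 3)

    # adaptive cut: keep the fraction of the height range that covers the
    # most genes with valid cores, preferring fewer clusters (no reward for
    # fragmenting).  A core spanning more than half the genes is accepted
    # only if it is tight (its top merge lies in the lower half of the
    # height range) — otherwise it is the undifferentiated near-root blur,
    # not a module.
    def _valid(node) -> bool:
        size = node.get_count()
        if size < core_min:
            return False
        return size <= n // 2 or node.dist <= 0.5 * max_height

    best: tuple[tuple[int, int], list] | None = None
    for frac in np.arange(0.90, params.cut_quantile + 1e-9, 0.005):
        branches = []
        for branch in _initial_branches(link, frac * max_height):
            branches.extend(_split_tree(branch, gap))
        sized = [b for b in branches if _valid(b)]
        score = (sum(b.get_count() for b in sized), -len(sized))
        if best is None or score > best[0]:
            best = (score, sized)
    assert best is not None
    cores = best[1]

    labels = {g: GREY for g in genes}
    provisional: dict[str, list[str]] = {}
    for i, node in enumerate(cores):
        provisional[f"tmp{i}"] = [genes[j] for j in node.pre_order(lambda leaf: leaf.id)]

    if expr is not None and provisional:
        provisional = _complete_by_kme(provisional, expr, genes, params)
        if len(provisional) > 1:
            provisional = _merge_by_eigengene(provisional, expr, params.merge_cut)
    provisional = {k: v for k, v in provisional.items() if len(v) >= params.min_module_size}

    # deterministic relabelling: descending size, ties by smallest member gene
    ordered = sorted(provisional.values(), key=lambda ms: (-len(ms), min(ms)))
    for rank, members in enumerate(ordered, start=1):
        for g in members:
            labels[g] = f"M{rank}"
    return ModuleAssignment(labels=labels, context=context)


def _complete_by_kme(
    provisional: dict[str, list[str]],
    expr,
    genes: list[str],
    params: NetworkParams,
) -> dict[str, list[str]]:
    """Grow/prune cluster cores by eigengene proximity: grey genes whose
    correlation with a core's eigengene reaches ``kme_assign`` join it
    (best-correlated core wins); core genes whose own-module kME drops below
    ``kme_stay`` are released to grey."""
    frame = expr.to_frame() if isinstance(expr, MetacellMatrix) else expr
    label_map = {g: m for m, ms in provisional.items() for g in ms}
    try:
        eig = modulestats.compute_eigengenes(frame, label_map)
    except ValueError:
        return provisional
    me = eig.values
    mat = frame.to_numpy(dtype=float)
    kme = np.column_stack(
        [modulestats._column_correlations(me[m].to_numpy(), mat) for m in me.columns]
    )
    module_names = list(me.columns)
    out: dict[str, list[str]] = {m: [] for m in module_names}
    for gi, g in enumerate(frame.columns):
        row = kme[gi]
        current = label_map.get(g)
        if current is not None and current in out:
            own = row[module_names.index(current)]
            if not np.isnan(own) and own >= params.kme_stay:
                out[current].append(g)
            continue
        if np.all(np.isnan(row)):
            continue
        best = int(np.nanargmax(row))
        if row[best] >= params.kme_assign:
            out[module_names[best]].append(g)
    return {m: ms for m, ms in out.items() if len(ms) >= 2}


def _merge_by_eigengene(
    provisional: dict[str, list[str]], expr, merge_cut: float
) -> dict[str, list[str]]:
    """Iteratively merge the closest module pair while their eigengene
    correlation is >= 1 - merge_cut."""
    frame = expr.to_frame() if isinstance(expr, MetacellMatrix) else expr
    modules = {k: list(v) for k, v in provisional.items()}
    while len(modules) > 1:
        label_map = {g: m for m, ms in modules.items() for g in ms}
        eig = modulestats.compute_eigengenes(frame, label_map)
        me = eig.values
        cor = np.corrcoef(me.to_numpy(), rowvar=False)
        names = list(me.columns)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] < 1.0 - merge_cut:
            break
        a, b = names[i], names[j]
        modules[a] = modules[a] + modules[b]
        del modules[b]
    return modules


# ---------------------------------------------------------------------------
# model / results


class CoexpressionNetwork:
    """Weighted co-expression network model for one context.

    Parameters
    ----------
    expr : sample x gene DataFrame or MetacellMatrix
        Normalized expression (typically normalized metacells).
    params : NetworkParams
    context : (cell-type, condition) label pair.

    Examples
    --------
    >>> model = CoexpressionNetwork(expr, context=("MSN", "2dpi"))
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(
        self,
        expr,
        params: NetworkParams = NetworkParams(),
        context: tuple[str, str] = ("all", "all"),
    ):
        self.values, self.genes = _extract_matrix(expr)
        self.frame = pd.DataFrame(self.values, columns=list(self.genes))
        self.params = params
        self.context = context

    @classmethod
    def from_metacells(cls, m: MetacellMatrix, group: str, params: NetworkParams = NetworkParams()):
        """Build a model for one annotation group of a metacell matrix,
        applying the detection-fraction gene filter first."""
        sub = m.subset_group(group)
        keep = filter_genes_by_fraction(sub, fraction=params.fraction)
        frame = sub.to_frame()[keep]
        frame = frame.loc[:, frame.std(axis=0) > 0]
        return cls(frame, params=params, context=(group, m.source_section))

    def fit(self) -> "CoexpressionResults":
        """Select the soft power, build adjacency and TOM, detect modules,
        and compute eigengenes and kME.  If no power qualifies the result is
        flagged excluded and carries no modules."""
        scan = scan_soft_powers(self.frame, self.params)
        qualifying = scan[scan["r_squared"] >= self.params.r2_threshold]
        if qualifying.empty:
            logger.warning("context %s excluded: no power reaches the fit threshold", self.context)
            return CoexpressionResults(
                model=self, power=EXCLUDED, power_scan=scan,
                adjacency=None, tom=None,
                modules=ModuleAssignment({g: GREY for g in self.genes}, self.context),
                eigengenes=None, kme=None,
            )
        power = int(qualifying.iloc[0]["power"])
        adjacency = compute_adjacency(self.frame, power, self.params.network_type)
        tom = compute_tom(adjacency)
        modules = detect_modules(tom, self.params, expr=self.frame, context=self.context)
        if modules.n_modules:
            eig = modulestats.compute_eigengenes(self.frame, modules)
            kme = modulestats.compute_kme(self.frame, eig)
        else:
            eig, kme = None, None
        return CoexpressionResults(
            model=self, power=power, power_scan=scan,
            adjacency=adjacency, tom=tom, modules=modules,
            eigengenes=eig, kme=kme,
        )


@dataclass
class CoexpressionResults:
    """Fitted co-expression network: selected power, per-power scale-free
    scan, adjacency/TOM, module assignment, eigengenes and kME."""

    model: CoexpressionNetwork
    power: int | _Excluded
    power_scan: pd.DataFrame
    adjacency: AdjacencyMatrix | None
    tom: TOMatrix | None
    modules: ModuleAssignment
    eigengenes: modulestats.EigengeneMatrix | None
    kme: pd.DataFrame | None
    _hub_cache: dict = field(default_factory=dict, repr=False)

    @property
    def excluded(self) -> bool:
        return self.power is EXCLUDED

    def hub_genes(self, n_hubs: int = 10, use_absolute: bool = False) -> pd.DataFrame:
        """Top-kME hub table per module (empty for excluded contexts)."""
        if self.excluded or self.kme is None:
            return pd.DataFrame(columns=modulestats.HUB_COLUMNS)
        key = (n_hubs, use_absolute)
        if key not in self._hub_cache:
            self._hub_cache[key] = modulestats.extract_hubs(
                self.kme, self.modules, n_hubs=n_hubs, use_absolute=use_absolute
            )
        return self._hub_cache[key]

    def summary(self) -> str:
        """Plain-text summary of the fitted network."""
        ct, cond = self.modules.context
        lines = [
            "Co-expression network results",
            "=============================",
            f"context:        {ct} / {cond}",
            f"genes:          {len(self.model.genes)}",
            f"samples:        {self.model.frame.shape[0]}",
        ]
        if self.excluded:
            best = self.power_scan["r_squared"].max() if len(self.power_scan) else float("nan")
            lines += [
                "soft power:     EXCLUDED (no candidate reached the fit threshold)",
                f"best R^2:       {best:.3f}",
            ]
            return "\n".join(lines)
        row = self.power_scan[self.power_scan["power"] == self.power].iloc[0]
        sizes = {m: s for m, s in self.modules.module_sizes().items() if m != GREY}
        lines += [
            f"soft power:     {self.power} (signed fit R^2 = {row['r_squared']:.3f})",
            f"mean k:         {row['mean_connectivity']:.2f}",
            f"modules:        {self.modules.n_modules}  {sizes}",
            f"grey genes:     {self.modules.n_grey}",
        ]
        if self.eigengenes is not None:
            ve = ", ".join(f"{m}: {v:.2f}" for m, v in self.eigengenes.variance_explained.items())
            lines.append(f"var explained:  {ve}")
        hubs = self.hub_genes(n_hubs=3)
        if len(hubs):
            top = "; ".join(
                f"{m}: " + ",".join(hubs[hubs['module'] == m]['gene'].head(3))
                for m in sorted(hubs["module"].unique())
            )
            lines.append(f"top hubs:       {top}")
        return "\n".join(lines)
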