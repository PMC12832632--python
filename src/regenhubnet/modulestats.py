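"""Module eigengenes, gene-module connectivity (kME), and hub-gene tables.

A module eigengene (ME) is the first principal component of the module's
standardized member-gene expression — the module's summary profile across
samples.  kME is the Pearson correlation of a gene with a module eigengene;
the genes with the highest own-module kME are the module's hub genes.  Hub
tables from many (cell-type, condition) contexts feed a frequency analysis
that counts how often each gene recurs as a hub across contexts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EigengeneMatrix",
    "compute_eigengenes",
    "compute_kme",
    "extract_hubs",
    "hub_frequency",
]

GREY = "grey"

HUB_COLUMNS = ["gene", "context", "module", "rank", "kme"]


@dataclass
class EigengeneMatrix:
    """Sample-by-module eigengene scores.

    Each column is scaled to unit variance and sign-oriented so its mean
    correlation with the module's member genes is non-negative.
    ``variance_explained`` gives the fraction of the module's standardized
    variance captured by its eigengene.
    """

    values: pd.DataFrame
    variance_explained: dict[str, float]

    @property
    def modules(self) -> list[str]:
        return list(self.values.columns)


def _as_frame(expr) -> pd.DataFrame:
    if isinstance(expr, pd.DataFrame):
        return expr
    if hasattr(expr, "to_frame") and hasattr(expr, "genes"):  # MetacellMatrix
        return expr.to_frame()
    raise TypeError("expr must be a sample x gene DataFrame or a MetacellMatrix")


def compute_eigengenes(expr, modules) -> EigengeneMatrix:
    """Compute module eigengenes from sample-by-gene expression.

    ``modules`` is a mapping of gene to module label (or an object with a
    ``labels`` mapping); grey genes are excluded.  Member-gene columns are
    standardized to zero mean and unit variance over samples before the SVD;
    a module whose genes are all constant is rejected by name.
    """
    frame = _as_frame(expr)
    labels: Mapping[str, str] = modules.labels if hasattr(modules, "labels") else modules
    by_module: dict[str, list[str]] = {}
    for gene, label in labels.items():
        if label != GREY and gene in frame.columns:
            by_module.setdefault(label, []).append(gene)
    if not by_module:
        raise ValueError("no non-grey modules to compute eigengenes for")

    n = len(frame)
    me = {}
    var_explained = {}
    for module in sorted(by_module):
        genes = by_module[module]
        sub = frame[genes].to_numpy(dtype=float)
        sd = sub.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError(f"module {module!r} contains only constant genes")
        sub = sub[:, keep]
        std = (sub - sub.mean(axis=0)) / sub.std(axis=0)
        u, s, _ = np.linalg.svd(std, full_matrices=False)
        scores = u[:, 0] * s[0]
        # orient: mean correlation with member genes >= 0
        cors = _column_correlations(scores, std)
        if np.nanmean(cors) < 0:
            scores = -scores
        scores = scores / scores.std(ddof=1)
        me[module] = scores
        var_explained[module] = float(s[0] ** 2 / (s**2).sum())
    values = pd.DataFrame(me, index=frame.index)
    return EigengeneMatrix(values=values, variance_explained=var_explained)


def _column_correlations(v: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``v`` with each column of ``mat``;
    constant columns yield NaN."""
    vc = v - v.mean()
    mc = mat - mat.mean(axis=0)
    denom = np.sqrt((vc**2).sum()) * np.sqrt((mc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (vc @ mc) / denom
    out[denom == 0] = np.nan
    return out


def compute_kme(expr, eig: EigengeneMatrix) -> pd.DataFrame:
    """Correlate every gene with every module eigengene.

    Returns a tidy table with columns ``gene``, ``module``, ``kme``.
    Constant genes have undefined kME and are recorded as missing (NaN),
    never silently zero.
    """
    frame = _as_frame(expr)
    if not frame.index.equals(eig.values.index):
        raise ValueError("expression and eigengene sample sets do not align")
    mat = frame.to_numpy(dtype=float)
    rows = []
    constant = frame.columns[mat.std(axis=0) == 0].tolist()
    if constant:
        logger.warning("%d constant genes have undefined kME", len(constant))
    for module in eig.modules:
        cors = _column_correlations(eig.values[module].to_numpy(), mat)
        rows.append(pd.DataFrame({"gene": frame.columns, "module": module, "kme": cors}))
    return pd.concat(rows, ignore_index=True)


def extract_hubs(
    kme: pd.DataFrame,
    modules,
    n_hubs: int = 10,
    context: tuple[str, str] | None = None,
    use_absolute: bool = False,
) -> pd.DataFrame:
    """Rank each module's members by own-module kME and keep the top hubs.

    Returns a table with columns ``gene, context, module, rank, kme`` holding
    ``min(n_hubs, module size)`` rows per module, ranks consecutive from 1,
    kME non-increasing with rank.  Ties are broken lexicographically by gene
    id (stable across runs).  With ``use_absolute`` the ranking key is |kME|.
    """
    labels: Mapping[str, str] = modules.labels if hasattr(modules, "labels") else modules
    if context is None:
        context = getattr(modules, "context", ("all", "all"))
    context_str = "/".join(context) if isinstance(context, tuple) else str(context)

    rows = []
    module_members: dict[str, list[str]] = {}
    for gene, label in labels.items():
        if label != GREY:
            module_members.setdefault(label, []).append(gene)
    kme_lookup = kme.set_index(["gene", "module"])["kme"]
    for module in sorted(module_members):
        members = module_members[module]
        scored = []
        for g in members:
            try:
                val = kme_lookup.loc[(g, module)]
            except KeyError:
                raise ValueError(f"kME table lacks entry for gene {g!r} in module {module!r}")
            if pd.isna(val):
                logger.warning("gene %r has missing kME in module %r; excluded from hubs", g, module)
                continue
            scored.append((g, float(val)))
        key = (lambda gv: (-abs(gv[1]), gv[0])) if use_absolute else (lambda gv: (-gv[1], gv[0]))
        scored.sort(key=key)
        for rank, (g, val) in enumerate(scored[:n_hubs], start=1):
            rows.append((g, context_str, module, rank, val))
    return pd.DataFrame(rows, columns=HUB_COLUMNS)


def hub_frequency(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Count distinct (context, module) hub occurrences per gene.

    Returns a table with columns ``gene``, ``hub_occurrences``,
    ``occurrences`` (list of ``(context, module)`` pairs) and ``best_rank``
    (minimum rank across occurrences), sorted by occurrences descending then
    gene id.  Genes never observed as hubs are absent.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("at least one hub table is required")
    nonempty = [t for t in tables if len(t)]
    if not nonempty:
        return pd.DataFrame(columns=["gene", "hub_occurrences", "occurrences", "best_rank"])
    combined = pd.concat(nonempty, ignore_index=True)
    records = []
    for gene, sub in combined.groupby("gene"):
        pairs = sorted({(c, m) for c, m in zip(sub["context"], sub["module"])})
        records.append(
            {
                "gene": gene,
                "hub_occurrences": len(pairs),
                "occurrences": pairs,
                "best_rank": int(sub["rank"].min()),
            }
        )
    out = pd.DataFrame(records)
    return out.sort_values(
        ["hub_occurrences", "gene"], ascending=[False, True], ignore_index=True
    )
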