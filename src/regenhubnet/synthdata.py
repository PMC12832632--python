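"""Synthetic multi-section spatial single-cell datasets with planted structure.

The generator emulates a regeneration time-course experiment: one tissue
section per timepoint (uninjured controls followed by a days-post-injury
series), each with several annotated cell-types laid out as spatial blobs,
a gene panel with planted co-expression modules, and a marker gene whose
positive-cell fraction follows an injury-induced rise-and-decay course.

Planted modules follow a latent-factor model with internal sub-structure:
each module spans a two-dimensional factor subspace and every member gene
sits at a random angle within it, with an overall loading drawn uniform in
[0.4, 1].  This gives each module a few strongly attached (hub-like)
members, a tail of peripheral ones, and graded pairwise correlations — the
diffuse neighbourhood structure real co-expression modules show — rather
than a single rank-one block.  The member-gene noise scale is calibrated
numerically per module so the mean pre-clipping pairwise correlation inside
the module equals the target ``within_module_rho``.  Regeneration-only
module factors are active only in sections whose timepoint label marks a
post-injury stage; in control sections those genes are plain background.

Besides the planted modules, two further layers mimic the correlation
texture of real tissue: (i) a configurable fraction of the background genes
is organised into many small, weak co-expression programs (3-12 genes,
correlations well below the planted modules, always below the module
detection size), and (ii) every gene carries a weak loading on a handful of
global "cell-state" factors, the analogue of the continuous cell-state
variation (cell cycle, stress, metabolic state) that touches most of a real
transcriptome.  Both layers matter: they give co-expression networks their
approximately scale-free degree distribution, and the state factors provide
the per-gene biological variance that survives metacell averaging — with a
purely independent background, aggregation would polarise the correlation
spectrum and the soft-power selection step would reject every context.

Marker positivity is imposed post hoc (designated cells receive a positive
draw, all others exactly zero), so the configured per-timepoint fractions are
realized exactly rather than stochastically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "ExpressionSection",
    "is_regeneration_label",
    "generate_sections",
    "generate_coloc_image",
    "generate_atlas_fixture",
]

#: Marker time-course defaults: positive-cell fraction per timepoint for
#: (juvenile control, 2, 5, 10, 15, 20, 30, 60 days post-injury).
DEFAULT_MARKER_COURSE = (0.06, 0.37, 0.33, 0.25, 0.24, 0.28, 0.07, 0.06)

DEFAULT_TIMEPOINTS = (
    "juvenile",
    "2dpi",
    "5dpi",
    "10dpi",
    "15dpi",
    "20dpi",
    "30dpi",
    "60dpi",
)

# Baseline shift keeps the clipped-at-zero expression mostly in the linear
# regime so planted correlations survive the non-negativity constraint.
_BASELINE = 3.0


def is_regeneration_label(label: str) -> bool:
    """True if a timepoint label marks a post-injury (DPI) stage."""
    return label.strip().lower().endswith("dpi")


@dataclass(frozen=True)
class ExpressionSection:
    """One section's cell-by-gene normalized matrix plus annotations.

    Attributes
    ----------
    values : (n_cells, n_genes) float array of normalized expression.
    genes : gene identifiers, column order of ``values``.
    cells : DataFrame with columns ``cell_id``, ``celltype``, ``x``, ``y``.
    condition : timepoint / condition label of the section.
    raw_gene_names : optional raw (pipe-delimited, suffixed) name per gene,
        as exported by upstream annotation pipelines.
    """

    values: np.ndarray
    genes: tuple[str, ...]
    cells: pd.DataFrame
    condition: str
    raw_gene_names: tuple[str, ...] | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene) if isinstance(self.genes, list) else tuple(self.genes).index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in section {self.condition!r}")

    def expression(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across the section's cells."""
        return self.values[:, self.gene_index(gene)]

    def cells_of_type(self, annotation: str) -> pd.DataFrame:
        return self.cells[self.cells["celltype"] == annotation]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror a desk-scale regeneration time course: one control plus a
    seven-stage post-injury series, four annotated cell-types per section,
    and four planted modules of which two are regeneration-only.
    """

    timepoint_labels: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_celltypes: int = 4
    cells_per_type: int = 150
    n_genes: int = 300
    n_modules_shared: int = 2
    n_modules_regen_only: int = 2
    module_size: int = 30
    within_module_rho: float = 0.7
    noise_sd: float = 1.0
    background_program_fraction: float = 0.5
    n_state_factors: int = 8
    state_factor_sd: float = 0.3
    regen_gene_control_detection: float = 0.02
    marker_fraction_course: tuple[float, ...] = DEFAULT_MARKER_COURSE
    amex_fraction: float = 0.1
    raw_name_fraction: float = 0.1
    seed: int = 0

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_labels)

    @property
    def n_modules(self) -> int:
        return self.n_modules_shared + self.n_modules_regen_only

    def validate(self) -> None:
        if len(set(self.timepoint_labels)) != len(self.timepoint_labels):
            raise ValueError("timepoint_labels must be unique")
        if self.n_timepoints < 1:
            raise ValueError("at least one timepoint label is required")
        for name in ("n_celltypes", "cells_per_type", "n_genes", "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_modules_shared < 0 or self.n_modules_regen_only < 0:
            raise ValueError("module counts must be non-negative")
        if self.module_size * self.n_modules > self.n_genes:
            raise ValueError(
                "module_size x (n_modules_shared + n_modules_regen_only) "
                f"= {self.module_size * self.n_modules} exceeds n_genes = {self.n_genes}"
            )
        for name in (
            "within_module_rho",
            "amex_fraction",
            "raw_name_fraction",
            "background_program_fraction",
            "regen_gene_control_detection",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_state_factors < 0 or self.state_factor_sd < 0:
            raise ValueError("state-factor parameters must be non-negative")
        if len(self.marker_fraction_course) != self.n_timepoints:
            raise ValueError(
                "marker_fraction_course must have one entry per timepoint "
                f"({len(self.marker_fraction_course)} != {self.n_timepoints})"
            )
        for f in self.marker_fraction_course:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"marker fraction {f} outside [0, 1]")


@dataclass
class SynthTruth:
    """Ground truth of the planted structure, for recovery tests.

    ``module_membership`` maps module-member genes to their planted module id;
    genes absent from the mapping are background.  ``marker_positive_cells``
    maps each timepoint label to the exact set of marker-positive cell ids.
    """

    module_membership: dict[str, str]
    regen_only_modules: set[str]
    marker_gene: str
    marker_positive_cells: dict[str, set[str]]
    celltype_of_cell: dict[str, str]
    module_loadings: dict[str, float] = field(default_factory=dict)
    background_programs: list[list[str]] = field(default_factory=list)

    def genes_of_module(self, module_id: str) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == module_id]


#: Maximum angular spread of member genes inside a module's 2-D factor
#: subspace (radians); larger values give more diffuse modules.
_THETA_MAX = 1.3

#: Range of member-gene loadings: a >2x gradient from peripheral to hub-like
#: members, scaled so that typical correlation targets stay attainable on
#: top of the cell-state variance every gene carries.
_LOADING_RANGE = (0.5, 1.2)


@dataclass
class _BlockPlan:
    """Frozen generative plan of one co-expression block (planted module or
    weak background program): gene columns, per-gene loading and angle in
    the block's 2-D factor subspace, and the calibrated noise scale."""

    cols: list[int]
    loadings: np.ndarray
    theta: np.ndarray
    noise_sd: float

    def realize(self, rng: np.random.Generator, n_cells: int) -> np.ndarray:
        """Draw the block's factor scores and noise for one section."""
        factors = rng.normal(size=(n_cells, 2))
        dirs = np.stack([np.cos(self.theta), np.sin(self.theta)]) * self.loadings
        noise = rng.normal(size=(n_cells, len(self.cols))) * self.noise_sd
        return factors @ dirs + noise


def _plan_block(
    rng: np.random.Generator,
    cols: list[int],
    rho: float,
    fallback_sd: float,
    extra_var: np.ndarray | None = None,
) -> _BlockPlan:
    """Draw loadings/angles for a block and calibrate its noise scale so the
    mean pairwise correlation equals ``rho``.

    The pairwise correlation of the model ``x_g = l_g (cos t_g F1 +
    sin t_g F2) + s e_g (+ state noise of variance v_g)`` is ``l_i l_j
    cos(t_i - t_j) / sqrt((l_i^2 + s^2 + v_i)(l_j^2 + s^2 + v_j))``; the
    mean over pairs is monotone decreasing in ``s``.  If the target exceeds
    what the angular spread allows, the angles are shrunk toward a single
    factor first; if it is unreachable even then, the closest attainable
    block is returned.  rho = 0 disables the factors.
    """
    from scipy.optimize import brentq

    size = len(cols)
    loadings = rng.uniform(*_LOADING_RANGE, size=size)
    theta = rng.uniform(0.0, _THETA_MAX, size=size)
    if rho <= 0:
        return _BlockPlan(cols, np.zeros(size), theta, fallback_sd)
    v = np.zeros(size) if extra_var is None else np.asarray(extra_var, dtype=float)
    iu = np.triu_indices(size, 1)

    def mean_corr(s: float, th: np.ndarray) -> float:
        d = np.sqrt(loadings**2 + s**2 + v)
        c = (np.outer(loadings, loadings) * np.cos(th[:, None] - th[None, :])) / np.outer(d, d)
        return float(c[iu].mean())

    s_min, s_max = 1e-9, 50.0
    if mean_corr(s_min, theta) < rho:
        # target tighter than the angular spread allows: shrink the angles
        if mean_corr(s_min, theta * 0.0) <= rho:
            return _BlockPlan(cols, loadings, theta * 0.0, s_min)
        alpha = brentq(lambda a: mean_corr(s_min, theta * a) - rho, 0.0, 1.0)
        return _BlockPlan(cols, loadings, theta * alpha, s_min)
    if mean_corr(s_max, theta) > rho:  # pragma: no cover - unreachable for rho>0
        return _BlockPlan(cols, loadings, theta, s_max)
    s = brentq(lambda s: mean_corr(s, theta) - rho, s_min, s_max)
    return _BlockPlan(cols, loadings, theta, float(s))


def _gene_names(config: SynthConfig, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Assign gene identifiers: marker 'TRH', an AMEX-prefixed subset, and
    symbol-like names; a raw_name_fraction subset also gets a pipe-delimited
    raw form with a taxonomic suffix."""
    n = config.n_genes
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    names: list[str] = []
    n_amex = int(round(config.amex_fraction * n))
    amex_idx = set(rng.choice(n, size=n_amex, replace=False).tolist())
    amex_numbers = rng.choice(900_000, size=n, replace=False) + 100_000
    marker_idx = config.n_modules * config.module_size  # first non-module gene
    for i in range(n):
        if i == marker_idx:
            names.append("TRH")
        elif i in amex_idx:
            names.append(f"AMEX60DD_{amex_numbers[i]:06d}")
        else:
            a, b = divmod(i, len(letters))
            names.append(f"SYN{letters[a % len(letters)]}{letters[b]}{i:03d}")
    raw = list(names)
    symbol_positions = [i for i, nm in enumerate(names) if not nm.startswith("AMEX60DD_")]
    n_raw = int(round(config.raw_name_fraction * len(symbol_positions)))
    if n_raw:
        chosen = rng.choice(len(symbol_positions), size=n_raw, replace=False)
        for j in chosen:
            i = symbol_positions[j]
            raw[i] = f"{names[i]} | {names[i]}_XENLA"
    return names, raw


def generate_sections(config: SynthConfig) -> tuple[list[ExpressionSection], SynthTruth]:
    """Generate one :class:`ExpressionSection` per timepoint plus ground truth.

    Deterministic given ``config.seed``: the same configuration produces
    bitwise-identical matrices on repeated calls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    names, raw_names = _gene_names(config, rng)
    marker_gene = names[config.n_modules * config.module_size]

    module_ids = [f"shared{i + 1}" for i in range(config.n_modules_shared)] + [
        f"regen{i + 1}" for i in range(config.n_modules_regen_only)
    ]
    regen_only = {m for m in module_ids if m.startswith("regen")}

    # global cell-state loadings, fixed per gene across sections; drawn first
    # so block calibration can account for the extra per-gene variance.
    # Per-gene scales are exponential: most genes track the cell state
    # weakly, a minority strongly — the heavy-tailed "state attachment"
    # profile of real transcriptomes.
    state_scale = config.state_factor_sd * np.clip(
        rng.exponential(1.0, size=config.n_genes), 0.2, 4.0
    )
    # planted-module members spend their variance budget on the program and
    # track the global state correspondingly less
    state_scale[: config.n_modules * config.module_size] *= 0.5
    state_loadings = rng.normal(size=(config.n_state_factors, config.n_genes)) * state_scale
    state_var = (state_loadings**2).sum(axis=0)

    membership: dict[str, str] = {}
    module_plans: list[_BlockPlan] = []
    for m, mid in enumerate(module_ids):
        lo, hi = m * config.module_size, (m + 1) * config.module_size
        module_plans.append(
            _plan_block(
                rng,
                list(range(lo, hi)),
                config.within_module_rho,
                config.noise_sd,
                extra_var=state_var[lo:hi],
            )
        )
        for i in range(lo, hi):
            membership[names[i]] = mid

    # weak background programs: many small gene groups with mild
    # co-regulation (geometric size distribution, decreasing-density
    # strengths), always below the planted-module (and detection) size
    marker_col = config.n_modules * config.module_size
    bg_cols = list(range(marker_col + 1, config.n_genes))
    n_prog_genes = int(round(config.background_program_fraction * len(bg_cols)))
    max_prog = max(3, min(24, config.module_size - 1))
    programs: list[_BlockPlan] = []
    cursor = 0
    while n_prog_genes - cursor >= 3:
        size = int(min(2 + rng.geometric(0.35), max_prog, n_prog_genes - cursor))
        cols = bg_cols[cursor : cursor + size]
        rho = float(0.1 + 0.5 * rng.beta(1.0, 2.0))
        programs.append(
            _plan_block(rng, cols, rho, config.noise_sd, extra_var=state_var[cols])
        )
        cursor += size

    n_cells = config.n_celltypes * config.cells_per_type
    celltypes = [f"type{chr(ord('A') + t)}" for t in range(config.n_celltypes)]
    sections: list[ExpressionSection] = []
    marker_positive: dict[str, set[str]] = {}
    celltype_of_cell: dict[str, str] = {}

    # fixed blob centers shared across sections, so territories are comparable
    centers = rng.uniform(20.0, 80.0, size=(config.n_celltypes, 2))

    for t_idx, label in enumerate(config.timepoint_labels):
        regen = is_regeneration_label(label)
        cell_ids = [f"{label}_c{i:05d}" for i in range(n_cells)]
        ct_labels = np.repeat(celltypes, config.cells_per_type)
        xy = np.empty((n_cells, 2))
        for t, ct in enumerate(celltypes):
            sl = slice(t * config.cells_per_type, (t + 1) * config.cells_per_type)
            xy[sl] = centers[t] + rng.normal(scale=6.0, size=(config.cells_per_type, 2))

        values = _BASELINE + config.noise_sd * rng.normal(size=(n_cells, config.n_genes))
        for plan, mid in zip(module_plans, module_ids):
            active = (mid not in regen_only) or regen
            # block drawn regardless of activity, for RNG-stream stability
            block = plan.realize(rng, n_cells)
            if active:
                values[:, plan.cols] = _BASELINE + block
        for plan in programs:  # background programs: active everywhere
            values[:, plan.cols] = _BASELINE + plan.realize(rng, n_cells)
        if config.n_state_factors:
            state = rng.normal(size=(n_cells, config.n_state_factors))
            values += state @ state_loadings
        np.clip(values, 0.0, None, out=values)

        if not regen:
            # injury-induced program genes are essentially off pre-injury:
            # sparse low expression, below any sensible detection fraction
            for plan, mid in zip(module_plans, module_ids):
                if mid not in regen_only:
                    continue
                det = rng.random((n_cells, len(plan.cols))) < config.regen_gene_control_detection
                draws = 0.5 + np.abs(rng.normal(size=det.shape))
                values[:, plan.cols] = draws * det

        # marker positivity imposed exactly
        frac = config.marker_fraction_course[t_idx]
        n_pos = int(round(frac * n_cells))
        pos_idx = rng.choice(n_cells, size=n_pos, replace=False)
        marker = np.zeros(n_cells)
        marker[pos_idx] = 0.5 + np.abs(rng.normal(size=n_pos))
        values[:, marker_col] = marker
        marker_positive[label] = {cell_ids[i] for i in pos_idx}

        cells = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "celltype": ct_labels,
                "x": xy[:, 0],
                "y": xy[:, 1],
            }
        )
        celltype_of_cell.update(dict(zip(cell_ids, ct_labels)))
        sections.append(
            ExpressionSection(
                values=values,
                genes=tuple(names),
                cells=cells,
                condition=label,
                raw_gene_names=tuple(raw_names),
            )
        )

    truth = SynthTruth(
        module_membership=membership,
        regen_only_modules=regen_only,
        marker_gene=marker_gene,
        marker_positive_cells=marker_positive,
        celltype_of_cell=celltype_of_cell,
        module_loadings={
            names[i]: float(l)
            for plan in module_plans
            for i, l in zip(plan.cols, plan.loadings)
        },
        background_programs=[[names[i] for i in plan.cols] for plan in programs],
    )
    return sections, truth


# ---------------------------------------------------------------------------
# image fixtures


def _disk_mask(height: int, width: int, center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def generate_coloc_image(
    width: int,
    height: int,
    marker_blobs: Sequence[tuple[tuple[float, float], float, float]],
    population_blobs: Sequence[tuple[tuple[float, float], float]],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a marker-expression image, a population image, and the true
    pixel overlap of their filled disks.

    Parameters
    ----------
    marker_blobs : iterable of ``((cx, cy), radius, intensity)`` with
        intensity in [0, 1]; rendered into the red channel.
    population_blobs : iterable of ``((cx, cy), radius)``; rendered yellow.

    Returns ``(marker_rgba, population_rgba, truth_overlap)`` with RGBA uint8
    images (origin top-left, row-major, 0-based pixel coordinates) and a
    boolean overlap mask.
    """
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be positive")
    for (cx, cy), radius, *_ in list(marker_blobs) + [(c, r) for c, r in population_blobs]:
        if not (0 <= cx < width and 0 <= cy < height):
            raise ValueError(f"blob center ({cx}, {cy}) outside image bounds")
        if radius < 0:
            raise ValueError("blob radius must be non-negative")

    rng = np.random.default_rng(seed)

    marker = np.zeros((height, width, 4), dtype=np.uint8)
    marker[..., 3] = 255
    # faint background speckle, well below any sensible detection threshold
    marker[..., 0] = rng.integers(0, 8, size=(height, width), dtype=np.uint8)
    marker_any = np.zeros((height, width), dtype=bool)
    for center, radius, intensity in marker_blobs:
        if not 0.0 <= intensity <= 1.0:
            raise ValueError("marker intensity must lie in [0, 1]")
        disk = _disk_mask(height, width, center, radius)
        marker[disk, 0] = np.maximum(marker[disk, 0], np.uint8(round(255 * intensity)))
        marker_any |= disk

    population = np.zeros((height, width, 4), dtype=np.uint8)
    population[..., 3] = 255
    pop_any = np.zeros((height, width), dtype=bool)
    for center, radius in population_blobs:
        disk = _disk_mask(height, width, center, radius)
        population[disk, 0] = 255
        population[disk, 1] = 255
        pop_any |= disk

    return marker, population, marker_any & pop_any


# ---------------------------------------------------------------------------
# membership-atlas fixtures


def generate_atlas_fixture(
    n_genes: int,
    contexts: Sequence[tuple[str, str]],
    assignment_probabilities: dict[tuple[str, str], dict[str, float]] | dict[str, float],
    seed: int = 0,
):
    """Random but seed-deterministic gene-to-module assignments per context.

    ``contexts`` is a list of ``(timepoint, celltype)`` pairs;
    ``assignment_probabilities`` maps each context (or all contexts, if a
    single flat mapping is given) to a module-label distribution; the label
    ``"grey"`` marks unassigned genes and is allowed.
    Returns a :class:`regenhubnet.setops.MembershipAtlas`.
    """
    from .setops import MembershipAtlas, classify_condition

    if not contexts:
        raise ValueError("context list must be non-empty")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    per_context: dict[tuple[str, str], dict[str, float]]
    if assignment_probabilities and isinstance(next(iter(assignment_probabilities)), tuple):
        per_context = dict(assignment_probabilities)  # type: ignore[arg-type]
    else:
        per_context = {ctx: dict(assignment_probabilities) for ctx in contexts}  # type: ignore[arg-type]
    for ctx in contexts:
        probs = per_context.get(ctx)
        if probs is None:
            raise ValueError(f"no assignment probabilities for context {ctx}")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities for context {ctx} sum to {total}, not 1")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    rows = []
    for timepoint, celltype in contexts:
        probs = per_context[(timepoint, celltype)]
        labels = list(probs)
        p = np.array([probs[l] for l in labels])
        draw = rng.choice(len(labels), size=n_genes, p=p)
        for g, d in zip(genes, draw):
            label = labels[d]
            if label != "grey":
                rows.append((g, timepoint, celltype, label))
    entries = pd.DataFrame(rows, columns=["gene", "timepoint", "celltype", "module"])
    condition_class = {tp: classify_condition(tp) for tp, _ in contexts}
    return MembershipAtlas(entries=entries, condition_class=condition_class)
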