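"""End-to-end orchestration: synthesize (or load) sections, build metacells,
fit one co-expression network per (cell-type, condition) context, compile
the membership atlas and derived gene sets, extract hubs and hub
frequencies, measure the marker time course, and render co-localization
composites.  A run is fully determined by its configuration and seed; rerun
with the same config produces byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as rio
from .metacells import MetacellParams, build_metacells, normalize_metacells
from .modulestats import hub_frequency
from .netcore import EXCLUDED, CoexpressionNetwork, NetworkParams, filter_genes_by_fraction
from .setops import GeneSetReport, build_membership_atlas, derive_gene_sets
from .spatialcoloc import compose, dilate, positive_cell_fraction, threshold_rgb
from .synthdata import ExpressionSection, SynthConfig, generate_sections

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "render_section_images"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Single configuration for a full pipeline run.

    Either ``synth`` (synthetic mode) or ``input_dir`` (a directory of
    section subdirectories in MTX+TSV form) must be set.
    """

    synth: SynthConfig | None = SynthConfig()
    input_dir: str | None = None
    metacell: MetacellParams = MetacellParams()
    network: NetworkParams = NetworkParams()
    n_hubs: int = 10
    marker_gene: str | None = None  # default: the synthetic truth marker
    population_annotation: str | None = None  # default: first annotation label
    coloc_rule: str = "R>=100,G<=80,B<=80"
    dilate_radius: int = 2
    image_size: int = 100
    seed: int = 0

    def validate(self) -> None:
        if (self.synth is None) == (self.input_dir is None):
            raise ValueError("exactly one of synth / input_dir must be set")
        if self.synth is not None:
            self.synth.validate()
        if self.n_hubs < 1:
            raise ValueError("n_hubs must be >= 1")

    def config_hash(self) -> str:
        payload = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one seed to every stochastic stage."""
        synth = dataclasses.replace(self.synth, seed=seed) if self.synth is not None else None
        metacell = dataclasses.replace(self.metacell, seed=seed)
        return dataclasses.replace(self, seed=seed, synth=synth, metacell=metacell)


@dataclass
class RunManifest:
    """Record of one pipeline run: per-context outcomes, derived set sizes,
    hub counts, the marker time course, and the file inventory."""

    config_hash: str
    contexts: list[dict] = field(default_factory=list)
    set_sizes: dict = field(default_factory=dict)
    n_hub_rows: int = 0
    n_hub_genes: int = 0
    marker_course: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def render_section_images(
    section: ExpressionSection,
    marker_gene: str,
    annotation: str,
    size: int = 100,
    threshold: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a section into a marker image (red intensity at positive
    cells) and a population image (yellow at annotated cells), both RGBA on
    a dim grey tissue background."""
    xy = section.cells[["x", "y"]].to_numpy()
    lo = xy.min(axis=0)
    span = np.maximum(xy.max(axis=0) - lo, 1e-9)
    px = np.clip(((xy - lo) / span * (size - 1)).astype(int), 0, size - 1)

    marker = np.zeros((size, size, 4), dtype=np.uint8)
    marker[..., 3] = 255
    pop = marker.copy()
    # dim tissue background at every cell pixel
    for img in (marker, pop):
        img[px[:, 1], px[:, 0], :3] = 30

    expr = section.expression(marker_gene)
    pos = expr > threshold
    if pos.any():
        inten = expr[pos]
        inten = inten / inten.max()
        reds = (120 + 135 * inten).astype(np.uint8)
        marker[px[pos, 1], px[pos, 0], 0] = reds
        marker[px[pos, 1], px[pos, 0], 1] = 0
        marker[px[pos, 1], px[pos, 0], 2] = 0

    ann = (section.cells["celltype"] == annotation).to_numpy()
    pop[px[ann, 1], px[ann, 0], 0] = 255
    pop[px[ann, 1], px[ann, 0], 1] = 255
    pop[px[ann, 1], px[ann, 0], 2] = 0
    return marker, pop


def _write_tsv(frame: pd.DataFrame, path: str, manifest: RunManifest) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest.files.append(os.path.basename(path))


def run_pipeline(config: PipelineConfig, outdir: str) -> RunManifest:
    """Execute all stages and write the outputs under ``outdir``.

    Outputs: per-context module TSV and network summary, membership atlas,
    gene-set TSVs, hub and frequency tables, the marker positive-fraction
    time course, co-localization composites (PNG) and report, and a JSON
    manifest.  Any stage error aborts with the stage and context named.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash())

    # --- stage: input -----------------------------------------------------
    if config.synth is not None:
        sections, truth = generate_sections(config.synth)
        marker_gene = config.marker_gene or truth.marker_gene
    else:
        entries = sorted(
            d for d in os.listdir(config.input_dir)
            if os.path.isdir(os.path.join(config.input_dir, d))
        )
        if not entries:
            raise RuntimeError(f"stage input: no section directories under {config.input_dir!r}")
        sections = [rio.read_section(os.path.join(config.input_dir, d)) for d in entries]
        if config.marker_gene is None:
            raise ValueError("marker_gene must be set when loading real sections")
        marker_gene = config.marker_gene

    annotation = config.population_annotation or sorted(sections[0].cells["celltype"].unique())[0]

    # --- stage: metacells + networks per context --------------------------
    assignments = []
    hub_tables = []
    summary_rows = []
    module_rows = []
    for section in sections:
        try:
            mc = normalize_metacells(build_metacells(section, config.metacell))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage metacells failed for section {section.condition!r}: {exc}") from exc
        for group in sorted(set(mc.group)):
            context = (group, section.condition)
            try:
                # detection filter runs on cells (a sparsely expressed gene
                # looks densely detected after 25-cell aggregation)
                keep = filter_genes_by_fraction(section, group, config.network.fraction)
                frame = mc.subset_group(group).to_frame()[keep]
                frame = frame.loc[:, frame.std(axis=0) > 0]
                if frame.shape[1] < 3 or frame.shape[0] < 3:
                    logger.warning("context %s: too few genes/metacells after filtering; excluded", context)
                    summary_rows.append(
                        {"celltype": group, "condition": section.condition, "power": "EXCLUDED",
                         "r_squared": "", "n_modules": 0, "n_grey": frame.shape[1]}
                    )
                    manifest.contexts.append(
                        {"celltype": group, "condition": section.condition, "power": None,
                         "n_modules": 0, "n_grey": frame.shape[1], "excluded": True}
                    )
                    continue
                model = CoexpressionNetwork(frame, config.network, context=context)
                res = model.fit()
            except Exception as exc:
                raise RuntimeError(f"stage network failed for context {context}: {exc}") from exc
            if res.excluded:
                logger.info("context %s: EXCLUDED", context)
                summary_rows.append(
                    {"celltype": group, "condition": section.condition, "power": "EXCLUDED",
                     "r_squared": "", "n_modules": 0, "n_grey": res.modules.n_grey}
                )
                manifest.contexts.append(
                    {"celltype": group, "condition": section.condition, "power": None,
                     "n_modules": 0, "n_grey": res.modules.n_grey, "excluded": True}
                )
                continue
            fit_row = res.power_scan[res.power_scan["power"] == res.power].iloc[0]
            logger.info(
                "context %s: power=%d R2=%.3f modules=%d grey=%d",
                context, res.power, fit_row["r_squared"], res.modules.n_modules, res.modules.n_grey,
            )
            summary_rows.append(
                {"celltype": group, "condition": section.condition, "power": res.power,
                 "r_squared": round(float(fit_row["r_squared"]), 6),
                 "n_modules": res.modules.n_modules, "n_grey": res.modules.n_grey}
            )
            manifest.contexts.append(
                {"celltype": group, "condition": section.condition, "power": res.power,
                 "n_modules": res.modules.n_modules, "n_grey": res.modules.n_grey, "excluded": False}
            )
            assignments.append(res.modules)
            for gene, module in sorted(res.modules.labels.items()):
                module_rows.append({"gene": gene, "module": module,
                                    "celltype": group, "condition": section.condition})
            hub_tables.append(res.hub_genes(n_hubs=config.n_hubs))

    _write_tsv(pd.DataFrame(summary_rows), os.path.join(outdir, "network_summary.tsv"), manifest)
    _write_tsv(pd.DataFrame(module_rows), os.path.join(outdir, "modules.tsv"), manifest)

    # --- stage: set algebra ----------------------------------------------
    try:
        atlas = build_membership_atlas(assignments)
        if atlas.entries.empty or not atlas.regeneration_timepoints:
            logger.warning("membership atlas has no regeneration entries; gene sets are empty")
            report = GeneSetReport(set(), set(), set(), set(), [], [])
        else:
            report = derive_gene_sets(atlas)
    except Exception as exc:
        raise RuntimeError(f"stage sets failed: {exc}") from exc
    manifest.set_sizes = report.sizes()
    _write_tsv(atlas.entries, os.path.join(outdir, "membership_atlas.tsv"), manifest)
    for name, genes in (
        ("genes_all_regeneration", sorted(report.all_regen)),
        ("genes_shared_all_stages", sorted(report.shared_all_stages)),
        ("genes_control", sorted(report.all_control)),
        ("genes_regeneration_specific", sorted(report.regen_specific)),
    ):
        _write_tsv(pd.DataFrame({"gene": genes}), os.path.join(outdir, f"{name}.tsv"), manifest)
    _write_tsv(pd.DataFrame({"gene": report.amex_genes}),
               os.path.join(outdir, "genes_regen_specific_amex.tsv"), manifest)
    _write_tsv(pd.DataFrame({"gene": report.ortholog_genes}),
               os.path.join(outdir, "genes_regen_specific_ortholog.tsv"), manifest)

    # --- stage: hubs ------------------------------------------------------
    hub_tables = [t for t in hub_tables if len(t)]
    try:
        hubs = (
            pd.concat(hub_tables, ignore_index=True)
            if hub_tables else pd.DataFrame(columns=["gene", "context", "module", "rank", "kme"])
        )
        freq = hub_frequency(hub_tables) if hub_tables else pd.DataFrame(
            columns=["gene", "hub_occurrences", "occurrences", "best_rank"]
        )
    except Exception as exc:
        raise RuntimeError(f"stage hubs failed: {exc}") from exc
    manifest.n_hub_rows = len(hubs)
    manifest.n_hub_genes = hubs["gene"].nunique() if len(hubs) else 0
    _write_tsv(hubs, os.path.join(outdir, "hub_table.tsv"), manifest)
    if len(freq):
        freq = freq.assign(occurrences=[";".join(f"{c}:{m}" for c, m in occ) for occ in freq["occurrences"]])
    _write_tsv(freq, os.path.join(outdir, "hub_frequency.tsv"), manifest)

    # --- stage: marker time course + co-localization ----------------------
    course_rows = []
    coloc_rows = []
    for section in sections:
        try:
            frac = positive_cell_fraction(section, marker_gene)
            course_rows.append({"condition": section.condition, "gene": marker_gene,
                                "positive_fraction": round(frac, 10)})
            marker_img, pop_img = render_section_images(
                section, marker_gene, annotation, size=config.image_size
            )
            mask = dilate(threshold_rgb(marker_img, config.coloc_rule), config.dilate_radius)
            pop_mask = threshold_rgb(pop_img, "R>=200,G>=200,B<=60")
            composite, coloc = compose(marker_img, mask, pop_mask)
            png = os.path.join(outdir, f"coloc_{section.condition}.png")
            rio.write_image(composite, png)
            manifest.files.append(os.path.basename(png))
            coloc_rows.append(
                {"condition": section.condition, "marker_pixels": coloc.marker_pixels,
                 "population_pixels": coloc.population_pixels,
                 "overlap_pixels": coloc.overlap_pixels,
                 "overlap_fraction_of_marker": round(coloc.overlap_fraction_of_marker, 10)}
            )
        except Exception as exc:
            raise RuntimeError(f"stage coloc failed for section {section.condition!r}: {exc}") from exc
        manifest.marker_course[section.condition] = round(frac, 10)
    _write_tsv(pd.DataFrame(course_rows), os.path.join(outdir, "marker_time_course.tsv"), manifest)
    _write_tsv(pd.DataFrame(coloc_rows), os.path.join(outdir, "coloc_report.tsv"), manifest)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    manifest.files.append("manifest.json")
    return manifest
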