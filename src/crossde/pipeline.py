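"""End-to-end orchestration: simulate -> preprocess -> differential tests
-> GO association -> concordance, with a machine-readable run manifest.

Each stage writes plain TSV tables into the output directory; the
manifest (JSON) echoes the configuration and records per-stage outputs,
row counts and wall time.  Statistical outputs are byte-deterministic for
a fixed configuration and seed; only the manifest carries timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .errors import CrossDEError
from . import de_stats, go_rank
from .concordance import (
    attenuation_analysis,
    concordance_report,
    heatmap_order,
)
from .io_config import (
    GOAnnotation,
    PipelineConfig,
    ProbesetGeneMap,
    StudyDesign,
    read_annotation,
    read_design,
    read_gene_map,
    read_probeset_matrix,
    write_annotation,
    write_design,
    write_gene_map,
    write_gene_matrix,
    write_probeset_matrix,
)
from .preprocess import preprocess_experiment
from .synthetic import PROGRAM_TERM, SimulationConfig, SyntheticStudy, generate

logger = logging.getLogger("crossde")

#: canonical file names inside an output directory
FILES = {
    "invivo_intensity": "invivo_intensities.tsv",
    "invivo_calls": "invivo_calls.tsv",
    "invitro_intensity": "invitro_intensities.tsv",
    "invitro_calls": "invitro_calls.tsv",
    "design": "design.tsv",
    "map": "map.tsv",
    "annotation": "annotation.tsv",
    "terms": "terms.tsv",
    "truth": "truth.tsv",
}


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list  # {name, outputs: {path: n_rows}, seconds}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def simulate_to_dir(sim_config: SimulationConfig, outdir: Path) -> SyntheticStudy:
    """Generate a synthetic study and write all input artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate(sim_config)
    write_probeset_matrix(
        study.invivo, outdir / FILES["invivo_intensity"], outdir / FILES["invivo_calls"]
    )
    write_probeset_matrix(
        study.invitro,
        outdir / FILES["invitro_intensity"],
        outdir / FILES["invitro_calls"],
    )
    write_design(study.design, outdir / FILES["design"])
    write_gene_map(study.gene_map, outdir / FILES["map"])
    write_annotation(
        study.annotation, outdir / FILES["annotation"], outdir / FILES["terms"]
    )
    study.truth.to_csv(outdir / FILES["truth"], sep="\t", index=False)
    return study


def load_inputs(indir: Path) -> tuple:
    indir = Path(indir)
    invivo = read_probeset_matrix(
        indir / FILES["invivo_intensity"], indir / FILES["invivo_calls"]
    )
    invitro = read_probeset_matrix(
        indir / FILES["invitro_intensity"], indir / FILES["invitro_calls"]
    )
    design = read_design(indir / FILES["design"])
    gene_map = read_gene_map(indir / FILES["map"])
    annotation = read_annotation(indir / FILES["annotation"], indir / FILES["terms"])
    return invivo, invitro, design, gene_map, annotation


def run_all(
    config: PipelineConfig,
    outdir,
    sim_config: Optional[SimulationConfig] = None,
    simulate: bool = True,
) -> RunManifest:
    """Run every stage in order and write all tables plus the manifest.

    With ``simulate`` (the default) a synthetic study is generated into
    ``outdir`` first; otherwise existing input artifacts are read either
    from ``config.paths['indir']`` or from ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    alpha = config.alpha

    def record(name: str, started: float, outputs: dict) -> None:
        stages.append(
            {
                "name": name,
                "outputs": outputs,
                "seconds": round(time.perf_counter() - started, 3),
            }
        )

    def emit(df: pd.DataFrame, name: str, outputs: dict) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = len(df)

    # -- inputs ----------------------------------------------------------
    t0 = time.perf_counter()
    if simulate:
        if sim_config is None:
            sim_config = SimulationConfig(seed=config.seed)
        study = simulate_to_dir(sim_config, outdir)
        invivo, invitro = study.invivo, study.invitro
        design, gene_map, annotation = (
            study.design,
            study.gene_map,
            study.annotation,
        )
        record(
            "simulate",
            t0,
            {FILES[k]: None for k in FILES},
        )
    else:
        indir = Path(config.paths.get("indir", outdir))
        invivo, invitro, design, gene_map, annotation = load_inputs(indir)
        record("load", t0, {})

    # -- preprocess ------------------------------------------------------
    t0 = time.perf_counter()
    outputs: dict = {}
    gm_vivo, rep_vivo = preprocess_experiment(
        invivo, design.subset("invivo"), gene_map
    )
    gm_vitro, rep_vitro = preprocess_experiment(
        invitro, design.subset("invitro"), gene_map
    )
    write_gene_matrix(gm_vivo, outdir / "gene_matrix_invivo.tsv")
    write_gene_matrix(gm_vitro, outdir / "gene_matrix_invitro.tsv")
    outputs["gene_matrix_invivo.tsv"] = len(gm_vivo.gene_ids)
    outputs["gene_matrix_invitro.tsv"] = len(gm_vitro.gene_ids)
    filter_report = pd.concat(
        [
            rep_vivo.to_frame().assign(experiment="invivo"),
            rep_vitro.to_frame().assign(experiment="invitro"),
        ],
        ignore_index=True,
    )
    emit(filter_report, "filter_report.tsv", outputs)
    record("preprocess", t0, outputs)

    # -- differential tests ---------------------------------------------
    t0 = time.perf_counter()
    outputs = {}
    design_vivo = design.subset("invivo")
    design_vitro = design.subset("invitro")
    anova = de_stats.anova_table(gm_vivo, design_vivo, ["S", "M", "F"])
    de_ms = de_stats.welch_table(gm_vivo, design_vivo, "S", "M")
    de_fm = de_stats.welch_table(gm_vivo, design_vivo, "M", "F")
    de_lps = de_stats.paired_table(gm_vitro, design_vitro, "control", "LPS")
    emit(anova, "anova_SMF.tsv", outputs)
    emit(de_ms, "de_M-S.tsv", outputs)
    emit(de_fm, "de_F-M.tsv", outputs)
    emit(de_lps, "de_LPS-control.tsv", outputs)
    record("de", t0, outputs)

    # -- GO association --------------------------------------------------
    t0 = time.perf_counter()
    outputs = {}
    contrasts = {"M-S": de_ms, "F-M": de_fm, "LPS-control": de_lps}
    for label, de in contrasts.items():
        ranked = go_rank.rank_genes(de, alpha)
        table = go_rank.go_associations(
            ranked,
            annotation,
            min_term_size=config.min_term_size,
            max_term_size=config.max_term_size,
        )
        emit(table, f"go_{label}.tsv", outputs)
    fk_genes = de_fm.loc[de_fm["p"] < alpha, "gene_id"]
    venn = go_rank.term_membership_counts(
        fk_genes, annotation, list(config.go_terms)
    )
    emit(venn, "venn_counts.tsv", outputs)
    record("go", t0, outputs)

    # -- concordance -----------------------------------------------------
    t0 = time.perf_counter()
    outputs = {}
    report, common = concordance_report(de_ms, de_lps, alpha, label="global")
    report_rows = [report.to_frame().iloc[0]]
    restrict = PROGRAM_TERM if PROGRAM_TERM in set(config.go_terms) else (
        config.go_terms[-1] if config.go_terms else None
    )
    if restrict is not None:
        r_rep, _ = concordance_report(
            de_ms,
            de_lps,
            alpha,
            annotation=annotation,
            restriction_term=restrict,
            label=f"restricted:{restrict}",
        )
        report_rows.append(r_rep.to_frame().iloc[0])
    if not common.empty:
        quad = pd.Series("", index=common.index)
        quad[(common["delta_a"] > 0) & (common["delta_b"] > 0)] = "up/up"
        quad[(common["delta_a"] > 0) & (common["delta_b"] < 0)] = "up/down"
        quad[(common["delta_a"] < 0) & (common["delta_b"] > 0)] = "down/up"
        quad[(common["delta_a"] < 0) & (common["delta_b"] < 0)] = "down/down"
        common = common.assign(quadrant=quad)
    emit(common, "concordance.tsv", outputs)
    emit(
        pd.DataFrame(report_rows).reset_index(drop=True),
        "concordance_report.tsv",
        outputs,
    )
    atten = attenuation_analysis(de_ms, de_fm, alpha)
    emit(atten.to_frame(), "attenuation_report.tsv", outputs)
    emit(atten.table, "attenuation_genes.tsv", outputs)
    if restrict is not None:
        heat_genes = sorted(
            set(fk_genes) & set(annotation.genes_for(restrict))
        )
    else:
        heat_genes = sorted(fk_genes)
    heat = heatmap_order(heat_genes, de_ms, de_lps, alpha)
    emit(heat, "heatmap_order.tsv", outputs)
    record("concord", t0, outputs)

    manifest = RunManifest(
        config={
            "alpha": config.alpha,
            "seed": config.seed,
            "go_terms": list(config.go_terms),
            "min_term_size": config.min_term_size,
            "max_term_size": config.max_term_size,
            "paths": dict(config.paths),
            "simulate": simulate,
            "sim_config": dataclasses.asdict(sim_config) if sim_config else None,
        },
        seed=config.seed,
        version=__version__,
        stages=stages,
    )
    manifest.save(outdir / "manifest.json")
    return manifest
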