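"""Synthetic paired in vivo / in vitro microarray study with known truth.

The generator emulates the structure of a two-system neuroinflammation
study:

* an in vivo 3-condition stroke experiment — sham (S), insult (M) and
  insult + drug (F), n = 3 animals per group;
* an in vitro microglia experiment — matched control/LPS culture
  preparations, 4 pairs, where each preparation contributes a shared
  random intercept so the paired test's advantage is real;
* a shared "inflammatory program" gene set induced (positive log2 effect)
  in both systems, whose insult effect the drug attenuates by a factor
  ``attenuation`` in the F condition;
* system-specific responder genes with effects in one system only;
* multiple probesets per gene, each with its own affinity offset;
* log2-normal intensity noise and intensity-dependent Absent calls
  (a logistic detection model: low-intensity cells are more often A).

All effects are additive on the log2 scale; observed linear intensities
are ``2**(log2 mean + offsets + noise)``.  Everything is reproducible from
the seed.  Program genes are annotated to a designated inflammatory
response term whose ancestors (response to wounding, response to external
stimulus, immune system process) carry additional random direct
annotations, alongside a configurable number of random background terms.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError
from .io_config import (
    GOAnnotation,
    ProbesetGeneMap,
    ProbesetMatrix,
    StudyDesign,
    expand_annotation,
)

logger = logging.getLogger("crossde")

PROGRAM_TERM = "GO:INFLAM"
#: the four category terms of the drug-affected gene overlap analysis
CATEGORY_TERMS = ("GO:EXT", "GO:WOUND", "GO:IMMUNE", "GO:INFLAM")


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-system experiment.

    Defaults describe the design this pipeline targets: 10,000 genes of
    which 400 form the shared inflammatory program with a mean induction
    of 1.5 log2 units in both systems, attenuated by 80% in the drugged
    condition, n = 3 per in vivo group and 4 matched in vitro pairs,
    residual log2 noise of 0.25.
    """

    n_genes: int = 10_000
    probesets_per_gene: tuple[int, int] = (1, 3)
    n_invivo_per_group: int = 3
    n_invitro_pairs: int = 4
    n_program_genes: int = 400
    program_effect: float = 1.5  # mean log2 induction, both systems
    attenuation: float = 0.8  # fraction of the insult effect removed in F
    n_invivo_specific: int = 150
    n_invitro_specific: int = 150
    baseline_mean: float = 8.0  # log2 scale
    baseline_sd: float = 1.5
    noise_sd: float = 0.25  # residual log2 noise
    probeset_offset_sd: float = 0.3
    pair_sd: float = 0.3  # per-preparation random intercept (log2)
    detect_threshold: float = 5.0  # log2 intensity of 50% Absent calls
    detect_slope: float = 1.0
    marginal_rate: float = 0.05  # P(M | detected)
    n_background_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes,
            self.n_program_genes,
            self.n_invivo_specific,
            self.n_invitro_specific,
            self.n_invivo_per_group,
            self.n_invitro_pairs,
            self.n_background_terms,
        )
        if any(c < 0 for c in counts):
            raise FormatError("simulation counts must be nonnegative")
        if (
            self.n_program_genes + self.n_invivo_specific + self.n_invitro_specific
            > self.n_genes
        ):
            raise FormatError("program + specific genes exceed n_genes")
        if self.noise_sd <= 0:
            raise FormatError("noise_sd must be > 0")
        if not (0.0 <= self.attenuation <= 1.0):
            raise FormatError("attenuation must be in [0, 1]")
        lo, hi = self.probesets_per_gene
        if lo < 1 or hi < lo:
            raise FormatError("probesets_per_gene bounds invalid")


@dataclasses.dataclass
class SyntheticStudy:
    """Everything :func:`generate` produces."""

    invivo: ProbesetMatrix
    invitro: ProbesetMatrix
    design_invivo: StudyDesign
    design_invitro: StudyDesign
    gene_map: ProbesetGeneMap
    annotation: GOAnnotation
    truth: pd.DataFrame

    @property
    def design(self) -> StudyDesign:
        return StudyDesign(
            pd.concat(
                [self.design_invivo.table, self.design_invitro.table],
                ignore_index=True,
            )
        )


def generate(config: SimulationConfig) -> SyntheticStudy:
    """Draw one complete synthetic study from the given conditions."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(1, n + 1)])

    # --- gene roles and true effects -----------------------------------
    is_program = np.zeros(n, dtype=bool)
    is_program[: config.n_program_genes] = True
    iv_lo = config.n_program_genes
    iv_hi = iv_lo + config.n_invivo_specific
    is_invivo_spec = np.zeros(n, dtype=bool)
    is_invivo_spec[iv_lo:iv_hi] = True
    vt_hi = iv_hi + config.n_invitro_specific
    is_invitro_spec = np.zeros(n, dtype=bool)
    is_invitro_spec[iv_hi:vt_hi] = True

    s = config.program_effect
    lam = config.attenuation
    true_ms = np.zeros(n)  # M - S
    true_lps = np.zeros(n)  # LPS - control
    true_ms[is_program] = s
    true_lps[is_program] = s
    spec_sign_iv = rng.choice([-1.0, 1.0], size=int(is_invivo_spec.sum()))
    true_ms[is_invivo_spec] = s * spec_sign_iv
    spec_sign_vt = rng.choice([-1.0, 1.0], size=int(is_invitro_spec.sum()))
    true_lps[is_invitro_spec] = s * spec_sign_vt
    # drug removes a fraction `lam` of the program genes' insult effect;
    # system-specific in vivo responders are left untouched by the drug
    true_fs = true_ms.copy()
    true_fs[is_program] = (1.0 - lam) * true_ms[is_program]
    true_fm = true_fs - true_ms

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    # --- probesets ------------------------------------------------------
    lo, hi = config.probesets_per_gene
    k = rng.integers(lo, hi + 1, size=n)
    gene_of_probe = np.repeat(np.arange(n), k)
    probe_idx_within = np.concatenate([np.arange(c) for c in k])
    probe_ids = np.array(
        [
            f"{gene_ids[g]}_ps{j + 1}"
            for g, j in zip(gene_of_probe, probe_idx_within)
        ]
    )
    affinity = rng.normal(0.0, config.probeset_offset_sd, size=len(probe_ids))

    # --- in vivo matrix -------------------------------------------------
    ng = config.n_invivo_per_group
    invivo_samples = (
        [f"S{i+1}" for i in range(ng)]
        + [f"M{i+1}" for i in range(ng)]
        + [f"F{i+1}" for i in range(ng)]
    )
    cond_effect_invivo = np.column_stack(
        [np.zeros(n), true_ms, true_fs]
    )  # genes x {S, M, F}
    cond_of_sample = np.repeat(np.arange(3), ng)
    mean_vivo = (
        baseline[gene_of_probe, None]
        + cond_effect_invivo[gene_of_probe][:, cond_of_sample]
        + affinity[:, None]
    )
    log2_vivo = mean_vivo + rng.normal(
        0.0, config.noise_sd, size=mean_vivo.shape
    )
    invivo = _to_matrix(log2_vivo, probe_ids, invivo_samples, config, rng)
    design_invivo = StudyDesign(
        pd.DataFrame(
            {
                "sample_id": invivo_samples,
                "experiment": "invivo",
                "condition": ["S"] * ng + ["M"] * ng + ["F"] * ng,
                "pair_id": "",
            }
        )
    )

    # --- in vitro matrix ------------------------------------------------
    npair = config.n_invitro_pairs
    ctrl = [f"ctrl{i+1}" for i in range(npair)]
    lps = [f"lps{i+1}" for i in range(npair)]
    invitro_samples = ctrl + lps
    pair_intercept = rng.normal(0.0, config.pair_sd, size=(n, npair))
    cond_effect_invitro = np.concatenate(
        [np.zeros((n, npair)), np.tile(true_lps[:, None], (1, npair))], axis=1
    )
    pair_block = np.concatenate([pair_intercept, pair_intercept], axis=1)
    mean_vitro = (
        baseline[gene_of_probe, None]
        + (cond_effect_invitro + pair_block)[gene_of_probe]
        + affinity[:, None]
    )
    log2_vitro = mean_vitro + rng.normal(
        0.0, config.noise_sd, size=mean_vitro.shape
    )
    invitro = _to_matrix(log2_vitro, probe_ids, invitro_samples, config, rng)
    design_invitro = StudyDesign(
        pd.DataFrame(
            {
                "sample_id": invitro_samples,
                "experiment": "invitro",
                "condition": ["control"] * npair + ["LPS"] * npair,
                "pair_id": [f"p{i+1}" for i in range(npair)] * 2,
            }
        )
    )

    gene_map = ProbesetGeneMap(
        pd.DataFrame(
            {
                "probeset_id": probe_ids,
                "gene_id": gene_ids[gene_of_probe],
                "gene_symbol": [f"Sym{g[1:]}" for g in gene_ids[gene_of_probe]],
            }
        )
    )

    annotation = _build_annotation(gene_ids, is_program, config, rng)

    role = np.where(
        is_program,
        "program",
        np.where(
            is_invivo_spec,
            "invivo_specific",
            np.where(is_invitro_spec, "invitro_specific", "null"),
        ),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "role": role,
            "true_delta_ms": true_ms,
            "true_delta_fs": true_fs,
            "true_delta_fm": true_fm,
            "true_delta_lps": true_lps,
        }
    )
    return SyntheticStudy(
        invivo=invivo,
        invitro=invitro,
        design_invivo=design_invivo,
        design_invitro=design_invitro,
        gene_map=gene_map,
        annotation=annotation,
        truth=truth,
    )


def _to_matrix(
    log2_values: np.ndarray,
    probe_ids: np.ndarray,
    samples: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ProbesetMatrix:
    """Exponentiate to linear intensities and draw detection calls."""
    intensity = 2.0**log2_values
    # logistic Absent model: P(A) -> 1 well below the threshold intensity
    p_absent = 1.0 / (
        1.0 + np.exp((log2_values - config.detect_threshold) / config.detect_slope)
    )
    u = rng.uniform(size=log2_values.shape)
    u2 = rng.uniform(size=log2_values.shape)
    calls = np.where(
        u < p_absent, "A", np.where(u2 < config.marginal_rate, "M", "P")
    )
    inten = pd.DataFrame(intensity, index=probe_ids, columns=samples)
    callsdf = pd.DataFrame(calls, index=probe_ids, columns=samples)
    inten.index.name = "probeset_id"
    callsdf.index.name = "probeset_id"
    return ProbesetMatrix(intensity=inten, calls=callsdf)


def _build_annotation(
    gene_ids: np.ndarray,
    is_program: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GOAnnotation:
    n = len(gene_ids)
    program_genes = list(gene_ids[is_program])
    terms = [
        ("GO:ROOT", "biological process (synthetic)", ""),
        ("GO:EXT", "response to external stimulus (synthetic)", "GO:ROOT"),
        ("GO:WOUND", "response to wounding (synthetic)", "GO:EXT"),
        ("GO:IMMUNE", "immune system process (synthetic)", "GO:ROOT"),
        (PROGRAM_TERM, "inflammatory response (synthetic)", "GO:WOUND"),
    ]
    pairs: list[tuple[str, str]] = [(g, PROGRAM_TERM) for g in program_genes]

    def sample_genes(count: int) -> list[str]:
        count = min(count, n)
        return list(rng.choice(gene_ids, size=count, replace=False))

    # ancestors carry extra direct annotations so they are supersets of the
    # program term, as in a real ontology
    pairs += [(g, "GO:WOUND") for g in sample_genes(min(150, n))]
    pairs += [(g, "GO:EXT") for g in sample_genes(min(300, n))]
    n_imm = max(1, int(0.6 * len(program_genes))) if program_genes else 0
    if n_imm:
        pairs += [
            (g, "GO:IMMUNE")
            for g in rng.choice(program_genes, size=n_imm, replace=False)
        ]
    pairs += [(g, "GO:IMMUNE") for g in sample_genes(min(200, n))]
    for b in range(config.n_background_terms):
        tid = f"GO:BG{b + 1:02d}"
        terms.append((tid, f"background process {b + 1} (synthetic)", "GO:ROOT"))
        size = int(rng.integers(20, 201))
        pairs += [(g, tid) for g in sample_genes(size)]

    pairs_df = pd.DataFrame(pairs, columns=["gene_id", "term_id"]).drop_duplicates()
    terms_df = pd.DataFrame(terms, columns=["term_id", "term_name", "parent_ids"])
    return expand_annotation(pairs_df, terms_df)


# ---------------------------------------------------------------------------
# recovery metrics against ground truth
# ---------------------------------------------------------------------------


def truth_metrics(
    truth: pd.DataFrame,
    de_ms: Optional[pd.DataFrame] = None,
    de_lps: Optional[pd.DataFrame] = None,
    de_fm: Optional[pd.DataFrame] = None,
    common: Optional[pd.DataFrame] = None,
    go_table: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    program_term: str = PROGRAM_TERM,
) -> dict:
    """Compare pipeline outputs against the generator's ground truth.

    Returns a dict with estimated-vs-true delta RMSEs, the concordance
    stage's sensitivity/specificity against program membership (a gene is
    called concordantly induced when it lands in the up/up quadrant of the
    common-gene table), the program reversal fraction under the drug, and
    the program term's rank in the GO association table.
    """
    truth_idx = truth.set_index("gene_id")
    program = set(truth.loc[truth["role"] == "program", "gene_id"])
    out: dict = {}

    def _rmse(de: pd.DataFrame, col: str) -> float:
        genes = de["gene_id"]
        unknown = [g for g in genes if g not in truth_idx.index]
        if unknown:
            raise FormatError(f"gene {unknown[0]!r} absent from ground truth")
        err = de["delta"].to_numpy() - truth_idx.loc[genes, col].to_numpy()
        return float(np.sqrt(np.mean(err**2)))

    if de_ms is not None:
        out["rmse_delta_ms"] = _rmse(de_ms, "true_delta_ms")
    if de_lps is not None:
        out["rmse_delta_lps"] = _rmse(de_lps, "true_delta_lps")
    if de_fm is not None:
        out["rmse_delta_fm"] = _rmse(de_fm, "true_delta_fm")

    if common is not None and de_ms is not None and de_lps is not None:
        tested = set(de_ms["gene_id"]) & set(de_lps["gene_id"])
        both_up = set(
            common.loc[
                (common["delta_a"] > 0) & (common["delta_b"] > 0), "gene_id"
            ]
        )
        pos = program & tested
        neg = tested - program
        out["concordance_sensitivity"] = (
            len(both_up & pos) / len(pos) if pos else None
        )
        out["concordance_specificity"] = (
            1.0 - len(both_up & neg) / len(neg) if neg else None
        )

    if de_ms is not None and de_fm is not None:
        ms_idx = de_ms.set_index("gene_id")
        fm_idx = de_fm.set_index("gene_id")
        detected = [
            g
            for g in sorted(program)
            if g in ms_idx.index
            and ms_idx.loc[g, "p"] < alpha
            and ms_idx.loc[g, "delta"] > 0
            and g in fm_idx.index
        ]
        if detected:
            rev = sum(1 for g in detected if fm_idx.loc[g, "delta"] < 0)
            out["program_fraction_reversed"] = rev / len(detected)
            out["n_program_detected_induced"] = len(detected)
        else:
            out["program_fraction_reversed"] = None
            out["n_program_detected_induced"] = 0

    if go_table is not None and len(go_table):
        hits = go_table.index[go_table["term_id"] == program_term]
        out["program_term_rank"] = int(hits[0]) + 1 if len(hits) else None

    return out
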