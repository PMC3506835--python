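"""Detection-call filtering and probeset-to-gene summarization.

The pipeline consumes MAS5-style output (linear intensities plus P/M/A
detection calls) and reduces it to a gene-level log2 matrix in two steps:

1. keep only probesets consistently detected — call P or M in *every*
   hybridization of at least one condition of the experiment;
2. for each gene, average the linear intensities of its retained
   probesets per sample, then log2-transform the averaged profile.

Averaging precedes the log transform, so a gene's value is
``log2(mean_k intensity_k)``, not the mean of log2 intensities.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import FormatError
from .io_config import GeneMatrix, ProbesetGeneMap, ProbesetMatrix, StudyDesign

logger = logging.getLogger("crossde")

DETECTED = ("P", "M")


@dataclasses.dataclass
class FilterReport:
    """Bookkeeping from one preprocess run."""

    n_probesets_in: int
    n_probesets_retained: int
    n_probesets_unmapped: int
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def filter_detected(matrix: ProbesetMatrix, design: StudyDesign) -> ProbesetMatrix:
    """Retain probesets detected in all hybridizations of >= 1 condition.

    A probeset passes when there exists a condition whose every sample has
    a call in {P, M}.  Sample columns and probeset order are preserved.
    An empty result is not an error.
    """
    missing = [s for s in matrix.sample_ids if s not in set(design.sample_ids)]
    if missing:
        raise FormatError(f"sample {missing[0]!r} not present in design")
    detected = matrix.calls.isin(DETECTED)
    keep = np.zeros(len(matrix.probeset_ids), dtype=bool)
    for cond in design.conditions:
        samples = [s for s in design.samples_for(cond) if s in detected.columns]
        if not samples:
            continue
        keep |= detected[samples].all(axis=1).to_numpy()
    out = ProbesetMatrix(
        intensity=matrix.intensity.loc[keep].copy(),
        calls=matrix.calls.loc[keep].copy(),
    )
    logger.info(
        "detection filter: retained %d of %d probesets", int(keep.sum()), len(keep)
    )
    return out


def collapse_to_genes(matrix: ProbesetMatrix, pmap: ProbesetGeneMap) -> GeneMatrix:
    """Average each gene's probesets on the linear scale, then log2.

    Probesets absent from the map are dropped (count logged).  Genes are
    emitted in sorted gene_id order.  An averaged intensity of zero (which
    would give -inf on the log scale) is an error naming gene and sample.
    """
    gene_of = pmap.gene_of()
    mapped = [p for p in matrix.probeset_ids if p in gene_of.index]
    n_unmapped = len(matrix.probeset_ids) - len(mapped)
    if n_unmapped:
        logger.info("dropped %d unmapped probeset(s)", n_unmapped)
    inten = matrix.intensity.loc[mapped]
    genes = gene_of.loc[mapped]
    avg = inten.groupby(genes.values).mean()
    avg = avg.sort_index()
    nonpos = (avg.to_numpy() <= 0)
    if nonpos.any():
        i, j = np.argwhere(nonpos)[0]
        raise FormatError(
            f"averaged intensity <= 0 for gene {avg.index[i]!r}, "
            f"sample {avg.columns[j]!r}"
        )
    x = np.log2(avg)
    x.index.name = "gene_id"
    return GeneMatrix(x=x)


def preprocess_experiment(
    matrix: ProbesetMatrix, design: StudyDesign, pmap: ProbesetGeneMap
) -> tuple[GeneMatrix, FilterReport]:
    """Filter, collapse and report for one experiment's matrix."""
    filtered = filter_detected(matrix, design)
    gene_of = pmap.gene_of()
    n_unmapped = sum(1 for p in filtered.probeset_ids if p not in gene_of.index)
    gm = collapse_to_genes(filtered, pmap)
    report = FilterReport(
        n_probesets_in=len(matrix.probeset_ids),
        n_probesets_retained=len(filtered.probeset_ids),
        n_probesets_unmapped=n_unmapped,
        n_genes=len(gm.gene_ids),
    )
    return gm, report
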