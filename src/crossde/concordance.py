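"""Cross-system concordance and drug-attenuation analysis.

Given differential tables from two systems (an in vivo insult contrast and
an in vitro stimulation contrast) measured on a shared gene universe, this
module extracts the genes significant in both, correlates their log2
changes, classifies them by sign into a 2x2 quadrant contingency table,
tests the association with Fisher's exact test, and evaluates how well
induction in one system predicts induction in the other
(sensitivity/specificity), optionally restricted to one GO term's genes.

The attenuation analysis quantifies how a drug given with the insult
reverses insult-induced changes: among genes significantly induced by the
insult, the fraction whose drug-vs-insult change has the opposite sign.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateError, FormatError
from .de_stats import ContingencyTable2x2, fisher_exact_2x2, pearson_r
from .io_config import GOAnnotation

logger = logging.getLogger("crossde")


@dataclasses.dataclass
class ConcordanceReport:
    """Scalar metrics of one cross-system comparison."""

    label: str
    n_common: int
    r: Optional[float]
    r_p: Optional[float]
    quadrants: Optional[ContingencyTable2x2]
    n_excluded_zero_delta: int
    n_same_direction: Optional[int]
    n_both_up: Optional[int]
    fisher_p: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    restriction_term: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        q = self.quadrants
        return pd.DataFrame(
            [
                {
                    "label": self.label,
                    "n_common": self.n_common,
                    "r": self.r,
                    "r_p": self.r_p,
                    "quad_a": q.a if q else None,
                    "quad_b": q.b if q else None,
                    "quad_c": q.c if q else None,
                    "quad_d": q.d if q else None,
                    "n_excluded_zero_delta": self.n_excluded_zero_delta,
                    "n_same_direction": self.n_same_direction,
                    "n_both_up": self.n_both_up,
                    "fisher_p": self.fisher_p,
                    "sensitivity": self.sensitivity,
                    "specificity": self.specificity,
                    "restriction_term": self.restriction_term,
                }
            ]
        )


@dataclasses.dataclass
class AttenuationReport:
    """Drug reversal of insult-induced expression changes."""

    table: pd.DataFrame  # gene_id, delta_ms, delta_fm for insult-significant genes
    n_induced: int
    n_induced_reversed: int
    fraction_reversed: Optional[float]
    n_fk_significant: int
    r: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_induced": self.n_induced,
                    "n_induced_reversed": self.n_induced_reversed,
                    "fraction_reversed": self.fraction_reversed,
                    "n_fk_significant": self.n_fk_significant,
                    "r": self.r,
                }
            ]
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def intersect_significant(
    de_a: pd.DataFrame, de_b: pd.DataFrame, alpha: float
) -> pd.DataFrame:
    """Genes with p < alpha in both tables, with both deltas.

    Returns columns gene_id, delta_a, delta_b ordered by delta_a
    descending (ties by gene_id).  An empty intersection is allowed.
    """
    sig_a = de_a.loc[de_a["p"] < alpha, ["gene_id", "delta"]].rename(
        columns={"delta": "delta_a"}
    )
    sig_b = de_b.loc[de_b["p"] < alpha, ["gene_id", "delta"]].rename(
        columns={"delta": "delta_b"}
    )
    common = sig_a.merge(sig_b, on="gene_id", how="inner")
    if common.empty:
        logger.info("intersect_significant: empty intersection at alpha=%g", alpha)
    return common.sort_values(
        ["delta_a", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def quadrant_contingency(
    common: pd.DataFrame,
) -> tuple[ContingencyTable2x2, int]:
    """Classify common genes by delta signs into a 2x2 table.

    a = up/up, b = up(A)/down(B), c = down(A)/up(B), d = down/down, using
    strict inequalities; genes with a delta of exactly 0 in either system
    are excluded and counted separately.
    """
    if common.empty:
        raise FormatError("quadrant_contingency: common table is empty")
    da = common["delta_a"].to_numpy()
    db = common["delta_b"].to_numpy()
    nonzero = (da != 0) & (db != 0)
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("quadrant_contingency: excluded %d zero-delta gene(s)", n_excluded)
    if not nonzero.any():
        raise DegenerateError("quadrant_contingency: all genes have zero delta")
    da, db = da[nonzero], db[nonzero]
    tab = ContingencyTable2x2(
        a=int(((da > 0) & (db > 0)).sum()),
        b=int(((da > 0) & (db < 0)).sum()),
        c=int(((da < 0) & (db > 0)).sum()),
        d=int(((da < 0) & (db < 0)).sum()),
    )
    return tab, n_excluded


def prediction_metrics(
    tab: ContingencyTable2x2,
) -> tuple[Optional[float], Optional[float]]:
    """Sensitivity and specificity of predicting system-A induction from
    system-B induction.

    Positives are system-A-up genes; a gene is predicted positive when it
    is up in system B.  With the quadrant convention here sensitivity =
    a/(a+b) and specificity = d/(c+d); an undefined denominator yields
    None (missing), never 0.
    """
    sens = tab.a / (tab.a + tab.b) if (tab.a + tab.b) > 0 else None
    spec = tab.d / (tab.c + tab.d) if (tab.c + tab.d) > 0 else None
    return sens, spec


def restrict_to_term(
    common: pd.DataFrame, annotation: GOAnnotation, term_id: str
) -> pd.DataFrame:
    """Subset of the common-gene table annotated to one GO term."""
    known = set(annotation.term_ids) | set(annotation.pairs["term_id"])
    if term_id not in known:
        raise FormatError(f"unknown GO term {term_id!r}")
    members = annotation.genes_for(term_id)
    return common[common["gene_id"].isin(members)].reset_index(drop=True)


def concordance_report(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    alpha: float,
    annotation: Optional[GOAnnotation] = None,
    restriction_term: Optional[str] = None,
    label: str = "global",
) -> tuple[ConcordanceReport, pd.DataFrame]:
    """Full cross-system comparison; returns (report, common-gene table).

    When ``restriction_term`` is given the metrics are computed on the
    subset of common genes annotated to that term.
    """
    common = intersect_significant(de_a, de_b, alpha)
    if restriction_term is not None:
        if annotation is None:
            raise FormatError("restriction requires an annotation")
        common = restrict_to_term(common, annotation, restriction_term)
    n_common = len(common)
    if n_common == 0:
        report = ConcordanceReport(
            label=label, n_common=0, r=None, r_p=None, quadrants=None,
            n_excluded_zero_delta=0, n_same_direction=None, n_both_up=None,
            fisher_p=None, sensitivity=None, specificity=None,
            restriction_term=restriction_term,
        )
        return report, common
    r = r_p = None
    if n_common >= 3:
        try:
            r, r_p = pearson_r(common["delta_a"], common["delta_b"])
        except FormatError as exc:
            logger.info("concordance correlation skipped: %s", exc)
    try:
        tab, n_excl = quadrant_contingency(common)
    except DegenerateError as exc:
        logger.info("concordance quadrants skipped: %s", exc)
        report = ConcordanceReport(
            label=label, n_common=n_common, r=r, r_p=r_p, quadrants=None,
            n_excluded_zero_delta=n_common, n_same_direction=None,
            n_both_up=None, fisher_p=None, sensitivity=None, specificity=None,
            restriction_term=restriction_term,
        )
        return report, common
    sens, spec = prediction_metrics(tab)
    report = ConcordanceReport(
        label=label,
        n_common=n_common,
        r=r,
        r_p=r_p,
        quadrants=tab,
        n_excluded_zero_delta=n_excl,
        n_same_direction=tab.a + tab.d,
        n_both_up=tab.a,
        fisher_p=fisher_exact_2x2(tab),
        sensitivity=sens,
        specificity=spec,
        restriction_term=restriction_term,
    )
    return report, common


def attenuation_analysis(
    de_ms: pd.DataFrame, de_fm: pd.DataFrame, alpha: float
) -> AttenuationReport:
    """Drug attenuation of insult-induced changes.

    ``de_ms`` is the insult-vs-control contrast (delta > 0 = induced by
    the insult); ``de_fm`` is the drug-vs-insult contrast (delta < 0 =
    reduced by the drug).  Induced genes are those with p < alpha and
    delta > 0 in ``de_ms``; the reversal fraction is the share of induced
    genes whose ``de_fm`` delta is negative.
    """
    universe_a = set(de_ms["gene_id"])
    universe_b = set(de_fm["gene_id"])
    if universe_a != universe_b:
        raise FormatError("attenuation_analysis: tables cover different genes")
    sig = de_ms.loc[de_ms["p"] < alpha, ["gene_id", "delta"]].rename(
        columns={"delta": "delta_ms"}
    )
    fm = de_fm[["gene_id", "delta", "p"]].rename(
        columns={"delta": "delta_fm", "p": "p_fm"}
    )
    table = sig.merge(fm, on="gene_id", how="left").sort_values(
        ["delta_ms", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    induced = table[table["delta_ms"] > 0]
    n_induced = len(induced)
    n_rev = int((induced["delta_fm"] < 0).sum())
    frac = n_rev / n_induced if n_induced > 0 else None
    if n_induced == 0:
        logger.info("attenuation_analysis: no induced genes at alpha=%g", alpha)
    r = None
    if len(table) >= 3:
        try:
            r, _ = pearson_r(table["delta_ms"], table["delta_fm"])
        except FormatError as exc:
            logger.info("attenuation correlation skipped: %s", exc)
    n_fk = int((de_fm["p"] < alpha).sum())
    return AttenuationReport(
        table=table[["gene_id", "delta_ms", "delta_fm", "p_fm"]],
        n_induced=n_induced,
        n_induced_reversed=n_rev,
        fraction_reversed=frac,
        n_fk_significant=n_fk,
        r=r,
    )


def heatmap_order(
    genes,
    de_ms: pd.DataFrame,
    de_invitro: pd.DataFrame,
    alpha: float,
) -> pd.DataFrame:
    """Order a gene set by insult-induced change for heatmap display.

    Sorted by the insult contrast's delta descending, ties broken by
    gene_id; each gene carries a boolean flag marking significance in the
    in vitro contrast (the asterisk of a published heatmap row label).
    """
    genes = list(genes)
    ms = de_ms.set_index("gene_id")
    missing = [g for g in genes if g not in ms.index]
    if missing:
        raise FormatError(f"gene {missing[0]!r} missing from insult contrast table")
    invitro_sig = set(
        de_invitro.loc[de_invitro["p"] < alpha, "gene_id"]
    )
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "delta_ms": ms.loc[genes, "delta"].to_numpy(),
        }
    )
    out["invitro_significant"] = out["gene_id"].isin(invitro_sig)
    return out.sort_values(
        ["delta_ms", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
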