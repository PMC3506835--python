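"""Rank-based Gene Ontology association over an effect-ranked gene list.

Genes passing the significance threshold in one contrast are ranked on
their log2 change (largest increase first).  Each GO term whose membership
inside the list falls within configured size bounds is scored by a
rank-sum comparison of in-term vs out-of-term positions; p-values are
Benjamini-Hochberg adjusted across the tested terms of that one list, and
each term receives a signed score ``sign * -log10(p_fdr)`` where the sign
marks association with the increased (+1) or decreased (-1) end of the
ranking — the plot-ready quantity for a divergent bar chart.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError
from .de_stats import bh_adjust, wilcoxon_rank
from .io_config import GOAnnotation

logger = logging.getLogger("crossde")

#: floor applied to adjusted p before the log10 transform
SCORE_P_FLOOR = 1e-300


def rank_genes(de: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Filter a differential table at p < alpha and rank on delta.

    Returns columns gene_id, delta, rank with rank 1 the largest increase;
    tied deltas share their average rank.  An empty result (nothing passes
    alpha) is returned as an empty frame and logged.
    """
    for col in ("gene_id", "delta", "p"):
        if col not in de.columns:
            raise FormatError(f"differential table missing column {col!r}")
    kept = de.loc[de["p"] < alpha, ["gene_id", "delta"]].copy()
    if kept.empty:
        logger.info("rank_genes: no gene passes alpha=%g", alpha)
        kept["rank"] = pd.Series(dtype=float)
        return kept.reset_index(drop=True)
    kept = kept.sort_values(
        ["delta", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    kept["rank"] = stats.rankdata(-kept["delta"].to_numpy(), method="average")
    return kept


def go_associations(
    ranked: pd.DataFrame,
    annotation: GOAnnotation,
    min_term_size: int = 2,
    max_term_size: int | None = None,
) -> pd.DataFrame:
    """Score every testable GO term against the ranked list.

    A term is testable when its in-list gene count lies in
    ``[min_term_size, max_term_size]`` (default upper bound: list size - 2,
    so that the out-group always keeps at least two members).  Returns a
    frame with term_id, term_name, n_genes, p, p_fdr, sign, signed_score
    sorted by signed_score descending.
    """
    if ranked.empty:
        logger.info("go_associations: empty ranked list, nothing to test")
        return _empty_go_table()
    list_genes = ranked["gene_id"].to_numpy()
    ranks = ranked["rank"].to_numpy()
    n_list = len(list_genes)
    upper = max_term_size if max_term_size is not None else n_list - 2
    in_list = set(list_genes)
    pairs = annotation.pairs
    pairs_in = pairs[pairs["gene_id"].isin(in_list)]
    rows = []
    for term_id, grp in pairs_in.groupby("term_id"):
        members = grp["gene_id"].unique()
        n = len(members)
        if n < min_term_size or n > upper or n_list - n < 1:
            continue
        member_mask = np.isin(list_genes, members)
        res = wilcoxon_rank(ranks[member_mask], ranks[~member_mask])
        rows.append(
            {
                "term_id": term_id,
                "term_name": annotation.term_name(term_id),
                "n_genes": n,
                "p": res.p,
                "sign": res.sign,
            }
        )
    if not rows:
        logger.info("go_associations: no testable term")
        return _empty_go_table()
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p"].to_numpy())
    floored = np.maximum(out["p_fdr"].to_numpy(), SCORE_P_FLOOR)
    if (out["p_fdr"].to_numpy() < SCORE_P_FLOOR).any():
        logger.info("go_associations: p_fdr floored at %g before log", SCORE_P_FLOOR)
    out["signed_score"] = out["sign"] * (-np.log10(floored))
    out = out[
        ["term_id", "term_name", "n_genes", "p", "p_fdr", "sign", "signed_score"]
    ]
    return out.sort_values(
        ["signed_score", "term_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _empty_go_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["term_id", "term_name", "n_genes", "p", "p_fdr", "sign", "signed_score"]
    )


def term_membership_counts(
    genes, annotation: GOAnnotation, terms: list[str]
) -> pd.DataFrame:
    """Venn-region counts of a gene set over <= 4 configured terms.

    Every nonempty term combination is one region; a gene falls in the
    region matching exactly its membership pattern, so the regions
    partition the subset of input genes annotated to at least one term.
    Returns a frame with columns terms (ampersand-joined), bitmask (one
    character per configured term) and count.
    """
    if len(terms) > 4:
        raise FormatError("term_membership_counts supports at most 4 terms")
    known = set(annotation.term_ids) | set(annotation.pairs["term_id"])
    for t in terms:
        if t not in known:
            raise FormatError(f"term {t!r} absent from annotation")
    gene_set = set(genes)
    memberships = {t: annotation.genes_for(t) & gene_set for t in terms}
    rows = []
    for combo in range(1, 2 ** len(terms)):
        mask = [(combo >> i) & 1 for i in range(len(terms))]
        inside = [t for t, m in zip(terms, mask) if m]
        outside = [t for t, m in zip(terms, mask) if not m]
        region = set.intersection(*(memberships[t] for t in inside))
        for t in outside:
            region -= memberships[t]
        rows.append(
            {
                "terms": "&".join(inside),
                "bitmask": "".join(str(m) for m in mask),
                "count": len(region),
            }
        )
    return pd.DataFrame(rows)


def write_go_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
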