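"""Readers and writers for the pipeline's on-disk artifacts.

All artifacts are tab-separated UTF-8 text with a header row:

* ``intensities.tsv`` / ``calls.tsv`` — probesets x samples, first column
  ``probeset_id``.  Intensities are linear-scale and nonnegative; calls are
  the per-hybridization detection flags ``P`` (present), ``M`` (marginal)
  or ``A`` (absent).
* ``design.tsv`` — columns ``sample_id``, ``experiment``, ``condition``,
  ``pair_id`` (``pair_id`` may be empty; when set it links exactly two
  samples of different conditions, e.g. a matched control/stimulated
  culture preparation).
* ``map.tsv`` — columns ``probeset_id``, ``gene_id``, ``gene_symbol``.
* ``annotation.tsv`` — columns ``gene_id``, ``term_id``;
  ``terms.tsv`` — columns ``term_id``, ``term_name``, ``parent_ids``
  (comma-joined, may be empty).

Gene-ontology annotations are kept as plain relational data; ancestor
expansion is performed here from the supplied parent table rather than by
parsing an ontology release, so the annotation used in any run is exactly
the one on disk.
"""

from __future__ import annotations

import dataclasses
import graphlib
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

logger = logging.getLogger("crossde")

VALID_CALLS = frozenset({"P", "M", "A"})

#: format used for linear-scale intensities on disk (6 significant digits)
INTENSITY_FMT = "%.6g"


def configure_logging(verbose: bool = False) -> None:
    """Set up stderr logging for CLI use (INFO by default)."""
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level, format="%(levelname)s %(name)s: %(message)s", force=True
    )


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ProbesetMatrix:
    """Raw linear-scale intensities plus detection calls, probesets x samples.

    ``intensity`` and ``calls`` are DataFrames with identical index
    (probeset ids) and columns (sample ids), both unique and order-preserving.
    """

    intensity: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        inten, calls = self.intensity, self.calls
        if list(inten.index) != list(calls.index):
            bad = _first_label_mismatch(inten.index, calls.index)
            raise FormatError(
                f"intensity/call probeset ids differ; first offending label: {bad!r}"
            )
        if list(inten.columns) != list(calls.columns):
            bad = _first_label_mismatch(inten.columns, calls.columns)
            raise FormatError(
                f"intensity/call sample ids differ; first offending label: {bad!r}"
            )
        if inten.index.duplicated().any():
            dup = inten.index[inten.index.duplicated()][0]
            raise FormatError(f"duplicate probeset_id {dup!r}")
        if inten.columns.duplicated().any():
            dup = inten.columns[inten.columns.duplicated()][0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        values = inten.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            _raise_at_bad_cell(inten, "non-numeric intensity")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"negative or non-finite intensity at probeset "
                f"{inten.index[i]!r}, sample {inten.columns[j]!r}"
            )
        callvals = calls.to_numpy().ravel()
        invalid = [v for v in pd.unique(callvals) if v not in VALID_CALLS]
        if invalid:
            raise FormatError(
                f"detection call not in {{P, M, A}}: {invalid[0]!r}"
            )

    @property
    def probeset_ids(self) -> list:
        return list(self.intensity.index)

    @property
    def sample_ids(self) -> list:
        return list(self.intensity.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclasses.dataclass
class GeneMatrix:
    """Gene-level log2 expression, genes x samples."""

    x: pd.DataFrame

    def __post_init__(self) -> None:
        if self.x.index.duplicated().any():
            dup = self.x.index[self.x.index.duplicated()][0]
            raise FormatError(f"duplicate gene_id {dup!r}")
        if not np.isfinite(self.x.to_numpy()).all():
            raise FormatError("gene matrix contains non-finite values")

    @property
    def gene_ids(self) -> list:
        return list(self.x.index)

    @property
    def sample_ids(self) -> list:
        return list(self.x.columns)


@dataclasses.dataclass
class StudyDesign:
    """Sample-to-condition assignment for one or more experiments."""

    table: pd.DataFrame  # sample_id, experiment, condition, pair_id

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "experiment", "condition", "pair_id"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FormatError(f"design missing column(s): {missing}")
        if len(t) == 0:
            raise FormatError("design has no samples")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r} in design")
        for pid, grp in t[t["pair_id"].notna() & (t["pair_id"] != "")].groupby(
            "pair_id"
        ):
            if len(grp) != 2:
                raise FormatError(
                    f"pair_id {pid!r} used by {len(grp)} samples (expected 2)"
                )
            if grp["condition"].nunique() != 2:
                raise FormatError(
                    f"pair_id {pid!r} links two samples of the same condition"
                )

    def subset(self, experiment: str) -> "StudyDesign":
        sub = self.table[self.table["experiment"] == experiment]
        if len(sub) == 0:
            raise FormatError(f"no samples for experiment {experiment!r}")
        return StudyDesign(sub.reset_index(drop=True))

    def samples_for(self, condition: str) -> list:
        return list(
            self.table.loc[self.table["condition"] == condition, "sample_id"]
        )

    @property
    def conditions(self) -> list:
        return list(pd.unique(self.table["condition"]))

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def pairs(self, cond_a: str, cond_b: str) -> list[tuple[str, str]]:
        """Matched (sample_a, sample_b) tuples for the two conditions.

        Samples without a pair_id, or paired with another condition, are
        excluded (logged).
        """
        t = self.table
        paired = t[t["pair_id"].notna() & (t["pair_id"] != "")]
        out = []
        for pid, grp in paired.groupby("pair_id"):
            conds = set(grp["condition"])
            if conds == {cond_a, cond_b}:
                sa = grp.loc[grp["condition"] == cond_a, "sample_id"].iloc[0]
                sb = grp.loc[grp["condition"] == cond_b, "sample_id"].iloc[0]
                out.append((sa, sb))
        n_unpaired = len(t[t["condition"].isin([cond_a, cond_b])]) - 2 * len(out)
        if n_unpaired:
            logger.info(
                "excluded %d unpaired sample(s) from %s/%s paired contrast",
                n_unpaired,
                cond_a,
                cond_b,
            )
        return sorted(out)


@dataclasses.dataclass
class ProbesetGeneMap:
    """Many-probesets-to-one-gene mapping."""

    table: pd.DataFrame  # probeset_id, gene_id, gene_symbol

    def __post_init__(self) -> None:
        t = self.table
        for col in ("probeset_id", "gene_id"):
            if col not in t.columns:
                raise FormatError(f"map missing column {col!r}")
        multi = t.drop_duplicates(["probeset_id", "gene_id"])
        counts = multi["probeset_id"].value_counts()
        if (counts > 1).any():
            bad = counts.index[counts > 1][0]
            raise FormatError(
                f"probeset {bad!r} maps to multiple gene_ids; one-to-many "
                "probeset mappings are rejected"
            )

    def gene_of(self) -> pd.Series:
        t = self.table.drop_duplicates("probeset_id")
        return pd.Series(t["gene_id"].values, index=t["probeset_id"].values)


@dataclasses.dataclass
class GOAnnotation:
    """Gene-to-term memberships plus term metadata.

    ``pairs`` holds unique (gene_id, term_id) rows; ``terms`` holds
    term_id, term_name and the comma-joined parent_ids.  After
    :func:`expand_annotation` the pairs are closed under the parent
    relation.
    """

    pairs: pd.DataFrame
    terms: pd.DataFrame

    def genes_for(self, term_id: str) -> set:
        return set(self.pairs.loc[self.pairs["term_id"] == term_id, "gene_id"])

    def term_name(self, term_id: str) -> str:
        hit = self.terms.loc[self.terms["term_id"] == term_id, "term_name"]
        return str(hit.iloc[0]) if len(hit) else term_id

    @property
    def term_ids(self) -> list:
        return list(self.terms["term_id"])


@dataclasses.dataclass
class PipelineConfig:
    """Run-level settings for the analysis stages."""

    alpha: float = 0.05
    seed: int = 0
    go_terms: tuple[str, ...] = (
        "GO:EXT",
        "GO:WOUND",
        "GO:IMMUNE",
        "GO:INFLAM",
    )
    min_term_size: int = 2
    max_term_size: int | None = None
    paths: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise FormatError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise FormatError(f"seed must be a nonnegative integer, got {self.seed}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _first_label_mismatch(a: Sequence, b: Sequence) -> object:
    sa, sb = list(a), list(b)
    only_a = [x for x in sa if x not in set(sb)]
    only_b = [x for x in sb if x not in set(sa)]
    if only_a:
        return only_a[0]
    if only_b:
        return only_b[0]
    # same labels, different order
    for x, y in zip(sa, sb):
        if x != y:
            return y
    return None


def _raise_at_bad_cell(df: pd.DataFrame, what: str) -> None:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"{what} at probeset {df.index[i]!r}, sample {col!r}: "
                f"{df[col].iloc[i]!r}"
            )
    raise FormatError(what)


def read_probeset_matrix(intensity_path, call_path) -> ProbesetMatrix:
    """Load a matched intensity/call TSV pair into a validated matrix."""
    inten = pd.read_csv(intensity_path, sep="\t", index_col=0, dtype=object)
    calls = pd.read_csv(call_path, sep="\t", index_col=0, dtype=str)
    try:
        inten = inten.astype(float)
    except (TypeError, ValueError):
        _raise_at_bad_cell(inten, "non-numeric intensity")
    return ProbesetMatrix(intensity=inten, calls=calls)


def write_probeset_matrix(pm: ProbesetMatrix, intensity_path, call_path) -> None:
    pm.intensity.to_csv(
        intensity_path, sep="\t", index_label="probeset_id",
        float_format=INTENSITY_FMT,
    )
    pm.calls.to_csv(call_path, sep="\t", index_label="probeset_id")


def read_design(path) -> StudyDesign:
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(t) == 0:
        raise FormatError("design has no samples")
    t["pair_id"] = t.get("pair_id", "")
    return StudyDesign(t)


def write_design(design: StudyDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gene_map(path) -> ProbesetGeneMap:
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ProbesetGeneMap(t)


def write_gene_map(pmap: ProbesetGeneMap, path) -> None:
    pmap.table.to_csv(path, sep="\t", index=False)


def read_gene_matrix(path) -> GeneMatrix:
    return GeneMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_gene_matrix(gm: GeneMatrix, path) -> None:
    gm.x.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(annotation_path, terms_path, expand: bool = True) -> GOAnnotation:
    pairs = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    terms = pd.read_csv(terms_path, sep="\t", dtype=str, keep_default_na=False)
    ann = GOAnnotation(pairs=pairs, terms=terms)
    return expand_annotation(ann.pairs, ann.terms) if expand else ann


def write_annotation(ann: GOAnnotation, annotation_path, terms_path) -> None:
    ann.pairs.to_csv(annotation_path, sep="\t", index=False)
    ann.terms.to_csv(terms_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO ancestor expansion
# ---------------------------------------------------------------------------


def _parent_map(terms: pd.DataFrame) -> dict[str, list[str]]:
    parents: dict[str, list[str]] = {}
    for _, row in terms.iterrows():
        raw = row.get("parent_ids", "") or ""
        parents[row["term_id"]] = [p for p in str(raw).split(",") if p]
    return parents


def expand_annotation(pairs: pd.DataFrame, terms: pd.DataFrame) -> GOAnnotation:
    """Close gene-term pairs under the term parent relation.

    If gene g is annotated to term t and t has parent u, the expanded
    annotation also contains (g, u); applied transitively.  Duplicates are
    removed.  A cycle in the parent relation is an error naming one term on
    the cycle.  Expansion is idempotent.
    """
    parents = _parent_map(terms)
    sorter = graphlib.TopologicalSorter(parents)
    try:
        sorter.prepare()
    except graphlib.CycleError as exc:
        cycle = exc.args[1]
        raise FormatError(
            f"cycle in GO parent relation involving term {cycle[0]!r}"
        ) from exc

    ancestors: dict[str, set[str]] = {}

    def anc(t: str) -> set[str]:
        if t not in ancestors:
            out: set[str] = set()
            for p in parents.get(t, []):
                out.add(p)
                out |= anc(p)
            ancestors[t] = out
        return ancestors[t]

    rows: set[tuple[str, str]] = set()
    for gene, term in zip(pairs["gene_id"], pairs["term_id"]):
        rows.add((gene, term))
        for a in anc(term):
            rows.add((gene, a))
    expanded = pd.DataFrame(sorted(rows), columns=["gene_id", "term_id"])
    return GOAnnotation(pairs=expanded, terms=terms.reset_index(drop=True))


# ---------------------------------------------------------------------------
# configuration file
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"alpha", "seed", "go_terms", "min_term_size", "max_term_size", "paths"}


def load_config(path) -> PipelineConfig:
    """Load a YAML config with keys alpha, seed, go_terms, min_term_size,
    max_term_size and paths.*"""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key in _CONFIG_KEYS - {"go_terms", "paths"}:
        if key in raw and raw[key] is not None:
            kwargs[key] = raw[key]
    if "go_terms" in raw and raw["go_terms"] is not None:
        kwargs["go_terms"] = tuple(raw["go_terms"])
    kwargs["paths"] = dict(raw.get("paths") or {})
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["go_terms"] = list(data["go_terms"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
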