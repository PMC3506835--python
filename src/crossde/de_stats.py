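"""Statistics kernel: per-gene tests, FDR procedures, correlation and
exact tests.

Implements the gene-wise tests used across the pipeline (Welch unpaired t,
paired t, one-way ANOVA), the Benjamini-Hochberg and Storey q-value FDR
procedures, Pearson correlation, a two-sided Fisher exact test for 2x2
tables, and the rank-sum comparison used by the GO association stage.
Everything is written from the defining formulas; only distribution
functions (t, F, normal, log-gamma) come from scipy.

Degenerate inputs (zero-variance genes) yield logged sentinel p-values
rather than exceptions, so a full-matrix run never aborts on one flat gene.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import FormatError
from .io_config import GeneMatrix, StudyDesign

logger = logging.getLogger("crossde")

#: sentinel for p-values that are exactly 0 in the limit (zero variance,
#: nonzero effect); smallest representable positive double
TINY_P = np.nextafter(0.0, 1.0)


class TestResult(NamedTuple):
    t_stat: float
    df: float
    p: float


class ContingencyTable2x2(NamedTuple):
    """Quadrant counts: rows = in vivo up/down, columns = in vitro up/down."""

    a: int  # up in both
    b: int  # up in vivo, down in vitro
    c: int  # down in vivo, up in vitro
    d: int  # down in both

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


class WilcoxonResult(NamedTuple):
    statistic: float  # rank sum of the in-group
    p: float  # two-sided
    sign: int  # +1 if the in-group sits toward the top (rank 1) end
    tail: float  # smaller one-sided tail probability


# ---------------------------------------------------------------------------
# t tests and ANOVA
# ---------------------------------------------------------------------------


def welch_t(xa: Sequence[float], xb: Sequence[float]) -> TestResult:
    """Two-sample t test with Welch-Satterthwaite degrees of freedom.

    Orientation: ``t = (mean(xb) - mean(xa)) / sqrt(sa^2/na + sb^2/nb)``,
    i.e. positive t means group B exceeds group A.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise FormatError("welch_t requires >= 2 values per group")
    t, df, p = _welch_from_moments(
        xa.mean(), xa.var(ddof=1), xa.size, xb.mean(), xb.var(ddof=1), xb.size
    )
    return TestResult(float(t), float(df), float(p))


def _welch_from_moments(ma, va, na, mb, vb, nb):
    """Vector-safe Welch t from group means/variances/sizes."""
    ma, va = np.asarray(ma, float), np.asarray(va, float)
    mb, vb = np.asarray(mb, float), np.asarray(vb, float)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = se2 == 0
    if np.any(degenerate):
        n_deg = int(np.count_nonzero(degenerate))
        logger.info("welch_t: %d zero-variance case(s), sentinel p used", n_deg)
    with np.errstate(invalid="ignore"):
        t = np.where(
            degenerate, np.where(mb == ma, 0.0, np.inf * np.sign(mb - ma)), t
        )
    df = np.where(degenerate, float(na + nb - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (mb != ma), TINY_P, p)
    p = np.where(degenerate & (mb == ma), 1.0, p)
    return t, df, p


def paired_t(diffs: Sequence[float]) -> TestResult:
    """One-sample t test of per-pair differences against zero mean."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise FormatError("paired_t requires >= 2 pairs")
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            logger.info("paired_t: all differences zero; p = 1")
            return TestResult(0.0, float(n - 1), 1.0)
        logger.info("paired_t: constant nonzero differences; sentinel p used")
        return TestResult(math.copysign(math.inf, d.mean()), float(n - 1), TINY_P)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(n - 1), float(p))


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects F test across >= 2 groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise FormatError("anova_oneway requires >= 2 groups of >= 2 values")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df1 = len(arrs) - 1
    df2 = allv.size - len(arrs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        logger.info("anova_oneway: zero within-group variance; sentinel p used")
        return math.inf, TINY_P
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def _check_pvalues(p: np.ndarray) -> None:
    if p.size and ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise FormatError(f"p-value outside [0, 1]: {bad}")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def storey_qvalues(
    p: Sequence[float], lambdas: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    lambda = 0.05, 0.10, ..., 0.90, smoothed with a cubic fit and evaluated
    at lambda = 0.90, then clamped to (0, 1].  For fewer than 100 p-values
    the smoother is unreliable and pi0 is fixed at 1 (logged), making the
    q-values identical to Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    _check_pvalues(p)
    m = p.size
    if m == 0:
        return p.copy(), 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.9001, 0.05)
    if m < 100:
        logger.info("storey_qvalues: m=%d < 100, pi0 fixed at 1", m)
        pi0 = 1.0
    else:
        pi0_lambda = np.array(
            [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
        )
        coef = np.polyfit(lambdas, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
        if pi0 > 1.0:
            pi0 = 1.0
        if pi0 <= 0.0:
            logger.info("storey_qvalues: pi0 estimate <= 0, clamped")
            pi0 = float(np.nextafter(0.0, 1.0))
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    raw = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with the t-transform p-value (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise FormatError("pearson_r requires two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FormatError("pearson_r: constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(tab: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is <= that of the observed table (within
    relative tolerance 1e-7).  Probabilities are computed in log space so
    large counts do not overflow.  Any zero margin makes the table
    degenerate and returns p = 1.
    """
    a, b, c, d = (int(v) for v in tab)
    if min(a, b, c, d) < 0:
        raise FormatError("contingency counts must be nonnegative")
    n = a + b + c + d
    if n < 1:
        raise FormatError("contingency table is empty")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        logger.info("fisher_exact_2x2: zero margin, p = 1")
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    k = np.arange(kmin, kmax + 1)
    logpmf = (
        _log_comb(r1, k)
        + _log_comb(r2, c1 - k)
        - _log_comb(n, c1)
    )
    obs = logpmf[a - kmin]
    p = float(np.exp(logpmf[logpmf <= obs + math.log1p(1e-7)]).sum())
    return min(p, 1.0)


def _log_comb(n, k):
    n = np.asarray(n, float)
    k = np.asarray(k, float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# rank-sum comparison (GO association)
# ---------------------------------------------------------------------------

EXACT_WILCOXON_MAX_N = 12


def wilcoxon_rank(
    in_ranks: Sequence[float], out_ranks: Sequence[float]
) -> WilcoxonResult:
    """Rank-sum comparison of in-category vs out-of-category positions.

    Both groups carry (average, tie-shared) ranks from one common ranked
    list in which rank 1 is the top — the most increased expression.  The
    statistic is the in-group rank sum W.  For total list length <= 12 the
    exact permutation null of W (all subsets of the observed rank multiset)
    is computed by dynamic programming; otherwise a normal approximation
    with tie correction and continuity correction is used.

    Two-sided p is the probability of |W - E[W]| at least as large as
    observed; ``tail`` is the smaller one-sided tail.  ``sign`` is +1 when
    the in-group mean rank is at or above the top (increased) end relative
    to the out-group, else -1.
    """
    rin = np.asarray(in_ranks, dtype=float)
    rout = np.asarray(out_ranks, dtype=float)
    if rin.size == 0 or rout.size == 0:
        raise FormatError("wilcoxon_rank: both groups must be nonempty")
    n1, n2 = rin.size, rout.size
    ntot = n1 + n2
    allr = np.concatenate([rin, rout])
    w = float(rin.sum())
    mu = n1 * allr.sum() / ntot
    # rank 1 = most increased; a smaller mean rank means "up" association
    sign = 1 if rin.mean() <= rout.mean() else -1

    if ntot <= EXACT_WILCOXON_MAX_N:
        p, tail = _exact_ranksum_p(allr, n1, w, mu)
    else:
        p, tail = _normal_ranksum_p(allr, n1, n2, w, mu)
    return WilcoxonResult(w, p, sign, tail)


def _exact_ranksum_p(allr: np.ndarray, n1: int, w: float, mu: float):
    """Exact two-sided p over all C(N, n1) subsets, DP on doubled ranks."""
    r2 = np.rint(allr * 2).astype(int)  # average ranks are half-integers
    total2 = int(r2.sum())
    # ways[k, s] = number of size-k subsets with doubled-rank sum s
    ways = np.zeros((n1 + 1, total2 + 1))
    ways[0, 0] = 1.0
    for v in r2:
        ways[1:, v:] += ways[:-1, : total2 + 1 - v]
    dist = ways[n1]
    ncomb = dist.sum()
    w2 = w * 2
    mu2 = mu * 2
    dev = abs(w2 - mu2)
    sums = np.arange(total2 + 1)
    eps = 1e-9
    p = dist[np.abs(sums - mu2) >= dev - eps].sum() / ncomb
    lo = dist[sums <= w2 + eps].sum() / ncomb
    hi = dist[sums >= w2 - eps].sum() / ncomb
    return min(float(p), 1.0), float(min(lo, hi))


def _normal_ranksum_p(allr: np.ndarray, n1: int, n2: int, w: float, mu: float):
    """Normal approximation with tie and continuity corrections."""
    ntot = n1 + n2
    _, counts = np.unique(allr, return_counts=True)
    tie_term = (counts.astype(float) ** 3 - counts).sum() / (ntot * (ntot - 1))
    var = n1 * n2 / 12.0 * ((ntot + 1) - tie_term)
    if var <= 0:
        logger.info("wilcoxon_rank: zero variance (all ranks tied), p = 1")
        return 1.0, 0.5
    dev = w - mu
    cc = 0.5 if abs(dev) > 0.5 else abs(dev)  # continuity correction
    z = (abs(dev) - cc) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(z)
    tail = stats.norm.sf((dev - math.copysign(cc, dev)) / math.sqrt(var))
    tail = tail if dev > 0 else 1.0 - tail
    # smaller one-sided tail
    tail = min(tail, 1.0 - tail) if dev != 0 else 0.5
    return min(float(p), 1.0), float(tail)


# ---------------------------------------------------------------------------
# gene-wise tables
# ---------------------------------------------------------------------------


def _finalize_table(
    gene_ids, delta, t_stat, df, p, contrast: str
) -> pd.DataFrame:
    q, _ = storey_qvalues(np.asarray(p))
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "contrast": contrast,
            "delta": delta,
            "t_stat": t_stat,
            "df": df,
            "p": p,
            "q": q,
        }
    )
    return out.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)


def welch_table(
    gm: GeneMatrix, design: StudyDesign, cond_a: str, cond_b: str
) -> pd.DataFrame:
    """Gene-wise Welch t table for contrast ``cond_b - cond_a``.

    delta is mean(cond_b) - mean(cond_a) on the log2 scale.  The contrast
    label is ``"{cond_b}-{cond_a}"``.
    """
    sa = [s for s in design.samples_for(cond_a) if s in gm.x.columns]
    sb = [s for s in design.samples_for(cond_b) if s in gm.x.columns]
    if len(sa) < 2 or len(sb) < 2:
        raise FormatError(
            f"welch_table: conditions {cond_a!r}/{cond_b!r} need >= 2 samples"
        )
    xa = gm.x[sa].to_numpy()
    xb = gm.x[sb].to_numpy()
    t, df, p = _welch_from_moments(
        xa.mean(axis=1),
        xa.var(axis=1, ddof=1),
        xa.shape[1],
        xb.mean(axis=1),
        xb.var(axis=1, ddof=1),
        xb.shape[1],
    )
    delta = xb.mean(axis=1) - xa.mean(axis=1)
    return _finalize_table(gm.gene_ids, delta, t, df, p, f"{cond_b}-{cond_a}")


def paired_table(
    gm: GeneMatrix, design: StudyDesign, cond_a: str, cond_b: str
) -> pd.DataFrame:
    """Gene-wise paired t table for matched ``cond_b - cond_a`` samples."""
    pairs = design.pairs(cond_a, cond_b)
    pairs = [
        (a, b) for a, b in pairs if a in gm.x.columns and b in gm.x.columns
    ]
    if len(pairs) < 2:
        raise FormatError("paired_table requires >= 2 matched pairs")
    xa = gm.x[[a for a, _ in pairs]].to_numpy()
    xb = gm.x[[b for _, b in pairs]].to_numpy()
    d = xb - xa
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    zero_sd = sd == 0
    t = np.where(zero_sd, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(zero_sd & (mean != 0), TINY_P, p)
    p = np.where(zero_sd & (mean == 0), 1.0, p)
    if zero_sd.any():
        logger.info("paired_table: %d zero-variance gene(s)", int(zero_sd.sum()))
    df = np.full(len(mean), float(n - 1))
    return _finalize_table(gm.gene_ids, mean, t, df, p, f"{cond_b}-{cond_a}")


def anova_table(
    gm: GeneMatrix, design: StudyDesign, conditions: Sequence[str]
) -> pd.DataFrame:
    """Gene-wise one-way ANOVA screen across the given conditions."""
    groups = []
    for cond in conditions:
        samples = [s for s in design.samples_for(cond) if s in gm.x.columns]
        if len(samples) < 2:
            raise FormatError(f"anova_table: condition {cond!r} needs >= 2 samples")
        groups.append(gm.x[samples].to_numpy())
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    ntot = int(ns.sum())
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = sum(g.sum(axis=1) for g in groups) / ntot
    ssb = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    df1, df2 = k - 1, ntot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    zero_w = ssw == 0
    f = np.where(zero_w, np.where(ssb == 0, 0.0, np.inf), f)
    p = np.where(zero_w & (ssb == 0), 1.0, p)
    p = np.where(zero_w & (ssb > 0), TINY_P, p)
    q, _ = storey_qvalues(p)
    out = pd.DataFrame(
        {
            "gene_id": gm.gene_ids,
            "contrast": "anova:" + "/".join(conditions),
            "f_stat": f,
            "df1": df1,
            "df2": df2,
            "p": p,
            "q": q,
        }
    )
    return out.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)


def write_differential(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_differential(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
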