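"""Reference-gene stability ranking and candidate-gene group discrimination.

Implements the four standard qPCR reference-gene stability algorithms on a
genes x samples Cq table:

* geNorm — pairwise-variation M value with iterative exclusion of the
  least stable gene and the V(n/n+1) criterion for the optimal number of
  reference genes;
* NormFinder-style — variance decomposition of sample-centered log
  quantities into intragroup variance and intergroup bias;
* BestKeeper — raw-Cq standard deviation plus Pearson correlation with
  the BestKeeper index (per-sample geometric mean of Cq);
* comparative delta-Ct — mean SD of pairwise Cq differences.

A composite ranking averages the per-method ranks (arithmetic mean by
default, geometric variant reported alongside).  The candidate-gene arm
normalizes genes of interest by the geometric mean Cq of chosen reference
genes and tests group discrimination with Bartlett's and
Wilcoxon-Mann-Whitney tests under Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import bh_adjust

#: conventional geNorm pairwise-variation cut-off for "no extra gene needed"
GENORM_V_CUTOFF = 0.15


def _as_frame(cq: pd.DataFrame) -> pd.DataFrame:
    cq = pd.DataFrame(cq).astype(float)
    if not np.isfinite(cq.to_numpy()).all():
        raise ValueError("Cq table contains non-finite values")
    return cq


def relative_quantities(cq: pd.DataFrame, efficiency: pd.Series | float = 2.0) -> pd.DataFrame:
    """Efficiency-corrected relative quantities Q = E^(min Cq - Cq), max 1 per gene.

    The per-gene amplification efficiency E is the fold increase per
    cycle (2.0 = perfect doubling); the gene's most-expressed sample
    (lowest Cq) is the reference with Q = 1.
    """
    cq = _as_frame(cq)
    if np.isscalar(efficiency):
        eff = pd.Series(float(efficiency), index=cq.index)
    else:
        eff = pd.Series(efficiency).astype(float).reindex(cq.index)
        if eff.isna().any():
            raise ValueError("efficiency missing for some genes")
    if ((eff <= 1) | (eff > 2.2)).any():
        raise ValueError("efficiencies must lie in (1, 2.2]")
    delta = cq.min(axis=1).to_numpy()[:, None] - cq.to_numpy()
    q = np.power(eff.to_numpy()[:, None], delta)
    return pd.DataFrame(q, index=cq.index, columns=cq.columns)


# ---------------------------------------------------------------------------
# geNorm

@dataclass
class GenormResult:
    m_values: pd.Series            # M from the full gene set
    ranking: list[str]             # most stable first; final pair shares rank 1
    ranks: pd.Series               # integer ranks (final pair both 1)
    pairwise_v: pd.Series          # V(n/n+1) indexed "V2/3", ...
    optimal_n: int | None          # smallest n with V(n/n+1) < cut-off


def _genorm_m(logq: pd.DataFrame) -> pd.Series:
    """M_j = mean over partners k of SD(log2 Q_j - log2 Q_k)."""
    genes = list(logq.index)
    values = logq.to_numpy()
    m = np.zeros(len(genes))
    for j in range(len(genes)):
        sds = [np.std(values[j] - values[k], ddof=1)
               for k in range(len(genes)) if k != j]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=genes, name="genorm_m")


def genorm(q: pd.DataFrame) -> GenormResult:
    """geNorm stability analysis on relative quantities.

    M values are reported for the full gene set; the ranking comes from
    iteratively excluding the highest-M gene (recomputing M each round)
    until two genes remain, which share rank 1.  V(n/n+1) is the SD
    across samples of log2(NF_n / NF_{n+1}), NF_n being the per-sample
    geometric mean of the n best genes' quantities.
    """
    q = _as_frame(q)
    if (q.to_numpy() <= 0).any():
        raise ValueError("quantities must be strictly positive")
    if q.shape[0] < 3:
        raise ValueError("geNorm requires at least 3 genes")
    if q.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 samples")

    logq = np.log2(q)
    m_full = _genorm_m(logq)

    remaining = logq.copy()
    excluded: list[str] = []
    while remaining.shape[0] > 2:
        m = _genorm_m(remaining)
        worst = m.sort_values(kind="stable").index[-1]
        excluded.append(worst)
        remaining = remaining.drop(index=worst)
    ranking = list(remaining.index) + excluded[::-1]

    ranks = pd.Series(0, index=ranking, dtype=int, name="rank_genorm")
    ranks.iloc[0] = ranks.iloc[1] = 1            # final pair is unresolvable
    for i in range(2, len(ranking)):
        ranks.iloc[i] = i + 1
    ranks = ranks.reindex(q.index)

    v_values, v_index = [], []
    for n in range(2, q.shape[0]):
        nf_n = logq.loc[ranking[:n]].mean(axis=0)
        nf_n1 = logq.loc[ranking[: n + 1]].mean(axis=0)
        v_values.append(float(np.std(nf_n - nf_n1, ddof=1)))
        v_index.append(f"V{n}/{n + 1}")
    pairwise_v = pd.Series(v_values, index=v_index, name="pairwise_v")

    optimal_n = None
    for n, v in zip(range(2, q.shape[0]), v_values):
        if v < GENORM_V_CUTOFF:
            optimal_n = n
            break
    return GenormResult(m_values=m_full, ranking=ranking, ranks=ranks,
                        pairwise_v=pairwise_v, optimal_n=optimal_n)


# ---------------------------------------------------------------------------
# NormFinder-style

def normfinder(q: pd.DataFrame, groups: pd.Series | None = None) -> pd.Series:
    """NormFinder-style stability values (lower = more stable).

    Works on log2 quantities centered per sample (removing the common
    sample effect).  With group labels, SV combines the mean absolute
    intergroup deviation and the mean standard error of the intragroup
    variation: SV_i = mean_g |d_ig| + mean_g sqrt(v_ig / n_g).  Without
    usable groups it reduces to the SD of the centered values.  Groups
    with a single sample are excluded with a warning.
    """
    q = _as_frame(q)
    if (q.to_numpy() <= 0).any():
        raise ValueError("quantities must be strictly positive")
    if q.shape[0] < 2:
        raise ValueError("NormFinder requires at least 2 genes")
    y = np.log2(q.to_numpy())
    z = y - y.mean(axis=0, keepdims=True)       # remove common sample effect
    zf = pd.DataFrame(z, index=q.index, columns=q.columns)

    usable: list[str] = []
    if groups is not None:
        groups = pd.Series(groups).reindex(q.columns)
        if groups.isna().any():
            raise ValueError("group labels missing for some samples")
        for g, cols in groups.groupby(groups).groups.items():
            if len(cols) < 2:
                warnings.warn(f"NormFinder: group {g!r} has a single sample; excluded")
            else:
                usable.append(g)

    if groups is None or len(usable) < 2:
        sv = zf.std(axis=1, ddof=1)
        sv.name = "normfinder_sv"
        return sv

    m_ig, se_ig = [], []
    for g in usable:
        cols = groups.index[groups == g]
        sub = zf[cols]
        n_g = sub.shape[1]
        m_ig.append(sub.mean(axis=1))
        se_ig.append(np.sqrt(sub.var(axis=1, ddof=1) / n_g))
    m_ig = pd.concat(m_ig, axis=1)
    se_ig = pd.concat(se_ig, axis=1)
    d_ig = m_ig.sub(m_ig.mean(axis=1), axis=0)
    sv = d_ig.abs().mean(axis=1) + se_ig.mean(axis=1)
    sv.name = "normfinder_sv"
    return sv


# ---------------------------------------------------------------------------
# BestKeeper

@dataclass
class BestkeeperResult:
    sd: pd.Series                  # sample SD of raw Cq per gene
    r: pd.Series                   # Pearson correlation with the BestKeeper index
    r_pvalue: pd.Series
    index: pd.Series               # BKI: per-sample geometric mean of Cq
    unstable: pd.Series            # SD > 1 flag (tool convention)


def bestkeeper(cq: pd.DataFrame) -> BestkeeperResult:
    """BestKeeper descriptive stability: raw-Cq SD and correlation with the BKI.

    Unlike geNorm/NormFinder this operates on raw Cq values (documented
    tool behaviour), so it is *not* invariant to per-sample shifts.
    Genes with SD > 1 cycle are flagged as unstable.  When the BKI has
    zero variance the correlations are undefined and reported as NaN.
    """
    cq = _as_frame(cq)
    if cq.shape[0] < 2:
        raise ValueError("BestKeeper requires at least 2 genes")
    sd = cq.std(axis=1, ddof=1)
    sd.name = "bestkeeper_sd"
    bki = pd.Series(np.exp(np.log(cq.to_numpy()).mean(axis=0)),
                    index=cq.columns, name="bestkeeper_index")

    r_vals, p_vals = [], []
    bki_arr = bki.to_numpy()
    degenerate = np.std(bki_arr) == 0
    for gene in cq.index:
        x = cq.loc[gene].to_numpy()
        if degenerate or np.std(x) == 0:
            r_vals.append(np.nan)
            p_vals.append(np.nan)
        else:
            r, p = stats.pearsonr(x, bki_arr)
            r_vals.append(r)
            p_vals.append(p)
    r = pd.Series(r_vals, index=cq.index, name="bestkeeper_r")
    p = pd.Series(p_vals, index=cq.index, name="bestkeeper_r_pvalue")
    return BestkeeperResult(sd=sd, r=r, r_pvalue=p, index=bki, unstable=sd > 1.0)


# ---------------------------------------------------------------------------
# comparative delta-Ct

def delta_ct_stability(cq: pd.DataFrame) -> pd.Series:
    """Mean over partner genes of SD across samples of the pairwise Cq difference."""
    cq = _as_frame(cq)
    if cq.shape[0] < 2:
        raise ValueError("delta-Ct requires at least 2 genes")
    genes = list(cq.index)
    values = cq.to_numpy()
    score = np.zeros(len(genes))
    for j in range(len(genes)):
        sds = [np.std(values[j] - values[k], ddof=1)
               for k in range(len(genes)) if k != j]
        score[j] = float(np.mean(sds))
    return pd.Series(score, index=genes, name="delta_ct_sd")


# ---------------------------------------------------------------------------
# composite ranking

def rank_min_ties(values: pd.Series, ascending: bool = True) -> pd.Series:
    """Integer ranks, ties sharing the minimum rank (1 = best)."""
    v = values if ascending else -values
    return pd.Series(stats.rankdata(v.to_numpy(), method="min").astype(int),
                     index=values.index)


@dataclass
class StabilityReport:
    table: pd.DataFrame            # per-gene measures, ranks, composite ranking
    pairwise_v: pd.Series
    optimal_n: int | None
    methods_included: tuple = ("genorm", "normfinder", "bestkeeper")


def composite_rank(
    method_ranks: pd.DataFrame,
    methods_included: tuple = ("genorm", "normfinder", "bestkeeper"),
    genorm_tiebreak: pd.Series | None = None,
) -> pd.DataFrame:
    """Arithmetic-mean composite ranking (geometric variant alongside).

    ``method_ranks`` holds one integer-rank column per method
    (rank_<method>); the composite orders genes by the arithmetic mean
    of the included methods' ranks, ties broken by geNorm rank then gene
    label.
    """
    cols = [f"rank_{m}" for m in methods_included]
    missing = [c for c in cols if c not in method_ranks.columns]
    if missing:
        raise ValueError(f"missing method rank columns: {missing}")
    sub = method_ranks[cols].astype(float)
    if sub.isna().any().any():
        raise ValueError("incomplete ranking for an included method")
    out = method_ranks.copy()
    out["ranking_mean"] = sub.mean(axis=1)
    out["ranking_geomean"] = np.exp(np.log(sub).mean(axis=1))
    tiebreak = (genorm_tiebreak if genorm_tiebreak is not None
                else out.get("rank_genorm", pd.Series(0, index=out.index)))
    order = (pd.DataFrame({"mean": out["ranking_mean"], "tb": tiebreak,
                           "gene": out.index.astype(str)})
             .sort_values(["mean", "tb", "gene"], kind="stable").index)
    final = pd.Series(np.arange(1, len(order) + 1), index=order)
    out["final_rank"] = final.reindex(out.index)
    return out


def stability_report(
    cq: pd.DataFrame,
    efficiency: pd.Series | float = 2.0,
    groups: pd.Series | None = None,
    include_delta_ct: bool = False,
) -> StabilityReport:
    """Run all stability algorithms and assemble the composite ranking table.

    The default composite averages the geNorm, NormFinder and BestKeeper
    ranks; ``include_delta_ct=True`` adds the comparative delta-Ct rank
    to the mean.
    """
    cq = _as_frame(cq)
    q = relative_quantities(cq, efficiency)
    gn = genorm(q)
    sv = normfinder(q, groups)
    bk = bestkeeper(cq)
    dct = delta_ct_stability(cq)

    table = pd.DataFrame({
        "genorm_m": gn.m_values,
        "normfinder_sv": sv,
        "bestkeeper_sd": bk.sd,
        "bestkeeper_r": bk.r,
        "bestkeeper_r_pvalue": bk.r_pvalue,
        "delta_ct_sd": dct,
        "rank_genorm": gn.ranks,
        "rank_normfinder": rank_min_ties(sv),
        "rank_bestkeeper": rank_min_ties(bk.sd),
        "rank_delta_ct": rank_min_ties(dct),
    })
    methods = ("genorm", "normfinder", "bestkeeper")
    if include_delta_ct:
        methods = methods + ("delta_ct",)
    table = composite_rank(table, methods_included=methods,
                           genorm_tiebreak=table["rank_genorm"])
    table = table.sort_values("final_rank", kind="stable")
    return StabilityReport(table=table, pairwise_v=gn.pairwise_v,
                           optimal_n=gn.optimal_n, methods_included=methods)


# ---------------------------------------------------------------------------
# genes of interest

def normalize_goi(
    cq_goi: pd.DataFrame, cq_refs: pd.DataFrame, mean: str = "quantity"
) -> pd.DataFrame:
    """Normalize candidate-gene Cq against reference genes (delta-Cq).

    Default ``mean='quantity'`` subtracts the per-sample arithmetic mean
    of the reference Cq values — the Cq-scale equivalent of dividing by
    the geometric mean of reference *quantities* (the geNorm
    normalization-factor convention) — which makes the result exactly
    invariant to adding a constant cycle shift to every gene of a
    sample.  ``mean='geometric_cq'`` takes the geometric mean of the Cq
    values themselves (the literal reading; only approximately
    shift-invariant).  Lower normalized values mean higher expression.
    """
    cq_goi = _as_frame(cq_goi)
    cq_refs = _as_frame(cq_refs)
    if list(cq_goi.columns) != list(cq_refs.columns):
        raise ValueError("GOI and reference tables must share the same samples")
    if mean == "quantity":
        ref_mean = cq_refs.to_numpy().mean(axis=0)
    elif mean == "geometric_cq":
        ref_mean = np.exp(np.log(cq_refs.to_numpy()).mean(axis=0))
    else:
        raise ValueError("mean must be 'quantity' or 'geometric_cq'")
    return cq_goi - ref_mean


def goi_group_tests(
    normalized: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bartlett + Wilcoxon-Mann-Whitney group discrimination per gene.

    Both test families are Benjamini-Hochberg adjusted across genes
    separately; a gene is flagged ``reliable`` when both adjusted
    p-values are <= alpha (the both-tests-significant rule).  The
    Wilcoxon test is exact for small tie-free samples (both n <= 25),
    asymptotic with tie correction otherwise.  Degenerate genes
    (identical values everywhere) get Wilcoxon p = 1 and a missing
    Bartlett p.
    """
    normalized = _as_frame(normalized)
    groups = pd.Series(groups).reindex(normalized.columns)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    cols_a = groups.index[groups == levels[0]]
    cols_b = groups.index[groups == levels[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    rows = []
    for gene in normalized.index:
        a = normalized.loc[gene, cols_a].to_numpy()
        b = normalized.loc[gene, cols_b].to_numpy()
        pooled = np.concatenate((a, b))
        if np.ptp(pooled) == 0:
            rows.append((np.nan, 1.0))
            continue
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            bart_p = np.nan
        else:
            bart_p = stats.bartlett(a, b).pvalue
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (len(a) <= 25 and len(b) <= 25 and not has_ties) else "asymptotic"
        wil_p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        rows.append((bart_p, wil_p))

    out = pd.DataFrame(rows, index=normalized.index,
                       columns=["bartlett_p", "wilcoxon_p"])
    out["bartlett_p_adjusted"] = bh_adjust(out["bartlett_p"])
    out["wilcoxon_p_adjusted"] = bh_adjust(out["wilcoxon_p"])
    out["reliable"] = ((out["bartlett_p_adjusted"] <= alpha)
                       & (out["wilcoxon_p_adjusted"] <= alpha)).fillna(False)
    return out
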