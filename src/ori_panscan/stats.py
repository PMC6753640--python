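"""Statistical procedures used across the pipeline.

Thin, explicitly-parameterized wrappers over scipy / statsmodels /
scikit-learn: one-sided Mann-Whitney U (exact below a sample-size cutoff,
midrank normal approximation with tie and continuity corrections above),
Pearson correlation, pairwise rank-sum comparisons with multiplicity
correction, Fisher's-exact term enrichment with Benjamini-Hochberg FDR,
ordinary least squares and PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    alternative: str  # less | greater | two-sided
    n1: int
    n2: int
    method: str  # exact | normal_approx

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # list genes with term
    K: int  # background genes with term
    n: int  # list size
    N: int  # background size
    odds_ratio: float
    p_value: float
    fdr_adjusted_p: float
    significant: bool


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_cutoff: int = 25,
) -> TestReport:
    """Mann-Whitney U test of ``x`` against ``y``.

    The exact null distribution is used when both samples are at or below
    ``exact_cutoff`` and the pooled data are tie-free; otherwise the midrank
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    use_exact = (
        len(x) <= exact_cutoff and len(y) <= exact_cutoff and not _has_ties(x, y)
    )
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestReport(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n1=len(x),
        n2=len(y),
        method="exact" if use_exact else "normal_approx",
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]],
    correction: str = "holm",
    exact_cutoff: int = 25,
):
    """All-pairs two-sided rank-sum tests with multiplicity correction.

    ``correction`` is ``holm`` or ``bh``.  Returns a DataFrame of adjusted
    p-values indexed/columned by group name (NaN diagonal).
    """
    import pandas as pd

    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name in names:
        if len(groups[name]) == 0:
            raise ValueError(f"group {name!r} is empty")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw = [
        mann_whitney_u(groups[a], groups[b], "two-sided", exact_cutoff).p_value
        for a, b in pairs
    ]
    method = {"holm": "holm", "bh": "fdr_bh"}[correction]
    adjusted = multipletests(raw, method=method)[1] if raw else np.array([])
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), p in zip(pairs, adjusted):
        out.loc[a, b] = out.loc[b, a] = p
    return out


def fisher_enrichment(
    gene_list: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, set[str] | frozenset[str] | list[str]],
    fdr_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher's-exact term enrichment of ``gene_list`` vs background.

    Per term the 2x2 table is [[k, n-k], [K-k, N-n-K+k]]; p-values are BH
    adjusted and ``significant`` flags results at ``fdr_cutoff``.  The full
    table is returned regardless of significance.
    """
    gene_list = list(dict.fromkeys(gene_list))
    background = list(dict.fromkeys(background))
    bg = set(background)
    missing = [g for g in gene_list if g not in bg]
    if missing:
        raise ValueError(f"genes not in background: {missing}")
    n, N = len(gene_list), len(background)
    listed = set(gene_list)
    terms: dict[str, tuple[int, int]] = {}
    for gene in background:
        for term in term_map.get(gene, ()):  # genes without terms allowed
            k, K = terms.get(term, (0, 0))
            terms[term] = (k + (gene in listed), K + 1)
    if not terms:
        return []
    term_ids = sorted(terms)
    raws, odds = [], []
    for term in term_ids:
        k, K = terms[term]
        table = [[k, n - k], [K - k, N - n - K + k]]
        odd, p = sps.fisher_exact(table, alternative="greater")
        raws.append(p)
        odds.append(odd)
    adjusted = multipletests(raws, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term_id=term,
            k=terms[term][0],
            K=terms[term][1],
            n=n,
            N=N,
            odds_ratio=float(o),
            p_value=float(p),
            fdr_adjusted_p=float(q),
            significant=bool(q <= fdr_cutoff),
        )
        for term, o, p, q in zip(term_ids, odds, raws, adjusted)
    ]
    results.sort(key=lambda r: r.p_value)
    return results


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares y = slope*x + intercept; returns (slope, intercept, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def pca(feature_matrix, standardize: bool = True):
    """PCA of a samples x features matrix.

    Columns are centered (and scaled to unit variance when ``standardize``).
    Component signs are fixed so the largest-magnitude loading of each
    component is positive.  Returns (scores, loadings, explained_fractions);
    loadings has shape (n_components, n_features).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2D matrix with >=2 rows and >=2 columns")
    if np.isnan(X).any():
        raise ValueError("missing values; apply a policy before PCA")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        bad = np.where(sd == 0)[0]
        if len(bad):
            raise ValueError(f"constant column(s) under standardization: {bad.tolist()}")
        X = X / sd
    model = PCA()
    scores = model.fit_transform(X)
    loadings = model.components_
    # deterministic sign convention
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return scores, loadings, model.explained_variance_ratio_
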