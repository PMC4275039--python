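"""Hub vs non-hub and centrality-by-selection-class comparisons.

The tests of record are the Wilcoxon rank-sum test (exact by enumeration
for small untied samples, normal approximation with tie and continuity
corrections otherwise) and the 2x2 chi-square test with Yates correction.
Hub-vs-non-hub gamma comparisons are one-tailed (hubs expected to be under
stronger negative selection); all other comparisons are two-tailed.  Each
comparison row carries n, mean and SEM per group so bar-plot style
summaries can be regenerated from the output alone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclass
class GroupComparison:
    comparison_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    test: str
    alternative: str
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided"
                      ) -> tuple[float, float]:
    """Rank-sum test; returns (rank sum of x with midranks, p-value).

    The p-value is exact (full enumeration) when both samples have at most
    8 observations and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction is used.
    ``alternative="less"`` means x tends to be smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    alt = _ALTERNATIVES[alternative]
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method,
                             use_continuity=True)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:len(x)].sum())
    return w, float(res.pvalue)


def chi_square_2x2(table, correction: bool = True) -> tuple[float, float]:
    """Chi-square test of a 2x2 table (Yates-corrected by default)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("a zero margin leaves expected counts undefined")
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def _one_comparison(comparison_id, label_a, label_b, a, b, test,
                    alternative, statistic, p) -> GroupComparison:
    return GroupComparison(
        comparison_id=comparison_id, group_a=label_a, group_b=label_b,
        n_a=len(a), n_b=len(b),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        sem_a=_sem(np.asarray(a, float)), sem_b=_sem(np.asarray(b, float)),
        test=test, alternative=alternative, statistic=statistic, p_value=p)


def compare_hub_vs_nonhub(gamma: pd.DataFrame, metrics: pd.DataFrame,
                          negative_threshold: float = 0.0
                          ) -> list[GroupComparison]:
    """The four hub-vs-non-hub gamma contrasts plus the enrichment tests.

    For each role (TF, target) and context (coding, regulatory) a one-tailed
    Wilcoxon tests whether hub gamma is lower than non-hub gamma; per role a
    Yates chi-square tests whether hubs are enriched for genes with negative
    coding gamma (gamma < ``negative_threshold``, default 0).
    """
    out: list[GroupComparison] = []
    merged = gamma.merge(metrics, left_on="gene_id", right_on="node_id")
    for role, hub_col in (("TF", "hub_tf"), ("target", "hub_target")):
        in_role = merged["role"].isin([role, "both"])
        for context in ("coding", "regulatory"):
            sub = merged[in_role & (merged["context"] == context)]
            hub = sub.loc[sub[hub_col], "gamma_hat"].to_numpy()
            non = sub.loc[~sub[hub_col], "gamma_hat"].to_numpy()
            if len(hub) == 0 or len(non) == 0:
                raise ValueError(f"empty hub or non-hub class for "
                                 f"{role}/{context}")
            w, p = wilcoxon_rank_sum(hub, non, alternative="less")
            out.append(_one_comparison(
                f"{role}_{context}_hub_vs_nonhub", "hub", "non-hub",
                hub, non, "wilcoxon", "less", w, p))
        sub = merged[in_role & (merged["context"] == "coding")]
        hub_mask = sub[hub_col].to_numpy()
        neg = (sub["gamma_hat"] < negative_threshold).to_numpy()
        table = [[int((hub_mask & neg).sum()), int((hub_mask & ~neg).sum())],
                 [int((~hub_mask & neg).sum()), int((~hub_mask & ~neg).sum())]]
        stat, p = chi_square_2x2(table)
        out.append(_one_comparison(
            f"{role}_negative_coding_enrichment", "hub", "non-hub",
            sub.loc[hub_mask, "gamma_hat"], sub.loc[~hub_mask, "gamma_hat"],
            "chi_square", "two_sided", stat, p))
    return out


def compare_betweenness_by_selection(gamma: pd.DataFrame,
                                     metrics: pd.DataFrame,
                                     context: str) -> GroupComparison:
    """Two-sided Wilcoxon on betweenness: positive- vs negative-gamma genes.

    Positive selection is gamma_hat > 1, negative is gamma_hat < -1;
    near-neutral genes are excluded.
    """
    merged = gamma[gamma["context"] == context].merge(
        metrics, left_on="gene_id", right_on="node_id")
    pos = merged.loc[merged["gamma_hat"] > 1, "betweenness"].to_numpy()
    neg = merged.loc[merged["gamma_hat"] < -1, "betweenness"].to_numpy()
    if len(pos) == 0:
        raise ValueError(f"no genes with positive {context} gamma (> 1)")
    if len(neg) == 0:
        raise ValueError(f"no genes with negative {context} gamma (< -1)")
    w, p = wilcoxon_rank_sum(pos, neg, alternative="two_sided")
    return _one_comparison(
        f"betweenness_by_selection_{context}", "positive", "negative",
        pos, neg, "wilcoxon", "two_sided", w, p)


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in comparisons])


def write_comparisons(comparisons: list[GroupComparison], path,
                      version: str = "0.1.0") -> None:
    with open(path, "w") as fh:
        fh.write(f"# trnsel.group_stats v{version}\n")
        comparisons_to_frame(comparisons).to_csv(fh, sep="\t", index=False)
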