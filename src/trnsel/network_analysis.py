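"""Directed TRN construction, centrality metrics, hubs and power-law tails.

Connectedness ``k`` of a node is its out-degree for transcription factors
and its in-degree for targets (nodes acting as both report both).  Hubs are
the top 20% most connected nodes of their role class under a strict
greater-than threshold at the empirical 80th percentile, so ties at the
threshold are never hubs.

The degree-tail fit is the discrete maximum-likelihood procedure of the
Clauset-Shalizi-Newman school: for each candidate x_min the exponent is
estimated by maximising the zeta-normalised log likelihood, x_min is chosen
to minimise the Kolmogorov-Smirnov distance between the empirical and
fitted tail CDFs, and goodness of fit is a semi-parametric bootstrap
p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# probe mapping
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def map_probes(probes: dict[str, str],
               transcripts: dict[str, str | list[str]]
               ) -> tuple[dict[str, str], dict[str, str]]:
    """Assign probes to genes by exact (sub)string match.

    A probe (or its reverse complement) must match transcripts of exactly
    one gene; probes matching zero or several genes are dropped with the
    reason recorded.  Returns (assigned probe->gene, dropped probe->reason).
    """
    gene_seqs: dict[str, list[str]] = {}
    for gid, seqs in transcripts.items():
        seq_list = [seqs] if isinstance(seqs, str) else list(seqs)
        for s in seq_list:
            if set(s.upper()) - set("ACGT"):
                raise ValueError(f"non-nucleotide characters in transcript "
                                 f"of {gid}")
        gene_seqs[gid] = [s.upper() for s in seq_list]
    assigned: dict[str, str] = {}
    dropped: dict[str, str] = {}
    for pid, probe in probes.items():
        p = probe.upper()
        if set(p) - set("ACGT"):
            raise ValueError(f"non-nucleotide characters in probe {pid}")
        rc = _revcomp(p)
        hits = {gid for gid, seqs in gene_seqs.items()
                if any(p in s or rc in s for s in seqs)}
        if len(hits) == 1:
            assigned[pid] = hits.pop()
        elif not hits:
            dropped[pid] = "no_perfect_match"
        else:
            dropped[pid] = "ambiguous"
    if dropped:
        logger.info("map_probes: %d/%d probes dropped",
                    len(dropped), len(probes))
    return assigned, dropped


# ---------------------------------------------------------------------------
# network construction and metrics
# ---------------------------------------------------------------------------

def build_network(edges: pd.DataFrame, allow_self_loops: bool = False
                  ) -> nx.DiGraph:
    """Deduplicated directed graph from a two-column TF->target edge list.

    Node roles are inferred: source-only -> TF, sink-only -> target,
    both -> both.  Self-loop rows are rejected (logged) by default.
    """
    if edges.shape[1] < 2:
        raise ValueError("edge list needs two columns (tf_id, target_id)")
    src_col, dst_col = edges.columns[:2]
    g = nx.DiGraph()
    n_self = 0
    for s, d in edges[[src_col, dst_col]].itertuples(index=False):
        if s == d and not allow_self_loops:
            n_self += 1
            continue
        g.add_edge(str(s), str(d))
    if n_self:
        logger.warning("build_network: dropped %d self-loop rows", n_self)
    for node in g.nodes:
        out_ = g.out_degree(node) > 0
        in_ = g.in_degree(node) > 0
        g.nodes[node]["role"] = "both" if (out_ and in_) else (
            "TF" if out_ else "target")
    return g


def degree_profile(net: nx.DiGraph) -> pd.DataFrame:
    """Per-node connectedness: out-degree for TFs, in-degree for targets."""
    rows = []
    for node, data in net.nodes(data=True):
        role = data["role"]
        k_out = net.out_degree(node)
        k_in = net.in_degree(node)
        k = k_out if role == "TF" else (k_in if role == "target" else np.nan)
        rows.append({"node_id": node, "role": role, "k_out": k_out,
                     "k_in": k_in, "k": k})
    return pd.DataFrame(rows)


def hub_threshold(k_values, fraction: float = 0.20) -> float:
    """Empirical (1 - fraction) quantile of connectedness."""
    k = np.asarray(k_values, dtype=float)
    if k.size == 0:
        raise ValueError("empty degree list")
    return float(np.quantile(k, 1.0 - fraction))


def hub_flags(k_values, fraction: float = 0.20) -> np.ndarray:
    """Strict-threshold hub flags: hub iff k > (1-fraction) quantile."""
    k = np.asarray(k_values, dtype=float)
    t = hub_threshold(k, fraction)
    flags = k > t
    if not flags.any():
        logger.warning("hub_flags: no node exceeds the threshold %.3g "
                       "(tied degrees?)", t)
    return flags


def classify_hubs(k_values, fraction: float = 0.20) -> np.ndarray:
    """Hub flags for one role class (requires at least 5 nodes)."""
    k = np.asarray(k_values, dtype=float)
    if k.size < 5:
        raise ValueError("need at least 5 nodes to classify hubs")
    return hub_flags(k, fraction)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def betweenness_centrality(net: nx.DiGraph, rescale: bool = True,
                           directed: bool = True) -> pd.Series:
    """Brandes betweenness over directed shortest paths, min-max rescaled.

    With ``rescale=True`` the most central node scores 1 and the least 0;
    if all raw scores are 0 (e.g. a star) everything is 0.
    """
    g = net if directed else net.to_undirected(as_view=True)
    raw = nx.betweenness_centrality(g, normalized=False)
    nodes = list(net.nodes)
    values = np.array([raw[n] for n in nodes], dtype=float)
    if rescale:
        values = _minmax(values)
    return pd.Series(values, index=nodes, name="betweenness")


def eigenvector_centrality(net: nx.DiGraph, tol: float = 1e-10,
                           max_iter: int = 10_000) -> pd.Series:
    """Power iteration on the symmetrised adjacency, normalised to max 1.

    The undirected view is used because on a near-bipartite directed TRN the
    directed variant degenerates to zero on all source nodes.
    """
    nodes = list(net.nodes)
    n = len(nodes)
    if n == 0:
        return pd.Series(dtype=float, name="eigenvector")
    idx = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v in net.edges:
        A[idx[u], idx[v]] = 1.0
        A[idx[v], idx[u]] = 1.0
    # shift by +I: same eigenvectors, but breaks the +/-lambda symmetry of
    # (near-)bipartite graphs that makes plain power iteration oscillate
    A = A + np.eye(n)
    v = np.full(n, 1.0 / math.sqrt(n))
    for it in range(max_iter):
        w = A @ v
        norm = np.linalg.norm(w)
        if norm == 0:  # no edges at all
            return pd.Series(np.zeros(n), index=nodes, name="eigenvector")
        w /= norm
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} "
            f"iterations (residual {np.max(np.abs(w - v)):.2e})")
    v = np.abs(v)
    return pd.Series(v / v.max(), index=nodes, name="eigenvector")


def node_metrics(net: nx.DiGraph, hub_fraction: float = 0.20) -> pd.DataFrame:
    """Degree, hub flags, betweenness and eigenvector centrality per node."""
    prof = degree_profile(net)
    btw = betweenness_centrality(net)
    eig = eigenvector_centrality(net)
    prof["betweenness"] = prof["node_id"].map(btw)
    prof["eigenvector"] = prof["node_id"].map(eig)
    tf_mask = prof["role"].isin(["TF", "both"])
    tg_mask = prof["role"].isin(["target", "both"])
    prof["hub_tf"] = False
    prof["hub_target"] = False
    if tf_mask.sum() >= 5:
        prof.loc[tf_mask, "hub_tf"] = hub_flags(
            prof.loc[tf_mask, "k_out"], hub_fraction)
    if tg_mask.sum() >= 5:
        prof.loc[tg_mask, "hub_target"] = hub_flags(
            prof.loc[tg_mask, "k_in"], hub_fraction)
    return prof


def write_node_metrics(metrics: pd.DataFrame, path,
                       version: str = "0.1.0") -> None:
    with open(path, "w") as fh:
        fh.write(f"# trnsel.network_analysis v{version}\n")
        metrics.to_csv(fh, sep="\t", index=False)


def read_node_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# discrete power-law tail fitting
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    x_min: int
    alpha: float
    ks_statistic: float
    n_tail: int
    gof_p: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _tail_loglik(alpha: float, sum_log_k: float, n: int, x_min: int) -> float:
    return -alpha * sum_log_k - n * math.log(special.zeta(alpha, x_min))


def _mle_alpha(tail: np.ndarray, x_min: int,
               bounds: tuple[float, float] = (1.01, 6.0)) -> float:
    sum_log = float(np.log(tail).sum())
    n = len(tail)
    res = optimize.minimize_scalar(
        lambda a: -_tail_loglik(a, sum_log, n, x_min),
        bounds=bounds, method="bounded",
        options={"xatol": 1e-7})
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, x_min: int) -> float:
    """Sup distance between empirical and model tail CDFs.

    Both CDFs are integer step functions, so the supremum is attained at an
    observed value or one below it; the model CDF is
    F(k) = 1 - zeta(alpha, k+1) / zeta(alpha, x_min).
    """
    n = len(tail)
    uniq, cum = np.unique(tail, return_counts=True)
    ecdf_at = np.cumsum(cum) / n            # empirical CDF at each unique value
    ecdf_before = ecdf_at - cum / n         # just below each unique value
    z0 = special.zeta(alpha, x_min)
    model_at = 1.0 - special.zeta(alpha, uniq + 1) / z0
    model_before = 1.0 - special.zeta(alpha, uniq) / z0
    d = np.maximum(np.abs(ecdf_at - model_at),
                   np.abs(ecdf_before - model_before))
    return float(d.max())


def fit_power_law_tail(k_values, x_min: int | None = None) -> PowerLawFit:
    """Discrete MLE power-law tail fit with KS-optimal x_min selection.

    With ``x_min`` given the exponent is fitted on that fixed tail;
    otherwise every unique value (leaving at least 2 tail points) is tried
    and the candidate with the smallest KS distance wins.
    """
    k = np.asarray(k_values, dtype=float)
    k = k[np.isfinite(k)]
    if np.any(k < 1):
        raise ValueError("degrees must be >= 1")
    k = k.astype(int)
    if len(np.unique(k)) < 2:
        raise ValueError("degenerate input: need at least 2 unique values")
    if x_min is not None:
        tail = k[k >= x_min]
        if len(tail) < 2:
            raise ValueError(f"fewer than 2 points at or above x_min={x_min}")
        alpha = _mle_alpha(tail, x_min)
        return PowerLawFit(x_min=int(x_min), alpha=alpha,
                           ks_statistic=_ks_distance(tail, alpha, x_min),
                           n_tail=len(tail))
    if len(k) < 10:
        raise ValueError("need at least 10 values to scan x_min")
    best: PowerLawFit | None = None
    for cand in np.unique(k):
        tail = k[k >= cand]
        if len(tail) < 2 or len(np.unique(tail)) < 2:
            continue
        alpha = _mle_alpha(tail, int(cand))
        ks = _ks_distance(tail, alpha, int(cand))
        if best is None or ks < best.ks_statistic:
            best = PowerLawFit(x_min=int(cand), alpha=alpha, ks_statistic=ks,
                               n_tail=len(tail))
    if best is None:
        raise ValueError("no candidate x_min leaves a fittable tail")
    return best


def sample_power_law_tail(alpha: float, x_min: int, size: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Exact inverse-CDF draws from the (infinite-support) discrete tail."""
    if size == 0:
        return np.array([], dtype=int)
    z0 = special.zeta(alpha, x_min)
    v = rng.random(size) * z0  # target: smallest k with zeta(alpha, k+1) <= v
    v = np.maximum(v, z0 * 1e-12)  # truncates only the 1e-12 extreme tail
    lo = np.full(size, x_min, dtype=np.int64)
    hi = lo.copy()
    # bracket by doubling the offset from x_min
    need = special.zeta(alpha, hi + 1) > v
    step = np.ones(size, dtype=np.int64)
    while np.any(need):
        lo[need] = hi[need] + 1
        hi[need] = hi[need] + step[need]
        step[need] *= 2
        need = special.zeta(alpha, hi + 1) > v
    while np.any(lo < hi):
        mid = (lo + hi) // 2
        takes = special.zeta(alpha, mid + 1) <= v
        hi = np.where(takes, mid, hi)
        lo = np.where(takes, lo, mid + 1)
    return lo.astype(int)


def bootstrap_gof(fit: PowerLawFit, k_values, n_boot: int = 200,
                  seed: int | np.random.Generator = 0) -> float:
    """Semi-parametric bootstrap goodness-of-fit p-value.

    Each replicate resamples below-x_min values empirically and draws tail
    values from the fitted power law, refits (x_min, alpha) by the same
    scan, and records its KS distance; p is the fraction of replicate KS
    values at or above the observed one.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = np.asarray(k_values, dtype=int)
    body = k[k < fit.x_min]
    n = len(k)
    p_tail = (n - len(body)) / n
    exceed = 0
    for _ in range(n_boot):
        from_tail = rng.random(n) < p_tail
        n_tail = int(from_tail.sum())
        rep = np.empty(n, dtype=int)
        rep[from_tail] = sample_power_law_tail(fit.alpha, fit.x_min,
                                               n_tail, rng)
        if n - n_tail > 0:
            rep[~from_tail] = rng.choice(body, size=n - n_tail, replace=True)
        try:
            rep_fit = fit_power_law_tail(rep)
        except ValueError:  # degenerate replicate
            continue
        if rep_fit.ks_statistic >= fit.ks_statistic:
            exceed += 1
    return exceed / n_boot
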