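"""Per-gene selection-coefficient estimation from McDonald-Kreitman count tables.

The model is a Poisson random-effects (log-linear mixed) formulation of the
MK test.  For gene ``i`` and count cell ``c`` in {silent-polymorphic,
silent-fixed, selected-polymorphic, selected-fixed} the expected count is

    log E[y_ic] = log L_ic + mu + beta_F * I_fixed
                + (beta_R + r_i) * I_sel
                + (beta_RF + s_i) * I_fixed * I_sel + a_i

with independent normal gene-level random effects ``a_i`` (baseline
diversity), ``r_i`` (selected-class constraint) and ``s_i`` (gene-specific
divergence excess).  ``L_ic`` is the site opportunity of the cell.  The
"selected" class is replacement sites for the coding context and the
upstream cis-regulatory window for the regulatory context; the silent class
is synonymous sites of the same gene in both contexts.

The gene-level log fixation-rate ratio ``e_i = beta_RF + s_i`` is converted
to a population-scaled selection coefficient through the Poisson-random-field
fixation-probability ratio g(gamma) = gamma / (1 - exp(-gamma)), i.e.
``gamma_i = g^{-1}(exp(e_i))``.

Fitting is deterministic: the marginal likelihood is approximated gene by
gene with a Laplace approximation (the random effects are independent across
genes, so the 3-dimensional integrals factorise), maximised over the fixed
effects and variance components with L-BFGS-B, and the per-gene random
effects are reported at their posterior modes (shrinkage estimates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

logger = logging.getLogger(__name__)

#: classification thresholds on the point estimate of gamma
GAMMA_POSITIVE_THRESHOLD = 1.0
GAMMA_NEGATIVE_THRESHOLD = -1.0

_ETA_CAP = 30.0  # guards exp() in the inner Newton iterations


# ---------------------------------------------------------------------------
# fixation-probability ratio and its inverse
# ---------------------------------------------------------------------------

def fixation_ratio(gamma):
    """Relative fixation probability g(gamma) = gamma / (1 - exp(-gamma)).

    The removable singularity at 0 is filled with g(0) = 1.  ``gamma`` may
    be a scalar or array; the result is strictly increasing and positive.
    """
    g = np.asarray(gamma, dtype=float)
    out = np.empty_like(g)
    small = np.abs(g) < 1e-8
    # second-order expansion around 0: g(x) ~ 1 + x/2 + x^2/12
    out[small] = 1.0 + g[small] / 2.0 + g[small] ** 2 / 12.0
    gs = g[~small]
    out[~small] = gs / (-np.expm1(-gs))
    if np.ndim(gamma) == 0:
        return float(out)
    return out


def invert_fixation_ratio(r):
    """Unique gamma with ``fixation_ratio(gamma) == r`` (r > 0).

    Solved by bracketed root finding to |g(gamma) - r| < 1e-10.
    """
    if np.ndim(r) > 0:
        return np.array([invert_fixation_ratio(v) for v in np.asarray(r).ravel()]).reshape(np.shape(r))
    r = float(r)
    if not np.isfinite(r) or r <= 0.0:
        raise ValueError(f"fixation ratio must be positive and finite, got {r}")
    if r == 1.0:
        return 0.0
    # g(x) ~ x for large x and ~ -x * exp(x) for very negative x
    lo, hi = -1.0, 1.0
    while fixation_ratio(lo) > r:
        lo *= 2.0
        if lo < -745.0:  # g underflows to 0 here; r below that is unreachable
            lo = -745.0
            break
    while fixation_ratio(hi) < r:
        hi *= 2.0
    gamma = optimize.brentq(lambda x: fixation_ratio(x) - r, lo, hi,
                            xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return float(gamma)


def classify_selection(gamma_hat: float) -> str:
    """Selection regime of a point estimate: positive / negative / near_neutral.

    The closed interval [-1, 1] is near-neutral (boundary values included).
    """
    if not np.isfinite(gamma_hat):
        raise ValueError("gamma estimate must be finite")
    if gamma_hat > GAMMA_POSITIVE_THRESHOLD:
        return "positive"
    if gamma_hat < GAMMA_NEGATIVE_THRESHOLD:
        return "negative"
    return "near_neutral"


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------

@dataclass
class EffectsFit:
    """Result of the Poisson random-effects fit for one context."""

    context: str
    gene_ids: np.ndarray
    mu: float
    beta_F: float
    beta_R: float
    beta_RF: float
    sigma_a: float
    sigma_r: float
    sigma_s: float
    a: np.ndarray            # per-gene posterior modes
    r: np.ndarray
    s: np.ndarray
    sd_s: np.ndarray         # per-gene conditional sd of s_i
    converged: bool
    n_iter: int
    loglik: float
    n_dropped: int = 0
    message: str = ""

    def to_report(self) -> dict:
        return {
            "context": self.context,
            "n_genes": int(len(self.gene_ids)),
            "n_dropped": int(self.n_dropped),
            "fixed_effects": {"mu": self.mu, "beta_F": self.beta_F,
                              "beta_R": self.beta_R, "beta_RF": self.beta_RF},
            "variance_components": {"sigma_a": self.sigma_a,
                                    "sigma_r": self.sigma_r,
                                    "sigma_s": self.sigma_s},
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "loglik": float(self.loglik),
            "message": self.message,
        }


def _context_columns(context: str) -> tuple[str, str, str]:
    """(polymorphic-selected, fixed-selected, selected-length) column names."""
    if context == "coding":
        return "PR", "FR", "L_repl"
    if context == "regulatory":
        return "PC", "FC", "L_reg"
    raise ValueError(f"unknown context {context!r}")


def _laplace_pieces(y, off, theta, sigma2, b0, tol=1e-9, max_iter=60):
    """Per-gene Laplace approximation, vectorised across genes.

    ``y``/``off`` are (n, 4) count and log-offset arrays with cells ordered
    PS, FS, Psel, Fsel.  Returns (marginal loglik per gene, posterior modes
    b (n,3), conditional sd of s (n,)).
    """
    n = y.shape[0]
    mu0, bF, bR, bRF = theta
    # fixed-effect linear predictor per cell
    xF = np.array([0.0, 1.0, 0.0, 1.0])
    xR = np.array([0.0, 0.0, 1.0, 1.0])
    xRF = np.array([0.0, 0.0, 0.0, 1.0])
    eta_fixed = off + mu0 + bF * xF + bR * xR + bRF * xRF  # (n,4)
    # random-effect design per cell: columns a, r, s
    Z = np.stack([np.ones(4), xR, xRF], axis=1)  # (4,3)
    prec = 1.0 / sigma2  # (3,)

    b = b0.copy()

    def neg_parts(bcur):
        eta = np.clip(eta_fixed + bcur @ Z.T, -_ETA_CAP, _ETA_CAP)
        lam = np.exp(eta)
        f = np.sum(y * eta - lam, axis=1) - 0.5 * np.sum(bcur ** 2 * prec, axis=1)
        return eta, lam, f

    eta, lam, f = neg_parts(b)
    for _ in range(max_iter):
        grad = (y - lam) @ Z - b * prec              # (n,3)
        W = lam[:, :, None, None] * (Z[None, :, :, None] * Z[None, :, None, :])
        H = W.sum(axis=1) + np.eye(3)[None, :, :] * prec  # (n,3,3)
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        # damped update: halve steps for genes whose objective would drop
        scale = np.ones(n)
        for _half in range(30):
            b_new = b + step * scale[:, None]
            eta_n, lam_n, f_new = neg_parts(b_new)
            bad = f_new < f - 1e-12
            if not np.any(bad):
                break
            scale[bad] *= 0.5
        b, eta, lam, f = b_new, eta_n, lam_n, f_new
        if np.max(np.abs(grad)) < tol:
            break
    # final Hessian at the mode
    W = lam[:, :, None, None] * (Z[None, :, :, None] * Z[None, :, None, :])
    H = W.sum(axis=1) + np.eye(3)[None, :, :] * prec
    sign, logdetH = np.linalg.slogdet(H)
    # log integral ~ f(bhat) - sum(log sigma) - 0.5 log|H|
    ll = f - 0.5 * np.sum(np.log(sigma2)) - 0.5 * logdetH
    ll = ll - special.gammaln(y + 1.0).sum(axis=1)
    Hinv = np.linalg.inv(H)
    sd_s = np.sqrt(Hinv[:, 2, 2])
    return ll, b, sd_s


def fit_mk_glmm(counts: pd.DataFrame, context: str = "coding",
                min_genes_warn: int = 30, allow_single_gene: bool = False,
                max_outer_iter: int = 300) -> EffectsFit:
    """Fit the Poisson random-effects MK model to a count table.

    Parameters
    ----------
    counts
        MK count table with columns gene_id, PS, FS and the selected-class
        pair for ``context`` (PR/FR + L_repl for coding, PC/FC + L_reg for
        regulatory) plus L_syn.
    context
        "coding" or "regulatory".

    Genes with zero silent counts in both status classes, or with a
    non-positive opportunity length, are dropped with a logged reason.
    """
    pcol, fcol, lcol = _context_columns(context)
    df = counts.copy()
    required = {"gene_id", "PS", "FS", "L_syn", pcol, fcol, lcol}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table misses columns {sorted(missing)}")

    keep = (df["PS"] + df["FS"] > 0) & (df["L_syn"] > 0) & (df[lcol] > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d genes with no silent counts or zero-length "
                    "opportunities (%s context)", n_dropped, context)
    df = df.loc[keep].reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ValueError("no usable genes after filtering")
    if n == 1 and not allow_single_gene:
        raise ValueError("a single gene cannot identify the variance "
                         "components; pass allow_single_gene=True to force a "
                         "degenerate fit")
    if int(df[pcol].sum() + df[fcol].sum()) == 0:
        raise ValueError(f"all {pcol}/{fcol} counts are zero: the "
                         "selected-class effect is unidentifiable")
    nonzero_silent = int(((df["PS"] > 0) | (df["FS"] > 0)).sum())
    if nonzero_silent < min_genes_warn:
        warnings.warn(f"only {nonzero_silent} genes with nonzero silent "
                      "counts; estimates will be unstable", stacklevel=2)

    y = df[["PS", "FS", pcol, fcol]].to_numpy(dtype=float)
    Ls = df["L_syn"].to_numpy(dtype=float)
    Lr = df[lcol].to_numpy(dtype=float)
    off = np.stack([np.log(Ls), np.log(Ls), np.log(Lr), np.log(Lr)], axis=1)

    # moment-based starting values from pooled counts
    eps = 0.5
    mu0 = float(np.log((y[:, 0].sum() + eps) / Ls.sum()))
    bF0 = float(np.log((y[:, 1].sum() + eps) / (y[:, 0].sum() + eps)))
    bR0 = float(np.log(((y[:, 2].sum() + eps) / Lr.sum()) /
                       ((y[:, 0].sum() + eps) / Ls.sum())))
    bRF0 = float(np.log((y[:, 3].sum() + eps) * (y[:, 0].sum() + eps) /
                        ((y[:, 2].sum() + eps) * (y[:, 1].sum() + eps))))
    x0 = np.array([mu0, bF0, bR0, bRF0,
                   np.log(0.3), np.log(0.3), np.log(0.3)])
    bounds = [(-20, 20)] * 4 + [(-6.0, 2.0)] * 3

    state = {"b": np.zeros((n, 3))}

    def negloglik(x):
        theta = x[:4]
        sigma2 = np.exp(2.0 * x[4:])
        ll, b, _ = _laplace_pieces(y, off, theta, sigma2, state["b"])
        state["b"] = b
        return -float(ll.sum())

    res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_outer_iter, "ftol": 1e-10,
                                     "gtol": 1e-7})
    xhat = res.x
    theta = xhat[:4]
    sigma = np.exp(xhat[4:])
    ll, b, sd_s = _laplace_pieces(y, off, theta, sigma ** 2, state["b"],
                                  tol=1e-11, max_iter=120)
    if not res.success:
        logger.warning("outer optimisation did not report convergence: %s",
                       res.message)
    return EffectsFit(
        context=context,
        gene_ids=df["gene_id"].to_numpy(),
        mu=float(theta[0]), beta_F=float(theta[1]),
        beta_R=float(theta[2]), beta_RF=float(theta[3]),
        sigma_a=float(sigma[0]), sigma_r=float(sigma[1]),
        sigma_s=float(sigma[2]),
        a=b[:, 0], r=b[:, 1], s=b[:, 2], sd_s=sd_s,
        converged=bool(res.success), n_iter=int(res.nit),
        loglik=float(ll.sum()), n_dropped=n_dropped,
        message=str(res.message),
    )


def estimate_gamma(fit: EffectsFit) -> pd.DataFrame:
    """Per-gene gamma estimates with 95% intervals and selection classes.

    The selection effect ``e_i = beta_RF + s_i`` and its conditional 95%
    interval are pushed through the monotone inverse fixation-ratio mapping.
    """
    e = fit.beta_RF + fit.s
    lo_e = e - 1.96 * fit.sd_s
    hi_e = e + 1.96 * fit.sd_s
    gamma_hat = np.array([invert_fixation_ratio(np.exp(v)) for v in e])
    lo = np.array([invert_fixation_ratio(np.exp(v)) for v in lo_e])
    hi = np.array([invert_fixation_ratio(np.exp(v)) for v in hi_e])
    sel = [classify_selection(g) for g in gamma_hat]
    return pd.DataFrame({
        "gene_id": fit.gene_ids,
        "context": fit.context,
        "e": e,
        "gamma_hat": gamma_hat,
        "lo": lo,
        "hi": hi,
        "sel_class": sel,
    })


def naive_gamma(counts: pd.DataFrame, context: str = "coding") -> pd.DataFrame:
    """Unshrunk per-gene estimates from each gene's own 2x2 table.

    Uses the add-half log odds ratio of (fixed-selected, polymorphic-selected)
    vs (fixed-silent, polymorphic-silent) as the log fixation-rate ratio.
    Mainly a reference point for quantifying shrinkage.
    """
    pcol, fcol, _ = _context_columns(context)
    e = np.log((counts[fcol] + 0.5) * (counts["PS"] + 0.5) /
               ((counts[pcol] + 0.5) * (counts["FS"] + 0.5)))
    gamma = np.array([invert_fixation_ratio(np.exp(v)) for v in e])
    return pd.DataFrame({"gene_id": counts["gene_id"], "e": e,
                         "gamma_naive": gamma})


def write_gamma_table(gamma: pd.DataFrame, path, version: str = "0.1.0") -> None:
    with open(path, "w") as fh:
        fh.write(f"# trnsel.selection_model v{version}\n")
        gamma.to_csv(fh, sep="\t", index=False)


def read_gamma_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
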