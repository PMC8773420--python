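"""Stratified conditional logistic regression for matched / stratified case-control data.

For a stratum with m subjects of which k are cases, the conditional
likelihood of the case set given the number of cases is

    exp(beta * sum_{cases} x) / B(beta),
    B(beta) = sum over all k-subsets S of the m subjects of exp(beta * sum_S x).

B and its first two derivatives in beta are evaluated by the standard
two-index recursion over (subjects considered, cases used) in O(m*k) time
(never by subset enumeration), and the single-parameter model is maximized
by Newton-Raphson. Stratum-specific baseline risks are eliminated by the
conditioning, so the model is "adjusted for" the stratifying variable
(Lauren histology here) without estimating per-stratum intercepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalCohort, ExpressionMatrix, ValidationError

__all__ = ["CLogitFit", "conditional_loglik", "clogit_fit", "per_gene_clogit"]

logger = logging.getLogger(__name__)

#: |beta| beyond which the likelihood is considered monotone (separation).
DIVERGENCE_BOUND = 30.0


def _stratum_denominator(x: np.ndarray, k: int, beta: float):
    """B(beta), B'(beta), B''(beta) for one stratum via the O(m*k) recursion.

    x is the (centered) exposure vector of the stratum's m subjects.
    """
    f0 = np.zeros(k + 1)
    f1 = np.zeros(k + 1)
    f2 = np.zeros(k + 1)
    f0[0] = 1.0
    for xj in x:
        w = np.exp(beta * xj)
        for l in range(min(k, len(x)), 0, -1):
            f2[l] += w * (f2[l - 1] + 2 * xj * f1[l - 1] + xj * xj * f0[l - 1])
            f1[l] += w * (f1[l - 1] + xj * f0[l - 1])
            f0[l] += w * f0[l - 1]
    return f0[k], f1[k], f2[k]


def _split_strata(x, case, strata):
    x = np.asarray(x, dtype=float)
    case = np.asarray(case, dtype=bool)
    strata = np.asarray(strata)
    if not (len(x) == len(case) == len(strata)):
        raise ValidationError("x, case and strata must have equal length")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite exposure values")
    groups = []
    for s in pd.unique(strata):
        idx = strata == s
        k = int(case[idx].sum())
        m = int(idx.sum())
        if k == 0 or k == m:
            logger.info("stratum %r has %d/%d cases; contributes no information", s, k, m)
            continue
        groups.append((s, x[idx], case[idx]))
    return groups


def conditional_loglik(beta: float, x, case, strata):
    """Log conditional likelihood, gradient and Hessian at ``beta``.

    Strata with zero or all cases are informationless and skipped (logged).
    Exposures are centered within each stratum before exponentiation (the
    likelihood is invariant to within-stratum shifts), which keeps the
    recursion numerically safe.
    """
    ll = grad = hess = 0.0
    for _, xs, cs in _split_strata(x, case, strata):
        xc = xs - xs.mean()
        k = int(cs.sum())
        s_obs = float(xc[cs].sum())
        B, dB, d2B = _stratum_denominator(xc, k, beta)
        r1 = dB / B
        r2 = d2B / B
        ll += beta * s_obs - np.log(B)
        grad += s_obs - r1
        hess += -(r2 - r1 * r1)
    return ll, grad, hess


@dataclass
class CLogitFit:
    """One univariable conditional-logistic fit."""

    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    loglik: float
    converged: bool
    strata_sizes: list[tuple[int, int]] = field(default_factory=list)  # (m, k)
    n_iter: int = 0
    gene_symbol: str | None = None


def clogit_fit(
    x,
    case,
    strata,
    tol_score: float = 1e-8,
    tol_step: float = 1e-10,
    max_iter: int = 50,
) -> CLogitFit:
    """Newton-Raphson maximization of the conditional likelihood from beta=0.

    Convergence when |score| < 1e-8 or |step| < 1e-10; a monotone likelihood
    (within-stratum separation) is detected by |beta| exceeding a bound and
    reported as non-estimable (``converged=False``) rather than as a huge
    odds ratio.
    """
    groups = _split_strata(x, case, strata)
    sizes = [(len(xs), int(cs.sum())) for _, xs, cs in groups]
    if not groups:
        raise ValidationError("no informative strata (each has 0 or all cases)")

    # Exact separation check: if the observed case exposure sum attains the
    # largest (smallest) sum achievable by any k-subset in every stratum, the
    # likelihood is monotone in beta and the MLE sits at +inf (-inf).
    obs = hi = lo = 0.0
    for _, xs, cs in groups:
        k = int(cs.sum())
        srt = np.sort(xs)
        obs += float(xs[cs].sum())
        hi += float(srt[-k:].sum())
        lo += float(srt[:k].sum())
    if hi > lo and (obs >= hi - 1e-12 * max(1.0, abs(hi)) or obs <= lo + 1e-12 * max(1.0, abs(lo))):
        logger.warning("conditional logistic fit is separated; odds ratio not estimable")
        ll0, _, _ = conditional_loglik(0.0, x, case, strata)
        return CLogitFit(
            beta=float("nan"), se=float("nan"), odds_ratio=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), p_value=float("nan"),
            loglik=ll0, converged=False, strata_sizes=sizes, n_iter=0,
        )

    beta = 0.0
    converged = False
    n_iter = 0
    ll, grad, hess = conditional_loglik(beta, x, case, strata)
    for n_iter in range(1, max_iter + 1):
        if abs(grad) < tol_score:
            converged = True
            break
        if hess >= -1e-14:  # no curvature: exposure constant within strata
            converged = abs(grad) < tol_score
            break
        step = -grad / hess
        # Step-halving keeps the ascent monotone on hard instances.
        for _ in range(30):
            ll_new, grad_new, hess_new = conditional_loglik(beta + step, x, case, strata)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        beta += step
        ll, grad, hess = ll_new, grad_new, hess_new
        if abs(beta) > DIVERGENCE_BOUND:
            converged = False
            break
        if abs(step) < tol_step:
            converged = True
            break
    else:
        converged = abs(grad) < tol_score

    if abs(beta) > DIVERGENCE_BOUND:
        logger.warning("conditional logistic fit diverged (|beta| > %.0f)", DIVERGENCE_BOUND)
        return CLogitFit(
            beta=float("nan"), se=float("nan"), odds_ratio=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), p_value=float("nan"),
            loglik=ll, converged=False, strata_sizes=sizes, n_iter=n_iter,
        )

    if hess < -1e-14:
        se = float(np.sqrt(-1.0 / hess))
        z = beta / se
        p = float(min(max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
        ci_low, ci_high = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    else:
        se, p, ci_low, ci_high = float("nan"), 1.0, float("nan"), float("nan")
    return CLogitFit(
        beta=float(beta),
        se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        loglik=float(ll),
        converged=converged,
        strata_sizes=sizes,
        n_iter=n_iter,
    )


def per_gene_clogit(
    matrix: ExpressionMatrix,
    genes,
    cohort: ClinicalCohort,
    strata: str | pd.Series = "lauren",
    zscore: bool = False,
) -> pd.DataFrame:
    """Univariable conditional-logistic fit per gene, stratified by histology.

    ``strata`` may be "lauren" (the default, one stratum per Lauren subtype),
    or a Series of stratum labels indexed by patient id (e.g. matched-pair
    ids, under which the model reduces to the matched-pairs conditional
    likelihood). Per-gene failures are reported in the output, not raised.
    """
    gene_list = list(genes.genes) if hasattr(genes, "genes") else list(genes)
    missing = [g for g in gene_list if g not in set(matrix.genes)]
    if missing:
        raise ValidationError(f"genes not in matrix: {missing}")

    t = cohort.table.set_index("patient_id")
    samples = [s for s in matrix.samples if s in t.index]
    if not samples:
        raise ValidationError("no overlap between matrix samples and cohort")
    case = t.loc[samples, "vte"].to_numpy(dtype=bool)
    if isinstance(strata, str):
        if strata != "lauren":
            raise ValidationError(f"unknown strata mode: {strata!r}")
        labels = t.loc[samples, "lauren"].to_numpy()
    else:
        labels = strata.reindex(samples).to_numpy()
        if pd.isna(labels).any():
            raise ValidationError("strata labels missing for some samples")

    rows = []
    for gene in gene_list:
        xg = matrix.values.loc[gene, samples].to_numpy(dtype=float)
        if zscore:
            xg = (xg - xg.mean()) / xg.std(ddof=1)
        try:
            fit = clogit_fit(xg, case, labels)
        except ValidationError as exc:
            logger.warning("clogit failed for %s: %s", gene, exc)
            fit = CLogitFit(
                beta=float("nan"), se=float("nan"), odds_ratio=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"), p_value=float("nan"),
                loglik=float("nan"), converged=False,
            )
        rows.append(
            {
                "gene_symbol": gene,
                "p_value": fit.p_value,
                "odds_ratio": fit.odds_ratio,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "beta": fit.beta,
                "se": fit.se,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
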