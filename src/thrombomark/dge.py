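"""Per-stratum differential expression between VTE cases and controls.

Each gene gets a two-sample Student (pooled-variance) t test, a mean log2
difference (VTE minus control), the signed fold change, a raw two-sided
p-value and a Benjamini-Hochberg q-value. An optional empirical-Bayes stage
shrinks per-gene variances toward a common prior (limma-style moderated t);
it is off by default because the primary screen uses plain Student t tests.

Signed fold-change convention: an expression ratio r >= 1 is reported as +r
and a ratio 1/r as -r, so magnitudes are symmetric about +/-1 and |FC| >= 1
always.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "student_t_dge",
    "signed_fold_change",
    "delta_log2_from_fold_change",
    "bh_adjust",
    "ebayes_moderate",
    "squeeze_variances",
]

logger = logging.getLogger(__name__)


def signed_fold_change(delta_log2):
    """Signed fold change from a log2 difference: 2**d if d >= 0 else -2**(-d)."""
    d = np.asarray(delta_log2, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite log2 difference")
    out = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return float(out) if np.isscalar(delta_log2) or d.ndim == 0 else out


def delta_log2_from_fold_change(fc):
    """Inverse of :func:`signed_fold_change`: sign(fc) * log2|fc|."""
    f = np.asarray(fc, dtype=float)
    if np.any(np.abs(f) < 1):
        raise ValidationError("signed fold changes must satisfy |FC| >= 1")
    out = np.sign(f) * np.log2(np.abs(f))
    return float(out) if np.isscalar(fc) or f.ndim == 0 else out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def student_t_dge(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    stratum_samples=None,
    stratum_label: str = "all",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t test of VTE cases vs controls within a stratum.

    Parameters
    ----------
    labels
        Boolean VTE indicator indexed by sample id.
    stratum_samples
        Optional subset of sample ids defining the stratum; default all.
    welch
        Use the unequal-variance (Welch) test instead of the pooled-variance
        Student test.

    Genes whose pooled variance is zero are excluded with a logged reason
    (their p-value is undefined). Returns a frame with one row per retained
    gene: delta_log2 (VTE - control), fold_change, t_stat, p_value, q_value
    (BH across the retained genes of this stratum), group sizes and df.
    """
    samples = list(matrix.samples) if stratum_samples is None else [
        s for s in stratum_samples if s in set(matrix.samples)
    ]
    lab = labels.reindex(samples)
    if lab.isna().any():
        raise ValidationError("labels missing for some samples in the stratum")
    case_ids = [s for s in samples if bool(lab[s])]
    ctrl_ids = [s for s in samples if not bool(lab[s])]
    n1, n2 = len(case_ids), len(ctrl_ids)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {n1} cases / {n2} controls"
        )

    X = matrix.values[case_ids].to_numpy()
    Y = matrix.values[ctrl_ids].to_numpy()
    m1, m2 = X.mean(axis=1), Y.mean(axis=1)
    v1, v2 = X.var(axis=1, ddof=1), Y.var(axis=1, ddof=1)
    delta = m1 - m2

    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            t = delta / np.sqrt(se2)
        s2 = se2 * n1 * n2 / (n1 + n2)  # nominal scale, reported only
        degenerate = se2 == 0
    else:
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = np.full_like(s2, n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = delta / np.sqrt(s2 * (1 / n1 + 1 / n2))
        degenerate = s2 == 0

    if degenerate.any():
        logger.info(
            "excluding %d genes with zero pooled variance (p undefined): %s",
            int(degenerate.sum()),
            list(matrix.genes[degenerate][:10]),
        )

    keep = ~degenerate
    t, df, delta, s2 = t[keep], df[keep], delta[keep], s2[keep]
    p = 2 * stats.t.sf(np.abs(t), df)
    result = pd.DataFrame(
        {
            "gene_symbol": matrix.genes[keep],
            "stratum": stratum_label,
            "delta_log2": delta,
            "fold_change": signed_fold_change(delta),
            "t_stat": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "s2_pooled": s2,
            "df": df,
            "n_case": n1,
            "n_ctrl": n2,
        }
    ).reset_index(drop=True)
    return result


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, as in the classic eBayes fit)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square variance prior.

    Moments are taken on log variances: returns (prior_df d0, prior_var s0^2),
    with d0 = inf when the observed spread of log variances is no larger than
    expected under a common variance.
    """
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2 * _trigamma_inverse(excess)
    s0_2 = np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s0_2)


def squeeze_variances(s2, df, prior_df: float, prior_var: float) -> np.ndarray:
    """Posterior variances (d0*s0^2 + df*s^2) / (d0 + df); d0 = inf -> s0^2."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(prior_df):
        return np.full_like(s2, prior_var)
    return (prior_df * prior_var + df * s2) / (prior_df + df)


def ebayes_moderate(de: pd.DataFrame) -> pd.DataFrame:
    """Empirical-Bayes moderated t statistics (variance shrinkage).

    Requires the ``s2_pooled``/``df`` columns produced by
    :func:`student_t_dge` and at least 10 genes (the prior is estimated from
    the variance ensemble). When all variances are identical the ensemble
    carries no information and the stage is a logged no-op.
    """
    if len(de) < 10:
        raise ValidationError("eBayes moderation needs >= 10 genes")
    s2 = de["s2_pooled"].to_numpy()
    df = float(de["df"].iloc[0])
    if np.ptp(np.log(s2)) < 1e-12:
        logger.warning("degenerate variance ensemble (all equal); moderation is a no-op")
        return de.copy()

    d0, s0_2 = _fit_variance_prior(s2, df)
    s2_post = squeeze_variances(s2, df, d0, s0_2)
    n1 = int(de["n_case"].iloc[0])
    n2 = int(de["n_ctrl"].iloc[0])
    t_mod = de["delta_log2"].to_numpy() / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    df_mod = df + (d0 if np.isfinite(d0) else np.inf)
    if np.isinf(df_mod):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_mod)

    out = de.copy()
    out["t_stat"] = t_mod
    out["p_value"] = p
    out["q_value"] = bh_adjust(p)
    out["s2_pooled"] = s2_post
    out["df"] = df_mod
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_2
    return out
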