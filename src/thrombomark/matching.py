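"""Nested case-control construction by propensity-score matching.

Cases (VTE) and controls are paired 1:1 by greedy nearest-neighbor matching
without replacement on the logit propensity scale, with a caliper expressed
as a multiple (default 0.2) of the standard deviation of the logit
propensity score. Balance before and after matching is reported as
standardized differences in percent, with the control-minus-case sign
convention; |D*| < 10% conventionally indicates adequate balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ClinicalCohort, ValidationError

__all__ = [
    "PropensityModel",
    "MatchResult",
    "fit_propensity",
    "match_nearest_neighbor",
    "standardized_difference",
    "standardized_difference_continuous",
    "balance_report",
]

logger = logging.getLogger(__name__)


@dataclass
class PropensityModel:
    """Fitted logistic model of case status on the matching covariates."""

    covariates: tuple[str, ...]
    coefficients: pd.Series
    intercept: float
    propensity: pd.Series  # indexed by patient_id, in (0, 1)
    vte: pd.Series  # indexed by patient_id, bool

    def __post_init__(self) -> None:
        p = self.propensity.to_numpy()
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValidationError("propensities must lie strictly in (0, 1)")
        if len(self.coefficients) != len(self.covariates):
            raise ValidationError("coefficient vector length != covariate count")


@dataclass
class MatchResult:
    """1:1 matched pairs plus the per-covariate balance diagnostics."""

    pairs: list[tuple[str, str]]
    caliper: float
    caliper_width: float  # caliper * SD(logit propensity), on the logit scale
    unmatched_cases: list[str]
    balance_table: pd.DataFrame | None = field(default=None)

    @property
    def matched_case_ids(self) -> list[str]:
        return [c for c, _ in self.pairs]

    @property
    def matched_control_ids(self) -> list[str]:
        return [c for _, c in self.pairs]

    def matched_ids(self) -> list[str]:
        return self.matched_case_ids + self.matched_control_ids


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for name in X.columns:
        x = X[name].to_numpy()
        if len(np.unique(x)) != 2:
            continue
        lo, hi = np.unique(x)
        case_vals = set(np.unique(x[y == 1]))
        ctrl_vals = set(np.unique(x[y == 0]))
        if case_vals.isdisjoint(ctrl_vals):
            raise SeparationError(
                f"covariate {name!r} perfectly separates cases from controls"
            )


def fit_propensity(cohort: ClinicalCohort, covariates: list[str]) -> PropensityModel:
    """Maximum-likelihood logistic fit of VTE status on the covariates.

    Thromboprophylaxis users must already have been excluded upstream (the
    study's exclusion rule); the function refuses cohorts still carrying them.
    """
    missing = [c for c in covariates if c not in cohort.table.columns]
    if missing:
        raise ValidationError(f"covariates not in cohort: {missing}")
    if cohort.table["thromboprophylaxis"].astype(bool).any():
        raise ValidationError(
            "cohort still contains thromboprophylaxis users; "
            "call exclude_thromboprophylaxis() first"
        )
    y = cohort.table["vte"].to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("cohort needs at least one case and one control")

    X = cohort.table[list(covariates)].astype(float)
    constant = [c for c in covariates if X[c].nunique() == 1]
    if constant:
        raise ValidationError(
            f"covariates with zero variance cannot enter the model: {constant}"
        )
    _check_separation(X, y)
    design = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise SeparationError(f"logistic fit failed: {exc}") from exc

    propensity = pd.Series(
        np.asarray(fit.predict(design)), index=cohort.table["patient_id"]
    )
    # Guard against numerically saturated fits.
    eps = 1e-12
    propensity = propensity.clip(eps, 1 - eps)
    return PropensityModel(
        covariates=tuple(covariates),
        coefficients=pd.Series(fit.params[list(covariates)].to_numpy(), index=list(covariates)),
        intercept=float(fit.params["const"]),
        propensity=propensity,
        vte=pd.Series(y.astype(bool).tolist(), index=cohort.table["patient_id"]),
    )


def match_nearest_neighbor(
    model: PropensityModel, ratio: int = 1, caliper: float = 0.2
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Distances are computed on the logit propensity scale; cases are processed
    in descending propensity order (ties by input order) and a control is
    eligible only within ``caliper`` x SD(logit propensity). Cases with no
    eligible control are listed in ``unmatched_cases``, never dropped
    silently.
    """
    if ratio != 1:
        raise ValidationError("only 1:1 matching is supported")
    if caliper <= 0:
        raise ValidationError("caliper must be positive")

    ids = model.propensity.index.to_numpy()
    ps = model.propensity.to_numpy()
    logit_ps = np.log(ps / (1 - ps))
    vte = model.vte.to_numpy(dtype=bool)

    sd = float(np.std(logit_ps, ddof=1)) if len(logit_ps) > 1 else 0.0
    # Degenerate case: all propensities identical -> any distance-0 match is in.
    width = caliper * sd if sd > 0 else np.inf

    case_idx = np.flatnonzero(vte)
    ctrl_idx = np.flatnonzero(~vte)
    # Descending propensity; stable sort keeps input order on ties.
    case_order = case_idx[np.argsort(-logit_ps[case_idx], kind="stable")]

    available = np.ones(len(ctrl_idx), dtype=bool)
    ctrl_logit = logit_ps[ctrl_idx]
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for ci in case_order:
        dist = np.abs(ctrl_logit - logit_ps[ci])
        dist[~available] = np.inf
        j = int(np.argmin(dist))  # ties -> lowest input index
        if np.isfinite(dist[j]) and dist[j] <= width:
            available[j] = False
            pairs.append((str(ids[ci]), str(ids[ctrl_idx[j]])))
        else:
            unmatched.append(str(ids[ci]))
    if unmatched:
        logger.info("%d cases left unmatched by the caliper", len(unmatched))
    return MatchResult(
        pairs=pairs,
        caliper=caliper,
        caliper_width=float(width) if np.isfinite(width) else 0.0,
        unmatched_cases=unmatched,
    )


def standardized_difference(p_case: float, p_ctrl: float) -> float:
    """Standardized difference (%) between two proportions.

    100 * (p_ctrl - p_case) / sqrt((p_case(1-p_case) + p_ctrl(1-p_ctrl)) / 2);
    the control-minus-case sign convention makes case-excess covariates
    negative.
    """
    for p in (p_case, p_ctrl):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"proportion out of [0, 1]: {p}")
    pooled_var = (p_case * (1 - p_case) + p_ctrl * (1 - p_ctrl)) / 2
    if pooled_var == 0:
        raise ValidationError(
            "standardized difference undefined: both groups have zero variance"
        )
    return 100.0 * (p_ctrl - p_case) / np.sqrt(pooled_var)


def standardized_difference_continuous(
    m_case: float, m_ctrl: float, s_case: float, s_ctrl: float
) -> float:
    """Standardized difference (%) between two means with group SDs."""
    pooled_var = (s_case**2 + s_ctrl**2) / 2
    if pooled_var == 0:
        raise ValidationError(
            "standardized difference undefined: both groups have zero variance"
        )
    return 100.0 * (m_ctrl - m_case) / np.sqrt(pooled_var)


def _group_dstar(case_vals: np.ndarray, ctrl_vals: np.ndarray, binary: bool) -> float:
    try:
        if binary:
            return standardized_difference(case_vals.mean(), ctrl_vals.mean())
        return standardized_difference_continuous(
            case_vals.mean(),
            ctrl_vals.mean(),
            case_vals.std(ddof=1),
            ctrl_vals.std(ddof=1),
        )
    except ValidationError:
        return float("nan")


def balance_report(cohort: ClinicalCohort, match: MatchResult) -> pd.DataFrame:
    """Per-covariate balance table before and after matching.

    Binary covariates use the proportion form of the standardized difference,
    continuous ones (``age``) the mean/SD form. Covariates that are constant
    in both groups get NaN.
    """
    t = cohort.table.set_index("patient_id")
    vte = t["vte"].astype(bool)
    matched_cases = match.matched_case_ids
    matched_ctrls = match.matched_control_ids

    rows = []
    for cov in ("age",) + tuple(cohort.covariates):
        vals = t[cov].astype(float)
        binary = set(np.unique(vals)) <= {0.0, 1.0}
        before_case = vals[vte].to_numpy()
        before_ctrl = vals[~vte].to_numpy()
        after_case = vals.loc[matched_cases].to_numpy()
        after_ctrl = vals.loc[matched_ctrls].to_numpy()
        rows.append(
            {
                "covariate": cov,
                "case_before": before_case.mean(),
                "ctrl_before": before_ctrl.mean(),
                "d_star_before": _group_dstar(before_case, before_ctrl, binary),
                "case_after": after_case.mean() if len(after_case) else float("nan"),
                "ctrl_after": after_ctrl.mean() if len(after_ctrl) else float("nan"),
                "d_star_after": (
                    _group_dstar(after_case, after_ctrl, binary)
                    if len(after_case) and len(after_ctrl)
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
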