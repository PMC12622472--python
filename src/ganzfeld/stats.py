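"""Group statistics: dispersion mixed model with Tukey pairwise contrasts,
one-sample tests against the zero anchor with Bonferroni correction, and
qualitative count-to-percentage summary tables.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "dispersion_lmm_tukey",
    "DispersionLMMResult",
    "t_vs_zero_bonferroni",
    "category_percentages",
    "asc_dimension_summary",
]

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# dispersion mixed model
# ----------------------------------------------------------------------

@dataclass
class DispersionLMMResult:
    """Random-intercept model of per-epoch gaze SD for one eye x axis.

    ``fixed_effects`` holds the epoch means relative to baseline (treatment
    coding); ``pairwise`` holds every epoch-type contrast with familywise
    Tukey-adjusted p-values from the studentized range distribution.
    """

    eye: str
    axis: str
    fixed_effects: pd.DataFrame
    pairwise: pd.DataFrame
    converged: bool


def dispersion_lmm_tukey(
    records: pd.DataFrame, eye: str = "left", axis: str = "x"
) -> DispersionLMMResult:
    """Fit ``sd_deg ~ epoch_type`` (baseline reference) with participant
    random intercepts and report all pairwise Tukey-corrected contrasts.

    Degrees of freedom use a between-within residual approximation.
    A singular random-effects fit falls back to pooled OLS with a warning.
    """
    import statsmodels.formula.api as smf

    df = records[(records.eye == eye) & (records.axis == axis)].copy()
    if df.participant.nunique() < 2:
        raise ValueError("need at least 2 participants")
    types = [
        t for t in ("baseline", "hallucination", "decay", "pre_decay")
        if t in set(df.epoch_type)
    ]
    if len(types) < 2:
        raise ValueError("need at least 2 epoch types")
    missing = {"baseline", "hallucination", "decay", "pre_decay"} - set(types)
    if missing:
        warnings.warn(f"epoch types absent, contrasts omitted: {sorted(missing)}")

    ref = "baseline" if "baseline" in types else types[0]
    formula = f"sd_deg ~ C(epoch_type, Treatment('{ref}'))"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, df, groups=df["participant"]).fit(
                reml=True, method="lbfgs"
            )
            if not fit.converged or not np.isfinite(np.asarray(fit.bse)).all():
                raise np.linalg.LinAlgError("singular mixed fit")
            params, cov = fit.params, fit.cov_params()
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn("singular mixed-model fit; falling back to pooled OLS")
            converged = False
            ols = smf.ols(formula, df).fit()
            params, cov = ols.params, ols.cov_params()

    dof = max(float(len(df) - df.participant.nunique() - len(types) + 1), 1.0)

    def term(t: str) -> str:
        return f"C(epoch_type, Treatment('{ref}'))[T.{t}]"

    # cell mean of each epoch type as a linear combination of the parameters
    combos: Dict[str, pd.Series] = {}
    for t in types:
        c = pd.Series(0.0, index=params.index)
        c["Intercept"] = 1.0
        if t != ref:
            c[term(t)] = 1.0
        combos[t] = c

    fixed_rows = []
    for t in types:
        est = float(combos[t] @ params)
        se = float(np.sqrt(combos[t] @ cov.values @ combos[t]))
        fixed_rows.append({"epoch_type": t, "mean_sd_deg": est, "SE": se})
    fixed = pd.DataFrame(fixed_rows)

    k = len(types)
    # estimates and SEs below machine-noise scale are exact zeros
    zero_tol = 1e-10 * max(1.0, float(np.abs(df.sd_deg).max()))
    pair_rows = []
    for t1, t2 in itertools.combinations(types, 2):
        c = combos[t1] - combos[t2]
        est = float(c @ params)
        se = float(np.sqrt(c @ cov.values @ c))
        if abs(est) < zero_tol and se < zero_tol:
            est, se = 0.0, 0.0
        if se == 0.0:
            tval, p_raw = (0.0, 1.0) if est == 0.0 else (np.inf, 0.0)
        else:
            tval = est / se
            p_raw = float(2 * sps.t.sf(abs(tval), dof))
        p_adj = float(sps.studentized_range.sf(abs(tval) * np.sqrt(2), k, dof)) if k > 2 else p_raw
        p_adj = min(1.0, max(p_adj, p_raw))
        pair_rows.append(
            {
                "contrast": f"{t1} - {t2}",
                "estimate": est,
                "SE": se,
                "df": dof,
                "t": tval,
                "p_raw": p_raw,
                "p_tukey": p_adj,
            }
        )
    return DispersionLMMResult(
        eye=eye, axis=axis, fixed_effects=fixed, pairwise=pd.DataFrame(pair_rows),
        converged=converged,
    )


# ----------------------------------------------------------------------
# one-sample tests against the zero anchor
# ----------------------------------------------------------------------

def t_vs_zero_bonferroni(
    scores: Mapping[str, Sequence[float]], m: Optional[int] = None
) -> pd.DataFrame:
    """One-sample t-test of each score vector against zero, with Bonferroni
    adjustment ``p_adj = min(1, m * p_raw)`` over ``m`` tests (default: the
    number of vectors)."""
    m = m if m is not None else len(scores)
    if m < len(scores):
        raise ValueError("m must cover the number of tests")
    rows = []
    for label, vec in scores.items():
        x = np.asarray(vec, dtype=float)
        if len(x) < 2:
            raise ValueError(f"{label}: need at least 2 observations")
        if np.std(x, ddof=1) == 0:
            raise ValueError(f"{label}: degenerate scores (zero variance)")
        t, p = sps.ttest_1samp(x, 0.0)
        rows.append(
            {
                "label": label,
                "n": len(x),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "t": float(t),
                "df": len(x) - 1,
                "p_raw": float(p),
                "p_adj": min(1.0, m * float(p)),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# qualitative count -> percentage tables
# ----------------------------------------------------------------------

#: Interviewed sample sizes per experiment (denominators for percentages).
DEFAULT_DENOMINATORS: Dict[int, int] = {1: 27, 2: 41, 3: 66}


def category_percentages(
    counts: pd.DataFrame, denominators: Optional[Mapping[int, int]] = None
) -> pd.DataFrame:
    """Per-experiment and pooled percentages for interview category counts.

    ``counts`` has columns category, experiment, count.  The pooled
    percentage of a category uses the sum of counts over the sum of the
    denominators of the experiments present in that category's rows (a
    weighted mean of the per-experiment percentages).  Full precision is
    retained; display rounding is left to the caller.
    """
    denominators = dict(denominators or DEFAULT_DENOMINATORS)
    for d in denominators.values():
        if d <= 0:
            raise ValueError("denominators must be positive")
    rows = []
    for category, grp in counts.groupby("category", sort=False):
        n_total, d_total = 0, 0
        for _, r in grp.iterrows():
            exp = int(r.experiment)
            if exp not in denominators:
                raise ValueError(f"no denominator for experiment {exp}")
            if not 0 <= r["count"] <= denominators[exp]:
                raise ValueError(
                    f"count {r['count']} exceeds denominator {denominators[exp]} "
                    f"({category}, experiment {exp})"
                )
            n_total += int(r["count"])
            d_total += denominators[exp]
            rows.append(
                {
                    "category": category,
                    "experiment": exp,
                    "n": int(r["count"]),
                    "pct": 100.0 * r["count"] / denominators[exp],
                    "n_total": np.nan,
                    "pct_total": np.nan,
                }
            )
        rows.append(
            {
                "category": category,
                "experiment": 0,  # 0 marks the pooled row
                "n": n_total,
                "pct": np.nan,
                "n_total": n_total,
                "pct_total": 100.0 * n_total / d_total,
            }
        )
    return pd.DataFrame(rows)


def asc_dimension_summary(
    scores: pd.DataFrame, m: Optional[int] = None
) -> pd.DataFrame:
    """Mean/SD per questionnaire dimension and experiment (radar-chart data),
    with one-sample tests against the zero anchor Bonferroni-corrected across
    dimensions.

    ``scores`` has columns dimension, experiment, score (one row per
    participant x dimension).  Degenerate dimensions (zero variance or a
    single participant) are flagged rather than tested.
    """
    dims = list(scores.dimension.unique())
    m = m if m is not None else len(dims)
    rows = []
    for (dim, exp), grp in scores.groupby(["dimension", "experiment"], sort=False):
        x = grp.score.to_numpy(float)
        n = len(x)
        if n == 1:
            warnings.warn(f"{dim} (experiment {exp}): single participant, SD reported as 0")
            sd = 0.0
        else:
            sd = float(np.std(x, ddof=1))
        row = {
            "dimension": dim,
            "experiment": exp,
            "n": n,
            "mean": float(np.mean(x)),
            "sd": sd,
            "t": np.nan,
            "df": n - 1,
            "p_raw": np.nan,
            "p_adj": np.nan,
            "degenerate": False,
        }
        if n >= 2 and sd > 0:
            t, p = sps.ttest_1samp(x, 0.0)
            row.update(t=float(t), p_raw=float(p), p_adj=min(1.0, m * float(p)))
        else:
            row["degenerate"] = True
            log.info("degenerate score vector flagged: %s (experiment %s)", dim, exp)
        rows.append(row)
    return pd.DataFrame(rows)
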