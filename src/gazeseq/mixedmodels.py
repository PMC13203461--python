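"""Linear mixed-effects models for the gaze stability index.

Two specifications, both with a random intercept per participant and
REML estimation (delegated to statsmodels' ``MixedLM``):

* ``aoi_only``:     stability ~ AOI + (1 | participant), fit on
  participant x zone aggregates;
* ``aoi_by_event``: stability ~ AOI * EventType + (1 | participant),
  fit on trial-level rows carrying a ``condition`` column.

Fixed-effect contrasts are reported relative to the Lower Facial Zone.
Per-term ANOVA F statistics use Wald contrasts on the fixed effects
with residual (containment) denominator degrees of freedom
``n_obs - k_fixed`` — for 27 participants x 3 zones that is
81 - 3 = 78.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = ["MixedModelResult", "fit_stability_lmm"]

REFERENCE_ZONE = "LFZ"

_FORMULAS = {
    "aoi_only": "stability ~ C(zone, Treatment('LFZ'))",
    "aoi_by_event": "stability ~ C(zone, Treatment('LFZ')) * C(condition)",
}


@dataclass
class MixedModelResult:
    """REML fit of a stability mixed model."""

    variant: str
    formula: str
    fixed_effects: pd.DataFrame  # term, estimate, se, t, p
    anova: pd.DataFrame  # term, F, df_num, df_den, p
    reference_zone: str
    n_obs: int
    n_participants: int
    random_intercept_var: float
    residual_var: float
    singular: bool
    converged: bool


def _pretty_term(name: str) -> str:
    return (
        name.replace("C(zone, Treatment('LFZ'))", "zone")
        .replace("C(condition)", "condition")
        .replace("[T.", "[")
    )


def fit_stability_lmm(table: pd.DataFrame, variant: str = "aoi_only") -> MixedModelResult:
    """Fit a stability mixed model and summarize contrasts and ANOVA.

    ``table`` is a long stability table with columns ``participant``,
    ``zone``, ``stability`` (plus ``condition`` for ``aoi_by_event``).
    Each fixed factor needs >= 2 observed levels.  A singular fit
    (random-intercept variance estimated at ~0, or non-convergence) is
    flagged in the result, not raised.
    """
    if variant not in _FORMULAS:
        raise ValueError(f"unknown variant {variant!r}")
    required = {"participant", "zone", "stability"}
    if variant == "aoi_by_event":
        required.add("condition")
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for factor in ("zone",) + (("condition",) if variant == "aoi_by_event" else ()):
        if table[factor].nunique() < 2:
            raise ValueError(f"fixed factor {factor!r} needs >= 2 levels")

    formula = _FORMULAS[variant]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=table, groups=table["participant"])
        fit = model.fit(reml=True)

    fe = fit.fe_params
    cov = np.asarray(fit.cov_params())[: len(fe), : len(fe)]
    se = np.sqrt(np.diag(cov))
    n_obs = int(fit.nobs)
    k_fixed = len(fe)
    df_den = n_obs - k_fixed
    tvals = fe.to_numpy() / se
    fixed = pd.DataFrame(
        {
            "term": [_pretty_term(t) for t in fe.index],
            "estimate": fe.to_numpy(),
            "se": se,
            "t": tvals,
            "p": 2 * stats.t.sf(np.abs(tvals), df_den),
        }
    )

    # Per-term Wald F tests against the residual/containment df.
    design_info = model.data.design_info
    anova_rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(fe))[sl]
        b = fe.to_numpy()[idx]
        v = cov[np.ix_(idx, idx)]
        q = len(idx)
        f_stat = float(b @ np.linalg.solve(v, b)) / q
        anova_rows.append(
            {
                "term": _pretty_term(term),
                "F": f_stat,
                "df_num": q,
                "df_den": df_den,
                "p": float(stats.f.sf(f_stat, q, df_den)),
            }
        )

    re_var = float(np.asarray(fit.cov_re)[0, 0])
    singular = (not fit.converged) or re_var < 1e-10 * max(fit.scale, 1e-300)
    return MixedModelResult(
        variant=variant,
        formula=formula,
        fixed_effects=fixed,
        anova=pd.DataFrame(anova_rows),
        reference_zone=REFERENCE_ZONE,
        n_obs=n_obs,
        n_participants=int(table["participant"].nunique()),
        random_intercept_var=re_var,
        residual_var=float(fit.scale),
        singular=bool(singular),
        converged=bool(fit.converged),
    )
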