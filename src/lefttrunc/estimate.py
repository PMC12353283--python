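"""Risks, risk differences and risk ratios in two analysis scopes.

The same cohort is analysed twice, stratified by abnormal placentation (Z):

* ``unobserved`` — the conception cohort: every implanted conceptus is in the
  denominator of its (Z, X) arm, and conceptuses lost to spontaneous abortion
  contribute zero outcome events (a spontaneous abortion precludes stillbirth
  and neonatal death).
* ``observed`` — the left-truncated cohort a study entering at 20 weeks would
  see: denominators restricted to survivors (C=0), exposure read from the
  abruption diagnosis M (equal to the onset X on C=0).

Numerators coincide in the two scopes, so the observed risk is never smaller
than the unobserved one; differential censoring across exposure arms is what
turns this into bias in the risk difference and the risk ratio.

The primary computation is closed-form cell arithmetic. A saturated log-link
binomial GLM fit is provided as a cross-check: for a saturated model the MLE
reproduces the empirical cell risks exactly, so the two routes must agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import CohortCounts

__all__ = [
    "SCOPES",
    "EffectEstimates",
    "InestimableError",
    "estimate_effects",
    "fit_saturated_log_binomial",
]

SCOPES = ("observed", "unobserved")


class InestimableError(ValueError):
    """The saturated model cannot be fit (an empty cell or zero-risk cell)."""


@dataclass(frozen=True)
class EffectEstimates:
    """Exposure-outcome contrasts in one stratum under one analysis scope.

    Undefined quantities are NaN with the reason in ``flags``: a zero
    denominator makes the risk (and everything downstream) undefined; a zero
    unexposed risk leaves the risks and RD defined but the RR undefined.
    """

    scope: str
    stratum: int
    risk_exposed: float
    risk_unexposed: float
    rd: float
    rr: float
    # (denom exposed, denom unexposed, events exposed, events unexposed)
    cell_denominators: tuple[int, int, int, int]
    flags: tuple[str, ...] = ()

    @property
    def is_defined(self) -> bool:
        return not self.flags


def _stratum_estimate(counts: CohortCounts, scope: str, z: int) -> EffectEstimates:
    c = counts.counts
    flags: list[str] = []
    # events never occur in C=1 cells, but sum over c for robustness to
    # externally constructed counts
    events = {x: int(c[z, x, :, 1].sum()) for x in (0, 1)}
    if scope == "unobserved":
        denom = {x: int(c[z, x, :, :].sum()) for x in (0, 1)}
    else:
        denom = {x: int(c[z, x, 0, :].sum()) for x in (0, 1)}

    if denom[1] == 0 or denom[0] == 0:
        flags.append("zero_denominator")
        risk1 = events[1] / denom[1] if denom[1] else math.nan
        risk0 = events[0] / denom[0] if denom[0] else math.nan
        rd = rr = math.nan
    else:
        risk1 = events[1] / denom[1]
        risk0 = events[0] / denom[0]
        rd = risk1 - risk0
        if risk0 == 0.0:
            flags.append("zero_unexposed_risk")
            rr = math.nan
        else:
            rr = risk1 / risk0
    return EffectEstimates(scope=scope, stratum=z,
                           risk_exposed=risk1, risk_unexposed=risk0,
                           rd=rd, rr=rr,
                           cell_denominators=(denom[1], denom[0], events[1], events[0]),
                           flags=tuple(flags))


def estimate_effects(counts: CohortCounts, scope: str) -> tuple[EffectEstimates, EffectEstimates]:
    """Closed-form risks, RD and RR per placentation stratum.

    Returns the (stratum 0, stratum 1) pair. In the observed scope the
    exposure is the abruption diagnosis M, which equals the onset X on the
    C=0 survivors, so both scopes share the same exposure columns.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    return _stratum_estimate(counts, scope, 0), _stratum_estimate(counts, scope, 1)


def fit_saturated_log_binomial(counts: CohortCounts, scope: str) -> dict[str, float]:
    """ML coefficients of the saturated model log Pr(out) = a0 + a1 X + a2 Z + a3 XZ.

    Because the model is saturated, exp of the fitted coefficients reproduces
    the four empirical cell risks exactly; this is the equivalence check on
    :func:`estimate_effects`, not the workhorse. The iteration is started at
    the closed-form solution, so convergence is immediate and the usual
    log-link fragility near risk 1 cannot bite.

    Returns ``{"a0": ..., "a1": ..., "a2": ..., "a3": ...}`` on the log scale.
    """
    import warnings

    import statsmodels.api as sm

    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    c = counts.counts
    rows = []  # (x, z, events, denom)
    for z in (0, 1):
        for x in (0, 1):
            events = int(c[z, x, :, 1].sum())
            denom = int(c[z, x, :, :].sum()) if scope == "unobserved" \
                else int(c[z, x, 0, :].sum())
            rows.append((x, z, events, denom))
    if any(d == 0 for *_, d in rows):
        raise InestimableError("empty (Z, X) cell under this scope")
    if any(e == 0 for _, _, e, _ in rows):
        raise InestimableError("zero-event cell: log-scale coefficients undefined")

    exog = np.array([[1.0, x, z, x * z] for x, z, _, _ in rows])
    endog = np.array([[e, d - e] for _, _, e, d in rows], dtype=float)
    risks = np.array([e / d for _, _, e, d in rows])
    # closed-form MLE of the saturated model
    start = np.linalg.solve(exog, np.log(risks))
    with warnings.catch_warnings():
        # saturated log-link fit: domain warning and zero residual df are inherent
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, exog,
                       family=sm.families.Binomial(link=sm.families.links.Log()))
        res = model.fit(start_params=start, maxiter=100)
    a = res.params
    return {"a0": float(a[0]), "a1": float(a[1]), "a2": float(a[2]), "a3": float(a[3])}
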