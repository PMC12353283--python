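"""Closed-form expectations of every simulated quantity.

Under the generative model all expectations are available in closed form,
which makes this module the backbone of testing: Monte-Carlo output must
converge to these values as cohorts grow.

Writing q(x, z) = 1 - Pr(C=1 | X=x, Z=z) for the survival (non-SAB) fraction
of an exposure arm and r(x, z) for the outcome risk among survivors,

* observed risk   = r(x, z)             (denominator: survivors),
* unobserved risk = q(x, z) * r(x, z)   (denominator: all conceptions),
* RR fold bias    = q(0, z) / q(1, z)   (the outcome model cancels),
* RD bias         = r(1,z) * (1 - q(1,z)) - r(0,z) * (1 - q(0,z)).

The marginal censoring proportion is linear in the per-cohort abruption
probability, so taking the uniform-support midpoint E[pX|z] is exact even
though cohorts draw pX at random; the within-stratum risks, RD and RR do not
involve pX at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .scenarios import ParameterError, ScenarioParams, validate_params

__all__ = [
    "AnalyticExpectation",
    "survival_fraction",
    "survivor_risk",
    "expected_censoring",
    "expected_risks",
    "expected_bias",
    "expectation",
    "grid_expectations",
]


def _validated(p: ScenarioParams) -> None:
    if not validate_params(p).valid:
        raise ParameterError("setup implies probability > 1")


def survival_fraction(p: ScenarioParams, x: int, z: int) -> float:
    """q(x, z): probability of escaping spontaneous abortion in arm (x, z)."""
    return 1.0 - p.pC_base * p.rr_C_Z**z * p.rr_C_X**x * p.rr_C_interaction**(x * z)


def survivor_risk(p: ScenarioParams, x: int, z: int) -> float:
    """r(x, z): outcome risk among survivors (diagnosis m = x on C=0)."""
    return p.pOut_base * p.rr_Out_M**x * p.rr_Out_Z**z * p.rr_Out_interaction**(x * z)


def expected_censoring(p: ScenarioParams) -> float:
    """Expected marginal Pr(C=1), averaging over the abruption-probability draw."""
    _validated(p)
    total = 0.0
    for z, pz in ((0, 1.0 - p.pi_Z), (1, p.pi_Z)):
        e_px = sum(p.pX_range_Z1 if z else p.pX_range_Z0) / 2.0
        rr_x = p.rr_C_X * p.rr_C_interaction**z
        total += pz * p.pC_base * p.rr_C_Z**z * (1.0 + (rr_x - 1.0) * e_px)
    return total


def expected_risks(p: ScenarioParams, z: int) -> dict[str, dict[str, float]]:
    """Expected risks, RD and RR per scope in stratum z."""
    _validated(p)
    out: dict[str, dict[str, float]] = {}
    for scope in ("observed", "unobserved"):
        risk = {x: survivor_risk(p, x, z) * (1.0 if scope == "observed"
                                             else survival_fraction(p, x, z))
                for x in (0, 1)}
        out[scope] = {
            "risk_exposed": risk[1],
            "risk_unexposed": risk[0],
            "rd": risk[1] - risk[0],
            "rr": risk[1] / risk[0],
        }
    return out


def expected_bias(p: ScenarioParams, z: int) -> tuple[float, float]:
    """(rd_bias, rr_relative_bias) expected in stratum z.

    The fold bias q(0,z)/q(1,z) depends only on the censoring model — the
    outcome parameters cancel — while the RD bias scales with the survivor
    risks: r(1,z)*(1-q(1,z)) - r(0,z)*(1-q(0,z)).
    """
    _validated(p)
    q0, q1 = survival_fraction(p, 0, z), survival_fraction(p, 1, z)
    if q1 == 0.0:
        raise ParameterError("q(1, z) = 0: fold bias undefined")
    rd_bias = survivor_risk(p, 1, z) * (1.0 - q1) - survivor_risk(p, 0, z) * (1.0 - q0)
    return rd_bias, q0 / q1


@dataclass(frozen=True)
class AnalyticExpectation:
    """All closed-form expectations for one setup (strata keyed 0/1)."""

    setup_id: int
    expected_censoring: float
    q: dict[tuple[int, int], float]          # (x, z) -> survival fraction
    risks: dict[int, dict[str, dict[str, float]]]  # z -> scope -> quantities
    rd_bias: dict[int, float]
    rr_relative_bias: dict[int, float]


def expectation(p: ScenarioParams) -> AnalyticExpectation:
    _validated(p)
    risks = {z: expected_risks(p, z) for z in (0, 1)}
    biases = {z: expected_bias(p, z) for z in (0, 1)}
    return AnalyticExpectation(
        setup_id=p.setup_id,
        expected_censoring=expected_censoring(p),
        q={(x, z): survival_fraction(p, x, z) for x in (0, 1) for z in (0, 1)},
        risks=risks,
        rd_bias={z: biases[z][0] for z in (0, 1)},
        rr_relative_bias={z: biases[z][1] for z in (0, 1)},
    )


def grid_expectations(grid: list[ScenarioParams]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-setup expectation table plus across-grid spans.

    Returns ``(table, spans)``: one row per (setup, stratum) with every
    expected quantity, and one row per (stratum, quantity) with the min and
    max across the grid — the analytic counterpart of the headline
    across-setup ranges.
    """
    if not grid:
        raise ValueError("empty grid")
    rows = []
    for p in grid:
        e = expectation(p)
        for z in (0, 1):
            rows.append({
                "setup_id": p.setup_id,
                "stratum": z,
                "expected_censoring": e.expected_censoring,
                "q_unexposed": e.q[(0, z)],
                "q_exposed": e.q[(1, z)],
                "risk_exposed_observed": e.risks[z]["observed"]["risk_exposed"],
                "risk_unexposed_observed": e.risks[z]["observed"]["risk_unexposed"],
                "risk_exposed_unobserved": e.risks[z]["unobserved"]["risk_exposed"],
                "risk_unexposed_unobserved": e.risks[z]["unobserved"]["risk_unexposed"],
                "rd_observed": e.risks[z]["observed"]["rd"],
                "rd_unobserved": e.risks[z]["unobserved"]["rd"],
                "rr_observed": e.risks[z]["observed"]["rr"],
                "rr_unobserved": e.risks[z]["unobserved"]["rr"],
                "rd_bias": e.rd_bias[z],
                "rr_relative_bias": e.rr_relative_bias[z],
            })
    table = pd.DataFrame(rows)
    quantities = [c for c in table.columns if c not in ("setup_id", "stratum")]
    span_rows = []
    for z, grp in table.groupby("stratum"):
        for q in quantities:
            span_rows.append({"stratum": z, "quantity": q,
                              "min": float(grp[q].min()),
                              "max": float(grp[q].max())})
    return table, pd.DataFrame(span_rows)
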