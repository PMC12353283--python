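"""Simulation-setup grid for the abruption → perinatal-mortality truncation study.

Each setup is one combination of the generative parameters of a conception
cohort: the prevalence of abnormal placentation (Z), the uniform supports for
the per-cohort abruption-onset probability Pr(X|Z), a multiplicative risk model
for spontaneous abortion (C) given Z and X, and a multiplicative risk model for
the outcome (perinatal mortality Y, or stillbirth S in the sensitivity family)
given abruption diagnosis M and Z among pregnancies surviving past 20 weeks.

The full design is 80 setups: 10 primary perinatal-mortality setups, 30
mortality sensitivity setups (higher Z prevalence and/or the alternative
baseline-risk / abruption-RR outcome pairing), and 40 stillbirth setups
mirroring the first 40.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ScenarioParams",
    "ValidationResult",
    "ParameterError",
    "FAMILIES",
    "validate_params",
    "build_grid",
    "full_grid",
    "grid_to_frame",
    "grid_from_frame",
    "write_grid",
    "read_grid",
]

FAMILIES = ("primary", "sensitivity_mortality", "sensitivity_stillbirth")
OUTCOME_TYPES = ("perinatal_mortality", "stillbirth")

# Shared across every setup (single published design).
PX_RANGE_Z1 = (0.005, 0.050)
PX_RANGE_Z0 = (0.001, 0.020)
PC_BASE = 0.05

RR_C_Z_LEVELS = (2.0, 4.0, 6.0)
RR_C_X_LEVELS = (2.0, 4.5)
RR_OUT_Z_LEVELS = (2.0, 4.0)

PI_Z_PRIMARY = 0.1
PI_Z_ALT = 0.2

# (baseline outcome risk, outcome RR for diagnosed abruption). The alternative
# pairing keeps the abruption-stratum baseline risk nearly constant
# (0.0082*14.5 ~= 0.0120*9.9).
MORTALITY_PAIRINGS = ((0.0082, 14.5), (0.0120, 9.9))
STILLBIRTH_PAIRINGS = ((0.0053, 14.5), (0.0077, 9.9))


class ParameterError(ValueError):
    """A scenario field is malformed (negative, non-finite, or out of domain)."""


@dataclass(frozen=True)
class ScenarioParams:
    """One simulation setup: all generative probabilities and risk ratios.

    Multiplicative (log-link) risk models:

    * spontaneous abortion:
      ``Pr(C=1|Z,X) = pC_base * rr_C_Z**Z * rr_C_X**X * rr_C_interaction**(X*Z)``
    * outcome among survivors (C=0, with diagnosis M = X):
      ``Pr(out=1|M,Z,C=0) = pOut_base * rr_Out_M**M * rr_Out_Z**Z
      * rr_Out_interaction**(M*Z)``; the outcome is deterministically 0 when
      C=1 (a spontaneous abortion precludes stillbirth and neonatal death).
    """

    setup_id: int
    analysis_family: str
    pi_Z: float
    pX_range_Z1: tuple[float, float]
    pX_range_Z0: tuple[float, float]
    pC_base: float
    rr_C_Z: float
    rr_C_X: float
    rr_C_interaction: float
    pOut_base: float
    rr_Out_M: float
    rr_Out_Z: float
    rr_Out_interaction: float
    outcome_type: str

    @property
    def max_sab_prob(self) -> float:
        """Largest fitted Pr(C=1): the (Z=1, X=1) cell."""
        return self.pC_base * self.rr_C_Z * self.rr_C_X * self.rr_C_interaction

    @property
    def max_outcome_prob(self) -> float:
        """Largest fitted outcome probability: the (M=1, Z=1, C=0) cell."""
        return self.pOut_base * self.rr_Out_M * self.rr_Out_Z * self.rr_Out_interaction


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    max_sab_prob: float
    max_outcome_prob: float


def _check_malformed(p: ScenarioParams) -> None:
    import math

    probs = {
        "pi_Z": p.pi_Z,
        "pC_base": p.pC_base,
        "pOut_base": p.pOut_base,
        "pX_range_Z1[0]": p.pX_range_Z1[0],
        "pX_range_Z1[1]": p.pX_range_Z1[1],
        "pX_range_Z0[0]": p.pX_range_Z0[0],
        "pX_range_Z0[1]": p.pX_range_Z0[1],
    }
    for name, v in probs.items():
        if not math.isfinite(v) or not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name}={v!r} is not a probability in [0, 1]")
    rrs = {
        "rr_C_Z": p.rr_C_Z,
        "rr_C_X": p.rr_C_X,
        "rr_C_interaction": p.rr_C_interaction,
        "rr_Out_M": p.rr_Out_M,
        "rr_Out_Z": p.rr_Out_Z,
        "rr_Out_interaction": p.rr_Out_interaction,
    }
    for name, v in rrs.items():
        if not math.isfinite(v) or v <= 0.0:
            raise ParameterError(f"{name}={v!r} must be a finite positive risk ratio")
    for name, (lo, hi) in (("pX_range_Z1", p.pX_range_Z1), ("pX_range_Z0", p.pX_range_Z0)):
        if lo > hi:
            raise ParameterError(f"{name} low {lo!r} exceeds high {hi!r}")
    if p.analysis_family not in FAMILIES:
        raise ParameterError(f"unknown analysis_family {p.analysis_family!r}")
    if p.outcome_type not in OUTCOME_TYPES:
        raise ParameterError(f"unknown outcome_type {p.outcome_type!r}")


def validate_params(p: ScenarioParams) -> ValidationResult:
    """Check that every fitted value of both risk models is a probability.

    Returns the verdict together with the two maximal implied probabilities,
    Pr(C=1|Z=1,X=1) and Pr(outcome=1|M=1,Z=1,C=0). A setup is *invalid* (but
    well formed) iff either exceeds 1; malformed fields raise
    :class:`ParameterError` instead.
    """
    _check_malformed(p)
    max_c = p.max_sab_prob
    max_y = p.max_outcome_prob
    return ValidationResult(valid=(max_c <= 1.0 and max_y <= 1.0),
                            max_sab_prob=max_c, max_outcome_prob=max_y)


def _core_combinations() -> list[tuple[float, float, float]]:
    """The validity-filtered factorial over (rr_C_Z, rr_C_X, rr_Out_Z).

    The 3x2x2 factorial has 12 cells; the two with rr_C_Z=6 and rr_C_X=4.5
    imply Pr(C|Z=1,X=1) = 0.05*6*4.5 = 1.35 > 1 and are dropped, leaving 10.
    Ordered ascending by rr_C_Z, then rr_C_X, then rr_Out_Z.
    """
    combos = []
    for cz, cx, oz in itertools.product(RR_C_Z_LEVELS, RR_C_X_LEVELS, RR_OUT_Z_LEVELS):
        if PC_BASE * cz * cx <= 1.0:
            combos.append((cz, cx, oz))
    return combos


def _block(family: str, outcome_type: str, pi_z: float,
           pairing: tuple[float, float], first_id: int) -> list[ScenarioParams]:
    p_out, rr_m = pairing
    block = []
    for i, (cz, cx, oz) in enumerate(_core_combinations()):
        block.append(ScenarioParams(
            setup_id=first_id + i,
            analysis_family=family,
            pi_Z=pi_z,
            pX_range_Z1=PX_RANGE_Z1,
            pX_range_Z0=PX_RANGE_Z0,
            pC_base=PC_BASE,
            rr_C_Z=cz,
            rr_C_X=cx,
            rr_C_interaction=1.0,
            pOut_base=p_out,
            rr_Out_M=rr_m,
            rr_Out_Z=oz,
            rr_Out_interaction=1.0,
            outcome_type=outcome_type,
        ))
    return block


def build_grid(family: str = "primary") -> list[ScenarioParams]:
    """Construct one analysis family of the 80-setup design.

    ``primary``: 10 perinatal-mortality setups (setup_id 1-10) with
    pi_Z=0.1 and the (0.0082, 14.5) outcome pairing.

    ``sensitivity_mortality``: 30 setups (11-40) crossing the same 10-setup
    core with the alternative global settings — higher prevalence of abnormal
    placentation (pi_Z=0.2) and/or the alternative outcome pairing
    (0.0120, 9.9).

    ``sensitivity_stillbirth``: 40 setups (41-80) mirroring setups 1-40 with
    the stillbirth outcome pairings (0.0053, 14.5) and (0.0077, 9.9).
    """
    if family == "primary":
        return _block("primary", "perinatal_mortality", PI_Z_PRIMARY,
                      MORTALITY_PAIRINGS[0], first_id=1)
    if family == "sensitivity_mortality":
        grid = []
        for j, (pi_z, pairing) in enumerate([
            (PI_Z_ALT, MORTALITY_PAIRINGS[0]),
            (PI_Z_PRIMARY, MORTALITY_PAIRINGS[1]),
            (PI_Z_ALT, MORTALITY_PAIRINGS[1]),
        ]):
            grid.extend(_block("sensitivity_mortality", "perinatal_mortality",
                               pi_z, pairing, first_id=11 + 10 * j))
        return grid
    if family == "sensitivity_stillbirth":
        grid = []
        for j, (pi_z, pairing) in enumerate([
            (PI_Z_PRIMARY, STILLBIRTH_PAIRINGS[0]),
            (PI_Z_ALT, STILLBIRTH_PAIRINGS[0]),
            (PI_Z_PRIMARY, STILLBIRTH_PAIRINGS[1]),
            (PI_Z_ALT, STILLBIRTH_PAIRINGS[1]),
        ]):
            grid.extend(_block("sensitivity_stillbirth", "stillbirth",
                               pi_z, pairing, first_id=41 + 10 * j))
        return grid
    raise ParameterError(f"unknown family {family!r}; expected one of {FAMILIES}")


def full_grid() -> list[ScenarioParams]:
    """All 80 setups, setup_id 1-80."""
    return [p for fam in FAMILIES for p in build_grid(fam)]


# -- flat-table serialization (the analog of a design spreadsheet) -----------

_RANGE_COLS = {
    "pX_range_Z1": ("pX_low_Z1", "pX_high_Z1"),
    "pX_range_Z0": ("pX_low_Z0", "pX_high_Z0"),
}


def grid_to_frame(grid: Sequence[ScenarioParams]) -> pd.DataFrame:
    rows = []
    for p in grid:
        d = asdict(p)
        for field, (lo_col, hi_col) in _RANGE_COLS.items():
            lo, hi = d.pop(field)
            d[lo_col], d[hi_col] = lo, hi
        rows.append(d)
    return pd.DataFrame(rows)


def grid_from_frame(frame: pd.DataFrame) -> list[ScenarioParams]:
    grid = []
    for _, row in frame.iterrows():
        d = row.to_dict()
        kwargs = {}
        for field, (lo_col, hi_col) in _RANGE_COLS.items():
            kwargs[field] = (float(d.pop(lo_col)), float(d.pop(hi_col)))
        kwargs["setup_id"] = int(d.pop("setup_id"))
        kwargs["analysis_family"] = str(d.pop("analysis_family"))
        kwargs["outcome_type"] = str(d.pop("outcome_type"))
        kwargs.update({k: float(v) for k, v in d.items()})
        grid.append(ScenarioParams(**kwargs))
    return grid


def write_grid(grid: Sequence[ScenarioParams], path: str | Path) -> None:
    grid_to_frame(grid).to_csv(path, index=False)


def read_grid(path: str | Path) -> list[ScenarioParams]:
    return grid_from_frame(pd.read_csv(path))
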