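"""Left-truncation bias estimands and across-replicate aggregation.

Three estimands per placentation stratum, comparing the truncated (observed)
analysis with the conception-cohort (unobserved) analysis of the same cohort:

* absolute bias of risk per exposure arm: risk_observed - risk_unobserved;
* absolute bias of the risk difference: RD_observed - RD_unobserved;
* relative bias of the risk ratio: RR_observed / RR_unobserved (fold).

Because numerators coincide and observed denominators are subsets, the per-arm
risk biases are nonnegative, and the fold bias reduces exactly to the ratio of
empirical survival fractions q^(x=0,z) / q^(x=1,z), where q^ is the C=0
fraction of the (z, x) arm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import EffectEstimates

__all__ = [
    "BiasResult",
    "compute_bias",
    "bias_to_frame",
    "estimates_to_frame",
    "aggregate",
    "round_percent",
    "round_fold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasResult:
    """The three truncation-bias estimands for one stratum of one cohort."""

    stratum: int
    risk_bias_exposed: float
    risk_bias_unexposed: float
    rd_bias: float
    rr_relative_bias: float
    flags: tuple[str, ...] = ()

    @property
    def is_defined(self) -> bool:
        return not self.flags


def compute_bias(observed: EffectEstimates, unobserved: EffectEstimates) -> BiasResult:
    """Contrast the two scopes of the same cohort and stratum.

    Undefined inputs (zero denominators, undefined RRs) propagate as NaN with
    flags rather than raising; mismatched scopes or strata are usage errors.
    """
    if observed.scope != "observed" or unobserved.scope != "unobserved":
        raise ValueError("expected (observed, unobserved) scope pair, got "
                         f"({observed.scope!r}, {unobserved.scope!r})")
    if observed.stratum != unobserved.stratum:
        raise ValueError("stratum mismatch between scopes")
    flags = list(dict.fromkeys(observed.flags + unobserved.flags))
    if math.isnan(observed.rr) or math.isnan(unobserved.rr):
        rr_fold = math.nan
    elif unobserved.rr == 0.0:
        # zero events in the exposed arm: both RRs are 0 and the fold is 0/0
        rr_fold = math.nan
        flags.append("zero_exposed_events")
    else:
        rr_fold = observed.rr / unobserved.rr
    flags = tuple(flags)
    return BiasResult(
        stratum=observed.stratum,
        risk_bias_exposed=observed.risk_exposed - unobserved.risk_exposed,
        risk_bias_unexposed=observed.risk_unexposed - unobserved.risk_unexposed,
        rd_bias=observed.rd - unobserved.rd,
        rr_relative_bias=rr_fold,
        flags=flags,
    )


def estimates_to_frame(records: list[tuple[int, int, EffectEstimates]]) -> pd.DataFrame:
    """Tidy frame from (setup_id, replicate_id, estimate) records."""
    rows = []
    for setup_id, replicate_id, e in records:
        rows.append({
            "setup_id": setup_id, "replicate_id": replicate_id,
            "scope": e.scope, "stratum": e.stratum,
            "risk_exposed": e.risk_exposed, "risk_unexposed": e.risk_unexposed,
            "rd": e.rd, "rr": e.rr,
            "n_exposed": e.cell_denominators[0],
            "n_unexposed": e.cell_denominators[1],
            "flags": ";".join(e.flags),
        })
    return pd.DataFrame(rows)


def bias_to_frame(records: list[tuple[int, int, BiasResult]]) -> pd.DataFrame:
    """Tidy frame from (setup_id, replicate_id, bias result) records."""
    rows = []
    for setup_id, replicate_id, b in records:
        rows.append({
            "setup_id": setup_id, "replicate_id": replicate_id,
            "stratum": b.stratum,
            "risk_bias_exposed": b.risk_bias_exposed,
            "risk_bias_unexposed": b.risk_bias_unexposed,
            "rd_bias": b.rd_bias,
            "rr_relative_bias": b.rr_relative_bias,
            "flags": ";".join(b.flags),
        })
    return pd.DataFrame(rows)


def aggregate(frame: pd.DataFrame, by: list[str],
              value_cols: list[str] | None = None) -> pd.DataFrame:
    """Across-replicate summary of every value column, per group.

    Returns one row per (group, quantity) with the replicate count actually
    used, mean, median, the 2.5 and 97.5 percentiles, and the number of
    replicates excluded because the quantity was undefined (NaN). Groups in
    which a quantity is never defined are dropped with a logged warning.
    """
    if value_cols is None:
        skip = set(by) | {"replicate_id", "flags", "scope", "stratum",
                          "setup_id", "n_exposed", "n_unexposed", "seed"}
        value_cols = [c for c in frame.columns
                      if c not in skip and pd.api.types.is_numeric_dtype(frame[c])]
    rows = []
    for keys, grp in frame.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col in value_cols:
            vals = grp[col].to_numpy(dtype=float)
            ok = vals[~np.isnan(vals)]
            n_excluded = int(len(vals) - len(ok))
            if len(ok) == 0:
                logger.warning("aggregate: %s empty for group %s; row omitted",
                               col, dict(zip(by, keys)))
                continue
            rows.append({
                **dict(zip(by, keys)),
                "quantity": col,
                "n_replicates_used": int(len(ok)),
                "mean": float(np.mean(ok)),
                "median": float(np.median(ok)),
                "pct_2_5": float(np.percentile(ok, 2.5)),
                "pct_97_5": float(np.percentile(ok, 97.5)),
                "n_excluded": n_excluded,
            })
    return pd.DataFrame(rows)


# Rounding conventions for headline summaries: risks, RDs and their biases are
# quoted in percent to the nearest integer (censoring to one decimal); fold
# biases to one decimal. Stated once, used everywhere.

def round_percent(x: float, decimals: int = 0) -> float:
    """Proportion -> percent, rounded half away from zero."""
    scaled = x * 100.0 * 10**decimals
    return float(math.copysign(math.floor(abs(scaled) + 0.5), scaled)) / 10**decimals


def round_fold(x: float) -> float:
    """Fold-change rounded to one decimal, half away from zero."""
    return float(math.copysign(math.floor(abs(x) * 10 + 0.5), x)) / 10
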