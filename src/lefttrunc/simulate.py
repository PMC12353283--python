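"""Synthetic conception cohorts under one simulation setup.

A cohort of implanted conceptuses is generated by nested binomial sampling
over the cells of (Z, X, C, outcome): abnormal placentation Z, abruption onset
X (its probability drawn once per cohort per Z stratum from a uniform
support), spontaneous abortion C (multiplicative risk model in Z and X), and
the outcome (multiplicative risk model in M and Z among survivors, where the
abruption diagnosis M equals X when C=0 and is missing when C=1; a spontaneous
abortion precludes the outcome). Within every cell the conceptuses are
exchangeable, so cell counts carry the full information of individual records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .scenarios import ParameterError, ScenarioParams, validate_params

__all__ = [
    "AbruptionProbs",
    "CohortCounts",
    "draw_abruption_probs",
    "cell_probability",
    "simulate_cohort",
    "simulate_study",
    "counts_to_frame",
    "to_individuals",
]

PX_MODES = ("per_cohort", "midpoint")


class AbruptionProbs(NamedTuple):
    """Realized Pr(X=1|Z) for one cohort."""

    z1: float
    z0: float


@dataclass
class CohortCounts:
    """One simulated cohort summarized as counts over the 16 (z,x,c,y) cells.

    ``counts[z, x, c, y]`` is the number of conceptuses in that cell; the
    abruption diagnosis is not stored because it is deterministic (M = X when
    C=0, missing when C=1). Cells with c=1 and y=1 are structurally empty.
    """

    n_total: int
    drawn_pX_Z1: float
    drawn_pX_Z0: float
    counts: np.ndarray  # shape (2, 2, 2, 2), int64, indexed [z, x, c, y]
    replicate_id: int = 0
    setup_id: int = 0
    seed: int = 0

    @property
    def sab_fraction(self) -> float:
        """Marginal proportion censored by spontaneous abortion."""
        return float(self.counts[:, :, 1, :].sum()) / self.n_total


def _sab_prob(p: ScenarioParams, z: int, x: int) -> float:
    return p.pC_base * p.rr_C_Z**z * p.rr_C_X**x * p.rr_C_interaction**(x * z)


def _outcome_prob(p: ScenarioParams, m: int, z: int) -> float:
    return p.pOut_base * p.rr_Out_M**m * p.rr_Out_Z**z * p.rr_Out_interaction**(m * z)


def draw_abruption_probs(p: ScenarioParams, rng: np.random.Generator) -> AbruptionProbs:
    """Draw this cohort's abruption-onset probabilities, one per Z stratum.

    Independent uniforms on the supports U(0.005, 0.050) for Z=1 and
    U(0.001, 0.020) for Z=0 (or whatever supports the setup carries);
    zero-width supports return the point mass.
    """
    lo1, hi1 = p.pX_range_Z1
    lo0, hi0 = p.pX_range_Z0
    return AbruptionProbs(z1=float(rng.uniform(lo1, hi1)),
                          z0=float(rng.uniform(lo0, hi0)))


def cell_probability(p: ScenarioParams, pX: AbruptionProbs,
                     z: int, x: int, c: int, y: int) -> float:
    """Probability of one (z, x, c, y) cell under the generative model.

    Factorizes as Pr(Z=z) Pr(X=x|Z=z) Pr(C=c|Z=z,X=x) Pr(out=y|...), with
    Pr(out=1|C=1)=0 and, on C=0, the outcome model evaluated at m=x.
    The 16 cell probabilities sum to 1.
    """
    if not all(v in (0, 1) for v in (z, x, c, y)):
        raise ValueError("z, x, c, y must be binary")
    v = validate_params(p)
    if not v.valid:
        raise ParameterError(
            f"setup implies probability > 1 (Pr(C) max {v.max_sab_prob}, "
            f"Pr(outcome) max {v.max_outcome_prob})")
    p_z = p.pi_Z if z else 1.0 - p.pi_Z
    px_z = pX.z1 if z else pX.z0
    if not 0.0 <= px_z <= 1.0:
        raise ParameterError(f"abruption probability {px_z!r} outside [0, 1]")
    p_x = px_z if x else 1.0 - px_z
    pc = _sab_prob(p, z, x)
    p_c = pc if c else 1.0 - pc
    if c:
        p_y = 0.0 if y else 1.0
    else:
        py = _outcome_prob(p, m=x, z=z)
        p_y = py if y else 1.0 - py
    return p_z * p_x * p_c * p_y


def simulate_cohort(p: ScenarioParams, n_total: int, rng: np.random.Generator,
                    px_mode: str = "per_cohort", *,
                    replicate_id: int = 0, seed: int = 0) -> CohortCounts:
    """Simulate one cohort of ``n_total`` implanted conceptuses.

    Sequential binomial splits: Z, then X within Z (at this cohort's drawn
    abruption probabilities), then C within (Z, X), then the outcome within
    the surviving (Z, X, C=0) cells. ``px_mode="midpoint"`` fixes the
    abruption probabilities at the uniform-support midpoints instead of
    drawing them (the distribution each conceptus faces marginally).
    """
    if n_total <= 0:
        raise ValueError("empty cohort: n_total must be positive")
    if px_mode not in PX_MODES:
        raise ValueError(f"px_mode must be one of {PX_MODES}")
    v = validate_params(p)
    if not v.valid:
        raise ParameterError("setup implies probability > 1; refusing to simulate")

    if px_mode == "midpoint":
        pX = AbruptionProbs(z1=sum(p.pX_range_Z1) / 2.0, z0=sum(p.pX_range_Z0) / 2.0)
    else:
        pX = draw_abruption_probs(p, rng)

    counts = np.zeros((2, 2, 2, 2), dtype=np.int64)
    n_z = {1: int(rng.binomial(n_total, p.pi_Z))}
    n_z[0] = n_total - n_z[1]
    for z in (0, 1):
        px_z = pX.z1 if z else pX.z0
        n_x = {1: int(rng.binomial(n_z[z], px_z))}
        n_x[0] = n_z[z] - n_x[1]
        for x in (0, 1):
            n_c1 = int(rng.binomial(n_x[x], _sab_prob(p, z, x)))
            n_c0 = n_x[x] - n_c1
            counts[z, x, 1, 0] = n_c1  # SAB precludes the outcome
            n_y1 = int(rng.binomial(n_c0, _outcome_prob(p, m=x, z=z)))
            counts[z, x, 0, 1] = n_y1
            counts[z, x, 0, 0] = n_c0 - n_y1
    return CohortCounts(n_total=n_total, drawn_pX_Z1=pX.z1, drawn_pX_Z0=pX.z0,
                        counts=counts, replicate_id=replicate_id,
                        setup_id=p.setup_id, seed=seed)


def simulate_study(p: ScenarioParams, n_replicates: int = 200,
                   n_total: int = 100_000, master_seed: int = 0,
                   px_mode: str = "per_cohort") -> list[CohortCounts]:
    """Simulate independent replicate cohorts for one setup.

    A single master seed spawns one independent substream per (setup,
    replicate) via :class:`numpy.random.SeedSequence`, so studies are
    reproducible and replicates are statistically independent. The same
    master seed yields bit-identical counts.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(p.setup_id,))
    children = ss.spawn(n_replicates)
    out = []
    for rep, child in enumerate(children):
        seed = int(child.generate_state(1, dtype=np.uint32)[0])
        rng = np.random.Generator(np.random.PCG64(child))
        out.append(simulate_cohort(p, n_total, rng, px_mode,
                                   replicate_id=rep, seed=seed))
    return out


def counts_to_frame(cohorts: CohortCounts | list[CohortCounts]) -> pd.DataFrame:
    """Tidy one-row-per-cell table with provenance columns."""
    if isinstance(cohorts, CohortCounts):
        cohorts = [cohorts]
    rows = []
    for co in cohorts:
        for z in (0, 1):
            for x in (0, 1):
                for c in (0, 1):
                    for y in (0, 1):
                        rows.append({
                            "setup_id": co.setup_id,
                            "replicate_id": co.replicate_id,
                            "seed": co.seed,
                            "n_total": co.n_total,
                            "drawn_pX_Z1": co.drawn_pX_Z1,
                            "drawn_pX_Z0": co.drawn_pX_Z0,
                            "z": z, "x": x, "c": c, "y": y,
                            "count": int(co.counts[z, x, c, y]),
                        })
    return pd.DataFrame(rows)


def to_individuals(cohort: CohortCounts) -> pd.DataFrame:
    """Expand counts into one row per conceptus (columns z, x, c, m, y).

    The diagnosis m is recovered deterministically: missing (<NA>) when c=1,
    equal to x when c=0. Intended for small fixtures only.
    """
    frames = []
    for z in (0, 1):
        for x in (0, 1):
            for c in (0, 1):
                for y in (0, 1):
                    n = int(cohort.counts[z, x, c, y])
                    if n == 0:
                        continue
                    m = pd.NA if c == 1 else x
                    frames.append(pd.DataFrame({
                        "z": z, "x": x, "c": c,
                        "m": pd.array([m] * n, dtype="Int64"),
                        "y": y,
                    }, index=range(n)))
    if not frames:
        return pd.DataFrame(columns=["z", "x", "c", "m", "y"])
    return pd.concat(frames, ignore_index=True)
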