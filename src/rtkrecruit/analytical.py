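"""Single-occupancy analytical approximation of competitive recruitment.

Assume each active receptor binds at most one partner at a time.  With
free active receptor concentration R, partner totals X_i^tot and apparent
dissociation constants K_i, equilibrium binding gives

    X_i^bound = R * X_i^tot / (K_i + R)

and the free receptor R solves the balance over the total active receptor

    R * (1 + sum_i X_i^tot / (K_i + R)) = R^tot.

The left side is strictly increasing in R, so the root is unique on
[0, R^tot]; by construction R + sum_i X_i^bound = R^tot exactly.  The
approximation ignores multi-site occupancy and therefore deviates from
the full network model when receptors carry several partners at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .params import AVOGADRO
from . import kinetics

__all__ = [
    "AnalyticalInputs",
    "AnalyticalResult",
    "solve_free_active_receptor",
    "bound_estimates",
    "effective_inputs_from_model",
]


@dataclass(frozen=True)
class AnalyticalInputs:
    """Totals and apparent K_D per partner, plus total active receptor (molar)."""

    names: tuple
    x_tot: tuple
    k: tuple
    r_tot: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.names) != len(self.x_tot) or len(self.names) != len(self.k):
            raise ValueError("names, x_tot and k must have equal length")
        if any(x < 0 for x in self.x_tot) or self.r_tot < 0:
            raise ValueError("concentrations must be nonnegative")
        if any(k <= 0 for k in self.k):
            raise ValueError("apparent K_D values must be positive")


@dataclass
class AnalyticalResult:
    r_free: float
    names: tuple
    bound: dict                    # partner -> molar
    ranking: list                  # rank 1 first
    meta: dict = field(default_factory=dict)

    def bound_copies(self, volume: float) -> dict:
        return {p: b * AVOGADRO * volume for p, b in self.bound.items()}

    def to_frame(self, inputs: "AnalyticalInputs" = None):
        """Tidy table: protein, K_i, X_tot, X_bound, rank."""
        import pandas as pd

        rank = {p: i + 1 for i, p in enumerate(self.ranking)}
        rows = {"protein": list(self.names),
                "x_bound_M": [self.bound[p] for p in self.names],
                "rank": [rank[p] for p in self.names]}
        if inputs is not None:
            k = dict(zip(inputs.names, inputs.k))
            x = dict(zip(inputs.names, inputs.x_tot))
            rows["k_i_M"] = [k[p] for p in self.names]
            rows["x_tot_M"] = [x[p] for p in self.names]
        return pd.DataFrame(rows).set_index("protein").sort_values("rank")


def _balance(r, inputs):
    x = np.asarray(inputs.x_tot)
    k = np.asarray(inputs.k)
    return r * (1.0 + np.sum(x / (k + r))) - inputs.r_tot


def solve_free_active_receptor(inputs: AnalyticalInputs) -> float:
    """Unique positive root of the active-receptor balance equation.

    Bracketed on [0, R^tot] (the left side is 0 at 0 and >= R^tot at
    R^tot), refined to relative 1e-12 and polished with one Newton step.
    """
    r_tot = inputs.r_tot
    if r_tot == 0.0 or not inputs.names:
        return float(r_tot)
    if _balance(r_tot, inputs) <= 0:      # no partners bind anything
        return float(r_tot)
    r = optimize.brentq(
        _balance, 0.0, r_tot, args=(inputs,), xtol=1e-300, rtol=1e-14
    )
    x = np.asarray(inputs.x_tot)
    k = np.asarray(inputs.k)
    deriv = 1.0 + np.sum(x * k / (k + r) ** 2)
    r = r - _balance(r, inputs) / deriv
    return float(max(r, 0.0))


def bound_estimates(r_free: float, inputs: AnalyticalInputs) -> AnalyticalResult:
    """Per-partner bound concentrations and the implied ranking.

    Rank 1 is the most-recruited partner; ties break alphabetically.
    """
    bound = {
        p: r_free * x / (k + r_free)
        for p, x, k in zip(inputs.names, inputs.x_tot, inputs.k)
    }
    ranking = sorted(bound, key=lambda p: (-bound[p], p))
    return AnalyticalResult(
        r_free=r_free, names=tuple(inputs.names), bound=bound,
        ranking=ranking, meta=dict(inputs.meta),
    )


def solve(inputs: AnalyticalInputs) -> AnalyticalResult:
    return bound_estimates(solve_free_active_receptor(inputs), inputs)


def effective_inputs_from_model(model, dose_nM: float,
                                phospho_scale: bool = True,
                                aggregation: str = "harmonic") -> AnalyticalInputs:
    """Map a cell model onto the single-occupancy approximation.

    R^tot is the crosslinked (active) IGF1R monomer concentration at the
    clamped dose, scaled by the phospho-availability factor kp/(kp+kdp);
    a partner binding several sites gets one apparent constant, by default
    the harmonic combination 1/K_i = sum_edges 1/K_edge (parallel binding
    routes).  Both choices are defaults, recorded in the metadata, and
    ``aggregation="min"`` keeps the strongest edge instead.
    """
    params = model.params
    if dose_nM < 0:
        raise ValueError("dose must be nonnegative")
    if dose_nM == 0:
        f_active = 0.0
    else:
        eq, states = kinetics.equilibrium_distribution(params, [dose_nM * 1e-9])
        f_active = float(sum(
            x for x, s in zip(eq, states)
            if any(kinetics._is_crosslinked(t) for t in s)
        ))
    conv = 1.0 / (AVOGADRO * model.volume)
    r_tot = f_active * model.profile.igf1r_copies * conv
    if phospho_scale:
        r_tot *= params.kp / (params.kp + params.kdp)

    names, xs, ks = [], [], []
    for p in model.partners:
        edges = [kd for s, kd in model.imap.edges_for(p) if s in model.forms]
        if not edges:
            continue
        if aggregation == "harmonic":
            k_eff = 1.0 / sum(1.0 / kd for kd in edges)
        elif aggregation == "min":
            k_eff = min(edges)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        names.append(p)
        xs.append(model.profile.copies[p] * conv)
        ks.append(k_eff)
    return AnalyticalInputs(
        names=tuple(names), x_tot=tuple(xs), k=tuple(ks), r_tot=r_tot,
        meta={
            "dose_nM": dose_nM,
            "f_active": f_active,
            "phospho_scale": phospho_scale,
            "aggregation": aggregation,
        },
    )
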