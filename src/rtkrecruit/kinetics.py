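"""Ligand-binding kinetics of the dimeric receptor.

The receptor dimer carries two equivalent binding pockets.  Each pocket is
empty, singly bound at S1 or S2, or crosslinked (both sites engaged by one
ligand).  At most one pocket of a dimer can be crosslinked at a time: when
one pocket is crosslinked the sites of the other pocket are held too far
apart, so the second pocket may still bind ligand at a single site but
cannot crosslink.  A dimer is active (autophosphorylation-competent) iff a
pocket is crosslinked.

This module enumerates the dimer configurations (nine for one ligand
species), builds the mass-action dynamics over them for one or two ligand
species (labeled tracer vs unlabeled competitor, kinetically identical),
and implements the two protocols used to parameterize the scheme:
steady-state competition and washout dissociation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.integrate import solve_ivp

from .params import LigandBindingParams

__all__ = [
    "PocketState",
    "DimerConfig",
    "enumerate_dimer_configs",
    "ordered_dimer_states",
    "ordered_rate_matrix",
    "equilibrium_distribution",
    "simulate_ligand_binding",
    "competition_equilibrium_curve",
    "washout_dissociation_curve",
    "BindingTrajectory",
]


class PocketState(enum.Enum):
    EMPTY = "E"
    S1_BOUND = "S1"
    S2_BOUND = "S2"
    CROSSLINKED = "X"


@dataclass(frozen=True)
class DimerConfig:
    """Unordered pair of pocket states; active iff one pocket is crosslinked."""

    pockets: tuple

    def __post_init__(self):
        a, b = self.pockets
        ordered = tuple(sorted((a, b), key=lambda s: s.value))
        object.__setattr__(self, "pockets", ordered)
        n_x = sum(p is PocketState.CROSSLINKED for p in ordered)
        if n_x > 1:
            raise ValueError("at most one pocket of a dimer can be crosslinked")

    @property
    def active(self) -> bool:
        return any(p is PocketState.CROSSLINKED for p in self.pockets)

    @property
    def label(self) -> str:
        return ".".join(p.value for p in self.pockets)

    def __repr__(self):
        return f"DimerConfig({self.label})"


def enumerate_dimer_configs(states=tuple(PocketState)) -> list:
    """All admissible dimer configurations, lexicographic by pocket labels.

    With the full four-letter pocket alphabet this yields nine
    configurations, three of which are crosslinked (active).
    """
    seen = {}
    for a in states:
        for b in states:
            if a is PocketState.CROSSLINKED and b is PocketState.CROSSLINKED:
                continue
            cfg = DimerConfig((a, b))
            seen[cfg.label] = cfg
    return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# Internal multi-ligand state space.  A pocket token is "E" or (kind, lig)
# with kind in {"S1", "S2", "X"} and lig the ligand-species index.
# ---------------------------------------------------------------------------

_EMPTY = "E"


def _pocket_tokens(n_ligands: int):
    toks = [_EMPTY]
    for kind in ("S1", "S2", "X"):
        for lig in range(n_ligands):
            toks.append((kind, lig))
    return toks


def _is_crosslinked(tok) -> bool:
    return tok != _EMPTY and tok[0] == "X"


def _token_label(tok) -> str:
    return tok if tok == _EMPTY else f"{tok[0]}{tok[1]}"


def ordered_dimer_states(n_ligands: int = 1) -> list:
    """Ordered pocket-pair states (both orders kept; no double-crosslink)."""
    toks = _pocket_tokens(n_ligands)
    return [
        (p, q)
        for p in toks
        for q in toks
        if not (_is_crosslinked(p) and _is_crosslinked(q))
    ]


def n_bound(state, lig: int) -> int:
    """Number of molecules of ligand species `lig` held by a dimer state."""
    return sum(1 for tok in state if tok != _EMPTY and tok[1] == lig)


def _pocket_transitions(params: LigandBindingParams, n_ligands: int):
    """(from_tok, to_tok, rate_const, bind_lig, release_lig) per pocket.

    `bind_lig` marks second-order ligand-capture steps (rate must be
    multiplied by that ligand's free concentration); `release_lig` marks
    steps that return a ligand to solution.
    """
    out = []
    for lig in range(n_ligands):
        s1, s2, x = ("S1", lig), ("S2", lig), ("X", lig)
        out += [
            (_EMPTY, s1, params.a1, lig, None),
            (s1, _EMPTY, params.d1, None, lig),
            (_EMPTY, s2, params.a2, lig, None),
            (s2, _EMPTY, params.d2, None, lig),
            # crosslinking: a2' completes a pocket pre-bound at S1, a1' at S2
            (s1, x, params.a2p, None, None),
            (x, s1, params.d2p, None, None),
            (s2, x, params.a1p, None, None),
            (x, s2, params.d1p, None, None),
        ]
    return out


def _dimer_reactions(params: LigandBindingParams, n_ligands: int):
    """Elementary transitions on ordered dimer states.

    Returns (states, reactions) with reactions as tuples
    (i_from, i_to, rate_const, bind_lig, release_lig).
    """
    states = ordered_dimer_states(n_ligands)
    index = {s: i for i, s in enumerate(states)}
    trans = _pocket_transitions(params, n_ligands)
    reactions = []
    for s, i in index.items():
        for pos in (0, 1):
            other = s[1 - pos]
            for frm, to, k, bind, rel in trans:
                if s[pos] != frm:
                    continue
                if _is_crosslinked(to) and _is_crosslinked(other):
                    continue  # geometric exclusion: one crosslink per dimer
                new = list(s)
                new[pos] = to
                j = index.get(tuple(new))
                if j is None:
                    continue
                reactions.append((i, j, k, bind, rel))
    return states, reactions


def ordered_rate_matrix(params: LigandBindingParams, ligand_concs) -> tuple:
    """Generator matrix Q over ordered dimer states at clamped ligand.

    dx/dt = Q @ x for the receptor-linear system.  Returns (Q, states).
    """
    ligand_concs = np.atleast_1d(np.asarray(ligand_concs, dtype=float))
    if np.any(ligand_concs < 0):
        raise ValueError("ligand concentrations must be nonnegative")
    states, reactions = _dimer_reactions(params, len(ligand_concs))
    n = len(states)
    Q = np.zeros((n, n))
    for i, j, k, bind, _rel in reactions:
        rate = k * ligand_concs[bind] if bind is not None else k
        Q[j, i] += rate
        Q[i, i] -= rate
    return Q, states


def equilibrium_distribution(params: LigandBindingParams, ligand_concs) -> tuple:
    """Stationary distribution over ordered dimer states at clamped ligand."""
    Q, states = ordered_rate_matrix(params, ligand_concs)
    n = len(states)
    A = np.vstack([Q, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = np.linalg.norm(Q @ x)
    if resid > 1e-9 or np.any(x < -1e-10):
        raise RuntimeError(f"equilibrium solve failed (residual {resid:.3g})")
    return np.clip(x, 0.0, None), states


@dataclass
class BindingTrajectory:
    """Time course over the nine dimer configurations plus free ligand(s)."""

    t: np.ndarray
    configs: list                    # DimerConfig, canonical order
    config_conc: np.ndarray          # (T, 9)
    free_ligand: np.ndarray          # (T, n_ligands)
    total_dimers: float
    ordered_states: list = field(repr=False, default=None)
    ordered_conc: np.ndarray = field(repr=False, default=None)

    @property
    def crosslinked_fraction(self) -> np.ndarray:
        act = np.array([c.active for c in self.configs])
        return self.config_conc[:, act].sum(axis=1) / self.total_dimers

    @property
    def bound_fraction(self) -> np.ndarray:
        occ = np.array(
            [sum(p is not PocketState.EMPTY for p in c.pockets) for c in self.configs]
        )
        return (self.config_conc * occ).sum(axis=1) / (2 * self.total_dimers)

    def conservation_drift(self) -> float:
        tot = self.config_conc.sum(axis=1)
        return float(np.max(np.abs(tot - self.total_dimers)) / self.total_dimers)


def _lump_to_configs(states, x):
    """Sum ordered, ligand-labeled states into the nine canonical configs."""
    configs = enumerate_dimer_configs()
    pos = {c.label: i for i, c in enumerate(configs)}
    kind_map = {"S1": PocketState.S1_BOUND, "S2": PocketState.S2_BOUND,
                "X": PocketState.CROSSLINKED}
    out = np.zeros(x.shape[:-1] + (len(configs),))
    for i, s in enumerate(states):
        toks = [PocketState.EMPTY if t == _EMPTY else kind_map[t[0]] for t in s]
        out[..., pos[DimerConfig(tuple(toks)).label]] += x[..., i]
    return configs, out


def simulate_ligand_binding(
    params: LigandBindingParams,
    total_dimers: float,
    ligand,
    t_grid,
    mode: str = "clamped",
    x0=None,
) -> BindingTrajectory:
    """Integrate the dimer-configuration mass-action system.

    Parameters
    ----------
    total_dimers : receptor dimer concentration (molar).
    ligand : clamped concentration(s), or initial pool concentration(s) in
        ``mode="depleting"`` (one value per ligand species).
    t_grid : increasing times (s), starting at 0.
    x0 : optional initial ordered-state concentrations; defaults to all
        receptors ligand-free.
    """
    if total_dimers < 0:
        raise ValueError("total_dimers must be nonnegative")
    t_grid = np.asarray(t_grid, dtype=float)
    ligand = np.atleast_1d(np.asarray(ligand, dtype=float))
    if np.any(ligand < 0):
        raise ValueError("ligand amounts must be nonnegative")
    n_lig = len(ligand)
    states, reactions = _dimer_reactions(params, n_lig)
    n = len(states)
    if x0 is None:
        x0 = np.zeros(n)
        x0[states.index((_EMPTY, _EMPTY))] = total_dimers
    else:
        x0 = np.asarray(x0, dtype=float)
        if np.any(x0 < 0):
            raise ValueError("initial amounts must be nonnegative")

    if mode == "clamped":
        Q, _ = ordered_rate_matrix(params, ligand)
        xs = np.empty((len(t_grid), n))
        x = x0.copy()
        prev = t_grid[0]
        if prev != 0:
            x = expm(Q * prev) @ x
        xs[0] = x
        for k, t in enumerate(t_grid[1:], start=1):
            x = expm(Q * (t - prev)) @ x
            prev = t
            xs[k] = x
        free = np.broadcast_to(ligand, (len(t_grid), n_lig)).copy()
    elif mode == "depleting":
        def rhs(_t, y):
            x, L = y[:n], y[n:]
            dx = np.zeros(n)
            dL = np.zeros(n_lig)
            for i, j, k, bind, rel in reactions:
                flux = k * x[i] * (L[bind] if bind is not None else 1.0)
                dx[i] -= flux
                dx[j] += flux
                if bind is not None:
                    dL[bind] -= flux
                if rel is not None:
                    dL[rel] += flux
            return np.concatenate([dx, dL])

        y0 = np.concatenate([x0, ligand])
        sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                        method="LSODA", rtol=1e-10, atol=1e-12 * max(total_dimers, 1e-30))
        if not sol.success:
            raise RuntimeError(
                f"integrator failure: {sol.message}; last state {sol.y[:, -1]}"
            )
        xs = sol.y[:n].T
        free = sol.y[n:].T
    else:
        raise ValueError(f"unknown ligand mode {mode!r}")

    configs, lumped = _lump_to_configs(states, xs)
    return BindingTrajectory(
        t=t_grid, configs=configs, config_conc=lumped, free_ligand=free,
        total_dimers=float(total_dimers), ordered_states=states, ordered_conc=xs,
    )


def _bound_tracer_at_equilibrium(params, tracer, competitor):
    x, states = equilibrium_distribution(params, [tracer, competitor])
    return float(sum(xi * n_bound(s, 0) for xi, s in zip(x, states)))


def competition_equilibrium_curve(params, tracer_dose, competitor_doses) -> np.ndarray:
    """Steady-state bound labeled-ligand fraction vs competitor dose.

    Tracer and competitor are kinetically identical species; the result is
    normalized to the zero-competitor value, so it starts at 1 and is
    non-increasing in competitor dose.  Doses are clamped concentrations
    (molar); receptor linearity makes the normalized curve independent of
    receptor abundance.
    """
    competitor_doses = np.asarray(competitor_doses, dtype=float)
    if competitor_doses.size == 0:
        raise ValueError("competitor dose list is empty")
    if tracer_dose <= 0:
        raise ValueError("tracer dose must be positive")
    if np.any(competitor_doses < 0):
        raise ValueError("competitor doses must be nonnegative")
    ref = _bound_tracer_at_equilibrium(params, tracer_dose, 0.0)
    return np.array(
        [_bound_tracer_at_equilibrium(params, tracer_dose, c) / ref
         for c in competitor_doses]
    )


def washout_dissociation_curve(
    params,
    tracer_dose,
    competitor_doses,
    preincubation: float = 7200.0,
    chase_times=(1200.0, 3600.0),
) -> dict:
    """Retained bound tracer after washout, vs competitor dose.

    Protocol: incubate with clamped tracer for `preincubation` seconds,
    set free tracer to zero (washout into excess medium), add unlabeled
    competitor at a clamped dose, and read the bound-tracer fraction
    (relative to the end of preincubation) after each chase time.

    Returns {chase_time: array over competitor_doses}.
    """
    competitor_doses = np.asarray(competitor_doses, dtype=float)
    if competitor_doses.size == 0:
        raise ValueError("competitor dose list is empty")
    if tracer_dose <= 0:
        raise ValueError("tracer dose must be positive")
    if np.any(competitor_doses < 0):
        raise ValueError("competitor doses must be nonnegative")

    states = ordered_dimer_states(2)
    n = len(states)
    w_tracer = np.array([n_bound(s, 0) for s in states], dtype=float)

    Q1, _ = ordered_rate_matrix(params, [tracer_dose, 0.0])
    x0 = np.zeros(n)
    x0[states.index((_EMPTY, _EMPTY))] = 1.0
    x_pre = expm(Q1 * preincubation) @ x0
    b0 = float(w_tracer @ x_pre)
    if b0 <= 0:
        raise RuntimeError("no tracer bound at end of preincubation")

    out = {}
    for tc in chase_times:
        out[tc] = np.empty(len(competitor_doses))
    for k, c in enumerate(competitor_doses):
        Q2, _ = ordered_rate_matrix(params, [0.0, c])
        for tc in chase_times:
            x = expm(Q2 * tc) @ x_pre
            out[tc][k] = float(w_tracer @ x) / b0
    return out


def write_curve_csv(path, doses, values, protocol: str, chase: float = None) -> None:
    """Write a (dose, value) curve with a header naming the protocol."""
    header = f"protocol={protocol}" + (f";chase_s={chase:g}" if chase is not None else "")
    with open(path, "w") as fh:
        fh.write(f"# {header}\ndose_M,value\n")
        for d, v in zip(doses, values):
            fh.write(f"{d:.10g},{v:.10g}\n")
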