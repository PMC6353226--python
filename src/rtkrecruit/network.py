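"""Rule-derived mass-action reaction networks for receptor recruitment.

Two equivalent formulations of the same rule set are generated:

* the *natural* formulation, in which one dimer species tracks the joint
  state of both binding pockets and every tyrosine site of both protomers
  (combinatorially large; usable only for small instances, where it serves
  as the exactness oracle);

* the *restructured* formulation, obtained by three exact transformations:
  *bunching* (the four ligand-contact sites of a dimer are represented as
  two pocket variables), *decoupling* (each tyrosine site lives on its own
  receptor form, since site phospho-dynamics are mutually independent), and
  *scaling* (receptor and ligand abundances are doubled while the
  second-order ligand-association rates a1, a2 are halved, so that each
  single-site receptor form carries the statistics of one site copy).

The decoupled forms remain coupled through the shared free-partner pools,
so the generated system is one joint ODE.  Ligand is clamped by default;
a depleting ligand pool is only exact for single-form (or natural)
networks, because six decoupled forms would each deplete the pool.

Rules: phosphorylation fires only on active (crosslinked) dimers;
dephosphorylation only on phosphorylated, unoccupied sites; a partner may
bind any phosphorylated cognate site regardless of receptor activity and
persists after de-crosslinking.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .params import LigandBindingParams
from .kinetics import _pocket_transitions, _is_crosslinked, _token_label, _EMPTY

__all__ = [
    "ModelSpec",
    "Reaction",
    "ReactionNetwork",
    "NetworkSizeError",
    "restructure",
    "generate_network",
    "generate_natural_network",
    "mass_action_rhs",
    "integrate_network",
    "species_count",
]

LIGAND_SPECIES = "IGF1"


class NetworkSizeError(RuntimeError):
    def __init__(self, count, cap):
        super().__init__(
            f"natural formulation implies {count} species, exceeding cap {cap}"
        )
        self.count = count
        self.cap = cap


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one recruitment model instance.

    Concentrations are molar.  ``edges`` are (site, partner, K_D) triples;
    per-edge off-rates are ``ka * K_D`` with a single association rate
    ``ka`` for all SH2/PTB interactions.
    """

    sites: tuple
    partners: tuple
    edges: tuple                      # (site, partner, kd_molar)
    params: LigandBindingParams
    receptor_dimers: float            # dimer concentration
    ligand: float                     # clamp value, or initial pool
    partner_conc: dict = field(default_factory=dict)
    ligand_clamped: bool = True
    ka: float = 1.0e6                 # M^-1 s^-1
    restructured: bool = False
    receptor_scale: int = 1           # units per dimer represented per form

    def __post_init__(self):
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("site identifiers must be unique")
        if len(set(self.partners)) != len(self.partners):
            raise ValueError("partner identifiers must be unique")
        for site, partner, kd in self.edges:
            if site not in self.sites:
                raise ValueError(f"edge references undeclared site {site!r}")
            if partner not in self.partners:
                raise ValueError(f"edge references undeclared partner {partner!r}")
            if kd <= 0:
                raise ValueError(f"edge ({site},{partner}) has non-positive K_D")
        if self.receptor_dimers < 0 or self.ligand < 0:
            raise ValueError("amounts must be nonnegative")

    def partners_at(self, site) -> list:
        return sorted(p for s, p, _ in self.edges if s == site)

    def edge_kd(self, site, partner) -> float:
        for s, p, kd in self.edges:
            if s == site and p == partner:
                return kd
        raise KeyError((site, partner))

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)


#: How each observable of the natural model is recovered from the
#: restructured state (recorded on restructure() output for reference).
OBSERVABLE_MAP = {
    "bound(partner)": "sum over forms of phospho-bound species holding the partner",
    "phospho(site)": "phosphorylated (free or bound) fraction of that site's form",
    "crosslinked_fraction": "active-configuration fraction of any single form "
                            "(identical across forms; averaged)",
    "free_ligand": "restructured free ligand divided by two (scaling doubles it)",
}


def restructure(spec: ModelSpec) -> ModelSpec:
    """Apply bunching, decoupling and scaling to a natural-formulation spec.

    Doubles receptor and ligand abundances and halves a1/a2; the returned
    spec generates one single-tyrosine receptor form per site.
    """
    if spec.restructured:
        return spec
    p = spec.params
    return spec.replace(
        restructured=True,
        params=p.replace(a1=p.a1 / 2.0, a2=p.a2 / 2.0),
        ligand=2.0 * spec.ligand,
        receptor_scale=2 * spec.receptor_scale,
    )


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    reactants: tuple
    products: tuple
    rate: float


class ReactionNetwork:
    """Enumerated species + elementary mass-action reactions (order <= 2)."""

    def __init__(self, species, reactions, x0, clamped, conservation,
                 observable_weights, meta):
        self.species = list(species)
        self.index = {s: i for i, s in enumerate(self.species)}
        self.reactions = list(reactions)
        self.x0 = np.asarray(x0, dtype=float)
        self.clamped = np.asarray(sorted(clamped), dtype=int)
        self.conservation = conservation        # list of (name, vector)
        self.observable_weights = observable_weights  # name -> vector
        self.meta = meta                        # dict: formulation, forms, totals...
        self._compiled = None

    @property
    def n_species(self) -> int:
        return len(self.species)

    def _compile(self):
        if self._compiled is None:
            n_r = len(self.reactions)
            ra = np.empty(n_r, dtype=int)
            rb = np.full(n_r, -1, dtype=int)
            rates = np.empty(n_r)
            rows, cols, vals = [], [], []
            for k, rxn in enumerate(self.reactions):
                if not 1 <= len(rxn.reactants) <= 2:
                    raise ValueError("reactions must have order 1 or 2")
                ra[k] = rxn.reactants[0]
                if len(rxn.reactants) == 2:
                    rb[k] = rxn.reactants[1]
                rates[k] = rxn.rate
                for i in rxn.reactants:
                    rows.append(i); cols.append(k); vals.append(-1.0)
                for i in rxn.products:
                    rows.append(i); cols.append(k); vals.append(1.0)
            S = sp.csr_matrix(
                (vals, (rows, cols)), shape=(self.n_species, n_r)
            )
            self._compiled = (ra, rb, rates, S)
        return self._compiled

    def rhs(self, state) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species,):
            raise ValueError(
                f"state length {state.shape} != species count {self.n_species}"
            )
        ra, rb, rates, S = self._compile()
        flux = rates * state[ra]
        mask = rb >= 0
        flux[mask] *= state[rb[mask]]
        dx = S @ flux
        dx[self.clamped] = 0.0
        return dx

    def conservation_residual(self, deriv) -> float:
        """Max |c . dx| over conservation laws (0 to round-off for valid dx)."""
        return max(
            (abs(float(np.dot(vec, deriv))) for _name, vec in self.conservation),
            default=0.0,
        )

    def observables(self, state) -> dict:
        """Mapped observables shared by both formulations (molar / fractions)."""
        out = {}
        for name, w in self.observable_weights.items():
            out[name] = float(np.dot(w, state))
        d_tot = self.meta["receptor_dimers"]
        if d_tot > 0:
            scale = self.meta["receptor_scale"]
            act = [v for k, v in out.items() if k.startswith("active:")]
            out["crosslinked_fraction"] = float(np.mean(act)) / (scale * d_tot)
        ilig = self.index[LIGAND_SPECIES]
        # scaling doubles the ligand bookkeeping in the restructured net
        lig_div = 2.0 if self.meta["formulation"] == "restructured" else 1.0
        out["free_ligand"] = float(state[ilig]) / lig_div
        return out


def export_network(network: ReactionNetwork, path, fmt: str = "reactions") -> None:
    """Dump the network as text: a species table plus the reaction list.

    ``fmt="reactions"`` writes ``index  label  initial`` rows followed by
    ``A [+ B] -> C [+ D]  rate`` lines; ``fmt="bngl"`` writes a minimal
    BNGL-flavored species/reactions dump for cross-checking against
    rule-based tooling.
    """
    sp = network.species
    with open(path, "w") as fh:
        if fmt == "reactions":
            fh.write(f"# species: {network.n_species}  "
                     f"reactions: {len(network.reactions)}\n")
            fh.write("# formulation: " + network.meta["formulation"] + "\n")
            for i, s in enumerate(sp):
                fh.write(f"{i}\t{s}\t{network.x0[i]:.10g}\n")
            fh.write("# reactions\n")
            for rxn in network.reactions:
                lhs = " + ".join(sp[i] for i in rxn.reactants)
                rhs = " + ".join(sp[i] for i in rxn.products) or "0"
                fh.write(f"{lhs} -> {rhs}\t{rxn.rate:.10g}\n")
        elif fmt == "bngl":
            fh.write("begin species\n")
            for i, s in enumerate(sp):
                fh.write(f"  {s} {network.x0[i]:.10g}\n")
            fh.write("end species\nbegin reactions\n")
            for k, rxn in enumerate(network.reactions, start=1):
                lhs = ",".join(str(i + 1) for i in rxn.reactants)
                rhs = ",".join(str(i + 1) for i in rxn.products) or "0"
                fh.write(f"  {k} {lhs} {rhs} {rxn.rate:.10g}\n")
            fh.write("end reactions\n")
        else:
            raise ValueError(f"unknown export format {fmt!r}")


def mass_action_rhs(network: ReactionNetwork, state) -> np.ndarray:
    """Standard mass-action rate law for the network (clamped species pinned)."""
    return network.rhs(state)


def integrate_network(network: ReactionNetwork, t_grid, x0=None,
                      rtol=1e-8, atol_scale=1e-14) -> np.ndarray:
    """Integrate the network ODEs over t_grid; returns (T, n_species)."""
    t_grid = np.asarray(t_grid, dtype=float)
    x0 = network.x0 if x0 is None else np.asarray(x0, dtype=float)
    scale = max(float(np.max(x0)), 1e-30)
    sol = solve_ivp(
        lambda _t, y: network.rhs(y), (t_grid[0], t_grid[-1]), x0,
        t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol_scale * scale,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failure: {sol.message}")
    return sol.y.T


# ---------------------------------------------------------------------------
# Symmetry lumping.  Microstates carry an internal protomer/pocket order;
# physical species are orbits under the swap symmetry.  Because initial
# conditions are symmetric, orbit members stay equally populated and the
# lumped system (rate k divided by the source-orbit size, duplicates
# merged) is exact.
# ---------------------------------------------------------------------------

def _lump(micro_states, micro_reactions, swap, label_of):
    """Return (species labels, lumped reactions on labels, orbit sizes)."""
    canon = {}
    orbit_size = {}
    for s in micro_states:
        lbl = min(label_of(s), label_of(swap(s)))
        canon[label_of(s)] = lbl
        orbit_size[lbl] = orbit_size.get(lbl, 0) + 1
    labels = sorted(set(canon.values()))
    acc = {}
    for reactants, products, k in micro_reactions:
        src_receptor = reactants[0]        # receptor microstate label first
        lump_r = tuple(canon.get(r, r) for r in reactants)
        lump_p = tuple(sorted(canon.get(p, p) for p in products))
        key = (lump_r, lump_p)
        acc[key] = acc.get(key, 0.0) + k / orbit_size[canon[src_receptor]]
    return labels, acc, orbit_size


def _finalize(spec, receptor_labels, lumped, receptor_init_label,
              formulation, extra_weights, per_form_of_label):
    """Assemble a ReactionNetwork from lumped receptor species + free pools."""
    free = [LIGAND_SPECIES] + list(spec.partners)
    species = free + receptor_labels
    index = {s: i for i, s in enumerate(species)}
    n = len(species)

    reactions = [
        Reaction(
            reactants=tuple(index[r] for r in reactants),
            products=tuple(index[p] for p in products),
            rate=k,
        )
        for (reactants, products), k in sorted(
            lumped.items(), key=lambda kv: (kv[0][0], kv[0][1])
        )
    ]

    x0 = np.zeros(n)
    x0[index[LIGAND_SPECIES]] = spec.ligand
    for p in spec.partners:
        x0[index[p]] = float(spec.partner_conc.get(p, 0.0))
    if formulation == "natural":
        x0[index[receptor_init_label]] = spec.receptor_dimers
    else:
        for lbl in receptor_init_label:   # one ligand-free/unphos label per form
            x0[index[lbl]] = spec.receptor_scale * spec.receptor_dimers

    clamped = {index[LIGAND_SPECIES]} if spec.ligand_clamped else set()

    conservation = []
    # receptor totals (per form for the restructured net, global for natural)
    forms = sorted(set(per_form_of_label.values()))
    for f in forms:
        vec = np.zeros(n)
        for lbl, ff in per_form_of_label.items():
            if ff == f:
                vec[index[lbl]] = 1.0
        conservation.append((f"receptor:{f}", vec))
    # partner totals: free + bound occurrences
    for p in spec.partners:
        vec = np.zeros(n)
        vec[index[p]] = 1.0
        wname = f"bound:{p}"
        if wname in extra_weights:
            vec += extra_weights[wname]
        conservation.append((f"partner:{p}", vec))
    if not spec.ligand_clamped:
        vec = np.zeros(n)
        vec[index[LIGAND_SPECIES]] = 1.0
        vec += extra_weights["_ligand_held"]
        conservation.append(("ligand", vec))

    meta = {
        "formulation": formulation,
        "receptor_dimers": spec.receptor_dimers,
        "receptor_scale": spec.receptor_scale,
        "sites": spec.sites,
        "partners": spec.partners,
    }
    weights = {k: v for k, v in extra_weights.items() if not k.startswith("_")}
    return ReactionNetwork(species, reactions, x0, clamped, conservation,
                           weights, meta)


# ---------------------------------------------------------------------------
# Restructured formulation: one single-tyrosine receptor form per site.
# ---------------------------------------------------------------------------

def _status_label(st):
    return st if isinstance(st, str) else f"B:{st[1]}"


def generate_network(spec: ModelSpec) -> ReactionNetwork:
    """Enumerate the restructured network: 9 x (2 + n_i) species per form."""
    if not spec.restructured:
        raise ValueError("generate_network expects a restructured spec; "
                         "call restructure() first")
    if not spec.ligand_clamped and len(spec.sites) > 1:
        raise ValueError("a depleting ligand pool is only exact for a "
                         "single-form restructured network; clamp the ligand")
    params = spec.params
    pocket_trans = _pocket_transitions(params, 1)

    all_labels = []
    lumped_all = {}
    per_form = {}
    init_labels = []
    n_total = 1 + len(spec.partners)
    weights = {f"bound:{p}": None for p in spec.partners}

    # per-form enumeration; forms only couple through free pools
    form_states = {}
    for site in spec.sites:
        partners_i = spec.partners_at(site)
        statuses = ["U", "P"] + [("B", p) for p in partners_i]
        toks = [_EMPTY, ("S1", 0), ("S2", 0), ("X", 0)]
        micro = [
            (p, q, st)
            for p in toks for q in toks for st in statuses
            if not (_is_crosslinked(p) and _is_crosslinked(q))
        ]

        def label_of(s, _site=site):
            p, q, st = s
            return f"{_site}|{_token_label(p)}.{_token_label(q)}|{_status_label(st)}"

        def swap(s):
            p, q, st = s
            return (q, p, st)

        micro_rxns = []
        for s in micro:
            p, q, st = s
            # ligand transitions on each pocket
            for pos in (0, 1):
                cur, other = (p, q) if pos == 0 else (q, p)
                for frm, to, k, bind, rel in pocket_trans:
                    if cur != frm:
                        continue
                    if _is_crosslinked(to) and _is_crosslinked(other):
                        continue
                    new = (to, q, st) if pos == 0 else (p, to, st)
                    reactants = (label_of(s),) + ((LIGAND_SPECIES,) if bind is not None else ())
                    products = (label_of(new),) + ((LIGAND_SPECIES,) if rel is not None else ())
                    micro_rxns.append((reactants, products, k))
            active = _is_crosslinked(p) or _is_crosslinked(q)
            if st == "U" and active:
                micro_rxns.append(((label_of(s),), (label_of((p, q, "P")),), params.kp))
            if st == "P":
                micro_rxns.append(((label_of(s),), (label_of((p, q, "U")),), params.kdp))
                for prt in partners_i:
                    kd_off = spec.ka * spec.edge_kd(site, prt)
                    bnd = (p, q, ("B", prt))
                    micro_rxns.append(
                        ((label_of(s), prt), (label_of(bnd),), spec.ka))
                    micro_rxns.append(
                        ((label_of(bnd),), (label_of(s), prt), kd_off))
        labels, lumped, _orb = _lump(micro, micro_rxns, swap, label_of)
        form_states[site] = labels
        all_labels.extend(labels)
        lumped_all.update(lumped)
        for lbl in labels:
            per_form[lbl] = site
        init_labels.append(f"{site}|E.E|U")

    # observable weight vectors (assembled after the full species list exists)
    free = [LIGAND_SPECIES] + list(spec.partners)
    species = free + all_labels
    index = {s: i for i, s in enumerate(species)}
    n = len(species)
    extra = {}
    for p in spec.partners:
        vec = np.zeros(n)
        for lbl in all_labels:
            if lbl.endswith(f"|B:{p}"):
                vec[index[lbl]] = 1.0
        extra[f"bound:{p}"] = vec
    for site in spec.sites:
        vec = np.zeros(n)
        for lbl in form_states[site]:
            st = lbl.rsplit("|", 1)[1]
            if st != "U":
                vec[index[lbl]] = 1.0
        extra[f"phospho:{site}"] = vec
        act = np.zeros(n)
        for lbl in form_states[site]:
            cfg = lbl.split("|")[1]
            if "X" in cfg:
                act[index[lbl]] = 1.0
        extra[f"active:{site}"] = act
    held = np.zeros(n)
    for lbl in all_labels:
        cfg = lbl.split("|")[1]
        held[index[lbl]] = sum(tok != "E" for tok in cfg.split("."))
    extra["_ligand_held"] = held

    return _finalize(spec, all_labels, lumped_all, init_labels,
                     "restructured", extra, per_form)


def species_count(spec: ModelSpec) -> int:
    """Closed-form restructured species count: F + 9 * sum_i (2 + n_i)."""
    free = 1 + len(spec.partners)
    return free + 9 * sum(2 + len(spec.partners_at(s)) for s in spec.sites)


# ---------------------------------------------------------------------------
# Natural formulation (small-instance oracle)
# ---------------------------------------------------------------------------

def generate_natural_network(spec: ModelSpec, size_cap: int = 20000) -> ReactionNetwork:
    """Unreduced dimer state space: pockets and all sites jointly.

    Each dimer microstate is (pocket, pocket, protomer-A site statuses,
    protomer-B site statuses); species are orbits under the protomer/pocket
    swap.  Refuses to enumerate if the implied species count exceeds
    ``size_cap``.
    """
    if spec.restructured:
        raise ValueError("generate_natural_network expects a natural spec")
    n_sites = len(spec.sites)
    T = 1
    for s in spec.sites:
        T *= 2 + len(spec.partners_at(s))
    implied = (15 * T * T + 3 * T) // 2 + 1 + len(spec.partners)
    if implied > size_cap:
        raise NetworkSizeError(implied, size_cap)

    params = spec.params
    pocket_trans = _pocket_transitions(params, 1)
    toks = [_EMPTY, ("S1", 0), ("S2", 0), ("X", 0)]
    site_statuses = [
        ["U", "P"] + [("B", p) for p in spec.partners_at(s)] for s in spec.sites
    ]

    def protomer_tuples():
        out = [()]
        for statuses in site_statuses:
            out = [t + (st,) for t in out for st in statuses]
        return out

    prot = protomer_tuples()
    micro = [
        (p, q, sa, sb)
        for p in toks for q in toks
        if not (_is_crosslinked(p) and _is_crosslinked(q))
        for sa in prot for sb in prot
    ]

    def prot_label(t):
        return ",".join(_status_label(st) for st in t)

    def label_of(s):
        p, q, sa, sb = s
        return f"R|{_token_label(p)}.{_token_label(q)}|{prot_label(sa)}|{prot_label(sb)}"

    def swap(s):
        p, q, sa, sb = s
        return (q, p, sb, sa)

    micro_rxns = []
    for s in micro:
        p, q, sa, sb = s
        for pos in (0, 1):
            cur, other = (p, q) if pos == 0 else (q, p)
            for frm, to, k, bind, rel in pocket_trans:
                if cur != frm:
                    continue
                if _is_crosslinked(to) and _is_crosslinked(other):
                    continue
                new = (to, q, sa, sb) if pos == 0 else (p, to, sa, sb)
                reactants = (label_of(s),) + ((LIGAND_SPECIES,) if bind is not None else ())
                products = (label_of(new),) + ((LIGAND_SPECIES,) if rel is not None else ())
                micro_rxns.append((reactants, products, k))
        active = _is_crosslinked(p) or _is_crosslinked(q)
        for prot_pos in (0, 1):
            tup = sa if prot_pos == 0 else sb
            for i_site, st in enumerate(tup):
                def with_status(new_st):
                    new_t = tup[:i_site] + (new_st,) + tup[i_site + 1:]
                    return (p, q, new_t, sb) if prot_pos == 0 else (p, q, sa, new_t)

                site = spec.sites[i_site]
                if st == "U" and active:
                    micro_rxns.append(
                        ((label_of(s),), (label_of(with_status("P")),), params.kp))
                elif st == "P":
                    micro_rxns.append(
                        ((label_of(s),), (label_of(with_status("U")),), params.kdp))
                    for prt in spec.partners_at(site):
                        kd_off = spec.ka * spec.edge_kd(site, prt)
                        micro_rxns.append(
                            ((label_of(s), prt),
                             (label_of(with_status(("B", prt))),), spec.ka))
                        micro_rxns.append(
                            ((label_of(with_status(("B", prt))),),
                             (label_of(s), prt), kd_off))

    labels, lumped, _orb = _lump(micro, micro_rxns, swap, label_of)

    free = [LIGAND_SPECIES] + list(spec.partners)
    species = free + labels
    index = {sp_: i for i, sp_ in enumerate(species)}
    n = len(species)

    def parse(lbl):
        _r, cfg, sa, sb = lbl.split("|")
        return cfg, sa.split(","), sb.split(",")

    extra = {}
    for prt in spec.partners:
        vec = np.zeros(n)
        for lbl in labels:
            _cfg, sa, sb = parse(lbl)
            vec[index[lbl]] = (sa + sb).count(f"B:{prt}")
        extra[f"bound:{prt}"] = vec
    for i_site, site in enumerate(spec.sites):
        vec = np.zeros(n)
        act = np.zeros(n)
        for lbl in labels:
            cfg, sa, sb = parse(lbl)
            # site-copy concentration scale (two copies per dimer), matching
            # the restructured form convention
            vec[index[lbl]] = sum(1 for t in (sa[i_site], sb[i_site]) if t != "U")
            if "X" in cfg:
                act[index[lbl]] = 1.0
        extra[f"phospho:{site}"] = vec
        if i_site == 0:
            extra["active:dimer"] = act
    held = np.zeros(n)
    for lbl in labels:
        cfg, _sa, _sb = parse(lbl)
        held[index[lbl]] = sum(tok != "E" for tok in cfg.split("."))
    extra["_ligand_held"] = held

    per_form = {lbl: "dimer" for lbl in labels}
    init = f"R|E.E|{','.join(['U'] * n_sites)}|{','.join(['U'] * n_sites)}"
    return _finalize(spec, labels, lumped, init, "natural", extra, per_form)
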