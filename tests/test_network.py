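import numpy as np
import pytest

from rtkrecruit import network as net
from rtkrecruit.network import (
    ModelSpec,
    NetworkSizeError,
    Reaction,
    ReactionNetwork,
    generate_natural_network,
    generate_network,
    integrate_network,
    mass_action_rhs,
    restructure,
    species_count,
)
from rtkrecruit import synth


def toy_spec(params, sites=("Y980",), partners=("SHC1",),
             edges=(("Y980", "SHC1", 5e-7),), ligand=1e-9, clamped=True,
             partner_conc=None):
    if partner_conc is None:
        partner_conc = {p: 2e-8 for p in partners}
    return ModelSpec(
        sites=sites, partners=partners, edges=edges, params=params,
        receptor_dimers=1e-8, ligand=ligand, partner_conc=partner_conc,
        ligand_clamped=clamped,
    )


SHARED_SPEC = dict(
    sites=("Y980", "Y1161"),
    partners=("SHC1", "STAT1"),
    edges=(("Y980", "SHC1", 5e-7), ("Y1161", "SHC1", 2e-6),
           ("Y1161", "STAT1", 1e-6)),
    partner_conc={"SHC1": 5e-9, "STAT1": 8e-9},
)


class TestRestructure:
    def test_halves_association_rates_and_doubles_counts(self, balanced_params):
        spec = toy_spec(balanced_params)
        rs = restructure(spec)
        assert rs.restructured
        assert rs.params.a1 == spec.params.a1 / 2
        assert rs.params.a2 == spec.params.a2 / 2
        assert rs.ligand == 2 * spec.ligand
        assert rs.receptor_scale == 2 * spec.receptor_scale
        # first-order rates untouched
        assert rs.params.d1 == spec.params.d1
        assert rs.params.a1p == spec.params.a1p

    def test_idempotent(self, balanced_params):
        rs = restructure(toy_spec(balanced_params))
        assert restructure(rs) is rs

    def test_single_site_spec_maps_back_identically(self, balanced_params):
        """For one site, restructuration is just the count/rate rescaling."""
        spec = toy_spec(balanced_params)
        n_r = generate_network(restructure(spec))
        n_n = generate_natural_network(spec)
        t = np.linspace(0, 300, 4)
        xr = integrate_network(n_r, t, rtol=1e-10)
        xn = integrate_network(n_n, t, rtol=1e-10)
        for k in range(len(t)):
            a, b = n_r.observables(xr[k]), n_n.observables(xn[k])
            for key in ("bound:SHC1", "phospho:Y980", "crosslinked_fraction",
                        "free_ligand"):
                assert a[key] == pytest.approx(b[key], rel=1e-6, abs=1e-18)


class TestSpeciesCounts:
    def test_toy_single_site_single_partner_is_29(self, balanced_params):
        spec = restructure(toy_spec(balanced_params))
        nw = generate_network(spec)
        # 9 configurations x (2 + 1) statuses + free ligand + free partner
        assert nw.n_species == 29 == species_count(spec)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_count_formula_on_random_maps(self, balanced_params, seed):
        """N = F + 9 * sum_i (2 + n_i) for arbitrary bipartite maps."""
        s = synth.SyntheticSpec(seed=seed, n_proteins=6, n_sites=4,
                                edge_density=0.6)
        imap = synth.generate_interaction_map(s)
        edges = tuple((site, p, kd) for p, site, kd in imap.edges)
        spec = restructure(ModelSpec(
            sites=s.sites[:4], partners=s.proteins, edges=edges,
            params=balanced_params, receptor_dimers=1e-9, ligand=1e-9,
            partner_conc={p: 1e-8 for p in s.proteins},
        ))
        nw = generate_network(spec)
        F = 1 + len(s.proteins)
        n_i = [len(spec.partners_at(x)) for x in spec.sites]
        assert nw.n_species == F + 9 * sum(2 + n for n in n_i)
        assert nw.n_species == species_count(spec)

    def test_full_scale_map_yields_577_species(self, balanced_params):
        imap = synth.full_scale_interaction_map()
        assert len(imap.edges) == 50
        edges = tuple((site, p, kd) for p, site, kd in imap.edges)
        spec = restructure(ModelSpec(
            sites=synth.DEFAULT_SITES, partners=imap.proteins, edges=edges,
            params=balanced_params, receptor_dimers=1e-9, ligand=1e-9,
            partner_conc={p: 1e-8 for p in imap.proteins},
        ))
        assert generate_network(spec).n_species == 577

    def test_removing_an_edge_removes_nine_species(self, balanced_params):
        spec = restructure(toy_spec(
            balanced_params, **SHARED_SPEC))
        full = generate_network(spec).n_species
        smaller = generate_network(spec.replace(edges=spec.edges[:-1])).n_species
        assert full - smaller == 9

    def test_count_invariant_under_relabeling(self, balanced_params):
        spec = restructure(toy_spec(balanced_params, **SHARED_SPEC))
        renamed = spec.replace(
            partners=("AAA", "BBB"),
            edges=tuple(
                (s, {"SHC1": "AAA", "STAT1": "BBB"}[p], kd)
                for s, p, kd in spec.edges
            ),
            partner_conc={"AAA": 5e-9, "BBB": 8e-9},
        )
        reordered = spec.replace(sites=("Y1161", "Y980"))
        assert (generate_network(spec).n_species
                == generate_network(renamed).n_species
                == generate_network(reordered).n_species)


class TestMassActionRHS:
    def test_handwritten_reversible_binding(self):
        nw = ReactionNetwork(
            species=["A", "B", "C"],
            reactions=[Reaction((0, 1), (2,), 3.0), Reaction((2,), (0, 1), 0.5)],
            x0=np.zeros(3), clamped=set(),
            conservation=[("A+C", np.array([1.0, 0, 1.0]))],
            observable_weights={}, meta={"formulation": "natural",
                                         "receptor_dimers": 0,
                                         "receptor_scale": 1},
        )
        x = np.array([2.0, 5.0, 1.0])
        flux = 3.0 * 2.0 * 5.0 - 0.5 * 1.0
        expect = np.array([-flux, -flux, flux])
        got = nw.rhs(x)
        assert np.allclose(got, expect)
        assert nw.conservation_residual(got) < 1e-12

    def test_zero_state_zero_derivative(self, balanced_params):
        nw = generate_network(restructure(toy_spec(balanced_params)))
        z = np.zeros(nw.n_species)
        z[nw.index[net.LIGAND_SPECIES]] = 1e-9   # clamped ligand alone
        assert np.all(mass_action_rhs(nw, z) == 0)

    @pytest.mark.parametrize("formulation", ["restructured", "natural"])
    def test_conservation_orthogonality_random_state(self, balanced_params,
                                                     formulation, rng):
        spec = toy_spec(balanced_params, **SHARED_SPEC)
        nw = (generate_network(restructure(spec)) if formulation == "restructured"
              else generate_natural_network(spec))
        x = rng.uniform(0, 1e-8, nw.n_species)
        dx = mass_action_rhs(nw, x)
        scale = np.max(np.abs(dx)) + 1e-300
        assert nw.conservation_residual(dx) / scale < 1e-10

    def test_dimension_mismatch_rejected(self, balanced_params):
        nw = generate_network(restructure(toy_spec(balanced_params)))
        with pytest.raises(ValueError):
            nw.rhs(np.zeros(nw.n_species + 1))


class TestExactEquivalence:
    """The headline restructuration property: along trajectories every mapped
    observable of the natural formulation is reproduced exactly."""

    @pytest.mark.parametrize("case", ["one_site", "shared_partner"])
    def test_restructured_matches_natural_along_trajectory(self, balanced_params, case):
        if case == "one_site":
            spec = toy_spec(balanced_params)
            keys = ("bound:SHC1", "phospho:Y980", "crosslinked_fraction")
        else:
            spec = toy_spec(balanced_params, **SHARED_SPEC)
            keys = ("bound:SHC1", "bound:STAT1", "phospho:Y980",
                    "phospho:Y1161", "crosslinked_fraction")
        n_r = generate_network(restructure(spec))
        n_n = generate_natural_network(spec)
        t = np.linspace(0, 600, 5)
        xr = integrate_network(n_r, t, rtol=1e-10)
        xn = integrate_network(n_n, t, rtol=1e-10)
        floor = 1e-6 * spec.receptor_dimers
        for k in range(1, len(t)):
            a, b = n_r.observables(xr[k]), n_n.observables(xn[k])
            for key in keys:
                assert abs(a[key] - b[key]) <= 1e-6 * max(abs(b[key]), floor)

    def test_depleting_pool_single_form(self, balanced_params):
        """Scaling bookkeeping: with a finite ligand pool the doubled
        restructured pool tracks exactly twice the natural free ligand."""
        spec = toy_spec(balanced_params, ligand=5e-10, clamped=False)
        n_r = generate_network(restructure(spec))
        n_n = generate_natural_network(spec)
        t = np.linspace(0, 2e3, 5)
        xr = integrate_network(n_r, t, rtol=1e-10)
        xn = integrate_network(n_n, t, rtol=1e-10)
        for k in range(len(t)):
            a, b = n_r.observables(xr[k]), n_n.observables(xn[k])
            assert a["free_ligand"] == pytest.approx(b["free_ligand"], rel=1e-6)
            assert a["bound:SHC1"] == pytest.approx(b["bound:SHC1"],
                                                    rel=1e-6, abs=1e-20)

    def test_depleting_pool_multi_form_refused(self, balanced_params):
        spec = restructure(toy_spec(balanced_params, clamped=False,
                                    **SHARED_SPEC))
        with pytest.raises(ValueError):
            generate_network(spec)


class TestNaturalGuard:
    def test_full_scale_spec_refused_with_count(self, balanced_params):
        imap = synth.full_scale_interaction_map()
        edges = tuple((site, p, kd) for p, site, kd in imap.edges)
        spec = ModelSpec(
            sites=synth.DEFAULT_SITES, partners=imap.proteins, edges=edges,
            params=balanced_params, receptor_dimers=1e-9, ligand=1e-9,
            partner_conc={p: 1e-8 for p in imap.proteins},
        )
        with pytest.raises(NetworkSizeError) as err:
            generate_natural_network(spec)
        assert err.value.count > 1e9

    def test_dangling_edge_rejected(self, balanced_params):
        with pytest.raises(ValueError):
            toy_spec(balanced_params, edges=(("Y999", "SHC1", 1e-6),))
        with pytest.raises(ValueError):
            toy_spec(balanced_params, edges=(("Y980", "NOPE", 1e-6),))


class TestExport:
    @pytest.mark.parametrize("fmt", ["reactions", "bngl"])
    def test_text_dump_lists_all_species_and_reactions(self, balanced_params,
                                                       tmp_path, fmt):
        nw = generate_network(restructure(toy_spec(balanced_params)))
        path = tmp_path / f"net.{fmt}"
        net.export_network(nw, path, fmt=fmt)
        text = path.read_text()
        for s in nw.species:
            assert s in text
        if fmt == "reactions":
            assert f"# species: {nw.n_species}" in text

    def test_unknown_format_rejected(self, balanced_params, tmp_path):
        nw = generate_network(restructure(toy_spec(balanced_params)))
        with pytest.raises(ValueError):
            net.export_network(nw, tmp_path / "x", fmt="sbml")
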