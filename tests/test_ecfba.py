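import itertools
import math

import numpy as np
import pytest

import sulfassim as sa
from sulfassim import ecfba
from sulfassim.ecfba import Enzyme, Metabolite, MetabolicModel, Reaction


# ---------------------------------------------------------------------------
# Independent LP oracle: exhaustive vertex enumeration


def enumerate_vertex_optimum(c, A_eq, bounds, pool_row=None, pool_cap=None):
    """Maximise c @ x over {A_eq x = 0, lb <= x <= ub, pool_row x <= cap} by
    enumerating every basic feasible solution (active-set combinations)."""
    n = len(bounds)
    ineqs = []  # (row, rhs) treated as equalities when active
    for j, (lb, ub) in enumerate(bounds):
        e = np.zeros(n)
        e[j] = 1.0
        ineqs.append((e.copy(), lb))
        if np.isfinite(ub):
            ineqs.append((e.copy(), ub))
    if pool_row is not None:
        ineqs.append((np.asarray(pool_row, float), pool_cap))

    best = None
    b_eq = np.zeros(A_eq.shape[0])
    for k in range(n + 1):
        for subset in itertools.combinations(range(len(ineqs)), k):
            M = np.vstack([A_eq] + [ineqs[i][0] for i in subset])
            rhs = np.concatenate([b_eq, [ineqs[i][1] for i in subset]])
            if np.linalg.matrix_rank(M) < n:
                continue
            x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
            if not np.allclose(M @ x, rhs, atol=1e-9):
                continue
            feasible = np.allclose(A_eq @ x, 0, atol=1e-9)
            feasible &= all(lb - 1e-9 <= x[j] <= ub + 1e-9
                            for j, (lb, ub) in enumerate(bounds))
            if pool_row is not None:
                feasible &= float(np.asarray(pool_row) @ x) <= pool_cap + 1e-9
            if feasible:
                val = float(np.asarray(c) @ x)
                best = val if best is None else max(best, val)
    return best


def toy_chain(uptake=2.0, yield_coef=1.0):
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("EX_A", {"A": 1.0}, upper_bound=uptake, exchange=True),
        Reaction("R1", {"A": -1.0, "B": yield_coef}),
        Reaction("OBJ", {"B": -1.0}),
    ]
    return MetabolicModel(mets, rxns, objective="OBJ")


class TestSolveFba:
    def test_linear_chain_biomass_is_uptake_times_yield(self):
        res = sa.solve_fba(toy_chain(uptake=2.0, yield_coef=3.0))
        assert res.status == "optimal"
        assert res.biomass_flux == pytest.approx(6.0)

    def test_steady_state_residual(self):
        model = sa.build_sulfur_model()
        res = sa.solve_fba(model)
        met_ids = list(model.metabolites)
        residual = {m: 0.0 for m in met_ids}
        for rid, v in res.fluxes.items():
            for m, coef in model.reactions[rid].stoichiometry.items():
                residual[m] += coef * v
        assert max(abs(x) for x in residual.values()) <= 1e-6

    def test_infeasible_is_status_not_exception(self):
        mets = [Metabolite("A")]
        rxns = [Reaction("R", {"A": 1.0}, lower_bound=1.0, upper_bound=2.0),
                Reaction("OBJ", {"A": -1.0}, upper_bound=0.5)]
        res = sa.solve_fba(MetabolicModel(mets, rxns, objective="OBJ"))
        assert res.status == "infeasible"
        assert res.fluxes == {}

    def test_lp_matches_vertex_enumeration(self):
        # three small rational networks, with and without a pool constraint
        cases = []
        m1 = toy_chain(uptake=2.0, yield_coef=1.0)
        cases.append((m1, None, None))
        m2 = toy_chain(uptake=5.0, yield_coef=2.0)
        cases.append((m2, None, None))
        mets = [Metabolite("A"), Metabolite("B")]
        rxns = [
            Reaction("EX_A", {"A": 1.0}, upper_bound=10.0, exchange=True),
            Reaction("SLOW", {"A": -1.0, "B": 1.0}, enzyme="slow"),
            Reaction("FAST", {"A": -1.0, "B": 1.0}, enzyme="fast"),
            Reaction("OBJ", {"B": -1.0}),
        ]
        m3 = ecfba.add_enzyme_constraints(MetabolicModel(
            mets, rxns, [Enzyme("slow", 1.0), Enzyme("fast", 4.0)],
            enzyme_pool=1.0, objective="OBJ"))
        cases.append((m3, None, None))

        for model, _, _ in cases:
            variables = ecfba._split_variables(model)
            met_index = {m: i for i, m in enumerate(model.metabolites)}
            n = len(variables)
            A_eq = np.zeros((len(met_index), n))
            c = np.zeros(n)
            pool = np.zeros(n)
            bounds = []
            for j, (rid, sign, lb, ub) in enumerate(variables):
                r = model.reactions[rid]
                for m, coef in r.stoichiometry.items():
                    A_eq[met_index[m], j] = sign * coef
                if rid == model.objective and sign > 0:
                    c[j] = 1.0
                if model.enzyme_constrained and r.enzyme:
                    pool[j] = 1.0 / model.enzymes[r.enzyme].kcat
                bounds.append((lb, ub))
            use_pool = model.enzyme_constrained and math.isfinite(model.enzyme_pool)
            oracle = enumerate_vertex_optimum(
                c, A_eq, bounds,
                pool_row=pool if use_pool else None,
                pool_cap=model.enzyme_pool if use_pool else None)
            lp = sa.solve_fba(model).biomass_flux
            assert lp == pytest.approx(oracle, abs=1e-7)


class TestEnzymeConstraints:
    def test_huge_kcats_recover_unconstrained_optimum(self):
        constrained = sa.build_sulfur_model(
            kcats={k: 1e12 for k in ecfba.DEFAULT_KCATS})
        free = sa.build_sulfur_model()
        free.enzyme_pool = math.inf
        assert sa.solve_fba(constrained).biomass_flux == pytest.approx(
            sa.solve_fba(free).biomass_flux, rel=1e-6)

    def test_zero_pool_kills_catalyzed_fluxes(self):
        model = sa.build_sulfur_model(enzyme_pool=0.0)
        res = sa.solve_fba(model)
        for rid, v in res.fluxes.items():
            if model.reactions[rid].enzyme is not None:
                assert abs(v) <= 1e-9
        assert res.biomass_flux == 0.0

    def test_usage_within_pool(self):
        model = sa.build_sulfur_model()
        res = sa.solve_fba(sa.knockout(model, "MET15"))
        assert sum(res.enzyme_usage.values()) <= model.enzyme_pool + 1e-7

    def test_pool_tight_with_nonneg_shadow_price_at_bound(self):
        res = sa.solve_fba(sa.knockout(sa.build_sulfur_model(), "MET15"))
        assert "enzyme_pool" in res.binding_constraints
        assert res.pool_shadow_price is not None and res.pool_shadow_price >= 0

    def test_halving_binding_enzyme_kcat_never_raises_biomass(self):
        model = sa.knockout(sa.build_sulfur_model(), "MET15")
        base = sa.solve_fba(model).biomass_flux
        worse = model.copy()
        worse.enzymes["Yll058w"].kcat /= 2.0
        assert sa.solve_fba(worse).biomass_flux <= base + 1e-9

    def test_nonpositive_kcat_rejected(self):
        with pytest.raises(ValueError, match="kcat"):
            Enzyme("bad", 0.0)


class TestSulfurModel:
    def test_sulfur_atoms_balance_in_every_reaction(self):
        model = sa.build_sulfur_model()
        assert model.check_sulfur_balance()

    def test_homocysteine_synthase_is_the_only_route_on_sulfate(self):
        import networkx as nx

        model = sa.build_sulfur_model(medium="sulfate")
        for removed, expect in [((), True), (("MET15", "YLL058W"), False)]:
            g = nx.DiGraph()
            for rid, r in model.reactions.items():
                if rid in removed or r.upper_bound == 0:
                    continue
                subs = [m for m, c in r.stoichiometry.items() if c < 0]
                prods = [m for m, c in r.stoichiometry.items() if c > 0]
                for m in subs:
                    g.add_edge(m, rid)
                for m in prods:
                    g.add_edge(rid, m)
                if not subs:  # source exchange
                    g.add_edge("SOURCE", rid)
            reachable = nx.descendants(g, "SOURCE")
            assert ("biomass" in reachable) is expect

    def test_organosulfur_medium_bypasses_sap(self):
        model = sa.build_sulfur_model(medium="met")
        dbl = sa.knockout(sa.knockout(model, "MET15"), "YLL058W")
        res = sa.solve_fba(dbl)
        assert res.biomass_flux > 0
        assert all(abs(res.fluxes[r]) <= 1e-9
                   for r in ("MET3", "MET14", "MET16", "MET5_MET10"))

    def test_phenotype_ordering_on_sulfate(self):
        model = sa.build_sulfur_model(medium="sulfate")
        wt = sa.solve_fba(model).biomass_flux
        m15 = sa.solve_fba(sa.knockout(model, "MET15")).biomass_flux
        dbl = sa.solve_fba(
            sa.knockout(sa.knockout(model, "MET15"), "YLL058W")).biomass_flux
        assert wt > m15 > 0
        assert dbl == 0.0

    def test_unknown_medium_rejected(self):
        with pytest.raises(ValueError, match="medium"):
            sa.build_sulfur_model(medium="ypd")


class TestKnockout:
    def test_restriction_never_raises_biomass(self):
        model = sa.build_sulfur_model()
        wt = sa.solve_fba(model).biomass_flux
        for gene in ("MET15", "MET6", "CYS3", "MET3"):
            assert sa.solve_fba(sa.knockout(model, gene)).biomass_flux <= wt + 1e-9

    def test_met3_knockout_zero_on_sulfate(self):
        # the textbook SAP prediction: no sulfate reduction, no biomass
        model = sa.build_sulfur_model(medium="sulfate")
        assert sa.solve_fba(sa.knockout(model, "MET3")).biomass_flux == 0.0

    def test_double_knockout_commutes(self):
        model = sa.build_sulfur_model()
        ab = sa.knockout(sa.knockout(model, "MET15"), "YLL058W")
        ba = sa.knockout(sa.knockout(model, "YLL058W"), "MET15")
        assert set(ab.reactions) == set(ba.reactions)

    def test_input_model_untouched(self):
        model = sa.build_sulfur_model()
        before = set(model.reactions)
        sa.knockout(model, "MET15")
        assert set(model.reactions) == before

    def test_unknown_id_lists_known_ids(self):
        with pytest.raises(KeyError, match="MET3"):
            sa.knockout(sa.build_sulfur_model(), "NOPE999")


class TestKcatScan:
    def test_factor_one_equals_reference_solve(self):
        model = sa.knockout(sa.build_sulfur_model(), "MET15")
        ref = model.copy()
        ref.enzymes["Yll058w"].kcat = ecfba.DEFAULT_KCATS["Met15"]
        expected = sa.solve_fba(ref).biomass_flux
        table = sa.kcat_scan(model, "Yll058w", [1.0])
        assert table["biomass"].iloc[0] == pytest.approx(expected)

    def test_monotone_non_increasing(self):
        model = sa.knockout(sa.build_sulfur_model(), "MET15")
        table = sa.kcat_scan(model, "Yll058w", [1, 10, 100, 1000])
        assert (np.diff(table["biomass"]) <= 1e-9).all()

    def test_plateau_then_decline(self):
        model = sa.knockout(sa.build_sulfur_model(), "MET15")
        table = sa.kcat_scan(model, "Yll058w", [1, 2, 5, 10, 20, 50, 200, 500, 1000])
        b = table["biomass"].to_numpy()
        assert b[1] == pytest.approx(b[0], rel=1e-6)  # plateau at low factors
        assert b[-1] < 0.5 * b[0]  # clear decline at high factors

    def test_large_factor_approaches_double_knockout(self):
        model = sa.knockout(sa.build_sulfur_model(), "MET15")
        dbl = sa.solve_fba(sa.knockout(model, "YLL058W")).biomass_flux
        table = sa.kcat_scan(model, "Yll058w", [1e9])
        assert table["biomass"].iloc[0] == pytest.approx(dbl, abs=1e-5)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError, match="factors"):
            sa.kcat_scan(sa.build_sulfur_model(), "Yll058w", [0.0])


class TestModelIO:
    def test_json_round_trip_equals_hand_built(self, tmp_path):
        model = sa.build_sulfur_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ecfba.load_external_model(path)
        assert set(back.reactions) == set(model.reactions)
        assert back.enzyme_pool == model.enzyme_pool
        assert sa.solve_fba(back).biomass_flux == pytest.approx(
            sa.solve_fba(model).biomass_flux)

    def test_absent_file_clean_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ecfba.load_external_model(tmp_path / "missing.json")

    def test_unsupported_dialect_names_expected_format(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"format": "sbml-ish", "reactions": []}')
        with pytest.raises(ValueError, match="sulfassim-model-v1"):
            ecfba.load_external_model(path)
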