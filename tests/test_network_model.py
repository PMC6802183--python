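"""Network container, table I/O, assembly and right-hand-side tests."""

import io

import numpy as np
import pandas as pd
import pytest

from hypoxsim.network_model import (
    AssemblyError,
    CouplingConfig,
    Environment,
    ModelSchemaError,
    ModelValidationError,
    NORMOXIA,
    ReactionDef,
    ReactionNetwork,
    SpeciesDef,
    assemble_integrated_model,
    jacobian,
    load_model_tables,
    moiety_conservation_totals,
    reaction_rates,
    rhs,
)
from hypoxsim.population import toy_fixture_network
from hypoxsim.simulation import integrate_to_steady_state


def _table(text):
    return pd.read_csv(io.StringIO(text), sep="\t")


SPECIES_2 = """id\tinitial_conc\tunit\tmodule
A\t2.0\tnM\ttumor
B\t0.0\tnM\ttumor
"""

REACTIONS_1 = """id\treactants\tproducts\trate_law\tparams
r1\tA\tB\tmass_action\tkf=1.0; kr=1.0
"""


class TestLoadModelTables:
    def test_minimal_two_species_network(self):
        net = load_model_tables(_table(SPECIES_2), _table(REACTIONS_1))
        assert net.n_species == 2
        assert net.n_reactions == 1
        assert net.species_ids() == ["A", "B"]  # row order preserved

    def test_unknown_rate_law_names_row(self):
        bad = REACTIONS_1.replace("mass_action", "teleportation")
        with pytest.raises(ModelSchemaError, match="teleportation"):
            load_model_tables(_table(SPECIES_2), _table(bad))

    def test_dangling_species_reference(self):
        bad = REACTIONS_1.replace("A\tB", "A\tX")
        with pytest.raises(ModelValidationError, match="X"):
            load_model_tables(_table(SPECIES_2), _table(bad))

    def test_micromolar_unit_converted(self):
        sp = SPECIES_2.replace("A\t2.0\tnM", "A\t2.0\tuM")
        net = load_model_tables(_table(sp), _table(REACTIONS_1))
        assert net.initial_state()[0] == pytest.approx(2000.0)

    def test_builtin_tables_load_and_validate(self, hif_network, tumor_network):
        assert hif_network.n_species == 4
        assert tumor_network.n_species == 35
        assert all(s.module == "hif" for s in hif_network.species)
        # every phospho form's partner exists
        for s in tumor_network.species:
            if s.phospho_pair:
                assert s.phospho_pair in tumor_network.index

    def test_duplicate_species_rejected(self):
        dup = SPECIES_2 + "A\t1.0\tnM\ttumor\n"
        with pytest.raises(ModelValidationError, match="duplicate"):
            load_model_tables(_table(dup), _table(REACTIONS_1))


class TestRhs:
    def test_mass_action_two_species(self):
        sp = [SpeciesDef("A", 2.0), SpeciesDef("B", 0.0)]
        rx = [ReactionDef("r", (("A", 1),), (("B", 1),), "mass_action", {"kf": 1.0})]
        net = ReactionNetwork(sp, rx)
        dx = rhs(net, np.array([2.0, 0.0]))
        assert dx == pytest.approx([-2.0, 2.0])

    def test_stoichiometric_consistency_matrix_vs_accumulation(self, model):
        """dx from the stoichiometry contraction equals a per-reaction
        accumulation loop exactly (same summation order)."""
        rng = np.random.default_rng(0)
        state = model.initial_state() * np.exp(rng.normal(0, 0.3, model.n_species))
        rates = reaction_rates(model, state, NORMOXIA)
        manual = np.zeros(model.n_species)
        for j, r in enumerate(model.reactions):
            for sid, coef in r.reactants:
                manual[model.index[sid]] += -coef * rates[j]
            for sid, coef in r.products:
                manual[model.index[sid]] += coef * rates[j]
        auto = rhs(model, state, NORMOXIA)
        assert np.array_equal(auto, manual)

    def test_nonfinite_state_names_species(self, model):
        state = model.initial_state()
        state[model.index["pERK"]] = np.nan
        with pytest.raises(FloatingPointError, match="pERK"):
            rhs(model, state, NORMOXIA)

    def test_small_negative_clamped_large_negative_aborts(self, model):
        state = model.initial_state()
        state[0] = -1e-9  # within 10*atol: clamped
        rhs(model, state, NORMOXIA)
        state[0] = -1e-3
        with pytest.raises(FloatingPointError):
            rhs(model, state, NORMOXIA)

    def test_analytic_jacobian_matches_finite_differences(self, model):
        rng = np.random.default_rng(1)
        x = model.initial_state() * np.exp(rng.normal(0, 0.4, model.n_species))
        env = Environment(o2_fraction=0.3, drugs=(("MEK_phospho", 25.0),))
        jac = jacobian(model, x, env)
        f0 = rhs(model, x, env)
        for i in range(x.size):
            h = 1e-6 * max(abs(x[i]), 1e-3)
            xp = x.copy()
            xp[i] += h
            fd = (rhs(model, xp, env) - f0) / h
            assert np.allclose(jac[:, i], fd, rtol=1e-4, atol=1e-6)


class TestEnvironment:
    def test_o2_fraction_bounds(self):
        with pytest.raises(ModelValidationError):
            Environment(o2_fraction=0.0)
        with pytest.raises(ModelValidationError):
            Environment(o2_fraction=1.5)

    def test_unknown_target_rejected(self):
        with pytest.raises(ModelValidationError):
            Environment(drugs=(("CDK_phospho", 1.0),))

    def test_negative_dose_rejected(self):
        with pytest.raises(ModelValidationError):
            Environment(drugs=(("RAF_phospho", -1.0),))


class TestAssembly:
    def test_toy_union_species_count(self):
        hif = toy_fixture_network("toy_hif")
        tumor = toy_fixture_network("vegf_loop")
        net = assemble_integrated_model(hif, tumor, CouplingConfig())
        assert net.n_species == hif.n_species + tumor.n_species
        assert net.integrated
        assert net.coupling.mrna0 > 0

    def test_missing_mrna_species_reported(self):
        hif = toy_fixture_network("linear_chain")  # no mRNA species
        tumor = toy_fixture_network("vegf_loop")
        with pytest.raises(AssemblyError, match="mRNA"):
            assemble_integrated_model(hif, tumor, CouplingConfig())

    def test_untagged_phospho_reaction_reported(self):
        from dataclasses import replace

        hif = toy_fixture_network("toy_hif")
        cyc = toy_fixture_network("phospho_cycle")
        loop = toy_fixture_network("vegf_loop")
        # strip the atp_dependent tag but keep the law -> assembly error
        reactions = [
            replace(r, atp_dependent=False) if r.id == "phos" else r
            for r in cyc.reactions
        ] + loop.reactions
        bad = ReactionNetwork(cyc.species + loop.species, reactions)
        with pytest.raises(AssemblyError, match="atp_dependent"):
            assemble_integrated_model(hif, bad, CouplingConfig())

    def test_vegf_rebaseline_hits_configured_baseline(self):
        """Assembled toy loop settles at the VEGF value from the table."""
        hif = toy_fixture_network("toy_hif")
        tumor = toy_fixture_network("vegf_loop")
        net = assemble_integrated_model(hif, tumor, CouplingConfig())
        ss = integrate_to_steady_state(net, net.initial_state(), NORMOXIA)
        assert ss.converged
        v0 = tumor.species[tumor.index["VEGF"]].initial_conc
        assert ss.state[net.index["VEGF"]] == pytest.approx(v0, rel=1e-5)

    def test_hypoxic_vegf_synthesis_follows_squared_mrna(self):
        """At low O2 the synthesis rate scales as (mRNA/mRNA0)^2."""
        hif = toy_fixture_network("toy_hif")
        tumor = toy_fixture_network("vegf_loop")
        net = assemble_integrated_model(hif, tumor, CouplingConfig())
        env = Environment(o2_fraction=0.6)
        ss = integrate_to_steady_state(net, net.initial_state(), env)
        assert ss.converged
        j = [i for i, r in enumerate(net.reactions) if r.rate_law == "vegf_synthesis"][0]
        k_syn = float(dict(net.reactions[j].params)["k_syn"])
        mrna = ss.state[net.index["mRNA"]]
        expected = k_syn * (mrna / net.coupling.mrna0) ** 2
        got = reaction_rates(net, ss.state, env)[j]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_kab_calibration_identity_all_reactions(self, model):
        """(K_M,ATP/ATP_normoxia + 1) K^AB == K' for every converted reaction."""
        from hypoxsim.rate_laws import UM_TO_NM, atp_level

        atp_norm = atp_level(1.0, model.coupling.atp_params) * UM_TO_NM
        assert model.coupling.kab_calibration
        for rid, (k_prime, k_m_atp, k_ab) in model.coupling.kab_calibration.items():
            assert (k_m_atp / atp_norm + 1.0) * k_ab == pytest.approx(
                k_prime, rel=1e-12
            ), rid


class TestMoietyConservation:
    def test_phospho_cycle_total_conserved(self, phospho_cycle):
        totals = moiety_conservation_totals(phospho_cycle)
        assert any(
            set(t) == {"E", "pE"} and t["E"] == t["pE"] for t in totals
        )

    def test_purely_open_species_yields_empty_list(self):
        """A species with only synthesis and degradation has no conserved total."""
        sp = [SpeciesDef("V", 1.0)]
        rx = [
            ReactionDef("syn", (), (("V", 1),), "mass_action", {"kf": 1.0}),
            ReactionDef("deg", (("V", 1),), (), "degradation", {"k": 0.5}),
        ]
        assert moiety_conservation_totals(ReactionNetwork(sp, rx)) == []

    def test_vegf_loop_totals_are_conserved_combinations(self, vegf_loop):
        """Every returned combination is in the left null space of the
        interconversion stoichiometry (receptor + complex, ligand + complex)."""
        totals = moiety_conservation_totals(vegf_loop)
        assert totals
        keep = [
            j
            for j, r in enumerate(vegf_loop.reactions)
            if r.reactants and r.products and r.rate_law != "degradation"
        ]
        s = vegf_loop.stoichiometry[:, keep]
        for combo in totals:
            vec = np.zeros(vegf_loop.n_species)
            for sid, coef in combo.items():
                vec[vegf_loop.index[sid]] = coef
            assert np.allclose(vec @ s, 0.0)

    def test_totals_constant_along_closed_trajectory(self, tumor_network):
        """With open (synthesis/degradation) reactions removed, every
        returned total drifts < 1e-6 relative over a long trajectory."""
        from hypoxsim.simulation import timecourse

        keep = [
            r
            for r in tumor_network.reactions
            if r.reactants
            and r.products
            and r.rate_law not in ("degradation", "vegf_synthesis")
        ]
        closed = ReactionNetwork(tumor_network.species, keep)
        totals = moiety_conservation_totals(closed)
        assert totals
        t, states = timecourse(
            closed, closed.initial_state(), NORMOXIA, np.linspace(0, 1e4, 9)
        )
        assert t[-1] == pytest.approx(1e4)
        for combo in totals:
            series = sum(
                coef * states[:, closed.index[sid]] for sid, coef in combo.items()
            )
            assert np.max(np.abs(series - series[0])) <= 1e-6 * max(
                abs(series[0]), 1.0
            )
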