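"""SBML reading, labeled matrix I/O, and run configuration."""

import textwrap

import numpy as np
import pytest

import invjac
from invjac import read_matrix, read_sbml_model, write_matrix
from invjac.io import RunConfig, load_config
from invjac.sbml import SBMLError

SBML_HEADER = '<?xml version="1.0" encoding="UTF-8"?>\n'
NS = 'xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4"'


def write_sbml(tmp_path, body, name="model.xml"):
    path = tmp_path / name
    path.write_text(SBML_HEADER + f"<sbml {NS}>\n{body}\n</sbml>\n")
    return str(path)


DECAY_MODEL = textwrap.dedent("""\
    <model id="decay">
      <listOfCompartments>
        <compartment id="cell" size="1"/>
      </listOfCompartments>
      <listOfSpecies>
        <species id="S" compartment="cell" initialConcentration="2"/>
      </listOfSpecies>
      <listOfReactions>
        <reaction id="deg" reversible="false">
          <listOfReactants>
            <speciesReference species="S"/>
          </listOfReactants>
          <kineticLaw>
            <math xmlns="http://www.w3.org/1998/Math/MathML">
              <apply><times/><ci>k</ci><ci>S</ci></apply>
            </math>
            <listOfParameters>
              <parameter id="k" value="0.7"/>
            </listOfParameters>
          </kineticLaw>
        </reaction>
      </listOfReactions>
    </model>""")


BOUNDARY_MODEL = textwrap.dedent("""\
    <model id="boundary_demo">
      <listOfCompartments>
        <compartment id="cell" size="1"/>
      </listOfCompartments>
      <listOfSpecies>
        <species id="A" compartment="cell" initialConcentration="1"/>
        <species id="B" compartment="cell" initialConcentration="0.5"/>
        <species id="X" compartment="cell" initialConcentration="3"
                 boundaryCondition="true"/>
        <species id="Y" compartment="cell" initialConcentration="4"
                 constant="true"/>
      </listOfSpecies>
      <listOfParameters>
        <parameter id="k1" value="2"/>
      </listOfParameters>
      <listOfReactions>
        <reaction id="v1" reversible="true">
          <listOfReactants>
            <speciesReference species="A"/>
          </listOfReactants>
          <listOfProducts>
            <speciesReference species="B"/>
          </listOfProducts>
          <listOfModifiers>
            <modifierSpeciesReference species="B"/>
          </listOfModifiers>
          <kineticLaw>
            <math xmlns="http://www.w3.org/1998/Math/MathML">
              <apply><times/><ci>k1</ci><ci>X</ci><ci>A</ci></apply>
            </math>
          </kineticLaw>
        </reaction>
      </listOfReactions>
    </model>""")


FUNCDEF_MODEL = textwrap.dedent("""\
    <model id="funcdef_demo">
      <listOfFunctionDefinitions>
        <functionDefinition id="mm">
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <lambda>
              <bvar><ci>s</ci></bvar>
              <bvar><ci>vm</ci></bvar>
              <bvar><ci>km</ci></bvar>
              <apply><divide/>
                <apply><times/><ci>vm</ci><ci>s</ci></apply>
                <apply><plus/><ci>km</ci><ci>s</ci></apply>
              </apply>
            </lambda>
          </math>
        </functionDefinition>
      </listOfFunctionDefinitions>
      <listOfCompartments>
        <compartment id="cell" size="2"/>
      </listOfCompartments>
      <listOfSpecies>
        <species id="S" compartment="cell" initialConcentration="1"/>
      </listOfSpecies>
      <listOfParameters>
        <parameter id="vmax" value="4"/>
      </listOfParameters>
      <listOfRules>
        <assignmentRule variable="km_eff">
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <cn>0.5</cn>
          </math>
        </assignmentRule>
      </listOfRules>
      <listOfReactions>
        <reaction id="uptake" reversible="false">
          <listOfReactants>
            <speciesReference species="S"/>
          </listOfReactants>
          <kineticLaw>
            <math xmlns="http://www.w3.org/1998/Math/MathML">
              <apply><ci>mm</ci><ci>S</ci><ci>vmax</ci><ci>km_eff</ci></apply>
            </math>
          </kineticLaw>
        </reaction>
      </listOfReactions>
    </model>""")


class TestReadSBML:
    def test_minimal_decay_model(self, tmp_path):
        m = read_sbml_model(write_sbml(tmp_path, DECAY_MODEL))
        assert m.species_ids == ["S"]
        assert m.n_reactions == 1
        np.testing.assert_allclose(m.rates([2.0]), [1.4])  # k * S = 0.7 * 2
        np.testing.assert_allclose(
            invjac.ode_rhs(m, [2.0]), [-1.4]
        )

    def test_boundary_and_constant_species_excluded(self, tmp_path):
        m = read_sbml_model(write_sbml(tmp_path, BOUNDARY_MODEL))
        assert m.species_ids == ["A", "B"]  # X, Y held constant
        assert m.parameters["X"] == 3.0 and m.parameters["Y"] == 4.0
        # rate k1 * X * A = 2 * 3 * A with X substituted
        np.testing.assert_allclose(m.rates([1.5, 0.0]), [9.0])
        assert m.reversibility == [True]
        assert m.modifiers == [["B"]]

    def test_reversible_reaction_pattern_includes_product(self, tmp_path):
        m = read_sbml_model(write_sbml(tmp_path, BOUNDARY_MODEL))
        pat = invjac.pattern_from_stoichiometry(m)
        assert pat.mask.all()  # A and B both influence both rows

    def test_function_definition_and_assignment_rule(self, tmp_path):
        m = read_sbml_model(write_sbml(tmp_path, FUNCDEF_MODEL))
        # mm(S, 4, 0.5) = 4 S / (0.5 + S); compartment size 2 scales dS/dt
        np.testing.assert_allclose(m.rates([1.0]), [4.0 / 1.5])
        np.testing.assert_allclose(invjac.ode_rhs(m, [1.0]), [-4.0 / 3.0])

    def test_missing_kinetic_law_names_reaction(self, tmp_path):
        bad = textwrap.dedent("""\
            <model id="nolaw">
              <listOfCompartments><compartment id="c" size="1"/></listOfCompartments>
              <listOfSpecies>
                <species id="S" compartment="c" initialConcentration="1"/>
              </listOfSpecies>
              <listOfReactions>
                <reaction id="deg" reversible="false">
                  <listOfReactants><speciesReference species="S"/></listOfReactants>
                </reaction>
              </listOfReactions>
            </model>""")
        with pytest.raises(SBMLError, match="deg"):
            read_sbml_model(write_sbml(tmp_path, bad))

    def test_unsupported_rate_rule_rejected(self, tmp_path):
        bad = DECAY_MODEL.replace(
            "<listOfReactions>",
            '<listOfRules><rateRule variable="S">'
            '<math xmlns="http://www.w3.org/1998/Math/MathML"><cn>1</cn></math>'
            "</rateRule></listOfRules><listOfReactions>",
        )
        with pytest.raises(SBMLError, match="rateRule"):
            read_sbml_model(write_sbml(tmp_path, bad))

    def test_time_csymbol_rejected_by_name(self, tmp_path):
        bad = DECAY_MODEL.replace(
            "<apply><times/><ci>k</ci><ci>S</ci></apply>",
            '<csymbol encoding="text" definitionURL='
            '"http://www.sbml.org/sbml/symbols/time">t</csymbol>',
        )
        with pytest.raises(SBMLError, match="csymbol"):
            read_sbml_model(write_sbml(tmp_path, bad))


class TestMatrixIO:
    def test_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((4, 4)) * 1e-7
        labels = ["Fru", "Glc", "HexP", "Suc"]
        path = tmp_path / "cov.csv"
        write_matrix(path, M, labels)
        M2, labels2 = read_matrix(path)
        np.testing.assert_array_equal(M, M2)
        assert labels2 == labels

    def test_shuffled_labels_canonicalized(self, tmp_path):
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        path = tmp_path / "m.csv"
        write_matrix(path, M, ["b", "a"])
        M2, labels = read_matrix(path, labels=["a", "b"])
        assert labels == ["a", "b"]
        np.testing.assert_array_equal(M2, [[4.0, 3.0], [2.0, 1.0]])

    def test_label_mismatch_reports_difference(self, tmp_path):
        path = tmp_path / "m.csv"
        write_matrix(path, np.eye(2), ["a", "b"])
        with pytest.raises(ValueError, match="'c'"):
            read_matrix(path, labels=["a", "c"])

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",a,b\na,1.0,oops\nb,2.0,3.0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_matrix(path)


class TestRunConfig:
    def test_defaults_validate(self):
        RunConfig().validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(
            "synthetic_n: 5\nrepeats: 10\ncov_fractions: [1.0, 0.5]\nseed: 3\n"
        )
        cfg = load_config(cfg_path)
        assert cfg.synthetic_n == 5 and cfg.repeats == 10 and cfg.seed == 3

    def test_unknown_key_rejected(self, tmp_path):
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text("not_a_setting: 1\n")
        with pytest.raises(ValueError, match="not_a_setting"):
            load_config(cfg_path)

    def test_invalid_values_listed(self, tmp_path):
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text("repeats: 0\ncov_fractions: [2.0]\n")
        with pytest.raises(ValueError) as exc:
            load_config(cfg_path)
        assert "repeats" in str(exc.value) and "cov_fractions" in str(exc.value)


class TestLinearSystemExport:
    def test_export_round_trips_A_and_b(self, tmp_path):
        import invjac
        from invjac.io import export_linear_system
        import json as _json

        pat = invjac.JacobianPattern(np.array([[True, False], [True, True]]))
        sys = invjac.build_linear_system(
            np.array([[2.0, 0.3], [0.3, 1.0]]), np.diag([0.1, 0.2]), pat
        )
        paths = export_linear_system(sys, tmp_path / "sys")
        A = np.loadtxt(paths[0], delimiter=",")
        b = np.loadtxt(paths[1], delimiter=",")
        np.testing.assert_array_equal(A, sys.A)
        np.testing.assert_array_equal(b, sys.b)
        meta = _json.loads(paths[2].read_text())
        assert meta["index_map"] == [[0, 0], [1, 0], [1, 1]]
        assert meta["kappa_A"] == pytest.approx(sys.kappa_A)
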