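import pytest

from paramdag import fixtures as fx


@pytest.fixture
def decay_model():
    return fx.make_model(fx.DECAY)


@pytest.fixture
def conversion_model():
    return fx.make_model(fx.CONVERSION)


@pytest.fixture
def oscillator_model():
    return fx.make_model(fx.OSCILLATOR)


@pytest.fixture
def mdt_project():
    return fx.make_mdt_project()


@pytest.fixture
def fig3_project():
    return fx.make_fig3_project()


@pytest.fixture
def conflict_project():
    return fx.make_conflict_project()


EVENT_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="with_event">
    <listOfCompartments>
      <compartment id="cell" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialAmount="1"
               hasOnlySubstanceUnits="true" boundaryCondition="false"
               constant="false"/>
    </listOfSpecies>
    <listOfEvents>
      <event id="e1"/>
    </listOfEvents>
  </model>
</sbml>
"""

BAD_REF_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="bad_ref">
    <listOfCompartments>
      <compartment id="cell" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialAmount="1"
               hasOnlySubstanceUnits="true" boundaryCondition="false"
               constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="deg" reversible="false">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>kX</ci><ci>A</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

L2_CONCENTRATION_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="l2conc">
    <listOfCompartments>
      <compartment id="cyt" size="2.0"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cyt" initialConcentration="3.0"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k" value="1.5"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="deg">
        <listOfReactants>
          <speciesReference species="A"/>
        </listOfReactants>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>k</ci><ci>A</ci></apply>
          </math>
          <listOfParameters>
            <parameter id="kl" value="0.25"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


@pytest.fixture
def event_sbml(tmp_path):
    p = tmp_path / "event.xml"
    p.write_text(EVENT_SBML)
    return p


@pytest.fixture
def bad_ref_sbml(tmp_path):
    p = tmp_path / "bad_ref.xml"
    p.write_text(BAD_REF_SBML)
    return p


@pytest.fixture
def l2_sbml(tmp_path):
    p = tmp_path / "l2.xml"
    p.write_text(L2_CONCENTRATION_SBML)
    return p
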