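import numpy as np
import pytest

from cyanoprio.chem_mass import parse_formula
from cyanoprio.dereplication import CompoundRecord, load_compound_db
from cyanoprio.synthetic_data import (
    GeneratorConfig,
    SpikeSpec,
    generate_features,
    generate_screen,
)

#: Synthetic halogenated compounds used alongside the bundled database in
#: end-to-end tests (the bundled metabolites carry no Cl/Br).
SYNTHETIC_HALOGENATED = [
    ("synthetic chloro peptide", "C30H40ClN5O6", (1, 0)),
    ("synthetic dichloro lipid", "C25H38Cl2N2O4", (2, 0)),
    ("synthetic chlorobromo siderophore", "C32H35BrClN5O6S", (1, 1)),
]


@pytest.fixture(scope="session")
def small_screen_cfg():
    return GeneratorConfig(seed=11, n_strains=8, fractions_per_strain=8)


@pytest.fixture(scope="session")
def screen_result(small_screen_cfg):
    return generate_screen(small_screen_cfg)


@pytest.fixture(scope="session")
def closure_spikes():
    spikes = [
        SpikeSpec(rec.name, str(rec.formula), scaffold=rec.note.split(";")[0])
        for rec in load_compound_db()
        if rec.formula is not None
    ]
    spikes += [
        SpikeSpec(name, formula, scaffold="synthetic halogenated")
        for name, formula, _ in SYNTHETIC_HALOGENATED
    ]
    return spikes


@pytest.fixture(scope="session")
def closure_db():
    return load_compound_db() + [
        CompoundRecord(name, parse_formula(formula))
        for name, formula, _ in SYNTHETIC_HALOGENATED
    ]


@pytest.fixture(scope="session")
def feature_gen(closure_spikes):
    cfg = GeneratorConfig(seed=7)
    return generate_features(cfg, spikes=closure_spikes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
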