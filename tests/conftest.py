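import pytest

from sco2sol import empagliflozin_fixture

# Published correlation constants for the bundled dataset (used both to
# check printed-parameter reproduction and as plausible truth vectors for
# synthetic-data experiments).
TABLE4_PARAMS = {
    "alwi_garlapati": [-1.8293, -14.218, 2.8519],
    "bartle": [12.195, -5972.3, 7.7336e-3],
    "bian": [-0.062205, -5.7629e-4, -6230.8, 2.9473, 4.5582],
    "chrastil": [3.9083, -18.97, -3674.3],
    "garlapati_madras": [-750.2, 852.82, 1.0855, -7397.7, -11.163],
    "kumar_johnstone": [-14.274, -0.53652, 2.12162],
    "mahesh_garlapati": [-14.266, -0.52714, 2.0972],
    "mendez_teja": [-7775.4, 2.3557, 12.694],
    "sodeifian": [-23.94, 1.6043e-3, 2.4939, 2.6639e-4, -9.5238e-3, -1.037e3],
    "reformulated_chrastil": [3.8748, -33.58, -2705.8],
    "tippana_garlapati": [-6.4027e-5, -1.1813e-5, 2.0367e-5,
                          4.4544e-5, 3.5989e-5, -2.467e-5],
}

TABLE5_WILSON = [36634.0, -0.096039, -9673.6, -0.16480]
TABLE5_KIJ_LIJ = [0.32061, 0.1949]


@pytest.fixture(scope="session")
def fixture_bundle():
    return empagliflozin_fixture()


@pytest.fixture(scope="session")
def dataset(fixture_bundle):
    return fixture_bundle[0]


@pytest.fixture(scope="session")
def solute(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture(scope="session")
def solvent(fixture_bundle):
    return fixture_bundle[2]
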