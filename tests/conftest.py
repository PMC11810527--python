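import pytest

from heaa import default_references, load_hachijojima

# Published per-sample estimates recomputed independently from the clock
# equation with decimal rounding (frozen; keyed by sample_id).
PUBLISHED_AGES = {
    "1": 13.34, "2a": 10.21, "2b": 6.55, "3": 6.68, "4": 18.98, "5": 17.99,
    "6": 4.00, "7a": 9.65, "7b": 11.98, "8": 12.58, "9": 2.95, "10": 10.33,
    "11": 12.14, "12": 11.18, "13": 5.30, "14": 30.40, "15": 19.14,
    "16a": 15.53, "16b": 14.02, "17": 11.21, "18": 6.84, "19": 10.86,
    "20": 12.67, "21a": 13.41, "21b": 10.11,
}

PUBLISHED_CIS = {
    "1": (8.87, 17.81), "2a": (5.74, 14.68), "2b": (2.08, 11.02),
    "3": (2.21, 11.15), "4": (14.51, 23.45), "5": (13.52, 22.46),
    "6": (0.00, 8.47), "7a": (5.18, 14.12), "7b": (7.51, 16.45),
    "8": (8.11, 17.05), "9": (0.00, 7.42), "10": (5.86, 14.80),
    "11": (7.67, 16.61), "12": (6.71, 15.65), "13": (0.83, 9.77),
    "14": (25.93, 34.87), "15": (14.67, 23.61), "16a": (11.06, 20.00),
    "16b": (9.55, 18.49), "17": (6.74, 15.68), "18": (2.37, 11.31),
    "19": (6.39, 15.33), "20": (8.20, 17.14), "21a": (8.94, 17.88),
    "21b": (5.64, 14.58),
}


@pytest.fixture(scope="session")
def refs():
    return default_references()


@pytest.fixture(scope="session")
def biopsy_table():
    return load_hachijojima()


@pytest.fixture(scope="session")
def published_ages():
    return PUBLISHED_AGES


@pytest.fixture(scope="session")
def published_cis():
    return PUBLISHED_CIS
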