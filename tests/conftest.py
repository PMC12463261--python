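from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mednorm.fixtures import DATA_DIR
from mednorm.preprocess import load_rules
from mednorm.vocab import Tier, load_vocabulary


@pytest.fixture(scope="session")
def rules():
    return load_rules(
        DATA_DIR / "unwanted_terms.txt",
        DATA_DIR / "abbreviations.tsv",
        DATA_DIR / "special_cases.tsv",
    )


@pytest.fixture(scope="session")
def primary(rules):
    return load_vocabulary(DATA_DIR / "demo_vocab", Tier.PRIMARY, rules)


@pytest.fixture(scope="session")
def extended(rules):
    return load_vocabulary(DATA_DIR / "demo_vocab", Tier.EXTENDED, rules)


@pytest.fixture()
def cache_dir(tmp_path: Path) -> Path:
    return tmp_path / "cache"


# the seven demo raw names and the outcome each should produce
DEMO_NAMES = [
    ("TYLENOL 500 MG CAPLETS", "MATCHED", "B01"),
    ("Humira (no strength given)", "MATCHED", "B02"),
    ("Metformn (misspelled)", "MATCHED", "I02"),
    ("Losartan/HCTZ 50/12.5", "MATCHED", "M01"),
    ("Doliprane (*International Brand*)", "MATCHED", "I01"),
    ("???? (garbled entry)", "UNMATCHED", None),
    ("ACCU-CHEK AVIVA PLUS (device)", "UNMATCHED", None),
]
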