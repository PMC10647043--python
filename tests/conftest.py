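import json
from pathlib import Path

import pytest
from rdkit import RDLogger

from pswdesign import fixtures, reactor

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def all_rules():
    return reactor.build_rule_set()


@pytest.fixture(scope="session")
def toy_catalog():
    return fixtures.toy_library()


@pytest.fixture(scope="session")
def mini_db(tmp_path_factory):
    """Seeded mini ChEMBL-dialect database + its manifest."""
    root = tmp_path_factory.mktemp("minidb")
    path = fixtures.generate_mini_chembl(root / "mini.db")
    manifest = json.loads(
        (root / "mini.db.manifest.json").read_text())
    return path, manifest


@pytest.fixture(scope="session")
def toy_pocket(tmp_path_factory) -> Path:
    root = tmp_path_factory.mktemp("pocket")
    return fixtures.write_toy_pocket(root / "pocket.pdb")
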