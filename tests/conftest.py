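import dataclasses
from pathlib import Path

import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass

from omixid.synth import FixtureSpec, gen_reference, gen_user_tables
from omixid.workflows import load_bundle_stores


@dataclasses.dataclass
class World:
    """A generated bundle plus everything loaded from it."""

    spec: object
    bundle: Path
    manifest: object
    user_files: dict
    stores: object


def _make_world(spec: FixtureSpec, root: Path) -> World:
    bundle, manifest = gen_reference(spec, root)
    user_files = gen_user_tables(spec, manifest, root / "user")
    manifest.save(bundle / "ground_truth.json")
    return World(spec=spec, bundle=bundle, manifest=manifest,
                 user_files=user_files, stores=load_bundle_stores(bundle))


@pytest.fixture(scope="session")
def default_world(tmp_path_factory) -> World:
    spec = FixtureSpec(seed=11)
    return _make_world(spec, tmp_path_factory.mktemp("default_world"))


@pytest.fixture(scope="session")
def stress_world(tmp_path_factory) -> World:
    spec = dataclasses.replace(
        FixtureSpec(seed=23), n_genes_per_taxon=60, n_mirnas_per_taxon=40,
        targets_per_mirna=15, db_probs=(0.7, 0.6, 0.5, 0.4))
    return _make_world(spec, tmp_path_factory.mktemp("stress_world"))
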