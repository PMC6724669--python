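"""Shared fixtures: one synthetic suite and one pipeline run per session."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from medaltriage.config import Config
from medaltriage.fixtures import generate_suite
from medaltriage.pipeline import run_pipeline

SUITE_SEED = 7


@pytest.fixture(scope="session")
def default_cfg() -> Config:
    return Config()


@pytest.fixture(scope="session")
def suite_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("suite")
    generate_suite(SUITE_SEED, out)
    return out


@pytest.fixture(scope="session")
def suite_manifest(suite_dir) -> dict:
    return json.loads((suite_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def suite_result(suite_dir):
    return run_pipeline(
        suite_dir / "suite.vcf",
        suite_dir / "panel.tsv",
        suite_dir / "annotations.tsv",
        suite_dir / "exons.tsv",
        suite_dir / "kb",
        Config(),
        whitelist=suite_dir / "whitelist.txt",
        blacklist=suite_dir / "blacklist.txt",
        genes=suite_dir / "genes.tsv",
    )
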