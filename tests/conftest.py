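"""Shared fixtures: seeded synthetic projects built once per test session."""

import pytest

from neuroqc.checks import build_registry
from neuroqc.engine import run_validator
from neuroqc.fixtures import make_project, make_selfcheck_project
from neuroqc.model import load_project

SEED = 20240101


@pytest.fixture(scope="session")
def selfcheck_root(tmp_path_factory):
    """The self-check fixture project: clean sessions plus one single-defect
    session per registered defect."""
    root = tmp_path_factory.mktemp("selfcheck")
    return make_selfcheck_project(root / "fx", seed=SEED)


@pytest.fixture(scope="session")
def selfcheck_project(selfcheck_root):
    return load_project(selfcheck_root)


@pytest.fixture(scope="session")
def validated_project(tmp_path_factory):
    """A 10-session PET project (3 sessions deliberately defective) with all
    PET validators run and reports persisted — the aggregation substrate."""
    root = tmp_path_factory.mktemp("proj") / "p"
    plan = {1: ["dose_low"], 4: ["weight_high"], 7: ["missing_tracer"]}
    make_project(root, n_sessions=10, defect_plan=plan, seed=SEED + 7)
    project = load_project(root)
    validator = build_registry()["PetSessionValidator"]
    for session in project.sessions:
        if session.modality == "PET":
            run_validator(validator, session, project, persist=True,
                          timestamp="2024-06-01T12:00:00+00:00")
    return project


@pytest.fixture(scope="session")
def registry():
    return build_registry()
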