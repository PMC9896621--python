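"""Shared fixtures: hand-built geometry and small synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest

from posevote.io_model import Atom, BindingSite, Pose, ScoreTable
from posevote.synthetic_fixtures import FixtureConfig, generate


def make_atom(
    name="CA",
    resname="ALA",
    resnum=1,
    chain="A",
    element=None,
    coords=(0.0, 0.0, 0.0),
):
    element = element or name[0]
    return Atom(
        atom_name=name,
        residue_name=resname,
        residue_number=resnum,
        chain_id=chain,
        element=element,
        coords=tuple(float(c) for c in coords),
        is_hydrogen=element.upper() in ("H", "D", "T"),
    )


def make_site(points, resname="ALA"):
    """A binding site with one carbon atom per point (unique residue numbers)."""
    atoms = [
        make_atom(name="CA", resname=resname, resnum=i + 1, coords=p)
        for i, p in enumerate(points)
    ]
    return BindingSite(atoms=atoms)


def make_pose(points, compound_id="C1", pose_id="C1#1", elements=None):
    elements = elements or ["C"] * len(points)
    atoms = [
        (el, el.upper() == "H", tuple(float(c) for c in p))
        for el, p in zip(elements, points)
    ]
    return Pose(compound_id=compound_id, pose_id=pose_id, atoms=atoms)


def make_score_table(values, directions):
    """values: {pose_id: {name: value}}."""
    return ScoreTable(rows={k: dict(v) for k, v in values.items()},
                      directions=dict(directions))


@pytest.fixture(scope="session")
def small_bundle():
    """~60-compound bundle with a strong planted signal (session-cached)."""
    config = FixtureConfig(
        n_compounds=60,
        poses_per_compound=(3, 8),
        n_site_atoms=40,
        planted_contact_ids=(2, 11, 27),
        signal_strength=0.9,
        seed=11,
    )
    return generate(config)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Very small bundle for fast plumbing tests."""
    config = FixtureConfig(
        n_compounds=20,
        poses_per_compound=(2, 4),
        n_site_atoms=20,
        planted_contact_ids=(1, 7),
        signal_strength=0.95,
        seed=5,
    )
    return generate(config)
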