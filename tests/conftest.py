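"""Shared fixtures: small designs, planted parameter sets, and cached
simulation studies reused across test modules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gazedcm import synth
from gazedcm.forward import (DCMParameters, InputChannel, RegionSet,
                             StimulusDesign, SwitchSpec)


@pytest.fixture(scope="session")
def regions3():
    return RegionSet(("OCP", "PPA", "HPC"))


@pytest.fixture(scope="session")
def full_switch(regions3):
    return SwitchSpec.full_design(regions3)


@pytest.fixture(scope="session")
def scene_run_design():
    """One realized scene run of the study's schedule (seeded)."""
    td = synth.make_task_design(n_scene_runs=1, n_scrambled_runs=0, seed=11)
    return td.condition_design("scene")


@pytest.fixture(scope="session")
def design_200(scene_run_design):
    """The schedule truncated to exactly 200 scans at TR = 2 s."""
    return synth.crop_design(scene_run_design, 200, 2.0)


@pytest.fixture(scope="session")
def mean_params():
    """Group-mean scene parameters (no between-subject deviation)."""
    truth = dataclasses.replace(synth.GroundTruth(), between_sd=0.0,
                                hemo_sd=0.0)
    return synth.make_group_parameters(truth, N=2, seed=0)[0]


def two_node_switch(n_channels: int = 2) -> SwitchSpec:
    """A 2-node model (OCP -> PPA chain) used for cheap inversion tests."""
    a = np.array([[True, True], [True, True]])
    b = a.copy()[None]
    c = np.zeros((2, n_channels), bool)
    c[0, 0] = True
    return SwitchSpec(a, b, c)


def two_node_params(a_forward=0.4, a_back=-0.2, b_forward=0.0,
                    c=0.5) -> DCMParameters:
    A = np.array([[0.0, a_back], [a_forward, 0.0]])
    B = np.zeros((1, 2, 2))
    B[0, 1, 0] = b_forward
    C = np.zeros((2, 2))
    C[0, 0] = c
    return DCMParameters(A, B, C, regions=RegionSet(("OCP", "PPA")))


def simple_design(n_trials=30, gap=6.0, dur=4.0, dt=0.125,
                  lead=10.0) -> StimulusDesign:
    """Regularly spaced trials, half of them 'free', one run."""
    onsets = lead + np.arange(n_trials) * (dur + gap)
    total = onsets[-1] + dur + 10.0
    free = onsets[::2]
    chans = (InputChannel("all", onsets, np.full(n_trials, dur),
                          mean_center=True),
             InputChannel("free", free, np.full(free.size, dur)))
    return StimulusDesign(chans, dt, total, np.zeros(1))


@pytest.fixture(scope="session")
def design2():
    return simple_design()
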