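"""Shared fixtures: parametric closed curves and small synthetic datasets."""

import numpy as np
import pytest

from musselshape.outline_io import Outline


def parametric_outline(kind: str, n: int = 512, view: str = "lateral") -> Outline:
    """Closed test curves sampled uniformly in the angle parameter."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if kind == "circle":
        xy = np.column_stack([np.cos(t), np.sin(t)])
    elif kind == "ellipse":
        xy = np.column_stack([2 * np.cos(t), np.sin(t)])
    elif kind == "mussel":
        r = (
            1.0
            + 0.28 * np.cos(t)
            + 0.06 * np.sin(t)
            + 0.10 * np.sin(2 * t)
            + 0.045 * np.cos(3 * t)
            + 0.018 * np.sin(4 * t)
            + 0.008 * np.cos(5 * t)
            + 0.004 * np.sin(6 * t)
        )
        xy = np.column_stack([r * np.cos(t), 0.58 * r * np.sin(t)])
    elif kind == "square":
        # four corners, n//4 points per side
        side = np.linspace(-1, 1, n // 4, endpoint=False)
        xy = np.concatenate(
            [
                np.column_stack([side, np.full_like(side, -1.0)]),
                np.column_stack([np.full_like(side, 1.0), side]),
                np.column_stack([-side, np.full_like(side, 1.0)]),
                np.column_stack([np.full_like(side, -1.0), -side]),
            ]
        )
    else:
        raise ValueError(kind)
    return Outline(kind, view, xy)


@pytest.fixture
def circle():
    return parametric_outline("circle")


@pytest.fixture
def ellipse():
    return parametric_outline("ellipse")


@pytest.fixture
def mussel():
    return parametric_outline("mussel")


@pytest.fixture
def square():
    return parametric_outline("square", n=400)


@pytest.fixture(scope="session")
def small_dataset():
    """A small generated dataset shared across read-only tests."""
    from musselshape import synth

    env = synth.generate_environment(6, seed=11)
    return synth.generate_dataset(env, 8, synth.GeneratorConfig(seed=11))
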