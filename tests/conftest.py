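"""Shared fixtures: small ground-truthed phantoms and component helpers.

Expensive phantom pipelines are session-scoped so several tests can
share one preprocessing + feature-extraction pass.
"""

from __future__ import annotations

import numpy as np
import pytest

from nephtrack.features import (
    CrossSection,
    Node,
    StackFeatures,
    compute_shape_factors,
    extract_features,
)
from nephtrack.phantom import PhantomSpec, TubeSpec, generate_stack
from nephtrack.preprocess import preprocess_stack


def make_cross_section(mask: np.ndarray, slice_index: int = 0, label: int = 1) -> CrossSection:
    """CrossSection from a full-image boolean mask, shape factors filled."""
    mask = np.asarray(mask, dtype=bool)
    rr, cc = np.nonzero(mask)
    r0, c0 = rr.min(), cc.min()
    cs = CrossSection(
        slice_index=slice_index,
        label=label,
        mask=mask[r0 : rr.max() + 1, c0 : cc.max() + 1],
        bbox_origin=(int(r0), int(c0)),
    )
    cs.shape = compute_shape_factors(cs)
    return cs


def make_node(x, y, z=0, cs=None, k=0, profile=None) -> Node:
    node = Node(x=int(x), y=int(y), z=int(z), cs_id=(z, cs.label if cs else 1), k=k)
    node.cross_section = cs
    node.profile = profile
    return node


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture(scope="session")
def single_tube_pipeline():
    """One mildly tortuous tube, 40 slices, preprocessed with features."""
    spec = PhantomSpec(
        image_size=(160, 160),
        n_slices=40,
        tubes=(TubeSpec(start=(80.0, 80.0), cortex_radius=10, tortuosity=0.8),),
        seed=11,
    )
    stack, truth = generate_stack(spec)
    binary = preprocess_stack(stack)
    feats = extract_features(binary)
    return stack, truth, binary, feats


@pytest.fixture(scope="session")
def two_tube_clutter_pipeline():
    """Two well-separated tubes plus clutter, for purity/capture tests."""
    spec = PhantomSpec(
        image_size=(200, 200),
        n_slices=30,
        tubes=(
            TubeSpec(start=(50.0, 50.0), cortex_radius=9, tortuosity=0.7),
            TubeSpec(start=(150.0, 150.0), cortex_radius=9, tortuosity=0.7),
        ),
        clutter_density=30,
        seed=13,
        min_separation=70,
    )
    stack, truth = generate_stack(spec)
    binary = preprocess_stack(stack)
    feats = extract_features(binary)
    return stack, truth, binary, feats
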