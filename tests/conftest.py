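import numpy as np
import pytest
from hypothesis import settings

import phylomorph as pm
from phylomorph.matrices import DistanceMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_distance_matrix(n: int, rng: np.random.Generator, labels=None) -> DistanceMatrix:
    """Random symmetric nonnegative matrix (not necessarily metric)."""
    m = rng.random((n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    if labels is None:
        labels = [f"L{i:02d}" for i in range(n)]
    return DistanceMatrix(labels, m)


@pytest.fixture(scope="session")
def colony_bundle():
    """One synthetic colony carried through rasterization and skeletonization."""
    params = dict(mean_radius=3.0, mean_branch_length=24.0, branch_angle=45.0,
                  n_generations=3, angle_jitter=3.0, radius_taper=1.0)
    bp = pm.generate_colony_blueprint(params, seed=7)
    vol = pm.rasterize(bp, (0.5, 0.5, 1.5))
    skel = pm.skeletonize(vol)
    measures = pm.measure_branches(skel)
    return dict(params=params, blueprint=bp, volume=vol, skeleton=skel, measures=measures)


def make_y_blueprint(deflection_deg=30.0, radius=2.5, trunk_len=30.0, child_len=25.0):
    """Hand-built Y: vertical trunk, two children deflected +/-deflection in the xy plane."""
    import math

    from phylomorph.synthetic import ColonyBlueprint, ColonySegment

    a = math.radians(deflection_deg)
    top = np.array([0.0, trunk_len, 0.0])
    d1 = np.array([math.sin(a), math.cos(a), 0.0])
    d2 = np.array([-math.sin(a), math.cos(a), 0.0])
    segs = [
        ColonySegment(np.zeros(3), top, radius, None, 0),
        ColonySegment(top.copy(), top + child_len * d1, radius, 0, 1),
        ColonySegment(top.copy(), top + child_len * d2, radius, 0, 1),
    ]
    return ColonyBlueprint("Y", segs, true_b_angles={0: 2 * deflection_deg})
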