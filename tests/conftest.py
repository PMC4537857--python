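import itertools

import numpy as np
import pytest
from scipy.linalg import null_space

from rootbox import imaging as im
from rootbox import synthetic as syn


def make_sim_spec(
    n_parents=5,
    n_checks=2,
    envs=("E1", "E2"),
    reps=2,
    mu=10.0,
    heterosis=0.6,
    residual_sd=0.0,
    seed=0,
    effect_rng=None,
):
    """A small diallel ground truth with every effect family populated."""
    rng = np.random.default_rng(11) if effect_rng is None else effect_rng
    parents = tuple(f"P{i:02d}" for i in range(n_parents))
    checks = tuple(f"CK{i+1}" for i in range(n_checks))
    crosses = list(itertools.combinations(parents, 2))

    def centered(n, scale):
        v = rng.normal(0.0, scale, n)
        return v - v.mean()

    a = centered(n_parents, 0.5)
    g = centered(n_parents, 0.3)
    C = np.zeros((n_parents, len(crosses)))
    for i, l in enumerate(parents):
        for c, pair in enumerate(crosses):
            if l in pair:
                C[i, c] = 1.0
    B = null_space(C)
    s = B @ (B.T @ rng.normal(0.0, 0.25, len(crosses)))
    ck = centered(n_checks, 0.3)
    e_vals = centered(len(envs), 0.5)
    b = {"parent": -heterosis / 2, "F1": heterosis / 2, "check": 0.0}
    shift = sum(b.values()) / 3
    b = {k: v - shift for k, v in b.items()}
    return syn.DiallelSimSpec(
        parent_ids=parents,
        check_ids=checks,
        env_ids=tuple(envs),
        reps_per_env=reps,
        mu=mu,
        env_effects=dict(zip(envs, e_vals)),
        class_effects=b,
        additive=dict(zip(parents, a)),
        gca=dict(zip(parents, g)),
        sca=dict(zip(crosses, s)),
        check_effects=dict(zip(checks, ck)),
        residual_sd=residual_sd,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def root_ensemble():
    """~50 grown root systems at 256 px with per-view RA/SD/FD measurements.

    Shared across tests that check cross-view consistency. Cone half-angles
    span 15-43 degrees — the kind of root-angle diversity a genetically
    broad population shows — with moderate lateral branching so silhouettes
    look like real cores rather than bare cones; the robust percentile
    envelope is used because branched silhouettes are noisy.
    """
    records = []
    for s in range(50):
        params = syn.GrowthParams(
            canvas_size_px=256,
            stem_length_px=45,
            segment_length_px=75,
            stem_diameter_px=12,
            cone_half_angle_deg=15.0 + 4.0 * (s % 8),
            branch_prob=0.25 + 0.05 * (s % 7),
            rng_seed=1000 + s,
        )
        views = syn.project_views(syn.grow_root_system(params))
        res = im.phenotype_viewset(views, robust_angle=True)
        res["params"] = params
        records.append(res)
    return records
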