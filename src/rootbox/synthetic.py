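"""Synthetic root systems, fractal fixtures, and diallel phenotype tables.

Everything downstream of this module is tested against ground truth that the
generators here control: rendered silhouettes with known box dimension,
stochastic branching root systems with known cone geometry and stem width,
and plot-mean trait tables produced from the generation-block diallel model
with chosen effect sizes and Gaussian residual noise.

The root growth model is a deliberately simple stochastic recursive
branching process, not a biomechanical one: a vertical stem carrying whorls
("nodes") of shoot-borne roots whose initial directions lie within a cone
about the downward vertical, with lateral branches spawned per segment with
a fixed probability per branching order. Only the silhouette statistics
(branching density, cone angle, stem width) matter to the analysis stages,
and those are the controllable knobs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import BinaryImage, ViewSet

__all__ = [
    "FractalFixtureSpec",
    "GrowthParams",
    "Segment",
    "RootSystemModel",
    "DiallelSimSpec",
    "render_known_fractal",
    "render_wedge",
    "grow_root_system",
    "project_views",
    "simulate_diallel_dataset",
]

SIERPINSKI_DIM = math.log(3) / math.log(2)


def _check_pow2(side: int) -> None:
    if side < 1 or side & (side - 1):
        raise ValueError(f"canvas side must be a power of two, got {side}")


@dataclass(frozen=True)
class FractalFixtureSpec:
    """A deterministic raster with analytically known box dimension.

    kinds: ``line`` (one full-width 1-px row; dimension 1), ``filled``
    (every pixel foreground; dimension 2), ``sierpinski_triangle``
    (dimension log3/log2 ≈ 1.585).
    """

    kind: str
    canvas_size_px: int = 512
    level: int = 0

    def __post_init__(self):
        if self.kind not in ("line", "filled", "sierpinski_triangle"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        _check_pow2(self.canvas_size_px)
        max_level = int(math.log2(self.canvas_size_px))
        if self.kind == "sierpinski_triangle" and not (0 <= self.level <= max_level):
            raise ValueError(
                f"level {self.level} too deep for a {self.canvas_size_px}-px canvas"
            )

    @property
    def theoretical_dim(self) -> float:
        return {"line": 1.0, "filled": 2.0, "sierpinski_triangle": SIERPINSKI_DIM}[
            self.kind
        ]


def render_known_fractal(spec: FractalFixtureSpec) -> BinaryImage:
    """Rasterize a fixture with known box dimension.

    The Sierpinski triangle at level ℓ keeps the blocks (i, j) of side
    canvas/2**ℓ with ``i & j == 0`` — the Pascal-triangle-mod-2 pattern whose
    box counts follow N(2^m) = 3^(ℓ-m) exactly on the power-of-two ladder.
    """
    n = spec.canvas_size_px
    if spec.kind == "filled":
        return BinaryImage(np.ones((n, n), dtype=bool))
    if spec.kind == "line":
        mask = np.zeros((n, n), dtype=bool)
        mask[n // 2, :] = True
        return BinaryImage(mask)
    blocks = 1 << spec.level
    i, j = np.meshgrid(np.arange(blocks), np.arange(blocks), indexing="ij")
    pattern = (i & j) == 0
    mask = np.kron(pattern, np.ones((n // blocks, n // blocks), dtype=bool))
    return BinaryImage(mask)


def render_wedge(
    half_angle_deg: float,
    canvas_size_px: int = 512,
    stem_width_px: int = 0,
    stem_length_px: int = 0,
) -> BinaryImage:
    """A filled symmetric wedge (apex up) with edges at ±half_angle from
    vertical, optionally topped by a vertical stem bar — an analytic fixture
    for the root-angle and stalk-diameter measurements."""
    n = canvas_size_px
    mask = np.zeros((n, n), dtype=bool)
    cx = n / 2.0
    apex_row = stem_length_px
    t = math.tan(math.radians(half_angle_deg))
    rows = np.arange(n)
    cols = np.arange(n)
    cc, rr = np.meshgrid(cols, rows)
    depth = rr - apex_row
    in_wedge = (depth >= 0) & (np.abs(cc + 0.5 - cx) <= depth * t + 0.5)
    mask |= in_wedge & (rr < n - max(4, n // 16))  # leave a background margin
    if stem_width_px > 0 and stem_length_px > 0:
        half = stem_width_px / 2.0
        stem = (rr < apex_row) & (np.abs(cc + 0.5 - cx) <= half)
        mask |= stem
    return BinaryImage(mask)


@dataclass(frozen=True)
class GrowthParams:
    """Knobs of the stochastic branching root-system generator.

    ``cone_half_angle_deg`` bounds the polar angle of shoot-borne root
    directions from the downward vertical, so the silhouette's root cone has
    a full apex angle of about twice this value. ``branch_prob`` is the
    per-segment, per-site probability of spawning a lateral; laterals deeper
    than ``max_order`` never branch. All randomness flows through
    ``rng_seed`` — no global RNG state is touched.
    """

    stem_diameter_px: int = 24
    cone_half_angle_deg: float = 35.0
    n_nodes: int = 6
    roots_per_node: int = 5
    branch_prob: float = 0.5
    max_order: int = 2
    segment_length_px: float = 150.0
    length_decay: float = 0.55
    branch_sites: int = 3
    canvas_size_px: int = 512
    stem_length_px: int = 90
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.cone_half_angle_deg < 90):
            raise ValueError("cone_half_angle_deg must lie in (0, 90)")
        if not (0 <= self.branch_prob <= 1):
            raise ValueError("branch_prob must lie in [0, 1]")
        for name in ("stem_diameter_px", "n_nodes", "roots_per_node",
                     "segment_length_px", "length_decay", "stem_length_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_order < 0:
            raise ValueError("max_order must be non-negative")
        _check_pow2(self.canvas_size_px)


@dataclass(frozen=True)
class Segment:
    """One straight capsule: 3D start/end (x, y, z with z pointing down,
    in pixels from the stem top) plus radius and an order tag."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_px: float
    order_tag: str  # stem | shoot_borne | lateral


@dataclass(frozen=True)
class RootSystemModel:
    segments: tuple[Segment, ...]
    canvas_size_px: int

    def rotated(self, angle_deg: float) -> "RootSystemModel":
        """Rotate the whole system about the vertical stem axis.

        Multiples of 90° use exact integer rotation matrices so projections
        of rotated models are bit-identical to rotated projections.
        """
        a = angle_deg % 360
        if a in (0, 90, 180, 270):
            c, s = {0: (1, 0), 90: (0, 1), 180: (-1, 0), 270: (0, -1)}[a]
        else:
            c, s = math.cos(math.radians(a)), math.sin(math.radians(a))
        rot = lambda p: (c * p[0] - s * p[1], s * p[0] + c * p[1], p[2])
        return RootSystemModel(
            tuple(
                Segment(rot(sg.start), rot(sg.end), sg.radius_px, sg.order_tag)
                for sg in self.segments
            ),
            self.canvas_size_px,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def grow_root_system(params: GrowthParams) -> RootSystemModel:
    """Grow one root system: stem, whorls of shoot-borne roots, laterals.

    Each whorl's shoot-borne roots emerge *at* the cone half-angle from the
    downward vertical — the splayed shell of nodal roots that defines the
    visible root cone — with evenly spaced azimuths rotated by a random
    offset per whorl, so side-view silhouettes carry the cone angle almost
    exactly. Each segment of order < max_order exposes ``branch_sites``
    candidate sites, each spawning a lateral with probability
    ``branch_prob``; laterals fill the cone interior and their length
    decays geometrically with order.
    """
    rng = np.random.default_rng(params.rng_seed)
    segs: list[Segment] = []
    stem_r = params.stem_diameter_px / 2.0
    segs.append(Segment((0.0, 0.0, 0.0), (0.0, 0.0, float(params.stem_length_px)),
                        stem_r, "stem"))
    # whorls form a compact band of nodes just above the stem base, like the
    # crowded underground nodes that bear the shoot-borne roots
    z_lo, z_hi = 0.86 * params.stem_length_px, 0.98 * params.stem_length_px
    node_z = np.linspace(z_hi, z_lo, params.n_nodes)
    root_r = max(1.0, params.stem_diameter_px / 8.0)

    frontier: list[tuple[Segment, int]] = []
    for z in node_z:
        offset = rng.uniform(0.0, 2.0 * math.pi)
        for i_root in range(params.roots_per_node):
            phi = offset + 2.0 * math.pi * i_root / params.roots_per_node
            theta = math.radians(params.cone_half_angle_deg)
            d = np.array(
                [math.sin(theta) * math.cos(phi),
                 math.sin(theta) * math.sin(phi),
                 math.cos(theta)]
            )
            start = np.array([0.0, 0.0, z])
            end = start + d * params.segment_length_px
            sg = Segment(tuple(start), tuple(end), root_r, "shoot_borne")
            segs.append(sg)
            frontier.append((sg, 0))

    while frontier:
        parent, order = frontier.pop()
        if order >= params.max_order:
            continue
        p0, p1 = np.array(parent.start), np.array(parent.end)
        axis = _unit(p1 - p0)
        length = params.segment_length_px * params.length_decay ** (order + 1)
        radius = max(0.75, parent.radius_px * 0.6)
        for _ in range(params.branch_sites):
            if rng.uniform() >= params.branch_prob:
                continue
            t = rng.uniform(0.25, 1.0)
            start = p0 + t * (p1 - p0)
            # rotate the parent direction away by 30–60° at a random azimuth
            dev = math.radians(rng.uniform(30.0, 60.0))
            ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            u = _unit(np.cross(axis, ref))
            w = np.cross(axis, u)
            psi = rng.uniform(0.0, 2.0 * math.pi)
            d = _unit(
                math.cos(dev) * axis
                + math.sin(dev) * (math.cos(psi) * u + math.sin(psi) * w)
            )
            if d[2] < 0.05:  # keep laterals growing downward-ish
                d = _unit(d + np.array([0.0, 0.0, 0.3]))
            sg = Segment(tuple(start), tuple(start + d * length), radius, "lateral")
            segs.append(sg)
            frontier.append((sg, order + 1))

    return RootSystemModel(tuple(segs), params.canvas_size_px)


def _draw_capsule(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, r: float) -> None:
    """Set pixels whose centers lie within distance r of the 2D segment.

    No anti-aliasing: a pixel is foreground iff its center is inside the
    capsule, which keeps box counts integer-reproducible.
    """
    n = mask.shape[0]
    lo = np.clip(np.floor(np.minimum(p0, p1) - r - 1).astype(int), 0, n - 1)
    hi = np.clip(np.ceil(np.maximum(p0, p1) + r + 1).astype(int), 0, n - 1)
    if np.any(hi < lo):
        return
    cols = np.arange(lo[0], hi[0] + 1)
    rows = np.arange(lo[1], hi[1] + 1)
    cc, rr = np.meshgrid(cols + 0.5, rows + 0.5)
    d = p1 - p0
    denom = float(d @ d)
    px = np.stack([cc - p0[0], rr - p0[1]], axis=-1)
    if denom == 0:
        dist2 = (px**2).sum(-1)
    else:
        t = np.clip((px @ d) / denom, 0.0, 1.0)
        proj = t[..., None] * d
        dist2 = ((px - proj) ** 2).sum(-1)
    mask[lo[1] : hi[1] + 1, lo[0] : hi[0] + 1] |= dist2 <= r * r


def project_views(model: RootSystemModel) -> ViewSet:
    """Orthographic projections: side views at 0/90/180/270° about the stem
    axis and one underside view along the vertical axis.

    Side views map (x', z) to (column, row) with the stem top near the top
    margin; the underside maps (x, y) centered on the canvas. Segments are
    drawn as filled capsules at their own radius.
    """
    if not model.segments:
        raise ValueError("cannot project an empty root system model")
    n = model.canvas_size_px
    cx = n / 2.0
    top = n / 16.0
    sides = []
    for ang in (0, 90, 180, 270):
        c, s = {0: (1, 0), 90: (0, 1), 180: (-1, 0), 270: (0, -1)}[ang]
        mask = np.zeros((n, n), dtype=bool)
        for sg in model.segments:
            q0 = np.array([c * sg.start[0] - s * sg.start[1] + cx, sg.start[2] + top])
            q1 = np.array([c * sg.end[0] - s * sg.end[1] + cx, sg.end[2] + top])
            _draw_capsule(mask, q0, q1, sg.radius_px)
        sides.append(BinaryImage(mask))
    under = np.zeros((n, n), dtype=bool)
    for sg in model.segments:
        q0 = np.array([sg.start[0] + cx, sg.start[1] + cx])
        q1 = np.array([sg.end[0] + cx, sg.end[1] + cx])
        _draw_capsule(under, q0, q1, sg.radius_px)
    return ViewSet(side_views=tuple(sides), underside=BinaryImage(under))


# ---------------------------------------------------------------------------
# Diallel phenotype simulation
# ---------------------------------------------------------------------------

_SUM_TOL = 1e-8


@dataclass(frozen=True)
class DiallelSimSpec:
    """Ground truth for a generation-block diallel trial.

    Entries are the parental inbreds, all p(p-1)/2 unordered F1 crosses, and
    commercial checks, laid out as env × rep × entry plot means generated
    from the fixed-effects model

        Y = μ + e_i + r_ij + b_k + β(a_l + a_m) + γ(g_l + g_m) + δ·s_lm
              + eb_ik + rb_ijk + d_ilm + c_n + ec_in + ε

    with β = 1 for a parent on its own additive effect, β = ½ for each
    parent of a cross, γ = δ = 1 only for crosses, and every effect family
    obeying the sum-to-zero restriction so the truth is identifiable.
    Effect maps are dicts keyed by level (or tuple of levels); omitted
    families are zero.
    """

    parent_ids: tuple[str, ...]
    env_ids: tuple[str, ...] = ("E1", "E2")
    reps_per_env: int = 3
    check_ids: tuple[str, ...] = ("CK1", "CK2", "CK3", "CK4", "CK5", "CK6")
    mu: float = 0.0
    env_effects: dict = field(default_factory=dict)          # e_i
    rep_effects: dict = field(default_factory=dict)          # r_ij keyed (env, rep)
    class_effects: dict = field(default_factory=dict)        # b_k keyed parent/F1/check
    additive: dict = field(default_factory=dict)             # a_l
    gca: dict = field(default_factory=dict)                  # g_l
    sca: dict = field(default_factory=dict)                  # s_lm keyed (l, m) sorted
    check_effects: dict = field(default_factory=dict)        # c_n
    env_class: dict = field(default_factory=dict)            # eb_ik keyed (env, class)
    rep_class: dict = field(default_factory=dict)            # rb_ijk keyed (env, rep, class)
    env_additive: dict = field(default_factory=dict)         # d_il keyed (env, l)
    env_check: dict = field(default_factory=dict)            # ec_in keyed (env, check)
    residual_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if len(set(self.parent_ids)) != len(self.parent_ids):
            raise ValueError("duplicate parent ids")

    @property
    def crosses(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.parent_ids, 2))

    def _require_zero_sum(self, name: str, values) -> None:
        total = float(np.sum(list(values)))
        if abs(total) > _SUM_TOL:
            raise ValueError(f"effect family {name!r} must sum to zero (sum={total:g})")

    def validate(self) -> None:
        if self.env_effects:
            self._require_zero_sum("env_effects", self.env_effects.values())
        if self.class_effects:
            self._require_zero_sum("class_effects", self.class_effects.values())
        if self.additive:
            self._require_zero_sum("additive", self.additive.values())
        if self.gca:
            self._require_zero_sum("gca", self.gca.values())
        if self.check_effects:
            self._require_zero_sum("check_effects", self.check_effects.values())
        if self.rep_effects:
            for env in self.env_ids:
                vals = [v for (e, _), v in self.rep_effects.items() if e == env]
                if vals:
                    self._require_zero_sum(f"rep_effects[{env}]", vals)
        if self.sca:
            for l in self.parent_ids:
                vals = [v for (a, b), v in self.sca.items() if l in (a, b)]
                if vals:
                    self._require_zero_sum(f"sca[{l}]", vals)
        if self.env_additive:
            for env in self.env_ids:
                vals = [v for (e, _), v in self.env_additive.items() if e == env]
                if vals:
                    self._require_zero_sum(f"env_additive[{env}]", vals)
            for l in self.parent_ids:
                vals = [v for (_, p), v in self.env_additive.items() if p == l]
                if vals:
                    self._require_zero_sum(f"env_additive[,{l}]", vals)
        if self.env_class:
            for env in self.env_ids:
                vals = [v for (e, _), v in self.env_class.items() if e == env]
                if vals:
                    self._require_zero_sum(f"env_class[{env}]", vals)
            for k in ("parent", "F1", "check"):
                vals = [v for (_, c), v in self.env_class.items() if c == k]
                if vals:
                    self._require_zero_sum(f"env_class[,{k}]", vals)


def simulate_diallel_dataset(
    spec: DiallelSimSpec, trait: str = "Y"
) -> pd.DataFrame:
    """Generate one plot-mean row per env × rep × entry from the spec.

    Entry classes receive the β/γ/δ design coefficients exactly: parents
    carry their own additive effect at full weight; crosses carry half of
    each parent's additive effect plus both GCAs and their SCA; checks carry
    only the check effect. Gaussian residual noise with ``residual_sd`` is
    added, reproducibly from ``rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    entries: list[tuple[str, str | None, str | None, str | None]] = []
    for p in spec.parent_ids:
        entries.append(("parent", p, None, None))
    for l, m in spec.crosses:
        entries.append(("F1", l, m, None))
    for ck in spec.check_ids:
        entries.append(("check", None, None, ck))

    g = spec
    for env in g.env_ids:
        for rep in range(1, g.reps_per_env + 1):
            for klass, p1, p2, ck in entries:
                y = g.mu
                y += g.env_effects.get(env, 0.0)
                y += g.rep_effects.get((env, rep), 0.0)
                y += g.class_effects.get(klass, 0.0)
                y += g.env_class.get((env, klass), 0.0)
                y += g.rep_class.get((env, rep, klass), 0.0)
                if klass == "parent":
                    y += g.additive.get(p1, 0.0)
                    y += g.env_additive.get((env, p1), 0.0)
                elif klass == "F1":
                    y += 0.5 * (g.additive.get(p1, 0.0) + g.additive.get(p2, 0.0))
                    y += g.gca.get(p1, 0.0) + g.gca.get(p2, 0.0)
                    y += g.sca.get((p1, p2), g.sca.get((p2, p1), 0.0))
                    y += 0.5 * (
                        g.env_additive.get((env, p1), 0.0)
                        + g.env_additive.get((env, p2), 0.0)
                    )
                else:
                    y += g.check_effects.get(ck, 0.0)
                    y += g.env_check.get((env, ck), 0.0)
                if g.residual_sd > 0:
                    y += rng.normal(0.0, g.residual_sd)
                rows.append(
                    {
                        "env": env,
                        "rep": rep,
                        "entry_class": klass,
                        "parent1": p1,
                        "parent2": p2,
                        "check_id": ck,
                        trait: y,
                    }
                )
    return pd.DataFrame(rows)
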