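"""End-to-end orchestration: fixtures → image phenotyping → diallel fit →
multivariate summary, with reproducible seeding and provenance-stamped CSVs.

The demo pipeline is fully synthetic: root systems are grown and projected
to view sets, traits are measured from the rasters, a diallel phenotype
table is simulated from chosen genetic effects, the fixed-effects model is
fitted, and the hybrid entry means feed correlation/PCA/clustering. Every
output CSV starts with ``#``-prefixed provenance lines (config hash, seed,
package version) so a run directory is self-describing; bodies are
byte-identical across runs with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import diallel as dl
from . import imaging as im
from . import multivariate as mv
from . import synthetic as syn

log = logging.getLogger("rootbox")

__all__ = ["RunConfig", "run_pipeline", "write_csv", "read_csv"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    canvas_size_px: int = 512
    threshold: float = 0.5
    flare_factor: float = 1.5
    r2_min: float = 0.95
    mad_factor: float = 4.0
    n_parents: int = 12
    n_checks: int = 6
    env_ids: tuple[str, ...] = ("E1", "E2")
    reps_per_env: int = 3
    residual_sd: float = 0.05
    heterosis: float = 0.4
    additive_scale: float = 0.5
    sca_scale: float = 0.15
    n_image_samples: int = 4
    cluster_k: int = 3
    traits: tuple[str, ...] = ("FD", "FA", "RA", "SD")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("env_ids", "traits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["env_ids"] = list(d["env_ids"])
        d["traits"] = list(d["traits"])
        return json.dumps(d, indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"# rootbox {__version__}",
        f"# config_hash {config.config_hash}",
        f"# seed {config.seed}",
    ]


def write_csv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    body = df.to_csv(index=index, lineterminator="\n", float_format="%.10g")
    path.write_text("\n".join(_provenance(config)) + "\n" + body)


def read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def _write_fixtures(outdir: Path, config: RunConfig) -> pd.DataFrame:
    from PIL import Image

    fixdir = outdir / "fixtures"
    fixdir.mkdir(parents=True, exist_ok=True)
    rows = []
    level = int(np.log2(config.canvas_size_px))
    specs = [
        syn.FractalFixtureSpec("line", config.canvas_size_px),
        syn.FractalFixtureSpec("filled", config.canvas_size_px),
        syn.FractalFixtureSpec("sierpinski_triangle", config.canvas_size_px, level),
    ]
    for spec in specs:
        img = syn.render_known_fractal(spec)
        path = fixdir / f"{spec.kind}_{config.canvas_size_px}.png"
        Image.fromarray((img.mask * np.uint8(255))).save(path)
        rows.append(
            {
                "path": str(path),
                "kind": spec.kind,
                "level": spec.level,
                "theoretical_dim": spec.theoretical_dim,
                "seed": config.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    write_csv(manifest, outdir / "fixtures_manifest.csv", config)
    return manifest


def _phenotype_demo_samples(outdir: Path, config: RunConfig) -> pd.DataFrame:
    """Grow a few synthetic root systems, project them, and measure traits."""
    rows = []
    for s in range(config.n_image_samples):
        params = syn.GrowthParams(
            canvas_size_px=config.canvas_size_px,
            branch_prob=0.3 + 0.4 * (s % 3) / 2.0,
            cone_half_angle_deg=25.0 + 5.0 * (s % 4),
            rng_seed=config.seed * 1000 + s,
        )
        views = syn.project_views(syn.grow_root_system(params))
        res = im.phenotype_viewset(views, flare_factor=config.flare_factor)
        for i, ang in enumerate(im.SIDE_VIEW_ANGLES):
            rows.append(
                {
                    "sample_id": f"S{s:03d}",
                    "view": "side",
                    "view_angle": ang,
                    "FD": res["fd_per_side_view"][i],
                    "RA": res["ra_per_view"][i],
                    "SD": res["sd_per_view"][i],
                    "FA": np.nan,
                    "fit_r2": np.nan,
                }
            )
        rows.append(
            {
                "sample_id": f"S{s:03d}",
                "view": "underside",
                "view_angle": np.nan,
                "FD": res["FD"],
                "RA": np.nan,
                "SD": np.nan,
                "FA": res["FA"],
                "fit_r2": res["fit_r2"],
            }
        )
    per_view = pd.DataFrame(rows)
    write_csv(per_view, outdir / "image_phenotypes_per_view.csv", config)
    return per_view


def _default_sim_spec(config: RunConfig) -> syn.DiallelSimSpec:
    """Planted genetic truth for the tabular demo: a heterosis gap between
    the F1 and parent blocks, centered additive effects on an evenly spaced
    grid, and small random (centered) SCA deviations."""
    rng = np.random.default_rng(config.seed)
    parents = tuple(f"P{i+1:02d}" for i in range(config.n_parents))
    checks = tuple(f"CK{i+1}" for i in range(config.n_checks))
    a_vals = np.linspace(-1.0, 1.0, config.n_parents) * config.additive_scale
    a_vals -= a_vals.mean()
    additive = dict(zip(parents, a_vals))
    crosses = list(__import__("itertools").combinations(parents, 2))
    s_raw = rng.normal(0.0, config.sca_scale, len(crosses))
    # project onto the per-line sum-to-zero subspace so truth is identifiable
    C = np.zeros((len(parents), len(crosses)))
    for i, l in enumerate(parents):
        for c, pair in enumerate(crosses):
            if l in pair:
                C[i, c] = 1.0
    from scipy.linalg import null_space

    B = null_space(C)
    s_proj = B @ (B.T @ s_raw)
    sca = dict(zip(crosses, s_proj))
    h = config.heterosis
    class_effects = {"parent": -h / 2.0, "F1": h / 2.0, "check": 0.0}
    # keep b_k summing to zero
    shift = sum(class_effects.values()) / 3.0
    class_effects = {k: v - shift for k, v in class_effects.items()}
    return syn.DiallelSimSpec(
        parent_ids=parents,
        check_ids=checks,
        env_ids=config.env_ids,
        reps_per_env=config.reps_per_env,
        mu=10.0,
        class_effects=class_effects,
        additive=additive,
        sca=sca,
        residual_sd=config.residual_sd,
        rng_seed=config.seed,
    )


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages into ``outdir`` and return it.

    Stages: (1) fractal fixtures + manifest, (2) synthetic image phenotyping
    demo, (3) diallel simulation and fixed-effects fit per trait, (4)
    multivariate summary of hybrid entry means. Any stage failure aborts
    with the stage name in the raised error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    try:
        stage = "fixtures"
        log.info("stage %s", stage)
        _write_fixtures(outdir, config)

        stage = "phenotype"
        log.info("stage %s", stage)
        per_view = _phenotype_demo_samples(outdir, config)
        filtered, removal_log = im.filter_outliers(
            per_view, plot_cols=("sample_id",), r2_min=config.r2_min,
            mad_factor=config.mad_factor,
        )
        write_csv(filtered, outdir / "image_phenotypes_filtered.csv", config)
        (outdir / "removal_log.txt").write_text("\n".join(removal_log) + "\n")

        stage = "diallel"
        log.info("stage %s", stage)
        sim = _default_sim_spec(config)
        data = syn.simulate_diallel_dataset(sim, trait="FD")
        rng = np.random.default_rng(config.seed + 1)
        # correlated companion traits on their own scales
        data["FA"] = 11.0 + 2.0 * (data["FD"] - data["FD"].mean()) + rng.normal(
            0.0, 0.1, len(data)
        )
        data["RA"] = 70.0 - 20.0 * (data["FD"] - data["FD"].mean()) + rng.normal(
            0.0, 2.0, len(data)
        )
        data["SD"] = 118.0 + 15.0 * (data["FD"] - data["FD"].mean()) + rng.normal(
            0.0, 4.0, len(data)
        )
        write_csv(data, outdir / "plot_phenotypes.csv", config)
        spec = dl.DiallelSpec(
            parent_ids=sim.parent_ids,
            check_ids=sim.check_ids,
            env_ids=sim.env_ids,
            reps_per_env=sim.reps_per_env,
        )
        design = dl.build_design(spec, data)
        anova_frames, eff_frames, con_frames, ls_frames = [], [], [], []
        for trait in config.traits:
            fit = dl.fit_ols(data, design, trait)
            anova_frames.append(dl.type3_anova(fit, data, trait).assign(trait=trait))
            eff_frames.append(dl.genetic_effect_table(fit).assign(trait=trait))
            con_frames.append(dl.estimate_contrasts(fit).assign(trait=trait))
            ls_frames.append(dl.class_lsmeans(fit).rename(trait))
        write_csv(pd.concat(anova_frames).reset_index(), outdir / "term_tests.csv", config)
        write_csv(pd.concat(eff_frames, ignore_index=True), outdir / "genetic_effects.csv", config)
        write_csv(pd.concat(con_frames).reset_index(), outdir / "contrasts.csv", config)
        write_csv(
            pd.concat(ls_frames, axis=1).rename_axis("entry_class").reset_index(),
            outdir / "class_lsmeans.csv", config,
        )

        stage = "multivariate"
        log.info("stage %s", stage)
        f1 = data[data["entry_class"] == "F1"].copy()
        f1["entry"] = f1["parent1"] + " x " + f1["parent2"]
        means = f1.groupby("entry")[list(config.traits)].mean()
        r, p = mv.class_correlations(data, "F1", trait_cols=config.traits)
        write_csv(r.rename_axis("trait").reset_index(), outdir / "correlations_F1.csv", config)
        z = mv.zscore(means)
        pca = mv.pca_correlation(means)
        write_csv(
            pca.loadings_frame().rename_axis("trait").reset_index(),
            outdir / "pca_loadings.csv", config,
        )
        write_csv(
            pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(len(pca.eigenvalues))],
                    "eigenvalue": pca.eigenvalues,
                    "variance_explained": pca.variance_explained,
                }
            ),
            outdir / "pca_eigenvalues.csv", config,
        )
        clus = mv.hcluster(z, k=config.cluster_k)
        write_csv(
            clus.labels.rename_axis("entry").reset_index(), outdir / "clusters.csv", config
        )
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir
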