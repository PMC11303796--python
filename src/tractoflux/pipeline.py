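"""Pipeline configuration, tract dictionary and the end-to-end driver.

The default tract list is 29 bundles in five groups: five midline corpus
callosum segments (commissural) plus twelve bilateral families (association,
projection, thalamic and striatal pathways) expanded to left/right.

``run_pipeline`` strings the stages together on synthetic inputs:
simulate a phantom -> fit the multi-compartment model -> tractometry on a
synthetic bundle -> group and AES statistics on a synthetic cohort of
bundle profiles. Outputs are deterministic per master seed (each stage
derives its own seed by a fixed offset).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .mcm import FitConfig, McmFit, ZeppelinCompartment, fit_volume, METRIC_NAMES
from .stats import aes_analysis, group_analysis
from .synthetic import (PhantomSpec, ProfileSimSpec, gen_bundle, gen_phantom,
                        gen_profiles, gen_scheme)
from .tractometry import Bundle, Streamline, build_subject_profiles

__all__ = ["PipelineConfig", "COMMISSURAL_TRACTS", "BILATERAL_FAMILIES",
           "expand_tract_list", "run_pipeline"]

# midline corpus callosum segments: rostrum, genu, posterior midbody,
# isthmus, splenium
COMMISSURAL_TRACTS = ("CC_1", "CC_2", "CC_5", "CC_6", "CC_7")
# families with a left and a right homologue
BILATERAL_FAMILIES = ("ATR", "CG", "CST", "FPT", "ILF", "SLF_I", "SLF_II",
                      "SLF_III", "STR", "ST_PREM", "T_PREM", "UF")

_VALID_FAMILIES = set(COMMISSURAL_TRACTS) | set(BILATERAL_FAMILIES)


def expand_tract_list(families=None) -> list[str]:
    """Concrete bundle names from tract families.

    Commissural segments stay midline; every other family expands to
    ``_left`` / ``_right``. The default configuration yields 29 bundles.
    """
    if families is None:
        families = COMMISSURAL_TRACTS + BILATERAL_FAMILIES
    names = []
    for fam in families:
        if fam in COMMISSURAL_TRACTS:
            names.append(fam)
        elif fam in BILATERAL_FAMILIES:
            names.extend([f"{fam}_left", f"{fam}_right"])
        else:
            raise ValueError(f"unknown tract family {fam!r}; valid: "
                             f"{sorted(_VALID_FAMILIES)}")
    return sorted(names)


@dataclass
class PipelineConfig:
    """All stage parameters plus the master seed."""

    tract_families: tuple[str, ...] = COMMISSURAL_TRACTS + BILATERAL_FAMILIES
    max_compartments: int = 2
    d_iso: float = 3.0e-3
    n_starts: int = 3
    nodes: int = 100
    prune_threshold: float = 0.8
    var_target: float = 0.80
    alpha: float = 0.05
    n_perm: int = 200
    seed: int = 0
    covariates: tuple[str, ...] = ("age", "sex", "center")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("tract_families", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tract_families"] = list(d["tract_families"])
        d["covariates"] = list(d["covariates"])
        return d


def _stage_seed(master: int, offset: int) -> int:
    return (master * 1000 + offset) % (2**31 - 1)


def _demo_phantom_spec(config: PipelineConfig, seed: int) -> PhantomSpec:
    shape = (4, 2, 2)
    csf = np.zeros(shape, dtype=bool)
    csf[:2] = True
    fiber = np.zeros(shape, dtype=bool)
    fiber[2:] = True
    fiber_fit = McmFit(fw_weight=0.2, compartments=(
        ZeppelinCompartment(weight=0.8, axis=np.array([1.0, 0.0, 0.0]),
                            lambda_par=1.7e-3, lambda_perp=0.3e-3),))
    csf_fit = McmFit(fw_weight=1.0)
    return PhantomSpec(shape=shape, regions=(("csf", csf, csf_fit),
                                             ("fiber", fiber, fiber_fit)),
                       voxel_size=2.0, snr=40.0, seed=seed)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Synthetic end-to-end run; returns the results directory.

    Everything except the manifest (which records wall-clock timings) is
    byte-identical across reruns with the same config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.perf_counter()

    # 1. acquisition + phantom + model fit
    scheme = gen_scheme(seed=_stage_seed(config.seed, 1))
    tio.write_gradient_table(scheme, out / "demo.bval", out / "demo.bvec")
    spec = _demo_phantom_spec(config, _stage_seed(config.seed, 2))
    dwi, mask, _ = gen_phantom(spec, scheme)
    tio.write_nifti(out / "demo_dwi.nii.gz", dwi, spec.affine)
    fit_cfg = FitConfig(max_compartments=config.max_compartments,
                        d_iso=config.d_iso, n_starts=config.n_starts,
                        seed=_stage_seed(config.seed, 3))
    metric_maps, n_map, _ = fit_volume(dwi, mask, scheme, fit_cfg)
    for name in METRIC_NAMES:
        tio.write_nifti(out / f"demo_{name}.nii.gz", metric_maps[name], spec.affine)
    tio.write_nifti(out / "demo_n_aniso.nii.gz", n_map.astype(np.int16), spec.affine)
    timings["mcm"] = time.perf_counter() - t0

    # 2. tractometry on a synthetic bundle through the fiber half
    t0 = time.perf_counter()
    raw = gen_bundle("line", n_streamlines=10, jitter_sd=0.3,
                     seed=_stage_seed(config.seed, 4))
    # place the 80 mm line inside the phantom's fiber region (x in [4, 7] mm)
    placed = Bundle(name="demo_line", streamlines=tuple(
        Streamline(s.points * np.array([3.0 / 80.0, 0.05, 0.05])
                   + np.array([4.2, 1.0, 1.0]))
        for s in raw.streamlines))
    tio.write_bundle(placed, out / "demo_line.trk", spec.affine, spec.shape)
    profiles = build_subject_profiles(metric_maps, spec.affine,
                                      {placed.name: placed}, s=config.nodes)
    long_df = tio.profiles_to_long(profiles, subject="sub-demo")
    long_df.to_csv(out / "demo_profiles.tsv", sep="\t", index=False)
    timings["tractometry"] = time.perf_counter() - t0

    # 3. group + AES statistics on a synthetic cohort
    t0 = time.perf_counter()
    sim = ProfileSimSpec(seed=_stage_seed(config.seed, 5),
                         effects=(("group", 0, (40, 60), 1.0),
                                  ("aes", 0, (20, 35), -0.8)))
    profile, meta, effect_mask = gen_profiles(sim)
    meta.to_csv(out / "cohort_meta.tsv", sep="\t", index=False)
    g_res, g_model = group_analysis(profile, meta, alpha=config.alpha,
                                    n_perm=config.n_perm,
                                    seed=_stage_seed(config.seed, 6),
                                    prune_threshold=config.prune_threshold,
                                    var_target=config.var_target,
                                    covariates=config.covariates)
    a_res, _ = aes_analysis(profile, meta, alpha=config.alpha,
                            n_perm=config.n_perm,
                            seed=_stage_seed(config.seed, 7),
                            prune_threshold=config.prune_threshold,
                            var_target=config.var_target,
                            covariates=config.covariates)
    _write_result_tsv(out / "group_results.tsv", g_res, kind="group")
    _write_result_tsv(out / "aes_results.tsv", a_res, kind="aes")
    tio.write_json(out / "stats_summary.json", {
        "bundle": "synthetic_cohort",
        "group": {"fwe_cluster_size": g_res.fwe_cluster_size,
                  "cluster_pvalue": g_res.cluster_pvalue,
                  "n_significant_nodes": int(g_res.significant_mask.sum()),
                  "n_permutations": g_res.n_permutations},
        "aes": {"fwe_cluster_size": a_res.fwe_cluster_size,
                "cluster_pvalue": a_res.cluster_pvalue,
                "n_significant_nodes": int(a_res.significant_mask.sum()),
                "n_permutations": a_res.n_permutations},
        "pca": {"L": g_model.L,
                "retained_metrics": list(g_model.retained_metrics),
                "explained_variance_ratio": g_model.explained_variance_ratio},
        "planted_nodes": np.flatnonzero(effect_mask),
        "seed": config.seed,
    })
    timings["stats"] = time.perf_counter() - t0

    tio.write_json(out / "manifest.json", {
        "config": config.to_dict(),
        "timings_s": timings,
        "outputs": sorted(p.name for p in out.iterdir()
                          if p.name != "manifest.json"),
    })
    return out


def _write_result_tsv(path, res, kind: str) -> None:
    import pandas as pd

    n = len(res.pvalues)
    df = pd.DataFrame({"node": np.arange(1, n + 1),
                       "statistic": res.statistic,
                       "p": res.pvalues})
    if kind == "group":
        for c in range(res.effect_size.shape[1]):
            df[f"cohens_d_PC{c + 1}"] = res.effect_size[:, c]
    else:
        df["r"] = res.effect_size
    df["significant"] = res.significant_mask.astype(int)
    df.to_csv(path, sep="\t", index=False)
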