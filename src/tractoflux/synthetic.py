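"""Synthetic data generators for every pipeline stage.

Provides seeded, deterministic emulations of every pipeline input: a
CUSP-like multi-shell gradient scheme (directions on a sphere and on a
cube, effective b-values 1000-3000 s/mm^2), voxel signals from known
compartment mixtures under Rician noise, geometric streamline bundles, and
group bundle-profile datasets (subjects x 100 nodes x 5 metrics) whose
inter-metric correlation comes from shared smooth latent factors and which
can carry planted group shifts, covariate effects and score associations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcm import GradientScheme, McmFit, predict_signal
from .stats import BundleProfile, DEFAULT_METRICS
from .tractometry import Bundle, Streamline

__all__ = [
    "ProfileSimSpec",
    "PhantomSpec",
    "gen_scheme",
    "simulate_voxel",
    "gen_phantom",
    "gen_bundle",
    "gen_profiles",
]


# ---------------------------------------------------------------------------
# gradient scheme


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _cube_points() -> np.ndarray:
    """The 26 non-zero points of the {-1,0,1}^3 lattice (cube vertices,
    edge midpoints, face centers); squared norms 1, 2 and 3."""
    pts = np.array([[x, y, z] for x in (-1, 0, 1) for y in (-1, 0, 1)
                    for z in (-1, 0, 1) if (x, y, z) != (0, 0, 0)], dtype=float)
    return pts


def gen_scheme(n_grad: int = 60, b_range: tuple[float, float] = (1000.0, 3000.0),
               n_b0: int = 1, seed: int = 0) -> GradientScheme:
    """CUSP-like gradient table: inner-shell sphere directions plus cube
    directions whose effective b-value scales with the squared norm.

    Cube points have squared norms 1..3, so with ``b_range = (1000, 3000)``
    their effective b-values span exactly that range. The sphere points
    (electrostatic-style even spread, randomly rotated per seed) sit on the
    inner shell.
    """
    if n_grad < 6:
        raise ValueError("need at least 6 gradients")
    if b_range[0] > b_range[1]:
        raise ValueError("inverted b-value range")
    if n_b0 < 1:
        raise ValueError("gradient scheme requires at least one b=0 entry")
    rng = np.random.default_rng(seed)
    cube = _cube_points()
    n_cube = min(len(cube), n_grad // 2)
    cube = cube[rng.permutation(len(cube))[:n_cube]]
    n_sphere = n_grad - n_cube
    sphere = _fibonacci_sphere(n_sphere)
    # random rotation so different seeds give different tables
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    sphere = sphere @ q.T
    cube_rot = cube @ q.T

    b_inner = b_range[0]
    norms2 = np.sum(cube_rot**2, axis=1)
    scale = (b_range[1] - b_range[0]) / (norms2.max() - 1.0) if norms2.max() > 1 else 0.0
    b_cube = np.clip(b_range[0] + (norms2 - 1.0) * scale, b_range[0], b_range[1])
    dirs_cube = cube_rot / np.sqrt(norms2)[:, None]

    bvals = np.concatenate([np.zeros(n_b0), np.full(n_sphere, b_inner), b_cube])
    bvecs = np.vstack([np.zeros((n_b0, 3)), sphere, dirs_cube])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# voxel signals


def simulate_voxel(fit: McmFit, scheme: GradientScheme, snr: float = math.inf,
                   seed: int = 0, noise: str = "rician") -> np.ndarray:
    """Noisy magnitude signal (S0 = 1) from a known mixture.

    Rician noise: the magnitude of the complex signal perturbed by two
    independent Gaussian channels with sigma = 1/snr (referenced to the
    b0 amplitude). ``snr = inf`` returns the noise-free attenuation.
    """
    clean = predict_signal(fit, scheme)
    if math.isinf(snr):
        return clean
    if snr <= 0:
        raise ValueError("snr must be positive or infinite")
    rng = np.random.default_rng(seed)
    sigma = 1.0 / snr
    if noise == "rician":
        re = clean + sigma * rng.standard_normal(clean.shape)
        im = sigma * rng.standard_normal(clean.shape)
        return np.hypot(re, im)
    if noise == "gaussian":
        return clean + sigma * rng.standard_normal(clean.shape)
    raise ValueError(f"unknown noise model {noise!r}")


# ---------------------------------------------------------------------------
# phantom volumes


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth layout of a small test volume.

    ``regions`` maps a region name to (boolean mask, McmFit ground truth);
    masks must be disjoint. SNR is Rician, referenced to the b0 amplitude.
    """

    shape: tuple[int, int, int]
    regions: tuple[tuple[str, np.ndarray, McmFit], ...]
    voxel_size: float = 2.0
    snr: float = math.inf
    seed: int = 0

    def __post_init__(self):
        total = np.zeros(self.shape, dtype=int)
        for _, mask, _ in self.regions:
            if mask.shape != self.shape:
                raise ValueError("region mask shape mismatch")
            total += mask.astype(int)
        if np.any(total > 1):
            raise ValueError("phantom regions must be disjoint")
        if not (self.snr > 0 or math.isinf(self.snr)):
            raise ValueError("SNR must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size
        return aff


def gen_phantom(spec: PhantomSpec, scheme: GradientScheme):
    """4-D magnitude volume + union mask + ground-truth per-region fits.

    Returns (dwi: x,y,z,n array; mask; truth: dict region -> (mask, fit)).
    Voxels outside every region stay zero.
    """
    n = len(scheme)
    dwi = np.zeros(spec.shape + (n,))
    mask = np.zeros(spec.shape, dtype=bool)
    truth = {}
    rng = np.random.default_rng(spec.seed)
    for name, region_mask, fit in spec.regions:
        clean = predict_signal(fit, scheme)
        idxs = np.argwhere(region_mask)
        for idx in idxs:
            if math.isinf(spec.snr):
                sig = clean
            else:
                sigma = 1.0 / spec.snr
                re = clean + sigma * rng.standard_normal(n)
                im = sigma * rng.standard_normal(n)
                sig = np.hypot(re, im)
            dwi[tuple(idx)] = sig
        mask |= region_mask
        truth[name] = (region_mask, fit)
    return dwi, mask, truth


# ---------------------------------------------------------------------------
# bundles


def _base_curve(kind: str, n_points: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_points)
    if kind == "line":
        return np.column_stack([80.0 * t, np.zeros_like(t), np.zeros_like(t)])
    if kind == "arc":
        ang = 0.5 * math.pi * t
        r = 50.0
        return np.column_stack([r * np.sin(ang), r * (1.0 - np.cos(ang)), np.zeros_like(t)])
    if kind == "helix":
        ang = 2.0 * math.pi * t
        return np.column_stack([20.0 * np.cos(ang), 20.0 * np.sin(ang), 40.0 * t])
    raise ValueError(f"unknown bundle kind {kind!r}")


def gen_bundle(kind: str = "line", n_streamlines: int = 20, jitter_sd: float = 0.5,
               seed: int = 0, n_points: int = 80, name: str | None = None) -> Bundle:
    """Geometric bundle: a base curve plus a smooth per-streamline offset
    and pointwise Gaussian jitter; deterministic per seed."""
    if n_streamlines < 1:
        raise ValueError("need at least one streamline")
    rng = np.random.default_rng(seed)
    base = _base_curve(kind, n_points)
    streamlines = []
    for _ in range(n_streamlines):
        offset = rng.normal(scale=jitter_sd, size=3) if jitter_sd > 0 else np.zeros(3)
        pts = base + offset
        if jitter_sd > 0:
            pts = pts + rng.normal(scale=jitter_sd * 0.2, size=pts.shape)
        streamlines.append(Streamline(pts))
    return Bundle(name=name or f"{kind}_bundle", streamlines=tuple(streamlines))


# ---------------------------------------------------------------------------
# group bundle-profile datasets


def _default_loadings() -> np.ndarray:
    """Latent-factor loadings per metric (FW, FA, MD, AD, RD) x 2 factors.

    Chosen so the pooled FA-RD correlation is strongly negative (around
    -0.84, matching white-matter tractometry data, and past the default
    pruning threshold so the pruning stage is exercised — RD, the more
    redundant member, is the one removed) and factor 2 carries mostly
    diffusivity (MD/AD) information. Each column is oriented by the same
    convention the PCA stage applies (largest-|loading| entry positive),
    so an effect planted on factor k with a given sign appears with that
    sign on the matching principal component.
    """
    return np.array([
        [-0.75, +0.10],   # FW
        [+0.92, -0.10],   # FA
        [-0.55, +0.55],   # MD
        [-0.35, +0.75],   # AD
        [-0.88, +0.30],   # RD
    ])


@dataclass(frozen=True)
class ProfileSimSpec:
    """Conditions for a synthetic group bundle-profile dataset.

    Defaults mirror a late-life depression case-control cohort: 21
    controls (HC) vs 35 patients (LLD), 100 nodes, 5 metrics
    (FW, FA, MD, AD, RD), age ~ N(75, 6),
    AES ~ N(41.78, 8.71) in the patient group. ``effects`` plants
    localized structure:

    - ("group", factor_index, (start, stop), d): standardized mean shift d
      added to the latent factor of the patient group on nodes
      [start, stop) (0-based half-open interval);
    - ("aes", factor_index, (start, stop), slope): the factor gains
      slope * z(AES) within the patient group on those nodes.
    """

    n_group1: int = 21              # HC
    n_group2: int = 35              # LLD
    n_nodes: int = 100
    metric_names: tuple[str, ...] = DEFAULT_METRICS
    loadings: np.ndarray = field(default_factory=_default_loadings)
    noise_sd: float | None = None   # per-metric residual SD; default from loadings
    smooth_width: int = 5           # moving-average width of latent factors, nodes
    effects: tuple[tuple, ...] = ()
    age_mean: float = 75.0
    age_sd: float = 6.0
    p_female: float = 0.75
    p_center: float = 0.5
    aes_mean: float = 41.78
    aes_sd: float = 8.71
    covariate_slopes: dict | None = None  # e.g. {"age": (factor_index, slope)}
    seed: int = 0

    def __post_init__(self):
        loadings = np.asarray(self.loadings, dtype=float)
        if loadings.shape[0] != len(self.metric_names):
            raise ValueError("one loading row per metric required")
        object.__setattr__(self, "loadings", loadings)
        K = loadings.shape[1]
        for eff in self.effects:
            kind, fac, (a, b), _ = eff
            if kind not in ("group", "aes"):
                raise ValueError(f"unknown effect kind {kind!r}")
            if not 0 <= fac < K:
                raise ValueError("effect on a factor index beyond the latent dimension")
            if not (0 <= a < b <= self.n_nodes):
                raise ValueError("effect interval outside [0, n_nodes]")


def _smooth_factors(rng: np.random.Generator, n_sub: int, n_nodes: int, K: int,
                    width: int) -> np.ndarray:
    """Node-smooth standardized latent factors (subjects x nodes x K)."""
    pad = width // 2
    raw = rng.standard_normal((n_sub, n_nodes + 2 * pad, K))
    kernel = np.ones(width) / width
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid"), 1, raw)
    sm = sm[:, :n_nodes, :]
    # restore unit variance after averaging
    return sm * math.sqrt(width)


# realistic metric means / SDs on the natural scales (FW, FA: fractions;
# MD/AD/RD: mm^2/s) used to place the standardized simulation output
_METRIC_MEAN = np.array([0.15, 0.55, 0.75e-3, 1.40e-3, 0.45e-3])
_METRIC_SD = np.array([0.05, 0.08, 0.08e-3, 0.15e-3, 0.10e-3])


def gen_profiles(spec: ProfileSimSpec):
    """Generate (BundleProfile, SubjectMeta table, ground-truth effect mask).

    Metrics = loadings @ smooth latent factors + independent noise, then
    scaled to realistic means/SDs per metric. Group shifts and AES slopes
    act on the latent factors over the stated node intervals, so the PCA
    stage has recoverable structure. The returned mask is nodes-length
    boolean, true where any effect was planted.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_group1, spec.n_group2
    S = n1 + n2
    N = spec.n_nodes
    M, K = spec.loadings.shape

    group = np.array(["HC"] * n1 + ["LLD"] * n2)
    age = rng.normal(spec.age_mean, spec.age_sd, S)
    sex = np.where(rng.random(S) < spec.p_female, "F", "M")
    center = np.where(rng.random(S) < spec.p_center, "A", "B")
    aes = np.full(S, np.nan)
    aes[n1:] = rng.normal(spec.aes_mean, spec.aes_sd, n2)

    factors = _smooth_factors(rng, S, N, K, spec.smooth_width)

    z_aes = np.zeros(S)
    sd = np.nanstd(aes[n1:])
    if n2 > 0 and sd > 0:
        z_aes[n1:] = (aes[n1:] - np.nanmean(aes[n1:])) / sd

    if spec.covariate_slopes:
        z_age = (age - age.mean()) / age.std()
        cov_z = {"age": z_age, "sex": (sex == "F").astype(float),
                 "center": (center == "A").astype(float)}
        for name, (fac, slope) in spec.covariate_slopes.items():
            factors[:, :, fac] += slope * cov_z[name][:, None]

    effect_mask = np.zeros(N, dtype=bool)
    is_lld = group == "LLD"
    for kind, fac, (a, b), size in spec.effects:
        effect_mask[a:b] = True
        if kind == "group":
            factors[is_lld, a:b, fac] += size
        else:  # aes
            factors[:, a:b, fac] += (z_aes * size)[:, None]

    if spec.noise_sd is None:
        resid_var = np.clip(1.0 - np.sum(spec.loadings**2, axis=1), 0.05, None)
        noise_sd = np.sqrt(resid_var)
    else:
        noise_sd = np.full(M, float(spec.noise_sd))
    z = factors @ spec.loadings.T + rng.standard_normal((S, N, M)) * noise_sd

    mean = _METRIC_MEAN[:M] if M <= 5 else np.zeros(M)
    sdv = _METRIC_SD[:M] if M <= 5 else np.ones(M)
    data = mean + sdv * z

    meta = pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(S)],
        "group": group, "age": age, "sex": sex, "center": center, "AES": aes,
    })
    profile = BundleProfile(data=data, subject_ids=tuple(meta["subject_id"]),
                            metric_names=spec.metric_names)
    return profile, meta, effect_mask
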