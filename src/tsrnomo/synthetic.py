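"""Synthetic fixtures: IHC-like TMA core images and survival cohorts.

Real CK/DAB-stained tissue-microarray cores show brown (DAB) tumor nests,
off-white stroma with a faint pink cast, scattered blue hematoxylin-stained
stromal nuclei, and a near-white background outside the circular core.  The
image generator emulates exactly those features on an abstract pixel grid
and records pixel-perfect ground-truth masks, so the segmentation pipeline
can be tested without any scanned slide.

The cohort generator draws covariates independently at the development
cohort's marginal frequencies and event times from an exponential
proportional-hazards model at the published multivariable log-hazards, with
administrative censoring at the follow-up horizon.  Both generators are
byte-reproducible given a seed.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from . import reference

__all__ = [
    "ImageSpec",
    "GroundTruth",
    "CohortSpec",
    "GenerationError",
    "generate_core_image",
    "generate_cohort",
    "save_fixture",
]


class GenerationError(RuntimeError):
    """Raised when a fixture cannot be realized within its tolerances."""


# Default palette (RGB, 8-bit), chosen to mimic DAB/hematoxylin appearance:
# brown tumor (R>G>B), off-white pink stroma, blue nuclei, near-white glass.
TUMOR_RGB = (150, 100, 55)
STROMA_RGB = (235, 222, 218)
NUCLEUS_RGB = (70, 70, 150)
BACKGROUND_RGB = (246, 245, 244)


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic TMA-core image.

    ``true_stroma_frac`` is the target stromal fraction of the core area;
    nests are placed and then morphologically adjusted until the realized
    fraction is within ``area_tol`` of the target.
    """

    width: int = 512
    height: int = 512
    core_radius_frac: float = 0.45
    n_nests: int = 12
    nest_radius_range: tuple[float, float] = (20.0, 55.0)
    true_stroma_frac: float = 0.6
    nucleus_density: float = 0.0  # speckles per 1000 core pixels
    nucleus_radius: float = 3.0
    noise_sd: float = 3.0
    seed: int = 0
    area_tol: float = 0.03
    edge_softness: float = 3.0  # px over which the core rim fades to glass
    tumor_rgb: tuple[int, int, int] = TUMOR_RGB
    stroma_rgb: tuple[int, int, int] = STROMA_RGB
    nucleus_rgb: tuple[int, int, int] = NUCLEUS_RGB
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB

    def validate(self) -> None:
        if not (0.0 <= self.true_stroma_frac <= 1.0):
            raise ValueError("true_stroma_frac must lie in [0, 1]")
        if min(self.width, self.height) < 64:
            raise ValueError("frame must be at least 64x64 pixels")
        if not (0.0 < self.core_radius_frac <= 0.5):
            raise ValueError("core disc must fit fully inside the frame")
        if self.n_nests < 0:
            raise ValueError("n_nests must be non-negative")
        lo, hi = self.nest_radius_range
        if not (0 < lo <= hi):
            raise ValueError("nest_radius_range must be increasing and positive")


@dataclass(frozen=True)
class GroundTruth:
    """Pixel-level truth for one synthetic core image."""

    tumor_mask: np.ndarray
    stroma_mask: np.ndarray
    core_mask: np.ndarray
    true_tsr: float


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_core_image(spec: ImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic core and its ground truth.

    Returns ``(pixels, truth)`` where ``pixels`` is an (H, W, 3) uint8 RGB
    raster.  The realized stromal fraction of the ground truth is within
    ``spec.area_tol`` of ``spec.true_stroma_frac``; if nest geometry cannot
    reach the target after bounded morphological adjustment a
    :class:`GenerationError` is raised.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    core_r = spec.core_radius_frac * min(h, w)
    core = _disc_mask((h, w), center, core_r)
    core_area = int(core.sum())

    target_tumor = 1.0 - spec.true_stroma_frac
    tumor = np.zeros((h, w), dtype=bool)
    if target_tumor > spec.area_tol and spec.n_nests == 0:
        raise GenerationError("cannot reach a nonzero tumor fraction with zero nests")
    if spec.n_nests > 0 and target_tumor > 0.0:
        # Tumor = union of discs around seed points clustered near a random
        # focus (invasive tumor grows as a coherent lobulated mass, so the
        # stroma stays connected to the rim rather than being swallowed as
        # enclosed pockets).  The union's size is set by a single radial
        # offset solved exactly on the distance transform, so the realized
        # fraction matches the target to within one pixel shell.
        ang = rng.uniform(0, 2 * math.pi)
        focus = (
            center[0] + 0.3 * core_r * math.sin(ang),
            center[1] + 0.3 * core_r * math.cos(ang),
        )
        rr, cc = np.ogrid[:h, :w]
        signed = np.full((h, w), np.inf)
        for _ in range(spec.n_nests):
            cy = focus[0] + rng.normal(0.0, 0.30 * core_r)
            cx = focus[1] + rng.normal(0.0, 0.30 * core_r)
            r = rng.uniform(*spec.nest_radius_range)
            d = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2) - r
            signed = np.minimum(signed, d)
        vals = np.sort(signed[core])
        k = int(round(target_tumor * core_area))
        if k >= core_area:
            tumor = core.copy()
        elif k > 0:
            tumor = (signed <= vals[k - 1]) & core
        realized = tumor.sum() / core_area
        if abs((1.0 - realized) - spec.true_stroma_frac) > spec.area_tol:
            raise GenerationError(
                f"stroma fraction {1 - realized:.3f} unreachable within "
                f"+/-{spec.area_tol} of {spec.true_stroma_frac}"
            )

    stroma = core & ~tumor
    true_tsr = stroma.sum() / core_area

    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background_rgb
    img[stroma] = spec.stroma_rgb
    img[tumor] = spec.tumor_rgb

    # Blue nucleus speckles inside stroma (they remain stroma in the truth).
    if spec.nucleus_density > 0:
        n_nuc = int(round(spec.nucleus_density * core_area / 1000.0))
        sr, sc = np.nonzero(stroma)
        if len(sr) and n_nuc:
            idx = rng.integers(0, len(sr), size=n_nuc)
            for y, x in zip(sr[idx], sc[idx]):
                m = _disc_mask((h, w), (float(y), float(x)), spec.nucleus_radius)
                img[m & stroma] = spec.nucleus_rgb

    # Soften only the core rim: blend toward glass over edge_softness px so
    # the rim gradient stays far below tumor-nest edges (as in scanned
    # cores, where stroma fades into glass).
    if spec.edge_softness > 0:
        dist_in = ndimage.distance_transform_edt(core)
        alpha = np.clip(dist_in / spec.edge_softness, 0.0, 1.0)
        rim = (dist_in > 0) & (alpha < 1.0)
        bg = np.array(spec.background_rgb, dtype=float)
        img[rim] = alpha[rim, None] * img[rim] + (1 - alpha[rim, None]) * bg

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return pixels, GroundTruth(tumor, stroma, core, float(true_tsr))


def save_fixture(
    pixels: np.ndarray, truth: GroundTruth, spec: ImageSpec, out_dir: str | Path, stem: str
) -> dict[str, Path]:
    """Write image + mask PNGs and a JSON sidecar; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}.png",
        "tumor_mask": out / f"{stem}_tumor.png",
        "stroma_mask": out / f"{stem}_stroma.png",
        "core_mask": out / f"{stem}_core.png",
        "sidecar": out / f"{stem}.json",
    }
    iio.imwrite(paths["image"], pixels)
    for key in ("tumor_mask", "stroma_mask", "core_mask"):
        iio.imwrite(paths[key], (getattr(truth, key) * np.uint8(255)))
    sidecar = {
        "true_tsr": truth.true_tsr,
        "seed": spec.seed,
        "spec": {k: v for k, v in vars(spec).items()},
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, default=list))
    return paths


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _default_betas() -> dict[str, dict[str, float]]:
    betas = reference.multivariable_log_hazards()
    betas["pr"] = {lvl: math.log(hr) for lvl, hr in reference.PR_HR.items()}
    return betas


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic survival cohort.

    Defaults reproduce the development cohort's structure: covariate
    marginals from the clinico-pathological table, per-level log-hazards
    from the multivariable Cox model, administrative censoring at 60 months,
    and a baseline event rate solved so the marginal 5-year disease-free
    survival equals the cohort's 62.0%.
    """

    n_patients: int = 240
    covariate_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            **{k: dict(v) for k, v in reference.COVARIATE_FREQS.items()},
            "tsr_group": {
                "high": reference.STROMA_HIGH_FRAC,
                "low": 1.0 - reference.STROMA_HIGH_FRAC,
            },
        }
    )
    betas: dict[str, dict[str, float]] = field(default_factory=_default_betas)
    baseline_rate: float | None = None  # events/month; None -> solve for DFS
    target_survival: float = reference.FIVE_YEAR_DFS
    admin_censor_months: float = reference.FOLLOWUP_MONTHS
    tsr_cutoff: float = reference.TSR_CUTOFF
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        for cov, freqs in self.covariate_freqs.items():
            tot = sum(freqs.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-6):
                raise ValueError(f"frequencies for {cov!r} sum to {tot}, not 1")
        if self.baseline_rate is not None and self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")


def solve_baseline_rate(spec: CohortSpec) -> float:
    """Baseline hazard giving the target marginal survival at the horizon.

    Enumerates the exact discrete distribution of the linear predictor over
    all covariate-level combinations (covariates are independent) and solves
    E[exp(-t * lambda0 * exp(eta))] = target by Brent's method.
    """
    covs = [c for c in spec.betas if c in spec.covariate_freqs]
    level_sets = []
    for c in covs:
        levels = list(spec.covariate_freqs[c].items())
        level_sets.append([(spec.betas[c].get(lvl, 0.0), p) for lvl, p in levels])
    etas, weights = [], []
    for combo in itertools.product(*level_sets):
        etas.append(sum(b for b, _ in combo))
        weights.append(math.prod(p for _, p in combo))
    etas = np.asarray(etas)
    weights = np.asarray(weights)
    t = spec.admin_censor_months

    def marginal_survival(lam: float) -> float:
        return float(np.sum(weights * np.exp(-t * lam * np.exp(etas))))

    target = spec.target_survival
    if marginal_survival(1e-10) < target:
        raise ValueError("target survival unreachable")
    return float(brentq(lambda lam: marginal_survival(lam) - target, 1e-10, 10.0))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort in the ClinicalTable schema.

    Covariates are sampled independently at ``covariate_freqs``; event times
    are exponential with rate ``baseline_rate * exp(sum of betas)`` and are
    administratively censored at ``admin_censor_months``.  The continuous
    ``tsr`` column is drawn uniformly within the low/high segment chosen for
    ``tsr_group``, so dichotomizing at the cutoff reproduces the group.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    data: dict[str, np.ndarray] = {"patient_id": np.array([f"P{i:04d}" for i in range(n)])}

    eta = np.zeros(n)
    for cov, freqs in spec.covariate_freqs.items():
        levels = list(freqs)
        probs = np.array([freqs[l] for l in levels])
        draw = rng.choice(len(levels), size=n, p=probs / probs.sum())
        vals = np.array(levels, dtype=object)[draw]
        data[cov] = vals
        if cov in spec.betas:
            lut = spec.betas[cov]
            eta += np.array([lut.get(v, 0.0) for v in vals])

    tsr_group = data.pop("tsr_group", np.full(n, "high", dtype=object))
    u_tsr = rng.uniform(size=n)
    cut = spec.tsr_cutoff
    tsr = np.where(tsr_group == "low", 0.05 + u_tsr * (cut - 0.05), cut + 1e-6 + u_tsr * (0.95 - cut))
    data["tsr"] = np.round(tsr, 4)

    lam0 = spec.baseline_rate if spec.baseline_rate is not None else solve_baseline_rate(spec)
    # Inverse-transform sampling keeps the event fraction monotone in the
    # baseline rate under common random numbers (same seed).
    u = rng.uniform(size=n)
    with np.errstate(divide="ignore"):
        rate = lam0 * np.exp(eta)
        t_event = np.where(rate > 0, -np.log(u) / np.where(rate > 0, rate, 1.0), np.inf)
    horizon = spec.admin_censor_months
    data["time_months"] = np.round(np.minimum(t_event, horizon), 3)
    data["event"] = (t_event <= horizon).astype(int)
    df = pd.DataFrame(data)
    return df[
        ["patient_id", "age_group", "menopausal", "histotype", "t_stage", "n_status",
         "grade", "er", "pr", "her2", "tsr", "time_months", "event"]
    ]
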