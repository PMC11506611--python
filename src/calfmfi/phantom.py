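"""Synthetic calf-phantom cohort generator.

Builds axial multi-slice raster "MR images" of a lower leg — a circular leg
cross-section with a subcutaneous fat annulus, a fibula (cortical ring plus
marrow disk) and calf muscle carrying spatially clumped fat marbling — plus
the matching ground-truth label masks and a cohort manifest with planted
demographic structure (sex-specific SFT/BMA distributions, a four-level
fat-infiltration severity mixture, and configurable covariate slopes).

Every downstream stage of the pipeline (bias correction, morphometry,
histogram analysis, severity clustering, association statistics) is testable
against the planted truth without any external data.

Conventions: in-plane pixels are square (default 0.7 mm), nine slices with
4 mm thickness and 2 mm gap (6 mm centre spacing); the row index increases
toward the inferior direction; slices are numbered 1-based in user-facing
APIs. Intensities are arbitrary units with fat roughly 4x brighter than lean
muscle, as on T2-weighted images.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.stats import truncnorm

__all__ = [
    "PhantomSpec",
    "SubjectTruth",
    "CohortConfig",
    "ImageStack",
    "MaskStack",
    "GeometryError",
    "SEVERITY_CLASSES",
    "rasterize_slice",
    "generate_subject",
    "iter_cohort",
    "generate_cohort",
    "save_subject_nifti",
    "load_subject_nifti",
]

SEVERITY_CLASSES = ("normal", "mild", "moderate", "severe")

REGION_LABELS = {"subcutaneous": 1, "marrow": 2, "muscle": 3, "cortex": 4}

SLICE_SPACING_MM = 6.0  # 4 mm slice thickness + 2 mm gap


class GeometryError(ValueError):
    """Planted geometry does not fit (e.g. fibula outside the muscle bed)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Planted geometry / intensity parameters for one subject's phantom.

    Attributes
    ----------
    image_size : (int, int)
        Raster rows, cols.
    pixel_size : float
        In-plane pixel edge, mm.
    n_slices : int
        Number of axial slices.
    leg_radius : float
        Outer radius of the leg cross-section, mm.
    sf_thickness : float
        Subcutaneous fat annulus thickness, mm (the planted SFT).
    fibula_center : (float, float)
        (row, col) offset of the fibula centre from the leg centre, mm.
        Negative row = superior to the leg centre in the image.
    marrow_area : float
        Fibula marrow disk area, mm^2 (the planted BMA).
    cortical_rim : float
        Cortical bone ring thickness around the marrow, mm.
    fat_fraction : float
        Mean fat partial volume planted in the muscle bed (the MFI truth).
    clump_scale : float
        Correlation length of the marbling random field, mm.
    marbling_softness : float
        Width of the soft threshold mapping the marbling field to fat
        partial volume, in field-sd units; 0 gives hard binary patches.
    intensity_model : dict
        Region -> mean intensity (a.u.): background, cortex, muscle, fat.
        Subcutaneous tissue and marrow share the fat intensity.
    bias_amplitude : float
        Peak fractional deviation of the multiplicative bias field.
    noise_sigma : float
        Noise standard deviation, a.u.
    noise_model : str
        "gaussian" (additive) or "rician".
    seed : int
        Base seed for the subject's random stream.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size: float = 0.7
    n_slices: int = 9
    leg_radius: float = 45.0
    sf_thickness: float = 5.0
    fibula_center: tuple[float, float] = (-10.0, 15.0)
    marrow_area: float = 35.0
    cortical_rim: float = 2.0
    fat_fraction: float = 0.10
    clump_scale: float = 2.0
    marbling_softness: float = 0.35
    intensity_model: dict = field(
        default_factory=lambda: {
            "background": 5.0,
            "cortex": 20.0,
            "muscle": 100.0,
            "fat": 400.0,
        }
    )
    bias_amplitude: float = 0.2
    noise_sigma: float = 15.0
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sf_thickness <= 0:
            raise ValueError("sf_thickness must be > 0")
        if not (0.0 <= self.fat_fraction < 1.0):
            raise ValueError("fat_fraction must be in [0, 1)")
        if self.marrow_area >= np.pi * self.leg_radius**2:
            raise GeometryError("marrow_area exceeds the leg cross-section")
        if any(v <= 0 for v in self.intensity_model.values()):
            raise ValueError("all intensities must be > 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth covariates and planted measurements for one subject."""

    subject_id: str
    sex: str  # "M" or "F"
    age: float  # years
    bmi: float  # kg/m^2
    true_sft: float  # mm
    true_bma: float  # mm^2
    true_fat_fraction: float
    severity_class: str

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if not (11.0 <= self.age <= 79.0):
            raise ValueError("age outside the cohort range 11-79")
        if not (19.0 <= self.bmi <= 44.3):
            raise ValueError("bmi outside the cohort range 19.0-44.3")
        if self.true_sft <= 0 or self.true_bma <= 0:
            raise ValueError("true_sft and true_bma must be > 0")
        if self.severity_class not in SEVERITY_CLASSES:
            raise ValueError(f"unknown severity class {self.severity_class!r}")


#: per-sex (mean, sd, (lo, hi)) defaults emulating the study cohort
_COHORT_AGE = {"M": (57.9, 17.8, (11.0, 79.0)), "F": (52.7, 14.6, (15.0, 78.0))}
_COHORT_BMI = {"M": (28.4, 4.4, (19.0, 38.5)), "F": (30.3, 5.7, (19.7, 44.3))}
_COHORT_SFT = {"M": (4.3, 2.2), "F": (8.9, 3.7)}
_COHORT_BMA = {"M": (35.7, 21.1), "F": (32.6, 20.0)}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level sampling parameters.

    Per-sex marginal distributions default to the study cohort: 64 males /
    43 females; SFT 4.3±2.2 mm (M) vs 8.9±3.7 mm (F); BMA 35.7±21.1 mm² (M)
    vs 32.6±20.0 mm² (F); severity mixture 42/42/14/2 %.

    ``slopes`` plants linear covariate effects on the truths, keyed
    ``(outcome, predictor, sex)`` with outcome in {sft, bma, mfi} and
    predictor in {age, bmi}; truths are generated as
    ``mean + slope_age*(age - mean_age) + slope_bmi*(bmi - mean_bmi) + eps``
    with the residual sd shrunk so the planted marginal sd is preserved.
    """

    n_male: int = 64
    n_female: int = 43
    age: dict = field(default_factory=lambda: dict(_COHORT_AGE))
    bmi: dict = field(default_factory=lambda: dict(_COHORT_BMI))
    sft: dict = field(default_factory=lambda: dict(_COHORT_SFT))
    bma: dict = field(default_factory=lambda: dict(_COHORT_BMA))
    sft_floor: float = 1.0  # mm
    bma_floor: float = 5.0  # mm^2
    severity_proportions: tuple = (0.42, 0.42, 0.14, 0.02)
    severity_fat_fraction: tuple = (0.05, 0.15, 0.30, 0.60)
    severity_allocation: str = "exact"  # or "multinomial"
    slopes: dict = field(
        default_factory=lambda: {
            ("sft", "age", "M"): -0.05,  # mm / yr: SFT falls with age in men
            ("sft", "bmi", "F"): 0.40,  # mm per kg/m^2: SFT rises with BMI in women
            ("bma", "age", "F"): 0.50,  # mm^2 / yr: BMA rises with age in women
            ("bma", "bmi", "M"): 1.00,  # mm^2 per kg/m^2: BMA rises with BMI in men
            ("mfi", "age", "F"): 0.0008,  # fat fraction / yr
            ("mfi", "bmi", "M"): 0.0030,  # fat fraction per kg/m^2
        }
    )
    sampling: str = "iid"  # or "stratified" (variance-reduced inverse-CDF draws)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.severity_proportions) - 1.0) > 1e-12:
            raise ValueError("severity proportions must sum to 1")
        if self.n_male + self.n_female < 2:
            raise ValueError("need at least 2 subjects")
        if self.severity_allocation not in ("exact", "multinomial"):
            raise ValueError("severity_allocation must be 'exact' or 'multinomial'")
        if self.sampling not in ("iid", "stratified"):
            raise ValueError("sampling must be 'iid' or 'stratified'")


@dataclass
class ImageStack:
    """Multi-slice image volume with raster metadata."""

    data: np.ndarray  # (n_slices, rows, cols), a.u.
    pixel_size: float  # mm
    slice_positions: np.ndarray  # mm along the leg axis
    meta: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class MaskStack:
    """Binary region masks aligned with an :class:`ImageStack`.

    ``masks`` holds one boolean layer per region; ``leg`` is the full leg
    support, the tissue layers (subcutaneous / marrow / muscle / cortex)
    are mutually disjoint subsets of it.
    """

    masks: dict
    pixel_size: float

    def slice_mask(self, region: str, slice_number: int) -> np.ndarray:
        """Return one region layer for a 1-based slice number."""
        return self.masks[region][slice_number - 1]


# ---------------------------------------------------------------------------
# slice rasterization


def _mm_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    nr, nc = spec.image_size
    rows = (np.arange(nr) - (nr - 1) / 2.0) * spec.pixel_size
    cols = (np.arange(nc) - (nc - 1) / 2.0) * spec.pixel_size
    return np.meshgrid(rows, cols, indexing="ij")


def _marbling_fraction_map(
    muscle: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Per-pixel fat partial-volume map over the muscle bed.

    A Gaussian random field smoothed to correlation length ``clump_scale`` is
    passed through a soft threshold (logistic, width ``marbling_softness`` in
    field-sd units); the threshold is solved by bisection so the mean fat
    fraction over the muscle mask equals the planted value exactly.  With
    ``marbling_softness = 0`` the map degenerates to hard binary patches of
    exactly the planted pixel count.
    """
    ff = spec.fat_fraction
    g = np.zeros_like(muscle, dtype=float)
    if ff == 0.0 or not muscle.any():
        return g
    sigma_px = max(spec.clump_scale / spec.pixel_size, 0.5)
    z = ndimage.gaussian_filter(rng.standard_normal(muscle.shape), sigma_px)
    zm = z[muscle]
    zm = (zm - zm.mean()) / max(zm.std(), 1e-12)
    w = spec.marbling_softness
    if w <= 0.0:  # hard threshold: top-k pixels carry pure fat
        k = int(round(ff * zm.size))
        vals = np.zeros(zm.size)
        if k > 0:
            vals[np.argsort(zm)[::-1][:k]] = 1.0
    else:

        def mean_fraction(t: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(zm - t) / w)))) - ff

        t = brentq(mean_fraction, -60.0, 60.0, xtol=1e-12)
        vals = 1.0 / (1.0 + np.exp(-(zm - t) / w))
    g[muscle] = vals
    return g


def _draw_bias_coeffs(rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal(5)


def _bias_field(
    spec: PhantomSpec, coeffs: np.ndarray, leg: np.ndarray
) -> np.ndarray:
    """Smooth multiplicative field, unit peak deviation scaled by amplitude."""
    nr, nc = spec.image_size
    u = np.linspace(-1.0, 1.0, nr)[:, None] * np.ones((1, nc))
    v = np.ones((nr, 1)) * np.linspace(-1.0, 1.0, nc)[None, :]
    f = (
        coeffs[0] * u
        + coeffs[1] * v
        + coeffs[2] * u * v
        + coeffs[3] * (u**2 - 1.0 / 3.0)
        + coeffs[4] * (v**2 - 1.0 / 3.0)
    )
    peak = np.abs(f[leg]).max() if leg.any() else np.abs(f).max()
    if peak < 1e-12:
        return np.ones_like(f)
    field = 1.0 + spec.bias_amplitude * f / peak
    # mean 1 over the leg so the planted field only reshapes, never rescales,
    # the tissue intensities (mirrors the corrector's normalization contract)
    return field / field[leg].mean() if leg.any() else field


def rasterize_slice(
    spec: PhantomSpec,
    slice_index: int,
    rng: np.random.Generator,
    radius_scale: float = 1.0,
    bias_coeffs: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one axial slice and its ground-truth region masks.

    Parameters
    ----------
    spec : PhantomSpec
    slice_index : int
        1-based slice number in ``[1, n_slices]``.
    rng : numpy Generator
        Source for marbling, bias coefficients and noise.
    radius_scale : float
        Smooth slice-to-slice geometric variation factor applied to the leg
        radii (the annulus thickness itself stays at the planted value).
    bias_coeffs : array, optional
        Fix the bias-field shape (shared across a subject's slices); drawn
        from ``rng`` when omitted.

    Returns
    -------
    image : (rows, cols) float array
    masks : dict of boolean arrays — leg, subcutaneous, marrow, cortex, muscle
    """
    if not (1 <= slice_index <= spec.n_slices):
        raise ValueError(f"slice_index {slice_index} outside [1, {spec.n_slices}]")
    r_out = spec.leg_radius * radius_scale
    r_in = r_out - spec.sf_thickness
    if r_in <= 0:
        raise GeometryError("subcutaneous annulus swallows the whole leg")
    r_marrow = float(np.sqrt(spec.marrow_area / np.pi))
    r_fib = r_marrow + spec.cortical_rim
    off_r, off_c = spec.fibula_center
    if np.hypot(off_r, off_c) + r_fib >= r_in:
        raise GeometryError(
            "fibula (outer radius %.1f mm at offset %.1f mm) does not fit "
            "inside the muscle bed (inner radius %.1f mm)"
            % (r_fib, float(np.hypot(off_r, off_c)), r_in)
        )

    rr, cc = _mm_grids(spec)
    d_leg = np.hypot(rr, cc)
    d_fib = np.hypot(rr - off_r, cc - off_c)

    leg = d_leg <= r_out
    subcut = leg & (d_leg > r_in)
    marrow = d_fib <= r_marrow
    cortex = (d_fib <= r_fib) & ~marrow
    muscle = leg & ~subcut & ~marrow & ~cortex

    im = spec.intensity_model
    clean = np.full(spec.image_size, im["background"], dtype=float)
    clean[muscle] = im["muscle"]
    clean[subcut] = im["fat"]
    clean[marrow] = im["fat"]
    clean[cortex] = im["cortex"]

    g = _marbling_fraction_map(muscle, spec, rng)
    clean = clean + (im["fat"] - im["muscle"]) * g

    if bias_coeffs is None:
        bias_coeffs = _draw_bias_coeffs(rng)
    if spec.bias_amplitude > 0:
        image = clean * _bias_field(spec, bias_coeffs, leg)
    else:
        image = clean.copy()

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
            np.clip(image, 0.0, None, out=image)  # magnitude images are >= 0
        else:  # rician: magnitude of a complex signal with iid Gaussian noise
            n1 = rng.normal(0.0, spec.noise_sigma, size=image.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, size=image.shape)
            image = np.hypot(image + n1, n2)

    masks = {
        "leg": leg,
        "subcutaneous": subcut,
        "marrow": marrow,
        "cortex": cortex,
        "muscle": muscle,
    }
    return image, masks


# ---------------------------------------------------------------------------
# subjects and cohorts


def _subject_rng(base_seed: int, subject_id: str) -> np.random.Generator:
    # crc32 gives a stable (cross-session) fold of the id into the stream
    key = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([base_seed, key]))


def spec_for_truth(truth: SubjectTruth, spec: PhantomSpec) -> PhantomSpec:
    """Specialize a base spec to one subject's planted truth.

    The leg radius is enlarged when needed so a large planted SFT or BMA
    still fits the fibula inside the muscle bed under the worst-case 3 %
    slice-to-slice shrinkage.
    """
    r_fib = float(np.sqrt(truth.true_bma / np.pi)) + spec.cortical_rim
    off = float(np.hypot(*spec.fibula_center))
    needed = (truth.true_sft + off + r_fib + 3.0) / 0.97
    return replace(
        spec,
        sf_thickness=truth.true_sft,
        marrow_area=truth.true_bma,
        fat_fraction=truth.true_fat_fraction,
        leg_radius=max(spec.leg_radius, needed),
    )


def generate_subject(
    truth: SubjectTruth, spec: PhantomSpec | None = None
) -> tuple[ImageStack, MaskStack]:
    """Render a subject's 9-slice stack with aligned truth masks.

    Slice radii vary smoothly by at most 3 % around the planted value; the
    annulus thickness and the marrow area are held at the planted truth on
    every slice. The bias-field shape is drawn once per subject (a fixed
    coil-sensitivity pattern); marbling and noise are per-slice.
    """
    spec = spec_for_truth(truth, spec or PhantomSpec())
    rng = _subject_rng(spec.seed, truth.subject_id)
    amp = rng.uniform(0.01, 0.03)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    bias_coeffs = _draw_bias_coeffs(rng)

    images, mask_layers = [], {name: [] for name in REGION_LABELS}
    leg_layers = []
    for i in range(1, spec.n_slices + 1):
        scale = 1.0 + amp * np.sin(
            2.0 * np.pi * (i - 1) / max(spec.n_slices - 1, 1) + phase
        )
        img, masks = rasterize_slice(
            spec, i, rng, radius_scale=scale, bias_coeffs=bias_coeffs
        )
        images.append(img.astype(np.float32))
        leg_layers.append(masks["leg"])
        for name in REGION_LABELS:
            mask_layers[name].append(masks[name])

    positions = (np.arange(spec.n_slices) - (spec.n_slices - 1) / 2.0) * SLICE_SPACING_MM
    image_stack = ImageStack(
        data=np.stack(images),
        pixel_size=spec.pixel_size,
        slice_positions=positions,
        meta={
            "subject_id": truth.subject_id,
            "true_sft": truth.true_sft,
            "true_bma": truth.true_bma,
            "true_fat_fraction": truth.true_fat_fraction,
            "severity_class": truth.severity_class,
        },
    )
    stacked = {name: np.stack(layers) for name, layers in mask_layers.items()}
    stacked["leg"] = np.stack(leg_layers)
    mask_stack = MaskStack(masks=stacked, pixel_size=spec.pixel_size)
    return image_stack, mask_stack


def _trunc_draws(
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    n: int,
    rng: np.random.Generator,
    stratified: bool,
) -> np.ndarray:
    if sd == 0:  # degenerate: every draw is the (clipped) mean
        return np.full(n, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = truncnorm(a, b, loc=mean, scale=sd)
    if stratified:
        # inverse-CDF at shuffled stratum midpoints: same marginal law,
        # near-zero Monte-Carlo error on the sample mean
        u = (rng.permutation(n) + 0.5) / n
        return dist.ppf(u)
    return dist.rvs(size=n, random_state=rng)


def _severity_assignment(config: CohortConfig, n: int, rng: np.random.Generator):
    p = np.asarray(config.severity_proportions, dtype=float)
    if config.severity_allocation == "multinomial":
        return rng.choice(len(p), size=n, p=p)
    # exact largest-remainder counts, randomly permuted over subjects
    raw = p * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for idx in np.argsort(rem)[::-1][: n - counts.sum()]:
        counts[idx] += 1
    labels = np.repeat(np.arange(len(p)), counts)
    return labels[rng.permutation(n)]


def draw_cohort_truths(config: CohortConfig) -> list[SubjectTruth]:
    """Draw per-subject ground truth from the cohort configuration.

    Non-positive (below-floor) SFT/BMA draws are redrawn; redraw counts are
    recorded on the returned list as the ``redraws`` attribute of the
    accompanying log via :func:`generate_cohort`.
    """
    truths, _ = _draw_truths_with_log(config)
    return truths


def _draw_truths_with_log(config: CohortConfig):
    rng = np.random.default_rng(config.seed)
    sexes = ["M"] * config.n_male + ["F"] * config.n_female
    n = len(sexes)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    severity_idx = _severity_assignment(config, n, rng)
    stratified = config.sampling == "stratified"

    cols: dict[str, np.ndarray] = {
        "age": np.empty(n),
        "bmi": np.empty(n),
        "sft": np.empty(n),
        "bma": np.empty(n),
    }
    redraws = 0
    for sex in ("M", "F"):
        sel = np.array([s == sex for s in sexes])
        m = int(sel.sum())
        if m == 0:
            continue
        a_mean, a_sd, (a_lo, a_hi) = config.age[sex]
        b_mean, b_sd, (b_lo, b_hi) = config.bmi[sex]
        cols["age"][sel] = _trunc_draws(a_mean, a_sd, a_lo, a_hi, m, rng, stratified)
        cols["bmi"][sel] = _trunc_draws(b_mean, b_sd, b_lo, b_hi, m, rng, stratified)
        for name, table, floor in (
            ("sft", config.sft, config.sft_floor),
            ("bma", config.bma, config.bma_floor),
        ):
            mean, sd = table[sex]
            s_age = config.slopes.get((name, "age", sex), 0.0)
            s_bmi = config.slopes.get((name, "bmi", sex), 0.0)
            # keep the planted marginal sd: shrink the residual sd by the
            # variance the slopes explain (floored at 25 % of the target sd)
            expl = (s_age * a_sd) ** 2 + (s_bmi * b_sd) ** 2
            resid_sd = float(np.sqrt(max(sd**2 - expl, (0.25 * sd) ** 2)))
            base = _trunc_draws(mean, resid_sd, floor, np.inf, m, rng, stratified)
            vals = (
                base
                + s_age * (cols["age"][sel] - a_mean)
                + s_bmi * (cols["bmi"][sel] - b_mean)
            )
            bad = vals < floor
            while bad.any():
                redraws += int(bad.sum())
                vals[bad] = floor + np.abs(rng.normal(0.0, resid_sd, size=int(bad.sum())))
                bad = vals < floor
            cols[name][sel] = vals

    ff_levels = np.asarray(config.severity_fat_fraction)
    truths = []
    for i, (sid, sex) in enumerate(zip(ids, sexes)):
        ff = float(ff_levels[severity_idx[i]])
        s_age = config.slopes.get(("mfi", "age", sex), 0.0)
        s_bmi = config.slopes.get(("mfi", "bmi", sex), 0.0)
        ff += s_age * (cols["age"][i] - config.age[sex][0])
        ff += s_bmi * (cols["bmi"][i] - config.bmi[sex][0])
        truths.append(
            SubjectTruth(
                subject_id=sid,
                sex=sex,
                age=float(np.clip(cols["age"][i], *config.age[sex][2])),
                bmi=float(np.clip(cols["bmi"][i], *config.bmi[sex][2])),
                true_sft=float(cols["sft"][i]),
                true_bma=float(cols["bma"][i]),
                true_fat_fraction=float(np.clip(ff, 0.0, 0.95)),
                severity_class=SEVERITY_CLASSES[severity_idx[i]],
            )
        )
    return truths, {"redraws": redraws}


def manifest_frame(truths: list[SubjectTruth], seed: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in truths],
            "sex": [t.sex for t in truths],
            "age": [t.age for t in truths],
            "bmi": [t.bmi for t in truths],
            "true_sft": [t.true_sft for t in truths],
            "true_bma": [t.true_bma for t in truths],
            "true_fat_fraction": [t.true_fat_fraction for t in truths],
            "severity_class": [t.severity_class for t in truths],
            "seed": seed,
        }
    )


def iter_cohort(
    config: CohortConfig,
) -> Iterator[tuple[SubjectTruth, ImageStack, MaskStack]]:
    """Stream (truth, images, masks) per subject without holding the cohort."""
    base = replace(config.phantom, seed=config.seed)
    for truth in draw_cohort_truths(config):
        image_stack, mask_stack = generate_subject(truth, base)
        yield truth, image_stack, mask_stack


def generate_cohort(config: CohortConfig, out_dir=None) -> pd.DataFrame:
    """Draw a cohort manifest; optionally render and write all subjects.

    With ``out_dir`` set, writes ``manifest.csv`` plus one NIfTI image and
    one multi-label mask volume per subject.
    """
    truths, log = _draw_truths_with_log(config)
    manifest = manifest_frame(truths, config.seed)
    manifest.attrs["redraws"] = log["redraws"]
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        base = replace(config.phantom, seed=config.seed)
        for truth in truths:
            image_stack, mask_stack = generate_subject(truth, base)
            save_subject_nifti(out_dir, truth.subject_id, image_stack, mask_stack)
    return manifest


# ---------------------------------------------------------------------------
# NIfTI persistence


def _affine(pixel_size: float) -> np.ndarray:
    return np.diag([pixel_size, pixel_size, SLICE_SPACING_MM, 1.0])


def save_subject_nifti(
    out_dir, subject_id: str, image_stack: ImageStack, mask_stack: MaskStack
) -> tuple[str, str]:
    """Write ``<id>_image.nii`` and ``<id>_labels.nii`` (multi-label mask)."""
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    img_path = out_dir / f"{subject_id}_image.nii"
    lab_path = out_dir / f"{subject_id}_labels.nii"
    vol = np.ascontiguousarray(np.moveaxis(image_stack.data, 0, -1))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), _affine(image_stack.pixel_size)), img_path)
    labels = np.zeros(image_stack.data.shape, dtype=np.int16)
    for name, code in REGION_LABELS.items():
        labels[mask_stack.masks[name]] = code
    lab_vol = np.ascontiguousarray(np.moveaxis(labels, 0, -1))
    nib.save(nib.Nifti1Image(lab_vol, _affine(mask_stack.pixel_size)), lab_path)
    return str(img_path), str(lab_path)


def load_subject_nifti(out_dir, subject_id: str) -> tuple[ImageStack, MaskStack]:
    """Load a subject written by :func:`save_subject_nifti`."""
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    img = nib.load(out_dir / f"{subject_id}_image.nii")
    lab = nib.load(out_dir / f"{subject_id}_labels.nii")
    pixel_size = float(img.header.get_zooms()[0])
    data = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    labels = np.moveaxis(np.asarray(lab.dataobj, dtype=np.int16), -1, 0)
    masks = {name: labels == code for name, code in REGION_LABELS.items()}
    masks["leg"] = labels > 0
    n = data.shape[0]
    positions = (np.arange(n) - (n - 1) / 2.0) * SLICE_SPACING_MM
    return (
        ImageStack(data=data, pixel_size=pixel_size, slice_positions=positions,
                   meta={"subject_id": subject_id}),
        MaskStack(masks=masks, pixel_size=pixel_size),
    )
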