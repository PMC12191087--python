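"""Synthetic paired T2/ADC prostate-MRI phantom cohorts.

Generates patient visits with three rendered organs (bladder, prostate,
rectum with a gas-filled lumen), planted artifact severities drawn from a
latent Gaussian copula, ordinal 1-3 quality labels per modality, and an
acquisition-metadata table emulating DICOM header fields.

The copula is calibrated numerically so that the *discretized* quality
labels reproduce the requested Pearson correlations: within-visit T2 vs ADC
correlation (``rho_cross_modality``) and same-patient same-modality
correlation across sites (``rho_cross_site``). Susceptibility severity is an
increasing function of rectal gas area and crosses the upper quality
cut-point exactly at ``area_threshold_mm2``, which plants a recoverable
area -> ADC-quality breakpoint.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

log = logging.getLogger(__name__)

ARTIFACT_KINDS = ("gas_susceptibility", "motion", "low_contrast", "aliasing", "noise")
#: artifact-severity keys used in per-visit severity maps
SEVERITY_KEYS = ("gas", "motion", "low_contrast", "aliasing", "noise")
MODALITIES = ("t2", "adc")

_DEFAULT_SEVERITY_BETA = {"t2": (1.0, 2.8), "adc": (1.1, 2.0)}
_DEFAULT_DOMINANT = {
    # T2 failures are primarily breathing-motion driven; ADC failures are
    # dominated by rectal-gas susceptibility, then low contrast
    "t2": {"motion": 0.8, "low_contrast": 0.1, "aliasing": 0.1},
    "adc": {"gas": 0.7, "low_contrast": 0.2, "aliasing": 0.1},
}
# weighted-max composite: gas degrades ADC but not T2; motion mainly T2
_DEFAULT_WEIGHTS = {
    "t2": {"gas": 0.0, "motion": 1.0, "low_contrast": 1.0, "aliasing": 1.0, "noise": 0.5},
    "adc": {"gas": 1.0, "motion": 0.5, "low_contrast": 1.0, "aliasing": 1.0, "noise": 0.5},
}


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration is inconsistent."""


@dataclass
class PhantomConfig:
    """Cohort-level generation parameters.

    ``rho_cross_modality`` / ``rho_cross_site`` are targets for the Pearson
    correlation of the ordinal labels (computed with ``label_noise = 0``).
    ``artifact_severity_distributions`` maps modality -> Beta(a, b) shape
    parameters of the composite-severity marginal.
    """

    n_patients: int
    n_sites: int = 1
    slices_per_volume: int = 14
    image_size: int = 128
    pixel_spacing: float = 1.0
    rho_cross_modality: float = 0.4
    rho_cross_site: float = 0.2
    artifact_severity_distributions: dict = field(
        default_factory=lambda: {m: _DEFAULT_SEVERITY_BETA[m] for m in MODALITIES}
    )
    dominant_probs: dict = field(
        default_factory=lambda: {m: dict(_DEFAULT_DOMINANT[m]) for m in MODALITIES}
    )
    artifact_weights: dict = field(
        default_factory=lambda: {m: dict(_DEFAULT_WEIGHTS[m]) for m in MODALITIES}
    )
    area_threshold_mm2: float = 700.0
    area_floor_mm2: float = 120.0
    cut_low: float = 0.35
    cut_high: float = 0.65
    label_noise: float = 0.0
    seed: int = 0
    render_images: bool = True

    def __post_init__(self):
        if self.n_patients < 1 or self.n_sites < 1:
            raise PhantomConfigError("n_patients and n_sites must be positive")
        if self.slices_per_volume < 1 or self.image_size < 32:
            raise PhantomConfigError("slices_per_volume >= 1 and image_size >= 32 required")
        if self.pixel_spacing <= 0:
            raise PhantomConfigError("pixel_spacing must be positive")
        for name in ("rho_cross_modality", "rho_cross_site", "label_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PhantomConfigError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.cut_low < self.cut_high < 1.0):
            raise PhantomConfigError("require 0 < cut_low < cut_high < 1")
        if self.area_floor_mm2 < 0 or self.area_threshold_mm2 <= self.area_floor_mm2:
            raise PhantomConfigError("area_threshold_mm2 must exceed area_floor_mm2 >= 0")


@dataclass
class PhantomVisit:
    """One synthetic patient visit (paired T2 and ADC slice stacks)."""

    patient_id: str
    site_id: str
    t2_stack: np.ndarray | None
    adc_stack: np.ndarray | None
    artifact_severities: dict  # {"t2": {...}, "adc": {...}} severities in [0, 1]
    rectal_area_true: float  # mm^2, central-slice gas/lumen ellipse
    quality_t2: int
    quality_adc: int
    masks: dict | None = None  # central-slice organ masks when rendered
    spacing: float = 1.0


@dataclass
class MetadataRecord:
    """Tabular emulation of the DICOM header fields analysed downstream."""

    patient_id: str
    site_id: str
    modality: str
    repetition_time_ms: float | None
    echo_time_ms: float | None
    fov_h_mm: float | None
    fov_v_mm: float | None
    resolution_h_px: float | None
    resolution_v_px: float | None
    phase_encoding_direction: str | None
    b_values: list | None  # ADC only; None = not retrievable

    def __post_init__(self):
        for f in ("repetition_time_ms", "echo_time_ms", "fov_h_mm", "fov_v_mm",
                  "resolution_h_px", "resolution_v_px"):
            v = getattr(self, f)
            if v is not None and v <= 0:
                raise ValueError(f"{f} must be positive when present")
        if self.b_values is not None:
            self.b_values = sorted(float(b) for b in self.b_values)


# ---------------------------------------------------------------------------
# label copula calibration
# ---------------------------------------------------------------------------

def _latent_cuts(cfg: PhantomConfig, modality: str) -> tuple[float, float]:
    """Latent-Gaussian thresholds equivalent to the severity cut-points."""
    a, b = cfg.artifact_severity_distributions[modality]
    return (
        float(ndtri(stats.beta.cdf(cfg.cut_low, a, b))),
        float(ndtri(stats.beta.cdf(cfg.cut_high, a, b))),
    )


def _label_corr_given_latent(r: float, cuts1, cuts2) -> float:
    """Pearson correlation of two 3-level labels cut from a bivariate normal."""
    def surv(a, b, rho):
        if rho >= 1.0 - 1e-12:
            return 1.0 - ndtr(max(a, b))
        mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        return 1.0 - ndtr(a) - ndtr(b) + float(mvn.cdf([a, b]))

    q1 = [1.0 - ndtr(t) for t in cuts1]
    q2 = [1.0 - ndtr(t) for t in cuts2]
    cov = sum(
        surv(cuts1[k], cuts2[l], r) - q1[k] * q2[l]
        for k in range(2) for l in range(2)
    )
    var1 = sum(surv(cuts1[k], cuts1[l], 1.0) - q1[k] * q1[l]
               for k in range(2) for l in range(2))
    var2 = sum(surv(cuts2[k], cuts2[l], 1.0) - q2[k] * q2[l]
               for k in range(2) for l in range(2))
    return cov / np.sqrt(var1 * var2)


def calibrate_latent_rho(target: float, cuts1, cuts2=None) -> float:
    """Latent Gaussian correlation whose discretized labels have Pearson
    correlation ``target``. Exact (bivariate-normal quadrature + root find)."""
    if cuts2 is None:
        cuts2 = cuts1
    if target <= 1e-9:
        return 0.0
    hi = 0.999
    top = _label_corr_given_latent(hi, cuts1, cuts2)
    if target >= top:
        raise PhantomConfigError(
            f"label correlation target {target} unreachable (max ~{top:.3f})"
        )
    return float(brentq(
        lambda r: _label_corr_given_latent(r, cuts1, cuts2) - target, 0.0, hi,
        xtol=1e-4,
    ))


# ---------------------------------------------------------------------------
# anatomy rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(size: int, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    cr, ccen = center
    ar, ac = max(axes[0], 1e-6), max(axes[1], 1e-6)
    return ((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2 <= 1.0


def render_base_anatomy(
    size: int,
    spacing: float,
    gas_area_mm2: float = 300.0,
    n_slices: int = 14,
    rng: np.random.Generator | None = None,
    anatomy_jitter: dict | None = None,
):
    """Noise-free paired T2/ADC stacks with bladder / prostate / rectum.

    The rectum is modelled as a gas-filled elliptical lumen in the lower
    third of the image; its central-slice rasterized area defines
    ``rectal_area_true``. Returns ``(t2_stack, adc_stack, layout)`` where
    layout carries the central-slice organ masks and ellipse geometry.
    """
    if size < 32:
        raise ValueError("image size too small to place organs (need >= 32 px)")
    rng = rng or np.random.default_rng(0)
    jit = anatomy_jitter or {}
    n = size

    def j(name, lo, hi):
        return jit.get(name, (lo + hi) / 2.0)

    bl_c = (j("bladder_r", 0.24, 0.32) * n, 0.5 * n)
    bl_ax = (j("bladder_ar", 0.13, 0.19) * n, j("bladder_ac", 0.18, 0.26) * n)
    pr_c = (j("prostate_r", 0.49, 0.55) * n, 0.5 * n)
    pr_ax = (j("prostate_ar", 0.10, 0.15) * n, j("prostate_ac", 0.13, 0.19) * n)
    gas_c = (j("gas_r", 0.75, 0.81) * n, 0.5 * n)

    area_px = gas_area_mm2 / spacing**2
    aspect = j("gas_aspect", 1.2, 1.8)  # wider than tall
    gar = np.sqrt(area_px / (np.pi * aspect))
    gac = np.sqrt(area_px * aspect / np.pi)
    gar = min(gar, 0.12 * n)
    gac = min(gac, 0.20 * n)

    zc = (n_slices - 1) / 2.0
    zscale = np.sqrt(np.clip(1.0 - ((np.arange(n_slices) - zc) / (0.75 * n_slices / 2 + 1e-9)) ** 2, 0.05, 1.0))

    t2 = np.empty((n_slices, n, n), np.float32)
    adc = np.empty((n_slices, n, n), np.float32)
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (n_slices, n, n)), sigma=(0, 2, 2))
    for z in range(n_slices):
        s = zscale[z]
        bl = _ellipse_mask(n, bl_c, (bl_ax[0] * s, bl_ax[1] * s))
        pr = _ellipse_mask(n, pr_c, (pr_ax[0] * s, pr_ax[1] * s))
        gas = _ellipse_mask(n, gas_c, (gar * s, gac * s))
        sl_t2 = np.full((n, n), 0.30, np.float32)
        sl_adc = np.full((n, n), 0.45, np.float32)
        sl_t2[bl] = 0.85
        sl_adc[bl] = 0.90
        sl_t2[pr] = 0.55
        sl_adc[pr] = 0.62
        sl_t2[gas] = 0.05
        sl_adc[gas] = 0.05
        sl_t2 += 0.025 * texture[z]
        sl_adc += 0.025 * texture[z]
        t2[z] = ndimage.gaussian_filter(sl_t2, 0.7)
        adc[z] = ndimage.gaussian_filter(sl_adc, 0.7)
    np.clip(t2, 0.0, 1.0, out=t2)
    np.clip(adc, 0.0, 1.0, out=adc)

    zc_i = n_slices // 2
    s = zscale[zc_i]
    layout = {
        "bladder_mask": _ellipse_mask(n, bl_c, (bl_ax[0] * s, bl_ax[1] * s)),
        "prostate_mask": _ellipse_mask(n, pr_c, (pr_ax[0] * s, pr_ax[1] * s)),
        "rectum_mask": _ellipse_mask(n, gas_c, (gar * s, gac * s)),
        "gas_center": gas_c,
        "gas_axes": (gar * s, gac * s),
        "central_slice": zc_i,
        "spacing": spacing,
    }
    layout["rectal_area_mm2"] = float(layout["rectum_mask"].sum()) * spacing**2
    return t2, adc, layout


# ---------------------------------------------------------------------------
# artifact operators
# ---------------------------------------------------------------------------

def gas_displacement_field(shape, layout, severity: float):
    """Radial displacement (dr, dc) in pixels induced by rectal-gas
    susceptibility: magnitude scales with severity and with gas area."""
    h, w = shape
    cr, cc = layout["gas_center"]
    ar, ac = layout["gas_axes"]
    radius = max(np.sqrt(max(ar * ac, 1e-6)), 1.0)
    sigma = 2.5 * radius
    rr, cc_ = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr = rr - cr
    dc = cc_ - cc
    d = np.sqrt(dr**2 + dc**2) + 1e-9
    area_factor = (ar * ac) / (0.02 * h * w)  # ~1 for a mid-size lumen
    mag = severity * 0.12 * h * min(area_factor, 2.0) * np.exp(-(d**2) / (2 * sigma**2)) * 0.25
    return mag * dr / d, mag * dc / d


def apply_artifact(
    stack: np.ndarray,
    kind: str,
    severity: float,
    layout: dict | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one artifact class at the given severity to a slice stack.

    severity = 0 returns the input unchanged for every kind.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; choose from {ARTIFACT_KINDS}")
    if not (0.0 <= severity <= 1.0):
        raise ValueError("severity must lie in [0, 1]")
    x = np.asarray(stack, np.float32)
    single = x.ndim == 2
    if single:
        x = x[None]
    if severity == 0.0:
        out = x.copy()
        return out[0] if single else out
    rng = rng or np.random.default_rng(0)
    s, h, w = x.shape

    if kind == "gas_susceptibility":
        if layout is None:
            raise ValueError("gas_susceptibility requires the organ layout")
        dr, dc = gas_displacement_field((h, w), layout, severity)
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([rr - dr, cc - dc])
        crv, ccv = layout["gas_center"]
        d = np.sqrt((rr - crv) ** 2 + (cc - ccv) ** 2)
        radius = max(np.sqrt(max(layout["gas_axes"][0] * layout["gas_axes"][1], 1e-6)), 1.0)
        dropout = 1.0 - 0.7 * severity * np.exp(-(d**2) / (2 * (2.0 * radius) ** 2))
        out = np.empty_like(x)
        for z in range(s):
            warped = ndimage.map_coordinates(x[z], coords, order=1, mode="nearest")
            out[z] = warped * dropout
    elif kind == "motion":
        # fine ghost train along the phase-encode axis: periodic replicas
        # survive local contrast equalization better than coarse ones
        alpha = 0.6 * severity
        ghosts = sum(np.roll(x, h * k // 8, axis=1) for k in range(1, 8)) / 7.0
        out = (1 - alpha) * x + alpha * ghosts
    elif kind == "low_contrast":
        mean = x.mean(axis=(1, 2), keepdims=True)
        out = mean + (1.0 - severity) * (x - mean)
    elif kind == "aliasing":
        alpha = 0.5 * severity
        out = (1 - alpha) * x + alpha * np.roll(x, w // 2, axis=2)
    else:  # noise -> Rician
        sigma = 0.12 * severity
        n1 = rng.normal(0, sigma, x.shape).astype(np.float32)
        n2 = rng.normal(0, sigma, x.shape).astype(np.float32)
        out = np.sqrt((x + n1) ** 2 + n2**2)
    out = np.clip(out, 0.0, 1.0).astype(np.float32)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# quality labels
# ---------------------------------------------------------------------------

def composite_severity(severities: dict, weights: dict) -> float:
    """Weighted max of per-artifact severities."""
    return max(weights.get(k, 1.0) * severities.get(k, 0.0) for k in SEVERITY_KEYS)


def assign_quality(
    severities: dict,
    config: PhantomConfig,
    label_noise: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Map per-modality artifact severities to ordinal 1-3 quality labels.

    ``severities`` is ``{"t2": {...}, "adc": {...}}``. The composite
    (weighted max) is cut at ``cut_low``/``cut_high``: below cut_low -> 3
    (optimal), below cut_high -> 2 (adequate), else 1 (non-diagnostic). With
    probability ``label_noise`` a label moves one step (clipped to [1, 3]).
    """
    noise = config.label_noise if label_noise is None else label_noise
    rng = rng or np.random.default_rng(0)
    labels = []
    for m in MODALITIES:
        comp = composite_severity(severities[m], config.artifact_weights[m])
        lab = 3 if comp < config.cut_low else (2 if comp < config.cut_high else 1)
        if noise > 0 and rng.random() < noise:
            if lab == 3:
                lab = 2
            elif lab == 1:
                lab = 2
            else:
                lab = 2 + (1 if rng.random() < 0.5 else -1)
        labels.append(lab)
    return labels[0], labels[1]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def severity_to_gas_area(severity: float, cfg: PhantomConfig) -> float:
    """Monotone severity -> gas area map; crosses area_threshold_mm2 exactly
    at the 2->1 quality cut."""
    a0, at = cfg.area_floor_mm2, cfg.area_threshold_mm2
    return a0 + (at - a0) * severity / cfg.cut_high


def _draw_severities(modality, comp, rng, cfg):
    """Decompose a composite severity into per-artifact severities whose
    weighted max equals the composite."""
    probs = cfg.dominant_probs[modality]
    classes = list(probs)
    dom = rng.choice(classes, p=np.array([probs[c] for c in classes]) / sum(probs.values()))
    sev = {}
    for k in SEVERITY_KEYS:
        if k == dom:
            sev[k] = float(comp)
        else:
            sev[k] = float(0.8 * comp * rng.random())
    return sev


def _draw_metadata(pid, sid, modality, site_params, rng) -> MetadataRecord:
    p = site_params[(sid, modality)]
    def maybe(v, p_missing=0.10):
        return None if rng.random() < p_missing else v
    fov = p["fov"] * rng.uniform(0.95, 1.05)
    res_h = float(rng.choice(p["res_choices"]))
    b_values = None
    if modality == "adc":
        # max b-value retrievable only rarely, mirroring sparse DICOM headers
        if rng.random() < 0.19:
            b_values = [0.0, 500.0, float(rng.choice([800, 1000, 1400, 1500]))]
    return MetadataRecord(
        patient_id=pid,
        site_id=sid,
        modality=modality,
        repetition_time_ms=maybe(p["tr"] * rng.uniform(0.9, 1.1)),
        echo_time_ms=maybe(p["te"] * rng.uniform(0.9, 1.1)),
        fov_h_mm=maybe(fov),
        fov_v_mm=maybe(fov * rng.uniform(0.9, 1.0)),
        resolution_h_px=maybe(res_h),
        resolution_v_px=maybe(res_h),
        phase_encoding_direction=maybe(
            "horizontal" if rng.random() < p["p_horiz"] else "vertical"
        ),
        b_values=b_values,
    )


def generate_cohort(config: PhantomConfig):
    """Generate the synthetic cohort.

    Returns ``(visits, metadata)``: ``n_patients * n_sites`` PhantomVisit
    objects and two MetadataRecord per visit. Deterministic under a fixed
    config + seed; the label/metadata stream is unchanged by
    ``render_images``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    lab_seed, meta_seed, render_seed = ss.spawn(3)
    rng = np.random.default_rng(lab_seed)

    cuts = {m: _latent_cuts(cfg, m) for m in MODALITIES}
    # calibrate both latent correlations; cross-modality uses the two
    # modality-specific margins, cross-site a single-modality margin (mean
    # of per-modality solutions keeps one shared patient loading)
    if cfg.rho_cross_modality > 0:
        r_cm = calibrate_latent_rho(cfg.rho_cross_modality, cuts["t2"], cuts["adc"])
    else:
        r_cm = 0.0
    if cfg.rho_cross_site > 0 and cfg.n_sites > 1:
        r_cs = float(np.mean([
            calibrate_latent_rho(cfg.rho_cross_site, cuts[m], cuts[m]) for m in MODALITIES
        ]))
    elif cfg.rho_cross_site > 0:
        r_cs = float(np.mean([
            calibrate_latent_rho(cfg.rho_cross_site, cuts[m], cuts[m]) for m in MODALITIES
        ]))
    else:
        r_cs = 0.0

    shared_trait = r_cm >= r_cs
    if shared_trait:
        a2, b2 = r_cs, r_cm - r_cs
    else:
        a2, b2 = r_cs, r_cm
    if a2 + b2 > 1.0 + 1e-9:
        raise PhantomConfigError(
            "requested correlations are jointly unreachable "
            f"(latent loadings a^2={a2:.3f}, b^2={b2:.3f})"
        )
    a, b = np.sqrt(a2), np.sqrt(b2)
    c = np.sqrt(max(1.0 - a2 - b2, 0.0))

    npat, nsit = cfg.n_patients, cfg.n_sites
    trait_shared = rng.normal(size=npat)
    trait_perm = rng.normal(size=(npat, 2))
    visit_fac = rng.normal(size=(npat, nsit))
    eps = rng.normal(size=(npat, nsit, 2))
    if shared_trait:
        latent = (a * trait_shared[:, None, None] + b * visit_fac[:, :, None] + c * eps)
    else:
        latent = (a * trait_perm[:, None, :] + b * visit_fac[:, :, None] + c * eps)

    composites = np.empty_like(latent)
    for mi, m in enumerate(MODALITIES):
        al, be = cfg.artifact_severity_distributions[m]
        composites[:, :, mi] = stats.beta.ppf(ndtr(latent[:, :, mi]), al, be)

    # per-patient anatomy jitter (consistent across sites)
    anat_rng = np.random.default_rng(lab_seed.spawn(1)[0])
    jitters = []
    for _ in range(npat):
        jitters.append({
            "bladder_r": anat_rng.uniform(0.24, 0.32),
            "bladder_ar": anat_rng.uniform(0.13, 0.19),
            "bladder_ac": anat_rng.uniform(0.18, 0.26),
            "prostate_r": anat_rng.uniform(0.49, 0.55),
            "prostate_ar": anat_rng.uniform(0.10, 0.15),
            "prostate_ac": anat_rng.uniform(0.13, 0.19),
            "gas_r": anat_rng.uniform(0.75, 0.81),
            "gas_aspect": anat_rng.uniform(1.2, 1.8),
        })

    meta_rng = np.random.default_rng(meta_seed)
    site_params = {}
    for s in range(nsit):
        sid = f"S{s:02d}"
        for m in MODALITIES:
            site_params[(sid, m)] = {
                "tr": meta_rng.uniform(4000, 6500) if m == "t2" else meta_rng.uniform(3000, 5500),
                "te": meta_rng.uniform(90, 130) if m == "t2" else meta_rng.uniform(55, 90),
                "fov": meta_rng.uniform(180, 260),
                "res_choices": [96, 128, 160] if m == "adc" else [256, 320, 384, 512],
                "p_horiz": meta_rng.uniform(0.3, 0.7),
            }

    render_children = render_seed.spawn(npat * nsit) if cfg.render_images else None

    visits, metadata = [], []
    idx = 0
    for p in range(npat):
        pid = f"P{p:04d}"
        for s in range(nsit):
            sid = f"S{s:02d}"
            sev = {
                m: _draw_severities(m, composites[p, s, mi], rng, cfg)
                for mi, m in enumerate(MODALITIES)
            }
            # rectal gas is a single physical property of the visit
            gas_sev = sev["adc"]["gas"]
            sev["t2"]["gas"] = gas_sev
            q_t2, q_adc = assign_quality(sev, cfg, rng=rng)
            gas_area = severity_to_gas_area(gas_sev, cfg)

            t2_stack = adc_stack = None
            masks = None
            area_true = gas_area
            if cfg.render_images:
                vr = np.random.default_rng(render_children[idx])
                t2_base, adc_base, layout = render_base_anatomy(
                    cfg.image_size, cfg.pixel_spacing, gas_area,
                    cfg.slices_per_volume, vr, jitters[p],
                )
                area_true = layout["rectal_area_mm2"]
                t2_stack = t2_base
                adc_stack = apply_artifact(
                    adc_base, "gas_susceptibility", gas_sev, layout, vr
                )
                for kind, key in (("motion", "motion"), ("low_contrast", "low_contrast"),
                                  ("aliasing", "aliasing"), ("noise", "noise")):
                    t2_stack = apply_artifact(t2_stack, kind, sev["t2"][key], layout, vr)
                    adc_stack = apply_artifact(adc_stack, kind, sev["adc"][key], layout, vr)
                masks = {
                    k: layout[k] for k in ("bladder_mask", "prostate_mask", "rectum_mask")
                }
                masks["central_slice"] = layout["central_slice"]

            visits.append(PhantomVisit(
                patient_id=pid, site_id=sid,
                t2_stack=t2_stack, adc_stack=adc_stack,
                artifact_severities=sev,
                rectal_area_true=float(area_true),
                quality_t2=int(q_t2), quality_adc=int(q_adc),
                masks=masks, spacing=cfg.pixel_spacing,
            ))
            metadata.append(_draw_metadata(pid, sid, "t2", site_params, meta_rng))
            metadata.append(_draw_metadata(pid, sid, "adc", site_params, meta_rng))
            idx += 1
    return visits, metadata


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def labels_frame(visits) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [v.patient_id for v in visits],
        "site_id": [v.site_id for v in visits],
        "quality_t2": [v.quality_t2 for v in visits],
        "quality_adc": [v.quality_adc for v in visits],
        "rectal_area_true": [v.rectal_area_true for v in visits],
    })


def metadata_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.__dict__.copy()
        d["b_values"] = "" if r.b_values is None else ";".join(
            f"{b:g}" for b in r.b_values
        )
        rows.append(d)
    return pd.DataFrame(rows)


def _parse_b_values(cell) -> list | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return None
    return [float(x) for x in str(cell).split(";")]


def write_dataset(visits, metadata, out_dir) -> None:
    """Write one NIfTI volume per modality per visit plus labels/metadata CSVs."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for v in visits:
        if v.t2_stack is None:
            continue
        affine = np.diag([v.spacing, v.spacing, 1.0, 1.0])
        for m, stack in (("t2", v.t2_stack), ("adc", v.adc_stack)):
            q = np.round(np.clip(stack, 0, 1) * 65535).astype(np.uint16)
            img = nib.Nifti1Image(np.moveaxis(q, 0, -1), affine)
            img.header["scl_slope"] = 1.0 / 65535
            img.header["scl_inter"] = 0.0
            nib.save(img, out / f"{v.patient_id}_{v.site_id}_{m}.nii.gz")
    labels_frame(visits).to_csv(out / "labels.csv", index=False)
    metadata_frame(metadata).to_csv(out / "metadata.csv", index=False)
    with open(out / "spacing.json", "w") as fh:
        json.dump({"pixel_spacing_mm": visits[0].spacing if visits else 1.0}, fh)


def read_dataset(in_dir):
    """Round-trip reader for :func:`write_dataset` output."""
    import nibabel as nib

    p = Path(in_dir)
    labels = pd.read_csv(p / "labels.csv")
    meta_df = pd.read_csv(p / "metadata.csv")
    with open(p / "spacing.json") as fh:
        spacing = json.load(fh)["pixel_spacing_mm"]
    visits = []
    for _, row in labels.iterrows():
        stacks = {}
        for m in MODALITIES:
            f = p / f"{row.patient_id}_{row.site_id}_{m}.nii.gz"
            if f.exists():
                # dataobj applies the stored slope: values come back in [0, 1]
                raw = np.asarray(nib.load(f).dataobj, np.float32)
                stacks[m] = np.moveaxis(raw, -1, 0)
            else:
                stacks[m] = None
        visits.append(PhantomVisit(
            patient_id=row.patient_id, site_id=row.site_id,
            t2_stack=stacks["t2"], adc_stack=stacks["adc"],
            artifact_severities={},
            rectal_area_true=float(row.rectal_area_true),
            quality_t2=int(row.quality_t2), quality_adc=int(row.quality_adc),
            spacing=spacing,
        ))
    records = []
    for _, row in meta_df.iterrows():
        def opt(x):
            return None if pd.isna(x) else float(x)
        records.append(MetadataRecord(
            patient_id=row.patient_id, site_id=row.site_id, modality=row.modality,
            repetition_time_ms=opt(row.repetition_time_ms),
            echo_time_ms=opt(row.echo_time_ms),
            fov_h_mm=opt(row.fov_h_mm), fov_v_mm=opt(row.fov_v_mm),
            resolution_h_px=opt(row.resolution_h_px),
            resolution_v_px=opt(row.resolution_v_px),
            phase_encoding_direction=(
                None if pd.isna(row.phase_encoding_direction)
                else str(row.phase_encoding_direction)
            ),
            b_values=_parse_b_values(row.b_values),
        ))
    return visits, records


def empirical_label_correlations(visits) -> dict:
    """Empirical Pearson correlations of the ordinal labels: within-visit
    T2 vs ADC, and same-patient same-modality across the first two sites."""
    df = labels_frame(visits)
    out = {"cross_modality": float(np.corrcoef(df.quality_t2, df.quality_adc)[0, 1])}
    sites = sorted(df.site_id.unique())
    if len(sites) >= 2:
        a = df[df.site_id == sites[0]].set_index("patient_id")
        bdf = df[df.site_id == sites[1]].set_index("patient_id")
        common = a.index.intersection(bdf.index)
        cs = []
        for m in ("quality_t2", "quality_adc"):
            cs.append(float(np.corrcoef(a.loc[common, m], bdf.loc[common, m])[0, 1]))
        out["cross_site"] = float(np.mean(cs))
        out["cross_site_by_modality"] = {"t2": cs[0], "adc": cs[1]}
    return out
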