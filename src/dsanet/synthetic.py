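"""Seeded phantom angiography videos and a synthetic patient cohort.

Every phantom has known generative structure — liver silhouette, branching
vessel tree, tumor blushes riding a gamma-variate bolus curve that peaks at
a programmed frame, optional moving confounders (bowel, diaphragm) outside
the liver, and additive Gaussian noise — so downstream stages have a
recoverable target.  Cohort generation adds correlated clinical covariates,
a logistic response label, and exponential progression-free survival with a
programmed responder/non-responder hazard ratio and administrative
censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd
from scipy import ndimage

from .evalstats import SurvivalRecord
from .preprocess import DsaVideo, MaskImage
from .respnet import ClinicalRecord, ResponseLabel

#: image width represented as 20 cm of anatomy at native field of view;
#: converts lesion diameter fractions to the size strata used in reports
CM_PER_IMAGE = 20.0


@dataclass
class PhantomConfig:
    frame_count: int = 24
    height: int = 256
    width: int = 256
    lesion_count_probs: tuple[float, ...] = (0.45, 0.25, 0.15, 0.10, 0.05)  # P(1..5)
    lesion_diameter_range: tuple[float, float] = (0.05, 0.35)
    blush_intensity_range: tuple[float, float] = (0.45, 0.85)
    hypovascular_fraction: float = 0.0
    p_bowel_motion: float = 0.0
    p_diaphragm_motion: float = 0.0
    p_magnified_fov: float = 0.0
    magnified_scale: float = 1.5
    confounder_intensity: float = 0.15
    noise_sd: float = 0.02
    peak_frame_range: tuple[int, int] = (10, 18)  # inclusive
    border_px: int = 0
    gamma_shape: float = 10.0
    invert_polarity: bool = False

    def __post_init__(self):
        probs = np.asarray(self.lesion_count_probs, dtype=float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("lesion_count_probs must be a distribution over 1..5")
        lo, hi = self.lesion_diameter_range
        if not 0 < lo <= hi < 0.5:
            raise ValueError("lesion_diameter_range must lie within (0, 0.5)")
        if not 3 <= self.frame_count:
            raise ValueError("frame_count must be >= 3")


@dataclass
class CohortConfig:
    n_patients: int = 40
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    #: logistic model for P(responder); keys are derived per-patient features
    response_intercept: float = 1.1
    response_coefs: dict = field(default_factory=lambda: {
        "burden": -1.5,        # standardized total lesion area
        "multiplicity": -0.6,  # 1 if >= 2 lesions
        "blush": 1.0,          # mean blush amplitude, standardized
        "afp": -0.8,           # AFP >= 200
        "child_pugh": -0.5,    # score - 5
        "hbv": -0.3,
    })
    #: exponential PFS: responder median (months) and the non-responder
    #: hazard ratio; administrative censoring at ``censor_months``
    responder_median_pfs: float = 18.0
    hazard_ratio: float = 2.5
    censor_months: float = 36.0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")


class GenerationError(RuntimeError):
    """Raised when a phantom cannot satisfy its own constraints."""


def gamma_variate(t: np.ndarray, peak: float, shape: float = 3.0) -> np.ndarray:
    """Bolus time–intensity curve normalized to 1.0 at ``peak``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = np.maximum(peak, 1e-6)
    out[pos] = (t[pos] / tp) ** shape * np.exp(shape * (1.0 - t[pos] / tp))
    return out


def _ellipse_mask(h, w, cy, cx, ry, rx, angle=0.0):
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = rr - cy, cc - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dy + sa * dx
    v = -sa * dy + ca * dx
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _draw_vessels(liver: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Branching tree of line segments clipped to the liver silhouette."""
    h, w = liver.shape
    amp = np.zeros((h, w), dtype=np.float32)
    ys, xs = np.nonzero(liver)
    cy, cx = ys.mean(), xs.mean()
    start = np.array([cy - 0.25 * (ys.max() - ys.min()), cx])

    def segment(p0, ang, length, width_px, depth):
        p1 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
        npts = max(int(length * 2), 2)
        pts = p0[None] + np.linspace(0, 1, npts)[:, None] * (p1 - p0)[None]
        rr = np.clip(pts[:, 0].round().astype(int), 0, h - 1)
        cc = np.clip(pts[:, 1].round().astype(int), 0, w - 1)
        amp[rr, cc] = np.maximum(amp[rr, cc], 0.9 ** depth)
        if depth < 4:
            for dang in rng.uniform(0.3, 0.9, size=2) * rng.choice([-1, 1], size=2):
                segment(p1, ang + dang, length * 0.7, max(width_px - 1, 1), depth + 1)

    segment(start, np.pi / 2 + rng.uniform(-0.4, 0.4), 0.22 * h, 3, 0)
    amp = ndimage.grey_dilation(amp, size=2)
    amp = ndimage.gaussian_filter(amp, 0.8)
    amp[~liver] = 0.0
    return amp * 0.6


def generate_phantom(config: PhantomConfig, seed: int,
                     patient_id: str | None = None,
                     lesion_count: int | None = None
                     ) -> tuple[DsaVideo, MaskImage, MaskImage, dict]:
    """Render one phantom video plus tumor/liver masks and the truth record."""
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width
    T = config.frame_count
    pid = patient_id or f"phantom_{seed:05d}"

    magnified = rng.random() < config.p_magnified_fov
    fov_scale = config.magnified_scale if magnified else 1.0

    # liver silhouette: smooth rotated ellipse in the image center
    liver = _ellipse_mask(
        h, w,
        cy=h * rng.uniform(0.44, 0.52), cx=w * rng.uniform(0.46, 0.54),
        ry=h * 0.30 * min(fov_scale, 1.3), rx=w * 0.36 * min(fov_scale, 1.3),
        angle=rng.uniform(-0.25, 0.25),
    )

    vessels = _draw_vessels(liver, rng)

    # tumor blushes inside the liver
    n_lesions = (lesion_count if lesion_count is not None
                 else int(rng.choice(np.arange(1, 6), p=config.lesion_count_probs)))
    dist_in = ndimage.distance_transform_edt(liver)
    tumor = np.zeros((h, w), dtype=bool)
    tumor_amp = np.zeros((h, w), dtype=np.float32)
    diameters_cm, amps = [], []
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(200):
            frac = rng.uniform(*config.lesion_diameter_range)
            r_px = max(frac * fov_scale * w / 2.0, 2.0)
            ecc = rng.uniform(0.8, 1.2)
            r_eff = r_px * max(ecc, 1.0 / ecc)  # worst-case ellipse radius
            if tumor.any():
                dist_other = ndimage.distance_transform_edt(~tumor)
            else:
                dist_other = np.full((h, w), np.inf)
            ok = (dist_in >= r_eff + 2) & (dist_other > r_eff + 3)
            ys, xs = np.nonzero(ok)
            if ys.size == 0:
                continue
            k = rng.integers(ys.size)
            cy, cx = ys[k], xs[k]
            lesion = _ellipse_mask(h, w, cy, cx, r_px * ecc, r_px / ecc,
                                   rng.uniform(0, np.pi))
            lesion &= liver
            if not lesion.any():
                continue
            amp = rng.uniform(*config.blush_intensity_range)
            if rng.random() < config.hypovascular_fraction:
                amp *= 0.3
            tumor |= lesion
            tumor_amp = np.maximum(tumor_amp, lesion * amp)
            diameters_cm.append(frac * CM_PER_IMAGE)
            amps.append(amp)
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place lesion {len(diameters_cm) + 1} of {n_lesions} "
                f"inside the liver (seed {seed})"
            )

    # moving confounders strictly outside the liver
    outside = ~ndimage.binary_dilation(liver, iterations=3)
    bowel = rng.random() < config.p_bowel_motion
    diaphragm = rng.random() < config.p_diaphragm_motion
    conf_frames = np.zeros((T, h, w), dtype=np.float32)
    if bowel:
        ys, xs = np.nonzero(outside[int(0.7 * h):])
        if ys.size:
            k = rng.integers(ys.size)
            by, bx = ys[k] + int(0.7 * h), xs[k]
            br = rng.uniform(0.04, 0.08) * h
            for t in range(T):
                off = 3.0 * np.sin(2 * np.pi * t / 7.0 + rng.random() * 0)
                blob = _ellipse_mask(h, w, by + off, bx + 0.5 * off, br, br * 1.3)
                conf_frames[t] += (blob & outside) * config.confounder_intensity
    if diaphragm:
        for t in range(T):
            off = int(round(2.5 * np.sin(2 * np.pi * t / 9.0)))
            y0 = max(int(0.06 * h) + off, 0)
            band = np.zeros((h, w), dtype=bool)
            band[y0 : y0 + max(int(0.05 * h), 2)] = True
            conf_frames[t] += (band & outside) * 0.8 * config.confounder_intensity

    peak = int(rng.integers(config.peak_frame_range[0],
                            config.peak_frame_range[1] + 1))
    peak = min(peak, T - 1)
    tic = gamma_variate(np.arange(T), peak, config.gamma_shape)

    signal = vessels + tumor_amp
    noise = rng.normal(0.0, config.noise_sd, size=(T, h, w)).astype(np.float32)
    frames = tic[:, None, None] * signal[None] + conf_frames + noise
    frames = np.clip(frames, 0.0, 1.0).astype(np.float32)
    if config.invert_polarity:
        frames = 1.0 - frames
    if config.border_px:
        b = config.border_px
        framed = np.zeros((T, h + 2 * b, w + 2 * b), dtype=np.float32)
        framed[:, b:-b, b:-b] = frames
        frames = framed
        tpad = np.zeros((h + 2 * b, w + 2 * b), dtype=bool)
        tpad[b:-b, b:-b] = tumor
        tumor = tpad
        lpad = np.zeros((h + 2 * b, w + 2 * b), dtype=bool)
        lpad[b:-b, b:-b] = liver
        liver = lpad

    truth = {
        "patient_id": pid,
        "seed": int(seed),
        "lesion_count": n_lesions,
        "diameters_cm": [round(d, 3) for d in diameters_cm],
        "blush_amplitudes": [round(a, 4) for a in amps],
        "burden": float(tumor.mean()),
        "peak_frame": peak,
        "bowel_motion": bool(bowel),
        "diaphragm_motion": bool(diaphragm),
        "fov_scale": float(fov_scale),
    }
    video = DsaVideo(patient_id=pid, frames=frames, fov_scale=fov_scale)
    return (video,
            MaskImage(role="tumor_gt", pixels=tumor.astype(np.uint8)),
            MaskImage(role="liver_gt", pixels=liver.astype(np.uint8)),
            truth)


def _sample_clinical(rng: np.random.Generator) -> ClinicalRecord:
    """Covariates with marginals matched to a real intermediate-stage HCC
    cohort (mean age 55, ~90% male, ~87% HBV+, Child–Pugh skewed to 5)."""
    ascites = rng.random() < 0.07
    cp_probs = np.array([0.72, 0.18, 0.06, 0.03, 0.01])
    if ascites:  # ascites shifts the score upward
        cp_probs = np.array([0.15, 0.25, 0.30, 0.20, 0.10])
    return ClinicalRecord(
        age=float(np.clip(rng.normal(55.0, 11.9), 18, 90)),
        sex="male" if rng.random() < 0.906 else "female",
        hbv="pos" if rng.random() < 0.876 else "neg",
        child_pugh=int(rng.choice(np.arange(5, 10), p=cp_probs)),
        ascites="yes" if ascites else "no",
        pt=float(np.clip(rng.normal(12.8, 1.6), 8, 30)),
        tbil=float(np.clip(rng.lognormal(np.log(16.0), 0.45), 3, 120)),
        alb=float(np.clip(rng.normal(40.7, 5.0), 20, 60)),
        ast_ge40="yes" if rng.random() < 0.58 else "no",
        alt_ge40="yes" if rng.random() < 0.514 else "no",
        crp_ge1="yes" if rng.random() < 0.869 else "no",
        afp_ge200="yes" if rng.random() < 0.441 else "no",
    )


def _response_features(truth: dict, clin: ClinicalRecord) -> dict[str, float]:
    # standardization constants: empirical mean/sd of the default phantom
    # prior, so each feature is O(1) and coefficients are comparable
    return {
        "burden": (truth["burden"] - 0.0625) / 0.0405,
        "multiplicity": 1.0 if truth["lesion_count"] >= 2 else 0.0,
        "blush": (float(np.mean(truth["blush_amplitudes"])) - 0.646) / 0.091,
        "afp": 1.0 if clin.afp_ge200 == "yes" else 0.0,
        "child_pugh": float(clin.child_pugh - 5),
        "hbv": 1.0 if clin.hbv == "pos" else 0.0,
    }


def sample_cohort_tables(cfg: CohortConfig, truths: list[dict] | None = None
                         ) -> pd.DataFrame:
    """Sample covariates, response labels, and survival without rendering
    videos.  If generator truth records are supplied the logistic response
    model uses their imaging features; otherwise imaging features are drawn
    from the phantom priors."""
    rng = np.random.default_rng(cfg.seed + 104729)
    rows = []
    for i in range(cfg.n_patients):
        clin = _sample_clinical(rng)
        if truths is not None:
            truth = truths[i]
        else:
            pc = cfg.phantom
            n_les = int(rng.choice(np.arange(1, 6), p=pc.lesion_count_probs))
            fracs = rng.uniform(*pc.lesion_diameter_range, size=n_les)
            truth = {
                "lesion_count": n_les,
                "burden": float(np.sum(np.pi * (fracs / 2) ** 2) * 0.8),
                "blush_amplitudes": list(rng.uniform(*pc.blush_intensity_range,
                                                     size=n_les)),
            }
        feats = _response_features(truth, clin)
        z = cfg.response_intercept + sum(
            cfg.response_coefs.get(k, 0.0) * v for k, v in feats.items())
        p_resp = 1.0 / (1.0 + np.exp(-z))
        responder = rng.random() < p_resp
        lam = np.log(2.0) / cfg.responder_median_pfs
        if not responder:
            lam *= cfg.hazard_ratio
        t_event = rng.exponential(1.0 / lam)
        event = t_event <= cfg.censor_months
        pfs = min(t_event, cfg.censor_months)
        row = {
            "patient_id": f"pt_{i:04d}",
            **{k: getattr(clin, k) for k in (
                "age", "sex", "hbv", "child_pugh", "ascites", "pt", "tbil",
                "alb", "ast_ge40", "alt_ge40", "crp_ge1", "afp_ge200")},
            "p_responder": float(p_resp),
            "label": "responder" if responder else "non_responder",
            "pfs_months": float(pfs),
            "event": bool(event),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(cfg: CohortConfig, render_videos: bool = True,
                    easy: bool = False) -> dict:
    """Full synthetic dataset: per-patient videos/masks (optional), clinical
    covariates, response labels, survival, and the truth table.

    ``easy`` narrows the phantom priors to single large high-contrast
    lesions without confounders (used for fast training checks).
    """
    pc = cfg.phantom
    if easy:
        pc = PhantomConfig(
            frame_count=pc.frame_count, height=pc.height, width=pc.width,
            lesion_count_probs=(1.0, 0, 0, 0, 0),
            lesion_diameter_range=(0.22, 0.35),
            blush_intensity_range=(0.65, 0.9),
            noise_sd=0.01, peak_frame_range=pc.peak_frame_range,
        )
    patients = []
    truths = []
    for i in range(cfg.n_patients):
        pid = f"pt_{i:04d}"
        entry: dict = {"patient_id": pid}
        if render_videos:
            video, tumor, liver, truth = generate_phantom(
                pc, seed=cfg.seed * 1_000_003 + i, patient_id=pid)
            entry.update(video=video, tumor_mask=tumor, liver_mask=liver,
                         truth=truth)
        else:
            rng_i = np.random.default_rng(cfg.seed * 1_000_003 + i)
            n_les = int(rng_i.choice(np.arange(1, 6), p=pc.lesion_count_probs))
            fracs = rng_i.uniform(*pc.lesion_diameter_range, size=n_les)
            truth = {
                "patient_id": pid, "lesion_count": n_les,
                "diameters_cm": [float(f * CM_PER_IMAGE) for f in fracs],
                "burden": float(np.sum(np.pi * (fracs / 2) ** 2) * 0.8),
                "blush_amplitudes": list(
                    rng_i.uniform(*pc.blush_intensity_range, size=n_les)),
                "peak_frame": None, "fov_scale": 1.0,
                "bowel_motion": False, "diaphragm_motion": False,
            }
            entry["truth"] = truth
        truths.append(entry["truth"])
        patients.append(entry)

    table = sample_cohort_tables(cfg, truths=truths)
    for entry, (_, row) in zip(patients, table.iterrows()):
        entry["clinical"] = ClinicalRecord(**{
            k: row[k] for k in (
                "age", "sex", "hbv", "child_pugh", "ascites", "pt", "tbil",
                "alb", "ast_ge40", "alt_ge40", "crp_ge1", "afp_ge200")})
        entry["label"] = ResponseLabel(row["label"])
        entry["survival"] = SurvivalRecord(
            pfs_months=row["pfs_months"], event=bool(row["event"]),
            group=row["label"])
    return {"patients": patients, "table": table, "config": cfg}


def write_cohort(cohort: dict, outdir) -> Path:
    """Write PNG frame stacks, PNG masks, the cohort table, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"patients": {}}
    for entry in cohort["patients"]:
        pid = entry["patient_id"]
        rel_paths = {}
        if "video" in entry:
            pdir = outdir / pid
            (pdir / "frames").mkdir(parents=True, exist_ok=True)
            for t, frame in enumerate(entry["video"].frames):
                fp = pdir / "frames" / f"frame_{t:03d}.png"
                imageio.imwrite(fp, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
            imageio.imwrite(pdir / "tumor_mask.png",
                            entry["tumor_mask"].pixels * 255)
            imageio.imwrite(pdir / "liver_mask.png",
                            entry["liver_mask"].pixels * 255)
            rel_paths = {
                "frames": f"{pid}/frames",
                "tumor_mask": f"{pid}/tumor_mask.png",
                "liver_mask": f"{pid}/liver_mask.png",
            }
        manifest["patients"][pid] = {"truth": entry["truth"], **rel_paths}
    table_path = outdir / "cohort.csv"
    cohort["table"].to_csv(table_path, index=False)
    manifest["cohort_table"] = "cohort.csv"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return outdir
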