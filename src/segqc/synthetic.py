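"""Seeded synthetic brain-tumor-like cohorts with controllable calibration
and failure modes.

Each subject is a smooth random tumor phantom (deformed nested spheres
WT ⊇ TC ⊇ ET inside an ellipsoidal brain mask) plus a simulated
probabilistic predictor.  The predictor blurs the ground truth into a latent
foreground probability p* and reports p̂ = sigmoid(logit(p*)/τ): the
temperature τ controls calibration (τ < 1 overconfident, τ > 1
underconfident) without changing the segmentation p̂ ≥ 0.5.

Two generator modes:

* ``calibration`` — the ground truth is *redrawn* voxel-wise as
  Bernoulli(p*), so p* is perfectly calibrated by construction and τ is the
  only source of miscalibration.  The redrawn labels are speckled and
  anatomically implausible, which is irrelevant for calibration metrics.
* ``morphology`` — the ground truth stays the clean phantom and smooth
  logit noise perturbs the prediction, keeping plausible shapes for
  aggregation and shape-feature analyses.

Failure modes decouple mean uncertainty from segmentation quality:
``remote_blob`` plants multifocal spurious structures far from the tumor —
a confidently predicted false-positive focus (Dice drops, mean uncertainty
barely moves) next to an unpredicted, mildly uncertain satellite focus
whose uncertainty sits far from every predicted boundary; ``missed_core``
suppresses the prediction inside part of a region; ``boundary_jitter``
perturbs the predicted surface.  The cohort is a pure function of
(spec, master seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .datamodel import Cohort, SubjectRecord, UncertaintyMap
from .failure import dice_coefficient
from .uncertainty import EPS, CohortExtrema, normalize_native_map

FAILURE_MODES = ("clean", "boundary_jitter", "remote_blob", "missed_core")


@dataclass
class RemoteBlobParams:
    """False-positive spheres planted at least ``d_min_mm`` from the tumor."""

    n_blobs_range: tuple[int, int] = (1, 2)
    radius_fraction: float = 0.75  # of the WT effective radius
    confidence: float = 0.995  # predicted probability in the detected focus
    d_min_mm: float = 10.0
    edge_sigma_mm: float = 0.0  # soft edge of the detected focus (0 = hard)
    #: spurious structures are typically multifocal and only partially
    #: detected: next to each confidently predicted blob (the false positive
    #: that lowers the Dice) sits an unpredicted satellite focus over which
    #: the model hesitates at a low foreground probability — mild
    #: uncertainty far from any predicted boundary, the signature the
    #: prior-knowledge weightings are built to catch.
    satellite_radius_fraction: float = 0.9  # of the blob radius
    satellite_gap_mm: float = 3.0
    undetected_prob: float = 0.04
    #: fraction of detected-interior voxels where the predictor is
    #: ambivalent (p̂ = 0.5): heterogeneous confidence that leaves a
    #: high-entropy, shape-visible trace without moving the brain-wide mean.
    interior_uncertain_fraction: float = 0.04


@dataclass
class MissedCoreParams:
    """Suppressed prediction inside part of a ground-truth subregion."""

    region: str = "TC"
    fraction: float = 0.5  # axial fraction of the region to miss
    suppressed_prob: float = 0.02
    edge_sigma_mm: float = 1.0


@dataclass
class BoundaryJitterParams:
    """Morphological perturbation of the predicted surface."""

    amplitude: float = 0.15  # local shift of the 0.5 decision level
    scale_mm: float = 8.0


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults emulate a BraTS-like setting at desk scale: 1 mm isotropic
    voxels, a 96×96×48 grid, tumors of 8-13 mm WT radius nested inside an
    ellipsoidal brain, boundary blur of 1.2 mm, per-subject segmentation
    difficulty (noise amplitude) variation, and the train/validation/test
    proportions of a 100/25/160-style split.
    """

    n_subjects: int = 100
    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_axes_fraction: float = 0.45  # brain semi-axes / grid extent
    brain_axes_jitter: float = 0.08  # per-subject relative variation
    regions: tuple[str, ...] = ("WT", "TC", "ET")
    wt_radius_range: tuple[float, float] = (8.0, 13.0)  # mm
    tc_fraction_range: tuple[float, float] = (0.55, 0.75)
    et_fraction_range: tuple[float, float] = (0.45, 0.70)
    center_offset_fraction: float = 0.15  # tumor center offset / brain semi-axes
    deformation_amplitude: float = 0.12  # relative radial deformation
    deformation_scale_mm: float = 12.0
    blur_sigma_mm: float = 1.2
    mode: str = "morphology"  # or "calibration"
    tau_range: tuple[float, float] = (1.0, 1.0)  # log-uniform per subject
    #: logit-space smooth noise (morphology mode); a (lo, hi) range drawn
    #: uniformly per subject — segmentation difficulty varies across
    #: subjects, which spreads boundary uncertainty and Dice realistically.
    noise_amplitude: tuple[float, float] = (0.25, 0.65)
    noise_scale_mm: float = 8.0
    failure_mix: dict[str, float] = field(default_factory=lambda: {"clean": 1.0})
    remote_blob: RemoteBlobParams = field(default_factory=RemoteBlobParams)
    missed_core: MissedCoreParams = field(default_factory=MissedCoreParams)
    boundary_jitter: BoundaryJitterParams = field(default_factory=BoundaryJitterParams)
    split_fractions: tuple[float, float, float] = (0.35, 0.10, 0.55)
    native_uncertainty: bool = False
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.mode not in ("morphology", "calibration"):
            raise ValueError(f"unknown generator mode {self.mode!r}")
        if not np.isclose(sum(self.failure_mix.values()), 1.0):
            raise ValueError(
                f"failure-mode fractions must sum to 1, got {self.failure_mix}"
            )
        unknown = set(self.failure_mix) - set(FAILURE_MODES)
        if unknown:
            raise ValueError(f"unknown failure modes {sorted(unknown)}")
        if min(self.tau_range) <= 0:
            raise ValueError("temperatures must be positive")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        semi = self._brain_semiaxes_mm()
        max_reach = self.wt_radius_range[1] * (1.0 + 2.5 * self.deformation_amplitude)
        room = semi.min() * (1.0 - self.center_offset_fraction)
        if max_reach > room:
            raise ValueError(
                f"tumor radii do not fit inside the brain mask: maximal reach "
                f"{max_reach:.1f} mm exceeds available room {room:.1f} mm"
            )

    def _brain_semiaxes_mm(self) -> np.ndarray:
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        return self.brain_axes_fraction * extent


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _coords_mm(shape, spacing) -> list[np.ndarray]:
    return [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]


def _smooth_noise(rng: np.random.Generator, shape, spacing, scale_mm: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field, correlation ~ scale_mm."""
    sigma = [scale_mm / s for s in spacing]
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


# --------------------------------------------------------------------------
# phantom
# --------------------------------------------------------------------------

def generate_phantom(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Hierarchical ground-truth labels and brain mask for one subject.

    The three regions are level sets {ρ(x)(1 + a·f(x)) ≤ R_r} of one shared
    radial deformation field f at strictly nested radii, so ET ⊆ TC ⊆ WT
    holds by construction; zero deformation amplitude yields exact nested
    spheres.
    """
    spec.validate()
    shape, spacing = spec.shape, spec.spacing
    semi = spec._brain_semiaxes_mm() * (
        1.0 + rng.uniform(-spec.brain_axes_jitter, spec.brain_axes_jitter, size=3)
    )
    cx, cy, cz = _coords_mm(shape, spacing)
    brain = (
        (cx[:, None, None] / semi[0]) ** 2
        + (cy[None, :, None] / semi[1]) ** 2
        + (cz[None, None, :] / semi[2]) ** 2
    ) <= 1.0

    offset = rng.uniform(-spec.center_offset_fraction, spec.center_offset_fraction, 3) * semi
    r_wt = rng.uniform(*spec.wt_radius_range)
    r_tc = r_wt * rng.uniform(*spec.tc_fraction_range)
    r_et = r_tc * rng.uniform(*spec.et_fraction_range)

    rho = np.sqrt(
        (cx[:, None, None] - offset[0]) ** 2
        + (cy[None, :, None] - offset[1]) ** 2
        + (cz[None, None, :] - offset[2]) ** 2
    )
    if spec.deformation_amplitude > 0:
        f = np.clip(
            _smooth_noise(rng, shape, spacing, spec.deformation_scale_mm), -2.5, 2.5
        )
        rho = rho * (1.0 + spec.deformation_amplitude * f)
    else:
        rng.standard_normal(shape)  # keep the stream aligned across amplitudes

    radii = {"WT": r_wt, "TC": r_tc, "ET": r_et}
    gt = {r: (rho <= radii[r]) & brain for r in spec.regions}
    return gt, brain


# --------------------------------------------------------------------------
# predictor
# --------------------------------------------------------------------------

def simulate_predictor(
    gt: dict[str, np.ndarray],
    brain: np.ndarray,
    spec: CohortSpec,
    rng: np.random.Generator,
    tau: float,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Simulated probabilistic predictions for all regions of one subject.

    Returns (prob maps p̂, predicted labels, ground truth) — in calibration
    mode the returned ground truth is the Bernoulli(p*) redraw that makes
    the latent field perfectly calibrated at τ = 1.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    spacing = spec.spacing
    sigma = [spec.blur_sigma_mm / s for s in spacing]
    noise = None
    amp_range = np.atleast_1d(spec.noise_amplitude)
    amplitude = float(rng.uniform(amp_range[0], amp_range[-1]))
    if spec.mode == "morphology" and amplitude > 0:
        noise = amplitude * _smooth_noise(
            rng, spec.shape, spacing, spec.noise_scale_mm
        )
    prob: dict[str, np.ndarray] = {}
    pred: dict[str, np.ndarray] = {}
    gt_out: dict[str, np.ndarray] = {}
    for region, g in gt.items():
        p_star = ndimage.gaussian_filter(g.astype(float), sigma=sigma)
        np.clip(p_star, 0.0, 1.0, out=p_star)
        p_star[~brain] = 0.0
        if spec.mode == "calibration":
            gt_out[region] = rng.random(spec.shape) < p_star
        else:
            gt_out[region] = g
        logits = logit(np.clip(p_star, EPS, 1.0 - EPS))
        if noise is not None:
            logits = logits + noise
        p_hat = expit(logits / tau).astype(np.float32)
        p_hat[~brain] = 0.0
        prob[region] = p_hat
        pred[region] = (p_hat >= 0.5) & brain
    return prob, pred, gt_out


# --------------------------------------------------------------------------
# failure injection
# --------------------------------------------------------------------------

def inject_failure(
    prob: dict[str, np.ndarray],
    pred: dict[str, np.ndarray],
    gt: dict[str, np.ndarray],
    brain: np.ndarray,
    mode: str,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> dict[str, object]:
    """Corrupt a subject's prediction in place according to a failure mode.

    Returns a provenance record (mode plus mode-specific parameters drawn).
    Predicted labels are recomputed from the corrupted probabilities.
    """
    record: dict[str, object] = {"failure_mode": mode}
    if mode == "clean":
        return record
    shape, spacing = spec.shape, spec.spacing

    if mode == "remote_blob":
        p = spec.remote_blob
        wt = gt.get("WT", next(iter(gt.values())))
        r_eff = (3.0 * wt.sum() * np.prod(spacing) / (4.0 * np.pi)) ** (1.0 / 3.0)
        dist_wt = ndimage.distance_transform_edt(~wt, sampling=spacing)
        dist_out = ndimage.distance_transform_edt(brain, sampling=spacing)
        # Retry with progressively smaller blobs before rejecting: large
        # tumors close to the brain boundary may leave no room at full size.
        candidates = np.empty((0, 3), dtype=int)
        r_blob = 0.0
        for shrink in (1.0, 0.85, 0.7, 0.55):
            r_blob = p.radius_fraction * r_eff * shrink
            feasible = (dist_wt >= p.d_min_mm + r_blob) & (dist_out >= r_blob + 1.0)
            candidates = np.argwhere(feasible)
            if len(candidates) > 0:
                break
        if len(candidates) == 0:
            raise ValueError(
                f"no feasible remote-blob location: blob radius {r_blob:.1f} mm "
                f"with d_min {p.d_min_mm} mm does not fit in the brain mask"
            )
        n_blobs = int(rng.integers(p.n_blobs_range[0], p.n_blobs_range[1] + 1))
        centers = candidates[rng.choice(len(candidates), size=n_blobs, replace=False)]
        detected = np.zeros(shape)  # profile of the detected focus
        undetected = np.zeros(shape, dtype=bool)

        def _dist_from(center_vox: np.ndarray) -> np.ndarray:
            axes = [
                ((np.arange(n) - ci) * s) ** 2
                for n, s, ci in zip(shape, spacing, center_vox)
            ]
            return np.sqrt(
                axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
            )

        r_sat = p.satellite_radius_fraction * r_blob
        for c in centers:
            d = _dist_from(c)
            t = np.clip(d - r_blob, 0.0, None)
            if p.edge_sigma_mm > 0:
                np.maximum(detected, np.exp(-0.5 * (t / p.edge_sigma_mm) ** 2),
                           out=detected)
            else:
                np.maximum(detected, (t == 0).astype(float), out=detected)
            # Missed second focus: an unpredicted satellite next to the
            # detected blob, placed in a direction that keeps it inside the
            # brain and clear of the tumor.
            if r_sat > 0 and p.undetected_prob > 0:
                # search the whole shell at the target offset, shrinking the
                # satellite before giving up
                for r_try in (r_sat, 0.75 * r_sat, 0.55 * r_sat):
                    offset = r_blob + p.satellite_gap_mm + r_try
                    shell = np.abs(d - offset) <= 1.0
                    ok = shell & (dist_out >= r_try + 1.0) & (dist_wt >= r_try + 1.0)
                    sites = np.argwhere(ok)
                    if len(sites) > 0:
                        s_vox = sites[rng.integers(len(sites))]
                        undetected |= _dist_from(s_vox) <= r_try
                        break
        detected[~brain] = 0.0
        undetected &= brain
        speckle = None
        if p.interior_uncertain_fraction > 0:
            speckle = (detected >= 0.999) & (
                rng.random(shape) < p.interior_uncertain_fraction
            )
        for region in prob:
            prob[region] = np.maximum(
                prob[region], (p.confidence * detected).astype(np.float32)
            )
            if p.undetected_prob > 0:
                prob[region][undetected] = np.maximum(
                    prob[region][undetected], np.float32(p.undetected_prob)
                )
            if speckle is not None:
                prob[region][speckle] = 0.5
        record.update(n_blobs=n_blobs, blob_radius_mm=float(r_blob))

    elif mode == "missed_core":
        p = spec.missed_core
        region = p.region if p.region in gt else next(iter(gt))
        target = gt[region]
        if target.any():
            xs = np.argwhere(target)[:, 0]
            cut = np.quantile(xs, p.fraction)
            miss = target & (np.arange(shape[0])[:, None, None] <= cut)
            soft = ndimage.gaussian_filter(
                miss.astype(float), sigma=[p.edge_sigma_mm / s for s in spacing]
            )
            m = soft.max()
            if m > 0:
                soft /= m
            for r in prob:
                if r == region or (r == "ET" and region == "TC"):
                    prob[r] = np.minimum(
                        prob[r],
                        (1.0 - soft * (1.0 - p.suppressed_prob)).astype(np.float32),
                    )
        record.update(missed_region=region, missed_fraction=p.fraction)

    elif mode == "boundary_jitter":
        p = spec.boundary_jitter
        if p.amplitude > 0:
            g = np.clip(_smooth_noise(rng, shape, spacing, p.scale_mm), -2.0, 2.0)
            level = 0.5 + p.amplitude * g
            for region in prob:
                pred[region] = (prob[region] >= level) & brain
            record.update(jitter_amplitude=p.amplitude)
            return record
        return record
    else:
        raise ValueError(f"unknown failure mode {mode!r}")

    for region in prob:
        pred[region] = (prob[region] >= 0.5) & brain
    return record


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def _allocate(n: int, fractions: Sequence[float], labels: Sequence[str]) -> list[str]:
    """Largest-remainder allocation of n items to labelled fractions."""
    raw = np.asarray(fractions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for label, c in zip(labels, counts):
        out.extend([label] * c)
    return out


def generate_subject(
    spec: CohortSpec,
    subject_seed: np.random.SeedSequence,
    subject_id: str,
    split: str,
    failure_mode: str,
) -> tuple[SubjectRecord, dict[str, object]]:
    """One deterministic subject: phantom, prediction, optional corruption."""
    rng = np.random.default_rng(subject_seed)
    gt, brain = generate_phantom(spec, rng)
    log_lo, log_hi = np.log(spec.tau_range[0]), np.log(spec.tau_range[1])
    tau = float(np.exp(rng.uniform(log_lo, log_hi)))
    prob, pred, gt = simulate_predictor(gt, brain, spec, rng, tau)
    provenance = inject_failure(prob, pred, gt, brain, failure_mode, spec, rng)

    record = SubjectRecord(
        subject_id=subject_id,
        spacing=spec.spacing,
        brain_mask=brain,
        gt_labels=gt,
        pred_labels=pred,
        prob_maps={r: np.clip(p.astype(float), 0.0, 1.0) for r, p in prob.items()},
        split=split,
    )
    row: dict[str, object] = {
        "subject_id": subject_id,
        "split": split,
        "tau": tau,
        "failure_mode": failure_mode,
    }
    row.update({k: v for k, v in provenance.items() if k != "failure_mode"})
    for region in spec.regions:
        row[f"true_dice_{region}"] = dice_coefficient(pred[region], gt[region])
    return record, row


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, pd.DataFrame]:
    """Deterministic cohort: a pure function of (spec, master seed).

    Returns the cohort and a manifest with per-subject τ, failure mode and
    true Dice per region.  When ``native_uncertainty`` is on, each subject
    additionally carries a native uncertainty map normalized with
    cohort-global extrema.
    """
    spec.validate()
    if spec.n_subjects < 10:
        warnings.warn(
            f"cohort of {spec.n_subjects} subjects is small for downstream "
            "regression/ROC analyses",
            stacklevel=2,
        )
    root = np.random.SeedSequence(spec.master_seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(spec.n_subjects)

    modes = _allocate(
        spec.n_subjects, list(spec.failure_mix.values()), list(spec.failure_mix.keys())
    )
    assign_rng.shuffle(modes)
    splits = _allocate(
        spec.n_subjects, spec.split_fractions, ["train", "validation", "test"]
    )
    assign_rng.shuffle(splits)

    subjects: list[SubjectRecord] = []
    rows: list[dict[str, object]] = []
    for i in range(spec.n_subjects):
        rec, row = generate_subject(
            spec, subject_seeds[i], f"subj_{i:04d}", splits[i], modes[i]
        )
        subjects.append(rec)
        rows.append(row)

    if spec.native_uncertainty:
        scale_rng = np.random.default_rng(root.spawn(1)[0])
        scales = scale_rng.uniform(0.5, 2.0, size=spec.n_subjects)
        raw = {
            region: [
                s * rec.prob_maps[region] * (1.0 - rec.prob_maps[region])
                for s, rec in zip(scales, subjects)
            ]
            for region in spec.regions
        }
        for region in spec.regions:
            extrema = CohortExtrema.from_volumes(raw[region], region=region)
            for rec, v in zip(subjects, raw[region]):
                maps = rec.uncertainty_maps or {}
                maps[region] = normalize_native_map(v, extrema)
                rec.uncertainty_maps = maps

    manifest = pd.DataFrame(rows)
    return Cohort(subjects, region_set=spec.regions), manifest
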