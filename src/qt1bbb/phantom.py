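"""Digital qT1 phantom: schematic brain with contrast-enhanced sessions.

The phantom is geometric, not anatomical — what matters downstream is
ROI identity, disjointness and adjacency, not shape fidelity.  A head
ellipsoid holds a cortical shell over white matter with a central CSF
blob; hippocampus, amygdala and piriform cortex are paired interior
blobs; the superior sagittal sinus (SSS) is a small blood-filled block
at the superior midline restricted to three consecutive coronal slices,
mirroring how the vascular reference ROI is drawn in practice.  A
smooth, seed-deterministic T1 texture field (zero-mean within every
labelled region) stands in for intra-tissue heterogeneity; without it a
piecewise-constant ellipsoid would leave the rigid pose of the subject
nearly unidentifiable to intensity-based registration.

Geometry is *analytic*: labels and T1 are functions of continuous
coordinates, so a rigidly displaced session is rendered sharply on its
own grid, the way a scanner acquires a moved subject — session
misalignment does not introduce interpolation blur at acquisition time.

Gadolinium is modelled by fast-exchange relaxivity,

.. math::  1/T_{1,post} = 1/T_{1,pre} + r_1 C,

with the vascular compartment at concentration ``c_vasc`` and each
parenchymal ROI at :math:`\\lambda_{roi} \\cdot c_{vasc}` — the leakage
fraction :math:`\\lambda` is the phantom's operationalization of
blood-brain-barrier dysfunction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .registration import RigidTransform
from .relaxometry import QT1Volume

__all__ = [
    "PhantomSpec",
    "ROILabelMap",
    "SessionSet",
    "PARENCHYMAL_ROIS",
    "BILATERAL_ROIS",
    "make_phantom",
    "apply_contrast",
    "simulate_sessions",
]

#: ROI names carrying left/right instances.
BILATERAL_ROIS = ("hippocampus", "amygdala", "piriform")

#: ROIs read out in the analysis (bilateral ones expand to _l/_r labels).
PARENCHYMAL_ROIS = ("cortex",) + BILATERAL_ROIS

#: Integer labels of the phantom label map.
LABELS = {
    "background": 0,
    "cortex": 1,
    "white_matter": 2,
    "csf": 3,
    "hippocampus_l": 4,
    "hippocampus_r": 5,
    "amygdala_l": 6,
    "amygdala_r": 7,
    "piriform_l": 8,
    "piriform_r": 9,
    "sss": 10,
}

#: Tissue name backing each label's baseline T1.
_LABEL_TISSUE = {
    "cortex": "cortex",
    "white_matter": "white_matter",
    "csf": "csf",
    "hippocampus_l": "hippocampus",
    "hippocampus_r": "hippocampus",
    "amygdala_l": "amygdala",
    "amygdala_r": "amygdala",
    "piriform_l": "piriform",
    "piriform_r": "piriform",
    "sss": "blood",
}

#: Baseline longitudinal relaxation times at 3 T (ms).
DEFAULT_TISSUE_T1 = {
    "cortex": 1300.0,
    "white_matter": 850.0,
    "csf": 4000.0,
    "hippocampus": 1350.0,
    "amygdala": 1330.0,
    "piriform": 1320.0,
    "blood": 1650.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one phantom subject.

    ``noise_sd`` is the voxel noise standard deviation as a fraction of
    the local T1 value; ``perturb_translation_mm`` /
    ``perturb_rotation_deg`` bound the random rigid misalignment of each
    post-contrast session.  Leakage fractions are per-session
    dictionaries mapping ROI name (``cortex``, ``hippocampus``,
    ``amygdala``, ``piriform``) to lambda in [0, 1].
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    tissue_t1: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_T1))
    r1: float = 5.0  # L mmol^-1 s^-1, gadobutrol at 3 T
    c_vasc_interictal: float = 0.5  # mmol/L at scan time
    c_vasc_postictal: float = 0.5
    leakage_interictal: dict = field(default_factory=dict)
    leakage_postictal: dict = field(default_factory=dict)
    noise_sd: float = 0.01
    perturb_translation_mm: float = 2.0
    perturb_rotation_deg: float = 2.0
    texture_sd: float = 0.04
    texture_smoothness: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 32 for s in self.shape):
            raise ValueError(f"grid {self.shape} too small to host all ROIs (min 32)")
        if any(t <= 0 for t in self.tissue_t1.values()):
            raise ValueError("all tissue T1 values must be positive")
        if self.r1 <= 0:
            raise ValueError("relaxivity r1 must be positive")
        for lam in (self.leakage_interictal, self.leakage_postictal):
            for roi, v in lam.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"leakage fraction for {roi!r} must lie in [0,1], got {v}")

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])


@dataclass
class ROILabelMap:
    """Integer-labelled volume with a name->label dictionary."""

    data: np.ndarray
    labels: dict[str, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of one named ROI.

        Bare bilateral names ('hippocampus') return the union of the
        left and right labels.
        """
        if name in self.labels:
            return self.data == self.labels[name]
        if name in BILATERAL_ROIS:
            return (self.data == self.labels[f"{name}_l"]) | (
                self.data == self.labels[f"{name}_r"]
            )
        raise KeyError(f"unknown ROI {name!r}; have {sorted(self.labels)}")

    def roi_names(self) -> list[str]:
        return [n for n in self.labels if n != "background"]


# ---------------------------------------------------------------- geometry


def _labels_at(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Evaluate the label geometry at canonical-frame voxel coordinates.

    ``pts`` has shape (..., 3); the result carries the leading shape.
    Later assignments overwrite earlier ones, so nested structures carve
    their hosts and the labels are disjoint by construction.
    """
    shape = spec.shape
    nx, ny, nz = shape
    c = np.array(shape, dtype=float) / 2.0 - 0.5
    scale = min(shape) / 64.0
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    lab = np.zeros(pts.shape[:-1], dtype=np.int16)

    def inside(center, radii):
        return (
            ((x - center[0]) / radii[0]) ** 2
            + ((y - center[1]) / radii[1]) ** 2
            + ((z - center[2]) / radii[2]) ** 2
        ) <= 1.0

    head_r = np.array([0.44 * nx, 0.47 * ny, 0.42 * nz])
    lab[inside(c, head_r)] = LABELS["cortex"]
    lab[inside(c, head_r * 0.82)] = LABELS["white_matter"]
    lab[inside(c, head_r * 0.16)] = LABELS["csf"]

    def blob(name, offset_vox, radius_vox):
        center = c + np.array(offset_vox) * scale
        # radius floor keeps every ROI >= 30 voxels down to 32^3 grids
        r = max(radius_vox * scale, 2.0)
        lab[inside(center, (r, r, r))] = LABELS[name]

    # paired medial temporal blobs; x is left-right, y anterior-posterior,
    # z inferior-superior
    blob("hippocampus_l", (-11, 3, -7), 4.2)
    blob("hippocampus_r", (+11, 3, -7), 4.2)
    blob("amygdala_l", (-12, -5, -8), 3.2)
    blob("amygdala_r", (+12, -5, -8), 3.2)
    blob("piriform_l", (-16, -2, -10), 3.0)
    blob("piriform_r", (+16, -2, -10), 3.0)

    # SSS: superior midline block on exactly 3 consecutive coronal (y) slices
    x0, y0 = round(c[0]), round(c[1])
    z_top = round(c[2] + 0.40 * nz * 0.95)
    rx_, ry_, rz_ = np.rint(x), np.rint(y), np.rint(z)
    sss = (
        (np.abs(rx_ - x0) <= 1)
        & (np.abs(ry_ - y0) <= 1)
        & (rz_ >= z_top - 3)
        & (rz_ <= z_top)
    )
    lab[sss] = LABELS["sss"]
    return lab


def _identity_grid(shape) -> np.ndarray:
    axes = [np.arange(s, dtype=float) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _texture_grid(spec: PhantomSpec, canonical_labels: np.ndarray) -> np.ndarray:
    """Smooth unit-SD noise field, demeaned within every labelled region."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    tex = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.texture_smoothness)
    tex /= tex.std()
    for val in np.unique(canonical_labels):
        if val == 0:
            continue
        m = canonical_labels == val
        tex[m] -= tex[m].mean()
    return tex


def _t1_lookup(spec: PhantomSpec) -> np.ndarray:
    table = np.zeros(max(LABELS.values()) + 1)
    for name, val in LABELS.items():
        if name != "background":
            table[val] = spec.tissue_t1[_LABEL_TISSUE[name]]
    return table


def _render(
    spec: PhantomSpec,
    pts: np.ndarray,
    tex: np.ndarray,
    conc_by_label: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and (optionally contrast-enhanced) T1 at the given coords."""
    lab = _labels_at(spec, pts)
    t1 = _t1_lookup(spec)[lab]
    if spec.texture_sd > 0:
        tex_at = ndimage.map_coordinates(
            tex, np.moveaxis(pts, -1, 0), order=1, mode="nearest"
        )
        t1 = t1 * (1.0 + spec.texture_sd * tex_at)
    if conc_by_label is not None:
        conc = conc_by_label[lab]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(conc > 0, 1.0 / (1.0 / t1 + spec.r1 / 1000.0 * conc), t1)
    t1 = np.where(lab > 0, t1, np.nan)
    return lab, t1


def make_phantom(spec: PhantomSpec) -> tuple[ROILabelMap, QT1Volume]:
    """Build the label map and the noiseless baseline T1 volume.

    Deterministic given ``spec.seed``.  Raises ``ValueError`` if any
    named ROI ends up with fewer than 30 voxels.
    """
    pts = _identity_grid(spec.shape)
    canonical = _labels_at(spec, pts)
    label_map = ROILabelMap(canonical, dict(LABELS), spec.affine)
    for name in label_map.roi_names():
        n = int(label_map.mask(name).sum())
        if n < 30:
            raise ValueError(f"grid {spec.shape} too small: ROI {name!r} has only {n} voxels")
    tex = _texture_grid(spec, canonical)
    _, t1 = _render(spec, pts, tex)
    return label_map, QT1Volume(t1, spec.affine, "noncontrast", canonical > 0)


def apply_contrast(t1_pre: QT1Volume, concentration: np.ndarray, r1: float) -> QT1Volume:
    """Shorten T1 by gadolinium at the given concentration map (mmol/L).

    Fast-exchange relaxivity: R1_post = R1_pre + r1*C with r1 in
    L mmol^-1 s^-1 converted to per-ms internally.  T1 never increases;
    zero concentration is the identity.
    """
    concentration = np.asarray(concentration, dtype=float)
    if concentration.shape != t1_pre.t1_map.shape:
        raise ValueError("concentration map shape mismatch")
    if np.any(concentration < 0):
        raise ValueError("concentration must be non-negative everywhere")
    r1_per_ms = r1 / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_post = 1.0 / t1_pre.t1_map + r1_per_ms * concentration
        t1_post = np.where(concentration > 0, 1.0 / r1_post, t1_pre.t1_map)
    t1_post = np.where(t1_pre.mask, t1_post, np.nan)
    return QT1Volume(t1_post, t1_pre.affine.copy(), t1_pre.session, t1_pre.mask.copy())


def _conc_by_label(spec: PhantomSpec, c_vasc: float, leakage: dict) -> np.ndarray:
    conc = np.zeros(max(LABELS.values()) + 1)
    conc[LABELS["sss"]] = c_vasc
    for roi, lam in leakage.items():
        if roi in BILATERAL_ROIS:
            conc[LABELS[f"{roi}_l"]] = conc[LABELS[f"{roi}_r"]] = lam * c_vasc
        elif roi in LABELS:
            conc[LABELS[roi]] = lam * c_vasc
        else:
            raise ValueError(f"unknown leakage ROI {roi!r}")
    return conc


@dataclass
class SessionSet:
    """Three simulated sessions plus the noiseless ground truth."""

    labels: ROILabelMap
    noncontrast: QT1Volume
    interictal: QT1Volume
    postictal: QT1Volume
    #: per-ROI noiseless mean raw delta-qT1 (ms), keyed (kind, roi)
    truth: dict[tuple[str, str], float]
    #: rigid pose of each post-contrast session relative to noncontrast
    applied_transforms: dict[str, RigidTransform]

    def volume(self, session: str) -> QT1Volume:
        return {"noncontrast": self.noncontrast, "interictal": self.interictal,
                "postictal": self.postictal}[session]


def _add_noise(vol: QT1Volume, noise_sd: float, rng: np.random.Generator) -> QT1Volume:
    if noise_sd <= 0:
        return vol
    noisy = vol.t1_map * (1.0 + rng.normal(0.0, noise_sd, vol.t1_map.shape))
    noisy = np.where(vol.mask, np.maximum(noisy, 1.0), np.nan)
    return QT1Volume(noisy, vol.affine.copy(), vol.session, vol.mask.copy())


def _random_rigid(spec: PhantomSpec, center: np.ndarray,
                  rng: np.random.Generator) -> RigidTransform:
    t = rng.uniform(-spec.perturb_translation_mm, spec.perturb_translation_mm, 3)
    r = rng.uniform(-spec.perturb_rotation_deg, spec.perturb_rotation_deg, 3)
    return RigidTransform(tuple(r), tuple(t), tuple(center))


def simulate_sessions(spec: PhantomSpec) -> SessionSet:
    """Simulate the three qT1 sessions of one phantom subject.

    The noncontrast session is the baseline phantom plus noise.  Each
    post-contrast session adds vascular plus leakage gadolinium and is
    rendered analytically in a randomly displaced pose (sharp on its own
    grid, like a real acquisition of a moved subject), then voxel noise
    is added.  Ground truth records the noiseless, canonical-frame
    per-ROI mean raw delta-qT1 for both map kinds including the SSS
    reference deltas.
    """
    labels, baseline = make_phantom(spec)
    tex = _texture_grid(spec, labels.data)
    rng = np.random.default_rng(spec.seed)
    pts = _identity_grid(spec.shape)

    conc_ii = _conc_by_label(spec, spec.c_vasc_interictal, spec.leakage_interictal)
    conc_pi = _conc_by_label(spec, spec.c_vasc_postictal, spec.leakage_postictal)
    # canonical-frame (unperturbed) enhanced volumes for the ground truth
    _, t1_ii_canon = _render(spec, pts, tex, conc_ii)
    _, t1_pi_canon = _render(spec, pts, tex, conc_pi)

    truth: dict[tuple[str, str], float] = {}
    rois = list(PARENCHYMAL_ROIS) + [f"{r}_{s}" for r in BILATERAL_ROIS for s in "lr"] + ["sss"]
    for roi in rois:
        m = labels.mask(roi)
        truth[("ni", roi)] = float(np.mean(baseline.t1_map[m] - t1_ii_canon[m]))
        truth[("ip", roi)] = float(np.mean(t1_ii_canon[m] - t1_pi_canon[m]))

    center = (spec.affine @ np.append((np.array(spec.shape) - 1) / 2.0, 1.0))[:3]
    perturbed = spec.perturb_translation_mm > 0 or spec.perturb_rotation_deg > 0
    sessions = {}
    transforms = {}
    for name, conc in (("interictal", conc_ii), ("postictal", conc_pi)):
        if perturbed:
            xf = _random_rigid(spec, center, rng)
            # acquired voxel i samples tissue at X^-1 A i (subject moved by X)
            inv_m = np.linalg.inv(spec.affine) @ xf.inverse().as_matrix() @ spec.affine
            moved = pts @ inv_m[:3, :3].T + inv_m[:3, 3]
            _, t1 = _render(spec, moved, tex, conc)
        else:
            xf = RigidTransform(center=tuple(center))
            t1 = t1_ii_canon if name == "interictal" else t1_pi_canon
        sessions[name] = QT1Volume(t1, spec.affine, name, np.isfinite(t1))
        transforms[name] = xf

    nc = _add_noise(baseline, spec.noise_sd, rng)
    ii = _add_noise(sessions["interictal"], spec.noise_sd, rng)
    pi = _add_noise(sessions["postictal"], spec.noise_sd, rng)
    return SessionSet(labels, nc, ii, pi, truth, transforms)


def sessions_to_vfa(
    ses: SessionSet,
    acq=None,
    m0: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Emit raw variable-flip-angle signal stacks for each session.

    Instead of handing T1 maps directly to the pipeline, forward-model
    the SPGR signals each session would have produced (uniform M0;
    optional additive signal noise), so the route through the
    relaxometry fit can be exercised end to end:
    ``fit_t1_despot1(vfa["interictal"])`` recovers the session's T1 map.
    """
    from .relaxometry import AcquisitionParams, simulate_vfa_series

    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    out = {}
    for name in ("noncontrast", "interictal", "postictal"):
        vol = ses.volume(name)
        t1 = np.where(vol.mask, vol.t1_map, 1.0)  # placeholder under mask
        series = simulate_vfa_series(t1, m0, acq, affine=vol.affine,
                                     noise_sd=noise_sd, rng=rng)
        for v in series.volumes:
            v[~vol.mask] = 0.0  # background carries no signal
        out[name] = series
    return out
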