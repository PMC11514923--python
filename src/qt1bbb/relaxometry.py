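"""Variable flip angle (VFA / DESPOT1) T1 relaxometry.

The spoiled gradient-recalled echo (SPGR) steady-state signal at flip
angle :math:`\\alpha` is

.. math::

    S(\\alpha) = M_0 \\sin\\alpha \\, \\frac{1 - E_1}{1 - E_1\\cos\\alpha},
    \\qquad E_1 = e^{-TR/T_1}.

Acquiring the same volume at two or more flip angles and plotting
:math:`S/\\sin\\alpha` against :math:`S/\\tan\\alpha` gives a line with
slope :math:`E_1` and intercept :math:`M_0(1-E_1)`, so T1 and the
equilibrium signal M0 follow from an ordinary least-squares line per
voxel.  T2*/TE weighting is a constant multiplier at fixed TE and is
absorbed into M0; B1 inhomogeneity is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionParams",
    "SPGRParams",
    "VFASeries",
    "QT1Volume",
    "DEFAULT_FLIP_ANGLES",
    "DEFAULT_PLAUSIBILITY_WINDOW",
    "spgr_signal",
    "fit_t1_despot1",
    "ernst_angle",
]

#: Default 4-angle schedule (degrees).  Spans the Ernst angle of ~1000 ms
#: tissue at TR = 16.4 ms (about 10.4 deg), giving good slope leverage for
#: grey/white matter T1 at 3 T.
DEFAULT_FLIP_ANGLES: tuple[float, ...] = (4.0, 10.0, 18.0, 25.0)

#: T1 plausibility window in ms; fitted values outside are flagged invalid.
DEFAULT_PLAUSIBILITY_WINDOW: tuple[float, float] = (50.0, 10000.0)


@dataclass(frozen=True)
class AcquisitionParams:
    """Spoiled gradient-echo acquisition parameters.

    Parameters
    ----------
    repetition_time : float
        TR in milliseconds, > 0.
    echo_time : float
        TE in milliseconds.  Carried as metadata only: at fixed TE the
        T2* decay is a constant factor absorbed into M0.
    flip_angles : tuple of float
        Nominal excitation angles in degrees; at least two, pairwise
        distinct, each in (0, 90].
    """

    repetition_time: float = 16.4
    echo_time: float = 6.7
    flip_angles: tuple[float, ...] = DEFAULT_FLIP_ANGLES

    def __post_init__(self) -> None:
        if not np.isfinite(self.repetition_time) or self.repetition_time <= 0:
            raise ValueError(f"repetition_time must be positive, got {self.repetition_time}")
        angles = tuple(float(a) for a in self.flip_angles)
        if len(angles) < 2:
            raise ValueError("at least two flip angles are required")
        if len(set(angles)) != len(angles):
            raise ValueError(f"flip angles must be pairwise distinct, got {angles}")
        if any(not (0.0 < a <= 90.0) for a in angles):
            raise ValueError(f"flip angles must lie in (0, 90] degrees, got {angles}")
        object.__setattr__(self, "flip_angles", angles)


@dataclass(frozen=True)
class SPGRParams:
    """Tissue/voxel parameters of the SPGR signal model.

    ``m0`` is the equilibrium signal amplitude (arbitrary units, >= 0)
    and ``t1`` the longitudinal relaxation time in ms (> 0).
    """

    m0: float
    t1: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.m0) or self.m0 < 0:
            raise ValueError(f"m0 must be finite and non-negative, got {self.m0}")
        if not np.isfinite(self.t1) or self.t1 <= 0:
            raise ValueError(f"t1 must be finite and positive, got {self.t1}")

    def e1(self, repetition_time: float) -> float:
        """Longitudinal recovery factor exp(-TR/T1), in (0, 1)."""
        return float(np.exp(-repetition_time / self.t1))


@dataclass
class VFASeries:
    """A stack of SPGR magnitude volumes, one per flip angle.

    All volumes share one shape, one affine and one TR.
    """

    volumes: list[np.ndarray]
    params: AcquisitionParams
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.params.flip_angles):
            raise ValueError(
                f"{len(self.volumes)} volumes for {len(self.params.flip_angles)} flip angles"
            )
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError(f"volumes must share one shape, got {sorted(shapes)}")
        self.volumes = [np.asarray(v, dtype=float) for v in self.volumes]
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape


@dataclass
class QT1Volume:
    """A voxelwise T1 map (ms) with a validity mask and session label."""

    t1_map: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    session: str = "noncontrast"
    mask: np.ndarray | None = None

    SESSIONS = ("noncontrast", "interictal", "postictal")

    def __post_init__(self) -> None:
        self.t1_map = np.asarray(self.t1_map, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.session not in self.SESSIONS:
            raise ValueError(f"session must be one of {self.SESSIONS}, got {self.session!r}")
        if self.mask is None:
            self.mask = np.isfinite(self.t1_map) & (self.t1_map > 0)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.t1_map.shape:
            raise ValueError("mask and t1_map must share shape")

    def with_session(self, session: str) -> "QT1Volume":
        return QT1Volume(self.t1_map.copy(), self.affine.copy(), session, self.mask.copy())


def spgr_signal(
    p: SPGRParams,
    acq: AcquisitionParams,
    angle: float | np.ndarray,
) -> float | np.ndarray:
    """SPGR steady-state signal amplitude at flip angle ``angle`` (degrees).

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)), E1 = exp(-TR/T1).

    Raises ``ValueError`` for angles outside (0, 180).
    """
    angle = np.asarray(angle, dtype=float)
    if np.any(angle <= 0.0) or np.any(angle >= 180.0):
        raise ValueError("flip angle must lie strictly within (0, 180) degrees")
    a = np.deg2rad(angle)
    e1 = p.e1(acq.repetition_time)
    s = p.m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    return float(s) if s.ndim == 0 else s


def ernst_angle(t1: float, repetition_time: float) -> float:
    """Flip angle (degrees) maximizing the SPGR signal: arccos(E1)."""
    return float(np.rad2deg(np.arccos(np.exp(-repetition_time / t1))))


def simulate_vfa_series(
    t1_map: np.ndarray,
    m0_map: np.ndarray | float,
    acq: AcquisitionParams,
    affine: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VFASeries:
    """Forward-simulate an SPGR volume stack from T1/M0 maps.

    ``noise_sd`` is additive Gaussian noise on magnitude in the units of
    M0 (high-SNR approximation of Rician noise); negative noisy samples
    are clipped at zero to keep magnitudes physical.
    """
    t1_map = np.asarray(t1_map, dtype=float)
    m0_map = np.broadcast_to(np.asarray(m0_map, dtype=float), t1_map.shape)
    if np.any(t1_map <= 0):
        raise ValueError("t1_map must be strictly positive")
    e1 = np.exp(-acq.repetition_time / t1_map)
    vols = []
    for angle in acq.flip_angles:
        a = np.deg2rad(angle)
        s = m0_map * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            s = np.clip(s + rng.normal(0.0, noise_sd, s.shape), 0.0, None)
        vols.append(s)
    return VFASeries(vols, acq, np.eye(4) if affine is None else affine)


def fit_t1_despot1(
    series: VFASeries,
    plausibility_window: tuple[float, float] = DEFAULT_PLAUSIBILITY_WINDOW,
    session: str = "noncontrast",
) -> tuple[QT1Volume, np.ndarray]:
    """Voxelwise DESPOT1 fit of T1 and M0 from a variable-flip-angle series.

    Linearizes S/sin(a) = E1 * S/tan(a) + M0 (1 - E1) and fits the line
    by least squares per voxel (the exact two-point solution when only
    two angles were acquired).  Voxels with any non-positive signal, a
    slope outside (0, 1), or fitted T1 outside ``plausibility_window``
    are flagged invalid in the returned mask; their T1 is set to NaN.

    Returns
    -------
    (QT1Volume, ndarray)
        The T1 map with validity mask, and the M0 map.
    """
    lo, hi = plausibility_window
    if not (0 < lo < hi):
        raise ValueError(f"invalid plausibility window {plausibility_window}")
    acq = series.params
    tr = acq.repetition_time
    angles = np.deg2rad(np.asarray(acq.flip_angles))
    sig = np.stack(series.volumes, axis=0)  # (n_angles, *shape)
    shape = series.shape

    valid = np.all(sig > 0, axis=0)

    sin_a = np.sin(angles).reshape((-1,) + (1,) * len(shape))
    tan_a = np.tan(angles).reshape((-1,) + (1,) * len(shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        y = sig / sin_a
        x = sig / tan_a
    # per-voxel least-squares line y = slope*x + intercept
    n = float(len(angles))
    sx = x.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    denom = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n

    valid &= np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = -tr / np.log(slope)
        m0 = intercept / (1.0 - slope)
    valid &= np.isfinite(t1) & (t1 >= lo) & (t1 <= hi)

    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)
    vol = QT1Volume(t1, series.affine, session=session, mask=valid)
    return vol, m0
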