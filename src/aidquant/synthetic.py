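"""Seeded synthetic microscopy data with known ground truth.

Every downstream stage of the pipeline (punctum quantification, kinetics
fitting, longitudinal in-vivo tracking, histology ratios) is testable against
scenes generated here, because each rendered object carries an exact
ground-truth record: its kinetic parameters, its position at every frame, and
the inter-session transforms that moved it.

The degradation model is a two-pool exponential: after the inducer is added
at time ``t_inducer`` a fraction ``f_major`` of the tagged protein decays
with time constant ``tau_major`` and the remainder with ``tau_minor``;
before the inducer the signal is flat.  An optional washout phase recovers
the signal toward its pre-treatment amplitude with a saturating exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import TimeLapseStack

__all__ = [
    "KineticsSpec",
    "PunctumSpec",
    "SomaSpec",
    "SceneSpec",
    "InVivoSpec",
    "GroundTruth",
    "simulate_decay_traces",
    "simulate_culture_movie",
    "simulate_invivo_sessions",
    "simulate_histology_fov",
    "correlated_amplitudes",
]


# --------------------------------------------------------------------------
# kinetic model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsSpec:
    """Two-pool exponential decay of one fluorescent object.

    ``amplitude`` is the constant pre-inducer fluorescence (a.u.).
    ``f_major`` is the fraction of signal in the major pool, decaying with
    ``tau_major`` hours; the remaining ``1 - f_major`` decays with
    ``tau_minor`` hours.  ``t_inducer`` is the clock time (hours) of inducer
    addition.  If ``t_washout`` and ``recovery_tau`` are set, the signal
    recovers toward ``amplitude`` after washout with that time constant.
    """

    amplitude: float = 1.0
    f_major: float = 1.0
    tau_major: float = 3.7
    tau_minor: float = 37.0
    t_inducer: float = 0.0
    t_washout: float | None = None
    recovery_tau: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_major <= 1.0:
            raise ValueError("f_major must lie in [0, 1]")
        if self.tau_major <= 0 or self.tau_minor <= 0:
            raise ValueError("time constants must be strictly positive")
        if self.t_washout is not None and self.recovery_tau is None:
            raise ValueError("t_washout requires recovery_tau")
        if self.recovery_tau is not None and self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be strictly positive")

    def value(self, times_h) -> np.ndarray:
        """Noiseless fluorescence at the given clock times (hours)."""
        t = np.asarray(times_h, dtype=float)
        out = np.full(t.shape, self.amplitude, dtype=float)
        post = t >= self.t_inducer
        dt = t[post] - self.t_inducer
        decayed = self.amplitude * (
            self.f_major * np.exp(-dt / self.tau_major)
            + (1.0 - self.f_major) * np.exp(-dt / self.tau_minor)
        )
        out[post] = decayed
        if self.t_washout is not None:
            rec = t >= self.t_washout
            dw = max(self.t_washout - self.t_inducer, 0.0)
            v_w = self.amplitude * (
                self.f_major * math.exp(-dw / self.tau_major)
                + (1.0 - self.f_major) * math.exp(-dw / self.tau_minor)
            )
            dtr = t[rec] - self.t_washout
            out[rec] = self.amplitude + (v_w - self.amplitude) * np.exp(
                -dtr / self.recovery_tau
            )
        return out


def simulate_decay_traces(
    spec: KineticsSpec,
    times_h,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_traces: int = 1,
) -> tuple[pd.DataFrame, "GroundTruth"]:
    """Sample (possibly noisy) decay traces from a kinetic model.

    Returns a long-format table with columns ``trace_id, time_h, value``
    and a :class:`GroundTruth` whose ``kinetics`` table holds the exact
    model parameters and noiseless values.
    """
    times = np.asarray(times_h, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not np.any(times < spec.t_inducer):
        raise ValueError("at least one time point must precede the inducer")

    rng = np.random.default_rng(seed)
    clean = spec.value(times)
    rows = []
    for i in range(n_traces):
        noisy = clean + rng.normal(0.0, noise_sd, size=times.size) \
            if noise_sd > 0 else clean.copy()
        rows.append(
            pd.DataFrame(
                {"trace_id": i, "time_h": times, "value": noisy}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(
        kinetics=pd.DataFrame(
            {
                "trace_id": np.arange(n_traces),
                "amplitude": spec.amplitude,
                "f_major": spec.f_major,
                "tau_major": spec.tau_major,
                "tau_minor": spec.tau_minor,
                "t_inducer": spec.t_inducer,
            }
        ),
        clean_traces=pd.DataFrame({"time_h": times, "value": clean}),
        seed=seed,
    )
    return table, truth


# --------------------------------------------------------------------------
# culture movie scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PunctumSpec:
    """One synaptic punctum: position, per-channel kinetics, event times."""

    position: tuple[int, int]                 # (row, col), 0-based
    kinetics: dict[str, KineticsSpec]
    appear_time_h: float | None = None        # None = present from start
    disappear_time_h: float | None = None     # None = never disappears

    def present_at(self, t: float) -> bool:
        if self.appear_time_h is not None and t < self.appear_time_h:
            return False
        if self.disappear_time_h is not None and t >= self.disappear_time_h:
            return False
        return True


@dataclass(frozen=True)
class SomaSpec:
    """Cytosolic somatic pool rendered as a uniform disk."""

    center: tuple[int, int]
    radius_px: float
    kinetics: dict[str, KineticsSpec]


@dataclass
class SceneSpec:
    """Full description of a synthetic culture movie.

    Puncta are rendered as isotropic 2-D Gaussians (``psf_sigma_px``) on
    their brightest z-plane with a Gaussian axial falloff
    (``z_sigma_planes``).  Noise is Poisson(signal * gain) / gain plus
    additive Gaussian; both terms are optional.  Photobleaching multiplies
    every channel by ``exp(-bleach_rate * frame_index)`` (off by default —
    sparse sampling is the usual mitigation, but bleaching must be
    simulable).
    """

    shape: tuple[int, int] = (128, 128)
    n_z: int = 3
    z_step_um: float = 0.8
    channels: tuple[str, ...] = ("target",)
    times_h: tuple[float, ...] = tuple(float(t) for t in range(-2, 17))
    t_inducer: float = 0.0
    puncta: list[PunctumSpec] = field(default_factory=list)
    somata: list[SomaSpec] = field(default_factory=list)
    background: dict[str, float] = field(default_factory=dict)
    psf_sigma_px: float = 1.5
    z_sigma_planes: float = 1.0
    poisson_gain: float | None = None
    gaussian_sd: float = 0.0
    bleach_rate: float = 0.0
    mixing_matrix: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        for p in self.puncta:
            r, c = p.position
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"punctum at {p.position} outside {self.shape}")
            missing = set(p.kinetics) - set(self.channels)
            if missing:
                raise ValueError(f"punctum kinetics for unknown channels {missing}")
        if self.mixing_matrix is not None:
            m = np.asarray(self.mixing_matrix, dtype=float)
            n = len(self.channels)
            if m.shape != (n, n):
                raise ValueError("mixing matrix must be square, one row per channel")
            if abs(np.linalg.det(m)) < 1e-12:
                raise ValueError("mixing matrix is singular")


@dataclass
class GroundTruth:
    """Exact truth for every rendered object in a synthetic scene."""

    kinetics: pd.DataFrame | None = None       # per-object model parameters
    clean_traces: pd.DataFrame | None = None   # noiseless values per time
    tracks: pd.DataFrame | None = None         # punctum_id, time_h, row, col, present
    mixing_matrix: np.ndarray | None = None
    nuclei: pd.DataFrame | None = None         # cell_id, session, row, col
    transforms: list[np.ndarray] | None = None  # 2x3 (row,col) affines per session
    masks: dict[str, np.ndarray] | None = None
    seed: int | None = None


def _render_gaussian(img: np.ndarray, row: float, col: float,
                     peak: float, sigma: float) -> None:
    """Add an isotropic 2-D Gaussian with given peak height, in place."""
    if peak == 0.0:
        return
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += peak * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma**2)
    )


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def simulate_culture_movie(
    spec: SceneSpec,
) -> tuple[TimeLapseStack, GroundTruth]:
    """Render a culture movie and its ground truth.

    The noiseless peak pixel of a punctum on its brightest plane equals its
    kinetic value plus the channel background at each frame; re-running with
    the same seed reproduces the stack bit-exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    n_t, n_c = len(spec.times_h), len(spec.channels)
    pixels = np.zeros((n_t, spec.n_z, n_c, h, w), dtype=float)
    z_best = spec.n_z // 2

    track_rows = []
    kin_rows = []
    for pid, p in enumerate(spec.puncta):
        for ch, k in p.kinetics.items():
            kin_rows.append(
                {
                    "punctum_id": pid,
                    "channel": ch,
                    "amplitude": k.amplitude,
                    "f_major": k.f_major,
                    "tau_major": k.tau_major,
                    "tau_minor": k.tau_minor,
                    "t_inducer": k.t_inducer,
                }
            )

    for ti, t in enumerate(spec.times_h):
        bleach = math.exp(-spec.bleach_rate * ti)
        for ci, ch in enumerate(spec.channels):
            for zi in range(spec.n_z):
                plane = pixels[ti, zi, ci]
                plane += spec.background.get(ch, 0.0)
                axial = math.exp(
                    -((zi - z_best) ** 2) / (2.0 * spec.z_sigma_planes**2)
                )
                for p in spec.puncta:
                    if ch not in p.kinetics or not p.present_at(t):
                        continue
                    val = float(p.kinetics[ch].value(np.array([t]))[0])
                    _render_gaussian(
                        plane, p.position[0], p.position[1],
                        val * axial * bleach, spec.psf_sigma_px,
                    )
                for s in spec.somata:
                    if ch not in s.kinetics:
                        continue
                    val = float(s.kinetics[ch].value(np.array([t]))[0])
                    plane[_disk_mask(spec.shape, s.center, s.radius_px)] += (
                        val * axial * bleach
                    )
        for pid, p in enumerate(spec.puncta):
            track_rows.append(
                {
                    "punctum_id": pid,
                    "time_h": t,
                    "row": p.position[0],
                    "col": p.position[1],
                    "present": p.present_at(t),
                }
            )

    if spec.mixing_matrix is not None:
        m = np.asarray(spec.mixing_matrix, dtype=float)
        # observed = M @ true, applied across the channel axis
        pixels = np.einsum("ij,tzjyx->tziyx", m, pixels)

    if spec.poisson_gain is not None:
        gain = spec.poisson_gain
        pixels = rng.poisson(np.clip(pixels, 0, None) * gain) / gain
    if spec.gaussian_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.gaussian_sd, size=pixels.shape)

    stack = TimeLapseStack(
        pixels=pixels,
        timestamps_h=np.asarray(spec.times_h, dtype=float),
        channel_names=list(spec.channels),
        z_step_um=spec.z_step_um,
        inducer_time_h=spec.t_inducer,
    )
    truth = GroundTruth(
        kinetics=pd.DataFrame(kin_rows) if kin_rows else None,
        tracks=pd.DataFrame(track_rows) if track_rows else None,
        mixing_matrix=(
            None if spec.mixing_matrix is None
            else np.asarray(spec.mixing_matrix, dtype=float)
        ),
        seed=spec.seed,
    )
    return stack, truth


def correlated_amplitudes(
    n: int,
    rho: float,
    mean_a: float = 100.0,
    mean_b: float = 50.0,
    cv: float = 0.25,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired per-punctum amplitudes with Pearson correlation ``rho``.

    Used to give a reporter channel a specified correlation with the target
    channel across a population of synapses.  Bivariate normal with a small
    coefficient of variation, clipped at a small positive floor.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    a = mean_a * (1.0 + cv * z[:, 0])
    b = mean_b * (1.0 + cv * z[:, 1])
    return np.clip(a, 1e-3, None), np.clip(b, 1e-3, None)


# --------------------------------------------------------------------------
# in-vivo sessions
# --------------------------------------------------------------------------

@dataclass
class InVivoSpec:
    """Longitudinal two-photon-style sessions of nuclear + cytosolic signal.

    Each session is a small z-stack with a nuclear-reference channel
    (constant across sessions — the stable marker) and a cytosolic signal
    channel following per-cell kinetics.  Sessions after the first are
    related to the first by a translation plus mild affine jitter; the exact
    transforms are stored in the ground truth.
    """

    shape: tuple[int, int] = (256, 256)
    n_z: int = 5
    z_step_um: float = 2.0
    session_times_h: tuple[float, ...] = (-1.0, -0.5, 1.0, 3.0, 6.0, 9.0,
                                          24.0, 48.0, 72.0)
    n_nuclei: int = 40
    nucleus_radius_px: float = 5.0
    cyto_outer_radius_px: float = 9.0
    nuclear_intensity: float = 100.0
    cyto_kinetics: KineticsSpec = field(
        default_factory=lambda: KineticsSpec(
            amplitude=80.0, f_major=0.9, tau_major=1.6, tau_minor=16.0,
            t_inducer=0.0, t_washout=9.0, recovery_tau=24.0,
        )
    )
    translation_sd_px: float = 4.0
    max_translation_px: float = 10.0
    rotation_sd_deg: float = 1.0
    scale_sd: float = 0.005
    gaussian_sd: float = 0.0
    poisson_gain: float | None = None
    seed: int = 0


def _affine_from(rot_deg: float, scale: float, shift: np.ndarray,
                 center: np.ndarray) -> np.ndarray:
    """2x3 (row, col) affine rotating/scaling about ``center`` then shifting."""
    th = math.radians(rot_deg)
    lin = scale * np.array(
        [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
    )
    off = center - lin @ center + shift
    return np.hstack([lin, off[:, None]])


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 2x3 (row, col) affine to an (n, 2) point array."""
    pts = np.asarray(points, dtype=float)
    return pts @ matrix[:, :2].T + matrix[:, 2]


def simulate_invivo_sessions(
    spec: InVivoSpec,
) -> tuple[list[TimeLapseStack], GroundTruth]:
    """Render per-session z-stacks plus exact centroids and transforms.

    Channel 0 is the nuclear reference (uniform disks of constant
    intensity), channel 1 the cytosolic signal (uniform annulus around each
    nucleus whose value follows ``cyto_kinetics``).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    margin = spec.cyto_outer_radius_px + spec.max_translation_px + 8
    # rejection-sample nucleus centres so annuli never overlap
    centers: list[np.ndarray] = []
    min_dist = 2 * spec.cyto_outer_radius_px + 2
    attempts = 0
    while len(centers) < spec.n_nuclei:
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 20000:
            raise ValueError("could not place nuclei; reduce n_nuclei or radius")
    ref_centers = np.array(centers)
    center_of_image = np.array([h / 2.0, w / 2.0])

    transforms: list[np.ndarray] = []
    stacks: list[TimeLapseStack] = []
    nuc_rows = []
    z_best = spec.n_z // 2
    for si, t in enumerate(spec.session_times_h):
        if si == 0:
            mat = np.hstack([np.eye(2), np.zeros((2, 1))])
        else:
            shift = rng.normal(0.0, spec.translation_sd_px, size=2)
            norm = np.linalg.norm(shift)
            if norm > spec.max_translation_px:
                shift *= spec.max_translation_px / norm
            rot = rng.normal(0.0, spec.rotation_sd_deg)
            scale = 1.0 + rng.normal(0.0, spec.scale_sd)
            mat = _affine_from(rot, scale, shift, center_of_image)
        if abs(np.linalg.det(mat[:, :2])) < 1e-9:
            raise ValueError("degenerate inter-session transform")
        transforms.append(mat)
        pos = apply_affine(mat, ref_centers)

        cyto_val = float(spec.cyto_kinetics.value(np.array([t]))[0])
        pixels = np.zeros((1, spec.n_z, 2, h, w), dtype=float)
        rr, cc = np.mgrid[0:h, 0:w]
        nuc_plane = np.zeros((h, w))
        cyt_plane = np.zeros((h, w))
        for cell_id, (r0, c0) in enumerate(pos):
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            nuc = d2 <= spec.nucleus_radius_px**2
            ann = (d2 <= spec.cyto_outer_radius_px**2) & (
                d2 > (spec.nucleus_radius_px - 2.0) ** 2
            )
            nuc_plane[nuc] = spec.nuclear_intensity
            cyt_plane[ann] = cyto_val
            nuc_rows.append(
                {
                    "cell_id": cell_id,
                    "session": si,
                    "time_h": t,
                    "row": r0,
                    "col": c0,
                    "true_cyto": cyto_val,
                    "true_nuclear": spec.nuclear_intensity,
                }
            )
        for zi in range(spec.n_z):
            axial = math.exp(-((zi - z_best) ** 2) / (2.0 * 1.5**2))
            pixels[0, zi, 0] = nuc_plane * axial
            pixels[0, zi, 1] = cyt_plane * axial
        if spec.poisson_gain is not None:
            pixels = rng.poisson(
                np.clip(pixels, 0, None) * spec.poisson_gain
            ) / spec.poisson_gain
        if spec.gaussian_sd > 0:
            pixels = pixels + rng.normal(0.0, spec.gaussian_sd,
                                         size=pixels.shape)
        stacks.append(
            TimeLapseStack(
                pixels=pixels,
                timestamps_h=np.array([t]),
                channel_names=["nuclear", "signal"],
                z_step_um=spec.z_step_um,
                inducer_time_h=spec.cyto_kinetics.t_inducer,
            )
        )
    truth = GroundTruth(
        nuclei=pd.DataFrame(nuc_rows),
        transforms=transforms,
        kinetics=pd.DataFrame(
            [
                {
                    "amplitude": spec.cyto_kinetics.amplitude,
                    "f_major": spec.cyto_kinetics.f_major,
                    "tau_major": spec.cyto_kinetics.tau_major,
                    "tau_minor": spec.cyto_kinetics.tau_minor,
                    "t_inducer": spec.cyto_kinetics.t_inducer,
                }
            ]
        ),
        seed=spec.seed,
    )
    return stacks, truth


# --------------------------------------------------------------------------
# histology fixture
# --------------------------------------------------------------------------

def simulate_histology_fov(
    shape: tuple[int, int] = (256, 256),
    neuropil_value: float = 200.0,
    background_value: float = 50.0,
    n_neuropil_rois: int = 4,
    n_background_rois: int = 4,
    roi_radius_px: float = 12.0,
    poisson_gain: float | None = None,
    gaussian_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray], GroundTruth]:
    """One histology field of view with labelled neuropil/background masks.

    The image is ``background_value`` everywhere except inside circular
    neuropil regions set to ``neuropil_value``; in the noiseless limit the
    mean inside each labelled mask equals its specified value exactly.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, background_value, dtype=float)
    margin = roi_radius_px + 4
    n_total = n_neuropil_rois + n_background_rois
    centers: list[np.ndarray] = []
    while len(centers) < n_total:
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.linalg.norm(cand - c) >= 2 * roi_radius_px + 4
               for c in centers):
            centers.append(cand)
    neuropil_mask = np.zeros(shape, dtype=bool)
    background_mask = np.zeros(shape, dtype=bool)
    for i, c in enumerate(centers):
        m = _disk_mask(shape, tuple(c), roi_radius_px)
        if i < n_neuropil_rois:
            neuropil_mask |= m
        else:
            background_mask |= m
    img[neuropil_mask] = neuropil_value

    if poisson_gain is not None:
        img = rng.poisson(np.clip(img, 0, None) * poisson_gain) / poisson_gain
    if gaussian_sd > 0:
        img = img + rng.normal(0.0, gaussian_sd, size=img.shape)

    masks = {"neuropil": neuropil_mask, "background": background_mask}
    truth = GroundTruth(
        masks=masks,
        kinetics=pd.DataFrame(
            [{"neuropil_value": neuropil_value,
              "background_value": background_value}]
        ),
        seed=seed,
    )
    return img, masks, truth
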