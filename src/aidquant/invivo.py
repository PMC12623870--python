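"""Longitudinal in-vivo nuclear/cytosolic quantification.

The pipeline follows the same neurons across imaging sessions using a
stable nuclear marker as reference: (i) select analysis planes at fixed
depths below the brain surface, (ii) re-identify each reference plane in
later sessions by keypoint matching, (iii) detect nuclei
(blur -> Otsu -> Laplacian-of-Gaussian blobs), (iv) align sessions with a
global xy-translation plus a local affine refined on matched nuclei, and
(v) read out cytosolic signal in a 4-8 px ring around each nuclear
centroid, normalized to the session-level mean nuclear fluorescence so
that session-to-session gain drifts cancel.

Also here: the histology neuropil/background ratio used to quantify bulk
synaptic signal in fixed-slice fields of view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import SIFT, blob_log, match_descriptors
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

log = logging.getLogger(__name__)

__all__ = [
    "FovSelection",
    "NucleusRecord",
    "AffinePlaneMap",
    "FovQuantRecord",
    "select_fovs",
    "match_fov",
    "detect_nuclei",
    "register_and_track",
    "ring_quantify",
    "ring_mask",
    "disk_mean",
    "normalize_nuclear",
    "apply_inclusion_filters",
    "neuropil_background_ratio",
    "run_invivo_pipeline",
]


@dataclass(frozen=True)
class FovSelection:
    """Planes selected for analysis within one z-stack."""

    stack_id: str
    plane_indices: tuple[int, ...]
    reference_offset_um: float
    plane_spacing_um: float
    truncated: bool = False


@dataclass
class NucleusRecord:
    """One tracked cell in one session."""

    cell_id: int
    session_id: int
    centroid: tuple[float, float]
    nuclear_mean: float
    ring_mean: float
    normalized: float = np.nan


@dataclass
class AffinePlaneMap:
    """Transform mapping reference-session coordinates to a later session."""

    session_pair: tuple[int, int]
    translation: tuple[float, float]        # (dy, dx) px
    affine: np.ndarray                      # 2x3 matrix in (row, col)
    score: float = np.nan                   # fraction of validated keypoints
    matched_pairs: int = 0
    translation_only: bool = False

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.affine[:, :2].T + self.affine[:, 2]


@dataclass
class FovQuantRecord:
    """Neuropil/background quantification for one field of view."""

    fov_id: str
    channel: str
    neuropil_means: list[float] = field(default_factory=list)
    background_means: list[float] = field(default_factory=list)
    ratio: float = np.nan


# --------------------------------------------------------------------------
# FOV/plane selection and matching
# --------------------------------------------------------------------------

def select_fovs(
    n_planes_in_stack: int,
    plane_spacing_um: float,
    surface_plane_index: int = 0,
    offset_um: float = 60.0,
    n_planes: int = 13,
    step_um: float = 10.0,
    stack_id: str = "stack",
    truncate: bool = False,
) -> FovSelection:
    """Select analysis planes at fixed depths below the surface plane.

    Default: 13 planes starting 60 um below the surface, 10 um apart.
    Requested depths beyond the stack are an error unless ``truncate`` is
    set, in which case the selection is clipped and flagged.
    """
    depths = offset_um + step_um * np.arange(n_planes)
    idx = surface_plane_index + np.rint(depths / plane_spacing_um).astype(int)
    out_of_range = idx >= n_planes_in_stack
    if np.any(idx < 0):
        raise ValueError("negative plane index requested")
    if np.any(out_of_range):
        if not truncate:
            raise ValueError(
                f"requested planes {idx[out_of_range].tolist()} exceed stack "
                f"depth {n_planes_in_stack}; pass truncate=True to clip"
            )
        idx = idx[~out_of_range]
    return FovSelection(
        stack_id=stack_id,
        plane_indices=tuple(int(i) for i in idx),
        reference_offset_um=offset_um,
        plane_spacing_um=plane_spacing_um,
        truncated=bool(np.any(out_of_range)),
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def match_fov(
    reference_plane: np.ndarray,
    candidate_planes: np.ndarray,
    max_ratio: float = 0.8,
    min_score: float = 0.05,
) -> tuple[int, float, bool]:
    """Find the candidate plane best matching a reference plane.

    SIFT keypoints and descriptors are computed on the reference and each
    candidate; mutual-nearest-neighbour descriptor matches validated by the
    Euclidean distance-ratio test are counted, and the plane with the most
    validated matches wins.  The score is validated matches divided by the
    number of reference keypoints.  When keypoints are scarce the routine
    falls back to normalized cross-correlation.

    Returns ``(best_index, score, matched)``; ``matched`` is False when the
    score stayed below ``min_score``.
    """
    cands = np.asarray(candidate_planes, dtype=float)
    if cands.ndim == 2:
        cands = cands[None]
    if cands.shape[0] == 0:
        raise ValueError("no candidate planes")
    ref = np.asarray(reference_plane, dtype=float)

    sift = SIFT()
    try:
        sift.detect_and_extract(ref)
        ref_desc = sift.descriptors
        n_ref = len(sift.keypoints)
    except RuntimeError:
        ref_desc, n_ref = None, 0

    if ref_desc is not None and n_ref > 0:
        counts = np.zeros(cands.shape[0], dtype=int)
        for i, plane in enumerate(cands):
            s2 = SIFT()
            try:
                s2.detect_and_extract(plane)
            except RuntimeError:
                continue
            if len(s2.keypoints) == 0:
                continue
            m = match_descriptors(
                ref_desc, s2.descriptors, cross_check=True,
                max_ratio=max_ratio,
            )
            counts[i] = len(m)
        best = int(np.argmax(counts))
        score = counts[best] / n_ref
        if score >= min_score:
            return best, float(score), True
        log.warning("keypoint matching weak (score %.3f); falling back to "
                    "cross-correlation", score)

    # fallback: normalized cross-correlation against each plane
    ncc = np.array([_ncc(ref, p) for p in cands])
    best = int(np.argmax(ncc))
    return best, float(ncc[best]), bool(ncc[best] >= 0.5)


# --------------------------------------------------------------------------
# nucleus detection and registration
# --------------------------------------------------------------------------

def detect_nuclei(
    image: np.ndarray,
    blur_sigma: float = 2.0,
    nuclear_radius_px: float = 5.0,
    blob_sigma_range: tuple[float, float] | None = None,
    blob_threshold: float = 0.02,
) -> np.ndarray:
    """Detect nuclei in a reference-channel image.

    Gaussian blur, Otsu binarization, then Laplacian-of-Gaussian blob
    detection restricted to the foreground.  The LoG sigma range defaults
    to the configured nuclear radius +/- 40% (converted via
    ``sigma = r / sqrt(2)``).  Returns an (n, 2) float array of (row, col)
    centroids; a degenerate single-intensity image yields an empty result.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_nuclei expects a 2-D image")
    blurred = gaussian_filter(img, blur_sigma)
    if np.ptp(blurred) == 0:
        return np.empty((0, 2))
    thr = threshold_otsu(blurred)
    mask = blurred > thr
    if blob_sigma_range is None:
        s = nuclear_radius_px / np.sqrt(2.0)
        blob_sigma_range = (0.6 * s, 1.4 * s)
    span = blurred.max() - blurred.min()
    work = (blurred - blurred.min()) / span
    work = work * mask
    blobs = blob_log(
        work,
        min_sigma=blob_sigma_range[0],
        max_sigma=blob_sigma_range[1],
        num_sigma=5,
        threshold=blob_threshold,
    )
    if blobs.size == 0:
        return np.empty((0, 2))
    cent = blobs[:, :2]
    keep = mask[cent[:, 0].astype(int), cent[:, 1].astype(int)]
    return cent[keep]


def _estimate_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares 2x3 affine mapping src (row, col) points onto dst."""
    n = src.shape[0]
    A = np.hstack([src, np.ones((n, 1))])
    sol, *_ = np.linalg.lstsq(A, dst, rcond=None)
    return sol.T                       # 2x3


def _mutual_nn_pairs(
    a: np.ndarray, b: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    if a.shape[0] == 0 or b.shape[0] == 0:
        return []
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    fwd = np.argmin(d, axis=1)
    bwd = np.argmin(d, axis=0)
    return [
        (i, int(fwd[i]))
        for i in range(a.shape[0])
        if bwd[fwd[i]] == i and d[i, fwd[i]] <= max_dist
    ]


def register_and_track(
    reference_centroids: np.ndarray,
    target_centroids: np.ndarray,
    reference_image: np.ndarray | None = None,
    target_image: np.ndarray | None = None,
    session_pair: tuple[int, int] = (0, 1),
    match_radius_px: float = 8.0,
) -> tuple[AffinePlaneMap, np.ndarray, list[tuple[int, int]]]:
    """Two-stage alignment of a later session onto the reference session.

    Stage 1 estimates a global xy-translation (phase correlation when
    images are given, mutual-nearest-neighbour median displacement
    otherwise).  Stage 2 refines with a least-squares affine on mutually
    matched centroids.  With fewer than 3 usable non-collinear pairs the
    map degrades to translation-only and is flagged.

    Returns the map, the reference centroids transformed into target
    coordinates, and the matched (reference, target) index pairs.
    """
    ref = np.asarray(reference_centroids, dtype=float)
    tgt = np.asarray(target_centroids, dtype=float)

    if reference_image is not None and target_image is not None:
        shift = phase_cross_correlation(
            np.asarray(target_image, float),
            np.asarray(reference_image, float),
            upsample_factor=10,
        )[0]
        translation = np.asarray(shift, dtype=float)
    else:
        pairs0 = _mutual_nn_pairs(ref, tgt, max_dist=np.inf)
        if not pairs0:
            raise ValueError("no centroids to register")
        disp = np.array([tgt[j] - ref[i] for i, j in pairs0])
        translation = np.median(disp, axis=0)

    shifted = ref + translation
    pairs = _mutual_nn_pairs(shifted, tgt, max_dist=match_radius_px)

    translation_only = False
    if len(pairs) >= 3:
        src = ref[[i for i, _ in pairs]]
        dst = tgt[[j for _, j in pairs]]
        spread = np.linalg.matrix_rank(src - src.mean(axis=0))
        if spread >= 2:
            affine = _estimate_affine(src, dst)
        else:
            translation_only = True
            affine = np.hstack([np.eye(2), translation[:, None]])
    else:
        translation_only = True
        affine = np.hstack([np.eye(2), translation[:, None]])
    if translation_only:
        log.warning("session pair %s: <3 usable pairs, translation-only map",
                    session_pair)

    mapped = ref @ affine[:, :2].T + affine[:, 2]
    score = len(pairs) / max(len(ref), 1)
    amap = AffinePlaneMap(
        session_pair=session_pair,
        translation=(float(translation[0]), float(translation[1])),
        affine=affine,
        score=float(min(score, 1.0)),
        matched_pairs=len(pairs),
        translation_only=translation_only,
    )
    return amap, mapped, pairs


# --------------------------------------------------------------------------
# ring quantification and normalization
# --------------------------------------------------------------------------

def ring_mask(
    shape: tuple[int, int],
    centroid: tuple[float, float],
    r_in: float = 4.0,
    r_out: float = 8.0,
) -> np.ndarray:
    """Boolean annulus: pixel centres with r_in <= distance < r_out.

    Half-open bounds make the nuclear disk (< r_in) and the ring disjoint.
    """
    if r_in >= r_out:
        raise ValueError("r_in must be smaller than r_out")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - centroid[0], cc - centroid[1])
    return (d >= r_in) & (d < r_out)


def ring_quantify(
    signal_image: np.ndarray,
    centroid: tuple[float, float],
    r_in: float = 4.0,
    r_out: float = 8.0,
) -> float:
    """Mean signal in the ring around a nuclear centroid.

    Rings extending past the image edge are clipped (logged).
    """
    img = np.asarray(signal_image, dtype=float)
    r0, c0 = centroid
    if (r0 - r_out < 0 or c0 - r_out < 0
            or r0 + r_out > img.shape[0] or c0 + r_out > img.shape[1]):
        log.warning("ring at %s clipped by image bounds", centroid)
    m = ring_mask(img.shape, centroid, r_in, r_out)
    if not m.any():
        raise ValueError("ring mask empty")
    return float(img[m].mean())


def disk_mean(
    image: np.ndarray, centroid: tuple[float, float], radius: float = 4.0
) -> float:
    """Mean intensity in the disk of pixel centres with distance < radius."""
    img = np.asarray(image, dtype=float)
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    m = np.hypot(rr - centroid[0], cc - centroid[1]) < radius
    if not m.any():
        raise ValueError("disk mask empty")
    return float(img[m].mean())


def normalize_nuclear(
    records: list[NucleusRecord], mode: str = "session"
) -> list[NucleusRecord]:
    """Set each record's normalized signal from the nuclear reference.

    ``session`` mode (default) divides every ring mean by the session-level
    mean of nuclear means, cancelling session-to-session gain drift;
    ``per_cell`` divides by each cell's own nuclear mean.
    """
    by_session: dict[int, list[NucleusRecord]] = {}
    for r in records:
        by_session.setdefault(r.session_id, []).append(r)
    for sess, recs in by_session.items():
        if mode == "session":
            denom = float(np.mean([r.nuclear_mean for r in recs]))
            if denom <= 0:
                raise ValueError(f"session {sess}: non-positive nuclear mean")
            for r in recs:
                r.normalized = r.ring_mean / denom
        elif mode == "per_cell":
            for r in recs:
                if r.nuclear_mean <= 0:
                    raise ValueError("non-positive per-cell nuclear mean")
                r.normalized = r.ring_mean / r.nuclear_mean
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return records


def apply_inclusion_filters(
    records: pd.DataFrame,
    min_pair_distance_px: float = 3.0,
    min_initial_norm: float = 0.3,
    initial_session: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop cells too close to a neighbour or too dim at the first session.

    ``records`` is a long table with columns ``cell_id, session_id, row,
    col, normalized``.  Distance is nearest-neighbour centroid distance in
    the initial session; cells with nearest neighbour closer than
    ``min_pair_distance_px`` (both members of the pair) or initial
    normalized signal below ``min_initial_norm`` are removed.  Returns the
    filtered table and counts dropped per rule.
    """
    if initial_session is None:
        initial_session = records["session_id"].min()
    first = records[records["session_id"] == initial_session]
    pts = first[["row", "col"]].to_numpy(dtype=float)
    ids = first["cell_id"].to_numpy()
    drop_dist: set = set()
    if len(pts) > 1:
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        drop_dist = set(ids[nn < min_pair_distance_px])
    dim = first[first["normalized"] < min_initial_norm]
    drop_dim = set(dim["cell_id"]) - drop_dist
    keep = ~records["cell_id"].isin(drop_dist | drop_dim)
    counts = {
        "dropped_min_distance": len(drop_dist),
        "dropped_min_initial_norm": len(drop_dim),
        "kept": int(records.loc[keep, "cell_id"].nunique()),
    }
    return records.loc[keep].reset_index(drop=True), counts


def neuropil_background_ratio(
    image: np.ndarray,
    neuropil_rois: list[np.ndarray],
    background_rois: list[np.ndarray],
    fov_id: str = "fov",
    channel: str = "ch0",
) -> FovQuantRecord:
    """Mean neuropil fluorescence divided by mean background fluorescence.

    ROIs are boolean masks; each ROI contributes its own mean, and the
    ratio is taken between the across-ROI means.
    """
    if not neuropil_rois or not background_rois:
        raise ValueError("need at least one ROI of each kind")
    img = np.asarray(image, dtype=float)
    np_means = [float(img[m].mean()) for m in neuropil_rois]
    bg_means = [float(img[m].mean()) for m in background_rois]
    bg = float(np.mean(bg_means))
    if bg <= 0:
        raise ValueError("background mean must be positive")
    return FovQuantRecord(
        fov_id=fov_id,
        channel=channel,
        neuropil_means=np_means,
        background_means=bg_means,
        ratio=float(np.mean(np_means)) / bg,
    )


# --------------------------------------------------------------------------
# end-to-end session pipeline
# --------------------------------------------------------------------------

def run_invivo_pipeline(
    sessions,
    nuclear_channel: str = "nuclear",
    signal_channel: str = "signal",
    nuclear_radius_px: float = 5.0,
    r_in: float = 4.0,
    r_out: float = 8.0,
    min_pair_distance_px: float = 3.0,
    min_initial_norm: float = 0.3,
    normalization: str = "session",
) -> tuple[pd.DataFrame, list[AffinePlaneMap]]:
    """Track nuclei across sessions and quantify normalized ring signal.

    ``sessions`` is a list of :class:`~aidquant.stack.TimeLapseStack`, one
    per imaging session (T = 1).  Nuclei are detected in the first
    session's nuclear channel; each later session is registered onto the
    first and the same cells are measured at their mapped positions.
    Returns a long table of per-cell per-session records (after inclusion
    filters) and the per-session transform maps.
    """
    from .culture import max_project

    if not sessions:
        raise ValueError("no sessions")
    ref_nuc = max_project(sessions[0], 0, nuclear_channel)
    ref_cent = detect_nuclei(ref_nuc, nuclear_radius_px=nuclear_radius_px)
    if ref_cent.shape[0] == 0:
        raise ValueError("no nuclei detected in the reference session")

    maps: list[AffinePlaneMap] = []
    rows = []
    h, w = ref_nuc.shape
    for si, stack in enumerate(sessions):
        nuc_img = max_project(stack, 0, nuclear_channel)
        sig_img = max_project(stack, 0, signal_channel)
        if si == 0:
            mapped = ref_cent
            maps.append(
                AffinePlaneMap(
                    session_pair=(0, 0), translation=(0.0, 0.0),
                    affine=np.hstack([np.eye(2), np.zeros((2, 1))]),
                    score=1.0, matched_pairs=len(ref_cent),
                )
            )
        else:
            tgt_cent = detect_nuclei(
                nuc_img, nuclear_radius_px=nuclear_radius_px
            )
            amap, mapped, _ = register_and_track(
                ref_cent, tgt_cent,
                reference_image=ref_nuc, target_image=nuc_img,
                session_pair=(0, si),
            )
            maps.append(amap)
        for cid, (r0, c0) in enumerate(mapped):
            if (r0 - r_out < 0 or c0 - r_out < 0
                    or r0 + r_out >= h or c0 + r_out >= w):
                continue
            rows.append(
                {
                    "cell_id": cid,
                    "session_id": si,
                    "time_h": float(stack.timestamps_h[0]),
                    "row": float(r0),
                    "col": float(c0),
                    "nuclear_mean": disk_mean(nuc_img, (r0, c0), r_in),
                    "ring_mean": ring_quantify(sig_img, (r0, c0), r_in, r_out),
                }
            )
    table = pd.DataFrame(rows)
    recs = [
        NucleusRecord(
            cell_id=int(r.cell_id), session_id=int(r.session_id),
            centroid=(r.row, r.col), nuclear_mean=r.nuclear_mean,
            ring_mean=r.ring_mean,
        )
        for r in table.itertuples()
    ]
    normalize_nuclear(recs, mode=normalization)
    table["normalized"] = [r.normalized for r in recs]
    filtered, counts = apply_inclusion_filters(
        table, min_pair_distance_px, min_initial_norm
    )
    log.info("inclusion filters: %s", counts)
    return filtered, maps
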