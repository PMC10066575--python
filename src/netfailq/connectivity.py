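"""DMN subsystem connectivity and the network failure quotient (NFQ).

The NFQ summarizes default-mode-network disruption as a ratio of median
inter-subsystem connectivities. With ``m(A, B)`` the median Pearson
correlation over all cross component pairs between subsystems A and B, the
default formula is::

    NFQ = [m(pDMN, avDMN) + m(pDMN, adDMN)] / m(pDMN, vDMN)

A configuration switch selects the alternative variant
``[m(pDMN, vDMN) + m(pDMN, adDMN)] / m(pDMN, vDMN)``; the pair sets of the
numerator and denominator are fully configurable.

The module covers the whole path from a resting-state scan session to a
per-subject connectivity profile: initial frame trimming, aCompCor-style
noise-ROI construction and principal-component extraction, nuisance design
assembly (motion + derivatives + noise components), simultaneous band-pass
filtering and nuisance regression, volumetric smoothing, dual
(spatial-temporal) regression against a labelled component atlas, median
inter-subsystem connectivity, session averaging and session ICC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from netfailq.filters import DEFAULT_BAND, bandpass_filter, validate_band

logger = logging.getLogger(__name__)

SUBSYSTEMS = ("pDMN", "vDMN", "avDMN", "adDMN")

#: numerator / denominator pair sets of the default NFQ formula
NFQ_DEFAULT_NUMERATOR = (("pDMN", "avDMN"), ("pDMN", "adDMN"))
#: the literal-text variant repeats the denominator pair in the numerator
NFQ_LITERAL_NUMERATOR = (("pDMN", "vDMN"), ("pDMN", "adDMN"))
NFQ_DENOMINATOR = (("pDMN", "vDMN"),)

NFQ_EPS = 1e-6


@dataclass
class ComponentAtlas:
    """Spatial component maps on a shared grid, labelled by DMN subsystem.

    maps : array (K, nx, ny, nz) of voxel weights.
    labels : component index -> subsystem name.
    affine : 4x4 voxel-to-world transform (mm).
    """

    maps: np.ndarray
    labels: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("atlas maps must be a (K, nx, ny, nz) array")
        k = self.maps.shape[0]
        bad = [i for i in self.labels if not 0 <= i < k]
        if bad:
            raise ValueError(f"label indices {bad} outside component range 0..{k - 1}")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]

    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class ScanSession:
    """One resting-state run.

    data : (T, K) component time courses or (T, nx, ny, nz) volume series.
    motion : (T, 6) trace — 3 translations (mm) + 3 rotations (radians).
    noise_mask : boolean voxel mask of the white-matter/CSF noise ROI
        (volume mode only).
    """

    data: np.ndarray
    tr: float
    motion: np.ndarray | None = None
    noise_mask: np.ndarray | None = None
    included: bool = True
    exclusion_reason: str | None = None
    subject_id: str | None = None
    session: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.ndim not in (2, 4):
            raise ValueError("data must be (T, K) time courses or a 4D volume series")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.n_frames, 6):
                raise ValueError(
                    f"motion trace shape {self.motion.shape} does not match "
                    f"({self.n_frames}, 6)"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def is_volume(self) -> bool:
        return self.data.ndim == 4


@dataclass
class ConnectivityProfile:
    """Median inter-subsystem connectivities and the NFQ for one subject."""

    pair_connectivity: dict[tuple[str, str], float]
    nfq: float
    n_sessions_used: int = 1
    subject_id: str | None = None


# ---------------------------------------------------------------------------
# volume-mode preprocessing


def trim_initial_frames(session: ScanSession, n: int = 10) -> ScanSession:
    """Drop the first ``n`` frames (dummy volumes) from data and motion."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if session.n_frames <= n:
        raise ValueError(
            f"cannot trim {n} frames from a session of {session.n_frames} frames"
        )
    motion = session.motion[n:] if session.motion is not None else None
    return replace(session, data=session.data[n:], motion=motion)


def build_noise_roi(
    csf_prob: np.ndarray,
    wm_prob: np.ndarray,
    threshold: float = 0.9,
    erosion: int = 2,
) -> np.ndarray:
    """Binarize CSF/WM probability maps and erode away grey-matter borders.

    The mask is ``(csf >= threshold) | (wm >= threshold)`` eroded ``erosion``
    times with a 6-connected structuring element. Threshold comparison is
    inclusive (a voxel exactly at the threshold is kept).
    """
    csf_prob = np.asarray(csf_prob, dtype=float)
    wm_prob = np.asarray(wm_prob, dtype=float)
    if csf_prob.shape != wm_prob.shape:
        raise ValueError("CSF and WM probability maps must share a grid")
    for name, img in (("csf", csf_prob), ("wm", wm_prob)):
        if img.min() < 0 or img.max() > 1:
            raise ValueError(f"{name} probabilities outside [0, 1]")
    mask = (csf_prob >= threshold) | (wm_prob >= threshold)
    if not mask.any():
        raise ValueError("no voxel reaches the probability threshold")
    if erosion > 0:
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connected
        mask = ndimage.binary_erosion(mask, structure=structure, iterations=erosion)
    if not mask.any():
        raise ValueError(
            f"noise ROI empty after eroding {erosion} voxels; reduce the erosion"
        )
    return mask


def noise_components(
    session: ScanSession, mask: np.ndarray, k: int = 6
) -> np.ndarray:
    """Top-k principal component time series of the noise-ROI voxels.

    Voxel time series are centred over time; components are ordered by
    explained variance and returned with unit variance (T x k).
    """
    if not session.is_volume:
        raise ValueError("noise components require a volume-mode session")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != session.data.shape[1:]:
        raise ValueError("mask grid does not match the session grid")
    if not mask.any():
        raise ValueError("empty noise mask")
    if k == 0:
        return np.empty((session.n_frames, 0))
    ts = session.data[:, mask]  # T x V
    ts = ts - ts.mean(axis=0)
    # PCA via SVD of the frame-by-voxel matrix
    u, s, _ = np.linalg.svd(ts, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"requested {k} components but masked data has rank {rank}")
    comps = u[:, :k] * s[:k]
    return comps / comps.std(axis=0, ddof=1)


def build_nuisance_matrix(motion: np.ndarray, noise_comps: np.ndarray) -> np.ndarray:
    """Assemble the nuisance design: motion, its derivatives, noise PCs.

    Columns are the 6 motion parameters, their backward-difference first
    temporal derivatives (first row zero), and the k noise components; all
    columns are mean-centred. Shape (T, 12 + k).
    """
    motion = np.asarray(motion, dtype=float)
    noise_comps = np.asarray(noise_comps, dtype=float)
    if noise_comps.size == 0:
        noise_comps = noise_comps.reshape(motion.shape[0], 0)
    if motion.shape[0] != noise_comps.shape[0]:
        raise ValueError(
            f"frame count mismatch: motion {motion.shape[0]} vs noise "
            f"components {noise_comps.shape[0]}"
        )
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a (T, 6) array")
    deriv = np.zeros_like(motion)
    deriv[1:] = np.diff(motion, axis=0)
    design = np.column_stack([motion, deriv, noise_comps])
    return design - design.mean(axis=0)


def bandpass_and_regress(
    series: np.ndarray,
    nuisance: np.ndarray | None,
    band: tuple[float, float] = DEFAULT_BAND,
    tr: float = 0.8,
    normalize: bool = True,
) -> np.ndarray:
    """Simultaneous band-pass filtering and nuisance regression.

    Both the data and the nuisance regressors are linearly detrended and
    band-pass filtered with the identical zero-phase operator, then the
    filtered nuisance is regressed out of the filtered data by least
    squares. Filtering the regressors alongside the data avoids spectral
    misspecification of motion artefact. Output columns are variance
    normalized (unit variance) unless ``normalize=False``.
    """
    series = np.asarray(series, dtype=float)
    validate_band(band, tr)
    filtered = bandpass_filter(series, band=band, tr=tr)
    filtered = filtered - filtered.mean(axis=0)  # DC is outside the pass band
    if nuisance is not None and np.asarray(nuisance).size:
        nuis = bandpass_filter(np.asarray(nuisance, dtype=float), band=band, tr=tr)
        nuis = nuis - nuis.mean(axis=0)
        # drop linearly dependent columns
        q, r, piv = _qr_pivot(nuis)
        rank = int((np.abs(np.diag(r)) > np.abs(r[0, 0]) * 1e-10).sum())
        if rank < nuis.shape[1]:
            keep = np.sort(piv[:rank])
            logger.warning(
                "nuisance matrix rank-deficient: dropping %d dependent column(s)",
                nuis.shape[1] - rank,
            )
            nuis = nuis[:, keep]
        beta, *_ = np.linalg.lstsq(nuis, filtered, rcond=None)
        filtered = filtered - nuis @ beta
    if normalize:
        sd = filtered.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        filtered = filtered / sd
    return filtered


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def smooth_volumes(series: np.ndarray, fwhm: float, voxel_sizes=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Per-frame Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma = fwhm / (2 * sqrt(2 * ln 2)) per axis, converted to voxels by the
    (possibly anisotropic) voxel size.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("smoothing expects a (T, nx, ny, nz) volume series")
    if fwhm == 0:
        return series.copy()
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in voxel_sizes]
    out = np.empty_like(series)
    for t in range(series.shape[0]):
        out[t] = ndimage.gaussian_filter(series[t], sigma=sigma_vox, mode="constant")
    return out


def dual_regression(series: np.ndarray, atlas: ComponentAtlas) -> np.ndarray:
    """Spatial-temporal regression of each frame on all atlas maps jointly.

    Every frame's voxel vector is regressed on the K column-centred atlas
    maps in one multivariate least-squares solve, returning the (T, K)
    coefficient time series. Joint estimation is what disambiguates
    correlated maps; per-map univariate regression does not.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("dual regression expects a (T, nx, ny, nz) volume series")
    if series.shape[1:] != atlas.grid_shape:
        raise ValueError(
            f"series grid {series.shape[1:]} does not match atlas grid "
            f"{atlas.grid_shape}"
        )
    k = atlas.n_components
    x = atlas.maps.reshape(k, -1).T  # voxels x K
    x = x - x.mean(axis=0)
    gram = x.T @ x
    cond = np.linalg.cond(gram)
    if cond > 1e10:
        corr = np.corrcoef(x.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"atlas maps are collinear (gram condition {cond:.2g}); "
            f"components {i} and {j} are the most correlated pair"
        )
    y = series.reshape(series.shape[0], -1).T  # voxels x T
    courses = np.linalg.solve(gram, x.T @ y)  # K x T
    return courses.T


# ---------------------------------------------------------------------------
# connectivity statistics


def subsystem_connectivity(
    courses: np.ndarray,
    labels: Mapping[int, str],
    include_within: bool = False,
    fisher_z: bool = False,
) -> dict[tuple[str, str], float]:
    """Median Pearson correlation over cross component pairs per subsystem pair.

    For each unordered subsystem pair (A, B) every cross pair (component in
    A, component in B) contributes one correlation; the pair connectivity is
    the median over those. Zero-variance courses are excluded with a
    warning. With ``fisher_z=True`` the median is taken on the z scale and
    transformed back.
    """
    courses = np.asarray(courses, dtype=float)
    if courses.ndim != 2:
        raise ValueError("courses must be a (T, K) array")
    t = courses.shape[0]
    if t < 3:
        raise ValueError("need at least 3 frames for a correlation")
    by_subsystem: dict[str, list[int]] = {}
    for idx, sub in labels.items():
        by_subsystem.setdefault(sub, []).append(idx)
    sd = courses.std(axis=0)
    usable = {
        sub: [i for i in idxs if sd[i] > 0] for sub, idxs in by_subsystem.items()
    }
    dropped = sum(len(v) for v in by_subsystem.values()) - sum(
        len(v) for v in usable.values()
    )
    if dropped:
        warnings.warn(f"excluded {dropped} zero-variance component course(s)")
    corr = np.corrcoef(courses, rowvar=False)
    out: dict[tuple[str, str], float] = {}
    subs = sorted(usable)
    for a_i, a in enumerate(subs):
        for b in subs[a_i:]:
            if a == b and not include_within:
                continue
            if a == b:
                pairs = [
                    (i, j)
                    for ii, i in enumerate(usable[a])
                    for j in usable[a][ii + 1 :]
                ]
            else:
                pairs = [(i, j) for i in usable[a] for j in usable[b]]
            if not pairs:
                raise ValueError(
                    f"no usable component pair for subsystems ({a}, {b})"
                )
            rs = np.array([corr[i, j] for i, j in pairs])
            if fisher_z:
                val = float(np.tanh(np.median(np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12)))))
            else:
                val = float(np.median(rs))
            out[pair_key(a, b)] = val
    return out


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered subsystem pair."""
    return (a, b) if a <= b else (b, a)


def subsystem_connectivity_from_matrix(
    corr: np.ndarray, labels: Mapping[int, str]
) -> dict[tuple[str, str], float]:
    """Pair connectivities implied by a known component correlation matrix
    (the infinite-data limit of ``subsystem_connectivity``)."""
    corr = np.asarray(corr, dtype=float)
    subs = sorted(set(labels.values()))
    out: dict[tuple[str, str], float] = {}
    for a_i, a in enumerate(subs):
        for b in subs[a_i + 1 :]:
            rs = [
                corr[i, j]
                for i in labels
                for j in labels
                if labels[i] == a and labels[j] == b
            ]
            out[pair_key(a, b)] = float(np.median(rs))
    return out


def compute_nfq(
    pair_connectivity: Mapping[tuple[str, str], float],
    numerator: Sequence[tuple[str, str]] = NFQ_DEFAULT_NUMERATOR,
    denominator: Sequence[tuple[str, str]] = NFQ_DENOMINATOR,
    eps: float = NFQ_EPS,
) -> float:
    """NFQ from median pair connectivities; NaN (flagged) when degenerate.

    Higher values indicate greater connectivity disruption between the DMN
    subsystems. The denominator guard ``eps`` makes the degenerate-input
    policy explicit: a near-zero denominator yields NaN with a warning so
    that the session can be excluded rather than produce an unstable ratio.
    """
    pc = {pair_key(*k): v for k, v in pair_connectivity.items()}
    missing = [p for p in list(numerator) + list(denominator) if pair_key(*p) not in pc]
    if missing:
        raise KeyError(f"missing pair connectivities: {missing}")
    num = sum(pc[pair_key(*p)] for p in numerator)
    den = sum(pc[pair_key(*p)] for p in denominator)
    if abs(den) < eps:
        warnings.warn(
            f"NFQ denominator {den:.3g} below guard {eps:.1g}; flagged undefined"
        )
        return float("nan")
    return float(num / den)


def nfq_numerator(variant: str = "default") -> tuple[tuple[str, str], ...]:
    """Numerator pair set for a named NFQ variant ('default' or 'literal')."""
    if variant == "default":
        return NFQ_DEFAULT_NUMERATOR
    if variant == "literal":
        return NFQ_LITERAL_NUMERATOR
    raise ValueError(f"unknown NFQ variant {variant!r}")


def session_profile(
    courses: np.ndarray,
    labels: Mapping[int, str],
    nfq_variant: str = "default",
    **kwargs,
) -> ConnectivityProfile:
    """Connectivity profile (pair medians + NFQ) for one cleaned session."""
    pc = subsystem_connectivity(courses, labels, **kwargs)
    nfq = compute_nfq(pc, numerator=nfq_numerator(nfq_variant))
    return ConnectivityProfile(pair_connectivity=pc, nfq=nfq)


def average_sessions(
    profiles: Sequence[ConnectivityProfile],
    included: Sequence[bool] | None = None,
) -> ConnectivityProfile:
    """Within-subject arithmetic mean of NFQ and pair connectivities.

    Only QC-passing sessions enter the average; a subject with no passing
    session is flagged missing (ValueError) rather than fabricated.
    """
    if included is None:
        included = [True] * len(profiles)
    kept = [p for p, ok in zip(profiles, included) if ok and np.isfinite(p.nfq)]
    if not kept:
        raise ValueError("no QC-passing session with a defined NFQ")
    keys = kept[0].pair_connectivity.keys()
    pc = {k: float(np.mean([p.pair_connectivity[k] for p in kept])) for k in keys}
    nfq = float(np.mean([p.nfq for p in kept]))
    return ConnectivityProfile(
        pair_connectivity=pc,
        nfq=nfq,
        n_sessions_used=len(kept),
        subject_id=kept[0].subject_id,
    )


def session_icc(values: np.ndarray, form: str = "icc2_1") -> float:
    """Intra-class correlation across sessions from a subjects x sessions matrix.

    Default form is the two-way random-effects, absolute-agreement,
    single-measure ICC(2,1) from the standard mean-squares decomposition;
    ICC(3,1) (consistency) is available via ``form='icc3_1'``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) x (sessions >= 2) matrix")
    if np.isnan(x).any():
        x = x[~np.isnan(x).any(axis=1)]  # listwise deletion
        if x.shape[0] < 2:
            raise ValueError("fewer than 2 complete subjects after listwise deletion")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    if form == "icc2_1":
        return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
    if form == "icc3_1":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValueError(f"unknown ICC form {form!r}")
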