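"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a large normative aging cohort plus small
dysexecutive (dAD) and amnestic (AD) Alzheimer's disease patient groups
and a handful of scanned-on-site controls:

* every biomarker follows an age-dependent normal location/scale law
  ``value ~ N(mu(age), sigma(age))`` with configurable linear curves;
* patient groups are shifted by an effect table expressed in normative-SD
  units at the subject's age, so age-adjusted Z-scores are directly
  plantable. The default shifts are the published group-mean Z-scores of
  each patient group per biomarker;
* each subject carries a true component-space correlation matrix encoding
  their NFQ, from which band-limited resting-state component time courses
  (and optionally volumetric scans) are synthesized;
* episodic-memory scores carry a planted mediation structure
  (hippocampal volume -> NFQ -> recall) with known ACME/ADE/proportion
  mediated on the standardized age-residual scale.

Everything is driven by one integer seed and is byte-for-byte
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netfailq.connectivity import ComponentAtlas, ScanSession, compute_nfq
from netfailq.filters import DEFAULT_BAND, bandpass_filter

BIOMARKERS = (
    "nfq",
    "meta_roi",
    "left_hippocampus",
    "right_hippocampus",
    "inferior_parietal",
)

#: per-biomarker (intercept, slope per year, sigma intercept, sigma slope)
DEFAULT_CURVES: dict[str, tuple[float, float, float, float]] = {
    "nfq": (0.55, 0.011, 0.30, 0.0),
    "meta_roi": (3.15, -0.004, 0.10, 0.0),  # mm
    "left_hippocampus": (5200.0, -16.0, 420.0, 0.0),  # mm^3 (ICV-adjusted)
    "right_hippocampus": (5300.0, -16.0, 430.0, 0.0),
    "inferior_parietal": (5.90, -0.008, 0.28, 0.0),  # mm, summed L+R
}

#: patient shifts in normative-SD units: the published group-mean Z-scores
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "dAD": {
        "nfq": 2.21,
        "meta_roi": -1.62,
        "left_hippocampus": -1.06,
        "right_hippocampus": -0.24,
        "inferior_parietal": -3.20,
    },
    "AD": {
        "nfq": 1.76,
        "meta_roi": -2.56,
        "left_hippocampus": -1.54,
        "right_hippocampus": -1.41,
        "inferior_parietal": -1.40,
    },
    "control": {b: 0.0 for b in BIOMARKERS},
}

#: mediation slopes on the standardized age-residual scale
#: (hippocampal residual -> NFQ residual -> recall residual); the defaults
#: give a proportion mediated a*b / (a*b + c') of ~12%, the order reported
#: for the recall model.
DEFAULT_MEDIATION = {"a": -0.28, "b": -0.25, "c_prime": 0.50}

#: patient age windows (years), mirroring the reported group medians
GROUP_AGE_RANGES = {"dAD": (56.0, 64.0), "AD": (67.0, 78.0), "control": (61.0, 69.0)}

SUVR_PARAMS = {  # (amyloid mean, amyloid sd, tau mean, tau sd)
    "dAD": (2.48, 0.30, 2.14, 0.30),
    "AD": (2.62, 0.25, 1.89, 0.35),
    "control": (1.30, 0.02, 1.21, 0.02),
}


@dataclass
class CohortConfig:
    n_normative: int = 500
    n_dad: int = 10
    n_ad: int = 8
    n_controls: int = 5
    age_range: tuple[float, float] = (36.0, 90.0)
    sessions_per_subject: int = 4
    frames_per_session: int = 488
    tr: float = 0.8
    seed: int = 0
    effect_table: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_EFFECTS.items()})
    mediation_params: dict = field(default_factory=lambda: dict(DEFAULT_MEDIATION))
    curves: dict = field(default_factory=lambda: dict(DEFAULT_CURVES))
    components_per_subsystem: int = 4
    within_subsystem_r: float = 0.7
    denominator_r: float = 0.6  # true m(pDMN, vDMN)
    background_r: float = 0.25  # cross pairs not involving pDMN

    def __post_init__(self) -> None:
        for name in ("n_normative", "n_dad", "n_ad", "n_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range low must be below high")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.frames_per_session <= 10:
            raise ValueError("frames_per_session must exceed 10")
        if self.sessions_per_subject < 1:
            raise ValueError("sessions_per_subject must be at least 1")


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream recovery tests need."""

    curves: dict
    effect_table: dict
    mediation: dict  # a, b, c_prime, acme, ade, proportion_mediated
    labels: dict[int, str]  # component -> subsystem
    corr_matrices: dict[str, np.ndarray]  # subject -> true correlation matrix
    true_nfq: dict[str, float]  # subject -> NFQ implied by the matrix

    def mu(self, biomarker: str, ages) -> np.ndarray:
        b0, b1, _, _ = self.curves[biomarker]
        return b0 + b1 * np.asarray(ages, dtype=float)

    def sigma(self, biomarker: str, ages) -> np.ndarray:
        _, _, s0, s1 = self.curves[biomarker]
        out = s0 + s1 * np.asarray(ages, dtype=float)
        if np.any(out <= 0):
            raise ValueError(f"true sigma non-positive for {biomarker}")
        return out


def default_labels(per_subsystem: int = 2) -> dict[int, str]:
    labels = {}
    for s_i, sub in enumerate(("pDMN", "vDMN", "avDMN", "adDMN")):
        for j in range(per_subsystem):
            labels[s_i * per_subsystem + j] = sub
    return labels


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the subject table and its ground truth.

    The NFQ column holds the NFQ implied by each subject's realized
    correlation matrix (identical to what infinitely long scans would
    recover), so table-driven and scan-driven analyses agree in
    expectation.
    """
    rng = np.random.default_rng(config.seed)
    med = config.mediation_params
    a, b, c_prime = med["a"], med["b"], med["c_prime"]
    groups = (
        ["normative"] * config.n_normative
        + ["dAD"] * config.n_dad
        + ["AD"] * config.n_ad
        + ["control"] * config.n_controls
    )
    lo, hi = config.age_range
    rows = []
    labels = default_labels(config.components_per_subsystem)
    corr_matrices: dict[str, np.ndarray] = {}
    true_nfq: dict[str, float] = {}
    counters: dict[str, int] = {}
    for group in groups:
        counters[group] = counters.get(group, 0) + 1
        prefix = {"normative": "HCA", "dAD": "dAD", "AD": "AD", "control": "CU"}[group]
        sid = f"{prefix}{counters[group]:04d}" if group == "normative" else f"{prefix}{counters[group]}"
        if group == "normative":
            age = rng.uniform(lo, hi)
        else:
            g_lo, g_hi = GROUP_AGE_RANGES[group]
            age = rng.uniform(max(g_lo, lo), min(g_hi, hi))
        shifts = config.effect_table.get(group, {}) if group != "normative" else {}

        # hippocampal residuals share a factor (left/right correlate ~0.7)
        rho = 0.7
        shared = rng.standard_normal()
        e_left = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal()
        e_right = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal()
        x_resid = (e_left + e_right) / np.sqrt(2 * (1 + rho))  # unit variance
        # mediator residual: NFQ loads on the hippocampal residual
        m_resid = a * x_resid + np.sqrt(1 - a**2) * rng.standard_normal()

        resid = {
            "left_hippocampus": e_left,
            "right_hippocampus": e_right,
            "nfq": m_resid,
            "meta_roi": rng.standard_normal(),
            "inferior_parietal": rng.standard_normal(),
        }
        values = {}
        for biom in BIOMARKERS:
            b0, b1, s0, s1 = config.curves[biom]
            sigma = s0 + s1 * age
            values[biom] = b0 + b1 * age + shifts.get(biom, 0.0) * sigma + sigma * resid[biom]

        # subject-level true correlation matrix encoding the NFQ value
        corr, nfq_val = _target_correlation(
            values["nfq"],
            labels,
            within=config.within_subsystem_r,
            denominator=config.denominator_r,
            background=config.background_r,
        )
        corr_matrices[sid] = corr
        true_nfq[sid] = nfq_val
        values["nfq"] = nfq_val  # realized (post-PSD-projection) value

        # cognition; recall carries the planted mediation structure
        eps_sd = np.sqrt(max(0.1, 1.0 - (b**2 + c_prime**2 + 2 * a * b * c_prime)))
        ravlt_resid = b * m_resid + c_prime * x_resid + eps_sd * rng.standard_normal()
        if group in ("dAD", "AD"):
            moca = float(np.clip(rng.normal(9.5 if group == "dAD" else 11.0, 2.5), 0, 30))
            ravlt = float(np.clip(rng.normal(20, 8), 0, 75))
            tmtb_mult = 2.5 if group == "dAD" else 2.0
        else:
            moca = float(np.clip(rng.normal(26.5 - 0.04 * (age - 58), 2.0), 0, 30))
            ravlt = float(np.clip(68 - 0.25 * (age - 35) + 10.0 * ravlt_resid, 0, 75))
            tmtb_mult = 1.0
        tmtb = float(
            tmtb_mult * np.exp(np.log(63) + 0.012 * (age - 58) + 0.45 * rng.standard_normal())
        )
        amy_m, amy_s, tau_m, tau_s = SUVR_PARAMS.get(group, (np.nan,) * 4)
        suvr_a = float(rng.normal(amy_m, amy_s)) if group != "normative" else np.nan
        suvr_t = float(rng.normal(tau_m, tau_s)) if group != "normative" else np.nan
        rows.append(
            {
                "id": sid,
                "group": group,
                "age": float(age),
                "sex": str(rng.choice(["M", "F"])),
                "site": str(rng.choice(["MGH", "UCLA", "UMinn", "WashU"]))
                if group == "normative"
                else "Mayo",
                "MoCA": moca,
                "RAVLT_total": ravlt,
                "TMTB": tmtb,
                "amyloid_suvr": suvr_a,
                "tau_suvr": suvr_t,
                "icv": float(rng.normal(1.45e6, 1.3e5)),
                **values,
            }
        )
    cohort = pd.DataFrame(rows)
    ab = a * b
    truth = GroundTruth(
        curves=dict(config.curves),
        effect_table={g: dict(v) for g, v in config.effect_table.items()},
        mediation={
            "a": a,
            "b": b,
            "c_prime": c_prime,
            "acme": ab,
            "ade": c_prime,
            "proportion_mediated": ab / (ab + c_prime),
        },
        labels=labels,
        corr_matrices=corr_matrices,
        true_nfq=true_nfq,
    )
    return cohort, truth


def _target_correlation(
    nfq: float,
    labels: dict[int, str],
    within: float,
    denominator: float,
    background: float,
) -> tuple[np.ndarray, float]:
    """Correlation matrix whose median-connectivity NFQ equals ~nfq.

    pDMN pairs with avDMN and adDMN at x = nfq * denominator / 2 each so
    that (x + x) / denominator = nfq; the matrix is projected to the
    nearest positive semi-definite correlation matrix and the realized NFQ
    recomputed from it.
    """
    k = len(labels)
    x = np.clip(nfq * denominator / 2.0, -0.95, 0.95)
    corr = np.full((k, k), background)
    for i in range(k):
        for j in range(k):
            si, sj = labels[i], labels[j]
            if i == j:
                corr[i, j] = 1.0
            elif si == sj:
                corr[i, j] = within
            elif {si, sj} == {"pDMN", "vDMN"}:
                corr[i, j] = denominator
            elif {si, sj} in ({"pDMN", "avDMN"}, {"pDMN", "adDMN"}):
                corr[i, j] = x
    corr = nearest_correlation(corr)
    realized = _matrix_nfq(corr, labels)
    return corr, realized


def nearest_correlation(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping followed by unit-diagonal rescaling."""
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    w = np.clip(w, eps, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _matrix_nfq(corr: np.ndarray, labels: dict[int, str]) -> float:
    from netfailq.connectivity import subsystem_connectivity_from_matrix

    return compute_nfq(subsystem_connectivity_from_matrix(corr, labels))


# ---------------------------------------------------------------------------
# scan generation


def generate_motion_trace(
    n_frames: int,
    rng: np.random.Generator,
    baseline_amplitude: float = 0.05,
    spike_rate: float = 0.0,
    spike_magnitude: float = 0.4,
    rotation_radius: float = 50.0,
) -> np.ndarray:
    """Motion trace (T x 6) with bounded baseline drift plus optional spikes.

    Baseline per-frame increments are bounded so that the frame-wise
    displacement of a spike-free trace stays strictly below
    ``baseline_amplitude`` at every frame. Spikes are additive translation
    steps with exponential magnitude occurring at Bernoulli(rate) frames.
    """
    b_t = 0.9 * baseline_amplitude / 6.0
    b_r = 0.9 * baseline_amplitude / (6.0 * rotation_radius)
    inc = np.column_stack(
        [
            rng.uniform(-b_t, b_t, size=(n_frames, 3)),
            rng.uniform(-b_r, b_r, size=(n_frames, 3)),
        ]
    )
    inc[0] = 0.0
    if spike_rate > 0:
        hits = rng.random(n_frames) < spike_rate
        hits[0] = False
        mags = rng.exponential(spike_magnitude, size=n_frames) * rng.choice(
            [-1.0, 1.0], size=n_frames
        )
        axis = rng.integers(0, 3, size=n_frames)
        for t in np.flatnonzero(hits):
            inc[t, axis[t]] += mags[t]
    return np.cumsum(inc, axis=0)


def generate_timecourses(
    corr: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
    tr: float = 0.8,
    band: tuple[float, float] = DEFAULT_BAND,
) -> np.ndarray:
    """Band-limited component courses with the target correlation matrix.

    White noise is passed through the same band-pass operator the analysis
    uses, standardized, then mixed by the symmetric square root of the
    target matrix; empirical correlations converge to the target as
    frames -> infinity.
    """
    k = corr.shape[0]
    noise = rng.standard_normal((n_frames, k))
    filtered = bandpass_filter(noise, band=band, tr=tr)
    filtered = filtered / filtered.std(axis=0, ddof=1)
    w, v = np.linalg.eigh(corr)
    root = (v * np.sqrt(np.clip(w, 0, None))) @ v.T
    return filtered @ root.T


def generate_scan(
    subject_id: str,
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    mode: str = "timecourse",
    scene: "SyntheticScene | None" = None,
    voxel_noise_sd: float = 0.0,
    nuisance_amplitude: float = 0.0,
    motion_artifact_amplitude: float = 0.0,
    spike_rate: float = 0.0,
    spike_magnitude: float = 0.4,
    session: int | None = None,
) -> ScanSession:
    """One resting-state session for a subject.

    timecourse mode returns component courses directly; volume mode mixes
    them through the scene's atlas maps, adds voxel noise, injects nuisance
    signals into the noise ROI and a motion-correlated artefact.
    """
    if subject_id not in truth.corr_matrices:
        raise KeyError(f"no ground-truth correlation matrix for {subject_id!r}")
    corr = truth.corr_matrices[subject_id]
    courses = generate_timecourses(corr, config.frames_per_session, rng, tr=config.tr)
    motion = generate_motion_trace(
        config.frames_per_session, rng, spike_rate=spike_rate, spike_magnitude=spike_magnitude
    )
    if mode == "timecourse":
        return ScanSession(
            data=courses, tr=config.tr, motion=motion, subject_id=subject_id, session=session
        )
    if mode != "volume":
        raise ValueError(f"unknown scan mode {mode!r}")
    if scene is None:
        raise ValueError("volume mode requires a SyntheticScene (atlas + tissue maps)")
    atlas = scene.atlas
    t = config.frames_per_session
    vol = np.einsum("tk,kxyz->txyz", courses, atlas.maps)
    if voxel_noise_sd > 0:
        vol = vol + rng.normal(0.0, voxel_noise_sd, size=vol.shape)
    if nuisance_amplitude > 0:
        mask = scene.noise_mask
        nuis = bandpass_filter(rng.standard_normal((t, 3)), tr=config.tr)
        nuis = nuis / nuis.std(axis=0, ddof=1)
        weights = rng.random((3, int(mask.sum())))
        vol[:, mask] += nuisance_amplitude * nuis @ weights
    if motion_artifact_amplitude > 0:
        from netfailq.motion_qc import framewise_displacement

        fd = framewise_displacement(motion)
        fd = (fd - fd.mean()) / (fd.std() + 1e-12)
        pattern = rng.standard_normal(atlas.grid_shape)
        vol += motion_artifact_amplitude * fd[:, None, None, None] * pattern
    return ScanSession(
        data=vol,
        tr=config.tr,
        motion=motion,
        noise_mask=scene.noise_mask,
        subject_id=subject_id,
        session=session,
    )


@dataclass
class SyntheticScene:
    """Volumetric stand-in: atlas maps + tissue probability maps (synthetic)."""

    atlas: ComponentAtlas
    csf_prob: np.ndarray
    wm_prob: np.ndarray
    noise_mask: np.ndarray


def make_default_scene(
    shape: tuple[int, int, int] = (30, 36, 30),
    voxel_mm: float = 4.0,
    components_per_subsystem: int = 2,
    blob_sigma: float = 2.5,
    rng: np.random.Generator | None = None,
) -> SyntheticScene:
    """Desk-scale synthetic volumetric scene with Gaussian-blob atlas maps.

    Component blobs occupy the x > 8 portion of the grid; the x <= 8 slab
    is 'white matter / CSF' with probability 1, whose 2-voxel erosion is
    the noise ROI.
    """
    from netfailq.connectivity import build_noise_roi

    if rng is None:
        rng = np.random.default_rng(7)
    labels = default_labels(components_per_subsystem)
    k = len(labels)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    maps = np.zeros((k,) + shape)
    centers = []
    for i in range(k):
        c = np.array(
            [
                rng.uniform(10, shape[0] - 4),
                rng.uniform(4, shape[1] - 4),
                rng.uniform(4, shape[2] - 4),
            ]
        )
        # keep blobs apart so maps are well-conditioned
        while centers and min(np.linalg.norm(c - np.asarray(o)) for o in centers) < 5.0:
            c = np.array(
                [
                    rng.uniform(10, shape[0] - 4),
                    rng.uniform(4, shape[1] - 4),
                    rng.uniform(4, shape[2] - 4),
                ]
            )
        centers.append(c)
        d2 = sum((g - cc) ** 2 for g, cc in zip(grids, c))
        maps[i] = np.exp(-d2 / (2 * blob_sigma**2))
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    atlas = ComponentAtlas(maps=maps, labels=labels, affine=affine)
    csf = np.zeros(shape)
    wm = np.zeros(shape)
    wm[:9, :, :] = 1.0
    noise_mask = build_noise_roi(csf, wm, threshold=0.9, erosion=2)
    return SyntheticScene(atlas=atlas, csf_prob=csf, wm_prob=wm, noise_mask=noise_mask)


# ---------------------------------------------------------------------------
# writers


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def write_timecourse_tsv(session: ScanSession, path) -> None:
    if session.is_volume:
        raise ValueError("use write_volume_nifti for volume-mode sessions")
    k = session.data.shape[1]
    pd.DataFrame(session.data, columns=[f"comp{i}" for i in range(k)]).to_csv(
        path, sep="\t", index=False
    )


def write_motion_txt(session: ScanSession, path) -> None:
    np.savetxt(path, session.motion, fmt="%.6f")


def write_volume_nifti(session: ScanSession, path, affine=None) -> None:
    import nibabel as nib

    if not session.is_volume:
        raise ValueError("session has no volume data")
    img = nib.Nifti1Image(
        np.moveaxis(session.data, 0, -1).astype(np.float32),
        affine if affine is not None else np.eye(4),
    )
    img.to_filename(str(path))


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "curves": {k: list(v) for k, v in truth.curves.items()},
        "effect_table": truth.effect_table,
        "mediation": truth.mediation,
        "labels": {str(k): v for k, v in truth.labels.items()},
        "true_nfq": truth.true_nfq,
        "corr_matrices": {k: v.tolist() for k, v in truth.corr_matrices.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
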