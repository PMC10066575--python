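"""Structural neurodegeneration biomarkers from regional morphometry tables.

Three biomarkers are derived from Desikan-Killiany regional statistics:

* meta-ROI cortical thickness — the unweighted mean of bilateral thickness
  in entorhinal, inferior temporal, middle temporal, inferior parietal,
  fusiform and precuneus cortex (the Alzheimer-signature composite);
* ICV-adjusted hippocampal volumes (left/right), residual method by
  default with a normative reference fit;
* inferior parietal thickness summed across hemispheres.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Desikan-Killiany parcels entering the thickness meta-ROI. The signature
#: composite uses the middle temporal parcel for its temporal-lobe term;
#: the parcel set is configurable.
META_ROI_REGIONS = (
    "entorhinal",
    "inferiortemporal",
    "middletemporal",
    "inferiorparietal",
    "fusiform",
    "precuneus",
)

HEMISPHERES = ("lh", "rh")


@dataclass
class RegionalStats:
    """Per-region thickness (mm), hippocampal volumes (mm^3) and ICV (mm^3)."""

    thickness: dict[str, float]  # keys like 'lh_entorhinal'
    hippocampus: dict[str, float]  # {'left': mm3, 'right': mm3}
    icv: float
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.thickness.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"invalid thickness for {name}: {v}")
        for side, v in self.hippocampus.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"invalid {side} hippocampal volume: {v}")
        if not np.isfinite(self.icv) or self.icv <= 0:
            raise ValueError(f"invalid ICV: {self.icv}")


@dataclass
class IcvReference:
    """Normative OLS fit of volume on ICV used for residual adjustment."""

    slope: float
    mean_icv: float
    n: int


def meta_roi_thickness(stats: RegionalStats, regions=META_ROI_REGIONS) -> float:
    """Unweighted mean thickness over the meta-ROI parcels, both hemispheres."""
    values = []
    for region in regions:
        for hemi in HEMISPHERES:
            key = f"{hemi}_{region}"
            if key not in stats.thickness:
                raise KeyError(f"missing regional thickness: {key}")
            values.append(stats.thickness[key])
    return float(np.mean(values))


def inferior_parietal_sum(stats: RegionalStats) -> float:
    """Inferior parietal thickness summed across hemispheres (mm)."""
    for key in ("lh_inferiorparietal", "rh_inferiorparietal"):
        if key not in stats.thickness:
            raise KeyError(f"missing regional thickness: {key}")
    return float(
        stats.thickness["lh_inferiorparietal"] + stats.thickness["rh_inferiorparietal"]
    )


def fit_icv_reference(volumes: np.ndarray, icvs: np.ndarray) -> IcvReference:
    """OLS of volume on ICV in the normative reference cohort.

    Patients must never enter this fit; the returned reference is what
    ``icv_correct`` uses to residualize external subjects.
    """
    volumes = np.asarray(volumes, dtype=float)
    icvs = np.asarray(icvs, dtype=float)
    if volumes.shape != icvs.shape or volumes.ndim != 1:
        raise ValueError("volumes and icvs must be 1-D arrays of equal length")
    n = volumes.size
    if n < 10:
        warnings.warn(f"ICV reference fitted on only {n} subjects")
    if np.var(icvs) == 0:
        warnings.warn("zero ICV variance in reference; slope set to 0 (ratio fallback advised)")
        return IcvReference(slope=0.0, mean_icv=float(icvs.mean()), n=n)
    slope = float(np.cov(icvs, volumes, ddof=1)[0, 1] / np.var(icvs, ddof=1))
    return IcvReference(slope=slope, mean_icv=float(icvs.mean()), n=n)


def icv_correct(
    volume: float | np.ndarray,
    icv: float | np.ndarray,
    reference: IcvReference,
    method: str = "residual",
) -> float | np.ndarray:
    """Head-size adjustment of a subcortical volume.

    residual (default): adjusted = volume - slope * (icv - reference mean ICV);
    ratio: adjusted = volume / icv * reference mean ICV.
    Both leave a subject at the reference-mean ICV unchanged.
    """
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if method == "residual":
        out = volume - reference.slope * (icv - reference.mean_icv)
    elif method == "ratio":
        out = volume / icv * reference.mean_icv
    else:
        raise ValueError(f"unknown ICV correction method {method!r}")
    return float(out) if out.ndim == 0 else out


def compute_biomarkers(stats: RegionalStats, reference: dict[str, IcvReference]) -> dict[str, float]:
    """All structural biomarkers for one subject as a flat dict."""
    return {
        "meta_roi": meta_roi_thickness(stats),
        "left_hippocampus": icv_correct(
            stats.hippocampus["left"], stats.icv, reference["left"]
        ),
        "right_hippocampus": icv_correct(
            stats.hippocampus["right"], stats.icv, reference["right"]
        ),
        "inferior_parietal": inferior_parietal_sum(stats),
    }


# ---------------------------------------------------------------------------
# parsing

_ASEG_NAMES = {"left": "Left-Hippocampus", "right": "Right-Hippocampus"}


def parse_regional_stats(
    aparc_lh: str | None = None,
    aparc_rh: str | None = None,
    aseg: str | None = None,
    flat_tsv: str | None = None,
) -> RegionalStats:
    """Build RegionalStats from FreeSurfer-style tables or a flat TSV.

    Either pass ``flat_tsv`` (columns: key, value — keys 'lh_<parcel>',
    'rh_<parcel>', 'left_hippocampus', 'right_hippocampus', 'icv') or the
    three FreeSurfer stats tables (lh/rh aparc + aseg).
    """
    if flat_tsv is not None:
        return _parse_flat_tsv(flat_tsv)
    if aparc_lh is None or aparc_rh is None or aseg is None:
        raise ValueError("need either flat_tsv or all of aparc_lh, aparc_rh, aseg")
    thickness: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for hemi, path in (("lh", aparc_lh), ("rh", aparc_rh)):
        for region, value in _parse_aparc(path).items():
            key = f"{hemi}_{region}"
            thickness[key] = value
            provenance[key] = str(path)
    volumes, icv = _parse_aseg(aseg)
    hippocampus = {}
    for side, struct in _ASEG_NAMES.items():
        if struct not in volumes:
            raise ValueError(f"{aseg}: missing structure row {struct!r}")
        hippocampus[side] = volumes[struct]
        provenance[f"{side}_hippocampus"] = str(aseg)
    provenance["icv"] = str(aseg)
    return RegionalStats(thickness, hippocampus, icv, provenance)


def _parse_flat_tsv(path: str) -> RegionalStats:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("key", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: flat table must have columns 'key' and 'value'")
    kv = dict(zip(df["key"], df["value"].astype(float)))
    hippocampus = {}
    for side in ("left", "right"):
        k = f"{side}_hippocampus"
        if k not in kv:
            raise ValueError(f"{path}: missing {_ASEG_NAMES[side]!r} ({k})")
        hippocampus[side] = kv.pop(k)
    if "icv" not in kv:
        raise ValueError(f"{path}: missing 'icv' row")
    icv = kv.pop("icv")
    return RegionalStats(kv, hippocampus, icv, {k: str(path) for k in kv})


def _parse_aparc(path: str) -> dict[str, float]:
    """FreeSurfer aparc.stats: whitespace table with a '# ColHeaders' line."""
    headers = None
    rows = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("# ColHeaders"):
                headers = line.split()[2:]
                continue
            if not line or line.startswith("#"):
                continue
            if headers is None:
                raise ValueError(f"{path}:{lineno}: data before '# ColHeaders' line")
            parts = line.split()
            if len(parts) != len(headers):
                raise ValueError(
                    f"{path}:{lineno}: {len(parts)} fields, expected {len(headers)}"
                )
            row = dict(zip(headers, parts))
            try:
                rows[row["StructName"]] = float(row["ThickAvg"])
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: missing column {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no parcel rows found")
    return rows


def _parse_aseg(path: str) -> tuple[dict[str, float], float]:
    """FreeSurfer aseg.stats: structure volumes + the eTIV measure line."""
    headers = None
    volumes = {}
    icv = None
    measure_re = re.compile(r"#\s*Measure\s+EstimatedTotalIntraCranialVol.*?,\s*([\d.eE+-]+)\s*,\s*mm\^3")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            m = measure_re.match(line)
            if m:
                icv = float(m.group(1))
                continue
            if line.startswith("# ColHeaders"):
                headers = line.split()[2:]
                continue
            if not line or line.startswith("#"):
                continue
            if headers is None:
                raise ValueError(f"{path}:{lineno}: data before '# ColHeaders' line")
            parts = line.split()
            if len(parts) != len(headers):
                raise ValueError(
                    f"{path}:{lineno}: {len(parts)} fields, expected {len(headers)}"
                )
            row = dict(zip(headers, parts))
            try:
                volumes[row["StructName"]] = float(row["Volume_mm3"])
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: missing column {exc}") from None
    if icv is None:
        raise ValueError(f"{path}: no EstimatedTotalIntraCranialVol measure line")
    return volumes, icv
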