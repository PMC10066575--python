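"""End-to-end orchestration: simulate -> QC -> connectivity -> normative ->
score -> group stats -> mediation -> report.

The pipeline runs the whole analysis on a synthetic cohort (time-course
mode) and writes plain-text artifacts plus a manifest with the config
hash and per-artifact checksums, so a rerun with the same seed reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netfailq import connectivity as conn
from netfailq import group_stats as gs
from netfailq import motion_qc as mqc
from netfailq import normative as norm
from netfailq.mediation import MediationSpec, fit_mediation, summarize_mediation
from netfailq.synthetic_cohort import (
    BIOMARKERS,
    CohortConfig,
    generate_cohort,
    generate_scan,
)

logger = logging.getLogger(__name__)

#: the standard centile-threshold count rules of the results report
DEFAULT_COUNT_RULES = [
    gs.ThresholdRule("nfq", "above", 0.90),
    gs.ThresholdRule("meta_roi", "at_or_below", 0.10),
    gs.ThresholdRule("left_hippocampus", "at_or_below", 0.10),
    gs.ThresholdRule("right_hippocampus", "at_or_below", 0.10),
    gs.ThresholdRule("inferior_parietal", "at_or_below", 0.02),
]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fd_threshold: float = 0.25
    gross_limit: float = 2.0
    band: tuple[float, float] = (0.009, 0.08)
    nfq_variant: str = "default"
    selection_criterion: str = "sbc"
    # calibrated so that ~2% of generated scans trip the motion rules,
    # the exclusion rate of the study cohort this pipeline emulates
    spike_rate: float = 0.005
    spike_magnitude: float = 0.35
    trim_frames: int = 10
    edf_candidates: tuple = tuple((em, es) for em in (2, 3, 4, 5, 6) for es in (2, 3))
    stages: tuple = (
        "simulate",
        "qc",
        "connectivity",
        "normative",
        "score",
        "stats",
        "mediation",
        "report",
    )

    #: stage -> stages that must run before it
    _DEPENDENCIES = {
        "qc": ("simulate",),
        "connectivity": ("simulate", "qc"),
        "normative": ("connectivity",),
        "score": ("normative",),
        "stats": ("score",),
        "mediation": ("connectivity",),
        "report": ("score",),
    }

    def validate_stages(self) -> None:
        for stage in self.stages:
            missing = [
                dep for dep in self._DEPENDENCIES.get(stage, ()) if dep not in self.stages
            ]
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires {missing[0]!r} to run first; "
                    f"enable it or disable {stage!r}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        if "edf_candidates" in raw:
            raw["edf_candidates"] = tuple(tuple(c) for c in raw["edf_candidates"])
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(cohort=cohort, **raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all stages; returns the in-memory artifacts and writes files.

    Stages execute in dependency order; per-stage exclusion counts are
    logged. The returned dict carries the cohort table, QC decisions,
    connectivity profiles, fitted normative models, the Z-score table,
    the counts report, the mediation summary and the manifest.
    """
    config.validate_stages()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.cohort
    enabled = set(config.stages)

    # ------------------------------------------------ simulate
    cohort, truth = generate_cohort(cfg)
    cohort_path = out / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False)

    # ------------------------------------------------ scans + QC + connectivity
    labels = truth.labels
    profiles = []
    qc_rows = []
    n_excluded = 0
    for idx, rec in cohort.iterrows():
        session_profiles = []
        included_flags = []
        for s in range(cfg.sessions_per_subject):
            rng = np.random.default_rng([cfg.seed, 1000 + idx, s])
            scan = generate_scan(
                rec["id"],
                truth,
                cfg,
                rng,
                mode="timecourse",
                spike_rate=config.spike_rate,
                spike_magnitude=config.spike_magnitude,
                session=s,
            )
            decision = mqc.qc_decision(
                f"{rec['id']}_s{s}",
                scan.motion,
                fd_threshold=config.fd_threshold,
                gross_limit=config.gross_limit,
            )
            qc_rows.append(
                {
                    "scan": decision.scan_id,
                    "subject": rec["id"],
                    "session": s,
                    "mean_fd": decision.mean_fd,
                    "included": decision.included,
                    "rule": decision.rule_triggered,
                }
            )
            included_flags.append(decision.included)
            if not decision.included:
                n_excluded += 1
                continue
            nuisance = conn.build_nuisance_matrix(
                scan.motion, np.empty((scan.n_frames, 0))
            )
            cleaned = conn.bandpass_and_regress(
                scan.data, nuisance, band=config.band, tr=cfg.tr
            )
            session_profiles.append(
                conn.session_profile(cleaned, labels, nfq_variant=config.nfq_variant)
            )
        if session_profiles:
            prof = conn.average_sessions(session_profiles)
            prof.subject_id = rec["id"]
            profiles.append(prof)
    qc_df = pd.DataFrame(qc_rows)
    qc_df.to_csv(out / "qc.tsv", sep="\t", index=False)
    logger.info(
        "QC removed %d/%d scans", n_excluded, len(qc_rows)
    )
    prof_df = pd.DataFrame(
        [
            {
                "id": p.subject_id,
                "nfq_measured": p.nfq,
                "n_sessions_used": p.n_sessions_used,
                **{f"{a}__{b}": v for (a, b), v in p.pair_connectivity.items()},
            }
            for p in profiles
        ]
    )
    prof_df.to_csv(out / "profiles.tsv", sep="\t", index=False)

    # measured NFQ replaces the table value for all downstream stages
    analysed = cohort.merge(prof_df[["id", "nfq_measured"]], on="id", how="inner")
    analysed = analysed.drop(columns=["nfq"]).rename(columns={"nfq_measured": "nfq"})

    # ------------------------------------------------ normative fits
    if "normative" not in enabled:
        return {"cohort": cohort, "truth": truth, "qc": qc_df, "profiles": prof_df}
    normative_rows = analysed[analysed["group"] == "normative"]
    models: dict[str, norm.NormativeModel] = {}
    (out / "models").mkdir(exist_ok=True)
    for biom in BIOMARKERS:
        model = norm.fit_normative(
            normative_rows[biom].to_numpy(),
            normative_rows["age"].to_numpy(),
            candidates=list(config.edf_candidates),
            criterion=config.selection_criterion,
            biomarker=biom,
        )
        models[biom] = model
        model.to_json(out / "models" / f"{biom}.json")

    # ------------------------------------------------ score patients/controls
    external = analysed[analysed["group"].isin(["dAD", "AD", "control"])]
    ztable = norm.score_table(models, external)
    ztable.to_csv(out / "zscores.tsv", sep="\t", index=False)

    # ------------------------------------------------ group stats
    counts = gs.centile_threshold_counts(
        ztable[ztable["group"].isin(["dAD", "AD"])], DEFAULT_COUNT_RULES
    )
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)

    # ------------------------------------------------ mediation (recall model)
    med_result = None
    if "mediation" in enabled:
        med_data = analysed[analysed["group"] == "normative"].copy()
        med_data["hippocampus_sum"] = (
            med_data["left_hippocampus"] + med_data["right_hippocampus"]
        )
        med_result = fit_mediation(
            med_data,
            MediationSpec(
                outcome="RAVLT_total",
                treatment="hippocampus_sum",
                mediator="nfq",
                covariates=("age",),
                n_sims=2000,
                seed=cfg.seed,
            ),
        )
        summarize_mediation(med_result).to_csv(
            out / "mediation.tsv", sep="\t", index=False
        )

    # ------------------------------------------------ report + manifest
    report = make_report(ztable, counts)
    (out / "report.txt").write_text(report)
    artifacts = [
        "cohort.tsv",
        "qc.tsv",
        "profiles.tsv",
        "zscores.tsv",
        "counts.tsv",
        "report.txt",
    ]
    if med_result is not None:
        artifacts.append("mediation.tsv")
    manifest = {
        "version": __import__("netfailq").__version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "cohort": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in vars(cfg).items()
                        if not isinstance(v, dict)
                    },
                    "fd_threshold": config.fd_threshold,
                    "band": list(config.band),
                    "nfq_variant": config.nfq_variant,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "scans_removed": n_excluded,
        "scans_total": len(qc_rows),
        "checksums": {a: _checksum(out / a) for a in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "cohort": cohort,
        "truth": truth,
        "qc": qc_df,
        "profiles": prof_df,
        "models": models,
        "ztable": ztable,
        "counts": counts,
        "mediation": med_result,
        "manifest": manifest,
    }


def make_report(ztable: pd.DataFrame, counts: pd.DataFrame | None = None) -> str:
    """Human-readable report: per-subject Z and centile rank per biomarker
    (patients then controls, ordered within group), plus the counts table."""
    wide = ztable.pivot_table(
        index=["group", "subject"],
        columns="biomarker",
        values=["z", "centile"],
        sort=False,
    )
    order = [g for g in ("dAD", "AD", "control") if g in ztable["group"].unique()]
    lines = ["Age-adjusted Z-scores and centile ranks", "=" * 72]
    biomarkers = [b for b in BIOMARKERS if b in ztable["biomarker"].unique()]
    header = f"{'subject':<10}" + "".join(f"{b:>22}" for b in biomarkers)
    sub = " " * 10 + "".join(f"{'Z':>12}{'rank':>10}" for _ in biomarkers)
    lines += [header, sub, "-" * len(sub)]
    for group in order:
        lines.append(f"[{group}]")
        block = wide.loc[group].sort_index(key=lambda s: s.map(_subject_sort_key))
        for subject, row in block.iterrows():
            cells = "".join(
                f"{row[('z', b)]:>12.2f}{row[('centile', b)]:>10.2f}"
                for b in biomarkers
            )
            lines.append(f"{subject:<10}{cells}")
    if counts is not None and not counts.empty:
        lines += ["", "Centile-threshold counts", "-" * 40]
        for _, r in counts.iterrows():
            rel = ">=" if r["direction"] == "above" else "<="
            lines.append(
                f"{r['biomarker']:<20} {r['group']:<8} rank {rel} {r['cutoff']:.2f}: "
                f"{r['count']}/{r['n']}"
            )
    return "\n".join(lines) + "\n"


def _subject_sort_key(s: str):
    import re

    m = re.search(r"(\d+)$", s)
    return (s[: m.start()] if m else s, int(m.group(1)) if m else 0)
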