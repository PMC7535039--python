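"""End-to-end orchestration: cohort in, feature table and statistics out.

A run takes either a manifest of NIfTI files (one volume + GTV + GTVr
[+ isodose] per subject) or a phantom configuration, validates every
subject, partitions each tumor into its two habitats, extracts the 47
features per habitat, and executes the paired statistical stage.
Subjects failing validation are excluded and listed in the run report,
never silently dropped.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from .io import ImageVolume, ROIMask, feature_table, read_mask, read_volume
from .partition import (
    INFIELD_THRESHOLD,
    HabitatPair,
    UnusableSubjectError,
    make_habitats,
    overlap_fraction,
)
from .phantom import PhantomConfig, TextureContrast, generate_cohort
from .quantize import DEFAULT_TOL
from .stats import HabitatComparison, HabitatComparisonResults
from .features.texture import NGTDM_EPS

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str
    manifest: str | None = None            # CSV of per-subject file names
    phantom: PhantomConfig | None = None   # or generate a synthetic cohort
    levels: int = 256                      # Lloyd-Max gray levels
    alpha: float = 0.05
    seed: int = 0
    plots: bool = False
    require_infield: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if (self.manifest is None) == (self.phantom is None):
            raise ValueError("exactly one of manifest / phantom must be given")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        phantom = None
        if "phantom" in raw and raw["phantom"] is not None:
            ph = dict(raw["phantom"])
            if "texture_contrast" in ph:
                ph["texture_contrast"] = TextureContrast(**ph["texture_contrast"])
            if "shape" in ph:
                ph["shape"] = tuple(ph["shape"])
            if "spacing" in ph:
                ph["spacing"] = tuple(ph["spacing"])
            phantom = PhantomConfig(**ph)
        quant = raw.get("quantization", {})
        return cls(
            outdir=raw["outdir"],
            manifest=raw.get("manifest"),
            phantom=phantom,
            levels=int(quant.get("levels", raw.get("levels", 256))),
            alpha=float(raw.get("alpha", 0.05)),
            seed=int(raw.get("seed", 0)),
            plots=bool(raw.get("plots", False)),
            require_infield=bool(raw.get("require_infield", False)),
        )


@dataclass
class SubjectVerdict:
    subject_id: str
    usable: bool
    reasons: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_gtv: int = 0
    n_gtvr: int = 0
    n_gtvnr: int = 0
    infield_fraction: float | None = None
    infield: bool | None = None


def validate_subject(
    volume: ImageVolume,
    gtv: ROIMask,
    gtvr: ROIMask,
    isodose95: ROIMask | None = None,
    subject_id: str = "",
    require_infield: bool = False,
) -> SubjectVerdict:
    """Check one subject's inputs; returns a verdict, never raises."""
    v = SubjectVerdict(subject_id=subject_id, usable=True)
    for name, m in (("GTV", gtv), ("GTVr", gtvr), ("isodose95", isodose95)):
        if m is not None and m.shape != volume.shape:
            v.reasons.append(f"grid mismatch: {name} {m.shape} vs volume {volume.shape}")
            v.usable = False
    if not v.usable:
        return v
    v.n_gtv = gtv.voxel_count
    v.n_gtvr = int(np.count_nonzero(gtvr.data & gtv.data))
    v.n_gtvnr = int(np.count_nonzero(gtv.data & ~gtvr.data))
    if v.n_gtvr < feat.MIN_HABITAT_VOXELS:
        v.reasons.append(f"recurrent habitat too small ({v.n_gtvr} voxels)")
        v.usable = False
    if v.n_gtvnr < feat.MIN_HABITAT_VOXELS:
        v.reasons.append(f"non-recurrent habitat too small ({v.n_gtvnr} voxels)")
        v.usable = False
    if isodose95 is not None and gtvr.voxel_count > 0:
        v.infield_fraction = overlap_fraction(gtvr, isodose95)
        v.infield = v.infield_fraction >= INFIELD_THRESHOLD
        if not v.infield:
            msg = f"out-of-field recurrence (overlap {v.infield_fraction:.3f} < {INFIELD_THRESHOLD})"
            if require_infield:
                v.reasons.append(msg)
                v.usable = False
            else:
                v.warnings.append(msg)
    return v


@dataclass
class RunResult:
    outdir: str
    n_subjects: int
    excluded: list[SubjectVerdict]
    features: pd.DataFrame
    results: HabitatComparisonResults


def _load_subjects(config: RunConfig):
    """Yield (subject_id, volume, gtv, gtvr, isodose|None)."""
    if config.phantom is not None:
        phantom_dir = os.path.join(config.outdir, "phantom")
        manifest = generate_cohort(config.phantom, phantom_dir)
        base = phantom_dir
    else:
        manifest = pd.read_csv(config.manifest)
        base = os.path.dirname(os.path.abspath(config.manifest))
    for _, row in manifest.iterrows():
        vol = read_volume(os.path.join(base, row["image"]))
        vol.id = str(row["subject_id"])
        gtv = read_mask(os.path.join(base, row["gtv"]), vol, role="GTV")
        gtvr = read_mask(os.path.join(base, row["gtvr"]), vol, role="GTVr")
        iso = None
        if "isodose95" in manifest.columns and isinstance(row["isodose95"], str) and row["isodose95"]:
            iso = read_mask(os.path.join(base, row["isodose95"]), vol, role="isodose95")
        yield vol.id, vol, gtv, gtvr, iso


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full workflow; deterministic given the config and seed."""
    os.makedirs(config.outdir, exist_ok=True)
    rec_rows, nonrec_rows = [], []
    verdicts: list[SubjectVerdict] = []
    excluded: list[SubjectVerdict] = []
    for sid, vol, gtv, gtvr, iso in _load_subjects(config):
        verdict = validate_subject(vol, gtv, gtvr, iso, sid, config.require_infield)
        try:
            if verdict.usable:
                pair = make_habitats(gtv, gtvr, subject_id=sid)
                fv_rec, fv_non = feat.extract_all(vol, pair, ng=config.levels)
                rec_rows.append(fv_rec)
                nonrec_rows.append(fv_non)
        except (UnusableSubjectError, feat.HabitatTooSmallError) as exc:
            verdict.usable = False
            verdict.reasons.append(str(exc))
        verdicts.append(verdict)
        if not verdict.usable:
            excluded.append(verdict)
            log.warning("subject %s excluded: %s", sid, "; ".join(verdict.reasons))
    if not rec_rows:
        raise ValueError("no valid subjects")

    table = feature_table(rec_rows + nonrec_rows)
    table = table.sort_values(["subject_id", "roi_role"]).reset_index(drop=True)
    table.to_csv(os.path.join(config.outdir, "features.csv"), index=False, float_format="%.17g")

    model = HabitatComparison(rec_rows, nonrec_rows)
    results = model.fit(alpha=config.alpha)
    results.save(config.outdir)
    _write_run_report(config, verdicts, excluded, results)

    if config.plots:
        from . import plotting

        plotting.plot_correlation_heatmap(results, os.path.join(config.outdir, "corr_heatmap.png"))
        plotting.plot_pca_scatter(results, os.path.join(config.outdir, "pca_scatter.png"))

    return RunResult(
        outdir=config.outdir,
        n_subjects=len(rec_rows),
        excluded=excluded,
        features=table,
        results=results,
    )


def _write_run_report(config, verdicts, excluded, results) -> None:
    lines = [
        "hetrad run report",
        "=" * 60,
        f"subjects analyzed: {len(verdicts) - len(excluded)} of {len(verdicts)}",
        f"quantization levels: {config.levels} (Lloyd-Max, quantile init, tol {DEFAULT_TOL})",
        f"NGTDM epsilon guard: {NGTDM_EPS}",
        f"alpha: {config.alpha}; Shapiro-Wilk branch level: 0.05",
        f"in-field threshold: {INFIELD_THRESHOLD} (inclusive); strict mode: {config.require_infield}",
        "",
        "per-subject log:",
    ]
    for v in verdicts:
        status = "ok" if v.usable else "EXCLUDED"
        extra = ""
        if v.infield_fraction is not None:
            extra = f", infield {v.infield_fraction:.3f} ({'in' if v.infield else 'out of'} field)"
        lines.append(
            f"  {v.subject_id}: {status} | GTV {v.n_gtv}, GTVr {v.n_gtvr}, GTVnr {v.n_gtvnr}{extra}"
        )
        for r in v.reasons:
            lines.append(f"      reason: {r}")
        for w in v.warnings:
            lines.append(f"      warning: {w}")
    lines += ["", results.summary()]
    with open(os.path.join(config.outdir, "run_report.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
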