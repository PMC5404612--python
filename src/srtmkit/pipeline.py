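"""End-to-end orchestration: simulate → fit → ΔBP → statistics → report.

A run is driven by a :class:`RunConfig` (YAML-serializable) and produces a
bundle of artifacts in the output directory: the BP table, the ΔBP table,
a Table-1-style condition report, the test–retest report, optional
parametric/significance maps, a log, and a manifest with the config hash
and per-output checksums.  Given a seed, runs are deterministic; analyze
mode performs no random-number generation at all.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    CohortConfig,
    LPS_ALONE,
    MP_LPS,
    MP_PBO,
    read_scan_table,
    simulate_cohort,
    write_cohort,
)
from .group_stats import (
    bonferroni_threshold,
    build_table1,
    percent_significant_voxels,
    voxelwise_contrast,
)
from .kinetics import (
    SRTMFitter,
    TimeActivityCurve,
    default_k2a_grid,
    fine_from_frames,
    fit_voxelwise,
)
from .occupancy import (
    delta_bp,
    icc_baseline,
    test_retest_variability,
    wilcoxon_signed_rank,
)
from .phantom import LABELS, NAME_TO_LABEL, make_phantom, render_dynamic_image, save_nifti
from .schedule import FrameSchedule

__all__ = ["RunConfig", "run_pipeline", "fit_cohort_bp", "delta_bp_table"]

log = logging.getLogger("srtmkit")

#: pooled report regions -> member simulation regions
POOLED_REGIONS: dict[str, tuple[str, ...]] = {
    "striatum": ("caudate_left", "caudate_right", "putamen_left", "putamen_right",
                 "ventral_striatum_left", "ventral_striatum_right"),
    "putamen": ("putamen_left", "putamen_right"),
    "caudate": ("caudate_left", "caudate_right"),
    "ventral_striatum": ("ventral_striatum_left", "ventral_striatum_right"),
}


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one input source: ``cohort`` (simulate mode) or ``input_dir``
    (analyze mode, consuming TAC tables written by a previous run).
    """

    mode: str = "simulate"                    # "simulate" | "analyze"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None
    outdir: str = "srtmkit_run"
    seed: int | None = None                   # overrides cohort.seed when set
    k2a_grid_size: int = 128
    k2a_min: float = 0.006
    k2a_max: float = 0.6
    voxel: bool = False                       # enable the phantom/voxel path
    voxel_noise_scale: float = 0.3
    phantom_dims: tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: tuple[float, float, float] = (2.1, 2.1, 2.4)
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.mode == "analyze" and not self.input_dir:
            raise ValueError("analyze mode requires input_dir")
        if self.mode == "simulate" and self.input_dir:
            raise ValueError("simulate mode must not set input_dir (one input source)")
        if self.seed is not None:
            self.cohort = dataclasses.replace(self.cohort, seed=int(self.seed))

    @property
    def k2a_grid(self) -> np.ndarray:
        return default_k2a_grid(self.k2a_grid_size, self.k2a_min, self.k2a_max)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["phantom_dims"] = list(self.phantom_dims)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "phantom_dims" in d:
            d["phantom_dims"] = tuple(d["phantom_dims"])
        if "voxel_size_mm" in d:
            d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        return cls(**d)


# ---------------------------------------------------------------------------
# fitting stages (no RNG below this line)

def _pooled_tacs(
    tacs: dict[str, TimeActivityCurve],
    volumes_ml: dict[str, float],
) -> dict[str, TimeActivityCurve]:
    """Volume-weighted pooled TACs for the standard report regions.

    Approximates voxel-pooling of sub-region ROIs: the pooled curve is the
    member-volume-weighted mean, exactly what pooling member voxels gives
    when each member region is internally homogeneous.
    """
    out: dict[str, TimeActivityCurve] = {}
    for name, members in POOLED_REGIONS.items():
        if not all(m in tacs for m in members):
            continue
        w = np.array([volumes_ml.get(m, 1.0) for m in members])
        acts = np.stack([tacs[m].activity for m in members])
        pooled = (w[:, None] * acts).sum(axis=0) / w.sum()
        out[name] = TimeActivityCurve(tacs[members[0]].schedule, pooled, name)
    return out


def fit_cohort_bp(
    scans: list,
    k2a_grid: np.ndarray | None = None,
    volumes_ml: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Fit the SRTM to every region TAC of every scan.

    The reference input for each scan is the fine-grid curve reconstructed
    from that scan's measured cerebellum TAC.  Pooled report regions
    (striatum, putamen, caudate, ventral striatum) are added when their
    members are present.  Returns the long-format BP table.
    """
    rows = []
    for scan in scans:
        tacs = dict(scan.tacs)
        cereb = tacs.pop("cerebellum", None)
        if cereb is None:
            raise ValueError(f"scan {scan.subject_id} has no cerebellum TAC")
        ref_fine = fine_from_frames(cereb)
        fitter = SRTMFitter(ref_fine, cereb.schedule, k2a_grid)
        tacs.update(_pooled_tacs(tacs, volumes_ml or {}))
        for region, tac in tacs.items():
            try:
                fit = fitter.fit(tac)
            except ValueError as exc:   # pragma: no cover - defensive
                log.warning("fit failed for %s %s ses-%s: %s",
                            scan.subject_id, region, scan.session, exc)
                continue
            rows.append(dict(
                subject=scan.subject_id, session=scan.session,
                condition=scan.condition, scan_type=scan.scan_type,
                region=region, bp=fit.bp_nd, r1=fit.r1, k2=fit.k2,
                k2a=fit.k2a, rss=fit.rss, boundary=fit.boundary_flag,
            ))
    return pd.DataFrame(rows)


def delta_bp_table(bp_table: pd.DataFrame) -> pd.DataFrame:
    """Per subject x session x region percent BP change, baseline vs post."""
    piv = bp_table.pivot_table(
        index=["subject", "session", "condition", "region"],
        columns="scan_type", values="bp",
    ).reset_index()
    if not {"baseline", "post"}.issubset(piv.columns):
        raise ValueError("need baseline and post scans to compute ΔBP")
    piv = piv.dropna(subset=["baseline", "post"])
    piv["delta_bp"] = delta_bp(piv["baseline"].to_numpy(), piv["post"].to_numpy())
    return piv.rename(columns={"baseline": "bp_baseline", "post": "bp_post"})[
        ["subject", "session", "condition", "region", "bp_baseline", "bp_post", "delta_bp"]
    ]


def test_retest_report(bp_table: pd.DataFrame) -> dict:
    """Reliability of baseline BP across the two sessions, per region."""
    base = bp_table[bp_table["scan_type"] == "baseline"]
    report: dict = {"regions": {}}
    pooled_rows = []
    for region, sub in base.groupby("region"):
        piv = sub.pivot_table(index="subject", columns="session", values="bp")
        if piv.shape[1] < 2:
            continue
        piv = piv.dropna()
        if piv.shape[0] < 2:
            continue
        m = piv.to_numpy()[:, :2]
        icc, icc_flag = icc_baseline(m)
        p, wflag = wilcoxon_signed_rank(m[:, 0], m[:, 1])
        var = test_retest_variability(m[:, 0], m[:, 1])
        report["regions"][region] = dict(
            icc=icc, icc_undefined=icc_flag, wilcoxon_p=p,
            wilcoxon_degenerate=wflag, mean_abs_percent_var=var, n=int(m.shape[0]),
        )
        if region in ("caudate", "putamen", "ventral_striatum"):
            pooled_rows.append(m)
    if pooled_rows:
        stacked = np.vstack(pooled_rows)
        icc, icc_flag = icc_baseline(stacked)
        report["striatal_subregions_pooled"] = dict(
            icc=icc, icc_undefined=icc_flag,
            mean_abs_percent_var=test_retest_variability(stacked[:, 0], stacked[:, 1]),
            n_region_pairs=int(stacked.shape[0]),
        )
    return report


# ---------------------------------------------------------------------------
# run driver

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    """TSV at 6 significant digits plus a full-precision JSON sidecar."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(df.to_dict(orient="list"), fh)


def _load_scans(input_dir: Path) -> list:
    from .cohort import ScanRecord

    with open(input_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    scans = []
    for entry in manifest["scans"]:
        tacs = read_scan_table(input_dir / entry["file"])
        scans.append(ScanRecord(
            subject_id=entry["subject"], session=int(entry["session"]),
            condition=entry["condition"], scan_type=entry["scan_type"], tacs=tacs,
        ))
    return scans


def _voxel_stage(
    config: RunConfig, cohort: Cohort, outdir: Path, checksums: dict
) -> dict:
    """Phantom/voxel path: render per-scan images, fit voxelwise, contrast
    ΔBP maps between the two MP conditions."""
    region_names = set(cohort.config.regions)
    vol_targets = {
        name: spec.volume_ml for name, spec in cohort.config.regions.items()
    }
    phantom = make_phantom(
        dims=config.phantom_dims, voxel_size_mm=config.voxel_size_mm,
        region_volume_targets_ml=vol_targets,
    )
    striatal_mask = phantom.region_mask([
        NAME_TO_LABEL[n] for n in region_names if n in NAME_TO_LABEL
    ])
    save_nifti(phantom.labels, phantom.voxel_size_mm, outdir / "phantom_labels.nii")

    rng = np.random.default_rng(np.random.SeedSequence(cohort.config.seed).spawn(5)[4])
    dbp_maps: dict[str, dict[str, np.ndarray]] = {MP_LPS: {}, MP_PBO: {}}
    valid_all = np.ones(phantom.labels.shape, dtype=bool)
    for subj in cohort.subjects:
        per_scan: dict[tuple[str, str], object] = {}
        for scan in cohort.scans:
            if scan.subject_id != subj.subject_id:
                continue
            tacs = {n: t for n, t in scan.tacs.items() if n in NAME_TO_LABEL or n == "cerebellum"}
            cereb = tacs["cerebellum"]
            img = render_dynamic_image(
                phantom, tacs, voxel_noise_scale=config.voxel_noise_scale, rng=rng
            )
            ref_fine = fine_from_frames(cereb)
            bp_map = fit_voxelwise(
                img.data, img.schedule, ref_fine, striatal_mask,
                k2a_grid=config.k2a_grid,
            )
            per_scan[(scan.condition, scan.scan_type)] = bp_map
        for cond in dbp_maps:
            if (cond, "baseline") in per_scan and (cond, "post") in per_scan:
                b, p = per_scan[(cond, "baseline")], per_scan[(cond, "post")]
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = 100.0 * (b.bp - p.bp) / b.bp
                dbp_maps[cond][subj.subject_id] = d
                valid_all &= b.valid & p.valid
    subjects = sorted(set(dbp_maps[MP_LPS]) & set(dbp_maps[MP_PBO]))
    result: dict = {"n_subjects": len(subjects)}
    if len(subjects) >= 2:
        a = np.stack([dbp_maps[MP_LPS][s] for s in subjects])
        b = np.stack([dbp_maps[MP_PBO][s] for s in subjects])
        sig = voxelwise_contrast(a, b, valid_all)
        save_nifti(sig.one_minus_p, phantom.voxel_size_mm, outdir / "one_minus_p.nii",
                   sidecar={"threshold": sig.threshold})
        save_nifti(sig.displayed.astype(np.uint8), phantom.voxel_size_mm,
                   outdir / "displayed_mask.nii")
        save_nifti(sig.direction.astype(np.int8), phantom.voxel_size_mm,
                   outdir / "direction.nii")
        pct = {}
        for pooled, members in (("putamen", (3, 4)), ("caudate", (1, 2)),
                                ("ventral_striatum", (5, 6))):
            mask = phantom.region_mask(members)
            if (mask & sig.valid).any():
                pct[pooled] = percent_significant_voxels(sig, mask)
        result["percent_significant_voxels"] = pct
        for f in ("one_minus_p.nii", "displayed_mask.nii", "direction.nii"):
            checksums[f] = _sha256(outdir / f)
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the manifest dict.

    Deterministic given the seed.  On a stage failure, outputs of completed
    stages remain in place together with a ``FAILED`` marker naming the
    stage, and the exception propagates (nonzero CLI exit).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    config_doc = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_doc, sort_keys=True).encode()
    ).hexdigest()
    checksums: dict[str, str] = {}
    stage = "init"
    try:
        if config.mode == "simulate":
            stage = "simulate"
            cohort = simulate_cohort(config.cohort)
            cohort_dir = outdir / "cohort"
            write_cohort(cohort, cohort_dir)
            scans = cohort.scans
            log.info("stage simulate: %d scans, seed %d", len(scans), config.cohort.seed)
        else:
            stage = "load"
            cohort = None
            scans = _load_scans(Path(config.input_dir))
            log.info("stage load: %d scans from %s", len(scans), config.input_dir)

        stage = "fit"
        volumes = {n: s.volume_ml for n, s in config.cohort.regions.items()}
        bp_table = fit_cohort_bp(scans, config.k2a_grid, volumes)
        _write_table(bp_table, outdir / "bp_table.tsv")
        checksums["bp_table.tsv"] = _sha256(outdir / "bp_table.tsv")
        log.info("stage fit: %d fits", len(bp_table))

        stage = "delta_bp"
        dbp = delta_bp_table(bp_table)
        _write_table(dbp, outdir / "delta_bp_table.tsv")
        checksums["delta_bp_table.tsv"] = _sha256(outdir / "delta_bp_table.tsv")
        log.info("stage delta_bp: %d rows", len(dbp))

        stage = "report"
        table1 = build_table1(dbp)
        _write_table(table1, outdir / "table1.tsv")
        checksums["table1.tsv"] = _sha256(outdir / "table1.tsv")
        with open(outdir / "table1.txt", "w") as fh:
            fh.write(_render_table1(table1))
        log.info("stage report: %d rows; Bonferroni threshold %.4f",
                 len(table1), bonferroni_threshold(0.05, 6))

        stage = "test_retest"
        trt = test_retest_report(bp_table)
        with open(outdir / "test_retest.json", "w") as fh:
            json.dump(trt, fh, indent=2)
        checksums["test_retest.json"] = _sha256(outdir / "test_retest.json")
        log.info("stage test_retest: %d regions", len(trt["regions"]))

        voxel_summary = None
        if config.voxel:
            stage = "voxel"
            if cohort is None:
                raise ValueError("the voxel path requires simulate mode")
            voxel_summary = _voxel_stage(config, cohort, outdir, checksums)
            log.info("stage voxel: %s", voxel_summary)

        stage = "manifest"
        manifest = dict(
            software="srtmkit", version=__version__, mode=config.mode,
            seed=config.cohort.seed, config=config_doc, config_hash=config_hash,
            checksums=checksums, voxel=voxel_summary,
            bonferroni_threshold_6=bonferroni_threshold(0.05, 6),
        )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        raise


def _render_table1(table1: pd.DataFrame) -> str:
    lines = [f"{'ROI':<22}{'Vol(ml)':>8}{'MP+LPS':>16}{'MP+PBO':>16}{'P':>9}{'LPS':>16}"]
    for _, r in table1.iterrows():
        def ms(key: str) -> str:
            if f"mean_{key}" not in r or pd.isna(r.get(f"mean_{key}", np.nan)):
                return "-"
            return f"{r[f'mean_{key}']:.1f} ({r[f'sd_{key}']:.1f})"
        p = f"{r['p_value']:.3f}" if "p_value" in r and pd.notna(r.get("p_value")) else "-"
        lines.append(
            f"{r['region']:<22}{r['volume_ml']:>8.1f}{ms('a'):>16}{ms('b'):>16}"
            f"{p:>9}{ms('lps'):>16}"
        )
    return "\n".join(lines) + "\n"
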