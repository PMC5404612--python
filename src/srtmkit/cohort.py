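"""Synthetic crossover-cohort generator for dynamic raclopride-like PET.

Emulates a four-scan crossover design: each subject is scanned at baseline
and after a dopamine-elevating challenge (methylphenidate, MP), once under
endotoxin (LPS) pre-treatment and once under saline placebo (PBO); a small
separate arm receives LPS alone.  Ground-truth kinetics are encoded as SRTM
parameters per region, the challenge reduces the true binding potential by
a subject-level percentage (competition of released dopamine with the
tracer), and noisy frame-averaged TACs are generated on the 33-frame,
120-min schedule.  Null-correlated covariates (MP plasma level, cytokine
curves, POMS fatigue) are produced alongside so that correlation screens
downstream have a known negative truth.

Every magnitude the generator needs that is not a published group statistic
(baseline BP, noise level, reference-curve shape) is a configurable default
documented in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import (
    C11_DECAY_LAMBDA,
    FINE_DT,
    TimeActivityCurve,
    _exp_conv_fine,
    exp_convolve,
    frame_average,
)
from .schedule import DEFAULT_BINNING, FrameSchedule, make_frame_schedule

__all__ = [
    "MP_LPS",
    "MP_PBO",
    "LPS_ALONE",
    "KNOWN_CONDITIONS",
    "ReferenceParams",
    "KineticTruth",
    "RegionSpec",
    "ConditionSpec",
    "CohortConfig",
    "SubjectTruth",
    "ScanRecord",
    "Cohort",
    "Covariates",
    "simulate_reference_tac",
    "simulate_target_tac",
    "simulate_covariates",
    "simulate_cohort",
    "noise_sigma",
    "write_cohort",
    "read_scan_table",
]

MP_LPS = "MP+LPS"
MP_PBO = "MP+PBO"
LPS_ALONE = "LPS"
KNOWN_CONDITIONS = (MP_LPS, MP_PBO, LPS_ALONE)

#: Covariate sampling times, minutes.
MP_DRAW_TIMES = (30.0, 90.0, 150.0)          # post-MP
CYTOKINE_TIMES = (0.0, 60.0, 90.0, 120.0, 180.0, 240.0)  # post pre-treatment
POMS_TIMES = (0.0, 60.0, 210.0)              # post pre-treatment


@dataclass(frozen=True)
class ReferenceParams:
    """Cerebellum reference-curve shape: a difference-of-exponentials bolus.

    ``C(t) = A * (exp(-lw*t) - exp(-lr*t))`` scaled so the maximum equals
    ``peak_amplitude``; the rise rate ``lr`` is solved so the maximum falls
    at ``peak_time``, and ``lw = ln2 / washout_halflife``.
    """

    peak_time: float = 4.0            # min
    peak_amplitude: float = 20.0      # kBq/ml
    washout_halflife: float = 25.0    # min

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")
        if not (self.peak_time > 0 and self.washout_halflife > 0):
            raise ValueError("peak time and washout half-life must be positive")


def simulate_reference_tac(
    params: ReferenceParams | None = None,
    fine_dt: float = FINE_DT,
    t_max: float = 120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free reference-region curve on a regular fine grid over [0, t_max].

    Returns ``(t, y)`` with ``y`` non-negative, zero at t=0, rising to the
    configured peak and decaying with the configured washout half-life.
    """
    if params is None:
        params = ReferenceParams()
    if not fine_dt > 0:
        raise ValueError("fine_dt must be positive")
    t = np.arange(0.0, t_max + fine_dt / 2, fine_dt)
    if params.peak_amplitude == 0.0:
        return t, np.zeros_like(t)
    lw = np.log(2.0) / params.washout_halflife
    tp = params.peak_time

    def peak_residual(lr: float) -> float:
        return np.log(lr / lw) / (lr - lw) - tp

    lr = brentq(peak_residual, lw * 1.0001, 1e3)
    y = np.exp(-lw * t) - np.exp(-lr * t)
    y *= params.peak_amplitude / y.max()
    return t, y


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth SRTM parameters for one region."""

    r1: float
    k2: float      # 1/min
    bp_nd: float
    region: str = ""

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.k2 > 0):
            raise ValueError("R1 and k2 must be positive")
        if self.bp_nd < 0:
            raise ValueError("ground-truth BP_nd must be non-negative")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)


def noise_sigma(
    clean: np.ndarray,
    schedule: FrameSchedule,
    noise_scale: float,
    decay_lambda: float = C11_DECAY_LAMBDA,
) -> np.ndarray:
    """Per-frame Gaussian noise SD for a count-statistics-like model.

    ``sigma = noise_scale * sqrt(C(t_mid) * exp(lambda * t_mid) / dt)`` —
    variance grows with physical decay (fewer true counts late in the scan)
    and shrinks with frame duration.
    """
    c = np.clip(np.asarray(clean, dtype=float), 0.0, None)
    return noise_scale * np.sqrt(
        c * np.exp(decay_lambda * schedule.midpoint) / schedule.duration
    )


def _srtm_forward_fine(
    truth: KineticTruth, t: np.ndarray, ref: np.ndarray
) -> np.ndarray:
    dt = float(t[1] - t[0])
    conv = _exp_conv_fine(ref, dt, truth.k2a)
    return truth.r1 * ref + (truth.k2 - truth.r1 * truth.k2a) * conv


def _two_tissue_forward_fine(
    truth: KineticTruth,
    t: np.ndarray,
    ref: np.ndarray,
    k1_ref: float = 0.1,
    k4: float = 0.1,
) -> np.ndarray:
    """Model-mismatch mode: generate the target with a 2-tissue compartment
    model whose plasma input is recovered from the reference curve.

    The reference is treated as one-tissue with ``K1r = k1_ref`` and
    ``k2r = k2/R1`` (the SRTM consistency condition), giving
    ``Cp = (dCr/dt + k2r*Cr) / K1r``.  The target then follows a 2TC with
    ``K1 = R1*K1r``, free-compartment efflux ``k2t = k2``, ``k3 = BP*k4``.
    """
    dt = float(t[1] - t[0])
    k2r = truth.k2 / truth.r1
    cp = (np.gradient(ref, dt) + k2r * ref) / k1_ref
    k1 = truth.r1 * k1_ref
    k2t = truth.k2
    k3 = truth.bp_nd * k4
    s = k2t + k3 + k4
    disc = np.sqrt(max(s * s - 4.0 * k2t * k4, 0.0))
    a1, a2 = 0.5 * (s - disc), 0.5 * (s + disc)
    if a2 - a1 < 1e-12:
        return k1 * _exp_conv_fine(cp, dt, a1)
    w1 = k1 * (k3 + k4 - a1) / (a2 - a1)
    w2 = k1 * (a2 - k3 - k4) / (a2 - a1)
    return w1 * _exp_conv_fine(cp, dt, a1) + w2 * _exp_conv_fine(cp, dt, a2)


def simulate_target_tac(
    truth: KineticTruth,
    ref_fine: tuple[np.ndarray, np.ndarray],
    schedule: FrameSchedule,
    noise_scale: float = 0.0,
    rng: np.random.Generator | int | None = None,
    forward_model: str = "srtm",
) -> TimeActivityCurve:
    """Frame-averaged noisy target TAC from ground-truth kinetics.

    With ``noise_scale = 0`` this is exactly the frame average of the
    forward model.  Noise is zero-mean Gaussian per frame with SD from
    :func:`noise_sigma` evaluated on the clean frame values.
    """
    t, ref = ref_fine
    if schedule.frame_end[-1] > t[-1] + 1e-9:
        raise ValueError("schedule extends past the reference curve support")
    if forward_model == "srtm":
        fine = _srtm_forward_fine(truth, np.asarray(t, float), np.asarray(ref, float))
    elif forward_model == "2tc":
        fine = _two_tissue_forward_fine(truth, np.asarray(t, float), np.asarray(ref, float))
    else:
        raise ValueError(f"unknown forward model {forward_model!r}")
    clean = frame_average(t, fine, schedule)
    if noise_scale > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        clean = clean + gen.normal(0.0, 1.0, clean.size) * noise_sigma(
            clean, schedule, noise_scale
        )
    return TimeActivityCurve(schedule=schedule, activity=clean, label=truth.region)


# ---------------------------------------------------------------------------
# cohort configuration

@dataclass(frozen=True)
class RegionSpec:
    baseline_bp: float
    volume_ml: float

    def __post_init__(self) -> None:
        if not self.baseline_bp > 0:
            raise ValueError("baseline BP must be positive")


@dataclass(frozen=True)
class ConditionSpec:
    """Population mean and SD of the true percent BP reduction."""

    delta_bp_mean: float
    delta_bp_sd: float

    def __post_init__(self) -> None:
        if self.delta_bp_sd < 0:
            raise ValueError("SD must be non-negative")


def default_regions() -> dict[str, RegionSpec]:
    """Bilateral striatal sub-regions with typical raclopride baseline BP
    and per-side volumes matching the reference ROI set."""
    return {
        "caudate_left": RegionSpec(2.4, 10.2),
        "caudate_right": RegionSpec(2.4, 10.5),
        "putamen_left": RegionSpec(2.8, 10.7),
        "putamen_right": RegionSpec(2.8, 11.3),
        "ventral_striatum_left": RegionSpec(2.2, 1.4),
        "ventral_striatum_right": RegionSpec(2.2, 1.5),
    }


def default_conditions() -> dict[str, ConditionSpec]:
    return {MP_LPS: ConditionSpec(17.1, 3.6), MP_PBO: ConditionSpec(8.8, 3.6)}


@dataclass
class CohortConfig:
    """Everything needed to generate one reproducible synthetic cohort."""

    n_subjects: int = 8
    seed: int = 0
    binning: list[tuple[int, float]] = field(default_factory=lambda: list(DEFAULT_BINNING))
    regions: dict[str, RegionSpec] = field(default_factory=default_regions)
    conditions: dict[str, ConditionSpec] = field(default_factory=default_conditions)
    recenter: bool = False
    noise_scale: float = 0.02
    reference: ReferenceParams = field(default_factory=ReferenceParams)
    r1_mean: float = 1.0
    r1_sd: float = 0.05
    k2_mean: float = 0.3          # 1/min
    k2_sd: float = 0.03
    baseline_bp_cv: float = 0.08  # inter-subject lognormal CV on baseline BP
    injection_cv: float = 0.15    # per-scan reference amplitude variability
    forward_model: str = "srtm"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in self.conditions:
            if name not in KNOWN_CONDITIONS:
                raise ValueError(
                    f"unknown condition {name!r}; expected one of {KNOWN_CONDITIONS}"
                )

    @property
    def schedule(self) -> FrameSchedule:
        return make_frame_schedule(self.binning)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = {k: dataclasses.asdict(v) for k, v in self.regions.items()}
        d["conditions"] = {k: dataclasses.asdict(v) for k, v in self.conditions.items()}
        d["reference"] = dataclasses.asdict(self.reference)
        d["binning"] = [list(b) for b in self.binning]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "regions" in d:
            d["regions"] = {k: RegionSpec(**v) for k, v in d["regions"].items()}
        if "conditions" in d:
            d["conditions"] = {k: ConditionSpec(**v) for k, v in d["conditions"].items()}
        if "reference" in d:
            d["reference"] = ReferenceParams(**d["reference"])
        if "binning" in d:
            d["binning"] = [tuple(b) for b in d["binning"]]
        return cls(**d)


@dataclass
class Covariates:
    """Blood and behavior measures for one subject-session."""

    subject_id: str
    condition: str
    mp_times: np.ndarray          # min post-MP; empty for LPS-alone
    mp_ng_ml: np.ndarray
    cytokine_times: np.ndarray    # min post pre-treatment
    cytokines: dict[str, np.ndarray]   # TNFa / IL6 / IL8, pg/ml
    poms_times: np.ndarray
    poms_fatigue: np.ndarray      # integers 0..4


@dataclass
class SubjectTruth:
    subject_id: str
    baseline_bp: dict[str, float]          # region -> true baseline BP_nd
    delta_bp_true: dict[str, float]        # condition -> true percent reduction
    r1: float
    k2: float
    noise_scale: float


@dataclass
class ScanRecord:
    subject_id: str
    session: int                  # 1-based session index
    condition: str
    scan_type: str                # "baseline" | "post"
    tacs: dict[str, TimeActivityCurve]     # regions + "cerebellum"


@dataclass
class Cohort:
    config: CohortConfig
    schedule: FrameSchedule
    subjects: list[SubjectTruth]
    scans: list[ScanRecord]
    covariates: list[Covariates]
    condition_order: dict[str, list[str]]  # subject -> session condition order

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for region, bp in s.baseline_bp.items():
                for cond, dbp in s.delta_bp_true.items():
                    rows.append(
                        dict(subject=s.subject_id, region=region, condition=cond,
                             baseline_bp=bp, delta_bp_true=dbp)
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate generation

_CYTOKINE_SHAPE = {
    # (baseline pg/ml, LPS peak amplitude pg/ml, peak time min)
    "TNFa": (1.0, 180.0, 90.0),
    "IL6": (1.5, 600.0, 150.0),
    "IL8": (5.0, 280.0, 120.0),
}
_MP_PLASMA = {MP_LPS: (12.7, 7.4), MP_PBO: (11.7, 5.2)}


def _gamma_bump(t: np.ndarray, peak_time: float) -> np.ndarray:
    """Unit-peak bump with maximum at peak_time (shape-2 gamma variate)."""
    x = np.clip(t / peak_time, 0.0, None)
    return (x**2) * np.exp(2.0 * (1.0 - x))


def simulate_covariates(
    subject_id: str,
    condition: str,
    rng: np.random.Generator | int | None = None,
) -> Covariates:
    """Generate blood/behavior covariates for one subject-session.

    Generated independently of the subject's true ΔBP, so any correlation
    with occupancy downstream is sampling noise (the null regime).  MP
    plasma draws exist only when MP is given; cytokines are elevated only
    under LPS; POMS fatigue is an integer 0–4 with an LPS-induced bump.
    """
    if condition not in KNOWN_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    if condition in _MP_PLASMA:
        mu, sd = _MP_PLASMA[condition]
        level = max(rng.normal(mu, sd), 0.5)
        mp_times = np.array(MP_DRAW_TIMES)
        mp = np.clip(level * rng.lognormal(0.0, 0.15, mp_times.size), 0.1, None)
    else:
        mp_times = np.array([])
        mp = np.array([])

    ct = np.array(CYTOKINE_TIMES)
    lps_given = condition in (MP_LPS, LPS_ALONE)
    cytokines: dict[str, np.ndarray] = {}
    for name, (base, amp, peak) in _CYTOKINE_SHAPE.items():
        baseline = base * rng.lognormal(0.0, 0.2, ct.size)
        if lps_given:
            subject_amp = amp * rng.lognormal(0.0, 0.4)
            cytokines[name] = baseline + subject_amp * _gamma_bump(ct, peak)
        else:
            cytokines[name] = baseline

    pt = np.array(POMS_TIMES)
    base_score = int(rng.choice([0, 1], p=[0.7, 0.3]))
    if lps_given:
        bump = int(rng.integers(1, 3))       # fatigue rises by 1 or 2
        late = int(rng.choice([0, 1], p=[0.7, 0.3]))
    else:
        bump = int(rng.choice([-1, 0, 1], p=[0.15, 0.7, 0.15]))
        late = int(rng.choice([-1, 0, 1], p=[0.15, 0.7, 0.15]))
    poms = np.clip(np.array([base_score, base_score + bump, base_score + late]), 0, 4)
    return Covariates(
        subject_id=subject_id,
        condition=condition,
        mp_times=mp_times,
        mp_ng_ml=mp,
        cytokine_times=ct,
        cytokines=cytokines,
        poms_times=pt,
        poms_fatigue=poms.astype(int),
    )


# ---------------------------------------------------------------------------
# cohort generation

def _draw_delta_bp(
    spec: ConditionSpec, n: int, rng: np.random.Generator, recenter: bool
) -> np.ndarray:
    draws = rng.normal(spec.delta_bp_mean, spec.delta_bp_sd, n)
    if recenter and n > 0:
        draws = draws + (spec.delta_bp_mean - draws.mean())
    return draws


def _session_orders(conditions: list[str], n: int, rng: np.random.Generator) -> list[list[str]]:
    """Crossover order per subject; for the two-condition design exactly
    floor(n/2) subjects receive LPS first."""
    if len(conditions) != 2:
        return [list(conditions) for _ in range(n)]
    lps_first_count = n // 2
    lps_first = set(rng.permutation(n)[:lps_first_count].tolist())
    a, b = conditions
    # put the LPS-containing condition first for the chosen half
    lps_cond = a if "LPS" in a else b
    other = b if lps_cond == a else a
    return [
        [lps_cond, other] if i in lps_first else [other, lps_cond]
        for i in range(n)
    ]


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort: truths, noisy TACs, covariates.

    Reproducible given ``config.seed``; per-subject and per-scan random
    streams are spawned deterministically from the root seed.  Post-
    treatment scans are generated with every region's BP reduced from the
    subject's baseline truth by the subject's true ΔBP percent for that
    condition.
    """
    schedule = config.schedule
    root = np.random.SeedSequence(config.seed)
    truth_ss, order_ss, scan_ss, cov_ss = root.spawn(4)
    truth_rng = np.random.default_rng(truth_ss)
    n = config.n_subjects
    conditions = list(config.conditions)

    delta_draws = {
        cond: _draw_delta_bp(spec, n, truth_rng, config.recenter)
        for cond, spec in config.conditions.items()
    }
    orders = _session_orders(conditions, n, np.random.default_rng(order_ss))

    subjects: list[SubjectTruth] = []
    for i in range(n):
        sid = f"sub-{i + 1:02d}"
        r1 = float(np.clip(truth_rng.normal(config.r1_mean, config.r1_sd), 0.3, None))
        k2 = float(np.clip(truth_rng.normal(config.k2_mean, config.k2_sd), 0.05, None))
        baseline = {
            reg: float(spec.baseline_bp * truth_rng.lognormal(0.0, config.baseline_bp_cv))
            for reg, spec in config.regions.items()
        }
        subjects.append(
            SubjectTruth(
                subject_id=sid,
                baseline_bp=baseline,
                delta_bp_true={c: float(delta_draws[c][i]) for c in conditions},
                r1=r1,
                k2=k2,
                noise_scale=config.noise_scale,
            )
        )

    scan_children = scan_ss.spawn(n)
    cov_children = cov_ss.spawn(n)
    scans: list[ScanRecord] = []
    covariates: list[Covariates] = []
    for i, subj in enumerate(subjects):
        per_scan = scan_children[i].spawn(2 * len(orders[i]))
        per_cov = cov_children[i].spawn(len(orders[i]))
        for s_idx, cond in enumerate(orders[i]):
            for k, scan_type in enumerate(("baseline", "post")):
                rng = np.random.default_rng(per_scan[2 * s_idx + k])
                amp = config.reference.peak_amplitude * float(
                    rng.lognormal(0.0, config.injection_cv)
                )
                ref_params = dataclasses.replace(config.reference, peak_amplitude=amp)
                t, ref = simulate_reference_tac(ref_params)
                tacs: dict[str, TimeActivityCurve] = {}
                cereb_clean = frame_average(t, ref, schedule)
                if config.noise_scale > 0:
                    cereb = cereb_clean + rng.normal(0, 1, cereb_clean.size) * noise_sigma(
                        cereb_clean, schedule, config.noise_scale
                    )
                else:
                    cereb = cereb_clean
                tacs["cerebellum"] = TimeActivityCurve(schedule, cereb, "cerebellum")
                reduction = (
                    1.0 - subj.delta_bp_true[cond] / 100.0 if scan_type == "post" else 1.0
                )
                for reg in config.regions:
                    bp = max(subj.baseline_bp[reg] * reduction, 0.0)
                    truth = KineticTruth(r1=subj.r1, k2=subj.k2, bp_nd=bp, region=reg)
                    tacs[reg] = simulate_target_tac(
                        truth, (t, ref), schedule,
                        noise_scale=config.noise_scale, rng=rng,
                        forward_model=config.forward_model,
                    )
                scans.append(
                    ScanRecord(
                        subject_id=subj.subject_id, session=s_idx + 1,
                        condition=cond, scan_type=scan_type, tacs=tacs,
                    )
                )
            covariates.append(
                simulate_covariates(
                    subj.subject_id, cond, np.random.default_rng(per_cov[s_idx])
                )
            )
    return Cohort(
        config=config, schedule=schedule, subjects=subjects, scans=scans,
        covariates=covariates,
        condition_order={s.subject_id: orders[i] for i, s in enumerate(subjects)},
    )


# ---------------------------------------------------------------------------
# on-disk layout: TSV TAC tables + JSON manifest + covariate/truth tables

def _scan_filename(scan: ScanRecord) -> str:
    return f"{scan.subject_id}_ses-{scan.session}_{scan.scan_type}_tacs.tsv"


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Write TAC tables (TSV), covariates (TSV), truth table (TSV) and a
    JSON manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sched = cohort.schedule
    scan_entries = []
    for scan in cohort.scans:
        df = pd.DataFrame(
            {"frame_start": sched.frame_start, "frame_end": sched.frame_end}
        )
        for name, tac in scan.tacs.items():
            df[name] = tac.activity
        fname = _scan_filename(scan)
        # full precision: TAC tables are data interchange, and analyze mode
        # must reproduce simulate-mode fits bit-for-bit from them
        df.to_csv(outdir / fname, sep="\t", index=False, float_format="%.17g")
        scan_entries.append(
            dict(subject=scan.subject_id, session=scan.session,
                 condition=scan.condition, scan_type=scan.scan_type, file=fname)
        )

    cov_rows = []
    for cov in cohort.covariates:
        for tt, v in zip(cov.mp_times, cov.mp_ng_ml):
            cov_rows.append(dict(subject=cov.subject_id, condition=cov.condition,
                                 measure="MP", time_min=tt, value=v))
        for name, curve in cov.cytokines.items():
            for tt, v in zip(cov.cytokine_times, curve):
                cov_rows.append(dict(subject=cov.subject_id, condition=cov.condition,
                                     measure=name, time_min=tt, value=v))
        for tt, v in zip(cov.poms_times, cov.poms_fatigue):
            cov_rows.append(dict(subject=cov.subject_id, condition=cov.condition,
                                 measure="POMS_fatigue", time_min=tt, value=v))
    pd.DataFrame(cov_rows).to_csv(outdir / "covariates.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    cohort.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False,
                                float_format="%.6g")
    manifest = dict(
        seed=cohort.config.seed,
        n_subjects=cohort.config.n_subjects,
        conditions=list(cohort.config.conditions),
        regions=list(cohort.config.regions),
        condition_order=cohort.condition_order,
        scans=scan_entries,
        units="kBq/ml",
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_scan_table(path: str | Path) -> dict[str, TimeActivityCurve]:
    """Read one TAC table (TSV) back into per-region curves."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    sched = FrameSchedule(
        frame_start=df["frame_start"].to_numpy(),
        frame_end=df["frame_end"].to_numpy(),
    )
    return {
        col: TimeActivityCurve(sched, df[col].to_numpy(), col)
        for col in df.columns
        if col not in ("frame_start", "frame_end")
    }
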