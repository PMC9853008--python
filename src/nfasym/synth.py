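"""Seeded synthetic EEG/ECG, ROI and voxel BOLD, and psychometric data.

Every generator takes an explicit seed and is bit-reproducible.  The planted
parameters (asymmetry increment, per-ROI percent signal change, differential
correlation edges, paired psychometric effects) are chosen so the downstream
estimators recover them: the BOLD amplitudes are solved against the same
trimmed blockwise-mean estimator the analysis uses, and the EEG alpha
components dominate the in-band background noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig

from . import glm as _glm
from .paradigm import (
    REST,
    UPREGULATION,
    VIEW,
    ExperimentSchedule,
    build_schedule,
    write_events,
)
from .recording import EEGRecording

__all__ = [
    "EEGSimParams",
    "ROIEffectTable",
    "ConnectivitySpec",
    "CohortSpec",
    "ROITimeSeriesSet",
    "DEFAULT_ROI_EFFECTS",
    "DEFAULT_DELTA_EDGES",
    "PSYCH_DEFAULTS",
    "simulate_eeg",
    "add_gradient_artifact",
    "simulate_roi_bold",
    "simulate_voxel_bold",
    "simulate_psychometrics",
    "simulate_cohort",
    "generate_cohort",
]

# Per-ROI percent-signal-change defaults (psc_up_vs_view, psc_up_vs_rest) for
# the 38-region set used by the connectivity analysis.  Regions without a
# significant published change default to 0.
DEFAULT_ROI_EFFECTS: dict[str, tuple[float, float]] = {
    "Left amygdala": (0.86, 0.70),
    "Right amygdala": (0.65, 0.72),
    "Left insula": (1.0, 0.64),
    "Right insula": (0.91, 0.62),
    "Left anterior cingulate cortex": (0.97, 0.81),
    "Right anterior cingulate cortex": (0.64, 0.38),
    "Left cuneus": (0.45, 1.56),
    "Right cuneus": (0.40, 1.90),
    "Left lingual gyrus": (1.21, 1.39),
    "Right lingual gyrus": (0.0, 0.0),
    "Left posterior cingulate cortex": (0.49, 0.33),
    "Right posterior cingulate cortex": (0.0, 0.0),
    "Left thalamus": (1.07, 0.85),
    "Right thalamus": (0.86, 0.65),
    "Left caudate": (0.86, 0.65),
    "Right caudate": (0.74, 0.49),
    "Left hippocampus": (0.57, 0.56),
    "Right hippocampus": (0.44, 0.59),
    "Left dorsomedial prefrontal cortex": (0.85, 1.02),
    "Right dorsomedial prefrontal cortex": (0.37, 0.81),
    "Left orbitofrontal cortex": (1.13, 1.04),
    "Right orbitofrontal cortex": (1.12, 0.81),
    "Left middle temporal gyrus": (0.66, 0.59),
    "Right middle temporal gyrus": (0.69, 0.70),
    "Left ventral striatum": (1.17, 0.84),
    "Right ventral striatum": (0.81, 0.66),
    "Left ventrolateral prefrontal cortex": (0.67, 0.81),
    "Right ventrolateral prefrontal cortex": (0.65, 0.58),
    "Left dorsolateral prefrontal cortex": (0.84, 0.90),
    "Right dorsolateral prefrontal cortex": (0.76, 0.75),
    "Left superior parietal": (0.46, 0.69),
    "Right superior parietal": (0.33, 0.89),
    "Left inferior parietal": (0.60, 0.41),
    "Right inferior parietal": (1.32, 0.53),
    "Left supramarginal": (0.87, 0.42),
    "Right supramarginal": (0.0, 0.0),
    "Left postcentral": (0.67, 0.56),
    "Right postcentral": (0.0, 0.0),
}

# Differential-connectivity edges planted for the experimental cohort (pairs
# whose Upregulation-block correlation is raised by delta_r).
DEFAULT_DELTA_EDGES: tuple[tuple[str, str, float], ...] = (
    ("Left amygdala", "Left thalamus", 0.3),
    ("Left thalamus", "Left dorsomedial prefrontal cortex", 0.3),
    ("Left thalamus", "Left insula", 0.3),
    ("Left thalamus", "Left orbitofrontal cortex", 0.3),
    ("Left thalamus", "Left ventrolateral prefrontal cortex", 0.3),
    ("Left thalamus", "Left postcentral", 0.3),
    ("Left dorsomedial prefrontal cortex", "Left ventral striatum", 0.3),
    ("Left orbitofrontal cortex", "Left ventrolateral prefrontal cortex", 0.3),
)

# scale -> group -> (mean_before, sd_before, planted_d)
PSYCH_DEFAULTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "PANAS": {"experimental": (52.2, 11.5, -0.058), "control": (54.2, 5.9, -0.22)},
    "PANAS negative mood states": {
        "experimental": (20.8, 7.2, -1.09),
        "control": (22.1, 6.0, -0.50),
    },
    "PANAS positive mood states": {
        "experimental": (31.4, 6.1, 0.97),
        "control": (32.1, 5.7, 0.28),
    },
    "POMS": {"experimental": (24.6, 10.9, -0.83), "control": (27.1, 11.3, -0.38)},
    "TMD": {"experimental": (7.5, 11.5, -1.27), "control": (6.6, 11.2, -0.26)},
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EEGSimParams:
    alpha_band: tuple[float, float] = (8.0, 12.0)
    asym_effect: float = 0.3
    noise_exponent: float = 1.0
    alpha_amp: float = 2.0
    noise_amp: float = 1.0
    heart_rate_bpm: float = 60.0
    rr_jitter_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_band[0] < self.alpha_band[1]:
            raise SimulationError("alpha band low must be below high")


@dataclass(frozen=True)
class ROIEffectTable:
    effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_EFFECTS)
    )

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(self.effects)

    def __len__(self) -> int:
        return len(self.effects)


@dataclass(frozen=True)
class ConnectivitySpec:
    base_corr: float | np.ndarray = 0.1
    delta_edges: tuple[tuple[str, str, float], ...] = ()
    ar1: float = 0.3

    def matrices(self, roi_names) -> tuple[np.ndarray, np.ndarray]:
        """(base, upregulation) correlation matrices, PD-repaired."""
        n = len(roi_names)
        if np.isscalar(self.base_corr):
            base = np.full((n, n), float(self.base_corr))
            np.fill_diagonal(base, 1.0)
        else:
            base = np.array(self.base_corr, dtype=float)
            if base.shape != (n, n):
                raise SimulationError(f"base_corr shape {base.shape} != ({n}, {n})")
        up = base.copy()
        index = {name: i for i, name in enumerate(roi_names)}
        bad = []
        for a, b, dr in self.delta_edges:
            if a not in index or b not in index:
                raise SimulationError(f"delta edge references unknown ROI: {(a, b)}")
            i, j = index[a], index[b]
            up[i, j] += dr
            up[j, i] += dr
            if abs(up[i, j]) >= 1.0:
                bad.append((a, b))
        if bad:
            raise SimulationError(f"delta edges push |r| >= 1: {bad}")
        return _nearest_pd_corr(base), _nearest_pd_corr(up)


@dataclass(frozen=True)
class ROITimeSeriesSet:
    """ROI-mean BOLD series (n_volumes x n_rois) aligned to a schedule."""

    frame: pd.DataFrame
    tr: float

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# tr={self.tr}\n")
            self.frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "ROITimeSeriesSet":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# tr="):
                raise ValueError(f"{path}: missing '# tr=' header")
            tr = float(first.split("=", 1)[1])
            frame = pd.read_csv(fh, sep="\t")
        return cls(frame=frame, tr=tr)


@dataclass(frozen=True)
class CohortSpec:
    n_experimental: int = 18
    n_control: int = 14
    schedule: ExperimentSchedule = field(default_factory=build_schedule)
    eeg: EEGSimParams = field(default_factory=EEGSimParams)
    roi: ROIEffectTable = field(default_factory=ROIEffectTable)
    conn: ConnectivitySpec = field(
        default_factory=lambda: ConnectivitySpec(delta_edges=DEFAULT_DELTA_EDGES)
    )
    psych_effects: dict = field(default_factory=lambda: PSYCH_DEFAULTS)
    bold_noise_sd: float = 0.5
    psych_rho: float = 0.5
    #: scale applied to the control group's planted PSC effects.  Both groups
    #: share the paradigm-driven activation by default; only the delta edges,
    #: the EEG asymmetry increment and the psych effects separate them.
    control_psc_scale: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experimental < 1 or self.n_control < 1:
            raise SimulationError("cohort sizes must be >= 1")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent noise with unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _alpha_component(
    rng: np.random.Generator, n: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-SD narrowband Gaussian noise confined to ``band``."""
    white = rng.standard_normal(n)
    nyq = rate / 2.0
    sos = spsig.butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    x = spsig.sosfiltfilt(sos, white)
    return x / x.std()


def _ecg_train(
    rng: np.random.Generator,
    duration: float,
    rate: float,
    bpm: float,
    jitter_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Spiky ECG-like signal plus the planted R-peak times."""
    mean_rr = 60.0 / bpm
    times = []
    t = mean_rr
    while t < duration - 0.5:
        times.append(t)
        rr = mean_rr + rng.normal(0.0, jitter_s)
        t += max(0.3, rr)
    peak_times = np.array(times)
    n = int(round(duration * rate))
    ecg = 0.02 * rng.standard_normal(n)
    width = 0.02  # seconds; narrow Gaussian R wave
    t_axis = np.arange(n) / rate
    for pt in peak_times:
        lo = max(0, int((pt - 5 * width) * rate))
        hi = min(n, int((pt + 5 * width) * rate))
        ecg[lo:hi] += np.exp(-0.5 * ((t_axis[lo:hi] - pt) / width) ** 2)
    return ecg, peak_times


def simulate_eeg(
    schedule: ExperimentSchedule,
    params: EEGSimParams,
    profile: str = "experimental",
) -> EEGRecording:
    """F3/F4/ECG recording with a block-dependent alpha-power asymmetry.

    For the experimental profile the F4 alpha amplitude is scaled by
    ``exp(asym_effect / 2)`` during Upregulation samples, i.e. the alpha
    *power* ratio F4/F3 is ``exp(asym_effect)`` there and 1 elsewhere; the
    control profile plants no asymmetry change anywhere.
    """
    if profile not in ("experimental", "control"):
        raise SimulationError(f"unknown profile {profile!r}")
    rate = schedule.eeg_rate
    if params.alpha_band[1] >= rate / 2.0:
        raise SimulationError("alpha band exceeds Nyquist frequency")
    rng = np.random.default_rng(params.seed)
    n = int(round(schedule.total_duration * rate))

    up_mask = np.zeros(n, dtype=bool)
    for _, _, sl in schedule.sample_slices(rate, label=UPREGULATION):
        up_mask[sl] = True

    f3 = params.noise_amp * _pink_noise(rng, n, params.noise_exponent)
    f4 = params.noise_amp * _pink_noise(rng, n, params.noise_exponent)
    a3 = _alpha_component(rng, n, rate, params.alpha_band)
    a4 = _alpha_component(rng, n, rate, params.alpha_band)
    gain = np.ones(n)
    if profile == "experimental" and params.asym_effect != 0.0:
        gain[up_mask] = np.exp(params.asym_effect / 2.0)
    f3 = f3 + params.alpha_amp * a3
    f4 = f4 + params.alpha_amp * gain * a4

    ecg, peaks = _ecg_train(
        rng, schedule.total_duration, rate, params.heart_rate_bpm, params.rr_jitter_s
    )
    return EEGRecording(
        data=np.vstack([f3, f4, ecg]),
        rate=rate,
        channels=("F3", "F4", "ECG"),
        meta={"r_peaks": peaks, "profile": profile},
    )


def add_gradient_artifact(
    recording: EEGRecording,
    period_s: float,
    template_amplitude: float,
    seed: int = 0,
) -> EEGRecording:
    """Add a fixed periodic high-amplitude template to the EEG channels.

    The template (smoothed random shape scaled to ``template_amplitude``) is
    stored on the returned recording's ``meta['gradient_template']`` so tests
    can subtract it exactly.
    """
    if period_s <= 0:
        raise SimulationError("period_s must be positive")
    rng = np.random.default_rng(seed)
    plen = int(round(period_s * recording.rate))
    raw = rng.standard_normal(plen)
    kernel = np.hanning(max(5, plen // 10))
    template = np.convolve(raw, kernel / kernel.sum(), mode="same")
    sd = template.std()
    if sd > 0:
        template = template / sd * template_amplitude
    else:
        template = template * 0.0
    data = recording.data.copy()
    n = recording.n_samples
    tiled = np.tile(template, n // plen + 1)[:n]
    for i, name in enumerate(recording.channels):
        if name.upper() != "ECG":
            data[i] += tiled
    meta = dict(recording.meta or {})
    meta["gradient_template"] = template
    meta["gradient_period_s"] = period_s
    return replace(recording, data=data, meta=meta)


def _nearest_pd_corr(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped projection to the nearest PD correlation matrix."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() > eps:
        return sym
    vals = np.clip(vals, eps, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _bold_amplitudes(
    schedule: ExperimentSchedule,
    psc_uv: float,
    psc_ur: float,
    trim_up_vols: int = 2,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Solve View/Up regressor amplitudes so the trimmed blockwise-mean PSC
    estimator returns exactly (psc_uv, psc_ur) on the noiseless signal."""
    x_v = _glm.condition_regressor(schedule, VIEW)
    x_u = _glm.condition_regressor(schedule, UPREGULATION)
    mv = _glm.block_volume_means(x_v, schedule, trim_up_vols)
    mu = _glm.block_volume_means(x_u, schedule, trim_up_vols)
    puv, pur = psc_uv / 100.0, psc_ur / 100.0
    a_mat = np.array(
        [
            [
                mv[UPREGULATION] - (1 + puv) * mv[VIEW],
                mu[UPREGULATION] - (1 + puv) * mu[VIEW],
            ],
            [
                mv[UPREGULATION] - (1 + pur) * mv[REST],
                mu[UPREGULATION] - (1 + pur) * mu[REST],
            ],
        ]
    )
    rhs = np.array([puv, pur])
    a_v, a_u = np.linalg.solve(a_mat, rhs)
    return a_v, a_u, x_v, x_u


def simulate_roi_bold(
    schedule: ExperimentSchedule,
    roi: ROIEffectTable,
    conn: ConnectivitySpec,
    noise_sd: float = 0.5,
    seed: int = 0,
    baseline: float = 100.0,
) -> ROITimeSeriesSet:
    """ROI-mean BOLD with planted PSC effects and block-dependent correlation.

    Signal: ``baseline * (1 + a_view * x_view + a_up * x_up)`` with the
    amplitudes calibrated against the trimmed PSC estimator.  Noise: AR(1)
    series whose innovations are drawn with the base correlation matrix in
    Rest/View volumes and the delta-augmented matrix in Upregulation volumes.
    """
    names = roi.roi_names
    n_roi = len(names)
    n_vol = schedule.n_volumes
    base_c, up_c = conn.matrices(names)
    l_base = np.linalg.cholesky(base_c)
    l_up = np.linalg.cholesky(up_c)

    up_vols = np.zeros(n_vol, dtype=bool)
    for _, _, sl in schedule.volume_slices(label=UPREGULATION):
        up_vols[sl] = True

    signal = np.empty((n_vol, n_roi))
    for j, name in enumerate(names):
        psc_uv, psc_ur = roi.effects[name]
        a_v, a_u, x_v, x_u = _bold_amplitudes(schedule, psc_uv, psc_ur)
        signal[:, j] = baseline * (1.0 + a_v * x_v + a_u * x_u)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_vol, n_roi))
    innov = np.empty_like(z)
    innov[~up_vols] = z[~up_vols] @ l_base.T
    innov[up_vols] = z[up_vols] @ l_up.T
    phi = conn.ar1
    noise = np.empty_like(innov)
    noise[0] = innov[0]
    fade = np.sqrt(1.0 - phi**2)
    for t in range(1, n_vol):
        noise[t] = phi * noise[t - 1] + fade * innov[t]

    frame = pd.DataFrame(signal + noise_sd * noise, columns=list(names))
    return ROITimeSeriesSet(frame=frame, tr=schedule.tr)


def simulate_voxel_bold(
    grid_shape: tuple[int, int, int],
    cluster_specs: list[tuple[np.ndarray, float]],
    schedule: ExperimentSchedule,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline: float = 100.0,
) -> np.ndarray:
    """4D volume with HRF-convolved active clusters (PSC vs Rest baseline).

    ``cluster_specs`` is a list of ``(voxel_coords, psc)`` where
    ``voxel_coords`` is an (m, 3) integer array.
    """
    n_vol = schedule.n_volumes
    x_u = _glm.condition_regressor(schedule, UPREGULATION)
    data = np.full((*grid_shape, n_vol), baseline, dtype=float)
    for coords, psc in cluster_specs:
        coords = np.asarray(coords, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise SimulationError("cluster coords must be (m, 3)")
        if (coords < 0).any() or (coords >= np.array(grid_shape)).any():
            raise SimulationError(f"cluster voxels outside grid {grid_shape}")
        for i, j, k in coords:
            data[i, j, k, :] += baseline * (psc / 100.0) * x_u
    rng = np.random.default_rng(seed)
    data += noise_sd * rng.standard_normal(data.shape)
    return data


def simulate_psychometrics(
    n: int,
    mean_before: float,
    sd_before: float,
    planted_d: float,
    rho_pair: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired before/after scores with a planted pooled-SD effect size.

    Before and after share the population SD, so the pooled-SD effect
    ``(m_after - m_before) / sd`` equals ``planted_d`` in expectation.
    """
    if n < 2:
        raise SimulationError("n must be >= 2")
    if not -1.0 < rho_pair < 1.0:
        raise SimulationError("|rho_pair| must be < 1")
    rng = np.random.default_rng(seed)
    zb = rng.standard_normal(n)
    za = rho_pair * zb + np.sqrt(1.0 - rho_pair**2) * rng.standard_normal(n)
    before = mean_before + sd_before * zb
    after = mean_before + planted_d * sd_before + sd_before * za
    return pd.DataFrame({"subject": np.arange(n), "before": before, "after": after})


# ---------------------------------------------------------------------------
# cohort assembly


def _subject_seeds(master_seed: int, n: int) -> list[int]:
    seq = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0]) for s in seq.spawn(n)]


def generate_cohort(spec: CohortSpec, with_eeg: bool = True) -> dict:
    """In-memory cohort: per-subject EEG recordings, ROI BOLD and psych table.

    Returns ``{"subjects": [...], "scores": DataFrame, "manifest": dict}``
    where each subject entry holds id, group, seed, eeg (or None) and roi
    series.  The experimental group carries the planted asymmetry, PSC and
    delta-edge effects; the control group is null (no asymmetry change, no
    delta edges) apart from the paradigm-driven activation shared by both.
    """
    n_total = spec.n_experimental + spec.n_control
    seeds = _subject_seeds(spec.master_seed, 2 * n_total + 1)
    groups = ["experimental"] * spec.n_experimental + ["control"] * spec.n_control

    scale = spec.control_psc_scale
    control_roi = ROIEffectTable(
        effects={
            name: (uv * scale, ur * scale) for name, (uv, ur) in spec.roi.effects.items()
        }
    )
    control_conn = replace(spec.conn, delta_edges=())

    subjects = []
    for idx, group in enumerate(groups):
        sid = f"sub-{idx + 1:02d}"
        eeg_seed, bold_seed = seeds[2 * idx], seeds[2 * idx + 1]
        eeg = None
        if with_eeg:
            params = replace(spec.eeg, seed=eeg_seed)
            eeg = simulate_eeg(spec.schedule, params, profile=group)
        roi_table = spec.roi if group == "experimental" else control_roi
        conn = spec.conn if group == "experimental" else control_conn
        bold = simulate_roi_bold(
            spec.schedule, roi_table, conn, noise_sd=spec.bold_noise_sd, seed=bold_seed
        )
        subjects.append(
            {"subject": sid, "group": group, "seed_eeg": eeg_seed, "seed_bold": bold_seed,
             "eeg": eeg, "roi_bold": bold}
        )

    psych_rng = np.random.default_rng(seeds[-1])
    score_rows = []
    for scale, per_group in spec.psych_effects.items():
        for group, (m0, s0, d) in per_group.items():
            n = spec.n_experimental if group == "experimental" else spec.n_control
            table = simulate_psychometrics(
                max(n, 2), m0, s0, d, rho_pair=spec.psych_rho,
                seed=int(psych_rng.integers(2**31)),
            ).iloc[:n]
            for _, row in table.iterrows():
                prefix = "exp" if group == "experimental" else "ctl"
                score_rows.append(
                    {
                        "subject": f"{prefix}-{int(row['subject']) + 1:02d}",
                        "group": group,
                        "scale": scale,
                        "before": row["before"],
                        "after": row["after"],
                    }
                )
    scores = pd.DataFrame(score_rows)

    manifest = {
        "master_seed": spec.master_seed,
        "n_experimental": spec.n_experimental,
        "n_control": spec.n_control,
        "asym_effect": spec.eeg.asym_effect,
        "delta_edges": [list(e) for e in spec.conn.delta_edges],
        "roi_effects": {k: list(v) for k, v in spec.roi.effects.items()},
        "bold_noise_sd": spec.bold_noise_sd,
        "subject_seeds": [
            {"subject": s["subject"], "group": s["group"],
             "seed_eeg": s["seed_eeg"], "seed_bold": s["seed_bold"]}
            for s in subjects
        ],
    }
    return {"subjects": subjects, "scores": scores, "manifest": manifest}


def simulate_cohort(spec: CohortSpec, out_dir, with_eeg: bool = True) -> dict:
    """Write a cohort dataset to ``out_dir`` and return the manifest.

    Layout: ``events.tsv``, ``scores.tsv``, ``manifest.json`` and one
    ``<subject>_eeg.tsv`` / ``<subject>_roi_bold.tsv`` pair per subject.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec, with_eeg=with_eeg)
    try:
        write_events(spec.schedule, out / "events.tsv")
        for sub in cohort["subjects"]:
            if sub["eeg"] is not None:
                sub["eeg"].to_tsv(out / f"{sub['subject']}_eeg.tsv")
            sub["roi_bold"].to_tsv(out / f"{sub['subject']}_roi_bold.tsv")
        cohort["scores"].to_csv(out / "scores.tsv", sep="\t", index=False)
        groups = pd.DataFrame(
            [{"subject": s["subject"], "group": s["group"]} for s in cohort["subjects"]]
        )
        groups.to_csv(out / "participants.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(cohort["manifest"], fh, indent=2)
    except Exception:
        for path in out.glob("*"):
            path.unlink()
        raise
    return cohort["manifest"]
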