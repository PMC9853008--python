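"""Block-design GLM: HRF, design matrix, OLS, cluster thresholding, PSC.

The activation analysis regresses each voxel (or ROI mean) time series on
HRF-convolved condition boxcars plus motion confounds and an intercept.
Cluster-level correction uses a permutation max-cluster-size null
(Freedman-Lane residual shuffling) rather than a random-field closed form,
which gives exact finite-sample control on small synthetic grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .paradigm import ANALYSIS_LABELS, REST, UPREGULATION, VIEW, ExperimentSchedule

__all__ = [
    "hrf",
    "condition_regressor",
    "DesignMatrix",
    "build_design",
    "highpass",
    "smooth",
    "GLMFit",
    "fit_glm",
    "contrast_t",
    "Cluster",
    "cluster_correct",
    "block_volume_means",
    "psc_from_series",
    "roi_percent_signal_change",
    "roi_effect_sizes",
]


class DesignError(ValueError):
    pass


def hrf(t, peak: float = 6.0, undershoot: float = 16.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response (h(0) = 0)."""
    t = np.asarray(t, dtype=float)
    pos = sps.gamma.pdf(t, peak)
    neg = sps.gamma.pdf(t, undershoot) / ratio
    out = pos - neg
    return np.where(t < 0, 0.0, out)


def condition_regressor(
    schedule: ExperimentSchedule, label: str, dt: float = 0.1
) -> np.ndarray:
    """HRF-convolved boxcar for ``label`` sampled at the volume grid.

    The HRF is area-normalized so a sustained block plateaus at 1, making
    regression coefficients directly interpretable as fractional amplitude.
    """
    total = schedule.total_duration
    n_fine = int(round(total / dt))
    box = np.zeros(n_fine)
    for _, lab, start, end in schedule.blocks():
        if lab == label:
            box[int(round(start / dt)) : int(round(end / dt))] = 1.0
    t_hrf = np.arange(0, 32.0, dt)
    kernel = hrf(t_hrf)
    kernel = kernel / (kernel.sum() * dt)
    conv = np.convolve(box, kernel)[:n_fine] * dt
    vol_idx = (np.arange(schedule.n_volumes) * schedule.tr / dt).astype(int)
    return conv[np.minimum(vol_idx, n_fine - 1)]


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_columns)
    names: tuple[str, ...]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.names))
        for name, w in weights.items():
            c[self.names.index(name)] = w
        return c


def build_design(
    schedule: ExperimentSchedule, motion: np.ndarray | None = None
) -> DesignMatrix:
    """Three condition regressors + 6 motion confounds + intercept."""
    n_vol = schedule.n_volumes
    if motion is None:
        motion = np.zeros((n_vol, 6))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_vol, 6):
        raise DesignError(f"motion table must be ({n_vol}, 6), got {motion.shape}")
    cols, names = [], []
    for label in (UPREGULATION, VIEW, REST):
        reg = condition_regressor(schedule, label)
        if not np.any(reg):
            raise DesignError(f"condition {label} produces an all-zero regressor")
        cols.append(reg)
        names.append(label)
    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion{j + 1}")
    cols.append(np.ones(n_vol))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=tuple(names))


def highpass(series: np.ndarray, cutoff_hz: float, tr: float) -> np.ndarray:
    """Discrete-cosine high-pass projection (drift removal, incl. the mean).

    Projects out DCT-II basis functions with frequency below ``cutoff_hz``.
    Idempotent by construction.
    """
    y = np.asarray(series, dtype=float)
    n = y.shape[0]
    if cutoff_hz >= 0.5 / tr:
        raise ValueError("cutoff must lie below the volume Nyquist frequency")
    n_basis = int(np.floor(2.0 * n * tr * cutoff_hz)) + 1  # k = 0 .. K
    i = np.arange(n)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n)) for k in range(n_basis)]
    )
    qmat, _ = np.linalg.qr(basis)
    return y - qmat @ (qmat.T @ y)


def smooth(volume4d: np.ndarray, fwhm_vox: float) -> np.ndarray:
    """Gaussian spatial smoothing (sigma = FWHM / 2.3548) on the 3 space axes."""
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return ndimage.gaussian_filter(
        np.asarray(volume4d, dtype=float), sigma=(sigma, sigma, sigma, 0), mode="reflect"
    )


@dataclass(frozen=True)
class GLMFit:
    design: DesignMatrix
    betas: np.ndarray  # (n_columns, n_series)
    sigma2: np.ndarray  # (n_series,)
    df: int
    xtx_inv: np.ndarray
    data_scale: float = 1.0  # RMS of the data, for degenerate-variance detection


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares of ``data`` (n_volumes x n_series) on the design."""
    y = np.asarray(data, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise DesignError(f"data rows {y.shape[0]} != design rows {x.shape[0]}")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # all-zero confound columns (e.g. motionless synthetic data) are
        # harmless; genuine collinearity among active columns is an error
        zero_cols = ~np.any(x != 0, axis=0)
        active_rank = np.linalg.matrix_rank(x[:, ~zero_cols])
        if active_rank < (~zero_cols).sum():
            bad = _collinear_columns(x[:, ~zero_cols], [n for n, z in zip(design.names, zero_cols) if not z])
            raise DesignError(f"design is rank deficient; collinear columns: {bad}")
    xtx_inv = np.linalg.pinv(x.T @ x)
    betas = xtx_inv @ x.T @ y
    resid = y - x @ betas
    df = x.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / df
    scale = float(np.sqrt(np.mean(y**2))) or 1.0
    return GLMFit(
        design=design, betas=betas, sigma2=sigma2, df=df, xtx_inv=xtx_inv,
        data_scale=scale,
    )


def _collinear_columns(x: np.ndarray, names) -> list[str]:
    bad = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ proj
        denom = np.linalg.norm(x[:, j])
        if denom == 0 or np.linalg.norm(resid) / denom < 1e-10:
            bad.append(names[j])
    return bad


def contrast_t(fit: GLMFit, weights: dict[str, float]) -> tuple[np.ndarray, int]:
    """t statistic per series; infinite where residual variance is zero."""
    c = fit.design.contrast_vector(weights)
    effect = c @ fit.betas
    var_unit = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(fit.sigma2 * var_unit)
    # (numerically) zero residual variance: infinite t in the direction of a
    # real effect, 0 where the effect itself is numerical noise
    degenerate = fit.sigma2 <= (1e-12 * fit.data_scale) ** 2
    if np.any(degenerate):
        real = np.abs(effect) > 1e-9 * fit.data_scale
        t = np.where(degenerate & real & (effect > 0), np.inf, t)
        t = np.where(degenerate & real & (effect < 0), -np.inf, t)
        t = np.where(degenerate & ~real, 0.0, t)
    return t, fit.df


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    size: int
    p_corrected: float
    voxels: np.ndarray  # (size, 3) integer coordinates


_CONN26 = np.ones((3, 3, 3), dtype=int)


def _max_cluster_size(tmap3d: np.ndarray, t_crit: float) -> int:
    labels, n = ndimage.label(tmap3d > t_crit, structure=_CONN26)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_correct(
    data4d: np.ndarray,
    design: DesignMatrix,
    weights: dict[str, float],
    voxel_p: float = 0.01,
    cluster_p: float = 0.01,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[list[Cluster], np.ndarray]:
    """Permutation cluster-extent correction of a positive contrast.

    Threshold at the one-sided ``voxel_p`` t quantile, build 26-connected
    clusters, and compare observed sizes against a max-cluster-size null
    obtained by Freedman-Lane shuffling: residuals of the reduced model
    (contrast columns removed) are permuted in time, added back to the
    reduced fit, and the full model is refit.  Returns surviving clusters
    and the full labeled cluster map.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    vol = np.asarray(data4d, dtype=float)
    shape3d = vol.shape[:3]
    y = vol.reshape(-1, vol.shape[3]).T  # (T, V)

    fit = fit_glm(y, design)
    tmap, df = contrast_t(fit, weights)
    t_crit = sps.t.ppf(1.0 - voxel_p, df)
    tmap3d = tmap.reshape(shape3d)
    labels, n_clusters = ndimage.label(tmap3d > t_crit, structure=_CONN26)

    c = design.contrast_vector(weights)
    keep = c == 0
    x_red = design.matrix[:, keep]
    beta_red, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    fitted_red = x_red @ beta_red
    resid_red = y - fitted_red

    x = design.matrix
    xtx_inv = np.linalg.pinv(x.T @ x)
    pinv = xtx_inv @ x.T
    var_unit = float(c @ xtx_inv @ c)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    t_len = y.shape[0]
    for k in range(n_perm):
        perm = rng.permutation(t_len)
        y_star = fitted_red + resid_red[perm]
        betas = pinv @ y_star
        resid = y_star - x @ betas
        sigma2 = (resid**2).sum(axis=0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = (c @ betas) / np.sqrt(sigma2 * var_unit)
        null_max[k] = _max_cluster_size(t_star.reshape(shape3d), t_crit)

    clusters: list[Cluster] = []
    for cid in range(1, n_clusters + 1):
        size = int((labels == cid).sum())
        p_corr = (1.0 + np.sum(null_max >= size)) / (n_perm + 1.0)
        if p_corr <= cluster_p:
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    size=size,
                    p_corrected=float(p_corr),
                    voxels=np.argwhere(labels == cid),
                )
            )
    return clusters, labels


def block_volume_means(
    series: np.ndarray, schedule: ExperimentSchedule, trim_up_vols: int = 2
) -> dict[str, float]:
    """Mean of a volume series per block label, pooled over runs.

    The first ``trim_up_vols`` volumes of every Upregulation block are
    dropped to discount hemodynamic carry-over from the View block.
    """
    y = np.asarray(series, dtype=float)
    parts: dict[str, list[np.ndarray]] = {lab: [] for lab in ANALYSIS_LABELS}
    for _, lab, sl in schedule.volume_slices():
        if lab not in parts:
            continue
        seg = y[sl]
        if lab == UPREGULATION:
            seg = seg[trim_up_vols:]
        parts[lab].append(seg)
    return {lab: float(np.concatenate(v).mean()) for lab, v in parts.items() if v}


def psc_from_series(
    series: np.ndarray, schedule: ExperimentSchedule, trim_up_vols: int = 2
) -> tuple[float, float]:
    """Percent signal change (Up vs View, Up vs Rest) of one mean series."""
    means = block_volume_means(series, schedule, trim_up_vols)
    m_up, m_view, m_rest = means[UPREGULATION], means[VIEW], means[REST]
    if m_view == 0 or m_rest == 0:
        raise ZeroDivisionError("reference block mean is zero; PSC undefined")
    return (
        100.0 * (m_up - m_view) / m_view,
        100.0 * (m_up - m_rest) / m_rest,
    )


def roi_percent_signal_change(
    data4d: np.ndarray,
    schedule: ExperimentSchedule,
    roi_mask: np.ndarray,
    activated_mask: np.ndarray | None = None,
    trim_up_vols: int = 2,
) -> tuple[float, float] | None:
    """PSC over activated voxels inside an ROI mask; None when empty."""
    mask = np.asarray(roi_mask, dtype=bool)
    if activated_mask is not None:
        mask = mask & np.asarray(activated_mask, dtype=bool)
    if not mask.any():
        return None
    series = np.asarray(data4d, dtype=float)[mask].mean(axis=0)
    return psc_from_series(series, schedule, trim_up_vols)


def roi_effect_sizes(psc_table, q: float = 0.05, family_size: int | None = None):
    """Per-ROI one-sample t / Cohen's d within the experimental group and a
    pooled two-sample comparison against the control group, BH-FDR over the
    ROI family.

    ``psc_table`` is a DataFrame with columns roi, subject, group, psc.
    ``family_size`` pads the FDR family (e.g. to an atlas-wide count) when
    larger than the number of supplied ROIs.
    """
    import pandas as pd

    from .stats import bh_fdr, two_sample_t

    rows = []
    for roi, sub in psc_table.groupby("roi", sort=False):
        exp = sub.loc[sub["group"] == "experimental", "psc"].to_numpy(float)
        ctl = sub.loc[sub["group"] == "control", "psc"].to_numpy(float)
        if exp.size < 2 or ctl.size < 2:
            continue
        sd = exp.std(ddof=1)
        if sd == 0:
            continue
        t_within = exp.mean() / (sd / np.sqrt(exp.size))
        p_within = 2.0 * sps.t.sf(abs(t_within), exp.size - 1)
        between = two_sample_t(exp, ctl)
        rows.append(
            {
                "roi": roi,
                "n_experimental": exp.size,
                "n_control": ctl.size,
                "mean_psc": exp.mean(),
                "t_within": t_within,
                "df_within": exp.size - 1,
                "p_within": p_within,
                "d_within": exp.mean() / sd,
                "t_between": between.statistic,
                "df_between": between.df,
                "p_between": between.p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    m = len(table)
    pad = max(0, (family_size or m) - m)
    for col in ("within", "between"):
        pvals = np.concatenate([table[f"p_{col}"].to_numpy(), np.ones(pad)])
        reject, qvals = bh_fdr(pvals, q=q)
        table[f"q_{col}"] = qvals[:m]
        table[f"sig_{col}"] = reject[:m]
    return table
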