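"""Default-mode-network coupling: component selection, ROI extraction,
band-pass filtering, partial correlation, and the group x FA interaction.

The analysis asks whether the coupling between the anterior (mPFC) and
posterior (PCC) midline nodes of the default mode network — measured as the
partial correlation of their band-limited signals controlling for the
bilateral TPJ — depends on marker-tract (cingulum) FA differently in the
two brain-type groups.  The interaction model regresses per-subject partial
r on group, standardized FA, and their product; per-group simple slopes are
reported as follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from nibabel.affines import apply_affine
from scipy import signal

logger = logging.getLogger(__name__)

BAND_HZ = (0.01, 0.1)
MNI_COORDS = {
    "PCC": (0.0, -52.0, 18.0),
    "mPFC": (1.0, 50.0, -5.0),
    "lTPJ": (-46.0, -68.0, 32.0),
    "rTPJ": (46.0, -68.0, 32.0),
}
SPHERE_RADIUS_MM = 8.0


def goodness_of_fit(component_map: np.ndarray, mask: np.ndarray) -> float:
    """Mean of the z-scored map inside the reference mask minus the mean
    outside it."""
    component_map = np.asarray(component_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if component_map.shape != mask.shape:
        raise ValueError("map and mask must share a grid")
    if not mask.any() or mask.all():
        raise ValueError("mask must be neither empty nor full")
    return float(component_map[mask].mean() - component_map[~mask].mean())


def select_component(maps: np.ndarray, mask: np.ndarray) -> int:
    """Index of the component map with the largest goodness-of-fit score.

    ``maps`` is (n_components, *grid).  Ties break to the lowest index.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 1:
        raise ValueError("need at least one component")
    scores = np.array([goodness_of_fit(m, mask) for m in maps])
    best = int(np.argmax(scores))
    if scores[best] < 0.1:
        logger.warning("best component has near-zero DMN fit (%.3f)", scores[best])
    return best


def sphere_mask(center_mm, grid_shape, affine, radius_mm: float = SPHERE_RADIUS_MM
                ) -> np.ndarray:
    """Binary mask of voxels whose mm-space centers lie within ``radius_mm``
    of a world-space coordinate (e.g. an MNI seed)."""
    affine = np.asarray(affine, dtype=float)
    if np.linalg.matrix_rank(affine[:3, :3]) < 3:
        raise ValueError("affine is not invertible")
    idx = np.indices(grid_shape).reshape(3, -1).T
    centers = apply_affine(affine, idx)
    d2 = np.sum((centers - np.asarray(center_mm, dtype=float)) ** 2, axis=1)
    mask = (d2 <= radius_mm ** 2).reshape(grid_shape)
    if not mask.any():
        raise ValueError("sphere lies entirely outside the grid")
    return mask


def bandpass(data: np.ndarray, tr: float, low: float = BAND_HZ[0],
             high: float = BAND_HZ[1], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The filter is applied forward and backward (second-order sections), so
    the phase is zero and the effective attenuation is the squared
    magnitude response.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    fs = 1.0 / tr
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={nyq:.3f})")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def partial_corr(x: np.ndarray, y: np.ndarray, controls: np.ndarray | None = None
                 ) -> float:
    """Partial Pearson correlation of x and y given control signals.

    Both series are residualized on the controls plus an intercept by least
    squares; with no controls this is the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "size") and controls.size == 0):
        Z = np.ones((len(x), 1))
    else:
        controls = np.atleast_2d(np.asarray(controls, dtype=float))
        if controls.shape[0] != len(x):
            controls = controls.T
        Z = np.column_stack([np.ones(len(x)), controls])
        if len(x) < Z.shape[1] + 3:
            raise ValueError("need at least 3 more samples than controls")
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("collinear controls")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValueError("zero residual variance")
    return float(np.clip(rx @ ry / denom, -1.0, 1.0))


def coupling_table(timeseries: dict, fa_marker: np.ndarray,
                   group_labels: np.ndarray) -> pd.DataFrame:
    """Per-participant mPFC-PCC partial correlation (controlling bilateral
    TPJ) on band-passed signals, joined with marker FA and group label."""
    data = np.asarray(timeseries["data"], dtype=float)
    tr = float(timeseries["tr"])
    channels = list(timeseries["channels"])
    i_mpfc = channels.index("mPFC")
    i_pcc = channels.index("PCC")
    i_ctl = [channels.index(c) for c in ("lTPJ", "rTPJ")]
    filtered = bandpass(data, tr)
    rows = []
    for s in range(data.shape[0]):
        r = partial_corr(filtered[s, i_mpfc], filtered[s, i_pcc],
                         filtered[s, i_ctl].T)
        rows.append(r)
    return pd.DataFrame({
        "partial_r": rows,
        "fa": np.asarray(fa_marker, dtype=float),
        "group": np.asarray(group_labels),
    })


@dataclass
class InteractionResult:
    interaction_t: float
    interaction_p: float
    df_resid: int
    slopes: dict[str, float]       # per-group slope of partial r on FA (z)
    slope_p: dict[str, float]
    params: pd.Series


def interaction_model(table: pd.DataFrame, covariates: list[str] | None = None
                      ) -> InteractionResult:
    """OLS fit of partial_r ~ group + FA_z + group:FA_z (+ covariates).

    FA is standardized before entering the model.  The per-group follow-up
    slopes are simple regressions of partial r on standardized FA within
    each group (the coefficient convention used for reporting betas).
    """
    groups = np.unique(table["group"])
    if len(groups) != 2:
        raise ValueError("need exactly 2 groups")
    for g in groups:
        if (table["group"] == g).sum() < 10:
            raise ValueError("need >= 10 participants per group")
    fa = table["fa"].to_numpy(dtype=float)
    fa_z = (fa - fa.mean()) / fa.std(ddof=0)
    g_ind = (table["group"] == groups[1]).astype(float).to_numpy()
    y = table["partial_r"].to_numpy(dtype=float)
    X = pd.DataFrame({"group": g_ind, "fa_z": fa_z, "group_x_fa": g_ind * fa_z})
    for c in covariates or []:
        X[c] = table[c].to_numpy(dtype=float)
    X = sm.add_constant(X)
    fit = sm.OLS(y, X).fit()
    slopes = {}
    slope_p = {}
    for g in groups:
        m = (table["group"] == g).to_numpy()
        Xg = sm.add_constant(fa_z[m])
        fg = sm.OLS(y[m], Xg).fit()
        slopes[str(g)] = float(fg.params[1])
        slope_p[str(g)] = float(fg.pvalues[1])
    return InteractionResult(
        interaction_t=float(fit.tvalues["group_x_fa"]),
        interaction_p=float(fit.pvalues["group_x_fa"]),
        df_resid=int(fit.df_resid),
        slopes=slopes,
        slope_p=slope_p,
        params=fit.params,
    )
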