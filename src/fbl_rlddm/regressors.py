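"""Model-based GLM ingredients: AS/PE parametric modulators and HRF designs.

Trial-wise association strength modulates stimulus onsets and prediction
error modulates feedback onsets; both are mean-centered within condition
before entering the design.  Onsets of missed ("too late") trials go into a
separate nuisance regressor.  Event trains are built on a 0.1 s micro-time
grid, convolved with a canonical double-gamma HRF and sampled at volume
acquisition times (defaults: 460 volumes, TR = 1.0 s).  A small synthetic-
BOLD generator plus OLS fitter closes the loop for validating that known
modulation coefficients are recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import DEADLINE_S

__all__ = [
    "extract_modulators",
    "canonical_hrf",
    "build_design",
    "simulate_bold",
    "fit_glm",
    "write_bids_events",
    "read_bids_events",
    "DesignMatrix",
]

CONDITIONS = ("stimulus", "feedback", "missed_stimulus", "missed_feedback")


def extract_modulators(trial_log: pd.DataFrame,
                       stimulus_modulator: str = "trial_mean") -> pd.DataFrame:
    """Event table (onset_s, duration_s, condition, modulator) from a log.

    ``stimulus_modulator`` selects which AS quantity rides on stimulus
    onsets: ``"trial_mean"`` uses (as_cor + as_inc)/2 (the drift's argument),
    ``"presented"`` uses the presented pair's pre-update AS.  Feedback events
    carry the trial PE.  Modulators are mean-centered within condition;
    missed trials contribute unmodulated nuisance events.
    """
    needed = {"stim_onset_s", "as_cor", "as_inc", "pe", "rt_s"}
    if not needed.issubset(trial_log.columns):
        raise ValueError(f"trial log lacks derived columns {sorted(needed - set(trial_log.columns))}")
    log = trial_log.sort_values("stim_onset_s", kind="stable").reset_index(drop=True)
    missing = log["missing"].astype(bool) if "missing" in log else log["rt_s"].isna()
    if stimulus_modulator == "trial_mean":
        as_mod = 0.5 * (log["as_cor"] + log["as_inc"])
    elif stimulus_modulator == "presented":
        as_mod = np.where(log["is_match"], log["as_cor"], log["as_inc"])
        as_mod = pd.Series(as_mod, index=log.index)
    else:
        raise ValueError("stimulus_modulator must be 'trial_mean' or 'presented'")
    fb_onset = log["stim_onset_s"] + np.where(missing, DEADLINE_S, log["rt_s"])
    rows = []
    for i in range(len(log)):
        if missing.iat[i]:
            rows.append((log["stim_onset_s"].iat[i], 0.0, "missed_stimulus", np.nan, np.nan))
            rows.append((fb_onset.iat[i], 0.0, "missed_feedback", np.nan, np.nan))
        else:
            rows.append((log["stim_onset_s"].iat[i], 0.0, "stimulus",
                         as_mod.iat[i], log["rt_s"].iat[i]))
            rows.append((fb_onset.iat[i], 0.0, "feedback",
                         log["pe"].iat[i], log["rt_s"].iat[i]))
    ev = pd.DataFrame(rows, columns=["onset_s", "duration_s", "condition",
                                     "modulator", "response_time_s"])
    for cond in ("stimulus", "feedback"):
        sel = ev["condition"] == cond
        if sel.any():
            ev.loc[sel, "modulator"] -= ev.loc[sel, "modulator"].mean()
    return ev.sort_values("onset_s", kind="stable").reset_index(drop=True)


def canonical_hrf(tr_s: float, duration_s: float = 32.0,
                  microtime_s: float = 0.1, decimate: bool = True) -> np.ndarray:
    """Canonical double-gamma HRF, unit-sum normalized.

    Response gamma peaks at 6 s, undershoot gamma at 16 s (mode-parameterized
    with unit dispersion), undershoot ratio 1/6, 32 s support.  Sampled on
    the micro-time grid; ``decimate=True`` returns it at TR resolution.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, duration_s, microtime_s)
    peak, under, disp, ratio = 6.0, 16.0, 1.0, 1.0 / 6.0
    # gamma with shape k and scale disp has mode (k-1)*disp
    h = (stats.gamma.pdf(t, peak / disp + 1, scale=disp)
         - ratio * stats.gamma.pdf(t, under / disp + 1, scale=disp))
    h /= h.sum()
    if decimate:
        step = max(1, int(round(tr_s / microtime_s)))
        h = h[::step]
    return h


@dataclass
class DesignMatrix:
    matrix: np.ndarray             # (n_volumes, n_regressors)
    columns: list[str]
    tr_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)


def build_design(events: pd.DataFrame, n_volumes: int = 460,
                 tr_s: float = 1.0, microtime_s: float = 0.1,
                 use_fft: bool = True,
                 extra_nuisance: pd.DataFrame | None = None) -> DesignMatrix:
    """HRF-convolved design matrix sampled at volume times.

    Columns: stimulus, stimulus_x_as, feedback, feedback_x_pe, missed (both
    missed conditions pooled into one nuisance regressor), optional
    pass-through nuisance columns, intercept.  Events past the scan end are
    truncated with a warning.
    """
    import warnings

    scan_end = n_volumes * tr_s
    if (events["onset_s"] >= scan_end).any():
        n_out = int((events["onset_s"] >= scan_end).sum())
        warnings.warn(f"{n_out} events beyond scan end ({scan_end:.1f} s) truncated")
        events = events[events["onset_s"] < scan_end]
    n_micro = int(round(scan_end / microtime_s))
    hrf = canonical_hrf(tr_s, microtime_s=microtime_s, decimate=False)

    def convolved_train(onsets: np.ndarray, heights: np.ndarray) -> np.ndarray:
        train = np.zeros(n_micro)
        idx = np.clip(np.round(onsets / microtime_s).astype(int), 0, n_micro - 1)
        np.add.at(train, idx, heights)
        if use_fft:
            from scipy.signal import fftconvolve
            full = fftconvolve(train, hrf)[:n_micro]
        else:
            full = np.convolve(train, hrf)[:n_micro]
        vol_idx = np.round(np.arange(n_volumes) * tr_s / microtime_s).astype(int)
        return full[np.clip(vol_idx, 0, n_micro - 1)]

    cols: dict[str, np.ndarray] = {}
    for cond, modname in (("stimulus", "as"), ("feedback", "pe")):
        ev = events[events["condition"] == cond]
        on = ev["onset_s"].to_numpy()
        cols[cond] = convolved_train(on, np.ones(len(ev)))
        cols[f"{cond}_x_{modname}"] = convolved_train(
            on, ev["modulator"].to_numpy())
    missed = events[events["condition"].isin(("missed_stimulus",
                                              "missed_feedback"))]
    if len(missed):  # an all-zero regressor would make the design singular
        cols["missed"] = convolved_train(missed["onset_s"].to_numpy(),
                                         np.ones(len(missed)))
    if extra_nuisance is not None:
        if len(extra_nuisance) != n_volumes:
            raise ValueError("nuisance columns must have n_volumes rows")
        for c in extra_nuisance.columns:
            cols[str(c)] = extra_nuisance[c].to_numpy(dtype=float)
    cols["intercept"] = np.ones(n_volumes)
    names = list(cols)
    return DesignMatrix(np.column_stack([cols[c] for c in names]), names, tr_s)


def simulate_bold(design: DesignMatrix, betas: dict[str, float] | np.ndarray,
                  noise_sd: float, rng_seed: int,
                  n_voxels: int = 1) -> np.ndarray:
    """BOLD = design @ betas + iid Gaussian noise; (n_volumes, n_voxels)."""
    if isinstance(betas, dict):
        b = np.array([betas.get(c, 0.0) for c in design.columns])
    else:
        b = np.asarray(betas, dtype=float)
    rng = np.random.default_rng(rng_seed)
    signal = design.matrix @ b
    return signal[:, None] + rng.normal(0.0, noise_sd,
                                        size=(design.matrix.shape[0], n_voxels))


def fit_glm(design: DesignMatrix, bold: np.ndarray,
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ordinary least squares per voxel; returns (betas, t-stats) frames.

    Raises on rank-deficient designs, naming the collinear columns.
    """
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the correlation
        _, R = np.linalg.qr(X)
        bad = [design.columns[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-10 * abs(R).max()]
        raise ValueError(f"design matrix is rank deficient (suspect columns: {bad})")
    if bold.ndim == 1:
        bold = bold[:, None]
    beta, _, _, _ = np.linalg.lstsq(X, bold, rcond=None)
    resid = bold - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    tstat = beta / se
    cols = [f"voxel{j}" for j in range(bold.shape[1])]
    return (pd.DataFrame(beta, index=design.columns, columns=cols),
            pd.DataFrame(tstat, index=design.columns, columns=cols))


BIDS_COLUMNS = ["onset", "duration", "trial_type", "response_time", "modulator"]


def write_bids_events(events: pd.DataFrame, path: str | Path) -> None:
    """BIDS-style events TSV: onset/duration in seconds, 3-decimal precision."""
    out = pd.DataFrame({
        "onset": events["onset_s"].round(3),
        "duration": events["duration_s"].round(3),
        "trial_type": events["condition"],
        "response_time": events["response_time_s"].round(3),
        "modulator": events["modulator"],
    })[BIDS_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_bids_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return pd.DataFrame({
        "onset_s": df["onset"],
        "duration_s": df["duration"],
        "condition": df["trial_type"],
        "modulator": df["modulator"],
        "response_time_s": df["response_time"],
    })
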