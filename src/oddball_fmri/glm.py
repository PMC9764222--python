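"""First-level GLM: design matrices, OLS estimation, beta standardisation.

The task model has six condition regressors — std0 (first standard of a
trial), std1 (standards before the deviant), std2 (standards after the
deviant), and dev4/dev5/dev6 (deviants by position) — plus linear
parametric modulators for std1 and std2 indexing each repeated standard
within its trial.  The modulation gives the fit the freedom to follow a
linear within-trial trend of the standard responses, which cannot be
estimated sound-by-sound at 750 ms spacing.  Condition estimates are
taken from the unmodulated main columns.

Betas are z-standardised within each (participant, run, ROI) slice —
jointly over that slice's voxels and conditions — before group-level
tests, removing participant-, run-, and region-specific scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import CONDITIONS
from .simulate import BOLDRun, MICROTIME, HRF_LENGTH, VoxelGrid, hrf

__all__ = [
    "DesignMatrix",
    "RunBetas",
    "BetaMaps",
    "build_design_matrix",
    "fit_glm",
    "standardize_betas",
]

TASK_COLUMNS = ("std0", "std1", "std1xmod", "std2", "std2xmod",
                "dev4", "dev5", "dev6")


@dataclass(frozen=True)
class DesignMatrix:
    """Named volumes × regressors matrix."""

    frame: pd.DataFrame
    tr: float

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _convolve_sample(onsets: np.ndarray, amplitudes: np.ndarray,
                     tr: float, n_volumes: int) -> np.ndarray:
    """HRF-convolve weighted impulses on the microtime grid, sample at TRs."""
    duration = n_volumes * tr + HRF_LENGTH
    n_micro = int(np.ceil(duration / MICROTIME)) + 1
    impulses = np.zeros(n_micro)
    idx = np.round(onsets / MICROTIME).astype(int)
    np.add.at(impulses, idx, amplitudes)
    kernel = hrf(np.arange(0, HRF_LENGTH, MICROTIME))
    convolved = np.convolve(impulses, kernel)[:n_micro]
    vol_idx = np.round(np.arange(n_volumes) * tr / MICROTIME).astype(int)
    return convolved[vol_idx]


def drift_regressors(tr: float, n_volumes: int,
                     highpass_hz: float = 1.0 / 120.0) -> pd.DataFrame:
    """Linear drift plus a cosine set up to the high-pass cutoff."""
    t = np.arange(n_volumes)
    cols = {"drift_linear": (t - t.mean()) / n_volumes}
    duration = n_volumes * tr
    n_cos = int(np.floor(2 * duration * highpass_hz))
    for k in range(1, n_cos + 1):
        cols[f"drift_cos{k:02d}"] = np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
    return pd.DataFrame(cols)


def build_design_matrix(events: pd.DataFrame, tr: float, n_volumes: int,
                        highpass_hz: float = 1.0 / 120.0) -> DesignMatrix:
    """Six condition regressors, two parametric modulators, nuisance set.

    Modulator values are z-standardised across each condition's events
    within the run before convolution weighting, and the resulting
    columns are mean-centred so they carry only the within-trial trend.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    run_end = n_volumes * tr
    if ((events["onset"] + events["duration"]) > run_end + 1e-9).any():
        raise ValueError("events extend beyond the run duration")

    cols: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        sel = events[events["trial_type"] == cond]
        if sel.empty:
            raise ValueError(f"no events for condition {cond!r}")
        onsets = sel["onset"].to_numpy()
        cols[cond] = _convolve_sample(onsets, np.ones(len(sel)), tr, n_volumes)
        if cond in ("std1", "std2"):
            mod = sel["modulator"].to_numpy(dtype=float)
            if np.isnan(mod).any():
                raise ValueError(f"missing modulator values for {cond!r}")
            z = (mod - mod.mean()) / mod.std()
            col = _convolve_sample(onsets, z, tr, n_volumes)
            cols[f"{cond}xmod"] = col - col.mean()

    frame = pd.DataFrame({c: cols[c] for c in TASK_COLUMNS})
    frame = pd.concat([frame, drift_regressors(tr, n_volumes, highpass_hz)],
                      axis=1)
    frame["intercept"] = 1.0
    return DesignMatrix(frame=frame, tr=tr)


@dataclass(frozen=True)
class RunBetas:
    """OLS estimates for one run: all regressors × voxels."""

    betas: pd.DataFrame             # index = regressor names, columns = voxels
    residual_variance: np.ndarray   # per voxel
    dof: int

    def condition_betas(self) -> np.ndarray:
        """(n_conditions, n_voxels) estimates from the main-effect columns."""
        return self.betas.loc[list(CONDITIONS)].to_numpy()


def fit_glm(run: BOLDRun | np.ndarray, X: DesignMatrix) -> RunBetas:
    """Voxel-wise ordinary least squares with residual variance and dof."""
    Y = run.data if isinstance(run, BOLDRun) else np.asarray(run, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    M = X.values
    if Y.shape[0] != M.shape[0]:
        raise ValueError("data and design matrix lengths differ")
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(M, Y, rcond=None)
    resid = Y - M @ beta
    dof = Y.shape[0] - rank
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return RunBetas(betas=pd.DataFrame(beta, index=X.columns),
                    residual_variance=sigma2, dof=dof)


@dataclass(frozen=True)
class BetaMaps:
    """Condition betas for a cohort: participants × runs × conditions × voxels.

    Voxels are the labelled voxels of a grid, in ascending flat-index
    order; ``roi_labels`` and ``coords`` are aligned with that axis.
    """

    betas: np.ndarray                   # (S, R, C, V)
    conditions: tuple[str, ...]
    roi_labels: np.ndarray              # (V,)
    roi_names: dict[int, str]
    coords: np.ndarray                  # (V, 3)
    grid_shape: tuple[int, ...]
    residual_variance: np.ndarray | None = None   # (S, R, V)
    dof: int | None = None
    standardized: bool = False

    @classmethod
    def from_runs(cls, run_betas: list[list[RunBetas]],
                  grid: VoxelGrid) -> "BetaMaps":
        """Assemble per-(participant, run) fits over a grid's labelled voxels."""
        betas = np.stack([
            np.stack([rb.condition_betas() for rb in subject])
            for subject in run_betas])
        resid = np.stack([
            np.stack([rb.residual_variance for rb in subject])
            for subject in run_betas])
        return cls(betas=betas, conditions=CONDITIONS,
                   roi_labels=grid.voxel_labels, roi_names=dict(grid.roi_names),
                   coords=grid.voxel_coords, grid_shape=grid.shape,
                   residual_variance=resid, dof=run_betas[0][0].dof)

    @property
    def n_participants(self) -> int:
        return self.betas.shape[0]

    @property
    def n_runs(self) -> int:
        return self.betas.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[3]

    def condition_index(self, name: str) -> int:
        return self.conditions.index(name)

    def run_average(self) -> np.ndarray:
        """(S, C, V) betas averaged over runs."""
        return self.betas.mean(axis=1)

    def to_table(self) -> pd.DataFrame:
        """Tidy (participant, run, roi, voxel, condition, beta) table."""
        S, R, C, V = self.betas.shape
        idx = pd.MultiIndex.from_product(
            [range(S), range(R), self.conditions, range(V)],
            names=["participant", "run", "condition", "voxel"])
        df = pd.DataFrame({"beta": self.betas.ravel()}, index=idx).reset_index()
        df["roi"] = df["voxel"].map(
            lambda v: self.roi_names[int(self.roi_labels[v])])
        return df


def standardize_betas(maps: BetaMaps, eps: float = 1e-12) -> BetaMaps:
    """Z-standardise betas within each (participant, run, ROI) slice.

    The mean and sd are taken jointly over the slice's voxels and
    conditions, so the transformation is order-preserving within the
    slice.  A zero-variance slice is an error.
    """
    if maps.standardized:
        raise ValueError("betas are already standardized")
    out = maps.betas.copy()
    for s in range(maps.n_participants):
        for r in range(maps.n_runs):
            for lab in maps.roi_names:
                cols = maps.roi_labels == lab
                if not cols.any():
                    continue
                block = out[s, r][:, cols]
                sd = block.std()
                if sd < eps:
                    raise ValueError(
                        f"zero-variance slice: participant {s}, run {r}, "
                        f"ROI {maps.roi_names[lab]}")
                out[s, r][:, cols] = (block - block.mean()) / sd
    return replace(maps, betas=out, standardized=True)
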