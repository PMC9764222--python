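"""Voxel-wise Bayesian comparison of the habituation and prediction-error models.

Each candidate amplitude model (h1, h2) yields a single task regressor
whose event amplitudes follow the model's per-position vectors,
z-standardised per run before convolution.  The log marginal likelihood
(log-evidence) of the resulting linear model is available in closed form
under a conjugate normal–inverse-gamma prior: a Zellner g-prior on the
coefficients (g = n by default, the unit-information choice) with an
inverse-gamma noise prior scaled to the data variance, which makes
log-evidence *differences* invariant to affine rescaling of the data.

Group inference combines subjects in two ways: a fixed-effects Bayes
factor K_{h2/h1} (the exponentiated sum of per-subject log-evidence
differences) and random-effects Bayesian model selection (RFX BMS),
which treats the model generating each subject's data as a draw from a
Dirichlet-distributed population and estimates the Dirichlet
concentrations variationally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .design import N_SOUNDS, SOA, RunSchedule, amplitude_model
from .glm import DesignMatrix, _convolve_sample, drift_regressors

__all__ = [
    "NIGPrior",
    "EvidenceMaps",
    "PosteriorMaps",
    "BMSResult",
    "model_design",
    "log_evidence",
    "rfx_bms",
    "group_maps",
]


def model_design(schedule: RunSchedule, model: str, tr: float,
                 n_volumes: int, highpass_hz: float = 1.0 / 120.0,
                 include_intercept: bool = True) -> DesignMatrix:
    """Single-regressor design whose amplitudes follow one amplitude model.

    Event amplitudes (one per sound) are taken from the model's vector
    for each trial's deviant position and z-standardised across the run
    before convolution, so only the shape of the profile — not its mean
    or scale — distinguishes the candidate models.  Nuisance columns are
    identical across models.
    """
    amp_model = amplitude_model(model)      # validates the name
    onsets, amps = [], []
    for trial, t0 in zip(schedule.trials, schedule.trial_onsets):
        vec = amp_model.trial_amplitudes(trial.deviant_position)
        for pos in range(N_SOUNDS):
            onsets.append(t0 + pos * SOA)
            amps.append(vec[pos])
    onsets = np.asarray(onsets)
    amps = np.asarray(amps, dtype=float)
    z = (amps - amps.mean()) / amps.std()
    task = _convolve_sample(onsets, z, tr, n_volumes)
    # Shared sound-onset regressor: z-standardising the amplitudes removes
    # their mean, so the model-independent response common to every sound
    # must be carried by a regressor present in both candidate designs —
    # otherwise the comparison is dominated by the unmodelled onset lump.
    sounds = _convolve_sample(onsets, np.ones_like(amps), tr, n_volumes)
    frame = pd.DataFrame({model: task - task.mean(),
                          "sounds": sounds - sounds.mean()})
    frame = pd.concat([frame, drift_regressors(tr, n_volumes, highpass_hz)],
                      axis=1)
    if include_intercept:
        frame["intercept"] = 1.0
    return DesignMatrix(frame=frame, tr=tr)


@dataclass(frozen=True)
class NIGPrior:
    """Conjugate normal–inverse-gamma prior for the linear-model evidence.

    Coefficients: β | σ² ~ N(0, g σ² (XᵀX)⁻¹) with g = ``g`` or, when
    None, g = n (unit information).  Noise: σ² ~ InvGamma(a0, b0) with
    b0 = a0 · var(y) when ``b0`` is None, tying the noise prior to the
    data scale.
    """

    g: float | None = None
    a0: float = 1.0
    b0: float | None = None

    def resolve(self, y: np.ndarray, n: int) -> tuple[float, float, float]:
        g = float(self.g) if self.g is not None else float(n)
        b0 = float(self.b0) if self.b0 is not None else \
            self.a0 * float(np.var(y))
        if g <= 0 or self.a0 <= 0 or b0 <= 0:
            raise ValueError("prior hyperparameters must be positive")
        return g, self.a0, b0


def log_evidence(y: np.ndarray, X: DesignMatrix | np.ndarray,
                 prior: NIGPrior = NIGPrior()) -> float:
    """Closed-form log marginal likelihood of the linear model.

    Demeaned data should be paired with a design without an intercept
    when an improper location prior is to be avoided; here the g-prior
    covers every supplied column.  Under the g-prior the marginal is

      log p(y) = lnΓ(a_n) − lnΓ(a_0) + a_0 ln b_0 − a_n ln b_n
                 − (p/2) ln(1+g) − (n/2) ln 2π,

    with a_n = a_0 + n/2 and b_n = b_0 + ½(yᵀy − g/(1+g) · yᵀP_X y),
    P_X the projection onto the column space of X.
    """
    y = np.asarray(y, dtype=float).ravel()
    M = X.values if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n, p = M.shape
    if y.size != n:
        raise ValueError("data and design lengths differ")
    if np.linalg.matrix_rank(M) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    g, a0, b0 = prior.resolve(y, n)
    coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    fit = y @ (M @ coef)                 # yᵀ P_X y
    an = a0 + n / 2.0
    bn = b0 + 0.5 * (y @ y - g / (1.0 + g) * fit)
    return float(gammaln(an) - gammaln(a0) + a0 * np.log(b0) - an * np.log(bn)
                 - 0.5 * p * np.log1p(g) - 0.5 * n * np.log(2 * np.pi))


def _log_evidence_many(Y: np.ndarray, M: np.ndarray,
                       prior: NIGPrior) -> np.ndarray:
    """Column-wise log-evidence of (volumes, voxels) data under one design."""
    n, p = M.shape
    if np.linalg.matrix_rank(M) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    coef = np.linalg.pinv(M) @ Y
    fit = np.einsum("tv,tv->v", Y, M @ coef)
    yty = np.einsum("tv,tv->v", Y, Y)
    g = float(prior.g) if prior.g is not None else float(n)
    a0 = prior.a0
    b0 = (np.full(Y.shape[1], float(prior.b0)) if prior.b0 is not None
          else a0 * Y.var(axis=0))
    an = a0 + n / 2.0
    bn = b0 + 0.5 * (yty - g / (1.0 + g) * fit)
    return (gammaln(an) - gammaln(a0) + a0 * np.log(b0) - an * np.log(bn)
            - 0.5 * p * np.log1p(g) - 0.5 * n * np.log(2 * np.pi))


@dataclass(frozen=True)
class BMSResult:
    """Random-effects model selection over one set of subjects."""

    alpha: np.ndarray                   # Dirichlet concentrations
    expected_posterior: np.ndarray      # r_k = alpha_k / sum(alpha)
    responsibilities: np.ndarray        # (subjects, models)
    exceedance: np.ndarray | None = None
    n_iterations: int = 0


def rfx_bms(log_evidences: np.ndarray, alpha0: float = 1.0,
            tol: float = 1e-6, max_iter: int = 10_000,
            exceedance_draws: int | None = 1_000_000,
            seed: int = 0) -> BMSResult:
    """Variational random-effects Bayesian model selection.

    ``log_evidences`` is (subjects, models).  Subject-level model
    responsibilities and Dirichlet concentrations are updated in
    alternation until the concentrations change by less than ``tol``.
    Exceedance probabilities are estimated from seeded Dirichlet draws
    (skipped when ``exceedance_draws`` is None).
    """
    logE = np.asarray(log_evidences, dtype=float)
    if logE.ndim != 2 or logE.shape[1] < 2:
        raise ValueError("need (subjects, >=2 models) log-evidences")
    if not np.isfinite(logE).all():
        raise ValueError("log-evidences must be finite")
    n_sub, n_mod = logE.shape
    alpha = np.full(n_mod, alpha0, dtype=float)
    u = np.full((n_sub, n_mod), 1.0 / n_mod)
    for it in range(1, max_iter + 1):
        log_u = logE + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        u = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = alpha0 + u.sum(axis=0)
        if np.abs(new_alpha - alpha).max() < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    xp = None
    if exceedance_draws:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=exceedance_draws)
        xp = np.bincount(draws.argmax(axis=1), minlength=n_mod) / exceedance_draws
    return BMSResult(alpha=alpha, expected_posterior=alpha / alpha.sum(),
                     responsibilities=u, exceedance=xp, n_iterations=it)


def _rfx_bms_voxelwise(logE: np.ndarray, alpha0: float = 1.0,
                       tol: float = 1e-6, max_iter: int = 10_000) -> np.ndarray:
    """Vectorised VB updates over voxels; returns alpha (voxels, models)."""
    V, n_sub, n_mod = logE.shape
    alpha = np.full((V, n_mod), alpha0)
    for _ in range(max_iter):
        bias = digamma(alpha) - digamma(alpha.sum(axis=1, keepdims=True))
        log_u = logE + bias[:, None, :]
        u = np.exp(log_u - logsumexp(log_u, axis=2, keepdims=True))
        new_alpha = alpha0 + u.sum(axis=1)
        if np.abs(new_alpha - alpha).max() < tol:
            return new_alpha
        alpha = new_alpha
    return alpha


@dataclass(frozen=True)
class EvidenceMaps:
    """Per-subject, per-model log-evidence over voxels."""

    log_evidence: np.ndarray            # (subjects, models, voxels)
    models: tuple[str, ...]
    roi_labels: np.ndarray
    roi_names: dict[int, str]
    prior: NIGPrior = NIGPrior()


@dataclass(frozen=True)
class PosteriorMaps:
    """Group-level summaries of the voxel-wise model comparison."""

    models: tuple[str, ...]
    alpha: np.ndarray                   # (voxels, models) Dirichlet parameters
    expected_posterior: np.ndarray      # (voxels, models)
    log_bayes_factor: np.ndarray        # (voxels,) fixed-effects ln K_{h2/h1}
    roi_labels: np.ndarray
    roi_names: dict[int, str]

    @property
    def bayes_factor(self) -> np.ndarray:
        """K_{h2/h1}; overflow-clipped in the exponent."""
        return np.exp(np.clip(self.log_bayes_factor, -700, 700))

    def fraction_favoring(self, model: str, threshold: float = 0.5
                          ) -> dict[str, float]:
        """Per-ROI fraction of voxels whose RFX posterior exceeds threshold."""
        k = self.models.index(model)
        out = {}
        for lab, name in self.roi_names.items():
            sel = self.roi_labels == lab
            if sel.any():
                out[name] = float(
                    (self.expected_posterior[sel, k] > threshold).mean())
        return out

    def roi_summary(self, model: str = "h2") -> pd.DataFrame:
        k = self.models.index(model)
        rows = []
        for lab, name in self.roi_names.items():
            sel = self.roi_labels == lab
            if sel.any():
                rows.append({
                    "roi": name,
                    f"pct_voxels_favoring_{model}": 100.0 * float(
                        (self.expected_posterior[sel, k] > 0.5).mean()),
                    "median_K": float(np.median(self.bayes_factor[sel])),
                    "median_lnK": float(np.median(self.log_bayes_factor[sel])),
                })
        return pd.DataFrame(rows)


def group_maps(evidence: EvidenceMaps, alpha0: float = 1.0) -> PosteriorMaps:
    """Fixed-effects Bayes factors and RFX posterior probability maps.

    The fixed-effects ln K is the sum over subjects of the log-evidence
    difference between the second and the first model (h2 over h1 in the
    default ordering); RFX expected posteriors come from the variational
    Dirichlet update run independently per voxel.
    """
    logE = np.asarray(evidence.log_evidence, dtype=float)
    if logE.ndim != 3:
        raise ValueError("expected (subjects, models, voxels) evidences")
    if not np.isfinite(logE).all():
        raise ValueError("log-evidences must be finite")
    if len(evidence.models) != 2:
        raise ValueError("fixed-effects K is defined for exactly two models")
    ln_k = (logE[:, 1, :] - logE[:, 0, :]).sum(axis=0)
    per_voxel = np.moveaxis(logE, 2, 0)          # (V, subjects, models)
    alpha = _rfx_bms_voxelwise(per_voxel, alpha0=alpha0)
    r = alpha / alpha.sum(axis=1, keepdims=True)
    return PosteriorMaps(models=tuple(evidence.models), alpha=alpha,
                         expected_posterior=r, log_bayes_factor=ln_k,
                         roi_labels=evidence.roi_labels,
                         roi_names=dict(evidence.roi_names))


def _estimate_ar1(Y: np.ndarray, nuisance: np.ndarray) -> float:
    """Pooled lag-1 residual autocorrelation after nuisance regression."""
    resid = Y - nuisance @ (np.linalg.pinv(nuisance) @ Y)
    num = np.einsum("tv,tv->", resid[1:], resid[:-1])
    den = np.einsum("tv,tv->", resid[:-1], resid[:-1])
    return float(np.clip(num / den, 0.0, 0.95))


def _whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) whitening filter applied along the time axis."""
    out = A - rho * np.roll(A, 1, axis=0)
    out[0] = np.sqrt(1.0 - rho ** 2) * A[0]
    return out


def evidence_for_cohort(runs_data, schedules, tr, grid,
                        models=("h1", "h2"),
                        prior: NIGPrior = NIGPrior(),
                        whiten: bool = True) -> EvidenceMaps:
    """Per-subject log-evidence maps, summing evidence over runs.

    ``runs_data`` is a nested list [subject][run] of (volumes, voxels)
    arrays; ``schedules`` the matching run schedules.  Data are demeaned
    per run and the intercept omitted from the evidence design so the
    g-prior covers only centred regressors.  Serial correlation is
    removed by AR(1) prewhitening with a coefficient estimated per run
    from nuisance-only residuals and applied identically to the data and
    to every candidate design.  Runs are independent given the model,
    so their log-evidences add.
    """
    n_sub = len(runs_data)
    n_vox = runs_data[0][0].shape[1]
    logE = np.zeros((n_sub, len(models), n_vox))
    for s in range(n_sub):
        for r, Y in enumerate(runs_data[s]):
            n_volumes = Y.shape[0]
            Yc = Y - Y.mean(axis=0, keepdims=True)
            designs = {model: model_design(schedules[s][r], model, tr,
                                           n_volumes, include_intercept=False)
                       for model in models}
            if whiten:
                first = designs[models[0]]
                nuis_cols = [c for c in first.columns if c not in models]
                rho = _estimate_ar1(Yc, first.frame[nuis_cols].to_numpy())
                Yc = _whiten(Yc, rho)
            for m, model in enumerate(models):
                M = designs[model].values
                if whiten:
                    M = _whiten(M, rho)
                logE[s, m, :] += _log_evidence_many(Yc, M, prior)
    return EvidenceMaps(log_evidence=logE, models=tuple(models),
                        roi_labels=grid.voxel_labels,
                        roi_names=dict(grid.roi_names), prior=prior)
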