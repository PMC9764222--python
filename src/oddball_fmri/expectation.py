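"""Predictability statistics within SSA regions.

Under prediction-error coding, deviant responses should decrease with
deviant predictability (1/3 at position four, 1/2 at five, 1 at six),
and a fully predictable deviant (dev6) should resemble a fully
predictable standard (std2).  Three complementary analyses test this:

* pairwise one-sided signed-rank tests over the ordered deviant
  contrasts plus the effect-size contrasts std0>std2 and dev4>std2 and
  the two-sided dev6 vs std2 comparison, Holm-corrected;
* a linear mixed-effects model of deviant betas on predictability with
  random effects for participants and runs;
* per-participant Spearman rank correlations between predictability and
  deviant betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ComparisonResult",
    "LMMResult",
    "SpearmanResult",
    "PREDICTABILITY_CODES",
    "holm_adjust",
    "pairwise_tests",
    "fit_lmm",
    "spearman_predictability",
]

#: Deviant predictability codes entering the correlational analyses.
PREDICTABILITY_CODES = {"dev4": 1.0 / 3.0, "dev5": 0.5, "dev6": 1.0}

#: contrast name -> (first condition, second condition, alternative)
PAIRWISE_CONTRASTS = (
    ("dev4>dev5", "dev4", "dev5", "greater"),
    ("dev4>dev6", "dev4", "dev6", "greater"),
    ("dev5>dev6", "dev5", "dev6", "greater"),
    ("dev6!=std2", "dev6", "std2", "two-sided"),
    ("std0>std2", "std0", "std2", "greater"),
    ("dev4>std2", "dev4", "std2", "greater"),
)

EXACT_MAX_N = 25   # exact signed-rank null up to here, normal approx above


def holm_adjust(p_raw: np.ndarray, family_size: int | None = None) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment.

    ``family_size`` may exceed the number of p-values supplied when the
    family spans tests performed elsewhere (e.g. the same contrasts in
    other regions); the unseen members are treated as non-rejections,
    which is conservative.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    m = family_size if family_size is not None else p_raw.size
    if m < p_raw.size:
        raise ValueError("family_size smaller than number of p-values")
    order = np.argsort(p_raw, kind="stable")
    # step-down: running maximum of (m - rank) * p from the smallest p upward
    adj_sorted = np.maximum.accumulate(
        np.minimum(1.0, (m - np.arange(p_raw.size)) * p_raw[order]))
    out = np.empty_like(p_raw)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class ComparisonResult:
    contrast: str
    statistic: float
    p_raw: float
    p_holm: float
    n_participants: int
    alternative: str


def _signed_rank(x: np.ndarray, y: np.ndarray, alternative: str):
    """Wilcoxon signed-rank with zero differences dropped.

    Exact null distribution for n <= 25 non-zero pairs, normal
    approximation with continuity correction above.  All-zero
    differences carry no information: statistic 0, p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    if nz.size <= EXACT_MAX_N and not _has_tied_ranks(nz):
        method = "exact"
    elif nz.size <= 14:
        # ties: enumerate all sign assignments conditional on the ranks
        method = stats.PermutationMethod(n_resamples=2 ** nz.size)
    else:
        method = "approx"
    res = stats.wilcoxon(nz, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def _has_tied_ranks(d: np.ndarray) -> bool:
    a = np.abs(d)
    return np.unique(a).size < a.size


def pairwise_tests(participant_means: pd.DataFrame,
                   family_size: int | None = None) -> list[ComparisonResult]:
    """Signed-rank tests of the six condition contrasts in one SSA region.

    ``participant_means`` has one row per participant and one column per
    condition (betas already averaged over runs and voxels within the
    region).  Holm correction uses ``family_size`` (e.g. 30 when the six
    contrasts are tested in five regions) or the number of contrasts.
    """
    if len(participant_means) < 5:
        raise ValueError("need at least 5 participants")
    stats_p = []
    for name, a, b, alternative in PAIRWISE_CONTRASTS:
        s, p = _signed_rank(participant_means[a].to_numpy(),
                            participant_means[b].to_numpy(), alternative)
        stats_p.append((name, a, b, alternative, s, p))
    p_holm = holm_adjust(np.array([t[5] for t in stats_p]),
                         family_size=family_size)
    return [
        ComparisonResult(contrast=name, statistic=s, p_raw=p,
                         p_holm=float(ph), n_participants=len(participant_means),
                         alternative=alt)
        for (name, a, b, alt, s, p), ph in zip(stats_p, p_holm)]


@dataclass(frozen=True)
class LMMResult:
    """Fixed effects of the predictability mixed model in one region."""

    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    slope_p: float
    slope_p_corrected: float            # Bonferroni over SSA regions
    dof: int
    n_obs: int
    converged: bool
    singular: bool
    random_effects: str

    def __post_init__(self):
        lo, hi = self.slope_ci
        if not (lo <= self.slope <= hi):
            raise ValueError("confidence interval must contain the estimate")


def fit_lmm(table: pd.DataFrame, n_rois: int = 1,
            alpha: float = 0.05) -> LMMResult:
    """Mixed model of deviant betas on predictability.

    ``table`` needs columns ``beta``, ``predictability``, ``participant``
    and ``run`` (optionally ``session``, folded into the run factor).
    The model is beta ~ 1 + predictability with a random intercept and
    predictability slope per participant and a random intercept per run
    within participant (variance component).  Fitted by REML; Wald
    confidence limits; the slope p-value is Bonferroni-corrected for the
    number of SSA regions analysed.  Singular or non-converged fits are
    flagged, not dropped.
    """
    required = {"beta", "predictability", "participant", "run"}
    if missing := required - set(table.columns):
        raise ValueError(f"table lacks columns {sorted(missing)}")
    data = table.copy()
    if "session" in data.columns:
        data["run"] = (data["session"].astype(str) + "/" +
                       data["run"].astype(str))
    re_desc = "1 + predictability | participant; 1 | run:participant"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm("beta ~ predictability", data,
                            groups=data["participant"],
                            re_formula="1 + predictability",
                            vc_formula={"run": "0 + C(run)"})
        fit = model.fit(reml=True)
    singular = any("singular" in str(w.message).lower() or
                   "boundary" in str(w.message).lower() for w in caught)
    converged = bool(getattr(fit, "converged", True))
    params = fit.params
    ci = fit.conf_int(alpha=alpha).loc["predictability"]
    p = float(fit.pvalues["predictability"])
    return LMMResult(
        intercept=float(params["Intercept"]),
        slope=float(params["predictability"]),
        slope_ci=(float(ci[0]), float(ci[1])),
        slope_p=p,
        slope_p_corrected=min(1.0, p * n_rois),
        dof=int(len(data) - 2),
        n_obs=int(len(data)),
        converged=converged,
        singular=singular,
        random_effects=re_desc,
    )


@dataclass(frozen=True)
class SpearmanResult:
    participant: int
    rho: float
    p: float
    defined: bool


def spearman_predictability(deviant_betas: np.ndarray) -> list[SpearmanResult]:
    """Per-participant Spearman ρ of deviant betas vs predictability.

    ``deviant_betas`` is (participants, 3, voxels) with the second axis
    ordered (dev4, dev5, dev6), already averaged over runs.  The
    correlation pools all (voxel, deviant-condition) observations of one
    participant.  Constant inputs leave ρ undefined (flagged).
    """
    deviant_betas = np.asarray(deviant_betas, dtype=float)
    if deviant_betas.ndim != 3 or deviant_betas.shape[1] != 3:
        raise ValueError("expected (participants, 3, voxels) array")
    pred = np.repeat([PREDICTABILITY_CODES["dev4"],
                      PREDICTABILITY_CODES["dev5"],
                      PREDICTABILITY_CODES["dev6"]],
                     deviant_betas.shape[2])
    results = []
    for s in range(deviant_betas.shape[0]):
        values = deviant_betas[s].ravel()
        if np.ptp(values) == 0:
            results.append(SpearmanResult(s, np.nan, np.nan, False))
            continue
        rho, p = stats.spearmanr(pred, values)
        results.append(SpearmanResult(s, float(rho), float(p), True))
    return results
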