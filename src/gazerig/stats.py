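"""Repeated-measures inference for within-subject designs.

Implements the one-way repeated-measures ANOVA from its sums of squares,
with the Mauchly sphericity test, Greenhouse-Geisser and Huynh-Feldt
degree-of-freedom corrections, partial eta squared and Bonferroni-adjusted
pairwise post-hoc t tests.  The decomposition is written out directly
(rather than delegated to a mixed-model fit) so every intermediate — the
contrast covariance, the epsilons, the corrected p values — is available
and auditable.

Model: x_ij = mu + s_i + b_j + e_ij for subject i and level j of a single
within-subject factor; the error term is the subject-by-level interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .detect import FixationWindow

__all__ = [
    "RmAnovaResult",
    "PairwiseResult",
    "PupilDirectionResult",
    "rm_anova",
    "mauchly_test",
    "sphericity_epsilons",
    "bonferroni_pairwise",
    "percent_deviation_range_mm",
    "pupil_direction_analysis",
]


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_effect: float
    df_error: float
    p_uncorrected: float
    partial_eta_sq: float
    mauchly_W: float
    mauchly_p: float
    epsilon_gg: float
    epsilon_hf: float
    p_gg: float
    p_hf: float
    n_subjects: int
    n_levels: int

    def summary(self) -> str:
        return (
            f"F({self.df_effect:g}; {self.df_error:g}) = {self.F:.3f}, "
            f"p = {self.p_uncorrected:.3f} (GG p = {self.p_gg:.3f}, HF p = {self.p_hf:.3f}), "
            f"partial eta^2 = {self.partial_eta_sq:.3f}; "
            f"Mauchly W = {self.mauchly_W:.3f} (p = {self.mauchly_p:.3f}), "
            f"eps_GG = {self.epsilon_gg:.3f}, eps_HF = {self.epsilon_hf:.3f}"
        )


@dataclass(frozen=True)
class PairwiseResult:
    level_a: str
    level_b: str
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float


def _as_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a subjects x levels matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells: the design must be complete")
    return x


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthonormal, each
    orthogonal to the unit vector)."""
    helmert = np.zeros((k - 1, k))
    for j in range(1, k):
        helmert[j - 1, :j] = 1.0
        helmert[j - 1, j] = -j
    return helmert / np.linalg.norm(helmert, axis=1, keepdims=True)


def mauchly_test(data) -> tuple[float, float, int, float]:
    """Mauchly's test of sphericity: W, chi-square, df, p.

    W is the ratio of the geometric to the arithmetic mean (raised to
    k-1) of the eigenvalues of the orthonormal-contrast covariance; the
    p value uses the standard chi-square approximation.  For k = 2
    sphericity holds trivially (W = 1, p = 1).
    """
    x = _as_matrix(data)
    n, k = x.shape
    if k == 2:
        return 1.0, 0.0, 0, 1.0
    C = _orthonormal_contrasts(k)
    Sc = C @ np.cov(x, rowvar=False, ddof=1) @ C.T
    tr = float(np.trace(Sc))
    if tr == 0.0:  # all contrasts constant: sphericity holds trivially
        return 1.0, 0.0, k * (k - 1) // 2 - 1, 1.0
    det = float(np.linalg.det(Sc))
    if det <= 0:
        return 0.0, float("inf"), k * (k - 1) // 2 - 1, 0.0
    W = det / (tr / (k - 1)) ** (k - 1)
    d = k - 1
    f = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    df = k * (k - 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return float(W), float(chi2), df, p


def sphericity_epsilons(data) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt sphericity epsilons.

    eps_GG = tr(Sc)^2 / ((k-1) tr(Sc^2)) from the orthonormal-contrast
    covariance Sc; eps_HF is its less conservative upward correction,
    capped at 1.  Both equal 1 for k = 2.
    """
    x = _as_matrix(data)
    n, k = x.shape
    if k == 2:
        return 1.0, 1.0
    C = _orthonormal_contrasts(k)
    Sc = C @ np.cov(x, rowvar=False, ddof=1) @ C.T
    tr = float(np.trace(Sc))
    tr2 = float(np.trace(Sc @ Sc))
    if tr2 == 0.0:  # no contrast variance at all: treat as spherical
        return 1.0, 1.0
    eps_gg = tr**2 / ((k - 1) * tr2)
    denom = (k - 1) * (n - 1 - (k - 1) * eps_gg)
    if denom <= 0:  # too few subjects for the HF correction: fall back to 1
        return float(eps_gg), 1.0
    eps_hf = (n * (k - 1) * eps_gg - 2.0) / denom
    return float(eps_gg), float(min(1.0, max(eps_hf, eps_gg)))


def rm_anova(data) -> RmAnovaResult:
    """One-way repeated-measures ANOVA of a subjects x levels matrix.

    F = MS_level / MS_(subject x level); partial eta^2 =
    SS_level / (SS_level + SS_error); sphericity diagnostics and the
    GG/HF-corrected p values are attached to the result.
    """
    x = _as_matrix(data)
    n, k = x.shape
    grand = x.mean()
    ss_level = n * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subject = k * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_error = ss_total - ss_level - ss_subject
    df_e, df_r = k - 1, (n - 1) * (k - 1)
    ms_error = ss_error / df_r
    F = (ss_level / df_e) / ms_error if ms_error > 0 else (0.0 if ss_level == 0 else float("inf"))
    p = float(sps.f.sf(F, df_e, df_r))
    denom = ss_level + ss_error
    peta = ss_level / denom if denom > 0 else 0.0
    W, _, _, mauchly_p = mauchly_test(x)
    eps_gg, eps_hf = sphericity_epsilons(x)
    p_gg = float(sps.f.sf(F, eps_gg * df_e, eps_gg * df_r))
    p_hf = float(sps.f.sf(F, eps_hf * df_e, eps_hf * df_r))
    return RmAnovaResult(
        F=float(F), df_effect=df_e, df_error=df_r, p_uncorrected=p,
        partial_eta_sq=float(peta), mauchly_W=W, mauchly_p=mauchly_p,
        epsilon_gg=eps_gg, epsilon_hf=eps_hf, p_gg=p_gg, p_hf=p_hf,
        n_subjects=n, n_levels=k,
    )


def bonferroni_pairwise(data, labels: list[str] | None = None) -> list[PairwiseResult]:
    """All k(k-1)/2 paired t tests between levels, Bonferroni adjusted
    (p multiplied by the number of comparisons, capped at 1)."""
    x = _as_matrix(data)
    n, k = x.shape
    labels = labels if labels is not None else [str(j) for j in range(k)]
    m = k * (k - 1) // 2
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            d = x[:, a] - x[:, b]
            sd = d.std(ddof=1)
            if sd == 0:
                t, p = 0.0, 1.0
            else:
                t = float(d.mean() / (sd / np.sqrt(n)))
                p = float(2.0 * sps.t.sf(abs(t), n - 1))
            out.append(
                PairwiseResult(
                    level_a=labels[a], level_b=labels[b], mean_diff=float(d.mean()),
                    t=t, df=n - 1, p_raw=p, p_bonferroni=min(1.0, m * p),
                )
            )
    return out


def percent_deviation_range_mm(percent_deviations, pupil_diameter_mm: float = 5.0) -> float:
    """Convert percent deviations of mean pupil size from the grand mean
    into the equivalent physical range of a pupil of known diameter:
    e.g. deviations of -3.12% and +2.83% of a 5 mm pupil span 0.298 mm."""
    p = np.asarray(percent_deviations, dtype=float)
    return float((p.max() - p.min()) / 100.0 * pupil_diameter_mm)


@dataclass(frozen=True)
class PupilDirectionResult:
    """Gaze-direction bias of the measured pupil size on the calibration
    grid: per-direction means, ANOVAs per axis and the mm-equivalent
    ranges under the stated a.u. <-> mm scale."""

    means_au: dict[str, float]
    percent_dev: dict[str, float]
    horizontal: RmAnovaResult
    vertical: RmAnovaResult
    horizontal_posthoc: list[PairwiseResult]
    vertical_posthoc: list[PairwiseResult]
    range_mm_horizontal: float
    range_mm_vertical: float


# grid indices of the direction groups on the 13-point pattern
_H_LEVELS = {"left": 3, "middle": 0, "right": 4}
_V_LEVELS = {"up": 1, "middle": 0, "down": 2}


def pupil_direction_analysis(
    fixations_by_trial: list[list[FixationWindow]],
    pupil_diameter_mm: float = 5.0,
    split_seed: int = 0,
) -> PupilDirectionResult:
    """Test whether measured pupil size depends on gaze direction.

    Uses the outer-medial and centre coordinates of the 13-point grid:
    leftmost-middle / centre / rightmost-middle form the horizontal
    factor, upmost-middle / centre / downmost-middle the vertical one.
    Trials are split evenly (random, seeded) between the two ANOVAs so
    the shared centre point never enters both.  Per-direction means are
    also expressed as percent deviation from each ANOVA's grand mean and
    converted to millimetres for a pupil of ``pupil_diameter_mm``.
    """
    per_trial: list[dict[int, float]] = []
    for trial in fixations_by_trial:
        d = {w.target_index: w.mean_pupil_au for w in trial}
        if all(i in d for i in set(_H_LEVELS.values()) | set(_V_LEVELS.values())):
            per_trial.append(d)
    if len(per_trial) < 4:
        raise ValueError("need at least 4 complete trials with all direction coordinates")

    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(per_trial))
    half = len(per_trial) // 2
    h_trials = [per_trial[i] for i in order[:half]]
    v_trials = [per_trial[i] for i in order[half : 2 * half]]

    h_mat = np.array([[t[_H_LEVELS[k]] for k in _H_LEVELS] for t in h_trials])
    v_mat = np.array([[t[_V_LEVELS[k]] for k in _V_LEVELS] for t in v_trials])

    means = {**{k: float(h_mat[:, j].mean()) for j, k in enumerate(_H_LEVELS)},
             **{k: float(v_mat[:, j].mean()) for j, k in enumerate(_V_LEVELS) if k != "middle"}}
    pct = {}
    for mat, levels in ((h_mat, _H_LEVELS), (v_mat, _V_LEVELS)):
        grand = mat.mean()
        for j, k in enumerate(levels):
            pct[f"{k}" if k != "middle" else f"middle_{'h' if levels is _H_LEVELS else 'v'}"] = float(
                (mat[:, j].mean() - grand) / grand * 100.0
            )

    h_res = rm_anova(h_mat)
    v_res = rm_anova(v_mat)
    h_pct = [pct["left"], pct["middle_h"], pct["right"]]
    v_pct = [pct["up"], pct["middle_v"], pct["down"]]
    return PupilDirectionResult(
        means_au=means,
        percent_dev=pct,
        horizontal=h_res,
        vertical=v_res,
        horizontal_posthoc=bonferroni_pairwise(h_mat, list(_H_LEVELS)),
        vertical_posthoc=bonferroni_pairwise(v_mat, list(_V_LEVELS)),
        range_mm_horizontal=percent_deviation_range_mm(h_pct, pupil_diameter_mm),
        range_mm_vertical=percent_deviation_range_mm(v_pct, pupil_diameter_mm),
    )
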