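"""Within-subject ANOVA, power-based replicate sufficiency, and
accumulation-curve extrapolation.

The hypothesis tested is whether mean protein abundance differs across
replicate groups (TR triads, BR triads, or each replicate separately).
Subjects are proteins detected in every involved replicate (complete cases);
each subject contributes one value per condition, the mean of its abundances
over that group's members.  The classical one-way repeated-measures
decomposition is used::

    SS_total = SS_between (conditions) + SS_subjects + SS_error
    F = (SS_between / (k-1)) / (SS_error / ((k-1)(s-1)))

with p from the central F distribution and no sphericity correction.

Power calculations use the noncentral F distribution with Cohen's f as
effect size (lambda = f^2 * k * n, df = (k-1, k(n-1))).  Replicate
sufficiency inverts the power function: the smallest per-group n whose power
reaches a target (0.8 by default at the Bonferroni-corrected alpha 0.016).

How many additional proteins further replicates would reveal is estimated
from a replicate-accumulation (rarefaction) curve: the expected number of
distinct proteins over random subsets of the observed replicates, fit with a
saturating model and extrapolated.  This is a clearly labelled heuristic;
the model choice is exposed.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .io_design import AbundanceTable, GroupingScheme
from .qualitative import PresenceMatrix

__all__ = [
    "AnovaResult",
    "PowerResult",
    "FoldIncreaseEstimate",
    "AccumulationModel",
    "rm_anova",
    "bonferroni_alpha",
    "anova_power",
    "cohens_f",
    "required_replicates",
    "fold_increase",
]


class AccumulationModel(str, enum.Enum):
    """Saturating fits for the replicate-accumulation curve."""

    MICHAELIS_MENTEN = "michaelis_menten"
    LOG_LINEAR = "log_linear"


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA summary."""

    f_value: float
    p_value: float
    df_between: int
    df_error: int
    n_subjects: int
    ss_between: float
    ss_subjects: float
    ss_error: float
    condition_means: dict[str, float]

    @property
    def n_conditions(self) -> int:
        return self.df_between + 1

    def to_dict(self) -> dict:
        return {
            "f_value": self.f_value,
            "p_value": self.p_value,
            "df_between": self.df_between,
            "df_error": self.df_error,
            "n_subjects": self.n_subjects,
            "ss_between": self.ss_between,
            "ss_subjects": self.ss_subjects,
            "ss_error": self.ss_error,
            "condition_means": dict(self.condition_means),
        }


@dataclass(frozen=True)
class PowerResult:
    """Smallest per-group replicate number reaching a target ANOVA power.

    ``n_required`` is None when no finite replicate number can reach the
    target (a zero effect size: power stays at alpha for every n).
    """

    k_groups: int
    effect_size_f: float
    alpha: float
    power_target: float
    n_required: int | None
    achieved_power: float

    def to_dict(self) -> dict:
        return {
            "k_groups": self.k_groups,
            "effect_size_f": self.effect_size_f,
            "alpha": self.alpha,
            "power_target": self.power_target,
            "n_required": self.n_required,
            "achieved_power": self.achieved_power,
        }


@dataclass(frozen=True)
class FoldIncreaseEstimate:
    """Accumulation-curve extrapolation of distinct-protein yield."""

    accumulation_curve: tuple[float, ...]  # S(1)..S(n_observed)
    s_observed: float
    n_target: int
    s_extrapolated: float
    fold_increase: float
    model: AccumulationModel

    def to_dict(self) -> dict:
        return {
            "accumulation_curve": list(self.accumulation_curve),
            "s_observed": self.s_observed,
            "n_target": self.n_target,
            "s_extrapolated": self.s_extrapolated,
            "fold_increase": self.fold_increase,
            "model": self.model.value,
        }


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _condition_matrix(
    table: AbundanceTable, grouping: GroupingScheme | None
) -> tuple[np.ndarray, list[str]]:
    """Complete-case subjects x conditions response matrix.

    With a grouping, the condition value is the protein's mean over the
    group's members; without one, every replicate is its own condition.
    """
    if grouping is None:
        labels = list(table.replicate_ids)
        member_sets = [[r] for r in labels]
    else:
        labels = list(grouping.group_labels)
        member_sets = [list(g) for g in grouping.groups]
    involved = [m for ms in member_sets for m in ms]
    col_idx = [table.replicate_ids.index(m) for m in involved]
    sub = table.values[:, col_idx]
    complete = np.all(sub > 0, axis=1)
    rows = table.values[complete]
    cond = np.stack(
        [
            rows[:, [table.replicate_ids.index(m) for m in ms]].mean(axis=1)
            for ms in member_sets
        ],
        axis=1,
    )
    return cond, labels


def rm_anova(
    table: AbundanceTable,
    grouping: GroupingScheme | None = None,
    log_transform: bool = False,
) -> AnovaResult:
    """One-way repeated-measures ANOVA of protein abundance across replicate
    groups (or across single replicates when ``grouping`` is None).

    Subjects are complete-case proteins (nonzero in every involved
    replicate).  ``log_transform`` applies a natural log to the responses
    before decomposition.  Raises on fewer than 2 conditions or complete
    cases.
    """
    y, labels = _condition_matrix(table, grouping)
    if y.shape[1] < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 conditions")
    if y.shape[0] < 2:
        raise ValueError(
            f"repeated-measures ANOVA needs >=2 complete-case subjects; got {y.shape[0]}"
        )
    if log_transform:
        y = np.log(y)
    s, k = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    cond_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_between = float(s * ((cond_means - grand) ** 2).sum())
    ss_subjects = float(k * ((subj_means - grand) ** 2).sum())
    ss_error = max(ss_total - ss_between - ss_subjects, 0.0)
    df_b, df_e = k - 1, (k - 1) * (s - 1)
    ms_b = ss_between / df_b
    ms_e = ss_error / df_e
    tol = 1e-12 * max(ss_total, 1.0)  # absorb rounding residue of the decomposition
    if ss_between <= tol:
        f_value, p_value = 0.0, 1.0
    elif ss_error <= tol:
        f_value, p_value = math.inf, 0.0
    else:
        f_value = ms_b / ms_e
        p_value = float(stats.f.sf(f_value, df_b, df_e))
    return AnovaResult(
        f_value=float(f_value),
        p_value=float(p_value),
        df_between=df_b,
        df_error=df_e,
        n_subjects=s,
        ss_between=ss_between,
        ss_subjects=ss_subjects,
        ss_error=ss_error,
        condition_means={lab: float(m) for lab, m in zip(labels, cond_means)},
    )


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Bonferroni-corrected per-comparison significance level, alpha / k."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be a positive integer")
    return alpha / k


# ---------------------------------------------------------------------------
# power


def anova_power(
    effect_size_f: float, k_groups: int, n_per_group: int, alpha: float
) -> float:
    """Power of a one-way ANOVA with Cohen's f effect size.

    ``power = P(F' > F_crit)`` where ``F'`` is noncentral F with
    df ``(k-1, k(n-1))`` and noncentrality ``f^2 * k * n``; ``F_crit`` is the
    upper-alpha quantile of the central F.  At f = 0 this equals alpha.
    """
    if effect_size_f < 0:
        raise ValueError("effect size f must be non-negative")
    if k_groups < 2 or n_per_group < 2:
        raise ValueError("need k >= 2 groups and n >= 2 per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    dfn = k_groups - 1
    dfd = k_groups * (n_per_group - 1)
    fcrit = stats.f.isf(alpha, dfn, dfd)
    nc = effect_size_f**2 * k_groups * n_per_group
    if nc == 0:
        return float(alpha)
    return float(stats.ncf.sf(fcrit, dfn, dfd, nc))


def cohens_f(condition_values: np.ndarray) -> float:
    """Cohen's f from a subjects x conditions matrix: the population SD of
    the condition means over the pooled within-condition SD."""
    y = np.asarray(condition_values, dtype=float)
    means = y.mean(axis=0)
    between_sd = float(np.sqrt(((means - means.mean()) ** 2).mean()))
    within_var = float(y.var(axis=0, ddof=1).mean())
    if within_var == 0:
        raise ValueError("zero within-condition variance; effect size undefined")
    return between_sd / math.sqrt(within_var)


def required_replicates(
    table: AbundanceTable,
    alpha: float = 0.016,
    power_target: float = 0.8,
    max_n: int = 1_000_000,
) -> PowerResult:
    """Smallest per-replicate-group n whose ANOVA power reaches the target.

    Conditions are the table's replicates (k = number of replicate columns);
    the effect size is Cohen's f computed from complete-case proteins'
    per-replicate means and pooled within-replicate variance.
    """
    if table.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    y, _ = _condition_matrix(table, None)
    if y.shape[0] < 2:
        raise ValueError("need >=2 complete-case proteins to estimate the effect size")
    f = cohens_f(y)
    k = table.n_replicates
    if f == 0:
        return PowerResult(
            k_groups=k,
            effect_size_f=0.0,
            alpha=float(alpha),
            power_target=float(power_target),
            n_required=None,
            achieved_power=float(alpha),
        )
    # bracket by doubling, then bisect (power is monotone increasing in n)
    lo, hi = 2, 2
    while anova_power(f, k, hi, alpha) < power_target:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise RuntimeError(
                f"power {power_target} not reachable below n = {max_n} (f = {f:.3g})"
            )
    while lo < hi:
        mid = (lo + hi) // 2
        if anova_power(f, k, mid, alpha) >= power_target:
            hi = mid
        else:
            lo = mid + 1
    n = hi
    power = anova_power(f, k, n, alpha)
    return PowerResult(
        k_groups=k,
        effect_size_f=float(f),
        alpha=float(alpha),
        power_target=float(power_target),
        n_required=n,
        achieved_power=float(power),
    )


# ---------------------------------------------------------------------------
# accumulation curve


def accumulation_curve(
    presence: PresenceMatrix,
    n_subsample_orders: int = 200,
    seed: int = 0,
    exhaustive_limit: int = 200,
) -> np.ndarray:
    """Expected distinct-protein count S(n) for n = 1..R observed replicates.

    Subset averaging: exhaustive over all C(R, n) subsets when that count is
    at most ``exhaustive_limit``, otherwise Monte-Carlo over
    ``n_subsample_orders`` seeded random subsets.
    """
    mat = presence.present
    n_reps = presence.n_replicates
    rng = np.random.default_rng(seed)
    curve = np.empty(n_reps)
    for n in range(1, n_reps + 1):
        n_subsets = math.comb(n_reps, n)
        if n_subsets <= exhaustive_limit:
            subsets = itertools.combinations(range(n_reps), n)
            counts = [int(mat[:, list(sub)].any(axis=1).sum()) for sub in subsets]
        else:
            counts = [
                int(mat[:, rng.choice(n_reps, size=n, replace=False)].any(axis=1).sum())
                for _ in range(n_subsample_orders)
            ]
        curve[n - 1] = float(np.mean(counts))
    return curve


def _fit_michaelis_menten(n: np.ndarray, s: np.ndarray):
    def mm(x, vmax, km):
        return vmax * x / (km + x)

    p0 = (float(s[-1]) * 1.2, 1.0)
    popt, _ = optimize.curve_fit(
        mm, n, s, p0=p0, bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10000
    )
    return lambda x: mm(np.asarray(x, dtype=float), *popt)


def _fit_log_linear(n: np.ndarray, s: np.ndarray):
    b, a = np.polyfit(np.log(n), s, 1)
    return lambda x: a + b * np.log(np.asarray(x, dtype=float))


def fold_increase(
    presence: PresenceMatrix,
    n_target: int,
    model: AccumulationModel | str = AccumulationModel.MICHAELIS_MENTEN,
    n_subsample_orders: int = 200,
    seed: int = 0,
) -> FoldIncreaseEstimate:
    """Fractional increase in distinct proteins expected from ``n_target``
    replicates, relative to the observed replicate set.

    Fits a saturating model to the accumulation curve and evaluates it at
    ``n_target``; the extrapolation is floored at the observed richness so
    the fold increase is never negative for n_target >= n_observed.
    """
    model = AccumulationModel(model)
    n_obs = presence.n_replicates
    if n_target < n_obs:
        raise ValueError(f"n_target ({n_target}) below observed replicates ({n_obs})")
    curve = accumulation_curve(presence, n_subsample_orders=n_subsample_orders, seed=seed)
    s_obs = float(curve[-1])
    if s_obs == 0:
        raise ValueError("no protein is present in any replicate")
    n = np.arange(1, n_obs + 1, dtype=float)
    if float(curve.max() - curve.min()) < 1e-9:
        s_ext = s_obs  # flat curve: already saturated
    else:
        fit = (
            _fit_michaelis_menten if model is AccumulationModel.MICHAELIS_MENTEN else _fit_log_linear
        )(n, curve)
        s_ext = max(float(fit(n_target)), s_obs)
    return FoldIncreaseEstimate(
        accumulation_curve=tuple(float(v) for v in curve),
        s_observed=s_obs,
        n_target=int(n_target),
        s_extrapolated=s_ext,
        fold_increase=(s_ext - s_obs) / s_obs,
        model=model,
    )
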