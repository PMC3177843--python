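"""Resampling-based statistical engine for two-group repeated-measures designs.

Implements the split-plot (mixed) ANOVA with one between-subjects factor at
two levels and one within-subjects factor, together with the resampling
machinery used around it: a bootstrap F-null built by structure-breaking
resampling of the pooled observations, Duncan's multiple range test,
one-sample t-tests, percentile-bootstrap confidence intervals for means and
Pearson correlations, and the Shapiro-Wilk / Levene assumption checks that
decide whether the bootstrap branch runs.

Each effect in the split-plot decomposition is tested against its own error
stratum: the group effect against subjects-within-groups, the condition and
interaction effects against the condition-by-subject residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = [
    "SplitPlotData",
    "SplitPlotResult",
    "BootstrapNull",
    "CorrelationResult",
    "split_plot_anova",
    "bootstrap_f_null",
    "duncan_posthoc",
    "one_sample_t",
    "bootstrap_mean_ci",
    "pearson_with_bootstrap_ci",
    "assumption_checks",
    "cohens_d",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SplitPlotData:
    """Complete-case response matrix for a 2 x k split-plot design.

    Parameters
    ----------
    values : (N, k) array
        One row per participant, one column per within-subject condition.
    groups : length-N sequence
        Between-subjects group label for each row; exactly two distinct
        labels must occur.
    conditions : optional sequence of k condition names.
    participants : optional sequence of N participant identifiers.
    """

    values: np.ndarray
    groups: np.ndarray
    conditions: list[str] = field(default_factory=list)
    participants: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D participant x condition matrix")
        if np.isnan(self.values).any():
            raise ValueError("values contains missing cells; apply listwise deletion first")
        if len(self.groups) != self.values.shape[0]:
            raise ValueError("groups length must match the number of rows")
        labels = pd.unique(self.groups)
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {len(labels)}")
        counts = [(self.groups == g).sum() for g in labels]
        if min(counts) < 2:
            raise ValueError("each group needs at least 2 participants")
        if not self.conditions:
            self.conditions = [f"c{j+1}" for j in range(self.values.shape[1])]
        if not self.participants:
            self.participants = list(range(self.values.shape[0]))

    @property
    def group_labels(self) -> list:
        return list(pd.unique(self.groups))

    def sorted_by_group(self) -> tuple[np.ndarray, int]:
        """Return (values with group-1 rows first, size of group 1)."""
        g1 = self.group_labels[0]
        mask = self.groups == g1
        return np.vstack([self.values[mask], self.values[~mask]]), int(mask.sum())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_col: str = "group") -> "SplitPlotData":
        """Build from a wide DataFrame (index = participant, one group column)."""
        cond_cols = [c for c in frame.columns if c != group_col]
        frame = frame.dropna(subset=cond_cols)
        return cls(
            values=frame[cond_cols].to_numpy(float),
            groups=frame[group_col].to_numpy(),
            conditions=list(cond_cols),
            participants=list(frame.index),
        )


@dataclass
class SplitPlotResult:
    """ANOVA table plus error strata for the 2 x k split-plot design."""

    effects: pd.DataFrame           # index: group, condition, interaction
    error_strata: pd.DataFrame      # index: subjects_within_group, residual
    n_per_group: tuple[int, int]
    conditions: list[str]

    @property
    def ss_total(self) -> float:
        return float(self.effects["SS"].sum() + self.error_strata["SS"].sum())

    def f(self, effect: str) -> float:
        return float(self.effects.loc[effect, "F"])

    def to_dict(self) -> dict:
        return {
            "effects": self.effects.reset_index().to_dict(orient="records"),
            "error_strata": self.error_strata.reset_index().to_dict(orient="records"),
            "n_per_group": list(self.n_per_group),
            "conditions": list(self.conditions),
        }


@dataclass
class BootstrapNull:
    """Empirical F-null distributions from structure-breaking resampling."""

    observed_f: dict
    null_f: dict                    # effect -> (B,) array
    p_boot: dict
    b: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_f": self.observed_f,
            "p_boot": self.p_boot,
            "B": self.b,
            "seed": self.seed,
        }


@dataclass
class CorrelationResult:
    """Pearson correlation with a percentile-bootstrap confidence interval."""

    r: float
    n: int
    p_parametric: float
    ci_low: float
    ci_high: float
    b: int
    seed: int
    level: float = 0.95

    @property
    def excludes_zero(self) -> bool:
        return bool(self.ci_low > 0 or self.ci_high < 0)

    def to_dict(self) -> dict:
        return {
            "r": self.r, "n": self.n, "p_parametric": self.p_parametric,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "excludes_zero": self.excludes_zero, "B": self.b,
            "seed": self.seed, "level": self.level,
        }


# ---------------------------------------------------------------------------
# split-plot core
# ---------------------------------------------------------------------------

def _split_plot_ss(y: np.ndarray, n1: int) -> dict:
    """Sums of squares for a 2-group split-plot layout.

    ``y`` has shape (..., N, k) with the first ``n1`` rows in group 1;
    leading axes are treated as independent replicate tables (used to
    vectorize the bootstrap).  Group means are frequency-weighted, which
    keeps the five strata an exact orthogonal decomposition of the total
    SS for this proportional-frequency design.
    """
    N, k = y.shape[-2], y.shape[-1]
    n2 = N - n1
    grand = y.mean(axis=(-2, -1))
    subj = y.mean(axis=-1)
    cell1 = y[..., :n1, :].mean(axis=-2)
    cell2 = y[..., n1:, :].mean(axis=-2)
    gm1 = cell1.mean(axis=-1)
    gm2 = cell2.mean(axis=-1)
    condm = (n1 * cell1 + n2 * cell2) / N
    g = grand[..., None]

    ss_group = k * (n1 * (gm1 - grand) ** 2 + n2 * (gm2 - grand) ** 2)
    ss_subj = k * (
        ((subj[..., :n1] - gm1[..., None]) ** 2).sum(-1)
        + ((subj[..., n1:] - gm2[..., None]) ** 2).sum(-1)
    )
    ss_cond = N * ((condm - g) ** 2).sum(-1)
    ss_cells = n1 * ((cell1 - g) ** 2).sum(-1) + n2 * ((cell2 - g) ** 2).sum(-1)
    ss_inter = np.maximum(ss_cells - ss_group - ss_cond, 0.0)

    cellfull = np.concatenate(
        [np.broadcast_to(cell1[..., None, :], cell1.shape[:-1] + (n1, k)),
         np.broadcast_to(cell2[..., None, :], cell2.shape[:-1] + (n2, k))],
        axis=-2,
    )
    gmfull = np.concatenate(
        [np.broadcast_to(gm1[..., None], gm1.shape + (n1,)),
         np.broadcast_to(gm2[..., None], gm2.shape + (n2,))],
        axis=-1,
    )
    resid = y - subj[..., :, None] - cellfull + gmfull[..., None]
    ss_resid = (resid ** 2).sum(axis=(-2, -1))

    return {
        "group": ss_group, "subj": ss_subj, "condition": ss_cond,
        "interaction": ss_inter, "resid": ss_resid,
        "df": {
            "group": 1, "subj": N - 2, "condition": k - 1,
            "interaction": k - 1, "resid": (N - 2) * (k - 1),
        },
    }


def _split_plot_f(y: np.ndarray, n1: int) -> dict:
    """F statistics (vectorized over leading axes)."""
    ss = _split_plot_ss(y, n1)
    df = ss["df"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_subj = ss["subj"] / df["subj"]
        ms_resid = ss["resid"] / df["resid"]
        return {
            "group": (ss["group"] / df["group"]) / ms_subj,
            "condition": (ss["condition"] / df["condition"]) / ms_resid,
            "interaction": (ss["interaction"] / df["interaction"]) / ms_resid,
        }


def split_plot_anova(data: SplitPlotData) -> SplitPlotResult:
    """Classical split-plot decomposition for a 2 x k mixed design.

    The between-subjects effect is tested against subjects-within-groups
    (df 1, N-2); the within-subjects effect and the interaction against the
    condition-by-subject residual (df k-1, (N-2)(k-1)).  Partial eta squared
    for each effect uses that effect's own error stratum.
    """
    y, n1 = data.sorted_by_group()
    N, k = y.shape
    ss = _split_plot_ss(y, n1)
    df = ss["df"]

    ms_subj = ss["subj"] / df["subj"]
    ms_resid = ss["resid"] / df["resid"]
    rows = []
    for effect, err_ss, err_df, err_ms in [
        ("group", ss["subj"], df["subj"], ms_subj),
        ("condition", ss["resid"], df["resid"], ms_resid),
        ("interaction", ss["resid"], df["resid"], ms_resid),
    ]:
        ss_e = float(ss[effect])
        df_e = df[effect]
        ms_e = ss_e / df_e
        if err_ms > 0:
            f = ms_e / err_ms
            p = float(sps.f.sf(f, df_e, err_df))
        else:
            f, p = np.inf if ss_e > 0 else np.nan, np.nan
        denom = ss_e + float(err_ss)
        pes = ss_e / denom if denom > 0 else np.nan
        rows.append({
            "effect": effect, "SS": ss_e, "df": df_e, "MS": ms_e,
            "df_error": err_df, "F": f, "p_parametric": p,
            "partial_eta_sq": pes,
        })
    effects = pd.DataFrame(rows).set_index("effect")
    strata = pd.DataFrame(
        [{"stratum": "subjects_within_group", "SS": float(ss["subj"]),
          "df": df["subj"], "MS": float(ms_subj)},
         {"stratum": "residual", "SS": float(ss["resid"]),
          "df": df["resid"], "MS": float(ms_resid)}]
    ).set_index("stratum")
    return SplitPlotResult(
        effects=effects, error_strata=strata,
        n_per_group=(n1, N - n1), conditions=list(data.conditions),
    )


# ---------------------------------------------------------------------------
# bootstrap F-null
# ---------------------------------------------------------------------------

def bootstrap_f_null(
    data: SplitPlotData,
    b: int = 2000,
    seed: int | None = None,
    plus_one: bool = False,
    unit: str = "observation",
) -> BootstrapNull:
    """Empirical F-null by resampling the pooled observations.

    Each of the ``b`` iterations pools all N x k observed values, draws
    N x k values with replacement, arranges them into the original design
    shape (same group sizes), and records the three F statistics.  This
    breaks every source of structure — group, condition and subject — so
    the resulting distributions play the role of the central F under the
    full null.  ``p_boot`` is the plain proportion of null F values at or
    above the observed one (``plus_one`` switches to (k+1)/(B+1)).

    ``unit='participant'`` instead resamples whole participant rows within
    each group, preserving subject covariance but still breaking
    condition labels by shuffling each drawn row's columns.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if unit not in ("observation", "participant"):
        raise ValueError("unit must be 'observation' or 'participant'")
    rng = np.random.default_rng(seed)
    y, n1 = data.sorted_by_group()
    N, k = y.shape
    observed = {e: float(v) for e, v in _split_plot_f(y, n1).items()}

    if unit == "observation":
        pool = y.ravel()
        draws = rng.choice(pool, size=(b, N, k), replace=True)
    else:
        rows = np.empty((b, N, k))
        idx1 = rng.integers(0, n1, size=(b, n1))
        idx2 = rng.integers(n1, N, size=(b, N - n1))
        for i in range(b):
            sel = np.concatenate([idx1[i], idx2[i]])
            r = y[sel]
            # break condition labels within each resampled row
            perm = rng.permuted(np.tile(np.arange(k), (N, 1)), axis=1)
            rows[i] = np.take_along_axis(r, perm, axis=1)
        draws = rows

    null_f = _split_plot_f(draws, n1)
    null_f = {e: np.asarray(v, dtype=float) for e, v in null_f.items()}
    p_boot = {}
    for e, obs in observed.items():
        ge = int(np.sum(null_f[e] >= obs))
        p_boot[e] = (ge + 1) / (b + 1) if plus_one else ge / b
    return BootstrapNull(
        observed_f=observed, null_f=null_f, p_boot=p_boot,
        b=b, seed=-1 if seed is None else int(seed),
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def duncan_critical_range(alpha: float, span: int, error_df: float,
                          error_ms: float, n: float) -> float:
    """Critical range for a pair spanning ``span`` ordered means.

    Uses the studentized-range quantile at Duncan's protection level
    alpha_p = 1 - (1 - alpha)**(span - 1).
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
    q = studentized_range.ppf(1.0 - alpha_p, span, error_df)
    return float(q * np.sqrt(error_ms / n))


def duncan_posthoc(
    cell_means: dict | pd.Series,
    error_ms: float,
    error_df: float,
    n_per_mean: float | dict,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Duncan's multiple range test over a set of cell means.

    Means are ranked; a pair spanning p ordered means is significant when
    its difference exceeds r_p = q(alpha_p, p, df) * sqrt(MS_err / n) with
    alpha_p = 1 - (1-alpha)**(p-1).  Following the multiple-range
    convention, a pair contained inside a wider pair already declared
    non-significant is never declared significant.  With unequal n the
    harmonic mean of the two cell sizes enters the critical range.
    """
    means = pd.Series(cell_means, dtype=float)
    if len(means) < 2:
        raise ValueError("need at least 2 means")
    if error_df < 1:
        raise ValueError("error_df must be >= 1")

    degenerate = error_ms <= 0
    if degenerate and means.nunique() > 1:
        warnings.warn("zero error MS with unequal means; all pairs flagged significant")

    order = means.sort_values().index.to_list()
    if np.isscalar(n_per_mean):
        n_of = {k: float(n_per_mean) for k in means.index}
    else:
        n_of = {k: float(v) for k, v in dict(n_per_mean).items()}

    # walk spans from widest to narrowest; a non-significant span protects
    # everything inside it
    m = len(order)
    nonsig_spans: list[tuple[int, int]] = []
    rows = []
    for span in range(m, 1, -1):
        for i in range(0, m - span + 1):
            j = i + span - 1
            a, bname = order[i], order[j]
            diff = float(means[bname] - means[a])
            n_h = 2.0 / (1.0 / n_of[a] + 1.0 / n_of[bname])
            if degenerate:
                crit = 0.0
                sig = means[a] != means[bname]
            else:
                crit = duncan_critical_range(alpha, span, error_df, error_ms, n_h)
                blocked = any(oi <= i and j <= oj for oi, oj in nonsig_spans)
                sig = (diff > crit) and not blocked
                if diff <= crit:
                    nonsig_spans.append((i, j))
            rows.append({
                "mean_low": a, "mean_high": bname, "span": span,
                "difference": diff, "critical_range": crit,
                "significant": bool(sig),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simple tests and bootstrap CIs
# ---------------------------------------------------------------------------

def one_sample_t(values, mu0: float = 0.0) -> dict:
    """Two-sided one-sample t-test against ``mu0`` (df = n - 1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(v) == 0:
        raise ValueError("zero variance sample")
    res = sps.ttest_1samp(v, popmean=mu0)
    return {"t": float(res.statistic), "df": int(v.size - 1),
            "p": float(res.pvalue), "mean": float(v.mean())}


def bootstrap_mean_ci(values, b: int = 2000, level: float = 0.95,
                      seed: int | None = None) -> dict:
    """Percentile-bootstrap CI for a mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(b, v.size))
    boot_means = v[idx].mean(axis=1)
    lo, hi = np.quantile(boot_means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return {
        "mean": float(v.mean()), "ci_low": float(lo), "ci_high": float(hi),
        "excludes_zero": bool(lo > 0 or hi < 0), "B": b, "level": level,
        "seed": -1 if seed is None else int(seed),
    }


def _pearson_batch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for (B, n) paired arrays."""
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(-1)
    den = np.sqrt((xc ** 2).sum(-1) * (yc ** 2).sum(-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def pearson_with_bootstrap_ci(x, y, b: int = 2000, level: float = 0.95,
                              seed: int | None = None) -> CorrelationResult:
    """Pearson r with a percentile-bootstrap CI over paired resampling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(b, n))
    rb = _pearson_batch(x[idx], y[idx])
    rb = rb[np.isfinite(rb)]   # drop degenerate resamples (constant draws)
    lo, hi = np.quantile(rb, [(1 - level) / 2, 1 - (1 - level) / 2])
    return CorrelationResult(
        r=float(r), n=int(n), p_parametric=float(p),
        ci_low=float(lo), ci_high=float(hi), b=b,
        seed=-1 if seed is None else int(seed), level=level,
    )


def cohens_d(sample_a, sample_b, paired: bool = False) -> float:
    """Cohen's d: pooled-SD standardized mean difference, or, for paired
    contrasts, the mean difference over the SD of the differences."""
    a = np.asarray(sample_a, dtype=float)
    bb = np.asarray(sample_b, dtype=float)
    if a.size < 2 or bb.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired:
        if a.size != bb.size:
            raise ValueError("paired samples must have equal length")
        d = a - bb
        sd = d.std(ddof=1)
        if sd == 0:
            if d.mean() == 0:
                return 0.0
            raise ValueError("zero SD of differences")
        return float(d.mean() / sd)
    va, vb = a.var(ddof=1), bb.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (bb.size - 1) * vb) / (a.size + bb.size - 2))
    if pooled == 0:
        if a.mean() == bb.mean():
            return 0.0
        raise ValueError("zero pooled SD")
    return float((a.mean() - bb.mean()) / pooled)


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def assumption_checks(values_by_cell: dict, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk per cell and Levene (mean-centered) per condition.

    ``values_by_cell`` maps (group, condition) -> 1-D array.  Returns per-cell
    W/p, per-condition Levene F/p across the two groups, and a routing flag
    ``bootstrap_recommended`` that is True when any check rejects at
    ``alpha`` — the trigger for the bootstrap branch of the analysis.
    """
    shapiro_rows, levene_rows = [], []
    any_violation = False
    by_condition: dict = {}
    for (group, cond), v in values_by_cell.items():
        v = np.asarray(v, dtype=float)
        by_condition.setdefault(cond, {})[group] = v
        if v.size < 3 or np.ptp(v) == 0:
            warnings.warn(f"normality check skipped for cell ({group}, {cond})")
            shapiro_rows.append({"group": group, "condition": cond,
                                 "W": np.nan, "p": np.nan, "skipped": True})
            continue
        w, p = sps.shapiro(v)
        any_violation |= p < alpha
        shapiro_rows.append({"group": group, "condition": cond,
                             "W": float(w), "p": float(p), "skipped": False})
    for cond, groups in by_condition.items():
        if len(groups) != 2:
            continue
        a, bb = groups.values()
        if min(a.size, bb.size) < 3:
            levene_rows.append({"condition": cond, "F": np.nan, "p": np.nan,
                                "skipped": True})
            continue
        f, p = sps.levene(a, bb, center="mean")
        any_violation |= p < alpha
        levene_rows.append({"condition": cond, "F": float(f), "p": float(p),
                            "skipped": False})
    return {
        "shapiro": pd.DataFrame(shapiro_rows),
        "levene": pd.DataFrame(levene_rows),
        "bootstrap_recommended": bool(any_violation),
    }
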