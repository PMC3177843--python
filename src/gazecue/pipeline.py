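"""End-to-end analysis pipeline and structured report.

Stages, in order: trial scoring and filtering, interference indices,
participant-level outlier exclusion, split-plot ANOVAs (accuracy and RT
indices) with an assumption-driven bootstrap F-null branch, Duncan
post-hocs within groups, per-cell one-sample tests against zero (with a
percentile-bootstrap CI fallback where normality fails), similarity and
emotion scoring, and similarity-interference correlations per character
(perceived and objective modes) with percentile-bootstrap CIs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indices, profiles, saccades, stats
from .synthetic import CohortConfig, SyntheticDataset, generate_cohort

logger = logging.getLogger("gazecue")

BOOT_POLICIES = ("always", "on-assumption-failure", "never")


@dataclass
class AnalysisConfig:
    """Knobs for one pipeline run."""

    cohort: CohortConfig | None = None      # synthetic input when set
    rt_min_ms: float = saccades.RT_MIN_MS
    rt_max_ms: float = saccades.RT_MAX_MS
    min_amplitude_deg: float = saccades.DEFAULT_MIN_AMPLITUDE_DEG
    velocity_threshold_deg_s: float = saccades.DEFAULT_VELOCITY_THRESHOLD
    outlier_k_sd: float = 3.0
    b_iterations: int = 2000
    alpha: float = 0.05
    seed: int = 0
    bootstrap_policy: str = "on-assumption-failure"
    residual_threshold: float = 2.5         # correlation outlier sensitivity

    def validate(self) -> None:
        if self.rt_min_ms >= self.rt_max_ms:
            raise ValueError("rt_min_ms must be below rt_max_ms")
        if self.b_iterations < 0:
            raise ValueError("b_iterations must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bootstrap_policy not in BOOT_POLICIES:
            raise ValueError(f"bootstrap_policy must be one of {BOOT_POLICIES}")


@dataclass
class AnalysisReport:
    """Structured results of one pipeline run."""

    filter_summary: dict
    excluded_participants: dict
    interference_acc: pd.DataFrame
    interference_rt: pd.DataFrame
    anova: dict                 # measure -> SplitPlotResult dict + bootstrap
    assumptions: dict
    duncan: dict
    one_sample: pd.DataFrame
    similarity: pd.DataFrame
    emotions: pd.DataFrame
    correlations: pd.DataFrame
    provenance: dict
    sensitivity: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, pd.DataFrame):
                return o.reset_index().to_dict(orient="records") \
                    if o.index.name else o.to_dict(orient="records")
            if isinstance(o, dict):
                return {str(k): conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.bool_,)):
                return bool(o)
            return o

        return {
            "filter_summary": conv(self.filter_summary),
            "excluded_participants": conv(self.excluded_participants),
            "interference_acc": conv(self.interference_acc),
            "interference_rt": conv(self.interference_rt),
            "anova": conv(self.anova),
            "assumptions": conv(self.assumptions),
            "duncan": conv(self.duncan),
            "one_sample": conv(self.one_sample),
            "similarity": conv(self.similarity),
            "emotions": conv(self.emotions),
            "correlations": conv(self.correlations),
            "sensitivity": conv(self.sensitivity),
            "provenance": conv(self.provenance),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def text_summary(self) -> str:
        lines = ["gaze-cueing interference analysis", "=" * 34, ""]
        fs = self.filter_summary
        lines.append(
            f"trials: {fs['n_total']}; no-saccade "
            f"{fs['counts']['excluded_no_saccade']} ({fs['pct_no_saccade']:.1f}%); "
            f"anticipations/delays {fs['pct_rejected_of_total']:.1f}% of total "
            f"({fs['pct_rejected_of_detected']:.1f}% of detected)")
        for measure in ("accuracy", "rt"):
            blk = self.anova.get(measure)
            if not blk:
                continue
            lines.append("")
            lines.append(f"{measure} interference — split-plot ANOVA "
                         f"(excluded: {self.excluded_participants[measure]})")
            for row in blk["effects"]:
                line = (f"  {row['effect']:<12} F({row['df']},{row['df_error']}) = "
                        f"{row['F']:.2f}, p = {row['p_parametric']:.4f}, "
                        f"partial eta^2 = {row['partial_eta_sq']:.3f}")
                if blk.get("p_boot"):
                    line += f", p_boot = {blk['p_boot'][row['effect']]:.4f}"
                lines.append(line)
        if len(self.correlations):
            lines.append("")
            lines.append("similarity-interference correlations (accuracy index)")
            for row in self.correlations.itertuples():
                lines.append(
                    f"  {row.character:<12} [{row.mode}] r = {row.r:+.3f} "
                    f"(n={row.n}), CI [{row.ci_low:+.3f}, {row.ci_high:+.3f}]"
                    f"{' *' if row.excludes_zero else ''}")
        lines.append("")
        lines.append(f"seed: {self.provenance['seed']}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def rescore_statuses(trials: pd.DataFrame, rt_min: float, rt_max: float) -> pd.DataFrame:
    """(Re)assign exclusion statuses from the recorded latencies."""
    t = trials.copy()
    no_sac = t["rt_ms"].isna() | t["saccade_direction"].isna()
    t.loc[no_sac, "status"] = saccades.STATUS_NO_SACCADE
    t.loc[~no_sac & (t["rt_ms"] < rt_min), "status"] = saccades.STATUS_ANTICIPATION
    t.loc[~no_sac & (t["rt_ms"] > rt_max), "status"] = saccades.STATUS_DELAY
    t.loc[~no_sac & t["rt_ms"].between(rt_min, rt_max), "status"] = saccades.STATUS_KEPT
    return t


def score_traces(traces: dict, design: pd.DataFrame,
                 config: AnalysisConfig) -> pd.DataFrame:
    """Run the saccade detector over raw traces and score each trial."""
    rows = []
    for row in design.itertuples():
        trace = traces[row.trial_id]
        rec = saccades.score_trial(
            trace, participant_id=row.participant_id, character=row.character,
            cue_direction=row.cue_direction, congruency=row.congruency,
            group=row.group,
            min_amplitude_deg=config.min_amplitude_deg,
            velocity_threshold_deg_s=config.velocity_threshold_deg_s,
        )
        rec["trial_id"] = row.trial_id
        rows.append(rec)
    return pd.DataFrame(rows)


def _cell_values(wide: pd.DataFrame) -> dict:
    cells = {}
    for g, sub in wide.groupby("group"):
        for c in [col for col in wide.columns if col != "group"]:
            cells[(g, c)] = sub[c].to_numpy(float)
    return cells


def _one_sample_block(wide: pd.DataFrame, shapiro: pd.DataFrame,
                      b: int, alpha: float, rng) -> pd.DataFrame:
    """Per group x character tests of the interference index against zero.

    Cells failing Shapiro-Wilk normality at ``alpha`` use the percentile
    bootstrap CI of the mean instead of the t-test.
    """
    rows = []
    conds = [c for c in wide.columns if c != "group"]
    for g, sub in wide.groupby("group"):
        for c in conds:
            v = sub[c].dropna().to_numpy(float)
            cell = {"group": g, "character": c, "n": v.size,
                    "mean": float(v.mean()) if v.size else np.nan}
            sw = shapiro[(shapiro["group"] == g) & (shapiro["condition"] == c)]
            normal = bool(len(sw)) and not sw["skipped"].iloc[0] \
                and sw["p"].iloc[0] >= alpha
            if v.size < 2 or np.ptp(v) == 0:
                cell.update(method="skipped", t=np.nan, p=np.nan,
                            ci_low=np.nan, ci_high=np.nan, significant=None)
            elif normal or b < 1:   # parametric-only when resampling disabled
                res = stats.one_sample_t(v)
                cell.update(method="t", t=res["t"], p=res["p"],
                            ci_low=np.nan, ci_high=np.nan,
                            significant=bool(res["p"] < alpha))
            else:
                ci = stats.bootstrap_mean_ci(
                    v, b=b, seed=int(rng.integers(2 ** 31)))
                cell.update(method="bootstrap_ci", t=np.nan, p=np.nan,
                            ci_low=ci["ci_low"], ci_high=ci["ci_high"],
                            significant=bool(ci["excludes_zero"]))
            rows.append(cell)
    return pd.DataFrame(rows)


def _duncan_block(result: stats.SplitPlotResult, wide: pd.DataFrame,
                  alpha: float) -> dict:
    """Duncan post-hocs across characters within each group, against the
    condition-by-subject residual MS of the split-plot ANOVA."""
    ms = float(result.error_strata.loc["residual", "MS"])
    df = float(result.error_strata.loc["residual", "df"])
    conds = [c for c in wide.columns if c != "group"]
    out = {}
    for g, sub in wide.groupby("group"):
        means = sub[conds].mean()
        out[str(g)] = stats.duncan_posthoc(
            means, error_ms=ms, error_df=df, n_per_mean=len(sub), alpha=alpha)
    return out


def _correlations(acc_wide: pd.DataFrame, sim: pd.DataFrame, b: int,
                  rng) -> pd.DataFrame:
    rows = []
    conds = [c for c in acc_wide.columns if c != "group"]
    for mode in ("perceived", "objective"):
        for c in conds:
            pivot = sim[sim["character"] == c].set_index("participant_id")[mode]
            joined = pd.concat([acc_wide[c], pivot], axis=1, join="inner").dropna()
            if len(joined) < 3 or joined.nunique().min() < 2:
                continue
            if b < 1:   # parametric-only: no bootstrap CI, no seed use
                from scipy import stats as sps
                r, p = sps.pearsonr(joined[mode], joined[c])
                rows.append({"character": c, "mode": mode, "r": float(r),
                             "n": len(joined), "p_parametric": float(p),
                             "ci_low": np.nan, "ci_high": np.nan,
                             "excludes_zero": None, "B": 0, "seed": None,
                             "level": np.nan})
                continue
            res = stats.pearson_with_bootstrap_ci(
                joined[mode], joined[c], b=b,
                seed=int(rng.integers(2 ** 31)))
            rows.append({"character": c, "mode": mode, **res.to_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def run_pipeline(
    config: AnalysisConfig,
    dataset: SyntheticDataset | None = None,
    trials: pd.DataFrame | None = None,
    ratings: pd.DataFrame | None = None,
    emotions: pd.DataFrame | None = None,
    traces: dict | None = None,
) -> AnalysisReport:
    """Run the full analysis and return a structured report.

    Input is either a :class:`SyntheticDataset` (or a cohort config inside
    ``config``), or user-supplied tables: a scored trial table (plus
    optional raw traces, which are then re-scored by the detector) and the
    questionnaire tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if dataset is None and config.cohort is not None:
        dataset = generate_cohort(config.cohort)
    if dataset is not None:
        trials = dataset.trials
        ratings = dataset.ratings
        emotions = dataset.emotions
        traces = dataset.traces or None
    if trials is None:
        raise ValueError("no input: provide a dataset, cohort config, or trial table")

    if traces:
        logger.info("scoring %d raw traces", len(traces))
        trials = score_traces(traces, trials, config)
    trials = rescore_statuses(trials, config.rt_min_ms, config.rt_max_ms)
    fsummary = saccades.filter_summary(trials)
    logger.info("filter summary: %.1f%% no-saccade, %.1f%% rejected",
                fsummary["pct_no_saccade"], fsummary["pct_rejected_of_total"])

    table = indices.interference_table(trials)
    wides = {"accuracy": indices.to_wide(table, "acc_interference"),
             "rt": indices.to_wide(table, "rt_interference")}

    excluded, anova, assumptions, duncan = {}, {}, {}, {}
    one_sample_frames = []
    acc_wide_kept = None
    for measure, wide in wides.items():
        wide = wide.dropna()
        kept, excl = indices.exclude_outlier_participants(wide, config.outlier_k_sd)
        excluded[measure] = excl
        if excl:
            logger.info("%s: excluded outlier participants %s", measure, excl)
        if measure == "accuracy":
            acc_wide_kept = kept

        data = stats.SplitPlotData.from_frame(kept)
        result = stats.split_plot_anova(data)
        checks = stats.assumption_checks(_cell_values(kept), alpha=config.alpha)
        assumptions[measure] = {
            "shapiro": checks["shapiro"], "levene": checks["levene"],
            "bootstrap_recommended": checks["bootstrap_recommended"],
        }
        run_boot = config.b_iterations > 0 and (
            config.bootstrap_policy == "always"
            or (config.bootstrap_policy == "on-assumption-failure"
                and checks["bootstrap_recommended"]))
        block = result.to_dict()
        if run_boot:
            boot = stats.bootstrap_f_null(
                data, b=config.b_iterations, seed=int(rng.integers(2 ** 31)))
            block["p_boot"] = boot.p_boot
            block["bootstrap"] = boot.to_dict()
        anova[measure] = block
        duncan[measure] = _duncan_block(result, kept, config.alpha)
        os_block = _one_sample_block(
            kept, checks["shapiro"], config.b_iterations, config.alpha, rng)
        os_block.insert(0, "measure", measure)
        one_sample_frames.append(os_block)

    one_sample = pd.concat(one_sample_frames, ignore_index=True)

    sim = (profiles.similarity_table(ratings)
           if ratings is not None and len(ratings) else pd.DataFrame())
    emo = (profiles.emotion_table(emotions)
           if emotions is not None and len(emotions) else pd.DataFrame())
    corrs = (_correlations(acc_wide_kept, sim, config.b_iterations, rng)
             if len(sim) and acc_wide_kept is not None else pd.DataFrame())

    report = AnalysisReport(
        filter_summary=fsummary,
        excluded_participants=excluded,
        interference_acc=wides["accuracy"].reset_index(),
        interference_rt=wides["rt"].reset_index(),
        anova=anova,
        assumptions=assumptions,
        duncan=duncan,
        one_sample=one_sample,
        similarity=sim,
        emotions=emo,
        correlations=corrs,
        provenance={
            "seed": config.seed,
            "b_iterations": config.b_iterations,
            "bootstrap_policy": config.bootstrap_policy,
            "outlier_k_sd": config.outlier_k_sd,
            "alpha": config.alpha,
            "cohort": config.cohort.to_dict() if config.cohort else None,
        },
    )
    if len(corrs) and acc_wide_kept is not None and len(sim):
        report.sensitivity = outlier_sensitivity(
            acc_wide_kept, sim, corrs, threshold=config.residual_threshold)
    return report


def outlier_sensitivity(acc_wide: pd.DataFrame, sim: pd.DataFrame,
                        correlations: pd.DataFrame,
                        threshold: float = 2.5) -> pd.DataFrame:
    """Recompute each similarity-interference correlation after dropping
    points with absolute standardized regression residuals above
    ``threshold``; reports the base and the trimmed r side by side."""
    rows = []
    for base in correlations.itertuples():
        pivot = sim[sim["character"] == base.character].set_index(
            "participant_id")[base.mode]
        joined = pd.concat([acc_wide[base.character], pivot],
                           axis=1, join="inner").dropna()
        x = joined[base.mode].to_numpy(float)
        y = joined[base.character].to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        sd = resid.std(ddof=2) if len(resid) > 2 else 0.0
        keep = np.abs(resid) <= threshold * sd if sd > 0 else np.ones_like(resid, bool)
        row = {"character": base.character, "mode": base.mode,
               "r_base": base.r, "n_base": len(x),
               "n_removed": int((~keep).sum())}
        if keep.sum() < 4:
            row.update(r_trimmed=np.nan, skipped=True)
        else:
            row.update(r_trimmed=float(np.corrcoef(x[keep], y[keep])[0, 1]),
                       skipped=False)
        rows.append(row)
    return pd.DataFrame(rows)
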