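"""ERP component analysis: artifact rejection, averaging, window
amplitudes, and group/condition statistics.

The chain mirrors a conventional visual-ERP analysis: trials with any
channel exceeding +-120 microvolts between -100 and 500 ms are rejected
(strictly greater than the limit; a trial peaking at exactly the limit
is retained); accepted trials are baseline-corrected to the pre-stimulus
mean and averaged per condition; component amplitudes are the mean over
a fixed latency window and electrode set, reported per hemisphere
(odd-numbered electrodes left, even right); and between-group /
within-condition effects are tested with a univariate mixed-model
repeated-measures ANOVA (between factor: group; within factor:
condition), which is how the multivariate repeated-measures analysis is
realized here — the output labels the formulation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from closurenet.containers import EpochSet, Evoked

__all__ = [
    "ComponentWindow",
    "DEFAULT_WINDOWS",
    "reject_artifacts",
    "baseline_and_average",
    "window_amplitude",
    "amplitude_table",
    "component_stats",
    "mixed_anova_oracle_frame",
    "component_correlations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentWindow:
    """A component's latency window, electrode set and expected polarity."""

    name: str
    window_ms: tuple[float, float]
    electrodes: tuple[str, ...]
    polarity: int  # +1 positive-going, -1 negative-going

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not lo < hi:
            raise ValueError("window must satisfy lo < hi")


#: Component analysis windows: P1 100-120 ms at PO5/PO6, N1 170-200 ms
#: and Ncl 300-340 ms at PO7/PO8.
DEFAULT_WINDOWS = {
    "P1": ComponentWindow("P1", (100.0, 120.0), ("PO5", "PO6"), +1),
    "N1": ComponentWindow("N1", (170.0, 200.0), ("PO7", "PO8"), -1),
    "Ncl": ComponentWindow("Ncl", (300.0, 340.0), ("PO7", "PO8"), -1),
}


def reject_artifacts(
    epochs: EpochSet,
    limit_uV: float = 120.0,
    window_ms: tuple[float, float] = (-100.0, 500.0),
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop trials with |v| strictly above the limit inside the window.

    Returns the accepted EpochSet and a per-condition rejection log.  An
    empty result is flagged with a warning, never returned silently.
    """
    lo, hi = window_ms
    step = 1000.0 / epochs.sfreq  # the epoch grid may end one sample short
    if lo < epochs.times.min() - step or hi > epochs.times.max() + step:
        raise ValueError("rejection window outside epoch extent")
    tmask = epochs.time_mask(lo, hi)
    bad = np.any(np.abs(epochs.data[:, :, tmask]) > limit_uV, axis=(1, 2))
    log = (
        pd.DataFrame({"condition": epochs.conditions, "rejected": bad})
        .groupby("condition")["rejected"]
        .agg(n_total="count", n_rejected="sum")
        .reset_index()
    )
    accepted = epochs.pick_trials(np.flatnonzero(~bad))
    if accepted.n_trials == 0:
        logger.warning("artifact rejection removed every trial (limit %.1f uV)", limit_uV)
    return accepted, log


def baseline_and_average(epochs: EpochSet, baseline_ms: tuple[float, float] = (-100.0, 0.0)) -> dict[str, Evoked]:
    """Baseline-correct each trial to the pre-stimulus mean, then average
    per condition.  Conditions left with zero trials are reported as
    missing (absent key) with a warning."""
    bmask = epochs.time_mask(*baseline_ms)
    if not bmask.any():
        raise ValueError("baseline interval outside epoch extent")
    base = epochs.data[:, :, bmask].mean(axis=2, keepdims=True)
    corrected = epochs.data - base
    out: dict[str, Evoked] = {}
    for cond in dict.fromkeys(epochs.conditions):
        idx = [i for i, c in enumerate(epochs.conditions) if c == cond]
        if not idx:
            logger.warning("condition %s has no accepted trials (missing cell)", cond)
            continue
        out[cond] = Evoked(data=corrected[idx].mean(axis=0), times=epochs.times,
                           ch_names=epochs.ch_names, condition=cond,
                           n_trials=len(idx), subject=epochs.subject, group=epochs.group)
    return out


_HEMI_RE = re.compile(r"(\d+)$")


def _hemisphere(ch: str) -> str:
    m = _HEMI_RE.search(ch)
    if not m:
        return "mid"
    return "left" if int(m.group(1)) % 2 == 1 else "right"


def window_amplitude(evoked: Evoked, window: ComponentWindow) -> dict[str, float]:
    """Mean microvolts over the window's samples and electrodes, split by
    hemisphere (odd electrode numbers left, even right)."""
    lo, hi = window.window_ms
    tmask = (evoked.times >= lo) & (evoked.times <= hi)
    if not tmask.any():
        raise ValueError("component window outside evoked extent")
    missing = [e for e in window.electrodes if e not in evoked.ch_names]
    if missing:
        raise ValueError(f"electrodes not in montage: {missing}")
    out: dict[str, float] = {}
    for hemi in ("left", "right", "mid"):
        chans = [evoked.ch_names.index(e) for e in window.electrodes if _hemisphere(e) == hemi]
        if chans:
            out[hemi] = float(evoked.data[np.ix_(chans, np.flatnonzero(tmask))].mean())
    return out


def amplitude_table(
    evoked_by_subject: dict[str, dict[str, Evoked]],
    groups: dict[str, str],
    windows: dict[str, ComponentWindow] | None = None,
) -> pd.DataFrame:
    """One row per subject x condition x component x hemisphere."""
    windows = windows or DEFAULT_WINDOWS
    rows = []
    for subject, by_cond in evoked_by_subject.items():
        for cond, evoked in by_cond.items():
            for comp, win in windows.items():
                for hemi, amp in window_amplitude(evoked, win).items():
                    rows.append({"subject": subject, "group": groups[subject],
                                 "condition": cond, "component": comp,
                                 "hemisphere": hemi, "amplitude": amp})
    return pd.DataFrame(rows)


def _mixed_anova_ss(df: pd.DataFrame) -> pd.DataFrame:
    """Univariate mixed-model ANOVA (between: group; within: condition).

    Classic sums-of-squares for a design where every subject sees every
    condition; group sizes may differ.  Degenerate zero-variance cells
    yield F = 0, p = 1 rather than NaN.
    """
    k = df["condition"].nunique()
    groups = sorted(df["group"].unique())
    n_g = {g: df[df.group == g]["subject"].nunique() for g in groups}
    N = sum(n_g.values())
    m = df["amplitude"].mean()
    subj_means = df.groupby(["group", "subject"])["amplitude"].mean()
    grp_means = df.groupby("group")["amplitude"].mean()
    cond_means = df.groupby("condition")["amplitude"].mean()
    cell_means = df.groupby(["group", "condition"])["amplitude"].mean()

    ss_group = k * sum(n_g[g] * (grp_means[g] - m) ** 2 for g in groups)
    ss_subj = k * sum((subj_means[g, s] - grp_means[g]) ** 2
                      for g, s in subj_means.index)
    ss_cond = N * ((cond_means - m) ** 2).sum()
    ss_cells = sum(n_g[g] * (cell_means[g, c] - m) ** 2 for g, c in cell_means.index)
    ss_inter = ss_cells - ss_group - ss_cond
    resid = df.apply(
        lambda r: r["amplitude"] - subj_means[r["group"], r["subject"]]
        - cell_means[r["group"], r["condition"]] + grp_means[r["group"]],
        axis=1,
    )
    ss_err_within = (resid ** 2).sum()

    df_group, df_subj = len(groups) - 1, N - len(groups)
    df_cond = k - 1
    df_inter = df_group * df_cond
    df_err = df_subj * df_cond

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        ms_eff = ss_eff / df_eff if df_eff > 0 else 0.0
        if ms_err <= 1e-300:
            return (0.0, 1.0) if ms_eff <= 1e-12 else (np.inf, 0.0)
        f = ms_eff / ms_err
        return float(f), float(stats.f.sf(f, df_eff, df_err))

    rows = []
    for name, ss_eff, d_eff, ss_err, d_err in [
        ("group", ss_group, df_group, ss_subj, df_subj),
        ("condition", ss_cond, df_cond, ss_err_within, df_err),
        ("group * condition", ss_inter, df_inter, ss_err_within, df_err),
    ]:
        f, p = f_and_p(ss_eff, d_eff, ss_err, d_err)
        rows.append({"effect": name, "F": f, "df1": d_eff, "df2": d_err, "p": p})
    return pd.DataFrame(rows)


def _cohens_d_group(df: pd.DataFrame) -> float:
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        return np.nan
    a = df[df.group == groups[0]].groupby("subject")["amplitude"].mean().to_numpy()
    b = df[df.group == groups[1]].groupby("subject")["amplitude"].mean().to_numpy()
    pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else np.nan


def component_stats(table: pd.DataFrame, collapse_hemisphere: bool = True) -> pd.DataFrame:
    """Group, condition, and group x condition F tests per component.

    The repeated-measures analysis is realized as a univariate
    mixed-model ANOVA (labeled in the ``formulation`` column); Cohen's d
    for the group effect is computed from subject means and the pooled
    SD.  Two-tailed, alpha 0.05 by convention of the reported p-values.
    """
    if table.groupby("group")["subject"].nunique().min() < 2:
        raise ValueError("at least 2 subjects per group required")
    out = []
    for comp, sub in table.groupby("component"):
        df = sub.copy()
        if collapse_hemisphere and "hemisphere" in df.columns:
            df = (df.groupby(["subject", "group", "condition"], as_index=False)
                    ["amplitude"].mean())
        complete = df.groupby("subject")["condition"].nunique()
        keep = complete[complete == df["condition"].nunique()].index
        dropped = sorted(set(df["subject"]) - set(keep))
        if dropped:
            logger.info("component %s: dropping subjects with missing cells: %s", comp, dropped)
            df = df[df["subject"].isin(keep)]
        res = _mixed_anova_ss(df)
        res.insert(0, "component", comp)
        res["cohens_d"] = [
            _cohens_d_group(df) if eff == "group" else np.nan for eff in res["effect"]
        ]
        res["formulation"] = "univariate mixed-model repeated-measures ANOVA"
        out.append(res)
    return pd.concat(out, ignore_index=True)


def mixed_anova_oracle_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format frame ready for an external mixed-ANOVA cross-check."""
    return (table.groupby(["subject", "group", "condition"], as_index=False)
                 ["amplitude"].mean())


def component_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (two-tailed p) between component measures, per group.

    A "measure" is a component x condition pair (e.g. closure Ncl vs.
    repeat P1), with one value per subject (hemispheres averaged);
    requires at least 3 subjects per group.
    """
    df = (table.groupby(["subject", "group", "condition", "component"], as_index=False)
               ["amplitude"].mean())
    df["measure"] = df["component"] + ":" + df["condition"]
    rows = []
    for grp, sub in df.groupby("group"):
        wide = sub.pivot(index="subject", columns="measure", values="amplitude")
        if len(wide) < 3:
            raise ValueError("at least 3 subjects required per group")
        measures = list(wide.columns)
        for i, m1 in enumerate(measures):
            for m2 in measures[i + 1:]:
                pair = wide[[m1, m2]].dropna()
                r, p = stats.pearsonr(pair[m1], pair[m2])
                rows.append({"group": grp, "measure_1": m1, "measure_2": m2,
                             "n": len(pair), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
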