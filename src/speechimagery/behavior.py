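"""Trial-level behavioral data: aggregation and repeated-measures statistics.

The experiment's design: each participant completes three blocks (conditions
AI, HI, BL) of 252 trials — 36 per continuum level, split 18/18 between
imagined tokens /ba/ and /da/ in the imagery blocks — responding /ba/ or
/da/ to each sound.  Analyses reduce trials to per-participant per-cell
proportions of /da/ responses (or median RTs) before the repeated-measures
ANOVA and the per-level paired post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "COLUMNS",
    "CONDITIONS",
    "TOKENS",
    "BehavioralDataset",
    "aggregate_curves",
    "rm_anova",
    "posthoc_level_tests",
]

COLUMNS = ["participant", "condition", "token", "level", "trial", "choice",
           "rt_ms"]
CONDITIONS = ("AI", "HI", "BL")
TOKENS = ("ba", "da", "none")
N_LEVELS = 7


@dataclass(frozen=True)
class BehavioralDataset:
    """Validated trial-level categorization records."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if df.empty:
            raise ValueError("empty dataset")
        bad = ~df["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValueError(
                f"invalid condition codes at rows {list(df.index[bad][:5])}")
        bad = ~df["token"].isin(TOKENS)
        if bad.any():
            raise ValueError(
                f"invalid token codes at rows {list(df.index[bad][:5])}")
        bad = (df["condition"] == "BL") & (df["token"] != "none")
        if bad.any():
            raise ValueError("BL trials must carry token 'none'")
        bad = (df["condition"] != "BL") & (df["token"] == "none")
        if bad.any():
            raise ValueError("imagery trials must carry an imagery token")
        bad = ~df["level"].isin(range(1, N_LEVELS + 1))
        if bad.any():
            raise ValueError(
                f"levels outside 1..7 at rows {list(df.index[bad][:5])}")
        bad = ~df["choice"].isin(("ba", "da"))
        if bad.any():
            raise ValueError(
                f"invalid choices at rows {list(df.index[bad][:5])}")
        if (df["rt_ms"] <= 0).any():
            raise ValueError("non-positive reaction times")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def participants(self) -> list:
        return sorted(self.frame["participant"].unique())

    def participant_proportions(self) -> pd.DataFrame:
        """Per-participant per-cell proportion of /da/ choices.

        Columns: participant, condition, token, level, p_da, n_trials.
        """
        df = self.frame.assign(is_da=(self.frame["choice"] == "da"))
        out = (df.groupby(["participant", "condition", "token", "level"],
                          sort=True)
                 .agg(p_da=("is_da", "mean"), n_trials=("is_da", "size"))
                 .reset_index())
        return out

    def participant_median_rt(self) -> pd.DataFrame:
        df = self.frame
        return (df.groupby(["participant", "condition", "token", "level"],
                           sort=True)
                  .agg(rt=("rt_ms", "median"), n_trials=("rt_ms", "size"))
                  .reset_index())


def aggregate_curves(data: BehavioralDataset) -> pd.DataFrame:
    """Across-participant psychometric curves with standard errors.

    Per-participant proportions are computed first; the across-participant
    mean and SEM are then taken per (condition, token, level).  Cells with
    no trials for some participant are reported via ``n_participants`` (the
    mean is over participants present in the cell, never silently over
    trials).
    """
    per = data.participant_proportions()
    agg = (per.groupby(["condition", "token", "level"], sort=True)
              .agg(p_da=("p_da", "mean"),
                   sem=("p_da", lambda s: float(s.sem(ddof=1))
                        if len(s) > 1 else 0.0),
                   n_participants=("p_da", "size"),
                   n_trials=("n_trials", "sum"))
              .reset_index())
    expected = len(data.participants)
    short = agg[agg["n_participants"] < expected]
    if not short.empty:
        cells = short[["condition", "token", "level"]].to_records(index=False)
        raise ValueError(f"cells missing participants: {list(cells)[:5]}")
    return agg


def _cell_means(data: BehavioralDataset, dv: str,
                conditions: tuple[str, ...],
                token: str | None) -> pd.DataFrame:
    per = (data.participant_proportions() if dv == "proportion"
           else data.participant_median_rt().rename(columns={"rt": "p_da"}))
    per = per[per["condition"].isin(conditions)]
    if token is not None:
        per = per[per["token"] == token]
    return per.rename(columns={"p_da": "dv"})


def rm_anova(data: BehavioralDataset, dv: str = "proportion",
             factors: list[str] | None = None,
             conditions: tuple[str, ...] = ("AI", "HI"),
             token: str | None = "ba") -> pd.DataFrame:
    """Repeated-measures ANOVA on participant cell means.

    ``dv`` is 'proportion' (of /da/ choices) or 'rt' (per-cell median, ms);
    ``factors`` is a subset of {'condition', 'level', 'token'} (default
    condition x level).  BL carries no imagery token, so token-bearing
    analyses must exclude it via ``conditions``.  Returns a table with one
    row per main effect / interaction: effect, F, df1, df2, p, np2.
    """
    factors = factors or ["condition", "level"]
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two within factors supported")
    if dv not in ("proportion", "rt"):
        raise ValueError("dv must be 'proportion' or 'rt'")
    cells = _cell_means(data, dv, conditions,
                        token if "token" not in factors else None)
    group_cols = ["participant"] + factors
    cells = (cells.groupby(group_cols, sort=True)["dv"].mean().reset_index())
    n_part = cells["participant"].nunique()
    if n_part < 2:
        raise ValueError("need at least 2 participants")
    counts = cells.groupby(factors, sort=True)["participant"].nunique()
    if (counts < n_part).any():
        raise ValueError("design has missing cells")
    if cells["dv"].nunique() == 1:
        # constant DV: all F are 0 by definition; pingouin divides 0/0
        rows = []
        levels = [cells[f].nunique() for f in factors]
        for i, f in enumerate(factors):
            df1 = levels[i] - 1
            rows.append((f, 0.0, df1, df1 * (n_part - 1), 1.0, 0.0))
        if len(factors) == 2:
            df1 = (levels[0] - 1) * (levels[1] - 1)
            rows.append((" * ".join(factors), 0.0, df1, df1 * (n_part - 1),
                         1.0, 0.0))
        return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p",
                                           "np2"])
    res = pg.rm_anova(data=cells, dv="dv",
                      within=factors if len(factors) > 1 else factors[0],
                      subject="participant", detailed=True, effsize="np2")
    res = res[res["Source"] != "Error"].copy()
    if "ddof1" in res.columns:
        df1, df2 = res["ddof1"], res["ddof2"]
    else:  # one-way detailed table reports DF against the error row
        df1 = res["DF"]
        df2 = df1 * (n_part - 1)
    p_col = "p_unc" if "p_unc" in res.columns else "p-unc"
    out = pd.DataFrame({
        "effect": res["Source"].values,
        "F": res["F"].values,
        "df1": np.asarray(df1, dtype=int),
        "df2": np.asarray(df2, dtype=int),
        "p": res[p_col].values,
        "np2": res["np2"].values if "np2" in res.columns else np.nan,
    })
    return out.dropna(subset=["F"]).reset_index(drop=True)


def posthoc_level_tests(data: BehavioralDataset,
                        conditions: tuple[str, str] = ("AI", "HI"),
                        token: str | None = "ba",
                        correction: int = N_LEVELS,
                        dv: str = "proportion") -> pd.DataFrame:
    """Paired t tests between two conditions at each continuum level.

    p-values are Bonferroni-multiplied by ``correction`` (default: the
    number of levels) and capped at 1.  Returns level, t, df, p_uncorrected,
    p_corrected, mean_diff.
    """
    a, b = conditions
    cells = _cell_means(data, dv, conditions, token)
    rows = []
    for level in sorted(cells["level"].unique()):
        sub = cells[cells["level"] == level].pivot_table(
            index="participant", columns="condition", values="dv")
        sub = sub.dropna()
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 complete pairs at level {level}")
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        if np.allclose(x, y):
            t_stat, p_unc = 0.0, 1.0
        else:
            t_stat, p_unc = stats.ttest_rel(x, y)
        rows.append((level, float(t_stat), len(sub) - 1, float(p_unc),
                     min(1.0, float(p_unc) * correction),
                     float(np.mean(x - y))))
    return pd.DataFrame(rows, columns=["level", "t", "df", "p_uncorrected",
                                       "p_corrected", "mean_diff"])
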