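"""Drug-screen statistics: per-day control normalization and rank tests.

A screen records, per animal, the three trace metrics (max dR/R0, delay
time, half-life) plus the responder flag, tagged with the compound and the
experiment day.  Because absolute response magnitudes drift between imaging
days, every treated value is normalized to the same-day control group mean
(median available) before pooling days.  Group comparisons use rank tests —
Mann-Whitney U for two groups, Kruskal-Wallis H for several — with the
conventional star tiers (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001,
strict inequalities).  Undefined half-lives (traces that never decayed to
half-maximum within the recording) are excluded from the tests, with counts
reported.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScreenRecord",
    "TestResult",
    "ScreenReport",
    "stars",
    "mann_whitney",
    "kruskal_wallis",
    "normalize_to_control",
    "screen_report",
]

METRICS = ("max_dRR", "delay_time", "half_life")
STAR_TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))
EXACT_MAX_N = 16  # exact Mann-Whitney enumeration limit (tie-free samples)


@dataclass(frozen=True)
class ScreenRecord:
    """One animal's trial in the screen."""

    animal_id: str
    compound: str  # "control" for the untreated group
    day: str
    max_dRR: float
    delay_time: float
    half_life: float | None
    responder: bool

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if d["half_life"] is None:
            d["half_life"] = np.nan
        return d


def records_frame(records) -> pd.DataFrame:
    """Normalize a record list / DataFrame to the screen's table layout."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.to_dict() for r in records])
    required = {"animal_id", "compound", "day", *METRICS, "responder"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen table is missing columns: {sorted(missing)}")
    return df


def stars(p: float) -> str:
    """Significance tier of a p-value (strict thresholds); 'ns' otherwise."""
    if not 0 <= p <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    for thresh, tier in STAR_TIERS:
        if p < thresh:
            return tier
    return "ns"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method: str
    stars: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "method": self.method,
            "stars": self.stars,
            "degenerate": self.degenerate,
        }


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (U statistic of the first sample).

    Small tie-free samples (n_x + n_y <= 16) use the exact permutation null
    of the rank sum; larger or tied samples use the normal approximation
    with midrank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size + y.size <= EXACT_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    p = float(res.pvalue)
    return TestResult(
        statistic=float(res.statistic),
        p_value=p,
        n_per_group=(int(x.size), int(y.size)),
        method="mann_whitney_exact" if exact else "mann_whitney_normal",
        stars=stars(p),
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across the given samples.

    H is the rank-variance statistic with midrank tie correction; the
    p-value comes from the chi-squared distribution with k-1 degrees of
    freedom.  When every observation is identical the test is flagged
    degenerate (H undefined) instead of raising.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    ns = tuple(int(g.size) for g in groups)
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return TestResult(
            statistic=np.nan,
            p_value=np.nan,
            n_per_group=ns,
            method="kruskal_wallis",
            stars="ns",
            degenerate=True,
        )
    h, p = sps.kruskal(*groups)
    return TestResult(
        statistic=float(h),
        p_value=float(p),
        n_per_group=ns,
        method="kruskal_wallis",
        stars=stars(float(p)),
    )


def _control_anchor(values: np.ndarray, stat: str) -> float:
    return float(np.median(values)) if stat == "median" else float(values.mean())


def normalize_to_control(
    records, metric: str, stat: str = "mean"
) -> pd.Series:
    """Divide each value of ``metric`` by the same-day control anchor.

    The anchor is the mean (default) or median of the control group's
    defined values on that day; at least 3 defined control values are
    required per day.  Control records normalize to mean (median) 1 by
    construction.  Undefined values stay NaN.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    df = records_frame(records)
    out = pd.Series(np.nan, index=df.index, name=f"{metric}_norm")
    for day, grp in df.groupby("day"):
        ctrl = grp.loc[grp["compound"] == "control", metric].dropna()
        if ctrl.size < 3:
            raise ValueError(
                f"day {day!r}: need a same-day control with >=3 defined "
                f"values of {metric!r} (got {ctrl.size})"
            )
        anchor = _control_anchor(ctrl.to_numpy(float), stat)
        if anchor == 0:
            raise ValueError(f"day {day!r}: control {metric!r} anchor is zero")
        out.loc[grp.index] = grp[metric] / anchor
    return out


@dataclass
class ScreenReport:
    """Per-compound summary of a screen.

    ``fractions`` — responder fraction and n per group;
    ``normalized`` — long table of per-day control-normalized metric values;
    ``compound_tests`` — control-vs-compound rank test per compound per
    metric (the per-compound star flags);
    ``global_tests`` — one Kruskal-Wallis across all groups per metric;
    ``half_life_excluded`` — count of undefined half-lives per group.
    """

    fractions: pd.DataFrame
    normalized: pd.DataFrame
    compound_tests: pd.DataFrame
    global_tests: dict[str, TestResult]
    half_life_excluded: pd.DataFrame

    def flagged(self, alpha: float = 0.05) -> dict[str, list[str]]:
        """Compounds whose control comparison is significant, per metric."""
        out: dict[str, list[str]] = {}
        for metric, grp in self.compound_tests.groupby("metric"):
            hits = grp.loc[grp["p_value"] < alpha, "compound"]
            out[str(metric)] = sorted(hits)
        return out

    def to_json(self, path) -> None:
        payload = {
            "fractions": self.fractions.to_dict(orient="records"),
            "compound_tests": self.compound_tests.to_dict(orient="records"),
            "global_tests": {m: t.to_dict() for m, t in self.global_tests.items()},
            "half_life_excluded": self.half_life_excluded.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def screen_report(records, stat: str = "mean") -> ScreenReport:
    """Assemble the full screen summary.

    Normalizes every metric per day to the control anchor, computes the
    responder fraction per group, tests each compound against control
    (two-group Kruskal-Wallis on the normalized values, matching how the
    per-compound stars are drawn) and all groups jointly per metric.
    Control-only input yields summaries without tests.
    """
    df = records_frame(records)
    if "control" not in set(df["compound"]):
        raise ValueError("screen needs a control group")
    compounds = sorted(c for c in df["compound"].unique() if c != "control")

    fractions = (
        df.groupby("compound")["responder"]
        .agg(responder_fraction="mean", n="size")
        .reset_index()
    )

    norm = df[["animal_id", "compound", "day"]].copy()
    for metric in METRICS:
        norm[metric] = normalize_to_control(df, metric, stat=stat)
    normalized = norm.melt(
        id_vars=["animal_id", "compound", "day"],
        value_vars=list(METRICS),
        var_name="metric",
        value_name="value",
    )

    half_life_excluded = (
        df.assign(undefined=df["half_life"].isna())
        .groupby("compound")["undefined"]
        .agg(n_undefined="sum", n="size")
        .reset_index()
    )

    rows = []
    global_tests: dict[str, TestResult] = {}
    for metric in METRICS:
        per_group = {
            comp: grp["value"].dropna().to_numpy(float)
            for comp, grp in normalized[normalized["metric"] == metric].groupby(
                "compound"
            )
        }
        ctrl = per_group.get("control", np.empty(0))
        if compounds:
            global_tests[metric] = kruskal_wallis(
                [ctrl] + [per_group[c] for c in compounds]
            )
        for comp in compounds:
            res = kruskal_wallis([ctrl, per_group[comp]])
            rows.append(
                {
                    "compound": comp,
                    "metric": metric,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "stars": res.stars,
                    "n_control": res.n_per_group[0],
                    "n_compound": res.n_per_group[1],
                    "degenerate": res.degenerate,
                }
            )
    compound_tests = pd.DataFrame(
        rows,
        columns=[
            "compound",
            "metric",
            "statistic",
            "p_value",
            "stars",
            "n_control",
            "n_compound",
            "degenerate",
        ],
    )
    return ScreenReport(
        fractions=fractions,
        normalized=normalized,
        compound_tests=compound_tests,
        global_tests=global_tests,
        half_life_excluded=half_life_excluded,
    )
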