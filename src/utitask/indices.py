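"""Participant-level indices: outlier exclusion, healthy-unhealthy
difference scores, explicit-scale scoring, internal consistency, diet
quality scoring, classification summaries.

The central construct is the unhealthy = tasty intuition (UTI): the lay
belief that healthiness and tastiness of food trade off.  It is
measured explicitly (mean of three 1-7 Likert items) and behaviourally
(difference scores dRT = RT(healthy) - RT(unhealthy) and dMAD =
MAD(healthy) - MAD(unhealthy); positive values mean costlier processing
of healthy items).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io import ffq_columns


@dataclass
class ExclusionReport:
    metric: str
    mean: float
    sd: float
    lower: float
    upper: float
    n_total: int
    n_excluded: int

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


def exclude_outliers(metrics: pd.DataFrame, k: float = 3.0,
                     rt_two_sided: bool = True,
                     mad_upper_only: bool = True,
                     ) -> tuple[pd.DataFrame, dict[str, ExclusionReport]]:
    """Flag trials whose RT or MAD is an outlier under the k-SD rule.

    The mean and SD are computed once over all non-degenerate trials in
    the whole sample (grand pooling, single pass — no iterative
    re-trimming).  RT is excluded on both tails ("slower and faster"
    than k SDs); MAD only when it exceeds mean + k*SD of the signed
    value.  Rows are flagged (``excluded_rt`` / ``excluded_mad``), not
    dropped, so reports can audit them.
    """
    out = metrics.copy()
    usable = ~out["degenerate"]
    if usable.sum() < 2:
        raise ValueError("need at least 2 non-degenerate trials for the "
                         "SD-based exclusion rule")
    reports: dict[str, ExclusionReport] = {}

    rt = out.loc[usable, "rt_ms"]
    mu, sd = float(rt.mean()), float(rt.std(ddof=1))
    lo = mu - k * sd if rt_two_sided else -np.inf
    hi = mu + k * sd
    out["excluded_rt"] = False
    out.loc[usable, "excluded_rt"] = (rt < lo) | (rt > hi)
    reports["rt_ms"] = ExclusionReport("rt_ms", mu, sd, lo, hi,
                                       int(usable.sum()),
                                       int(out["excluded_rt"].sum()))

    mad = out.loc[usable, "mad_px"]
    mu_m, sd_m = float(mad.mean()), float(mad.std(ddof=1))
    lo_m = -np.inf if mad_upper_only else mu_m - k * sd_m
    hi_m = mu_m + k * sd_m
    out["excluded_mad"] = False
    out.loc[usable, "excluded_mad"] = (mad < lo_m) | (mad > hi_m)
    reports["mad_px"] = ExclusionReport("mad_px", mu_m, sd_m, lo_m, hi_m,
                                        int(usable.sum()),
                                        int(out["excluded_mad"].sum()))
    return out, reports


def difference_scores(metrics: pd.DataFrame,
                      trials: pd.DataFrame) -> pd.DataFrame:
    """Healthy-minus-unhealthy participant means of RT and MAD over
    retained (non-degenerate, non-excluded) trials.

    A delta is NaN when either food-type cell has no retained trial;
    the participant row is kept.  Requires :func:`exclude_outliers` to
    have added the exclusion flags.
    """
    merged = metrics.merge(
        trials[["participant_id", "trial_id", "food_type"]],
        on=["participant_id", "trial_id"], how="left", validate="1:1")
    rows = []
    for pid, grp in merged.groupby("participant_id", sort=False):
        ok = ~grp["degenerate"]
        rt_ok = ok & ~grp["excluded_rt"]
        mad_ok = ok & ~grp["excluded_mad"]

        def cell_mean(mask, col, ft):
            sub = grp.loc[mask & (grp["food_type"] == ft), col]
            return (float(sub.mean()), len(sub)) if len(sub) else (np.nan, 0)

        rt_h, n_rt_h = cell_mean(rt_ok, "rt_ms", "healthy")
        rt_u, n_rt_u = cell_mean(rt_ok, "rt_ms", "unhealthy")
        mad_h, n_mad_h = cell_mean(mad_ok, "mad_px", "healthy")
        mad_u, n_mad_u = cell_mean(mad_ok, "mad_px", "unhealthy")
        rows.append((pid, rt_h - rt_u, mad_h - mad_u,
                     n_rt_h, n_rt_u, n_mad_h, n_mad_u))
    return pd.DataFrame(rows, columns=[
        "participant_id", "delta_rt_ms", "delta_mad_px",
        "n_rt_healthy", "n_rt_unhealthy", "n_mad_healthy",
        "n_mad_unhealthy"])


def score_uti_scale(items) -> float:
    """Mean of the three explicit-scale items (each 1-7)."""
    arr = np.asarray(items, dtype=float)
    if np.any((arr < 1) | (arr > 7)):
        raise ValueError("explicit-scale items must lie within [1, 7]")
    return float(arr.mean())


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances) / variance
    of row sums).  NaN when the total-score variance is zero."""
    x = np.asarray(item_matrix, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("alpha needs at least 2 rows and 2 items")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


# ---------------------------------------------------------------------
# Diet quality score (DQS)
# ---------------------------------------------------------------------
#
# The food-frequency questionnaire asks how often K (default 20) food
# categories are consumed on a 1 ("rarely or never") to 8 ("5+ times a
# day") scale.  Responses are summarised into five components, each
# scored 1-3 from configured frequency thresholds, and the DQS is their
# sum: 5 (poorest) to 15 (healthiest).  The component->item map and
# thresholds ship as a documented default config and are fully
# overridable, since threshold tables differ between questionnaire
# variants.

@dataclass
class DQSComponent:
    name: str
    items: list[int]          # 1-based FFQ item numbers
    direction: str            # "healthy": more frequent is better
    lo: float                 # component mean thresholds
    hi: float

    def score(self, item_values: np.ndarray) -> int:
        m = float(np.mean(item_values))
        if self.direction == "healthy":
            return 3 if m >= self.hi else (2 if m >= self.lo else 1)
        return 3 if m <= self.lo else (2 if m <= self.hi else 1)


@dataclass
class DQSConfig:
    components: list[DQSComponent] = field(default_factory=list)
    n_items: int = 20

    def to_yaml(self, path) -> None:
        data = {"n_items": self.n_items, "components": [
            {"name": c.name, "items": c.items, "direction": c.direction,
             "lo": c.lo, "hi": c.hi} for c in self.components]}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DQSConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(n_items=data["n_items"], components=[
            DQSComponent(**c) for c in data["components"]])


def default_dqs_config() -> DQSConfig:
    """Five components of four FFQ items each.  Healthy components score
    higher with more frequent consumption; the two unhealthy components
    are reverse-scored."""
    return DQSConfig(components=[
        DQSComponent("vegetables", [1, 2, 3, 4], "healthy", lo=3, hi=5),
        DQSComponent("fruit", [5, 6, 7, 8], "healthy", lo=3, hi=5),
        DQSComponent("fish_wholegrain", [9, 10, 11, 12], "healthy",
                     lo=3, hi=5),
        DQSComponent("processed_fast_food", [13, 14, 15, 16], "unhealthy",
                     lo=2, hi=4),
        DQSComponent("sugary_snacks_drinks", [17, 18, 19, 20], "unhealthy",
                     lo=2, hi=4),
    ], n_items=20)


def score_dqs(ffq, config: DQSConfig | None = None) -> int:
    """Diet quality score in [5, 15] from K frequency responses."""
    config = config or default_dqs_config()
    arr = np.asarray(ffq, dtype=float)
    if len(arr) != config.n_items:
        raise ConfigError(
            f"expected {config.n_items} FFQ responses, got {len(arr)}")
    if np.any((arr < 1) | (arr > 8)):
        raise ValueError("FFQ responses must lie within [1, 8]")
    covered = sorted(i for c in config.components for i in c.items)
    if covered != list(range(1, config.n_items + 1)):
        raise ConfigError("DQS config must cover each FFQ item exactly once")
    return int(sum(c.score(arr[np.array(c.items) - 1])
                   for c in config.components))


def classification_proportions(trials: pd.DataFrame,
                               grouping: pd.Series | None = None
                               ) -> pd.DataFrame:
    """Empirical P(classified tasty) by food type, optionally crossed
    with a participant-level grouping (e.g., a median-split label)."""
    df = trials.copy()
    df["tasty"] = (df["classification"] == "tasty").astype(float)
    keys = ["food_type"]
    if grouping is not None:
        df["group"] = df["participant_id"].map(grouping)
        keys = ["group", "food_type"]
    out = df.groupby(keys, dropna=False)["tasty"].agg(
        p_tasty="mean", n_trials="size").reset_index()
    return out


def median_split(scores: pd.Series) -> pd.Series:
    """Descriptive low/high labels: strictly above the median is high,
    at or below is low (documented tie rule)."""
    values = scores.dropna()
    if values.nunique() < 2:
        raise ValueError("median split needs at least 2 distinct values")
    med = values.median()
    return scores.map(lambda v: "high" if v > med else "low")


def build_participant_indices(participants: pd.DataFrame,
                              trials: pd.DataFrame,
                              metrics_flagged: pd.DataFrame,
                              dqs_config: DQSConfig | None = None
                              ) -> pd.DataFrame:
    """Assemble the participant-level index table: explicit UTI score,
    dRT, dMAD, DQS, condition, descriptive median-split group."""
    deltas = difference_scores(metrics_flagged, trials)
    out = participants[["participant_id", "age", "gender", "education",
                        "condition"]].copy()
    out["uti_explicit"] = participants[
        ["uti_item_1", "uti_item_2", "uti_item_3"]].mean(axis=1)
    ffq_cols = ffq_columns(participants)
    if ffq_cols:
        out["dqs"] = [
            score_dqs(row, dqs_config)
            for row in participants[ffq_cols].to_numpy()]
    else:
        out["dqs"] = np.nan
    out = out.merge(deltas, on="participant_id", how="left")
    out["median_split_group"] = median_split(out["uti_explicit"])
    return out
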