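"""Observed incidence rate ratios from ED-visit counts and model comparison.

The observed IRR for a region contrasts mean daily emergency-department
visits during the smoke-wave days against mean daily visits over baseline
(non-wildfire) days before and after the episode:

    IRR = (Σ smoke counts / n_smoke_days) / (Σ baseline counts / n_baseline_days)

with a 95% CI from the standard Poisson rate-ratio approximation on the log
scale, exp(log IRR ± 1.96 · sqrt(1/Σsmoke + 1/Σbaseline)).  The comparison
step lines these up against modeled IRRs per region and flags whether the
two confidence intervals intersect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .health import Z95

__all__ = ["VisitSeries", "observed_irr", "compare", "load_region_map"]


@dataclass
class VisitSeries:
    """Daily ED-visit counts for one region."""

    region_id: str
    counts: pd.Series  # integer counts indexed by calendar date

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index = pd.DatetimeIndex(pd.to_datetime(self.counts.index))
        if not self.counts.index.is_monotonic_increasing or self.counts.index.has_duplicates:
            raise ValueError("visit dates must be strictly increasing")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("visit counts must be non-negative integers")
        self.counts = self.counts.astype(int)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> dict[str, "VisitSeries"]:
        """Split a long (region_id, date, count) frame into per-region series."""
        out = {}
        for region_id, g in df.groupby("region_id", sort=False):
            s = g.sort_values("date").set_index("date")["count"]
            out[str(region_id)] = cls(str(region_id), s)
        return out


def observed_irr(
    series: VisitSeries, smoke_days, baseline_days
) -> tuple[float, float, float]:
    """Rate ratio of smoke-wave to baseline daily visit rates with 95% CI."""
    smoke = pd.DatetimeIndex(pd.to_datetime(list(smoke_days)))
    base = pd.DatetimeIndex(pd.to_datetime(list(baseline_days)))
    if len(smoke) == 0 or len(base) == 0:
        raise ValueError("both day windows must be non-empty")
    if len(smoke.intersection(base)):
        raise ValueError("smoke and baseline day windows must be disjoint")
    for name, idx in (("smoke", smoke), ("baseline", base)):
        missing = idx.difference(series.counts.index)
        if len(missing):
            raise ValueError(
                f"{name} days missing from region {series.region_id} series: "
                f"{list(missing.strftime('%Y-%m-%d'))}"
            )
    s_total = int(series.counts.loc[smoke].sum())
    b_total = int(series.counts.loc[base].sum())
    if b_total <= 0:
        raise ValueError("baseline window has zero total visits; IRR undefined")
    ratio = (s_total / len(smoke)) / (b_total / len(base))
    if s_total == 0:
        return 0.0, 0.0, np.nan
    se_log = np.sqrt(1.0 / s_total + 1.0 / b_total)
    lo = float(ratio * np.exp(-Z95 * se_log))
    hi = float(ratio * np.exp(Z95 * se_log))
    return float(ratio), lo, hi


def compare(observed: pd.DataFrame, modeled: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Line up observed and modeled per-region IRRs and flag CI overlap.

    Both inputs carry columns region_id, irr, ci_low, ci_high.  Regions
    present in only one input are excluded (with a warning via pandas merge
    indicator semantics).  Returns the comparison table and the fraction of
    matched regions whose CIs intersect.
    """
    required = {"region_id", "irr", "ci_low", "ci_high"}
    for name, df in (("observed", observed), ("modeled", modeled)):
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    merged = observed.merge(
        modeled, on="region_id", how="outer", suffixes=("_obs", "_mod"), indicator=True
    )
    unmatched = merged[merged["_merge"] != "both"]["region_id"].tolist()
    if unmatched:
        import logging

        logging.getLogger(__name__).warning(
            "regions present in only one input, excluded: %s", unmatched
        )
    both = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    both = both.rename(
        columns={
            "irr_obs": "observed_irr",
            "ci_low_obs": "observed_ci_low",
            "ci_high_obs": "observed_ci_high",
            "irr_mod": "modeled_irr",
            "ci_low_mod": "modeled_ci_low",
            "ci_high_mod": "modeled_ci_high",
        }
    )
    both["overlap"] = (both["observed_ci_low"] <= both["modeled_ci_high"]) & (
        both["modeled_ci_low"] <= both["observed_ci_high"]
    )
    fraction = float(both["overlap"].mean()) if len(both) else np.nan
    cols = [
        "region_id",
        "observed_irr",
        "observed_ci_low",
        "observed_ci_high",
        "modeled_irr",
        "modeled_ci_low",
        "modeled_ci_high",
        "overlap",
    ]
    return both[cols].reset_index(drop=True), fraction


def default_baseline_days(
    episode_start, episode_end, n_before: int = 7, n_after: int = 7, buffer_days: int = 3
) -> pd.DatetimeIndex:
    """Baseline windows buffered around the smoke episode.

    ``buffer_days`` on each side of the episode are excluded entirely; the
    baseline is the ``n_before`` days preceding the leading buffer plus the
    ``n_after`` days following the trailing buffer.  All three lengths are
    explicit parameters, not fixed constants.
    """
    start = pd.to_datetime(episode_start)
    end = pd.to_datetime(episode_end)
    before_end = start - pd.Timedelta(days=buffer_days + 1)
    before = pd.date_range(end=before_end, periods=n_before, freq="D")
    after_start = end + pd.Timedelta(days=buffer_days + 1)
    after = pd.date_range(start=after_start, periods=n_after, freq="D")
    return before.append(after)


def load_region_map(path=None) -> pd.Series:
    """County-to-region aggregation labels.

    Without a path, loads the bundled New York validation groupings (the
    five NYC boroughs plus the Upper Hudson, Eastern Lake Ontario, and
    Central county lists).  Returns a Series mapping county name to region
    label, suitable for the ``by`` argument of burden aggregation.
    """
    import yaml
    from importlib import resources

    if path is None:
        source = resources.files("smokewave").joinpath("data/ny_regions.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    pairs = {}
    for region, counties in raw.items():
        for county in counties:
            if county in pairs:
                raise ValueError(f"county {county!r} appears in two regions")
            pairs[county] = region
    return pd.Series(pairs, name="region_id")
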