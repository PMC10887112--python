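"""Per-chamber oxygen time series: consumption metrics and group comparisons.

Chamber oxygen after oil sealing falls rapidly while the spheroid respires
and then settles at a plateau set by the balance of residual supply and
demand.  The metrics summarize that shape without assuming a mechanistic
uptake model:

* ``initial_rate`` — negative slope of a least-squares line over the first
  few timepoints (default 5 points, i.e. 0-20 min at 5 min intervals);
* ``plateau_o2`` — mean of the last timepoints (default 7, i.e. 30-60 min);
* ``time_to_plateau`` — first timepoint within a tolerance band of the
  plateau (flagged censored when never reached inside the window);
* ``total_drop`` — O2 at t=0 minus the plateau.

An optional molar rate converts %/min into mol O2 per minute using the
chamber volume and the oxygen solubility of the buffer.

Group comparisons follow the per-timepoint convention of the assay: a
two-sided two-sample Student's t-test at each timepoint with mean +/- SD per
group, flagged significant at p < 0.05, with no multiple-testing correction
by default (a Bonferroni option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OxygenSeries",
    "ConsumptionMetrics",
    "assemble_series",
    "compute_metrics",
    "molar_rate",
    "compare_groups",
]

#: Oxygen solubility of air-equilibrated aqueous buffer at 37 C, uM.
DEFAULT_SOLUBILITY_UM = 200.0


@dataclass
class OxygenSeries:
    """One chamber's oxygen trajectory."""

    chamber_id: int
    timepoints: np.ndarray  # min
    o2: np.ndarray  # % O2
    group: str = "untreated"
    incomplete: bool = False

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.timepoints.shape != self.o2.shape:
            raise ValueError("timepoints and o2 must have equal length")
        if self.timepoints.size > 1 and np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class ConsumptionMetrics:
    chamber_id: int
    initial_rate: float  # % O2 / min (positive = consuming)
    plateau_o2: float  # % O2
    time_to_plateau: float  # min (NaN when censored)
    total_drop: float  # % O2
    censored: bool
    group: str = "untreated"


def assemble_series(
    table: pd.DataFrame,
    chamber_map,
    groups: dict[int, str] | None = None,
) -> list[OxygenSeries]:
    """Build one series per spheroid-occupied chamber from a per-chamber table.

    ``table`` is the oximetry output (columns ``chamber_id, timepoint_min,
    mean_o2_pct``).  Empty chambers are references, not samples, and are
    excluded.  Chambers missing timepoints (relative to the union of
    timepoints in the table) are flagged incomplete but retained.
    """
    groups = groups or {}
    known_ids = {ch.chamber_id for ch in chamber_map.chambers}
    for cid in table["chamber_id"].unique():
        if int(cid) not in known_ids:
            raise KeyError(f"chamber_id {cid} in table but not in chamber map")
    all_timepoints = np.sort(table["timepoint_min"].unique())
    series = []
    for ch in chamber_map.chambers:
        if ch.occupancy != "spheroid":
            continue
        sub = table[table["chamber_id"] == ch.chamber_id].sort_values("timepoint_min")
        series.append(
            OxygenSeries(
                chamber_id=ch.chamber_id,
                timepoints=sub["timepoint_min"].to_numpy(),
                o2=sub["mean_o2_pct"].to_numpy(),
                group=groups.get(ch.chamber_id, "untreated"),
                incomplete=len(sub) < len(all_timepoints),
            )
        )
    return series


def compute_metrics(
    series: OxygenSeries,
    rate_window: int = 5,
    plateau_window: int = 7,
    plateau_tolerance: float = 0.5,
) -> ConsumptionMetrics:
    """Summarize one oxygen trajectory.

    ``rate_window`` / ``plateau_window`` count points from the start / end of
    the series; at the default 5 min interval they span 0-20 min and
    30-60 min respectively.
    """
    n = series.o2.size
    if n < rate_window + plateau_window:
        raise ValueError(
            f"series of {n} points too short for rate_window={rate_window} "
            f"+ plateau_window={plateau_window}"
        )
    t, y = series.timepoints, series.o2
    slope = np.polyfit(t[:rate_window], y[:rate_window], 1)[0]
    plateau = float(y[-plateau_window:].mean())
    within = np.abs(y - plateau) <= plateau_tolerance
    censored = not within.any()
    time_to_plateau = float(t[np.argmax(within)]) if not censored else float("nan")
    return ConsumptionMetrics(
        chamber_id=series.chamber_id,
        initial_rate=float(-slope),
        plateau_o2=plateau,
        time_to_plateau=time_to_plateau,
        total_drop=float(y[0] - plateau),
        censored=censored,
        group=series.group,
    )


def molar_rate(
    metrics: ConsumptionMetrics,
    volume_nl: float,
    solubility_um: float = DEFAULT_SOLUBILITY_UM,
) -> float:
    """Convert the initial rate to mol O2 per minute for one chamber.

    ``rate(%/min) / 20.9 * solubility(uM) * volume(L)``: the solubility is
    the dissolved O2 concentration at air saturation (20.9%), so the
    fractional rate of tension change times solubility gives concentration
    change per minute, and the chamber volume converts it to moles.
    """
    if solubility_um <= 0:
        raise ValueError("solubility must be positive")
    volume_l = volume_nl * 1e-9
    return metrics.initial_rate / 20.9 * solubility_um * 1e-6 * volume_l


def metrics_table(metrics: list[ConsumptionMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chamber_id": m.chamber_id,
                "group": m.group,
                "initial_rate_pct_per_min": m.initial_rate,
                "plateau_o2_pct": m.plateau_o2,
                "time_to_plateau_min": m.time_to_plateau,
                "total_drop_pct": m.total_drop,
                "censored": m.censored,
            }
            for m in metrics
        ]
    )


def compare_groups(
    series_a: list[OxygenSeries],
    series_b: list[OxygenSeries],
    *,
    welch: bool = False,
    bonferroni: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint two-sample t-test between two groups of trajectories.

    Equal-variance Student's t-test by default (``welch=True`` for the
    unequal-variance form).  Returns one row per common timepoint with group
    means, SDs, sizes, the t statistic, p value and a significance flag at
    ``alpha`` (Bonferroni-adjusted across timepoints when requested).
    """
    if len(series_a) < 2 or len(series_b) < 2:
        raise ValueError("each group needs at least 2 series")
    common = sorted(
        set.intersection(
            *(set(s.timepoints.tolist()) for s in series_a + series_b)
        )
    )
    n_tests = len(common)
    rows = []
    for t in common:
        a = np.array([s.o2[np.where(s.timepoints == t)[0][0]] for s in series_a])
        b = np.array([s.o2[np.where(s.timepoints == t)[0][0]] for s in series_b])
        res = stats.ttest_ind(a, b, equal_var=not welch)
        p = res.pvalue * n_tests if bonferroni else res.pvalue
        p = min(float(p), 1.0)
        rows.append(
            {
                "timepoint_min": t,
                "mean_a": float(a.mean()),
                "sd_a": float(a.std(ddof=1)),
                "n_a": a.size,
                "mean_b": float(b.mean()),
                "sd_b": float(b.std(ddof=1)),
                "n_b": b.size,
                "t_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def plot_trajectories(
    groups: dict[str, list[OxygenSeries]], out_path=None, ax=None
):
    """Trajectory plot with per-group mean +/- SD bands (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, series in groups.items():
        t = series[0].timepoints
        values = np.vstack([s.o2 for s in series])
        mean, sd = values.mean(axis=0), values.std(axis=0, ddof=1)
        for s in series:
            ax.plot(s.timepoints, s.o2, alpha=0.25, lw=0.8)
        ax.errorbar(t, mean, yerr=sd, label=name, capsize=3, lw=2)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("oxygen tension (% O2)")
    ax.legend()
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
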