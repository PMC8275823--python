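"""Cohort aggregation: percentages ± SEM across experiments, recapture
contingency tables, and report output.

Percentages follow the "n EVs, N experiments" convention: the percentage
is computed per independent experiment first, and the mean and SEM
(SD/sqrt(N)) are taken across experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import MotionMetrics

__all__ = [
    "CohortRecord",
    "PercentResult",
    "percentage_with_sem",
    "recapture_table",
    "recapture_table_from_counts",
    "load_table1_counts",
    "report",
]


@dataclass
class CohortRecord:
    """One EV's entry in a cohort table."""

    ev_id: str
    experiment_id: str
    compartment: str = "neurite"
    adhered: bool = True
    mobility: Optional[str] = None
    direction: Optional[str] = None
    recaptured: Optional[bool] = None
    metrics: Optional[MotionMetrics] = None

    def __post_init__(self) -> None:
        if self.compartment not in ("neurite", "soma"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not self.adhered and self.mobility is not None:
            raise ValueError("mobility is defined only for adherent EVs")

    @property
    def moving(self) -> Optional[bool]:
        if self.mobility is None:
            return None
        return self.mobility == "mobile"


@dataclass
class PercentResult:
    """Percentage aggregated across experiments (mean ± SEM, n, N)."""

    mean_pct: float
    sem_pct: float
    n_records: int
    n_experiments: int
    single_experiment: bool = False


def percentage_with_sem(records: Sequence[CohortRecord],
                        predicate: Callable[[CohortRecord], Optional[bool]],
                        ) -> PercentResult:
    """Percentage of records satisfying ``predicate``, SEM across experiments.

    Records for which the predicate returns None are excluded. With a
    single experiment the SEM is reported as 0 and flagged.
    """
    per_exp: dict[str, list[bool]] = {}
    n = 0
    for rec in records:
        val = predicate(rec)
        if val is None:
            continue
        per_exp.setdefault(rec.experiment_id, []).append(bool(val))
        n += 1
    if not per_exp:
        raise ValueError("no eligible records in any experiment")
    pcts = np.array([100.0 * np.mean(v) for v in per_exp.values()])
    N = pcts.size
    if N == 1:
        return PercentResult(float(pcts[0]), 0.0, n, 1,
                             single_experiment=True)
    sem = float(np.std(pcts, ddof=1) / math.sqrt(N))
    return PercentResult(float(pcts.mean()), sem, n, N)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def recapture_table_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Contingency table from (compartment, motion, recaptured, total) counts.

    Adds a pooled "total" compartment row pair and integer percentages
    (rounded half-up). ``motion`` entries are "moving" / "not_moving".
    """
    required = {"compartment", "motion", "recaptured", "total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    df = counts.copy()
    pooled = df.groupby("motion", as_index=False)[["recaptured",
                                                   "total"]].sum()
    pooled.insert(0, "compartment", "total")
    df = pd.concat([df, pooled], ignore_index=True)
    if (df["recaptured"] > df["total"]).any():
        raise ValueError("recaptured count exceeds total")
    df["pct"] = [
        _round_half_up(100.0 * r / t) if t > 0 else 0
        for r, t in zip(df["recaptured"], df["total"])
    ]
    return df


def recapture_table(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Recapture contingency from per-EV records.

    Counts recaptured vs total split by moving/not-moving and
    compartment; records without a recapture flag or a mobility call are
    excluded.
    """
    rows = []
    for rec in records:
        if rec.recaptured is None or rec.moving is None:
            continue
        rows.append({
            "compartment": rec.compartment,
            "motion": "moving" if rec.moving else "not_moving",
            "recaptured": int(bool(rec.recaptured)),
            "total": 1,
        })
    if not rows:
        raise ValueError("no records carry a recapture flag")
    counts = (pd.DataFrame(rows)
              .groupby(["compartment", "motion"], as_index=False)
              .sum())
    return recapture_table_from_counts(counts)


def load_table1_counts() -> pd.DataFrame:
    """Published recapture counts shipped with the package."""
    with resources.files("evsurf.data").joinpath(
            "table1_counts.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def _summary_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Per-compartment metric means/SEMs across experiments."""
    metric_fields = ["path_length_um", "max_dist_contact_um",
                     "mean_speed_um_s", "fraction_time_moving",
                     "radial_displacement_um"]
    rows = []
    df_rows = []
    for rec in records:
        if rec.metrics is None:
            continue
        row = {"compartment": rec.compartment,
               "experiment_id": rec.experiment_id}
        for f in metric_fields:
            row[f] = getattr(rec.metrics, f)
        df_rows.append(row)
    if not df_rows:
        return pd.DataFrame()
    df = pd.DataFrame(df_rows)
    for comp, grp in df.groupby("compartment"):
        per_exp = grp.groupby("experiment_id")[metric_fields].mean()
        N = per_exp.shape[0]
        for f in metric_fields:
            vals = per_exp[f].to_numpy()
            sem = float(np.std(vals, ddof=1) / math.sqrt(N)) if N > 1 else 0.0
            rows.append({"compartment": comp, "metric": f,
                         "mean": float(vals.mean()), "sem": sem,
                         "n_evs": int(grp.shape[0]), "n_experiments": N})
    return pd.DataFrame(rows)


def report(records: Sequence[CohortRecord], out_dir: str | Path,
           make_plots: bool = True) -> dict:
    """Write cohort summary tables (CSV/JSON) and distribution figures.

    Emits per-compartment metric summaries, mobility/direction
    percentages, the recapture contingency when flags are present, a
    histogram of maximal distances split static/mobile, and a scatter of
    maximal anterograde vs retrograde excursions. Direction panels are
    omitted (with a note) when no mobile EV carries an axis projection.
    Output is deterministic for a fixed cohort.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ids = [r.ev_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ev_ids in cohort: {dupes}")

    summary: dict = {"n_records": len(records), "notes": []}

    with_labels = [r for r in records if r.mobility is not None]
    if with_labels:
        res = percentage_with_sem(with_labels, lambda r: r.moving)
        summary["moving_pct"] = {"mean": res.mean_pct, "sem": res.sem_pct,
                                 "n": res.n_records, "N": res.n_experiments}
        mobiles = [r for r in with_labels if r.moving]
        if mobiles and all(r.direction is not None for r in mobiles):
            counts = pd.Series([r.direction for r in mobiles]).value_counts()
            summary["direction_pct"] = {
                k: 100.0 * counts.get(k, 0) / len(mobiles)
                for k in ("anterograde", "retrograde", "bidirectional")}
        else:
            summary["notes"].append("direction panel omitted: no labelled "
                                    "mobile EVs")

    metric_df = _summary_frame(records)
    if not metric_df.empty:
        metric_df.to_csv(out_dir / "metric_summary.csv", index=False)

    try:
        cont = recapture_table(records)
        cont.to_csv(out_dir / "recapture_table.csv", index=False)
        summary["recapture_pct"] = {
            f"{c}_{m}": int(p) for c, m, p in
            zip(cont["compartment"], cont["motion"], cont["pct"])}
    except ValueError:
        summary["notes"].append("recapture table omitted: no recapture flags")

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")

    if make_plots:
        _write_figures(records, out_dir, summary)
    return summary


def _write_figures(records, out_dir: Path, summary: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    have = [r for r in records
            if r.metrics is not None and r.mobility is not None]
    if have:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        static = [r.metrics.max_dist_contact_um for r in have if not r.moving]
        mobile = [r.metrics.max_dist_contact_um for r in have if r.moving]
        bins = np.linspace(0, max(static + mobile + [1.0]), 25)
        ax.hist(static, bins=bins, color="tab:blue", alpha=0.7,
                label="static")
        ax.hist(mobile, bins=bins, color="tab:red", alpha=0.7,
                label="mobile")
        ax.set_xlabel("max distance from contact point (um)")
        ax.set_ylabel("EV count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "max_distance_hist.png", dpi=120)
        plt.close(fig)

    signed = [r for r in records if r.metrics is not None
              and np.isfinite(r.metrics.run_length_pos_um)
              and r.moving]
    if signed:
        fig, ax = plt.subplots(figsize=(4.2, 4.2))
        pos = [r.metrics.max_dist_pos_um for r in signed]
        neg = [r.metrics.max_dist_neg_um for r in signed]
        ax.scatter(pos, neg, s=12, c="tab:red", alpha=0.7)
        lim = max(pos + neg + [1.0]) * 1.05
        ax.plot([0, lim], [0, lim / 2], "k--", lw=0.8)
        ax.plot([0, lim / 2], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("max anterograde distance (um)")
        ax.set_ylabel("max retrograde distance (um)")
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
        fig.tight_layout()
        fig.savefig(out_dir / "signed_max_distance.png", dpi=120)
        plt.close(fig)
    else:
        summary["notes"].append("signed-excursion panel omitted: no mobile "
                                "EVs with axis projection")
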