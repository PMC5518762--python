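"""Scenario-change statistics: log ratios and mixed-model intercept tests.

The question is directional: does overlap (or range size) grow or shrink
under warming? Each garden plant contributes one response per future
scenario — the natural log of future/current for its mean overlap (or its
range size) — and a linear mixed model with a genus random intercept tests
whether the mean log ratio differs from zero, accounting for genera
represented by several species.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grids import DomainError

logger = logging.getLogger(__name__)

CHANGE_METRICS = ("mean_overlap_cells", "mean_tss_overlap", "range_size")


def log_ratio(current: float, future: float) -> float:
    """Natural log of future/current; positive means an increase."""
    if not (current > 0 and future > 0):
        raise DomainError(
            f"log ratio undefined for current={current}, future={future}"
        )
    return math.log(future / current)


def make_change_records(
    current: pd.DataFrame,
    future: pd.DataFrame,
    metric: str,
    id_col: str = "garden_id",
) -> tuple[pd.DataFrame, int]:
    """Per-species log ratios of ``metric`` between two scenario tables.

    Both tables need ``id_col``, ``genus`` and ``metric`` columns; the
    future table's scenario label is carried over. Species with a
    non-positive metric in either scenario are excluded and counted (zeros
    cannot enter a log ratio), so ``n_input = n_used + n_excluded``.
    """
    merged = current[[id_col, "genus", metric]].merge(
        future[[id_col, "genus", metric, "scenario_id"]],
        on=[id_col, "genus"],
        suffixes=("_current", "_future"),
    )
    ok = (merged[f"{metric}_current"] > 0) & (merged[f"{metric}_future"] > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info(
            "%s: excluded %d species with non-positive %s from log ratios",
            merged["scenario_id"].iloc[0] if len(merged) else "?",
            n_excluded,
            metric,
        )
    kept = merged[ok]
    out = pd.DataFrame(
        {
            id_col: kept[id_col],
            "genus": kept["genus"],
            "scenario_id": kept["scenario_id"],
            "metric": metric,
            "log_ratio": np.log(
                kept[f"{metric}_future"].to_numpy()
                / kept[f"{metric}_current"].to_numpy()
            ),
        }
    ).reset_index(drop=True)
    return out, n_excluded


@dataclass
class LMMResult:
    """Intercept-only mixed-model fit of log ratios with genus random effect."""

    intercept: float
    se: float
    p_value: float
    genus_var: float
    resid_var: float
    n_obs: int
    n_genera: int
    boundary: bool = False  # genus variance estimated at (or fell back to) zero
    method: str = "reml"


def lmm_intercept_test(records: pd.DataFrame, response: str = "log_ratio") -> LMMResult:
    """REML fit of ``y_ij = mu + u_i + e_ij`` with genus random intercepts,
    and a Wald test of mu = 0.

    When the REML fit is singular or fails (genus variance on the zero
    boundary), the estimate degrades gracefully to the ordinary one-sample
    t-test, flagged via ``boundary``/``method``.
    """
    y = records[response].to_numpy(dtype=float)
    genera = records["genus"].to_numpy()
    n_genera = len(np.unique(genera))
    if len(y) < 3 or n_genera < 2:
        raise DomainError("need >= 3 observations across >= 2 genera")
    if not np.isfinite(y).all():
        raise DomainError("non-finite responses; exclude them upstream")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.regression.mixed_linear_model.MixedLM(
                y, np.ones((len(y), 1)), groups=genera
            )
            res = model.fit(reml=True)
        genus_var = float(np.asarray(res.cov_re)[0, 0])
        se = float(res.bse[0])
        if not np.isfinite(se) or se <= 0:
            raise ValueError("degenerate standard error")
        return LMMResult(
            intercept=float(res.params[0]),
            se=se,
            p_value=float(res.pvalues[0]),
            genus_var=genus_var,
            resid_var=float(res.scale),
            n_obs=len(y),
            n_genera=n_genera,
            boundary=genus_var <= 1e-10,
            method="reml",
        )
    except Exception as exc:  # noqa: BLE001 - boundary/singular fits
        logger.info("mixed model fell back to t-test: %s", exc)
        t = stats.ttest_1samp(y, 0.0)
        return LMMResult(
            intercept=float(np.mean(y)),
            se=float(stats.sem(y)) if len(y) > 1 else float("nan"),
            p_value=float(t.pvalue),
            genus_var=0.0,
            resid_var=float(np.var(y, ddof=1)),
            n_obs=len(y),
            n_genera=n_genera,
            boundary=True,
            method="ttest_fallback",
        )


def scenario_summary(
    garden_summaries: pd.DataFrame,
    range_sizes: pd.DataFrame,
    taxa: pd.DataFrame,
    base_scenario: str = "BASE",
) -> dict[str, pd.DataFrame]:
    """Headline tables of the study.

    Parameters
    ----------
    garden_summaries : per-garden-plant overlap means, all scenarios.
    range_sizes : columns species_id, scenario_id, range_cells.
    taxa : the taxon table (for group membership and genus).

    Returns
    -------
    dict with:
      ``overlap_by_scenario`` — mean +- sd of the per-garden overlap
        metrics per scenario;
      ``range_by_group`` — mean +- sd of range size per species group and
        scenario;
      ``pair_log_ratios`` — per-garden log ratios of mean overlap cells,
        per future scenario (the change-figure analogue);
      ``lmm_tests`` — mixed-model intercept tests per future scenario and
        metric (overlap cells, TSS overlap, and per-group range size).
    """
    scenarios = list(pd.unique(garden_summaries["scenario_id"]))
    if base_scenario not in scenarios:
        raise DomainError(f"no rows for base scenario {base_scenario!r}")
    futures = [s for s in scenarios if s != base_scenario]

    overlap_by_scenario = (
        garden_summaries.groupby("scenario_id", as_index=False)
        .agg(
            mean_tss_overlap=("mean_tss_overlap", "mean"),
            sd_tss_overlap=("mean_tss_overlap", "std"),
            mean_overlap_cells=("mean_overlap_cells", "mean"),
            sd_overlap_cells=("mean_overlap_cells", "std"),
            n_garden_species=("garden_id", "size"),
        )
    )

    ranges = range_sizes.merge(
        taxa[["species_id", "genus", "group"]], on="species_id"
    )
    range_by_group = (
        ranges.groupby(["scenario_id", "group"], as_index=False)
        .agg(
            mean_range_cells=("range_cells", "mean"),
            sd_range_cells=("range_cells", "std"),
            n_species=("species_id", "size"),
        )
    )

    base = garden_summaries[garden_summaries["scenario_id"] == base_scenario]
    ratio_frames, lmm_rows = [], []
    for fut in futures:
        fut_sum = garden_summaries[garden_summaries["scenario_id"] == fut]
        for metric in ("mean_overlap_cells", "mean_tss_overlap"):
            records, n_excl = make_change_records(base, fut_sum, metric)
            if metric == "mean_overlap_cells":
                ratio_frames.append(records)
            if len(records) >= 3 and records["genus"].nunique() >= 2:
                r = lmm_intercept_test(records)
                lmm_rows.append(
                    {
                        "scenario_id": fut,
                        "metric": metric,
                        "group": "garden",
                        "intercept": r.intercept,
                        "se": r.se,
                        "p_value": r.p_value,
                        "genus_var": r.genus_var,
                        "resid_var": r.resid_var,
                        "n_obs": r.n_obs,
                        "n_genera": r.n_genera,
                        "n_excluded": n_excl,
                        "method": r.method,
                        "boundary": r.boundary,
                    }
                )
        # range-size change per species group
        base_r = ranges[ranges["scenario_id"] == base_scenario]
        fut_r = ranges[ranges["scenario_id"] == fut]
        for group in ("garden", "congener"):
            cur = base_r[base_r["group"] == group].rename(
                columns={"species_id": "garden_id"}
            )
            futr = fut_r[fut_r["group"] == group].rename(
                columns={"species_id": "garden_id"}
            )
            records, n_excl = make_change_records(cur, futr, "range_cells")
            if len(records) >= 3 and records["genus"].nunique() >= 2:
                r = lmm_intercept_test(records)
                lmm_rows.append(
                    {
                        "scenario_id": fut,
                        "metric": "range_size",
                        "group": group,
                        "intercept": r.intercept,
                        "se": r.se,
                        "p_value": r.p_value,
                        "genus_var": r.genus_var,
                        "resid_var": r.resid_var,
                        "n_obs": r.n_obs,
                        "n_genera": r.n_genera,
                        "n_excluded": n_excl,
                        "method": r.method,
                        "boundary": r.boundary,
                    }
                )
    return {
        "overlap_by_scenario": overlap_by_scenario,
        "range_by_group": range_by_group,
        "pair_log_ratios": (
            pd.concat(ratio_frames, ignore_index=True)
            if ratio_frames
            else pd.DataFrame()
        ),
        "lmm_tests": pd.DataFrame(lmm_rows),
    }
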