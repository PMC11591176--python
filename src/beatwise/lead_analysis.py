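"""Lead-subset ablation and the per-lead contribution statistic.

A reduced-lead model is trained on each member of an ensemble of lead
subsets; the contribution of a lead is the difference between the average
metric of models whose lead set includes it and the average of those that
exclude it.  Following the study design, reduced-lead evaluation is at
data level (per tensor) rather than case level.

Enumerating every non-empty subset of the 12 leads gives 2^12 - 1 = 4095
combinations; the desk-scale default ensemble (singles + leave-one-out +
a uniform sample over sizes) keeps the analysis tractable on one CPU.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .synthetic import LEAD_NAMES
from .train_eval import EvalResult, compare_configurations

LeadSet = tuple[str, ...]

_CANON_INDEX = {name: i for i, name in enumerate(LEAD_NAMES)}

METRICS = ("auc", "accuracy", "sensitivity", "specificity")

#: Lead-count bins used for the grouped performance comparison.
DEFAULT_BINS = ((1, 5), (6, 9), (10, 12))


def canonical_lead_set(leads) -> LeadSet:
    """Validate a lead collection and order it canonically (I..V6)."""
    leads = list(leads)
    if not leads:
        raise ValueError("lead set must be non-empty")
    unknown = set(leads) - set(LEAD_NAMES)
    if unknown:
        raise ValueError(f"unknown lead names: {sorted(unknown)}")
    if len(set(leads)) != len(leads):
        raise ValueError("lead set contains duplicates")
    return tuple(sorted(leads, key=_CANON_INDEX.__getitem__))


def enumerate_lead_sets(mode: str = "sampled", n_sample: int = 25,
                        seed: int = 0) -> list[LeadSet]:
    """Enumerate lead subsets for an ablation ensemble.

    Modes: ``all`` (every non-empty subset, 4095 sets), ``leave_one_out``
    (the full set plus the twelve 11-lead sets), ``singles`` (the twelve
    singletons), ``sampled`` (n_sample distinct subsets, sizes uniform).
    """
    if mode == "all":
        return [canonical_lead_set(c)
                for k in range(1, 13)
                for c in combinations(LEAD_NAMES, k)]
    if mode == "singles":
        return [(name,) for name in LEAD_NAMES]
    if mode == "leave_one_out":
        full = canonical_lead_set(LEAD_NAMES)
        return [full] + [canonical_lead_set(set(LEAD_NAMES) - {name})
                         for name in LEAD_NAMES]
    if mode == "sampled":
        total = 2 ** 12 - 1
        if n_sample > total:
            raise ValueError(f"cannot sample {n_sample} of {total} subsets")
        rng = np.random.default_rng(seed)
        seen: set[LeadSet] = set()
        out: list[LeadSet] = []
        while len(out) < n_sample:
            k = int(rng.integers(1, 13))
            picked = canonical_lead_set(
                rng.choice(LEAD_NAMES, size=k, replace=False))
            if picked not in seen:
                seen.add(picked)
                out.append(picked)
        return out
    raise ValueError(f"unknown enumeration mode {mode!r}")


def _metric_frame(results: dict[LeadSet, EvalResult | dict]) -> pd.DataFrame:
    rows = []
    for lead_set, res in results.items():
        lead_set = canonical_lead_set(lead_set)
        vals = {m: getattr(res, m, None) if not isinstance(res, dict)
                else res.get(m) for m in METRICS}
        rows.append({"lead_set": lead_set, "n_leads": len(lead_set), **vals})
    return pd.DataFrame(rows)


def contribution(results: dict[LeadSet, EvalResult | dict],
                 lead: str) -> dict[str, float | None]:
    """Contribution of one lead: mean metric over subsets containing it
    minus the mean over subsets lacking it, for each metric."""
    if lead not in LEAD_NAMES:
        raise ValueError(f"unknown lead {lead!r}")
    frame = _metric_frame(results)
    has = frame[frame["lead_set"].map(lambda s: lead in s)]
    lacks = frame[frame["lead_set"].map(lambda s: lead not in s)]
    if has.empty or lacks.empty:
        raise ValueError(
            f"lead {lead!r} must appear in some but not all evaluated sets")
    row: dict[str, float | None] = {}
    for m in METRICS:
        a, b = has[m].dropna(), lacks[m].dropna()
        row[f"delta_{m}"] = float(a.mean() - b.mean()) \
            if len(a) and len(b) else None
    return row


def contribution_table(results: dict[LeadSet, EvalResult | dict]
                       ) -> pd.DataFrame:
    """Per-lead contribution rows for every lead present in the ensemble,
    sorted by delta_auc descending."""
    frame = _metric_frame(results)
    present = [lead for lead in LEAD_NAMES
               if frame["lead_set"].map(lambda s: lead in s).any()
               and not frame["lead_set"].map(lambda s: lead in s).all()]
    table = pd.DataFrame(
        [{"lead": lead, **contribution(results, lead)} for lead in present])
    return table.sort_values("delta_auc", ascending=False,
                             ignore_index=True)


def group_by_lead_count(results: dict[LeadSet, EvalResult | dict],
                        bins=DEFAULT_BINS) -> dict:
    """Mean +/- SD AUC per lead-count bin with ANOVA/Tukey comparison.

    Empty bins are dropped (logged in the report); at least two non-empty
    bins are required.
    """
    frame = _metric_frame(results)
    groups: dict[str, list[float]] = {}
    dropped = []
    for lo, hi in bins:
        label = f"{lo}-{hi}"
        vals = frame.loc[(frame["n_leads"] >= lo) & (frame["n_leads"] <= hi),
                         "auc"].dropna().tolist()
        if vals:
            groups[label] = vals
        else:
            dropped.append(label)
    if len(groups) < 2:
        raise ValueError("need results spanning at least two lead-count bins")
    report = compare_configurations(groups, require_equal_n=False)
    report["dropped_bins"] = dropped
    return report
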