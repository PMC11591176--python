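"""The three headline experiments on synthetic cohorts.

Each experiment generates (or receives) a cohort with a planted
class-dependent effect, builds the requested ECG representation, trains the
block CNN over the stratified folds, and reports per-fold metrics plus the
comparison statistics:

* representation: 3 s strips vs single-beat vs two-beat tensors;
* segments: the five intra-beat segments (P, PQRS, QRS, QRST, PQRST) on
  single beats;
* leads: a reduced-lead ablation ensemble with the per-lead contribution
  statistic (data-level evaluation, MixUp disabled).

Everything is reproducible from (config, master seed): per-fold and
per-model seeds are derived deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocess as pp
from . import train_eval as te
from .lead_analysis import (canonical_lead_set, contribution_table,
                            enumerate_lead_sets, group_by_lead_count)
from .synthetic import CohortConfig, EcgRecord, make_cohort

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("strip3s", "single_beat", "two_beat")


@dataclass
class ExperimentConfig:
    """Desk-scale experiment settings.

    ``max_beats_per_record`` caps the beats taken from each record (first k
    after delineation) to bound the training-set size; ``folds_to_run``
    selects a subset of the four folds for quick runs.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    representations: tuple[str, ...] = REPRESENTATIONS
    segments: tuple[str, ...] = pp.SEGMENT_KINDS
    lead_mode: str = "singles"
    lead_n_sample: int = 12
    model_params: dict = field(default_factory=dict)
    folds_to_run: tuple[int, ...] = (1, 2, 3, 4)
    max_beats_per_record: int | None = 4
    use_truth_annotations: bool = True
    seed: int = 0
    out_dir: str | None = None

    def derived_seed(self, *tags: int) -> int:
        s = self.seed
        for t in tags:
            s = (s * 1_000_003 + t + 1) % (2 ** 31)
        return int(s)


def _config_hash(cfg: ExperimentConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    blob = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _record_annotations(record: EcgRecord, cfg: ExperimentConfig):
    anns = record.truth if (cfg.use_truth_annotations and record.truth) \
        else pp.delineate(record)
    if cfg.max_beats_per_record is not None:
        anns = anns[: cfg.max_beats_per_record]
    return anns


def _record_tensors(record: EcgRecord, cfg: ExperimentConfig,
                    representation: str, split_role: str,
                    segment: str = "PQRST") -> list[np.ndarray]:
    """Raw (unstandardised) tensors for one record and representation."""
    if representation == "strip3s":
        return [s.data for s in pp.extract_strips(record,
                                                  split_role=split_role)]
    anns = _record_annotations(record, cfg)
    beats = pp.extract_single_beats(record, anns)
    if segment != "PQRST":
        beats = [pp.make_partial(b, kind=segment) for b in beats]
    if representation == "single_beat":
        return [b.data for b in beats]
    if representation == "two_beat":
        return [b.data for b in pp.compose_two_beats(beats)]
    raise ValueError(f"unknown representation {representation!r}")


def build_fold_datasets(records: list[EcgRecord], plan: te.FoldPlan,
                        fold: int, cfg: ExperimentConfig,
                        representation: str, segment: str = "PQRST",
                        permute_case_labels_seed: int | None = None) -> dict:
    """Tensors, labels and case ids for one fold's train/dev/test splits,
    standardised with training statistics only.

    ``permute_case_labels_seed`` runs the permutation null: the binary
    labels are shuffled among cases (consistently across every split), so
    any genuine label-signal association is destroyed while the marginal
    class balance is preserved.
    """
    by_id = {r.case_id: r for r in records}
    label_of = {r.case_id: (0 if r.ef_class == "pEF" else 1)
                for r in records}
    if permute_case_labels_seed is not None:
        rng = np.random.default_rng(permute_case_labels_seed)
        cids = sorted(label_of)
        vals = rng.permutation([label_of[c] for c in cids])
        label_of = dict(zip(cids, (int(v) for v in vals)))
    roles = {}
    for f, train, dev, test in plan.folds():
        if f == fold:
            roles = {"train": train, "dev": dev, "test": test}
            break
    if not roles:
        raise ValueError(f"fold {fold} not in plan")
    splits: dict[str, dict] = {}
    for role, ids in roles.items():
        xs, ys, cids = [], [], []
        for cid in ids:
            rec = by_id[cid]
            label = label_of[cid]
            for tensor in _record_tensors(rec, cfg, representation, role,
                                          segment):
                xs.append(tensor)
                ys.append(label)
                cids.append(cid)
        splits[role] = {"X": np.stack(xs).astype(np.float32),
                        "y": np.asarray(ys, dtype=int),
                        "case_ids": np.asarray(cids)}
    std = pp.GlobalStandardizer().fit(splits["train"]["X"])
    for role in splits:
        splits[role]["X"] = std.transform(splits[role]["X"]).astype(np.float32)
    splits["standardizer"] = std
    return splits


def _train_and_eval(splits: dict, cfg: ExperimentConfig, *, label: str,
                    fold: int, seed: int, level: str = "case",
                    mixup: bool = True) -> te.EvalResult:
    params = dict(cfg.model_params)
    if not mixup:
        params["mixup_alpha"] = 0.0
    clf = te.train_fold(splits["train"]["X"], splits["train"]["y"],
                        splits["dev"]["X"], splits["dev"]["y"],
                        dev_case_ids=splits["dev"]["case_ids"],
                        model_params=params, seed=seed)
    case_ids = splits["test"]["case_ids"] if level == "case" else None
    return te.evaluate_fold(clf, splits["test"]["X"], splits["test"]["y"],
                            case_ids, configuration=label, fold=fold,
                            level=level)


def _finish_report(report: dict, cfg: ExperimentConfig) -> dict:
    report["config_hash"] = _config_hash(cfg)
    report["seed"] = cfg.seed
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"{report['experiment']}.json"
        path.write_text(json.dumps(report, indent=2, default=str))
        logger.info("wrote %s", path)
    return report


def run_representation_experiment(cfg: ExperimentConfig) -> dict:
    """Train strip/single-beat/two-beat models over the folds and compare."""
    records = make_cohort(cfg.cohort)
    plan = te.make_fold_plan({r.case_id: r.ef_class for r in records},
                             seed=cfg.derived_seed(11))
    te.assert_no_leakage(plan)
    results: list[te.EvalResult] = []
    for ri, rep in enumerate(cfg.representations):
        for fold in cfg.folds_to_run:
            splits = build_fold_datasets(records, plan, fold, cfg, rep)
            results.append(_train_and_eval(
                splits, cfg, label=rep, fold=fold,
                seed=cfg.derived_seed(ri, fold)))
    per_config = {rep: [r.auc for r in results if r.configuration == rep]
                  for rep in cfg.representations}
    comparison = te.compare_configurations(per_config) \
        if len(per_config) >= 2 and min(map(len, per_config.values())) >= 2 \
        else None
    ranking = sorted(per_config, key=lambda k: -float(np.mean(per_config[k])))
    report = {"experiment": "representation",
              "results": [dataclasses.asdict(r) for r in results],
              "mean_auc": {k: float(np.mean(v)) for k, v in per_config.items()},
              "comparison": comparison, "ranking": ranking}
    return _finish_report(report, cfg)


def run_segment_experiment(cfg: ExperimentConfig) -> dict:
    """Train one single-beat model per intra-beat segment kind and rank."""
    records = make_cohort(cfg.cohort)
    plan = te.make_fold_plan({r.case_id: r.ef_class for r in records},
                             seed=cfg.derived_seed(22))
    te.assert_no_leakage(plan)
    results: list[te.EvalResult] = []
    for si, seg in enumerate(cfg.segments):
        for fold in cfg.folds_to_run:
            splits = build_fold_datasets(records, plan, fold, cfg,
                                         "single_beat", segment=seg)
            results.append(_train_and_eval(
                splits, cfg, label=seg, fold=fold,
                seed=cfg.derived_seed(100 + si, fold)))
    per_config = {seg: [r.auc for r in results if r.configuration == seg]
                  for seg in cfg.segments}
    comparison = te.compare_configurations(per_config) \
        if len(per_config) >= 2 and min(map(len, per_config.values())) >= 2 \
        else None
    ranking = sorted(per_config, key=lambda k: -float(np.mean(per_config[k])))
    report = {"experiment": "segments",
              "results": [dataclasses.asdict(r) for r in results],
              "mean_auc": {k: float(np.mean(v)) for k, v in per_config.items()},
              "comparison": comparison, "ranking": ranking}
    return _finish_report(report, cfg)


def run_lead_experiment(cfg: ExperimentConfig) -> dict:
    """Reduced-lead ablation: one model per lead subset, data-level
    evaluation, MixUp disabled; emits the contribution table and the
    lead-count-binned comparison when the ensemble spans several bins."""
    lead_sets = enumerate_lead_sets(cfg.lead_mode, n_sample=cfg.lead_n_sample,
                                    seed=cfg.derived_seed(33))
    if len(lead_sets) < 2:
        raise ValueError("lead ensemble must contain at least 2 lead sets")
    records = make_cohort(cfg.cohort)
    plan = te.make_fold_plan({r.case_id: r.ef_class for r in records},
                             seed=cfg.derived_seed(44))
    te.assert_no_leakage(plan)
    fold = cfg.folds_to_run[0]
    base = build_fold_datasets(records, plan, fold, cfg, "single_beat")
    lead_to_row = {name: i for i, name in enumerate(
        canonical_lead_set(tuple(pp.LEAD_NAMES)))}
    set_results = {}
    for li, lead_set in enumerate(lead_sets):
        rows = [lead_to_row[lead] for lead in lead_set]
        splits = {role: {"X": base[role]["X"][:, rows, :],
                         "y": base[role]["y"],
                         "case_ids": base[role]["case_ids"]}
                  for role in ("train", "dev", "test")}
        res = _train_and_eval(splits, cfg, label="+".join(lead_set),
                              fold=fold, seed=cfg.derived_seed(200 + li),
                              level="data", mixup=False)
        set_results[lead_set] = res
    table = contribution_table(set_results)
    sizes = {len(s) for s in set_results}
    grouped = None
    if len({_bin_of(n) for n in sizes if _bin_of(n)}) >= 2:
        try:
            grouped = group_by_lead_count(set_results)
        except ValueError:
            grouped = None
    report = {"experiment": "leads",
              "results": {"+".join(k): dataclasses.asdict(v)
                          for k, v in set_results.items()},
              "contribution": table.to_dict(orient="records"),
              "grouped_by_lead_count": grouped}
    return _finish_report(report, cfg)


def _bin_of(n: int) -> str | None:
    for lo, hi in ((1, 5), (6, 9), (10, 12)):
        if lo <= n <= hi:
            return f"{lo}-{hi}"
    return None
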