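"""End-to-end orchestration: generate -> curate -> design -> train -> explain
-> aggregate -> map.

The run directory is the unit of reproducibility: every random draw derives
from the master seed, per-job artifacts are written once and reloaded on
resume, and all aggregate tables are recomputed from the on-disk artifacts
(so an interrupted run, once resumed, is byte-identical to an
uninterrupted one).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from sxc import aggregation as agg
from sxc.curation import curate_records
from sxc.design import DesignSpec, enumerate_jobs, make_trial_splits
from sxc.mapping import color_bins, map_feature_values_to_atoms
from sxc.models import TrainedModel, train_model_with_search
from sxc.seeding import derive_rng
from sxc.shapley import RFExplainer, ShapleyExplanation, orient_explanation, svm_tanimoto_shapley
from sxc.synthetic import (
    SyntheticDataset,
    SyntheticPairSpec,
    default_atom_map,
    generate_class_pair,
    write_truth,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Run configuration with desk-scale defaults."""

    master_seed: int = 0
    # generator
    n_features: int = 64
    planted_per_class: int = 8
    p_planted_on: float = 0.8
    p_cross_on: float = 0.1
    p_background: float = 0.1
    noise_rate: float = 0.05
    pool_per_class: int = 460
    # design
    class_ids: tuple[str, ...] = ("A", "B")
    size_schedule: tuple[int, ...] = (5, 8, 12, 16, 24, 32, 48, 64, 96, 128, 192, 256)
    n_trials: int = 3
    test_per_class: int = 100
    validation_fraction: float = 0.2
    algorithms: tuple[str, ...] = ("RF", "SVM")
    # training
    n_search: int = 8
    rf_grid: dict[str, list] | None = None
    svm_grid: dict[str, list] | None = None
    # explanation
    explain_per_class: int = 12
    rf_background: int = 25  # 0 = full training set
    # mapping
    map_tau: float = 1e-6
    map_examples: int = 3

    def __post_init__(self) -> None:
        self.class_ids = tuple(self.class_ids)
        self.size_schedule = tuple(self.size_schedule)
        self.algorithms = tuple(self.algorithms)
        if self.planted_per_class * len(self.class_ids) > self.n_features:
            raise ValueError("planted bits exceed the fingerprint length")
        if self.explain_per_class < 1:
            raise ValueError("explain_per_class must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def design(self) -> DesignSpec:
        return DesignSpec(
            class_ids=self.class_ids,
            size_schedule=self.size_schedule,
            n_trials=self.n_trials,
            test_per_class=self.test_per_class,
            validation_fraction=self.validation_fraction,
            algorithms=self.algorithms,
            master_seed=self.master_seed,
        )

    def planted_sets(self) -> dict[str, frozenset[int]]:
        """Disjoint planted-bit blocks, one per class, at the front of the vector."""
        ppc = self.planted_per_class
        return {
            cid: frozenset(range(k * ppc, (k + 1) * ppc))
            for k, cid in enumerate(self.class_ids)
        }

    def pair_spec(self, class_a: str, class_b: str) -> SyntheticPairSpec:
        planted = self.planted_sets()
        seed = int(derive_rng(self.master_seed, "pair-data", class_a, class_b).integers(2**31 - 1))
        return SyntheticPairSpec(
            n_features=self.n_features,
            n_per_class=self.pool_per_class,
            planted_a=planted[class_a],
            planted_b=planted[class_b],
            p_planted_on=self.p_planted_on,
            p_cross_on=self.p_cross_on,
            p_background=self.p_background,
            noise_rate=self.noise_rate,
            seed=seed,
            class_a=class_a,
            class_b=class_b,
        )


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(data)


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _explain_ids(
    cfg: PipelineConfig, pool: SyntheticDataset, test_idx: np.ndarray, pair, trial: int
) -> np.ndarray:
    """Balanced subset of test indices explained at every size of this trial."""
    rng = derive_rng(cfg.master_seed, "explain-subset", pair[0], pair[1], trial)
    labels = pool.labels()[test_idx]
    chosen = []
    for cid in pair:
        members = test_idx[labels == cid]
        take = min(cfg.explain_per_class, len(members))
        chosen.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def _run_job(
    cfg: PipelineConfig,
    pool: SyntheticDataset,
    job: Mapping[str, Any],
    split,
    explain_idx: np.ndarray,
    jobs_dir: Path,
    expl_dir: Path,
) -> None:
    job_id = job["job_id"]
    result_path = jobs_dir / f"{job_id}.json"
    expl_path = expl_dir / f"{job_id}.csv"
    if result_path.exists() and expl_path.exists():
        logger.info("job %s: artifacts present, skipping", job_id)
        return

    t0 = time.perf_counter()
    size = int(job["size_per_class"])
    algorithm = job["algorithm"]
    x_all = pool.fingerprint_matrix()
    labels_all = pool.labels()
    train_idx, val_idx = split.by_size[size]

    grid = cfg.rf_grid if algorithm == "RF" else cfg.svm_grid
    model = train_model_with_search(
        x_all[train_idx],
        labels_all[train_idx].tolist(),
        x_all[val_idx],
        labels_all[val_idx].tolist(),
        algorithm,
        grid=grid,
        n_search=cfg.n_search,
        seed=int(job["search_seed"]),
    )

    test_idx = split.test
    x_test = x_all[test_idx]
    y_true = labels_all[test_idx]
    y_pred = np.array(model.decode_labels(model.predict(x_test)))
    report = model.evaluate(x_test, y_true.tolist())

    explanations = _explain_compounds(cfg, pool, model, explain_idx, job)
    _write_explanations(explanations, pool, explain_idx, model, expl_path)

    payload = {
        "job_id": job_id,
        "algorithm": algorithm,
        "pair": [job["class_a"], job["class_b"]],
        "size_per_class": size,
        "trial": int(job["trial"]),
        "params": model.params,
        "validation_mcc": model.validation_mcc,
        "tie_break_loss": model.tie_break,
        "test": {
            "tp": report.tp, "tn": report.tn, "fp": report.fp, "fn": report.fn,
            "mcc": report.mcc, "ba": report.ba, "f1": report.f1,
        },
        "test_compound_ids": [pool.records[i].compound_id for i in test_idx],
        "test_correct": [int(t == p) for t, p in zip(y_true, y_pred)],
        "schema_version": SCHEMA_VERSION,
    }
    _json_dump(payload, result_path)
    logger.info("job %s: done in %.2fs (test MCC %.3f)", job_id,
                time.perf_counter() - t0, report.mcc)


def _explain_compounds(
    cfg: PipelineConfig,
    pool: SyntheticDataset,
    model: TrainedModel,
    explain_idx: np.ndarray,
    job: Mapping[str, Any],
) -> list[ShapleyExplanation]:
    x_all = pool.fingerprint_matrix()
    x_expl = x_all[explain_idx]
    ids = [pool.records[i].compound_id for i in explain_idx]
    if model.algorithm == "SVM":
        raw = [svm_tanimoto_shapley(model, x, cid) for x, cid in zip(x_expl, ids)]
    else:
        bg = model.x_train
        if cfg.rf_background and cfg.rf_background < bg.shape[0]:
            rng = derive_rng(cfg.master_seed, "rf-background", job["job_id"])
            bg = bg[rng.choice(bg.shape[0], size=cfg.rf_background, replace=False)]
        class_index = list(model.estimator.classes_).index(0)
        explainer = RFExplainer(model.estimator, bg, class_index=class_index)
        raw = explainer.explain_batch(x_expl, ids, orientation=model.classes[0])
    oriented = []
    for expl, i in zip(raw, explain_idx):
        true_class = pool.records[i].class_label
        oriented.append(orient_explanation(expl, true_class, model.classes))
    return oriented


def _write_explanations(
    explanations: list[ShapleyExplanation],
    pool: SyntheticDataset,
    explain_idx: np.ndarray,
    model: TrainedModel,
    path: Path,
) -> None:
    x_all = pool.fingerprint_matrix()
    y_pred = model.decode_labels(model.predict(x_all[explain_idx]))
    rows = []
    for expl, i, pred in zip(explanations, explain_idx, y_pred):
        rec = pool.records[i]
        row = {
            "compound_id": rec.compound_id,
            "true_class": rec.class_label,
            "predicted_class": pred,
            "correct": int(pred == rec.class_label),
            "base_value": expl.base_value,
            "model_output": expl.model_output,
            "orientation": expl.orientation,
            "kind": expl.kind,
        }
        for j, v in enumerate(expl.values):
            row[f"f{j}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def _load_explanations(path: Path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    values = df[value_cols].to_numpy(dtype=np.float64)
    return df, values


def run_pipeline(
    config: PipelineConfig | Mapping[str, Any],
    out_dir: str | Path,
    stop_after_jobs: int | None = None,
) -> Path:
    """Execute (or resume) a full run; returns the run directory.

    ``stop_after_jobs`` interrupts the run after that many training jobs
    (used to exercise resumability); aggregation only happens on complete
    runs.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "jobs").mkdir(exist_ok=True)
    (run_dir / "explanations").mkdir(exist_ok=True)
    (run_dir / "pairs").mkdir(exist_ok=True)

    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("sxc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, run_dir, stop_after_jobs)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, run_dir: Path, stop_after_jobs: int | None) -> Path:
    _json_dump({"schema_version": SCHEMA_VERSION, **asdict(cfg)}, run_dir / "config.json")
    design = cfg.design()
    manifest = enumerate_jobs(design)
    manifest.to_csv(run_dir / "manifest.csv", index=False)

    # generate + curate one dataset per unordered class pair
    pools: dict[tuple[str, str], SyntheticDataset] = {}
    for pair in design.pairs:
        spec = cfg.pair_spec(*pair)
        dataset = generate_class_pair(spec)
        kept, rejected = curate_records(dataset.records)
        if rejected:
            logger.warning("pair %s: %d generated records failed curation", pair, len(rejected))
        dataset = SyntheticDataset(records=kept, truth=dataset.truth, spec=spec)
        pools[pair] = dataset
        pair_dir = run_dir / "pairs" / f"{pair[0]}-vs-{pair[1]}"
        pair_dir.mkdir(exist_ok=True)
        if not (pair_dir / "truth.json").exists():
            write_truth(dataset, pair_dir / "truth.json")

    # training + explanation jobs
    n_done = 0
    splits_cache: dict[tuple[tuple[str, str], int], Any] = {}
    explain_cache: dict[tuple[tuple[str, str], int], np.ndarray] = {}
    for job in manifest.to_dict("records"):
        pair = (job["class_a"], job["class_b"])
        trial = int(job["trial"])
        key = (pair, trial)
        if key not in splits_cache:
            splits_cache[key] = make_trial_splits(pools[pair], design, pair, trial)
            explain_cache[key] = _explain_ids(cfg, pools[pair], splits_cache[key].test,
                                              pair, trial)
        _run_job(cfg, pools[pair], job, splits_cache[key], explain_cache[key],
                 run_dir / "jobs", run_dir / "explanations")
        n_done += 1
        if stop_after_jobs is not None and n_done >= stop_after_jobs:
            logger.info("stopping after %d jobs as requested", n_done)
            return run_dir

    _aggregate(cfg, design, manifest, pools, run_dir)
    return run_dir


# ---------------------------------------------------------------------------
# aggregation over on-disk job artifacts
# ---------------------------------------------------------------------------


def _aggregate(cfg, design, manifest, pools, run_dir: Path) -> None:
    jobs_dir = run_dir / "jobs"
    results = {
        row["job_id"]: json.loads((jobs_dir / f"{row['job_id']}.json").read_text())
        for row in manifest.to_dict("records")
    }

    metrics_rows = []
    for job_id, res in results.items():
        metrics_rows.append(
            {
                "job_id": job_id,
                "pair": "-vs-".join(res["pair"]),
                "class_a": res["pair"][0],
                "class_b": res["pair"][1],
                "size_per_class": res["size_per_class"],
                "trial": res["trial"],
                "algorithm": res["algorithm"],
                "params": json.dumps(res["params"], sort_keys=True),
                "validation_mcc": res["validation_mcc"],
                "tie_break_loss": res["tie_break_loss"],
                **{k: res["test"][k] for k in ("tp", "tn", "fp", "fn", "mcc", "ba", "f1")},
            }
        )
    metrics = pd.DataFrame(metrics_rows).sort_values("job_id", kind="stable")
    metrics.to_csv(run_dir / "metrics.csv", index=False, float_format="%.12g")

    patterns = _prediction_patterns(design, manifest, results)
    patterns.to_csv(run_dir / "patterns.csv", index=False)
    pattern_table = agg.pattern_tabulate(patterns)
    pattern_table.to_csv(run_dir / "pattern_table.csv", index=False, float_format="%.12g")

    fcs, pcc_table, feature_tables = _shapley_aggregates(cfg, design, manifest, results,
                                                         pools, run_dir)
    fcs.to_csv(run_dir / "fcs.csv", index=False, float_format="%.12g")
    pcc_table.to_csv(run_dir / "pcc.csv", index=False, float_format="%.12g")

    fc_rows = []
    for _, grp in pcc_table.groupby(["pair", "algorithm"]):
        grp = grp.sort_values("class_id", kind="stable")
        if len(grp) != 2 or grp["pcc"].isna().any():
            continue
        algorithm = grp["algorithm"].iloc[0]
        p1, p2 = float(grp["pcc"].iloc[0]), float(grp["pcc"].iloc[1])
        comb = agg.combined_pcc(p1, p2, algorithm)
        fc_rows.append(
            {
                "pair": grp["pair"].iloc[0],
                "algorithm": algorithm,
                "pcc_1": p1,
                "pcc_2": p2,
                "combined_pcc": comb,
                "fc_pattern": agg.classify_fc_pattern(p1, p2, comb, algorithm),
            }
        )
    fc_table = pd.DataFrame(
        fc_rows, columns=["pair", "algorithm", "pcc_1", "pcc_2", "combined_pcc", "fc_pattern"]
    )
    fc_table.to_csv(run_dir / "fc_patterns.csv", index=False, float_format="%.12g")

    feature_rows = []
    for (algorithm, size), table in sorted(feature_tables.items()):
        for cls in sorted(table.present_sum):
            for status, sums, counts in (
                ("present", table.present_sum[cls], table.present_count[cls]),
                ("absent", table.absent_sum[cls], table.absent_count[cls]),
            ):
                for j in range(table.n_features):
                    if counts[j] == 0 and sums[j] == 0.0:
                        continue
                    feature_rows.append(
                        {
                            "algorithm": algorithm,
                            "size_per_class": size,
                            "class_id": cls,
                            "status": status,
                            "feature": j,
                            "cumulative_value": sums[j],
                            "occurrence_count": int(counts[j]),
                        }
                    )
    pd.DataFrame(feature_rows).to_csv(
        run_dir / "feature_cumulative.csv", index=False, float_format="%.12g"
    )

    intersections = _top_k_intersections(feature_tables)
    _json_dump(intersections, run_dir / "intersections.json")

    atom_report = _map_examples(cfg, design, manifest, results, pools, patterns, run_dir)
    _json_dump(atom_report, run_dir / "atom_mapping.json")

    summary = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(cfg),
        "n_jobs": int(len(manifest)),
        "n_pairs": int(len(design.pairs)),
        "pattern_table": pattern_table.to_dict("records"),
        "fc_patterns": fc_table.to_dict("records"),
        "top15_intersections": intersections,
        "median_test_mcc_by_size": {
            algorithm: {
                str(size): float(grp["mcc"].median())
                for size, grp in metrics[metrics["algorithm"] == algorithm].groupby(
                    "size_per_class"
                )
            }
            for algorithm in design.algorithms
        },
    }
    _json_dump(summary, run_dir / "summary.json")


def _prediction_patterns(design, manifest, results) -> pd.DataFrame:
    rows = []
    schedule = list(design.size_schedule)
    for (ca, cb, trial, algorithm), grp in manifest.groupby(
        ["class_a", "class_b", "trial", "algorithm"]
    ):
        grp = grp.sort_values("size_index", kind="stable")
        per_size = [results[j] for j in grp["job_id"]]
        ids = per_size[0]["test_compound_ids"]
        bit_matrix = np.array([res["test_correct"] for res in per_size]).T  # (n_test, n_sizes)
        assert bit_matrix.shape[1] == len(schedule)
        for cid, bits in zip(ids, bit_matrix):
            rows.append(
                {
                    "compound_id": cid,
                    "pair": f"{ca}-vs-{cb}",
                    "trial": int(trial),
                    "algorithm": algorithm,
                    "bits": "".join(map(str, bits.tolist())),
                    "category": agg.classify_prediction_pattern(bits),
                }
            )
    return pd.DataFrame(rows)


def _shapley_aggregates(cfg, design, manifest, results, pools, run_dir):
    """f_cs per (job, class), PCC per (pair, algorithm, class), and
    feature-based cumulative tables per (algorithm, size)."""
    expl_dir = run_dir / "explanations"
    fcs_rows = []
    feature_tables: dict[tuple[str, int], agg.FeatureCumulative] = {}

    fingerprints = {
        pair: {r.compound_id: r.fingerprint for r in pool.records}
        for pair, pool in pools.items()
    }

    for row in manifest.to_dict("records"):
        job_id = row["job_id"]
        res = results[job_id]
        pair = (res["pair"][0], res["pair"][1])
        df, values = _load_explanations(expl_dir / f"{job_id}.csv")
        fps = np.array([fingerprints[pair][cid] for cid in df["compound_id"]])
        explanations = [
            ShapleyExplanation(
                compound_id=str(r.compound_id),
                values=values[i],
                base_value=float(r.base_value),
                model_output=float(r.model_output),
                orientation=str(r.orientation),
                kind=str(r.kind),
            )
            for i, r in enumerate(df.itertuples(index=False))
        ]
        correct = df["correct"].astype(bool).tolist()
        predicted = df["predicted_class"].astype(str).tolist()

        for cls in pair:
            cumulatives = [
                agg.instance_cumulative(expl, fp)
                for expl, fp, ok, true_cls in zip(
                    explanations, fps, correct, df["true_class"].astype(str)
                )
                if ok and true_cls == cls
            ]
            score = agg.feature_contribution_score(cumulatives)
            if score is None:
                logger.info("job %s class %s: no correct explained compounds; "
                            "f_cs undefined", job_id, cls)
            fcs_rows.append(
                {
                    "job_id": job_id,
                    "pair": "-vs-".join(pair),
                    "size_per_class": res["size_per_class"],
                    "trial": res["trial"],
                    "algorithm": res["algorithm"],
                    "class_id": cls,
                    "n_correct_explained": len(cumulatives),
                    "f_cs": np.nan if score is None else score,
                    "test_mcc": res["test"]["mcc"],
                }
            )

        key = (res["algorithm"], int(res["size_per_class"]))
        table = agg.feature_cumulative(explanations, fps, correct, predicted)
        if key not in feature_tables:
            feature_tables[key] = agg.FeatureCumulative(n_features=cfg.n_features)
        feature_tables[key].add(table)

    fcs = pd.DataFrame(fcs_rows)
    pcc_rows = []
    for (pair, algorithm, cls), grp in fcs.groupby(["pair", "algorithm", "class_id"]):
        valid = grp.dropna(subset=["f_cs"])
        pcc = None
        if len(valid) >= 2:
            pcc = agg.pearson_cc(valid["f_cs"].to_numpy(), valid["test_mcc"].to_numpy())
        pcc_rows.append(
            {
                "pair": pair,
                "algorithm": algorithm,
                "class_id": cls,
                "n_models": len(valid),
                "pcc": np.nan if pcc is None else pcc,
            }
        )
    pcc_table = pd.DataFrame(pcc_rows)
    return fcs, pcc_table, feature_tables


def _top_k_intersections(feature_tables, k: int = 15):
    """Per algorithm: intersect top-k sets across the size schedule."""
    out: dict[str, dict[str, list[int]]] = {}
    algorithms = sorted({a for a, _ in feature_tables})
    for algorithm in algorithms:
        per_model: dict[int, dict[tuple[str, str], np.ndarray]] = {}
        for (a, size), table in feature_tables.items():
            if a != algorithm:
                continue
            tables = {}
            for cls in table.present_sum:
                tables[(cls, "present")] = table.present_sum[cls]
                tables[(cls, "absent")] = table.absent_sum[cls]
            per_model[size] = tables
        if len(per_model) < 2:
            continue
        inter = agg.top_k_feature_intersection(per_model, k=k)
        out[algorithm] = {f"{cls}|{status}": sorted(v) for (cls, status), v in inter.items()}
    return out


def _map_examples(cfg, design, manifest, results, pools, patterns, run_dir) -> dict:
    """Atom-level maps for exemplary start-incorrect-end-correct compounds.

    Uses explained compounds of trial 0 of the first pair at the smallest,
    middle and largest sizes.
    """
    pair = design.pairs[0]
    pair_name = f"{pair[0]}-vs-{pair[1]}"
    pool = pools[pair]
    by_id = {r.compound_id: r for r in pool.records}
    schedule = design.size_schedule
    picks = patterns[
        (patterns["pair"] == pair_name)
        & (patterns["trial"] == 0)
        & (patterns["category"] == "start_incorrect_end_correct")
    ]["compound_id"].unique()

    sizes = sorted({schedule[0], schedule[len(schedule) // 2], schedule[-1]})
    expl_dir = run_dir / "explanations"
    report: dict[str, Any] = {"pair": pair_name, "trial": 0, "compounds": {}}
    n_mapped = 0
    for cid in picks:
        if n_mapped >= cfg.map_examples:
            break
        rec = by_id[cid]
        atom_map = default_atom_map(rec.fingerprint)
        entry: dict[str, Any] = {}
        for algorithm in design.algorithms:
            for size in sizes:
                job_id = f"{pair[0]}-vs-{pair[1]}_size{size}_trial0_{algorithm}"
                df, values = _load_explanations(expl_dir / f"{job_id}.csv")
                match = df.index[df["compound_id"] == cid]
                if len(match) == 0:
                    continue
                i = int(match[0])
                expl = ShapleyExplanation(
                    compound_id=cid,
                    values=values[i],
                    base_value=float(df["base_value"].iloc[i]),
                    model_output=float(df["model_output"].iloc[i]),
                    orientation=str(df["orientation"].iloc[i]),
                    kind=str(df["kind"].iloc[i]),
                )
                atom_values = map_feature_values_to_atoms(
                    expl, rec.fingerprint, atom_map, n_atoms=2 * cfg.n_features
                )
                entry[f"{algorithm}|size{size}"] = {
                    "atom_values": [round(float(v), 12) for v in atom_values],
                    "colors": color_bins(atom_values, tau=cfg.map_tau),
                }
        if entry:
            report["compounds"][cid] = entry
            n_mapped += 1
    return report
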