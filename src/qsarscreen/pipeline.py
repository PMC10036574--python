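"""End-to-end pipeline: curate -> select -> train -> evaluate -> validate -> screen.

Each stage writes its outputs under a run directory; a manifest records
stage order, timings, record counts, seeds and collected warnings. All
randomness derives from the single master seed. Rerunning an identical
config reproduces all numeric outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import __version__
from .config import PipelineConfig
from .containers import DescriptorMatrix, FingerprintSet
from .curation import assign_labels, deduplicate, records_from_frame, records_to_frame
from .evaluation import evaluate_model, probability_by_outcome
from .feature_selection import select_descriptors
from .fingerprints import bit_frequency, differential_bits
from .models import ALGORITHMS, ModelConfig, train_ensemble
from .screening import screen
from .synthetic_data import generate_dataset, generate_screening_library
from .validation import fit_ad, y_randomization


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _seed_for(master: int, stage: str) -> int:
    digest = sum(ord(c) * (i + 1) for i, c in enumerate(stage))
    return int(np.random.SeedSequence([master, digest]).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to the run dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stages": [],
        "warnings": [],
    }

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                info = fn() or {}
            except Exception as exc:  # abort with a machine-readable record
                record = {"stage": name, "status": "failed", "error": str(exc)}
                manifest["stages"].append(record)
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise StageError(name, exc) from exc
            record = {"stage": name, "status": "ok",
                      "seconds": round(time.perf_counter() - t0, 3), **info}
            manifest["stages"].append(record)
            return record

        return deco

    state: dict = {}

    @stage("curate")
    def _curate():
        if config.synthetic is not None:
            ds = generate_dataset(config.synthetic)
            state["descriptors_all"] = ds.descriptors
            state["fingerprints"] = ds.fingerprints
            compounds = ds.compounds
        else:
            compounds = pd.read_csv(config.compounds_csv)
            state["descriptors_all"] = DescriptorMatrix.from_csv(config.descriptors_csv)
            state["fingerprints"] = FingerprintSet.from_csv(config.fingerprints_csv)
        records = records_from_frame(compounds)
        records, removal_log = deduplicate(records, aggregate=config.dedup_aggregate)
        records, summary = assign_labels(
            records, boundary_um=config.boundary_um,
            exclude_range_um=config.exclude_range_um,
        )
        curated = records_to_frame(records)
        curated.to_csv(out / "curated_compounds.csv", index=False)
        ids = curated["compound_id"].tolist()
        state["descriptors_all"] = state["descriptors_all"].subset_rows(ids)
        state["labels"] = (curated["label"] == "active").astype(int).to_numpy()
        state["ids"] = ids
        return {"n_compounds": len(ids), "n_removed": len(removal_log), **{
            k: v for k, v in summary.items() if k in ("n_active", "n_inactive", "n_excluded")}}

    @stage("select")
    def _select():
        X, result = select_descriptors(
            state["descriptors_all"], state["labels"],
            corr_threshold=config.correlation_threshold,
            n_iterations=config.boruta_iterations,
            alpha=config.boruta_alpha,
            seed=_seed_for(config.master_seed, "select"),
        )
        (out / "selection.json").write_text(json.dumps(result.to_dict(), indent=2))
        X.to_csv(out / "descriptors_selected.csv")
        state["descriptors"] = X
        return {"n_kept": len(result.kept),
                "n_dropped_correlation": len(result.dropped_by_correlation)}

    @stage("train")
    def _train():
        seed = _seed_for(config.master_seed, "train")
        ids = np.array(state["ids"])
        y = state["labels"]
        train_ids, test_ids = train_test_split(
            ids, test_size=config.test_fraction, stratify=y, random_state=seed % (2**31)
        )
        state["train_ids"], state["test_ids"] = list(train_ids), list(test_ids)
        X_train = state["descriptors"].subset_rows(state["train_ids"])
        X_test = state["descriptors"].subset_rows(state["test_ids"])
        id_pos = {cid: i for i, cid in enumerate(ids)}
        y_train = y[[id_pos[c] for c in state["train_ids"]]]
        y_test = y[[id_pos[c] for c in state["test_ids"]]]
        state.update(X_train=X_train, X_test=X_test, y_train=y_train, y_test=y_test)
        configs = [
            ModelConfig(a, config.hyperparameters.get(a, {}), seed=seed + i)
            for i, a in enumerate(ALGORITHMS)
        ]
        state["bundle"] = train_ensemble(X_train, y_train, configs)
        state["bundle"].save(out / "bundle")
        return {"n_train": len(train_ids), "n_test": len(test_ids)}

    @stage("evaluate")
    def _evaluate():
        reports = {}
        probs = state["bundle"].predict_proba_frame(state["X_test"])
        for algo in ALGORITHMS:
            rep = evaluate_model(state["y_test"], probs[f"p_{algo}"].to_numpy())
            reports[algo] = rep.to_dict()
            reports[algo]["probability_by_outcome"] = {
                k: {kk: vv for kk, vv in v.items() if kk != "values"}
                for k, v in probability_by_outcome(
                    state["y_test"], probs[f"p_{algo}"].to_numpy()
                ).items()
            }
        active_ids = [c for c, lab in zip(state["ids"], state["labels"]) if lab == 1]
        inactive_ids = [c for c, lab in zip(state["ids"], state["labels"]) if lab == 0]
        fa = bit_frequency(state["fingerprints"], active_ids, "active")
        fi = bit_frequency(state["fingerprints"], inactive_ids, "inactive")
        state["fps_train_active"] = state["fingerprints"].subset(
            [c for c in state["train_ids"] if c in set(active_ids)]
        )
        reports["differential_bits"] = differential_bits(fa, fi)
        (out / "metrics.json").write_text(json.dumps(reports, indent=2))
        return {"mean_test_accuracy": float(np.mean(
            [reports[a]["accuracy"] for a in ALGORITHMS]))}

    @stage("validate")
    def _validate():
        ad = fit_ad(state["X_train"], n_components=config.ad_components,
                    margin=config.ad_margin)
        ad.to_json(out / "ad_model.json")
        state["ad"] = ad
        yr = y_randomization(
            state["X_train"], state["y_train"],
            ModelConfig(config.yrand_algorithm,
                        config.hyperparameters.get(config.yrand_algorithm, {}),
                        seed=_seed_for(config.master_seed, "yrand")),
            state["X_test"], state["y_test"],
            n_runs=config.yrand_runs,
            resample_fraction=config.yrand_fraction,
            seed=_seed_for(config.master_seed, "yrand"),
        )
        yr.to_frame().to_csv(out / "y_randomization.csv", index=False)
        return {
            "yrand_mean_accuracy": yr.mean_accuracy,
            "yrand_max_accuracy": yr.max_accuracy,
            "reference_accuracy": yr.reference_accuracy,
        }

    @stage("screen")
    def _screen():
        X_lib, fps_lib = generate_screening_library(
            n=config.library_size,
            frac_shifted=config.library_frac_shifted,
            shift=config.library_shift,
            seed=_seed_for(config.master_seed, "library"),
            descriptor_names=state["descriptors"].descriptor_names,
        )
        report = screen(
            state["bundle"], state["ad"], X_lib, fps_lib,
            state["fps_train_active"],
            probability_threshold=config.probability_threshold,
            novelty_threshold=config.novelty_threshold,
        )
        report.to_csv(out / "screening_report.csv")
        manifest["warnings"].extend(report.warnings)
        return {"n_library": config.library_size,
                "n_hits": int(report.table["final_pass"].sum())}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
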