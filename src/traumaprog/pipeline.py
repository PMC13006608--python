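"""End-to-end orchestration: simulate -> score text -> composite AIS ->
screen -> select features -> model -> report.

A single :class:`RunConfig` drives all stages.  The global seed fans out to
per-stage seeds through a fixed rule (``stage_seed = (seed * 1009 + stage
index) mod 2^31``) so each stage is independently reproducible.  Every run
writes a manifest with the config hash, per-stage output file hashes,
elapsed wall-clock and the effective seeds; re-running an identical config
reproduces identical hashes for the deterministic stages.  The manifest is
written even when a stage fails, with a structured error naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    feature_screening as fs,
    injury_composite as ic,
    preprocess_screen as ps,
    prognostic_models as pm,
    synthetic_cohort as sc,
    text_scoring as ts,
)

STAGES = ["simulate", "score_text", "composite", "screen", "select", "model",
          "report"]

DEFAULT_EXCLUSIONS = ["rescue_count", "surgery"]

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "encode_features"]


@dataclass
class RunConfig:
    outdir: str = "run_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    cohort: dict = field(default_factory=dict)
    optimize_text_weights: bool = True
    ga_population: int = 60
    ga_generations: int = 100
    alpha: float = 0.05
    exclusions: list[str] = field(default_factory=lambda: list(DEFAULT_EXCLUSIONS))
    importance_threshold: float = 0.05
    rebalance_method: str = "smote_enn"
    bench_models: tuple[str, ...] = ("l2_logistic", "rf", "xgb", "lgbm")
    inner_tuner: str = "ga"
    tuner_population: int = 6
    tuner_generations: int = 2
    n_boot_ci: int = 200
    nomogram_bootstrap: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bench_models" in data:
            data["bench_models"] = tuple(data["bench_models"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["bench_models"] = list(self.bench_models)
        return d

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGES.index(stage)) % (2**31)


@dataclass
class RunManifest:
    config_hash: str
    stages: list[dict] = field(default_factory=list)
    error: dict | None = None

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "stages": self.stages,
                "error": self.error}

    def fingerprint(self) -> dict:
        """Deterministic view of the manifest: config hash plus per-stage
        output hashes and seeds (wall-clock timings excluded)."""
        return {
            "config_hash": self.config_hash,
            "stages": [
                {"stage": s["stage"], "seed": s["seed"], "outputs": s["outputs"]}
                for s in self.stages
            ],
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return _hash_bytes(path.read_bytes())


def encode_features(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic numeric encoding of non-numeric feature columns.

    Binary and ordered categorical levels map to integer codes in the
    library's canonical level order (e.g. no/yes -> 0/1,
    no/yes/coma -> 0/1/2); unknown categoricals use sorted-level codes.
    """
    known_orders = {
        tuple(spec.levels)
        for spec in sc.default_feature_specs()
        if spec.kind == "categorical"
    }
    level_maps = {lv: {name: i for i, name in enumerate(lv)} for lv in known_orders}
    out = df.copy()
    for name in out.columns:
        col = out[name]
        if pd.api.types.is_numeric_dtype(col):
            continue
        levels = tuple(v for v in col.dropna().unique())
        mapping = None
        for order, m in level_maps.items():
            if set(levels) <= set(order):
                mapping = m
                break
        if mapping is None:
            mapping = {v: i for i, v in enumerate(sorted(levels))}
        out[name] = col.map(mapping).astype(float)
    return out


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write the run manifest.

    Stage outputs land under ``config.outdir``.  Any stage exception halts
    the run with a :class:`StageError`; the manifest (including the error
    record) is still written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashed_cfg = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    config_blob = json.dumps(hashed_cfg, sort_keys=True).encode()
    manifest = RunManifest(config_hash=_hash_bytes(config_blob))
    (outdir / "run_config.yaml").write_text(
        yaml.safe_dump(config.to_dict()), encoding="utf-8"
    )

    state: dict = {}

    def record(stage: str, outputs: list[Path], t0: float, seed: int | None,
               extra: dict | None = None) -> None:
        manifest.stages.append(
            {
                "stage": stage,
                "seed": seed,
                "elapsed_s": round(time.perf_counter() - t0, 3),
                "outputs": {p.name: _hash_file(p) for p in outputs},
                **(extra or {}),
            }
        )

    def _load_cohort() -> pd.DataFrame:
        if "cohort" in state:
            return state["cohort"]
        path = outdir / "cohort.csv"
        if not path.exists():
            raise FileNotFoundError(
                "cohort.csv missing: run the simulate stage or provide one"
            )
        state["cohort"] = pd.read_csv(path)
        return state["cohort"]

    def stage_simulate(seed: int) -> list[Path]:
        spec = sc.CohortSpec(**{"seed": seed, **config.cohort})
        records = sc.generate_cohort(spec)
        path = sc.write_cohort(records, spec, outdir / "cohort.csv")
        state["cohort"] = sc.cohort_to_frame(records)
        return [path, path.with_suffix(".spec.json")]

    def stage_score_text(seed: int) -> list[Path]:
        df = _load_cohort().copy()
        libraries = ts.default_libraries()
        weights_out = {}
        for cat, col in (("primary", "primary_dx_text"),
                         ("other", "other_dx_text")):
            lib = libraries[cat]
            counts = ts.count_matrix(df[col].fillna(""), lib)
            if config.optimize_text_weights:
                sol = ts.optimize_weights(
                    counts,
                    ts.GAConfig(population=config.ga_population,
                                generations=config.ga_generations, seed=seed),
                )
                weights = sol.weights
                weights_out[cat] = {
                    "weights": dict(zip(lib.module_names, weights.tolist())),
                    "objective": sol.objective,
                    "degenerate": sol.degenerate,
                }
            else:
                weights = lib.weights
                weights_out[cat] = {
                    "weights": dict(zip(lib.module_names, weights.tolist())),
                    "objective": ts.variance_objective(
                        ts.score_series(counts, weights)
                    ),
                }
            df[f"{cat}_dx_score"] = ts.score_series(counts, weights)
        path = outdir / "scored.csv"
        df.to_csv(path, index=False)
        wpath = outdir / "text_weights.json"
        wpath.write_text(json.dumps(weights_out, indent=2), encoding="utf-8")
        state["cohort"] = df
        return [path, wpath]

    def stage_composite(seed: int) -> list[Path]:
        df = _load_cohort().copy()
        ais = df[[f"ais_{r}" for r in ic.REGIONS]].to_numpy(dtype=float)
        critic = ic.critic_weights(ais)
        df["ais_weighted"] = ic.weighted_composite(ais, critic.weights)
        df["ais_equal"] = ic.equal_weight_composite(ais)
        df["iss"] = ic.iss_score(ais)
        y = sc.dichotomize_outcome(df["outcome"])
        comparison = ic.compare_schemes(ais, y, critic)
        path = outdir / "scored.csv"
        df.to_csv(path, index=False)
        cpath = outdir / "scheme_comparison.json"
        payload = {
            "critic_table": critic.to_frame().to_dict(),
            "schemes": {
                name: {"auc": d["auc"], "hl_stat": d["hl_stat"], "hl_p": d["hl_p"]}
                for name, d in comparison.schemes.items()
            },
        }
        cpath.write_text(json.dumps(payload, indent=2), encoding="utf-8")
        state["cohort"] = df
        return [path, cpath]

    _NON_FEATURES = {"patient_id", "primary_dx_text", "other_dx_text", "outcome"}

    def stage_screen(seed: int) -> list[Path]:
        df = _load_cohort()
        feats = df[[c for c in df.columns if c not in _NON_FEATURES]]
        audit = ps.impute_select(feats, seed=seed)
        rows = ps.univariate_screen(audit.imputed, df["outcome"],
                                    alpha=config.alpha)
        retained = ps.timeliness_filter(rows, config.exclusions)
        report = ps.univariate_report(rows)
        rpath = outdir / "univariate_report.csv"
        report.to_csv(rpath, index=False)
        spath = outdir / "screen_state.json"
        spath.write_text(
            json.dumps(
                {
                    "imputation": {"chosen": audit.chosen,
                                   "change_scores": audit.change_scores},
                    "significant": [r.feature for r in rows if r.significant],
                    "retained": retained,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        state["imputed"] = audit.imputed
        state["retained"] = retained
        return [rpath, spath]

    def stage_select(seed: int) -> list[Path]:
        df = _load_cohort()
        imputed = state.get("imputed")
        retained = state.get("retained")
        if imputed is None or retained is None:
            raise RuntimeError("select stage requires the screen stage outputs")
        X = encode_features(imputed[retained])
        y = sc.dichotomize_outcome(df["outcome"])
        Xr, yr, resample = fs.rebalance(
            X.to_numpy(dtype=float), y, method=config.rebalance_method, seed=seed
        )
        Xr = pd.DataFrame(Xr, columns=X.columns)
        screen = fs.importance_screen(
            Xr, yr, threshold=config.importance_threshold, seed=seed
        )
        sets = fs.build_candidate_sets(screen.retained["rf"],
                                       screen.retained["xgb"])
        fs.check_epv(len(sets.union), int(np.sum(y == 1)))
        table = fs.evaluate_candidate_sets(sets, Xr, yr, seed=seed)
        booster = fs.xgb.XGBClassifier(
            n_estimators=200, max_depth=6, learning_rate=0.05,
            random_state=seed, verbosity=0, eval_metric="logloss",
        ).fit(Xr[sets.union].to_numpy(dtype=float), yr)
        shap = fs.shap_summary(booster, Xr[sets.union])
        spath = outdir / "screening_report.json"
        spath.write_text(
            json.dumps(
                {
                    "resample": {
                        "method": resample.method,
                        "counts_before": resample.counts_before,
                        "counts_after": resample.counts_after,
                        "ratio_after": resample.ratio_after,
                    },
                    "importances": {k: v.to_dict()
                                    for k, v in screen.importances.items()},
                    "sets": sets.as_dict(),
                    "evaluation": table.to_dict(orient="records"),
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        hpath = outdir / "shap_summary.csv"
        shap.table.to_csv(hpath)
        state["sets"] = sets
        state["X_model"] = X
        state["y_binary"] = y
        return [spath, hpath]

    def stage_model(seed: int) -> list[Path]:
        df = _load_cohort()
        sets = state.get("sets")
        X = state.get("X_model")
        y = state.get("y_binary")
        if sets is None:
            raise RuntimeError("model stage requires the select stage outputs")
        features = sets.intersection or sets.union
        fit = pm.stepwise_logistic(X[features], y)
        tpath = outdir / "stepwise_table.csv"
        fit.table.to_csv(tpath)
        nomo = pm.build_nomogram(
            fit, X, y, n_bootstrap=config.nomogram_bootstrap, seed=seed
        )
        npath = outdir / "nomogram.json"
        npath.write_text(
            json.dumps(
                {
                    "variables": fit.retained,
                    "point_tables": {v: t.to_dict(orient="list")
                                     for v, t in nomo.point_tables.items()},
                    "c_index": nomo.c_index,
                    "c_index_ci": list(nomo.c_index_ci),
                    "calibration_mae": nomo.calibration_mae,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        bench_cfg = pm.BenchConfig(
            models=config.bench_models,
            task="binary",
            inner_tuner=config.inner_tuner,
            ga_population=config.tuner_population,
            ga_generations=config.tuner_generations,
            rebalance_method=config.rebalance_method,
            n_boot_ci=config.n_boot_ci,
            seed=seed,
        )
        bench = pm.run_benchmark(X[sets.union], y, bench_cfg)
        y3 = df["outcome"].map({"cure": 0, "improved": 1, "poor": 2}).to_numpy()
        bench3 = pm.run_benchmark(
            X[sets.union],
            y3,
            pm.BenchConfig(
                models=tuple(m for m in config.bench_models
                             if m != "l1_logistic"),
                task="multiclass",
                inner_tuner=config.inner_tuner,
                ga_population=config.tuner_population,
                ga_generations=config.tuner_generations,
                n_boot_ci=config.n_boot_ci,
                seed=seed,
            ),
        )
        bpath = outdir / "benchmark_report.json"

        def serialize(b: dict) -> dict:
            return {
                "models": b["models"],
                "skipped": b["skipped"],
                "overfit_gap": b["overfit_gap"].to_dict(orient="index"),
                "fold_fingerprints": b["fold_fingerprints"],
            }

        bpath.write_text(
            json.dumps({"binary": serialize(bench),
                        "multiclass": serialize(bench3)}, indent=2),
            encoding="utf-8",
        )
        state["benchmark"] = bench
        return [tpath, npath, bpath]

    def stage_report(seed: int) -> list[Path]:
        path = outdir / "summary.json"
        summary = {
            "stages_run": [s["stage"] for s in manifest.stages] + ["report"],
            "n_patients": int(len(state["cohort"])) if "cohort" in state else None,
        }
        path.write_text(json.dumps(summary, indent=2), encoding="utf-8")
        return [path]

    runners = {
        "simulate": stage_simulate,
        "score_text": stage_score_text,
        "composite": stage_composite,
        "screen": stage_screen,
        "select": stage_select,
        "model": stage_model,
        "report": stage_report,
    }

    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            seed = config.stage_seed(stage)
            t0 = time.perf_counter()
            try:
                outputs = runners[stage](seed)
            except Exception as exc:  # noqa: BLE001 - wrapped and re-raised
                manifest.error = {"stage": stage, "message": str(exc)}
                raise StageError(stage, exc) from exc
            record(stage, outputs, t0, seed)
    finally:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2), encoding="utf-8"
        )
    return manifest
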