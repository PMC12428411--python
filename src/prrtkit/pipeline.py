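"""End-to-end pipeline: generate -> bench -> importance -> validate -> report.

One seeded entry point chains the full analysis and writes every interface
artifact (cohort CSVs, bench grids, PI records, FI rankings, consensus list,
validation results, a JSON manifest and a human-readable report).  Two scale
presets exist: ``desk`` (the tested default: 10 splits, 10 permutations,
SMOTE on, 100 trees) and ``full`` (100 splits, 100 permutations, both SMOTE
arms, 500 trees — hours-scale).
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bench import BenchResult, default_grid, run_bench
from .cohort import CohortError, CohortTable, enumerate_group_subsets, write_cohort
from .importance import FIRanking, consensus, rank_features
from .synth import GeneratorConfig, generate_cohort
from .validation import results_frame, validate_features

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort"]


@dataclass
class PipelineConfig:
    """Every stage's knobs plus the global seed and scale preset."""

    seed: int = 0
    scale: str = "desk"  # "desk" | "full"
    out_dir: str = "prrtkit_run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # bench
    learners: tuple[str, ...] = ("bagged_trees", "boosted_trees")
    smote_options: tuple[bool, ...] = (True,)
    targets: tuple[str, ...] = ("krenning_bin", "pro_prrt_lesion", "pro_prrt_patient")
    subsets: tuple[tuple[str, ...], ...] | None = None  # None -> all 15
    n_splits: int = 10
    train_frac: float = 0.8
    smote_k: int = 5
    n_trees: int = 100
    include_linear_baseline: bool = True
    # importance
    n_perm: int = 10
    fraction: float = 0.10
    eps: float = 1e-6
    #: targets whose fitted models feed the FI ranking; the bench F1 surface
    #: always covers all of ``targets``
    importance_targets: tuple[str, ...] = ("pro_prrt_lesion", "pro_prrt_patient")
    # validation
    alpha: float = 0.05
    cutoffs: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.scale not in ("desk", "full"):
            raise CohortError(f"unknown scale preset {self.scale!r}")
        if self.scale == "desk" and (self.n_splits > 20 or self.n_perm > 20):
            raise CohortError("desk preset bounds n_splits <= 20 and n_perm <= 20")
        self.generator.validate()

    @classmethod
    def preset(cls, scale: str = "desk", seed: int = 0, **overrides) -> "PipelineConfig":
        if scale == "desk":
            cfg = cls(seed=seed, scale="desk")
        elif scale == "full":
            cfg = cls(
                seed=seed,
                scale="full",
                smote_options=(True, False),
                n_splits=100,
                n_perm=100,
                n_trees=500,
                importance_targets=(
                    "krenning_bin", "pro_prrt_lesion", "pro_prrt_patient"
                ),
            )
        else:
            raise CohortError(f"unknown scale preset {scale!r}")
        for key, val in overrides.items():
            if not hasattr(cfg, key):
                raise CohortError(f"unknown pipeline option {key!r}")
            setattr(cfg, key, val)
        cfg.generator = dataclasses.replace(cfg.generator, seed=seed)
        cfg.validate()
        return cfg

    # -- (de)serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["effects"] = [
            {"name": e.name, "effect": e.effect, "level": e.level}
            for e in self.generator.effects
        ]
        d["generator"]["thresholds"] = dataclasses.asdict(self.generator.thresholds)
        # YAML-safe: sequences as plain lists
        for key in ("learners", "smote_options", "targets", "importance_targets"):
            d[key] = list(d[key])
        if d["subsets"] is not None:
            d["subsets"] = [list(s) for s in d["subsets"]]
        for key in ("origin_probs", "nec_given_origin", "grade_probs"):
            d["generator"][key] = list(d["generator"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .cohort import KrenningThresholds
        from .synth import EffectSpec

        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "effects" in gen:
            gen["effects"] = tuple(EffectSpec(**e) for e in gen["effects"])
        if "thresholds" in gen:
            gen["thresholds"] = KrenningThresholds(**gen["thresholds"])
        for key in ("origin_probs", "nec_given_origin", "grade_probs"):
            if key in gen:
                gen[key] = tuple(gen[key])
        cfg = cls(generator=GeneratorConfig(**gen))
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise CohortError(f"unknown pipeline option {key!r}")
            if key in ("learners", "smote_options", "targets", "importance_targets"):
                val = tuple(val)
            if key == "subsets" and val is not None:
                val = tuple(tuple(s) for s in val)
            setattr(cfg, key, val)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def summarize_cohort(cohort: CohortTable) -> dict:
    """Descriptive counts: patients, lesions, Krenning bins, sites, origins."""
    k = cohort.lesions["krenning"]
    origins = {}
    for col in ("origin_gi", "origin_pancreas", "origin_lung", "origin_unknown",
                "origin_other", "nec"):
        if col in cohort.patients.columns:
            origins[col] = int(cohort.patients[col].fillna(0).sum())
    return {
        "n_patients": int(len(cohort.patients)),
        "n_lesions": int(len(cohort.lesions)),
        "patients_eligible": int(cohort.patients["eligible"].sum()),
        "patients_not_eligible": int((~cohort.patients["eligible"].astype(bool)).sum()),
        "krenning_0_1": int((k <= 1).sum()),
        "krenning_2": int((k == 2).sum()),
        "krenning_3_4": int((k >= 3).sum()),
        "lesions_per_site": {
            s: int(n) for s, n in cohort.lesions["site"].value_counts().items()
        },
        "patients_per_origin": origins,
    }


def _truth_payload(config: PipelineConfig) -> dict:
    return {
        "seed": config.seed,
        "baseline_log_uptake": config.generator.baseline_log_uptake,
        "planted_effects": [
            {"name": e.name, "effect": e.effect, "level": e.level}
            for e in config.generator.effects
        ],
    }


def run_pipeline(config: PipelineConfig, cohort: CohortTable | None = None) -> dict:
    """Execute all stages in order and write every artifact under ``out_dir``.

    Fully deterministic given the global seed.  Returns a bundle with the
    cohort, bench result, rankings, consensus frame, validation results and
    the manifest.  A stage failure aborts with the stage named; artifacts
    written so far are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "prrtkit",
        "version": __version__,
        "seed": config.seed,
        "scale": config.scale,
        "config": config.to_dict(),
        "timings_s": {},
        "warnings": [],
    }
    stage = "generate"
    try:
        t0 = time.perf_counter()
        if cohort is None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            cohort = generate_cohort(gen)
        write_cohort(cohort, out)
        (out / "truth.json").write_text(json.dumps(_truth_payload(config), indent=1))
        manifest["cohort_summary"] = summarize_cohort(cohort)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 2)

        stage = "bench"
        t0 = time.perf_counter()
        subsets = config.subsets or tuple(enumerate_group_subsets())
        grid = default_grid(
            learners=config.learners,
            smote_options=config.smote_options,
            targets=config.targets,
            subsets=subsets,
            n_splits=config.n_splits,
            train_frac=config.train_frac,
            smote_k=config.smote_k,
            seed=config.seed,
            n_trees=config.n_trees,
        )
        if config.include_linear_baseline:
            grid += default_grid(
                learners=("linear",),
                smote_options=(False,),
                targets=config.targets,
                subsets=(tuple(sorted({g for s in subsets for g in s})),),
                n_splits=config.n_splits,
                train_frac=config.train_frac,
                seed=config.seed,
            )
        # models are kept only where the importance stage needs them
        keep = [c for c in grid
                if c.target in config.importance_targets and c.learner != "linear"]
        rest = [c for c in grid if c not in keep]
        bench = run_bench(cohort, keep, keep_models=True)
        if rest:
            bench_rest = run_bench(cohort, rest, keep_models=False)
            bench = BenchResult(
                records=pd.concat(
                    [bench.records, bench_rest.records], ignore_index=True
                ),
                cells=bench.cells,
            )
        bench.records.drop(columns=["error"]).to_csv(out / "bench_results.csv", index=False)
        bench.summary().to_csv(out / "bench_summary.csv", index=False)
        n_failed = int(bench.records["failed"].sum())
        if n_failed:
            manifest["warnings"].append(f"{n_failed} bench cell(s) failed and were excluded")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 2)

        stage = "importance"
        t0 = time.perf_counter()
        rankings: dict[str, FIRanking] = {}
        for level in ("lesion", "patient"):
            if not any(c.config.level == level and c.config.learner != "linear"
                       for c in bench.cells):
                continue
            frame = (
                cohort.lesion_analysis_frame()[cohort.feature_names(level="lesion")]
                if level == "lesion"
                else cohort.patients[cohort.feature_names(level="patient")]
            )
            ranking, pi_table, triangle = rank_features(
                bench,
                level,
                feature_frame=frame,
                n_perm=config.n_perm,
                fraction=config.fraction,
                eps=config.eps,
                seed=config.seed,
            )
            rankings[level] = ranking
            pi_table.to_csv(out / f"pi_records_{level}.csv", index=False)
            ranking.table.to_csv(out / f"fi_ranking_{level}.csv", index=False)
            if triangle is not None:
                triangle.to_csv(out / f"correlation_triangle_{level}.csv")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 2)

        stage = "consensus"
        if set(rankings) != {"lesion", "patient"}:
            raise CohortError("both analysis levels are required for a consensus")
        cons = consensus(rankings["lesion"], rankings["patient"])
        cons.to_csv(out / "consensus.csv", index=False)

        stage = "validate"
        t0 = time.perf_counter()
        union = sorted(set(rankings["lesion"].selected) | set(rankings["patient"].selected))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            results = validate_features(union, cohort, cutoffs=config.cutoffs or None)
        manifest["warnings"].extend(str(w.message) for w in caught)
        vframe = results_frame(results)
        if len(vframe):
            vframe["consensus"] = vframe["feature"].isin(set(cons["feature"]))
        vframe.to_csv(out / "validation_results.csv", index=False)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 2)

        stage = "report"
        manifest["consensus_features"] = cons["feature"].tolist()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (out / "report.md").write_text(_render_report(manifest, bench, cons, vframe))
    except Exception as exc:
        raise CohortError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {
        "cohort": cohort,
        "bench": bench,
        "rankings": rankings,
        "consensus": cons,
        "validation": results,
        "manifest": manifest,
        "out_dir": out,
    }


def _render_report(
    manifest: dict, bench: BenchResult, cons: pd.DataFrame, vframe: pd.DataFrame
) -> str:
    s = manifest["cohort_summary"]
    summary = bench.summary().sort_values("mean_f1", ascending=False)
    lines = [
        "# prrtkit run report",
        "",
        f"seed: {manifest['seed']}  scale: {manifest['scale']}  version: {manifest['version']}",
        "",
        "## Cohort",
        f"- patients: {s['n_patients']} "
        f"(eligible {s['patients_eligible']} / not {s['patients_not_eligible']})",
        f"- lesions: {s['n_lesions']} "
        f"(Krenning 0-1: {s['krenning_0_1']}, 2: {s['krenning_2']}, "
        f"3-4: {s['krenning_3_4']})",
        "",
        "## Bench (top configurations by mean F1)",
    ]
    for _, row in summary.head(8).iterrows():
        lines.append(
            f"- {row['config_id']}: mean F1 = {row['mean_f1']:.3f} "
            f"(sd {0.0 if pd.isna(row['sd_f1']) else row['sd_f1']:.3f}, "
            f"{int(row['n_splits'])} splits)"
        )
    lines += ["", "## Consensus features (selected at both levels)"]
    if len(cons) == 0:
        lines.append("- (none)")
    for _, row in cons.iterrows():
        sub = vframe[vframe["feature"] == row["feature"]] if len(vframe) else pd.DataFrame()
        ps = "; ".join(
            f"{r['level']} {r['test']} p={r['p_value']:.3g}" for _, r in sub.iterrows()
        )
        lines.append(f"- {row['feature']} (FI mean {row['fi_mean']:.3f}) {ps}")
    if manifest["warnings"]:
        lines += ["", "## Warnings"] + [f"- {w}" for w in manifest["warnings"]]
    return "\n".join(lines) + "\n"
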