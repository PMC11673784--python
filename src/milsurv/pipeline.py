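"""End-to-end runner: simulate -> cluster -> train -> stratify -> evaluate
-> heatmap, with per-stage caching and a reproducibility manifest.

Cohort roles are explicit: the training cohort fits the phenotype
clustering, the MIL network and the risk cut-point; the validation cohort
only ever receives the frozen clustering, model and threshold (external-
validation discipline). Every stage draws its seed deterministically from
the single global seed, and the manifest records per-stage parameter
hashes and output checksums, so identical configs reproduce identical
manifests and any stage can be re-executed in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic, features as feat, model as milmodel, stratify as strat
from . import survival as surv
from .heatmap import tile_attention, render_heatmap

logger = logging.getLogger("milsurv.pipeline")

STAGES = ("simulate", "cluster", "train", "stratify", "evaluate", "heatmap")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage parameters plus the single global seed."""

    seed: int = 0
    outcome: str = "pfs"
    tile_size: int = 402
    max_white: float = 2 / 3
    synthetic: dict = field(default_factory=lambda: {
        "n_train": 150, "n_validation": 150, "K_true": 10, "d": 16,
        "bag_size_range": (100, 300), "effect": 2.0,
        "clinical_effects": {"node": 0.693}, "censor_rate": 0.3,
        "baseline": (1.3, 20.0)})
    cluster: dict = field(default_factory=lambda: {"k": 10})
    model: dict = field(default_factory=lambda: {
        "embed_dims": (64, 32), "attention_dim": 32, "learning_rate": 1e-2,
        "folds": 5, "epoch_grid": tuple(range(10, 81, 10)),
        "test_fraction": 0.2})
    stratify: dict = field(default_factory=lambda: {
        "min_prop": 0.1, "max_prop": 0.9, "n_perm": 1000})
    heatmap: dict = field(default_factory=lambda: {"downsample": 50})

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([int(self.seed), idx])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    summary: dict


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    """Content checksum; .npz files are hashed by member arrays so that
    zip timestamps do not break reproducibility."""
    h = hashlib.sha256()
    if path.suffix == ".npz":
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                h.update(name.encode())
                h.update(zf.read(name))
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _stage_done(manifest: dict, stage: str, stage_hash: str, outdir: Path) -> bool:
    info = manifest.get("stages", {}).get(stage)
    if not info or info["hash"] != stage_hash:
        return False
    for rel, digest in info["outputs"].items():
        p = outdir / rel
        if not p.exists() or _checksum(p) != digest:
            return False
    return True


def _record_stage(manifest: dict, stage: str, stage_hash: str,
                  outdir: Path, outputs: list[Path]) -> None:
    manifest.setdefault("stages", {})[stage] = {
        "hash": stage_hash,
        "outputs": {str(p.relative_to(outdir)): _checksum(p) for p in outputs},
    }


# ---------------------------------------------------------------------------
# the runner
# ---------------------------------------------------------------------------

def _build_cohort(cfg: dict, n: int, seed: int, prefix: str) -> synthetic.SyntheticCohort:
    K = cfg["K_true"]
    beta = synthetic.phenotype_effect_pattern(K, cfg["effect"])
    return synthetic.generate_cohort(
        n_patients=n, K_true=K, d=cfg["d"],
        bag_size_range=tuple(cfg["bag_size_range"]),
        beta_phenotype=beta, clinical_effects=cfg.get("clinical_effects"),
        baseline=tuple(cfg["baseline"]), censor_rate=cfg["censor_rate"],
        seed=seed, prefix=prefix)


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute all stages under ``outdir``; cached stages are skipped.

    A stage is skipped when its parameter hash matches the stored manifest
    and all its outputs still exist with matching checksums; its artifacts
    are then reloaded from disk. Any failure raises :class:`StageError`
    naming the stage; earlier outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    manifest["config"] = asdict(config)
    manifest["seed"] = config.seed
    config.to_json(outdir / "config.json")

    state: dict = {}
    hashes: dict[str, str] = {}

    def run_stage(stage, params, fn):
        hashes[stage] = _hash_obj({"params": params, "seed": config.seed,
                                   "upstream": [hashes[s] for s in STAGES
                                                if s in hashes]})
        sdir = outdir / stage
        sdir.mkdir(exist_ok=True)
        if _stage_done(manifest, stage, hashes[stage], outdir):
            logger.info("stage %s: cached, loading artifacts", stage)
            fn(sdir, load_only=True)
            return
        logger.info("stage %s: running (seed=%d, params=%s)",
                    stage, config.stage_seed(stage), params)
        try:
            outputs = fn(sdir, load_only=False)
        except Exception as err:
            raise StageError(stage, err) from err
        _record_stage(manifest, stage, hashes[stage], outdir, outputs)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # -- simulate -----------------------------------------------------------
    def stage_simulate(sdir: Path, load_only: bool):
        if load_only:
            state["train"] = synthetic.load_cohort(sdir / "train")
            state["validation"] = synthetic.load_cohort(sdir / "validation")
            return
        seed = config.stage_seed("simulate")
        cfg = config.synthetic
        state["train"] = _build_cohort(cfg, cfg["n_train"], seed, "TR")
        state["validation"] = _build_cohort(cfg, cfg["n_validation"],
                                            seed + 1, "VA")
        paths = []
        for role in ("train", "validation"):
            paths += synthetic.write_cohort(state[role], sdir / role).values()
        return list(paths)

    run_stage("simulate", {"synthetic": config.synthetic}, stage_simulate)

    # -- cluster ------------------------------------------------------------
    def stage_cluster(sdir: Path, load_only: bool):
        if load_only:
            state["clustering"] = feat.PhenotypeClustering.from_json(
                sdir / "clustering.json")
        else:
            X = np.concatenate([state["train"].features[p]
                                for p in state["train"].patients])
            _, clustering = feat.cluster_phenotypes(
                X, k=config.cluster["k"], seed=config.stage_seed("cluster"))
            clustering.to_json(sdir / "clustering.json")
            state["clustering"] = clustering
        state["bags_train"] = feat.bags_from_cohort(state["train"],
                                                    state["clustering"])
        state["bags_validation"] = feat.bags_from_cohort(state["validation"],
                                                         state["clustering"])
        if not load_only:
            return [sdir / "clustering.json"]

    run_stage("cluster", {"cluster": config.cluster}, stage_cluster)

    # -- train --------------------------------------------------------------
    def stage_train(sdir: Path, load_only: bool):
        if load_only:
            state["model"] = milmodel.MILEnsemble.load(sdir / "checkpoint")
        else:
            mcfg = config.model
            tr = state["train"]
            base = milmodel.ModelConfig(
                k=config.cluster["k"], d=config.synthetic["d"],
                embed_dims=tuple(mcfg["embed_dims"]),
                attention_dim=mcfg["attention_dim"],
                learning_rate=mcfg["learning_rate"],
                weight_decay=mcfg.get("weight_decay", 1e-3),
                instance_jitter=mcfg.get("instance_jitter", 1.0),
                seed=config.stage_seed("train"))
            cv = milmodel.cross_validate(
                state["bags_train"], tr.times, tr.events, [base],
                folds=mcfg["folds"], epoch_grid=tuple(mcfg["epoch_grid"]),
                seed=config.stage_seed("train"),
                test_fraction=mcfg["test_fraction"])
            cv.metrics.to_csv(sdir / "cv_metrics.csv", index=False)
            # final estimator: ensemble at the CV-selected epoch count,
            # fit on the train+validation portion (test portion untouched)
            dev = cv.train_indices
            ensemble = milmodel.train_ensemble(
                [state["bags_train"][i] for i in dev],
                tr.times[dev], tr.events[dev], cv.best_config,
                n_members=mcfg.get("n_members", 3))
            if cv.test_indices.size:
                from .survival import concordance_index
                risks = ensemble.predict_many(
                    [state["bags_train"][i] for i in cv.test_indices])
                test_c = concordance_index(risks, tr.times[cv.test_indices],
                                           tr.events[cv.test_indices])
            else:
                test_c = float("nan")
            (sdir / "selection.json").write_text(json.dumps({
                "best_epochs": cv.best_epochs,
                "internal_test_concordance": test_c}, indent=2))
            ensemble.save(sdir / "checkpoint")
            state["model"] = ensemble
        for role in ("train", "validation"):
            frame = state["model"].risk_frame(state[f"bags_{role}"])
            if not load_only:
                frame.to_csv(sdir / f"risks_{role}.csv", index=False)
            state[f"risks_{role}"] = frame
        if not load_only:
            outs = [sdir / "cv_metrics.csv", sdir / "selection.json",
                    sdir / "checkpoint.json",
                    sdir / "risks_train.csv", sdir / "risks_validation.csv"]
            for i in range(len(state["model"].members)):
                outs += [sdir / f"checkpoint_member{i}.npz",
                         sdir / f"checkpoint_member{i}.json"]
            return outs

    run_stage("train", {"model": config.model}, stage_train)

    # -- stratify ------------------------------------------------------------
    def stage_stratify(sdir: Path, load_only: bool):
        tr = state["train"]
        scores = state["risks_train"]["risk"].to_numpy()
        if load_only:
            info = json.loads((sdir / "cutpoint.json").read_text())
            state["cutpoint"] = info["cutpoint"]
            state["maxstat_p"] = info["p_value"]
        else:
            scfg = config.stratify
            res = strat.maxstat_cutpoint(
                scores, tr.times, tr.events, min_prop=scfg["min_prop"],
                max_prop=scfg["max_prop"], n_perm=scfg["n_perm"],
                seed=config.stage_seed("stratify"))
            (sdir / "cutpoint.json").write_text(json.dumps({
                "cutpoint": res.cutpoint, "statistic": res.statistic,
                "p_value": res.p_value, "p_method": res.p_method}, indent=2))
            res.candidates.to_csv(sdir / "candidates.csv", index=False)
            state["cutpoint"] = res.cutpoint
            state["maxstat_p"] = res.p_value
        for role in ("train", "validation"):
            sc = state[f"risks_{role}"]["risk"].to_numpy()
            labels = strat.transfer_threshold(state["cutpoint"], sc)
            frame = strat.stratification_frame(
                state[role].patients, sc, labels)
            state[f"groups_{role}"] = frame
            if not load_only:
                frame.to_csv(sdir / f"groups_{role}.csv", index=False)
        if not load_only:
            return [sdir / "cutpoint.json", sdir / "candidates.csv",
                    sdir / "groups_train.csv", sdir / "groups_validation.csv"]

    run_stage("stratify", {"stratify": config.stratify}, stage_stratify)

    # -- evaluate ------------------------------------------------------------
    def stage_evaluate(sdir: Path, load_only: bool):
        if load_only:
            state["summary"] = json.loads((sdir / "summary.json").read_text())
            return
        summary = {"outcome": config.outcome, "cutpoint": state["cutpoint"],
                   "train_maxstat_p": state["maxstat_p"]}
        outputs = []
        for role in ("train", "validation"):
            cohort = state[role]
            groups = state[f"groups_{role}"]["group"].to_numpy()
            records = cohort.survival_frame()
            records["ibp_group"] = groups
            records["ibp_high"] = (records["ibp_group"] == "high").astype(int)
            if len(set(groups)) > 1:
                lr = surv.logrank_test(cohort.times, cohort.events, groups)
                fit = surv.cox_fit(records, ["ibp_high"])
                s = fit.summary().iloc[0]
                summary[f"{role}_logrank_p"] = lr.p_value
                summary[f"{role}_hr_high_vs_low"] = s["HR"]
                summary[f"{role}_hr_ci"] = [s["ci_low"], s["ci_high"]]
            for grp in sorted(set(groups)):
                km = surv.kaplan_meier(cohort.times[groups == grp],
                                       cohort.events[groups == grp])
                p = sdir / f"km_{role}_{grp}.csv"
                km.table.to_csv(p, index=False)
                outputs.append(p)
                summary[f"{role}_median_{grp}"] = km.median
            clin = [c for c in cohort.clinical.columns]
            if clin and len(set(groups)) > 1:
                rep = surv.combined_model(records, clin,
                                          categorical=["ibp_group"])
                p = sdir / f"cox_table_{role}.csv"
                rep.table.to_csv(p, index=False)
                outputs.append(p)
                summary[f"{role}_lrt_p_combined_vs_clinical"] = rep.lrt.p_value
        (sdir / "summary.json").write_text(json.dumps(summary, indent=2))
        state["summary"] = summary
        return outputs + [sdir / "summary.json"]

    run_stage("evaluate", {"outcome": config.outcome}, stage_evaluate)

    # -- heatmap -------------------------------------------------------------
    def stage_heatmap(sdir: Path, load_only: bool):
        if load_only:
            return
        cohort = state["validation"]
        pid = cohort.patients[0]
        bag = state["bags_validation"][0]
        out = state["model"].predict(bag)
        X = cohort.features[pid]
        a = state["clustering"].assign(X)
        # synthetic grid layout: tiles in row-major order at tile_size pitch
        ncol = max(1, int(np.ceil(np.sqrt(X.shape[0]))))
        ts = config.tile_size
        assignments = pd.DataFrame({
            "x": (np.arange(X.shape[0]) % ncol) * ts,
            "y": (np.arange(X.shape[0]) // ncol) * ts,
            "cluster": a, "slide_id": pid})
        amap = tile_attention(out, assignments, tile_size=ts)
        png = sdir / f"heatmap_{pid}.png"
        tsv = sdir / f"heatmap_{pid}.tsv"
        render_heatmap(amap, png, tsv,
                       downsample=config.heatmap["downsample"])
        return [png, tsv]

    run_stage("heatmap", {"heatmap": config.heatmap}, stage_heatmap)

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(outdir, manifest, state.get("summary", {}))
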