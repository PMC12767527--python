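"""End-to-end orchestration on the synthetic genome.

Stages: synth -> prep -> train -> transfer -> evaluate -> attribute -> design.
Each stage reads its inputs from the output directory (so runs are
restartable), derives its RNG seed from the global seed and the stage name,
writes its outputs plus a manifest entry with content hashes, and is
skipped on re-run when its outputs already exist (unless forced).

The default problem sizes are desk-scale: a ~3.2 Mb four-chromosome genome
with 300 regions per tissue, a compact architecture, and small ensembles.
They exercise every part of the method in minutes on one CPU; the
full-size architecture and paper-scale ensembles are configuration away.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation
from .attribution import attribute, motif_contribution_table, pwm_from_consensus, scan_motifs
from .dataprep import (
    EncodedDataset,
    HOLDOUT,
    WINDOW,
    assign_folds,
    augment_and_balance,
    augment_reverse_complement,
    encode_dataset,
    sample_inaccessible_controls,
)
from .design import (
    DesignConfig,
    design_sequence,
    designs_to_frame,
    genome_kmer_set,
    novelty_screen,
    sample_seeds,
    score_designs,
    select_candidates,
)
from .genome import Genome
from .models import ArchitectureSpec, ModelEnsemble, TrainingConfig, train_ensemble
from .sequences import one_hot
from .synthetic import GroundTruth, MotifGrammar, emit_fixtures, generate_genome, plant_regulatory_landscape
from .tracks import SignalTrack

STAGES = ["synth", "prep", "train", "transfer", "evaluate", "attribute", "design"]


class DependencyError(RuntimeError):
    """An upstream stage's outputs are missing."""


class ReportError(RuntimeError):
    """The evaluation outputs needed for a report are missing."""


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    grammar: dict = field(default_factory=dict)  # MotifGrammar overrides
    n_chroms: int = 4
    chrom_length: int = 2_200_000
    n_regions_per_tissue: int = 300
    n_controls: int = 450
    n_folds: int = 20
    neg_ratio: float = 1.5
    architecture: str = "compact"  # 'compact' or 'full'
    acc_replicates: int = 1
    acc_test_folds: list[int] = field(default_factory=lambda: [1, 2])
    act_replicates: int = 1
    act_test_folds: list[int] = field(default_factory=lambda: [1])
    max_epochs: int = 32
    acc_lr: float = 0.02
    acc_patience: int = 10
    act_max_epochs: int = 20
    act_lr: float = 1e-3
    act_patience: int = 20
    min_support: int = 100
    n_random_controls: int = 400
    attribution_n_regions: int = 36
    attribution_n_refs: int = 8
    attribution_steps: int = 8
    n_decoy_pwms: int = 8
    design_n_seeds: int = 12
    design_max_iterations: int = 200
    design_target_accessibility: float = 5.0
    design_target_activity_logit: float = 12.0
    design_edit_penalty: float = 0.1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def make_grammar(self) -> MotifGrammar:
        return MotifGrammar(**self.grammar) if self.grammar else MotifGrammar()

    def make_spec(self) -> ArchitectureSpec:
        return ArchitectureSpec.compact() if self.architecture == "compact" else ArchitectureSpec()


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage RNG stream derived from the global seed by stage name."""
    return (int(global_seed) * 100_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = config.out_dir
        os.makedirs(self.out, exist_ok=True)
        self.manifest_path = os.path.join(self.out, "manifest.json")
        self.manifest = {}
        if os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
        self.manifest.setdefault("config", config.to_dict())
        self.manifest.setdefault("stages", {})

    # -- helpers -----------------------------------------------------------
    def _dir(self, *parts) -> str:
        path = os.path.join(self.out, *parts)
        os.makedirs(path, exist_ok=True)
        return path

    def _record(self, stage: str, outputs: dict[str, str], **extra) -> None:
        entry = {
            "seed": stage_seed(self.cfg.seed, stage),
            "outputs": {name: {"path": os.path.relpath(p, self.out), "sha256": _sha256(p)} for name, p in outputs.items()},
        }
        entry.update(extra)
        self.manifest["stages"][stage] = entry
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=float)

    def _done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry:
            return False
        return all(os.path.exists(os.path.join(self.out, o["path"])) for o in entry["outputs"].values())

    def _require(self, stage: str) -> None:
        if not self._done(stage):
            raise DependencyError(f"stage {stage!r} has not produced its outputs yet")

    # -- fixture access ----------------------------------------------------
    def _load_fixtures(self):
        fx = os.path.join(self.out, "fixtures")
        with open(os.path.join(fx, "holdout.txt")) as fh:
            holdout = fh.read().strip()
        genome = Genome.from_fasta(os.path.join(fx, "genome.fa"), holdout_chrom=holdout)
        truth = GroundTruth.from_json(os.path.join(fx, "truth.json"))
        tracks = {t: SignalTrack.read_bedgraph(os.path.join(fx, f"{t}.bedGraph")) for t in truth.grammar.tissues}
        return genome, truth, tracks

    # -- stages ------------------------------------------------------------
    def stage_synth(self) -> dict:
        seed = stage_seed(self.cfg.seed, "synth")
        grammar = self.cfg.make_grammar()
        genome = generate_genome(self.cfg.n_chroms, self.cfg.chrom_length, seed)
        genome, truth = plant_regulatory_landscape(genome, grammar, self.cfg.n_regions_per_tissue, seed + 1)
        paths = emit_fixtures(genome, truth, self._dir("fixtures"), seed=seed + 2)
        self._record("synth", paths, n_regions=len(truth.regions), n_instances=len(truth.planted_instances))
        return paths

    def stage_prep(self) -> dict:
        self._require("synth")
        seed = stage_seed(self.cfg.seed, "prep")
        genome, truth, tracks = self._load_fixtures()
        tissues = truth.grammar.tissues
        regions = truth.regions.copy()
        # one pool of inaccessible bins, split into training controls and a
        # disjoint reserve used later for control-rejection evaluation
        pool = sample_inaccessible_controls(
            genome, regions, self.cfg.n_controls + self.cfg.n_random_controls, seed
        )
        controls = pool.iloc[: self.cfg.n_controls].reset_index(drop=True)
        eval_controls = pool.iloc[self.cfg.n_controls :].reset_index(drop=True)
        universe = pd.concat(
            [regions[["region_id", "chrom", "start", "end"]], controls[["region_id", "chrom", "start", "end"]]],
            ignore_index=True,
        )
        folds = assign_folds(universe, n_folds=self.cfg.n_folds, holdout_chrom=genome.holdout_chrom)
        universe["fold"] = universe["region_id"].map(folds.mapping)
        universe["strand"] = "+"
        universe["source"] = np.where(universe["region_id"].str.startswith("control"), "control", "region")

        outputs = {}
        prep_dir = self._dir("prep")
        universe.to_csv(os.path.join(prep_dir, "universe.tsv"), sep="\t", index=False)
        outputs["universe"] = os.path.join(prep_dir, "universe.tsv")
        eval_controls.to_csv(os.path.join(prep_dir, "eval_controls.tsv"), sep="\t", index=False)
        outputs["eval_controls"] = os.path.join(prep_dir, "eval_controls.tsv")

        labels = {t: {rid: truth.region_labels[rid][t] for rid in truth.region_labels} for t in tissues}
        for t in tissues:
            labels[t].update({rid: 0 for rid in controls["region_id"]})

        for tissue in tissues:
            acc = encode_dataset(universe, genome, task="accessibility", signal_track=tracks[tissue])
            acc = augment_reverse_complement(acc)
            path = os.path.join(prep_dir, f"acc_{tissue}.npz")
            acc.save(path)
            outputs[f"acc_{tissue}"] = path

            act_bits = pd.Series(labels[tissue])
            pos_mask = universe["region_id"].map(act_bits).astype(float) == 1.0
            pos = encode_dataset(universe[pos_mask], genome, task="activity", activity=act_bits)
            neg = encode_dataset(universe[~pos_mask], genome, task="activity", activity=act_bits)
            act = augment_and_balance(pos, neg, neg_ratio=self.cfg.neg_ratio, seed=seed + 17)
            path = os.path.join(prep_dir, f"act_{tissue}.npz")
            act.save(path)
            outputs[f"act_{tissue}"] = path
        self._record("prep", outputs, n_universe=len(universe), n_controls=len(controls))
        return outputs

    def _load_dataset(self, name: str) -> EncodedDataset:
        return EncodedDataset.load(os.path.join(self.out, "prep", f"{name}.npz"))

    def stage_train(self) -> dict:
        self._require("prep")
        seed = stage_seed(self.cfg.seed, "train")
        _, truth, _ = self._load_fixtures()
        spec = self.cfg.make_spec()
        outputs = {}
        for i, tissue in enumerate(truth.grammar.tissues):
            data = self._load_dataset(f"acc_{tissue}")
            cfg = TrainingConfig.accessibility(
                learning_rate=self.cfg.acc_lr, patience=self.cfg.acc_patience,
                max_epochs=self.cfg.max_epochs, seed=seed + 100 * i,
            )
            ens = train_ensemble(
                spec, data, cfg, tissue, "accessibility",
                test_folds=self.cfg.acc_test_folds, replicates=self.cfg.acc_replicates,
            )
            path = self._dir("models", f"acc_{tissue}")
            ens.save(path)
            outputs[f"acc_{tissue}"] = os.path.join(path, "ensemble.json")
        self._record("train", outputs)
        return outputs

    def stage_transfer(self) -> dict:
        self._require("train")
        seed = stage_seed(self.cfg.seed, "transfer")
        _, truth, _ = self._load_fixtures()
        spec = self.cfg.make_spec()
        outputs = {}
        for i, tissue in enumerate(truth.grammar.tissues):
            data = self._load_dataset(f"act_{tissue}")
            pre = ModelEnsemble.load(os.path.join(self.out, "models", f"acc_{tissue}"))
            cfg = TrainingConfig.activity(
                learning_rate=self.cfg.act_lr, max_epochs=self.cfg.act_max_epochs,
                patience=self.cfg.act_patience, seed=seed + 100 * i,
            )
            ens = train_ensemble(
                spec, data, cfg, tissue, "activity",
                test_folds=self.cfg.act_test_folds, replicates=self.cfg.act_replicates,
                pretrained_members=pre.members,
            )
            path = self._dir("models", f"act_{tissue}")
            ens.save(path)
            outputs[f"act_{tissue}"] = os.path.join(path, "ensemble.json")

            direct = train_ensemble(
                spec, data, cfg, tissue, "activity",
                test_folds=self.cfg.act_test_folds, replicates=self.cfg.act_replicates,
                pretrained_members=None,
            )
            path = self._dir("models", f"direct_{tissue}")
            direct.save(path)
            outputs[f"direct_{tissue}"] = os.path.join(path, "ensemble.json")
        self._record("transfer", outputs)
        return outputs

    # -- evaluation --------------------------------------------------------
    def _holdout_eval_sets(self, genome, truth, tracks):
        """Center windows of holdout-chromosome regions (forward strand)."""
        regions = truth.regions[truth.regions["chrom"] == genome.holdout_chrom].reset_index(drop=True)
        X = np.stack([one_hot(genome.fetch_codes(r.chrom, r.start, r.end)) for r in regions.itertuples(index=False)])
        observed = pd.DataFrame(
            {
                t: [np.log2(tracks[t].mean(r.chrom, r.start, r.end) + 1.0) for r in regions.itertuples(index=False)]
                for t in truth.grammar.tissues
            },
            index=regions["region_id"],
        )
        labels = pd.DataFrame(
            {t: [truth.region_labels[rid][t] for rid in regions["region_id"]] for t in truth.grammar.tissues},
            index=regions["region_id"],
        )
        return regions, X, observed, labels

    def _holdout_activity_tiles(self, genome, truth):
        """Tiled holdout windows + reverse complements: the activity test set."""
        from .dataprep import GenomicInterval, tile_windows
        from .sequences import reverse_complement_one_hot

        regions = truth.regions[truth.regions["chrom"] == genome.holdout_chrom]
        mats, rids = [], []
        for r in regions.itertuples(index=False):
            for w in tile_windows(GenomicInterval(r.chrom, r.start, r.end), "vista",
                                  chrom_length=genome.length(r.chrom)):
                mat = one_hot(genome.fetch_codes(w.chrom, w.start, w.end))
                mats.append(mat)
                mats.append(reverse_complement_one_hot(mat))
                rids.extend([r.region_id] * 2)
        X = np.stack(mats)
        labels = pd.DataFrame(
            {t: [truth.region_labels[rid][t] for rid in rids] for t in truth.grammar.tissues},
            index=pd.Index(rids, name="region_id"),
        )
        return X, labels

    def stage_evaluate(self) -> dict:
        self._require("transfer")
        seed = stage_seed(self.cfg.seed, "evaluate")
        genome, truth, tracks = self._load_fixtures()
        tissues = truth.grammar.tissues
        regions, X, observed, labels = self._holdout_eval_sets(genome, truth, tracks)

        acc_ens = {t: ModelEnsemble.load(os.path.join(self.out, "models", f"acc_{t}")) for t in tissues}
        act_ens = {t: ModelEnsemble.load(os.path.join(self.out, "models", f"act_{t}")) for t in tissues}
        direct_ens = {t: ModelEnsemble.load(os.path.join(self.out, "models", f"direct_{t}")) for t in tissues}

        predicted = pd.DataFrame({t: acc_ens[t].predict(X) for t in tissues}, index=observed.index)
        reg = evaluation.regression_metrics(observed, predicted)
        km = evaluation.kmeans_clusters(observed, predicted, k=6, seed=seed)

        metrics = {"pcc": reg["pcc"], "delta_pcc": reg["delta_pcc"], "kmeans_agreement": km["agreement"],
                   "n_holdout_regions": len(regions), "ppv": {}}
        rng = np.random.default_rng(seed)
        rand_X = np.stack([one_hot(rng.integers(0, 4, WINDOW, dtype=np.uint8)) for _ in range(self.cfg.n_random_controls)])
        inacc = pd.read_csv(os.path.join(self.out, "prep", "eval_controls.tsv"), sep="\t")
        inacc_X = np.stack([one_hot(genome.fetch_codes(r.chrom, r.start, r.end)) for r in inacc.itertuples(index=False)])

        tile_X, tile_labels = self._holdout_activity_tiles(genome, truth)
        for tissue in tissues:
            y = tile_labels[tissue].to_numpy()
            transfer_scores = act_ens[tissue].predict(tile_X)
            curve = evaluation.ppv_curve(y, transfer_scores, min_support=self.cfg.min_support)
            thr = curve.max_ppv_threshold
            direct_scores = direct_ens[tissue].predict(tile_X)
            acc_scaled = evaluation.minmax_scale(acc_ens[tissue].predict(tile_X))
            rejection = evaluation.control_rejection(
                {"random": act_ens[tissue].predict(rand_X), "inaccessible": act_ens[tissue].predict(inacc_X)},
                threshold=thr,
            )
            metrics["ppv"][tissue] = {
                "transfer_max_ppv": curve.max_ppv,
                "threshold": thr,
                "direct_ppv_at_threshold": evaluation.ppv_at_threshold(y, direct_scores, thr),
                "scaled_accessibility_ppv_at_threshold": evaluation.ppv_at_threshold(y, acc_scaled, thr),
                "n_positives": int(y.sum()),
                "rejection": rejection,
            }
        path = self._dir("eval") + "/metrics.json"
        with open(path, "w") as fh:
            json.dump(metrics, fh, indent=2, default=float)
        self._record("evaluate", {"metrics": path})
        return metrics

    def stage_attribute(self) -> dict:
        self._require("transfer")
        seed = stage_seed(self.cfg.seed, "attribute")
        genome, truth, tracks = self._load_fixtures()
        tissues = truth.grammar.tissues
        regions, X, observed, labels = self._holdout_eval_sets(genome, truth, tracks)
        rng = np.random.default_rng(seed)
        # prefer motif-bearing regions so every PWM accrues instances
        order = regions.sample(frac=1.0, random_state=int(seed % 2**31)).sort_values("n_planted", ascending=False)
        chosen = order.head(self.cfg.attribution_n_regions)
        seqs = {
            r.region_id: genome.fetch(r.chrom, r.start, r.end) for r in chosen.itertuples(index=False)
        }

        acc_ens = {t: ModelEnsemble.load(os.path.join(self.out, "models", f"acc_{t}")) for t in tissues}
        act_ens = {t: ModelEnsemble.load(os.path.join(self.out, "models", f"act_{t}")) for t in tissues}
        actuals: dict[str, dict[str, dict[str, np.ndarray]]] = {"accessibility": {}, "activity": {}}
        for task, ens_map in (("accessibility", acc_ens), ("activity", act_ens)):
            for tissue in tissues:
                actuals[task][tissue] = {
                    sid: attribute(
                        ens_map[tissue], s, n_refs=self.cfg.attribution_n_refs,
                        steps=self.cfg.attribution_steps, seed=seed + 31 * i,
                    ).actual
                    for i, (sid, s) in enumerate(seqs.items())
                }

        pwms = {mid: pwm_from_consensus(cons) for mid, (cons, _) in truth.grammar.all_motifs().items()}
        for j in range(self.cfg.n_decoy_pwms):
            pwms[f"decoy_{j}"] = pwm_from_consensus("".join("ACGT"[b] for b in rng.integers(0, 4, 8)))
        instances = scan_motifs(seqs, pwms)
        table = motif_contribution_table(instances, actuals, z_min=0.0)

        out_dir = self._dir("attribution")
        table.table.to_csv(os.path.join(out_dir, "motif_table.tsv"), sep="\t")
        table.retained.to_csv(os.path.join(out_dir, "motif_clusters.tsv"), sep="\t")
        instances.to_csv(os.path.join(out_dir, "instances.tsv"), sep="\t", index=False)
        self._record(
            "attribute",
            {"motif_table": os.path.join(out_dir, "motif_table.tsv"),
             "motif_clusters": os.path.join(out_dir, "motif_clusters.tsv"),
             "instances": os.path.join(out_dir, "instances.tsv")},
            n_sequences=len(seqs), n_instances=len(instances),
        )
        return {"table": table, "instances": instances}

    def stage_design(self) -> dict:
        self._require("transfer")
        seed = stage_seed(self.cfg.seed, "design")
        genome, truth, tracks = self._load_fixtures()
        tissues = truth.grammar.tissues
        acc_ens = {t: ModelEnsemble.load(os.path.join(self.out, "models", f"acc_{t}")) for t in tissues}
        act_ens = {t: ModelEnsemble.load(os.path.join(self.out, "models", f"act_{t}")) for t in tissues}

        vista_seqs = [
            genome.fetch(r.chrom, r.start, r.end)
            for r in truth.regions.itertuples(index=False)
            if r.chrom != genome.holdout_chrom
        ][:200]
        # per-tissue selection thresholds: the logit of each classifier's
        # max-PPV operating point (its precision-first decision threshold)
        thresholds = dict(DesignConfig().selection_thresholds)
        metrics_path = os.path.join(self.out, "eval", "metrics.json")
        if os.path.exists(metrics_path):
            with open(metrics_path) as fh:
                metrics = json.load(fh)
            for t in tissues:
                p = metrics["ppv"].get(t, {}).get("threshold")
                if p is not None and np.isfinite(p):
                    p = min(max(p, 1e-6), 1 - 1e-6)
                    thresholds[t] = float(np.log(p / (1 - p)))
        dcfg = DesignConfig(
            n_seeds=self.cfg.design_n_seeds,
            edit_penalty=self.cfg.design_edit_penalty,
            target_accessibility=self.cfg.design_target_accessibility,
            target_activity_logit=self.cfg.design_target_activity_logit,
            max_iterations=self.cfg.design_max_iterations,
            selection_thresholds=thresholds,
        )
        designs = []
        for i, tissue in enumerate(tissues):
            seeds = sample_seeds(vista_seqs, n=dcfg.n_seeds, length=WINDOW, seed=seed + i)
            for j, s in enumerate(seeds):
                designs.append(
                    design_sequence(
                        s, {"accessibility": acc_ens[tissue], "activity": act_ens[tissue]},
                        dcfg, target_tissue=tissue, seed_id=f"{tissue}_{j:04d}",
                    )
                )
        score_designs(designs, act_ens)
        selected, counts = select_candidates(designs, dcfg)
        kmers = genome_kmer_set([genome], k=24)
        novelty_screen(designs, genome, k=24, kmer_set=kmers)

        frame = designs_to_frame(designs, tissues)
        out_dir = self._dir("design")
        frame.drop(columns=["sequence"]).to_csv(os.path.join(out_dir, "designs.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "designs.fa"), "w") as fh:
            for d in designs:
                fh.write(f">{d.seed_id} target={d.target_tissue} selected={d.selected}\n{d.sequence}\n")
        self._record(
            "design",
            {"designs": os.path.join(out_dir, "designs.tsv"), "fasta": os.path.join(out_dir, "designs.fa")},
            selected_counts=counts, n_designs=len(designs),
        )
        return {"designs": designs, "selected": selected, "counts": counts}

    def run(self, stages: list[str] | None = None, force: bool = False) -> dict:
        stages = stages or STAGES
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        results = {}
        for stage in STAGES:
            if stage not in stages:
                continue
            if self._done(stage) and not force:
                results[stage] = "skipped (already complete)"
                continue
            results[stage] = getattr(self, f"stage_{stage}")()
        return self.manifest


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None, force: bool = False) -> dict:
    return Pipeline(config).run(stages=stages, force=force)


def make_report(out_dir: str) -> str:
    """Human-readable summary of a completed run (markdown)."""
    metrics_path = os.path.join(out_dir, "eval", "metrics.json")
    if not os.path.exists(metrics_path):
        raise ReportError("evaluation stage has not run; no metrics to report")
    with open(metrics_path) as fh:
        metrics = json.load(fh)
    lines = ["# Pipeline report", "", "## Accessibility regression (holdout chromosome)", ""]
    lines.append("| tissue | PCC |")
    lines.append("|---|---|")
    for t, v in metrics["pcc"].items():
        lines.append(f"| {t} | {v:.3f} |")
    lines += ["", "| tissue pair | delta-PCC |", "|---|---|"]
    for p, v in metrics["delta_pcc"].items():
        lines.append(f"| {p} | {v:.3f} |")
    lines += ["", f"K-means cluster agreement (observed vs predicted): {metrics['kmeans_agreement']:.3f}", ""]
    lines += ["## Activity classification (PPV at matched thresholds)", "",
              "| tissue | transfer max PPV | direct | scaled accessibility | random rej. | inaccessible rej. |",
              "|---|---|---|---|---|---|"]
    for t, v in metrics["ppv"].items():
        lines.append(
            f"| {t} | {v['transfer_max_ppv']:.3f} | {v['direct_ppv_at_threshold']:.3f} | "
            f"{v['scaled_accessibility_ppv_at_threshold']:.3f} | {v['rejection']['random']:.3f} | "
            f"{v['rejection']['inaccessible']:.3f} |"
        )
    design_path = os.path.join(out_dir, "design", "designs.tsv")
    if os.path.exists(design_path):
        designs = pd.read_csv(design_path, sep="\t")
        lines += ["", "## Design", "",
                  f"designs: {len(designs)}; selected: {int(designs['selected'].sum())}; "
                  f"novel: {int(designs['novel'].sum())}"]
    else:
        lines += ["", "## Design", "", "(stage not run)"]
    report = "\n".join(lines) + "\n"
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(report)
    return report
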