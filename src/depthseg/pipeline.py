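"""End-to-end orchestration of the two experiments.

Experiment 1: train each family member on the unsegmented (object-in-
congruent-scene) diet, evaluate per-condition accuracy on human-matched
balanced subsets of the stimulus set, probe feature reliance with region-wise
noise and occlusion importance maps, and test condition and depth contrasts
nonparametrically.

Experiment 2: train the shallowest and deepest family members on segmented vs
unsegmented diets across seeds, record per-epoch validation accuracy, and
compare early accuracy and convergence speed between diets.

Every stochastic choice downstream traces to seeds listed in the
ExperimentConfig, so a rerun from the same config reproduces the report
tables bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .perturb import (GRAY_FILL, add_region_noise, filter_correct, layer_heatmap,
                      occlusion_sweep, region_importance)
from .scenegen import (CONDITIONS, GenConfig, Scene, StimulusSet,
                       build_stimulus_set, make_training_datasets,
                       sample_balanced_subset)
from .stats import (bh_fdr, convergence_epoch, early_mean_accuracy,
                    friedman, mann_whitney_u, wilcoxon_signed_rank)
from .zoo import (Classifier, ModelSpec, TrainingCurve, build_model,
                  default_family, default_top_k, evaluate, train)

log = logging.getLogger("depthseg")

__all__ = ["ExperimentConfig", "Report", "run_experiment1", "run_experiment2",
           "default_study_config"]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """Single source of truth for a full study.

    Training hyperparameters (SGD momentum, batch size, crop jitter) live in
    :func:`depthseg.zoo.train` defaults; everything that varies between
    studies is here.
    """

    gen: GenConfig = field(default_factory=GenConfig)
    exp2_gen: GenConfig | None = None  # None -> experiment-2 defaults from gen
    family: tuple[ModelSpec, ...] = ()
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    exp2_seeds: tuple[int, ...] = tuple(range(10))
    topk: int | None = None           # None -> top-5 iff n_classes >= 10 else top-1
    noise_sigma: float = 0.5
    patches: tuple[int, ...] = ()     # () -> (image_size // 4,)
    occl_stride: int | None = None    # None -> image_size // 16
    epochs_exp1: int = 8
    epochs_exp2: int = 16
    n_per_class: int = 24
    exp2_n_per_class: int = 40
    n_subsets: int = 10
    per_cat_per_cond: int = 3
    early_n: int = 10
    occl_max_scenes: int = 24
    lr: float = 0.05

    def resolved(self) -> "ExperimentConfig":
        cfg = self
        if cfg.exp2_gen is None:
            # the diet-comparison corpus: backgrounds weakly class-informative
            # (broadly shared scene statistics) and somewhat larger objects
            cfg = replace(cfg, exp2_gen=replace(cfg.gen, rho=0.25, object_scale=0.625))
        if not cfg.family:
            cfg = replace(cfg, family=tuple(default_family(cfg.gen.K, cfg.gen.image_size)))
        if not cfg.patches:
            cfg = replace(cfg, patches=(max(2, cfg.gen.image_size // 4),))
        if cfg.occl_stride is None:
            cfg = replace(cfg, occl_stride=max(1, cfg.gen.image_size // 16))
        if cfg.topk is None:
            cfg = replace(cfg, topk=default_top_k(cfg.gen.K))
        return cfg

    # ---- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gen"] = dataclasses.asdict(self.gen)
        d["exp2_gen"] = None if self.exp2_gen is None else dataclasses.asdict(self.exp2_gen)
        d["family"] = [dataclasses.asdict(s) for s in self.family]
        for k in ("seeds", "exp2_seeds", "patches"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["gen"] = GenConfig(**d.get("gen", {}))
        if d.get("exp2_gen") is not None:
            d["exp2_gen"] = GenConfig(**d["exp2_gen"])
        d["family"] = tuple(ModelSpec(**s) for s in d.get("family", ()))
        for k in ("seeds", "exp2_seeds", "patches"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def default_study_config(seed: int = 0) -> ExperimentConfig:
    """The desk-scale study the acceptance analyses run: 6 categories on
    32 px scenes, a 1/2/4-block family, 5 training seeds for the congruency
    and attribution analyses and 10 for the training-diet comparison."""
    base = int(seed) % 100_000
    return ExperimentConfig(
        gen=GenConfig(K=6, E=12, B=3, image_size=32, object_scale=0.5,
                      rho=0.8, seed=base),
        seeds=tuple(base + i for i in range(5)),
        exp2_seeds=tuple(base + i for i in range(10)),
    ).resolved()


def _train_seed(cfg: ExperimentConfig, run_seed: int) -> int:
    """Dataset seed for a training run: distinct from the evaluation-set seed
    so training and test exemplars carry different nuisance draws."""
    return (cfg.gen.seed + 7919 * (int(run_seed) + 1)) & 0x3FFFFFFF


# --------------------------------------------------------------------------
# report container
# --------------------------------------------------------------------------

@dataclass
class Report:
    tables: dict[str, pd.DataFrame]
    summary: dict
    provenance: dict

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump({"summary": self.summary, "provenance": self.provenance},
                      fh, indent=2, sort_keys=True, default=float)
        config = self.provenance.get("config")
        if config is not None:  # resolved-config snapshot
            with open(outdir / "config.yaml", "w") as fh:
                yaml.safe_dump(config, fh, sort_keys=True)
        return outdir


def _provenance(cfg: ExperimentConfig, experiment: str) -> dict:
    return {"experiment": experiment, "config_digest": cfg.digest(),
            "seeds": list(cfg.seeds), "exp2_seeds": list(cfg.exp2_seeds),
            "version": _pkg_version, "config": cfg.to_dict()}


# --------------------------------------------------------------------------
# experiment 1: congruency, noise, occlusion vs depth
# --------------------------------------------------------------------------

def _make_spec(cfg: ExperimentConfig, spec: ModelSpec) -> ModelSpec:
    return replace(spec, n_classes=cfg.gen.K, input_size=cfg.gen.image_size)


def _train_member(cfg: ExperimentConfig, spec: ModelSpec, seed: int,
                  diet: str, epochs: int,
                  gen: GenConfig | None = None,
                  n_per_class: int | None = None) -> tuple[Classifier, TrainingCurve]:
    gen = gen or cfg.gen
    seg, unseg = make_training_datasets(gen.K, n_per_class or cfg.n_per_class,
                                        gen, seed=_train_seed(cfg, seed))
    ds = seg if diet == "segmented" else unseg
    model = build_model(_make_spec(cfg, spec), seed)
    curve = train(model, ds.train, ds.val, epochs, seed, lr=cfg.lr, diet=diet)
    return model, curve


def _noised_set(sset: StimulusSet, region: str, sigma: float, base_seed: int) -> StimulusSet:
    scenes = [add_region_noise(sc, region, sigma, base_seed + i)
              for i, sc in enumerate(sset.scenes)]
    return StimulusSet(scenes=scenes, manifest=sset.manifest, design=sset.design)


def run_experiment1(config: ExperimentConfig) -> Report:
    cfg = config.resolved()
    cfg.gen.validate()
    log.info("experiment 1: %d specs x %d seeds", len(cfg.family), len(cfg.seeds))
    sset = build_stimulus_set(cfg.gen.K, cfg.gen.E, cfg.gen.B, cfg.gen)
    subsets = [sample_balanced_subset(sset, cfg.per_cat_per_cond, s)
               for s in range(cfg.n_subsets)]

    acc_rows, gap_rows, noise_rows, imp_rows = [], [], [], []
    for spec in cfg.family:
        for seed in cfg.seeds:
            model, _ = _train_member(cfg, spec, seed, "unsegmented", cfg.epochs_exp1)
            log.info("trained %s seed %d (%d params)", spec.name, seed, model.n_params)

            for si, sub in enumerate(subsets):
                ev = evaluate(model, sub, cfg.topk)
                for _, r in ev.per_condition.iterrows():
                    acc_rows.append({"model": spec.name, "seed": seed, "subset": si,
                                     "condition": r.condition, "n": r.n,
                                     "accuracy": r.accuracy})
                gap_rows.append({"model": spec.name, "seed": seed, "subset": si,
                                 "gap": ev.accuracy("congruent") - ev.accuracy("incongruent")})

            for region in ("none", "object", "background", "both"):
                nset = sset if region == "none" else _noised_set(
                    sset, region, cfg.noise_sigma, base_seed=cfg.gen.seed + 7 * seed)
                ev = evaluate(model, nset, cfg.topk)
                for _, r in ev.per_condition.iterrows():
                    noise_rows.append({"model": spec.name, "seed": seed,
                                       "noise_region": region, "condition": r.condition,
                                       "n": r.n, "accuracy": r.accuracy})

            cand = [sc for sc in sset.scenes if sc.condition in ("congruent", "incongruent")]
            correct, _counts = filter_correct(cand, model, cfg.topk)
            per_cond = cfg.occl_max_scenes // 2
            picked, tally = [], {"congruent": 0, "incongruent": 0}
            for sc in correct:
                if tally[sc.condition] < per_cond:
                    picked.append(sc)
                    tally[sc.condition] += 1
            for sc in picked:
                for patch in cfg.patches:
                    imap = occlusion_sweep(model, sc, patch, cfg.occl_stride, GRAY_FILL)
                    if not imap.defined:
                        continue
                    ri = region_importance(imap, sc.mask)
                    imp_rows.append({"model": spec.name, "seed": seed,
                                     "condition": sc.condition, "patch": patch,
                                     "object_importance": ri.object_importance,
                                     "background_importance": ri.background_importance})

    acc = pd.DataFrame(acc_rows)
    gaps = pd.DataFrame(gap_rows)
    noise = pd.DataFrame(noise_rows)
    imp = pd.DataFrame(imp_rows)

    # condition contrasts per member: Friedman over subsets, pairwise Wilcoxon
    stat_rows = []
    for spec in cfg.family:
        mat = (acc[acc.model == spec.name]
               .groupby(["subset", "condition"]).accuracy.mean().unstack()
               .reindex(columns=list(CONDITIONS)))
        fr = friedman(mat.to_numpy())
        stat_rows.append((f"{spec.name}:conditions", fr))
        for ca, cb in combinations(CONDITIONS, 2):
            wc = wilcoxon_signed_rank(mat[ca].to_numpy(), mat[cb].to_numpy())
            stat_rows.append((f"{spec.name}:{ca}-vs-{cb}", wc))
    # depth contrast on the congruency gap across subset replicates
    shallow, deep = cfg.family[0].name, cfg.family[-1].name
    mw = mann_whitney_u(gaps[gaps.model == shallow].gap.to_numpy(),
                        gaps[gaps.model == deep].gap.to_numpy())
    stat_rows.append((f"gap:{shallow}-vs-{deep}", mw))
    stats_df = pd.DataFrame([res.row(g) for g, res in stat_rows])
    if len(stats_df):
        stats_df["p_adj"] = bh_fdr(stats_df["p"].to_numpy())

    mean_gap = gaps.groupby("model", sort=False).gap.mean()
    mean_imp = imp.groupby("model", sort=False)[["object_importance",
                                                 "background_importance"]].mean()
    summary = {
        "mean_gap": {m: float(v) for m, v in mean_gap.items()},
        "mean_importance": {m: {k: float(v) for k, v in row.items()}
                            for m, row in mean_imp.iterrows()},
        "n_scenes": len(sset),
    }
    return Report(tables={"exp1_accuracy": acc, "exp1_gaps": gaps,
                          "exp1_noise": noise, "exp1_importance": imp,
                          "exp1_stats": stats_df},
                  summary=summary, provenance=_provenance(cfg, "exp1"))


# --------------------------------------------------------------------------
# experiment 2: segmented vs unsegmented training diets
# --------------------------------------------------------------------------

def exp2_specs(cfg: ExperimentConfig) -> tuple[ModelSpec, ModelSpec]:
    """Diet comparison runs on the shallowest and deepest family members."""
    return cfg.family[0], cfg.family[-1]


def run_experiment2(config: ExperimentConfig, outdir: str | Path | None = None) -> Report:
    cfg = config.resolved()
    cfg.gen.validate()
    specs = exp2_specs(cfg)
    log.info("experiment 2: %d specs x 2 diets x %d seeds", len(specs), len(cfg.exp2_seeds))

    curve_rows, summary_rows = [], []
    curves: dict[tuple[str, str, int], TrainingCurve] = {}
    for seed in cfg.exp2_seeds:
        for spec in specs:
            for diet in ("segmented", "unsegmented"):
                _model, curve = _train_member(cfg, spec, seed, diet, cfg.epochs_exp2,
                                              gen=cfg.exp2_gen,
                                              n_per_class=cfg.exp2_n_per_class)
                curves[(spec.name, diet, seed)] = curve
                for e, a in enumerate(curve.val_accuracy):
                    curve_rows.append({"model": spec.name, "diet": diet, "seed": seed,
                                       "epoch": e + 1, "val_accuracy": a})
                try:
                    conv = float(convergence_epoch(curve))
                except ValueError:  # curve never rose above zero
                    conv = float("nan")
                summary_rows.append({
                    "model": spec.name, "diet": diet, "seed": seed,
                    "early_mean_accuracy": early_mean_accuracy(curve, cfg.early_n),
                    "convergence_epoch": conv,
                    "max_accuracy": float(max(curve.val_accuracy)),
                })
                if outdir is not None and seed == cfg.exp2_seeds[0]:
                    _save_heatmaps(cfg, _model, Path(outdir), spec.name, diet)

    summ = pd.DataFrame(summary_rows)
    stat_rows = []
    for spec in specs:
        sub = summ[summ.model == spec.name]
        seg = sub[sub.diet == "segmented"].sort_values("seed")
        uns = sub[sub.diet == "unsegmented"].sort_values("seed")
        stat_rows.append((f"{spec.name}:early-acc-seg-vs-unseg",
                          mann_whitney_u(seg.early_mean_accuracy.to_numpy(),
                                         uns.early_mean_accuracy.to_numpy())))
        conv_s = seg.convergence_epoch.dropna().to_numpy()
        conv_u = uns.convergence_epoch.dropna().to_numpy()
        if len(conv_s) and len(conv_u):
            stat_rows.append((f"{spec.name}:convergence-seg-vs-unseg",
                              mann_whitney_u(conv_s, conv_u)))
    stats_df = pd.DataFrame([res.row(g) for g, res in stat_rows])
    if len(stats_df):
        stats_df["p_adj"] = bh_fdr(stats_df["p"].to_numpy())

    early = summ.pivot_table(index="model", columns="diet",
                             values="early_mean_accuracy", sort=False)
    summary = {"early_advantage": {m: float(early.loc[m, "segmented"] - early.loc[m, "unsegmented"])
                                   for m in early.index}}
    return Report(tables={"exp2_curves": pd.DataFrame(curve_rows),
                          "exp2_summary": summ, "exp2_stats": stats_df},
                  summary=summary, provenance=_provenance(cfg, "exp2"))


def headline_metrics(report1: Report | None, report2: Report | None) -> dict:
    """Flatten the two reports into the study's headline quantities.

    Accuracies and gaps are percentages; importance values are ratios.
    Either report may be None, in which case its entries are omitted.
    """
    out: dict[str, float] = {}
    if report1 is not None:
        acc = report1.tables["exp1_accuracy"]
        members = list(dict.fromkeys(acc.model))
        shallow, deep = members[0], members[-1]
        mean_acc = acc.groupby(["model", "condition"], sort=False).accuracy.mean()
        for m in members:
            for cond in CONDITIONS:
                out[f"exp1_{cond}_acc_{m}_pct"] = 100.0 * float(mean_acc[(m, cond)])
        gaps = report1.tables["exp1_gaps"].groupby("model", sort=False).gap.mean()
        out["exp1_gap_shallow_pct"] = 100.0 * float(gaps[shallow])
        out["exp1_gap_deep_pct"] = 100.0 * float(gaps[deep])
        imp = report1.tables["exp1_importance"].groupby("model", sort=False)[
            ["object_importance", "background_importance"]].mean()
        out["exp1_bg_importance_shallow"] = float(imp.loc[shallow, "background_importance"])
        out["exp1_bg_importance_deep"] = float(imp.loc[deep, "background_importance"])
        noise = report1.tables["exp1_noise"]
        inc = noise[noise.condition == "incongruent"].groupby(
            ["model", "noise_region"], sort=False).accuracy.mean()
        out["exp1_shallow_incongruent_acc_pct"] = 100.0 * float(inc[(shallow, "none")])
        out["exp1_shallow_incongruent_bgnoise_acc_pct"] = 100.0 * float(inc[(shallow, "background")])
    if report2 is not None:
        summ = report2.tables["exp2_summary"]
        members = list(dict.fromkeys(summ.model))
        shallow, deep = members[0], members[-1]
        piv = summ.groupby(["model", "diet"], sort=False)[
            ["early_mean_accuracy", "convergence_epoch"]].mean()
        for m, tag in ((shallow, "shallow"), (deep, "deep")):
            for diet in ("segmented", "unsegmented"):
                out[f"exp2_early_acc_{tag}_{diet}_pct"] = \
                    100.0 * float(piv.loc[(m, diet), "early_mean_accuracy"])
            out[f"exp2_convergence_{tag}_segmented"] = float(piv.loc[(m, "segmented"), "convergence_epoch"])
            out[f"exp2_convergence_{tag}_unsegmented"] = float(piv.loc[(m, "unsegmented"), "convergence_epoch"])
        st = report2.tables["exp2_stats"]
        row = st[st.groups == f"{shallow}:early-acc-seg-vs-unseg"]
        if len(row):
            out["exp2_shallow_diet_mwu_p"] = float(row.p.iloc[0])
    return out


def _save_heatmaps(cfg: ExperimentConfig, model: Classifier, outdir: Path,
                   model_name: str, diet: str) -> None:
    """Layer-wise |activation|-sum heatmaps for one probe scene per diet."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import image as mpimg

    gen = cfg.exp2_gen or cfg.gen
    seg, unseg = make_training_datasets(gen.K, 1, gen,
                                        seed=_train_seed(cfg, 0), val_fraction=0.5)
    probe = Scene(pixels=unseg.images[0].astype(float), mask=unseg.masks[0],
                  category=int(unseg.labels[0]), condition="congruent",
                  location=0, exemplar_id=0, background_id=0)
    hm_dir = outdir / "heatmaps"
    hm_dir.mkdir(parents=True, exist_ok=True)
    for layer in model.layer_names:
        hm = layer_heatmap(model, probe, layer)
        mpimg.imsave(hm_dir / f"{model_name}_{diet}_{layer}.png", hm, cmap="viridis")
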