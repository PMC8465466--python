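"""End-to-end study replica: generate -> split -> train -> evaluate ->
saliency -> regional quantification -> group comparison -> prevalence
scenarios.

Every run is a pure function of its :class:`RunConfig`; the global seed
fans out to per-stage seeds through a fixed counter scheme (stage k uses
``SeedSequence(seed).spawn()`` child k), so any stage can be re-run in
isolation with the same stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn, faceregions, featquant, gradcam, screenstats, synthgen

log = logging.getLogger(__name__)

_STAGES = ("data", "split", "train", "gradcam", "validation")


@dataclass
class RunConfig:
    synth: synthgen.SynthFaceParams = field(
        default_factory=lambda: synthgen.SynthFaceParams(
            image_size=64, n_case=150, n_control=300))
    train_fraction: float = 0.7
    experiment: cnn.ExperimentConfig = field(
        default_factory=lambda: cnn.ExperimentConfig(input_size=64))
    threshold: float = 0.5
    #: Grad-CAM layer for quantification. "finest" = the first (highest-
    #: resolution) conv layer — at desk scale the last conv stage is too
    #: coarse to resolve the six areas; None = the standard last-layer default.
    cam_layer: str | None = "finest"
    min_feature_frac: float = 10.0 / 224.0  # reference 10 px in a 224 px frame
    prevalence: float = 0.1
    margin: float = 0.15
    expansion_factors: tuple = (1.5, 2.0)
    validation_pool_case: int = 60
    validation_pool_control: int = 400
    gallery_size: int = 4
    seed: int = 0

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: int(ss.generate_state(1)[0] % (2**31))
                for name, ss in zip(_STAGES, children)}

    def min_feature_size(self) -> int:
        return max(2, round(self.min_feature_frac * self.synth.image_size))


def run_study(config: RunConfig, out_dir=None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the
    report bundle: confusion metrics, the per-region comparison table,
    prevalence-scenario evaluations and a machine-readable summary."""
    seeds = config.stage_seeds()
    size = config.synth.image_size

    params = replace(config.synth, seed=seeds["data"])
    dataset = synthgen.generate_dataset(params)
    log.info("stage data: generated %d images (%d case / %d control)",
             len(dataset), params.n_case, params.n_control)

    train_set, test_set = synthgen.split_dataset(dataset, config.train_fraction,
                                                 seed=seeds["split"])
    log.info("stage split: %d train / %d test", len(train_set), len(test_set))

    exp = replace(config.experiment, seed=seeds["train"], input_size=size)
    model = cnn.build_model(exp)
    cnn.apply_freezing(model, exp.freezing)
    history = cnn.train(model, train_set, exp)
    cm = cnn.evaluate(model, test_set)
    metrics = screenstats.confusion_metrics(cm)
    log.info("stage train: %d epochs, test ACC %.2f%%", len(history["loss"]),
             metrics.accuracy)

    # saliency for each test image, targeted at its true class
    min_size = config.min_feature_size()
    cam_layer = (model.conv_layer_names()[0] if config.cam_layer == "finest"
                 else config.cam_layer)
    case_hits, control_hits = [], []
    for i in range(len(test_set)):
        img = test_set.images[i]
        target = 1 if test_set.labels[i] == synthgen.CASE else 0
        heat = gradcam.gradcam(model, img, target_class=target, layer=cam_layer)
        partition = faceregions.partition_face(test_set.landmarks[i])
        hits = featquant.quantify_heatmap(
            heat, partition, threshold=config.threshold, min_size=min_size,
            image_id=test_set.manifest["id"].iloc[i])
        (case_hits if target == 1 else control_hits).append(hits)
    region_table = featquant.aggregate(case_hits, control_hits)
    log.info("stage gradcam: quantified %d test images", len(test_set))

    # prevalence-based validation scenarios on a fresh synthetic pool
    sens_est = min(max(metrics.sensitivity / 100.0, 0.05), 0.95)
    design = screenstats.ValidationDesign(
        prevalence=config.prevalence, sensitivity=sens_est,
        specificity=metrics.specificity / 100.0, margin=config.margin,
        expansion_factors=tuple(config.expansion_factors))
    base = screenstats.min_validation_sample(design)
    scenarios = screenstats.scenario_expand(base, design.expansion_factors)
    pool_params = replace(
        params,
        n_case=max(config.validation_pool_case, max(s[0] for s in scenarios)),
        n_control=max(config.validation_pool_control, max(s[1] for s in scenarios)),
        seed=seeds["validation"])
    pool = synthgen.generate_dataset(pool_params)
    validation_rows = []
    for k, scen in enumerate(scenarios):
        sub = screenstats.sample_validation_set(
            pool.manifest.reset_index().rename(columns={"index": "row"}),
            scen, seed=seeds["validation"] + k + 1)
        subset = pool.subset(sub["row"].tolist())
        vcm = cnn.evaluate(model, subset)
        vmet = screenstats.confusion_metrics(vcm)
        validation_rows.append({
            "dataset": "validation-base" if k == 0 else
                       f"validation-x{design.expansion_factors[k - 1]:g}",
            "n_case": scen[0], "n_control": scen[1],
            "TP": vcm.TP, "FN": vcm.FN, "FP": vcm.FP, "TN": vcm.TN,
            "ACC": vmet.accuracy, "SEN": vmet.sensitivity, "SPE": vmet.specificity,
        })
    validation_table = pd.DataFrame(validation_rows)
    log.info("stage validation: evaluated %d scenarios", len(scenarios))

    bundle = {
        "seeds": seeds,
        "config": _config_dict(config),
        "history": history,
        "confusion": {"TP": cm.TP, "FN": cm.FN, "FP": cm.FP, "TN": cm.TN},
        "metrics": asdict(metrics),
        "region_table": region_table,
        "validation_table": validation_table,
        "model": model,
        "test_set": test_set,
    }
    if out_dir is not None:
        _write_bundle(bundle, config, Path(out_dir))
    return bundle


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["synth"]["effect_regions"] = sorted(config.synth.effect_regions)
    return d


def summary_dict(bundle: dict) -> dict:
    """JSON-serializable summary of a run bundle (no arrays, no model)."""
    return {
        "seeds": bundle["seeds"],
        "config": bundle["config"],
        "confusion": bundle["confusion"],
        "metrics": bundle["metrics"],
        "epochs": len(bundle["history"]["loss"]),
        "final_loss": bundle["history"]["loss"][-1],
        "region_table": bundle["region_table"].to_dict(orient="records"),
        "validation_table": bundle["validation_table"].to_dict(orient="records"),
    }


def _write_bundle(bundle: dict, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["region_table"].to_csv(out / "region_table.csv", index=False)
    bundle["validation_table"].to_csv(out / "validation_table.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary_dict(bundle), indent=2))
    (out / "report.md").write_text(render_report(bundle))
    # a few example overlays for visual inspection
    try:
        import imageio.v3 as iio

        model, test_set = bundle["model"], bundle["test_set"]
        for i in range(min(config.gallery_size, len(test_set))):
            target = 1 if test_set.labels[i] == synthgen.CASE else 0
            heat = gradcam.gradcam(model, test_set.images[i], target_class=target)
            rgb = gradcam.overlay(heat, np.clip(test_set.images[i], 0, 1))
            iio.imwrite(out / f"overlay_{test_set.manifest['id'].iloc[i]}.png",
                        (rgb * 255).astype(np.uint8))
    except Exception:  # gallery is best-effort decoration
        log.exception("overlay gallery failed")


def heatmap_recovery_replicates(
        n_replicates: int = 100, n_per_group: int = 100, image_size: int = 64,
        effect_regions=("nose", "left-cheek", "right-cheek"),
        effect_weight: float = 0.9, baseline_weight: float = 0.4,
        background_noise: float = 0.2, alpha: float = 0.01, seed: int = 0) -> dict:
    """Planted-concentration recovery rate on synthetic heatmaps.

    Each replicate draws ``n_per_group`` case and control faces with
    jittered landmarks; cases carry saliency blobs of peak
    ``effect_weight`` in the effect regions (baseline elsewhere),
    controls carry the baseline everywhere, and uniform background noise
    is added to both.  The replicate succeeds when the aggregated
    region table shows every effect region case-higher with chi-square
    p < ``alpha``.  Returns the success fraction and per-replicate flags.
    """
    effect = set(effect_regions)
    min_size = max(2, round(10 / 224 * image_size))
    params = synthgen.SynthFaceParams(image_size=image_size, n_case=0, n_control=0)
    successes = []
    root = np.random.SeedSequence(seed)
    for rep_ss in root.spawn(n_replicates):
        rng = np.random.default_rng(rep_ss)
        case_hits, control_hits = [], []
        for group, sink in (("case", case_hits), ("control", control_hits)):
            for _ in range(n_per_group):
                lm = synthgen.jittered_landmarks(params, rng)
                partition = faceregions.partition_face(lm)
                weights = {
                    r: (effect_weight if group == "case" and r in effect else baseline_weight)
                    for r in faceregions.REGION_NAMES
                }
                heat = synthgen.generate_heatmap(
                    lm, weights, seed=int(rng.integers(2**31)),
                    background_noise=background_noise, partition=partition)
                sink.append(featquant.quantify_heatmap(heat, partition, min_size=min_size))
        table = featquant.aggregate(case_hits, control_hits)
        by_region = table.set_index("region")
        ok = all(
            by_region.loc[r, "direction"] == "case-higher"
            and by_region.loc[r, "p_value"] < alpha
            for r in effect
        )
        successes.append(bool(ok))
    return {"rate": float(np.mean(successes)), "successes": successes,
            "n_replicates": n_replicates, "n_per_group": n_per_group}


def render_report(bundle: dict) -> str:
    """Human-readable markdown report for a completed run bundle."""
    for key in ("metrics", "confusion", "region_table"):
        if key not in bundle:
            raise ValueError(f"incomplete bundle: missing {key!r}")
    m = bundle["metrics"]
    cm = bundle["confusion"]
    lines = [
        "# Synthetic screening study report",
        "",
        "## Classifier performance (held-out test set)",
        "",
        f"- Confusion counts: TP={cm['TP']}, FN={cm['FN']}, FP={cm['FP']}, TN={cm['TN']}",
        f"- Accuracy {m['accuracy']:.2f}%, sensitivity {m['sensitivity']:.2f}%, "
        f"specificity {m['specificity']:.2f}%",
        "",
        "## Regional saliency comparison (case vs control)",
        "",
        bundle["region_table"].to_markdown(index=False),
        "",
    ]
    vt = bundle.get("validation_table")
    if vt is not None and len(vt):
        lines += ["## Prevalence-based validation scenarios", "",
                  vt.to_markdown(index=False), ""]
    return "\n".join(lines)
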