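"""End-to-end experiment: cohort -> split -> train -> evaluate -> compare.

The workflow mirrors the segmentation study design: for each dataset
stratum (normal-only, displaced-only, and both pooled) the samples are
split 80/20, each requested network family is trained on the training
patches, and the test patches are scored with Dice / sensitivity / PPV.
Per-image records feed a mean +- SD summary table, box-plot statistics,
and a one-way ANOVA + Tukey HSD comparison with letter groups.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import dataio, evaluation, phantom, stats
from .architectures import SegmentationModelSpec, build_model
from .config import RunConfig
from .training import TrainConfig, train

log = logging.getLogger("discseg")


@dataclass
class ExperimentResult:
    """Everything `run_experiment` computed, plus where it was written."""

    run_dir: Path
    per_image: pd.DataFrame
    summary: pd.DataFrame
    box_stats: pd.DataFrame
    comparisons: dict[tuple[str, str], stats.ComparisonResult]
    loss_curves: dict[tuple[str, str], list[float]]
    split_sizes: dict[str, tuple[int, int]]


def _roi_for(cfg: RunConfig, image_shape) -> dataio.ROISpec:
    if cfg.roi is None:
        h, w = image_shape
        scale = min(h, w) / 512.0
        return dataio.ROISpec.centered(
            image_shape,
            height=max(2, round(161 * scale)),
            width=max(2, round(184 * scale)),
        )
    return dataio.ROISpec(
        origin=tuple(cfg.roi.get("origin", (0, 0))),
        height=cfg.roi["height"],
        width=cfg.roi["width"],
    )


def _prepare_patches(samples, idxs, roi, input_size):
    pairs = [dataio.preprocess_sample(samples[i], roi, input_size) for i in idxs]
    return dataio.patches_to_arrays(pairs)


def get_cohort(cfg: RunConfig, run_dir: Path) -> list[phantom.Sample]:
    """Load the cohort named by ``cfg.data_dir`` or generate one."""
    if cfg.data_dir is not None:
        return phantom.load_cohort(Path(cfg.data_dir) / "manifest.csv")
    cohort_dir = run_dir / "cohort"
    manifest = phantom.generate_cohort(
        cohort_dir,
        n_patients=cfg.cohort.n_patients,
        n_controls=cfg.cohort.n_controls,
        slices_per_subject=cfg.cohort.slices_per_subject,
        seed=cfg.seed,
        image_size=cfg.cohort.image_size,
    )
    log.info("generated cohort of %d samples in %s", len(manifest), cohort_dir)
    return phantom.load_cohort(cohort_dir / "manifest.csv")


def run_experiment(cfg: RunConfig, run_dir: str | Path | None = None) -> ExperimentResult:
    """Execute the full workflow; artifacts land in a run directory."""
    if run_dir is None:
        run_dir = Path(cfg.out_dir) / time.strftime("run-%Y%m%d-%H%M%S")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.save(run_dir / "config.yaml")

    samples = get_cohort(cfg, run_dir)
    roi = _roi_for(cfg, samples[0].image.shape)
    input_size = tuple(cfg.model.input_size)

    records = []
    comparisons: dict[tuple[str, str], stats.ComparisonResult] = {}
    loss_curves: dict[tuple[str, str], list[float]] = {}
    split_sizes: dict[str, tuple[int, int]] = {}

    groups_present = {s.group for s in samples}
    for stratum in cfg.strata:
        if stratum != "both" and stratum not in groups_present:
            log.info("stratum %s empty; skipped", stratum)
            continue
        split = dataio.split_dataset(samples, cfg.split_fraction, cfg.seed, stratum)
        split_sizes[stratum] = (len(split.train), len(split.test))
        split.save(run_dir / f"split_{stratum}.csv",
                   ids=[f"{s.subject_id}_{s.side}_{s.jaw_state}_{i}" for i, s in enumerate(samples)])
        x_tr, y_tr = _prepare_patches(samples, split.train, roi, input_size)
        x_te, y_te = _prepare_patches(samples, split.test, roi, input_size)
        log.info("stratum %s: %d train / %d test", stratum, len(x_tr), len(x_te))

        for family in cfg.model.families:
            mdir = run_dir / stratum / family
            mdir.mkdir(parents=True, exist_ok=True)
            spec = SegmentationModelSpec(
                family=family,
                input_size=input_size,
                depth=cfg.model.depth,
                base_filters=cfg.model.base_filters,
                kernel_size=cfg.model.kernel_size,
                dropout_rate=cfg.model.dropout_rate,
                seed=cfg.seed,
            )
            model = build_model(spec)
            tcfg = TrainConfig(
                learning_rate=cfg.train.learning_rate,
                epochs=cfg.train.epochs,
                batch_size=cfg.train.batch_size,
                loss=cfg.train.loss,
                seed=cfg.seed,
            )
            t0 = time.time()
            curve = train(model, x_tr, y_tr, tcfg, checkpoint_dir=mdir)
            log.info("trained %s on %s: %d epochs, final loss %.4f (%.1f s)",
                     family, stratum, len(curve), curve.train_loss[-1], time.time() - t0)
            loss_curves[(stratum, family)] = list(curve.train_loss)

            prob = model.forward(x_te[..., None], train=False)[..., 0]
            for j, i_sample in enumerate(split.test):
                pred = evaluation.binarize(prob[j], cfg.eval_threshold)
                rec = evaluation.compute_metrics(
                    pred, y_te[j], sample_id=f"{samples[i_sample].subject_id}:{i_sample}"
                )
                d = rec.as_dict()
                d.update(model=family, dataset=stratum)
                records.append(d)
            # a few qualitative overlays per model
            for j in range(min(3, len(x_te))):
                pred = evaluation.binarize(prob[j], cfg.eval_threshold)
                overlay = evaluation.render_overlay(pred, y_te[j], x_te[j])
                Image.fromarray(overlay, mode="RGB").save(mdir / f"overlay_{j}.png")

    per_image = pd.DataFrame(records)
    per_image.to_csv(run_dir / "per_image_metrics.csv", index=False)
    summary, box_stats = evaluation.summarize(per_image)
    summary.to_csv(run_dir / "summary.csv", index=False)
    box_stats.to_csv(run_dir / "box_stats.csv", index=False)

    letters_by_cell: dict[tuple[str, str], dict[str, str]] = {}
    if len(cfg.model.families) >= 2:
        comp_rows = []
        for stratum in per_image["dataset"].unique():
            sub = per_image[per_image["dataset"] == stratum]
            for metric in evaluation.METRIC_NAMES:
                groups = {m: g[metric].to_numpy() for m, g in sub.groupby("model")}
                try:
                    res = stats.compare_models(metric, groups, alpha=cfg.alpha)
                except ValueError as e:
                    log.warning("comparison skipped for %s/%s: %s", stratum, metric, e)
                    continue
                comparisons[(stratum, metric)] = res
                for model_name, letter in res.letters.items():
                    letters_by_cell.setdefault((stratum, model_name), {})[metric] = letter
                for p in res.tukey_pairs:
                    comp_rows.append({
                        "dataset": stratum, "metric": metric,
                        "f_statistic": res.f_statistic, "p_value": res.p_value,
                        "group_a": p.group_a, "group_b": p.group_b,
                        "mean_diff": p.mean_diff, "p_adj": p.p_adj,
                        "reject": p.reject,
                    })
        pd.DataFrame(comp_rows).to_csv(run_dir / "comparison.csv", index=False)
    else:
        log.info("single model family: comparison stage skipped")

    table = evaluation.format_summary_table(summary, letters=letters_by_cell or None)
    (run_dir / "summary_table.txt").write_text(table + "\n")

    for key, curve in loss_curves.items():
        pd.DataFrame({"epoch": np.arange(1, len(curve) + 1), "train_loss": curve}).to_csv(
            run_dir / f"loss_{key[0]}_{key[1]}.csv", index=False
        )
    if cfg.figures:
        _render_figures(run_dir, per_image, loss_curves)

    return ExperimentResult(
        run_dir=run_dir,
        per_image=per_image,
        summary=summary,
        box_stats=box_stats,
        comparisons=comparisons,
        loss_curves=loss_curves,
        split_sizes=split_sizes,
    )


def _render_figures(run_dir: Path, per_image: pd.DataFrame, loss_curves: dict) -> None:
    """Loss-curve and box-plot figures (one PNG per stratum/metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = sorted({k[0] for k in loss_curves})
    for stratum in strata:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for (st, fam), curve in loss_curves.items():
            if st == stratum:
                ax.plot(np.arange(1, len(curve) + 1), curve, label=fam)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss")
        ax.set_title(f"dataset: {stratum}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / f"loss_{stratum}.png", dpi=120)
        plt.close(fig)

    for metric in evaluation.METRIC_NAMES:
        fig, axes = plt.subplots(1, len(strata), figsize=(4 * len(strata), 3.5),
                                 squeeze=False)
        for ax, stratum in zip(axes[0], strata):
            sub = per_image[per_image["dataset"] == stratum]
            models = sorted(sub["model"].unique())
            ax.boxplot([sub[sub["model"] == m][metric] for m in models],
                       tick_labels=models)
            ax.set_title(f"{metric} — {stratum}")
            ax.set_ylim(0, 1.05)
        fig.tight_layout()
        fig.savefig(run_dir / f"box_{metric}.png", dpi=120)
        plt.close(fig)
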