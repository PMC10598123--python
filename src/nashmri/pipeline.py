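"""End-to-end orchestration: simulate -> segment -> quantify -> UDC ->
predict -> diagnostic statistics, with a JSON-serialisable run report.

The headline analysis mirrors the clinical question: can texture
signatures (UDC), relative liver enhancement (RLE) and fat fraction (FF),
computed from the same four sequences, separate NASH from simple
steatosis against the SAF histology labels?

Scoring orientation: NASH is the positive class. RLE falls with fibrosis
and inflammation, so the RLE-based ROC uses score = -rle_mean; FF rises
with steatosis and is used directly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    DCNConfig,
    DESK_N_PATCHES,
    PAPER_SCALE_N_PATCHES,
    concat_signatures,
    extract_patches,
    signature,
    train_dcn,
)
from .cohort import NASH, CohortConfig, cohort_table, generate_cohort, write_cohort
from .predict import SAF_COMPONENTS, cv_classify, cv_regress_components, lowhigh_test
from .quantify import place_rois, quantify_study
from .segmentation import SegmenterSpec, evaluate_segmentation, otsu_segment, segment, train_segmenter
from .stats import chi2_test, delong_test, icc_absolute, regress, roc_analysis, t_test


class ScaleGuardError(RuntimeError):
    """Raised when a paper_scale run is requested without --force."""


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    dcn: DCNConfig = field(default_factory=DCNConfig)
    n_patches: int = DESK_N_PATCHES
    segmentation: str = "otsu"  # truth | otsu | unet
    n_rois: int = 9
    min_roi_radius: int = 3
    folds: int = 5
    n_trees: int = 500
    include_csi: bool = True
    predict_components: bool = True
    scale: str = "desk"  # desk | paper_scale
    seed: int = 0

    def resolved(self) -> "PipelineConfig":
        """Propagate the global seed into every stage deterministically."""
        cfg = dataclasses.replace(self)
        cfg.cohort = dataclasses.replace(self.cohort, rng_seed=self.seed)
        cfg.dcn = dataclasses.replace(self.dcn, seed=self.seed + 101)
        if cfg.scale == "paper_scale":
            cfg.n_patches = PAPER_SCALE_N_PATCHES
        return cfg

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = CohortConfig(**d.pop("cohort", {}))
        dcn = DCNConfig(**d.pop("dcn", {}))
        return cls(cohort=cohort, dcn=dcn, **d)


def _roc_block(scores, labels) -> dict:
    r = roc_analysis(scores, labels)
    return {
        "auc": r.auc,
        "auc_ci95": list(r.auc_ci95),
        "youden_cutoff": r.youden_cutoff,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
        "ppv": r.ppv,
        "npv": r.npv,
        "accuracy": r.accuracy,
    }


def _group_stat(values, labels) -> dict:
    values = np.asarray(values, dtype=float)
    a, b = values[labels == 0], values[labels == 1]
    return {
        "simple_steatosis_mean": float(a.mean()),
        "simple_steatosis_sd": float(a.std(ddof=1)),
        "nash_mean": float(b.mean()),
        "nash_sd": float(b.std(ddof=1)),
        "p": t_test(a, b),
    }


def run_pipeline(config: PipelineConfig, outdir=None, force: bool = False) -> dict:
    """Execute all stages and return the run report as a nested dict
    (byte-identical across reruns of the same config)."""
    if config.scale == "paper_scale" and not force:
        raise ScaleGuardError(
            "paper_scale trains on 50,000 patches and is resource-intensive; "
            "pass force=True (CLI: --force) to proceed"
        )
    cfg = config.resolved()
    report: dict = {
        "config": dataclasses.asdict(cfg),
        "versions": {"nashmri": __version__, "numpy": np.__version__},
    }

    # -- simulate ---------------------------------------------------------
    cohort = generate_cohort(cfg.cohort)
    table = cohort_table(cohort)
    labels = (table["nash_label"] == NASH).to_numpy().astype(int)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(outdir / "cohort", cohort, cfg.cohort)

    # -- segment ----------------------------------------------------------
    if cfg.segmentation == "truth":
        masks = [study.liver_mask for _, study in cohort]
        seg_block = {"method": "truth"}
    elif cfg.segmentation == "otsu":
        masks = [otsu_segment(study.t1_hbp) for _, study in cohort]
        dices = [
            evaluate_segmentation(m, s.liver_mask).dice for m, (_, s) in zip(masks, cohort)
        ]
        seg_block = {"method": "otsu", "mean_dice_vs_truth": float(np.mean(dices))}
    elif cfg.segmentation == "unet":
        n_train = min(8, len(cohort))
        model = train_segmenter(
            [s for _, s in cohort[:n_train]], SegmenterSpec(rng_seed=cfg.seed)
        )
        masks = [segment(model, s.t1_hbp) for _, s in cohort]
        dices = [
            evaluate_segmentation(m, s.liver_mask).dice for m, (_, s) in zip(masks, cohort)
        ]
        seg_block = {
            "method": "unet",
            "n_train": n_train,
            "mean_dice_vs_truth": float(np.mean(dices)),
        }
    else:
        raise ValueError(f"unknown segmentation method {cfg.segmentation!r}")
    report["segmentation"] = seg_block

    # -- quantify (two emulated readers for ICC) --------------------------
    def _reader(offset: int) -> pd.DataFrame:
        rows = []
        for idx, ((record, study), mask) in enumerate(zip(cohort, masks)):
            stream = np.random.default_rng(cfg.seed + offset + 10 * idx)
            rois = place_rois(mask, n=cfg.n_rois, min_radius=cfg.min_roi_radius, stream=stream)
            q = quantify_study(study, rois)
            rows.append(
                {"subject_id": record.subject_id, "rle_mean": q.rle_mean, "ff_mean": q.ff_mean}
            )
        return pd.DataFrame(rows)

    reader1, reader2 = _reader(0), _reader(5000)
    quant = reader1.merge(table, on="subject_id")
    report["quantification"] = {
        "rle": _group_stat(quant["rle_mean"], labels),
        "ff": _group_stat(quant["ff_mean"], labels),
        "icc": {
            "rle": icc_absolute(
                np.column_stack([reader1["rle_mean"], reader2["rle_mean"]])
            ).icc,
            "ff": icc_absolute(
                np.column_stack([reader1["ff_mean"], reader2["ff_mean"]])
            ).icc,
        },
    }
    if outdir is not None:
        quant.to_csv(outdir / "quantification.csv", index=False)

    # -- UDC: per-sequence models, signatures, concatenation ---------------
    masked_cohort = [
        (record, dataclasses.replace(study, liver_mask=mask))
        for (record, study), mask in zip(cohort, masks)
    ]
    sequences = ["t1_pre", "t1_hbp"] + (["csi"] if cfg.include_csi else [])
    signatures = {}
    for i, seq in enumerate(sequences):
        stream = np.random.default_rng(cfg.seed + 200 + i)
        patches = extract_patches(
            masked_cohort, seq, cfg.n_patches, patch_size=cfg.dcn.patch_size, stream=stream
        )
        model = train_dcn(
            patches, k=cfg.dcn.k, config=dataclasses.replace(cfg.dcn, seed=cfg.dcn.seed + i)
        )
        signatures[seq] = [signature(model, study, seq) for _, study in masked_cohort]
        if outdir is not None:
            model.save(outdir / f"dcn_{seq}.npz")
    t1_sig = [
        concat_signatures(a, b) for a, b in zip(signatures["t1_pre"], signatures["t1_hbp"])
    ]
    udc_features = np.stack([s.proportions for s in t1_sig])
    report["udc"] = {
        "signature_dim": {
            "per_sequence": cfg.dcn.k,
            "t1_concat": int(udc_features.shape[1]),
            **({"csi": len(signatures["csi"][0].proportions)} if cfg.include_csi else {}),
        }
    }
    if outdir is not None:
        sig_df = pd.DataFrame(
            udc_features, columns=[f"c{i}" for i in range(udc_features.shape[1])]
        )
        sig_df.insert(0, "subject_id", table["subject_id"])
        sig_df.to_csv(outdir / "udc_signatures_t1.csv", index=False)

    # -- classification + ROC ----------------------------------------------
    classification = {}
    udc_pred = cv_classify(udc_features, labels, folds=cfg.folds, seed=cfg.seed, n_trees=cfg.n_trees)
    classification["udc_t1"] = _roc_block(udc_pred.scores, labels)
    classification["udc_t1"]["group_score"] = _group_stat(udc_pred.scores, labels)
    scores = {"udc_t1": udc_pred.scores}
    if cfg.include_csi:
        csi_features = np.stack([s.proportions for s in signatures["csi"]])
        csi_pred = cv_classify(
            csi_features, labels, folds=cfg.folds, seed=cfg.seed, n_trees=cfg.n_trees
        )
        classification["udc_csi"] = _roc_block(csi_pred.scores, labels)
        scores["udc_csi"] = csi_pred.scores
    scores["rle"] = -quant["rle_mean"].to_numpy()
    scores["ff"] = quant["ff_mean"].to_numpy()
    classification["rle"] = _roc_block(scores["rle"], labels)
    classification["rle"]["rle_cutoff"] = -classification["rle"]["youden_cutoff"]
    classification["ff"] = _roc_block(scores["ff"], labels)
    combined = np.column_stack(
        [udc_features]
        + ([np.stack([s.proportions for s in signatures["csi"]])] if cfg.include_csi else [])
        + [quant["rle_mean"], quant["ff_mean"]]
    )
    comb_pred = cv_classify(combined, labels, folds=cfg.folds, seed=cfg.seed, n_trees=cfg.n_trees)
    classification["combined"] = _roc_block(comb_pred.scores, labels)
    scores["combined"] = comb_pred.scores
    report["classification"] = classification
    report["delong"] = {
        "udc_vs_rle": dataclasses.asdict(delong_test(scores["udc_t1"], scores["rle"], labels)),
        "udc_vs_ff": dataclasses.asdict(delong_test(scores["udc_t1"], scores["ff"], labels)),
        "combined_vs_udc": dataclasses.asdict(
            delong_test(scores["combined"], scores["udc_t1"], labels)
        ),
    }

    # -- per-component regression + low/high tests --------------------------
    if cfg.predict_components:
        grades = table[list(SAF_COMPONENTS)]
        comp = cv_regress_components(
            udc_features, grades, folds=cfg.folds, seed=cfg.seed, n_trees=cfg.n_trees
        )
        report["component_prediction"] = {
            name: {
                "pearson_r": float(np.corrcoef(res.scores, grades[name])[0, 1]),
                "lowhigh_p": lowhigh_test(res, grades, name),
            }
            for name, res in comp.items()
        }

    # -- group tests and linear regressions ---------------------------------
    chi2_blocks = {}
    for name in SAF_COMPONENTS:
        counts = pd.crosstab(labels, table[name]).to_numpy()
        counts = counts[:, counts.sum(axis=0) > 0]
        stat, p = chi2_test(counts)
        chi2_blocks[name] = {"statistic": float(stat), "p": float(p)}
    report["group_tests"] = {"chi2": chi2_blocks}

    grades_X = table[list(SAF_COMPONENTS)]
    regression = {}
    for target in ("rle_mean", "ff_mean"):
        uni = regress(quant[target], grades_X, mode="univariate")
        back = regress(quant[target], grades_X, mode="multiple_backward")
        regression[target] = {
            "univariate": uni.predictors,
            "backward": back.predictors,
            "retained": back.retained,
        }
    report["regression"] = regression

    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        (outdir / "report.md").write_text(render_markdown(report))
    return report


def udc_discrimination_auroc(
    seed: int,
    null: bool = False,
    n_subjects: int = 60,
    class_mix: float = 0.6,
    n_patches: int = DESK_N_PATCHES,
    k: int = 10,
    folds: int = 5,
    n_trees: int = 500,
) -> float:
    """End-to-end NASH-vs-steatosis out-of-fold AUROC of the concatenated
    unenhanced-T1 + HBP UDC signature on a freshly generated cohort.

    ``null=True`` removes every class-informative image effect from the
    generator (flat textures, grade-independent RLE and FF), the negative
    control under which the signature should carry no class information.
    """
    from .cohort import null_effects

    cfg = CohortConfig(n_subjects=n_subjects, class_mix=class_mix, rng_seed=seed)
    if null:
        cfg = null_effects(cfg)
    cohort = generate_cohort(cfg)
    labels = np.array([r.nash_label == NASH for r, _ in cohort]).astype(int)
    sigs = {}
    for i, seq in enumerate(("t1_pre", "t1_hbp")):
        stream = np.random.default_rng(seed + 200 + i)
        patches = extract_patches(cohort, seq, n_patches, stream=stream)
        model = train_dcn(patches, k=k, config=DCNConfig(k=k, seed=seed + 101 + i))
        sigs[seq] = [signature(model, study, seq) for _, study in cohort]
    feats = np.stack(
        [
            concat_signatures(a, b).proportions
            for a, b in zip(sigs["t1_pre"], sigs["t1_hbp"])
        ]
    )
    pred = cv_classify(feats, labels, folds=folds, seed=seed, n_trees=n_trees)
    return roc_analysis(pred.scores, labels).auc


def render_markdown(report: dict) -> str:
    """Human-readable report summary."""
    lines = ["# nashmri run report", ""]
    cls = report["classification"]
    lines.append("## NASH vs simple steatosis (out-of-fold)")
    lines.append("")
    lines.append("| features | AUROC | accuracy | sensitivity | specificity | PPV | NPV |")
    lines.append("|---|---|---|---|---|---|---|")
    for name, b in cls.items():
        lines.append(
            f"| {name} | {b['auc']:.3f} | {b['accuracy']:.3f} | {b['sensitivity']:.3f} "
            f"| {b['specificity']:.3f} | {b['ppv']:.3f} | {b['npv']:.3f} |"
        )
    q = report["quantification"]
    lines += [
        "",
        "## Quantification (group mean ± SD)",
        "",
        f"- RLE: simple steatosis {q['rle']['simple_steatosis_mean']:.3f} ± "
        f"{q['rle']['simple_steatosis_sd']:.3f}, NASH {q['rle']['nash_mean']:.3f} ± "
        f"{q['rle']['nash_sd']:.3f} (p = {q['rle']['p']:.2e})",
        f"- FF (%): simple steatosis {q['ff']['simple_steatosis_mean']:.2f} ± "
        f"{q['ff']['simple_steatosis_sd']:.2f}, NASH {q['ff']['nash_mean']:.2f} ± "
        f"{q['ff']['nash_sd']:.2f} (p = {q['ff']['p']:.2e})",
        f"- Inter-reader ICC(A,1): RLE {q['icc']['rle']:.3f}, FF {q['icc']['ff']:.3f}",
        "",
        "## Backward-elimination regression",
        "",
        f"- RLE retained: {report['regression']['rle_mean']['retained']}",
        f"- FF retained: {report['regression']['ff_mean']['retained']}",
        "",
    ]
    return "\n".join(lines)
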