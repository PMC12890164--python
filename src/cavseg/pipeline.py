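"""End-to-end weakly supervised refinement pipeline.

Stages: load/preprocess -> classifier + CAM -> superpixel region graph
-> edge-affinity training -> dual-threshold pseudo labels -> voxel
affinity (+ optional focal-affinity projection head) -> random-walk CAM
refinement -> refreshed pseudo labels -> contour scribbles ->
segmentation training with EMA -> metric reports.  Every intermediate
is persisted under the run directory with the resolved configuration.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .affinity import GANetConfig, train_ganet
from .config import PipelineConfig
from .evaluation import hd95, overlap_metrics, paired_wilcoxon
from .graph import build_region_graph, compute_superpixels, export_edges_tsv
from .propagation import PropagationConfig, refine_cam
from .pseudolabel import (ClassifierConfig, affinity_to_logit, cavity_foreground_cam,
                          derive_affinity_targets, dual_threshold, focal_affinity_loss,
                          intensity_embedding, train_affinity_head,
                          train_classifier_and_cam, voxel_affinity)
from .segmentation import (LossWeights, ScribbleSet, SegmenterConfig, UNLABELED,
                           extract_scribbles, total_loss, train_segmenter)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, case: str, original: Exception):
        super().__init__(f"stage '{stage}' failed on case '{case}': {original}")
        self.stage, self.case = stage, case


def run_pipeline(manifest_path, config: PipelineConfig, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.dump(out_dir / "resolved_config.json")

    manifest = cio.load_manifest(manifest_path)
    cases = manifest["cases"]
    case_ids = [c["case_id"] for c in cases]

    volumes, masks, cams_manifest, labels = [], [], [], []
    for case in cases:
        try:
            vol, mask, cam = cio.load_case(manifest, case)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("load", case["case_id"], e)
        volumes.append(vol)
        masks.append(mask)
        cams_manifest.append(cam)
        labels.append(int(case["class"]))

    # -- classifier + CAM ------------------------------------------------
    try:
        cls_cfg = ClassifierConfig(n_classes=config.n_classes,
                                   steps=config.classifier_steps,
                                   lr=config.classifier_lr,
                                   epsilon=config.epsilon, seed=config.seed)
        classifier, cams_cls, cls_history = train_classifier_and_cam(
            volumes, labels, cls_cfg)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classifier", "all", e)
    l_cls = float(np.mean([h["loss_cls"] for h in cls_history[-10:]]))
    pd.DataFrame(cls_history).to_csv(out_dir / "loss_cls.csv", index=False)

    if config.cam_source == "classifier":
        cams = [cavity_foreground_cam(c) for c in cams_cls]
    else:
        cams = cams_manifest

    weights = LossWeights(config.lambda1, config.lambda2, config.lambda3,
                          config.lambda4, config.lambda5)
    struct_vals, smooth_vals, aff_vals = [], [], []
    refined_pseudos, scribble_sets = [], []
    dsc_raw_all, dsc_ref_all = [], []

    for i, case in enumerate(cases):
        cid = case["case_id"]
        vol, cam = volumes[i], cams[i]
        try:
            f_enc = classifier.encoder_features(vol)
            n_seg = min(config.n_segments, vol.data.size // 32)
            partition = compute_superpixels(vol, n_segments=n_seg,
                                            compactness=config.compactness)
            k = min(config.k, partition.n_regions - 1)
            graph = build_region_graph(partition, vol, f_enc, cam, k=k)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("graph", cid, e)

        try:
            ga_cfg = GANetConfig(
                n_layers=config.n_layers, feature_dim=config.feature_dim,
                steps=config.ganet_steps, lr=config.ganet_lr,
                struct_weight=1.0 if config.use_struct else 0.0,
                lambda_smooth=config.lambda2 if config.use_smooth else 0.0,
                seed=config.seed + i,
            )
            _, report = train_ganet(graph, ga_cfg)
            if config.use_struct:
                struct_vals.append(report.loss_struct / max(len(graph.edges), 1))
            if config.use_smooth:
                smooth_vals.append(report.loss_smooth / max(len(graph.edges), 1))
            export_edges_tsv(graph, out_dir / f"{cid}_edges.tsv")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("affinity-train", cid, e)

        try:
            pseudo_raw = dual_threshold(cam, config.phi_l, config.phi_h)
            targets = derive_affinity_targets(pseudo_raw, config.window)
            feats = np.concatenate([f_enc, intensity_embedding(vol.data)], axis=-1)
            if config.use_aff:
                feats, _ = train_affinity_head(
                    feats, targets, pseudo=pseudo_raw, n_pairs=config.aff_pairs,
                    steps=config.aff_head_steps, seed=config.seed + i)
            w_aff = voxel_affinity(feats, config.window)
            aff_vals.append(focal_affinity_loss(affinity_to_logit(w_aff), targets)
                            if config.use_aff else 0.0)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("voxel-affinity", cid, e)

        try:
            prop_cfg = PropagationConfig(
                eta=config.eta, block_size=config.block_size,
                overlap_fraction=config.overlap_fraction,
                use_region_graph=config.use_region_graph,
                n_iterations=config.n_iterations,
            )
            refined = refine_cam(cam, w_aff, prop_cfg,
                                 region_graph=graph, partition=partition)
            pseudo_ref = dual_threshold(refined, config.phi_l, config.phi_h)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("refine", cid, e)

        truth = masks[i] > 0
        dsc_raw_all.append(overlap_metrics(pseudo_raw.values > 0, truth)[0])
        dsc_ref_all.append(overlap_metrics(pseudo_ref.values > 0, truth)[0])

        scr = (extract_scribbles(pseudo_ref, config.scribble_stride, config.scribble_band)
               if config.use_pce
               else ScribbleSet(np.full(vol.data.shape, UNLABELED, dtype=np.int16),
                                provenance="disabled"))
        refined_pseudos.append(pseudo_ref)
        scribble_sets.append(scr)

        cio.save_nifti(refined.values.astype(np.float32),
                       out_dir / f"{cid}_refined_cam.nii.gz", vol.spacing)
        cio.save_pseudolabel(pseudo_ref, out_dir / f"{cid}_pseudo.nii.gz", vol.spacing)
        cio.save_scribbles(scr, out_dir / f"{cid}_scribbles.nii.gz", vol.spacing)

    # -- segmentation training -------------------------------------------
    try:
        seg_cfg = SegmenterConfig(
            channels=config.seg_channels, steps=config.seg_steps,
            epsilon=config.epsilon, delta=config.delta, gamma=config.gamma,
            lambda_pce=config.lambda4 if config.use_pce else 0.0,
            lambda_seg=config.lambda5, seed=config.seed,
        )
        model, ema, seg_history = train_segmenter(
            volumes, refined_pseudos, scribble_sets, seg_cfg, truth_masks=masks)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("segmentation", "all", e)
    pd.DataFrame(seg_history).to_csv(out_dir / "loss_seg.csv", index=False)

    # -- metrics ----------------------------------------------------------
    rows = []
    for i, cid in enumerate(case_ids):
        truth = masks[i] > 0
        if i in ema:
            pred = ema[i].y[..., 1] > 0.5
        else:
            pred = model.predict(volumes[i]) > 0.5
        dsc, iou = overlap_metrics(pred, truth)
        row = {"case_id": cid, "dsc": dsc, "iou": iou,
               "dsc_pseudo_raw": dsc_raw_all[i], "dsc_pseudo_refined": dsc_ref_all[i]}
        if pred.any() and truth.any():
            row["hd95"] = hd95(pred, truth, volumes[i].spacing)
        rows.append(row)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out_dir / "metrics.csv", index=False)

    l_pce = float(np.mean([h["loss_pce"] for h in seg_history[-10:]]))
    l_seg = float(np.mean([h["loss_seg"] for h in seg_history[-10:]]))
    decomposition = {
        "l_cls": l_cls,
        "l_struct": float(np.mean(struct_vals)) if struct_vals else 0.0,
        "l_smooth": float(np.mean(smooth_vals)) if smooth_vals else 0.0,
        "l_aff": float(np.mean(aff_vals)) if aff_vals else 0.0,
        "l_pce": l_pce if config.use_pce else 0.0,
        "l_seg": l_seg,
    }
    decomposition["total"] = total_loss(
        decomposition["l_cls"],
        decomposition["l_struct"] if config.use_struct else 0.0,
        decomposition["l_smooth"] if config.use_smooth else 0.0,
        decomposition["l_aff"] if config.use_aff else 0.0,
        decomposition["l_pce"], decomposition["l_seg"], weights)
    (out_dir / "loss_decomposition.json").write_text(json.dumps(decomposition, indent=2))

    summary = {
        "n_cases": len(cases),
        "mean_dsc": float(metrics["dsc"].mean()),
        "mean_iou": float(metrics["iou"].mean()),
        "mean_dsc_pseudo_raw": float(np.mean(dsc_raw_all)),
        "mean_dsc_pseudo_refined": float(np.mean(dsc_ref_all)),
    }
    if len(cases) >= 6:
        _, p = paired_wilcoxon(dsc_ref_all, dsc_raw_all)
        summary["wilcoxon_p_refined_vs_raw"] = p
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return out_dir
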