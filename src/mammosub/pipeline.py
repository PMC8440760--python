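"""End-to-end temporal-subtraction pipeline.

One pair flows through: preprocess both views with identical parameters,
register the prior onto the recent view (Demons), warp, subtract, detect
candidate microcalcifications in the difference image, extract features,
and match candidates to ground truth.  A ``recent_only`` arm skips
registration and subtraction and detects directly in the preprocessed
recent image — the comparison arm that temporal subtraction is measured
against.

Two-round classification chains on top: round 1 separates candidate
regions into normal tissue vs. true microcalcification; round 2 separates
the true microcalcifications into benign vs. suspicious.  By default round
2 consumes the ground-truth true microcalcifications (so its denominators
are the annotated counts); a flag switches it to round-1 survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as cls
from . import detection as det
from . import features as feat
from .config import load_config
from .io import MammoImage
from .phantom import PhantomSpec, make_phantom_pair
from .preprocess import preprocess
from .registration import DemonsParams, demons_register, warp
from .subtraction import RemovalStats, SubtractionResult, removal_stats, subtract


@dataclass
class PairResult:
    """Everything the pipeline produces for one image pair."""

    recent_pp: MammoImage
    prior_pp: Optional[MammoImage]
    mask: np.ndarray
    field: Optional[object]
    subtraction: Optional[SubtractionResult]
    candidates: list[det.CandidateRegion]
    match: Optional[det.MatchResult] = None
    removal: Optional[RemovalStats] = None


def _demons_params(cfg: dict) -> DemonsParams:
    r = cfg["registration"]
    return DemonsParams(
        sigma_fluid=r["sigma_fluid"],
        sigma_diffusion=r["sigma_diffusion"],
        pyramid_factors=tuple(r["pyramid_factors"]),
        iterations=r["iterations"],
        step_cap=r["step_cap"],
    )


def run_pair(
    recent: MammoImage,
    prior: Optional[MammoImage],
    config: Optional[dict] = None,
    annotations: Optional[Sequence] = None,
    truth: Optional[Sequence] = None,
    recent_only: bool = False,
) -> PairResult:
    """Run the full (or recent-only) pipeline on one pair.

    ``annotations`` are point marks used for candidate matching; ``truth``
    (phantom ground truth with old/new status) additionally enables removal
    accounting.
    """
    cfg = config or load_config()
    pcfg = cfg["preprocess"]
    recent_pp, mask = preprocess(recent, **pcfg)

    field_ = None
    sub = None
    prior_pp = None
    if not recent_only:
        if prior is None:
            raise ValueError("prior image required unless recent_only=True")
        prior_pp, _ = preprocess(prior, **pcfg)
        field_ = demons_register(
            recent_pp, prior_pp, params=_demons_params(cfg), mask=mask.mask
        )
        prior_warped = warp(prior_pp, field_)
        sub = subtract(recent_pp, prior_warped, mask)
        detect_img = sub.diff
        source = "subtracted"
    else:
        detect_img = recent_pp.pixels
        source = "recent_only"

    dcfg = cfg["detection"]
    candidates = det.detect(
        detect_img,
        mask=mask.mask,
        threshold=dcfg["threshold"],
        window=dcfg["window"],
        min_area=dcfg["min_area"],
        gap_close_radius=dcfg["gap_close_radius"],
        source=source,
    )
    for c in candidates:
        c.patient_id = recent.patient_id
        c.view = recent.view.value if recent.view else ""

    match = None
    if annotations is not None:
        match = det.match_candidates(candidates, annotations, tol_px=dcfg["tol_px"])

    removal = None
    if truth is not None and sub is not None:
        scfg = cfg["subtraction"]
        removal = removal_stats(
            sub.diff,
            recent_pp,
            truth,
            residual_frac_threshold=scfg["residual_frac_threshold"],
            window_half_px=scfg["window_half_px"],
        )

    return PairResult(
        recent_pp=recent_pp,
        prior_pp=prior_pp,
        mask=mask.mask,
        field=field_,
        subtraction=sub,
        candidates=candidates,
        match=match,
        removal=removal,
    )


def candidate_feature_table(
    result: PairResult,
    annotations: Sequence,
    tol_px: float = 8.0,
) -> pd.DataFrame:
    """Feature table for every candidate of a pair, labelled by matching:
    ``is_mc`` marks candidates matched to an annotation, ``mc_label`` the
    matched annotation's benign/suspicious label."""
    img = (
        result.subtraction.diff
        if result.subtraction is not None
        else result.recent_pp.pixels
    )
    match = det.match_candidates(result.candidates, annotations, tol_px=tol_px)
    matched = {ci: ai for ci, ai in match.pairs}
    rows = []
    for ci, cand in enumerate(result.candidates):
        try:
            fv = feat.extract_features(cand, img)
        except feat.FeatureError:
            continue
        row = {"patient_id": cand.patient_id, "source": cand.source}
        row.update(fv.values)
        row["is_mc"] = int(ci in matched)
        row["mc_label"] = (
            annotations[matched[ci]].label.value if ci in matched else ""
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_phantom_pair(spec: PhantomSpec, config: Optional[dict] = None, recent_only: bool = False):
    """Generate one phantom pair and push it through the pipeline; returns
    (pair, result)."""
    pair = make_phantom_pair(spec)
    anns = [t.annotation for t in pair.truth]
    result = run_pair(
        pair.recent,
        pair.prior,
        config=config,
        annotations=anns,
        truth=pair.truth,
        recent_only=recent_only,
    )
    return pair, result


def phantom_study(
    seeds: Sequence[int],
    config: Optional[dict] = None,
    grid: Sequence[float] = (0.05, 0.08, 0.12, 0.16, 0.2, 0.25, 0.3, 0.4),
    spec_kwargs: Optional[dict] = None,
    collect_tables: bool = False,
) -> dict:
    """Run the full pipeline over a batch of default phantoms and collect
    the desk-scale study quantities.

    One pass per seed covers three questions at once: how well Demons
    recovers the known inter-round deformation (mean endpoint error against
    the generator's true field, relative to leaving the pair unregistered);
    how well subtraction suppresses unchanged content (contrast ratios,
    intensity reduction, removal of old vs. new microcalcifications); and
    how detection in the subtracted image compares with detection in the
    recent image alone.  Sensitivity is counted on the *new*
    microcalcifications; false positives are candidates matching no
    ground-truth spot at all.  Each arm operates at its own optimised
    binarisation threshold (argmax of tp - fp over ``grid``, ties toward
    the higher threshold), and the recent-only arm is additionally read off
    at the smallest threshold whose pooled sensitivity reaches the
    subtracted arm's, giving a false-positive comparison at equal
    sensitivity.
    """
    from scipy import ndimage as _ndi

    cfg = config or load_config()
    tol = cfg["detection"]["tol_px"]
    pooled = {arm: {t: [0, 0, 0] for t in grid} for arm in ("subtracted", "recent_only")}
    per_seed: list[dict] = []
    tables = {"subtracted": [], "recent_only": []}
    for seed in seeds:
        pair = make_phantom_pair(PhantomSpec(seed=seed, **(spec_kwargs or {})))
        pair.recent.patient_id = f"S{seed}"
        new_anns = [t.annotation for t in pair.truth if t.status == "new"]
        all_anns = [t.annotation for t in pair.truth]
        res_s = run_pair(pair.recent, pair.prior, config=cfg, truth=pair.truth)
        res_r = run_pair(pair.recent, None, config=cfg, recent_only=True)
        if collect_tables:
            for arm, res in (("subtracted", res_s), ("recent_only", res_r)):
                tables[arm].append(candidate_feature_table(res, all_anns, tol_px=tol))

        eval_mask = _ndi.binary_erosion(pair.breast_mask & res_s.mask, iterations=8)
        tf = pair.true_field
        epe = float(
            np.hypot(res_s.field.dy - tf.dy, res_s.field.dx - tf.dx)[eval_mask].mean()
        )
        epe_zero = float(tf.magnitude[eval_mask].mean())
        sub = res_s.subtraction
        per_seed.append(
            {
                "epe_px": epe,
                "epe_zero_px": epe_zero,
                "contrast_ratio_recent": sub.contrast_ratio_recent,
                "contrast_ratio_diff": sub.contrast_ratio_diff,
                "intensity_reduction_pct": sub.intensity_reduction_pct,
                "n_old": res_s.removal.n_prior_mcs,
                "n_old_removed": res_s.removal.n_overlapping,
                "n_new": len(new_anns),
                "n_new_removed": res_s.removal.n_new_removed,
            }
        )
        for arm, res in (("subtracted", res_s), ("recent_only", res_r)):
            img = res.subtraction.diff if res.subtraction is not None else res.recent_pp.pixels
            for t in grid:
                cands = det.detect(img, mask=res.mask, threshold=t, source=arm)
                m_new = det.match_candidates(cands, new_anns, tol_px=tol)
                m_all = det.match_candidates(cands, all_anns, tol_px=tol)
                acc = pooled[arm][t]
                acc[0] += m_new.tp
                acc[1] += m_all.fp
                acc[2] += len(new_anns)

    def _optimum(arm: str) -> float:
        return max(sorted(grid), key=lambda t: (pooled[arm][t][0] - pooled[arm][t][1], t))

    t_sub = _optimum("subtracted")
    tp_s, fp_s, n_s = pooled["subtracted"][t_sub]
    sens_target = tp_s / n_s if n_s else float("nan")
    fp_rec = None
    sens_rec = None
    for t in sorted(grid):
        tp_r, fp_r, n_r = pooled["recent_only"][t]
        if n_r and tp_r / n_r >= sens_target and (fp_rec is None or fp_r < fp_rec):
            fp_rec, sens_rec = fp_r, tp_r / n_r
    epe_total = sum(s["epe_px"] for s in per_seed)
    epe_zero_total = sum(s["epe_zero_px"] for s in per_seed)
    return {
        "per_seed": per_seed,
        "epe_reduction_pct": 100.0 * (1.0 - epe_total / epe_zero_total),
        "threshold_subtracted": t_sub,
        "threshold_recent_only": _optimum("recent_only"),
        "sensitivity_subtracted": sens_target,
        "fp_subtracted": fp_s,
        "sensitivity_recent_only": sens_rec,
        "fp_recent_only": fp_rec,
        "curves": pooled,
        "n_pairs": len(per_seed),
        "tables": {
            arm: (pd.concat(parts, ignore_index=True) if parts else None)
            for arm, parts in tables.items()
        }
        if collect_tables
        else None,
    }


def two_round_classify(
    table: pd.DataFrame,
    cv_scheme: str = "LOPO",
    k: int = 5,
    classifiers: Sequence[str] = cls.CLASSIFIER_NAMES,
    seed: int = 0,
    round2_from_round1: bool = False,
    p_cut: float = 0.05,
    top_k: int = 20,
) -> dict:
    """Two-round classification over a labelled candidate feature table.

    The table needs columns ``patient_id``, ``is_mc``, ``mc_label`` and the
    96 canonical features.  Round 1: candidates -> normal tissue vs. true
    microcalcification.  Round 2: true microcalcifications -> benign vs.
    suspicious; by default it consumes the ground-truth true
    microcalcifications, optionally only round-1 survivors.
    """
    fnames = feat.FEATURE_NAMES
    X = table[fnames].to_numpy(dtype=np.float64)
    groups = table["patient_id"].to_numpy(dtype=str)

    out: dict = {}
    y1 = table["is_mc"].to_numpy(dtype=int)
    sel1 = feat.select_features(table[fnames], y1, p_cut=p_cut, top_k=top_k, seed=seed)
    cols1 = [fnames.index(n) for n in sel1.selected]
    cv1 = cls.build_cv(groups, scheme=cv_scheme, k=k, seed=seed)
    out["round1"], scores1 = cls.train_eval(
        X[:, cols1], y1, groups, cv1, classifiers, seed=seed, return_scores=True
    )
    out["round1_features"] = sel1.selected

    keep = (table["is_mc"] == 1).to_numpy()
    if round2_from_round1:
        best_name = max(out["round1"], key=lambda n: out["round1"][n].auc)
        cut = out["round1"][best_name].cutoff
        survived = scores1[best_name] >= cut
        keep &= survived
    sub = table[keep & (table["mc_label"] != "").to_numpy()]
    if sub["mc_label"].nunique() == 2 and sub["patient_id"].nunique() >= 2:
        y2 = (sub["mc_label"] == "suspicious").to_numpy(dtype=int)
        g2 = sub["patient_id"].to_numpy(dtype=str)
        sel2 = feat.select_features(sub[fnames], y2, p_cut=p_cut, top_k=top_k, seed=seed)
        cols2 = [fnames.index(n) for n in sel2.selected]
        cv2 = cls.build_cv(g2, scheme=cv_scheme, k=k, seed=seed)
        out["round2"] = cls.train_eval(
            sub[fnames].to_numpy(dtype=np.float64)[:, cols2], y2, g2, cv2, classifiers, seed=seed
        )
        out["round2_features"] = sel2.selected
    return out
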