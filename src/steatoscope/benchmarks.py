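"""Reproducible synthetic end-to-end studies.

Two desk-scale studies exercise the full pipelines on generated cohorts with
known ground truth:

* :func:`macro_recovery_study` — generate a graded cohort, train the
  five-class region classifier on part of it, cross-validate, quantify
  percent steatosis on the held-out slides and compare with the generator's
  truth.
* :func:`micro_detection_study` — train the pixel-wise foam classifier on
  subsampled annotated pixels and score held-out foamy-vs-plain pixels.

Both are deterministic given their seed and return plain dictionaries.
"""

from __future__ import annotations

import numpy as np

from . import classifier as clf
from .annotations import polygon_pixels, subsample_pixels
from .features import micro_feature_matrix
from .gabor_bank import macro_bank, micro_bank
from .metrics import auroc, col_recall, row_precision
from .pipeline import (analyze_slide, label_regions, macro_feature_matrix,
                       train_micro)
from .quantify import fit_grade_curve, grade_from_percent
from .synthetic import GeneratorParams, generate_dataset, generate_slide


def _slide_features(analysis, bank):
    if not analysis.regions:
        return None
    return macro_feature_matrix(analysis.channels, analysis.regions, bank,
                                analysis.tissue)


def macro_recovery_study(seed: int = 0, dims: tuple[int, int] = (512, 512),
                         grade_mix: tuple[int, int, int, int] = (3, 3, 3, 3),
                         n_heldout_per_grade: int = 1, folds: int = 10,
                         ) -> dict:
    """Train on part of a graded synthetic cohort, quantify the rest.

    The last ``n_heldout_per_grade`` slides of each grade are held out; the
    classifier never sees them.  Feature matrices are extracted once per
    slide and reused for training (labeled rows) and quantification (all
    rows).
    """
    slides = generate_dataset(grade_mix=grade_mix, seed=seed, dims=dims)
    bank = macro_bank()
    per_grade: dict[int, list[int]] = {}
    for i, s in enumerate(slides):
        per_grade.setdefault(s.grade, []).append(i)
    test_idx = sorted(
        i for g, idxs in per_grade.items()
        for i in idxs[len(idxs) - n_heldout_per_grade:])
    train_idx = [i for i in range(len(slides)) if i not in test_idx]

    analyses, feats, labels = [], [], []
    for s in slides:
        an = analyze_slide(s.image, slide_id=s.slide_id,
                           annotations=s.truth_annotations)
        analyses.append(an)
        feats.append(_slide_features(an, bank))
        labels.append(label_regions(an))

    X_parts, y_parts = [], []
    for i in train_idx:
        if feats[i] is None or not labels[i]:
            continue
        lab = labels[i]
        rows = [rid for rid in feats[i].index if rid in lab]
        X_parts.append(feats[i].loc[rows].to_numpy())
        y_parts.extend(lab[rid] for rid in rows)
    X = np.vstack(X_parts)
    y = np.array(y_parts)
    feature_names = list(feats[train_idx[0]].columns)
    model = clf.train(X, y, seed=seed, feature_names=feature_names,
                      kind="macro", bank_config=bank.to_json())
    cv = clf.cross_validate(X, y, folds=folds, seed=seed,
                            positive_class="macro_fat")

    def quantified_percent(i):
        if feats[i] is None:
            return 0.0
        pred, _ = clf.predict(model, feats[i].to_numpy())
        areas = np.array([r.pixel_count for r in analyses[i].regions])
        fat = areas[pred == "macro_fat"].sum()
        return 100.0 * fat / analyses[i].tissue.tissue_area_px

    est_all = np.array([quantified_percent(i) for i in range(len(slides))])
    truth_all = np.array([s.true_percent_steatosis for s in slides])
    est = est_all[test_idx]
    truth = truth_all[test_idx]
    ss_res = float(((est - truth) ** 2).sum())
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    r2_identity = 1.0 - ss_res / ss_tot
    grades_ok = [grade_from_percent(min(est_all[i], 100.0)) == slides[i].grade
                 for i in test_idx]
    curve = fit_grade_curve(est_all, [s.grade for s in slides])

    return {
        "n_slides": len(slides),
        "n_train_instances": int(len(y)),
        "heldout_slides": [slides[i].slide_id for i in test_idx],
        "heldout_est_percent": est.tolist(),
        "heldout_truth_percent": truth.tolist(),
        "heldout_r2": r2_identity,
        "heldout_grade_accuracy_pct": 100.0 * np.mean(grades_ok),
        "grade_curve_r2": curve.r_squared,
        "cv_accuracy_pct": cv.accuracy,
        "cv_macro_fat_precision_pct": row_precision(cv.confusion, "macro_fat"),
        "cv_macro_fat_recall_pct": col_recall(cv.confusion, "macro_fat"),
        "cv_auroc_pct": cv.auroc,
    }


def micro_detection_study(seed: int = 0, dims: tuple[int, int] = (512, 512),
                          n_train: int = 6, n_test: int = 4,
                          rate_micro: float = 0.02,
                          rate_other: float = 0.001,
                          eval_rate: float = 0.15) -> dict:
    """Pixel-wise foam detection with held-out AUROC.

    Training uses the annotation subsampling rule at desk-scale rates
    (the in-vivo rates scaled by 100 so a small cohort still yields a
    usable training set); evaluation scores a subsample of held-out foamy
    and non-foamy annotated pixels.
    """
    n = n_train + n_test
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    slides = [generate_slide(
        GeneratorParams(dims=dims, target_percent=10.0, micro_focus_count=6),
        seed=int(seeds[i]), slide_id=f"micro-{i}") for i in range(n)]
    analyses = [analyze_slide(s.image, slide_id=s.slide_id,
                              annotations=s.truth_annotations)
                for s in slides]
    bank = micro_bank(dims)
    model = train_micro(analyses[:n_train], rate_micro=rate_micro,
                        rate_other=rate_other, seed=seed, bank=bank)

    scores, truth = [], []
    for j, (an, s) in enumerate(zip(analyses[n_train:], slides[n_train:])):
        shape = an.channels.shape
        mic, oth = [], []
        for ann in s.truth_annotations:
            if not ann.is_polygon:
                continue
            px = polygon_pixels(ann, shape)
            (mic if ann.label == "micro_fat" else oth).extend(px)
        mic = list(dict.fromkeys(mic))
        oth = list(dict.fromkeys(oth))
        mic = subsample_pixels(mic, eval_rate, seed + 31 * j)
        oth = subsample_pixels(oth, eval_rate / 3.0, seed + 31 * j + 1)
        X = micro_feature_matrix(an.channels["gray"], mic + oth, bank)
        _, sc = clf.predict(model, X)
        pos_col = model.classes.index("micro_fat")
        scores.extend(sc[:, pos_col].tolist())
        truth.extend([1] * len(mic) + [0] * len(oth))

    return {
        "n_slides": n,
        "n_eval_pixels": len(truth),
        "n_eval_positive": int(sum(truth)),
        "auroc_pct": 100.0 * auroc(scores, truth),
    }
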