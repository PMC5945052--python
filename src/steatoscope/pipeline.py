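"""End-to-end orchestration of the macro and micro pipelines.

This module glues the stage modules together: channel derivation, tissue
masking, white-region detection, annotation matching, feature extraction,
training and quantification.  The CLI and the example scripts are thin
wrappers over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as clf
from .annotations import Annotation, match_regions, polygon_pixels, subsample_pixels
from .features import macro_feature_matrix, micro_feature_matrix, micro_feature_names
from .gabor_bank import GaborBank, macro_bank, micro_bank
from .image_io import ChannelStack, SlideImage, channel_stack
from .quantify import QuantResult, steatosis_fraction
from .tissue_mask import TissueMask, grow_background
from .white_regions import WhiteMask, WhiteRegion, detect_white_regions

logger = logging.getLogger(__name__)

#: The five white-region classes of the macro model (Table-1 convention);
#: microvesicular fat may be appended via configuration.
MACRO_CLASSES = ("central_vein", "macro_fat", "bile_duct", "portal_vein",
                 "portal_artery")


@dataclass
class SlideAnalysis:
    """Derived products of the candidate-detection stages for one slide."""

    slide_id: str
    image: SlideImage
    channels: ChannelStack
    tissue: TissueMask
    white: WhiteMask
    regions: list[WhiteRegion]
    annotations: list[Annotation] = field(default_factory=list)


def analyze_slide(image: SlideImage, slide_id: str = "",
                  annotations: list[Annotation] | None = None,
                  tolerance: float = 0.12, gamma: float = 6.0,
                  min_area: int = 60, max_area: int | None = None,
                  connectivity: int = 8, seed: int | None = None,
                  ) -> SlideAnalysis:
    """Run channels -> tissue mask -> white-region detection on one image."""
    channels = channel_stack(image)
    tissue = grow_background(channels["G"], tolerance=tolerance)
    white, regions = detect_white_regions(
        channels["G"], tissue, gamma=gamma, min_area=min_area,
        max_area=max_area, connectivity=connectivity, seed=seed)
    return SlideAnalysis(slide_id=slide_id, image=image, channels=channels,
                         tissue=tissue, white=white, regions=regions,
                         annotations=list(annotations or []))


def label_regions(analysis: SlideAnalysis,
                  classes=MACRO_CLASSES) -> dict[int, str]:
    """Map region_id -> class label using the slide's annotations.

    Point annotations label the region they fall on; polygon annotations
    label every region fully inside.  The first label wins on conflict.
    """
    labels: dict[int, str] = {}
    for ann in analysis.annotations:
        if ann.label not in classes:
            continue
        for reg in match_regions(ann, analysis.regions):
            labels.setdefault(reg.region_id, ann.label)
    return labels


def macro_training_table(analyses: list[SlideAnalysis], bank: GaborBank,
                         classes=MACRO_CLASSES) -> pd.DataFrame:
    """Feature rows for every annotated candidate region across slides.

    Columns: slide_id, region_id, label, then the 554 feature columns.
    """
    frames = []
    for an in analyses:
        labels = label_regions(an, classes)
        if not labels:
            continue
        labeled = [r for r in an.regions if r.region_id in labels]
        feats = macro_feature_matrix(an.channels, labeled, bank, an.tissue,
                                     all_regions=an.regions)
        feats.insert(0, "label", [labels[r.region_id] for r in labeled])
        feats.insert(0, "region_id", [r.region_id for r in labeled])
        feats.insert(0, "slide_id", an.slide_id)
        frames.append(feats.reset_index(drop=True))
    if not frames:
        raise ValueError("no annotated regions found on any slide")
    return pd.concat(frames, ignore_index=True)


def train_macro(analyses: list[SlideAnalysis], bank: GaborBank | None = None,
                C: float = 1.0, seed: int = 0,
                classes=MACRO_CLASSES) -> clf.TrainedModel:
    bank = bank or macro_bank()
    table = macro_training_table(analyses, bank, classes)
    feature_cols = [c for c in table.columns
                    if c not in ("slide_id", "region_id", "label")]
    return clf.train(table[feature_cols].to_numpy(),
                     table["label"].to_numpy(), C=C, seed=seed,
                     feature_names=feature_cols, kind="macro",
                     bank_config=bank.to_json())


def classify_regions(analysis: SlideAnalysis, model: clf.TrainedModel,
                     bank: GaborBank) -> pd.DataFrame:
    """Predicted class for every candidate region on a slide."""
    if not analysis.regions:
        return pd.DataFrame(columns=["region_id", "predicted", "area"])
    feats = macro_feature_matrix(analysis.channels, analysis.regions, bank,
                                 analysis.tissue)
    labels, _ = clf.predict(model, feats.to_numpy(),
                            feature_names=list(feats.columns))
    return pd.DataFrame({
        "region_id": [r.region_id for r in analysis.regions],
        "predicted": labels,
        "area": [r.pixel_count for r in analysis.regions]})


def quantify_slide(analysis: SlideAnalysis, model: clf.TrainedModel,
                   bank: GaborBank) -> QuantResult:
    """Percent macrosteatosis from classifier-identified fat regions."""
    preds = classify_regions(analysis, model, bank)
    fat_ids = set(preds.loc[preds["predicted"] == "macro_fat", "region_id"])
    fat_regions = [r for r in analysis.regions if r.region_id in fat_ids]
    return steatosis_fraction(fat_regions, analysis.tissue)


# --- microsteatosis ------------------------------------------------------

def micro_training_pixels(annotations: list[Annotation],
                          shape: tuple[int, int], rate_micro: float,
                          rate_other: float, seed: int,
                          ) -> tuple[list[tuple[int, int]], list[str]]:
    """Subsampled labeled pixels: micro_fat polygons vs every other polygon."""
    micro_px: list[tuple[int, int]] = []
    other_px: list[tuple[int, int]] = []
    for ann in annotations:
        if not ann.is_polygon:
            continue
        px = polygon_pixels(ann, shape)
        (micro_px if ann.label == "micro_fat" else other_px).extend(px)
    # overlapping survey polygons may repeat pixels; keep first occurrence
    micro_px = list(dict.fromkeys(micro_px))
    other_px = list(dict.fromkeys(other_px))
    coords, labels = [], []
    if micro_px:
        sub = subsample_pixels(micro_px, rate_micro, seed)
        coords.extend(sub)
        labels.extend(["micro_fat"] * len(sub))
    if other_px:
        sub = subsample_pixels(other_px, rate_other, seed + 1)
        coords.extend(sub)
        labels.extend(["other"] * len(sub))
    return coords, labels


def train_micro(analyses: list[SlideAnalysis],
                rate_micro: float = 0.0002, rate_other: float = 0.00001,
                C: float = 1.0, seed: int = 0,
                bank: GaborBank | None = None) -> clf.TrainedModel:
    """Pixel-wise binary micro classifier from polygon-annotated slides."""
    Xs, ys = [], []
    for i, an in enumerate(analyses):
        gray = an.channels["gray"]
        b = bank or micro_bank(gray.shape)
        coords, labels = micro_training_pixels(
            an.annotations, gray.shape, rate_micro, rate_other,
            seed + 1000 * i)
        if not coords:
            continue
        Xs.append(micro_feature_matrix(gray, coords, b))
        ys.extend(labels)
    if not Xs:
        raise ValueError("no polygon-annotated pixels on any slide")
    X = np.vstack(Xs)
    b = bank or micro_bank(analyses[0].channels.shape)
    return clf.train(X, np.array(ys), C=C, seed=seed,
                     feature_names=micro_feature_names(b), kind="micro",
                     bank_config=b.to_json())


def micro_scores(analysis: SlideAnalysis, model: clf.TrainedModel,
                 coords, bank: GaborBank | None = None) -> np.ndarray:
    """micro_fat decision scores at the given pixel coordinates."""
    gray = analysis.channels["gray"]
    b = bank or micro_bank(gray.shape)
    X = micro_feature_matrix(gray, coords, b)
    _, scores = clf.predict(model, X)
    return scores[:, model.classes.index("micro_fat")]
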