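"""The study's statistical protocol and the detection/segmentation evaluator.

Statistics: Shapiro-Wilk normality and Levene homogeneity checks, one- and
two-way ANOVA (with interaction), Tukey HSD pairwise comparisons at family
level alpha, and compact letter displays.  Assumption checks never block
the ANOVA — deviations are reported and the analysis proceeds, relying on
the robustness of the F statistic under a balanced design; the report is
always emitted so the caveat is visible.

Evaluation: COCO-style mean average precision for boxes and masks.  Per
class, predictions are sorted by confidence and greedily matched one-to-one
to ground truth at each IoU threshold; AP is the area under the
all-point-interpolated precision-recall curve; mAP averages over classes,
and mAP50-95 additionally averages over IoU thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .labels import polygon_to_mask

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


# ---- assumption checks -------------------------------------------------------


def check_assumptions(groups: Mapping[str, Sequence[float]]) -> dict:
    """Shapiro-Wilk normality per group plus Levene homogeneity across groups.

    Constant groups are flagged (normality is undefined there) rather than
    crashing.  Returns ``{"normality": DataFrame, "levene_stat", "levene_p"}``.
    """
    rows = []
    usable = []
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if len(arr) < 3:
            raise ValueError(f"group {name!r}: normality check needs n >= 3")
        constant = bool(np.ptp(arr) == 0)
        if constant:
            rows.append({"group": name, "n": len(arr), "shapiro_W": np.nan,
                         "shapiro_p": np.nan, "constant": True})
        else:
            w, p = stats.shapiro(arr)
            rows.append({"group": name, "n": len(arr), "shapiro_W": w,
                         "shapiro_p": p, "constant": False})
        usable.append(arr)
    if len(usable) >= 2 and any(np.ptp(a) > 0 for a in usable):
        lev_stat, lev_p = stats.levene(*usable)
    else:
        lev_stat, lev_p = np.nan, np.nan
    report = pd.DataFrame(rows)
    if report["constant"].any() or (report["shapiro_p"] < 0.05).any() or (
        np.isfinite(lev_p) and lev_p < 0.05
    ):
        warnings.warn(
            "assumption deviations detected; proceeding with ANOVA regardless "
            "(balanced-design robustness), see the assumption report",
            stacklevel=2,
        )
    return {"normality": report, "levene_stat": float(lev_stat), "levene_p": float(lev_p)}


# ---- ANOVA -------------------------------------------------------------------


def anova(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
) -> pd.DataFrame:
    """One-way or two-way (with interaction) ANOVA table.

    Two-way designs use the textbook SS decomposition via OLS (type II,
    identical to the balanced-design decomposition when cells are
    balanced); unbalanced input is accepted with a warning.  Empty cells in
    a two-way design are rejected.  The degenerate all-constant case is
    reported as F = 0, p = 1.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    factors = list(factors)
    if len(factors) not in (1, 2):
        raise ValueError("anova supports one or two factors")
    df = table.rename(columns={response: "_y", **{f: f"_f{i}" for i, f in enumerate(factors)}})
    if len(factors) == 1:
        formula = "_y ~ C(_f0)"
    else:
        counts = df.groupby(["_f0", "_f1"]).size().unstack(fill_value=0)
        if (counts.values == 0).any():
            raise ValueError("two-way design has empty cells; cannot decompose")
        if counts.values.std() > 0:
            warnings.warn("unbalanced design: using type-II sums of squares", stacklevel=2)
        formula = "_y ~ C(_f0) * C(_f1)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels emits noise on degenerate fits
        fit = ols(formula, data=df).fit()
        out = sm.stats.anova_lm(fit, typ=2)
    rename = {"C(_f0)": factors[0]}
    if len(factors) == 2:
        rename.update({"C(_f1)": factors[1], "C(_f0):C(_f1)": f"{factors[0]}:{factors[1]}"})
    out = out.rename(index=rename)
    # degenerate data: zero effect and zero residual variance -> F 0, p 1
    tol = 1e-10 * max(1.0, float(np.mean(df["_y"]) ** 2))
    resid_ss = out.loc["Residual", "sum_sq"]
    for term in out.index:
        if term == "Residual":
            continue
        if out.loc[term, "sum_sq"] < tol and resid_ss < tol:
            out.loc[term, "F"] = 0.0
            out.loc[term, "PR(>F)"] = 1.0
    return out


# ---- Tukey HSD and letter displays -------------------------------------------


@dataclass
class TukeyResult:
    table: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    significance: pd.DataFrame  # symmetric boolean matrix
    alpha: float


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD pairwise comparisons (studentized range, family level alpha)."""
    names = list(groups)
    if len(names) < 2:
        empty = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj", "reject"])
        sig = pd.DataFrame(False, index=names, columns=names)
        return TukeyResult(table=empty, significance=sig, alpha=alpha)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
    labels = np.concatenate([[n] * len(groups[n]) for n in names])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        res._results_table.data[1:], columns=[c.lower() for c in res._results_table.data[0]]
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    table = table.rename(columns={"p-adj": "p_adj"})
    # statsmodels rounds p-adj for display; recover full precision
    table["p_adj"] = res.pvalues
    table["reject"] = res.reject
    sig = pd.DataFrame(False, index=names, columns=names)
    for _, row in table.iterrows():
        sig.loc[row["group1"], row["group2"]] = bool(row["reject"])
        sig.loc[row["group2"], row["group1"]] = bool(row["reject"])
    return TukeyResult(table=table, significance=sig, alpha=alpha)


def compact_letter_display(
    significance: pd.DataFrame, uppercase: bool = False
) -> Dict[str, str]:
    """Letters such that groups sharing a letter are pairwise non-significant.

    Insert-and-absorb construction: start with one letter covering all
    groups; for each significant pair split every letter containing both;
    absorb letters whose group set is contained in another's.  By
    construction every non-significant pair shares at least one letter and
    no significant pair does.
    """
    names = list(significance.index)
    sets: List[set] = [set(names)]
    for i, j in itertools.combinations(names, 2):
        if not bool(significance.loc[i, j]):
            continue
        for col in [c for c in sets if i in c and j in c]:
            sets.remove(col)
            sets.extend([col - {j}, col - {i}])
        # absorb: drop sets contained in another (and exact duplicates)
        kept: List[set] = []
        for c in sets:
            if any(c < d for d in sets) or any(c == d for d in kept):
                continue
            kept.append(c)
        sets = [c for c in kept if c]
    sets.sort(key=lambda c: min(names.index(g) for g in c))
    alphabet = string.ascii_uppercase if uppercase else string.ascii_lowercase
    letters = {name: "" for name in names}
    for k, col in enumerate(sets):
        for name in names:
            if name in col:
                letters[name] += alphabet[k % 26]
    return letters


# ---- validation regression ---------------------------------------------------


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    residuals: np.ndarray
    residual_shapiro_p: float
    n: int


def validation_regression(
    estimates: Sequence[float], references: Sequence[float]
) -> RegressionResult:
    """OLS of automated estimates on reference measurements, with R^2 and
    residual diagnostics (the agreement analysis for the length estimator)."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if len(est) != len(ref) or len(est) < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.ptp(ref) == 0:
        raise ValueError("reference values have zero variance; regression undefined")
    fit = stats.linregress(ref, est)
    residuals = est - (fit.intercept + fit.slope * ref)
    shapiro_p = float(stats.shapiro(residuals)[1]) if np.ptp(residuals) > 0 else np.nan
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        residuals=residuals,
        residual_shapiro_p=shapiro_p,
        n=len(est),
    )


# ---- mAP evaluator -----------------------------------------------------------


@dataclass
class EvalInstance:
    """One predicted or ground-truth instance: class, polygon (pixel (x, y)
    vertices), and, for predictions, a confidence in [0, 1]."""

    cls: int
    polygon: np.ndarray  # (N, 2) pixel coords, columns (x, y)
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    def bbox(self) -> Tuple[float, float, float, float]:
        x0, y0 = self.polygon.min(axis=0)
        x1, y1 = self.polygon.max(axis=0)
        return float(x0), float(y0), float(x1), float(y1)

    def mask(self, image_shape: Sequence[int]) -> np.ndarray:
        h, w = image_shape[:2]
        pts = self.polygon / np.array([w, h])
        return polygon_to_mask(pts, (h, w))


@dataclass
class ImageEval:
    image_shape: Tuple[int, int]
    predictions: List[EvalInstance] = field(default_factory=list)
    truths: List[EvalInstance] = field(default_factory=list)


@dataclass
class DetectionSet:
    images: List[ImageEval]
    iou_thresholds: Sequence[float] = IOU_THRESHOLDS

    def __post_init__(self) -> None:
        allowed = set(IOU_THRESHOLDS)
        if any(round(float(t), 2) not in allowed for t in self.iou_thresholds):
            raise ValueError("IoU thresholds must come from {0.50, 0.55, ..., 0.95}")


def _box_iou(a, b) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 0.0


def _rasterize_crop(inst: "EvalInstance", image_shape) -> Tuple[np.ndarray, int, int]:
    """Rasterize a polygon into its own bounding window (plus origin)."""
    from skimage.draw import polygon as draw_polygon

    h, w = image_shape[:2]
    rows = np.clip(inst.polygon[:, 1], 0, h - 1)
    cols = np.clip(inst.polygon[:, 0], 0, w - 1)
    r0, c0 = int(np.floor(rows.min())), int(np.floor(cols.min()))
    crop = np.zeros(
        (int(np.ceil(rows.max())) - r0 + 2, int(np.ceil(cols.max())) - c0 + 2), bool
    )
    rr, cc = draw_polygon(rows - r0, cols - c0, shape=crop.shape)
    crop[rr, cc] = True
    return crop, r0, c0


def _crop_iou(a, b) -> float:
    """IoU of two cropped masks given their origins; 0 if windows disjoint."""
    (ma, ra, ca), (mb, rb, cb) = a, b
    r0 = max(ra, rb)
    c0 = max(ca, cb)
    r1 = min(ra + ma.shape[0], rb + mb.shape[0])
    c1 = min(ca + ma.shape[1], cb + mb.shape[1])
    area_a = int(ma.sum())
    area_b = int(mb.sum())
    if r1 <= r0 or c1 <= c0:
        inter = 0
    else:
        inter = int(
            np.logical_and(
                ma[r0 - ra : r1 - ra, c0 - ca : c1 - ca],
                mb[r0 - rb : r1 - rb, c0 - cb : c1 - cb],
            ).sum()
        )
    union = area_a + area_b - inter
    return inter / union if union else 0.0


def _average_precision(confidences, matched, n_positive) -> float:
    """All-point interpolated AP from per-prediction TP flags."""
    if n_positive == 0:
        return 0.0
    order = np.argsort(-np.asarray(confidences, dtype=float), kind="stable")
    tp = np.asarray(matched, dtype=float)[order]
    fp = 1.0 - tp
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_positive
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # precision envelope (monotone non-increasing from the right)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def _iou_matrix(image: ImageEval, cls: int, kind: str) -> Tuple[np.ndarray, List[int], int]:
    preds = [p for p in image.predictions if p.cls == cls]
    gts = [g for g in image.truths if g.cls == cls]
    iou = np.zeros((len(preds), len(gts)))
    if preds and gts:
        if kind == "box":
            pb = [p.bbox() for p in preds]
            gb = [g.bbox() for g in gts]
            for i, a in enumerate(pb):
                for j, b in enumerate(gb):
                    iou[i, j] = _box_iou(a, b)
        else:
            pm = [_rasterize_crop(p, image.image_shape) for p in preds]
            gm = [_rasterize_crop(g, image.image_shape) for g in gts]
            for i, a in enumerate(pm):
                for j, b in enumerate(gm):
                    iou[i, j] = _crop_iou(a, b)
    confs = [p.confidence if p.confidence is not None else 1.0 for p in preds]
    return iou, confs, len(gts)


def _class_ap(dets: DetectionSet, cls: int, kind: str, threshold: float,
              cache: dict) -> float:
    confidences: List[float] = []
    matched: List[bool] = []
    n_positive = 0
    for idx, image in enumerate(dets.images):
        key = (idx, cls, kind)
        if key not in cache:
            cache[key] = _iou_matrix(image, cls, kind)
        iou, confs, n_gt = cache[key]
        n_positive += n_gt
        order = np.argsort(-np.asarray(confs, dtype=float), kind="stable")
        taken = np.zeros(n_gt, dtype=bool)
        flags = [False] * len(confs)
        for i in order:
            if n_gt:
                candidates = np.where(~taken, iou[i], -1.0)
                j = int(np.argmax(candidates)) if len(candidates) else -1
                if j >= 0 and candidates[j] >= threshold:
                    taken[j] = True
                    flags[i] = True
        confidences.extend(confs)
        matched.extend(flags)
    return _average_precision(confidences, matched, n_positive)


def evaluate_map(dets: DetectionSet) -> dict:
    """Box and mask mAP at IoU 0.50 and averaged over 0.50:0.05:0.95.

    Classes are the union of classes appearing in predictions or ground
    truth; a class with predictions but no ground truth contributes AP 0
    (reported in ``per_class``).  Values are fractions in [0, 1].
    """
    classes = sorted(
        {i.cls for img in dets.images for i in img.predictions}
        | {i.cls for img in dets.images for i in img.truths}
    )
    if not classes:
        raise ValueError("detection set contains no instances")
    cache: dict = {}
    per_class: Dict[str, Dict[int, float]] = {}
    result = {}
    for kind in ("box", "mask"):
        ap_by_thr = {}
        for thr in dets.iou_thresholds:
            aps = {c: _class_ap(dets, c, kind, float(thr), cache) for c in classes}
            ap_by_thr[round(float(thr), 2)] = aps
        map_per_thr = {t: float(np.mean(list(aps.values()))) for t, aps in ap_by_thr.items()}
        result[f"map_{kind}50"] = map_per_thr.get(0.5, float("nan"))
        result[f"map_{kind}50_95"] = float(np.mean(list(map_per_thr.values())))
        per_class[kind] = ap_by_thr[0.5] if 0.5 in ap_by_thr else {}
    result["per_class_ap50"] = per_class
    result["n_classes"] = len(classes)
    return result
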