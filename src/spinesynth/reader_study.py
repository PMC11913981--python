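"""Turing-test reader-study analytics.

Radiologists judge standardized 2D images as natively acquired ("real") or
model-generated ("generated").  This module computes per-rater
misclassification rates (false / (false + correct)), cohort mean +/- sd,
Fleiss' kappa over the rated labels with a large-sample standard error and a
99% confidence interval, the conventional interpretation bands
(<=0.2 Poor, <=0.4 Fair, <=0.6 Moderate, <=0.8 Good, <=1.0 Very good), and
the standardized 150 x 150 px / 1.1 mm presentation images shown to raters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "RatingTable",
    "KappaResult",
    "misclassification_rate",
    "summarize_rates",
    "rate_summary",
    "fleiss_kappa",
    "interpret_kappa",
    "prepare_turing_image",
    "round_half_up",
    "load_example_rates",
]

CATEGORIES = ("real", "generated")
Z_99 = 2.576


def load_example_rates() -> pd.DataFrame:
    """Bundled per-rater misclassification rates of a seven-reader spine Turing study.

    Columns ``rater``, ``t1w``, ``stir``: each value is one radiologist's
    misclassification rate over 120 image pairs of that modality.
    """
    path = Path(__file__).parent / "data" / "turing_rates.csv"
    return pd.read_csv(path)


@dataclass
class RatingTable:
    """Items x raters binary judgments with per-item ground truth."""

    items: pd.DataFrame  # columns: item_id, modality, truth
    ratings: pd.DataFrame  # index aligned with items; one column per rater

    def __post_init__(self) -> None:
        if len(self.items) != len(self.ratings):
            raise ValueError("items and ratings row counts differ")
        if self.ratings.isna().any().any():
            raise ValueError("rating table has missing cells")
        bad = set(np.unique(self.ratings.values)) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unexpected rating labels: {sorted(bad)}")
        if not set(self.items["truth"]).issubset(CATEGORIES):
            raise ValueError("truth labels must be 'real' or 'generated'")

    @property
    def raters(self) -> list[str]:
        return list(self.ratings.columns)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingTable":
        df = pd.read_csv(path)
        meta_cols = ["item_id", "modality", "truth"]
        rater_cols = [c for c in df.columns if c not in meta_cols]
        return cls(df[meta_cols].copy(), df[rater_cols].copy())

    def subset(self, modality: str) -> "RatingTable":
        mask = self.items["modality"] == modality
        if not mask.any():
            raise ValueError(f"no items with modality {modality!r}")
        return RatingTable(self.items[mask].reset_index(drop=True),
                           self.ratings[mask.values].reset_index(drop=True))


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci99: tuple
    band: str
    degenerate: bool = False
    message: str = ""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up rounding (0.425 -> 0.43), as used for reported rates."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def misclassification_rate(table: RatingTable, rater: str, modality: str) -> float:
    """Fraction of a rater's judgments on one modality that disagree with truth."""
    if rater not in table.raters:
        raise ValueError(f"unknown rater {rater!r}")
    sub = table.subset(modality)
    wrong = (sub.ratings[rater].values != sub.items["truth"].values).sum()
    return wrong / len(sub.items)


def rate_summary(rates) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of per-rater rates, 2-dp half-up."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least two raters")
    return round_half_up(float(rates.mean())), round_half_up(float(rates.std(ddof=1)))


def summarize_rates(table_or_rates, modality: str | None = None) -> tuple[float, float]:
    """Cohort misclassification summary: mean +/- sd across raters.

    Accepts either a :class:`RatingTable` (with ``modality``) or a sequence of
    precomputed per-rater rates.
    """
    if isinstance(table_or_rates, RatingTable):
        if modality is None:
            raise ValueError("modality required when summarizing a RatingTable")
        rates = [
            misclassification_rate(table_or_rates, r, modality)
            for r in table_or_rates.raters
        ]
    else:
        rates = table_or_rates
    return rate_summary(rates)


def _fleiss_from_counts(counts: np.ndarray) -> tuple[float, float]:
    """Fleiss' kappa and its large-sample SE from an items x categories count matrix."""
    counts = np.asarray(counts, dtype=float)
    n_items, _ = counts.shape
    n_raters = counts.sum(axis=1)
    if not np.all(n_raters == n_raters[0]):
        raise ValueError("all items must have the same number of ratings")
    n = n_raters[0]
    p_j = counts.sum(axis=0) / (n_items * n)
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        raise ZeroDivisionError("chance agreement is 1: all ratings in one category")
    kappa = (p_bar - p_e) / (1.0 - p_e)
    # large-sample variance of overall kappa (Fleiss/Nee/Landis tradition)
    q_j = 1.0 - p_j
    s = float((p_j * q_j).sum())
    var = (2.0 / (n_items * n * (n - 1))) * (s**2 - float((p_j * q_j * (q_j - p_j)).sum())) / s**2
    return float(kappa), float(np.sqrt(max(var, 0.0)))


def fleiss_kappa(table: RatingTable, modality: str | None = None) -> KappaResult:
    """Fleiss' kappa over rated labels, with SE, 99% CI, and interpretation band.

    Agreement is computed on what the raters *said* (real vs generated), not
    on whether they were correct.  ``ci99 = kappa +/- 2.576 se``.
    """
    sub = table.subset(modality) if modality is not None else table
    if len(sub.raters) < 2 or len(sub.items) < 2:
        raise ValueError("fleiss_kappa needs >= 2 raters and >= 2 items")
    labels = sub.ratings.values
    counts = np.stack(
        [(labels == c).sum(axis=1) for c in CATEGORIES], axis=1
    )
    try:
        kappa, se = _fleiss_from_counts(counts)
    except ZeroDivisionError:
        return KappaResult(
            float("nan"), float("nan"), (float("nan"), float("nan")), "Poor",
            degenerate=True, message="all ratings fall in one category; kappa undefined",
        )
    ci = (kappa - Z_99 * se, kappa + Z_99 * se)
    return KappaResult(kappa, se, ci, interpret_kappa(kappa))


def interpret_kappa(k: float) -> str:
    """Conventional agreement bands; boundaries belong to the lower band."""
    if k > 1.0 + 1e-12:
        raise ValueError("kappa cannot exceed 1")
    if k <= 0.2:
        return "Poor"
    if k <= 0.4:
        return "Fair"
    if k <= 0.6:
        return "Moderate"
    if k <= 0.8:
        return "Good"
    return "Very good"


def prepare_turing_image(
    vol: ImageVolume,
    center,
    size: int = 150,
    resolution: float = 1.1,
) -> np.ndarray:
    """Standardized 2D sagittal presentation image for the reader study.

    Extracts the sagittal slice through the world-mm ``center``, resamples
    in-plane to ``resolution`` mm/px, crops/pads to ``size x size`` centred on
    the requested point, and windows intensities to [0, 1] for display.
    """
    cvox = vol.world_to_voxel(np.asarray(center, dtype=float))
    shape = np.asarray(vol.shape)
    if np.any(cvox < -0.5) or np.any(cvox > shape - 0.5):
        raise ValueError(f"center {center} lies outside the volume")
    i0 = int(round(cvox[0]))
    sl = np.asarray(vol.data[i0], dtype=float)
    sp = vol.spacing[1:]
    zoom = sp / resolution
    sl = ndimage.zoom(sl, zoom, order=1, mode="nearest")
    c = np.array([cvox[1] * zoom[0], cvox[2] * zoom[1]])

    half = size / 2.0
    out = np.zeros((size, size), dtype=float)
    lo = np.round(c - half).astype(int)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(lo + size, sl.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1]] = sl[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1]]
    vmin, vmax = out.min(), out.max()
    if vmax > vmin:
        out = (out - vmin) / (vmax - vmin)
    return out
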