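"""Image-quality metrics between native and generated volumes.

Per-case L1, MSE, PSNR and SSIM on a [0, 1] evaluation rescale of the
[-1, 1] tensors (``data_range`` 1, so PSNR = -10 log10 MSE in dB), cohort
aggregation, and paired Wilcoxon signed-rank comparison between methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ssim3d
from .volume import ImageVolume

__all__ = ["MetricsReport", "pairwise_metrics", "aggregate", "paired_signed_rank"]


@dataclass
class MetricsReport:
    per_case: pd.DataFrame  # columns: case, L1, MSE, PSNR, SSIM
    aggregate: dict
    method: str = ""


def _to_unit(x) -> np.ndarray:
    data = np.asarray(x.data if isinstance(x, ImageVolume) else x, dtype=np.float64)
    return (data + 1.0) / 2.0


def pairwise_metrics(real, gen, on_unit_scale: bool = False) -> dict:
    """L1, MSE, PSNR (dB) and SSIM between one native/generated pair.

    Inputs are [-1, 1] volumes (mapped internally to [0, 1]) unless
    ``on_unit_scale`` says they already live in [0, 1].  Identical volumes
    give MSE 0 and a PSNR of +inf.
    """
    a = np.asarray(real.data if isinstance(real, ImageVolume) else real, dtype=np.float64)
    b = np.asarray(gen.data if isinstance(gen, ImageVolume) else gen, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("metric volumes must share a grid")
    if not on_unit_scale:
        a = (a + 1.0) / 2.0
        b = (b + 1.0) / 2.0
    diff = a - b
    l1 = float(np.mean(np.abs(diff)))
    mse = float(np.mean(diff**2))
    psnr = float("inf") if mse == 0 else float(10.0 * np.log10(1.0 / mse))
    ssim = ssim3d(a, b, data_range=1.0)
    return {"L1": l1, "MSE": mse, "PSNR": psnr, "SSIM": ssim}


def aggregate(per_case: list[dict], method: str = "") -> MetricsReport:
    """Arithmetic per-metric means over cases (L1/MSE lower, PSNR/SSIM higher better)."""
    if not per_case:
        raise ValueError("aggregate needs at least one case")
    df = pd.DataFrame(per_case)
    cols = ["L1", "MSE", "PSNR", "SSIM"]
    agg = {c: float(df[c].mean()) for c in cols}
    return MetricsReport(df, agg, method)


def paired_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-case metrics.

    Zero differences are discarded (Wilcoxon's convention); the exact null
    distribution is used for n <= 25 without ties, otherwise the normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_signed_rank expects two equal-length 1D arrays")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return 1.0
    ties = len(np.unique(np.abs(nz))) < len(nz)
    if len(nz) <= 25 and not ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.pvalue)
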