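"""Paired comparison of enhancers with and without a prior linear transform.

For each of six classical enhancers (gamma, power law, log, CLAHE, HE,
AHE) the harness computes EME and PSNR on the enhancer applied to the
windowed 8-bit original (t0) and to the linearly transformed image (t1),
then runs a paired t-test per metric.  PSNR uses the untransformed
windowed original as the reference for both arms so the two are
comparable.  Raw two-sided p-values are reported; an optional Bonferroni
flag corrects across the twelve tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enhance import CLASSIC_ENHANCERS, linear_transform
from .metrics import eme, psnr
from .phantom import StagedSample
from .preprocess import DEFAULT_WINDOW, WindowConfig, to_uint8, window

__all__ = ["TTestResult", "paired_ttest", "enhancement_comparison"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float | None
    df: int
    degenerate: bool = False


def paired_ttest(x, y) -> TTestResult:
    """Two-sided paired t-test of ``y - x`` with sample (n-1) variance.

    Zero-variance differences are flagged degenerate and carry no p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        return TTestResult(t=0.0, p=None, df=n - 1, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(p), df=n - 1)


def enhancement_comparison(samples: list[StagedSample],
                           static_lt: tuple[float, float] = (1.25, 0.0),
                           methods: dict | None = None,
                           window_cfg: WindowConfig = DEFAULT_WINDOW,
                           block_size: int = 8,
                           bonferroni: bool = False) -> pd.DataFrame:
    """One row per enhancer with paired EME and PSNR statistics."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    methods = methods or CLASSIC_ENHANCERS
    alpha, beta = static_lt

    per_image = []
    for s in samples:
        orig8 = to_uint8(window(s.image, window_cfg), window_cfg.lo, window_cfg.hi)
        lt8 = to_uint8(window(linear_transform(s.image, alpha, beta), window_cfg),
                       window_cfg.lo, window_cfg.hi)
        per_image.append((orig8, lt8))

    rows = []
    n_tests = 2 * len(methods)
    for name, fn in methods.items():
        eme0, eme1, psnr0, psnr1 = [], [], [], []
        for orig8, lt8 in per_image:
            e0 = fn(orig8)
            e1 = fn(lt8)
            eme0.append(eme(e0, block_size))
            eme1.append(eme(e1, block_size))
            psnr0.append(psnr(orig8, e0))
            psnr1.append(psnr(orig8, e1))
        res_eme = paired_ttest(eme0, eme1)
        res_psnr = paired_ttest(psnr0, psnr1)

        def _p(res):
            if res.p is None:
                return None
            return min(1.0, res.p * n_tests) if bonferroni else res.p

        rows.append({
            "method": name, "n": len(samples),
            "eme_mean_t0": float(np.mean(eme0)), "eme_mean_t1": float(np.mean(eme1)),
            "eme_t": res_eme.t, "eme_p": _p(res_eme),
            "eme_degenerate": res_eme.degenerate,
            "psnr_mean_t0": float(np.mean(psnr0)), "psnr_mean_t1": float(np.mean(psnr1)),
            "psnr_t": res_psnr.t, "psnr_p": _p(res_psnr),
            "psnr_degenerate": res_psnr.degenerate,
        })
    return pd.DataFrame(rows)
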