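"""Crispant plate-reader screen statistics.

Relative-YFP normalization against unablated controls, the screen's
two-sample normal-approximation sample-size design, per-gene testing of
each crispant's ablated wells against the wild-type ablated reference with
a one-way ANOVA F (two-group case; equivalent to a two-sided pooled t), the
Benjamini-Krieger-Yekutieli two-stage linear step-up FDR correction, and
hit classification (significant at adjusted p <= 0.01, trending in
(0.01, 0.1], otherwise no effect).

The BKY procedure returns decisions, not adjusted p-values; adjusted p here
is defined by rejection-threshold inversion, the smallest q on a 1e-4 grid
at which the gene is rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "normalize_relative_yfp",
    "min_sample_size",
    "bky_reject",
    "bky_adjust",
    "screen_test",
    "classify_hits",
    "empirical_power",
    "null_screen_false_alarm_rate",
]

WT_REFERENCE = "wildtype_ablated"


@dataclass(frozen=True)
class ScreenParams:
    significance_fdr: float = 0.01
    trending_upper: float = 0.10
    design_alpha: float = 0.05
    design_power: float = 0.80
    design_effect_fraction: float = 0.30
    min_n: int = 8
    q_grid_resolution: float = 1e-4

    def __post_init__(self) -> None:
        if not self.significance_fdr < self.trending_upper < 1:
            raise ValueError("need significance_fdr < trending_upper < 1")


def normalize_relative_yfp(data: pd.DataFrame) -> pd.DataFrame:
    """Express each ablated well relative to its plate's unablated controls.

    Requires columns (well, gene, arm, genotype, fluorescence, plate); each
    plate must carry >= 2 unablated wild-type control wells (arm
    'unablated_control'). Returns the ablated rows with a ``relative_yfp``
    column: fluorescence / mean(plate's unablated wild-type controls).
    """
    required = {"well", "gene", "arm", "genotype", "fluorescence", "plate"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for plate, sub in data.groupby("plate"):
        ctrl = sub[(sub["arm"] == "unablated_control")
                   & (sub["genotype"] == "wildtype")]
        if len(ctrl) < 2:
            raise ValueError(f"plate {plate!r} has <2 unablated control wells")
        ref = ctrl["fluorescence"].mean()
        if ref <= 0:
            raise ValueError(f"plate {plate!r} control mean is <= 0")
        abl = sub[sub["arm"] == "ablated"].copy()
        abl["relative_yfp"] = abl["fluorescence"] / ref
        out.append(abl)
    return pd.concat(out, ignore_index=True)


def min_sample_size(alpha: float, power: float, d: float) -> int:
    """Two-sample two-sided normal-approximation sample size per group.

    n = ceil(2 * (z_{1-alpha/2} + z_{power})^2 / d^2), at least 2. With
    alpha 0.05 and power 0.80 this gives n = 16 at d = 1.0 and n = 8 at
    d = 1.41 (the screen's design point for a 30% effect).
    """
    if d <= 0:
        raise ValueError("standardized effect d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0,1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return max(2, math.ceil(2 * z**2 / d**2))


def _bh_count(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the BH linear step-up at ``level``."""
    m = p_sorted.size
    thresh = level * np.arange(1, m + 1) / m
    ok = np.flatnonzero(p_sorted <= thresh)
    return int(ok[-1] + 1) if ok.size else 0


def bky_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Krieger-Yekutieli two-stage step-up decisions at level q.

    Stage 1: BH at q' = q/(1+q); estimate true nulls m0 = m - r1. Stage 2:
    BH at q * m / m0. If stage 1 rejects nothing, nothing is rejected; if it
    rejects everything, everything is.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q1 = q / (1.0 + q)
    r1 = _bh_count(p_sorted, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    r2 = _bh_count(p_sorted, q1 * m / m0)
    reject = np.zeros(m, dtype=bool)
    reject[order[:r2]] = True
    return reject


def bky_adjust(pvals: np.ndarray, resolution: float = 1e-4) -> np.ndarray:
    """Adjusted p by rejection-threshold inversion on a fixed q-grid.

    The adjusted p of a test is the smallest q (grid of step ``resolution``)
    at which the two-stage procedure rejects it; tests never rejected on the
    grid get 1.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    adj = np.ones(m)
    grid = np.arange(resolution, 1.0 + resolution / 2, resolution)
    pending = np.ones(m, dtype=bool)
    for q in grid:  # rejection sets grow with q, so first hit is the minimum
        if not pending.any():
            break
        rej = bky_reject(p, q)
        newly = rej & pending
        adj[newly] = q
        pending &= ~rej
    return adj


def screen_test(
    relative: pd.DataFrame,
    params: ScreenParams | None = None,
    reference: str = WT_REFERENCE,
) -> pd.DataFrame:
    """Per-gene ANOVA against the wild-type ablated reference + two-stage FDR.

    ``relative`` needs columns (gene, relative_yfp); the reference group's
    rows carry ``reference`` as the gene label. Each crispant's ablated
    wells are compared with the reference wells by a one-way ANOVA F test
    (two groups, i.e. a two-sided pooled t). The per-gene p family is then
    BKY-adjusted and classified.
    """
    params = params or ScreenParams()
    groups = {g: sub["relative_yfp"].to_numpy()
              for g, sub in relative.groupby("gene")}
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    ref = groups.pop(reference)
    if ref.size < params.min_n:
        raise ValueError(
            f"reference group has {ref.size} wells, fewer than min_n={params.min_n}"
        )
    rows = []
    for gene, vals in sorted(groups.items()):
        if vals.size < 2:
            raise ValueError(f"gene {gene!r} has fewer than 2 wells")
        if vals.var(ddof=1) == 0 and ref.var(ddof=1) == 0:
            p = 1.0 if vals.mean() == ref.mean() else 0.0
        else:
            p = float(stats.f_oneway(vals, ref).pvalue)
        rows.append(dict(gene=gene, n_wells=int(vals.size),
                         relative_yfp=float(vals.mean()), p=p))
    out = pd.DataFrame(rows)
    out["p_adj"] = bky_adjust(out["p"].to_numpy(), params.q_grid_resolution)
    out = classify_hits(out, params, reference_mean=float(ref.mean()))
    logger.info(
        "screen_test: m=%d genes, %d significant, %d trending",
        len(out), int((out["class"] == "significant").sum()),
        int((out["class"] == "trending").sum()),
    )
    return out


def classify_hits(
    result: pd.DataFrame,
    params: ScreenParams | None = None,
    reference_mean: float = 1.0,
) -> pd.DataFrame:
    """Assign hit classes and effect directions from adjusted p-values.

    significant: p_adj <= 0.01; trending: 0.01 < p_adj <= 0.1; else
    no_effect. Direction: enhanced if the gene's mean relative YFP exceeds
    the wild-type reference mean, inhibited if below, none for no_effect.
    """
    params = params or ScreenParams()
    out = result.copy()
    p_adj = out["p_adj"].to_numpy()
    cls = np.where(
        p_adj <= params.significance_fdr, "significant",
        np.where(p_adj <= params.trending_upper, "trending", "no_effect"),
    )
    direction = np.where(out["relative_yfp"].to_numpy() > reference_mean,
                         "enhanced", "inhibited")
    direction = np.where(cls == "no_effect", "none", direction)
    out["class"] = cls
    out["direction"] = direction
    return out


def _pooled_z_reject(a: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized two-sample pooled-variance test against the normal critical
    value (the design's normal approximation); arrays are (reps, n)."""
    n1, n2 = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    z = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return np.abs(z) > stats.norm.ppf(1 - alpha / 2)


def empirical_power(plate_config, alpha: float = 0.05) -> float:
    """Monte-Carlo power of the screen's two-sample design.

    Simulates ``plate_config.n_reps`` replicate plates with the plate-reader
    simulator and counts rejections of the pooled-variance test at the
    normal-approximation critical value (the same approximation behind
    ``min_sample_size``).
    """
    from mgregen.synthetic_data import simulate_plate_reader

    df = simulate_plate_reader(plate_config)
    n = plate_config.n_wells_per_arm
    reps = plate_config.n_reps
    ctrl = (df[df["arm"] == "control"].sort_values(["rep", "well"])
            ["fluorescence"].to_numpy().reshape(reps, n))
    trt = (df[df["arm"] == "treated"].sort_values(["rep", "well"])
           ["fluorescence"].to_numpy().reshape(reps, n))
    return float(_pooled_z_reject(trt, ctrl, alpha).mean())


def null_screen_false_alarm_rate(
    m: int = 91,
    n_wells: int = 8,
    n_ref_wells: int = 8,
    q: float = 0.01,
    n_screens: int = 2000,
    seed: int = 0,
) -> float:
    """Fraction of global-null screens with any BKY discovery at level q.

    Every gene's wells and the reference wells are drawn from the same
    normal distribution; each screen runs the per-gene pooled two-sample
    test and the two-stage FDR decision at ``q``. Under the global null the
    procedure's FDR control implies this rate stays near (below ~2x) q.
    """
    rng = np.random.default_rng([seed, 91])
    any_hit = 0
    for _ in range(n_screens):
        ref = rng.normal(0.0, 1.0, size=n_ref_wells)
        genes = rng.normal(0.0, 1.0, size=(m, n_wells))
        vr = ref.var(ddof=1)
        vg = genes.var(axis=1, ddof=1)
        sp2 = ((n_wells - 1) * vg + (n_ref_wells - 1) * vr) / (
            n_wells + n_ref_wells - 2
        )
        t = (genes.mean(axis=1) - ref.mean()) / np.sqrt(
            sp2 * (1 / n_wells + 1 / n_ref_wells)
        )
        p = 2 * stats.t.sf(np.abs(t), n_wells + n_ref_wells - 2)
        if bky_reject(p, q).any():
            any_hit += 1
    return any_hit / n_screens
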