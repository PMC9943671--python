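"""Ratiometric decoding of matched spots into virtual codes.

Every matched spot yields a ratio vector ``r_c = I_De_c / I_Re``.  Because
both numerator and denominator scale with the amplicon repeat count K, the
ratio reads out the barcode repeat level independent of amplicon length —
this is the entire point of carrying a reference probe on every repeat.

Decoding is nearest-theoretical-level with rejection: after a per-channel
robust scale calibration, a spot is assigned the code minimizing the
level-relative L1 distance ``sum_c |r_c/s_c - level_c| / level_c`` (relative,
because the binomial spread of bound probes grows with level), and is
rejected when the best distance exceeds a margin, when the best distance is
tied, or when any calibrated ratio falls below 0.5 (under the lowest level —
where degenerate and nonspecific spots land).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import CodeBook

__all__ = [
    "REJECT",
    "DecoderConfig",
    "DecodeResult",
    "compute_ratio_vectors",
    "calibrate_ratio_scale",
    "classify_spots",
    "decode_cells",
]

REJECT = "REJECT"


@dataclass
class DecoderConfig:
    reject_margin: float = 0.35  # level-relative units, fixed a priori
    min_ratio: float = 0.5  # calibrated ratios below this reject the spot
    min_calibration_spots: int = 20
    scale_span: float = 3.0  # calibration searches s in [1/span, span]
    scale_grid_points: int = 241
    tie_tol: float = 1e-9


@dataclass
class DecodeResult:
    decoded: pd.DataFrame  # per-spot: ratios, assigned gene or REJECT, distance
    counts: pd.DataFrame  # genes x cells decoded copy numbers
    rejected_per_cell: pd.Series
    scales: np.ndarray  # per-channel calibration factors


def _ratio_columns(df: pd.DataFrame) -> list[str]:
    cols = sorted(c for c in df.columns if c.startswith("I_De"))
    if not cols:
        raise ValueError("no detection-channel intensity columns (I_De*) found")
    return cols


def compute_ratio_vectors(matched: pd.DataFrame) -> pd.DataFrame:
    """Per-spot De/Re ratios; spots with non-positive reference are flagged.

    Adds columns ``r_1..r_C`` and ``ref_ok``; ratios of flagged spots are NaN
    (never a division by zero) and such spots are later rejected.
    """
    de_cols = _ratio_columns(matched)
    out = matched.copy()
    i_re = out["I_Re"].to_numpy(dtype=float)
    ok = i_re > 0
    out["ref_ok"] = ok
    for ci, col in enumerate(de_cols):
        r = np.full(len(out), np.nan)
        r[ok] = out[col].to_numpy(dtype=float)[ok] / i_re[ok]
        out[f"r_{ci + 1}"] = r
    return out


def _level_residual(r_over_s: np.ndarray, n_levels: int) -> np.ndarray:
    level = np.clip(np.round(r_over_s), 1, n_levels)
    return np.abs(r_over_s - level) / level


def calibrate_ratio_scale(
    ratios: np.ndarray, n_levels: int, config: DecoderConfig | None = None
) -> np.ndarray:
    """Per-channel robust scale mapping observed ratios onto integer levels.

    A coarse geometric grid over ``s`` minimizes the median level-relative
    residual of ``r/s`` (ties resolved toward s = 1, the identity scale),
    then the estimate is refined by ``s = median(r / nearest level)``.  With
    too few usable spots a channel falls back to the identity scale with a
    warning.
    """
    config = config or DecoderConfig()
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    n_channels = ratios.shape[1]
    scales = np.ones(n_channels)
    exponents = np.linspace(-1, 1, config.scale_grid_points)
    grid = config.scale_span**exponents
    for c in range(n_channels):
        r = ratios[:, c]
        r = r[np.isfinite(r) & (r >= config.min_ratio)]
        if r.size < config.min_calibration_spots:
            warnings.warn(
                f"channel {c + 1}: only {r.size} spots for calibration; using identity scale"
            )
            continue
        costs = np.array([np.median(_level_residual(r / s, n_levels)) for s in grid])
        best = costs.min()
        candidates = grid[costs <= best + config.tie_tol]
        s = float(candidates[np.argmin(np.abs(np.log(candidates)))])
        for _ in range(2):  # median refinement on the locked-in level assignment
            level = np.clip(np.round(r / s), 1, n_levels)
            s = float(np.median(r / level))
        scales[c] = s
    return scales


def classify_spots(
    ratios: np.ndarray,
    codebook: CodeBook,
    scales: np.ndarray | None = None,
    config: DecoderConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each ratio vector to a codebook gene or reject it.

    Returns (labels, distances); ``labels`` holds gene ids or ``REJECT``.
    Rejection triggers on: non-finite ratios, any calibrated ratio below
    ``min_ratio``, best distance above ``reject_margin``, or a tie between
    the two best codes.
    """
    config = config or DecoderConfig()
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    n, c = ratios.shape
    levels = codebook.level_matrix()  # (M, C)
    if levels.shape[1] != c:
        raise ValueError("ratio vectors and codebook disagree on channel count")
    genes = np.array(codebook.genes, dtype=object)
    scales = np.ones(c) if scales is None else np.asarray(scales, dtype=float)
    r_cal = ratios / scales

    dist = np.abs(r_cal[:, None, :] - levels[None, :, :]) / levels[None, :, :]
    dist = dist.sum(axis=2)  # (n, M)
    order = np.argsort(dist, axis=1)
    best = order[:, 0]
    d_best = dist[np.arange(n), best]
    tie = np.zeros(n, dtype=bool)
    if levels.shape[0] > 1:
        d_second = dist[np.arange(n), order[:, 1]]
        tie = (d_second - d_best) <= config.tie_tol
    bad = (
        ~np.isfinite(r_cal).all(axis=1)
        | (np.nan_to_num(r_cal, nan=-1.0) < config.min_ratio).any(axis=1)
        | (d_best > config.reject_margin)
        | tie
    )
    labels = genes[best].copy()
    labels[bad] = REJECT
    distances = d_best.copy()
    distances[~np.isfinite(distances)] = np.inf
    return labels, distances


def decode_cells(
    matched: pd.DataFrame,
    codebook: CodeBook,
    config: DecoderConfig | None = None,
) -> DecodeResult:
    """Calibrate, classify and aggregate matched spots per cell.

    Calibration is per field (single-cell spot counts are far too small to
    calibrate per cell).  Decoded plus rejected spot counts always equal the
    input count.
    """
    config = config or DecoderConfig()
    n_channels = codebook.config.n_detection_channels
    ratio_cols = [f"r_{i + 1}" for i in range(n_channels)]
    genes = codebook.genes
    if matched.empty:
        counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=[])
        return DecodeResult(
            decoded=matched.copy(),
            counts=counts,
            rejected_per_cell=pd.Series(dtype=int),
            scales=np.ones(n_channels),
        )
    with_r = compute_ratio_vectors(matched)
    ratios = with_r[ratio_cols].to_numpy(dtype=float)
    scales = calibrate_ratio_scale(ratios, codebook.config.n_levels, config)
    labels, distances = classify_spots(ratios, codebook, scales, config)
    decoded = with_r.copy()
    decoded["assigned"] = labels
    decoded["distance"] = distances

    if "cell_id" not in decoded.columns:
        decoded["cell_id"] = -1
    cells = sorted(decoded["cell_id"].unique())
    accepted = decoded[decoded["assigned"] != REJECT]
    counts = (
        accepted.groupby(["assigned", "cell_id"]).size().unstack(fill_value=0)
        .reindex(index=genes, columns=cells, fill_value=0)
    )
    counts.index.name = "gene_id"
    rejected = (
        decoded[decoded["assigned"] == REJECT].groupby("cell_id").size()
        .reindex(cells, fill_value=0)
    )
    return DecodeResult(
        decoded=decoded, counts=counts.astype(int), rejected_per_cell=rejected, scales=scales
    )
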