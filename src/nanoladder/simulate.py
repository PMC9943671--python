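"""Synthetic single-cell amplicon data with the statistical structure the
ratiometric decoding analysis assumes.

The generator draws, per cell and gene, a true copy number from a negative
binomial (cell-to-cell overdispersion), thins it binomially with the in situ
detection efficiency (default 30%), places the surviving amplicons inside the
cell, and assigns each a rolling-circle repeat count ``K`` from a discretized
lognormal (RCA efficiency is heterogeneous in crowded cytoplasm, so amplicon
lengths — and hence raw brightnesses — vary widely).  Photometry then binds
detection probes ``Binomial(K * level, h_DFP)`` and reference probes
``Binomial(K, h_RFP)`` per amplicon; the detection/reference ratio cancels
``K``, which is exactly the normalization rationale the reference channel
exists for.  Nonspecific background spots are Poisson per cell: ~16 in
conventional primer-assisted RCA versus ~0.2 in the RNA-primed mode.

Rendering produces multi-channel z-stacks (Gaussian spots, Poisson shot
noise, Gaussian read noise, 16-bit quantization) plus label masks, written as
multi-page TIFF with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field

from .codebook import CodeBook

__all__ = [
    "GeneModel",
    "RepeatLaw",
    "NonspecificModel",
    "OpticsModel",
    "GeometryModel",
    "QpcrModel",
    "SimulationConfig",
    "GroundTruth",
    "ImageStack",
    "DEFAULT_GENE_PANEL",
    "default_cell_line_panel",
    "simulate_ground_truth",
    "simulate_spot_intensities",
    "render_image_stack",
    "simulate_qpcr",
]


class GeneModel(BaseModel):
    """Negative-binomial copy-number law for one gene (mean, dispersion).

    ``dispersion`` is the NB size/shape parameter r: variance = mean +
    mean^2 / r, so smaller r means stronger cell-to-cell overdispersion.
    """

    mean: float = Field(gt=0)
    dispersion: float = Field(default=5.0, gt=0)


class RepeatLaw(BaseModel):
    """Discretized lognormal for the RCA tandem-repeat count K (min 1)."""

    log_mean: float = math.log(60.0)
    log_sigma: float = Field(default=0.5, ge=0)
    minimum: int = Field(default=1, ge=1)


class NonspecificModel(BaseModel):
    """Poisson background-spot rate per cell by amplification mode."""

    mode: Literal["rna_primed", "primer_assisted"] = "rna_primed"
    rate_rna_primed: float = Field(default=0.2, ge=0)
    rate_primer_assisted: float = Field(default=16.0, ge=0)

    @property
    def rate(self) -> float:
        return self.rate_rna_primed if self.mode == "rna_primed" else self.rate_primer_assisted


class OpticsModel(BaseModel):
    """Fluorophore brightness and camera noise."""

    det_brightness: float = Field(default=60.0, gt=0)  # counts per bound DFP
    ref_brightness: float = Field(default=60.0, gt=0)  # counts per bound RFP
    shot_noise: bool = True
    read_noise_sigma: float = Field(default=2.0, ge=0)
    background: float = Field(default=100.0, ge=0)
    psf_sigma_px: float = Field(default=1.3, gt=0)


class GeometryModel(BaseModel):
    """Cell layout and acquisition geometry."""

    cell_radius_px: float = Field(default=45.0, gt=0)  # ~14 um at 0.16 um/px
    nucleus_radius_px: float = Field(default=18.0, gt=0)
    grid_pitch_px: int = Field(default=110, gt=0)
    n_z: int = Field(default=5, ge=1)
    pixel_size_um: float = Field(default=0.16, gt=0)
    z_step_um: float = Field(default=0.5, gt=0)  # 500 nm z-spacing
    min_spot_separation_px: float = Field(default=6.0, ge=0)


class QpcrModel(BaseModel):
    """Standard-curve parameters for simulated RT-qPCR.

    The default slope 1/log10(2) (~3.3219 cycles per 10-fold) corresponds to
    perfect doubling efficiency, so relative quantification recovers fold
    changes exactly at zero noise.
    """

    intercept: float = 35.0
    slope: float = 1.0 / math.log10(2.0)
    noise_sd: float = Field(default=0.0, ge=0)
    n_replicates: int = Field(default=3, ge=1)


# Nine-gene demonstration panel.  PFN1 and ER means follow the printed
# single-cell copy ranges (18-30 and 1-9); the rest are plausible values for
# a cultured epithelial line, chosen once for the synthetic regime.
DEFAULT_GENE_PANEL: dict[str, GeneModel] = {
    "GAPDH": GeneModel(mean=40.0),
    "THBS1": GeneModel(mean=20.0),
    "HER2": GeneModel(mean=12.0),
    "PR": GeneModel(mean=8.0),
    "PFN1": GeneModel(mean=24.0),
    "ER": GeneModel(mean=4.0),
    "EGFR": GeneModel(mean=10.0),
    "KI67": GeneModel(mean=15.0),
    "PRKCA": GeneModel(mean=9.0),
}


def default_cell_line_panel() -> dict[str, dict[str, float]]:
    """Per-cell-type gene means mirroring the qualitative cell-line ordering
    (PR/EGFR/KI67 elevated in the mesenchymal-like line, PRKCA in the normal
    line)."""
    base = {g: m.mean for g, m in DEFAULT_GENE_PANEL.items()}
    mda = dict(base, PR=24.0, EGFR=30.0, KI67=45.0, PRKCA=3.0)
    mcf7 = dict(base, PR=10.0, EGFR=8.0, KI67=18.0, PRKCA=5.0)
    mcf10a = dict(base, PR=6.0, EGFR=12.0, KI67=12.0, PRKCA=27.0)
    hela = dict(base)
    return {"MDA-MB-231": mda, "MCF-7": mcf7, "MCF-10A": mcf10a, "HeLa": hela}


class SimulationConfig(BaseModel):
    seed: int = 0
    n_cells: int = Field(default=50, ge=0)
    genes: dict[str, GeneModel] = Field(default_factory=lambda: dict(DEFAULT_GENE_PANEL))
    cell_types: dict[str, dict[str, float]] | None = None
    p_det: float = Field(default=0.30, ge=0, le=1)
    h_dfp: float = Field(default=0.8, ge=0, le=1)
    h_rfp: float = Field(default=0.8, ge=0, le=1)
    repeat_law: RepeatLaw = Field(default_factory=RepeatLaw)
    nonspecific: NonspecificModel = Field(default_factory=NonspecificModel)
    optics: OpticsModel = Field(default_factory=OpticsModel)
    geometry: GeometryModel = Field(default_factory=GeometryModel)
    qpcr: QpcrModel = Field(default_factory=QpcrModel)


@dataclass
class GroundTruth:
    """Simulated truth: cell geometry, per-cell copy numbers, amplicons."""

    cells: pd.DataFrame  # cell_id, cell_type, cx, cy, radius
    copies: pd.DataFrame  # cell_id, gene_id, true_copies, detected_amplicons
    amplicons: pd.DataFrame  # amplicon_id, cell_id, gene_id, levels, x, y, z, K


@dataclass
class ImageStack:
    """Multi-channel z-stack with acquisition metadata."""

    data: np.ndarray  # (channels, z, y, x) uint16
    channel_names: tuple[str, ...]
    pixel_size_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("image stack must be (channels, z, y, x)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one name per channel")

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    def save(self, path) -> None:
        """Write a multi-page TIFF plus a JSON metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data, metadata=None)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "channel_names": list(self.channel_names),
                    "pixel_size_um": self.pixel_size_um,
                    "z_step_um": self.z_step_um,
                    "shape": list(self.data.shape),
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path) -> "ImageStack":
        path = Path(path)
        data = tifffile.imread(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            data=data.reshape(meta["shape"]),
            channel_names=tuple(meta["channel_names"]),
            pixel_size_um=meta["pixel_size_um"],
            z_step_um=meta["z_step_um"],
        )


def _grid_layout(n_cells: int, pitch: int) -> tuple[np.ndarray, np.ndarray, int]:
    cols = max(1, int(np.ceil(np.sqrt(n_cells))))
    rows = int(np.ceil(n_cells / cols)) if n_cells else 1
    idx = np.arange(n_cells)
    cx = (idx % cols + 0.5) * pitch
    cy = (idx // cols + 0.5) * pitch
    side_x = cols * pitch
    side_y = rows * pitch
    return cx, cy, max(side_x, side_y)


def _sample_positions_in_disk(
    n: int,
    cx: float,
    cy: float,
    radius: float,
    min_sep: float,
    rng: np.random.Generator,
    existing: list[tuple[float, float]] | None = None,
    max_attempts: int = 200,
) -> np.ndarray:
    """Dart-throwing placement inside a disk with a minimum pair separation.

    Separation is enforced against ``existing`` points too (they are extended
    in place).  If a point cannot be placed after ``max_attempts`` tries the
    constraint is waived for that point (dense cells stay valid; only
    crowding-free rendering tests rely on the separation).
    """
    pts = existing if existing is not None else []
    new: list[tuple[float, float]] = []
    for _ in range(n):
        placed = False
        for attempt in range(max_attempts):
            r = radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            x, y = cx + r * np.cos(th), cy + r * np.sin(th)
            if min_sep <= 0 or all((x - a) ** 2 + (y - b) ** 2 >= min_sep**2 for a, b in pts):
                pts.append((x, y))
                new.append((x, y))
                placed = True
                break
        if not placed:
            r = radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            p = (cx + r * np.cos(th), cy + r * np.sin(th))
            pts.append(p)
            new.append(p)
    return np.asarray(new, dtype=float).reshape(n, 2)


def _draw_repeat_counts(n: int, law: RepeatLaw, rng: np.random.Generator) -> np.ndarray:
    k = np.round(rng.lognormal(law.log_mean, law.log_sigma, size=n)).astype(int)
    return np.maximum(k, law.minimum)


def simulate_ground_truth(config: SimulationConfig, codebook: CodeBook) -> GroundTruth:
    """Draw per-cell copy numbers, thin by detection efficiency, place amplicons.

    Per cell and gene: true copies ~ NB(mean, dispersion); detected amplicons
    ~ Binomial(copies, p_det); each amplicon gets a position in the cell disk,
    a z coordinate, a repeat count K, and the gene's code levels.  Nonspecific
    spots (count ~ Poisson(rate of the amplification mode)) carry a random
    level in one random detection channel and no gene identity.  Deterministic
    given ``config.seed``.
    """
    for gene in codebook.genes:
        if config.cell_types is None and gene not in config.genes:
            raise ValueError(f"codebook gene {gene} missing from config.genes")
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    n_channels = codebook.config.n_detection_channels
    level_cols = [f"level_{i + 1}" for i in range(n_channels)]

    cx, cy, _ = _grid_layout(config.n_cells, geom.grid_pitch_px)
    type_names = list(config.cell_types) if config.cell_types else ["default"]
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(config.n_cells, dtype=int),
            "cell_type": [type_names[i % len(type_names)] for i in range(config.n_cells)],
            "cx": cx,
            "cy": cy,
            "radius": geom.cell_radius_px,
        }
    )

    copy_rows = []
    amp_rows = []
    for cell in cells.itertuples(index=False):
        placed: list[tuple[float, float]] = []
        for gene in codebook.genes:
            gm = config.genes.get(gene, GeneModel(mean=1.0))
            mean = (
                config.cell_types[cell.cell_type].get(gene, gm.mean)
                if config.cell_types
                else gm.mean
            )
            disp = gm.dispersion
            true_copies = int(rng.negative_binomial(disp, disp / (disp + mean)))
            detected = int(rng.binomial(true_copies, config.p_det)) if true_copies else 0
            copy_rows.append(
                {
                    "cell_id": cell.cell_id,
                    "gene_id": gene,
                    "true_copies": true_copies,
                    "detected_amplicons": detected,
                }
            )
            if detected == 0:
                continue
            pos = _sample_positions_in_disk(
                detected, cell.cx, cell.cy, cell.radius,
                geom.min_spot_separation_px, rng, existing=placed,
            )
            z = rng.uniform(0, geom.n_z, size=detected)
            K = _draw_repeat_counts(detected, config.repeat_law, rng)
            levels = codebook.code_for(gene).levels
            for i in range(detected):
                amp_rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "gene_id": gene,
                        "is_nonspecific": False,
                        "x": pos[i, 0],
                        "y": pos[i, 1],
                        "z": z[i],
                        "K": int(K[i]),
                        **dict(zip(level_cols, levels)),
                    }
                )
        n_ns = int(rng.poisson(config.nonspecific.rate))
        if n_ns:
            pos = _sample_positions_in_disk(
                n_ns, cell.cx, cell.cy, cell.radius,
                geom.min_spot_separation_px, rng, existing=placed,
            )
            z = rng.uniform(0, geom.n_z, size=n_ns)
            K = _draw_repeat_counts(n_ns, config.repeat_law, rng)
            chan = rng.integers(0, n_channels, size=n_ns)
            lvl = rng.integers(1, codebook.config.n_levels + 1, size=n_ns)
            for i in range(n_ns):
                levels = [0] * n_channels
                levels[chan[i]] = int(lvl[i])
                amp_rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "gene_id": None,
                        "is_nonspecific": True,
                        "x": pos[i, 0],
                        "y": pos[i, 1],
                        "z": z[i],
                        "K": int(K[i]),
                        **dict(zip(level_cols, levels)),
                    }
                )

    copies = pd.DataFrame(
        copy_rows, columns=["cell_id", "gene_id", "true_copies", "detected_amplicons"]
    )
    amplicons = pd.DataFrame(
        amp_rows,
        columns=["cell_id", "gene_id", "is_nonspecific", "x", "y", "z", "K"] + level_cols,
    )
    amplicons.insert(0, "amplicon_id", np.arange(len(amplicons), dtype=int))
    return GroundTruth(cells=cells, copies=copies, amplicons=amplicons)


def simulate_spot_intensities(
    amplicons: pd.DataFrame, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-amplicon fluorophore binding and channel intensities.

    Detection channel c binds ``Binomial(K * level_c, h_DFP)`` DFPs and the
    reference channel ``Binomial(K, h_RFP)`` RFPs; intensities are brightness
    times bound count, with optional Poisson shot noise.  At unit
    hybridization efficiency and shot noise off the De/Re ratio equals the
    repeat level exactly for every K.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = amplicons.copy()
    n = len(out)
    level_cols = [c for c in out.columns if c.startswith("level_")]
    K = out["K"].to_numpy(dtype=int) if n else np.zeros(0, dtype=int)

    bound_re = rng.binomial(K, config.h_rfp) if n else np.zeros(0, dtype=int)
    out["bound_re"] = bound_re
    i_re = config.optics.ref_brightness * bound_re.astype(float)
    if config.optics.shot_noise and n:
        i_re = rng.poisson(i_re).astype(float)
    out["I_Re"] = i_re

    for ci, col in enumerate(level_cols):
        lv = out[col].to_numpy(dtype=int) if n else np.zeros(0, dtype=int)
        bound = rng.binomial(K * lv, config.h_dfp) if n else np.zeros(0, dtype=int)
        out[f"bound_de{ci + 1}"] = bound
        i_de = config.optics.det_brightness * bound.astype(float)
        if config.optics.shot_noise and n:
            i_de = rng.poisson(i_de).astype(float)
        out[f"I_De{ci + 1}"] = i_de
    return out


def _add_gaussian_spot(plane: np.ndarray, x: float, y: float, sigma: float, integral: float) -> None:
    h, w = plane.shape
    half = int(np.ceil(4 * sigma))
    x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    xs = np.arange(max(x0, 0), min(x1, w))
    ys = np.arange(max(y0, 0), min(y1, h))
    if xs.size == 0 or ys.size == 0:
        return
    gx = np.exp(-0.5 * ((xs - x) / sigma) ** 2)
    gy = np.exp(-0.5 * ((ys - y) / sigma) ** 2)
    amp = integral / (2 * np.pi * sigma**2)
    plane[np.ix_(ys, xs)] += amp * np.outer(gy, gx)


def render_image_stack(
    photometry: pd.DataFrame,
    cells: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Render channels x z x y x x images plus cell and nucleus label masks.

    Each spot is a 2D Gaussian (sigma = PSF sigma) in its nearest z-slice
    whose integral equals the spot's channel intensity, on a constant
    background with Gaussian read noise, quantized to uint16 with saturation.
    Spots outside the field are clipped to it with a warning.  A DAPI channel
    carries the nucleus disks.  Returns (stack, cell_labels, nucleus_labels).
    """
    geom = config.geometry
    opt = config.optics
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    _, _, side = _grid_layout(max(len(cells), 1), geom.grid_pitch_px)
    h = w = int(side)
    de_cols = sorted(c for c in photometry.columns if c.startswith("I_De"))
    names = ("Re", *[c.replace("I_", "") for c in de_cols], "DAPI")
    stack = np.full((len(names), geom.n_z, h, w), float(opt.background))

    yy, xx = np.mgrid[0:h, 0:w]
    cell_labels = np.zeros((h, w), dtype=np.uint16)
    nuc_labels = np.zeros((h, w), dtype=np.uint16)
    for cell in cells.itertuples(index=False):
        d2 = (xx - cell.cx) ** 2 + (yy - cell.cy) ** 2
        cell_labels[d2 <= cell.radius**2] = cell.cell_id + 1
        nuc_labels[d2 <= geom.nucleus_radius_px**2] = cell.cell_id + 1
    # nuclear stain: flat disks in every z-slice
    stack[-1, :, :, :] += 30.0 * (nuc_labels > 0)[None, :, :]

    n_clipped = 0
    for row in photometry.itertuples(index=False):
        x, y = float(row.x), float(row.y)
        if not (0 <= x < w and 0 <= y < h):
            n_clipped += 1
            x, y = float(np.clip(x, 0, w - 1)), float(np.clip(y, 0, h - 1))
        zi = int(np.clip(round(float(row.z)), 0, geom.n_z - 1))
        _add_gaussian_spot(stack[0, zi], x, y, opt.psf_sigma_px, float(row.I_Re))
        for ci, col in enumerate(de_cols):
            _add_gaussian_spot(stack[1 + ci, zi], x, y, opt.psf_sigma_px, float(getattr(row, col)))
    if n_clipped:
        warnings.warn(f"{n_clipped} spots outside the field were clipped to its border")

    if opt.read_noise_sigma > 0:
        stack = stack + rng.normal(0, opt.read_noise_sigma, size=stack.shape)
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    image = ImageStack(
        data=data,
        channel_names=names,
        pixel_size_um=geom.pixel_size_um,
        z_step_um=geom.z_step_um,
    )
    return image, cell_labels, nuc_labels


def simulate_qpcr(
    copies_by_sample: dict[str, pd.DataFrame],
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate RT-qPCR Ct values from per-cell copy tables.

    For each sample and gene, Ct = intercept - slope * log10(mean copies)
    plus Gaussian noise per replicate.  Input frames need columns
    ``gene_id`` and ``true_copies`` (one row per cell).
    """
    q = config.qpcr
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    rows = []
    for sample_id, df in copies_by_sample.items():
        means = df.groupby("gene_id")["true_copies"].mean()
        for gene_id, mean in means.items():
            if mean <= 0:
                continue
            base = q.intercept - q.slope * math.log10(mean)
            for rep in range(q.n_replicates):
                ct = base + (rng.normal(0, q.noise_sd) if q.noise_sd > 0 else 0.0)
                rows.append(
                    {"sample_id": sample_id, "gene_id": gene_id, "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "replicate", "ct"])
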