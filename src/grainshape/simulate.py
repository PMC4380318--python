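"""Synthetic genotype-to-grain-shape datasets.

Emulates the structure of a cereal germplasm collection: each accession
carries one genome-wide SNP genotype and several photographed grains.
Grain outlines come from a smooth three-parameter family — a tapered
superellipse whose latent parameters are the log length-to-width ratio
(the dominant axis of real grain-shape variation), a taper/asymmetry
coefficient, and a squareness ("roundness") exponent.  A configurable
number of QTL act additively on the latent parameters; heritability is
the grain-level intraclass correlation sigma_g^2 / (sigma_g^2 +
sigma_w^2), with sigma_w the within-accession (grain-to-grain) spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon

from .efd import ContourSequence, ShapeVector, average_shape, compute_efd, standardize
from .models import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_shapes",
    "simulate_dataset",
    "grain_outline",
    "rasterize_grains",
]

# latent-parameter scales: (log length-to-width ratio, taper, squareness)
_PARAM_NAMES = ("log_aspect", "taper", "roundness")
_PARAM_BASE = np.array([np.log(2.2), 0.18, 2.1])
_PARAM_SCALE = np.array([0.15, 0.06, 0.10])  # total latent sd at heritability split
_PARAM_LO = np.array([np.log(1.2), -0.45, 1.6])
_PARAM_HI = np.array([np.log(5.0), 0.45, 3.2])


@dataclass
class SimulationConfig:
    """Stated world for the generator.

    heritability is the grain-level intraclass correlation per latent
    shape parameter (scalar broadcasts to all three);
    ``grains_per_accession`` is a fixed count or an inclusive (lo, hi)
    range mirroring the 4-6 grains measured per accession in real
    collections; ``within_noise`` rescales the within-accession spread.
    """

    n_accessions: int = 200
    n_markers: int = 300
    n_qtl: int = 20
    maf_range: tuple[float, float] = (0.1, 0.5)
    heritability: float | tuple[float, float, float] = 0.8
    grains_per_accession: int | tuple[int, int] = (4, 6)
    within_noise: float = 1.0
    ld: float = 0.0  # probability an adjacent marker copies its neighbour
    n_harmonics: int = 20
    contour_points: int = 360
    raster_size: int = 256
    pixels_per_unit: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        h = np.broadcast_to(np.asarray(self.heritability, dtype=float), (3,))
        if np.any(h < 0.0) or np.any(h > 1.0):
            raise ValueError("heritability must lie in [0, 1]")
        if not (0.0 <= self.ld < 1.0):
            raise ValueError("ld must lie in [0, 1)")

    @property
    def h2(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.heritability, dtype=float), (3,)).copy()


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery checks."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray  # n_qtl x 3, on the standardized latent scale
    genetic_values: np.ndarray  # accessions x 3
    latent_params: np.ndarray  # accessions x 3 (genetic + base)
    heritability: np.ndarray  # target, per latent parameter
    realized_heritability: np.ndarray  # grain-level ICC realized in the sample
    within_sd: np.ndarray
    seed: int


def _rng_for(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, stream)))


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Biallelic genotypes of inbred accessions, coded 1 / -1.

    Marker allele frequencies are drawn uniformly from ``maf_range``;
    with ``ld`` > 0 each marker copies its left neighbour's genotype
    with that probability, giving first-order linkage disequilibrium.
    """
    rng = _rng_for(cfg, 0)
    n, m = cfg.n_accessions, cfg.n_markers
    p = rng.uniform(*cfg.maf_range, size=m)
    fresh = np.where(rng.random((n, m)) < p, 1.0, -1.0)
    X = fresh.copy()
    if cfg.ld > 0.0:
        copy = rng.random((n, m)) < cfg.ld
        for j in range(1, m):
            X[:, j] = np.where(copy[:, j], X[:, j - 1], fresh[:, j])
    ids = [f"acc{i:04d}" for i in range(n)]
    markers = [f"snp{j:05d}" for j in range(m)]
    return GenotypeMatrix(X, ids, markers)


def grain_outline(
    aspect: float, taper: float, roundness: float, n_points: int = 360
) -> ContourSequence:
    """Smooth grain-like closed outline with unit semi-minor axis.

    A superellipse |x/a|^p + |y|^p = 1 (a = aspect, p = roundness) whose
    half-width is modulated by (1 + taper * x/a), giving one blunt and
    one pointed end.  Simple (non-self-intersecting) for |taper| < 1.
    """
    if aspect <= 0 or roundness <= 0 or abs(taper) >= 1.0:
        raise ValueError("degenerate outline parameters")
    phi = 2.0 * np.pi * np.arange(n_points) / n_points
    e = 2.0 / roundness
    sx = np.sign(np.cos(phi)) * np.abs(np.cos(phi)) ** e
    sy = np.sign(np.sin(phi)) * np.abs(np.sin(phi)) ** e
    x = aspect * sx
    y = sy * (1.0 + taper * sx)
    return ContourSequence(np.column_stack([x, y]))


def _outline_is_simple(contour: ContourSequence) -> bool:
    try:
        from shapely.geometry import Polygon

        return Polygon(contour.points).is_valid
    except Exception:  # pragma: no cover - shapely always present in practice
        return True


def simulate_shapes(
    G: GenotypeMatrix, cfg: SimulationConfig, truth: GroundTruth | None = None
):
    """Per-grain contours and per-accession averaged shape vectors.

    Returns ``(contours, shape_values, grain_vectors, truth)`` where
    ``contours`` maps each accession to its grain contours,
    ``shape_values`` is the accessions x (4N-3) matrix of averaged
    standardized descriptors, and ``grain_vectors`` the per-grain ones.
    """
    rng = _rng_for(cfg, 1)
    n = G.n_accessions
    h2 = cfg.h2
    sigma_g = np.sqrt(h2) * _PARAM_SCALE
    sigma_w = cfg.within_noise * np.sqrt(1.0 - h2) * _PARAM_SCALE

    if truth is None:
        qtl = rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False)
        beta = rng.normal(size=(cfg.n_qtl, 3))
        g_raw = G.scores[:, qtl] @ beta
        sd = g_raw.std(axis=0)
        scale = np.divide(sigma_g, sd, out=np.zeros(3), where=sd > 0)
        g = g_raw * scale
        beta_scaled = beta * scale
        latent = _PARAM_BASE + g
        truth = GroundTruth(
            qtl_indices=qtl,
            qtl_effects=beta_scaled,
            genetic_values=g,
            latent_params=latent,
            heritability=h2,
            realized_heritability=np.zeros(3),
            within_sd=sigma_w,
            seed=cfg.seed,
        )
    latent = truth.latent_params

    gpa = cfg.grains_per_accession
    if isinstance(gpa, int):
        counts = np.full(n, gpa)
    else:
        counts = rng.integers(gpa[0], gpa[1] + 1, size=n)

    contours: list[list[ContourSequence]] = []
    grain_vectors: list[list[ShapeVector]] = []
    avg_rows = np.zeros((n, 4 * cfg.n_harmonics - 3))
    within_dev: list[np.ndarray] = []
    for l in range(n):
        acc_contours, acc_vecs = [], []
        for _ in range(int(counts[l])):
            for attempt in range(20):
                dev = rng.normal(scale=sigma_w) if np.any(sigma_w > 0) else np.zeros(3)
                params = np.clip(latent[l] + dev, _PARAM_LO, _PARAM_HI)
                contour = grain_outline(
                    float(np.exp(params[0])), float(params[1]), float(params[2]),
                    n_points=cfg.contour_points,
                )
                # random placement, orientation and trace start, removed
                # again by standardization — exercises the invariances
                theta = rng.uniform(0.0, 2.0 * np.pi)
                rot = np.array(
                    [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                )
                pts = contour.points @ rot.T
                shift = int(rng.integers(len(pts)))
                contour = ContourSequence(np.roll(pts, shift, axis=0))
                if _outline_is_simple(contour):
                    break
                logger.info("resampling a self-intersecting outline (accession %d)", l)
            else:
                raise RuntimeError("could not sample a simple outline")
            within_dev.append(dev)
            acc_contours.append(contour)
            acc_vecs.append(standardize(compute_efd(contour, cfg.n_harmonics)))
        contours.append(acc_contours)
        grain_vectors.append(acc_vecs)
        avg_rows[l] = average_shape(acc_vecs).values

    dev_arr = np.array(within_dev)
    var_g = truth.genetic_values.var(axis=0)
    var_w = dev_arr.var(axis=0) if dev_arr.size else np.zeros(3)
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(var_g + var_w > 0, var_g / (var_g + var_w), 0.0)
    truth.realized_heritability = icc
    return contours, avg_rows, grain_vectors, truth


def simulate_dataset(cfg: SimulationConfig):
    """Convenience wrapper: genotypes + averaged shapes + ground truth.

    Returns an object compatible with :func:`grainshape.evaluation.run_cv`.
    """
    from .io import Dataset

    G = simulate_genotypes(cfg)
    _, shape_values, _, truth = simulate_shapes(G, cfg)
    ds = Dataset(
        genotypes=G,
        shape_values=shape_values,
        accession_ids=list(G.accession_ids),
        N=cfg.n_harmonics,
        metadata={"source": "simulated", "seed": cfg.seed},
    )
    return ds, truth


def rasterize_grains(
    contours: list[ContourSequence], cfg: SimulationConfig
) -> list[np.ndarray]:
    """Filled binary masks of grain contours.

    With ``cfg.pixels_per_unit`` unset, each contour is scaled uniformly
    to fill the raster with a 5% margin; with it set, the contour is
    centred and drawn at that fixed scale and an outline reaching the
    image border is an error.
    """
    size = int(cfg.raster_size)
    masks = []
    for contour in contours:
        pts = contour.points
        center = (pts.min(axis=0) + pts.max(axis=0)) / 2.0
        span = float((pts.max(axis=0) - pts.min(axis=0)).max())
        if cfg.pixels_per_unit is None:
            scale = 0.9 * size / span
        else:
            scale = float(cfg.pixels_per_unit)
        xy = (pts - center) * scale + (size - 1) / 2.0
        if xy.min() < 0.5 or xy.max() > size - 1.5:
            raise ValueError("contour exceeds raster bounds")
        mask = np.zeros((size, size), dtype=np.uint8)
        rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=mask.shape)
        mask[rr, cc] = 1
        masks.append(mask)
    return masks
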