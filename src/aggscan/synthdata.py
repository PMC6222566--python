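"""Synthetic ground-truth data: yeast-cross genotypes/phenotypes and micrographs.

Two families of generators live here.

*Cross simulation* emulates a panel of haploid meiotic segregants from a
two-parent (laboratory x vineyard) yeast cross: each chromosome of each
segregant is a two-state Markov chain over the parental alleles, with a
per-interval switch probability standing in for recombination.  Phenotypes
(percent of fluorescent cells with foci) are generated from an additive
quantitative-trait model with Gaussian noise, clamped to the percentage
scale.

*Field rendering* emulates the micrograph pairs consumed by the imaging
pipeline: an off-focus-DIC proxy in which cells are bright smooth blobs,
and a GFP channel in which fluorescent cells carry a diffuse fill and a
subset carry small punctate foci rendered as isotropic Gaussians whose
full width at half maximum equals the planted diameter.

Every generator is seeded and deterministic: the same seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .micrograph import Micrograph

__all__ = [
    "LAB",
    "VINEYARD",
    "MISSING",
    "ALLELE_CODES",
    "GenotypeMatrix",
    "PhenotypeTable",
    "CrossTruth",
    "FieldTruth",
    "PlantedFocus",
    "simulate_cross",
    "simulate_phenotypes",
    "parental_phenotypes",
    "sample_field_truth",
    "render_field",
    "render_aggregate_field",
]

# Integer allele coding used throughout: the laboratory parent's allele is 0,
# the vineyard parent's allele is 1, missing genotypes are -1.
LAB: int = 0
VINEYARD: int = 1
MISSING: int = -1

#: text codes used in genotype TSV files
ALLELE_CODES = {LAB: "L", VINEYARD: "V", MISSING: "N"}
ALLELE_DECODES = {v: k for k, v in ALLELE_CODES.items()}


# ---------------------------------------------------------------------------
# cross genotypes and phenotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Segregants x markers allele matrix with marker map metadata.

    ``alleles`` is an int8 array of shape (n_strains, n_markers) over
    {LAB, VINEYARD, MISSING}.  ``marker_meta`` has one row per marker with
    columns ``chrom``, ``pos``, ``name``; positions are strictly increasing
    within a chromosome.
    """

    alleles: np.ndarray
    marker_meta: pd.DataFrame
    strain_ids: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2D (strains x markers) array")
        n_strains, n_markers = self.alleles.shape
        if len(self.strain_ids) != n_strains:
            raise ValueError(
                f"{len(self.strain_ids)} strain ids for {n_strains} rows"
            )
        if len(self.marker_meta) != n_markers:
            raise ValueError(
                f"{len(self.marker_meta)} marker_meta rows for {n_markers} markers"
            )
        for col in ("chrom", "pos", "name"):
            if col not in self.marker_meta.columns:
                raise ValueError(f"marker_meta missing column {col!r}")
        valid = np.isin(self.alleles, (LAB, VINEYARD, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid allele code at strain {bad[0]}, marker {bad[1]}"
            )
        for chrom, grp in self.marker_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_strains(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def marker_names(self) -> list[str]:
        return self.marker_meta["name"].tolist()

    def marker_index(self, name: str) -> int:
        idx = np.flatnonzero(self.marker_meta["name"].to_numpy() == name)
        if idx.size == 0:
            raise KeyError(f"unknown marker {name!r}")
        return int(idx[0])

    def subset_markers(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            alleles=self.alleles[:, keep].copy(),
            marker_meta=self.marker_meta.iloc[keep].reset_index(drop=True),
            strain_ids=list(self.strain_ids),
        )


@dataclass
class PhenotypeTable:
    """Per-strain aggregation phenotype (percent of fluorescent cells with foci).

    ``percent_foci`` is NaN where the phenotype is undefined (no fluorescent
    cells in any replicate).  When ``replicates`` is present, the strain value
    equals the unweighted mean of its defined replicate values.
    """

    strain_ids: list[str]
    percent_foci: np.ndarray
    replicates: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.percent_foci = np.asarray(self.percent_foci, dtype=np.float64)
        if self.percent_foci.ndim != 1:
            raise ValueError("percent_foci must be 1D")
        if len(self.strain_ids) != self.percent_foci.size:
            raise ValueError("strain_ids and percent_foci length mismatch")
        defined = ~np.isnan(self.percent_foci)
        vals = self.percent_foci[defined]
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError("percent_foci outside [0, 100]")
        if self.replicates is not None:
            if len(self.replicates) != len(self.strain_ids):
                raise ValueError("one replicate array required per strain")
            for i, reps in enumerate(self.replicates):
                reps = np.asarray(reps, dtype=np.float64)
                good = reps[~np.isnan(reps)]
                if good.size and not np.isclose(
                    self.percent_foci[i], good.mean(), atol=1e-6
                ):
                    raise ValueError(
                        f"strain {self.strain_ids[i]}: percent_foci does not equal "
                        "the mean of its defined replicates"
                    )

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"strain": self.strain_ids, "percent_foci": self.percent_foci}
        )


@dataclass
class CrossTruth:
    """Planted genetic architecture for phenotype simulation.

    ``qtl`` maps marker index -> additive effect, in phenotype percent units,
    of carrying the *laboratory* allele at that marker.  A negative effect is
    a vineyard-increasing locus.  ``baseline`` is the phenotype of a strain
    carrying the vineyard allele at every QTL.
    """

    qtl: list[tuple[int, float]]
    baseline: float = 12.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for idx, eff in self.qtl:
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect at marker index {idx}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        pos_sum = sum(e for _, e in self.qtl if e > 0)
        if self.baseline + pos_sum > 100:
            raise ValueError("baseline plus positive effects exceeds 100 percent")


def simulate_cross(
    n_segregants: int,
    chrom_lengths: Sequence[int],
    recomb_prob: float = 0.1,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate biallelic genotypes for a panel of haploid segregants.

    Each chromosome of each segregant is a two-state Markov chain over
    {LAB, VINEYARD}: the first marker is a fair coin and each subsequent
    marker switches parent with probability ``recomb_prob``.  Entries are
    then independently set to MISSING at ``missing_rate``.

    Parameters
    ----------
    n_segregants
        Number of strains (> 0).
    chrom_lengths
        Number of markers on each chromosome (each >= 1).
    recomb_prob
        Switch probability per adjacent-marker interval, in [0, 0.5].
    missing_rate
        Per-entry missingness probability, in [0, 1).
    seed
        RNG seed; identical seeds give bit-identical matrices.
    """
    if n_segregants <= 0:
        raise ValueError("n_segregants must be positive")
    if not 0 <= recomb_prob <= 0.5:
        raise ValueError("recomb_prob must lie in [0, 0.5]")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    chrom_lengths = [int(c) for c in chrom_lengths]
    if any(c < 1 for c in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 1")

    rng = np.random.default_rng(seed)
    n_markers = sum(chrom_lengths)
    alleles = np.empty((n_segregants, n_markers), dtype=np.int8)
    col = 0
    chroms: list[str] = []
    pos: list[int] = []
    names: list[str] = []
    for ci, clen in enumerate(chrom_lengths, start=1):
        first = rng.integers(0, 2, size=n_segregants)
        switches = rng.random((n_segregants, clen - 1)) < recomb_prob
        # cumulative XOR of switches gives the chain state
        flips = np.cumsum(switches, axis=1) % 2
        chrom_alleles = np.concatenate(
            [first[:, None], first[:, None] ^ flips], axis=1
        )
        alleles[:, col : col + clen] = chrom_alleles.astype(np.int8)
        chroms.extend([f"chr{ci:02d}"] * clen)
        pos.extend(range(1, clen + 1))
        names.extend(f"chr{ci:02d}_m{j + 1:03d}" for j in range(clen))
        col += clen
    if missing_rate > 0:
        miss = rng.random(alleles.shape) < missing_rate
        alleles[miss] = MISSING

    meta = pd.DataFrame({"chrom": chroms, "pos": pos, "name": names})
    strain_ids = [f"seg{i + 1:04d}" for i in range(n_segregants)]
    return GenotypeMatrix(alleles=alleles, marker_meta=meta, strain_ids=strain_ids)


def simulate_phenotypes(geno: GenotypeMatrix, truth: CrossTruth) -> PhenotypeTable:
    """Generate additive-QTL phenotypes for every strain in ``geno``.

    phenotype = baseline + sum_q effect_q * 1[allele at q == LAB] + N(0, sd),
    clamped to [0, 100].  A strain MISSING at a QTL marker receives no
    contribution from that locus (the linkage scan handles missingness on its
    own terms).
    """
    for idx, _ in truth.qtl:
        if not 0 <= idx < geno.n_markers:
            raise IndexError(f"qtl marker index {idx} out of range")
    rng = np.random.default_rng(truth.seed)
    values = np.full(geno.n_strains, truth.baseline, dtype=np.float64)
    for idx, eff in truth.qtl:
        values += eff * (geno.alleles[:, idx] == LAB)
    if truth.noise_sd > 0:
        values += rng.normal(0.0, truth.noise_sd, size=geno.n_strains)
    values = np.clip(values, 0.0, 100.0)
    return PhenotypeTable(strain_ids=list(geno.strain_ids), percent_foci=values)


def parental_phenotypes(truth: CrossTruth) -> tuple[float, float]:
    """Noise-free phenotypes of the two parents (lab, vineyard).

    The laboratory parent carries the LAB allele at every QTL, the vineyard
    parent the VINEYARD allele; with antagonistic effects the segregant range
    extends beyond both (transgressive segregation).
    """
    lab = float(np.clip(truth.baseline + sum(e for _, e in truth.qtl), 0, 100))
    vin = float(np.clip(truth.baseline, 0, 100))
    return lab, vin


# ---------------------------------------------------------------------------
# micrograph rendering
# ---------------------------------------------------------------------------

#: full width at half maximum of a Gaussian, in units of sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PlantedFocus:
    """One planted punctate focus: owning cell, centre (row, col) px, diameter um."""

    cell_index: int
    center: tuple[float, float]
    diameter_um: float
    oversize_control: bool = False


@dataclass
class FieldTruth:
    """Ground truth for one rendered micrograph pair.

    cells are axis-aligned ellipses given as ((row, col) centre px,
    (semi-axis row, semi-axis col) px).  Every focus must belong to a
    fluorescent cell and have diameter < 2 um unless planted as an explicit
    oversize control object.
    """

    cells: list[tuple[tuple[float, float], tuple[float, float]]]
    fluorescent: np.ndarray
    foci: list[PlantedFocus]
    pixel_size: float = 0.2
    background: float = 100.0
    noise_sd: float = 0.0
    # rendering amplitudes (intensity units above the respective background)
    cell_contrast: float = 300.0
    gfp_background: float = 20.0
    diffuse_level: float = 60.0
    focus_peak: float = 150.0

    def __post_init__(self) -> None:
        self.fluorescent = np.asarray(self.fluorescent, dtype=bool)
        if self.fluorescent.size != len(self.cells):
            raise ValueError("one fluorescent flag required per cell")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for f in self.foci:
            if not 0 <= f.cell_index < len(self.cells):
                raise ValueError(f"focus cell index {f.cell_index} out of range")
            if not self.fluorescent[f.cell_index]:
                raise ValueError(
                    f"focus planted in non-fluorescent cell {f.cell_index}"
                )
            if f.diameter_um >= 2.0 and not f.oversize_control:
                raise ValueError(
                    f"focus diameter {f.diameter_um} um >= 2 um; "
                    "mark it oversize_control to plant it deliberately"
                )

    @property
    def n_fluorescent(self) -> int:
        return int(self.fluorescent.sum())

    @property
    def n_with_foci(self) -> int:
        return len({f.cell_index for f in self.foci})

    def true_percent_foci(self) -> float:
        """The planted value of the percent-of-fluorescent-cells-with-foci statistic."""
        if self.n_fluorescent == 0:
            raise ValueError("no fluorescent cells: percent undefined")
        return 100.0 * self.n_with_foci / self.n_fluorescent

    def to_json(self) -> str:
        return json.dumps(
            {
                "cells": [
                    {"center": list(c), "axes": list(a)} for c, a in self.cells
                ],
                "fluorescent": self.fluorescent.astype(int).tolist(),
                "foci": [
                    {
                        "cell_index": f.cell_index,
                        "center": list(f.center),
                        "diameter_um": f.diameter_um,
                        "oversize_control": f.oversize_control,
                    }
                    for f in self.foci
                ],
                "pixel_size": self.pixel_size,
                "background": self.background,
                "noise_sd": self.noise_sd,
                "cell_contrast": self.cell_contrast,
                "gfp_background": self.gfp_background,
                "diffuse_level": self.diffuse_level,
                "focus_peak": self.focus_peak,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FieldTruth":
        d = json.loads(text)
        return cls(
            cells=[(tuple(c["center"]), tuple(c["axes"])) for c in d["cells"]],
            fluorescent=np.asarray(d["fluorescent"], dtype=bool),
            foci=[
                PlantedFocus(
                    cell_index=f["cell_index"],
                    center=tuple(f["center"]),
                    diameter_um=f["diameter_um"],
                    oversize_control=f.get("oversize_control", False),
                )
                for f in d["foci"]
            ],
            pixel_size=d["pixel_size"],
            background=d["background"],
            noise_sd=d["noise_sd"],
            cell_contrast=d["cell_contrast"],
            gfp_background=d["gfp_background"],
            diffuse_level=d["diffuse_level"],
            focus_peak=d["focus_peak"],
        )


def sample_field_truth(
    n_cells: int,
    frac_fluorescent: float,
    frac_with_foci: float,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.2,
    seed: int = 0,
    cell_radius_um: tuple[float, float] = (1.5, 2.5),
    focus_diameter_um: tuple[float, float] = (0.8, 1.4),
    noise_sd: float = 0.0,
    max_attempts: int = 20000,
    **render_kwargs: float,
) -> FieldTruth:
    """Draw a random non-overlapping field layout with exact planted counts.

    ``frac_fluorescent`` of the cells are fluorescent and ``frac_with_foci``
    of the *fluorescent* cells receive exactly one focus, with counts rounded
    to the nearest integer so the planted percent-foci statistic is exact.
    Foci are planted well inside their cell (within 40% of the semi-axes of
    the centre) so they do not interact with cell boundaries.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    margin = cell_radius_um[1] / pixel_size + 2.0
    centers: list[tuple[float, float]] = []
    axes: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in {image_shape}"
            )
        r_row = rng.uniform(*cell_radius_um) / pixel_size
        r_col = rng.uniform(*cell_radius_um) / pixel_size
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        r_max = max(r_row, r_col)
        ok = True
        for (oy, ox), (ar, ac) in zip(centers, axes):
            if (cy - oy) ** 2 + (cx - ox) ** 2 < (r_max + max(ar, ac) + 4.0) ** 2:
                ok = False
                break
        if ok:
            centers.append((cy, cx))
            axes.append((r_row, r_col))

    n_fluor = int(round(frac_fluorescent * n_cells))
    n_foci = int(round(frac_with_foci * n_fluor))
    order = rng.permutation(n_cells)
    fluor_idx = order[:n_fluor]
    fluorescent = np.zeros(n_cells, dtype=bool)
    fluorescent[fluor_idx] = True
    foci: list[PlantedFocus] = []
    for ci in fluor_idx[:n_foci]:
        (cy, cx), (ar, ac) = centers[ci], axes[ci]
        fy = cy + rng.uniform(-0.4, 0.4) * ar
        fx = cx + rng.uniform(-0.4, 0.4) * ac
        d = rng.uniform(*focus_diameter_um)
        foci.append(PlantedFocus(cell_index=int(ci), center=(fy, fx), diameter_um=d))

    return FieldTruth(
        cells=list(zip(centers, axes)),
        fluorescent=fluorescent,
        foci=foci,
        pixel_size=pixel_size,
        noise_sd=noise_sd,
        **render_kwargs,
    )


def _fill_ellipses(
    shape: tuple[int, int],
    cells: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    select: np.ndarray | None = None,
) -> np.ndarray:
    mask = np.zeros(shape, dtype=np.float64)
    for i, ((cy, cx), (ar, ac)) in enumerate(cells):
        if select is not None and not select[i]:
            continue
        r0 = max(int(np.floor(cy - ar)) - 1, 0)
        r1 = min(int(np.ceil(cy + ar)) + 2, shape[0])
        c0 = max(int(np.floor(cx - ac)) - 1, 0)
        c1 = min(int(np.ceil(cx + ac)) + 2, shape[1])
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = ((rr - cy) / ar) ** 2 + ((cc - cx) / ac) ** 2 <= 1.0
        mask[r0:r1, c0:c1][inside] = 1.0
    return mask


def render_field(
    truth: FieldTruth,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    edge_sigma_px: float = 1.0,
    diffuse_edge_sigma_px: float = 2.5,
) -> tuple[Micrograph, Micrograph]:
    """Render a (DIC proxy, GFP) micrograph pair from planted ground truth.

    The DIC proxy shows every cell as a bright smooth blob on a darker
    background (the detection contract needs only "cells brighter than
    background", not an optical DIC model).  The GFP channel shows a diffuse
    fill for fluorescent cells plus an isotropic Gaussian at each planted
    focus whose FWHM equals the planted diameter; both channels then receive
    independent additive Gaussian noise with ``truth.noise_sd``.

    The diffuse cytoplasmic fill falls off smoothly at the cell boundary
    (``diffuse_edge_sigma_px``), as real wide-field fluorescence does; the
    DIC proxy keeps a sharper edge (``edge_sigma_px``) for cell detection.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("zero-size image")
    for i, ((cy, cx), (ar, ac)) in enumerate(truth.cells):
        if cy - ar < 0 or cy + ar > h or cx - ac < 0 or cx + ac > w:
            raise ValueError(f"cell {i} extends outside the image bounds")

    cell_mask = _fill_ellipses((h, w), truth.cells)
    fluor_mask = _fill_ellipses((h, w), truth.cells, select=truth.fluorescent)

    dic = truth.background + truth.cell_contrast * gaussian_filter(
        cell_mask, edge_sigma_px, mode="reflect"
    )
    gfp = truth.gfp_background + truth.diffuse_level * gaussian_filter(
        fluor_mask, diffuse_edge_sigma_px, mode="reflect"
    )

    for f in truth.foci:
        sigma_px = (f.diameter_um / FWHM_PER_SIGMA) / truth.pixel_size
        fy, fx = f.center
        ext = int(np.ceil(5 * sigma_px)) + 1
        r0, r1 = max(int(fy) - ext, 0), min(int(fy) + ext + 1, h)
        c0, c1 = max(int(fx) - ext, 0), min(int(fx) + ext + 1, w)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        gfp[r0:r1, c0:c1] += truth.focus_peak * np.exp(
            -((rr - fy) ** 2 + (cc - fx) ** 2) / (2 * sigma_px ** 2)
        )

    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        dic = dic + rng.normal(0.0, truth.noise_sd, size=(h, w))
        gfp = gfp + rng.normal(0.0, truth.noise_sd, size=(h, w))
    dic = np.clip(dic, 0.0, None)
    gfp = np.clip(gfp, 0.0, None)
    return (
        Micrograph(dic, truth.pixel_size),
        Micrograph(gfp, truth.pixel_size),
    )


def render_aggregate_field(
    areas: Sequence[float],
    image_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.26,
    seed: int = 0,
    background: float = 20.0,
    level: float = 200.0,
    noise_sd: float = 0.0,
    max_attempts: int = 10000,
) -> tuple[Micrograph, np.ndarray]:
    """Render bright filled disks with the requested areas (um^2).

    Stand-in for the projected human-cell channel in which protein
    aggregates are segmented and size-binned.  Returns the image and the
    true integer label map (label i+1 marks the i-th requested aggregate).
    The number of aggregates in the field is simply ``len(areas)``.
    """
    areas = [float(a) for a in areas]
    if any(a <= 0 for a in areas):
        raise ValueError("aggregate areas must be positive")
    h, w = int(image_shape[0]), int(image_shape[1])
    rng = np.random.default_rng(seed)
    labels = np.zeros((h, w), dtype=np.int32)
    radii = [np.sqrt(a / np.pi) / pixel_size for a in areas]
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        placed = False
        if 2 * (r + 2) >= min(h, w):
            raise RuntimeError(
                f"could not place aggregate {i} (area {areas[i]} um^2) without overlap"
            )
        for _ in range(max_attempts):
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= (r + radii[j] + 3.0) ** 2
                for j, (oy, ox) in enumerate(centers)
            ):
                centers.append((cy, cx))
                rr, cc = np.mgrid[
                    int(cy - r) - 1 : int(cy + r) + 2, int(cx - r) - 1 : int(cx + r) + 2
                ]
                inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= r ** 2
                labels[rr[inside], cc[inside]] = i + 1
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place aggregate {i} (area {areas[i]} um^2) without overlap"
            )
    img = np.full((h, w), background, dtype=np.float64)
    img[labels > 0] = background + level
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, size=(h, w)), 0.0, None)
    return Micrograph(img, pixel_size), labels
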