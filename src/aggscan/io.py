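"""Readers and writers for the package's plain-text table and image formats.

Tables are tab-separated text with ``#``-prefixed metadata header lines
(seed, config hash, version), so runs are diff-able and language-neutral.
Round trips are exact for integers and full-precision for reals.

Genotypes: one row per marker -- chrom, pos, name, then one allele code per
strain (L = laboratory, V = vineyard, N = missing).  Phenotypes: one row
per strain -- strain, percent_foci, then any replicate values.  Images are
16-bit grayscale TIFF (PNG accepted) with the um/pixel scale carried by a
JSON sidecar file (``<image>.meta.json``) or supplied explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .micrograph import Micrograph
from .synthdata import (
    ALLELE_CODES,
    ALLELE_DECODES,
    GenotypeMatrix,
    PhenotypeTable,
)

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_image",
    "read_image",
    "write_table",
]


def _metadata_lines(metadata: dict | None) -> list[str]:
    if not metadata:
        return []
    return [f"# {key}={value}" for key, value in metadata.items()]


def _read_lines(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln for ln in lines if ln and not ln.startswith("#")]


def write_genotypes(
    path: str | Path, geno: GenotypeMatrix, metadata: dict | None = None
) -> None:
    lines = _metadata_lines(metadata)
    lines.append("\t".join(["chrom", "pos", "name", *geno.strain_ids]))
    meta = geno.marker_meta
    for j in range(geno.n_markers):
        codes = [ALLELE_CODES[int(a)] for a in geno.alleles[:, j]]
        lines.append(
            "\t".join(
                [str(meta["chrom"].iloc[j]), str(meta["pos"].iloc[j]),
                 str(meta["name"].iloc[j]), *codes]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    lines = _read_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if header[:3] != ["chrom", "pos", "name"]:
        raise ValueError(f"{path}: expected header 'chrom pos name <strains>'")
    strain_ids = header[3:]
    n_cols = len(header)
    chroms, pos, names = [], [], []
    rows = []
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValueError(
                f"{path}: row {r} has {len(fields)} columns, expected {n_cols}"
            )
        chroms.append(fields[0])
        pos.append(int(fields[1]))
        names.append(fields[2])
        row = []
        for c, code in enumerate(fields[3:], start=4):
            if code not in ALLELE_DECODES:
                raise ValueError(
                    f"{path}: unknown allele code {code!r} at row {r}, column {c}"
                )
            row.append(ALLELE_DECODES[code])
        rows.append(row)
    alleles = np.asarray(rows, dtype=np.int8).T  # markers x strains -> strains x markers
    meta = pd.DataFrame({"chrom": chroms, "pos": pos, "name": names})
    return GenotypeMatrix(alleles=alleles, marker_meta=meta, strain_ids=strain_ids)


def write_phenotypes(
    path: str | Path, pheno: PhenotypeTable, metadata: dict | None = None
) -> None:
    lines = _metadata_lines(metadata)
    lines.append("\t".join(["strain", "percent_foci", "replicates..."]))
    for i, strain in enumerate(pheno.strain_ids):
        val = pheno.percent_foci[i]
        fields = [strain, "NA" if np.isnan(val) else repr(float(val))]
        if pheno.replicates is not None:
            for r in np.asarray(pheno.replicates[i], dtype=float):
                fields.append("NA" if np.isnan(r) else repr(float(r)))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    lines = _read_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty phenotype file")
    strains, values, replicates = [], [], []
    has_reps = False
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: row {r} needs at least strain and value")
        strains.append(fields[0])
        val = np.nan if fields[1] == "NA" else float(fields[1])
        if not np.isnan(val) and not 0 <= val <= 100:
            raise ValueError(
                f"{path}: row {r}: percent_foci {val} outside [0, 100]"
            )
        values.append(val)
        reps = np.asarray(
            [np.nan if f == "NA" else float(f) for f in fields[2:]], dtype=float
        )
        if reps.size:
            has_reps = True
        replicates.append(reps)
    return PhenotypeTable(
        strain_ids=strains,
        percent_foci=np.asarray(values, dtype=float),
        replicates=replicates if has_reps else None,
    )


def write_table(
    path: str | Path, table: pd.DataFrame, metadata: dict | None = None
) -> None:
    """Write any result DataFrame as TSV with ``#`` metadata header lines."""
    header = "\n".join(_metadata_lines(metadata))
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        table.to_csv(fh, sep="\t", index=False)


def write_image(path: str | Path, img: Micrograph) -> None:
    """Write a 16-bit grayscale TIFF or PNG plus a pixel-size sidecar."""
    path = Path(path)
    data = img.to_uint16()
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps({"pixel_size_um": img.pixel_size}))


def read_image(path: str | Path, pixel_size: float | None = None) -> Micrograph:
    """Read a grayscale TIFF/PNG; pixel size from the sidecar unless given."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if pixel_size is None:
        sidecar = path.with_name(path.name + ".meta.json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no pixel size given and no sidecar {sidecar.name}"
            )
        pixel_size = float(json.loads(sidecar.read_text())["pixel_size_um"])
    data = np.asarray(data)
    if data.ndim == 3:
        # multi-plane TIFF z-stack: caller gets the planes
        raise ValueError(
            f"{path}: multi-plane image; use read_stack for z-stacks"
        )
    return Micrograph(data.astype(np.float64), pixel_size)


def read_stack(path: str | Path, pixel_size: float | None = None) -> list[Micrograph]:
    """Read a multi-plane TIFF as a list of planes for projection."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    if pixel_size is None:
        sidecar = path.with_name(path.name + ".meta.json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no pixel size given and no sidecar {sidecar.name}"
            )
        pixel_size = float(json.loads(sidecar.read_text())["pixel_size_um"])
    return [Micrograph(plane.astype(np.float64), pixel_size) for plane in data]
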