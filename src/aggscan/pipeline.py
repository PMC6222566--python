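"""End-to-end orchestration: simulate -> image -> quantify -> scan -> FDR -> peaks.

The pipeline ties the synthetic cross, the imaging quantitation and the
linkage scan into one seeded, reproducible run.  A single global seed is
expanded into independent per-stage substreams (via ``SeedSequence``), so
any stage rerun with the same configuration reproduces its output
bit-identically.  Every output table carries the seed and a configuration
hash in ``#`` header lines, and a JSON manifest records per-stage
checksums and wall times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .imaging import (
    SegmentationParams,
    aggregate_replicates,
    percent_foci,
    quantify_field,
)
from .io import write_genotypes, write_phenotypes, write_table
from .linkage import (
    PruneParams,
    call_peaks,
    linkage_scan,
    permutation_fdr,
)
from .synthdata import (
    CrossTruth,
    PhenotypeTable,
    render_field,
    sample_field_truth,
    simulate_cross,
    simulate_phenotypes,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "demo_config"]

_STAGES = ("simulate", "quantify", "scan", "fdr", "peaks")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic mapping run."""

    seed: int = 0
    out_dir: str = "aggscan_run"
    # cross simulation
    n_segregants: int = 120
    chrom_lengths: list[int] = field(default_factory=lambda: [10] * 15)
    recomb_prob: float = 0.2
    # kept low so the <=1-missing marker filter removes only a handful of
    # markers from a 120-strain panel
    missing_rate: float = 0.002
    qtl: list[tuple[int, float]] = field(default_factory=lambda: [(52, 10.0), (127, -8.0)])
    baseline: float = 12.0
    noise_sd: float = 2.0
    # imaging stage (set n_fields = 0 to map simulated phenotypes directly)
    n_fields: int = 8
    cells_per_field: int = 40
    frac_fluorescent: float = 0.8
    field_shape: tuple[int, int] = (320, 320)
    pixel_size: float = 0.2
    image_noise_sd: float = 20.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    # linkage stage
    prune: PruneParams = field(default_factory=PruneParams)
    n_perm: int = 100
    fdr_ceiling: float = 0.12

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qtl"] = [list(q) for q in self.qtl]
        d["field_shape"] = list(self.field_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "prune" in d and isinstance(d["prune"], dict):
            d["prune"] = PruneParams(**d["prune"])
        if "qtl" in d:
            d["qtl"] = [tuple(q) for q in d["qtl"]]
        if "field_shape" in d:
            d["field_shape"] = tuple(d["field_shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    """Record of one pipeline run: config, version, checksums, wall times."""

    config: dict
    version: str
    seed: int
    checksums: dict[str, str]
    wall_times: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


def demo_config(out_dir: str = "aggscan_demo", seed: int = 0) -> PipelineConfig:
    """Bundled demo: 2 antagonistic planted QTL, 120 segregants, 150 markers,
    8 synthetic fields per strain."""
    return PipelineConfig(seed=seed, out_dir=out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for name, child in zip(_STAGES, children)
    }


def _quantify_strain(
    percent_true: float, config: PipelineConfig, seed: int
) -> float | None:
    """Render and quantify ``n_fields`` micrograph pairs for one strain."""
    rng = np.random.default_rng(seed)
    reps = []
    frac = float(np.clip(percent_true / 100.0, 0.0, 1.0))
    for _ in range(config.n_fields):
        s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
        truth = sample_field_truth(
            n_cells=config.cells_per_field,
            frac_fluorescent=config.frac_fluorescent,
            frac_with_foci=frac,
            image_shape=config.field_shape,
            pixel_size=config.pixel_size,
            seed=s1,
            noise_sd=config.image_noise_sd,
        )
        dic, gfp = render_field(truth, config.field_shape, seed=s2)
        cells = quantify_field(dic, gfp, config.segmentation)
        reps.append(percent_foci(cells))
    return aggregate_replicates(reps).percent_foci


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all stage outputs to ``out_dir``.

    Stages: simulate cross genotypes and phenotypes; (optionally) render and
    quantify synthetic micrographs so the mapped phenotype is an *imaged*
    measurement; prune markers; scan; permutation FDR; call peaks.  Any
    stage failure aborts with the stage name; outputs of completed stages
    are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    checksums: dict[str, str] = {}
    wall: dict[str, float] = {}

    def _finish(stage: str, t0: float, *paths: Path) -> None:
        wall[stage] = time.perf_counter() - t0
        for p in paths:
            checksums[p.name] = _sha256(p)

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        geno = simulate_cross(
            config.n_segregants,
            config.chrom_lengths,
            recomb_prob=config.recomb_prob,
            missing_rate=config.missing_rate,
            seed=seeds["simulate"],
        )
        truth = CrossTruth(
            qtl=list(config.qtl),
            baseline=config.baseline,
            noise_sd=config.noise_sd,
            seed=seeds["simulate"] + 1,
        )
        pheno_true = simulate_phenotypes(geno, truth)
        geno_path = out / "genotypes.tsv"
        pheno_path = out / "phenotypes_true.tsv"
        write_genotypes(geno_path, geno, metadata=meta)
        write_phenotypes(pheno_path, pheno_true, metadata=meta)
        _finish(stage, t0, geno_path, pheno_path)

        stage = "quantify"
        t0 = time.perf_counter()
        if config.n_fields > 0:
            rng = np.random.default_rng(seeds["quantify"])
            measured = []
            for val in pheno_true.percent_foci:
                measured.append(
                    _quantify_strain(val, config, int(rng.integers(2**31)))
                )
            pheno = PhenotypeTable(
                strain_ids=list(pheno_true.strain_ids),
                percent_foci=np.asarray(
                    [np.nan if m is None else m for m in measured], dtype=float
                ),
            )
        else:
            pheno = pheno_true
        measured_path = out / "phenotypes_measured.tsv"
        write_phenotypes(measured_path, pheno, metadata=meta)
        _finish(stage, t0, measured_path)

        stage = "scan"
        t0 = time.perf_counter()
        from .linkage import prune_markers

        pruned, removal_log = prune_markers(geno, config.prune)
        scan = linkage_scan(pruned, pheno)
        scan_path = out / "scan.tsv"
        log_path = out / "marker_removals.tsv"
        write_table(scan_path, scan.table, metadata=meta)
        write_table(log_path, removal_log, metadata=meta)
        _finish(stage, t0, scan_path, log_path)

        stage = "fdr"
        t0 = time.perf_counter()
        fdr = permutation_fdr(
            pruned, pheno, n_perm=config.n_perm, seed=seeds["fdr"]
        )
        fdr_path = out / "fdr.tsv"
        write_table(fdr_path, fdr.table, metadata=meta)
        _finish(stage, t0, fdr_path)

        stage = "peaks"
        t0 = time.perf_counter()
        peaks = call_peaks(scan, fdr, fdr_ceiling=config.fdr_ceiling)
        peaks_path = out / "peaks.tsv"
        write_table(peaks_path, peaks, metadata=meta)
        _finish(stage, t0, peaks_path)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        checksums=checksums,
        wall_times=wall,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
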