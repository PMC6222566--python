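"""Single-marker linkage mapping with permutation FDR for a two-parent cross.

Workflow mirrors standard quantitative-trait-locus analysis of a haploid
yeast segregant panel:

1. Marker QC: redundant markers in high linkage disequilibrium with a
   neighbour (R^2 > 0.90) are pruned left-to-right within each chromosome,
   then markers with more than one missing genotype or minor-allele
   frequency below 25% are removed.
2. Scan: at each marker the strains are split by parental allele and the
   phenotype is regressed on the 0/1 allele code; the reported p-value
   tests the hypothesis that the fitted slope equals zero (algebraically
   the pooled two-sample t-test).
3. FDR: phenotype labels are shuffled across strains (genotypes, and hence
   linkage structure, fixed); the FDR at a p-value threshold is the average
   number of sub-threshold markers across permutations divided by the
   number observed in the real data.
4. Variance explained: single-locus and joint additive-model R^2 for named
   markers; peak calling collapses runs of adjacent significant markers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import LAB, MISSING, VINEYARD, GenotypeMatrix, PhenotypeTable

__all__ = [
    "PruneParams",
    "ScanResult",
    "FDRTable",
    "VarianceReport",
    "prune_markers",
    "linkage_scan",
    "permutation_fdr",
    "variance_explained",
    "call_peaks",
]


@dataclass
class PruneParams:
    """Marker QC thresholds.

    r2_max: retained neighbouring markers must have squared allele
    correlation <= this (default 0.90).  max_missing: maximum missing
    genotype entries per marker (default 1).  maf_min: minimum frequency of
    the rarer parental allele among non-missing entries (default 0.25).
    """

    r2_max: float = 0.90
    max_missing: int = 1
    maf_min: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must lie in (0, 1]")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")


@dataclass
class ScanResult:
    """Per-marker regression statistics, in marker_meta order.

    ``table`` columns: marker, chrom, pos, slope, se, t, p, n_used,
    defined.  Markers whose test is undefined (monomorphic among used
    strains, fewer than 3 complete strains, or zero phenotype variance) are
    flagged ``defined=False`` with NaN statistics, never silently dropped.
    """

    table: pd.DataFrame

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def defined(self) -> np.ndarray:
        return self.table["defined"].to_numpy()


@dataclass
class FDRTable:
    """Permutation FDR as a function of the p-value threshold.

    ``table`` columns: threshold (decreasing), mean_permuted_hits,
    real_hits, fdr.  fdr = mean_permuted_hits / real_hits, NaN (undefined)
    where real_hits == 0.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int | None = None


@dataclass
class VarianceReport:
    """Single-locus and joint additive-model variance explained."""

    single_r2: dict[str, float]
    joint_r2: float
    n_strains: int
    rank: int


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two allele vectors over pairwise-complete strains.

    Returns 0.0 when fewer than 2 complete pairs exist or either vector is
    constant on the complete subset (no correlation can be established, so
    the pair is never pruned on its account).
    """
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def prune_markers(
    geno: GenotypeMatrix,
    params: PruneParams | None = None,
    mode: str = "retained",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter redundant and low-quality markers; returns (filtered, removal log).

    Correlation pruning runs first (the earlier member of a violating pair
    is removed), then the missingness and minor-allele-frequency filters.
    Two pruning comparisons are available:

    - ``mode="retained"`` (default): each marker is compared against the
      last *retained* marker; on violation the retained marker (the earlier
      member) is dropped and the candidate is re-checked against the new
      tail.  This greedy left-to-right pass guarantees that every adjacent
      pair of surviving markers has R^2 <= r2_max.
    - ``mode="neighbor"``: each original adjacent pair is compared and the
      earlier member of a violating pair dropped; retained non-original
      neighbours are not re-checked (sensitivity-analysis variant).

    The removal log has columns (marker, chrom, pos, reason) with reason in
    {"r2", "missing", "maf", "insufficient_data"}; each removed marker
    appears exactly once.
    """
    params = params or PruneParams()
    if mode not in ("retained", "neighbor"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = geno.marker_meta
    alleles = geno.alleles
    removed: dict[int, str] = {}

    for chrom in meta["chrom"].unique():
        idx = np.flatnonzero(meta["chrom"].to_numpy() == chrom)
        usable = []
        for j in idx:
            if (alleles[:, j] != MISSING).sum() < 2:
                removed[j] = "insufficient_data"
            else:
                usable.append(int(j))
        if mode == "retained":
            retained: list[int] = []
            for j in usable:
                while retained and _pairwise_r2(
                    alleles[:, retained[-1]], alleles[:, j]
                ) > params.r2_max:
                    removed[retained.pop()] = "r2"
                retained.append(j)
        else:
            for prev, j in zip(usable[:-1], usable[1:]):
                if _pairwise_r2(alleles[:, prev], alleles[:, j]) > params.r2_max:
                    removed[prev] = "r2"

    for j in range(geno.n_markers):
        if j in removed:
            continue
        col = alleles[:, j]
        n_missing = int((col == MISSING).sum())
        if n_missing > params.max_missing:
            removed[j] = "missing"
            continue
        non_missing = col[col != MISSING]
        f_lab = float((non_missing == LAB).mean())
        if min(f_lab, 1.0 - f_lab) < params.maf_min:
            removed[j] = "maf"

    keep = [j for j in range(geno.n_markers) if j not in removed]
    log = pd.DataFrame(
        {
            "marker": [meta["name"].iloc[j] for j in sorted(removed)],
            "chrom": [meta["chrom"].iloc[j] for j in sorted(removed)],
            "pos": [meta["pos"].iloc[j] for j in sorted(removed)],
            "reason": [removed[j] for j in sorted(removed)],
        }
    )
    return geno.subset_markers(keep), log


# ---------------------------------------------------------------------------
# regression scan
# ---------------------------------------------------------------------------


def _scan_pvalues(
    alleles: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-marker simple regression of y on the 0/1 allele code.

    Strains MISSING at a marker are dropped for that marker.  Returns
    (slope, se, t, p, n_used, defined).
    """
    valid = alleles != MISSING
    x = np.where(valid, alleles, 0).astype(np.float64)
    yv = np.asarray(y, dtype=np.float64)

    n = valid.sum(axis=0).astype(np.float64)
    sx = x.sum(axis=0)
    sy = valid.T @ yv
    sxy = x.T @ yv
    syy = valid.T @ (yv * yv)

    with np.errstate(divide="ignore", invalid="ignore"):
        vx = sx - sx * sx / n  # x binary: sum(x^2) == sum(x)
        vy = syy - sy * sy / n
        cxy = sxy - sx * sy / n
        slope = cxy / vx
        sse = np.maximum(vy - cxy * cxy / vx, 0.0)
        dof = n - 2
        se = np.sqrt(sse / dof / vx)
        t = slope / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    # exact fits: se == 0 with a nonzero slope -> t = inf, p = 0
    exact = (se == 0) & (slope != 0) & np.isfinite(slope)
    t = np.where(exact, np.inf, t)
    p = np.where(exact, 0.0, p)
    defined = (n >= 3) & (vx > 1e-12) & (vy > 1e-12)
    for arr in (slope, se, t, p):
        arr[~defined] = np.nan
    return slope, se, t, p, n.astype(int), defined


def linkage_scan(geno: GenotypeMatrix, pheno: PhenotypeTable) -> ScanResult:
    """Single-marker regression scan of phenotype on parental allele.

    For each marker, strains with a missing genotype there are dropped,
    alleles are coded 0 (lab) / 1 (vineyard), and phenotype is fitted by
    least squares on intercept + slope * allele; the two-sided p comes from
    the t distribution with n_used - 2 degrees of freedom.  Strains with an
    undefined phenotype are excluded throughout.
    """
    if list(geno.strain_ids) != list(pheno.strain_ids):
        raise ValueError("strain ids of genotypes and phenotypes do not match")
    y = pheno.percent_foci
    keep = ~np.isnan(y)
    alleles = geno.alleles[keep]
    slope, se, t, p, n_used, defined = _scan_pvalues(alleles, y[keep])
    table = geno.marker_meta.copy()
    table = table.rename(columns={"name": "marker"})[["marker", "chrom", "pos"]]
    table["slope"] = slope
    table["se"] = se
    table["t"] = t
    table["p"] = p
    table["n_used"] = n_used
    table["defined"] = defined
    return ScanResult(table=table)


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------


def permutation_fdr(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    n_perm: int = 100,
    thresholds: np.ndarray | None = None,
    seed: int = 0,
    exhaustive: bool = False,
) -> FDRTable:
    """Estimate the FDR of the scan at each p-value threshold by permutation.

    Phenotype values are shuffled across strains (genotypes fixed,
    preserving linkage structure) and the scan re-run; at each threshold,
    FDR = (mean number of permuted markers with p <= threshold) /
    (number of real markers with p <= threshold), undefined (NaN) when the
    real count is zero.  Only markers with a defined test enter either
    count.  The default threshold grid is the sorted distinct observed
    p-values, which makes the FDR step function exact.

    ``exhaustive=True`` enumerates all n! phenotype permutations instead of
    sampling (tiny panels only); otherwise permutations are drawn from a
    seeded generator and are reproducible.
    """
    scan = linkage_scan(geno, pheno)
    p_real = scan.p[scan.defined]
    if thresholds is None:
        thresholds = np.unique(p_real[~np.isnan(p_real)])[::-1]
    else:
        thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")

    y = pheno.percent_foci
    keep = ~np.isnan(y)
    alleles = geno.alleles[keep]
    yv = y[keep]

    if exhaustive:
        n = yv.size
        if math.factorial(n) > 100000:
            raise ValueError("exhaustive enumeration infeasible for this panel size")
        perms = [np.asarray(p) for p in itertools.permutations(yv)]
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(yv) for _ in range(n_perm)]

    real_hits = np.array([(p_real <= thr).sum() for thr in thresholds])
    perm_hits = np.zeros(thresholds.size, dtype=float)
    for py in perms:
        _, _, _, pp, _, pdef = _scan_pvalues(alleles, py)
        pv = pp[pdef]
        perm_hits += np.array([(pv <= thr).sum() for thr in thresholds])
    mean_perm = perm_hits / len(perms)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(real_hits > 0, mean_perm / real_hits, np.nan)
    table = pd.DataFrame(
        {
            "threshold": thresholds,
            "mean_permuted_hits": mean_perm,
            "real_hits": real_hits,
            "fdr": fdr,
        }
    )
    return FDRTable(table=table, n_perm=len(perms), seed=None if exhaustive else seed)


# ---------------------------------------------------------------------------
# variance explained and peak calling
# ---------------------------------------------------------------------------


def variance_explained(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    marker_names: list[str],
) -> VarianceReport:
    """R^2 of additive least-squares models on named markers.

    Strains missing a genotype at any named marker (or an undefined
    phenotype) are excluded; single-locus R^2 values are computed on the
    same strain subset so they are comparable with the joint model.
    Collinear markers are handled by pseudoinverse and the design rank is
    reported.
    """
    if not marker_names:
        raise ValueError("at least one marker name required")
    idx = [geno.marker_index(name) for name in marker_names]
    y = pheno.percent_foci
    complete = ~np.isnan(y)
    for j in idx:
        complete &= geno.alleles[:, j] != MISSING
    n = int(complete.sum())
    if n < len(idx) + 2:
        raise ValueError("too few complete strains for the requested model")
    yv = y[complete]
    X = geno.alleles[complete][:, idx].astype(np.float64)

    def _r2(design: np.ndarray) -> float:
        A = np.column_stack([np.ones(design.shape[0]), design])
        beta = np.linalg.pinv(A) @ yv
        resid = yv - A @ beta
        sst = float(((yv - yv.mean()) ** 2).sum())
        if sst == 0:
            raise ValueError("zero phenotype variance among complete strains")
        return 1.0 - float((resid ** 2).sum()) / sst

    single = {name: _r2(X[:, [k]]) for k, name in enumerate(marker_names)}
    joint = _r2(X)
    rank = int(np.linalg.matrix_rank(np.column_stack([np.ones(n), X])))
    return VarianceReport(single_r2=single, joint_r2=joint, n_strains=n, rank=rank)


def call_peaks(
    scan: ScanResult,
    fdr_table: FDRTable,
    fdr_ceiling: float = 0.12,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """Call linkage peaks at an FDR ceiling.

    Finds the largest threshold with defined FDR <= ``fdr_ceiling``; markers
    with p at or below it are significant, and within each chromosome runs
    of adjacent significant markers are collapsed to their single best
    (lowest-p) marker.  ``merge_gap`` > 0 additionally merges significant
    markers separated by at most that many non-significant markers into one
    run, so a linked flank split off a peak by a single weak marker is not
    reported as a second locus.  Returns an empty table when no threshold
    qualifies.
    """
    tab = fdr_table.table
    ok = tab["fdr"].notna() & (tab["fdr"] <= fdr_ceiling)
    columns = ["marker", "chrom", "pos", "p", "threshold", "fdr"]
    if not ok.any():
        return pd.DataFrame(columns=columns)
    best = tab.loc[ok, "threshold"].max()
    fdr_at = float(tab.loc[tab["threshold"] == best, "fdr"].iloc[0])

    st = scan.table
    sig = st["defined"].to_numpy() & (st["p"].to_numpy() <= best)
    peaks = []
    for chrom in st["chrom"].unique():
        on_chrom = np.flatnonzero((st["chrom"] == chrom).to_numpy())
        run: list[int] = []
        last_sig: int | None = None
        for j in on_chrom:
            if sig[j]:
                if run and last_sig is not None and (j - last_sig) > merge_gap + 1:
                    peaks.append(min(run, key=lambda k: st["p"].iloc[k]))
                    run = []
                run.append(int(j))
                last_sig = int(j)
        if run:
            peaks.append(min(run, key=lambda k: st["p"].iloc[k]))
    out = st.iloc[peaks][["marker", "chrom", "pos", "p"]].copy()
    out["threshold"] = best
    out["fdr"] = fdr_at
    return out.sort_values("p").reset_index(drop=True)
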