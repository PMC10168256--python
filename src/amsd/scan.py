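"""Aggregate mutation spectrum distance (AMSD) genome scans.

At every informative marker the samples are split into the two parental-
allele groups, the de novo mutation spectra of each group are summed, and
the cosine distance between the two aggregate spectra is recorded.  Genome-
wide significance comes from a permutation test on the maximum per-scan
distance; relatedness between haplotype groups is absorbed by regressing
the per-marker distances on a between-group genetic-similarity correlation
and scanning the residuals ("adjusted" distances).  Peak localisation
uncertainty is estimated by a case-bootstrap over haplotypes.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import (
    HET,
    MISSING,
    P1,
    P2,
    GenotypeMatrix,
    MutationTable,
    SpectrumVector,
    ValidationError,
    spectra_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScanError",
    "ZeroSpectrumError",
    "cosine_distance",
    "group_haplotypes",
    "similarity_correlation",
    "adjust_distances",
    "amsd_scan",
    "permutation_threshold",
    "bootstrap_ci",
    "ScanResult",
    "PermutationNull",
    "BootstrapCI",
    "plot_scan",
]


class ScanError(ValueError):
    """The scan could not be carried out on the given inputs."""


class ZeroSpectrumError(ScanError):
    """Cosine distance is undefined against an all-zero spectrum."""


# ---------------------------------------------------------------------------
# Cosine distance
# ---------------------------------------------------------------------------


def _as_vector(x) -> np.ndarray:
    if isinstance(x, SpectrumVector):
        return x.values
    return np.asarray(x, dtype=float)


def cosine_distance(a, b) -> float:
    """``1 - A.B / (|A| |B|)`` with Euclidean norms.

    Scale-invariant, so aggregate spectra with very different total counts
    remain comparable.  Raises :class:`ZeroSpectrumError` if either vector
    is all zeros (the norm ratio is undefined); callers flag such markers
    instead of scoring them.
    """
    av, bv = _as_vector(a), _as_vector(b)
    if av.shape != bv.shape:
        raise ScanError(f"spectrum dimensions differ: {av.shape} vs {bv.shape}")
    na = float(np.linalg.norm(av))
    nb = float(np.linalg.norm(bv))
    if na == 0.0 or nb == 0.0:
        raise ZeroSpectrumError("cosine distance undefined for an all-zero spectrum")
    d = 1.0 - float(av @ bv) / (na * nb)
    # guard tiny negative round-off for identical directions
    return 0.0 if -1e-12 < d < 0.0 else d


def _group_distances(M0: np.ndarray, M1: np.ndarray, spectra: np.ndarray) -> np.ndarray:
    """Per-marker cosine distance between group-aggregate spectra.

    ``M0``/``M1`` are (markers x samples) 0/1 membership matrices and
    ``spectra`` is (samples x types); markers where either aggregate is all
    zero come back as NaN.
    """
    A = M0 @ spectra
    B = M1 @ spectra
    num = np.einsum("sd,sd->s", A, B)
    denom = np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - num / denom
    d[denom == 0.0] = np.nan
    np.clip(d, 0.0, 2.0, out=d)
    return d


def _group_distances_batch(
    M0: np.ndarray, M1: np.ndarray, spectra_stack: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`_group_distances` over a (trials x samples x types)
    stack of permuted spectra; returns (trials x markers)."""
    b, h, d = spectra_stack.shape
    flat = spectra_stack.transpose(1, 0, 2).reshape(h, b * d)  # BLAS-friendly
    A = (M0 @ flat).reshape(-1, b, d).transpose(1, 0, 2)
    B = (M1 @ flat).reshape(-1, b, d).transpose(1, 0, 2)
    num = np.einsum("bsd,bsd->bs", A, B)
    denom = np.linalg.norm(A, axis=2) * np.linalg.norm(B, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - num / denom
    d[denom == 0.0] = np.nan
    np.clip(d, 0.0, 2.0, out=d)
    return d


# ---------------------------------------------------------------------------
# Haplotype grouping and genetic similarity
# ---------------------------------------------------------------------------


def group_haplotypes(
    geno: GenotypeMatrix, marker_id: str
) -> tuple[set[str], set[str]]:
    """Split samples by parental allele at a marker.

    Heterozygous and missing calls belong to neither group; either group may
    come back empty (the marker is then flagged downstream, not an error).
    """
    row = geno.calls[geno.marker_index(marker_id)]
    samples = np.asarray(geno.sample_ids)
    return set(samples[row == P1]), set(samples[row == P2])


def _colwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of X and Y, NaN rows omitted
    pairwise; zero-variance or <2-observation columns give NaN."""
    both = np.isfinite(X) & np.isfinite(Y)
    Xz = np.where(both, X, 0.0)
    Yz = np.where(both, Y, 0.0)
    n = both.sum(axis=0).astype(float)
    sx = Xz.sum(axis=0)
    sy = Yz.sum(axis=0)
    sxx = (Xz * Xz).sum(axis=0)
    syy = (Yz * Yz).sum(axis=0)
    sxy = (Xz * Yz).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    r[(n < 2) | ~np.isfinite(r)] = np.nan
    return r


def _group_frequency_correlations(calls: np.ndarray) -> np.ndarray:
    """For every focal marker: Pearson r between the genome-wide P2-allele
    frequency vectors of the two allele groups defined at that marker.

    HET calls contribute dosage 0.5; MISSING calls are left out of the
    frequency denominator.  Markers where either group is empty give NaN.
    """
    dosage = np.full(calls.shape, np.nan)
    dosage[calls == P1] = 0.0
    dosage[calls == P2] = 1.0
    dosage[calls == HET] = 0.5
    finite = np.isfinite(dosage)
    Xz = np.where(finite, dosage, 0.0)
    # membership of each sample in the P1/P2 group of each *focal* marker
    in1 = (calls == P2).astype(float).T  # (samples, focal markers)
    in0 = (calls == P1).astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        F1 = (Xz @ in1) / (finite @ in1)  # (markers, focal markers)
        F0 = (Xz @ in0) / (finite @ in0)
    return _colwise_pearson(F1, F0)


def similarity_correlation(geno: GenotypeMatrix, marker_id: str) -> float:
    """Genetic-similarity correlation r_i for one marker (see module docs)."""
    i = geno.marker_index(marker_id)
    row = geno.calls[i]
    if not (row == P1).any() or not (row == P2).any():
        raise ScanError(f"marker {marker_id!r} has an empty allele group")
    return float(_group_frequency_correlations(geno.calls)[i])


# ---------------------------------------------------------------------------
# Relatedness adjustment
# ---------------------------------------------------------------------------


def adjust_distances(raw: Sequence[float], r: Sequence[float]) -> np.ndarray:
    """Residuals of an OLS fit of per-marker distance on similarity r.

    Markers where either quantity is undefined (NaN) receive NaN residuals
    and are excluded from the fit.  If r has no variance the regression is
    degenerate and the residuals fall back to deviations about the mean.
    """
    raw = np.asarray(raw, dtype=float)
    rv = np.asarray(r, dtype=float)
    if raw.shape != rv.shape:
        raise ScanError("distance and similarity vectors differ in length")
    valid = np.isfinite(raw) & np.isfinite(rv)
    if valid.sum() < 2:
        raise ScanError("need at least 2 markers with defined distance and r")
    out = np.full(raw.shape, np.nan)
    d = raw[valid]
    x = rv[valid]
    xc = x - x.mean()
    ss = float(xc @ xc)
    if ss == 0.0:
        out[valid] = d - d.mean()
        return out
    slope = float(xc @ (d - d.mean())) / ss
    intercept = d.mean() - slope * x.mean()
    out[valid] = d - (intercept + slope * x)
    return out


def _residualize_rows(D: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-wise OLS residuals of each row of D on r (refit per row).

    Used inside the permutation loop; columns are markers with finite r.
    NaN entries of a row (markers whose distance was undefined in that
    trial) are excluded from that row's fit and stay NaN in the output.
    Falls back to centring about the row mean when r has no variance.
    """
    W = np.isfinite(D)
    Dz = np.where(W, D, 0.0)
    n = W.sum(axis=1).astype(float)
    mean_d = Dz.sum(axis=1) / n
    mean_x = (W @ r) / n
    sxx = W @ (r * r) - n * mean_x**2
    sxy = Dz @ r - n * mean_x * mean_d
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0.0, sxy / sxx, 0.0)
    intercept = mean_d - slope * mean_x
    return D - intercept[:, None] - slope[:, None] * r[None, :]


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------


def _parse_allele(allele) -> int:
    mapping = {
        P1: P1, P2: P2,
        "P1": P1, "P2": P2,
        "B": P1, "D": P2,
        "0": P1, "1": P2,
    }
    try:
        return mapping[allele]
    except (KeyError, TypeError):
        raise ScanError(
            f"conditioning allele must be one of P1/P2 (or B/D), got {allele!r}"
        ) from None


def _resolve_samples(
    muts: MutationTable,
    geno: GenotypeMatrix,
    condition: tuple[str, object] | None,
    exclude_samples: Iterable[str],
    on_missing_samples: str,
) -> list[str]:
    mut_samples = set(muts.sample_ids)
    geno_samples = set(geno.sample_ids)
    absent = sorted(mut_samples - geno_samples)
    if absent:
        if on_missing_samples == "error":
            raise ScanError(
                f"{len(absent)} samples have mutations but no genotypes: "
                f"{absent[:5]}{'...' if len(absent) > 5 else ''}"
            )
        logger.warning(
            "dropping %d samples with mutations but no genotypes (first: %s)",
            len(absent),
            absent[:5],
        )
    excluded = set(exclude_samples)
    samples = [s for s in geno.sample_ids if s in mut_samples and s not in excluded]
    if condition is not None:
        marker_id, allele = condition
        code = _parse_allele(allele)
        row = geno.calls[geno.marker_index(marker_id)]
        lookup = dict(zip(geno.sample_ids, row))
        # heterozygous / missing samples at the conditioning marker are excluded
        samples = [s for s in samples if lookup[s] == code]
    if len(samples) < 2:
        raise ScanError(f"only {len(samples)} scannable samples remain")
    return samples


@dataclass
class ScanResult:
    """Per-marker distances plus scan-level statistics.

    ``table`` columns: marker, chrom, pos_mbp, raw_distance, similarity_r,
    adjusted_distance, n_p1, n_p2, scannable.  ``threshold`` is set after a
    permutation test, the CI bounds after a bootstrap.
    """

    table: pd.DataFrame
    settings: dict
    threshold: float | None = None
    n_permutations: int | None = None
    p: float | None = None
    ci_lo_mbp: float | None = None
    ci_hi_mbp: float | None = None

    @property
    def statistic_column(self) -> str:
        return "adjusted_distance" if self.settings.get("adjust", True) else "raw_distance"

    @property
    def peak(self) -> pd.Series:
        stat = self.statistic_column
        valid = self.table[self.table["scannable"] & np.isfinite(self.table[stat])]
        if len(valid) == 0:
            raise ScanError("no scannable markers with a defined statistic")
        best = valid[stat].max()
        ties = valid[valid[stat] == best]
        # deterministic tie-break: lowest genomic coordinate
        return ties.sort_values(["chrom", "pos_mbp"], kind="stable").iloc[0]

    @property
    def peak_marker(self) -> str:
        return str(self.peak["marker"])

    def significant(self) -> pd.DataFrame:
        if self.threshold is None:
            raise ScanError("run a permutation test before asking for significance")
        stat = self.statistic_column
        mask = self.table["scannable"] & (self.table[stat] >= self.threshold)
        return self.table[mask]

    def sidecar(self) -> dict:
        return {
            "settings": self.settings,
            "threshold": self.threshold,
            "n_permutations": self.n_permutations,
            "p": self.p,
            "peak_marker": self.peak_marker,
            "ci_lo_mbp": self.ci_lo_mbp,
            "ci_hi_mbp": self.ci_hi_mbp,
        }

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        tsv = prefix.with_suffix(".tsv")
        js = prefix.with_suffix(".json")
        self.table.to_csv(tsv, sep="\t", index=False, float_format="%.10g")
        js.write_text(json.dumps(self.sidecar(), indent=2, default=str) + "\n")
        return tsv, js


def _prepare(
    muts: MutationTable,
    geno: GenotypeMatrix,
    k: int,
    include_cpg: bool,
    condition,
    exclude_samples,
    on_missing_samples: str,
) -> tuple[GenotypeMatrix, np.ndarray, list[str]]:
    samples = _resolve_samples(muts, geno, condition, exclude_samples, on_missing_samples)
    sub = geno.subset_samples(samples)
    S = spectra_matrix(muts, sub.sample_ids, k, include_cpg).to_numpy(dtype=float)
    return sub, S, samples


def amsd_scan(
    muts: MutationTable,
    geno: GenotypeMatrix,
    *,
    k: int = 1,
    include_cpg: bool = True,
    adjust: bool = True,
    condition: tuple[str, object] | None = None,
    exclude_samples: Iterable[str] = (),
    on_missing_samples: str = "drop",
) -> ScanResult:
    """Genome-wide aggregate-spectrum cosine distance scan.

    Parameters
    ----------
    condition
        Optional ``(marker_id, allele)``: restrict the scan to samples
        homozygous for that parental allele at the conditioning marker
        (heterozygous samples are excluded).  The conditioning marker's own
        chromosome is still scanned.
    adjust
        Regress per-marker distances on the between-group genetic-similarity
        correlation and report residuals as ``adjusted_distance``.
    """
    sub, S, samples = _prepare(
        muts, geno, k, include_cpg, condition, exclude_samples, on_missing_samples
    )
    calls = sub.calls
    M0 = (calls == P1).astype(float)
    M1 = (calls == P2).astype(float)
    raw = _group_distances(M0, M1, S)
    n0 = M0.sum(axis=1).astype(int)
    n1 = M1.sum(axis=1).astype(int)
    scannable = (n0 > 0) & (n1 > 0) & np.isfinite(raw)
    r = _group_frequency_correlations(calls)
    if adjust:
        adj_input = np.where(scannable, raw, np.nan)
        adjusted = adjust_distances(adj_input, r)
    else:
        adjusted = np.full_like(raw, np.nan)
    table = sub.markers_frame()
    table["raw_distance"] = raw
    table["similarity_r"] = r
    table["adjusted_distance"] = adjusted
    table["n_p1"] = n0
    table["n_p2"] = n1
    table["scannable"] = scannable
    settings = {
        "k": k,
        "include_cpg": include_cpg,
        "adjust": adjust,
        "condition": list(condition) if condition else None,
        "exclude_samples": sorted(set(exclude_samples)),
        "n_samples": len(samples),
        "samples": samples,
    }
    return ScanResult(table=table, settings=settings)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Maximum scan statistic from each permutation trial."""

    max_statistics: np.ndarray
    stratified: bool
    seed: int | None
    p: float = 0.05

    def threshold(self, p: float | None = None) -> float:
        """Order-statistic (type-1) ``1 - p`` percentile: with N=10,000 and
        p=0.05 this is exactly the 9,500th sorted value."""
        p = self.p if p is None else p
        if not 0.0 < p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {p}")
        n = len(self.max_statistics)
        idx = max(0, math.ceil((1.0 - p) * n) - 1)
        return float(np.sort(self.max_statistics)[idx])


def _stratified_permutations(
    rng: np.random.Generator,
    n_samples: int,
    n_trials: int,
    strata_codes: np.ndarray | None,
) -> np.ndarray:
    """(trials x samples) permutation index matrix; when strata are given
    labels are shuffled only within each stratum."""
    base = np.tile(np.arange(n_samples), (n_trials, 1))
    if strata_codes is None:
        return rng.permuted(base, axis=1)
    out = base.copy()
    for code in np.unique(strata_codes):
        cols = np.flatnonzero(strata_codes == code)
        out[:, cols] = cols[rng.permuted(np.tile(np.arange(len(cols)), (n_trials, 1)), axis=1)]
    return out


def permutation_threshold(
    muts: MutationTable,
    geno: GenotypeMatrix,
    *,
    k: int = 1,
    include_cpg: bool = True,
    adjust: bool = True,
    n_permutations: int = 10_000,
    p: float = 0.05,
    stratified: bool = False,
    seed: int | None = None,
    refit_adjustment: bool = True,
    condition: tuple[str, object] | None = None,
    exclude_samples: Iterable[str] = (),
    on_missing_samples: str = "drop",
    batch_size: int = 500,
) -> PermutationNull:
    """Permutation null of the maximum per-scan distance.

    Each trial shuffles the sample-to-spectrum assignment (within strata
    when ``stratified``), reruns the whole scan — including, by default,
    re-fitting the relatedness regression — and records the maximum
    statistic over scannable markers.  Markers with an empty allele group or
    undefined similarity r are excluded from every trial's maximum, exactly
    as they are from the observed scan.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    sub, S, samples = _prepare(
        muts, geno, k, include_cpg, condition, exclude_samples, on_missing_samples
    )
    calls = sub.calls
    strata_codes = None
    if stratified:
        if sub.strata is None:
            raise ScanError("stratified permutations require per-sample strata labels")
        codes, counts = np.unique(sub.strata.to_numpy(), return_counts=True)
        singletons = counts == 1
        if singletons.any():
            warnings.warn(
                f"{int(singletons.sum())} strata contain a single sample; "
                "permutation is a no-op there",
                stacklevel=2,
            )
        strata_codes = pd.Categorical(sub.strata.to_numpy()).codes
    M0 = (calls == P1).astype(float)
    M1 = (calls == P2).astype(float)
    n0 = M0.sum(axis=1)
    n1 = M1.sum(axis=1)
    base_valid = (n0 > 0) & (n1 > 0)
    r = _group_frequency_correlations(calls)
    if adjust:
        valid = base_valid & np.isfinite(r)
    else:
        valid = base_valid
    if not valid.any():
        raise ScanError("no scannable markers for the permutation null")
    M0v, M1v, rv = M0[valid], M1[valid], r[valid]
    frozen = None
    if adjust and not refit_adjustment:
        raw_obs = _group_distances(M0v, M1v, S)
        resid = adjust_distances(raw_obs, rv)
        xc = rv - rv.mean()
        ss = float(xc @ xc)
        slope = float(xc @ (raw_obs - raw_obs.mean())) / ss if ss else 0.0
        intercept = raw_obs.mean() - slope * rv.mean()
        frozen = (intercept, slope)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_permutations)
    done = 0
    n_samples = len(samples)
    while done < n_permutations:
        b = min(batch_size, n_permutations - done)
        perms = _stratified_permutations(rng, n_samples, b, strata_codes)
        D = _group_distances_batch(M0v, M1v, S[perms])
        if adjust:
            if frozen is not None:
                stat = D - (frozen[0] + frozen[1] * rv)[None, :]
            else:
                stat = _residualize_rows(D, rv)
            stat[~np.isfinite(D)] = np.nan
        else:
            stat = D
        maxima[done : done + b] = np.nanmax(stat, axis=1)
        done += b
    return PermutationNull(max_statistics=maxima, stratified=stratified, seed=seed, p=p)


# ---------------------------------------------------------------------------
# Bootstrap confidence interval around a peak
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCI:
    """Case-bootstrap confidence interval for a peak's genomic position."""

    lo_mbp: float
    hi_mbp: float
    level: float
    peak_positions: np.ndarray
    n_discarded: int
    seed: int | None


def bootstrap_ci(
    muts: MutationTable,
    geno: GenotypeMatrix,
    chrom: str,
    *,
    k: int = 1,
    include_cpg: bool = True,
    adjust: bool = True,
    n_bootstrap: int = 10_000,
    level: float = 0.90,
    seed: int | None = None,
    condition: tuple[str, object] | None = None,
    exclude_samples: Iterable[str] = (),
    on_missing_samples: str = "drop",
) -> BootstrapCI:
    """Bootstrap the peak position on one chromosome.

    Each trial resamples haplotypes with replacement — jointly taking a
    sample's spectrum and its genotype column — rescans the chromosome, and
    records the position of the marker with the largest statistic (ties go
    to the lowest coordinate).  The interval spans the (1-level)/2 and
    1-(1-level)/2 order-statistic percentiles of those peak positions; at
    level 0.90 and N=10,000 these are the 5th and 95th percentile markers.
    Trials in which no marker separates the samples into two non-empty
    groups are discarded and counted.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    sub_all, S, samples = _prepare(
        muts, geno, k, include_cpg, condition, exclude_samples, on_missing_samples
    )
    sub = sub_all.subset_chrom(chrom)
    calls = sub.calls
    pos = sub.marker_pos_mbp
    h = calls.shape[1]
    rng = np.random.default_rng(seed)
    peaks = np.full(n_bootstrap, np.nan)
    discarded = 0
    for t in range(n_bootstrap):
        idx = rng.integers(0, h, size=h)
        c = calls[:, idx]
        Sb = S[idx]
        M0 = (c == P1).astype(float)
        M1 = (c == P2).astype(float)
        d = _group_distances(M0, M1, Sb)
        valid = (M0.sum(axis=1) > 0) & (M1.sum(axis=1) > 0) & np.isfinite(d)
        stat = d
        if adjust and valid.sum() >= 2:
            r = _group_frequency_correlations(c)
            fit_ok = valid & np.isfinite(r)
            if fit_ok.sum() >= 2:
                stat = adjust_distances(np.where(fit_ok, d, np.nan), r)
                valid = fit_ok
        if not valid.any():
            discarded += 1
            continue
        stat = np.where(valid, stat, -np.inf)
        # argmax with lowest-position tie-break (positions sorted within chrom)
        peaks[t] = pos[int(np.argmax(stat))]
    peaks = peaks[np.isfinite(peaks)]
    if discarded:
        logger.warning("discarded %d degenerate bootstrap trials", discarded)
    if len(peaks) == 0:
        raise ScanError("every bootstrap trial was degenerate")
    alpha = (1.0 - level) / 2.0
    lo = float(np.quantile(peaks, alpha, method="lower"))
    hi = float(np.quantile(peaks, 1.0 - alpha, method="higher"))
    return BootstrapCI(
        lo_mbp=lo,
        hi_mbp=hi,
        level=level,
        peak_positions=peaks,
        n_discarded=discarded,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_scan(result: ScanResult, path: str | Path) -> Path:
    """Manhattan-style plot of the scan statistic along the genome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table
    stat = result.statistic_column
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, labels = [], []
    for i, chrom in enumerate(dict.fromkeys(table["chrom"])):
        sub = table[table["chrom"] == chrom]
        x = sub["pos_mbp"].to_numpy() + offset
        ax.scatter(x, sub[stat], s=8, color=f"C{i % 2}")
        ticks.append(offset + sub["pos_mbp"].mean())
        labels.append(str(chrom))
        offset += sub["pos_mbp"].max() + 1.0
    if result.threshold is not None:
        ax.axhline(result.threshold, ls=":", color="grey")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(stat.replace("_", " "))
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
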