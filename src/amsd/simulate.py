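"""Synthetic RIL genotype/mutation data and AMSD power estimation.

The generative model mirrors a biparental recombinant inbred panel: each of
``h`` haplotypes is genotyped at ``s`` unlinked biallelic markers whose
alternate-allele frequency defaults to 0.5, and carries a 1-mer (or 3-mer)
mutation spectrum drawn as independent Poisson counts.  A single "mutator
locus" multiplies the Poisson mean of one mutation type by an effect size
``e`` on the haplotypes that carry its alternate allele.  The baseline
1-mer probabilities (C>T, CpG>TpG, C>A, C>G, A>T, A>C, A>G) =
(0.29, 0.17, 0.12, 0.075, 0.1, 0.075, 0.17) approximate the expected de
novo germline spectrum of laboratory mice.

Power of the scan is estimated over independent trials: a trial succeeds
when fewer than ``alpha * N`` of N permutation null statistics reach the
cosine distance observed at the mutator locus.  This module also doubles as
the repository's fixture generator (:func:`make_fixture`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import scan as _scan
from .spectra import (
    CPG_LABEL,
    P1,
    P2,
    GenotypeMatrix,
    MutationTable,
    ValidationError,
    mutation_type_labels,
    write_genotype_matrix,
    write_mutation_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "P_1MER",
    "SimParams",
    "RateVector",
    "PowerResult",
    "build_rate_vectors",
    "simulate_genotypes",
    "assign_mutation_counts",
    "simulate_spectra",
    "simulate_spectra_two_locus",
    "estimate_power",
    "make_fixture",
]

#: Baseline 1-mer mutation-type probabilities for the mouse germline.
P_1MER: dict[str, float] = {
    "C>T": 0.29,
    CPG_LABEL: 0.17,
    "C>A": 0.12,
    "C>G": 0.075,
    "A>T": 0.1,
    "A>C": 0.075,
    "A>G": 0.17,
}

_COUNT_MODELS = ("fixed", "grid", "uniform")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimParams:
    """Parameters of one simulated dataset.

    Defaults are the headline desk-scale scenario: 100 haplotypes with a
    mean of 500 mutations each, 100 markers at allele frequency 0.5, and a
    mutator at a random marker multiplying one 1-mer type's rate by ``e``.
    """

    n_haplotypes: int = 100
    n_markers: int = 100
    base_mutation_count: int = 500
    count_model: str = "fixed"
    mutator_effect: float = 1.2
    target_type: str = "C>A"
    k: int = 1
    include_cpg: bool = True
    mutator_allele_freq: float = 0.5
    mutator_marker_index: int | None = None

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1 or self.n_markers < 1 or self.base_mutation_count < 1:
            raise ValueError("n_haplotypes, n_markers and base_mutation_count must be positive")
        if self.mutator_effect < 1.0:
            raise ValueError(f"mutator effect must be >= 1, got {self.mutator_effect}")
        if self.count_model not in _COUNT_MODELS:
            raise ValueError(f"count_model must be one of {_COUNT_MODELS}")
        if not 0.0 <= self.mutator_allele_freq <= 1.0:
            raise ValueError("mutator_allele_freq must be in [0, 1]")
        if self.target_type not in mutation_type_labels(self.k, self.include_cpg):
            raise ValueError(
                f"target type {self.target_type!r} invalid for k={self.k}, "
                f"include_cpg={self.include_cpg}"
            )


@dataclass
class RateVector:
    """Per-type Poisson means at baseline (lam) and under the mutator (lam_prime)."""

    labels: list[str]
    probabilities: np.ndarray
    mean_count: float
    effect: float
    target_type: str

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("type probabilities must sum to 1")
        if self.target_type not in self.labels:
            raise ValueError(f"unknown target type {self.target_type!r}")
        if self.effect < 1.0:
            raise ValueError("effect must be >= 1")

    @property
    def target_index(self) -> int:
        return self.labels.index(self.target_type)

    @property
    def lam(self) -> np.ndarray:
        return self.probabilities * self.mean_count

    @property
    def lam_prime(self) -> np.ndarray:
        out = self.lam.copy()
        out[self.target_index] *= self.effect
        return out


def build_rate_vectors(
    k: int = 1,
    include_cpg: bool = True,
    m: int = 500,
    e: float = 1.0,
    target_type: str = "C>A",
) -> RateVector:
    """Baseline and mutator Poisson-mean vectors.

    At k=1 the probabilities come straight from :data:`P_1MER` (with the
    CpG category folded back into C>T when ``include_cpg`` is off).  At
    larger k every k-mer type inherits its central 1-mer type's probability
    divided evenly among the ``4**(k-1)`` flank combinations.
    """
    labels = mutation_type_labels(k, include_cpg)
    merged = {t: P_1MER[t] for t in P_1MER}
    if k == 1:
        if include_cpg:
            probs = np.array([merged[t] for t in labels])
        else:
            collapsed = dict(merged)
            collapsed["C>T"] = merged["C>T"] + merged[CPG_LABEL]
            probs = np.array([collapsed[t] for t in labels])
    else:
        collapsed = {t: merged[t] for t in merged if t != CPG_LABEL}
        collapsed["C>T"] = merged["C>T"] + merged[CPG_LABEL]
        n_flanks = 4 ** (k - 1)
        probs = np.array(
            [collapsed[lab.split("[")[1].split("]")[0]] / n_flanks for lab in labels]
        )
    return RateVector(
        labels=labels,
        probabilities=probs,
        mean_count=float(m),
        effect=float(e),
        target_type=target_type,
    )


def simulate_genotypes(
    n_markers: int = 100,
    n_haplotypes: int = 100,
    allele_freq: float = 0.5,
    rng=None,
    chrom: str = "1",
    strata: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Unlinked biallelic genotypes: each call is P2 with probability
    ``allele_freq`` (independent uniform draws), else P1.

    Markers are placed at 1 Mbp spacing on a single chromosome.
    """
    rng = _as_rng(rng)
    calls = np.where(
        rng.random((n_markers, n_haplotypes)) < allele_freq, P2, P1
    ).astype(np.int8)
    marker_ids = np.array([f"m{i + 1:04d}" for i in range(n_markers)])
    sample_ids = [f"sim{j + 1:04d}" for j in range(n_haplotypes)]
    strata_series = None
    if strata is not None:
        strata_series = pd.Series(list(strata), index=sample_ids)
    return GenotypeMatrix(
        marker_ids,
        np.full(n_markers, chrom),
        np.arange(1.0, n_markers + 1.0),
        sample_ids,
        calls,
        strata_series,
    )


def assign_mutation_counts(
    n_haplotypes: int,
    m: int = 500,
    count_model: str = "fixed",
    rng=None,
) -> np.ndarray:
    """Per-haplotype mean mutation counts.

    ``fixed``: every haplotype gets ``m``.  ``grid``: ``h`` evenly spaced
    integers from ``m`` to ``20 m`` inclusive (``np.linspace`` rounded to the
    nearest integer), assigned by haplotype index — a deterministic stand-in
    for inbreeding-duration variation.  ``uniform`` draws each count
    uniformly at random from the same range.
    """
    if count_model == "fixed":
        return np.full(n_haplotypes, m, dtype=int)
    if count_model == "grid":
        if n_haplotypes == 1:
            return np.array([m], dtype=int)
        return np.rint(np.linspace(m, 20 * m, n_haplotypes)).astype(int)
    if count_model == "uniform":
        return _as_rng(rng).integers(m, 20 * m + 1, size=n_haplotypes)
    raise ValueError(f"count_model must be one of {_COUNT_MODELS}")


def _carrier_mask(geno_or_calls, mutator_marker: int) -> np.ndarray:
    calls = geno_or_calls.calls if isinstance(geno_or_calls, GenotypeMatrix) else geno_or_calls
    return np.asarray(calls)[mutator_marker] == P2


def simulate_spectra(
    geno_or_calls,
    rates: RateVector,
    counts: np.ndarray,
    mutator_marker: int,
    rng=None,
) -> np.ndarray:
    """(haplotypes x types) spectrum counts.

    Every row is one independent Poisson draw per type; carriers of the
    alternate allele at ``mutator_marker`` draw from ``lam_prime``, others
    from ``lam``.  Each haplotype's whole rate vector is scaled by
    ``counts[i] / m`` so that its expected total matches its assigned mean
    count while preserving the spectrum shape.
    """
    rng = _as_rng(rng)
    carriers = _carrier_mask(geno_or_calls, mutator_marker)
    scale = np.asarray(counts, dtype=float) / rates.mean_count
    lam_matrix = np.where(carriers[:, None], rates.lam_prime[None, :], rates.lam[None, :])
    return rng.poisson(lam_matrix * scale[:, None]).astype(float)


def simulate_spectra_two_locus(
    geno_or_calls,
    rates: RateVector,
    counts: np.ndarray,
    marker_a: int,
    marker_b: int,
    effect_a: float,
    effect_b: float,
    interaction: float = 1.0,
    rng=None,
) -> np.ndarray:
    """Spectra with two mutator loci acting multiplicatively on the target
    type; carriers of both alleles get an extra ``interaction`` factor."""
    rng = _as_rng(rng)
    xa = _carrier_mask(geno_or_calls, marker_a).astype(float)
    xb = _carrier_mask(geno_or_calls, marker_b).astype(float)
    factor = effect_a**xa * effect_b**xb * interaction ** (xa * xb)
    scale = np.asarray(counts, dtype=float) / rates.mean_count
    lam_matrix = np.tile(rates.lam, (len(xa), 1)) * scale[:, None]
    lam_matrix[:, rates.target_index] *= factor
    return rng.poisson(lam_matrix).astype(float)


# ---------------------------------------------------------------------------
# Power estimation
# ---------------------------------------------------------------------------


@dataclass
class PowerResult:
    """Outcome of a power experiment."""

    n_trials: int
    n_success: int
    focal_distances: np.ndarray
    exceedance_fractions: np.ndarray
    settings: dict

    @property
    def power(self) -> float:
        return self.n_success / self.n_trials

    def to_json(self) -> dict:
        return {
            "power": self.power,
            "n_success": self.n_success,
            "n_trials": self.n_trials,
            "settings": self.settings,
        }


def _one_trial(
    params: SimParams,
    rates: RateVector,
    rng: np.random.Generator,
    n_permutations: int,
    null_statistic: str,
    batch_size: int = 500,
) -> tuple[float, float]:
    """Simulate one dataset, return (focal distance, fraction of permutation
    null statistics >= focal)."""
    s, h = params.n_markers, params.n_haplotypes
    for _ in range(50):
        calls = (rng.random((s, h)) < params.mutator_allele_freq).astype(np.int8)
        si = (
            params.mutator_marker_index
            if params.mutator_marker_index is not None
            else int(rng.integers(s))
        )
        carriers = calls[si] == 1
        if 0 < carriers.sum() < h:
            break
    else:
        raise ValueError("could not draw a marker with both alleles present")
    counts = assign_mutation_counts(h, params.base_mutation_count, params.count_model, rng)
    C = simulate_spectra(calls, rates, counts, si, rng)
    a = C[carriers].sum(axis=0)
    b = C[~carriers].sum(axis=0)
    focal = _scan.cosine_distance(a, b)
    M0 = (calls == 0).astype(float)
    M1 = (calls == 1).astype(float)
    valid = (M0.sum(axis=1) > 0) & (M1.sum(axis=1) > 0)
    null = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        nb = min(batch_size, n_permutations - done)
        perms = rng.permuted(np.tile(np.arange(h), (nb, 1)), axis=1)
        if null_statistic == "max":
            D = _scan._group_distances_batch(M0[valid], M1[valid], C[perms])
            null[done : done + nb] = np.nanmax(D, axis=1)
        else:  # distance at the focal marker only
            D = _scan._group_distances_batch(M0[[si]], M1[[si]], C[perms])
            null[done : done + nb] = D[:, 0]
        done += nb
    exceed = float(np.mean(null >= focal))
    return focal, exceed


def estimate_power(
    params: SimParams | None = None,
    *,
    n_trials: int = 100,
    n_permutations: int = 1_000,
    alpha: float = 0.05,
    seed: int | None = None,
    null_statistic: str = "max",
) -> PowerResult:
    """Estimate the scan's power under ``params``.

    A trial succeeds when fewer than ``alpha * n_permutations`` permutation
    null statistics are >= the cosine distance observed at the mutator
    locus.  ``null_statistic="max"`` records each permutation's maximum
    distance over all markers (the genome-wide scan null, the default);
    ``"focal"`` records the permuted distance at the mutator marker only
    (a single-locus null, useful for calibration studies).
    """
    params = params or SimParams()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if null_statistic not in ("max", "focal"):
        raise ValueError("null_statistic must be 'max' or 'focal'")
    rates = build_rate_vectors(
        params.k,
        params.include_cpg,
        params.base_mutation_count,
        params.mutator_effect,
        params.target_type,
    )
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    focal = np.empty(n_trials)
    exceed = np.empty(n_trials)
    for t in range(n_trials):
        rng = np.random.default_rng(streams[t])
        focal[t], exceed[t] = _one_trial(
            params, rates, rng, n_permutations, null_statistic
        )
    successes = int(np.sum(exceed < alpha))
    settings = asdict(params) | {
        "n_permutations": n_permutations,
        "alpha": alpha,
        "seed": seed,
        "null_statistic": null_statistic,
    }
    return PowerResult(
        n_trials=n_trials,
        n_success=successes,
        focal_distances=focal,
        exceedance_fractions=exceed,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

# minimal odd-length contexts consistent with each 1-mer label
_CONTEXT_FOR_1MER = {
    "C>A": "TCA",
    "C>G": "TCC",
    "C>T": "ACT",
    "A>C": "TAT",
    "A>G": "CAT",
    "A>T": "GAC",
    CPG_LABEL: "ACG",
}


def _context_for_label(label: str, k: int) -> tuple[str, str, str]:
    """(ref, alt, context) realising a mutation-type label."""
    if k == 1:
        if label == CPG_LABEL:
            return "C", "T", _CONTEXT_FOR_1MER[label]
        ref, alt = label.split(">")
        return ref, alt, _CONTEXT_FOR_1MER[label]
    left, rest = label.split("[")
    central, right = rest.split("]")
    ref, alt = central.split(">")
    return ref, alt, left + ref + right


def _spectra_to_mutation_frame(
    C: np.ndarray, labels: list[str], sample_ids: Sequence[str], k: int
) -> pd.DataFrame:
    rows = []
    for j, sample in enumerate(sample_ids):
        pos = 1
        for t, label in enumerate(labels):
            n = int(C[j, t])
            if n == 0:
                continue
            ref, alt, ctx = _context_for_label(label, k)
            for _ in range(n):
                rows.append((sample, "1", pos, ref, alt, ctx))
                pos += 100
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "context"]
    )


def make_fixture(
    out_dir: str | Path,
    params: SimParams | None = None,
    *,
    n_epochs: int = 2,
    seed: int = 0,
    second_mutator_marker_index: int | None = None,
    second_effect: float = 1.0,
    interaction_effect: float = 1.0,
    generations_range: tuple[int, int] = (20, 100),
    callable_bp: float = 1.1e9,
) -> dict:
    """Write a complete synthetic dataset to ``out_dir``.

    Produces ``mutations.tsv``, ``genotypes.csv`` and ``samples.tsv`` (epoch,
    generations inbred, callable base pairs) in the package's I/O formats,
    deterministically for a given seed.  When a second mutator marker is
    given, the two loci act multiplicatively on the target type with an
    optional interaction factor, which exercises the epistasis model.
    """
    params = params or SimParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _as_rng(seed)
    h, s = params.n_haplotypes, params.n_markers
    epochs = [f"epoch{1 + (j * n_epochs) // h}" for j in range(h)] if n_epochs else None
    geno = simulate_genotypes(
        s, h, params.mutator_allele_freq, rng, strata=epochs
    )
    marker_a = (
        params.mutator_marker_index
        if params.mutator_marker_index is not None
        else int(rng.integers(s))
    )
    counts = assign_mutation_counts(
        h, params.base_mutation_count, params.count_model, rng
    )
    rates = build_rate_vectors(
        params.k, params.include_cpg, params.base_mutation_count, 1.0, params.target_type
    )
    if second_mutator_marker_index is not None:
        C = simulate_spectra_two_locus(
            geno,
            rates,
            counts,
            marker_a,
            second_mutator_marker_index,
            params.mutator_effect,
            second_effect,
            interaction_effect,
            rng,
        )
    else:
        rates = build_rate_vectors(
            params.k,
            params.include_cpg,
            params.base_mutation_count,
            params.mutator_effect,
            params.target_type,
        )
        C = simulate_spectra(geno, rates, counts, marker_a, rng)
    labels = mutation_type_labels(params.k, params.include_cpg)
    mut_df = _spectra_to_mutation_frame(C, labels, geno.sample_ids, params.k)
    muts = MutationTable(mut_df)
    meta = pd.DataFrame(
        {
            "sample": geno.sample_ids,
            "epoch": epochs if epochs else ["epoch1"] * h,
            "generations": rng.integers(
                generations_range[0], generations_range[1] + 1, size=h
            ),
            "callable_bp": np.round(callable_bp * (0.9 + 0.2 * rng.random(h))),
        }
    )
    mut_path = out_dir / "mutations.tsv"
    geno_path = out_dir / "genotypes.csv"
    meta_path = out_dir / "samples.tsv"
    write_mutation_table(muts, mut_path)
    write_genotype_matrix(geno, geno_path)
    meta.to_csv(meta_path, sep="\t", index=False)
    manifest = {
        "seed": seed,
        "params": asdict(params),
        "n_epochs": n_epochs,
        "mutator_marker_index": marker_a,
        "mutator_marker": str(geno.marker_ids[marker_a]),
        "second_mutator_marker_index": second_mutator_marker_index,
        "second_mutator_marker": (
            str(geno.marker_ids[second_mutator_marker_index])
            if second_mutator_marker_index is not None
            else None
        ),
        "second_effect": second_effect,
        "interaction_effect": interaction_effect,
    }
    (out_dir / "fixture.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "mutations": mut_path,
        "genotypes": geno_path,
        "metadata": meta_path,
        "manifest": manifest,
        "mutation_table": muts,
        "genotype_matrix": geno,
        "metadata_frame": meta.set_index("sample"),
        "spectra": C,
    }
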