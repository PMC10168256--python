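"""Poisson-regression test for epistasis between two mutator loci.

Per-sample counts of a target mutation type (e.g. C>A) are modelled as
Poisson with a log link and an exposure offset:

    log lambda_i = b0 + b1 * X1_i + b2 * X2_i [+ b12 * X1_i X2_i] + log A_i

where X1/X2 are 0/1 genotypes at the two focal markers (0 = first parental
allele, 1 = second) and the exposure A_i — typically generations inbred
times callable target nucleotides, or callable bases alone — enters with a
fixed coefficient of 1 so that counts are modelled as rates.  Epistasis is
assessed by a chi-square likelihood-ratio comparison of the interaction
model against the additive one (1 degree of freedom).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .spectra import (
    HET,
    MISSING,
    P1,
    P2,
    GenotypeMatrix,
    MutationTable,
    ValidationError,
    mutation_type_labels,
    spectra_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IdentifiabilityError",
    "ExtrapolationWarning",
    "EpistasisInput",
    "EpistasisFit",
    "PredictedCount",
    "GroupCountsResult",
    "fit_epistasis",
    "predict_counts",
    "group_counts_table",
]


class IdentifiabilityError(ValueError):
    """The requested model has an unidentifiable coefficient."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested at an exposure outside the fitted range."""


@dataclass
class EpistasisInput:
    """Per-sample counts, binary genotypes at two loci, and exposures.

    Rows with non-positive exposure are rejected (dropped with a log
    message): the offset is ``log A_i``.
    """

    table: pd.DataFrame

    REQUIRED = ("count", "genotype_a", "genotype_b", "exposure")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"epistasis input missing columns: {missing}")
        tab = self.table.copy()
        bad = ~(tab["exposure"] > 0)
        if bad.any():
            logger.warning("dropping %d rows with non-positive exposure", int(bad.sum()))
            tab = tab[~bad]
        if (tab["count"] < 0).any() or (tab["count"] % 1 != 0).any():
            raise ValidationError("counts must be non-negative integers")
        if not tab["genotype_a"].isin([0, 1]).all() or not tab["genotype_b"].isin([0, 1]).all():
            raise ValidationError("genotypes must be coded 0/1 (homozygous only)")
        self.table = tab.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def cell_counts(self) -> pd.Series:
        return self.table.groupby(["genotype_a", "genotype_b"]).size()


class PredictedCount(NamedTuple):
    point: float
    lo: float
    hi: float


@dataclass
class EpistasisFit:
    """Nested additive and interaction Poisson fits plus their comparison."""

    additive: object  # statsmodels GLMResults
    interaction: object
    lrt_stat: float
    lrt_p: float
    exposure_range: tuple[float, float]
    lrt_df: int = 1

    @property
    def beta0(self) -> float:
        return float(self.interaction.params[0])

    @property
    def beta1(self) -> float:
        return float(self.interaction.params[1])

    @property
    def beta2(self) -> float:
        return float(self.interaction.params[2])

    @property
    def beta12(self) -> float:
        return float(self.interaction.params[3])

    def coefficients(self) -> pd.DataFrame:
        """Tidy coefficient table for both models (Wald 95% CIs)."""
        frames = []
        for model, res in (("additive", self.additive), ("interaction", self.interaction)):
            names = ["beta0", "beta1", "beta2", "beta12"][: len(res.params)]
            ci = res.conf_int()
            frames.append(
                pd.DataFrame(
                    {
                        "model": model,
                        "term": names,
                        "estimate": np.asarray(res.params),
                        "se": np.asarray(res.bse),
                        "ci_lo": np.asarray(ci)[:, 0],
                        "ci_hi": np.asarray(ci)[:, 1],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _design(tab: pd.DataFrame, interaction: bool) -> np.ndarray:
    cols = [
        np.ones(len(tab)),
        tab["genotype_a"].to_numpy(dtype=float),
        tab["genotype_b"].to_numpy(dtype=float),
    ]
    if interaction:
        cols.append(cols[1] * cols[2])
    return np.column_stack(cols)


def fit_epistasis(data: EpistasisInput | pd.DataFrame) -> EpistasisFit:
    """Fit the additive and interaction models and compare them by LRT.

    The additive model needs at least 4 samples spanning at least 3 of the
    4 genotype combinations; the interaction coefficient is identifiable
    only when all 4 combinations are observed (an empty cell is reported by
    name).  The likelihood-ratio statistic is the deviance difference,
    compared against chi-square with 1 df.
    """
    if not isinstance(data, EpistasisInput):
        data = EpistasisInput(data)
    tab = data.table
    cells = data.cell_counts()
    if len(tab) < 4 or len(cells) < 3:
        raise IdentifiabilityError(
            f"need >= 4 samples spanning >= 3 genotype combinations, got "
            f"{len(tab)} samples in {len(cells)} combinations"
        )
    empty = [
        cell
        for cell in [(0, 0), (0, 1), (1, 0), (1, 1)]
        if cell not in cells.index
    ]
    if empty:
        raise IdentifiabilityError(
            f"interaction coefficient unidentifiable: no samples with "
            f"(genotype_a, genotype_b) = {empty[0]}"
        )
    y = tab["count"].to_numpy(dtype=float)
    offset = np.log(tab["exposure"].to_numpy(dtype=float))
    def _fit(X: np.ndarray):
        model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            # all-zero-count or near-degenerate data emit harmless IRLS warnings
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            try:
                return model.fit()
            except ValueError:
                # IRLS cannot start from all-zero counts; start at beta = 0
                return model.fit(start_params=np.zeros(X.shape[1]))

    additive = _fit(_design(tab, False))
    interaction = _fit(_design(tab, True))
    lrt = max(float(additive.deviance - interaction.deviance), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return EpistasisFit(
        additive=additive,
        interaction=interaction,
        lrt_stat=lrt,
        lrt_p=p,
        exposure_range=(
            float(tab["exposure"].min()),
            float(tab["exposure"].max()),
        ),
    )


def predict_counts(
    fit: EpistasisFit,
    genotype_a: int,
    genotype_b: int,
    *,
    generations: float | None = None,
    callable_bp: float | None = None,
    exposure: float | None = None,
    model: str = "interaction",
    alpha: float = 0.05,
) -> PredictedCount:
    """Predicted target-type mutation count for a genotype combination.

    The exposure is either given directly or as ``generations *
    callable_bp``.  The point estimate is ``exp(x beta) * A`` and the CI is
    Wald on the linear predictor, exponentiated to the response scale.
    Warns when extrapolating beyond the exposures seen in the fit.
    """
    if exposure is None:
        if generations is None or callable_bp is None:
            raise ValueError("give exposure, or generations and callable_bp")
        exposure = float(generations) * float(callable_bp)
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    lo_e, hi_e = fit.exposure_range
    if not lo_e <= exposure <= hi_e:
        warnings.warn(
            f"exposure {exposure:g} outside fitted range [{lo_e:g}, {hi_e:g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    res = fit.interaction if model == "interaction" else fit.additive
    x = [1.0, float(genotype_a), float(genotype_b)]
    if model == "interaction":
        x.append(float(genotype_a) * float(genotype_b))
    x = np.asarray(x)
    eta = float(x @ res.params) + np.log(exposure)
    se = float(np.sqrt(x @ res.cov_params() @ x))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return PredictedCount(
        point=float(np.exp(eta)),
        lo=float(np.exp(eta - z * se)),
        hi=float(np.exp(eta + z * se)),
    )


@dataclass
class GroupCountsResult:
    """Per-sample model input plus group-level spectra and enrichment test.

    ``contingency`` is the 2x2 table of (target type, all other types)
    aggregate counts in the two ``genotype_b`` groups among samples carrying
    the alternate allele at marker A; ``chi2``/``chi2_p`` test whether the
    target type is enriched (no continuity correction, matching the
    large-count regime these tables live in)."""

    data: EpistasisInput
    group_spectra: pd.DataFrame
    contingency: pd.DataFrame | None
    chi2: float | None
    chi2_p: float | None
    target_type: str


def group_counts_table(
    muts: MutationTable,
    geno: GenotypeMatrix,
    marker_a: str,
    marker_b: str,
    target_type: str = "C>A",
    *,
    k: int = 1,
    include_cpg: bool = True,
    metadata: pd.DataFrame | None = None,
) -> GroupCountsResult:
    """Build the per-sample epistasis input from mutation + genotype tables.

    Only samples homozygous for a parental allele at *both* markers are
    kept.  Exposure is ``generations * callable_bp`` from ``metadata`` when
    available (either column alone if only one is present), else 1 for all
    samples (counts are then modelled directly, not as rates).
    """
    if target_type not in mutation_type_labels(k, include_cpg):
        raise ValidationError(f"invalid target type {target_type!r} for k={k}")
    ia = geno.marker_index(marker_a)
    ib = geno.marker_index(marker_b)
    samples = [s for s in geno.sample_ids if s in set(muts.sample_ids)]
    sub = geno.subset_samples(samples)
    calls_a = sub.calls[ia]
    calls_b = sub.calls[ib]
    hom = np.isin(calls_a, [P1, P2]) & np.isin(calls_b, [P1, P2])
    kept = [s for s, keep in zip(sub.sample_ids, hom) if keep]
    dropped = len(samples) - len(kept)
    if dropped:
        logger.info("excluding %d samples heterozygous/missing at a focal marker", dropped)
    S = spectra_matrix(muts, kept, k, include_cpg)
    ga = pd.Series(calls_a[hom], index=kept)
    gb = pd.Series(calls_b[hom], index=kept)
    if metadata is not None:
        meta = metadata.reindex(kept)
        gens = meta["generations"] if "generations" in meta else 1.0
        cbp = meta["callable_bp"] if "callable_bp" in meta else 1.0
        exposure = pd.Series(np.asarray(gens, dtype=float) * np.asarray(cbp, dtype=float), index=kept)
        if exposure.isna().any():
            raise ValidationError("metadata missing for some samples")
    else:
        exposure = pd.Series(1.0, index=kept)
    data = EpistasisInput(
        pd.DataFrame(
            {
                "sample": kept,
                "count": S[target_type].astype(int),
                "genotype_a": ga.astype(int),
                "genotype_b": gb.astype(int),
                "exposure": exposure,
            }
        ).reset_index(drop=True)
    )
    group_spectra = S.groupby([ga, gb]).sum()
    group_spectra.index.names = ["genotype_a", "genotype_b"]
    # target-vs-rest enrichment between the two marker-B groups among
    # samples carrying the alternate allele at marker A
    chi2 = chi2_p = None
    contingency = None
    rows = []
    for gb_val in (P2, P1):
        mask = (ga == P2) & (gb == gb_val)
        if not mask.any():
            logger.warning("empty genotype group (A=P2, B=%s); skipping chi-square test", gb_val)
            break
        grp = S.loc[mask[mask].index]
        target = float(grp[target_type].sum())
        rest = float(grp.drop(columns=target_type).sum().sum())
        rows.append((gb_val, target, rest))
    else:
        contingency = pd.DataFrame(
            [(r[1], r[2]) for r in rows],
            index=pd.Index([r[0] for r in rows], name="genotype_b"),
            columns=[target_type, "other"],
        )
        if (contingency.to_numpy().sum(axis=0) > 0).all():
            res = stats.chi2_contingency(contingency.to_numpy(), correction=False)
            chi2, chi2_p = float(res.statistic), float(res.pvalue)
    return GroupCountsResult(
        data=data,
        group_spectra=group_spectra,
        contingency=contingency,
        chi2=chi2,
        chi2_p=chi2_p,
        target_type=target_type,
    )
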