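"""k-mer mutation spectra: type classification, containers, and tabular I/O.

A *mutation spectrum* is the vector of counts of each k-mer mutation type in
a collection of de novo mutations, after collapsing reverse-complement pairs
so that the mutated base is written as a pyrimidine C or as A.  At k=1 the
spectrum has six categories (C>A, C>G, C>T, A>C, A>G, A>T), optionally
expanded with a seventh CpG>TpG category that separates C>T transitions at
CpG dinucleotides (spontaneous deamination of methylated cytosine) from
other C>T mutations.  At larger odd k the spectrum has ``6 * 4**(k-1)``
categories labelled COSMIC-style, e.g. ``"T[C>A]A"``.

This module also defines the two tabular inputs of a scan — a per-sample
mutation table and a markers x samples genotype matrix for a biparental
recombinant inbred population — and their delimited-text readers/writers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "P1",
    "P2",
    "HET",
    "MISSING",
    "DEFAULT_ALLELE_CODES",
    "BASE_TYPES",
    "CPG_LABEL",
    "MutationClassificationError",
    "ValidationError",
    "MutationRecord",
    "MutationTable",
    "SpectrumVector",
    "GenotypeMatrix",
    "reverse_complement",
    "mutation_type_labels",
    "spectrum_dim",
    "classify_mutation",
    "build_spectrum",
    "spectra_matrix",
    "read_mutation_table",
    "write_mutation_table",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_sample_metadata",
]

# Genotype call codes.  P1 and P2 are the two parental alleles of the cross
# (e.g. B = C57BL/6J and D = DBA/2J for the BXD family).
P1: int = 0
P2: int = 1
HET: int = 2
MISSING: int = 3

#: Default textual allele codes used in genotype CSV files (GeneNetwork style).
DEFAULT_ALLELE_CODES: dict[str, int] = {"B": P1, "D": P2, "H": HET, "U": MISSING}

_CALL_LETTERS = {P1: "P1", P2: "P2", HET: "HET", MISSING: "MISSING"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical strand-collapsed 1-mer mutation types (mutated base written C or A).
BASE_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "A>C", "A>G", "A>T")

#: Label of the separate CpG>TpG category (only used at k=1).
CPG_LABEL: str = "CpG>TpG"


class MutationClassificationError(ValueError):
    """A mutation record could not be assigned to a k-mer mutation type."""


class ValidationError(ValueError):
    """Tabular input violated a schema or content invariant."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spectrum_dim(k: int = 1, include_cpg: bool = True) -> int:
    """Number of spectrum categories: ``6 * 4**(k-1)``, plus one for the
    CpG>TpG category when ``k == 1`` and ``include_cpg``."""
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    return 6 * 4 ** (k - 1) + (1 if (k == 1 and include_cpg) else 0)


def mutation_type_labels(k: int = 1, include_cpg: bool = True) -> list[str]:
    """Canonical ordered labels of the k-mer mutation spectrum."""
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    if k == 1:
        labels = list(BASE_TYPES)
        if include_cpg:
            labels.append(CPG_LABEL)
        return labels
    flank = (k - 1) // 2
    flanks = ["".join(t) for t in itertools.product("ACGT", repeat=flank)]
    return [
        f"{left}[{central}]{right}"
        for central in BASE_TYPES
        for left in flanks
        for right in flanks
    ]


class MutationRecord(NamedTuple):
    """A single de novo mutation on one sample's haplotype.

    ``pos`` is 1-based (VCF convention).  ``context`` is an odd-length
    A/C/G/T string centered on the mutated reference base.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str


def classify_mutation(rec: MutationRecord, k: int = 1, include_cpg: bool = True) -> str:
    """Assign a record to its strand-collapsed k-mer mutation type.

    When the reference base is a purine G or T... strictly, when it is G or
    T (i.e. not the canonical C/A), the ref, alt, and context are jointly
    reverse-complemented before labelling.  CpG status is resolved from the
    3' neighbour in the (oriented) supplied context; a record whose context
    is too short to resolve the CpG category or the k-mer window is rejected
    rather than silently misclassified.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    ident = f"{rec.sample_id}:{rec.chrom}:{rec.pos}"
    ref, alt, ctx = rec.ref, rec.alt, rec.context
    if ref not in "ACGT" or len(ref) != 1:
        raise MutationClassificationError(f"{ident}: invalid ref base {ref!r}")
    if alt not in "ACGT" or len(alt) != 1:
        raise MutationClassificationError(f"{ident}: invalid alt base {alt!r}")
    if ref == alt:
        raise MutationClassificationError(f"{ident}: ref equals alt ({ref!r})")
    if not ctx or set(ctx) - set("ACGT"):
        raise MutationClassificationError(
            f"{ident}: context {ctx!r} contains non-ACGT characters"
        )
    if len(ctx) % 2 == 0:
        raise MutationClassificationError(
            f"{ident}: context {ctx!r} must have odd length"
        )
    mid = len(ctx) // 2
    if ctx[mid] != ref:
        raise MutationClassificationError(
            f"{ident}: context middle base {ctx[mid]!r} != ref {ref!r}"
        )
    if len(ctx) < k:
        raise MutationClassificationError(
            f"{ident}: context {ctx!r} shorter than k={k}"
        )
    if ref in "GT":
        ctx = reverse_complement(ctx)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    if k == 1:
        if include_cpg and ref == "C" and alt == "T":
            if len(ctx) < 3:
                raise MutationClassificationError(
                    f"{ident}: context {rec.context!r} too short to resolve "
                    "CpG status; supply at least the two flanking bases"
                )
            if ctx[mid + 1] == "G":
                return CPG_LABEL
        return f"{ref}>{alt}"
    flank = (k - 1) // 2
    window = ctx[mid - flank : mid + flank + 1]
    return f"{window[:flank]}[{ref}>{alt}]{window[flank + 1:]}"


@dataclass
class MutationTable:
    """Validated table of per-sample de novo mutation records.

    Wraps a DataFrame with columns ``sample, chrom, pos, ref, alt, context``.
    Exact duplicates of (sample, chrom, pos) are rejected by default because
    the records are meant to be *private* single-nucleotide mutations.
    """

    df: pd.DataFrame
    allow_duplicates: bool = False

    REQUIRED: tuple[str, ...] = ("sample", "chrom", "pos", "ref", "alt", "context")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"mutation table missing columns: {missing}")
        df = self.df.copy()
        for col in ("sample", "chrom", "ref", "alt", "context"):
            df[col] = df[col].astype(str)
        df["pos"] = df["pos"].astype(int)
        self.df = df.reset_index(drop=True)
        self._validate_rows()
        if not self.allow_duplicates:
            dup = self.df.duplicated(subset=["sample", "chrom", "pos"], keep=False)
            if dup.any():
                first = self.df[dup].iloc[0]
                raise ValidationError(
                    "duplicate (sample, chrom, pos) records, first at "
                    f"{first['sample']}:{first['chrom']}:{first['pos']}; "
                    "pass allow_duplicates=True to keep them"
                )

    def _validate_rows(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        bad = df["ref"] == df["alt"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValidationError(
                f"row {df.index[bad][0]} ({row['sample']}:{row['chrom']}:"
                f"{row['pos']}): ref equals alt ({row['ref']!r})"
            )
        ok_base = df["ref"].isin(list("ACGT")) & df["alt"].isin(list("ACGT"))
        ok_ctx = df["context"].str.fullmatch("[ACGT]+") & (
            df["context"].str.len() % 2 == 1
        )
        mid = df["context"].str.len() // 2
        centered = pd.Series(
            [c[m] == r for c, m, r in zip(df["context"], mid, df["ref"])],
            index=df.index,
        )
        bad = ~(ok_base & ok_ctx.fillna(False) & centered)
        if bad.any():
            row = df[bad].iloc[0]
            raise ValidationError(
                f"row {df.index[bad][0]} ({row['sample']}:{row['chrom']}:"
                f"{row['pos']}): invalid ref/alt/context "
                f"({row['ref']!r}>{row['alt']!r}, context {row['context']!r})"
            )

    @property
    def sample_ids(self) -> list[str]:
        """Distinct sample IDs, in order of first appearance."""
        return list(dict.fromkeys(self.df["sample"]))

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[MutationRecord]:
        for row in self.df.itertuples(index=False):
            yield MutationRecord(
                row.sample, row.chrom, row.pos, row.ref, row.alt, row.context
            )

    def classify(self, k: int = 1, include_cpg: bool = True) -> pd.Series:
        """Per-record mutation-type labels, aligned with ``self.df``."""
        labels = [classify_mutation(rec, k, include_cpg) for rec in self.records()]
        return pd.Series(labels, index=self.df.index, name="mutation_type")

    def subset(self, samples: Iterable[str]) -> "MutationTable":
        keep = set(samples)
        return MutationTable(
            self.df[self.df["sample"].isin(keep)].reset_index(drop=True),
            allow_duplicates=True,
        )


@dataclass
class SpectrumVector:
    """Counts per k-mer mutation type, in the canonical label order."""

    k: int
    include_cpg: bool
    counts: pd.Series

    def __post_init__(self) -> None:
        labels = mutation_type_labels(self.k, self.include_cpg)
        if set(self.counts.index) - set(labels):
            extra = sorted(set(self.counts.index) - set(labels))
            raise ValidationError(f"unknown mutation-type labels: {extra}")
        self.counts = self.counts.reindex(labels, fill_value=0).astype(float)
        if (self.counts < 0).any():
            raise ValidationError("spectrum counts must be non-negative")

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "SpectrumVector") -> "SpectrumVector":
        if (self.k, self.include_cpg) != (other.k, other.include_cpg):
            raise ValidationError("cannot add spectra with different k / CpG settings")
        return SpectrumVector(self.k, self.include_cpg, self.counts + other.counts)

    def __len__(self) -> int:
        return len(self.counts)


def build_spectrum(
    muts: MutationTable,
    samples: Iterable[str] | None = None,
    k: int = 1,
    include_cpg: bool = True,
) -> SpectrumVector:
    """Aggregate spectrum of the records belonging to ``samples``.

    ``samples=None`` aggregates over every sample in the table.  An *empty*
    sample subset is an error; a subset whose samples simply carry no
    mutations yields an all-zero spectrum.
    """
    if samples is None:
        sub = muts.df
    else:
        keep = set(samples)
        if not keep:
            raise ValidationError("empty sample subset (did you mean all samples?)")
        sub = muts.df[muts.df["sample"].isin(keep)]
    labels = mutation_type_labels(k, include_cpg)
    if len(sub) == 0:
        counts = pd.Series(0.0, index=labels)
    else:
        table = MutationTable(sub, allow_duplicates=True)
        counts = table.classify(k, include_cpg).value_counts()
    return SpectrumVector(k, include_cpg, counts)


def spectra_matrix(
    muts: MutationTable,
    sample_order: Sequence[str],
    k: int = 1,
    include_cpg: bool = True,
) -> pd.DataFrame:
    """Per-sample spectra as a (samples x types) count DataFrame.

    Rows follow ``sample_order``; samples without records get zero rows.
    """
    labels = mutation_type_labels(k, include_cpg)
    if len(muts) == 0:
        return pd.DataFrame(0.0, index=list(sample_order), columns=labels)
    cls = muts.classify(k, include_cpg)
    ct = pd.crosstab(muts.df["sample"], cls)
    return ct.reindex(index=list(sample_order), columns=labels, fill_value=0).astype(
        float
    )


@dataclass
class GenotypeMatrix:
    """Markers x samples parental-allele calls for a biparental RIL panel.

    ``calls`` holds integer codes ``P1/P2/HET/MISSING``; marker positions are
    stored in Mbp (GeneNetwork convention) and must be non-decreasing within
    each chromosome.  ``strata`` optionally labels each sample with a
    breeding epoch for stratified permutation tests.
    """

    marker_ids: np.ndarray
    marker_chrom: np.ndarray
    marker_pos_mbp: np.ndarray
    sample_ids: list[str]
    calls: np.ndarray
    strata: pd.Series | None = None

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=str)
        self.marker_chrom = np.asarray(self.marker_chrom, dtype=str)
        self.marker_pos_mbp = np.asarray(self.marker_pos_mbp, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        s, h = self.calls.shape
        if not (
            len(self.marker_ids) == len(self.marker_chrom) == len(self.marker_pos_mbp) == s
        ):
            raise ValidationError("marker annotation lengths do not match calls rows")
        if len(self.sample_ids) != h:
            raise ValidationError("sample_ids length does not match calls columns")
        if len(set(self.sample_ids)) != h:
            raise ValidationError("duplicate sample IDs in genotype matrix")
        if not np.isin(self.calls, [P1, P2, HET, MISSING]).all():
            raise ValidationError("genotype calls contain invalid codes")
        for chrom in dict.fromkeys(self.marker_chrom):
            pos = self.marker_pos_mbp[self.marker_chrom == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValidationError(
                    f"marker positions decrease within chromosome {chrom}"
                )
        if self.strata is not None:
            self.strata = pd.Series(self.strata).astype(str)
            missing = [s for s in self.sample_ids if s not in self.strata.index]
            if missing:
                raise ValidationError(f"strata missing for samples: {missing[:5]}")
            self.strata = self.strata.loc[self.sample_ids]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if len(idx) == 0:
            raise ValidationError(f"marker {marker_id!r} not found")
        return int(idx[0])

    def dosage(self) -> np.ndarray:
        """P2-allele dosage in [0, 1]; HET counts 0.5, MISSING is NaN."""
        out = np.full(self.calls.shape, np.nan)
        out[self.calls == P1] = 0.0
        out[self.calls == P2] = 1.0
        out[self.calls == HET] = 0.5
        return out

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        keep = set(samples)
        cols = [j for j, s in enumerate(self.sample_ids) if s in keep]
        ids = [self.sample_ids[j] for j in cols]
        strata = self.strata.loc[ids] if self.strata is not None else None
        return GenotypeMatrix(
            self.marker_ids,
            self.marker_chrom,
            self.marker_pos_mbp,
            ids,
            self.calls[:, cols],
            strata,
        )

    def subset_chrom(self, chrom: str) -> "GenotypeMatrix":
        rows = self.marker_chrom == str(chrom)
        if not rows.any():
            raise ValidationError(f"no markers on chromosome {chrom!r}")
        return GenotypeMatrix(
            self.marker_ids[rows],
            self.marker_chrom[rows],
            self.marker_pos_mbp[rows],
            self.sample_ids,
            self.calls[rows],
            self.strata,
        )

    def markers_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chrom": self.marker_chrom,
                "pos_mbp": self.marker_pos_mbp,
            }
        )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_mutation_table(
    path: str | Path,
    sep: str | None = None,
    allow_duplicates: bool = False,
) -> MutationTable:
    """Read a mutation table from TSV/CSV (delimiter inferred from suffix).

    Required columns: ``sample, chrom, pos, ref, alt, context``.  Extra
    columns are preserved untouched.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path), dtype={"chrom": str})
    return MutationTable(df, allow_duplicates=allow_duplicates)


def write_mutation_table(muts: MutationTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    muts.df.to_csv(path, sep=sep or _sep_for(path), index=False)


def read_genotype_matrix(
    path: str | Path,
    allele_codes: Mapping[str, int] | None = None,
    strata: Mapping[str, str] | pd.Series | None = None,
    sep: str | None = None,
) -> GenotypeMatrix:
    """Read a genotype CSV: columns ``marker, chrom, pos_mbp`` then one
    column per sample, cells holding allele codes (default B/D/H/U).

    Unrecognised codes are mapped to MISSING and counted in a log message.
    """
    path = Path(path)
    codes = dict(allele_codes or DEFAULT_ALLELE_CODES)
    df = pd.read_csv(path, sep=sep or _sep_for(path), dtype=str)
    required = ["marker", "chrom", "pos_mbp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"genotype file missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise ValidationError("genotype file has no sample columns")
    raw = df[sample_cols].to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    unknown = 0
    for code, value in codes.items():
        calls[raw == code] = value
    known = np.isin(raw, list(codes))
    unknown = int((~known).sum())
    if unknown:
        logger.warning(
            "%d genotype calls with unknown codes mapped to MISSING in %s",
            unknown,
            path,
        )
    strata_series = None
    if strata is not None:
        strata_series = pd.Series(strata)
    return GenotypeMatrix(
        df["marker"].to_numpy(),
        df["chrom"].to_numpy(),
        df["pos_mbp"].to_numpy(dtype=float),
        sample_cols,
        calls,
        strata_series,
    )


def write_genotype_matrix(
    geno: GenotypeMatrix,
    path: str | Path,
    allele_codes: Mapping[str, int] | None = None,
    sep: str | None = None,
) -> None:
    path = Path(path)
    codes = dict(allele_codes or DEFAULT_ALLELE_CODES)
    inverse = {v: k for k, v in codes.items()}
    letters = np.vectorize(inverse.__getitem__)(geno.calls)
    df = pd.concat(
        [geno.markers_frame(), pd.DataFrame(letters, columns=geno.sample_ids)],
        axis=1,
    )
    df.to_csv(path, sep=sep or _sep_for(path), index=False)


def read_sample_metadata(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read per-sample metadata (``sample`` plus e.g. ``epoch``,
    ``generations``, ``callable_bp``), indexed by sample ID."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path))
    if "sample" not in df.columns:
        raise ValidationError("sample metadata must have a 'sample' column")
    df["sample"] = df["sample"].astype(str)
    return df.set_index("sample")
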