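"""Shared fixtures: a hand-built four-haplotype toy dataset and a simulated
fixture directory, all generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amsd import (
    HET,
    P1,
    P2,
    GenotypeMatrix,
    MutationTable,
    SimParams,
    make_fixture,
)

# Contexts realising each 1-mer type without accidental CpG
CTX = {
    "C>A": "TCA",
    "C>G": "TCC",
    "C>T": "ACT",
    "A>C": "TAT",
    "A>G": "CAT",
    "A>T": "GAC",
    "CpG>TpG": "ACG",
}


def records_for(sample: str, type_counts: dict[str, int], chrom: str = "1") -> list[tuple]:
    """Rows of a mutation table realising the given per-type counts."""
    rows = []
    pos = 1
    for label, n in type_counts.items():
        ctx = CTX[label]
        ref = ctx[1]
        alt = "T" if label == "CpG>TpG" else label.split(">")[1]
        for _ in range(n):
            rows.append((sample, chrom, pos, ref, alt, ctx))
            pos += 10
    return rows


def table_from_counts(counts_by_sample: dict[str, dict[str, int]]) -> MutationTable:
    rows = []
    for sample, counts in counts_by_sample.items():
        rows.extend(records_for(sample, counts))
    return MutationTable(
        pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "context"])
    )


@pytest.fixture(scope="session")
def toy_dataset():
    """Four haplotypes, three markers, two mutation types.

    "Triangle" mutations are A>C and "square" mutations are C>A.  At marker
    g1 the P1 group (h1, h2) carries 3 triangles + 5 squares in aggregate
    and the P2 group (h3, h4) carries 6 triangles + 2 squares, so the g1
    cosine distance is 1 - 28 / (sqrt(34) * sqrt(40)).
    """
    per_sample = {
        "h1": {"A>C": 1, "C>A": 3},
        "h2": {"A>C": 2, "C>A": 2},
        "h3": {"A>C": 4, "C>A": 1},
        "h4": {"A>C": 2, "C>A": 1},
    }
    muts = table_from_counts(per_sample)
    calls = np.array(
        [
            [P1, P1, P2, P2],  # g1
            [P1, P2, P1, P2],  # g2
            [P2, P2, P1, P1],  # g3
        ],
        dtype=np.int8,
    )
    geno = GenotypeMatrix(
        np.array(["g1", "g2", "g3"]),
        np.array(["1", "1", "2"]),
        np.array([10.0, 20.0, 5.0]),
        ["h1", "h2", "h3", "h4"],
        calls,
        strata=pd.Series(
            {"h1": "epoch1", "h2": "epoch1", "h3": "epoch2", "h4": "epoch2"}
        ),
    )
    return muts, geno


@pytest.fixture(scope="session")
def sim_fixture(tmp_path_factory):
    """A small simulated dataset on disk: 30 haplotypes, 20 markers,
    two epochs, a planted mutator of effect 2 at marker index 7."""
    out = tmp_path_factory.mktemp("fixture")
    params = SimParams(
        n_haplotypes=30,
        n_markers=20,
        base_mutation_count=200,
        mutator_effect=2.0,
        target_type="C>A",
        mutator_marker_index=7,
    )
    return make_fixture(out, params, n_epochs=2, seed=42)


@pytest.fixture(scope="session")
def two_locus_fixture(tmp_path_factory):
    """Simulated dataset with two mutator loci and a multiplicative
    interaction, for the epistasis model."""
    out = tmp_path_factory.mktemp("fixture2")
    params = SimParams(
        n_haplotypes=80,
        n_markers=20,
        base_mutation_count=300,
        mutator_effect=1.6,
        target_type="C>A",
        mutator_marker_index=3,
    )
    return make_fixture(
        out,
        params,
        n_epochs=2,
        seed=7,
        second_mutator_marker_index=12,
        second_effect=1.0,
        interaction_effect=1.5,
    )
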