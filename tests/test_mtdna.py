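"""Haplotype collapsing, parsimony limit, network building and
introgression accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hybridscan.core_data import HaplotypeAlignment
from hybridscan.mtdna import (
    build_network,
    collapse_haplotypes,
    connection_limit,
    introgression_summary,
    pairwise_steps,
    parsimony_probability,
)


def test_collapse_multiplicity_and_order():
    aln = HaplotypeAlignment(
        sample_ids=[f"s{i}" for i in range(7)],
        sequences=["ACGT"] * 5 + ["ACGA", "ACGA"],
    )
    haps = collapse_haplotypes(aln)
    assert list(haps["multiplicity"]) == [5, 2]
    assert haps.loc[0, "hap_id"] == "H1"
    assert set(haps.loc[0, "sample_ids"]) == {f"s{i}" for i in range(5)}


def test_collapse_is_exact_string_even_with_n():
    aln = HaplotypeAlignment(sample_ids=["a", "b"], sequences=["ACGT", "ACGN"])
    haps = collapse_haplotypes(aln)
    assert len(haps) == 2  # N is a wildcard only for distances
    d = pairwise_steps(list(haps["sequence"]))
    assert d[0, 1] == 0  # the N site is excluded pairwise


def test_pairwise_steps_excludes_gap_sites():
    d = pairwise_steps(["ACGT", "A-TT"])
    assert d[0, 1] == 1  # gap site dropped, only position 3 counted... pos2 differs
    d2 = pairwise_steps(["AAAA", "TTTT"])
    assert d2[0, 1] == 4


def test_connection_limit_properties():
    # brute-force Poisson summation agrees with the closed form
    for j, m in [(3, 100), (7, 569), (12, 1138)]:
        assert parsimony_probability(j, m) == pytest.approx(
            parsimony_probability(j, m, brute_force=True), abs=1e-9
        )
    # an independent grid evaluation of the same limit definition
    def oracle_limit(m, conf):
        j = 1
        while 2 * (j + 1) < m and parsimony_probability(j + 1, m, brute_force=True) >= conf:
            j += 1
        return j

    assert connection_limit(569, 0.95) == oracle_limit(569, 0.95)
    # monotone in sequence length
    assert connection_limit(1138, 0.95) >= connection_limit(569, 0.95)
    # as confidence -> 1, only single-step connections remain trusted
    assert connection_limit(569, 0.999999) == 1
    with pytest.raises(ValueError):
        connection_limit(569, 1.5)


def test_network_two_clusters_and_star():
    # two 1-step stars separated by a long jump > limit
    base1 = "A" * 30
    base2 = "T" * 15 + "A" * 15
    def variants(base):
        out = [base]
        for i in range(3):
            s = list(base)
            s[20 + i] = "G"
            out.append("".join(s))
        return out

    seqs = variants(base1) + variants(base2)
    aln = HaplotypeAlignment(sample_ids=[f"s{i}" for i in range(len(seqs))], sequences=seqs)
    haps = collapse_haplotypes(aln)
    net = build_network(haps, limit=7)
    assert len(net.components) == 2
    assert set(net.clade_of.values()) == {"I", "II"}
    assert (net.edges["steps"] <= 7).all()
    # star edges inside each clade are single-step
    assert (net.edges["steps"] == 1).all()
    assert (net.edges["missing_nodes"] == 0).all()


def test_network_components_match_transitive_closure_oracle():
    rng = np.random.default_rng(42)
    seqs = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(30)]
    aln = HaplotypeAlignment(sample_ids=[f"s{i}" for i in range(30)], sequences=seqs)
    haps = collapse_haplotypes(aln)
    d = pairwise_steps(list(haps["sequence"]))
    limit = 15
    net = build_network(haps, limit)
    # oracle: repeated relaxation of the <=limit adjacency
    n = len(haps)
    comp = list(range(n))
    for _ in range(n):
        for i, j in itertools.combinations(range(n), 2):
            if d[i, j] <= limit and comp[i] != comp[j]:
                new = min(comp[i], comp[j])
                old = max(comp[i], comp[j])
                comp = [new if c == old else c for c in comp]
    def canon(p):
        out = {}
        for i, c in enumerate(p):
            out.setdefault(c, set()).add(i)
        return sorted((frozenset(v) for v in out.values()), key=min)

    mine = {h: k for k, members in enumerate(net.components) for h in members}
    ids = list(haps["hap_id"])
    assert canon([mine[h] for h in ids]) == canon(comp)
    # forest edge count = nodes - components
    assert len(net.edges) == n - len(net.components)


def _expanded_fixture():
    from hybridscan import datasets
    from hybridscan.reporting import expand_mtdna_counts

    return expand_mtdna_counts(
        datasets.load_mtdna_location_counts(),
        datasets.load_hybrid_mtdna_by_location(),
        datasets.load_hybrid_mtdna_by_class(),
    )


def test_introgression_polarity_invariance():
    clade, genetic, meta, hcls = _expanded_fixture()
    tab = introgression_summary(clade, genetic, meta, hcls)
    flipped = {k: ("I" if v == "II" else "II") for k, v in clade.items()}
    tab2 = introgression_summary(flipped, genetic, meta, hcls)
    assert tab.totals["intro_fab_pct"] == pytest.approx(tab2.totals["intro_fab_pct"])
    assert tab.totals["intro_obt_pct"] == pytest.approx(tab2.totals["intro_obt_pct"])
    assert tab.hybrid_totals == tab2.hybrid_totals


def test_introgression_conservation_and_exclusions():
    clade, genetic, meta, hcls = _expanded_fixture()
    # drop a genetic label: the sample must be excluded and reported
    some = next(iter(clade))
    genetic2 = {k: v for k, v in genetic.items() if k != some}
    tab = introgression_summary(clade, genetic2, meta, hcls)
    assert some in tab.excluded
    tab_full = introgression_summary(clade, genetic, meta, hcls)
    for col in ("n", "n_fabalis", "n_obtusata", "intro_fab_n", "intro_obt_n"):
        assert tab_full.per_location[col].sum() == tab_full.totals[col]


def test_introgression_all_concordant_is_zero():
    meta = pd.DataFrame(
        {"sample_id": ["a", "b"], "location": ["X", "X"], "context": ["sympatric"] * 2}
    )
    tab = introgression_summary(
        {"a": "I", "b": "II"}, {"a": "fabalis", "b": "obtusata"}, meta
    )
    assert tab.totals["intro_fab_n"] == 0 and tab.totals["intro_obt_n"] == 0
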