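"""Hybrid-genotype simulation: frequency estimation and Mendelian structure."""

import itertools

import numpy as np
import pytest

from hybridscan.core_data import MicrosatDataset, SampleMeta
from hybridscan.hybrid_simulation import (
    ANCESTRY_PROPORTIONS,
    CLASS_LABELS,
    F_ANCESTRY,
    GENOTYPE_CLASSES,
    estimate_allele_frequencies,
    simulate_class,
    simulate_classes,
)


def _tiny_dataset(genos):
    samples = [SampleMeta(f"s{i}", "X") for i in range(len(genos))]
    return MicrosatDataset(samples=samples, loci=["L1"], genotypes=[[g] for g in genos])


def test_frequency_estimation_counts():
    ds = _tiny_dataset([("a", "a"), ("a", "a")])
    m = estimate_allele_frequencies(ds, ["g", "g"])
    assert np.allclose(m.freqs["g"][0], [1.0])

    ds = _tiny_dataset([("a", "b"), ("a", "a")])
    m = estimate_allele_frequencies(ds, ["g", "g"])
    assert np.allclose(m.freqs["g"][0], [0.75, 0.25])


def test_frequency_estimation_excludes_missing_and_errors_on_empty():
    ds = _tiny_dataset([("a", "b"), None, ("a", "a")])
    m = estimate_allele_frequencies(ds, ["g", "g", "g"])
    assert np.allclose(m.freqs["g"][0], [0.75, 0.25])
    with pytest.raises(ValueError, match="L1"):
        estimate_allele_frequencies(_tiny_dataset([None, None]), ["g", "g"])


def test_frequencies_converge_to_generator():
    rng = np.random.default_rng(0)
    loci = ["L1"]
    alleles = [["a", "b", "c"]]
    true = [np.array([0.5, 0.3, 0.2])]
    genos = []
    for _ in range(1000):
        a, b = rng.choice(3, size=2, p=true[0])
        genos.append(tuple(sorted((alleles[0][a], alleles[0][b]))))
    ds = _tiny_dataset(genos)
    m = estimate_allele_frequencies(ds, ["g"] * 1000)
    assert np.abs(m.freqs["g"][0] - true[0]).max() < 0.03


def punnett_ancestry(cls: str) -> tuple[float, float, float]:
    """Brute-force enumeration oracle for per-locus ancestry proportions.

    Gametes are single allele origins; a parent of known per-locus origin
    pair contributes each of its two origins with probability 1/2.  All
    gamete combinations of the two parents are enumerated.
    """
    parents = {
        "F": ("F", "F"),
        "O": ("O", "O"),
        "F1": ("F", "O"),
    }

    def cross(p1: tuple, p2: tuple):
        out = {}
        for g1, g2 in itertools.product(p1, p2):
            key = tuple(sorted((g1, g2)))
            out[key] = out.get(key, 0) + 0.25
        return out

    if cls in parents:
        pair = parents[cls]
        dist = {tuple(sorted(pair)): 1.0}
    elif cls == "F2":
        dist = cross(parents["F1"], parents["F1"])
    elif cls == "BCF":
        dist = cross(parents["F1"], parents["F"])
    elif cls == "BCO":
        dist = cross(parents["F1"], parents["O"])
    else:
        raise ValueError(cls)
    return (
        dist.get(("F", "F"), 0.0),
        dist.get(("F", "O"), 0.0),
        dist.get(("O", "O"), 0.0),
    )


@pytest.mark.parametrize("cls", CLASS_LABELS)
def test_ancestry_proportions_match_punnett_enumeration(cls):
    assert ANCESTRY_PROPORTIONS[cls] == pytest.approx(punnett_ancestry(cls))
    assert sum(ANCESTRY_PROPORTIONS[cls]) == pytest.approx(1.0)


def test_f1_heterozygous_at_diagnostic_loci(diagnostic_model):
    m = diagnostic_model
    ds = simulate_class(
        GENOTYPE_CLASSES["F1"], 50, m.pool("fabalis"), m.pool("obtusata"),
        m.alleles, m.loci, seed=1,
    )
    for row in ds.genotypes:
        assert all(g == ("100", "102") for g in row)


def test_f2_genotype_proportions_match_mendel(diagnostic_model):
    m = diagnostic_model
    n = 2000
    ds = simulate_class(
        GENOTYPE_CLASSES["F2"], n, m.pool("fabalis"), m.pool("obtusata"),
        m.alleles, m.loci, seed=2,
    )
    counts = {("100", "100"): 0, ("100", "102"): 0, ("102", "102"): 0}
    for row in ds.genotypes:
        for g in row:
            counts[g] += 1
    tot = n * len(m.loci)
    # binomial 4-sigma bands around (0.25, 0.5, 0.25)
    for g, p in ((("100", "100"), 0.25), (("100", "102"), 0.5), (("102", "102"), 0.25)):
        se = np.sqrt(p * (1 - p) / tot)
        assert abs(counts[g] / tot - p) < 4 * se


def test_bco_homozygous_obtusata_fraction(diagnostic_model):
    m = diagnostic_model
    n = 2000
    ds = simulate_class(
        GENOTYPE_CLASSES["BCO"], n, m.pool("fabalis"), m.pool("obtusata"),
        m.alleles, m.loci, seed=3,
    )
    oo = sum(g == ("102", "102") for row in ds.genotypes for g in row)
    tot = n * len(m.loci)
    se = np.sqrt(0.25 / tot)
    assert abs(oo / tot - 0.5) < 4 * se


def test_class_allele_frequency_expectation():
    """E[freq of F-pool allele] = p_class * fF + (1 - p_class) * fO."""
    rng = np.random.default_rng(5)
    loci = [f"L{i}" for i in range(4)]
    alleles = [["a", "b", "c"] for _ in loci]
    fF = [rng.dirichlet(np.ones(3)) for _ in loci]
    fO = [rng.dirichlet(np.ones(3)) for _ in loci]
    from hybridscan.hybrid_simulation import AlleleFrequencyModel

    model = AlleleFrequencyModel(
        loci=loci, alleles=alleles, freqs={"fabalis": fF, "obtusata": fO}
    )
    for cls, p_cls in F_ANCESTRY.items():
        ds = simulate_class(
            GENOTYPE_CLASSES[cls], 5000, fF, fO, alleles, loci, seed=7
        )
        m = estimate_allele_frequencies(ds, ["sim"] * 5000)
        for l in range(len(loci)):
            expected = p_cls * fF[l] + (1 - p_cls) * fO[l]
            obs = np.zeros(3)
            for j, a in enumerate(alleles[l]):
                if a in [x for x in m.alleles[l]]:
                    obs[j] = m.freqs["sim"][l][m.alleles[l].index(a)]
            assert np.abs(obs - expected).max() < 0.02


def test_simulate_class_input_validation(diagnostic_model):
    m = diagnostic_model
    with pytest.raises(ValueError, match="positive"):
        simulate_class(
            GENOTYPE_CLASSES["F"], 0, m.pool("fabalis"), m.pool("obtusata"),
            m.alleles, m.loci,
        )


def test_simulate_classes_truth_alignment(diagnostic_model):
    m = diagnostic_model
    ds, truth = simulate_classes({"F": 3, "BCO": 2}, m, "fabalis", "obtusata", seed=1)
    assert len(truth) == ds.n_samples == 5
    assert truth == ["F"] * 3 + ["BCO"] * 2
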