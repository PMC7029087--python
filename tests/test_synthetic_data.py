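"""Synthetic-study generator: divergence targeting, determinism, truth table."""

import numpy as np
import pytest

from hybridscan.core_data import default_slider_spec
from hybridscan.hybrid_simulation import simulate_classes
from hybridscan.popgen import weir_cockerham_fst
from hybridscan.synthetic_data import (
    SimConfig,
    mean_shapes,
    simulate_dataset,
    simulate_parental_frequencies,
)


def test_weir_cockerham_on_hand_example():
    """Two populations fixed for alternate alleles give theta ~ 1."""
    from conftest import make_reference_dataset

    ds = make_reference_dataset(10)
    theta = weir_cockerham_fst(ds, ["f"] * 10 + ["o"] * 10)
    assert theta == pytest.approx(1.0, abs=1e-9)


def test_target_fst_zero_gives_identical_pools():
    m = simulate_parental_frequencies(SimConfig(seed=1, target_fst=0.0))
    for f, o in zip(m.freqs["fabalis"], m.freqs["obtusata"]):
        assert np.array_equal(f, o)


def test_target_fst_realized_in_band():
    cfg = SimConfig(seed=1, target_fst=0.45)
    m = simulate_parental_frequencies(cfg)
    sim, truth = simulate_classes({"F": 500, "O": 500}, m, "fabalis", "obtusata", seed=2)
    fst = weir_cockerham_fst(sim, truth)
    assert 0.40 <= fst <= 0.50


def test_extreme_fst_fixes_alternative_alleles():
    cfg = SimConfig(seed=3, alleles_per_locus=2, target_fst=0.95)
    m = simulate_parental_frequencies(cfg)
    diffs = [np.abs(f - o).max() for f, o in zip(m.freqs["fabalis"], m.freqs["obtusata"])]
    assert np.mean(diffs) > 0.8
    with pytest.raises(ValueError):
        simulate_parental_frequencies(SimConfig(seed=3, alleles_per_locus=1, target_fst=0.5))


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(target_fst=1.5)
    with pytest.raises(ValueError):
        SimConfig(hybrid_fractions={"F2": 0.9, "BCO": 0.6})
    with pytest.raises(ValueError):
        SimConfig(mtdna_introgression={"fabalis": 1.5})


def test_same_seed_reproduces_everything(tmp_path):
    a = simulate_dataset(SimConfig(seed=5, n_per_group=8))
    b = simulate_dataset(SimConfig(seed=5, n_per_group=8))
    assert a.genotypes.genotypes == b.genotypes.genotypes
    assert a.haplotypes.sequences == b.haplotypes.sequences
    assert np.array_equal(a.landmarks.configurations, b.landmarks.configurations)
    assert np.array_equal(a.genitalia.values, b.genitalia.values)
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    for name in ("genotypes.csv", "haplotypes.fasta", "shells.tps", "truth.csv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_no_hybrids_no_introgression_gives_concordant_truth():
    cfg = SimConfig(
        seed=6, n_per_group=10, hybrid_fractions={},
        mtdna_introgression={"fabalis": 0.0, "obtusata": 0.0},
    )
    s = simulate_dataset(cfg)
    assert set(s.truth["true_class"]) == {"F", "O"}
    fab = s.truth[s.truth["true_species"] == "fabalis"]
    obt = s.truth[s.truth["true_species"] == "obtusata"]
    assert (fab["true_clade"] == "I").all()
    assert (obt["true_clade"] == "II").all()


def test_introgression_fraction_recovered():
    cfg = SimConfig(
        seed=7, n_per_group=125, hybrid_fractions={},
        mtdna_introgression={"fabalis": 0.2, "obtusata": 0.0},
    )
    s = simulate_dataset(cfg)
    fab = s.truth[s.truth["true_species"] == "fabalis"]
    assert len(fab) == 500
    frac = (fab["true_clade"] == "II").mean()
    assert 0.15 <= frac <= 0.25  # binomial CI around 0.2


def test_clade_distances_match_config():
    from hybridscan.mtdna import pairwise_steps

    cfg = SimConfig(seed=8, n_per_group=10)
    s = simulate_dataset(cfg)
    haps = sorted(set(s.haplotypes.sequences))
    d = pairwise_steps(haps)
    truth_by_seq = {}
    for seq, clade in zip(s.haplotypes.sequences, s.truth["true_clade"]):
        truth_by_seq[seq] = clade
    clades = [truth_by_seq[h] for h in haps]
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            if clades[i] == clades[j]:
                assert d[i, j] <= 2 * cfg.mtdna_intraclade_max_steps
            else:
                assert d[i, j] >= cfg.mtdna_interclade_steps - 2 * cfg.mtdna_intraclade_max_steps


def test_mean_shapes_hit_requested_separation():
    ms = mean_shapes(0.08)
    dist = np.sqrt(((ms["fabalis"] - ms["obtusata"]) ** 2).sum())
    assert dist == pytest.approx(0.08, rel=1e-6)
    mid = mean_shapes(0.0)
    assert np.allclose(mid["fabalis"], mid["obtusata"])


def test_truth_table_is_complete():
    s = simulate_dataset(SimConfig(seed=9, n_per_group=10))
    assert len(s.truth) == s.genotypes.n_samples == s.haplotypes.n == s.landmarks.n
    assert set(s.truth.columns) >= {
        "sample_id", "location", "context", "true_class", "true_species",
        "true_clade", "sex", "true_log_cs",
    }
    males = (s.truth["sex"] == "M").sum()
    assert len(s.genitalia.sample_ids) == males


def test_chance_level_shell_dfa_at_zero_separation():
    """With no shape separation the shell DFA is at chance.

    Allometry and location shape offsets are switched off so that shape
    separation is the only species-shape channel; species size differences
    alone must then carry no shape signal.  Binomial test at 5% on the LOOCV
    accuracy, over 12 generator seeds; the null (accuracy = 0.5) should
    survive in at least 90% of seeds.
    """
    from scipy.stats import binomtest

    from hybridscan.morphometrics import gpa_align, train_shape_dfa

    not_rejected = 0
    seeds = range(12)
    for seed in seeds:
        cfg = SimConfig(seed=100 + seed, n_per_group=12, shape_separation=0.0,
                        hybrid_fractions={}, allometry_slope=0.0,
                        location_shape_sd=0.0)
        s = simulate_dataset(cfg)
        al = gpa_align(s.landmarks)
        labels = list(s.truth["true_species"])
        model = train_shape_dfa(al, labels)
        pred = [model.classes[i] for i in model.loocv_posteriors.argmax(1)]
        k = int(np.sum(np.array(pred) == np.array(labels)))
        if binomtest(k, len(labels), 0.5).pvalue > 0.05:
            not_rejected += 1
    assert not_rejected >= 0.9 * len(seeds) - 1e-9
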