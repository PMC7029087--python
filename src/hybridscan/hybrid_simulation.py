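"""Simulation of parental and hybrid multilocus genotypes from allele
frequencies.

This is the engine behind threshold calibration: given per-locus allele
frequencies of the two parental gene pools, genotypes of the six genotype
classes are drawn locus by locus (loci independent, Hardy-Weinberg within
pools):

* ``F`` / ``O`` - two independent alleles per locus from the own pool,
* ``F1`` - one allele from each pool per locus,
* ``F2`` - one gamete from each of two independently simulated F1 parents,
* ``BCF`` - one F1 gamete plus one allele from the F pool (``BCO`` symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import MicrosatDataset, SampleMeta, _canonical_pair

#: expected fraction of loci with (both alleles from F, one from each,
#: both from O) for each genotype class; these are the exact Mendelian
#: proportions from two-generation crosses.
ANCESTRY_PROPORTIONS: dict[str, tuple[float, float, float]] = {
    "F": (1.0, 0.0, 0.0),
    "O": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BCF": (0.5, 0.5, 0.0),
    "BCO": (0.0, 0.5, 0.5),
}

CLASS_LABELS = tuple(ANCESTRY_PROPORTIONS)

#: expected F-pool allele-frequency weight of each class
F_ANCESTRY: dict[str, float] = {
    "F": 1.0,
    "O": 0.0,
    "F1": 0.5,
    "F2": 0.5,
    "BCF": 0.75,
    "BCO": 0.25,
}


@dataclass(frozen=True)
class GenotypeClass:
    label: str
    ancestry_proportions: tuple[float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.ancestry_proportions) - 1.0) > 1e-12:
            raise ValueError("ancestry proportions must sum to 1")


GENOTYPE_CLASSES: dict[str, GenotypeClass] = {
    lab: GenotypeClass(lab, props) for lab, props in ANCESTRY_PROPORTIONS.items()
}


@dataclass
class AlleleFrequencyModel:
    """Per-locus allele frequency vectors for each gene pool.

    ``freqs[pool][l]`` is a vector over ``alleles[l]`` summing to 1.
    """

    loci: list[str]
    alleles: list[list[str]]
    freqs: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def pool(self, name: str) -> list[np.ndarray]:
        return self.freqs[name]

    def padded(self, pool: str) -> np.ndarray:
        """Frequencies as an ``(L, A_max)`` matrix padded with zeros."""
        amax = max(len(a) for a in self.alleles)
        out = np.zeros((len(self.loci), amax))
        for l, f in enumerate(self.freqs[pool]):
            out[l, : len(f)] = f
        return out


def estimate_allele_frequencies(
    dataset: MicrosatDataset,
    group_labels: list[str],
    smoothing: bool = False,
) -> AlleleFrequencyModel:
    """Observed relative allele frequencies per locus per group.

    Missing genotypes are excluded from the counts.  No pseudo-counts are
    added by default; ``smoothing=True`` adds 1/(2n) per observed allele,
    exposed for robustness experiments only.
    """
    codes, labels = dataset.allele_index()
    groups = sorted(set(group_labels))
    gl = np.asarray([groups.index(g) for g in group_labels])
    freqs: dict[str, list[np.ndarray]] = {g: [] for g in groups}
    for l in range(dataset.n_loci):
        A = len(labels[l])
        g = codes[:, l, :]
        present = g[:, 0] >= 0
        for k, name in enumerate(groups):
            sel = present & (gl == k)
            if sel.sum() < 2:
                raise ValueError(
                    f"locus {dataset.loci[l]!r}: fewer than 2 genotyped samples "
                    f"in group {name!r}"
                )
            counts = np.bincount(g[sel].ravel(), minlength=A).astype(float)
            if smoothing:
                counts += 1.0 / (2 * sel.sum())
            freqs[name].append(counts / counts.sum())
    return AlleleFrequencyModel(loci=list(dataset.loci), alleles=labels, freqs=freqs)


def _draw_alleles(
    rng: np.random.Generator, freqs: list[np.ndarray], alleles: list[list[str]], n: int
) -> list[np.ndarray]:
    """One allele per locus per individual, as integer codes."""
    return [rng.choice(len(f), size=n, p=f) for f in freqs]


def simulate_class(
    genotype_class: GenotypeClass | str,
    n: int,
    freqF: list[np.ndarray],
    freqO: list[np.ndarray],
    alleles: list[list[str]],
    loci: list[str],
    seed: int | np.random.Generator = 0,
    id_prefix: str | None = None,
) -> MicrosatDataset:
    """Draw ``n`` multilocus genotypes of one genotype class.

    Mirrors HybridLab: parental genotypes are Hardy-Weinberg draws from the
    observed pool frequencies; F2 and backcross gametes are single random
    allele picks from independently simulated F1 parents.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(genotype_class, str):
        genotype_class = GENOTYPE_CLASSES[genotype_class]
    if len(freqF) != len(freqO) or len(freqF) != len(loci):
        raise ValueError("frequency models must cover identical loci")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lab = genotype_class.label
    L = len(loci)

    def f1_gamete() -> list[np.ndarray]:
        # an F1 carries one F and one O allele per locus; a gamete picks one
        a_f = _draw_alleles(rng, freqF, alleles, n)
        a_o = _draw_alleles(rng, freqO, alleles, n)
        pick_f = rng.random((L, n)) < 0.5
        return [np.where(pick_f[l], a_f[l], a_o[l]) for l in range(L)]

    if lab == "F":
        g1, g2 = _draw_alleles(rng, freqF, alleles, n), _draw_alleles(rng, freqF, alleles, n)
    elif lab == "O":
        g1, g2 = _draw_alleles(rng, freqO, alleles, n), _draw_alleles(rng, freqO, alleles, n)
    elif lab == "F1":
        g1, g2 = _draw_alleles(rng, freqF, alleles, n), _draw_alleles(rng, freqO, alleles, n)
    elif lab == "F2":
        g1, g2 = f1_gamete(), f1_gamete()
    elif lab == "BCF":
        g1, g2 = f1_gamete(), _draw_alleles(rng, freqF, alleles, n)
    elif lab == "BCO":
        g1, g2 = f1_gamete(), _draw_alleles(rng, freqO, alleles, n)
    else:
        raise ValueError(f"unknown genotype class {lab!r}")

    prefix = id_prefix if id_prefix is not None else f"sim_{lab}"
    samples = [
        SampleMeta(sample_id=f"{prefix}_{i}", location_code="SIM")
        for i in range(n)
    ]
    genotypes = [
        [
            _canonical_pair(alleles[l][g1[l][i]], alleles[l][g2[l][i]])
            for l in range(L)
        ]
        for i in range(n)
    ]
    return MicrosatDataset(samples=samples, loci=list(loci), genotypes=genotypes)


def simulate_classes(
    class_counts: dict[str, int],
    model: AlleleFrequencyModel,
    pool_f: str,
    pool_o: str,
    seed: int = 0,
) -> tuple[MicrosatDataset, list[str]]:
    """Simulate several classes at once; returns the dataset and the truth
    labels aligned with its samples."""
    rng = np.random.default_rng(seed)
    parts: list[MicrosatDataset] = []
    truth: list[str] = []
    for lab, n in class_counts.items():
        if n == 0:
            continue
        ds = simulate_class(
            GENOTYPE_CLASSES[lab],
            n,
            model.pool(pool_f),
            model.pool(pool_o),
            model.alleles,
            model.loci,
            seed=rng,
        )
        parts.append(ds)
        truth.extend([lab] * n)
    if not parts:
        raise ValueError("no classes requested")
    out = parts[0]
    for p in parts[1:]:
        out = out.concat(p)
    return out, truth
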