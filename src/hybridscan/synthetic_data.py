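"""Synthetic flat-periwinkle datasets with the statistical structure the
downstream analyses assume.

The generator emulates the study system: two parental gene pools at high
microsatellite differentiation (multi-locus F_ST targeted at 0.45 over 11
loci), admixed genotype classes (F1/F2/backcrosses), two divergent mtDNA
clades with controllable cross-species haplotype sharing, and two shell
shape/size distributions with allometry and location effects, plus male
genital measurements.  Every latent label is recorded in a truth table, so
parameter-recovery of each downstream stage can be scored exactly.

Allele-frequency divergence uses a Balding-Nichols Dirichlet
parameterization: pool frequencies are Dirichlet draws centred on a common
ancestral frequency vector with concentration (1 - F)/F.  Per-locus draws
are lightly screened so that the parametric between-pool theta stays near
the target, keeping the realized multi-locus Weir-Cockerham F_ST within a
few points of the requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import (
    GenitalMeasurements,
    HaplotypeAlignment,
    LandmarkSet,
    MicrosatDataset,
    SampleMeta,
    default_slider_spec,
    write_fasta,
    write_genotypes,
    write_tps,
)
from .hybrid_simulation import (
    AlleleFrequencyModel,
    GENOTYPE_CLASSES,
    simulate_class,
)

BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Study-condition defaults for the generator.

    Divergence, locus count, sequence length, introgression levels and the
    predominance of BCO among hybrids follow the surveyed system; shape
    separation and noise are set so that reference-shell discrimination is
    strong but imperfect, as observed.
    """

    n_loci: int = 11
    alleles_per_locus: int = 8
    target_fst: float = 0.45
    n_per_group: int = 30  # individuals per species per occupied location
    hybrid_fractions: dict = field(
        default_factory=lambda: {"F2": 0.015, "BCF": 0.01, "BCO": 0.035}
    )
    seq_length: int = 569
    mtdna_interclade_steps: int = 20
    mtdna_intraclade_max_steps: int = 3
    mtdna_haplotypes_per_clade: int = 6
    mtdna_introgression: dict = field(
        default_factory=lambda: {"fabalis": 0.185, "obtusata": 0.16}
    )
    hybrid_clade2_prob: float = 0.8
    shape_separation: float = 0.06  # Procrustes distance between mean shapes
    landmark_noise_sd: float = 0.01
    location_shape_sd: float = 0.005
    size_means: dict = field(
        default_factory=lambda: {"fabalis": 2.0, "obtusata": 2.3}
    )
    size_sds: dict = field(default_factory=lambda: {"fabalis": 0.15, "obtusata": 0.15})
    allometry_slope: float = 0.05
    n_sympatric: int = 2
    n_allopatric_per_species: int = 2
    location_size_sd: float = 0.1
    genital_class_means: dict = field(
        default_factory=lambda: {
            "fabalis": np.array([2.0, 4.5, 1.0, 3.0, 15.0, 0.8, 0.30]),
            "obtusata": np.array([0.9, 5.0, 2.0, 6.0, 40.0, 1.0, 0.35]),
        }
    )
    genital_sds: np.ndarray = field(
        default_factory=lambda: np.array([0.15, 0.3, 0.15, 0.5, 2.0, 0.08, 0.04])
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        total = sum(self.hybrid_fractions.values())
        if any(v < 0 or v > 1 for v in self.hybrid_fractions.values()) or total > 1:
            raise ValueError("hybrid fractions must lie in [0,1] and sum to <= 1")
        for sp, v in self.mtdna_introgression.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"introgression proportion for {sp} outside [0,1]")
        if self.alleles_per_locus < 1:
            raise ValueError("need at least one allele per locus")


def _parametric_theta(p1: np.ndarray, p2: np.ndarray) -> float:
    """Large-sample two-deme Weir-Cockerham theta of two frequency vectors."""
    pbar = (p1 + p2) / 2
    s2 = (p1 - p2) ** 2 / 2
    num = s2.sum()
    den = (s2 / 2 + pbar * (1 - pbar)).sum()
    return float(num / den) if den > 0 else 0.0


def simulate_parental_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> AlleleFrequencyModel:
    """Two parental allele-frequency pools at the target divergence.

    ``target_fst = 0`` returns identical pools (one ancestral draw per
    locus).  Otherwise each pool is a Balding-Nichols Dirichlet draw around
    the ancestral vector; draws whose parametric theta strays more than 0.1
    from the target are redrawn (up to a bounded number of attempts), which
    controls the heavy between-locus dispersion of the raw model.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    A = cfg.alleles_per_locus
    if A == 1 and cfg.target_fst > 0:
        raise ValueError("cannot target positive Fst with a single allele")
    loci = [f"L{l + 1}" for l in range(cfg.n_loci)]
    alleles = [[f"{100 + 2 * a}" for a in range(A)] for _ in loci]
    freqF, freqO = [], []
    F = cfg.target_fst
    for _ in loci:
        anc = rng.dirichlet(np.ones(A))
        if F == 0:
            freqF.append(anc)
            freqO.append(anc.copy())
            continue
        conc = (1 - F) / F
        best = None
        for _try in range(200):
            p1 = rng.dirichlet(np.maximum(anc * conc, 1e-6))
            p2 = rng.dirichlet(np.maximum(anc * conc, 1e-6))
            theta = _parametric_theta(p1, p2)
            err = abs(theta - F)
            if best is None or err < best[0]:
                best = (err, p1, p2)
            if err <= 0.1:
                break
        freqF.append(best[1])
        freqO.append(best[2])
    return AlleleFrequencyModel(
        loci=loci,
        alleles=alleles,
        freqs={"fabalis": freqF, "obtusata": freqO},
    )


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, sites: np.ndarray) -> np.ndarray:
    out = seq.copy()
    for s in sites:
        out[s] = _TRANSITION[out[s]]
    return out


def _clade_pools(cfg: SimConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Two star-shaped haplotype clades separated by >= interclade steps.

    Mutations are transitions placed uniformly without replacement; clade
    variants sit 1..max intra-clade steps from their clade centre, at sites
    disjoint from the inter-clade sites so distances are exact.
    """
    L = cfg.seq_length
    base = rng.choice(BASES, size=L)
    sites = rng.permutation(L)
    inter = sites[: cfg.mtdna_interclade_steps]
    spare = sites[cfg.mtdna_interclade_steps :]
    center = {"I": base, "II": _mutate(base, inter)}
    pools: dict[str, list[str]] = {}
    cursor = 0
    for clade in ("I", "II"):
        haps = ["".join(center[clade])]
        for _ in range(cfg.mtdna_haplotypes_per_clade - 1):
            k = int(rng.integers(1, cfg.mtdna_intraclade_max_steps + 1))
            var_sites = spare[cursor : cursor + k]
            cursor += k
            haps.append("".join(_mutate(center[clade], var_sites)))
        pools[clade] = haps
    return pools


# ---------------------------------------------------------------------------
# shapes
# ---------------------------------------------------------------------------

def _outline(aspect: float, aperture: float, p: int = 28) -> np.ndarray:
    """A smooth closed shell-like outline: an ellipse with an aperture bulge.

    ``aspect`` controls elongation (height/width), ``aperture`` the relative
    widening of the lower-right quarter (the aperture region).  The first
    four points sit at the cardinal angles and play the fixed-landmark role.
    """
    order = [0, 7, 14, 21] + [i for i in range(p) if i % 7 != 0]
    angles = 2 * np.pi * np.array(order, dtype=float) / p
    r = 1.0 + aperture * np.exp(-((np.mod(angles - 5.2, 2 * np.pi) - np.pi) ** 2))
    x = np.cos(angles) * r
    y = np.sin(angles) * r * aspect
    return np.column_stack([x, y])


def mean_shapes(separation: float) -> dict[str, np.ndarray]:
    """Unit-centroid-size mean shapes at the requested Procrustes distance.

    *L. fabalis* is the rounder, wider-aperture form; *L. obtusata* the more
    elongated, narrower-aperture form.
    """
    from .morphometrics.gpa import _center_scale, _optimal_rotation

    fab = _center_scale(_outline(aspect=1.05, aperture=0.25))
    obt = _center_scale(_outline(aspect=1.45, aperture=0.05))
    obt = obt @ _optimal_rotation(obt, fab)
    mid = _center_scale((fab + obt) / 2)
    diff = obt - fab
    norm = np.sqrt((diff**2).sum())
    if norm == 0:
        return {"fabalis": mid, "obtusata": mid.copy(), "hybrid": mid.copy()}
    u = diff / norm
    return {
        "fabalis": mid - 0.5 * separation * u,
        "obtusata": mid + 0.5 * separation * u,
        "hybrid": mid,
    }


def _allometry_direction(p: int = 28) -> np.ndarray:
    """Fixed unit deformation (radial aperture widening) used as the
    allometric axis."""
    base = _outline(1.2, 0.15, p)
    c = base - base.mean(axis=0)
    d = c * np.linalg.norm(c, axis=1, keepdims=True)  # outward, radius-weighted
    d -= d.mean(axis=0)
    return d / np.sqrt((d**2).sum())


# ---------------------------------------------------------------------------
# the full study generator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    genotypes: MicrosatDataset
    haplotypes: HaplotypeAlignment
    landmarks: LandmarkSet
    genitalia: GenitalMeasurements
    truth: pd.DataFrame
    frequencies: AlleleFrequencyModel

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.genotypes, out / "genotypes.csv")
        write_fasta(self.haplotypes, out / "haplotypes.fasta")
        write_tps(self.landmarks, out / "shells.tps")
        self.genitalia.frame().to_csv(out / "genitalia.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _location_plan(cfg: SimConfig) -> list[dict]:
    plan = []
    for i in range(cfg.n_sympatric):
        plan.append({"code": f"SYM{i + 1}", "context": "sympatric",
                     "species": ("fabalis", "obtusata")})
    for i in range(cfg.n_allopatric_per_species):
        plan.append({"code": f"ALF{i + 1}", "context": "allopatric",
                     "species": ("fabalis",)})
        plan.append({"code": f"ALO{i + 1}", "context": "allopatric",
                     "species": ("obtusata",)})
    return plan


def simulate_dataset(cfg: SimConfig) -> SimulatedStudy:
    """Generate a full synthetic study; fully reproducible from ``cfg.seed``.

    Pure genotypes are Hardy-Weinberg draws within their pool; hybrid
    classes are generated by the hybrid-simulation engine and placed in
    sympatric locations; each individual receives an mtDNA clade (typical of
    its species unless introgressed), a haplotype from that clade's star
    pool, a landmark configuration (species mean + allometric term x
    (logCS - mean logCS) + location offset + isotropic noise, then randomly
    rotated, translated and scaled) and, if male, genital measurements.
    """
    rng = np.random.default_rng(cfg.seed)
    model = simulate_parental_frequencies(cfg, rng)
    pools = _clade_pools(cfg, rng)
    means = mean_shapes(cfg.shape_separation)
    allo = _allometry_direction()
    plan = _location_plan(cfg)

    ecotypes = ("ME", "ZS", "FI")
    samples: list[SampleMeta] = []
    genotypes: list[list] = []
    truth_rows: list[dict] = []
    counter = 0

    for loc_i, loc in enumerate(plan):
        eco = ecotypes[loc_i % 3]
        class_counts: list[tuple[str, int]] = []
        for sp in loc["species"]:
            class_counts.append(("F" if sp == "fabalis" else "O", cfg.n_per_group))
        if loc["context"] == "sympatric":
            site_n = cfg.n_per_group * len(loc["species"])
            for cls, frac in cfg.hybrid_fractions.items():
                n_h = int(np.floor(frac * site_n + 0.5))
                if n_h:
                    class_counts.append((cls, n_h))
        for cls, n_cls in class_counts:
            ds = simulate_class(
                GENOTYPE_CLASSES[cls],
                n_cls,
                model.pool("fabalis"),
                model.pool("obtusata"),
                model.alleles,
                model.loci,
                seed=rng,
            )
            for row in ds.genotypes:
                sid = f"sim{counter:05d}"
                counter += 1
                species = {"F": "fabalis", "O": "obtusata"}.get(cls, "hybrid")
                sex = "M" if rng.random() < 0.5 else "F"
                samples.append(
                    SampleMeta(
                        sample_id=sid,
                        location_code=loc["code"],
                        geographic_context=loc["context"],
                        putative_species=species if species != "hybrid" else "unknown",
                        ecotype=eco if species == "fabalis" else "NA",
                        sex=sex,
                    )
                )
                genotypes.append(row)
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "location": loc["code"],
                        "context": loc["context"],
                        "true_class": cls,
                        "true_species": species,
                        "sex": sex,
                    }
                )

    dataset = MicrosatDataset(samples=samples, loci=model.loci, genotypes=genotypes)
    truth = pd.DataFrame(truth_rows)

    # --- mtDNA clades
    clades, seqs = [], []
    for row in truth.itertuples():
        if row.true_species == "fabalis":
            typical, atypical = "I", "II"
            p_flip = cfg.mtdna_introgression.get("fabalis", 0.0)
            clade = atypical if rng.random() < p_flip else typical
        elif row.true_species == "obtusata":
            typical, atypical = "II", "I"
            p_flip = cfg.mtdna_introgression.get("obtusata", 0.0)
            clade = atypical if rng.random() < p_flip else typical
        else:
            clade = "II" if rng.random() < cfg.hybrid_clade2_prob else "I"
        clades.append(clade)
        seqs.append(pools[clade][int(rng.integers(len(pools[clade])))])
    truth["true_clade"] = clades
    haplotypes = HaplotypeAlignment(sample_ids=list(truth["sample_id"]), sequences=seqs)

    # --- shells
    loc_size = {p["code"]: rng.normal(0, cfg.location_size_sd) for p in plan}
    loc_shape = {
        p["code"]: rng.normal(0, cfg.location_shape_sd, size=(28, 2)) for p in plan
    }
    mean_logcs = float(np.mean(list(cfg.size_means.values())))
    configs, log_cs = [], []
    for row in truth.itertuples():
        sp = row.true_species if row.true_species != "hybrid" else "hybrid"
        mu = cfg.size_means.get(sp, mean_logcs)
        sd = cfg.size_sds.get(sp, 0.15)
        lcs = rng.normal(mu, sd) + loc_size[row.location]
        shape = (
            means[sp]
            + cfg.allometry_slope * (lcs - mean_logcs) * allo
            + loc_shape[row.location]
            + rng.normal(0, cfg.landmark_noise_sd, size=(28, 2))
        )
        ang = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        cfg_xy = shape @ rot * np.exp(lcs) + rng.uniform(-5, 5, size=2)
        configs.append(cfg_xy)
        log_cs.append(lcs)
    truth["true_log_cs"] = log_cs
    landmarks = LandmarkSet(
        sample_ids=list(truth["sample_id"]),
        configurations=np.stack(configs),
        slider_spec=default_slider_spec(28),
    )

    # --- male genitalia
    male = truth[truth["sex"] == "M"]
    gm_mid = (cfg.genital_class_means["fabalis"] + cfg.genital_class_means["obtusata"]) / 2
    vals, ids = [], []
    for row in male.itertuples():
        mu = cfg.genital_class_means.get(row.true_species, gm_mid)
        v = rng.normal(mu, cfg.genital_sds)
        v = np.maximum(v, 0.05)
        v[0] = min(v[0], 0.95 * v[1])  # filament cannot exceed total length
        vals.append(v)
        ids.append(row.sample_id)
    genitalia = GenitalMeasurements(
        sample_ids=ids, values=np.asarray(vals).reshape(len(ids), 7)
    )

    return SimulatedStudy(
        genotypes=dataset,
        haplotypes=haplotypes,
        landmarks=landmarks,
        genitalia=genitalia,
        truth=truth,
        frequencies=model,
    )
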