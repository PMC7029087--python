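"""Simulation-based calibration of the pure-vs-hybrid thresholds TQ and TPp.

The calibration minimises misclassification on simulated genotypes:
genotypes of every genotype class are simulated from the parental
reference pools, pushed through the same classifier that will be
applied to field data (the admixture model for TQ, the genotype-class model
for TPp), and the threshold is chosen on a grid to minimise the total number
of pure-simulated-called-hybrid plus hybrid-simulated-called-pure.  Ties are
resolved at the midpoint of the minimising plateau.  Calibration can be run
globally or per locality grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture_inference import McmcSettings, QMatrix, run_admixture
from .class_inference import CLASS_LABELS, ClassPosteriorMatrix, run_class_inference
from .core_data import MicrosatDataset
from .hybrid_simulation import CLASS_LABELS as ALL_CLASSES
from .hybrid_simulation import estimate_allele_frequencies, simulate_classes
from .popgen import great_circle_km

PURE_CLASSES = ("F", "O")
DEFAULT_GRID = np.round(np.arange(0.50, 0.995, 0.01), 2)


@dataclass
class ThresholdResult:
    threshold: float
    curve: pd.DataFrame  # threshold, pure_to_hybrid, hybrid_to_pure, total
    scale: str  # "global" or "local"
    locality: str
    n_sim_per_class: int
    per_class_correct: dict = field(default_factory=dict)
    unassigned_fraction: float = float("nan")
    warnings: list[str] = field(default_factory=list)


def _plateau_midpoint(grid: np.ndarray, totals: np.ndarray) -> float:
    best = np.flatnonzero(np.isclose(totals, totals.min()))
    return float(grid[best[len(best) // 2]])


def _check_pools(refs: MicrosatDataset, messages: list[str]) -> None:
    sp = pd.Series([s.putative_species for s in refs.samples])
    for species in ("fabalis", "obtusata"):
        n = int((sp == species).sum())
        if n < 2:
            raise ValueError(f"parental pool {species!r} has {n} individuals (< 2)")
        if n < 10:
            messages.append(f"parental pool {species!r} has only {n} individuals")


def _simulate_panel(
    parental_refs: MicrosatDataset, n_sim: int, seed: int
) -> tuple[MicrosatDataset, list[str]]:
    labels = [s.putative_species for s in parental_refs.samples]
    model = estimate_allele_frequencies(parental_refs, labels)
    sim, truth = simulate_classes(
        {c: n_sim for c in ALL_CLASSES}, model, "fabalis", "obtusata", seed=seed
    )
    return sim, truth


def calibrate_TQ(
    parental_refs: MicrosatDataset,
    n_sim: int = 200,
    settings: McmcSettings | None = None,
    grid: np.ndarray | None = None,
    scale: str = "global",
    locality: str = "all",
    seed: int = 0,
) -> ThresholdResult:
    """Threshold on the admixture coefficient Q separating pure from hybrid.

    ``parental_refs`` must carry putative species metadata for both pools
    (normally allopatric references).  ``n_sim`` genotypes per class are
    simulated, the admixture model is run jointly on references plus
    simulations, and each grid threshold t calls a simulated individual pure
    iff max(Q) >= t.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    messages: list[str] = []
    _check_pools(parental_refs, messages)
    sim, truth = _simulate_panel(parental_refs, n_sim, seed)
    joint = parental_refs.concat(sim)
    qm = run_admixture(joint, settings, anchor_samples=[s.sample_id for s in parental_refs.samples])
    q_sim = qm.q[parental_refs.n_samples :]
    truth = np.asarray(truth)
    is_pure = np.isin(truth, PURE_CLASSES)
    qmax = q_sim.max(axis=1)

    rows = []
    for t in grid:
        called_pure = qmax >= t
        p2h = float((is_pure & ~called_pure).sum())
        h2p = float((~is_pure & called_pure).sum())
        rows.append(
            {
                "threshold": float(t),
                "pure_to_hybrid": p2h / max(is_pure.sum(), 1),
                "hybrid_to_pure": h2p / max((~is_pure).sum(), 1),
                "total": (p2h + h2p) / len(truth),
            }
        )
    curve = pd.DataFrame(rows)
    thr = _plateau_midpoint(grid, curve["total"].to_numpy())
    for m in messages:
        warnings.warn(m)
    return ThresholdResult(
        threshold=thr,
        curve=curve,
        scale=scale,
        locality=locality,
        n_sim_per_class=n_sim,
        warnings=messages,
    )


def calibrate_TPp(
    parental_refs: MicrosatDataset,
    n_sim: int = 200,
    settings: McmcSettings | None = None,
    grid: np.ndarray | None = None,
    scale: str = "global",
    locality: str = "all",
    seed: int = 0,
) -> ThresholdResult:
    """Threshold on the genotype-class posterior Pp.

    A simulated individual is *assigned* at threshold t when its maximum
    class posterior reaches t; it is then pure or hybrid according to that
    class.  An individual is correctly classified when it is assigned on the
    right side; the minimised total therefore counts wrong-side assignments
    plus unassigned individuals (otherwise raising the threshold would hide
    errors as unassignment).  Wrong-side and unassigned rates are also
    reported separately, and per-class correct-assignment rates are
    evaluated at the optimum.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    messages: list[str] = []
    _check_pools(parental_refs, messages)
    sim, truth = _simulate_panel(parental_refs, n_sim, seed)
    joint = parental_refs.concat(sim)
    pm = run_class_inference(
        joint, settings, anchor_samples=[s.sample_id for s in parental_refs.samples]
    )
    pp_sim = pm.pp[parental_refs.n_samples :]
    truth = np.asarray(truth)
    is_pure = np.isin(truth, PURE_CLASSES)
    arg = pp_sim.argmax(axis=1)
    arg_labels = np.asarray([CLASS_LABELS[i] for i in arg])
    arg_pure = np.isin(arg_labels, PURE_CLASSES)
    pp_max = pp_sim.max(axis=1)

    rows = []
    for t in grid:
        assigned = pp_max >= t
        p2h = float((is_pure & assigned & ~arg_pure).sum())
        h2p = float((~is_pure & assigned & arg_pure).sum())
        n_un = float((~assigned).sum())
        rows.append(
            {
                "threshold": float(t),
                "pure_to_hybrid": p2h / max(is_pure.sum(), 1),
                "hybrid_to_pure": h2p / max((~is_pure).sum(), 1),
                "wrong_side": (p2h + h2p) / len(truth),
                "total": (p2h + h2p + n_un) / len(truth),
                "unassigned": n_un / len(truth),
            }
        )
    curve = pd.DataFrame(rows)
    thr = _plateau_midpoint(grid, curve["total"].to_numpy())
    assigned = pp_max >= thr
    per_class = {}
    for c in ALL_CLASSES:
        sel = truth == c
        per_class[c] = float((sel & assigned & (arg_labels == c)).sum() / max(sel.sum(), 1))
    for m in messages:
        warnings.warn(m)
    return ThresholdResult(
        threshold=thr,
        curve=curve,
        scale=scale,
        locality=locality,
        n_sim_per_class=n_sim,
        per_class_correct=per_class,
        unassigned_fraction=float((~assigned).mean()),
        warnings=messages,
    )


def classify_with_TQ(qmatrix: QMatrix | np.ndarray, TQ: float) -> list[str]:
    """Deterministic pure/hybrid call from admixture coefficients.

    ``pure_fab`` iff q_fab >= TQ (inclusive), ``pure_obt`` iff q_obt >= TQ,
    else ``hybrid``.
    """
    if not 0.5 < TQ < 1:
        raise ValueError("TQ must be in (0.5, 1)")
    q = qmatrix.q if isinstance(qmatrix, QMatrix) else np.asarray(qmatrix)
    out = []
    for qf, qo in q:
        if qf >= TQ:
            out.append("pure_fab")
        elif qo >= TQ:
            out.append("pure_obt")
        else:
            out.append("hybrid")
    return out


def classify_with_TPp(
    pp_matrix: ClassPosteriorMatrix | np.ndarray, TPp: float
) -> list[str]:
    """Class call from genotype-class posteriors: the argmax class if its
    posterior reaches TPp (inclusive), else ``unassigned``."""
    if not 0.5 < TPp < 1:
        raise ValueError("TPp must be in (0.5, 1)")
    pp = pp_matrix.pp if isinstance(pp_matrix, ClassPosteriorMatrix) else np.asarray(pp_matrix)
    out = []
    for row in pp:
        j = int(row.argmax())
        out.append(CLASS_LABELS[j] if row[j] >= TPp else "unassigned")
    return out


def local_scale_plan(locations: pd.DataFrame) -> list[dict]:
    """Locality groupings for local-scale calibration.

    ``locations`` needs columns ``code``, ``context``, ``species_present``
    (``both``/``fabalis``/``obtusata``), ``lat``, ``lon``.  Sympatric sites
    form their own grouping; an allopatric site is paired with the nearest
    site (great-circle distance) carrying the species it lacks; equidistant
    candidates resolve to the lexicographically smaller code with a warning.
    Sites of undetermined context are skipped.
    """
    df = locations.copy()
    plans = []
    both_or = lambda sp: df[(df["species_present"] == "both") | (df["species_present"] == sp)]
    for sp in ("fabalis", "obtusata"):
        if both_or(sp).empty:
            raise ValueError(f"species {sp!r} missing from every site")
    for _, row in df.iterrows():
        if row["context"] == "sympatric":
            plans.append({"sites": [row["code"]], "context": "sympatric"})
        elif row["context"] == "allopatric":
            missing = "obtusata" if row["species_present"] == "fabalis" else "fabalis"
            cands = df[
                ((df["species_present"] == "both") | (df["species_present"] == missing))
                & (df["code"] != row["code"])
            ]
            if cands.empty:
                raise ValueError(f"no site carries {missing!r} to pair with {row['code']}")
            dists = cands.apply(
                lambda c: great_circle_km(row["lat"], row["lon"], c["lat"], c["lon"]),
                axis=1,
            )
            dmin = dists.min()
            ties = sorted(cands.loc[np.isclose(dists, dmin), "code"])
            if len(ties) > 1:
                warnings.warn(
                    f"{row['code']}: equidistant partners {ties}, using {ties[0]}"
                )
            plans.append(
                {"sites": sorted([row["code"], ties[0]]), "context": "allopatric_pair"}
            )
    return plans
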