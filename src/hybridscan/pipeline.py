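"""End-to-end orchestration: simulate or load data, calibrate thresholds,
classify with both genetic models, account for mtDNA introgression, run the
shell morphometrics, and write all result tables.

One master seed is expanded into per-stage seeds by fixed offsets, so stages
are individually reproducible; the resolved configuration is serialized next
to the outputs and a rerun with the same configuration yields byte-identical
tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mtdna
from .admixture_inference import McmcSettings, desk_preset, paper_preset, run_admixture
from .calibration import calibrate_TPp, calibrate_TQ, classify_with_TPp, classify_with_TQ
from .class_inference import run_class_inference
from .core_data import read_fasta, read_genotypes, read_tps
from .morphometrics import (
    align_to_reference,
    concordance_report,
    gpa_align,
    predict_shape_dfa,
    train_shape_dfa,
)
from .synthetic_data import SimConfig, simulate_dataset

log = logging.getLogger("hybridscan")

STAGE_OFFSETS = {
    "simulate": 11,
    "calibrate_tq": 23,
    "calibrate_tpp": 37,
    "admixture": 53,
    "classes": 67,
}


@dataclass
class RunConfig:
    outdir: str = "hybridscan_run"
    preset: str = "desk"  # or "paper"
    master_seed: int = 0
    genotypes: str | None = None  # csv paths; None -> simulate
    fasta: str | None = None
    tps: str | None = None
    tq: float | str = "calibrate"
    tpp: float | str = "calibrate"
    n_sim_per_class: int = 200
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed * 1000 + STAGE_OFFSETS[stage]) % (2**31 - 1)


def _settings(cfg: RunConfig, stage: str, replicates: int | None = None):
    kw = {} if replicates is None else {"replicates": replicates}
    if cfg.preset == "paper":
        return paper_preset(seed=cfg.stage_seed(stage), **kw)
    if cfg.preset == "tiny":  # smoke runs and tests only
        kw.setdefault("burnin", 500)
        kw.setdefault("sweeps", 5_000)
        kw.setdefault("replicates", 2)
        return McmcSettings(seed=cfg.stage_seed(stage), **kw)
    return desk_preset(seed=cfg.stage_seed(stage), **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report bundle (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    bundle: dict = {}
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        timings[stage] = round(time.time() - t0, 2)
        log.info("stage %s done at %.1fs", stage, timings[stage])

    try:
        # --- data
        if config.genotypes is None:
            sim = simulate_dataset(
                SimConfig(seed=config.stage_seed("simulate"), **config.sim)
            )
            sim.write(out / "synthetic")
            dataset, alignment, landmarks = sim.genotypes, sim.haplotypes, sim.landmarks
            truth = sim.truth
        else:
            dataset = read_genotypes(config.genotypes, dialect="csv")
            alignment = read_fasta(config.fasta) if config.fasta else None
            landmarks = read_tps(config.tps) if config.tps else None
            truth = None
        tick("data")

        meta = dataset.meta_frame()
        allo = meta["context"] == "allopatric"
        known = meta["species"].isin(["fabalis", "obtusata"])
        ref_idx = np.flatnonzero((allo & known).to_numpy())
        refs = dataset.subset(ref_idx)

        # --- thresholds
        if config.tq == "calibrate":
            tq_res = calibrate_TQ(
                refs,
                n_sim=config.n_sim_per_class,
                settings=_settings(config, "calibrate_tq"),
                seed=config.stage_seed("calibrate_tq"),
            )
            tq = tq_res.threshold
            bundle["tq_curve"] = tq_res.curve
        else:
            tq = float(config.tq)
        if config.tpp == "calibrate":
            tpp_res = calibrate_TPp(
                refs,
                n_sim=config.n_sim_per_class,
                settings=_settings(config, "calibrate_tpp"),
                seed=config.stage_seed("calibrate_tpp"),
            )
            tpp = tpp_res.threshold
            bundle["tpp_curve"] = tpp_res.curve
        else:
            tpp = float(config.tpp)
        with open(out / "thresholds.json", "w") as fh:
            json.dump(
                {"TQ": tq, "TPp": tpp, "preset": config.preset,
                 "master_seed": config.master_seed}, fh, indent=2,
            )
        tick("calibration")

        # --- genetic classification
        qm = run_admixture(
            dataset,
            _settings(config, "admixture"),
            anchor_samples=[dataset.samples[i].sample_id for i in ref_idx],
        )
        q_df = qm.frame()
        q_df["label"] = classify_with_TQ(qm, tq)
        q_df.to_csv(out / "q.csv", index=False)
        bundle["q"] = q_df

        pm = run_class_inference(
            dataset,
            _settings(config, "classes"),
            anchor_samples=[dataset.samples[i].sample_id for i in ref_idx],
        )
        pp_df = pm.frame()
        pp_df["label"] = classify_with_TPp(pm, tpp)
        pp_df.to_csv(out / "pp.csv", index=False)
        bundle["pp"] = pp_df
        tick("genetics")

        genetic_species = {
            r.sample_id: {"pure_fab": "fabalis", "pure_obt": "obtusata"}.get(
                r.label, "hybrid"
            )
            for r in q_df.itertuples()
        }
        hybrid_classes = {
            r.sample_id: r.label
            for r in pp_df.itertuples()
            if r.label not in ("F", "O", "unassigned")
        }

        # --- mtDNA
        if alignment is not None and alignment.n:
            haps = mtdna.collapse_haplotypes(alignment)
            limit = mtdna.connection_limit(alignment.length)
            net = mtdna.build_network(haps, limit)
            net.edges.to_csv(out / "network.tsv", sep="\t", index=False)
            table = mtdna.introgression_summary(
                net.clade_of_sample(), genetic_species, meta, hybrid_classes
            )
            table.per_location.to_csv(out / "introgression.csv", index=False)
            bundle["introgression"] = table
        tick("mtdna")

        # --- shell morphometrics
        if landmarks is not None and landmarks.n:
            sid_to_row = {s: i for i, s in enumerate(landmarks.sample_ids)}
            ref_ids = [
                meta.loc[i, "sample_id"]
                for i in ref_idx
                if meta.loc[i, "sample_id"] in sid_to_row
            ]
            ref_rows = [sid_to_row[s] for s in ref_ids]
            sub = landmarks.configurations[ref_rows]
            from .core_data import LandmarkSet

            ref_lms = LandmarkSet(
                sample_ids=ref_ids, configurations=sub, slider_spec=landmarks.slider_spec
            )
            aligned_ref = gpa_align(ref_lms)
            sp_map = dict(zip(meta["sample_id"], meta["species"]))
            model = train_shape_dfa(aligned_ref, [sp_map[s] for s in ref_ids])
            other_ids = [s for s in landmarks.sample_ids if s not in set(ref_ids)]
            shape_labels = dict(
                zip(model.training_ids, model.loocv_frame()["label"])
            )
            if other_ids:
                other = LandmarkSet(
                    sample_ids=other_ids,
                    configurations=landmarks.configurations[
                        [sid_to_row[s] for s in other_ids]
                    ],
                    slider_spec=landmarks.slider_spec,
                )
                pred = predict_shape_dfa(model, align_to_reference(other, aligned_ref))
                pred.to_csv(out / "shape_dfa.csv", index=False)
                shape_labels.update(dict(zip(pred["sample_id"], pred["label"])))
            conc = concordance_report(
                {"genetic": genetic_species, "shape": shape_labels}, meta
            )
            bundle["concordance"] = conc
        tick("morphometrics")

        if truth is not None:
            merged = truth.merge(q_df[["sample_id", "label"]], on="sample_id")
            merged = merged.merge(
                pp_df[["sample_id", "label"]], on="sample_id",
                suffixes=("_tq", "_tpp"),
            )
            merged.to_csv(out / "truth_vs_calls.csv", index=False)
            bundle["truth_vs_calls"] = merged

        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh)
        with open(out / "timings.json", "w") as fh:
            json.dump(timings, fh, indent=2)
        bundle["timings"] = timings
        bundle["thresholds"] = {"TQ": tq, "TPp": tpp}
        return bundle
    except Exception as exc:  # partial outputs stay on disk for inspection
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
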