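"""Bundled summary tables from the north-western Iberian flat-periwinkle
hybridization survey.

These are the published per-location counts (sampling metadata, mtDNA clade
and introgression counts for the genetically pure individuals, clade
membership of the genetic hybrids, and hybrid detections per location); the
raw genotypes and sequences are not redistributed here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("hybridscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_locations() -> pd.DataFrame:
    """Sampling locations: code, name, geographic context, species present,
    *L. fabalis* ecotype, decimal coordinates."""
    return _load("locations.csv")


def load_mtdna_location_counts() -> pd.DataFrame:
    """Per-location mtDNA counts of genetically pure individuals: sequenced
    totals per genetic species, clade counts and atypical-clade counts."""
    return _load("mtdna_location_counts.csv")


def load_hybrid_mtdna_by_location() -> pd.DataFrame:
    """mtDNA clade membership of admixture-detected hybrids per location."""
    return _load("hybrid_mtdna_by_location.csv")


def load_hybrid_mtdna_by_class() -> pd.DataFrame:
    """mtDNA clade membership of class-assigned hybrids per genotype class."""
    return _load("hybrid_mtdna_by_class.csv")


def load_hybrid_counts() -> pd.DataFrame:
    """Hybrid detections per location: admixture-based (global and local
    scale) and genotype-class-based counts among confidently assigned
    individuals."""
    return _load("hybrid_counts_by_location.csv")
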