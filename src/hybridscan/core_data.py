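"""Domain types and file I/O for genotypes, sequences, landmarks and metadata.

The package works with four kinds of raw material:

* multilocus codominant microsatellite genotypes (diploid, unordered allele
  pairs, 11 loci by default) with per-sample metadata,
* aligned mitochondrial haplotype sequences (equal-length, 569 bp by default),
* 2-D shell landmark configurations (4 fixed landmarks + 24 semilandmarks),
* linear genital measurements of males (7 features).

Formats: a documented CSV dialect and GenePop (3-digit alleles) for genotypes,
FASTA for sequences, and TPS (``LM=`` / ``IMAGE=`` / ``ID=`` / ``SCALE=``
records) for landmarks.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = None  # internal missing-genotype token

GEOG_CONTEXTS = ("sympatric", "allopatric", "undetermined")
SPECIES = ("fabalis", "obtusata", "unknown")
ECOTYPES = ("ME", "ZS", "FI", "NA")
SEXES = ("M", "F", "unknown")

DNA_ALPHABET = set("ACGTN-")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SampleMeta:
    """Per-individual metadata.

    ``ecotype`` only applies to *L. fabalis*; it is coerced to ``"NA"`` for
    *L. obtusata* individuals (ecotype terminology is not used for that
    species).
    """

    sample_id: str
    location_code: str
    geographic_context: str = "undetermined"
    putative_species: str = "unknown"
    ecotype: str = "NA"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if not self.location_code:
            raise ValueError(f"sample {self.sample_id!r}: empty location_code")
        if self.geographic_context not in GEOG_CONTEXTS:
            raise ValueError(f"bad geographic_context {self.geographic_context!r}")
        if self.putative_species not in SPECIES:
            raise ValueError(f"bad putative_species {self.putative_species!r}")
        if self.ecotype not in ECOTYPES:
            raise ValueError(f"bad ecotype {self.ecotype!r}")
        if self.sex not in SEXES:
            raise ValueError(f"bad sex {self.sex!r}")
        if self.putative_species == "obtusata":
            self.ecotype = "NA"


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered allele pair stored lexicographically (tie-free equality)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class MicrosatDataset:
    """Diploid multilocus genotypes plus sample metadata.

    ``genotypes[i][l]`` is either a lexicographically ordered pair of allele
    labels (opaque strings) or ``None`` for missing.
    """

    samples: list[SampleMeta]
    loci: list[str]
    genotypes: list[list[tuple[str, str] | None]]

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.samples):
            raise ValueError("genotype rows != number of samples")
        L = len(self.loci)
        for meta, row in zip(self.samples, self.genotypes):
            if len(row) != L:
                raise ParseError(
                    f"sample {meta.sample_id!r}: {len(row)} genotypes for {L} loci"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "location": [s.location_code for s in self.samples],
                "context": [s.geographic_context for s in self.samples],
                "species": [s.putative_species for s in self.samples],
                "ecotype": [s.ecotype for s in self.samples],
                "sex": [s.sex for s in self.samples],
            }
        )

    def allele_index(self) -> tuple[np.ndarray, list[list[str]]]:
        """Integer-coded genotypes for numerical work.

        Returns ``(codes, labels)`` where ``codes`` is an ``(n, L, 2)`` int
        array (``-1`` marks a missing genotype) and ``labels[l]`` lists the
        observed allele labels of locus ``l`` in sorted order.
        """
        n, L = self.n_samples, self.n_loci
        labels: list[list[str]] = []
        maps: list[dict[str, int]] = []
        for l in range(L):
            seen = sorted(
                {a for row in self.genotypes if row[l] is not None for a in row[l]}
            )
            labels.append(seen)
            maps.append({a: i for i, a in enumerate(seen)})
        codes = np.full((n, L, 2), -1, dtype=np.int32)
        for i, row in enumerate(self.genotypes):
            for l, g in enumerate(row):
                if g is not None:
                    codes[i, l, 0] = maps[l][g[0]]
                    codes[i, l, 1] = maps[l][g[1]]
        return codes, labels

    def subset(self, indices: Sequence[int]) -> "MicrosatDataset":
        return MicrosatDataset(
            samples=[self.samples[i] for i in indices],
            loci=list(self.loci),
            genotypes=[self.genotypes[i] for i in indices],
        )

    def concat(self, other: "MicrosatDataset") -> "MicrosatDataset":
        if self.loci != other.loci:
            raise ValueError("cannot concatenate datasets with different loci")
        return MicrosatDataset(
            samples=self.samples + other.samples,
            loci=list(self.loci),
            genotypes=self.genotypes + other.genotypes,
        )


@dataclass
class HaplotypeAlignment:
    """Equal-length nucleotide sequences keyed by sample id."""

    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ParseError(f"ragged alignment: lengths {sorted(lengths)}")
        for sid, seq in zip(self.sample_ids, self.sequences):
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ParseError(f"sequence {sid!r}: invalid symbols {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class LandmarkSet:
    """Raw 2-D landmark configurations.

    ``configurations`` is ``(n, p, 2)``; by default p = 28 with landmarks
    0..3 fixed and 4..27 sliding semilandmarks.  ``slider_spec`` lists
    ``(before, slider, after)`` index triplets defining the chord along which
    each semilandmark may slide.
    """

    sample_ids: list[str]
    configurations: np.ndarray
    slider_spec: list[tuple[int, int, int]] = field(default_factory=list)
    fixed_ids: tuple[int, ...] = (0, 1, 2, 3)
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.configurations = np.asarray(self.configurations, dtype=float)
        if self.configurations.ndim != 3 or self.configurations.shape[2] != 2:
            raise ValueError("configurations must be (n, p, 2)")

    @property
    def n(self) -> int:
        return self.configurations.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.configurations.shape[1]


def default_slider_spec(n_landmarks: int = 28, n_fixed: int = 4) -> list[tuple[int, int, int]]:
    """Sliding triplets for the standard shell scheme.

    The 24 semilandmarks form a closed outline chain following the fixed
    points; each slides along the chord between its outline neighbours.
    """
    semis = list(range(n_fixed, n_landmarks))
    spec = []
    for k, s in enumerate(semis):
        before = semis[k - 1] if k > 0 else n_fixed - 1
        after = semis[k + 1] if k < len(semis) - 1 else 0
        spec.append((before, s, after))
    return spec


@dataclass
class GenitalMeasurements:
    """Per-male vector of 7 linear/count penis features (mm / counts).

    Feature order: filament_length, total_penis_length, gland_row_length,
    n_rows, n_glands, base_width, tip_width.  The first five are the features
    reported to drive species discrimination; the last two complete the
    7-feature panel.
    """

    FEATURES = (
        "filament_length",
        "total_penis_length",
        "gland_row_length",
        "n_rows",
        "n_glands",
        "base_width",
        "tip_width",
    )

    sample_ids: list[str]
    values: np.ndarray  # (n, 7)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.FEATURES):
            raise ValueError("values must be (n, 7)")
        ok = np.isnan(self.values) | (self.values >= 0)
        if not ok.all():
            raise ValueError("genital measurements must be non-negative")
        fil = self.values[:, 0]
        tot = self.values[:, 1]
        with np.errstate(invalid="ignore"):
            if np.any(fil > tot):
                raise ValueError("filament_length exceeds total_penis_length")

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.FEATURES))
        df.insert(0, "sample_id", self.sample_ids)
        return df


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

_CSV_META_COLS = ["sample_id", "location", "context", "species", "ecotype", "sex"]


def _meta_from_row(row: pd.Series) -> SampleMeta:
    def get(col: str, default: str) -> str:
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "":
            return default
        return str(v)

    return SampleMeta(
        sample_id=str(row["sample_id"]),
        location_code=get("location", "UNK"),
        geographic_context=get("context", "undetermined"),
        putative_species=get("species", "unknown"),
        ecotype=get("ecotype", "NA"),
        sex=get("sex", "unknown"),
    )


def _read_genotypes_csv(path: Path) -> MicrosatDataset:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    locus_cols = [c for c in df.columns if c not in _CSV_META_COLS]
    loci: list[str] = []
    for c in locus_cols:
        if c.endswith("a"):
            name = c[:-1]
            if name + "b" not in locus_cols:
                raise ParseError(f"{path}: locus column {c!r} has no matching '{name}b'")
            loci.append(name)
        elif not c.endswith("b"):
            raise ParseError(f"{path}: unrecognised column {c!r}")
    samples, genotypes = [], []
    for _, row in df.iterrows():
        meta = _meta_from_row(row)
        geno_row: list[tuple[str, str] | None] = []
        for locus in loci:
            a, b = row[locus + "a"].strip(), row[locus + "b"].strip()
            missing_a = a in ("", "NA", "000")
            missing_b = b in ("", "NA", "000")
            if missing_a != missing_b:
                raise ParseError(
                    f"{path}: sample {meta.sample_id!r} locus {locus!r}: "
                    "half-missing genotype"
                )
            geno_row.append(MISSING if missing_a else _canonical_pair(a, b))
        samples.append(meta)
        genotypes.append(geno_row)
    return MicrosatDataset(samples=samples, loci=loci, genotypes=genotypes)


def _read_genotypes_genepop(path: Path) -> MicrosatDataset:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty GenePop file")
    body = lines[1:]  # first line is the title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names: one per line, or comma-separated on one line
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    if i == len(body):
        raise ParseError(f"{path}: no 'Pop' line found")
    samples, genotypes = [], []
    pop_idx = 0
    while i < len(body):
        if body[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = body[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ParseError(f"{path}: malformed individual line {line!r}")
        sid, rest = line.split(",", 1)
        sid = sid.strip()
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}: sample {sid!r}: {len(tokens)} genotypes for "
                f"{len(loci)} loci"
            )
        row: list[tuple[str, str] | None] = []
        for locus, tok in zip(loci, tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(
                    f"{path}: sample {sid!r} locus {locus!r}: bad allele code {tok!r}"
                )
            h = len(tok) // 2
            a, b = tok[:h], tok[h:]
            if a == "0" * h or b == "0" * h:
                if a != b:
                    raise ParseError(
                        f"{path}: sample {sid!r} locus {locus!r}: half-missing {tok!r}"
                    )
                row.append(MISSING)
            else:
                row.append(_canonical_pair(a, b))
        samples.append(SampleMeta(sample_id=sid, location_code=f"pop{pop_idx}"))
        genotypes.append(row)
    return MicrosatDataset(samples=samples, loci=loci, genotypes=genotypes)


def read_genotypes(path: str | Path, dialect: str = "csv") -> MicrosatDataset:
    """Read a genotype table in the ``csv`` or ``genepop`` dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_genotypes_csv(path)
    if dialect == "genepop":
        return _read_genotypes_genepop(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(dataset: MicrosatDataset, path: str | Path) -> None:
    """Write the CSV dialect; round-trips bit-identically through
    :func:`read_genotypes`."""
    cols: dict[str, list[str]] = {c: [] for c in _CSV_META_COLS}
    for s in dataset.samples:
        cols["sample_id"].append(s.sample_id)
        cols["location"].append(s.location_code)
        cols["context"].append(s.geographic_context)
        cols["species"].append(s.putative_species)
        cols["ecotype"].append(s.ecotype)
        cols["sex"].append(s.sex)
    df = pd.DataFrame(cols)
    for l, locus in enumerate(dataset.loci):
        a_col, b_col = [], []
        for row in dataset.genotypes:
            g = row[l]
            a_col.append("NA" if g is None else g[0])
            b_col.append("NA" if g is None else g[1])
        df[locus + "a"] = a_col
        df[locus + "b"] = b_col
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sequence I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> HaplotypeAlignment:
    """Read an equal-length FASTA alignment; lowercase bases are uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return HaplotypeAlignment(sample_ids=ids, sequences=seqs)


def write_fasta(alignment: HaplotypeAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.sample_ids, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TPS landmark I/O
# ---------------------------------------------------------------------------

def read_tps(path: str | Path, n_landmarks: int = 28) -> LandmarkSet:
    """Parse TPS blocks (``LM=`` / coordinate lines / ``IMAGE=`` / ``ID=`` /
    ``SCALE=``).

    Coordinates are multiplied by the block's SCALE when present.  Blocks
    without an ID or IMAGE get a synthetic id ``cfg_<k>``.
    """
    text = Path(path).read_text()
    blocks = re.split(r"(?=^LM=)", text, flags=re.MULTILINE)
    ids, configs = [], []
    k = 0
    for block in blocks:
        block = block.strip()
        if not block:
            continue
        lines = [ln.strip() for ln in block.splitlines() if ln.strip()]
        m = re.match(r"LM=(\d+)", lines[0])
        if not m:
            raise ParseError(f"{path}: block does not start with LM=")
        lm = int(m.group(1))
        if lm != n_landmarks:
            raise ParseError(f"{path}: block has LM={lm}, expected {n_landmarks}")
        coords = []
        sid = None
        scale = 1.0
        for ln in lines[1:]:
            upper = ln.upper()
            if upper.startswith("SCALE="):
                scale = float(ln.split("=", 1)[1])
            elif upper.startswith("ID="):
                sid = ln.split("=", 1)[1].strip()
            elif upper.startswith("IMAGE="):
                if sid is None:
                    sid = ln.split("=", 1)[1].strip()
            else:
                parts = ln.split()
                if len(parts) != 2:
                    raise ParseError(f"{path}: bad coordinate line {ln!r}")
                coords.append((float(parts[0]), float(parts[1])))
        if len(coords) != lm:
            raise ParseError(
                f"{path}: block declares LM={lm} but has {len(coords)} points"
            )
        if sid is None:
            sid = f"cfg_{k}"
        ids.append(sid)
        configs.append(np.asarray(coords) * scale)
        k += 1
    arr = np.stack(configs) if configs else np.empty((0, n_landmarks, 2))
    return LandmarkSet(
        sample_ids=ids,
        configurations=arr,
        slider_spec=default_slider_spec(n_landmarks),
    )


def write_tps(lms: LandmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, cfg in zip(lms.sample_ids, lms.configurations):
            fh.write(f"LM={lms.n_landmarks}\n")
            for x, y in cfg:
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={sid}\n")
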