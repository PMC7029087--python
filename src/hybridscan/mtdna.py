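"""Mitochondrial haplotype networks and introgression accounting.

Haplotypes are collapsed by exact sequence identity, connected in a
minimum-spanning forest restricted to pairs within the statistical-parsimony
connection limit, and partitioned into clades (connected components).  The
introgression summary then counts, per location and overall, individuals of
each genetically assigned species carrying the mtDNA clade typical of the
other species, plus the clade composition of genetic hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import HaplotypeAlignment


# ---------------------------------------------------------------------------
# haplotype collapsing and distances
# ---------------------------------------------------------------------------

def collapse_haplotypes(alignment: HaplotypeAlignment) -> pd.DataFrame:
    """Unique sequences with multiplicity and member sample ids.

    Collapsing is exact-string; ambiguous sites (N) act as wildcards only in
    distance computation, never at collapse time.  Haplotypes are ordered by
    descending multiplicity then sequence, and named ``H1``, ``H2``, ...
    """
    members: dict[str, list[str]] = {}
    for sid, seq in zip(alignment.sample_ids, alignment.sequences):
        members.setdefault(seq, []).append(sid)
    rows = sorted(members.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return pd.DataFrame(
        {
            "hap_id": [f"H{i + 1}" for i in range(len(rows))],
            "sequence": [seq for seq, _ in rows],
            "multiplicity": [len(m) for _, m in rows],
            "sample_ids": [list(m) for _, m in rows],
        }
    )


def pairwise_steps(sequences: list[str]) -> np.ndarray:
    """Pairwise mutational differences; sites with N or a gap in either
    sequence are excluded pairwise (the 569 bp frame is kept global)."""
    if not sequences:
        return np.zeros((0, 0), dtype=int)
    arr = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(
        len(sequences), -1
    )
    known = (arr != b"N") & (arr != b"-")
    n = len(sequences)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = known[i] & known
        diff = (arr[i] != arr) & both
        d[i] = diff.sum(axis=1)
    return d


# ---------------------------------------------------------------------------
# statistical-parsimony connection limit
# ---------------------------------------------------------------------------

def parsimony_probability(j: int, seq_length: int, brute_force: bool = False) -> float:
    """Probability that j observed differences reflect exactly j mutations.

    Per-site mutation counts are modelled as independent Poisson(theta) with
    two effective states, so a site shows a difference iff its count is odd.
    theta is the maximum-likelihood value given the observed fraction of
    differing sites, P(odd) = (1 - exp(-2 theta)) / 2 = j / m.  The
    parsimonious connection requires every differing site to have mutated
    exactly once and every identical site not at all:

        P = P(count=1 | odd)^j * P(count=0 | even)^(m-j)
          = (theta / sinh(theta))^j * (1 / cosh(theta))^(m-j).

    ``brute_force=True`` evaluates the same conditional probabilities by
    direct summation of the Poisson series instead of the closed forms.
    """
    m = seq_length
    if j <= 0:
        return 1.0
    if 2 * j >= m:
        return 0.0
    theta = -0.5 * np.log1p(-2.0 * j / m)
    if brute_force:
        ks = np.arange(0, 200)
        pmf = np.exp(-theta + ks * np.log(theta) - _log_factorial(ks))
        p_odd = pmf[1::2].sum()
        p_even = pmf[0::2].sum()
        p1_given_odd = pmf[1] / p_odd
        p0_given_even = pmf[0] / p_even
    else:
        p1_given_odd = theta / np.sinh(theta)
        p0_given_even = 1.0 / np.cosh(theta)
    return float(p1_given_odd**j * p0_given_even ** (m - j))


def _log_factorial(k: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(k + 1.0)


def connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest number of steps j whose parsimonious-connection probability is
    at least ``confidence``; never below 1 (single-step connections are
    always trusted)."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    j = 1
    while 2 * (j + 1) < seq_length and parsimony_probability(j + 1, seq_length) >= confidence:
        j += 1
    return j


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    haplotypes: pd.DataFrame  # collapse_haplotypes output
    distances: np.ndarray
    connection_limit: int
    edges: pd.DataFrame  # hap_i, hap_j, steps, missing_nodes
    clade_of: dict[str, str]  # hap_id -> clade label ("I", "II", "U3", ...)
    components: list[list[str]] = field(default_factory=list)

    def clade_of_sample(self) -> dict[str, str]:
        out = {}
        for _, row in self.haplotypes.iterrows():
            lab = self.clade_of[row["hap_id"]]
            for sid in row["sample_ids"]:
                out[sid] = lab
        return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[max(ri, rj)] = min(ri, rj)
        return True


def build_network(
    haplotypes: pd.DataFrame,
    limit: int,
    distances: np.ndarray | None = None,
) -> HaplotypeNetwork:
    """Minimum-spanning forest over pairs within the connection limit.

    Kruskal order with ties broken by (distance, lexicographic hap-id pair);
    each edge of d steps implies d - 1 unobserved intermediate haplotypes.
    Connected components are the clades: the two largest are labelled I and
    II, any remainder is flagged unconnected (``U3``, ``U4``, ...).
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    hap_ids = list(haplotypes["hap_id"])
    n = len(hap_ids)
    if distances is None:
        distances = pairwise_steps(list(haplotypes["sequence"]))
    cand = [
        (int(distances[i, j]), hap_ids[i], hap_ids[j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if distances[i, j] <= limit
    ]
    cand.sort(key=lambda e: (e[0], e[1], e[2]))
    uf = _UnionFind(n)
    rows = []
    for d, hi, hj, i, j in cand:
        if uf.union(i, j):
            rows.append({"hap_i": hi, "hap_j": hj, "steps": d, "missing_nodes": d - 1})
    comp_members: dict[int, list[int]] = {}
    for i in range(n):
        comp_members.setdefault(uf.find(i), []).append(i)
    mult = list(haplotypes["multiplicity"])
    comps = sorted(
        comp_members.values(),
        key=lambda idxs: (-sum(mult[i] for i in idxs), hap_ids[idxs[0]]),
    )
    clade_of: dict[str, str] = {}
    comp_ids = []
    for rank, idxs in enumerate(comps):
        label = ["I", "II"][rank] if rank < 2 else f"U{rank + 1}"
        comp_ids.append([hap_ids[i] for i in idxs])
        for i in idxs:
            clade_of[hap_ids[i]] = label
    return HaplotypeNetwork(
        haplotypes=haplotypes,
        distances=distances,
        connection_limit=limit,
        edges=pd.DataFrame(rows, columns=["hap_i", "hap_j", "steps", "missing_nodes"]),
        clade_of=clade_of,
        components=comp_ids,
    )


# ---------------------------------------------------------------------------
# introgression accounting
# ---------------------------------------------------------------------------

PURE_LABELS = {"fabalis", "obtusata"}


@dataclass
class IntrogressionTable:
    """Per-location and total introgression accounting.

    ``per_location`` columns: location, context, n, n_fabalis, n_obtusata,
    clade_fab (count of fabalis-typical haplotypes), clade_obt, intro_fab_n /
    intro_fab_pct (atypical haplotypes among genetic *L. fabalis*) and the
    obtusata counterparts.  Percentages are count ratios x 100.
    """

    per_location: pd.DataFrame
    totals: dict
    hybrid_by_location: pd.DataFrame
    hybrid_by_class: pd.DataFrame
    hybrid_totals: dict
    site_fractions: dict
    typical_clade: dict  # species -> network clade label
    excluded: list[str] = field(default_factory=list)


def _pct(n: int, d: int) -> float:
    return 100.0 * n / d if d else float("nan")


def introgression_summary(
    clade_labels: dict[str, str],
    genetic_labels: dict[str, str],
    metadata: pd.DataFrame,
    hybrid_classes: dict[str, str] | None = None,
) -> IntrogressionTable:
    """Account for mtDNA introgression between the two genetic species.

    ``clade_labels`` maps sequenced samples to network clades;
    ``genetic_labels`` maps samples to ``fabalis`` / ``obtusata`` (from the
    global admixture classification) or ``hybrid``; ``metadata`` provides
    ``sample_id``, ``location`` and ``context`` columns; ``hybrid_classes``
    optionally maps hybrid samples to their genotype class.  Clade polarity
    (which clade is typical of which species) is set by the majority clade
    within each pure species, so relabelling clades leaves percentages
    unchanged.  Sequenced samples without a genetic label are excluded and
    reported.
    """
    meta = metadata.set_index("sample_id")
    rows = []
    excluded = []
    for sid, clade in clade_labels.items():
        lab = genetic_labels.get(sid)
        if lab is None:
            excluded.append(sid)
            continue
        loc = meta.loc[sid, "location"] if sid in meta.index else "UNK"
        ctx = meta.loc[sid, "context"] if sid in meta.index else "undetermined"
        rows.append((sid, clade, lab, loc, ctx))
    df = pd.DataFrame(rows, columns=["sample_id", "clade", "genetic", "location", "context"])

    pure = df[df["genetic"].isin(PURE_LABELS)]
    if pure.empty:
        raise ValueError("no pure-species samples to polarise clades")
    fab_counts = pure[pure["genetic"] == "fabalis"]["clade"].value_counts()
    typical_fab = fab_counts.idxmax() if len(fab_counts) else None
    obt_counts = pure[pure["genetic"] == "obtusata"]["clade"].value_counts()
    # the obtusata-typical clade is the majority clade among obtusata unless
    # that collides with the fabalis-typical one; then take its complement
    typical_obt = None
    for c in obt_counts.index:
        if c != typical_fab:
            typical_obt = c
            break
    if typical_obt is None:
        others = sorted(set(df["clade"]) - {typical_fab})
        typical_obt = others[0] if others else typical_fab
    typical = {"fabalis": typical_fab, "obtusata": typical_obt}

    loc_rows = []
    for loc, sub in pure.groupby("location", sort=True):
        fab = sub[sub["genetic"] == "fabalis"]
        obt = sub[sub["genetic"] == "obtusata"]
        intro_fab = int((fab["clade"] != typical_fab).sum())
        intro_obt = int((obt["clade"] == typical_fab).sum())
        loc_rows.append(
            {
                "location": loc,
                "context": sub["context"].iloc[0],
                "n": len(sub),
                "n_fabalis": len(fab),
                "n_obtusata": len(obt),
                "clade_fab_typical": int((sub["clade"] == typical_fab).sum()),
                "clade_obt_typical": int((sub["clade"] != typical_fab).sum()),
                "intro_fab_n": intro_fab,
                "intro_fab_pct": _pct(intro_fab, len(fab)),
                "intro_obt_n": intro_obt,
                "intro_obt_pct": _pct(intro_obt, len(obt)),
                "atypical_present": bool(intro_fab or intro_obt),
            }
        )
    per_location = pd.DataFrame(loc_rows)

    n_fab = int(per_location["n_fabalis"].sum())
    n_obt = int(per_location["n_obtusata"].sum())
    tot_fab = int(per_location["intro_fab_n"].sum())
    tot_obt = int(per_location["intro_obt_n"].sum())
    totals = {
        "n": int(per_location["n"].sum()),
        "n_fabalis": n_fab,
        "n_obtusata": n_obt,
        "clade_fab_typical": int(per_location["clade_fab_typical"].sum()),
        "clade_obt_typical": int(per_location["clade_obt_typical"].sum()),
        "intro_fab_n": tot_fab,
        "intro_fab_pct": _pct(tot_fab, n_fab),
        "intro_obt_n": tot_obt,
        "intro_obt_pct": _pct(tot_obt, n_obt),
    }

    frac = {}
    for ctx in ("sympatric", "allopatric"):
        sub = per_location[per_location["context"] == ctx]
        frac[ctx] = {
            "n_sites": len(sub),
            "n_with_atypical": int(sub["atypical_present"].sum()),
            "pct": _pct(int(sub["atypical_present"].sum()), len(sub)),
        }

    # hybrids by location = admixture-detected hybrids; hybrids by class =
    # samples with a genotype-class assignment (the two methods need not
    # agree on which individuals are hybrid)
    hyb = df[df["genetic"] == "hybrid"]
    hyb_loc_rows = []
    for loc, sub in hyb.groupby("location", sort=True):
        cII = int((sub["clade"] != typical_fab).sum())
        hyb_loc_rows.append(
            {
                "location": loc,
                "n": len(sub),
                "clade_fab_typical": len(sub) - cII,
                "clade_obt_typical": cII,
            }
        )
    hybrid_by_location = pd.DataFrame(
        hyb_loc_rows, columns=["location", "n", "clade_fab_typical", "clade_obt_typical"]
    )
    hyb_cls_rows = []
    if hybrid_classes:
        hc = df[df["sample_id"].isin(hybrid_classes)]
        hc = hc.assign(cls=[hybrid_classes[s] for s in hc["sample_id"]])
        for cls, sub in hc.groupby("cls", sort=True):
            cII = int((sub["clade"] != typical_fab).sum())
            hyb_cls_rows.append(
                {
                    "hybrid_class": cls,
                    "n": len(sub),
                    "clade_fab_typical": len(sub) - cII,
                    "clade_obt_typical": cII,
                }
            )
    hybrid_by_class = pd.DataFrame(
        hyb_cls_rows,
        columns=["hybrid_class", "n", "clade_fab_typical", "clade_obt_typical"],
    )
    n_h = int(len(hyb))
    cII_h = int((hyb["clade"] != typical_fab).sum())
    n_hc = int(hybrid_by_class["n"].sum()) if len(hybrid_by_class) else 0
    cII_hc = (
        int(hybrid_by_class["clade_obt_typical"].sum()) if len(hybrid_by_class) else 0
    )
    hybrid_totals = {
        "n": n_h,
        "clade_obt_typical": cII_h,
        "pct_clade_obt": _pct(cII_h, n_h),
        "n_by_class": n_hc,
        "clade_obt_typical_by_class": cII_hc,
        "pct_clade_obt_by_class": _pct(cII_hc, n_hc),
    }

    return IntrogressionTable(
        per_location=per_location,
        totals=totals,
        hybrid_by_location=hybrid_by_location,
        hybrid_by_class=hybrid_by_class,
        hybrid_totals=hybrid_totals,
        site_fractions=frac,
        typical_clade=typical,
        excluded=excluded,
    )
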