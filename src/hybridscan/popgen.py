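"""Small population-genetics utilities shared across modules."""

from __future__ import annotations

import numpy as np

from .core_data import MicrosatDataset


def weir_cockerham_fst(dataset: MicrosatDataset, group_labels: list[str]) -> float:
    """Multi-allelic Weir & Cockerham (1984) theta over all loci.

    ``group_labels`` assigns each sample to a population.  Missing genotypes
    are excluded per locus.  Returns the ratio-of-sums estimator
    ``sum(a) / sum(a + b + c)`` pooled over loci and alleles.
    """
    codes, labels = dataset.allele_index()
    groups = sorted(set(group_labels))
    gl = np.asarray([groups.index(g) for g in group_labels])
    r = len(groups)
    if r < 2:
        raise ValueError("need at least two populations")
    num = 0.0
    den = 0.0
    for l in range(dataset.n_loci):
        A = len(labels[l])
        g = codes[:, l, :]  # (n, 2)
        present = g[:, 0] >= 0
        if A < 2:
            continue
        n_i = np.array([np.sum(present & (gl == k)) for k in range(r)], dtype=float)
        if np.any(n_i < 1) or r < 2:
            continue
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for a in range(A):
            cnt = (g == a).sum(axis=1)  # 0,1,2 copies per individual
            p_i = np.array(
                [cnt[present & (gl == k)].sum() / (2 * n_i[k]) for k in range(r)]
            )
            het = (cnt == 1).astype(float)
            h_i = np.array(
                [het[present & (gl == k)].mean() for k in range(r)]
            )
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a_comp = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
            )
            b_comp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c_comp = hbar / 2
            num += a_comp
            den += a_comp + b_comp + c_comp
    if den == 0:
        return 0.0
    return num / den


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in kilometres."""
    rlat1, rlon1, rlat2, rlon2 = np.radians([lat1, lon1, lat2, lon2])
    dlat = rlat2 - rlat1
    dlon = rlon2 - rlon1
    h = np.sin(dlat / 2) ** 2 + np.cos(rlat1) * np.cos(rlat2) * np.sin(dlon / 2) ** 2
    return float(2 * 6371.0 * np.arcsin(np.sqrt(h)))
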