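"""Six-class genotype-frequency-class inference (pure, F1, F2, backcrosses).

Each individual belongs to one of six genotype classes {F, O, F1, F2, BCF,
BCO}.  A class fixes, per locus, the probability that both alleles descend
from the *L. fabalis* pool, one from each pool, or both from the *L.
obtusata* pool (the Mendelian ancestry proportions).  Given the latent
per-locus ancestry state, genotype probabilities follow Hardy-Weinberg
products of the pool allele frequencies; for the one-from-each state the
heterozygote (a, b) has probability ``pF(a) pO(b) + pF(b) pO(a)`` and the
homozygote (a, a) has ``pF(a) pO(a)``.

Priors: class mixing proportions pi ~ Dirichlet(1); pool allele frequencies
carry a "Jeffreys-like" Dirichlet(1/A_l) prior, where A_l is the number of
alleles observed at locus l, which keeps rare or unobserved alleles
plausible in either pool.  No prior population information is used.  Gibbs
sampling alternates class assignments, per-locus ancestry states, allele
origins within heterozygous mixed states, pool frequencies and pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture_inference import McmcSettings, desk_preset
from .core_data import MicrosatDataset
from .hybrid_simulation import ANCESTRY_PROPORTIONS, CLASS_LABELS

W_CLASS = np.array([ANCESTRY_PROPORTIONS[c] for c in CLASS_LABELS])  # (6, 3)

#: permutation of class columns induced by swapping the two pools
_POOL_SWAP = [CLASS_LABELS.index(c) for c in ("O", "F", "F1", "F2", "BCO", "BCF")]


def class_proportion_table() -> pd.DataFrame:
    """Exact ancestry proportions (both-F, one-each, both-O) per class."""
    return pd.DataFrame(
        W_CLASS, index=list(CLASS_LABELS), columns=["p_FF", "p_FO", "p_OO"]
    )


@dataclass
class ClassPosteriorMatrix:
    """Per-sample posterior over the six genotype classes."""

    sample_ids: list[str]
    pp: np.ndarray  # (n, 6) in CLASS_LABELS order
    replicate_pp: np.ndarray  # (R, n, 6) aligned
    loglik_traces: list[np.ndarray]
    flags: list[str] = field(default_factory=list)
    max_replicate_tv: float = 0.0

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pp, columns=list(CLASS_LABELS))
        df.insert(0, "sample_id", self.sample_ids)
        df["assigned_class"] = [CLASS_LABELS[i] for i in self.pp.argmax(axis=1)]
        df["assigned_pp"] = self.pp.max(axis=1)
        return df


def _class_gibbs(
    codes: np.ndarray,
    n_alleles: list[int],
    settings: McmcSettings,
    rng: np.random.Generator,
) -> dict:
    n, L, _ = codes.shape
    amax = max(max(n_alleles), 1)
    miss = codes[:, :, 0] < 0
    nonmiss = ~miss
    a_code = np.where(codes[:, :, 0] < 0, 0, codes[:, :, 0])
    b_code = np.where(codes[:, :, 1] < 0, 0, codes[:, :, 1])
    het = (a_code != b_code) & nonmiss
    lidx = np.arange(L)
    ia = lidx[None, :] * amax + a_code  # (n, L) flat indices
    ib = lidx[None, :] * amax + b_code

    valid = np.zeros((L, amax), dtype=bool)
    jeffreys = np.zeros((L, amax))
    for l, A in enumerate(n_alleles):
        valid[l, :A] = True
        jeffreys[l, :A] = 1.0 / max(A, 1)

    # init pools from pooled counts with jitter (symmetry breaking)
    pooled = (
        np.bincount(ia[nonmiss], minlength=L * amax)
        + np.bincount(ib[nonmiss], minlength=L * amax)
    ).astype(float).reshape(L, amax)
    theta = np.empty((2, L, amax))
    for k in range(2):
        j = (pooled + 1.0) * np.exp(0.2 * rng.standard_normal((L, amax)))
        j[~valid] = 0.0
        theta[k] = j / j.sum(axis=1, keepdims=True)
    pi = np.full(6, 1.0 / 6)

    pp_sum = np.zeros((n, 6))
    n_acc = 0
    loglik = []
    tiny = 1e-300

    for sweep in range(settings.sweeps):
        tf = theta[0].reshape(-1)
        to = theta[1].reshape(-1)
        fa, fb = tf[ia], tf[ib]
        oa, ob = to[ia], to[ib]
        mult = np.where(het, 2.0, 1.0)
        Lff = mult * fa * fb
        Loo = mult * oa * ob
        Lfo = np.where(het, fa * ob + fb * oa, fa * oa)
        Ls = np.stack([Lff, Lfo, Loo], axis=-1)  # (n, L, 3)

        M = Ls @ W_CLASS.T  # (n, L, 6)
        M[miss] = 1.0
        np.clip(M, tiny, None, out=M)
        logp = np.log(M).sum(axis=1) + np.log(pi + tiny)  # (n, 6)
        logp -= logp.max(axis=1, keepdims=True)
        prob = np.exp(logp)
        prob /= prob.sum(axis=1, keepdims=True)

        cdf = np.cumsum(prob, axis=1)
        c = (cdf < rng.random((n, 1))).sum(axis=1)

        # ancestry states given class
        w = W_CLASS[c][:, None, :]  # (n, 1, 3)
        ps = w * Ls
        pss = ps.sum(axis=2, keepdims=True)
        pss[pss == 0] = 1.0
        ps /= pss
        cdf3 = np.cumsum(ps, axis=2)
        s = (cdf3 < rng.random((n, L, 1))).sum(axis=2)  # 0=FF, 1=FO, 2=OO

        # allele-origin orientation inside heterozygous FO states
        num = fa * ob
        den = num + fb * oa
        den[den == 0] = 1.0
        a_from_f = rng.random((n, L)) < (num / den)

        # pool allele counts: FF -> both copies to F; OO -> both to O;
        # FO het -> one copy each by sampled orientation; FO hom -> one each
        ff = (s == 0) & nonmiss
        oo = (s == 2) & nonmiss
        fo = (s == 1) & nonmiss
        fo_het = fo & het
        fo_hom = fo & ~het
        f_af = fo_het & a_from_f
        f_bf = fo_het & ~a_from_f
        cf = np.bincount(
            np.concatenate([ia[ff], ib[ff], ia[f_af], ib[f_bf], ia[fo_hom]]),
            minlength=L * amax,
        ).reshape(L, amax)
        co = np.bincount(
            np.concatenate([ia[oo], ib[oo], ib[f_af], ia[f_bf], ib[fo_hom]]),
            minlength=L * amax,
        ).reshape(L, amax)

        for k, ck in enumerate((cf, co)):
            g = rng.standard_gamma(jeffreys + ck)
            g[~valid] = 0.0
            ssum = g.sum(axis=1, keepdims=True)
            ssum[ssum == 0] = 1.0
            theta[k] = g / ssum

        pi_counts = np.bincount(c, minlength=6).astype(float)
        pi = rng.dirichlet(1.0 + pi_counts)

        if sweep >= settings.burnin and (sweep - settings.burnin) % settings.thin == 0:
            pp_sum += prob  # Rao-Blackwellised class posterior
            n_acc += 1
            ml = np.log(M).sum(axis=1) + np.log(pi + tiny)
            mx = ml.max(axis=1)
            loglik.append(float((mx + np.log(np.exp(ml - mx[:, None]).sum(1))).sum()))

    return {"pp": pp_sum / n_acc, "loglik": np.asarray(loglik)}


def _align_class_replicates(
    reps: list[np.ndarray],
    anchor_idx: np.ndarray | None,
    anchor_species: list[str] | None,
) -> tuple[np.ndarray, float]:
    """Resolve the pool-swap mode across replicates and anchor F to fabalis."""
    ref = reps[0]
    aligned = [ref]
    for pp in reps[1:]:
        swapped = pp[:, _POOL_SWAP]
        aligned.append(pp if np.abs(pp - ref).sum() <= np.abs(swapped - ref).sum() else swapped)
    arr = np.stack(aligned)
    if anchor_idx is not None and anchor_species is not None and len(anchor_idx):
        mean_pp = arr.mean(axis=0)
        f_col = CLASS_LABELS.index("F")
        o_col = CLASS_LABELS.index("O")
        sp = np.asarray(anchor_species)
        score = 0.0
        fab = anchor_idx[sp == "fabalis"]
        obt = anchor_idx[sp == "obtusata"]
        if len(fab):
            score += float(np.mean(mean_pp[fab, f_col] - mean_pp[fab, o_col]))
        if len(obt):
            score += float(np.mean(mean_pp[obt, o_col] - mean_pp[obt, f_col]))
        if score < 0:
            arr = arr[:, :, _POOL_SWAP]
    max_tv = 0.0
    R = arr.shape[0]
    for a in range(R):
        for b in range(a + 1, R):
            tv = 0.5 * np.abs(arr[a] - arr[b]).sum(axis=1).max()
            max_tv = max(max_tv, float(tv))
    return arr, max_tv


def run_class_inference(
    dataset: MicrosatDataset,
    settings: McmcSettings | None = None,
    anchor_samples: list[str] | None = None,
) -> ClassPosteriorMatrix:
    """Posterior probabilities of the six genotype classes per sample.

    No prior population information enters the likelihood; anchoring only
    names the two latent pools after the fact so that class F consistently
    means parental *L. fabalis*.  Samples with no genotyped locus are
    flagged and given a uniform posterior.
    """
    if settings is None:
        settings = desk_preset(replicates=2)
    if dataset.n_loci < 1:
        raise ValueError("need at least one locus")
    codes, labels = dataset.allele_index()
    n_alleles = [max(len(a), 1) for a in labels]
    all_missing = (codes[:, :, 0] < 0).all(axis=1)
    flags = [s.sample_id for s, m in zip(dataset.samples, all_missing) if m]
    if flags:
        warnings.warn(f"samples with no genotypes get a uniform class posterior: {flags}")

    ss = np.random.SeedSequence(settings.seed)
    child = ss.spawn(settings.replicates)
    reps, logliks = [], []
    for r in range(settings.replicates):
        res = _class_gibbs(codes, n_alleles, settings, np.random.default_rng(child[r]))
        reps.append(res["pp"])
        logliks.append(res["loglik"])

    ids = dataset.sample_ids()
    if anchor_samples is None:
        anchor_mask = np.array(
            [s.putative_species in ("fabalis", "obtusata") for s in dataset.samples]
        )
    else:
        wanted = set(anchor_samples)
        anchor_mask = np.array([sid in wanted for sid in ids])
    anchor_idx = np.flatnonzero(anchor_mask)
    anchor_species = [dataset.samples[i].putative_species for i in anchor_idx]

    arr, max_tv = _align_class_replicates(
        reps, anchor_idx if len(anchor_idx) else None, anchor_species or None
    )
    if max_tv > 0.1:
        warnings.warn(
            f"replicate class posteriors disagree (max row-wise TV {max_tv:.3f} > 0.1)"
        )
    pp = arr.mean(axis=0)
    pp[all_missing] = 1.0 / 6
    pp /= pp.sum(axis=1, keepdims=True)
    return ClassPosteriorMatrix(
        sample_ids=ids,
        pp=pp,
        replicate_pp=arr,
        loglik_traces=logliks,
        flags=flags,
        max_replicate_tv=max_tv,
    )
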