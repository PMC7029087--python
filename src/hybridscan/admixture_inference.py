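"""Bayesian two-population admixture inference for codominant genotypes.

The model is the classic admixture mixture: each allele copy of individual
``i`` at locus ``l`` originates from cluster ``k`` with probability
``q_ik``; cluster allele frequencies have independent Dirichlet(lambda)
priors per locus; individual admixture vectors ``q_i ~ Dirichlet(alpha)``
with a single alpha shared across individuals, itself updated by a
random-walk Metropolis step under a Uniform(0, alpha_prior_max) prior.

Inference is by Gibbs sampling over allele-origin indicators, cluster
frequencies and admixture vectors, vectorized over individuals and loci.
Missing genotypes contribute no likelihood term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import MicrosatDataset

K = 2  # the analysis is specific to the two-species problem


@dataclass
class McmcSettings:
    """Sampler settings.

    The ``paper`` preset mirrors the emulated analysis (1e6 sweeps after 1e5
    burn-in, 5 replicates); the ``desk`` preset is sized for interactive and
    test use and converges comfortably on well-differentiated data.
    """

    burnin: int = 100_000
    sweeps: int = 1_000_000
    replicates: int = 5
    k: int = K
    alpha_prior_max: float = 10.0
    lambda_: float = 1.0
    thin: int = 10
    alpha_init: float = 1.0
    alpha_sd: float = 0.025
    update_alpha: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin >= self.sweeps:
            raise ValueError("burnin must be smaller than sweeps")
        if self.k != K:
            raise ValueError("only k=2 is supported")


def paper_preset(seed: int = 0, **kw) -> McmcSettings:
    return McmcSettings(burnin=100_000, sweeps=1_000_000, replicates=5, seed=seed, **kw)


def desk_preset(seed: int = 0, **kw) -> McmcSettings:
    kw.setdefault("burnin", 3_000)
    kw.setdefault("sweeps", 30_000)
    kw.setdefault("replicates", 2)
    return McmcSettings(seed=seed, **kw)


@dataclass
class QMatrix:
    """Per-individual membership coefficients (q_fab, q_obt)."""

    sample_ids: list[str]
    q: np.ndarray  # (n, 2), columns (fab, obt), rows sum to 1
    replicate_q: np.ndarray  # (R, n, 2), aligned
    mean_alpha: float
    loglik_traces: list[np.ndarray]
    flags: list[str] = field(default_factory=list)  # all-missing sample ids
    min_replicate_correlation: float = 1.0

    @property
    def q_fab(self) -> np.ndarray:
        return self.q[:, 0]

    @property
    def q_obt(self) -> np.ndarray:
        return self.q[:, 1]

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "q_fab": self.q[:, 0],
                "q_obt": self.q[:, 1],
                "flag": [
                    "all_missing" if s in set(self.flags) else ""
                    for s in self.sample_ids
                ],
            }
        )


def _gibbs_replicate(
    codes: np.ndarray,
    n_alleles: list[int],
    settings: McmcSettings,
    rng: np.random.Generator,
    store_trace: bool = False,
) -> dict:
    """One MCMC replicate; returns posterior-mean q and diagnostics."""
    n, L, _ = codes.shape
    amax = max(max(n_alleles), 1)
    miss = codes[:, :, 0] < 0  # (n, L); both copies missing together
    nonmiss = ~miss
    geno = np.where(codes < 0, 0, codes)
    lidx = np.arange(L)
    flat_idx = lidx[None, :, None] * amax + geno  # (n, L, 2)
    copies_mask = np.repeat(nonmiss[:, :, None], 2, axis=2)
    obs_flat = flat_idx[copies_mask]
    tot_copies = copies_mask.sum(axis=(1, 2)).astype(float)  # per individual

    valid = np.zeros((L, amax), dtype=bool)
    for l, A in enumerate(n_alleles):
        valid[l, :A] = True
    lam = settings.lambda_

    # init: cluster frequencies from pooled counts with multiplicative jitter
    pooled = np.bincount(obs_flat, minlength=L * amax).astype(float).reshape(L, amax)
    P = np.empty((2, L, amax))
    for k in range(2):
        jit = pooled + lam
        jit = jit * np.exp(0.1 * rng.standard_normal(jit.shape))
        jit[~valid] = 0.0
        s = jit.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        P[k] = jit / s
    Pflat = P.reshape(2, L * amax)
    Q = np.full((n, 2), 0.5)
    alpha = settings.alpha_init

    q_sum = np.zeros((n, 2))
    alpha_sum = 0.0
    n_acc = 0
    loglik = []
    trace = [] if store_trace else None

    tiny = 1e-300
    for sweep in range(settings.sweeps):
        # --- allele-origin indicators
        pg0 = Pflat[0][flat_idx]
        pg1 = Pflat[1][flat_idx]
        w0 = Q[:, 0, None, None] * pg0
        w1 = Q[:, 1, None, None] * pg1
        tot = w0 + w1 + tiny
        z0 = rng.random((n, L, 2)) < (w0 / tot)

        # --- cluster allele frequencies
        sel0 = z0 & copies_mask
        sel1 = (~z0) & copies_mask
        c0 = np.bincount(flat_idx[sel0], minlength=L * amax).reshape(L, amax)
        c1 = np.bincount(flat_idx[sel1], minlength=L * amax).reshape(L, amax)
        for k, ck in enumerate((c0, c1)):
            g = rng.standard_gamma(lam + ck)
            g[~valid] = 0.0
            s = g.sum(axis=1, keepdims=True)
            s[s == 0] = 1.0
            P[k] = g / s
        Pflat = P.reshape(2, L * amax)

        # --- admixture vectors
        n0 = sel0.sum(axis=(1, 2)).astype(float)
        g0 = rng.standard_gamma(alpha + n0)
        g1 = rng.standard_gamma(alpha + (tot_copies - n0))
        s = g0 + g1
        s[s == 0] = 1.0
        Q[:, 0] = g0 / s
        Q[:, 1] = g1 / s
        np.clip(Q, 1e-12, 1 - 1e-12, out=Q)

        # --- alpha (random-walk Metropolis, Uniform(0, max) prior)
        if settings.update_alpha:
            from scipy.special import gammaln

            prop = alpha + settings.alpha_sd * rng.standard_normal()
            if 0.0 < prop < settings.alpha_prior_max:
                slq = np.log(Q).sum()
                cur = n * (gammaln(2 * alpha) - 2 * gammaln(alpha)) + (alpha - 1) * slq
                new = n * (gammaln(2 * prop) - 2 * gammaln(prop)) + (prop - 1) * slq
                if np.log(rng.random() + tiny) < new - cur:
                    alpha = prop

        if sweep >= settings.burnin and (sweep - settings.burnin) % settings.thin == 0:
            q_sum += Q
            alpha_sum += alpha
            n_acc += 1
            loglik.append(float(np.log(tot[copies_mask]).sum()))
            if store_trace:
                trace.append(Q.copy())

    out = {
        "q": q_sum / n_acc,
        "alpha": alpha_sum / n_acc,
        "loglik": np.asarray(loglik),
    }
    if store_trace:
        out["trace"] = np.asarray(trace)
    return out


def align_replicates(
    replicate_qs: list[np.ndarray],
    anchor_idx: np.ndarray | None = None,
    anchor_species: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Resolve label switching across replicates and anchor column identity.

    Each replicate's columns are permuted (k=2: kept or swapped) to maximise
    agreement with replicate 1; the species identity of the columns is then
    anchored so that column 0 tracks the cluster dominating the *L. fabalis*
    anchor samples.  Returns ``(mean_q, aligned (R,n,2), min pairwise r)``.
    """
    if not replicate_qs:
        raise ValueError("need at least one replicate")
    ref = replicate_qs[0]
    aligned = [ref]
    for q in replicate_qs[1:]:
        same = np.abs(q - ref).sum()
        swapped = np.abs(q[:, ::-1] - ref).sum()
        aligned.append(q if same <= swapped else q[:, ::-1])
    arr = np.stack(aligned)

    if anchor_idx is not None and anchor_species is not None and len(anchor_idx):
        mean_q0 = arr.mean(axis=0)[:, 0]
        sp = np.asarray(anchor_species)
        fab = mean_q0[anchor_idx[sp == "fabalis"]]
        obt = mean_q0[anchor_idx[sp == "obtusata"]]
        if len(fab) and len(obt):
            if np.isclose(fab.mean(), obt.mean()):
                raise ValueError(
                    "anchor ambiguous: fabalis and obtusata anchors have equal "
                    "mean membership; supply explicit anchors"
                )
            if fab.mean() < obt.mean():
                arr = arr[:, :, ::-1]
        elif len(fab):
            if np.isclose(fab.mean(), 0.5):
                raise ValueError("anchor ambiguous (mean membership 0.5)")
            if fab.mean() < 0.5:
                arr = arr[:, :, ::-1]
        elif len(obt):
            if np.isclose(obt.mean(), 0.5):
                raise ValueError("anchor ambiguous (mean membership 0.5)")
            if obt.mean() > 0.5:
                arr = arr[:, :, ::-1]

    min_r = 1.0
    R = arr.shape[0]
    for a in range(R):
        for b in range(a + 1, R):
            x, y = arr[a, :, 0], arr[b, :, 0]
            if np.std(x) == 0 or np.std(y) == 0:
                r = 1.0 if np.allclose(x, y) else 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            min_r = min(min_r, r)
    return arr.mean(axis=0), arr, min_r


def run_admixture(
    dataset: MicrosatDataset,
    settings: McmcSettings | None = None,
    anchor_samples: list[str] | None = None,
    store_trace: bool = False,
) -> QMatrix:
    """Posterior mean admixture proportions for every sample.

    ``anchor_samples`` name individuals of known putative species (normally
    allopatric references) used to give the two clusters reproducible species
    identities; when omitted, every sample with a non-unknown putative
    species anchors.  Samples with no genotyped locus are flagged and given
    Q = (0.5, 0.5).
    """
    if settings is None:
        settings = desk_preset()
    if dataset.n_samples < 2 or dataset.n_loci < 1:
        raise ValueError("need at least 2 samples and 1 locus")
    codes, labels = dataset.allele_index()
    n_alleles = [max(len(a), 1) for a in labels]
    all_missing = (codes[:, :, 0] < 0).all(axis=1)
    flags = [s.sample_id for s, m in zip(dataset.samples, all_missing) if m]
    if flags:
        warnings.warn(f"samples with no genotypes assigned Q=(0.5,0.5): {flags}")

    ss = np.random.SeedSequence(settings.seed)
    child = ss.spawn(settings.replicates)
    reps = []
    traces = []
    logliks = []
    alphas = []
    for r in range(settings.replicates):
        res = _gibbs_replicate(
            codes, n_alleles, settings, np.random.default_rng(child[r]), store_trace
        )
        reps.append(res["q"])
        logliks.append(res["loglik"])
        alphas.append(res["alpha"])
        if store_trace:
            traces.append(res["trace"])

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
    mean_q, aligned, min_r = align_replicates(
        reps, anchor_idx if len(anchor_idx) else None, anchor_species or None
    )
    mean_q[all_missing] = 0.5

    qm = QMatrix(
        sample_ids=ids,
        q=mean_q,
        replicate_q=aligned,
        mean_alpha=float(np.mean(alphas)),
        loglik_traces=logliks,
        flags=flags,
        min_replicate_correlation=min_r,
    )
    if store_trace:
        qm.traces = traces  # thinned per-replicate Q chains, small runs only
    return qm
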