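"""Shape-space PCA and permutational GLMs with residual randomization.

The GLM decomposes variation in a (possibly multivariate) response with
sequential (Type-I) sums of squares measured as squared Procrustes
distances.  For each term, residuals of the model reduced by that term are
permuted (RRPP) to build the null distribution of its SS; the p-value is
``(1 + #{SS* >= SS}) / (nperm + 1)`` and the standardized effect size Z is
computed on the log-transformed SS distribution (observed value included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def shape_pca(shapes_or_vars) -> dict:
    """Principal components of shape variation.

    Accepts an :class:`~hybridscan.morphometrics.gpa.AlignedShapes` or a raw
    (n, d) variable matrix.  Returns scores, eigenvalues, explained-variance
    proportions and the loading matrix; total variance is preserved
    (sum of eigenvalues equals the total variance of the input).
    """
    Y = getattr(shapes_or_vars, "shape_variables", shapes_or_vars)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 observations")
    Yc = Y - Y.mean(axis=0)
    u, s, vt = np.linalg.svd(Yc, full_matrices=False)
    eig = s**2 / (n - 1)
    scores = u * s
    total = eig.sum()
    return {
        "scores": scores,
        "eigenvalues": eig,
        "explained": eig / total if total > 0 else eig,
        "components": vt,
        "mean": Y.mean(axis=0),
    }


@dataclass
class GlmResult:
    formula: str
    table: pd.DataFrame  # term, df, SS, Z, p (+ Residuals/Total rows)
    nperm: int

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def _factor_design(col: pd.Series) -> np.ndarray:
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        return np.empty((len(col), 0))
    arr = np.zeros((len(col), len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        arr[:, j] = (col.astype(str) == lev).astype(float)
    return arr


def _term_columns(term: str, data: pd.DataFrame) -> np.ndarray:
    """Design columns for one term: numeric covariate, factor, or ``A:B``
    interaction of factors."""
    if ":" in term:
        parts = term.split(":")
        mats = [_term_columns(p, data) for p in parts]
        out = mats[0]
        for m in mats[1:]:
            out = np.einsum("ni,nj->nij", out, m).reshape(len(data), -1)
        return out
    col = data[term]
    if pd.api.types.is_numeric_dtype(col):
        v = col.to_numpy(dtype=float)
        return (v - v.mean())[:, None]
    counts = col.astype(str).value_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"factor {term!r} has levels with < 2 observations: {bad}")
    return _factor_design(col)


def _projection(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projection onto the column space of X, plus its rank."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def procrustes_glm(
    response: np.ndarray,
    data: pd.DataFrame,
    terms: list[str],
    nperm: int = 1000,
    seed: int = 0,
) -> GlmResult:
    """Sequential permutational GLM (RRPP) for shape or size responses.

    ``response`` is (n,) or (n, d); ``terms`` are entered in order (a nested
    location factor is simply entered after its parent factor; an
    interaction ``A:B`` after its main effects).  Deterministic for a fixed
    seed.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if len(data) != n:
        raise ValueError("response and data have different lengths")
    rng = np.random.default_rng(seed)

    designs = [np.ones((n, 1))]
    for t in terms:
        cols = _term_columns(t, data)
        designs.append(np.hstack([designs[-1], cols]))
    projs, ranks = zip(*(_projection(X) for X in designs))

    Yc = Y - Y.mean(axis=0)
    total_ss = float((Yc**2).sum())
    rows = []
    for k, term in enumerate(terms):
        H_red, H_full = projs[k], projs[k + 1]
        df = ranks[k + 1] - ranks[k]
        D = H_full - H_red
        R = Y - H_red @ Y  # reduced-model residuals
        G = R @ R.T
        ss_obs = float(np.sum(D * G))
        ss_perm = np.empty(nperm + 1)
        ss_perm[0] = ss_obs
        for b in range(nperm):
            pi = rng.permutation(n)
            ss_perm[b + 1] = float(np.sum(D * G[np.ix_(pi, pi)]))
        p = float(np.mean(ss_perm >= ss_obs - 1e-12))
        logss = np.log(ss_perm + 1e-300)
        sd = logss.std(ddof=1)
        z = float((logss[0] - logss.mean()) / sd) if sd > 0 else 0.0
        rows.append({"term": term, "df": df, "SS": ss_obs, "Z": z, "p": p})

    rss = float(((Y - projs[-1] @ Y) ** 2).sum())
    rows.append({"term": "Residuals", "df": n - ranks[-1], "SS": rss,
                 "Z": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": total_ss,
                 "Z": np.nan, "p": np.nan})
    return GlmResult(
        formula=" + ".join(terms), table=pd.DataFrame(rows), nperm=nperm
    )
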