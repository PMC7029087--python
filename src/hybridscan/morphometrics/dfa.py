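"""Linear discriminant classification of shells, with LOOCV posteriors.

The discriminant function is trained on allopatric reference individuals of
both species.  Shape variables are first reduced to principal-component
scores retaining 99% of the variance (the raw Procrustes residuals are
rank-deficient, which would make the pooled covariance singular).  Priors
equal the training class frequencies.  Assignment posteriors of training
individuals are estimated by leave-one-out cross-validation; individuals
from other sites are scored with the full model.  An individual is assigned
to a species only when its posterior probability reaches the cutoff
(default 0.90, inclusive); otherwise it has "intermediate" shell shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .gpa import AlignedShapes

INTERMEDIATE = "intermediate"


@dataclass
class DfaModel:
    classes: list[str]
    priors: np.ndarray
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (k, d)
    lda: LinearDiscriminantAnalysis
    cutoff: float
    training_ids: list[str]
    loocv_posteriors: np.ndarray  # (n_train, 2)

    def loocv_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.loocv_posteriors, columns=self.classes)
        df.insert(0, "sample_id", self.training_ids)
        df["label"] = _labels_from_pp(self.loocv_posteriors, self.classes, self.cutoff)
        return df


def _labels_from_pp(pp: np.ndarray, classes: list[str], cutoff: float) -> list[str]:
    out = []
    for row in pp:
        j = int(row.argmax())
        out.append(classes[j] if row[j] >= cutoff else INTERMEDIATE)
    return out


def _as_matrix(shapes) -> np.ndarray:
    if isinstance(shapes, AlignedShapes):
        return shapes.shape_variables
    return np.asarray(shapes, dtype=float)


def train_shape_dfa(
    shapes,
    labels: list[str],
    sample_ids: list[str] | None = None,
    cutoff: float = 0.90,
    var_explained: float = 0.99,
) -> DfaModel:
    """Two-class linear discriminant on reduced shape variables.

    ``shapes`` is an AlignedShapes (allopatric references) or an (n, d)
    variable matrix; ``labels`` gives the species of each row.  If the
    retained dimensionality exceeds what the smallest class can support,
    it is reduced further with a warning.
    """
    X = _as_matrix(shapes)
    y = np.asarray(labels)
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError("shape DFA requires exactly two classes")
    if sample_ids is None:
        sample_ids = (
            shapes.sample_ids
            if isinstance(shapes, AlignedShapes)
            else [f"s{i}" for i in range(len(X))]
        )

    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2
    positive = eig > 1e-12 * eig.max()
    cum = np.cumsum(eig[positive]) / eig[positive].sum()
    k = int(np.searchsorted(cum, var_explained) + 1)
    min_class = min(int((y == c).sum()) for c in classes)
    if k > min_class - 1:
        warnings.warn(
            f"reducing DFA space from {k} to {min_class - 1} dimensions "
            "(smallest class too small for the retained components)"
        )
        k = max(1, min_class - 1)
    comps = vt[:k]
    Z = Xc @ comps.T

    priors = np.array([(y == c).mean() for c in classes])
    lda = LinearDiscriminantAnalysis(priors=priors)
    lda.fit(Z, y)

    n = len(y)
    loo = np.zeros((n, 2))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        m = LinearDiscriminantAnalysis(priors=priors)
        m.fit(Z[mask], y[mask])
        loo[i] = m.predict_proba(Z[i : i + 1])[0]
    return DfaModel(
        classes=classes,
        priors=priors,
        pca_mean=mean,
        pca_components=comps,
        lda=lda,
        cutoff=cutoff,
        training_ids=list(sample_ids),
        loocv_posteriors=loo,
    )


def predict_shape_dfa(model: DfaModel, shapes, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Posterior probabilities and labels for shapes aligned in the model's
    reference frame (see :func:`~hybridscan.morphometrics.gpa.align_to_reference`)."""
    X = _as_matrix(shapes)
    if sample_ids is None:
        sample_ids = (
            shapes.sample_ids
            if isinstance(shapes, AlignedShapes)
            else [f"s{i}" for i in range(len(X))]
        )
    Z = (X - model.pca_mean) @ model.pca_components.T
    pp = model.lda.predict_proba(Z)
    df = pd.DataFrame(pp, columns=model.classes)
    df.insert(0, "sample_id", list(sample_ids))
    df["label"] = _labels_from_pp(pp, model.classes, model.cutoff)
    return df


def concordance_report(
    label_sets: dict[str, dict[str, str]],
    metadata: pd.DataFrame,
    species_labels: tuple[str, str] = ("fabalis", "obtusata"),
) -> dict:
    """Cross-tabulate classifications from different evidence sources.

    ``label_sets`` maps a source name (e.g. ``genetic``, ``shape``,
    ``genital``) to per-sample labels; species labels agree/mismatch, any
    other label (intermediate, hybrid classes, unknown) is tallied
    separately.  Returns per-pair overall and per-location tables.
    """
    meta = metadata.set_index("sample_id")
    names = list(label_sets)
    pairs = {}
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            shared = sorted(set(label_sets[a]) & set(label_sets[b]))
            if not shared:
                warnings.warn(f"no samples shared between {a!r} and {b!r}")
                pairs[(a, b)] = {"n": 0, "per_location": pd.DataFrame()}
                continue
            rows = []
            for sid in shared:
                la, lb = label_sets[a][sid], label_sets[b][sid]
                if la in species_labels and lb in species_labels:
                    status = "concordant" if la == lb else "mismatch"
                elif la in species_labels or lb in species_labels:
                    status = "one_intermediate"
                else:
                    status = "both_intermediate"
                loc = meta.loc[sid, "location"] if sid in meta.index else "UNK"
                rows.append({"sample_id": sid, "location": loc, "status": status})
            df = pd.DataFrame(rows)
            per_loc = (
                df.pivot_table(
                    index="location", columns="status", values="sample_id",
                    aggfunc="count", fill_value=0,
                )
                .reset_index()
            )
            both = df[df["status"].isin(["concordant", "mismatch"])]
            conc = float((both["status"] == "concordant").mean()) if len(both) else float("nan")
            pairs[(a, b)] = {
                "n": len(shared),
                "n_comparable": len(both),
                "concordance": conc,
                "per_location": per_loc,
            }
    return pairs
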