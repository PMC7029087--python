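"""Male genital morphology classification.

Two classifiers are provided: the visual rule comparing filament length to
total penis length (relative length 10-25% typical of *L. obtusata*, 30-60%
typical of *L. fabalis*, 25-30% intermediate, anything else unknown), and a
7-feature linear discriminant with priors equal to training-set class
frequencies and a strict posterior cutoff (default 0.99) for assignment to
a pure species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ..core_data import GenitalMeasurements
from .dfa import INTERMEDIATE, _labels_from_pp


def genitalia_visual_classify(filament_length: float, total_length: float) -> str:
    """Classify a male from the filament-to-total-penis length ratio."""
    if filament_length < 0 or total_length < 0:
        raise ValueError("lengths must be non-negative")
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    r = filament_length / total_length
    if 0.10 <= r <= 0.25:
        return "obtusata"
    if 0.25 < r < 0.30:
        return INTERMEDIATE
    if 0.30 <= r <= 0.60:
        return "fabalis"
    return "unknown"


def genitalia_dfa(
    measurements: GenitalMeasurements | pd.DataFrame,
    training_ids: list[str],
    training_labels: list[str],
    cutoff: float = 0.99,
) -> dict:
    """7-feature discriminant classification of male genitalia.

    Trains on ``training_ids`` (normally genetically confirmed allopatric
    males), with priors set to the species frequencies in the training set,
    then scores every complete sample.  Samples with missing features are
    excluded and listed under ``excluded``.  A sample is labelled a pure
    species only when its posterior reaches ``cutoff`` (inclusive).
    """
    df = measurements.frame() if isinstance(measurements, GenitalMeasurements) else measurements.copy()
    feat_cols = [c for c in df.columns if c != "sample_id"]
    complete = df[feat_cols].notna().all(axis=1)
    excluded = list(df.loc[~complete, "sample_id"])
    df = df[complete].reset_index(drop=True)

    lab = dict(zip(training_ids, training_labels))
    train_mask = df["sample_id"].isin(lab).to_numpy()
    y = np.asarray([lab[s] for s in df.loc[train_mask, "sample_id"]])
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError("genital DFA requires training samples of both species")
    X = df[feat_cols].to_numpy(dtype=float)
    priors = np.array([(y == c).mean() for c in classes])
    lda = LinearDiscriminantAnalysis(priors=priors)
    lda.fit(X[train_mask], y)

    pp = lda.predict_proba(X)
    out = pd.DataFrame(pp, columns=classes)
    out.insert(0, "sample_id", df["sample_id"].to_list())
    out["label"] = _labels_from_pp(pp, classes, cutoff)
    out["in_training"] = train_mask

    n_tr = int(train_mask.sum())
    idx = np.flatnonzero(train_mask)
    loo = np.zeros((n_tr, 2))
    for j, i in enumerate(idx):
        keep = np.setdiff1d(idx, [i])
        m = LinearDiscriminantAnalysis(priors=priors)
        m.fit(X[keep], np.asarray([lab[df.loc[t, "sample_id"]] for t in keep]))
        loo[j] = m.predict_proba(X[i : i + 1])[0]
    loocv = pd.DataFrame(loo, columns=classes)
    loocv.insert(0, "sample_id", df.loc[train_mask, "sample_id"].to_list())
    loocv["label"] = _labels_from_pp(loo, classes, cutoff)
    return {"posteriors": out, "loocv": loocv, "priors": dict(zip(classes, priors)),
            "excluded": excluded}
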