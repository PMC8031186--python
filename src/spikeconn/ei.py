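"""Excitatory/inhibitory neuron classification from SLTE features.

Each neuron's candidate output connections are ranked by firing-rate-
normalized peak TE; the weakest 10% are discarded and the E-I biases (SLTE
at the TE-peak delay) of the rest are summed.  That sum, paired with
log10 firing rate, feeds a two-cluster Ward agglomeration; the cluster on
the positive side of the SLTE-sum axis is labeled excitatory (Dale's
principle: a neuron's outgoing interactions share one sign).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .te import AllPairsTE

__all__ = ["neuron_features", "classify_ei", "categorization_accuracy"]

DROP_FRAC_DEFAULT = 0.10


def neuron_features(
    profiles: AllPairsTE,
    rates_hz: np.ndarray | pd.Series,
    drop_frac: float = DROP_FRAC_DEFAULT,
) -> pd.DataFrame:
    """Per-neuron (sum_slte, log10_fr) features.

    For each presynaptic neuron, candidate output connections (all ordered
    pairs with positive strength) are ranked by ``te_nor`` descending; the
    bottom ``drop_frac`` of the ranking is cut and ``sum_slte`` is the sum
    of ``ei_bias`` over the retained connections (floor(0.9 n) kept,
    minimum 1).  Neurons with no candidates are flagged unlabeled.
    """
    if not 0 <= drop_frac < 1:
        raise ValueError("drop_frac must lie in [0, 1)")
    n = profiles.n_neurons
    rates = np.asarray(rates_hz, dtype=float)
    if rates.shape != (n,):
        raise ValueError("rates length mismatch")
    offdiag = profiles.offdiag_mask()
    rows = []
    for j in range(n):
        cand = np.flatnonzero(offdiag[j] & (profiles.strength[j] > 0))
        if cand.size == 0:
            rows.append((profiles.neuron_ids[j], np.nan, np.nan, False))
            continue
        order = cand[np.argsort(-profiles.te_nor[j, cand], kind="stable")]
        keep = max(int(np.floor((1.0 - drop_frac) * order.size)), 1)
        sum_slte = float(profiles.ei_bias[j, order[:keep]].sum())
        log_fr = float(np.log10(rates[j])) if rates[j] > 0 else np.nan
        rows.append((profiles.neuron_ids[j], sum_slte, log_fr, True))
    return pd.DataFrame(
        rows, columns=["neuron_id", "sum_slte", "log10_fr", "labelable"]
    ).set_index("neuron_id")


def classify_ei(features: pd.DataFrame) -> pd.Series:
    """Two-cluster Ward agglomeration on standardized (sum_slte, log10_fr).

    The cluster with the larger mean ``sum_slte`` is labeled 'E', the other
    'I'.  Neurons flagged unlabelable (or with non-finite features) are
    returned as 'unlabeled' and excluded from clustering.
    """
    ok = features["labelable"] & np.isfinite(features["sum_slte"]) \
        & np.isfinite(features["log10_fr"])
    X = features.loc[ok, ["sum_slte", "log10_fr"]].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 labelable neurons to cluster")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).all():
        raise ValueError("all features identical; no cluster structure")
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd
    cl = fcluster(linkage(Z, method="ward"), t=2, criterion="maxclust")
    mean1 = X[cl == 1, 0].mean()
    mean2 = X[cl == 2, 0].mean() if (cl == 2).any() else -np.inf
    e_cluster = 1 if mean1 >= mean2 else 2
    lab = np.where(cl == e_cluster, "E", "I")
    out = pd.Series("unlabeled", index=features.index, name="label", dtype=object)
    out.loc[ok] = lab
    return out


def categorization_accuracy(pred, truth) -> dict[str, float]:
    """Per-class recall (%) and overall accuracy (%) of E/I labels.

    ``pred`` and ``truth`` are aligned mappings/Series from neuron id to
    {'E','I'}; neurons with unknown truth or 'unlabeled' prediction are
    excluded from scoring.
    """
    pred = pd.Series(pred)
    truth = pd.Series(truth)
    common = pred.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("prediction and truth share no neurons")
    p = pred.loc[common]
    t = truth.loc[common]
    valid = t.isin(["E", "I"]) & p.isin(["E", "I"])
    p, t = p[valid], t[valid]
    out: dict[str, float] = {}
    for cls in ("E", "I"):
        m = t == cls
        out[f"recall_{cls}"] = 100.0 * float((p[m] == cls).mean()) if m.any() else np.nan
    out["overall"] = 100.0 * float((p == t).mean()) if len(t) else np.nan
    return out
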