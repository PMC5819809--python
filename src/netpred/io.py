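"""Tabular I/O for data matrices, outcomes, networks and partitions."""

from __future__ import annotations

import numpy as np
import pandas as pd


def load_matrix(path):
    """Read a samples x features CSV/TSV (header row, first column = IDs).

    Returns ``(values, sample_ids, feature_names)``.  Any non-numeric or
    missing cell is an error naming the offending sample/feature; duplicate
    feature names are rejected.
    """
    # check the raw header before pandas mangles duplicate names
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    delim = "\t" if header.count("\t") >= header.count(",") else ","
    raw_feats = header.split(delim)[1:]
    if len(set(raw_feats)) != len(raw_feats):
        dupes = sorted({f for f in raw_feats if raw_feats.count(f) > 1})
        raise ValueError(f"duplicate feature names: {dupes}")
    df = pd.read_csv(path, sep=delim, index_col=0,
                     float_precision="round_trip")
    feats = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing value at sample {df.index[r]!r}, "
            f"feature {feats[c]!r}")
    return numeric.to_numpy(dtype=float), [str(i) for i in df.index], feats


def load_outcome(path):
    """Read a sample ID + value CSV; returns (values, sample_ids)."""
    vals, ids, cols = load_matrix(path)
    if vals.shape[1] != 1:
        raise ValueError("outcome file must have exactly one value column")
    return vals[:, 0], ids


def save_matrix(path, values, sample_ids, feature_names):
    # %.17g guarantees a bit-exact float round trip through text
    pd.DataFrame(values, index=sample_ids,
                 columns=feature_names).to_csv(path, index_label="sample",
                                               float_format="%.17g")


def save_edge_list(path, net, feature_names=None):
    """Write nonzero edges (i < j) as a 3-column TSV."""
    W = net.weights
    p = W.shape[0]
    names = feature_names or [f"f{i+1}" for i in range(p)]
    iu = np.triu_indices(p, 1)
    mask = W[iu] > 0
    df = pd.DataFrame({
        "feature_i": [names[i] for i in iu[0][mask]],
        "feature_j": [names[j] for j in iu[1][mask]],
        "weight": W[iu][mask],
    })
    df.to_csv(path, sep="\t", index=False)


def load_edge_list(path, feature_names):
    """Reconstruct a dense weight matrix from an edge-list TSV."""
    from netpred.network import WeightedNetwork

    idx = {n: i for i, n in enumerate(feature_names)}
    df = pd.read_csv(path, sep="\t")
    p = len(feature_names)
    W = np.zeros((p, p))
    for _, row in df.iterrows():
        i, j = idx[str(row["feature_i"])], idx[str(row["feature_j"])]
        W[i, j] = W[j, i] = float(row["weight"])
    return WeightedNetwork(W, method="loaded")
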