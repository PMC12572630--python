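"""Taxon-level similarity: mean feature profiles, cosine matrix S, the
Sankey flow transform Q = -log(1 - S), hierarchical heatmap ordering and
sympatry-filtered mimic-model flow tables.

All between-taxon comparison happens between mean feature vectors, one per
taxon; Q turns a bounded similarity into an unbounded flow width (in nats)
so that near-identical taxa get visibly dominant Sankey bands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "TaxonProfile",
    "taxon_mean_features",
    "cosine_similarity_matrix",
    "flow_transform",
    "hierarchical_order",
    "sympatry_matrix",
    "sankey_flows",
    "flows_to_sankey_json",
]


@dataclass
class TaxonProfile:
    taxon_id: str
    mean_vector: np.ndarray
    n_specimens: int

    def __post_init__(self):
        self.mean_vector = np.asarray(self.mean_vector, float)
        if self.n_specimens < 1:
            raise ValueError(f"{self.taxon_id}: n_specimens must be >= 1")
        if not np.all(np.isfinite(self.mean_vector)):
            raise ValueError(f"{self.taxon_id}: non-finite mean vector")


def taxon_mean_features(features: pd.DataFrame,
                        manifest: pd.DataFrame) -> list[TaxonProfile]:
    """Arithmetic mean feature vector per taxon.

    ``features`` is indexed by specimen_id; taxa present in the manifest but
    with no extracted specimens are omitted with a warning.
    """
    labels = manifest.set_index("specimen_id")["taxon_id"]
    missing = labels.index.difference(features.index)
    if len(missing) == len(labels):
        raise ValueError("no labelled specimen has features")
    profiles = []
    for taxon, grp in labels.groupby(labels, sort=True):
        ids = grp.index.intersection(features.index)
        if len(ids) == 0:
            warnings.warn(f"taxon {taxon} has no specimens with features; omitted")
            continue
        profiles.append(TaxonProfile(taxon_id=str(taxon),
                                     mean_vector=features.loc[ids].mean(axis=0).to_numpy(),
                                     n_specimens=len(ids)))
    return profiles


def cosine_similarity_matrix(profiles: Sequence[TaxonProfile]) -> pd.DataFrame:
    """S_ij = f̄_i · f̄_j / (||f̄_i|| ||f̄_j||) between taxon mean vectors.

    Returned as a square DataFrame with taxon ids on both axes; symmetric,
    unit diagonal, entries in [-1, 1].
    """
    taxa = [p.taxon_id for p in profiles]
    M = np.stack([p.mean_vector for p in profiles])
    norms = np.linalg.norm(M, axis=1)
    zero = [t for t, nz in zip(taxa, norms == 0) if nz]
    if zero:
        raise ValueError(f"zero-norm mean vector for taxa: {zero}")
    Mn = M / norms[:, None]
    S = np.clip(Mn @ Mn.T, -1.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=taxa, columns=taxa)


def flow_transform(S: pd.DataFrame, clamp_eps: float = 1e-6) -> pd.DataFrame:
    """Sankey flow widths Q_ij = -ln(1 - S_ij).

    Negative similarities clamp to flow 0 (band widths cannot be negative);
    off-diagonal similarities at or above ``1 - clamp_eps`` are clamped with
    a warning.  The diagonal is NaN — a taxon has no flow to itself.
    """
    Sv = S.to_numpy(dtype=float)
    if not np.all(np.isfinite(Sv)):
        raise ValueError("similarity matrix contains non-finite entries")
    off = ~np.eye(len(S), dtype=bool)
    if np.any(Sv[off] >= 1.0 - clamp_eps):
        warnings.warn("off-diagonal similarities ~1 clamped before -log(1-S)")
    Sc = np.minimum(Sv, 1.0 - clamp_eps)
    Q = -np.log1p(-Sc)
    Q = np.maximum(Q, 0.0)
    Q[~off] = np.nan
    return pd.DataFrame(Q, index=S.index, columns=S.columns)


def hierarchical_order(S: pd.DataFrame,
                       method: str = "average") -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of taxa on distance 1 - S.

    Returns the scipy linkage matrix and the dendrogram leaf order.  Taxa
    are sorted by name before linkage so that tie-breaking is deterministic.
    """
    if len(S) < 2:
        raise ValueError("need at least 2 taxa to cluster")
    order = sorted(S.index)
    D = 1.0 - S.loc[order, order].to_numpy()
    if np.any(np.isnan(D)):
        raise ValueError("NaN distances")
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    leaves = [order[i] for i in hierarchy.leaves_list(Z)]
    return Z, leaves


def sympatry_matrix(regions: Mapping[str, frozenset[str] | set[str]]) -> pd.DataFrame:
    """Boolean taxon x taxon matrix: true iff region sets intersect."""
    taxa = sorted(regions)
    M = np.zeros((len(taxa), len(taxa)), bool)
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            M[i, j] = bool(set(regions[a]) & set(regions[b])) or i == j
    return pd.DataFrame(M, index=taxa, columns=taxa)


def sankey_flows(Q: pd.DataFrame, groups: Mapping[str, str],
                 sympatry: pd.DataFrame | None = None,
                 mode: str = "sympatric_only") -> pd.DataFrame:
    """Mimic -> model flow table (mimic_taxon, model_taxon, width).

    ``mode='sympatric_only'`` keeps only pairs whose distribution ranges
    overlap (current mimicry); ``'all_pairs'`` keeps every mimic-model pair
    and is used to probe possible historical, nonsympatric mimicry.
    """
    if mode not in ("sympatric_only", "all_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    mimics = sorted(t for t in Q.index if groups.get(t) == "mimic")
    models = sorted(t for t in Q.index if groups.get(t) == "model")
    if not mimics or not models:
        raise ValueError("groups must include at least one mimic and one model")
    if mode == "sympatric_only":
        if sympatry is None:
            raise ValueError("sympatric_only mode requires a sympatry matrix")
        missing = (set(mimics) | set(models)) - set(sympatry.index)
        if missing:
            raise ValueError(f"taxa missing from sympatry matrix: {sorted(missing)}")
    rows = []
    for a in mimics:
        for b in models:
            if mode == "sympatric_only" and not bool(sympatry.loc[a, b]):
                continue
            rows.append({"mimic_taxon": a, "model_taxon": b,
                         "width": float(Q.loc[a, b])})
    return pd.DataFrame(rows, columns=["mimic_taxon", "model_taxon", "width"])


def flows_to_sankey_json(flows: pd.DataFrame, path: str | Path | None = None) -> dict:
    """Nodes/links document consumable by standard Sankey renderers."""
    nodes = (sorted(flows["mimic_taxon"].unique())
             + sorted(flows["model_taxon"].unique()))
    index = {n: i for i, n in enumerate(nodes)}
    doc = {
        "nodes": [{"name": n} for n in nodes],
        "links": [{"source": index[r.mimic_taxon], "target": index[r.model_taxon],
                   "value": round(float(r.width), 10)}
                  for r in flows.itertuples()],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
    return doc
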