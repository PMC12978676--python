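"""Inter-participant representational dissimilarity matrices (RDMs).

Connectivity-pattern dissimilarity between two participants is 1 - r, the
Pearson correlation between their vectorized upper-triangle edge weights.
Feature-vector dissimilarity (segregation profiles, node ALFF, speech scores)
is the Euclidean distance; for scalar features this reduces to the absolute
difference.  Three normalized RDMs (connectivity, segregation, ALFF) average
into an integrated brain-state RDM.  Pairs are labeled by comparison group:
within-younger (-0.5), within-older (0), between groups (+0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

WITHIN_YOUNGER = -0.5
WITHIN_OLDER = 0.0
BETWEEN = 0.5


class AlignmentError(ValueError):
    pass


@dataclass
class DissimilarityMatrix:
    participants: list[str]
    d: np.ndarray
    measure: str = ""
    space: str = ""          # language | whole_brain | behavior

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.participants)
        if self.d.shape != (n, n):
            raise AlignmentError("matrix shape does not match participants")

    def upper(self) -> np.ndarray:
        return self.d[np.triu_indices(len(self.participants), k=1)]


def correlation_rdm(vectors: dict[str, np.ndarray], measure: str = "",
                    space: str = "") -> DissimilarityMatrix:
    """d(i,j) = 1 - pearson(v_i, v_j) over participants' edge vectors."""
    ids = list(vectors)
    mat = np.vstack([np.asarray(vectors[i], dtype=float) for i in ids])
    if mat.shape[1] < 3:
        raise ValueError("edge vectors must have length >= 3")
    sds = mat.std(axis=1)
    if np.any(sds == 0):
        bad = [i for i, s in zip(ids, sds) if s == 0]
        raise ValueError(f"zero-variance vector for participant(s): {bad}")
    d = 1.0 - np.corrcoef(mat)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(ids, d, measure=measure, space=space)


def euclidean_rdm(features: dict[str, np.ndarray | float], measure: str = "",
                  space: str = "") -> DissimilarityMatrix:
    """d(i,j) = Euclidean distance between feature vectors (|difference| for scalars)."""
    ids = list(features)
    arrs = [np.atleast_1d(np.asarray(features[i], dtype=float)) for i in ids]
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise AlignmentError(f"inconsistent feature lengths: {sorted(lengths)}")
    mat = np.vstack(arrs)
    d = squareform(pdist(mat, metric="euclidean"))
    return DissimilarityMatrix(ids, d, measure=measure, space=space)


def _standardized_upper(rdm: DissimilarityMatrix) -> np.ndarray:
    u = rdm.upper()
    sd = u.std(ddof=1)
    if sd == 0:
        raise ValueError(f"constant dissimilarity matrix ({rdm.measure!r}): cannot normalize")
    return (u - u.mean()) / sd


def integrate_rdms(rdms: list[DissimilarityMatrix], measure: str = "integrated"
                   ) -> DissimilarityMatrix:
    """Average of the three upper-triangle-standardized RDMs.

    Each input's pairwise values are standardized (mean 0, SD 1 over the
    n(n-1)/2 pairs, diagonal excluded) and averaged entrywise, then
    re-symmetrized with a zero diagonal.
    """
    if len(rdms) != 3:
        raise ValueError("integration expects exactly 3 matrices")
    ids = rdms[0].participants
    for r in rdms[1:]:
        if r.participants != ids:
            raise AlignmentError("participant sets/order differ across matrices")
    avg = np.mean([_standardized_upper(r) for r in rdms], axis=0)
    n = len(ids)
    d = np.zeros((n, n))
    d[np.triu_indices(n, k=1)] = avg
    d = d + d.T
    return DissimilarityMatrix(ids, d, measure=measure, space=rdms[0].space)


def label_pairs(participants: list[str], groups: dict[str, str] | pd.Series
                ) -> pd.DataFrame:
    """All unordered pairs with comparison-group codes, lexicographic id order.

    Codes: both younger -0.5, both older 0, mixed +0.5.
    """
    groups = dict(groups)
    known = {"younger", "older"}
    for p in participants:
        if groups.get(p) not in known:
            raise KeyError(f"participant {p!r} has unknown group {groups.get(p)!r}")
    rows = []
    for i, j in combinations(sorted(participants), 2):
        gi, gj = groups[i], groups[j]
        if gi != gj:
            code = BETWEEN
        elif gi == "younger":
            code = WITHIN_YOUNGER
        else:
            code = WITHIN_OLDER
        rows.append({"participant_i": i, "participant_j": j, "comparison_group": code})
    return pd.DataFrame(rows)


def build_pair_table(
    groups: dict[str, str] | pd.Series,
    rdms: dict[str, DissimilarityMatrix],
) -> pd.DataFrame:
    """PairTable: one row per unordered pair, one column per dissimilarity measure.

    Each measure column also gets a standardized copy suffixed ``_z``
    (mean 0, SD 1 over rows).
    """
    ids = None
    for r in rdms.values():
        if ids is None:
            ids = r.participants
        elif r.participants != ids:
            raise AlignmentError("all RDMs must share participants and order")
    table = label_pairs(ids, groups)
    for name, rdm in rdms.items():
        pos = {p: k for k, p in enumerate(rdm.participants)}
        table[name] = [
            rdm.d[pos[i], pos[j]]
            for i, j in zip(table["participant_i"], table["participant_j"])
        ]
        col = table[name].to_numpy()
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"measure {name!r} constant over pairs")
        table[name + "_z"] = (col - col.mean()) / sd
    return table
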