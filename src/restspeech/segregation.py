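"""Network segregation: (within - between) / within mean connectivity.

Within-network connectivity W is the mean Fisher-z edge weight over all
unordered node pairs inside a network; between-network connectivity B is the
mean over all pairs linking that network to any other network.  Segregation
S = (W - B) / W is computed per network; whole-brain segregation is the
unweighted mean of the per-network values, and the language value is the S of
the left-hemisphere language network.  Zero-clipped edges count as zeros in
the means (they are set to zero upstream, not removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import LANGUAGE_LEFT
from .connectome import ConnectivityMatrix


class UndefinedSegregationError(ValueError):
    """Within-network mean connectivity is zero; S = (W-B)/W is undefined."""


class InvalidPartitionError(ValueError):
    """A network has fewer than 2 nodes."""


@dataclass
class SegregationProfile:
    participant: str
    per_network: dict[str, tuple[float, float, float]]  # network -> (W, B, S)
    language_S: float | None
    whole_brain_S: float


def segregation_for_network(
    cm: ConnectivityMatrix, atlas: pd.DataFrame, network: str
) -> tuple[float, float, float]:
    """Return (W, B, S) for one network of a filtered atlas."""
    nodes = atlas.loc[atlas["network"] == network, "node_id"].tolist()
    if len(nodes) < 2:
        raise InvalidPartitionError(f"network {network!r} has {len(nodes)} node(s); need >= 2")
    others = atlas.loc[atlas["network"] != network, "node_id"].tolist()
    idx = {n: i for i, n in enumerate(cm.nodes)}
    ii = np.array([idx[n] for n in nodes])
    jj = np.array([idx[n] for n in others])
    z = cm.z_matrix
    within = z[np.ix_(ii, ii)][np.triu_indices(len(ii), k=1)]
    w = float(within.mean())
    b = float(z[np.ix_(ii, jj)].mean()) if len(jj) else 0.0
    if w == 0.0:
        raise UndefinedSegregationError(
            f"within-network connectivity of {network!r} is zero"
        )
    s = (w - b) / w
    return w, b, s


def segregation_profile(cm: ConnectivityMatrix, atlas: pd.DataFrame,
                        node_weighted: bool = False) -> SegregationProfile:
    """Per-network (W, B, S) plus language and whole-brain summaries.

    ``node_weighted=True`` weights the whole-brain mean by network size
    instead of the default unweighted mean across networks.
    """
    networks = list(dict.fromkeys(atlas["network"]))
    per_network: dict[str, tuple[float, float, float]] = {}
    for net in networks:
        per_network[net] = segregation_for_network(cm, atlas, net)
    s_vals = np.array([v[2] for v in per_network.values()])
    if node_weighted:
        sizes = np.array([(atlas["network"] == net).sum() for net in networks], dtype=float)
        whole = float(np.average(s_vals, weights=sizes))
    else:
        whole = float(s_vals.mean())
    language = per_network.get(LANGUAGE_LEFT)
    return SegregationProfile(
        participant=cm.participant,
        per_network=per_network,
        language_S=None if language is None else language[2],
        whole_brain_S=whole,
    )


def flag_outliers(
    values: dict[str, float],
    sd_threshold: float = 2.5,
    also_flag_negative: bool = False,
) -> set[str]:
    """Participants whose value lies outside mean +- sd_threshold * SD.

    The mean and (n-1 denominator) SD are computed over all supplied values.
    With ``also_flag_negative``, negative values are flagged regardless of the
    SD rule — used for measures that are meaningful only when positive.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 values to define outliers")
    ids = list(values)
    arr = np.array([values[i] for i in ids], dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        warnings.warn("zero SD: no SD-based outliers flagged", stacklevel=2)
        flagged = set()
    else:
        mean = arr.mean()
        flagged = {i for i, v in zip(ids, arr) if abs(v - mean) > sd_threshold * sd}
    if also_flag_negative:
        flagged |= {i for i, v in zip(ids, arr) if v < 0}
    return flagged


def profiles_to_frame(profiles: list[SegregationProfile]) -> pd.DataFrame:
    """Long table: participant, network, W, B, S."""
    rows = []
    for p in profiles:
        for net, (w, b, s) in p.per_network.items():
            rows.append({"participant": p.participant, "network": net, "W": w, "B": b, "S": s})
    return pd.DataFrame(rows)


def summaries_to_frame(profiles: list[SegregationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [p.participant for p in profiles],
            "language_S": [p.language_S for p in profiles],
            "whole_brain_S": [p.whole_brain_S for p in profiles],
        }
    )
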