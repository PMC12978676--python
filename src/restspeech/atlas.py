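"""Node atlas handling: a Power-style 264-node parcellation table.

An atlas is a :class:`pandas.DataFrame` with columns
``node_id, x, y, z, network, excluded, language_side``.  Each included node
belongs to exactly one functional network; a subset of left-hemisphere nodes
forms the language network (and their right-hemisphere homologues a right
language network, carried along but not analyzed).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

ATLAS_COLUMNS = ["node_id", "x", "y", "z", "network", "excluded", "language_side"]

#: The 12 large-scale networks of the Power scheme.
POWER_NETWORKS = [
    "somatomotor_hand",
    "somatomotor_mouth",
    "visual",
    "salience",
    "auditory",
    "cingulo_opercular",
    "frontoparietal",
    "ventral_attention",
    "dorsal_attention",
    "default_mode",
    "subcortical",
    "cerebellar",
]

LANGUAGE_LEFT = "language_left"
LANGUAGE_RIGHT = "language_right"


class AtlasFormatError(ValueError):
    """Raised when an atlas table violates its schema."""


def make_power_like_atlas(
    n_nodes: int = 264,
    n_excluded: int = 33,
    n_networks: int = 12,
    n_language_left: int = 9,
    n_language_right: int = 9,
) -> pd.DataFrame:
    """Build a synthetic Power-style atlas.

    This is a synthetic stand-in for the published 264-node parcellation: node
    counts and the network partition match the reference scheme (264 nodes, 33
    excluded for poor classification, 231 retained; 12 base networks plus left
    and right language networks of 9 nodes each, 14 networks total), but the
    MNI coordinates are a deterministic grid, informational only.

    Language nodes are re-labeled out of their base network so that each node
    carries exactly one network label, with language taking precedence.
    """
    if n_excluded >= n_nodes:
        raise AtlasFormatError("cannot exclude every node")
    retained = n_nodes - n_excluded
    if n_language_left + n_language_right >= retained:
        raise AtlasFormatError("language nodes exceed retained nodes")
    networks = POWER_NETWORKS[:n_networks]
    if n_networks > len(POWER_NETWORKS):
        networks = networks + [f"network_{i}" for i in range(len(POWER_NETWORKS), n_networks)]

    node_id = [f"node_{i:03d}" for i in range(n_nodes)]
    # spread exclusions evenly through the table
    excl_idx = set(np.linspace(0, n_nodes - 1, n_excluded, dtype=int).tolist())
    excluded = np.array([i in excl_idx for i in range(n_nodes)])

    network = np.empty(n_nodes, dtype=object)
    language_side = np.full(n_nodes, "none", dtype=object)
    kept = [i for i in range(n_nodes) if i not in excl_idx]
    # first retained nodes become language nodes (left then right homologues)
    for j, i in enumerate(kept[:n_language_left]):
        network[i] = LANGUAGE_LEFT
        language_side[i] = "left"
    for j, i in enumerate(kept[n_language_left : n_language_left + n_language_right]):
        network[i] = LANGUAGE_RIGHT
        language_side[i] = "right"
    rest = kept[n_language_left + n_language_right :]
    for j, i in enumerate(rest):
        network[i] = networks[j % n_networks]
    # excluded nodes keep a base-network label; they are dropped before analysis
    for j, i in enumerate(sorted(excl_idx)):
        network[i] = networks[j % n_networks]

    # deterministic pseudo-MNI grid; x sign encodes hemisphere for language nodes
    xs = np.round(np.linspace(-60, 60, n_nodes), 1)
    xs[language_side == "left"] = -np.abs(xs[language_side == "left"]) - 1.0
    xs[language_side == "right"] = np.abs(xs[language_side == "right"]) + 1.0
    ys = np.round(np.linspace(-90, 60, n_nodes), 1)
    zs = np.round(np.linspace(-40, 70, n_nodes), 1)

    return pd.DataFrame(
        {
            "node_id": node_id,
            "x": xs,
            "y": ys,
            "z": zs,
            "network": network,
            "excluded": excluded,
            "language_side": language_side,
        }
    )


def validate_atlas(atlas: pd.DataFrame) -> pd.DataFrame:
    """Check schema and uniqueness constraints; return the atlas unchanged."""
    missing = [c for c in ATLAS_COLUMNS if c not in atlas.columns]
    if missing:
        raise AtlasFormatError(f"atlas missing columns: {missing}")
    dup = atlas["node_id"][atlas["node_id"].duplicated()]
    if len(dup):
        raise AtlasFormatError(f"duplicate node_id(s): {sorted(set(dup))}")
    bad_side = set(atlas["language_side"]) - {"left", "right", "none"}
    if bad_side:
        raise AtlasFormatError(f"invalid language_side value(s): {sorted(bad_side)}")
    if atlas["network"].isna().any():
        raise AtlasFormatError("every node needs exactly one network label")
    return atlas


def filter_atlas(atlas: pd.DataFrame) -> pd.DataFrame:
    """Drop nodes flagged ``excluded``, preserving row order.

    The reference scheme drops 33 of 264 nodes for poor classification,
    retaining 231.
    """
    validate_atlas(atlas)
    kept = atlas.loc[~atlas["excluded"].astype(bool)].reset_index(drop=True)
    if len(kept) == 0:
        warnings.warn("all atlas nodes are flagged excluded", stacklevel=2)
    return kept


def language_nodes(atlas: pd.DataFrame, side: str = "left") -> list[str]:
    """Node ids of the language network on the given hemisphere."""
    return atlas.loc[atlas["language_side"] == side, "node_id"].tolist()


def read_atlas_csv(path) -> pd.DataFrame:
    atlas = pd.read_csv(path, dtype={"node_id": str, "network": str, "language_side": str})
    atlas["excluded"] = atlas["excluded"].astype(bool)
    return validate_atlas(atlas)


def write_atlas_csv(atlas: pd.DataFrame, path) -> None:
    validate_atlas(atlas).to_csv(path, index=False)
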