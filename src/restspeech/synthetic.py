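"""Synthetic resting-state cohorts with a known brain-speech structure.

The generator produces, for each participant, band-limited BOLD-like node
signals with block network covariance, and five speech measures driven by a
single latent speech factor that can be coupled to the participant's true
brain state.  It emulates the study conditions the analysis assumes:

* 38 younger and 24 older adults by default; 240 volumes at TR = 2.5 s,
  signals confined to the 0.008-0.09 Hz band;
* a Power-style atlas (264 nodes, 33 excluded, 231 retained, 12 base networks
  plus 9 left / 9 right language nodes, 14 networks);
* stronger within- than between-network correlation, with group effects on
  the non-language networks' within-correlation and on node amplitude (hence
  ALFF), while the language subnetwork is group-invariant by default;
* a latent speech factor loading positively on four complexity measures and
  negatively on disfluency, optionally coupled to the participant's (true)
  whole-brain segregation and amplitude.

Signals are sums of sinusoids at DFT-aligned frequencies inside the band with
random phases, shared at global / network / node level so that the population
correlation between two nodes of the same network is the configured
within-network value and between networks the configured between value.  The
construction makes ALFF exactly proportional to the node amplitude scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

from .alff import DEFAULT_BAND, band_bins
from .atlas import LANGUAGE_LEFT, make_power_like_atlas
from .connectome import TimeSeriesMatrix
from .speech_factor import SPEECH_VARS

YOUNGER = "younger"
OLDER = "older"

#: loadings of the speech factor on (mlu, verbs, lcc, re, disfluency)
DEFAULT_LOADINGS = (0.81, 0.63, 0.76, 0.73, -0.67)

#: observable scales: measure = offset + spread * standardized value
SPEECH_SCALES = {
    "mlu": (8.0, 2.0),
    "verbs": (1.5, 0.4),
    "lcc": (30.0, 8.0),
    "re": (10.0, 4.0),
    "disfluency": (0.15, 0.05),
}


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; the defaults are the emulated study conditions."""

    n_younger: int = 38
    n_older: int = 24
    n_nodes: int = 264
    n_excluded: int = 33
    n_networks: int = 12
    n_language: int = 9
    n_volumes: int = 240
    tr_seconds: float = 2.5
    band: tuple[float, float] = DEFAULT_BAND
    # population within-network correlation of non-language networks, per group
    within_corr_younger: float = 0.50
    within_corr_older: float = 0.32
    # population between-network correlation (group-invariant by default:
    # the language subnetwork stays stable with age)
    between_corr_younger: float = 0.10
    between_corr_older: float = 0.10
    # language network parameters, group-invariant
    language_within_corr: float = 0.50
    language_alff_scale: float = 1.0
    # node amplitude scale per group (drives ALFF)
    alff_scale_younger: float = 1.0
    alff_scale_older: float = 0.70
    # inter-individual spread of the participant-level parameters
    subject_corr_sd: float = 0.05
    subject_alff_sd: float = 0.08
    # speech model
    speech_loadings: tuple[float, ...] = DEFAULT_LOADINGS
    brain_speech_coupling: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> "CohortConfig":
        nyq = 1.0 / (2.0 * self.tr_seconds)
        low, high = self.band
        if self.n_volumes < 2:
            raise InvalidConfigError("n_volumes must be at least 2")
        if not (0 < low < high):
            raise InvalidConfigError(f"band must satisfy 0 < low < high, got {self.band}")
        if high > nyq:
            raise InvalidConfigError(f"band high {high} Hz above Nyquist {nyq} Hz")
        if self.n_volumes * self.tr_seconds * low < 1:
            warnings.warn("band low edge under-resolved by the scan duration",
                          stacklevel=2)
        for name in ("within_corr_younger", "within_corr_older",
                     "between_corr_younger", "between_corr_older",
                     "language_within_corr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidConfigError(f"{name} must lie in (0,1), got {v}")
        for grp in (YOUNGER, OLDER):
            if self.between_corr(grp) > self.within_corr(grp):
                raise InvalidConfigError("within_corr must be >= between_corr")
        if len(self.speech_loadings) != 5:
            raise InvalidConfigError("speech_loadings must have exactly 5 entries")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        if self.n_younger < 1 or self.n_older < 1:
            raise InvalidConfigError("group sizes must be positive")
        return self

    def within_corr(self, group: str) -> float:
        return self.within_corr_younger if group == YOUNGER else self.within_corr_older

    def between_corr(self, group: str) -> float:
        return self.between_corr_younger if group == YOUNGER else self.between_corr_older

    def alff_scale(self, group: str) -> float:
        return self.alff_scale_younger if group == YOUNGER else self.alff_scale_older


@dataclass
class SyntheticCohort:
    config: CohortConfig
    atlas: pd.DataFrame
    timeseries: list[TimeSeriesMatrix]
    manifest: pd.DataFrame      # participant, group, seed
    speech: pd.DataFrame        # participant-indexed speech measures
    latent: pd.Series           # true latent speech factor
    true_state: pd.DataFrame    # participant-level true segregation / amplitude

    @property
    def groups(self) -> pd.Series:
        return self.manifest.set_index("participant")["group"]


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    # per-participant streams derived from the cohort seed; stable under
    # sub-sampling because stream i never depends on how many others exist
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _band_signal(rng: np.random.Generator, ks: np.ndarray, n: int) -> np.ndarray:
    """Unit-variance signal: equal-amplitude sinusoids at DFT bins ks, random phases."""
    t = np.arange(n)
    phases = rng.uniform(0, 2 * np.pi, size=len(ks))
    amp = np.sqrt(2.0 / len(ks))
    return amp * np.cos(2 * np.pi * np.outer(ks, t) / n + phases[:, None]).sum(axis=0)


def _participant_params(config: CohortConfig, group: str,
                        rng: np.random.Generator) -> dict:
    """Draw participant-level within-corr and amplitude around the group values."""
    b = config.between_corr(group)
    w = rng.normal(config.within_corr(group), config.subject_corr_sd)
    w = float(np.clip(w, b, 0.98))
    w_lang = rng.normal(config.language_within_corr, config.subject_corr_sd)
    w_lang = float(np.clip(w_lang, b, 0.98))
    # multiplicative jitter so the group scale acts as an exact gain
    amp = config.alff_scale(group) * float(max(rng.normal(1.0, config.subject_alff_sd), 0.05))
    return {"within": w, "within_language": w_lang, "between": b, "amp": amp,
            "amp_language": config.language_alff_scale}


def generate_timeseries(
    config: CohortConfig,
    participant: str,
    group: str,
    seed: int,
    atlas: pd.DataFrame | None = None,
    params: dict | None = None,
) -> TimeSeriesMatrix:
    """One participant's node-by-volume band-limited signal with block covariance.

    Node i of network m is ``amp_i * (sqrt(b) G + sqrt(w_m - b) L_m +
    sqrt(1 - w_m) E_i)`` where G, L_m, E_i are independent unit-variance
    band-limited signals, so the population correlation is w_m within network
    m and b between networks; amp encodes the group ALFF scale (language
    nodes use the group-invariant language scale).
    """
    config.validate()
    if group not in (YOUNGER, OLDER):
        raise InvalidConfigError(f"unknown group {group!r}")
    if atlas is None:
        atlas = make_power_like_atlas(config.n_nodes, config.n_excluded,
                                      config.n_networks, config.n_language,
                                      config.n_language)
    rng = np.random.default_rng(seed)
    if params is None:
        params = _participant_params(config, group, rng)
    n = config.n_volumes
    ks = band_bins(n, config.tr_seconds, config.band)

    networks = list(dict.fromkeys(atlas["network"]))
    g_sig = _band_signal(rng, ks, n)
    net_sig = {net: _band_signal(rng, ks, n) for net in networks}
    b = params["between"]
    data = np.empty((len(atlas), n))
    for row, (nid, net, side) in enumerate(
        zip(atlas["node_id"], atlas["network"], atlas["language_side"])
    ):
        is_lang = side in ("left", "right")
        w = params["within_language"] if is_lang else params["within"]
        amp = params["amp_language"] if is_lang else params["amp"]
        e = _band_signal(rng, ks, n)
        data[row] = amp * (
            np.sqrt(b) * g_sig + np.sqrt(w - b) * net_sig[net] + np.sqrt(1 - w) * e
        )
    return TimeSeriesMatrix(participant=participant, data=data,
                            node_ids=atlas["node_id"].tolist(),
                            tr_seconds=config.tr_seconds, group=group)


def generate_speech(
    latent_factor: float | np.ndarray,
    loadings: tuple[float, ...] = DEFAULT_LOADINGS,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Speech measures from a latent factor.

    On the standardized scale each measure is ``lambda * latent +
    noise_sd * sqrt(1 - lambda^2) * eps`` with eps ~ N(0,1); with unit-variance
    latent and noise_sd = 1 this reproduces the loading pattern exactly in
    population.  Values are then mapped affinely to plausible observable
    scales; disfluency is clipped to [0, 1].
    """
    if len(loadings) != 5:
        raise InvalidConfigError("need exactly 5 loadings")
    if noise_sd <= 0:
        raise InvalidConfigError("noise_sd must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = np.atleast_1d(np.asarray(latent_factor, dtype=float))
    out = {}
    for var, lam in zip(SPEECH_VARS, loadings):
        unique_sd = noise_sd * np.sqrt(max(1.0 - lam**2, 0.0))
        z = lam * latent + rng.normal(0.0, 1.0, size=latent.size) * unique_sd
        offset, spread = SPEECH_SCALES[var]
        vals = offset + spread * z
        if var == "disfluency":
            vals = np.clip(vals, 0.0, 1.0)
        elif var in ("mlu", "verbs", "lcc", "re"):
            vals = np.maximum(vals, 0.0)
        out[var] = vals
    return pd.DataFrame(out)


def true_segregation(params: dict, config: CohortConfig) -> float:
    """Population whole-brain segregation implied by a participant's parameters.

    Per-network S = (w - b)/w on the correlation scale, averaged unweighted
    over the 12 non-language networks and the 2 language networks.
    """
    s_base = (params["within"] - params["between"]) / params["within"]
    s_lang = (params["within_language"] - params["between"]) / params["within_language"]
    n_base, n_lang = config.n_networks, 2
    return (n_base * s_base + n_lang * s_lang) / (n_base + n_lang)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full cohort: time series, speech measures and ground truth.

    The latent speech factor is ``c * (z_seg + z_amp)/2 + sqrt(1 - c^2) eps``
    where z_seg / z_amp are the cohort-standardized true whole-brain
    segregation and amplitude and c is ``brain_speech_coupling`` (|c| <= 1).
    """
    config.validate()
    c = config.brain_speech_coupling
    if abs(c) > 1:
        raise InvalidConfigError("brain_speech_coupling must lie in [-1, 1]")
    atlas = make_power_like_atlas(config.n_nodes, config.n_excluded,
                                  config.n_networks, config.n_language,
                                  config.n_language)
    if config.n_language == 0:
        warnings.warn("no language nodes: language-level measures unavailable",
                      stacklevel=2)
    groups = [YOUNGER] * config.n_younger + [OLDER] * config.n_older
    ids = [f"sub-{i + 1:03d}" for i in range(len(groups))]

    timeseries, params_list, seeds = [], [], []
    for i, (pid, grp) in enumerate(zip(ids, groups)):
        rng = _participant_rng(config.seed, i)
        seed_i = int(rng.integers(0, 2**31 - 1))
        prng = np.random.default_rng(seed_i)
        params = _participant_params(config, grp, prng)
        ts = generate_timeseries(config, pid, grp, seed_i, atlas=atlas, params=params)
        timeseries.append(ts)
        params_list.append(params)
        seeds.append(seed_i)

    true_seg = np.array([true_segregation(p, config) for p in params_list])
    true_amp = np.array([p["amp"] for p in params_list])

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    latent_rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                              spawn_key=(10**6,)))
    eps = latent_rng.normal(size=len(ids))
    latent = c * (_z(true_seg) + _z(true_amp)) / 2.0 + np.sqrt(1 - c**2) * eps

    speech_rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                              spawn_key=(10**6 + 1,)))
    speech = generate_speech(latent, config.speech_loadings, config.noise_sd,
                             seed=speech_rng)
    speech.index = pd.Index(ids, name="participant")

    manifest = pd.DataFrame({"participant": ids, "group": groups, "seed": seeds})
    true_state = pd.DataFrame(
        {"participant": ids, "true_segregation": true_seg, "true_amplitude": true_amp,
         "group": groups}
    ).set_index("participant")
    return SyntheticCohort(
        config=config, atlas=atlas, timeseries=timeseries, manifest=manifest,
        speech=speech, latent=pd.Series(latent, index=speech.index, name="latent"),
        true_state=true_state,
    )


def null_config(**overrides) -> CohortConfig:
    """Config with no group effects and no brain-speech coupling."""
    base = CohortConfig(
        within_corr_older=CohortConfig.within_corr_younger,
        alff_scale_older=CohortConfig.alff_scale_younger,
        brain_speech_coupling=0.0,
    )
    return replace(base, **overrides)
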