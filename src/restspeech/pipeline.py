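"""End-to-end orchestration of the resting-state / speech analysis.

Stages: connectivity -> segregation + ALFF -> outlier exclusion -> speech
factor -> RDMs (language and whole-brain x {connectivity, segregation, ALFF}
plus integrated and speech) -> group t-tests, comparison-group ANOVAs, k-NN
classification, score-level moderated regressions, and pair-level
dissimilarity regressions with Mantel-style permutation p-values and
per-group slope comparisons.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import alff as alff_mod
from . import segregation as seg_mod
from .atlas import filter_atlas, language_nodes, read_atlas_csv, write_atlas_csv
from .connectome import TimeSeriesMatrix, compute_connectivity, edge_vector
from .inference import (group_slopes, knn_classify, moderated_regression,
                        comparison_anova, permutation_p, slope_diff_z, welch_t)
from .rsa import build_pair_table, correlation_rdm, euclidean_rdm, integrate_rdms
from .speech_factor import adequacy_checks, fit_speech_factor
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

GROUP_CODES = {"younger": -0.5, "older": 0.5}


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults mirror the analysis conventions.

    Exactly one of ``synthetic`` and the four input paths must be supplied.
    """

    synthetic: CohortConfig | None = None
    atlas_path: str | None = None
    timeseries_dir: str | None = None
    speech_path: str | None = None
    groups_path: str | None = None
    band: tuple[float, float] = (0.008, 0.09)
    outlier_sd_threshold: float = 2.5
    permutation_B: int = 1000
    train_fraction: float = 0.7
    seed: int = 0
    node_weighted_whole_brain: bool = False
    scalar_wb_segregation_rdm: bool = False
    run_permutations: bool = True
    output_dir: str | None = None

    def validate(self) -> "PipelineConfig":
        has_paths = all(p is not None for p in
                        (self.atlas_path, self.timeseries_dir,
                         self.speech_path, self.groups_path))
        if (self.synthetic is None) == (not has_paths):
            raise ValueError("provide either a synthetic config or all four input paths")
        return self


@dataclass
class BrainMeasures:
    """Per-participant derived brain measures for one cohort."""

    ids: list[str]
    atlas: pd.DataFrame                       # filtered
    language: list[str]
    lang_edges: dict[str, np.ndarray]
    wb_edges: dict[str, np.ndarray]
    seg_profiles: dict[str, seg_mod.SegregationProfile]
    alff_profiles: dict[str, alff_mod.ALFFProfile]

    def seg_summary(self) -> pd.DataFrame:
        return seg_mod.summaries_to_frame(
            [self.seg_profiles[i] for i in self.ids]).set_index("participant")

    def alff_summary(self) -> pd.DataFrame:
        return alff_mod.summaries_to_frame(
            [self.alff_profiles[i] for i in self.ids]).set_index("participant")


def compute_brain_measures(timeseries: list[TimeSeriesMatrix], atlas: pd.DataFrame,
                           band=(0.008, 0.09),
                           node_weighted: bool = False) -> BrainMeasures:
    kept = filter_atlas(atlas)
    lang = language_nodes(kept, "left")
    ids, lang_edges, wb_edges, segs, alffs = [], {}, {}, {}, {}
    for ts in timeseries:
        cm = compute_connectivity(ts, kept)
        ids.append(ts.participant)
        wb_edges[ts.participant] = edge_vector(cm)
        if len(lang) >= 2:
            lang_edges[ts.participant] = edge_vector(cm, lang)
        segs[ts.participant] = seg_mod.segregation_profile(cm, kept,
                                                           node_weighted=node_weighted)
        alffs[ts.participant] = alff_mod.alff_profile(ts, kept, band)
    return BrainMeasures(ids=ids, atlas=kept, language=lang,
                         lang_edges=lang_edges, wb_edges=wb_edges,
                         seg_profiles=segs, alff_profiles=alffs)


def apply_exclusions(measures: BrainMeasures, sd_threshold: float = 2.5
                     ) -> tuple[list[str], pd.DataFrame]:
    """Outlier participants by the 2.5-SD rules, dropped from all analyses.

    Language-network segregation flags values outside the mean +- threshold*SD
    band or negative; whole-brain ALFF likewise (ALFF is meaningful only when
    positive).  A single common participant set is used downstream.
    """
    seg_vals = {i: measures.seg_profiles[i].language_S for i in measures.ids
                if measures.seg_profiles[i].language_S is not None}
    alff_vals = {i: measures.alff_profiles[i].whole_brain_mean for i in measures.ids}
    rows = []
    flagged: set[str] = set()
    if seg_vals:
        f = seg_mod.flag_outliers(seg_vals, sd_threshold, also_flag_negative=True)
        rows += [{"participant": i, "measure": "language_segregation",
                  "rule": f"|x-mean|>{sd_threshold}SD or x<0"} for i in sorted(f)]
        flagged |= f
    f = seg_mod.flag_outliers(alff_vals, sd_threshold, also_flag_negative=True)
    rows += [{"participant": i, "measure": "whole_brain_alff",
              "rule": f"|x-mean|>{sd_threshold}SD or x<0"} for i in sorted(f)]
    flagged |= f
    kept = [i for i in measures.ids if i not in flagged]
    return kept, pd.DataFrame(rows, columns=["participant", "measure", "rule"])


def build_rdms(measures: BrainMeasures, ids: list[str]) -> dict[str, dict]:
    """All brain RDMs, keyed by space then measure."""
    out: dict[str, dict] = {"language": {}, "whole_brain": {}}
    if measures.lang_edges:
        out["language"]["connectivity"] = correlation_rdm(
            {i: measures.lang_edges[i] for i in ids}, "connectivity", "language")
        out["language"]["segregation"] = euclidean_rdm(
            {i: measures.seg_profiles[i].language_S for i in ids},
            "segregation", "language")
        out["language"]["alff"] = euclidean_rdm(
            {i: np.array([measures.alff_profiles[i].node_alff[n]
                          for n in measures.language]) for i in ids},
            "alff", "language")
        out["language"]["integrated"] = integrate_rdms(
            [out["language"][m] for m in ("connectivity", "segregation", "alff")])
    out["whole_brain"]["connectivity"] = correlation_rdm(
        {i: measures.wb_edges[i] for i in ids}, "connectivity", "whole_brain")
    networks = list(dict.fromkeys(measures.atlas["network"]))
    out["whole_brain"]["segregation"] = euclidean_rdm(
        {i: np.array([measures.seg_profiles[i].per_network[n][2] for n in networks])
         for i in ids}, "segregation", "whole_brain")
    nodes = measures.atlas["node_id"].tolist()
    out["whole_brain"]["alff"] = euclidean_rdm(
        {i: np.array([measures.alff_profiles[i].node_alff[n] for n in nodes])
         for i in ids}, "alff", "whole_brain")
    out["whole_brain"]["integrated"] = integrate_rdms(
        [out["whole_brain"][m] for m in ("connectivity", "segregation", "alff")])
    return out


def _result_json(res) -> dict:
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(res).items()
            if not isinstance(v, (pd.DataFrame, pd.Series))}


def _pair_fit_factory(pairs: pd.DataFrame, predictor_col: str):
    """Pair-level refit closure: rebuild speech dissimilarity from scores."""
    pi = pairs["participant_i"].to_numpy()
    pj = pairs["participant_j"].to_numpy()
    codes = pairs["comparison_group"].to_numpy(dtype=float)
    pred = pairs[predictor_col].to_numpy(dtype=float)

    def fit(scores: pd.Series):
        d = np.abs(scores.loc[pi].to_numpy() - scores.loc[pj].to_numpy())
        return moderated_regression(d, pred, codes, predictor_name=predictor_col)

    return fit


def analyze(measures: BrainMeasures, speech: pd.DataFrame, groups: pd.Series,
            config: PipelineConfig) -> dict:
    """Run the full statistical battery on precomputed brain measures."""
    kept, exclusions = apply_exclusions(measures, config.outlier_sd_threshold)
    ids = kept
    groups = groups.loc[ids]
    report: dict = {"n_total": len(measures.ids), "n_analyzed": len(ids),
                    "exclusions": exclusions.to_dict("records")}

    adequacy = adequacy_checks(speech.loc[ids])
    model = fit_speech_factor(speech.loc[ids])
    scores = model.scores
    report["speech_factor"] = {
        "loadings": model.loadings.round(6).to_dict(),
        "variance_explained": model.variance_explained,
        "eigenvalues": model.eigenvalues.tolist(),
        "n_factors_kaiser": model.n_factors_kaiser,
        "adequacy": {"bartlett_chi2": adequacy.bartlett_chi2,
                     "bartlett_p": adequacy.bartlett_p,
                     "kmo": adequacy.kmo_overall,
                     "vif": adequacy.vif},
    }

    young = groups.index[groups == "younger"]
    old = groups.index[groups == "older"]
    seg_sum = measures.seg_summary().loc[ids]
    alff_sum = measures.alff_summary().loc[ids]
    alff_lang_z = pd.Series(alff_mod.normalize_values(alff_sum["language_mean"].to_dict()))
    alff_wb_z = pd.Series(alff_mod.normalize_values(alff_sum["whole_brain_mean"].to_dict()))

    score_measures = {
        "speech_factor": scores,
        "language_segregation": seg_sum["language_S"],
        "whole_brain_segregation": seg_sum["whole_brain_S"],
        "language_alff": alff_lang_z,
        "whole_brain_alff": alff_wb_z,
    }
    report["group_t_tests"] = {
        name: _result_json(welch_t(vals.loc[young], vals.loc[old]))
        for name, vals in score_measures.items()
        if vals.notna().all()
    }

    report["knn"] = {}
    for space, feats in (("language", measures.lang_edges),
                         ("whole_brain", measures.wb_edges)):
        if not feats:
            continue
        res = knn_classify({i: feats[i] for i in ids}, groups,
                           config.train_fraction, seed=config.seed)
        report["knn"][space] = {"k": res.k, "accuracy": res.accuracy,
                                "confusion": res.confusion.to_dict(),
                                "n_train": len(res.train_ids),
                                "n_test": len(res.test_ids)}

    rdms = build_rdms(measures, ids)
    speech_rdm = euclidean_rdm(scores.to_dict(), "speech", "behavior")
    report["anova"] = {}
    report["pair_regressions"] = {}
    pair_tables = {}
    for space, space_rdms in rdms.items():
        if not space_rdms:
            continue
        table = build_pair_table(groups, {**{m: r for m, r in space_rdms.items()},
                                          "speech": speech_rdm})
        pair_tables[space] = table
        report["anova"][space] = {}
        for m in space_rdms:
            res, follow = comparison_anova(table, m)
            report["anova"][space][m] = {
                **_result_json(res),
                "followups": follow.to_dict("records"),
            }
        report["pair_regressions"][space] = {}
        for m in space_rdms:
            fit = _pair_fit_factory(table, m)
            res = fit(scores)
            if config.run_permutations:
                res.p_perm = permutation_p(fit, scores, B=config.permutation_B,
                                           seed=config.seed + 1)
            report["pair_regressions"][space][m] = {
                "terms": res.terms, "betas": res.betas.tolist(),
                "ses": res.ses.tolist(), "t": res.t.tolist(),
                "p": res.p.tolist(),
                "p_perm": None if res.p_perm is None else res.p_perm.tolist(),
                "n": res.n,
            }

    # score-level moderated regressions with per-group follow-ups
    codes = groups.map(GROUP_CODES).to_numpy()
    report["score_regressions"] = {}
    for name in ("language_segregation", "whole_brain_segregation",
                 "language_alff", "whole_brain_alff"):
        pred = score_measures[name]
        if pred.isna().any():
            continue

        def fit(sc, _pred=pred):
            return moderated_regression(sc.loc[ids], _pred.loc[ids], codes,
                                        predictor_name=name)

        res = fit(scores)
        if config.run_permutations:
            res.p_perm = permutation_p(fit, scores, B=config.permutation_B,
                                       seed=config.seed + 2)
        slopes = group_slopes(scores.loc[ids], pred.loc[ids], groups.to_numpy(),
                              predictor_name=name)
        zres = slope_diff_z(
            slopes["younger"].term(name)["beta"], slopes["younger"].term(name)["se"],
            slopes["older"].term(name)["beta"], slopes["older"].term(name)["se"])
        report["score_regressions"][name] = {
            "terms": res.terms, "betas": res.betas.tolist(),
            "ses": res.ses.tolist(), "t": res.t.tolist(), "p": res.p.tolist(),
            "p_perm": None if res.p_perm is None else res.p_perm.tolist(),
            "group_slopes": {g: r.term(name) for g, r in slopes.items()},
            "slope_diff": _result_json(zres),
        }

    report["_internal"] = {"scores": scores, "pair_tables": pair_tables,
                           "rdms": rdms, "kept_ids": ids}
    return report


# ---------------------------------------------------------------------------
# file I/O

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort as the documented CSV layout (atlas, manifest, speech,
    per-participant time-series files)."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    write_atlas_csv(cohort.atlas, out / "atlas.csv")
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    cohort.speech.reset_index().to_csv(out / "speech.csv", index=False)
    for ts in cohort.timeseries:
        df = pd.DataFrame(ts.data, index=ts.node_ids,
                          columns=[str(v) for v in range(ts.data.shape[1])])
        df.index.name = "node_id"
        df.to_csv(out / "timeseries" / f"{ts.participant}.csv")
    return out


def load_inputs(config: PipelineConfig
                ) -> tuple[pd.DataFrame, list[TimeSeriesMatrix], pd.DataFrame, pd.Series]:
    """Load and cross-validate (atlas, time series, speech, groups)."""
    config.validate()
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        return cohort.atlas, cohort.timeseries, cohort.speech, cohort.groups
    atlas = read_atlas_csv(config.atlas_path)
    manifest = pd.read_csv(config.groups_path, dtype={"participant": str})
    groups = manifest.set_index("participant")["group"]
    speech = pd.read_csv(config.speech_path, dtype={"participant": str}
                         ).set_index("participant")
    tsdir = Path(config.timeseries_dir)
    timeseries = []
    tr = 2.5 if config.synthetic is None else config.synthetic.tr_seconds
    for pid in groups.index:
        path = tsdir / f"{pid}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing time-series file for participant {pid!r}")
        df = pd.read_csv(path, index_col="node_id")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = df.columns[df.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
            raise ValueError(f"non-numeric cell(s) in {path.name}, column(s) {list(bad)}")
        timeseries.append(TimeSeriesMatrix(participant=pid, data=vals,
                                           node_ids=[str(i) for i in df.index],
                                           tr_seconds=tr, group=groups[pid]))
    missing = set(groups.index) - set(speech.index)
    if missing:
        raise ValueError(f"participants missing from speech table: {sorted(missing)}")
    return atlas, timeseries, speech, groups


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and (optionally) write the artifact bundle."""
    t0 = time.time()
    config.validate()
    atlas, timeseries, speech, groups = load_inputs(config)
    measures = compute_brain_measures(timeseries, atlas, config.band,
                                      config.node_weighted_whole_brain)
    report = analyze(measures, speech, groups, config)
    internal = report.pop("_internal")
    report["manifest"] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "wall_time_s": round(time.time() - t0, 2),
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        internal["scores"].rename("speech_factor").to_csv(out / "speech_scores.csv")
        seg_mod.summaries_to_frame(
            [measures.seg_profiles[i] for i in measures.ids]
        ).to_csv(out / "segregation_summary.csv", index=False)
        alff_mod.summaries_to_frame(
            [measures.alff_profiles[i] for i in measures.ids]
        ).to_csv(out / "alff_summary.csv", index=False)
        for space, table in internal["pair_tables"].items():
            table.to_csv(out / f"pairs_{space}.csv", index=False)
        for space, space_rdms in internal["rdms"].items():
            for m, rdm in space_rdms.items():
                pd.DataFrame(rdm.d, index=rdm.participants,
                             columns=rdm.participants
                             ).to_csv(out / f"rdm_{space}_{m}.csv")
    report["_internal"] = internal
    return report
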