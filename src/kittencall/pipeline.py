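"""End-to-end study replica: synthesize -> extract -> annotate -> analyse.

``run_study`` executes, in order: (1) the condition-order control
(independent t-tests with Fisher-omnibus gatekeeper), (2) the
sender-identity battery per condition plus crossed/nested permuted DFA,
(3) sex and body-weight controls, (4) the arousal battery on per-kitten
condition means, and (5) non-linear-phenomena prevalence with paired
Wilcoxon comparisons. All tables are written as CSV (rounded for reading)
and a single JSON summary keeps full precision; the run's configuration is
copied into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import nlp as nlpmod
from .audio import CallSegment, read_wav
from .discriminate import arousal_analysis, identity_analysis
from .pdfa import crossed_pdfa, nested_pdfa
from .stats import fisher_omnibus, independent_t, paired_t, pearson
from .synth import (DEFAULT_EFFECTS, PARAMETER_COLUMNS, CohortManifest,
                    make_cohort, sample_feature_table, synthesize_cohort)

log = logging.getLogger("kittencall")


@dataclass
class RunConfig:
    """Fully serializable configuration of one study run."""

    seed: int = 0
    n_kittens: int = 18
    n_litters: int = 6
    calls_per_cell: int = 10
    signature_ratio: float = 0.5
    source: str = "audio"  # "audio" renders+measures WAVs; "table" samples directly
    n_perm: int = 1000
    n_selections_crossed: int = 10
    n_selections_nested: int = 100
    null_conditions: bool = False  # both conditions drawn from the Low profile
    out_dir: str = "study_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def best_segment(w, config: feat.FeatureConfig = feat.DEFAULT_CONFIG
                 ) -> CallSegment | None:
    """The call segment with the highest envelope peak (one per file)."""
    segs = feat.segment_calls(w, config=config)
    if not segs:
        return None
    peaks = [float(np.max(np.abs(s.samples))) for s in segs]
    return segs[int(np.argmax(peaks))]


def analyze_cohort_audio(
    manifest: CohortManifest,
    config: feat.FeatureConfig = feat.DEFAULT_CONFIG,
    nlp_config: nlpmod.NLPConfig = nlpmod.DEFAULT_NLP_CONFIG,
) -> tuple[pd.DataFrame, list[nlpmod.NLPAnnotation]]:
    """Segment every WAV of a cohort, extract the feature table, and
    annotate non-linear phenomena.

    Inter-call intervals come from the manifest (calls are stored one per
    file); unsegmentable files yield missing-value rows (logged).
    """
    assert manifest.out_dir is not None, "manifest must point at rendered audio"
    segs: list[CallSegment | None] = []
    labels = []
    for _, row in manifest.rows.iterrows():
        w = read_wav(manifest.out_dir / row["wav_path"])
        seg = best_segment(w, config)
        if seg is None:
            log.warning("no call found in %s", row["wav_path"])
        segs.append(seg)
        labels.append({
            "call_id": row["call_id"],
            "kitten_id": row["kitten_id"],
            "litter_id": row["litter_id"],
            "sex": row["sex"],
            "body_weight_g": row["body_weight_g"],
            "condition": row["condition"],
            "first_condition": row["first_condition"],
            "ici_ms": row["ici_ms"],
        })
    good = [i for i, s in enumerate(segs) if s is not None]
    table = feat.extract_all([segs[i] for i in good],
                             [labels[i] for i in good], config)
    if len(good) < len(segs):
        empty = pd.DataFrame([labels[i] for i in range(len(segs))
                              if segs[i] is None])
        table = pd.concat([table, empty], ignore_index=True)
    annotations = [
        nlpmod.classify_call(segs[i], call_id=labels[i]["call_id"],
                             config=nlp_config, feature_config=config)
        for i in good
    ]
    return table, annotations


# ---------------------------------------------------------------------------
# study stages
# ---------------------------------------------------------------------------


def order_effect_tests(ft: pd.DataFrame) -> dict:
    """Independent t-tests per parameter: kittens first exposed to Low vs
    first exposed to High (per-kitten call means), Fisher omnibus on top."""
    params = [c for c in PARAMETER_COLUMNS if c in ft.columns]
    means = ft.groupby(["kitten_id", "first_condition"], sort=True)[params].mean()
    means = means.reset_index()
    rows, pvals = [], []
    for p in params:
        a = means.loc[means["first_condition"] == "Low", p].dropna()
        b = means.loc[means["first_condition"] == "High", p].dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append({"parameter": p, "t": np.nan, "p": np.nan})
            continue
        res = independent_t(a, b)
        rows.append({"parameter": p, "t": res.statistic, "p": res.p})
        if np.isfinite(res.p) and res.p > 0:
            pvals.append(res.p)
    omnibus = fisher_omnibus(pvals) if pvals else None
    return {"t_tests": pd.DataFrame(rows), "fisher_omnibus": omnibus}


def sex_weight_tests(ft: pd.DataFrame) -> dict:
    """Sex t-tests and body-weight Pearson correlations per parameter and
    condition (per-kitten means), each with a Fisher-omnibus gatekeeper,
    plus the sex-difference-in-weight t-test."""
    params = [c for c in PARAMETER_COLUMNS if c in ft.columns]
    rows_sex, rows_wt, p_sex, p_wt = [], [], [], []
    for condition in ("Low", "High"):
        sub = ft[ft["condition"] == condition]
        means = sub.groupby(["kitten_id", "sex", "body_weight_g"],
                            sort=True)[params].mean().reset_index()
        for p in params:
            males = means.loc[means["sex"] == "male", p].dropna()
            females = means.loc[means["sex"] == "female", p].dropna()
            if len(males) >= 2 and len(females) >= 2:
                res = independent_t(males, females)
                rows_sex.append({"condition": condition, "parameter": p,
                                 "t": res.statistic, "p": res.p})
                if np.isfinite(res.p) and res.p > 0:
                    p_sex.append(res.p)
            ok = means[[p, "body_weight_g"]].dropna()
            if len(ok) >= 3:
                res = pearson(ok["body_weight_g"], ok[p])
                rows_wt.append({"condition": condition, "parameter": p,
                                "r": res.statistic, "p": res.p})
                if np.isfinite(res.p) and res.p > 0:
                    p_wt.append(res.p)
    kittens = ft.drop_duplicates("kitten_id")
    wt_m = kittens.loc[kittens["sex"] == "male", "body_weight_g"]
    wt_f = kittens.loc[kittens["sex"] == "female", "body_weight_g"]
    weight_by_sex = (independent_t(wt_m, wt_f)
                     if len(wt_m) >= 2 and len(wt_f) >= 2 else None)
    return {
        "sex_t_tests": pd.DataFrame(rows_sex),
        "sex_omnibus": fisher_omnibus(p_sex) if p_sex else None,
        "weight_correlations": pd.DataFrame(rows_wt),
        "weight_omnibus": fisher_omnibus(p_wt) if p_wt else None,
        "weight_by_sex": weight_by_sex,
    }


def identity_accuracy_comparison(rep_low: dict, rep_high: dict) -> dict:
    """Dependent t-test on per-kitten percent-correct between conditions,
    restricted to kittens present in both analyses."""
    a = rep_low["dfa"].per_class.set_index("class")
    b = rep_high["dfa"].per_class.set_index("class")
    common = a.index.intersection(b.index)
    out = {}
    for kind in ("original", "loo"):
        pa = 100.0 * a.loc[common, f"n_correct_{kind}"] / a.loc[common, "n"]
        pb = 100.0 * b.loc[common, f"n_correct_{kind}"] / b.loc[common, "n"]
        out[kind] = paired_t(pa.to_numpy(), pb.to_numpy()) if len(common) >= 2 else None
    out["n_kittens"] = int(len(common))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Index, pd.Series)):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _write_csv(df: pd.DataFrame, path: Path, decimals: int = 2) -> None:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(4 if c in ("p", "r") else decimals)
    out.to_csv(path, index=False)


def run_study(config: RunConfig) -> dict:
    """Execute the full study replica and write all reports.

    Returns the JSON-serializable summary (also written to summary.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger().addHandler(handler)
    try:
        config.to_yaml(out / "config.yaml")
        profiles = make_cohort(config.n_kittens, config.n_litters,
                               seed=config.seed,
                               signature_ratio=config.signature_ratio)
        log.info("stage synth: %d kittens in %d litters", config.n_kittens,
                 config.n_litters)
        if config.null_conditions:
            low = DEFAULT_EFFECTS["Low"]
            effects = {"Low": low, "High": dataclasses.replace(low, condition="High")}
        else:
            effects = DEFAULT_EFFECTS
        annotations = None
        if config.source == "audio":
            manifest = synthesize_cohort(
                profiles, effects, config.calls_per_cell,
                seed=config.seed, out_dir=out / "audio",
                signature_ratio=config.signature_ratio)
            log.info("stage synth: %d calls rendered", len(manifest))
            ft, annotations = analyze_cohort_audio(manifest)
        else:
            ft = sample_feature_table(
                profiles, effects, config.calls_per_cell,
                seed=config.seed, signature_ratio=config.signature_ratio)
        _write_csv(ft, out / "feature_table.csv")
        qc = ft.attrs.get("qc", {})
        log.info("stage extract: %d calls, missing values per column: %s",
                 len(ft), qc.get("missing_values", {}))

        # (1) order-effect control
        order = order_effect_tests(ft)
        _write_csv(order["t_tests"], out / "order_effect_t_tests.csv")

        # (2) sender identity
        identity = {}
        for condition in ("Low", "High"):
            rep = identity_analysis(ft, condition)
            identity[condition] = rep
            _write_csv(rep["anova"], out / f"anova_identity_{condition.lower()}.csv")
            rep["pca"].loadings.round(3).to_csv(
                out / f"pca_loadings_identity_{condition.lower()}.csv")
            _write_csv(rep["dfa"].per_class,
                       out / f"dfa_per_class_{condition.lower()}.csv")
            rep["dfa"].df_pc_correlations.round(3).to_csv(
                out / f"df_pc_correlations_{condition.lower()}.csv")
        accuracy_cmp = identity_accuracy_comparison(identity["Low"],
                                                    identity["High"])
        crossed = crossed_pdfa(ft, n_perm=config.n_perm, seed=config.seed,
                               n_selections=config.n_selections_crossed)
        nested = nested_pdfa(ft, n_perm=config.n_perm, seed=config.seed,
                             n_selections=config.n_selections_nested)
        pd.DataFrame({"null_original": crossed.null_original,
                      "null_loo": crossed.null_loo}).to_csv(
            out / "pdfa_crossed_null.csv", index=False)
        pd.DataFrame({"null_original": nested.null_original,
                      "null_loo": nested.null_loo}).to_csv(
            out / "pdfa_nested_null.csv", index=False)

        # (3) sex and body-weight controls
        controls = sex_weight_tests(ft)
        _write_csv(controls["sex_t_tests"], out / "sex_t_tests.csv")
        _write_csv(controls["weight_correlations"],
                   out / "weight_correlations.csv")

        # (4) arousal
        arousal = arousal_analysis(ft)
        _write_csv(arousal["t_tests"], out / "arousal_t_tests.csv")
        if arousal["scatter"] is not None:
            _write_csv(arousal["scatter"], out / "arousal_pc_scatter.csv")

        # (5) non-linear phenomena
        nlp_summary = None
        if annotations is not None:
            with open(out / "nlp_annotations.jsonl", "w") as fh:
                for ann in annotations:
                    fh.write(json.dumps(_jsonable(ann)) + "\n")
            nlp_stats = nlpmod.nlp_condition_stats(
                annotations, ft[["call_id", "kitten_id", "condition"]])
            _write_csv(nlp_stats["per_kitten"], out / "nlp_per_kitten.csv")
            nlp_summary = {
                "overall_pct": nlp_stats["overall_pct"],
                "wilcoxon": {k: _jsonable(v) for k, v in
                             nlp_stats["wilcoxon"].items()},
                "excluded_kittens": nlp_stats["excluded_kittens"],
            }

        summary = {
            "config": dataclasses.asdict(config),
            "n_calls": int(len(ft)),
            "qc": _jsonable(qc),
            "order_effect": {
                "fisher_omnibus": _jsonable(order["fisher_omnibus"]),
            },
            "identity": {
                cond: {
                    "n_calls": rep["n_calls"],
                    "fisher_omnibus": _jsonable(rep["fisher_omnibus"]),
                    "retained_pcs": rep["pca"].retained,
                    "variance_explained_pct": rep["pca"].variance_explained,
                    "original_accuracy_pct": rep["dfa"].original_accuracy,
                    "loo_accuracy_pct": rep["dfa"].loo_accuracy,
                    "chance_pct": rep["dfa"].chance,
                }
                for cond, rep in identity.items()
            },
            "identity_accuracy_comparison": _jsonable(accuracy_cmp),
            "pdfa": {"crossed": _jsonable(crossed), "nested": _jsonable(nested)},
            "sex_weight": {
                "sex_omnibus": _jsonable(controls["sex_omnibus"]),
                "weight_omnibus": _jsonable(controls["weight_omnibus"]),
                "weight_by_sex": _jsonable(controls["weight_by_sex"]),
            },
            "arousal": {
                "fisher_omnibus": _jsonable(arousal["fisher_omnibus"]),
                "directions": {
                    r["parameter"]: r["direction"]
                    for _, r in arousal["t_tests"].iterrows() if r["direction"]
                },
                "original_accuracy_pct": (arousal["dfa"].original_accuracy
                                          if arousal["dfa"] else None),
                "loo_accuracy_pct": (arousal["dfa"].loo_accuracy
                                     if arousal["dfa"] else None),
            },
            "nlp": nlp_summary,
        }
        (out / "summary.json").write_text(json.dumps(_jsonable(summary),
                                                     indent=1, sort_keys=True))
        return summary
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()
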