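"""End-to-end orchestration: generate -> preprocess -> match -> cluster ->
enrich -> compare, reproducible under a single seed.

The pipeline produces two feature sets per cohort ("arms"): raw charted
window means for every eligible patient, and model-derived features for
every acceptably fitted patient.  Both arms are consensus-clustered and
tested for enrichment of diagnosis codes and hospital of origin; the
summary reports whether hospital-origin bias dominates the raw arm and
whether the model arm recovers an ARDS-enriched cluster.

Desk-scale defaults (200 patients, 3 hospitals, 20 model compartments,
200 consensus resamples, 100-evaluation fit budget) keep a full run in
the minutes range on one CPU; every knob is exposed in the YAML config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    HospitalProfile,
    NoiseModel,
    default_hospitals,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .consensus import (
    ConsensusResult,
    FeatureMatrix,
    consensus_cluster,
    quality_curve,
)
from .enrichment import compare_arms, enrich_clusters
from .matching import (
    MODEL_FEATURE_NAMES,
    fit_patient,
    model_derived_features,
)
from .preprocessing import EligiblePatient, preprocess_cohort

__all__ = ["RunConfig", "run_all", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs, each with a default; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "results/run"
    # cohort
    n_patients: int = 200
    hospital_profiles: Optional[List[dict]] = None
    p_dx: float = 0.6
    noise: Optional[Dict[str, float]] = None
    # gas-exchange model
    n_comp: int = 20
    tol: float = 1e-6
    max_iter: int = 200
    # matching
    budget: int = 100
    # clustering
    k_final: int = 5
    k_range: Tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    n_resamples: int = 200
    frac: float = 0.8
    tau: float = 0.5
    quality_repeats: int = 100
    quality_inner_resamples: int = 100
    run_quality_curve: bool = True
    # statistics
    alpha: float = 0.05
    equal_var: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.k_final < 2:
            raise ValueError("k_final must be >= 2")
        if any(k < 2 for k in cfg.k_range):
            raise ValueError("all k values must be >= 2")
        return cfg

    def profiles(self) -> List[HospitalProfile]:
        if self.hospital_profiles is None:
            return default_hospitals(self.n_patients)
        return [HospitalProfile(**p) for p in self.hospital_profiles]

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise) if self.noise else NoiseModel()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "k_range" in data:
        data["k_range"] = tuple(data["k_range"])
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# stages

def stage_cohort(config: RunConfig, outdir: Path):
    records, truths = generate_cohort(
        config.profiles(), seed=config.seed, n_comp=config.n_comp,
        noise=config.noise_model(), p_dx=config.p_dx)
    write_cohort(records, truths, outdir, manifest_extra={
        "seed": config.seed, "n_comp": config.n_comp, "p_dx": config.p_dx,
        "noise": dataclasses.asdict(config.noise_model()),
        "profiles": [
            {**dataclasses.asdict(p),
             "archetype_mix": dict(p.archetype_mix)}
            for p in config.profiles()],
    })
    log.info("cohort: %d patients written to %s", len(records), outdir)
    return records, truths


def stage_preprocess(config: RunConfig, outdir: Path, records=None):
    if records is None:
        records, _ = read_cohort(outdir)
    pre = preprocess_cohort(records)
    pre.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    rows = []
    for ep in pre.eligible:
        rows.append({"patient_id": ep.record.patient_id,
                     "hospital_id": ep.record.hospital_id,
                     "t0": ep.windows.t0,
                     **ep.features.values})
    feat = pd.DataFrame(rows)
    feat[["patient_id", "hospital_id", "t0"]].to_csv(
        outdir / "eligible.csv", index=False)
    feat.drop(columns=["hospital_id", "t0"]).to_csv(
        outdir / "raw_features.csv", index=False, float_format="%.6f")
    log.info("preprocess: %d eligible, %d excluded",
             len(pre.eligible), len(pre.exclusions))
    return pre


def stage_fit(config: RunConfig, outdir: Path, pre=None):
    if pre is None:
        pre = stage_preprocess(config, outdir)
    rng = np.random.default_rng([config.seed, 2])
    seeds = rng.integers(2 ** 31, size=len(pre.eligible))
    fit_rows, feat_rows = [], []
    for ep, s in zip(pre.eligible, seeds):
        fr = fit_patient(ep, seed=int(s), budget=config.budget,
                         n_comp=config.n_comp)
        row = {"patient_id": fr.patient_id,
               "obj_w1": fr.obj_w1, "obj_w2": fr.obj_w2,
               "acceptable_w1": fr.acceptable_w1,
               "acceptable_w2": fr.acceptable_w2,
               "ncc_w2": fr.ncc_w2, "n_sim_calls": fr.n_sim_calls}
        for name, val in zip(fr.config_w1.param_names(),
                             fr.config_w1.as_vector()):
            row[name] = val
        fit_rows.append(row)
        if fr.acceptable_w1 and fr.acceptable_w2:
            mdf = model_derived_features(fr, ep.slices, n_comp=config.n_comp)
            feat_rows.append({"patient_id": mdf.patient_id, **mdf.values})
        else:
            log.info("patient %s excluded from model arm "
                     "(acceptable w1=%s w2=%s)", fr.patient_id,
                     fr.acceptable_w1, fr.acceptable_w2)
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(outdir / "fits.csv", index=False, float_format="%.6f")
    feats = pd.DataFrame(feat_rows)
    feats.to_csv(outdir / "model_features.csv", index=False,
                 float_format="%.6f")
    log.info("fit: %d patients, %d acceptable in both windows",
             len(fits), len(feats))
    return fits, feats


def _feature_matrices(outdir: Path):
    """Both clustering arms cover the same reliably fitted patients.

    The comparison contrasts two representations (charted window means vs
    model-derived parameters) of one cohort; clustering different patient
    sets would confound representation with population.
    """
    raw = pd.read_csv(outdir / "raw_features.csv").set_index("patient_id")
    model = pd.read_csv(outdir / "model_features.csv").set_index("patient_id")
    raw = raw.loc[model.index]
    return (FeatureMatrix.from_frame(raw), FeatureMatrix.from_frame(model))


def stage_cluster(config: RunConfig, outdir: Path):
    fm_raw, fm_model = _feature_matrices(outdir)
    results = {}
    for arm, fm, sub in (("raw", fm_raw, 3), ("model", fm_model, 4)):
        res = consensus_cluster(
            fm.X, config.k_final, n_resamples=config.n_resamples,
            frac=config.frac, tau=config.tau,
            seed=int(np.random.default_rng([config.seed, sub])
                     .integers(2 ** 31)))
        np.savez_compressed(
            outdir / f"consensus_{arm}_{config.k_final}.npz",
            D=res.D, labels=res.labels,
            m_k=np.array(sorted(res.m_k.items()), dtype=float),
            mean_consensus=res.mean_consensus, items=np.array(fm.items))
        results[arm] = (fm, res)
        log.info("cluster[%s]: k=%d mean consensus %.3f",
                 arm, config.k_final, res.mean_consensus)
    return results


def stage_quality(config: RunConfig, outdir: Path):
    fm_raw, fm_model = _feature_matrices(outdir)
    curves = {}
    for arm, fm, sub in (("raw", fm_raw, 5), ("model", fm_model, 6)):
        curves[arm] = quality_curve(
            fm.X, config.k_range, repeats=config.quality_repeats,
            frac=config.frac, inner_resamples=config.quality_inner_resamples,
            tau=config.tau,
            seed=int(np.random.default_rng([config.seed, sub])
                     .integers(2 ** 31)))
    rows = []
    for arm, qc in curves.items():
        for k, m, ci in zip(qc.k_values, qc.mean, qc.ci_halfwidth):
            rows.append({"arm": arm, "k": k, "mean_quality": m,
                         "ci95_halfwidth": ci})
    pd.DataFrame(rows).to_csv(outdir / "quality_curve.csv", index=False,
                              float_format="%.6f")
    comp_rows = []
    comparisons = {}
    for k in config.k_range:
        ac = compare_arms(curves["raw"].samples[k],
                          curves["model"].samples[k], k=k,
                          equal_var=config.equal_var)
        comparisons[k] = ac
        comp_rows.append(dataclasses.asdict(ac))
    pd.DataFrame(comp_rows).to_csv(outdir / "comparison.csv", index=False,
                                   float_format="%.6g")
    return curves, comparisons


def stage_enrich(config: RunConfig, outdir: Path, cluster_results):
    records, _ = read_cohort(outdir)
    by_id = {r.patient_id: r for r in records}
    out = {}
    for arm, (fm, res) in cluster_results.items():
        cats = pd.DataFrame({
            "conditions": [by_id[i].icd_codes for i in fm.items],
            "hospital": [by_id[i].hospital_id for i in fm.items],
        })
        results, top = enrich_clusters(res.labels, cats, alpha=config.alpha)
        df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        df.to_csv(outdir / f"enrichment_{arm}.csv", index=False,
                  float_format="%.6g")
        top.to_csv(outdir / f"enrichment_top_{arm}.csv", index=False,
                   float_format="%.6g")
        out[arm] = (results, top)
    return out


def _headline(config: RunConfig, outdir: Path, cluster_results, enrich_results):
    """The qualitative bias-reduction findings, as booleans."""
    model_feats = pd.read_csv(outdir / "model_features.csv").set_index(
        "patient_id")
    summary: Dict[str, object] = {}

    # (a) raw arm: >=1 cluster whose most significant enrichment overall
    #     is a hospital
    _, top_raw = enrich_results["raw"]
    a = bool(((top_raw["top_hospital_p_raw"] < top_raw["top_condition_p_raw"])
              & top_raw["top_hospital_significant"]).any())

    # (b) model arm: a diagnosed-ARDS-enriched cluster whose mean delta_ncc
    #     is the largest across clusters
    results_model, top_model = enrich_results["model"]
    fm_model, res_model = cluster_results["model"]
    mean_delta = {}
    labels = res_model.labels
    for cl in sorted(set(labels.tolist()) - {-1}):
        ids = [fm_model.items[i] for i in np.where(labels == cl)[0]]
        mean_delta[cl] = float(model_feats.loc[ids, "delta_ncc"].mean())
    ards_clusters = [r.cluster_id for r in results_model
                     if r.family == "condition" and r.category == "J80"
                     and r.significant]
    b = bool(ards_clusters and mean_delta and
             max(mean_delta, key=mean_delta.get) in ards_clusters)

    # (c) strongest hospital enrichment weaker in the model arm
    def max_neglog10_hosp(results):
        ps = [r.p_raw for r in results if r.family == "hospital"]
        return float(-np.log10(max(min(ps), 1e-300))) if ps else 0.0
    raw_strength = max_neglog10_hosp(enrich_results["raw"][0])
    model_strength = max_neglog10_hosp(enrich_results["model"][0])
    c = bool(model_strength < raw_strength)

    # (d) model arm at least as stable as the raw arm at k_final
    d = bool(cluster_results["model"][1].mean_consensus
             >= cluster_results["raw"][1].mean_consensus)

    summary.update({
        "raw_top_enrichment_is_hospital": a,
        "model_ards_cluster_max_delta_ncc": b,
        "model_hospital_enrichment_weaker": c,
        "model_consensus_geq_raw": d,
        "max_neglog10_hospital_p_raw_arm": raw_strength,
        "max_neglog10_hospital_p_model_arm": model_strength,
        "mean_delta_ncc_by_cluster": {str(k): v
                                      for k, v in mean_delta.items()},
    })
    return summary


def _fig3_style_plot(outdir: Path, enrich_results) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, arm in zip(axes, ("raw", "model")):
        _, top = enrich_results[arm]
        x = np.arange(len(top))
        cond = -np.log10(np.maximum(top["top_condition_p_raw"], 1e-300))
        hosp = -np.log10(np.maximum(top["top_hospital_p_raw"], 1e-300))
        ax.bar(x - 0.2, cond, width=0.4, color="tab:green",
               label="top condition")
        ax.bar(x + 0.2, hosp, width=0.4, color="tab:red",
               label="top hospital")
        ax.set_xticks(x)
        ax.set_xticklabels([f"C{c}" for c in top["cluster_id"]])
        ax.set_title(f"{arm} features")
        ax.set_xlabel("cluster")
    axes[0].set_ylabel("-log10 p (raw)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(outdir / "enrichment_comparison.svg")
    plt.close(fig)


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write a machine-readable summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truths = stage_cohort(config, outdir)
    pre = stage_preprocess(config, outdir, records=records)
    if not pre.eligible:
        raise RuntimeError("preprocessing produced no eligible patients")
    fits, feats = stage_fit(config, outdir, pre=pre)
    if feats.empty:
        raise RuntimeError("no patient reached an acceptable fit")
    cluster_results = stage_cluster(config, outdir)
    enrich_results = stage_enrich(config, outdir, cluster_results)
    summary: Dict[str, object] = {
        "seed": config.seed,
        "n_generated": len(records),
        "n_eligible": len(pre.eligible),
        "n_fitted": int(len(fits)),
        "acceptable_w1_pct": float(100 * fits["acceptable_w1"].mean()),
        "acceptable_w2_pct": float(100 * fits["acceptable_w2"].mean()),
        "acceptable_both_pct": float(
            100 * (fits["acceptable_w1"] & fits["acceptable_w2"]).mean()),
        "n_model_arm": int(len(feats)),
        "mean_consensus_raw": cluster_results["raw"][1].mean_consensus,
        "mean_consensus_model": cluster_results["model"][1].mean_consensus,
        "k_final": config.k_final,
    }
    summary.update(_headline(config, outdir, cluster_results, enrich_results))
    if config.run_quality_curve:
        curves, comparisons = stage_quality(config, outdir)
        summary["quality"] = {
            str(k): {
                "raw": curves["raw"].mean[i],
                "model": curves["model"].mean[i],
                "t_p_value": comparisons[k].p_value,
            } for i, k in enumerate(config.k_range)}
    _fig3_style_plot(outdir, enrich_results)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
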