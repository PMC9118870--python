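"""End-to-end orchestration: simulate -> preprocess -> features -> stats.

One :class:`RunConfig` drives the whole chain with per-stage toggles; a
manifest (seeds, parameter hash, stage timings) is written next to the
stage outputs so identical configs yield identical results. The demo
configuration exercises every stage on a small synthetic cohort with a
known reactivity age-by-group interaction and one strongly coupled
channel pair, which the cluster statistics should recover.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from . import classify as classify_mod
from .cluster import feature_graph, link_adjacency, ols_node_pvalues, \
    lme_node_pvalues, permutation_test
from .cohort import CohortSpec, CouplingSpec, generate_cohort
from .connectivity import fc_tensor
from .data import CHANNELS_DEMO, channel_positions
from .preprocess import average_reference, bandpass_fir, epoch, inclusion_check
from .spectral import morlet_transform, relative_power, welch_psd
from .stats import TRANSFORMS, group_tests, make_feature_table

__all__ = ["RunConfig", "run", "demo_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults follow the study
    parameters (order-2000 1-32 Hz FIR, 2.5 s epochs, q = 4.88 wavelets,
    15-epoch/100-repetition wPLI, 2000 cluster permutations)."""

    seed: int = 0
    cohort: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: dict(
        preprocess=True, alpha=True, spectra=True, connectivity=True,
        stats=True, cluster=True, classify=False, split=True))
    preprocess: dict = field(default_factory=lambda: dict(
        lo=1.0, hi=32.0, order=2000, pad=2.0, epoch_length=2.5))
    connectivity: dict = field(default_factory=lambda: dict(
        metrics=("wPLI",), n_epochs=15, n_reps=100))
    cluster: dict = field(default_factory=lambda: dict(
        metric="wPLI", stat="mean", n_perm=2000, alpha=0.05,
        node_test="ols", adjacency_radius=0.08))
    classify: dict = field(default_factory=lambda: dict(
        model_id="linsvc", n_splits=15, cv=10))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["connectivity"]["metrics"] = list(d["connectivity"]["metrics"])
        return d


def demo_config(seed: int = 0, n_per_group: int = 20) -> RunConfig:
    """Small cohort with a strong injected link effect and a reactivity
    age-by-group interaction, on the reduced 23-channel montage."""
    coupling = [dict(ch_a="F3", ch_b="P4", freq=10.0, lag=float(np.pi / 2),
                     env_corr=1.0, snr=2.0, group_snr_delta=1.0)]
    cfg = RunConfig(seed=seed)
    cfg.cohort = dict(
        n_per_group=n_per_group, seed=seed, channels=list(CHANNELS_DEMO),
        srate=256.0, coupling_plan=coupling,
        age_slope_by_group={"NT": 0.016, "ASD": 0.0})
    cfg.cluster.update(n_perm=400)
    return cfg


def _hash_config(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig, out_dir=None) -> dict:
    """Execute the toggled stages and return (and optionally write) results.

    Stage order: simulate, preprocess, alpha metrics, relative power
    spectra, connectivity, univariate stats on the alpha measures,
    cluster-corrected link statistics, classification, train/validation
    split. Failures abort with the stage name; earlier outputs survive in
    the returned dict.
    """
    results: dict = {"manifest": {"config_hash": _hash_config(config),
                                  "seed": config.seed, "timings": {}}}
    t_all = time.time()

    def _stage(name):
        results["manifest"]["timings"][name] = time.time() - t_stage[0]
        t_stage[0] = time.time()

    t_stage = [time.time()]
    spec_kw = dict(config.cohort)
    coupling = [CouplingSpec(**c) if isinstance(c, dict) else c
                for c in spec_kw.pop("coupling_plan", [])]
    spec = CohortSpec(coupling_plan=coupling, **spec_kw)
    metas, recordings = generate_cohort(spec)
    meta_df = pd.DataFrame([m.__dict__ for m in metas])
    results["meta"] = meta_df
    _stage("simulate")

    pp = config.preprocess
    epoch_sets = []
    reports = []
    for rec in recordings:
        if config.stages.get("preprocess", True):
            rec = bandpass_fir(rec, pp["lo"], pp["hi"], pp["order"], pp["pad"])
        es = average_reference(epoch(rec, pp["epoch_length"]))
        epoch_sets.append(es)
        reports.append(inclusion_check(es, n_usable_channels=len(es.channels),
                                       max_adjacent_bad=0, n_artifact_ics=0,
                                       n_good_channels=len(es.channels)))
    results["quality"] = reports
    _stage("preprocess")

    if config.stages.get("alpha", True):
        rows = []
        for meta, es in zip(metas, epoch_sets):
            psd_eo = welch_psd(es.select("EO"))
            psd_ec = welch_psd(es.select("EC"))
            summ = alpha_mod.alpha_summary(psd_eo, psd_ec)
            if summ is None:
                continue
            rows.append(dict(id=meta.id, f_p=summ.f_p, p_eo=summ.p_eo,
                             p_ec=summ.p_ec, r=summ.r))
        results["alpha"] = pd.DataFrame(rows)
        _stage("alpha")

    wavelets = None
    if config.stages.get("spectra", True) or config.stages.get(
            "connectivity", True):
        wavelets = [morlet_transform(es) for es in epoch_sets]
    if config.stages.get("spectra", True):
        results["relative_ps"] = [relative_power(wc) for wc in wavelets]
        _stage("spectra")

    if config.stages.get("connectivity", True):
        cc = config.connectivity
        tensors = [fc_tensor(wc, metrics=tuple(cc["metrics"]),
                             n_epochs=cc["n_epochs"], n_reps=cc["n_reps"],
                             seed=config.seed + 17 * k)
                   for k, wc in enumerate(wavelets)]
        results["fc"] = tensors
        _stage("connectivity")

    if config.stages.get("stats", True) and "alpha" in results \
            and len(results["alpha"]) >= 10:
        adf = results["alpha"].merge(meta_df, on="id")
        stats_out = {}
        for measure, transform in (("r", "x4"), ("p_ec", "log"),
                                   ("f_p", "identity")):
            y = TRANSFORMS[transform](adf[measure].to_numpy())
            table = make_feature_table(adf, y)
            res = group_tests(table)
            fit2 = res.fits[1]
            stats_out[measure] = dict(
                p_mean=res.p_mean, p_var=res.p_var, d=res.cohens_d,
                transform=transform,
                group_age_coef=float(
                    fit2.beta[fit2.coef_names.index("group:age")]),
                f_tests=res.f_tests)
        results["alpha_stats"] = stats_out
        _stage("stats")

    if config.stages.get("cluster", True) and "fc" in results:
        cl = config.cluster
        tensors = results["fc"]
        metric = cl["metric"]
        vals = np.stack([t.metric(metric) for t in tensors])  # subj,L,F,C
        n_subj, n_links, n_freq, n_cond = vals.shape
        y = TRANSFORMS["x0.11"](np.maximum(vals, 0.0)).reshape(n_subj, -1)
        pos = channel_positions(tensors[0].channels)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        ch_adj = (d > 0) & (d <= cl["adjacency_radius"])
        la = link_adjacency(ch_adj, tensors[0].links)
        graph = feature_graph(la, n_freq, n_cond)
        node_test = (lme_node_pvalues if cl.get("node_test") == "lme"
                     else ols_node_pvalues)
        cres = permutation_test(y, meta_df, graph, n_perm=cl["n_perm"],
                                seed=config.seed + 101, stat=cl["stat"],
                                alpha=cl["alpha"], node_test=node_test)
        results["cluster"] = cres
        results["cluster_layout"] = dict(links=tensors[0].links,
                                         n_freqs=n_freq, n_conditions=n_cond)
        _stage("cluster")

    if config.stages.get("classify", False) and "fc" in results:
        cf = config.classify
        tensors = results["fc"]
        feats = np.stack([t.values.reshape(-1) for t in tensors])
        resid = classify_mod.residualize(feats, meta_df)
        scores, _ = classify_mod.pca_reduce(resid)
        labels = (meta_df["group"] == "ASD").astype(int).to_numpy()
        results["classifier"] = classify_mod.evaluate_models(
            scores, labels, cf["model_id"], n_splits=cf["n_splits"],
            cv=cf["cv"], seed=config.seed)
        _stage("classify")

    if config.stages.get("split", True):
        from .replication import stratified_split

        results["split"] = stratified_split(meta_df, seed=config.seed)
        _stage("split")

    results["manifest"]["total_seconds"] = time.time() - t_all
    if out_dir is not None:
        _write_outputs(Path(out_dir), config, results)
    return results


def _write_outputs(out_dir: Path, config: RunConfig, results: dict) -> None:
    from .io import write_json

    out_dir.mkdir(parents=True, exist_ok=True)
    results["meta"].to_csv(out_dir / "covariates.tsv", sep="\t", index=False)
    if "alpha" in results:
        results["alpha"].to_csv(out_dir / "alpha_summary.tsv", sep="\t",
                                index=False)
    if "alpha_stats" in results:
        write_json(out_dir / "alpha_stats.json", results["alpha_stats"])
    if "cluster" in results:
        c = results["cluster"]
        write_json(out_dir / "clusters.json", {
            "sizes": c.sizes, "p": c.p,
            "members": [m for m in c.clusters],
            "null_max_sizes": c.null_max_sizes})
    if "classifier" in results:
        write_json(out_dir / "classifier.json",
                   results["classifier"].to_dict())
    if "split" in results:
        results["split"].assignment.rename("part").to_csv(
            out_dir / "split.tsv", sep="\t")
    write_json(out_dir / "manifest.json",
               {**results["manifest"], "config": config.to_dict()})
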