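"""End-to-end pipeline: curation -> clustering -> laminar -> tuning -> ISI ->
propagation -> connectivity, with deterministic stage tables.

``run_pipeline`` takes a config (dict or YAML path) naming either a
synthetic population recipe or an existing phy-style session directory,
runs the stages in order, and writes one TSV per stage plus a machine-
readable run log (parameters, seed, per-table digests) under the output
directory.  Identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import connectivity as conn
from . import io as wio
from . import isi as wisi
from . import laminar as lam
from . import propagation as prop
from . import qc
from . import synthetic as syn
from . import tuning as tun

__all__ = ["default_pipeline_config", "run_pipeline"]

_KNOWN_KEYS = {"seed", "synthetic", "input_dir", "qc", "cluster", "tuning",
               "isi", "propagation", "connectivity"}


def default_pipeline_config() -> dict:
    """Default study configuration: the six-class synthetic population."""
    return {
        "seed": 0,
        "synthetic": {
            "units_per_class": 25,
            "train_duration_s": 240.0,
            "trials_per_condition": 5,
            "template_noise_sd_uv": 2.0,
        },
        "qc": {"snr_min": 3.0},
        "cluster": {"n_neighbors": 20, "min_dist": 0.2, "resolution": 1.0},
        "connectivity": {"n_sample_pairs": 20, "n_jitter": 200, "min_spikes": 500},
    }


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate_config(config: dict):
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "synthetic" not in config and "input_dir" not in config:
        raise ValueError("config must name either 'synthetic' or 'input_dir'")


def run_pipeline(config=None, out_dir="results/pipeline", seed: Optional[int] = None) -> Path:
    """Run all stages and return the output directory.

    Any stage failure is re-raised naming the stage.  ``seed`` overrides the
    config seed when given.
    """
    if config is None:
        config = default_pipeline_config()
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    _validate_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    log = {"seed": seed, "config": json.loads(json.dumps(config, default=str)),
           "versions": {"wavepipe": __version__, "numpy": np.__version__,
                        "pandas": pd.__version__},
           "stages": {}}
    stage = "simulate"
    try:
        if "synthetic" in config:
            scfg = dict(config["synthetic"])
            session = syn.build_population(syn.default_config(**scfg), seed=seed)
            duration_s = session.config.train_duration_s
            protocol = session.config.protocol
            templates = [u.template for u in session.units]
            trains = {u.unit_id: u.spike_times_s for u in session.units}
            trials = session.trials
            boundary_edges = np.asarray(session.config.layer_edges_um, dtype=float)
            layer_names = session.config.layer_names
            truth = session.ground_truth
            coupled = [(e.source, e.target) for e in session.config.coupling]
            noise_sd = session.config.template_noise_sd_uv or None
        else:
            bundle = wio.read_sorted_session(config["input_dir"])
            session = None
            templates = bundle.templates
            trains = bundle.spike_trains
            trials = bundle.trials
            truth = bundle.ground_truth
            b = bundle.boundaries
            layer_names = tuple(b["layer"])
            boundary_edges = b["top_um"].to_numpy(dtype=float)
            duration_s = float(bundle.provenance.get("train_duration_s", 0)) or None
            protocol = syn.StimulusProtocol()
            coupled = []
            noise_sd = None

        stage = "qc"
        units = qc.curate(templates, snr_min=config.get("qc", {}).get("snr_min", 3.0),
                          residual_noise_sd=noise_sd, spike_times=trains)
        qc_df = pd.DataFrame(
            dict(
                unit_id=[u.unit_id for u in units],
                polarity=[u.polarity for u in units],
                n_phases=[u.n_phases for u in units],
                amplitude_uv=[u.amplitude_uv for u in units],
                snr=[u.snr for u in units],
                duration_ms=[u.duration_ms for u in units],
                depth_um=[u.depth_um for u in units],
            )
        )
        _write_tsv(qc_df, out / "qc_units.tsv")

        stage = "cluster"
        ccfg = config.get("cluster", {})
        negatives = [u for u in units if u.polarity == "negative"]
        W = np.vstack([u.waveform_norm for u in negatives])
        result = cl.wavemap(
            W,
            n_neighbors=ccfg.get("n_neighbors", 20),
            min_dist=ccfg.get("min_dist", 0.2),
            resolution=ccfg.get("resolution", 1.0),
            seed=seed,
        )
        names = cl.name_clusters(
            result.labels,
            [u.duration_ms for u in negatives],
            [u.n_phases for u in negatives],
        )
        cluster_df = pd.DataFrame(
            dict(
                unit_id=[u.unit_id for u in negatives],
                cluster=result.labels,
                cluster_name=[names[c] for c in result.labels],
                embedding_x=result.embedding_2d[:, 0],
                embedding_y=result.embedding_2d[:, 1],
            )
        )
        _write_tsv(cluster_df, out / "cluster_assignments.tsv")
        log["stages"]["cluster"] = {
            "modularity_q": result.modularity_q,
            "n_clusters": int(np.unique(result.labels).size),
        }
        cluster_of = dict(zip(cluster_df["unit_id"], cluster_df["cluster_name"]))

        stage = "laminar"
        model = lam.LayerModel.from_sessions(
            {"s0": boundary_edges}, layer_names=layer_names
        )
        lam_rows = []
        for u in units:
            scaled = lam.scale_depth(u.depth_um, boundary_edges, model.average_edges)
            u.layer = lam.assign_layer(scaled, model)
            lam_rows.append((u.unit_id, u.depth_um, scaled, u.layer))
        lam_df = pd.DataFrame(
            lam_rows, columns=["unit_id", "depth_um", "scaled_depth_um", "layer"]
        )
        _write_tsv(lam_df, out / "laminar.tsv")
        layer_of = dict(zip(lam_df["unit_id"], lam_df["layer"]))
        clustered = [u for u in negatives if u.unit_id in cluster_of]
        enr_rows = []
        rng_enr = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        labels_arr = np.array([cluster_of[u.unit_id] for u in clustered])
        layers_arr = np.array([layer_of[u.unit_id] for u in clustered])
        for cname in sorted(set(labels_arr)):
            res = lam.enrichment_shuffle_test(
                labels_arr, layers_arr, cname, ["L4a/4b", "L4c"],
                n_shuffles=1000, seed=rng_enr,
            )
            enr_rows.append((cname, res.observed, res.percentile, res.flag, res.p_value))
        _write_tsv(
            pd.DataFrame(enr_rows, columns=["cluster", "frac_in_L4", "percentile",
                                            "flag", "p"]),
            out / "layer_enrichment.tsv",
        )

        stage = "tuning"
        tun_rows = []
        for u in units:
            sub = trials[trials["unit_id"] == u.unit_id]
            if not len(sub):
                continue
            curve = tun.compute_tuning_curve(
                sub, protocol.trial_duration_s, protocol.baseline_duration_s
            )
            best_sf = sub.groupby("spatial_frequency")["stimulus_count"].mean().idxmax()
            at_best = sub[sub["spatial_frequency"] == best_sf]
            responsive, p = tun.responsiveness(
                at_best["stimulus_count"], at_best["baseline_count"],
                protocol.trial_duration_s, protocol.baseline_duration_s,
            )
            u.visually_responsive = responsive
            tun_rows.append(
                (u.unit_id, curve.preferred_direction_deg, curve.baseline_hz,
                 curve.dsi, curve.osi, responsive, p)
            )
        tun_df = pd.DataFrame(
            tun_rows,
            columns=["unit_id", "preferred_direction_deg", "baseline_hz",
                     "dsi", "osi", "visually_responsive", "p_responsive"],
        )
        _write_tsv(tun_df, out / "tuning.tsv")

        stage = "isi"
        profiles, kept = [], []
        for u in units:
            try:
                profiles.append(wisi.isi_histogram(u.spike_times_s))
                kept.append(u.unit_id)
            except wisi.InsufficientSpikesError:
                continue
        pca_res = wisi.isi_pca(np.vstack(profiles))
        bidx = wisi.bursting_index(pca_res.loadings)
        isi_df = pd.DataFrame(
            dict(
                unit_id=kept,
                pc1=pca_res.loadings[:, 0],
                pc2=pca_res.loadings[:, 1],
                pc3=pca_res.loadings[:, 2],
                bursting_index=np.atleast_1d(bidx),
            )
        )
        _write_tsv(isi_df, out / "isi_bursting.tsv")

        stage = "propagation"
        prop_unit_rows, cluster_profiles = [], {}
        tpl_of = {t.unit_id: t for t in templates}
        for u in negatives:
            if u.unit_id not in cluster_of or u.unit_id not in tpl_of:
                continue
            profile = prop.unit_profile(tpl_of[u.unit_id])
            cname = cluster_of[u.unit_id]
            cluster_profiles.setdefault(cname, []).append(profile)
            prop_unit_rows.append(
                (u.unit_id, cname, profile.slope_above, profile.slope_below,
                 profile.asymmetry)
            )
        _write_tsv(
            pd.DataFrame(prop_unit_rows, columns=["unit_id", "cluster", "slope_above",
                                                  "slope_below", "asymmetry"]),
            out / "propagation_units.tsv",
        )
        prop_rows = []
        for i, (cname, profs) in enumerate(sorted(cluster_profiles.items())):
            boot = prop.bootstrap_slope_tests(
                profs, n_boot=500, seed=np.random.default_rng(np.random.SeedSequence([seed, 2, i]))
            )
            prop_rows.append(
                (cname, len(profs), boot.slope_above, boot.slope_below,
                 boot.asymmetry, boot.se_above, boot.se_below, boot.se_asymmetry,
                 boot.ci_below_95[0], boot.ci_below_95[1], boot.below_excludes_zero)
            )
        _write_tsv(
            pd.DataFrame(
                prop_rows,
                columns=["cluster", "n_units", "slope_above", "slope_below",
                         "asymmetry", "se_above", "se_below", "se_asymmetry",
                         "ci_below_lo", "ci_below_hi", "below_excludes_zero"],
            ),
            out / "propagation_clusters.tsv",
        )

        stage = "connectivity"
        ncfg = config.get("connectivity", {})
        min_spikes = ncfg.get("min_spikes", 500)
        eligible = [u.unit_id for u in negatives
                    if u.unit_id in cluster_of and trains[u.unit_id].size >= min_spikes]
        rng_pairs = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        pairs = [p for p in coupled
                 if p[0] in eligible and p[1] in eligible]
        want = ncfg.get("n_sample_pairs", 20)
        guard = 0
        while len(pairs) < want + len(coupled) and guard < 10 * want:
            i, j = rng_pairs.choice(len(eligible), size=2, replace=False)
            cand = (eligible[i], eligible[j])
            if cand not in pairs:
                pairs.append(cand)
            guard += 1
        records, rec_rows = [], []
        for k, (a, b) in enumerate(pairs):
            rec = conn.analyze_pair(
                trains[a], trains[b],
                seed=np.random.default_rng(np.random.SeedSequence([seed, 4, k])),
                duration_s=duration_s,
                n_jitter=ncfg.get("n_jitter", 200),
                min_spikes=min_spikes,
                reference_unit=a, target_unit=b,
                reference_cluster=cluster_of.get(a), target_cluster=cluster_of.get(b),
                reference_layer=layer_of.get(a), target_layer=layer_of.get(b),
            )
            records.append(rec)
            rec_rows.append(
                (a, b, rec.reference_cluster, rec.target_cluster,
                 rec.reference_layer, rec.target_layer, rec.significant,
                 rec.peak_lag_ms, rec.peak_width_ms, rec.lead_lag_index)
            )
        _write_tsv(
            pd.DataFrame(
                rec_rows,
                columns=["reference_unit", "target_unit", "reference_cluster",
                         "target_cluster", "reference_layer", "target_layer",
                         "significant", "peak_lag_ms", "peak_width_ms", "lli"],
            ),
            out / "ccg_records.tsv",
        )
        median, pvals, counts, edges = conn.pairwise_summary(records)
        median.to_csv(out / "lli_matrix.tsv", sep="\t", float_format="%.10g")
        _write_tsv(edges, out / "network_edges.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for tsv in sorted(out.glob("*.tsv")):
        log["stages"].setdefault("digests", {})[tsv.name] = _digest(tsv)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
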