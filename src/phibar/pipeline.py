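"""End-to-end orchestration: ingest -> preprocess -> phi -> networks -> descriptors.

A run is described by a single YAML/dict config.  Sample units are drawn
once, from the baseline state, and reused across every state and band; all
stage seeds derive deterministically from the master seed.  The phi stage
(the long pole) caches its per-(state, band) output keyed by a content hash
of the relevant config, so re-runs over a grid are incremental.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .io import (ConfigurationError, EpochSet, Montage, ResultTable,
                 apply_channel_exclusion, bundled_exclusion_32, load_montage,
                 read_recording, write_results)
from .preprocess import (BANDS, average_reference, bandpass_fir,
                         relative_band_power, segment_epochs)
from .phi import PhiBarModel, SampleUnitSet, draw_sample_units
from .connectivity import WpliNetwork
from .statespace import StateMetrics, build_descriptor

logger = logging.getLogger(__name__)

DEFAULTS = {
    "epoch_seconds": 6.0,
    "n_epochs": 20,
    "baseline": "baseline",
    "bands": ["alpha"],
    "baseline_blocks": 4,
    "phi": {"n": 8, "k": 600, "tau": 1, "estimator": "ar", "n_surrogates": 20,
            "k_regional": 30, "normalize_mip": False, "ridge": 1e-8},
    "conn": {"threshold": 0.35, "n_surrogates": 20, "long_range_cm": 9.0,
             "window_seconds": 3.0, "overlap": 0.5},
    "seed": 0,
    "subject": "S01",
}


def stage_seed(master: int, *context) -> int:
    """Deterministic per-stage seed: master seed + CRC of the context strings."""
    import zlib
    tag = zlib.crc32("/".join(str(c) for c in context).encode())
    return int(np.random.SeedSequence([int(master), tag]).generate_state(1)[0] % 2**31)


def _merged(config: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULTS))
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _config_hash(cfg: dict, *keys) -> str:
    sub = {k: cfg[k] for k in keys if k in cfg}
    return hashlib.sha256(json.dumps(sub, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        return _merged(yaml.safe_load(fh))


def _ingest(cfg: dict) -> dict[str, "np.ndarray"]:
    states = cfg.get("states")
    if not states:
        raise ConfigurationError("config must define 'states'")
    if cfg["baseline"] not in states:
        raise ConfigurationError(f"baseline state {cfg['baseline']!r} missing from states")
    recs = {}
    for state, entry in states.items():
        rec = read_recording(entry["path"], entry.get("format"), entry.get("fs"))
        rec.state_label = state
        if cfg.get("exclusion"):
            excl = (bundled_exclusion_32() if cfg["exclusion"] == "bundled"
                    else [l.strip() for l in Path(cfg["exclusion"]).read_text().splitlines()
                          if l.strip()])
            rec = apply_channel_exclusion(rec, excl)
        recs[state] = rec
    return recs


def _preprocessed(cfg: dict, recs: dict) -> dict[tuple[str, str], EpochSet]:
    out = {}
    for state, rec in recs.items():
        ref = average_reference(rec)
        for band in cfg["bands"]:
            filt = bandpass_fir(ref, BANDS[band])
            eps = segment_epochs(filt, cfg["epoch_seconds"], cfg["n_epochs"])
            eps.band = band
            out[(state, band)] = eps
    return out


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full pipeline; returns a dict of result paths and tables."""
    cfg = _merged(config)
    out_dir = Path(out_dir or cfg.get("out_dir", "phibar_results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    cache_dir = out_dir / "cache"
    cache_dir.mkdir(exist_ok=True)
    seed = int(cfg["seed"])
    subject = cfg["subject"]
    baseline = cfg["baseline"]

    recs = _ingest(cfg)
    montage = load_montage(cfg["montage"]) if cfg.get("montage") else None
    epochs = _preprocessed(cfg, recs)

    table = ResultTable()
    # spectral power on the broadband (unfiltered-band) signal per state
    for state, rec in recs.items():
        eps = segment_epochs(average_reference(rec), cfg["epoch_seconds"], cfg["n_epochs"])
        try:
            rp = relative_band_power(eps)
        except ConfigurationError:
            rp = None
        if rp is not None:
            for ch, row in rp.iterrows():
                for band, val in row.items():
                    table.add(subject, state, band, "rel_power", val, channel=ch)

    pool = epochs[(baseline, cfg["bands"][0])].n_channels
    units = draw_sample_units(pool, cfg["phi"]["n"], cfg["phi"]["k"],
                              seed=stage_seed(seed, "units", baseline))

    phi_hash = _config_hash(cfg, "phi", "epoch_seconds", "n_epochs", "seed", "bands")
    metrics: dict[str, dict[str, StateMetrics]] = {b: {} for b in cfg["bands"]}
    for (state, band), eps in epochs.items():
        cache = cache_dir / f"phi_{state}_{band}_{phi_hash}.json"
        if cache.exists():
            payload = json.loads(cache.read_text())
            logger.info("phi stage cached for %s/%s", state, band)
        else:
            payload = _phi_stage(cfg, eps, units, seed, state, band)
            cache.write_text(json.dumps(payload, sort_keys=True))
        net = _conn_stage(cfg, eps, montage, seed, state, band)
        table.add(subject, state, band, "phi_bar", payload["phi_bar"])
        table.add(subject, state, band, "phi_bar_mean", payload["mean_phi"])
        table.add(subject, state, band, "phi_bar_surrogate", payload["surrogate_median_mean"])
        for ch, v in zip(eps.channel_labels, payload["regional"]):
            table.add(subject, state, band, "phi_regional", v, channel=ch)
        table.add(subject, state, band, "avg_degree", net.metrics.average_degree)
        table.add(subject, state, band, "n_modules", net.modules.n_modules)
        table.add(subject, state, band, "modularity_q", net.modules.Q)
        for ch, v in zip(eps.channel_labels, net.metrics.degrees):
            table.add(subject, state, band, "wpli_degree", v, channel=ch)
        if net.metrics.long_range_degrees is not None:
            for ch, v in zip(eps.channel_labels, net.metrics.long_range_degrees):
                table.add(subject, state, band, "long_range_degree", v, channel=ch)
        metrics[band][state] = StateMetrics(
            phi_bar=payload["phi_bar"], avg_degree=net.metrics.average_degree,
            phi_map=np.asarray(payload["regional"]),
            degree_map=net.metrics.degrees.astype(float),
            phi_bar_samples=np.asarray(payload["block_phi_bar"]),
            degree_samples=None,
        )

    for band, by_state in metrics.items():
        descs = build_descriptor(by_state, baseline,
                                 provenance={"band": band, "tau": cfg["phi"]["tau"],
                                             "seed": seed})
        for d in descs:
            table.add(subject, d.state, band, "rel_phi", d.rel_phi)
            table.add(subject, d.state, band, "rel_degree", d.rel_degree)
            table.add(subject, d.state, band, "sim_phi_topo", d.sim_phi_topo)
            table.add(subject, d.state, band, "sim_degree_topo", d.sim_degree_topo)
            table.add(subject, d.state, band, "descriptor_area", d.area)

    run_info = {"config": cfg, "version": __version__, "seed": seed}
    paths = write_results(table, out_dir, run_info)
    return {"paths": [str(p) for p in paths], "table": table}


def _phi_stage(cfg, eps, units: SampleUnitSet, seed, state, band) -> dict:
    p = cfg["phi"]
    model = PhiBarModel(eps, n=p["n"], k=p["k"], tau=p["tau"], estimator=p["estimator"],
                        n_surrogates=p["n_surrogates"], normalize_mip=p["normalize_mip"],
                        ridge=p["ridge"], seed=stage_seed(seed, "phi_surr", state, band))
    res = model.fit(units=units)
    regional = model.regional(units_per_channel=p["k_regional"],
                              seed=stage_seed(seed, "regional", state, band))
    # per-block phi_bar values give the baseline min/max range for descriptors
    nb = max(2, int(cfg["baseline_blocks"]))
    blocks = np.array_split(np.arange(eps.n_epochs), nb)
    block_vals = []
    for bi, idx in enumerate(blocks):
        if len(idx) == 0:
            continue
        sub = EpochSet([eps.epochs[i] for i in idx], eps.epoch_length, eps.band)
        bm = PhiBarModel(sub, n=p["n"], k=p["k"], tau=p["tau"], estimator=p["estimator"],
                         n_surrogates=p["n_surrogates"], ridge=p["ridge"],
                         seed=stage_seed(seed, "phi_surr_block", state, band, bi))
        block_vals.append(bm.fit(units=units).phi_bar)
    return {"phi_bar": res.phi_bar, "mean_phi": res.mean_phi,
            "surrogate_median_mean": res.surrogate_median_mean,
            "regional": [float(v) for v in regional.values],
            "block_phi_bar": block_vals}


def _conn_stage(cfg, eps, montage: Montage | None, seed, state, band):
    c = cfg["conn"]
    net = WpliNetwork(eps, band=band, montage=montage, threshold=c["threshold"],
                      n_surrogates=c["n_surrogates"], long_range_cm=c["long_range_cm"],
                      window_seconds=c["window_seconds"], overlap=c["overlap"],
                      seed=stage_seed(seed, "conn_surr", state, band))
    return net.fit()
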