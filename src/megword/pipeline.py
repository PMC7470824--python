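"""End-to-end orchestration: simulate -> features -> decode -> neurobehav -> stats -> rsa.

``run_full`` executes the whole analysis on simulated data with a single
top-level seed, from which every stage deterministically derives its own
stream, so repeated runs with the same config are bit-identical.  Outputs are
TSV/JSON files stamped with the config hash and seed; stage timings go to the
log (stderr and ``run.log``), not to the data files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decode, features, neurobehav, rsa, stats, synthgen

__all__ = ["RunConfig", "run_full"]

logger = logging.getLogger("megword")


@dataclass
class RunConfig:
    """Generator plus analysis settings for a full seeded run."""

    generator: synthgen.GeneratorConfig = field(default_factory=synthgen.GeneratorConfig)
    radius_mm: float = 12.0
    window_ms: float = 500.0
    bin_ms: float = 20.0
    fwhm_mm: float = 3.0
    n_perm: int = 200
    min_cluster_size: int = 10
    first_level_percentile: float = 99.95
    alpha: float = 0.05
    ceiling_threshold: float = 0.95
    lam: float = 1.0
    n_subsets: int = 50
    bf_scale: float = 0.707
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.radius_mm < 0 or self.fwhm_mm < 0:
            raise ValueError("radius_mm and fwhm_mm must be non-negative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        # fail early on inconsistent windowing
        _ = self.generator.window_samples

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("active_region", "relevant_region"):
            if d["generator"][key] is not None:
                d["generator"][key] = [int(v) for v in np.asarray(d["generator"][key])]
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        gen = d.pop("generator")
        for key in ("active_region", "relevant_region"):
            if gen.get(key) is not None:
                gen[key] = np.asarray(gen[key], dtype=int)
        return cls(generator=synthgen.GeneratorConfig(**gen), **d)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific settings (the output location is excluded)."""
        d = json.loads(self.to_json())
        d.pop("out_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _stamp(path: Path, df: pd.DataFrame, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_json(path: Path, payload: dict, cfg: RunConfig) -> None:
    payload = {"config_hash": cfg.config_hash, "seed": cfg.seed, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def _cluster_payload(clusters: list[stats.ClusterResult]) -> list[dict]:
    return [
        {
            "members": [int(m) for m in c.members],
            "t_sum": float(c.t_sum),
            "p": float(c.p),
            "peak": int(c.peak),
            "size": int(c.size),
        }
        for c in clusters
    ]


def run_full(config: RunConfig) -> dict:
    """Run every stage in order on synthetic data and return the report.

    Any stage failure is re-raised with the stage name attached.  When
    ``config.out_dir`` is set, all report tables are written there.
    """
    gen = config.generator
    report: dict = {"seed": config.seed, "config_hash": config.config_hash}
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
    ss = np.random.SeedSequence(config.seed)
    (s_sim, s_behav, s_feat, s_decode, s_neuro, s_rsa) = [
        int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(6)
    ]

    stage = "setup"
    t0 = time.perf_counter()
    try:
        grid = synthgen.make_grid(gen.grid_spacing, gen.grid_extent)
        sls = features.build_searchlights(grid, config.radius_mm)
        adjacency = stats.grid_adjacency(grid)
        mirror = features.mirror_index(grid)
        inventory = synthgen.generate_word_features(gen, seed=s_feat)
        smooth_w = (
            features.smoothing_weights(grid, config.fwhm_mm)
            if config.fwhm_mm > 0
            else None
        )
        logger.info("setup: %d grid points, %.2fs", grid.n_points, time.perf_counter() - t0)

        stage = "simulate"
        t0 = time.perf_counter()
        sim_rng = np.random.default_rng(s_sim)
        behav_rng = np.random.default_rng(s_behav)
        participants = []
        for i in range(gen.n_participants):
            trials = synthgen.generate_trials(
                gen, grid, seed=int(sim_rng.integers(2**31))
            )
            d_true = synthgen.ground_truth_distance(gen, grid, trials)
            behaviour = synthgen.generate_behaviour(
                gen, trials, d_true, seed=int(behav_rng.integers(2**31))
            )
            participants.append((trials, behaviour))
        report["n_participants"] = gen.n_participants
        report["mean_accuracy"] = float(
            np.mean([b["accuracy"].mean() for _, b in participants])
        )
        logger.info("simulate: %.2fs", time.perf_counter() - t0)

        stage = "features+decode"
        t0 = time.perf_counter()
        dec_rng = np.random.default_rng(s_decode)
        conditions = list(range(gen.n_conditions))
        perf = {c: [] for c in conditions}
        perm_perf = {c: [] for c in conditions}
        dists = {c: [] for c in conditions}
        accs = {c: [] for c in conditions}
        cats = {c: [] for c in conditions}
        cross_maps = []
        for trials, behaviour in participants:
            if smooth_w is not None:
                trials = dataclasses.replace(
                    trials,
                    activity=np.einsum("qp,npt->nqt", smooth_w, trials.activity),
                )
            trials = features.zscore_trials(trials)
            feats = features.extract_word_window(
                trials, sls, window_ms=config.window_ms, bin_ms=config.bin_ms
            )
            cond_feats = {}
            for c in conditions:
                mask = trials.conditions == c
                sub = features.FeatureTensor(
                    binned=feats.binned[mask],
                    searchlights=sls,
                    bin_ms=config.bin_ms,
                    window_ms=config.window_ms,
                )
                cond_feats[c] = (sub, mask)
                n_c = int(mask.sum())
                perms = np.stack(
                    [dec_rng.permutation(n_c) for _ in range(config.n_perm)]
                )
                res = decode.decode_full(
                    sub,
                    trials.words[mask],
                    trials.candidates[mask],
                    trials.categories[mask],
                    permutations=perms,
                )
                perf[c].append(res.classification.performance)
                perm_perf[c].append(res.perm_performance)
                dists[c].append(res.distances.d)
                accs[c].append(behaviour["accuracy"].to_numpy()[mask])
                cats[c].append(trials.categories[mask])
            if len(conditions) >= 2:
                (f0, m0), (f1, m1) = cond_feats[0], cond_feats[1]
                cross = decode.cross_classify(
                    f0,
                    trials.words[m0],
                    trials.candidates[m0],
                    f1,
                    trials.words[m1],
                    trials.categories[m0],
                )
                cross_maps.append(cross.performance)
        logger.info("features+decode: %.2fs", time.perf_counter() - t0)

        stage = "stats-classification"
        t0 = time.perf_counter()
        class_clusters = {}
        lateralisation = {}
        for c in conditions:
            maps = np.stack(perf[c])
            pmaps = np.stack(perm_perf[c], axis=1)  # (n_perm, n_part, P)
            clusters = stats.cluster_perm_classification(
                maps,
                pmaps,
                adjacency,
                min_size=config.min_cluster_size,
                percentile=config.first_level_percentile,
            )
            class_clusters[c] = clusters
            lateralisation[c] = stats.lateralisation_test(maps, clusters, mirror)
        bayes_map = None
        if len(conditions) >= 2:
            diff = np.stack(perf[0]) - np.stack(perf[1])
            sd = diff.std(axis=0, ddof=1)
            tvals = np.divide(
                diff.mean(axis=0),
                sd / np.sqrt(diff.shape[0]),
                out=np.zeros(diff.shape[1]),
                where=sd > 0,
            )
            bayes_map = np.array(
                [
                    stats.jzs_bf_ttest(t, diff.shape[0], scale=config.bf_scale).bf10
                    for t in tvals
                ]
            )
        logger.info("stats-classification: %.2fs", time.perf_counter() - t0)

        stage = "neurobehav"
        t0 = time.perf_counter()
        neuro_rng = np.random.default_rng(s_neuro)
        neuro = {}
        for c in conditions:
            kept, excluded = neurobehav.exclude_ceiling(
                dict(enumerate(accs[c])), threshold=config.ceiling_threshold
            )
            betas, t_obs, t_perms = neurobehav.neurobehavioural_t_maps(
                [dists[c][i] for i in kept],
                [accs[c][i] for i in kept],
                [cats[c][i] for i in kept],
                n_perm=config.n_perm,
                n_subsets=config.n_subsets,
                lam=config.lam,
                rng=neuro_rng,
            )
            flt = stats.critical_t(len(kept), config.alpha)
            clusters = stats.cluster_perm_t(
                t_obs, t_perms, adjacency, first_level_t=flt,
                min_size=config.min_cluster_size,
            )
            relation = neurobehav.classification_vs_relevance(
                np.stack([perf[c][i] for i in kept]), betas, bf_scale=config.bf_scale
            )
            neuro[c] = {
                "kept": kept,
                "excluded": excluded,
                "betas": betas,
                "t_obs": t_obs,
                "first_level_t": flt,
                "clusters": clusters,
                "relation": relation,
            }
        logger.info("neurobehav: %.2fs", time.perf_counter() - t0)

        stage = "rsa"
        t0 = time.perf_counter()
        words_per_cat = gen.n_words // gen.n_categories
        z_phon, z_sem = [], []
        for trials, behaviour in participants:
            zp, zs = [], []
            for cat in range(gen.n_categories):
                cat_words = list(
                    range(cat * words_per_cat, (cat + 1) * words_per_cat)
                )
                mask = trials.categories == cat
                try:
                    brdm = rsa.behavioural_rdm(
                        trials.words[mask],
                        behaviour["response"].to_numpy()[mask],
                        trials.candidates[mask],
                        labels=cat_words,
                    )
                    prdm = rsa.phonological_rdm(
                        [inventory.phonemes[w] for w in cat_words], labels=cat_words
                    )
                    srdm = rsa.semantic_rdm(
                        inventory.vectors[cat_words], labels=cat_words
                    )
                    zp.append(rsa.compare_rdms(brdm, prdm)[1])
                    zs.append(rsa.compare_rdms(brdm, srdm)[1])
                except ValueError:
                    continue  # degenerate (e.g. error-free) category
            z_phon.append(np.mean(zp) if zp else np.nan)
            z_sem.append(np.mean(zs) if zs else np.nan)
        logger.info("rsa: %.2fs", time.perf_counter() - t0)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        if out is not None:
            logger.removeHandler(handler)
            handler.close()

    report["classification"] = {
        str(c): {
            "group_mean_peak": float(np.stack(perf[c]).mean(axis=0).max()),
            "clusters": _cluster_payload(class_clusters[c]),
            "lateralisation": lateralisation[c],
        }
        for c in conditions
    }
    if cross_maps:
        report["cross_classification_mean"] = float(np.mean(cross_maps))
    report["neurobehav"] = {
        str(c): {
            "excluded": [int(i) for i in neuro[c]["excluded"]],
            "first_level_t": float(neuro[c]["first_level_t"]),
            "clusters": _cluster_payload(neuro[c]["clusters"]),
            "relation": {
                "t": neuro[c]["relation"].t,
                "p": neuro[c]["relation"].p,
                "bf10": neuro[c]["relation"].bf.bf10,
                "verdict": neuro[c]["relation"].bf.verdict,
            },
        }
        for c in conditions
    }
    report["rsa"] = {
        "z_phonological": [float(z) for z in z_phon],
        "z_semantic": [float(z) for z in z_sem],
        "mean_z_phonological": float(np.nanmean(z_phon)),
        "mean_z_semantic": float(np.nanmean(z_sem)),
    }

    if out is not None:
        _stamp(out / "grid.tsv", grid.to_frame(), config)
        rows = []
        for c in conditions:
            for i, pm in enumerate(perf[c]):
                rows.append(
                    pd.DataFrame(
                        {
                            "participant": i,
                            "condition": c,
                            "grid_point": np.arange(pm.size),
                            "performance": pm,
                        }
                    )
                )
        _stamp(out / "classification_map.tsv", pd.concat(rows, ignore_index=True), config)
        beta_rows = []
        t_rows = []
        for c in conditions:
            for k, i in enumerate(neuro[c]["kept"]):
                beta_rows.append(
                    pd.DataFrame(
                        {
                            "participant": i,
                            "condition": c,
                            "grid_point": np.arange(neuro[c]["betas"].shape[1]),
                            "beta": neuro[c]["betas"][k],
                        }
                    )
                )
            t_rows.append(
                pd.DataFrame(
                    {
                        "condition": c,
                        "grid_point": np.arange(neuro[c]["t_obs"].size),
                        "t": neuro[c]["t_obs"],
                    }
                )
            )
        _stamp(out / "betas.tsv", pd.concat(beta_rows, ignore_index=True), config)
        _stamp(out / "group_t.tsv", pd.concat(t_rows, ignore_index=True), config)
        if bayes_map is not None:
            _stamp(
                out / "bayes_map.tsv",
                pd.DataFrame(
                    {"grid_point": np.arange(bayes_map.size), "bf10": bayes_map}
                ),
                config,
            )
        _write_json(
            out / "clusters.json",
            {
                "classification": {
                    str(c): _cluster_payload(class_clusters[c]) for c in conditions
                },
                "neurobehav": {
                    str(c): _cluster_payload(neuro[c]["clusters"]) for c in conditions
                },
            },
            config,
        )
        _write_json(out / "report.json", report, config)

    return report
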