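"""End-to-end pipeline driver over a synthetic session.

Runs the full chain — simulate, detect and track assemblies, classify
striatal units, cross-correlograms with theta-shift surrogates, light
rate scores, GLM train/score, behavior scores — and returns a report
bundle with a fixed key schema (missing analyses are explicitly ``None``,
never absent).  Every randomized stage consumes an independent, logged
substream of the master seed, so reruns with the same configuration are
numerically identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assemblies, behavior, celltypes, glm, synthetic, timing
from .core import SpikeTrainSet

logger = logging.getLogger(__name__)

REPORT_KEYS = (
    "seed",
    "session",
    "assemblies",
    "classification",
    "spike_timing",
    "rate_scores",
    "glm",
    "behavior",
)


@dataclass
class PipelineConfig:
    """Parameters of the demonstration pipeline.

    ``session`` configures the synthetic recording; the remaining fields
    carry the per-stage analysis parameters with the package defaults.
    """

    session: synthetic.SessionConfig = None
    seed: int = 0
    bin_width_s: float = assemblies.DEFAULT_BIN_WIDTH_S
    kernel_sd_s: float = assemblies.DEFAULT_KERNEL_SD_S
    step_s: float = assemblies.DEFAULT_STEP_S
    r_thres: float = assemblies.R_THRES
    n_surrogates: int = 200
    glm_family: str = "gaussian"
    train_fraction: float = 0.5
    out_dir: str = None

    def __post_init__(self):
        if self.session is None:
            ffi = [(62, 52, 1.0), (62, 53, 1.0)]
            coupling = [(0, 62, 4.0, 0.2), (1, 62, 4.0, 0.2), (2, 63, 5.0, 0.2)]
            asm = [
                (tuple(range(6 * k, 6 * k + 6)), 1.0, 0.8) for k in range(3)
            ]
            self.session = synthetic.SessionConfig(
                duration=300.0,
                n_pyr=40,
                n_msn=20,
                n_fsi=4,
                n_tan=4,
                assembly_spec=asm,
                coupling_spec=coupling,
                ffi_spec=ffi,
                light_epochs=[
                    (200.0, 250.0, {62: 0.1, 63: 1.0}),
                ],
                seed=self.seed,
            )
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def _stage_seed(master: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence((int(master), zlib.crc32(stage.encode())))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig = None) -> dict:
    """Execute the full synthetic-session -> analysis -> report chain."""
    cfg = config or PipelineConfig()
    report = {k: None for k in REPORT_KEYS}
    report["seed"] = cfg.seed
    stage = "simulate"
    try:
        # -- simulate ------------------------------------------------------
        logger.info("stage=simulate seed=%d", cfg.session.seed)
        spikes, cycles, position, waveforms, truth = synthetic.generate_session(
            cfg.session
        )
        scfg = cfg.session
        duration = scfg.duration
        split = cfg.train_fraction * duration
        report["session"] = {
            "duration_s": duration,
            "n_neurons": scfg.n_total,
            "n_pyr": scfg.n_pyr,
            "n_assemblies_embedded": len(scfg.assembly_spec),
        }

        # -- assemblies on the PYR ensemble, detected on the first part ----
        stage = "assemblies"
        seed_a = _stage_seed(cfg.seed, stage)
        logger.info("stage=assemblies seed=%d", seed_a)
        pyr = spikes.by_class("PYR")
        binned = assemblies.bin_and_zscore(pyr, (0.0, split), cfg.bin_width_s)
        n_pat = assemblies.count_significant_patterns(binned)
        patterns = (
            assemblies.extract_patterns(binned, n_pat, seed=seed_a) if n_pat else []
        )
        per_pattern = []
        for p in patterns:
            trace = assemblies.activation_strength(
                p, pyr, (split, duration), cfg.kernel_sd_s, cfg.step_s
            )
            peaks = assemblies.detect_activations(trace, cfg.r_thres)
            per_pattern.append(
                {
                    "members": sorted(p.members),
                    "mean_strength": float(trace.strength.mean()),
                    "activation_rate_hz": float(peaks.size / (duration - split)),
                }
            )
        report["assemblies"] = {
            "n_significant_patterns": n_pat,
            "patterns": per_pattern,
        }

        # -- striatal classification --------------------------------------
        stage = "classification"
        seed_c = _stage_seed(cfg.seed, stage)
        logger.info("stage=classification seed=%d", seed_c)
        nac_ids = waveforms["ids"]
        if len(nac_ids) >= 3:
            feats = {}
            for nid in nac_ids:
                try:
                    feats[nid] = celltypes.waveform_features(
                        waveforms["bank"][nid], waveforms["fs_hz"]
                    )
                except celltypes.FeatureUndefinedError:
                    logger.info("neuron %d unclassifiable", nid)
            rates = {nid: spikes.rate(nid, (0.0, duration)) for nid in feats}
            labels = celltypes.classify(feats, rates, seed=seed_c)
            n_correct = sum(
                labels.labels[i] == truth.true_classes[i] for i in labels.labels
            )
            report["classification"] = {
                "labels": {str(i): labels.labels[i] for i in sorted(labels.labels)},
                "agreement": labels.agreement,
                "truth_accuracy": n_correct / len(labels.labels),
            }

        # -- spike timing: CCG + surrogates for the coupled pairs ----------
        stage = "spike_timing"
        seed_t = _stage_seed(cfg.seed, stage)
        logger.info("stage=spike_timing seed=%d n_surrogates=%d", seed_t, cfg.n_surrogates)
        pairs = []
        for c in scfg.coupling_spec[:3]:
            ccg = timing.theta_shift_surrogates(
                spikes[c.pyr],
                spikes[c.fsi],
                cycles,
                n_surrogates=cfg.n_surrogates,
                seed=seed_t,
            )
            pairs.append(
                {
                    "pyr": c.pyr,
                    "fsi": c.fsi,
                    "latency_ms": c.latency_ms,
                    "short_latency_excess": ccg.exceeds_band((3.2, 8.0)),
                }
            )
        report["spike_timing"] = {"pairs": pairs} if pairs else None

        # -- light rate scores --------------------------------------------
        stage = "rate_scores"
        if scfg.light_epochs:
            on = [(e.start, e.stop) for e in scfg.light_epochs]
            t_on = sum(b - a for a, b in on)
            off = [(max(0.0, on[0][0] - t_on), on[0][0])]
            scores = {}
            for e in scfg.light_epochs:
                for nid in e.factors:
                    scores[str(nid)] = timing.light_rate_score(spikes[nid], on, off)
            report["rate_scores"] = scores
        # -- GLM: train on first half, score on second --------------------
        stage = "glm"
        if scfg.n_msn and scfg.n_pyr:
            counts = glm.bin_by_cycles(spikes, cycles)
            b = cycles.boundaries[counts.cycle_indices]
            train = b < split
            test = ~train
            pyr_ids = list(scfg.pyr_ids)
            X = counts.submatrix(pyr_ids)
            accs = []
            for msn in list(scfg.msn_ids)[:10]:
                y = counts.column(msn)
                model = glm.fit_ensemble_model(
                    y[train], X[train], pyr_ids, family=cfg.glm_family,
                    training_session="train-half",
                )
                accs.append(glm.predict_and_score(model, X[test], y[test]))
            report["glm"] = {
                "n_models": len(accs),
                "mean_test_r": float(np.nanmean(accs)) if accs else None,
            }

        # -- behavior ------------------------------------------------------
        stage = "behavior"
        geom = behavior.EnclosureGeometry.two_box_bridge()
        occ, _, _ = behavior.occupancy_map(position)
        report["behavior"] = {
            "preference_score": behavior.preference_score(position, geom, "A"),
            "occupancy_total_s": float(occ.sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
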