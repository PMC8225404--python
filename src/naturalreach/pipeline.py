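"""End-to-end orchestration of the analysis stages on a synthetic study.

A single master seed deterministically derives every stage seed through a
spawned seed tree; rerunning the same config writes byte-identical outputs.
Every stage directory carries a ``provenance.json`` with the config hash,
the master seed, and the stage name.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .events import annotate_events, detect_onsets, prune_events
from .features import compute_feature_table
from .groupstats import aggregate, bootstrap_baseline_mask, kruskal_wallis_bands
from .hsmm import SingularModelError, StateSequence, decode_states, fit_arhsmm
from .preprocess import preprocess
from .regression import regress_all
from .roi import compute_weights, mirror_electrodes, project_power
from .spectral import (baseline_subtract, compute_band_powers, extract_segments,
                       morlet_power, reject_bad_segments)
from .synthetic import SyntheticConfig, generate_study

ALL_STAGES = [
    "simulate", "segment", "detect-events", "preprocess", "spectral",
    "project", "group-stats", "features", "regress",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "synthetic": {"n_subjects": 2, "days": [1, 2, 3], "events_per_day": 100},
    "segment": {"max_iter": 20, "max_dwell": 300},
    "spectral": {"decim": 25},
    "project": {"fwhm": 20.0, "density_threshold": 3.0},
    "group_stats": {"n_boot": 2000, "alpha": 0.05},
    "regress": {"n_splits": 200, "test_frac": 0.1},
}


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def _provenance(stage_dir: Path, config: dict, stage: str) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "provenance.json").write_text(
        json.dumps(
            {"stage": stage, "config_hash": config_hash(config), "seed": config["seed"]},
            indent=2, sort_keys=True,
        )
        + "\n"
    )


def _session_key(subject: int, day: int) -> str:
    return f"sub{subject:02d}_day{day:02d}"


def run_pipeline(config: Optional[dict] = None, out_dir: str | Path = "naturalreach_out") -> dict:
    """Execute the configured stages; returns a dict of in-memory results.

    Stage failures raise ``PipelineError`` naming the stage.  Omitting a
    stage from ``config['stages']`` skips it (downstream stages that need its
    products are skipped too, with a warning).
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    master = int(cfg["seed"])
    results: dict = {"config": cfg}

    def guard(stage: str):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
                return False

        return _Ctx()

    study = None
    if "simulate" in stages:
        with guard("simulate"):
            syn = dict(cfg["synthetic"])
            syn["days"] = tuple(syn.get("days", (1, 2, 3)))
            syn["seed"] = _stage_seed(master, "simulate")
            if "true_betas" in syn:
                syn["true_betas"] = {k: tuple(v) for k, v in syn["true_betas"].items()}
            study = generate_study(SyntheticConfig(**syn))
            d = out / "simulate"
            _provenance(d, cfg, "simulate")
            io.save_atlas(d / "atlas.csv", study.atlas)
            for sess in study.sessions:
                key = _session_key(sess.subject, sess.day)
                io.save_trajectory(d / f"{key}_contra.csv", sess.contra_traj)
                io.save_trajectory(d / f"{key}_ipsi.csv", sess.ipsi_traj)
                io.save_states(d / f"{key}_true_states.csv", sess.contra_states)
                io.save_events(d / f"{key}_true_events.csv", sess.events)
                sess.features.to_csv(d / f"{key}_true_features.csv", index=False)
                io.save_recording(d / f"{key}_raw", sess.recording)
                io.save_audio(d / f"{key}.wav", sess.audio)
            results["study"] = study
    if study is None:
        warnings.warn("no simulate stage: remaining stages skipped", stacklevel=2)
        return results

    states: dict[str, tuple[StateSequence, StateSequence]] = {}
    if "segment" in stages:
        with guard("segment"):
            d = out / "segment"
            _provenance(d, cfg, "segment")
            seg_seed = _stage_seed(master, "segment")
            for sess in study.sessions:
                key = _session_key(sess.subject, sess.day)
                contra = _segment_one(sess.contra_traj, seg_seed, cfg["segment"])
                ipsi = _segment_one(sess.ipsi_traj, seg_seed, cfg["segment"])
                states[key] = (contra, ipsi)
                io.save_states(d / f"{key}_contra_states.csv", contra)
                io.save_states(d / f"{key}_ipsi_states.csv", ipsi)
            results["states"] = states

    events_by_key: dict[str, list] = {}
    if "detect-events" in stages and states:
        with guard("detect-events"):
            d = out / "detect-events"
            _provenance(d, cfg, "detect-events")
            for sess in study.sessions:
                key = _session_key(sess.subject, sess.day)
                contra, _ = states[key]
                evs = detect_onsets(contra)
                annotate_events(evs, sess.contra_traj, day=sess.day,
                                day_start_clock=sess.day_start_clock)
                evs = prune_events(evs)
                events_by_key[key] = evs
                io.save_events(d / f"{key}_events.csv", evs)
            results["events"] = events_by_key

    prerecs: dict[str, object] = {}
    if "preprocess" in stages:
        with guard("preprocess"):
            d = out / "preprocess"
            _provenance(d, cfg, "preprocess")
            for sess in study.sessions:
                key = _session_key(sess.subject, sess.day)
                rec = preprocess(sess.recording)
                prerecs[key] = rec
                io.save_recording(d / f"{key}_clean", rec)
            results["preprocessed"] = prerecs

    band_rows = []
    planes: dict[str, dict] = {}  # key -> {event_gid: {channel: plane}}
    plane_grid: dict[str, np.ndarray] = {}
    if "spectral" in stages and events_by_key and prerecs:
        with guard("spectral"):
            d = out / "spectral"
            _provenance(d, cfg, "spectral")
            decim = int(cfg["spectral"].get("decim", 25))
            for sess in study.sessions:
                key = _session_key(sess.subject, sess.day)
                kept = [ev for ev in events_by_key[key] if ev.kept]
                segs, _dropped = extract_segments(prerecs[key], kept)
                if len(segs) < 2:
                    warnings.warn(f"{key}: fewer than 2 segments; session skipped", stacklevel=2)
                    continue
                segs, _rej = reject_bad_segments(segs)
                bp = compute_band_powers(segs, decim=decim)
                bp.insert(0, "subject", sess.subject)
                bp.insert(1, "day", sess.day)
                bp["event"] = [f"{key}_e{e}" for e in bp["event"]]
                band_rows.append(bp)
                planes[key] = {}
                for seg in segs:
                    gid = f"{key}_e{seg.event_id}"
                    chmap = {}
                    for spec in morlet_power(seg, decim=decim):
                        sub = baseline_subtract(spec)
                        chmap[spec.channel] = sub.power_db
                        plane_grid["freqs"] = sub.freqs
                        plane_grid["times"] = sub.times
                    planes[key][gid] = chmap
            band_powers = pd.concat(band_rows, ignore_index=True) if band_rows else pd.DataFrame()
            band_powers.to_csv(d / "band_powers.csv", index=False)
            results["band_powers"] = band_powers
            results["planes"] = planes

    weights_by_subject = {}
    if "project" in stages and prerecs:
        with guard("project"):
            d = out / "project"
            _provenance(d, cfg, "project")
            fwhm = float(cfg["project"]["fwhm"])
            thresh = float(cfg["project"]["density_threshold"])
            densities: dict[str, list[float]] = {r: [] for r in study.atlas.names}
            per_subject = {}
            for subject, layout in study.layouts.items():
                key0 = _session_key(subject, study.config.days[0])
                rec = prerecs.get(key0)
                good = ~rec.bad_channels if rec is not None else np.ones(len(layout.names), bool)
                names = [n for n, g in zip(layout.names, good) if g]
                pos = mirror_electrodes(layout.positions[good], layout.hemisphere)
                w = compute_weights(pos, names, study.atlas, fwhm=fwhm)
                per_subject[subject] = (pos, names, w)
                for r in study.atlas.names:
                    densities[r].append(w.density[r])
            rows = []
            for subject, (pos, names, _w) in per_subject.items():
                w = compute_weights(pos, names, study.atlas, fwhm=fwhm,
                                    density_by_subject=densities, density_threshold=thresh)
                weights_by_subject[subject] = w
                for region in w.retained:
                    for e, we in sorted(w.weights[region].items()):
                        rows.append({"subject": subject, "region": region,
                                     "electrode": e, "weight": we})
            pd.DataFrame(rows, columns=["subject", "region", "electrode", "weight"]).to_csv(
                d / "weights.csv", index=False
            )
            results["weights"] = weights_by_subject

    if "group-stats" in stages and planes and weights_by_subject:
        with guard("group-stats"):
            d = out / "group-stats"
            _provenance(d, cfg, "group-stats")
            gs_seed = _stage_seed(master, "group-stats")
            times = plane_grid["times"]
            freqs = plane_grid["freqs"]
            regions = sorted({r for w in weights_by_subject.values() for r in w.retained})
            prow = []
            for region in regions:
                per_subject_stacks = {}
                for subject, w in weights_by_subject.items():
                    if region not in w.retained:
                        continue
                    stack = []
                    for sess in study.sessions_for(subject):
                        key = _session_key(sess.subject, sess.day)
                        for gid, chmap in planes.get(key, {}).items():
                            proj = project_power(chmap, w)
                            stack.append(proj[region])
                    if stack:
                        per_subject_stacks[str(subject)] = np.stack(stack)
                group_plane = aggregate(per_subject_stacks)
                masked, pvals = bootstrap_baseline_mask(
                    group_plane, times,
                    n_boot=int(cfg["group_stats"]["n_boot"]),
                    alpha=float(cfg["group_stats"]["alpha"]),
                    seed=gs_seed,
                    per_subject_event_planes=per_subject_stacks,
                )
                pd.DataFrame(masked, index=freqs, columns=times).to_csv(
                    d / f"{region}_masked.csv"
                )
                for i, f in enumerate(freqs):
                    for j, t in enumerate(times):
                        prow.append({"region": region, "freq": f, "time": t,
                                     "p": pvals[i, j]})
            pd.DataFrame(prow, columns=["region", "freq", "time", "p"]).to_csv(
                d / "pvalues.csv", index=False
            )
            bp = results.get("band_powers")
            if bp is not None and len(bp):
                kw_rows = []
                for band, grp in bp.groupby("band"):
                    groups = [g["value"].to_numpy() for _, g in grp.groupby("subject")]
                    if len(groups) >= 2:
                        h, p = kruskal_wallis_bands(groups)
                        kw_rows.append({"band": band, "grouping": "subject", "H": h, "p": p})
                    groups = [g["value"].to_numpy() for _, g in grp.groupby("day")]
                    if len(groups) >= 2:
                        h, p = kruskal_wallis_bands(groups)
                        kw_rows.append({"band": band, "grouping": "day", "H": h, "p": p})
                pd.DataFrame(kw_rows, columns=["band", "grouping", "H", "p"]).to_csv(
                    d / "kruskal_wallis.csv", index=False
                )

    feature_frames = []
    if "features" in stages and events_by_key and states:
        with guard("features"):
            d = out / "features"
            _provenance(d, cfg, "features")
            for sess in study.sessions:
                key = _session_key(sess.subject, sess.day)
                contra_states, ipsi_states = states[key]
                ft = compute_feature_table(
                    events_by_key[key], sess.contra_traj, sess.ipsi_traj,
                    contra_states, ipsi_states, audio=sess.audio,
                )
                ft.insert(0, "subject", sess.subject)
                ft["event"] = [f"{key}_e{e}" for e in ft["event"]]
                ft.to_csv(d / f"{key}_features.csv", index=False)
                feature_frames.append(ft)
            features = pd.concat(feature_frames, ignore_index=True) if feature_frames else pd.DataFrame()
            features.to_csv(d / "features.csv", index=False)
            results["features"] = features

    if "regress" in stages and feature_frames and band_rows:
        with guard("regress"):
            d = out / "regress"
            _provenance(d, cfg, "regress")
            reg_seed = _stage_seed(master, "regress")
            bp = results["band_powers"]
            features = results["features"]
            all_results = []
            for subject, ft in features.groupby("subject"):
                sub_bp = bp[bp["subject"] == subject]
                res = regress_all(
                    sub_bp[["event", "channel", "band", "value"]],
                    ft.drop(columns=["subject"]),
                    n_splits=int(cfg["regress"]["n_splits"]),
                    test_frac=float(cfg["regress"]["test_frac"]),
                    seed=reg_seed,
                )
                for r in res:
                    r.subject = subject  # type: ignore[attr-defined]
                all_results.extend(res)
            coef_rows, dr2_rows, ret_rows = [], [], []
            for r in all_results:
                subj = getattr(r, "subject", -1)
                for f, c in sorted(r.mean_coefs.items()):
                    for i, ci in enumerate(np.atleast_1d(c)):
                        coef_rows.append({"subject": subj, "electrode": r.electrode,
                                          "band": r.band, "feature": f, "component": i,
                                          "coef": ci})
                for f, v in sorted(r.delta_r2.items()):
                    dr2_rows.append({"subject": subj, "electrode": r.electrode,
                                     "band": r.band, "feature": f, "delta_r2": v,
                                     "full_r2": r.mean_full_r2})
                for f, v in sorted(r.retention.items()):
                    ret_rows.append({"subject": subj, "electrode": r.electrode,
                                     "band": r.band, "feature": f, "retention": v})
            pd.DataFrame(coef_rows, columns=["subject", "electrode", "band", "feature",
                                             "component", "coef"]).to_csv(d / "coefficients.csv", index=False)
            pd.DataFrame(dr2_rows, columns=["subject", "electrode", "band", "feature",
                                            "delta_r2", "full_r2"]).to_csv(d / "delta_r2.csv", index=False)
            pd.DataFrame(ret_rows, columns=["subject", "electrode", "band", "feature",
                                            "retention"]).to_csv(d / "retention.csv", index=False)
            results["regression"] = all_results

    return results


def _segment_one(traj, seed: int, seg_cfg: dict) -> StateSequence:
    """Fit + decode one wrist; an unsegmentable (near-constant) wrist is all rest."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = fit_arhsmm(traj, init_seed=seed,
                                max_iter=int(seg_cfg.get("max_iter", 20)),
                                max_dwell=int(seg_cfg.get("max_dwell", 300)))
        return decode_states(params, traj)
    except SingularModelError:
        return StateSequence(labels=np.zeros(traj.n_frames, dtype=int),
                             frame_rate=traj.frame_rate, source="fitted")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""
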