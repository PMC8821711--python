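"""End-to-end orchestration: synthesize -> detect -> track -> ipi -> noise
-> recall -> range -> density -> stats, with a manifest and resumability.

Each stage writes its outputs into a named subfolder of the run directory
and drops a ``.done`` marker; re-running the pipeline skips completed
stages, so a run can be resumed or selectively re-executed by deleting a
stage folder.  A stage that needs a missing upstream output fails with a
diagnostic naming the stage to (re-)enable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import read_wav
from .classifier import RecallModel
from .detection import DetectorConfig, detect_clicks
from .ipi_size import estimate_ipi
from .noise import octave_levels, period_compare, OCTAVE_CENTERS_HZ
from .range_density import McConfig, density, habitat_area, mc_effective_area
from .stats import presence_probability
from .synthdata import (
    ArrayGeometry,
    ClickModel,
    NoiseConfig,
    WhaleSim,
    render_scene,
)
from .tracking import (
    TrackerConfig,
    build_tracks,
    passages_to_frame,
    segment_passages,
    tdoas_for_scene,
)

__all__ = ["DEFAULT_CONFIG", "demo_config", "run_pipeline", "make_fixtures"]

STAGES = ("synth", "detect", "track", "ipi", "noise", "range", "density", "stats")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "scene": {
        "duration_s": 60.0,
        "sea_state": 2.0,
        "ferry_windows": [],
        "ferry_boost_db": 0.0,
        "whales": [
            {"x_km": 2.0, "y_km": 2.0, "depth_m": 400.0, "ici_s": 1.0, "ipi_ms": 4.5},
            {"x_km": -3.0, "y_km": 1.0, "depth_m": 700.0, "ici_s": 1.3, "ipi_ms": 6.0},
        ],
    },
    "geometry": {},          # ArrayGeometry overrides
    "detector": {},          # DetectorConfig overrides
    "tracker": {"min_points": 10, "min_duration_s": 5.0},
    "ipi": {"window_s": 0.040},
    "noise": {"chunk_s": 1.0},
    "recall": {"L": 0.95, "x0": 5.0, "k": 0.8},
    "range": {
        "n_emissions": 100_000,
        "nl_db": 44.0,
        "sl_db": 200.0,
        "alpha_db_per_km": 1.43,
        "beam_model": "piston",
        "ka": 10.0,
    },
    "density": {"habitat_fraction": 0.5, "n_days": 1.0},
}


def demo_config() -> dict:
    """A copy of the bundled two-whale demo configuration."""
    return json.loads(json.dumps(DEFAULT_CONFIG))


def _deep_update(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = demo_config()
    if path is not None:
        cfg = _deep_update(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _whales_from_config(cfg: dict) -> list[WhaleSim]:
    whales = []
    duration = float(cfg["scene"]["duration_s"])
    for w in cfg["scene"]["whales"]:
        model = ClickModel(ipi_ms=float(w.get("ipi_ms", 5.0)),
                           source_level_db=float(w.get("source_level_db", 200.0)))
        whales.append(WhaleSim.stationary(
            float(w["x_km"]), float(w["y_km"]), float(w["depth_m"]),
            duration, ici_s=float(w.get("ici_s", 1.0)), click_model=model,
        ))
    return whales


class StageError(RuntimeError):
    """Raised when a stage's upstream outputs are missing."""


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing {path.name}: enable or rerun the '{producer}' stage first"
        )
    return path


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Run all enabled stages; returns the run directory.

    The manifest records the package version, seed, a stable hash of the
    configuration and per-stage wall time, so two runs of the same config
    and seed are byte-comparable.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else _deep_update(
        demo_config(), config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = ArrayGeometry(**cfg.get("geometry", {}))
    fs = geom.sample_rate_hz
    seed = int(cfg["seed"])
    enabled = cfg["stages"]
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    def done(name: str) -> bool:
        return (out / name / ".done").exists()

    def finish(name: str, t0: float) -> None:
        (out / name / ".done").touch()
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}

    # ---- synth ----------------------------------------------------------
    if enabled.get("synth") and not done("synth"):
        t0 = time.time()
        d = stage_dir("synth")
        scene = cfg["scene"]
        noise_cfg = NoiseConfig(
            sea_state=float(scene["sea_state"]),
            ferry_windows=tuple(tuple(w) for w in scene.get("ferry_windows", [])),
            ferry_boost_db=float(scene.get("ferry_boost_db", 0.0)),
        )
        render_scene(
            _whales_from_config(cfg), geom, float(scene["duration_s"]),
            noise_cfg, seed=seed,
            out_wav=d / "scene.wav", out_truth_prefix=d / "truth",
        )
        finish("synth", t0)

    wav_path = out / "synth" / "scene.wav"

    # ---- detect ---------------------------------------------------------
    if enabled.get("detect") and not done("detect"):
        t0 = time.time()
        d = stage_dir("detect")
        fs_r, data = read_wav(_require(wav_path, "synth"))
        events = detect_clicks(data, fs_r, DetectorConfig(**cfg.get("detector", {})))
        pd.DataFrame([{
            "time_s": e.time_s, "channel": e.channel, "tk_peak": e.tk_peak,
            "click_spl_db": e.click_spl_db, "noise_spl_db": e.noise_spl_db,
        } for e in events]).to_csv(d / "detections.csv", index=False)
        finish("detect", t0)

    # ---- track ----------------------------------------------------------
    if enabled.get("track") and not done("track"):
        t0 = time.time()
        d = stage_dir("track")
        det_csv = _require(out / "detect" / "detections.csv", "detect")
        fs_r, data = read_wav(_require(wav_path, "synth"))
        det_df = pd.read_csv(det_csv)
        east_times = det_df[det_df.channel == "east"].time_s.tolist()
        pts = tdoas_for_scene(data, east_times, fs_r, geom)
        pd.DataFrame({
            "time_s": [p.time_s for p in pts],
            "tdoa_s": [p.tdoa_s for p in pts],
            "correlation_peak": [p.correlation_peak for p in pts],
            "low_confidence": [p.low_confidence for p in pts],
        }).to_csv(d / "tdoa.csv", index=False)
        tracks = build_tracks(pts, TrackerConfig(**cfg.get("tracker", {})))
        if tracks:
            pd.concat([t.to_frame() for t in tracks]).to_csv(
                d / "tracks.csv", index=False)
        else:
            pd.DataFrame(columns=["time_s", "tdoa_s", "correlation_peak",
                                  "whale_label"]).to_csv(d / "tracks.csv", index=False)
        passages = segment_passages(tracks)
        passages_to_frame(passages).to_csv(d / "passages.csv", index=False)
        finish("track", t0)

    # ---- ipi ------------------------------------------------------------
    if enabled.get("ipi") and not done("ipi"):
        t0 = time.time()
        d = stage_dir("ipi")
        tracks_csv = _require(out / "track" / "tracks.csv", "track")
        passages_csv = _require(out / "track" / "passages.csv", "track")
        fs_r, data = read_wav(_require(wav_path, "synth"))
        tracks_df = pd.read_csv(tracks_csv)
        passages_df = pd.read_csv(passages_csv)
        win = int(float(cfg["ipi"].get("window_s", 0.040)) * fs_r)
        rows = []
        for label, grp in tracks_df.groupby("whale_label"):
            # exclude tracks inside passages with more than 2 individuals
            mid = 0.5 * (grp.time_s.min() + grp.time_s.max())
            n_ind = 1
            for _, p in passages_df.iterrows():
                if p.start_s <= mid <= p.end_s:
                    n_ind = int(p.n_individuals)
                    break
            if n_ind > 2:
                rows.append({"whale_label": label, "ipi_ms": np.nan,
                             "size_m": np.nan, "size_class": "excluded",
                             "reliable": False, "n_clicks": 0})
                continue
            clicks = []
            for t in grp.time_s:
                i0 = int((t - 0.002) * fs_r)
                if 0 <= i0 and i0 + win <= data.shape[0]:
                    clicks.append(data[i0:i0 + win, 0])
            if not clicks:
                continue
            est = estimate_ipi(clicks, fs_r, n_individuals=min(n_ind, 2))
            rows.append({
                "whale_label": label, "ipi_ms": est.ipi_ms, "size_m": est.size_m,
                "size_class": est.size_class, "reliable": est.reliable,
                "n_clicks": est.n_clicks,
            })
        pd.DataFrame(rows, columns=["whale_label", "ipi_ms", "size_m",
                                    "size_class", "reliable", "n_clicks"]
                     ).to_csv(d / "ipi.csv", index=False)
        finish("ipi", t0)

    # ---- noise ----------------------------------------------------------
    if enabled.get("noise") and not done("noise"):
        t0 = time.time()
        d = stage_dir("noise")
        fs_r, data = read_wav(_require(wav_path, "synth"))
        chunk = int(float(cfg["noise"].get("chunk_s", 1.0)) * fs_r)
        east = data[:, 0]
        rows, labels = [], []
        ferry = [tuple(w) for w in cfg["scene"].get("ferry_windows", [])]
        for i in range(0, east.size - chunk + 1, chunk):
            t_mid = (i + chunk / 2) / fs_r
            lv = octave_levels(east[i:i + chunk], fs_r, timestamp=t_mid)
            rows.append(lv.spl_db)
            labels.append("ferry" if any(s <= t_mid < e for s, e in ferry)
                          else "quiet")
        lv_df = pd.DataFrame(np.array(rows), columns=[str(c) for c in OCTAVE_CENTERS_HZ])
        lv_df["label"] = labels
        lv_df.to_csv(d / "octave_levels.csv", index=False)
        if len(set(labels)) > 1:
            period_compare(np.array(rows), labels).to_csv(
                d / "period_compare.csv", index=False)
        finish("noise", t0)

    # ---- range ----------------------------------------------------------
    if enabled.get("range") and not done("range"):
        t0 = time.time()
        d = stage_dir("range")
        r = cfg["range"]
        recall = RecallModel(**cfg["recall"])
        mc = McConfig(n_emissions=int(r["n_emissions"]), seed=seed)
        res = mc_effective_area(
            mc, recall, nl_db=float(r["nl_db"]), sl_db=float(r["sl_db"]),
            alpha_db_per_km=float(r["alpha_db_per_km"]),
            beam_model=r.get("beam_model", "piston"), ka=float(r.get("ka", 10.0)),
        )
        (d / "range.json").write_text(json.dumps(asdict(res), indent=2))
        finish("range", t0)

    # ---- density --------------------------------------------------------
    if enabled.get("density") and not done("density"):
        t0 = time.time()
        d = stage_dir("density")
        range_json = _require(out / "range" / "range.json", "range")
        passages_csv = _require(out / "track" / "passages.csv", "track")
        re_km = json.loads(range_json.read_text())["re_km"]
        passages_df = pd.read_csv(passages_csv)
        n_animals = int(passages_df.n_individuals.sum()) if len(passages_df) else 0
        dcfg = cfg["density"]
        area = habitat_area(re_km, float(dcfg.get("habitat_fraction", 0.5)))
        res = density(max(n_animals, 0), float(dcfg.get("n_days", 1.0)), area) \
            if n_animals > 0 else None
        (d / "density.json").write_text(json.dumps({
            "re_km": re_km,
            "habitat_area_km2": area,
            "n_animals": n_animals,
            "n_days": float(dcfg.get("n_days", 1.0)),
            "density_per_1000km2": res.density_per_1000km2 if res else 0.0,
        }, indent=2))
        finish("density", t0)

    # ---- stats ----------------------------------------------------------
    if enabled.get("stats") and not done("stats"):
        t0 = time.time()
        d = stage_dir("stats")
        passages_csv = _require(out / "track" / "passages.csv", "track")
        passages_df = pd.read_csv(passages_csv)
        duration = float(cfg["scene"]["duration_s"])
        presence = presence_probability(
            list(zip(passages_df.start_s, passages_df.end_s)),
            [(0.0, duration)],
        )
        presence.to_csv(d / "presence.csv", index=False)
        finish("stats", t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# --------------------------------------------------------------------------
# bundled fixtures
# --------------------------------------------------------------------------

def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures",
                  duration_s: float = 20.0) -> dict:
    """Small bundled scenes with truth tables; returns a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = ArrayGeometry()

    def whale(x, y, z, ipi=5.0, ici=1.0):
        return WhaleSim.stationary(x, y, z, duration_s, ici_s=ici,
                                   click_model=ClickModel(ipi_ms=ipi))

    scenes = {
        "single_whale": ([whale(2.0, 2.0, 400.0, ipi=4.5)], NoiseConfig()),
        "two_whales": ([whale(2.0, 2.0, 400.0, ipi=3.5),
                        whale(-3.0, 1.0, 700.0, ipi=6.5, ici=1.3)], NoiseConfig()),
        "nine_whales": (
            [whale(2.0 * np.cos(a), 2.0 * np.sin(a), 300.0 + 100.0 * i,
                   ipi=3.0 + 0.5 * i)
             for i, a in enumerate(np.linspace(0, 2 * np.pi, 9, endpoint=False))],
            NoiseConfig(),
        ),
        "noise_only": ([], NoiseConfig()),
        "ferry_boost": ([], NoiseConfig(
            ferry_windows=((0.0, duration_s / 2),), ferry_boost_db=3.0)),
    }
    manifest = {}
    for name, (whales, ncfg) in scenes.items():
        wav = out / f"{name}.wav"
        render_scene(whales, geom, duration_s, ncfg, seed=seed,
                     out_wav=wav, out_truth_prefix=out / name)
        manifest[name] = hashlib.sha256(wav.read_bytes()).hexdigest()
    (out / "checksums.json").write_text(json.dumps(manifest, indent=2))
    return manifest
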