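"""Simulate -> analyze -> report orchestration with reproducible datasets.

Dataset directory contract::

    <dataset>/
      config.json          # full config snapshot + seed
      inputs/
        irf.csv            # time_ns, counts
        decays.h5          # /<genotype>/<nerve>/counts (n_px, n_bins), coords
        masks/<genotype>_<nerve>.tif   # 16-bit axon label image
        ratio_<genotype>_<nerve>.csv   # time_s, cfp, fret, yfp
        cap_series_<genotype>_<nerve>.csv  # time_s, area
        cap_sweep_<genotype>_<i>mA.csv # time_ms, voltage_mv
        protocol.json
      truth/*.json         # generator ground truth per nerve/experiment
      reports/             # written by analyze
        manifest.json, *.csv
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import cap as cap_mod
from . import image_stats, ratio, synth
from .flim import IRFHistogram, phasor_transform
from .protocol import ProtocolSpec, standard_gd_protocol

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CONFIG",
    "simulate_dataset",
    "analyze_dataset",
    "phasor_dataset",
    "load_config",
]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "n_nerves": 2,
    "flim": {
        "rep_frequency": 8.0e7,
        "bin_width": 0.027,
        "irf_center": 2.0,
        "irf_width_sigma": 0.1,
        "photons_per_pixel": 800.0,
        "min_photons": 100,
        "min_pixels": 20,
    },
    "scene": {"axon_length_um": 8.0, "stripe_height": 3, "gap": 1},
    # two-genotype contrast: longer mean lifetime (lower ATP) and larger
    # variability in the null-like group
    "genotypes": {
        "control": {
            "mean_lifetime": 1.45, "within_axon_sd": 0.058,
            "across_axon_sd": 0.044, "n_axons": 8,
        },
        "plp_null": {
            "mean_lifetime": 1.55, "within_axon_sd": 0.093,
            "across_axon_sd": 0.078, "n_axons": 8,
        },
    },
    "ratio": {
        "noise_sd": 0.003,
        "kinetics": {
            "control": {
                "GD": {"rate_per_s": 1.0 / 400.0, "plateau": 0.05},
                "reperfusion": {"delay_s": 180.0, "tau_s": 200.0,
                                "plateau": 0.607},
                "MBGD": {"ramp_s": 300.0},
            },
            "plp_null": {
                "GD": {"rate_per_s": 1.0 / 600.0, "plateau": 0.05},
                "reperfusion": {"delay_s": 60.0, "tau_s": 200.0,
                                "plateau": 0.82},
                "MBGD": {"ramp_s": 300.0},
            },
        },
    },
    "cap": {
        "noise_sd": 0.01,
        "amplitude": {"control": 4.0, "plp_null": 2.4},
        "excitability_intensities": [0.0, 0.1, 0.2, 0.3, 0.45, 0.6, 0.75, 1.0],
        "kinetics": {
            "control": {
                "GD": {"rate_per_s": 1.0 / 350.0, "plateau": 0.02},
                "reperfusion": {"delay_s": 150.0, "tau_s": 180.0,
                                "plateau": 0.85},
                "MBGD": {"ramp_s": 300.0},
            },
            "plp_null": {
                "GD": {"rate_per_s": 1.0 / 550.0, "plateau": 0.02},
                "reperfusion": {"delay_s": 50.0, "tau_s": 180.0,
                                "plateau": 0.85},
                "MBGD": {"ramp_s": 300.0},
            },
        },
    },
    "kinetics_params": {"slope_window_s": 52.0, "k_sd": 3.0},
    "protocol": {"baseline_min": 15.0, "gd_min": 30.0, "reperfusion_min": 45.0,
                 "mbgd_min": 15.0},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Default config, optionally overridden by a TOML file."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    import tomllib

    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    return _deep_merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _version() -> str:
    try:
        return metadata.version("axonatp")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: dict[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
    force: bool = False,
) -> Path:
    """Generate the four input families plus ground-truth sidecars."""
    for section in ("genotypes", "ratio", "cap", "flim", "protocol"):
        if section not in config:
            raise ValueError(f"config is missing the {section!r} section")
    out = Path(out_dir)
    existing = [p for p in out.iterdir() if p.name != "run.log"] if out.exists() else []
    if existing and not force:
        raise FileExistsError(
            f"output directory {out} is not empty (use force=True / --force)"
        )
    inputs = out / "inputs"
    truth_dir = out / "truth"
    (inputs / "masks").mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    seed = int(config["seed"] if seed is None else seed)
    root_rng = np.random.default_rng(seed)
    flim_cfg = config["flim"]
    cfg = synth.SimConfig(
        seed=seed,
        rep_frequency=flim_cfg["rep_frequency"],
        bin_width=flim_cfg["bin_width"],
        irf_center=flim_cfg["irf_center"],
        irf_width_sigma=flim_cfg["irf_width_sigma"],
        photons_per_pixel=flim_cfg["photons_per_pixel"],
    )
    protocol = standard_gd_protocol(**config["protocol"])
    (inputs / "protocol.json").write_text(json.dumps(protocol.to_dict(), indent=1))

    irf = synth.gen_irf(cfg)
    pd.DataFrame({"time_ns": irf.bin_times, "counts": irf.counts}).to_csv(
        inputs / "irf.csv", index=False
    )

    n_nerves = int(config["n_nerves"])
    scene_cfg = config["scene"]
    truth: dict[str, Any] = {"seed": seed, "nerves": {}}
    with h5py.File(inputs / "decays.h5", "w") as h5:
        h5.attrs.update({
            "bin_width": cfg.bin_width, "n_bins": cfg.n_bins,
            "rep_frequency": cfg.rep_frequency,
        })
        for geno_name, geno_cfg in config["genotypes"].items():
            geno = synth.GenotypeModel(
                axon_length_um=scene_cfg["axon_length_um"], **geno_cfg
            )
            for nerve in range(n_nerves):
                scene = synth.gen_flim_scene(
                    geno, cfg, rng=root_rng,
                    stripe_height=scene_cfg["stripe_height"],
                    gap=scene_cfg["gap"],
                )
                grp = h5.create_group(f"{geno_name}/nerve{nerve}")
                grp.create_dataset("counts", data=scene.decay_counts,
                                   track_times=False)
                grp.create_dataset("coords", data=scene.pixel_coords,
                                   track_times=False)
                tifffile.imwrite(
                    inputs / "masks" / f"{geno_name}_nerve{nerve}.tif",
                    scene.labels.astype(np.uint16),
                )
                truth["nerves"][f"{geno_name}/nerve{nerve}"] = {
                    "axon_tau_ns": scene.truth_axon_tau.tolist(),
                    "mean_lifetime_ns": geno.mean_lifetime,
                    "within_axon_sd_ns": geno.within_axon_sd,
                    "across_axon_sd_ns": geno.across_axon_sd,
                }

                series, r_truth = synth.gen_ratio_timeseries(
                    protocol, config["ratio"]["kinetics"][geno_name],
                    noise_sd=config["ratio"]["noise_sd"], rng=root_rng,
                )
                series.to_frame().to_csv(
                    inputs / f"ratio_{geno_name}_nerve{nerve}.csv", index=False
                )
                cap_series, c_truth = synth.gen_cap_series(
                    protocol, config["cap"]["kinetics"][geno_name],
                    baseline_area=1.0,
                    noise_sd=config["cap"]["noise_sd"], rng=root_rng,
                )
                pd.DataFrame(
                    {"time_s": cap_series.time, "area": cap_series.area}
                ).to_csv(inputs / f"cap_series_{geno_name}_nerve{nerve}.csv",
                         index=False)
                del r_truth, c_truth  # scalar parameters already in config

            sweeps = synth.gen_excitability_traces(
                config["cap"]["amplitude"][geno_name],
                intensities_ma=tuple(config["cap"]["excitability_intensities"]),
                noise_sd=config["cap"]["noise_sd"], rng=root_rng,
            )
            for intensity, trace in sweeps:
                pd.DataFrame(
                    {"time_ms": trace.time, "voltage_mv": trace.voltage}
                ).to_csv(
                    inputs / f"cap_sweep_{geno_name}_{intensity:.2f}mA.csv",
                    index=False,
                )

    (truth_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    snapshot = {"seed": seed, "config": config, "version": _version()}
    (out / "config.json").write_text(json.dumps(snapshot, indent=1))
    return out


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _load_irf(inputs: Path, bin_width: float, rep_frequency: float
              ) -> IRFHistogram:
    irf_path = inputs / "irf.csv"
    if not irf_path.exists():
        raise FileNotFoundError(
            "dataset has no IRF (inputs/irf.csv); moment analysis requires it"
        )
    df = pd.read_csv(irf_path)
    return IRFHistogram(
        bin_times=df["time_ns"].to_numpy(), counts=df["counts"].to_numpy(),
        bin_width=bin_width, rep_frequency=rep_frequency,
    )


def _validate_mask(labels: np.ndarray, name: str) -> None:
    if labels.ndim != 2 or np.any(labels < 0):
        raise ValueError(f"corrupted mask label file for {name}")


def _lifetime_map_for(
    h5: h5py.File, inputs: Path, key: str, irf: IRFHistogram,
    min_photons: int,
) -> tuple[image_stats.LifetimeMap, image_stats.AxonSegmentation]:
    grp = h5[key]
    counts = grp["counts"][()]
    coords = grp["coords"][()]
    labels = tifffile.imread(inputs / "masks" / f"{key.replace('/', '_')}.tif")
    _validate_mask(labels, key)
    stack = np.zeros(labels.shape + (counts.shape[1],), dtype=np.float64)
    stack[coords[:, 0], coords[:, 1]] = counts
    lt_map = image_stats.pixel_lifetime_map(
        stack, irf.bin_times, irf, min_photons=min_photons
    )
    return lt_map, image_stats.AxonSegmentation(labels.astype(np.int32))


def analyze_dataset(dataset_dir: str | Path, out_dir: str | Path | None = None
                    ) -> Path:
    """Run the full analysis over a simulated (or conforming) dataset."""
    ds = Path(dataset_dir)
    inputs = ds / "inputs"
    if not inputs.is_dir():
        raise FileNotFoundError(f"{ds} does not conform to the dataset layout")
    snapshot = json.loads((ds / "config.json").read_text())
    config = snapshot["config"]
    reports = Path(out_dir) if out_dir else ds / "reports"
    reports.mkdir(parents=True, exist_ok=True)

    protocol = ProtocolSpec.from_dict(
        json.loads((inputs / "protocol.json").read_text())
    )
    flim_cfg = config["flim"]
    irf = _load_irf(inputs, flim_cfg["bin_width"], flim_cfg["rep_frequency"])
    min_photons = int(flim_cfg["min_photons"])
    min_pixels = int(flim_cfg["min_pixels"])
    kp = config["kinetics_params"]

    axon_rows, nerve_rows, kin_rows = [], [], []
    with h5py.File(inputs / "decays.h5", "r") as h5:
        for geno_name in h5:
            for nerve_name in h5[geno_name]:
                key = f"{geno_name}/{nerve_name}"
                lt_map, seg = _lifetime_map_for(h5, inputs, key, irf,
                                                min_photons)
                summ = image_stats.nerve_summary(lt_map, seg,
                                                 min_pixels=min_pixels)
                nerve_rows.append({
                    "genotype": geno_name, "nerve": nerve_name,
                    "whole_nerve_tau_ns": summ.whole_nerve_tau,
                    "mean_within_axon_cv": float(summ.within_cv.mean()),
                    "across_axon_cv": summ.across_cv,
                })
                for axon_id in summ.axon_means.index:
                    axon_rows.append({
                        "genotype": geno_name, "nerve": nerve_name,
                        "axon_id": int(axon_id),
                        "mean_tau_ns": float(summ.axon_means[axon_id]),
                        "cv": float(summ.within_cv.get(axon_id, np.nan)),
                        "n_pixels": int(
                            ((seg.labels == axon_id) & lt_map.mask).sum()
                        ),
                    })

    for path in sorted(inputs.glob("ratio_*.csv")):
        geno_name, nerve_name = path.stem.split("_", 1)[1].rsplit("_", 1)
        df = pd.read_csv(path)
        series = ratio.ChannelTimeSeries(
            time=df["time_s"].to_numpy(), cfp=df["cfp"].to_numpy(),
            fret=df["fret"].to_numpy(), yfp=df["yfp"].to_numpy(),
            protocol=protocol,
        )
        trace = ratio.normalize_trace(series.time, ratio.fc_ratio(series),
                                      protocol)
        summ = ratio.summarize_kinetics(trace, window_s=kp["slope_window_s"],
                                        k_sd=kp["k_sd"])
        _, yfp_dev, yfp_flag = ratio.yfp_stability(series)
        kin_rows.append({
            "signal": "atp", "genotype": geno_name, "nerve": nerve_name,
            "decay_rate_per_s": summ.decay_rate,
            "onset_delay_s": summ.onset_delay,
            "recovery_amplitude": summ.recovery_amplitude,
            "yfp_max_deviation": yfp_dev, "yfp_flagged": yfp_flag,
        })

    for path in sorted(inputs.glob("cap_series_*.csv")):
        geno_name, nerve_name = path.stem.split("_", 2)[2].rsplit("_", 1)
        df = pd.read_csv(path)
        series = cap_mod.CAPSeries(time=df["time_s"].to_numpy(),
                                   area=df["area"].to_numpy(),
                                   protocol=protocol)
        trace = cap_mod.normalize_cap_series(series)
        summ = ratio.summarize_kinetics(trace, window_s=kp["slope_window_s"],
                                        k_sd=kp["k_sd"])
        kin_rows.append({
            "signal": "cap", "genotype": geno_name, "nerve": nerve_name,
            "decay_rate_per_s": summ.decay_rate,
            "onset_delay_s": summ.onset_delay,
            "recovery_amplitude": summ.recovery_amplitude,
            "yfp_max_deviation": np.nan, "yfp_flagged": False,
        })

    excit_rows = []
    sweep_paths = sorted(inputs.glob("cap_sweep_*.csv"))
    by_geno: dict[str, list[tuple[float, cap_mod.CAPTrace]]] = {}
    for path in sweep_paths:
        rest = path.stem[len("cap_sweep_"):]
        geno_name, intensity_part = rest.rsplit("_", 1)
        intensity = float(intensity_part.replace("mA", ""))
        df = pd.read_csv(path)
        trace = cap_mod.CAPTrace(time=df["time_ms"].to_numpy(),
                                 voltage=df["voltage_mv"].to_numpy())
        by_geno.setdefault(geno_name, []).append((intensity, trace))
    for geno_name, pairs in by_geno.items():
        curve = cap_mod.excitability_curve(pairs)
        curve.insert(0, "genotype", geno_name)
        excit_rows.append(curve)

    axon_df = pd.DataFrame(axon_rows)
    nerve_df = pd.DataFrame(nerve_rows)
    kin_df = pd.DataFrame(kin_rows)
    axon_df.to_csv(reports / "axon_table.csv", index=False)
    nerve_df.to_csv(reports / "nerve_summary.csv", index=False)
    kin_df.to_csv(reports / "kinetics_summary.csv", index=False)
    if excit_rows:
        pd.concat(excit_rows, ignore_index=True).to_csv(
            reports / "excitability.csv", index=False
        )

    test_rows = []
    genotypes = sorted(nerve_df["genotype"].unique())
    if len(genotypes) == 2 and (nerve_df.groupby("genotype").size() >= 2).all():
        a, b = genotypes
        for col, tname in (
            ("whole_nerve_tau_ns", "student_t"),
            ("mean_within_axon_cv", "welch"),
            ("across_axon_cv", "student_t"),
        ):
            res = image_stats.compare_groups(
                nerve_df.loc[nerve_df.genotype == a, col].to_numpy(),
                nerve_df.loc[nerve_df.genotype == b, col].to_numpy(),
                test=tname,
            )
            test_rows.append({"quantity": col, "group_a": a, "group_b": b,
                              "test": tname, "statistic": res.statistic,
                              "pvalue": res.pvalue})
    pd.DataFrame(test_rows).to_csv(reports / "group_tests.csv", index=False)

    manifest = {
        "version": _version(),
        "seed": snapshot["seed"],
        "config": config,
        "parameters": {
            "min_photons": min_photons,
            "min_pixels": min_pixels,
            "slope_window_s": kp["slope_window_s"],
            "k_sd": kp["k_sd"],
            "bin_convention": "bin-center",
            "mbgd_anchor_window_s": ratio.DEFAULT_MBGD_WINDOW_S,
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(reports.glob("*.csv"))
        },
    }
    (reports / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return reports


# ---------------------------------------------------------------------------
# phasor plot
# ---------------------------------------------------------------------------

def phasor_dataset(dataset_dir: str | Path, out_dir: str | Path | None = None
                   ) -> Path:
    """Per-pixel phasor coordinates, group centroids and the semicircle
    overlay figure."""
    ds = Path(dataset_dir)
    inputs = ds / "inputs"
    snapshot = json.loads((ds / "config.json").read_text())
    flim_cfg = snapshot["config"]["flim"]
    reports = Path(out_dir) if out_dir else ds / "reports"
    reports.mkdir(parents=True, exist_ok=True)
    irf = _load_irf(inputs, flim_cfg["bin_width"], flim_cfg["rep_frequency"])

    from .flim import DecayHistogram

    rows = []
    with h5py.File(inputs / "decays.h5", "r") as h5:
        for geno_name in h5:
            for nerve_name in h5[geno_name]:
                counts = h5[geno_name][nerve_name]["counts"][()]
                for px, c in enumerate(counts):
                    if c.sum() == 0:
                        continue
                    hist = DecayHistogram(
                        bin_times=irf.bin_times, counts=c,
                        bin_width=irf.bin_width,
                        rep_frequency=irf.rep_frequency,
                    )
                    p = phasor_transform(hist, irf)
                    rows.append({"genotype": geno_name, "nerve": nerve_name,
                                 "pixel": px, "g": p.g, "s": p.s})
    df = pd.DataFrame(rows)
    df.to_csv(reports / "phasor.csv", index=False)

    centroids = df.groupby("genotype")[["g", "s"]].mean()
    centroids.to_csv(reports / "phasor_centroids.csv")
    if len(centroids) == 2:
        shift = float(centroids["g"].iloc[1] - centroids["g"].iloc[0])
        logger.info("centroid shift along g (%s - %s): %+0.4f",
                    centroids.index[1], centroids.index[0], shift)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.25 * np.cos(theta), 0.25 * np.sin(theta), "k--", lw=1,
            label="universal semicircle")
    for geno_name, sub in df.groupby("genotype"):
        ax.scatter(sub["g"], sub["s"], s=2, alpha=0.3, label=geno_name)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.legend(markerscale=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(reports / "phasor.png", dpi=120)
    plt.close(fig)
    return reports
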