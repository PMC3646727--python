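"""TSV/JSON formats: block lists, population tables, spectra, channel and
scenario configurations.

All on-disk lengths and positions are centiMorgans.  Block lists follow a
fastIBD-like tab-delimited dialect with a header:
sample_a, sample_b, chromosome, start_cM, end_cM[, score][, run_id].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channel import DetectionModel, FalsePositiveModel, named_channel
from .genome import GeneticMap, default_map, make_time_grid
from .inversion import LengthBins, LengthSpectrum
from .simulate import Scenario, preset_curve

__all__ = [
    "read_blocks", "write_blocks",
    "read_population_table", "write_population_table",
    "read_spectrum", "write_spectrum",
    "write_curve",
    "read_channel_config", "write_channel_config",
    "read_scenario",
    "RunConfig",
]


def read_blocks(path) -> pd.DataFrame:
    """Read a block/segment TSV; malformed rows are reported by line number."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_a", "sample_b", "chromosome", "start_cM", "end_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = np.nonzero(~(df["end_cM"].to_numpy(float)
                       > df["start_cM"].to_numpy(float)))[0]
    bad = np.concatenate([bad, np.nonzero(df["sample_a"].astype(str).to_numpy()
                                          == df["sample_b"].astype(str).to_numpy())[0]])
    if bad.size:
        lines = sorted(int(i) + 2 for i in set(bad))  # +2: header + 1-based
        raise ValueError(f"{path}: invalid rows at lines {lines[:20]}"
                         f"{' ...' if len(lines) > 20 else ''}")
    return df


def write_blocks(blocks: pd.DataFrame, path) -> None:
    blocks.to_csv(path, sep="\t", index=False)


def read_population_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample", "population") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_population_table(pops: pd.DataFrame, path) -> None:
    pops.to_csv(path, sep="\t", index=False)


def write_spectrum(spectrum: LengthSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_pairs={spectrum.n_pairs}\n")
        pd.DataFrame({"bin_lo_cM": spectrum.bins.lower,
                      "bin_hi_cM": spectrum.bins.upper,
                      "count": spectrum.counts}).to_csv(fh, sep="\t", index=False)


def read_spectrum(path) -> LengthSpectrum:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# n_pairs="):
            raise ValueError(f"{path}: expected '# n_pairs=' metadata line")
        n_pairs = int(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    edges = np.append(df["bin_lo_cM"].to_numpy(float),
                      df["bin_hi_cM"].to_numpy(float)[-1])
    if not np.allclose(df["bin_hi_cM"].to_numpy(float)[:-1],
                       df["bin_lo_cM"].to_numpy(float)[1:]):
        raise ValueError(f"{path}: bins must be contiguous")
    return LengthSpectrum(LengthBins(edges), df["count"].to_numpy(), n_pairs)


def write_curve(mu, gmap: GeneticMap, path) -> None:
    """Fitted-curve TSV: per-interval density and expected ancestors."""
    from .genome import genetic_ancestors_per_generation
    grid = mu.grid
    pd.DataFrame({"n_lo_meioses": grid.lower,
                  "n_hi_meioses": grid.upper,
                  "mu_density": mu.values,
                  "ancestors_per_generation":
                      genetic_ancestors_per_generation(mu, gmap)}
                 ).to_csv(path, sep="\t", index=False)


_CHANNEL_KEYS = ["power_alpha", "power_beta", "sign_alpha", "sign_beta",
                 "lam_pos_a", "lam_pos_b", "lam_neg_a", "lam_neg_b",
                 "fp_a", "fp_b", "fp_c"]


def write_channel_config(det: DetectionModel, fp: FalsePositiveModel | None,
                         path) -> None:
    vals = list(det.power_params) + list(det.sign_params) \
        + list(det.pos_rate_params) + list(det.neg_rate_params) \
        + (list(fp.fp_params) if fp is not None else [-np.inf, -1.0, 0.0])
    with open(path, "w") as fh:
        for k, v in zip(_CHANNEL_KEYS, vals):
            fh.write(f"{k} = {float(v)!r}\n")


def read_channel_config(path) -> tuple[DetectionModel, FalsePositiveModel]:
    vals = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            vals[k.strip()] = float(v)
    missing = [k for k in _CHANNEL_KEYS if k not in vals]
    if missing:
        raise ValueError(f"{path}: missing channel keys {missing}")
    det = DetectionModel(
        power_params=(vals["power_alpha"], vals["power_beta"]),
        sign_params=(vals["sign_alpha"], vals["sign_beta"]),
        pos_rate_params=(vals["lam_pos_a"], vals["lam_pos_b"]),
        neg_rate_params=(vals["lam_neg_a"], vals["lam_neg_b"]))
    fp = FalsePositiveModel(fp_params=(vals["fp_a"], vals["fp_b"], vals["fp_c"]))
    return det, fp


def _channel_from_spec(name_or_path: str):
    try:
        return named_channel(name_or_path)
    except KeyError:
        return read_channel_config(name_or_path)


def read_scenario(path) -> Scenario:
    """Build a Scenario from a JSON config.

    Schema: {"seed": int, "channel": name-or-path, "map": optional path,
    "grid": {"n_intervals", "max_meioses", "generation_time"} (optional),
    "populations": [{"name", "n", "lon", "lat"}, ...],
    "curves": [{"pops": [x] or [x, y], "preset": name, "mass": m,
                "depth_years": d, ...}, ...]}
    Every unordered population pair (including within-population) must have
    a curve entry.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    gmap = GeneticMap.from_tsv(cfg["map"]) if "map" in cfg else default_map()
    g = cfg.get("grid", {})
    grid = make_time_grid(g.get("n_intervals", 60),
                          g.get("max_meioses", 400.0),
                          g.get("generation_time", 30.0))
    det, fp = _channel_from_spec(cfg.get("channel", "fastibd"))
    pops = pd.DataFrame(cfg["populations"]).rename(columns={"name": "population"})
    curves = {}
    for entry in cfg["curves"]:
        key = frozenset(entry["pops"])
        kw = {k: v for k, v in entry.items() if k not in ("pops", "preset")}
        curves[key] = preset_curve(entry["preset"], grid, **kw)
    names = list(pops["population"])
    for i, x in enumerate(names):
        for y in names[i:]:
            if frozenset((x, y)) not in curves:
                raise ValueError(f"scenario missing curve for pair ({x}, {y})")
    return Scenario(populations=pops, pair_curves=curves, gmap=gmap,
                    det=det, fp=fp, seed=int(cfg.get("seed", 0)))


@dataclass(frozen=True)
class RunConfig:
    """Bundled settings for the CLI pipeline."""

    map_path: str | None = None
    channel: str = "fastibd"
    min_length_cM: float = 2.0
    n_intervals: int = 360
    max_meioses: float = 6660.0
    generation_time: float = 30.0
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
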