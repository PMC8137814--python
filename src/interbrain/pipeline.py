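"""End-to-end orchestration: simulate -> preprocess -> fit -> evaluate -> report.

A run is fully described by a :class:`RunConfig`; every stochastic stage
derives its stream from the master seed, so re-running the same config
reproduces every output bit for bit. All outputs embed the config hash.
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

from interbrain.core import DyadDataset, HbO2Series
from interbrain.inference import (
    DEFAULT_ACF_THRESHOLD,
    DEFAULT_ALPHA,
    DEFAULT_B,
    evaluate_dyad,
)
from interbrain.models import DEFAULT_COST, DEFAULT_EPSILON, SplitSpec, fit_all_channels
from interbrain.preprocess import DEFAULT_BAND, DEFAULT_DPF, bandpass
from interbrain.simulate import SimulationConfig, generate_dyad

logger = logging.getLogger("interbrain")

__all__ = ["RunConfig", "RunReport", "run", "summarize", "config_hash"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    ``coupled_pairs`` assigns, per dyad index, a mapping of 1-based
    (teacher_channel, student_channel) pairs to gains; dyads without an
    entry are null dyads.
    """

    n_dyads: int = 5
    seed: int = 0
    # simulation
    n_channels: int = 18
    sampling_rate: float = 7.81
    duration_s: float = 900.0
    target_snr: float | None = 1.0
    coupled_pairs: dict[int, dict[tuple[int, int], float]] = field(default_factory=dict)
    # preprocessing
    band: tuple[float, float] = DEFAULT_BAND
    dpf: tuple[float, float] = DEFAULT_DPF
    apply_bandpass: bool = True
    # modelling
    fraction_train: float = 0.5
    families: tuple[str, ...] = ("SVR", "OLS")
    epsilon: float = DEFAULT_EPSILON
    cost: float = DEFAULT_COST
    # inference
    B: int = DEFAULT_B
    alpha: float = DEFAULT_ALPHA
    acf_threshold: float = DEFAULT_ACF_THRESHOLD
    max_lag: int = 200
    # reporting
    make_figures: bool = False

    def validate(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.fraction_train < 1:
            raise ValueError("fraction_train must lie in (0, 1)")
        unknown = set(self.families) - {"SVR", "OLS"}
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")

    def dyad_seed(self, index: int) -> int:
        state = np.random.SeedSequence((self.seed, index)).generate_state(1)[0]
        return int(state % (2**31))

    def simulation_config(self, index: int) -> SimulationConfig:
        gain = np.zeros((self.n_channels, self.n_channels))
        for (ti, sj), g in self.coupled_pairs.get(index, {}).items():
            gain[sj - 1, ti - 1] = g
        return SimulationConfig(
            n_channels=self.n_channels,
            sampling_rate=self.sampling_rate,
            duration_s=self.duration_s,
            coupling_gain=gain,
            target_snr=self.target_snr,
            seed=self.dyad_seed(index),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coupled_pairs"] = {
            str(i): {f"{ti},{sj}": g for (ti, sj), g in pairs.items()}
            for i, pairs in self.coupled_pairs.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pairs_raw = d.pop("coupled_pairs", {}) or {}
        pairs: dict[int, dict[tuple[int, int], float]] = {}
        for i, mapping in pairs_raw.items():
            pairs[int(i)] = {
                tuple(int(x) for x in key.split(",")): float(g)
                for key, g in mapping.items()
            }
        for key in ("band", "dpf", "families"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(coupled_pairs=pairs, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Concatenated results plus recomputable summary counts."""

    tables: pd.DataFrame
    summary: dict
    config_hash: str
    out_dir: Path | None = None


def summarize(tables: pd.DataFrame, alpha: float | None = None) -> dict:
    """Significant channel-pair counts per family, as 'x/denominator'.

    The denominator is channels x dyads actually evaluated (NA channels,
    e.g. QC-excluded, are not counted into it).
    """
    if tables.empty:
        return {"families": {}, "alpha": alpha}
    alphas = tables.attrs.get("alpha")
    out: dict = {"families": {}, "alpha": alpha if alpha is not None else alphas}
    for fam, sub in tables.groupby("family"):
        evaluated = int(sub["p"].notna().sum())
        sig_unc = int(sub["sig_uncorrected"].sum())
        sig_fdr = int(sub["sig_fdr"].sum())
        out["families"][fam] = {
            "evaluated": evaluated,
            "significant_uncorrected": sig_unc,
            "significant_fdr": sig_fdr,
            "uncorrected": f"{sig_unc}/{evaluated}",
            "fdr": f"{sig_fdr}/{evaluated}",
        }
    return out


def _significance_figure(table: pd.DataFrame, dyad_id: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fams = sorted(table["family"].unique())
    fig, axes = plt.subplots(1, len(fams), figsize=(4 * len(fams), 3), squeeze=False)
    for ax, fam in zip(axes[0], fams):
        sub = table[table["family"] == fam]
        for _, row in sub.iterrows():
            ch = int(row["channel"])
            x = (ch - 1) % 9
            y = 1 if row["region"] == "PFC" else 0
            color = "red" if row["sig_uncorrected"] else "lightgray"
            edge = "black" if row["sig_fdr"] else "none"
            ax.scatter(x, y, s=200, c=color, edgecolors=edge, linewidths=1.5)
            ax.text(x, y, str(ch), ha="center", va="center", fontsize=7)
        ax.set_yticks([0, 1], ["TPJ", "PFC"])
        ax.set_xticks([])
        ax.set_ylim(-0.5, 1.5)
        ax.set_title(f"{dyad_id} - {fam}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline for ``config.n_dyads`` simulated dyads.

    Writes, when ``out_dir`` is given: per-dyad HbO2 TSVs and ground-truth
    sidecars, per-dyad results TSV, a combined results TSV, and a summary
    JSON embedding the config hash. Returns the in-memory report either way.
    """
    from interbrain import io as _io

    config.validate()
    chash = config_hash(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    all_tables: list[pd.DataFrame] = []
    for i in range(config.n_dyads):
        t0 = time.time()
        sim = config.simulation_config(i)
        dyad, truth = generate_dyad(sim)
        if config.apply_bandpass:
            low, high = config.band
            dyad = DyadDataset(
                teacher=HbO2Series(
                    bandpass(dyad.teacher.values, sim.sampling_rate, low, high),
                    sim.sampling_rate, dyad.montage, "band-passed"),
                student=HbO2Series(
                    bandpass(dyad.student.values, sim.sampling_rate, low, high),
                    sim.sampling_rate, dyad.montage, "band-passed"),
                dyad_id=f"dyad-{i + 1}",
                meta=dyad.meta,
            )
        else:
            dyad.dyad_id = f"dyad-{i + 1}"
        split = SplitSpec(fraction_train=config.fraction_train)
        grid = fit_all_channels(
            dyad, split, families=config.families,
            epsilon=config.epsilon, cost=config.cost,
        )
        boundary = split.boundary(dyad.n_samples)
        result = evaluate_dyad(
            dyad, grid, B=config.B, alpha=config.alpha, families=config.families,
            split=split, epsilon=config.epsilon, cost=config.cost,
            acf_threshold=config.acf_threshold,
            max_lag=min(config.max_lag, (boundary - 1) // 2),
            seed=config.dyad_seed(i) ^ 0x5A5A5A,
        )
        table = result.table
        table.insert(0, "config_hash", chash)
        all_tables.append(table)
        logger.info(
            "dyad %d/%d: lag=%d, %.1fs", i + 1, config.n_dyads, result.lag.lag,
            time.time() - t0,
        )
        if out is not None:
            _io.write_hbo2_tsv(dyad.teacher, out / f"dyad{i + 1}_teacher_hbo2.tsv")
            _io.write_hbo2_tsv(dyad.student, out / f"dyad{i + 1}_student_hbo2.tsv")
            _io.write_ground_truth_json(truth, out / f"dyad{i + 1}_truth.json")
            _io.write_model_grid_json(grid, out / f"dyad{i + 1}_models.json")
            _io.write_results(table, out / f"dyad{i + 1}_results.tsv")
            if config.make_figures:
                _significance_figure(table, dyad.dyad_id, out / f"dyad{i + 1}_map.png")
    tables = pd.concat(all_tables, ignore_index=True)
    tables.attrs["alpha"] = config.alpha
    summary = summarize(tables, alpha=config.alpha)
    summary["config_hash"] = chash
    summary["n_dyads"] = config.n_dyads
    if out is not None:
        _io.write_results(tables, out / "results_all.tsv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return RunReport(tables=tables, summary=summary, config_hash=chash, out_dir=out)
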