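"""End-to-end orchestration: configuration, I/O, logging, pipeline run.

A run reads per-subject delimited-text recordings plus a traits table,
preprocesses each subject, sweeps the sparsity grid with null ensembles,
integrates AUCs, identifies cohort-level hubs, and correlates traits with
global metric AUCs.  All outputs are plain text (CSV/JSON) and every run is
reproducible bit for bit from (inputs, config, seed); the archived run log
records the seed, the resolved integration window and the aggregation mode.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import trait_metric_table
from .connectivity import correlation_matrix
from .core import Recording, SparsityGrid, TraitScores
from .preprocess import PreprocessConfig, preprocess
from .sweep import (
    HUB_CRITERIA,
    common_defined_window,
    identify_hubs,
    metric_curves,
    significant_range,
    subject_profile,
)

logger = logging.getLogger("nirsnet")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass(frozen=True)
class ChannelLayout:
    """Measurement-channel geometry: MNI coordinates and cortical labels."""

    table: pd.DataFrame

    @property
    def n_channels(self) -> int:
        return len(self.table)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.table["channel"])


def load_channel_layout(path: str | Path | None = None) -> ChannelLayout:
    """The packaged 12-channel bilateral-dlPFC layout, or a user CSV."""
    if path is None:
        with resources.files("nirsnet.data").joinpath("channel_layout.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = {"channel", "mni_x", "mni_y", "mni_z", "region", "probability"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"channel layout missing columns {sorted(missing)}")
    return ChannelLayout(table=table)


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    input_dir: str = "."
    output_dir: str = "out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    grid: SparsityGrid = field(default_factory=SparsityGrid)
    n_nulls: int = 100
    seed: int = 0
    signal_type: str = "HbO"
    association_window: tuple[float, float] | None = None  # None -> auto
    group_z_mode: str = "per_subject"  # or "group_mean"
    hub_mode: str = "group_mean"  # or "per_subject"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["association_window"] = (
            list(self.association_window) if self.association_window else None
        )
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value config file (YAML-compatible)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pp = PreprocessConfig(**raw.pop("preprocess", {}))
        grid = SparsityGrid(**raw.pop("grid", {}))
        window = raw.pop("association_window", None)
        return cls(
            preprocess=pp,
            grid=grid,
            association_window=tuple(window) if window else None,
            **raw,
        )


def _parse_recording_file(path: Path, default_fs: float, signal_type: str) -> Recording:
    fs = default_fs
    stype = signal_type
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                key, val = token.split("=", 1)
                if key == "sampling_rate_hz":
                    fs = float(val)
                elif key == "signal_type":
                    stype = val
        data = np.loadtxt(path, skiprows=1, ndmin=2)
    else:
        data = np.loadtxt(path, ndmin=2)
    return Recording(data=data, sampling_rate_hz=fs, signal_type=stype)


def load_inputs(
    config: RunConfig, default_fs: float = 50.0
) -> tuple[list[str], list[Recording], list[TraitScores], ChannelLayout]:
    """Load and cross-validate recordings, traits, and the channel layout."""
    in_dir = Path(config.input_dir)
    rec_files = sorted(in_dir.glob("*_timeseries.tsv"))
    if not rec_files:
        raise FileNotFoundError(f"no subjects found in {in_dir}")
    subject_ids = [f.name.replace("_timeseries.tsv", "") for f in rec_files]
    recordings = [
        _parse_recording_file(f, default_fs, config.signal_type) for f in rec_files
    ]
    traits_path = in_dir / "traits.csv"
    if not traits_path.exists():
        raise FileNotFoundError(f"traits table {traits_path} not found")
    traits_df = pd.read_csv(traits_path).set_index("subject")
    missing = [s for s in subject_ids if s not in traits_df.index]
    if missing:
        raise ValueError(f"traits.csv missing subjects {missing}")
    traits = [
        TraitScores.from_array(traits_df.loc[s, ["O", "C", "E", "A", "N"]].to_numpy())
        for s in subject_ids
    ]
    layout_path = in_dir / "channel_layout.csv"
    user_layout = layout_path.exists()
    layout = load_channel_layout(layout_path if user_layout else None)
    n_ch = {r.n_channels for r in recordings}
    if len(n_ch) != 1:
        raise ValueError(f"inconsistent channel counts across subjects: {sorted(n_ch)}")
    n_ch = n_ch.pop()
    if layout.n_channels != n_ch:
        if user_layout:
            raise ValueError(
                f"channel layout has {layout.n_channels} channels "
                f"but recordings have {n_ch}"
            )
        logger.warning(
            "packaged layout has %d channels but recordings have %d; "
            "keeping recordings", layout.n_channels, n_ch,
        )
    return subject_ids, recordings, traits, layout


def run_pipeline(config: RunConfig) -> Path:
    """Preprocess -> connectivity -> sweep -> association, cohort-wide.

    Writes per-subject curves, the AUC table, z/gamma/lambda/sigma reports,
    significant sparsity ranges, the hub report and the association table to
    ``config.output_dir``; returns that directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    subject_ids, recordings, traits, layout = load_inputs(config)
    logger.info("loaded %d subjects, %d channels", len(subject_ids),
                recordings[0].n_channels)

    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(len(subject_ids))

    sweeps = []
    curve_rows = []
    norm_rows = []
    for sid, rec, sseed in zip(subject_ids, recordings, subject_seeds):
        try:
            clean = preprocess(rec, config.preprocess)
            corr = correlation_matrix(clean)
            sw = metric_curves(
                corr, grid=config.grid, n_nulls=config.n_nulls, seed=sseed
            )
        except Exception as exc:  # surface stage + subject, then abort
            raise RuntimeError(f"pipeline failed for {sid}: {exc}") from exc
        sweeps.append(sw)
        for name, curve in sw.curves.items():
            for s, v in zip(curve.grid, curve.values):
                curve_rows.append(
                    {"subject": sid, "sparsity": s, "metric": name, "value": v}
                )
        if config.n_nulls:
            for s, nm, zres in zip(
                sw.grid, sw.normalized,
                zip(*[sw.zscores[m] for m in sw.curves]),
            ):
                row = {"subject": sid, "sparsity": s, **nm.as_dict()}
                for zr in zres:
                    row[f"z_{zr.metric}"] = zr.z
                norm_rows.append(row)
        logger.debug("subject %s swept", sid)

    pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False)
    if norm_rows:
        pd.DataFrame(norm_rows).to_csv(out / "normalized.csv", index=False)

    window = config.association_window
    if window is None:
        window = common_defined_window([sw.curves for sw in sweeps], sweeps[0].grid)
        logger.info("auto integration window: [%.2f, %.2f]", *window)

    profiles = [
        subject_profile(sid, sw, tr, window=window)
        for sid, sw, tr in zip(subject_ids, sweeps, traits)
    ]
    auc_rows = []
    for prof in profiles:
        row = {"subject": prof.subject_id, **prof.global_aucs}
        auc_rows.append(row)
    pd.DataFrame(auc_rows).to_csv(out / "auc.csv", index=False)

    # group-level z per sparsity. Default: mean over subjects of each
    # subject's z against its own nulls. Alternative: z of the group-mean
    # metric against the distribution of the mean of one null draw per
    # subject (independent nulls, so var of the mean = sum(sd^2)/n^2).
    sig_report = {}
    if config.n_nulls:
        for metric in sweeps[0].curves:
            if config.group_z_mode == "group_mean":
                reals = np.vstack(
                    [[zr.x_real for zr in sw.zscores[metric]] for sw in sweeps]
                )
                null_means = np.vstack(
                    [[zr.null_mean for zr in sw.zscores[metric]] for sw in sweeps]
                )
                null_sds = np.vstack(
                    [[zr.null_sd for zr in sw.zscores[metric]] for sw in sweeps]
                )
                n_subj = reals.shape[0]
                with np.errstate(invalid="ignore", divide="ignore"):
                    sd_mean = np.sqrt(np.sum(null_sds**2, axis=0)) / n_subj
                    group_z = (reals.mean(axis=0) - null_means.mean(axis=0)) / sd_mean
            else:
                z_stack = np.vstack([sw.z_array(metric) for sw in sweeps])
                finite = np.isfinite(z_stack)
                with np.errstate(invalid="ignore", divide="ignore"):
                    group_z = np.where(
                        finite.any(axis=0),
                        np.nansum(np.where(finite, z_stack, 0.0), axis=0)
                        / np.maximum(finite.sum(axis=0), 1),
                        np.nan,
                    )
            sig_report[metric] = significant_range(group_z, sweeps[0].grid)
        (out / "significant_ranges.json").write_text(
            json.dumps(sig_report, indent=2, default=_json_default)
        )

    # hubs from the cohort-mean per-node AUCs (per-subject mode available)
    if config.hub_mode == "group_mean":
        mean_nodal = {
            crit: np.mean([p.nodal_aucs[crit] for p in profiles], axis=0)
            for crit in HUB_CRITERIA
        }
        hubs = identify_hubs(mean_nodal)
        hub_payload = {
            "mode": "group_mean",
            "criteria": {
                crit: {
                    "auc": mean_nodal[crit].tolist(),
                    "mean": hubs.means[crit],
                    "sd": hubs.sds[crit],
                    "hubs": np.flatnonzero(hubs.flags[crit]).tolist(),
                }
                for crit in HUB_CRITERIA
            },
            "union_hubs": hubs.hub_nodes(),
            "channel_ids": recordings[0].channel_ids,
        }
    else:
        per_subject = {
            p.subject_id: identify_hubs(p.nodal_aucs).hub_nodes() for p in profiles
        }
        hub_payload = {"mode": "per_subject", "hubs": per_subject}
    (out / "hubs.json").write_text(json.dumps(hub_payload, indent=2, default=_json_default))

    table = trait_metric_table(profiles)
    table.r.to_csv(out / "association_r.csv")
    table.starred().to_csv(out / "association_table.csv")
    table.long_format().to_csv(out / "association_long.csv", index=False)

    config_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (out / "run_config.yaml").write_text(config_text)
    log = {
        "seed": config.seed,
        "n_subjects": len(subject_ids),
        "n_nulls": config.n_nulls,
        "integration_window": list(window),
        "group_z_mode": config.group_z_mode,
        "hub_mode": config.hub_mode,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=_json_default))
    logger.info("run complete: %s", out)
    return out
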