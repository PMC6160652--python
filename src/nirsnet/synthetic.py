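"""Synthetic resting-state cohort generator with a planted, trait-linked effect.

No public dataset pairs multichannel prefrontal hemodynamics with five-factor
personality scores, so validation runs on simulated cohorts whose ground
truth is known.  The generator emulates, per subject:

* five trait totals drawn from a multivariate normal with the field-typical
  means/SDs for young adults and a planted negative conscientiousness-
  neuroticism correlation, truncated to the attainable [12, 60] range;
* an unobserved functional topology — a Watts-Strogatz graph whose rewiring
  probability p increases linearly with the subject's standardized
  conscientiousness (higher p -> more shortcuts -> shorter path length), the
  planted effect the analysis pipeline must recover;
* band-limited (0.01-0.1 Hz) latent hemodynamics whose cross-channel
  correlations are elevated exactly on the topology's edges, built by mixing
  white Gaussian series through a square root of the target correlation
  matrix and band-passing (the same linear filter on every channel leaves
  cross-channel correlations untouched);
* additive physiological nuisance — cardiac (~1 Hz), respiratory (~0.3 Hz)
  and Mayer-wave (~0.1 Hz) sinusoids with per-subject frequency jitter and
  per-channel phase — plus white sensor noise.

Everything is deterministic under the spec seed: sub-streams are derived per
subject and per stage, so cohorts are reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal as _signal

from .core import (
    InvalidSpecError,
    Recording,
    TRAIT_FACTORS,
    TRAIT_SCORE_MAX,
    TRAIT_SCORE_MIN,
    TraitScores,
)

#: nuisance band centers, Hz
NUISANCE_BANDS = {"cardiac": 1.0, "respiratory": 0.3, "mayer": 0.1}

#: trait totals (O, C, E, A, N) typical of young-adult cohorts
DEFAULT_TRAIT_MEANS = (41.57, 45.13, 41.13, 39.80, 28.30)
DEFAULT_TRAIT_SDS = (5.86, 6.60, 7.91, 5.06, 7.55)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of one simulated cohort.

    Defaults reproduce the emulated acquisition: 30 subjects, 12 channels,
    50 Hz, 10-minute recordings.
    """

    n_subjects: int = 30
    n_channels: int = 12
    sampling_rate_hz: float = 50.0
    duration_s: float = 600.0
    trait_means: tuple[float, ...] = DEFAULT_TRAIT_MEANS
    trait_sds: tuple[float, ...] = DEFAULT_TRAIT_SDS
    cn_correlation: float = -0.53
    effect_slope: float = 0.2
    p_base: float = 0.3
    ring_degree: int = 4
    r_in: float = 0.6
    r_out: float = 0.15
    noise_amplitudes: dict = field(
        default_factory=lambda: {
            "cardiac": 0.5,
            "respiratory": 0.4,
            "mayer": 0.3,
            "white": 0.5,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 2:
            raise InvalidSpecError("need n_subjects >= 1 and n_channels >= 2")
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise InvalidSpecError("sampling rate and duration must be positive")
        if len(self.trait_means) != 5 or len(self.trait_sds) != 5:
            raise InvalidSpecError("trait_means and trait_sds must have 5 entries")
        if any(sd <= 0 for sd in self.trait_sds):
            raise InvalidSpecError("trait SDs must be positive")
        if not -1.0 < self.cn_correlation < 1.0:
            raise InvalidSpecError("cn_correlation must lie in (-1, 1)")
        if self.ring_degree % 2 or self.ring_degree >= self.n_channels:
            raise InvalidSpecError(
                "ring_degree must be even and < n_channels "
                f"(got k={self.ring_degree}, N={self.n_channels})"
            )

    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass
class GenerativeTopology:
    """A subject's planted Watts-Strogatz topology."""

    subject_id: str
    ring_degree: int
    rewiring_p: float
    adjacency: np.ndarray


@dataclass
class Cohort:
    """Paired recordings + traits, with the manifest of planted parameters."""

    recordings: list[Recording]
    traits: list[TraitScores]
    topologies: list[GenerativeTopology]
    manifest: pd.DataFrame
    spec: CohortSpec


def _stream(spec_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(spec_seed), *map(int, key)])


def gen_trait_scores(spec: CohortSpec) -> list[TraitScores]:
    """Draw the cohort's five-factor totals.

    Multivariate normal with the spec means/SDs; the conscientiousness-
    neuroticism pair carries the spec's planted correlation, all other pairs
    are independent.  Totals are truncated to [12, 60] (a mild distortion at
    the defaults, where the bounds sit >2 SD from every mean).
    """
    if spec.n_subjects < 3:
        raise InvalidSpecError("trait generation needs n_subjects >= 3")
    sds = np.asarray(spec.trait_sds)
    cov = np.diag(sds**2)
    i_c, i_n = TRAIT_FACTORS.index("conscientiousness"), TRAIT_FACTORS.index("neuroticism")
    cov[i_c, i_n] = cov[i_n, i_c] = spec.cn_correlation * sds[i_c] * sds[i_n]
    rng = np.random.default_rng(_stream(spec.seed, 0))
    raw = rng.multivariate_normal(spec.trait_means, cov, size=spec.n_subjects,
                                  method="cholesky")
    clipped = np.clip(raw, TRAIT_SCORE_MIN, TRAIT_SCORE_MAX)
    return [TraitScores.from_array(row) for row in clipped]


def gen_subject_topology(
    traits: TraitScores,
    spec: CohortSpec,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sub-01",
) -> GenerativeTopology:
    """A subject's Watts-Strogatz graph, rewired according to conscientiousness.

    p = clamp(p_base + effect_slope * z(C), 0, 1), where z standardizes
    conscientiousness by the spec's population mean and SD (not the sample's,
    so the planted map is identical across cohorts).
    """
    i_c = TRAIT_FACTORS.index("conscientiousness")
    z = (traits.conscientiousness - spec.trait_means[i_c]) / spec.trait_sds[i_c]
    p = float(np.clip(spec.p_base + spec.effect_slope * z, 0.0, 1.0))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    nx_seed = int(ss.generate_state(1)[0])
    graph = nx.watts_strogatz_graph(spec.n_channels, spec.ring_degree, p, seed=nx_seed)
    adjacency = nx.to_numpy_array(graph, nodelist=range(spec.n_channels), dtype=np.int8)
    return GenerativeTopology(
        subject_id=subject_id, ring_degree=spec.ring_degree, rewiring_p=p,
        adjacency=adjacency,
    )


def _target_correlation(adjacency: np.ndarray, r_in: float, r_out: float) -> np.ndarray:
    """Valid correlation matrix with r_in on edges, r_out elsewhere.

    If the patterned matrix is not positive semidefinite it is projected by
    eigenvalue clipping and rescaled back to unit diagonal.
    """
    n = adjacency.shape[0]
    sigma = np.where(adjacency > 0, r_in, r_out).astype(float)
    np.fill_diagonal(sigma, 1.0)
    w = np.linalg.eigvalsh(sigma)
    if w[0] < 1e-10:
        vals, vecs = np.linalg.eigh(sigma)
        sigma = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    return sigma


def gen_timeseries(
    topology: GenerativeTopology,
    spec: CohortSpec,
    seed: int | np.random.SeedSequence,
) -> Recording:
    """One subject's channels x samples recording.

    Latent band-limited hemodynamics realize the topology's correlation
    structure; nuisance sinusoids and white noise are added at the spec
    amplitudes (in units of the unit-variance latent signal).
    """
    n_samples = spec.n_samples()
    if n_samples < 2 * spec.n_channels:
        raise InvalidSpecError("recording too short for the channel count")
    rng = np.random.default_rng(seed)
    sigma = _target_correlation(topology.adjacency, spec.r_in, spec.r_out)
    vals, vecs = np.linalg.eigh(sigma)
    mixing = vecs * np.sqrt(np.clip(vals, 0.0, None))
    latent = mixing @ rng.standard_normal((spec.n_channels, n_samples))
    sos = _signal.butter(3, [0.01, 0.1], btype="bandpass",
                         fs=spec.sampling_rate_hz, output="sos")
    latent = _signal.sosfiltfilt(sos, latent, axis=1)
    sd = latent.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    data = latent / sd

    t = np.arange(n_samples) / spec.sampling_rate_hz
    for band, base_freq in NUISANCE_BANDS.items():
        amp = float(spec.noise_amplitudes.get(band, 0.0))
        if amp == 0.0:
            continue
        freq = base_freq * (1.0 + 0.1 * rng.uniform(-1.0, 1.0))  # +/-10% jitter
        phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_channels)
        data = data + amp * np.sin(2.0 * np.pi * freq * t[None, :] + phases[:, None])
    white = float(spec.noise_amplitudes.get("white", 0.0))
    if white > 0.0:
        data = data + white * rng.standard_normal(data.shape)
    return Recording(
        data=data,
        sampling_rate_hz=spec.sampling_rate_hz,
        signal_type="HbO",
        channel_ids=[f"CH{i + 1:02d}" for i in range(spec.n_channels)],
    )


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort with a manifest of planted parameters."""
    traits = gen_trait_scores(spec)
    recordings: list[Recording] = []
    topologies: list[GenerativeTopology] = []
    rows = []
    for i, tr in enumerate(traits):
        sid = f"sub-{i + 1:02d}"
        topo = gen_subject_topology(tr, spec, _stream(spec.seed, 1, i), subject_id=sid)
        rec = gen_timeseries(topo, spec, _stream(spec.seed, 2, i))
        topologies.append(topo)
        recordings.append(rec)
        rows.append(
            {
                "subject": sid,
                **{f: getattr(tr, f) for f in TRAIT_FACTORS},
                "rewiring_p": topo.rewiring_p,
                "ring_degree": topo.ring_degree,
            }
        )
    manifest = pd.DataFrame(rows)
    return Cohort(recordings=recordings, traits=traits, topologies=topologies,
                  manifest=manifest, spec=spec)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write recordings (TSV, one row per channel), traits CSV, and the
    JSON manifest of planted parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trait_rows = []
    for rec, tr, topo in zip(cohort.recordings, cohort.traits, cohort.topologies):
        sid = topo.subject_id
        header = (
            f"# subject={sid} sampling_rate_hz={rec.sampling_rate_hz} "
            f"signal_type={rec.signal_type}"
        )
        path = out / f"{sid}_timeseries.tsv"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, rec.data, delimiter="\t", fmt="%.10g")
        trait_rows.append(
            {
                "subject": sid,
                "O": tr.openness,
                "C": tr.conscientiousness,
                "E": tr.extraversion,
                "A": tr.agreeableness,
                "N": tr.neuroticism,
            }
        )
    pd.DataFrame(trait_rows).to_csv(out / "traits.csv", index=False)
    manifest = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cohort.spec).items()
            if not isinstance(v, dict)
        },
        "noise_amplitudes": cohort.spec.noise_amplitudes,
        "subjects": cohort.manifest.to_dict(orient="records"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
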