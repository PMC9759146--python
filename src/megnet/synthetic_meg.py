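"""Synthetic multi-channel source-level ("virtual sensor") recordings.

Generates multi-subject resting-state-like recordings with a known band-wise
coupling structure so that every downstream stage — filtering, artifact
handling, correlation thresholding, graph metrics, group statistics — can be
tested against ground truth without real MEG data.

Construction. Each node's signal is a sum over frequency bands of
band-limited Gaussian components. Within a band the cross-node correlation
structure is imposed exactly by Cholesky-mixing i.i.d. band-limited noises
with the target correlation matrix, which for a single planted edge (i, j)
with correlation rho reduces to the shared-variance form
``x_i = sqrt(rho) z_common + sqrt(1 - rho) z_i``. Components are synthesized
in the frequency domain, confined to the band interior with a small spectral
guard margin (5% of the band width on each side by default). The margin
keeps each component strictly inside the flat passband of the Butterworth
analysis filter, so band-pass filtering acts identically on shared and
private parts and the expected band-filtered Pearson correlation of a
planted pair equals rho; the disjoint spectral supports also make the band
components of one node exactly uncorrelated.

Units are nominal picotesla so the 6 pT amplitude-artifact rule is
meaningful; the default background SD is 0.5 pT split evenly across bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bands import DEFAULT_BANDS, BandDefinition

__all__ = [
    "SimulationConfig",
    "VirtualSensorRecording",
    "ConfigError",
    "default_roles",
    "generate_recording",
    "generate_cohort",
    "inject_spikes",
    "GROUP_IMPAIRED",
    "GROUP_NON_IMPAIRED",
    "GROUP_CONTROL",
]

GROUP_IMPAIRED = "impaired"
GROUP_NON_IMPAIRED = "non_impaired"
GROUP_CONTROL = "control"
DEFAULT_GROUPS = (GROUP_IMPAIRED, GROUP_NON_IMPAIRED, GROUP_CONTROL)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class VirtualSensorRecording:
    """A samples x nodes source-level time-series matrix.

    ``annotations`` holds (onset_s, duration_s, kind) event markers with
    kind in {"spike", "artifact"}.
    """

    data: np.ndarray
    fs: float
    node_labels: list[str]
    node_roles: list[str] = field(default_factory=list)
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D samples x nodes array")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        if not self.node_roles:
            self.node_roles = ["other"] * self.data.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def default_roles(n_nodes: int, n_frontal: int = 4, n_pcc: int = 4) -> list[str]:
    """Role labels: the first nodes frontal, the next PCC, the rest other."""
    if n_frontal + n_pcc > n_nodes:
        raise ConfigError("n_frontal + n_pcc exceeds n_nodes")
    return ["frontal"] * n_frontal + ["pcc"] * n_pcc + ["other"] * (n_nodes - n_frontal - n_pcc)


@dataclass
class SimulationConfig:
    """Ground-truth description of a synthetic cohort.

    planted_edges entries are (node_i, node_j, band_name, rho) with rho the
    target expected band-filtered correlation, |rho| < 1. group_effects maps
    a group label to {(role_a, role_b, band_name): multiplier} applied to the
    rho of planted edges whose node roles match the (unordered) role pair.
    ``noise_sd`` is the total background SD in nominal pT, split evenly
    across bands; ``subject_rho_sd`` adds between-subject jitter to each
    planted rho (truncated to keep |rho| < 1).
    """

    n_nodes: int = 20
    node_roles: list[str] | None = None
    fs: float = 6000.0
    duration: float = 120.0
    bands: Sequence[BandDefinition] = DEFAULT_BANDS
    planted_edges: list[tuple[int, int, str, float]] = field(default_factory=list)
    group_effects: Mapping[str, Mapping[tuple[str, str, str], float]] = field(default_factory=dict)
    noise_sd: float = 0.5
    subject_rho_sd: float = 0.0
    guard_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.node_roles is None:
            self.node_roles = default_roles(self.n_nodes)
        if len(self.node_roles) != self.n_nodes:
            raise ConfigError("node_roles length must equal n_nodes")
        hi = max(b.hi for b in self.bands)
        if self.fs <= 2 * hi:
            raise ConfigError(f"fs={self.fs} must exceed twice the highest band edge ({hi} Hz)")
        band_names = {b.name for b in self.bands}
        for i, j, band, rho in self.planted_edges:
            if i == j or not (0 <= i < self.n_nodes) or not (0 <= j < self.n_nodes):
                raise ConfigError(f"invalid planted edge nodes ({i}, {j})")
            if band not in band_names:
                raise ConfigError(f"planted edge references unknown band {band!r}")
            if not -1 < rho < 1:
                raise ConfigError(f"planted rho must satisfy |rho| < 1, got {rho}")

    @property
    def node_labels(self) -> list[str]:
        return [f"{role}_{i}" for i, role in enumerate(self.node_roles)]

    def edge_rho(self, group: str | None = None, rng: np.random.Generator | None = None) -> list[tuple[int, int, str, float]]:
        """Planted edges with group multipliers (and optional subject jitter) applied."""
        effects = dict(self.group_effects.get(group, {})) if group else {}
        out = []
        for i, j, band, rho in self.planted_edges:
            pair = tuple(sorted((self.node_roles[i], self.node_roles[j])))
            mult = effects.get((*pair, band), effects.get((pair[1], pair[0], band), 1.0))
            r = rho * mult
            if rng is not None and self.subject_rho_sd > 0:
                r = float(np.clip(r + rng.normal(0.0, self.subject_rho_sd), -0.99, 0.99))
            out.append((i, j, band, r))
        return out


def generate_recording(
    config: SimulationConfig,
    group: str | None = None,
    rng: np.random.Generator | None = None,
) -> VirtualSensorRecording:
    """Generate one recording with the configured band-wise coupling.

    Deterministic given the config seed (or the supplied ``rng``). *group*
    selects which group_effects multipliers apply.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration))
    band_sd = config.noise_sd / np.sqrt(len(config.bands))
    edges = config.edge_rho(group, rng=None if config.subject_rho_sd == 0 else rng)
    # one white-noise field per node; disjoint spectral masks make the band
    # components mutually uncorrelated, so a single FFT pair suffices
    white = rng.standard_normal((n, config.n_nodes))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    out_spec = np.zeros_like(spec)
    for band in config.bands:
        corr = np.eye(config.n_nodes)
        for i, j, bname, rho in edges:
            if bname == band.name:
                corr[i, j] = corr[j, i] = rho
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigError(f"planted correlations in band {band.name!r} are not positive definite") from exc
        g = config.guard_frac * band.width
        mask = (freqs >= band.lo + g) & (freqs <= band.hi - g)
        if not mask.any():
            raise ConfigError(f"band {band.name!r} has no spectral support at fs={config.fs}")
        comp = spec[mask] @ chol.T
        # exact per-column variance via Parseval (DC and Nyquist bins are masked out)
        var = 2.0 * (np.abs(comp) ** 2).sum(axis=0) / n**2
        comp *= band_sd / np.sqrt(var)
        out_spec[mask] = comp
    data = np.fft.irfft(out_spec, n=n, axis=0)
    return VirtualSensorRecording(
        data=data,
        fs=config.fs,
        node_labels=config.node_labels,
        node_roles=list(config.node_roles),
    )


def generate_cohort(
    config: SimulationConfig,
    n_per_group: int | Mapping[str, int],
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> list[tuple[VirtualSensorRecording, str]]:
    """Generate a labelled cohort of recordings.

    ``n_per_group`` is an int (same size for every group) or a mapping
    group -> size. Per-subject seeds derive deterministically from the base
    seed and the subject index.
    """
    sizes = {g: n_per_group for g in groups} if isinstance(n_per_group, int) else dict(n_per_group)
    out: list[tuple[VirtualSensorRecording, str]] = []
    idx = 0
    for g in groups:
        for _ in range(int(sizes.get(g, 0))):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, idx]))
            out.append((generate_recording(config, group=g, rng=rng), g))
            idx += 1
    return out


def _spike_waveform(fs: float, duration_s: float = 0.06) -> np.ndarray:
    """Brief biphasic transient: one windowed sine period (< 100 ms)."""
    k = max(4, int(round(duration_s * fs)))
    t = np.arange(k) / k
    w = np.sin(2 * np.pi * t) * np.hanning(k)
    return w / np.abs(w).max()  # unit peak so the amplitude argument is the peak value


def inject_spikes(
    rec: VirtualSensorRecording,
    rate: float,
    amplitude: float,
    seed: int = 0,
    duration_s: float = 0.06,
) -> VirtualSensorRecording:
    """Add Poisson-timed biphasic spike transients of the given peak amplitude.

    ``rate`` is in events per minute; each event hits every channel with a
    random gain in [0.6, 1]. Annotations gain one (onset, duration, "spike")
    entry per event. Rate 0 returns the recording unchanged.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return rec
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate * rec.duration / 60.0)
    data = rec.data.copy()
    annotations = list(rec.annotations)
    wave = _spike_waveform(rec.fs, duration_s) * amplitude
    k = len(wave)
    for _ in range(n_events):
        onset = rng.uniform(0.0, rec.duration - duration_s)
        i0 = int(round(onset * rec.fs))
        gains = rng.uniform(0.9, 1.0, size=rec.n_nodes)
        data[i0 : i0 + k] += wave[: data.shape[0] - i0, None] * gains[None, :]
        annotations.append((onset, duration_s, "spike"))
    return replace(rec, data=data, annotations=sorted(annotations))
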