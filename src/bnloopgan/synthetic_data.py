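"""Synthetic two-class connectivity datasets for end-to-end testing.

The generator emulates a balanced case/control cohort of symmetric
region-by-region networks: a single base connectome shared by everyone,
plus (for the abnormal class) a mean shift on a configurable subset of
edges, plus independent symmetric Gaussian edge noise.  ``effect_size``
is the standardized mean difference on the affected edges (mean shift =
effect_size * noise_sd), so effect_size 0 is an exact null.  Each
modality channel draws its own effect mask, so channels carry
complementary signal.

A companion latent-factor model emits regional time series whose
population correlation structure differs between classes, for testing
the functional-network construction path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_construction import (FUNCTIONAL, STRUCTURAL, ConnectivityMatrix,
                                   MultiModalSample, TimeSeriesSet)

#: Default desk-scale geometry: 40 regions, 40 subjects per class, two
#: modalities.  The full-cohort geometry (164 regions, 42 + 42 subjects)
#: is available via :func:`paper_geometry`.
DEFAULT_N_REGIONS = 40
DEFAULT_N_PER_CLASS = 40


@dataclass
class SyntheticSpec:
    n_regions: int = DEFAULT_N_REGIONS
    n_per_class: int = DEFAULT_N_PER_CLASS
    n_modalities: int = 2
    effect_edges: float = 0.1
    effect_size: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 4:
            raise ValueError("need at least 4 regions")
        if not 0.0 <= self.effect_edges <= 1.0:
            raise ValueError("effect_edges must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        n_edges = self.n_regions * (self.n_regions - 1) // 2
        if self.effect_size > 0 and self.effect_edges * n_edges < 1:
            raise ValueError("effect_edges selects no edge at this size")


def paper_geometry(**overrides) -> SyntheticSpec:
    """Full-cohort geometry: 164 regions, 42 subjects per class."""
    kw = dict(n_regions=164, n_per_class=42)
    kw.update(overrides)
    return SyntheticSpec(**kw)


def _modality_name(k: int) -> str:
    return FUNCTIONAL if k % 2 == 0 else STRUCTURAL


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


def generate_connectomes(spec: SyntheticSpec) -> list[MultiModalSample]:
    """Balanced labeled dataset of multi-channel symmetric matrices.

    Channel conventions follow the modality: even channels are
    functional-like (unit diagonal, entries clipped to [-1, 1]), odd
    channels structural-like (non-negative, zero diagonal).
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.n_regions
    iu = np.triu_indices(r, k=1)
    n_edges = iu[0].size
    n_effect = int(round(spec.effect_edges * n_edges))

    bases, masks = [], []
    for k in range(spec.n_modalities):
        if _modality_name(k) == FUNCTIONAL:
            base = _symmetrize(rng.uniform(-0.8, 0.8, size=(r, r)))
        else:
            base = _symmetrize(rng.uniform(0.0, 1.0, size=(r, r)))
        mask = np.zeros((r, r))
        if n_effect:
            chosen = rng.choice(n_edges, size=n_effect, replace=False)
            mask[iu[0][chosen], iu[1][chosen]] = 1.0
            mask = mask + mask.T
        bases.append(base)
        masks.append(mask)

    shift = spec.effect_size * spec.noise_sd
    samples: list[MultiModalSample] = []
    for idx in range(2 * spec.n_per_class):
        label = idx % 2                       # alternate HC / AB
        sid = f"sub{idx:04d}"
        chans = []
        for k in range(spec.n_modalities):
            noise = _symmetrize(rng.normal(0.0, spec.noise_sd, size=(r, r)))
            m = bases[k] + label * shift * masks[k] + noise
            modality = _modality_name(k)
            if modality == FUNCTIONAL:
                m = np.clip(m, -1.0, 1.0)
                np.fill_diagonal(m, 1.0)
            else:
                m = np.clip(m, 0.0, None)
                np.fill_diagonal(m, 0.0)
            chans.append(ConnectivityMatrix(sid, modality, m))
        samples.append(MultiModalSample(sid, chans, label))
    return samples


@dataclass
class TimeSeriesModel:
    """Latent-factor time-series generator with per-class loadings."""

    spec: SyntheticSpec
    loadings: dict[int, np.ndarray] = field(default_factory=dict)
    series_noise_sd: float = 0.3

    def __post_init__(self):
        rng = np.random.default_rng(self.spec.seed + 1)
        r = self.spec.n_regions
        n_factors = max(2, r // 8)
        base = rng.normal(0.0, 1.0, size=(r, n_factors))
        self.loadings[0] = base
        pert = rng.normal(0.0, self.spec.effect_size * 0.3, size=base.shape)
        self.loadings[1] = base + pert

    def target_correlation(self, label: int) -> np.ndarray:
        load = self.loadings[label]
        cov = load @ load.T + self.series_noise_sd ** 2 * np.eye(load.shape[0])
        d = 1.0 / np.sqrt(np.diag(cov))
        return cov * np.outer(d, d)


def generate_timeseries(spec: SyntheticSpec, t: int) -> list[TimeSeriesSet]:
    """Regional time series whose correlations follow the class model."""
    if t < 3:
        raise ValueError("need at least 3 timepoints")
    model = TimeSeriesModel(spec)
    rng = np.random.default_rng(spec.seed + 2)
    out: list[TimeSeriesSet] = []
    for idx in range(2 * spec.n_per_class):
        label = idx % 2
        load = model.loadings[label]
        factors = rng.normal(size=(load.shape[1], t))
        noise = rng.normal(0.0, model.series_noise_sd,
                           size=(spec.n_regions, t))
        series = load @ factors + noise
        out.append(TimeSeriesSet(
            subject_id=f"sub{idx:04d}",
            regions=[f"r{i}" for i in range(spec.n_regions)],
            series=series))
    return out
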