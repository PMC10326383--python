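"""Symmetry-preserving cyclic augmentation and min-max scaling.

One augmentation step moves a matrix's first column to the last column
and then its first row to the last row.  Because row and column are
moved together, the step is a simultaneous cyclic relabeling of the
regions — a permutation similarity — so symmetry (and the eigenvalue
spectrum) is preserved.  Repeating the step on each newly produced
matrix yields R - 1 distinct variants before the original recurs, e.g.
163 additional matrices from one 164-region network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_construction import ConnectivityMatrix, MultiModalSample


@dataclass
class AugmentationOrbit:
    """A source sample together with its R - 1 shifted variants.

    ``variants[k - 1]`` carries ``shift == k``, the number of
    column-then-row moves applied to the source.
    """

    source: MultiModalSample
    variants: list[MultiModalSample]

    def __post_init__(self):
        if len(self.variants) != self.source.n_regions - 1:
            raise ValueError("orbit must hold exactly R - 1 variants")

    def all_samples(self) -> list[MultiModalSample]:
        return [self.source] + list(self.variants)


def cyclic_shift(m: np.ndarray) -> np.ndarray:
    """One column-then-row cyclic move: out[i, j] = in[(i+1) % R, (j+1) % R]."""
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("cyclic_shift requires a square matrix")
    return np.roll(m, shift=(-1, -1), axis=(0, 1))


def augment(sample: MultiModalSample) -> AugmentationOrbit:
    """All R - 1 shifted variants of a sample, channels shifted in lockstep.

    Variant k applies ``cyclic_shift`` k times to every channel; the
    region labels are rotated identically so each variant is a valid
    (relabeled) network carrying the source's subject id and label.
    """
    r = sample.n_regions
    variants: list[MultiModalSample] = []
    mats = [c.matrix for c in sample.channels]
    regions = [list(c.regions) for c in sample.channels]
    for k in range(1, r):
        mats = [cyclic_shift(m) for m in mats]
        regions = [labels[1:] + labels[:1] for labels in regions]
        chans = [ConnectivityMatrix(c.subject_id, c.modality, m, list(lbls))
                 for c, m, lbls in zip(sample.channels, mats, regions)]
        variants.append(MultiModalSample(sample.subject_id, chans, sample.label,
                                         is_original=False, shift=k))
    return AugmentationOrbit(sample, variants)


def minmax_scale(m: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]: (m - min) / (max - min)."""
    m = np.asarray(m, dtype=float)
    lo, hi = m.min(), m.max()
    if hi == lo:
        raise ValueError("min-max scaling undefined for a constant matrix")
    return (m - lo) / (hi - lo)


def scale_sample(sample: MultiModalSample) -> MultiModalSample:
    """Min-max scale each channel independently (per subject, per channel).

    Scaling is per sample so no statistic crosses the train/test split,
    and the result lands in the [0, 1] range of the generator's Sigmoid
    output.  Scaled channels are plain weighted networks, so modality
    range conventions no longer apply and channels become ``structural``-
    tagged non-negative matrices with their diagonal preserved as data.
    """
    chans = []
    for c in sample.channels:
        scaled = minmax_scale(c.matrix)
        scaled = (scaled + scaled.T) / 2.0
        chans.append(ConnectivityMatrix(c.subject_id, "structural", scaled,
                                        list(c.regions)))
    return MultiModalSample(sample.subject_id, chans, sample.label,
                            is_original=sample.is_original, shift=sample.shift)


def split_dataset(samples: list, fraction: float, mode: str = "matrix_level",
                  seed: int = 0) -> tuple[list, list]:
    """Deterministic train/test split.

    ``matrix_level`` splits over individual (possibly augmented)
    matrices, mirroring an 80/20 pool over all enhanced matrices;
    ``subject_level`` keeps every variant of a subject on one side,
    which removes the leakage risk of augmented copies straddling the
    split.  Train size is floor(fraction * total) at matrix level (and
    floor over subjects at subject level); assignment is a seeded
    shuffle.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if mode not in ("matrix_level", "subject_level"):
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "matrix_level":
        order = rng.permutation(len(samples))
        n_train = int(np.floor(fraction * len(samples)))
        train_idx = set(order[:n_train].tolist())
        train = [s for i, s in enumerate(samples) if i in train_idx]
        test = [s for i, s in enumerate(samples) if i not in train_idx]
        return train, test
    subjects = sorted({s.subject_id for s in samples})
    n_train_subj = int(np.floor(fraction * len(subjects)))
    if n_train_subj < 1 or n_train_subj >= len(subjects):
        raise ValueError(
            f"too few subjects ({len(subjects)}) for a subject-level "
            f"split at fraction {fraction}")
    order = rng.permutation(len(subjects))
    train_subj = {subjects[i] for i in order[:n_train_subj]}
    train = [s for s in samples if s.subject_id in train_subj]
    test = [s for s in samples if s.subject_id not in train_subj]
    return train, test
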