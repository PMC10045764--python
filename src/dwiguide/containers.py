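"""Shared in-memory containers for multi-NEX DWI data.

Volumes are numpy arrays with the slice axis first, shape ``(n_slices, H, W)``
(single slices are 2-D ``(H, W)`` arrays).  Magnitude images are nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RepetitionStack", "DWISeries", "PatchTriple"]


@dataclass
class RepetitionStack:
    """Per-excitation magnitude images for one slice volume at one b-value.

    ``repetitions`` has shape ``(nex, ...)``: the leading axis indexes the
    individual excitations, pre-averaging.
    """

    b_value: float
    repetitions: np.ndarray
    seed_used: int

    def __post_init__(self) -> None:
        self.repetitions = np.asarray(self.repetitions)
        if self.repetitions.ndim < 3:
            raise ValueError("repetitions must be (nex, H, W) or (nex, S, H, W)")

    @property
    def nex(self) -> int:
        return self.repetitions.shape[0]


@dataclass
class DWISeries:
    """Aligned guide / noisy / reference volumes for one subject.

    guide
        Low b-value volume (averaged over the low-b excitations), the
        anatomical guide channel.
    noisy
        Mapping from NEX in {1, 2, 4} to the high b-value volume averaged
        over that many excitations.
    reference
        High b-value volume averaged over all 16 excitations.
    norm_scale_highb, norm_scale_guide
        Divisors that have been applied to (noisy, reference) and guide
        respectively; 1.0 means raw simulator units.
    """

    guide: np.ndarray
    noisy: dict[int, np.ndarray]
    reference: np.ndarray
    subject_id: str
    norm_scale_highb: float = 1.0
    norm_scale_guide: float = 1.0
    b_low: float = 50.0
    b_high: float = 800.0

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference)
        if np.asarray(self.guide).shape != ref.shape:
            raise ValueError("guide and reference volumes must share shape")
        for n, vol in self.noisy.items():
            if np.asarray(vol).shape != ref.shape:
                raise ValueError(f"noisy NEX={n} volume shape mismatch")
        if self.norm_scale_highb <= 0 or self.norm_scale_guide <= 0:
            raise ValueError("normalization scales must be positive")

    @property
    def n_slices(self) -> int:
        return self.reference.shape[0]

    @property
    def nex_levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.noisy))


@dataclass
class PatchTriple:
    """Co-located guide / noisy / reference patches — the training unit.

    ``origin`` is ``(slice, row, col)`` of the top-left corner, 0-based.
    ``augmentation_id`` indexes the dihedral-group operation already applied
    (0 = identity).
    """

    guide_patch: np.ndarray
    noisy_patch: np.ndarray
    reference_patch: np.ndarray
    origin: tuple[int, int, int]
    augmentation_id: int = 0
    nex: int = field(default=1)

    def __post_init__(self) -> None:
        if not (self.guide_patch.shape == self.noisy_patch.shape == self.reference_patch.shape):
            raise ValueError("patch triple members must share shape")
        if not 0 <= self.augmentation_id <= 7:
            raise ValueError("augmentation_id must be in [0, 7]")
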