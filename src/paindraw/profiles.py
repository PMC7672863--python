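"""Per-disease pain profiles: pixel-wise averages of binary drawings.

A pain profile is the overlap of all drawings from one disease: each cell
holds the fraction of contributing drawings that marked that pixel.  The
count grid is stored as integers so cell values are exact rationals
(count / n); the float grid is derived on demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PainDrawing

__all__ = ["PainProfile", "compute_profile", "leave_one_out_profile",
           "render_profile"]


@dataclass(frozen=True)
class PainProfile:
    disease_label: str
    counts: np.ndarray        # int, per-pixel number of drawings marking
    n_contributors: int

    def __post_init__(self):
        if self.n_contributors < 1:
            raise ValueError("a profile needs at least one contributor")
        if self.counts.min() < 0 or self.counts.max() > self.n_contributors:
            raise ValueError("counts outside [0, n_contributors]")

    @property
    def grid(self) -> np.ndarray:
        """Fraction of contributors marking each pixel, in [0, 1]."""
        return self.counts / self.n_contributors


def compute_profile(drawings: list[PainDrawing]) -> PainProfile:
    """Average the binary masks of one disease's non-excluded drawings."""
    if not drawings:
        raise ValueError("cannot average an empty drawing list")
    labels = {d.label for d in drawings}
    if len(labels) != 1:
        raise ValueError(f"mixed disease labels in one profile: {sorted(labels)}")
    shape = drawings[0].mask.shape
    counts = np.zeros(shape, dtype=np.int32)
    for d in drawings:
        if d.excluded:
            raise ValueError(f"excluded drawing {d.id!r} passed to compute_profile")
        if d.mask.shape != shape:
            raise ValueError("all masks must share the canvas dimensions")
        counts += d.mask.astype(np.int32)
    return PainProfile(disease_label=labels.pop(), counts=counts,
                       n_contributors=len(drawings))


def leave_one_out_profile(drawings: list[PainDrawing], held_out_id: str) -> PainProfile:
    """Profile over all drawings except the held-out one."""
    ids = [d.id for d in drawings]
    if held_out_id not in ids:
        raise KeyError(f"held-out id {held_out_id!r} not in cohort")
    rest = [d for d in drawings if d.id != held_out_id]
    if not rest:
        raise ValueError("leave-one-out needs at least 2 drawings")
    return compute_profile(rest)


# -- rendering --------------------------------------------------------------

# RGB anchors for the diverging profile colormap (band semantics: white for
# never-marked, blue shades below the 50% mark, green exactly at it, yellow
# to red above it).
_WHITE = np.array([1.0, 1.0, 1.0])
_LIGHT_BLUE = np.array([0.80, 0.90, 1.00])
_BLUE = np.array([0.05, 0.25, 0.85])
_GREEN = np.array([0.00, 0.70, 0.20])
_YELLOW = np.array([1.00, 0.90, 0.10])
_RED = np.array([0.85, 0.05, 0.05])


def render_profile(profile: PainProfile) -> np.ndarray:
    """Render a profile as an RGB uint8 heatmap.

    0 -> white; (0, 0.5) -> light-blue..blue gradient; 0.5 (within half of
    one count step) -> green; (0.5, 1] -> yellow..red gradient.
    """
    v = profile.grid
    img = np.ones(v.shape + (3,), dtype=float)
    half_step = 1.0 / (2.0 * profile.n_contributors)
    at_half = np.abs(v - 0.5) < half_step / 2.0
    below = (v > 0) & (v < 0.5) & ~at_half
    above = (v > 0.5) & ~at_half
    t = (v[below] / 0.5)[:, None]
    img[below] = _LIGHT_BLUE + t * (_BLUE - _LIGHT_BLUE)
    img[at_half] = _GREEN
    t = ((v[above] - 0.5) / 0.5)[:, None]
    img[above] = _YELLOW + t * (_RED - _YELLOW)
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
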