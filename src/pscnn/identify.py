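"""Database screening: which library compounds are in a mixture spectrum?

The mixture spectrum is paired with every entry of the spectral library,
each pair's inclusion probability is predicted by the trained two-branch
model, and entries with probability strictly greater than the threshold
(default 0.5) are reported as candidates, ranked from high to low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PSCNN
from .spectra import SpectralLibrary, Spectrum

__all__ = ["IdentificationResult", "identify"]


@dataclass
class IdentificationResult:
    """Per-entry probabilities plus the thresholded, ranked candidate list."""

    names: list[str]
    probabilities: np.ndarray  # in library order
    threshold: float
    candidates: list[tuple[int, str, float]] = field(init=False)

    def __post_init__(self) -> None:
        hits = [
            (i, self.names[i], float(p))
            for i, p in enumerate(self.probabilities)
            if p > self.threshold
        ]
        # descending probability; ties broken by library index
        self.candidates = sorted(hits, key=lambda t: (-t[2], t[0]))

    @property
    def candidate_indices(self) -> list[int]:
        return [i for i, _, _ in self.candidates]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (name, index, probability, is_candidate), ranked."""
        order = np.argsort(-self.probabilities, kind="stable")
        return pd.DataFrame(
            {
                "name": [self.names[i] for i in order],
                "index": order,
                "probability": self.probabilities[order],
                "is_candidate": self.probabilities[order] > self.threshold,
            }
        )


def identify(
    model: PSCNN,
    library: SpectralLibrary,
    mixture: Spectrum,
    threshold: float = 0.5,
) -> IdentificationResult:
    """Screen every library entry against ``mixture``.

    The mixture must already be on the library grid (use
    :func:`pscnn.spectra.resample` otherwise) and preprocessed the same way
    as the training mixtures (unit-max normalization, optional solvent
    masking).
    """
    if len(library) == 0:
        raise ValueError("cannot identify against an empty library")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if len(mixture) != len(library.grid) or not np.allclose(
        mixture.ppm, library.grid, rtol=0.0, atol=1e-9
    ):
        raise ValueError("mixture spectrum is not on the library grid")
    x_pure = library.matrix().astype(np.float32)
    x_mix = np.broadcast_to(
        mixture.intensities.astype(np.float32), x_pure.shape
    ).copy()
    probs = model.predict(x_pure, x_mix)
    return IdentificationResult(
        names=library.names, probabilities=probs, threshold=threshold
    )
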