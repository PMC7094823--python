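"""Recorded trajectories: per-compartment species counts over time."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """Counts sampled on a fixed grid of times.

    ``counts`` has shape (n_times, n_compartments, n_species); event
    ``tallies`` hold the number of firings of each reaction channel over
    the whole run.
    """

    times: np.ndarray
    counts: np.ndarray
    compartment_names: list[str]
    species_names: list[str]
    tallies: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    channel_names: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.counts.shape != (
            len(self.times),
            len(self.compartment_names),
            len(self.species_names),
        ):
            raise ValueError("counts shape inconsistent with labels")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def _sidx(self, species: str) -> int:
        return self.species_names.index(species)

    def _cidx(self, compartment: str) -> int:
        return self.compartment_names.index(compartment)

    def series(self, species: str, compartment: str | None = None) -> np.ndarray:
        """Count of one species over time, in one compartment or summed."""
        s = self._sidx(species)
        if compartment is None:
            return self.counts[:, :, s].sum(axis=1)
        return self.counts[:, self._cidx(compartment), s]

    def final(self, species: str, compartment: str | None = None) -> int:
        return int(self.series(species, compartment)[-1])

    def tally(self, channel: str) -> int:
        return int(self.tallies[self.channel_names.index(channel)])

    def final_counts(self) -> dict:
        """Species name -> total count at the final time."""
        tot = self.counts[-1].sum(axis=0)
        return {nm: int(tot[i]) for i, nm in enumerate(self.species_names)}

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: time, compartment, species, count."""
        nt, nc, ns = self.counts.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, nc * ns),
                "compartment": np.tile(np.repeat(self.compartment_names, ns), nt),
                "species": np.tile(self.species_names, nt * nc),
                "count": self.counts.ravel(),
            }
        )
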