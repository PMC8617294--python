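"""Core containers: protein x sample intensity matrices and sample designs.

The intensity matrix is a thin wrapper around a pandas DataFrame (proteins
as rows, samples as columns, NaN = missing) that tracks which processing
scale the values are on.  Scale transitions are one-way:
``raw -> normalized -> log10``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("raw", "normalized", "log10")

_SCALE_ORDER = {s: i for i, s in enumerate(SCALES)}


class InputError(ValueError):
    """Malformed or inconsistent user-supplied input."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class IntensityMatrix:
    """Proteins x samples LFQ intensities.

    Parameters
    ----------
    values
        DataFrame indexed by protein ID with one column per sample.
        NaN marks a missing (not-quantified) cell; observed values must be
        positive on the raw/normalized scales.
    scale
        One of ``raw``, ``normalized``, ``log10``.
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            raise InputError("duplicate protein IDs in intensity matrix")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate sample IDs in intensity matrix")
        if self.scale in ("raw", "normalized"):
            vals = self.values.to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise InputError("negative intensities on a linear scale")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def with_values(self, values: pd.DataFrame, scale: str) -> "IntensityMatrix":
        """Return a new matrix, enforcing the one-way scale transition."""
        if _SCALE_ORDER[scale] < _SCALE_ORDER[self.scale]:
            raise ConfigError(
                f"scale may not move backwards ({self.scale} -> {scale})"
            )
        return IntensityMatrix(values=values, scale=scale)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(values=self.values.copy(), scale=self.scale)


@dataclass
class SampleDesign:
    """Maps each sample to its condition label and replicate index."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"design table lacks columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise InputError("duplicate sample IDs in design")

    @classmethod
    def from_records(cls, records: list[tuple[str, str, int]]) -> "SampleDesign":
        """Build from (sample_id, condition, replicate) tuples."""
        df = pd.DataFrame(records, columns=["sample", "condition", "replicate"])
        return cls(df.set_index("sample"))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.table["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        hits = [s for s, c in self.table["condition"].items() if c == condition]
        if not hits:
            raise InputError(f"condition {condition!r} absent from design")
        return hits

    def groups(self) -> dict[str, list[str]]:
        return {c: self.samples_of(c) for c in self.conditions}

    def check_matches(self, m: IntensityMatrix) -> None:
        """Every matrix sample must appear exactly once in the design."""
        missing = set(m.sample_ids) - set(self.sample_ids)
        if missing:
            raise InputError(f"samples absent from design: {sorted(missing)}")
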