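"""Core in-memory containers for label-free quantification (LFQ) experiments.

The central object is :class:`LFQMatrix`: a protein x sample grid of
non-negative LFQ intensities where 0 encodes "not detected", together with
per-sample metadata (condition label and replicate index). One condition is
the empty-vector control; every other condition is a bait acyltransferase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_CONTROL_LABEL = "EV"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True, order=True)
class SampleDescriptor:
    """Identity of one mass-spectrometry run: which condition, which replicate."""

    sample_id: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.condition:
            raise ValidationError("condition must be non-empty")
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass
class LFQMatrix:
    """Protein x sample grid of LFQ intensities with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id,
        holding non-negative intensities (0 = undetected).
    samples
        One :class:`SampleDescriptor` per column of ``values``, in column order.
    control_label
        The condition name reserved for the empty-vector control.
    """

    values: pd.DataFrame
    samples: tuple[SampleDescriptor, ...]
    control_label: str = DEFAULT_CONTROL_LABEL

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups[:5]}")
        if len(self.samples) != v.shape[1]:
            raise ValidationError(
                f"{len(self.samples)} sample descriptors for {v.shape[1]} columns"
            )
        expected = [s.sample_id for s in self.samples]
        if list(v.columns) != expected:
            raise ValidationError("column order does not match sample descriptors")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise ValidationError("intensities must be finite")
        if (arr < 0).any():
            raise ValidationError("negative intensity encountered")
        pairs = [(s.condition, s.replicate) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("(condition, replicate) pairs must be unique")
        if self.control_label not in self.conditions:
            raise ValidationError(
                f"no control condition {self.control_label!r} among {self.conditions}"
            )

    # -- views -------------------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    @property
    def baits(self) -> list[str]:
        return [c for c in self.conditions if c != self.control_label]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_for(self, condition: str) -> list[SampleDescriptor]:
        out = [s for s in self.samples if s.condition == condition]
        if not out:
            raise KeyError(f"no samples for condition {condition!r}")
        return out

    def condition_values(self, condition: str) -> pd.DataFrame:
        """Columns of ``values`` belonging to one condition."""
        ids = [s.sample_id for s in self.samples_for(condition)]
        return self.values[ids]

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    # -- derived matrices --------------------------------------------------

    def drop_samples(self, sample_ids: set[str] | list[str]) -> "LFQMatrix":
        drop = set(sample_ids)
        unknown = drop - {s.sample_id for s in self.samples}
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)}")
        kept = tuple(s for s in self.samples if s.sample_id not in drop)
        return LFQMatrix(
            values=self.values[[s.sample_id for s in kept]].copy(),
            samples=kept,
            control_label=self.control_label,
        )

    def copy(self) -> "LFQMatrix":
        return LFQMatrix(self.values.copy(), self.samples, self.control_label)


def missingness_rate(matrix: LFQMatrix) -> float:
    """Fraction of cells equal to 0 (undetected)."""
    arr = matrix.values.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValidationError("empty matrix has no missingness rate")
    return float((arr == 0).mean())
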