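"""Hypnogram container and plain-text I/O.

A hypnogram is the per-30 s-epoch sequence of sleep-stage labels for one
night.  Six labels are used: the five AASM stages WK, REM, N1, N2, N3 plus
LV ("getting out of bed": all channels absent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

#: Canonical 6-stage alphabet.
STAGES: tuple[str, ...] = ("WK", "REM", "N1", "N2", "N3", "LV")

_STAGE_SET = frozenset(STAGES)


@dataclass(frozen=True)
class Hypnogram:
    """Sequence of sleep-stage labels, one per 30 s epoch."""

    labels: tuple[str, ...]
    epoch_seconds: int = 30

    def __init__(self, labels: Iterable[str], epoch_seconds: int = 30):
        labels = tuple(str(l).upper() for l in labels)
        for i, l in enumerate(labels):
            if l not in _STAGE_SET:
                raise ValueError(f"unknown stage label {l!r} at epoch {i}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "epoch_seconds", epoch_seconds)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return Hypnogram(self.labels[idx], self.epoch_seconds)
        return self.labels[idx]

    @property
    def duration_seconds(self) -> float:
        return len(self.labels) * self.epoch_seconds

    def counts(self) -> dict[str, int]:
        return {s: sum(1 for l in self.labels if l == s) for s in STAGES}


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a plain-text hypnogram, one label per line, case-insensitive."""
    path = Path(path)
    labels: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            if tok.upper() not in _STAGE_SET:
                raise ValueError(
                    f"{path}:{lineno}: unknown stage token {tok!r} "
                    f"(expected one of {', '.join(STAGES)})"
                )
            labels.append(tok.upper())
    if not labels:
        warnings.warn(f"{path}: empty hypnogram", stacklevel=2)
    return Hypnogram(labels)


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as one label per line (UTF-8, Unix newlines)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for label in hypnogram.labels:
            fh.write(label + "\n")
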