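"""Control groups: ordered collections of binned samples with a shared
correction status.

Every prediction statistic is a comparison of a test sample against such a
group of presumed-euploid reference samples, so the group must be
homogeneous: same bin size, same strand mode, same sequence of corrections.
All mutators return new groups (value semantics); curation is explicit and
user-driven.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import StatusMismatchError
from .samples import BinnedSample, _read_json, _write_json

logger = logging.getLogger(__name__)


@dataclass
class ControlGroup:
    samples: list[BinnedSample]
    description: str = ""

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if not self.samples:
            raise StatusMismatchError("control group must be non-empty")
        ref = self.samples[0]
        offenders = [
            s.sample_id for s in self.samples
            if (s.bin_size != ref.bin_size
                or s.strands != ref.strands
                or s.autosomal_correction_status != ref.autosomal_correction_status
                or s.sex_correction_status != ref.sex_correction_status)
        ]
        if offenders:
            raise StatusMismatchError(
                "control-group members differ in correction status, bin "
                f"size or strand mode: {offenders}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def autosomal_correction_status(self) -> list[str]:
        return self.samples[0].autosomal_correction_status

    @property
    def sex_correction_status(self) -> list[str]:
        return self.samples[0].sex_correction_status

    @property
    def bin_size(self) -> int:
        return self.samples[0].bin_size

    @property
    def strands(self) -> tuple[str, ...]:
        return self.samples[0].strands

    def to_dict(self) -> dict:
        return {"description": self.description,
                "samples": [s.to_dict() for s in self.samples]}

    @classmethod
    def from_dict(cls, data: dict) -> "ControlGroup":
        return cls(samples=[BinnedSample.from_dict(d)
                            for d in data["samples"]],
                   description=data.get("description", ""))

    def save(self, path: str | Path) -> None:
        _write_json(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "ControlGroup":
        return cls.from_dict(_read_json(path))


def as_control_group(samples: Sequence[BinnedSample],
                     description: str = "") -> ControlGroup:
    """Bundle samples into a control group, enforcing homogeneity."""
    return ControlGroup(samples=list(samples), description=description)


def add_samples_controlgroup(group: ControlGroup,
                             samples: Iterable[BinnedSample]) -> ControlGroup:
    """Return a new group with ``samples`` appended (revalidated)."""
    return ControlGroup(samples=group.samples + list(samples),
                        description=group.description)


def remove_sample_controlgroup(group: ControlGroup,
                               sample_id: str) -> ControlGroup:
    """Return a new group without any sample whose id matches."""
    kept = [s for s in group.samples if s.sample_id != sample_id]
    if len(kept) == len(group.samples):
        warnings.warn(f"no sample with id {sample_id!r} in control group",
                      stacklevel=2)
        return ControlGroup(samples=list(group.samples),
                            description=group.description)
    if len(kept) < 2:
        warnings.warn("control group left with fewer than 2 samples; "
                      "SD-based statistics will fail", stacklevel=2)
    return ControlGroup(samples=kept, description=group.description)


def remove_duplicates_controlgroup(group: ControlGroup) -> ControlGroup:
    """Keep the first occurrence of each sample_id."""
    seen: set[str] = set()
    kept = []
    for s in group.samples:
        if s.sample_id not in seen:
            seen.add(s.sample_id)
            kept.append(s)
    return ControlGroup(samples=kept, description=group.description)
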